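# Methods

## The model

`topicnets` treats literature-derived disease–gene associations as a text
corpus: each disease is a document and each association contributes one
token of a gene. A latent Dirichlet allocation (LDA) model with K topics is
placed over this corpus:

- topic–gene distributions φ_k ~ Dirichlet(β·1_C), one per topic;
- disease–topic mixtures θ_j ~ Dirichlet(α·1_K), one per disease;
- each token draws a topic z from θ_j, then a gene from φ_z.

A topic is therefore a probability distribution over genes, and a disease
a mixture of topics — a bi-clustering in which two genes are close when
they co-occur across the same diseases, and two diseases are close when
they draw from the same gene distributions.

Defaults are α = 0.1 and β = 0.01 (both configurable). Small β makes
topics sparse over the gene vocabulary; small α makes each disease use few
topics. These are the standard symmetric-prior settings for sparse
biomedical co-occurrence data.

## Inference

The collapsed posterior is approximated by CVB0, the zeroth-order collapsed
variational update: each unique (disease, gene) pair holds a responsibility
vector over topics, updated as

    r(k) ∝ (n⁻_ck + β)(n⁻_pk + α) / (n⁻_k + Cβ)

where the n⁻ counts exclude one token's own responsibility mass.
Responsibilities are initialized from seeded uniform-Dirichlet draws and
updated in batch; the procedure is fully deterministic given the seed.
Collapsed Gibbs sampling is available (`algorithm="gibbs"`) as a
stochastic cross-check; it operates per token and is slower.

Point estimates are the Dirichlet-smoothed expected counts:

    φ̂[k,i]  = (n_ck[k,i] + β) / (Σ_i n_ck[k,i] + Cβ)
    θ̂[j,k] = (n_pk[j,k] + α) / (Σ_k n_pk[j,k] + Kα)

The θ̂ denominator uses Kα — the only smoothing consistent with
row-stochasticity.

Fits run a fixed iteration budget (default 1000) with an optional early
stop when the relative change of the log-likelihood stays below `tol`
(default 1e-4) for `patience` (default 10) consecutive recorded
evaluations.

## Model comparison and topic-number selection

`log_likelihood` reports the collapsed log evidence of the tokens given
their assignments,

    log p(c|z) = K·[lnΓ(Cβ) − C·lnΓ(β)] + Σ_k [Σ_i lnΓ(n_ki+β) − lnΓ(n_k+Cβ)],

computed with log-gamma throughout (finite for any non-negative, including
fractional, counts).

`select_topic_number` fits every K on a grid for several seeds and picks
the argmax of the mean score, smallest K on ties. Its default score is the
complete collapsed joint log p(c, z) = log p(c|z) + log p(z|α). The
distinction matters: at a converged variational optimum, log p(c|z) alone
improves monotonically with K (extra topics always help the in-sample
token fit), whereas the assignment-prior term log p(z|α) charges each
document for spreading over more topics. The joint score peaks at the
planted topic number in recovery simulations; `score="tokens"` exposes the
token-only ranking for comparison.

## Topic statistics

- **Symmetric KL (gene coherence).** For two genes with topic-probability
  vectors p, q: `ldakl(p,q) = KL(p‖q) + KL(q‖p)` with natural logarithm.
  Inputs are validated as probability vectors; add-ε smoothing (ε = 1e-12,
  then renormalization) guards exact zeros — a no-op on Dirichlet-smoothed
  posteriors. A gene's vector is its column of φ̂ renormalized over topics
  (`conditioning="gene_given_topic"`), or the mass-weighted posterior
  p(t|c) (`"topic_given_gene"`).
- **Topic cosine similarity.** Gene level compares φ̂ rows; disease level
  compares each topic's normalized mass over diseases (n_pk columns).
  Off-diagonal pairs are histogrammed in ten equal bins on [0, 1]. A
  `binary` flag thresholds vectors to membership indicators.
- **Association coverage.** `dgac(A,B) = |A∩B| / |A|` for association-pair
  sets: the fraction of a topic's disease–gene pairs confirmed by a gold
  standard.
- Membership uses an expected-count threshold `membership_epsilon`
  (default 1e-6): under Dirichlet smoothing no probability is exactly
  zero, so "non-zero proportion" is operationalized as assigned mass above
  the threshold.

## Ontology-anchored evaluation

Two diseases are related when any of their annotated ontology terms share
an ancestor within `levels` parent edges (default 3), each term counting
itself. For a ranked disease list, cumulative fold f extracts the top
⌈f·n/folds⌉ diseases; precision is the fraction of extracted diseases that
are annotated and have a related partner among the extracted; recall
divides the same numerator by the gold-standard count (annotated diseases
of the full list with a related partner in the list). Unannotated diseases
dilute precision but cannot enter the numerator; they are reported as a
distinguished "unannotated" state rather than dissimilar. A
disjoint-partition fold mode is available behind `mode="partition"`. AUC
is the trapezoidal integral over recall after collapsing duplicate recalls
to their maximum precision, clipped to [0, 1] — order-invariant by
construction.

## Networks and motifs

A topic induces a bipartite network: member diseases and genes as colored
nodes, association pairs with both endpoints in the topic as edges
(undirected, deduplicated; predication direction is dropped). Diameter and
characteristic path length are computed on the largest connected component
(component sizes are reported and disconnection flagged). Hubs are nodes
whose degree reaches mean + 2·sd of the component's degrees; a zero-spread
degree sequence yields no hubs.

Degree distributions are fit by discrete power-law maximum likelihood:
the exponent maximizes the Hurwitz-zeta likelihood on degrees ≥ k_min,
with k_min chosen by Kolmogorov–Smirnov minimization; the KS distance is
the goodness score and degenerate (single-valued) sequences are flagged
"no heavy tail" instead of fitted.

Connected three-node subgraphs are enumerated exactly by scanning each
node's neighbor pairs (triangles, impossible in a bipartite graph, would
be counted once via the thirds rule); counts are grouped by colored
isomorphism class — disease–gene–disease and gene–disease–gene in a
bipartite graph. The null model is degree-preserving bipartite double-edge
swapping (100 attempted swaps per edge, parallel-edge rejections), and
significance compares the real count against 1000 randomized networks via
z = (N_real − ⟨N_rand⟩)/σ_rand and the empirical p (fraction of null
networks with at least the real count). Patterns occurring fewer than 5
times are not candidates; p ≤ 0.05 flags significance.

**Known limitation.** In a simple bipartite graph both three-node pattern
counts are functions of one side's degree sequence alone (Σ C(deg, 2)), so
an exactly degree-preserving null reproduces them with zero variance: z is
undefined and p = 1. The machinery is exact and calibrated — on networks
drawn from the null family nothing is flagged — but motif significance
only becomes informative when edges carry extra structure (types,
direction) or a looser null is chosen. This is why the counting and
testing apparatus is validated against brute-force oracles rather than
against discovered motifs.

## Enrichment

A topic's genes are tested against each set of a GMT collection with the
upper-tail hypergeometric probability of at least the observed overlap
given the background universe (default: the union of all set members;
overridable with the corpus vocabulary). P-values are Benjamini–Hochberg
adjusted; adjusted p < 0.01 flags enrichment. Reported ratio is
overlap/set-size. Only over-representation is tested.

## Synthetic data

The generators produce every pipeline input with known ground truth:

- **Corpus**: the generative process above, with document lengths
  Poisson(`mean_doc_len`) truncated at one token. The planted φ and θ are
  retained for parameter-recovery scoring (Hungarian matching of learned to
  planted topics by row cosine). Recovery simulations use K = 10, P = 300
  diseases, C = 200 genes, α = 0.1, β = 0.01, mean length 50 — a scale at
  which CVB0 converges in seconds while leaving the problem non-trivial
  (≈ 15k tokens over a sparse vocabulary).
- **Ontology**: a complete rooted tree. In aligned mode each planted topic
  is anchored at a node exactly three levels above the leaves and its
  dominant diseases are annotated to leaves below the anchor, so same-topic
  diseases are always ontology-related and (for depth > 3) cross-topic
  ones are not; random mode annotates uniformly over leaves. Alignment
  experiments use depth 6, branching 3 (27 anchors), so permuted
  annotations scatter over many groups and the aligned/permuted AUC gap is
  informative.
- **Gold standards**: a `coverage` fraction of the truly generated
  disease–gene pairs plus `noise` (relative to the kept count) pairs drawn
  uniformly from the never-generated complement — no structure is assumed
  in the noise.
- **Bipartite networks**: uniform pair sampling, or preferential-attachment
  growth (shuffled node arrivals attaching to the opposite side
  ∝ degree+1), which yields heavy-tailed degrees with maximum-likelihood
  exponents near 3.

What the generators do not emulate: the extraction-error model of real
predication databases (beyond the uniform noise knob), empirical document
length distributions, correlated annotation sparsity across ontologies, or
typed/directed associations. Passing tests therefore demonstrate that the
machinery is correct and well calibrated under the stated generative
assumptions, not that real literature corpora satisfy those assumptions.

## Numerical choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; CVB0 fits are bitwise reproducible.
- Row-stochasticity asserted to 1e-9; probability-vector inputs validated
  to 1e-9; tie-breaks are lexicographic (entities) or smallest-index
  (topics, K grid).
- Log-gamma is used for all evidence computations; responsibilities are
  clipped at zero before smoothing to absorb floating-point drift in the
  excluded-mass subtraction.
- Degenerate inputs fail loudly: empty corpora, empty documents, zero
  vectors, unknown ontology terms and out-of-range topic indices raise
  with named context; unannotated diseases and undefined recalls are
  flagged states, not silent zeros.

## Problem sizes

Test and demonstration runs use corpora of 40–300 documents, 50–200 genes
and 150–500 inference iterations, motif nulls of 100–1000 randomizations,
and ontologies of ~1100 terms. These sizes were chosen so that every
claimed property is measurable with clear margins while each stage remains
interactive-speed; all are parameters, and nothing in the implementation
assumes them.
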