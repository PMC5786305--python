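"""Predication parsing, semantic filtering, and disease-as-document corpora.

Disease-gene associations arrive as subject-predicate-object predications
with UMLS semantic type codes on each concept (SemMedDB sentence-predication
layout). Two filters produce the analysis corpus: the disease side must carry
semantic type ``dsyn`` (Disease or Syndrome) or ``neop`` (Neoplastic
Process), and the gene side must be an approved (HGNC-style) gene symbol.
Each disease then becomes a document whose tokens are its associated genes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: UMLS semantic types accepted on the disease side of an association.
DISEASE_SEMTYPES = frozenset({"dsyn", "neop"})

_SEMTYPE_RE = re.compile(r"^[a-z0-9]+$")

#: Default predication column order when the file carries no header.
PREDICATION_COLUMNS = (
    "subject_name",
    "subject_semtype",
    "predicate",
    "object_name",
    "object_semtype",
    "citation_id",
)


@dataclass(frozen=True)
class PredicationRecord:
    """One subject-predicate-object predication with semantic types."""

    subject_name: str
    subject_semtype: str
    predicate: str
    object_name: str
    object_semtype: str
    citation_id: str | None = None

    def __post_init__(self) -> None:
        if not self.subject_name or not self.object_name:
            raise ValueError("subject_name and object_name must be non-empty")
        for code in (self.subject_semtype, self.object_semtype):
            if not _SEMTYPE_RE.match(code):
                raise ValueError(f"semantic type code {code!r} must be lowercase alphanumeric")


@dataclass(frozen=True)
class AssociationRecord:
    """One filtered disease-gene association.

    ``disease_id`` is the normalized disease name (lowercased, whitespace
    collapsed); ``gene_symbol`` is uppercase-normalized.
    """

    disease_id: str
    disease_name: str
    disease_semtype: str
    gene_symbol: str

    def __post_init__(self) -> None:
        if self.disease_semtype not in DISEASE_SEMTYPES:
            raise ValueError(f"disease_semtype must be one of {sorted(DISEASE_SEMTYPES)}")


class PredicationList(list):
    """List of :class:`PredicationRecord` carrying a malformed-row counter."""

    n_malformed: int = 0


def normalize_disease(name: str) -> str:
    """Normalize a disease name into a stable document key."""
    return " ".join(name.strip().lower().split())


def read_gene_symbols(path: str | Path) -> set[str]:
    """Read an approved gene-symbol list (one symbol per line, ``#`` comments).

    Symbols are uppercase-normalized.
    """
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.add(line.upper())
    if not symbols:
        raise ValueError(f"no gene symbols found in {path}")
    return symbols


def read_predications(
    path: str | Path, delimiter: str = "\t", columns: tuple[str, ...] | None = None
) -> PredicationList:
    """Parse a delimited predication file into :class:`PredicationRecord` rows.

    The column order defaults to :data:`PREDICATION_COLUMNS`; a header row
    naming those columns (in any order) is detected and honoured. Malformed
    rows (too few fields, invalid semantic type codes, empty concept names)
    are counted on the returned list's ``n_malformed`` attribute and logged,
    never silently dropped.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If no valid predication rows are found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"predication file not found: {path}")
    lines = path.read_text().splitlines()

    order = list(columns) if columns is not None else list(PREDICATION_COLUMNS)
    start = 0
    if lines:
        header = [f.strip() for f in lines[0].split(delimiter)]
        if set(PREDICATION_COLUMNS[:5]).issubset(header):
            order = header
            start = 1

    idx = {name: order.index(name) for name in PREDICATION_COLUMNS if name in order}
    records = PredicationList()
    n_malformed = 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split(delimiter)
        try:
            cit_i = idx.get("citation_id")
            citation = fields[cit_i].strip() if cit_i is not None and cit_i < len(fields) else None
            records.append(
                PredicationRecord(
                    subject_name=fields[idx["subject_name"]].strip(),
                    subject_semtype=fields[idx["subject_semtype"]].strip(),
                    predicate=fields[idx["predicate"]].strip(),
                    object_name=fields[idx["object_name"]].strip(),
                    object_semtype=fields[idx["object_semtype"]].strip(),
                    citation_id=citation or None,
                )
            )
        except (IndexError, ValueError) as exc:
            n_malformed += 1
            logger.warning("malformed predication row %d in %s: %s", lineno, path, exc)
    records.n_malformed = n_malformed
    if n_malformed:
        logger.warning("%d malformed row(s) skipped in %s", n_malformed, path)
    if not records:
        raise ValueError(f"no valid predication rows in {path}")
    return records


def filter_associations(
    records,
    gene_symbols: set[str],
    dedupe: bool = False,
) -> list[AssociationRecord]:
    """Apply the two-stage semantic filter to predications.

    A predication yields an association when one side carries a disease
    semantic type (``dsyn``/``neop``) and the other side's uppercase name is
    an approved gene symbol. The filter is direction-agnostic: the disease
    may be subject or object. Duplicate disease-gene predications are kept
    as repeated tokens unless ``dedupe`` is set.
    """
    if not gene_symbols:
        raise ValueError("gene_symbols must be non-empty")
    out: list[AssociationRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        if isinstance(rec, AssociationRecord):  # idempotence on own output
            pair = (rec.disease_id, rec.gene_symbol)
            if rec.gene_symbol in gene_symbols and (not dedupe or pair not in seen):
                seen.add(pair)
                out.append(rec)
            continue
        for d_name, d_sem, g_name in (
            (rec.subject_name, rec.subject_semtype, rec.object_name),
            (rec.object_name, rec.object_semtype, rec.subject_name),
        ):
            symbol = g_name.strip().upper()
            if d_sem in DISEASE_SEMTYPES and symbol in gene_symbols:
                assoc = AssociationRecord(
                    disease_id=normalize_disease(d_name),
                    disease_name=d_name.strip(),
                    disease_semtype=d_sem,
                    gene_symbol=symbol,
                )
                pair = (assoc.disease_id, assoc.gene_symbol)
                if dedupe:
                    if pair in seen:
                        continue
                    seen.add(pair)
                out.append(assoc)
    return out


@dataclass
class Corpus:
    """Disease documents over a gene vocabulary with a count matrix.

    ``counts[j, i]`` is the number of tokens of gene ``vocabulary[i]`` in the
    document of disease ``documents[j]``. Every document has at least one
    token and every vocabulary column is used at least once.
    """

    documents: list[str]
    vocabulary: list[str]
    counts: np.ndarray
    disease_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        P, C = self.counts.shape
        if P != len(self.documents) or C != len(self.vocabulary):
            raise ValueError("counts shape does not match documents/vocabulary")
        if len(set(self.vocabulary)) != C:
            raise ValueError("vocabulary entries must be unique")
        if len(set(self.documents)) != P:
            raise ValueError("document ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) < 1):
            raise ValueError("empty document (zero row sum)")
        if np.any(self.counts.sum(axis=0) < 1):
            raise ValueError("unused vocabulary entry (zero column sum)")

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_vocabulary(self) -> int:
        return len(self.vocabulary)

    @property
    def n_tokens(self) -> int:
        return int(self.counts.sum())

    def association_set(self) -> set[tuple[str, str]]:
        """Unique (disease, gene) pairs present in the corpus."""
        rows, cols = np.nonzero(self.counts)
        return {(self.documents[j], self.vocabulary[i]) for j, i in zip(rows, cols)}

    def to_dir(self, path: str | Path) -> None:
        """Serialize as documents TSV, vocabulary TSV and triplet sparse counts."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"disease_id": self.documents,
             "disease_name": [self.disease_names.get(d, d) for d in self.documents]}
        ).to_csv(path / "documents.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": self.vocabulary}).to_csv(
            path / "vocabulary.tsv", sep="\t", index=False
        )
        rows, cols = np.nonzero(self.counts)
        pd.DataFrame(
            {"row": rows, "col": cols, "count": self.counts[rows, cols]}
        ).to_csv(path / "counts.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "Corpus":
        path = Path(path)
        docs = pd.read_csv(path / "documents.tsv", sep="\t")
        vocab = pd.read_csv(path / "vocabulary.tsv", sep="\t")["gene"].tolist()
        trip = pd.read_csv(path / "counts.tsv", sep="\t")
        counts = np.zeros((len(docs), len(vocab)), dtype=np.int64)
        counts[trip["row"], trip["col"]] = trip["count"]
        return cls(
            documents=docs["disease_id"].tolist(),
            vocabulary=vocab,
            counts=counts,
            disease_names=dict(zip(docs["disease_id"], docs["disease_name"])),
        )


def build_corpus(
    associations,
    min_doc_tokens: int = 1,
) -> Corpus:
    """Build the disease-as-document corpus from filtered associations.

    Each association contributes one token of its gene to its disease's
    document. Diseases with fewer than ``min_doc_tokens`` tokens are removed,
    and the vocabulary is then restricted to genes still occurring.

    Raises
    ------
    ValueError
        If ``associations`` is empty or every document is removed.
    """
    associations = list(associations)
    if not associations:
        raise ValueError("associations must be non-empty")
    if min_doc_tokens < 1:
        raise ValueError("min_doc_tokens must be a positive integer")

    documents = sorted({a.disease_id for a in associations})
    vocabulary = sorted({a.gene_symbol for a in associations})
    doc_index = {d: j for j, d in enumerate(documents)}
    voc_index = {g: i for i, g in enumerate(vocabulary)}
    counts = np.zeros((len(documents), len(vocabulary)), dtype=np.int64)
    names: dict[str, str] = {}
    for a in associations:
        counts[doc_index[a.disease_id], voc_index[a.gene_symbol]] += 1
        names.setdefault(a.disease_id, a.disease_name)

    keep_docs = counts.sum(axis=1) >= min_doc_tokens
    if not keep_docs.any():
        raise ValueError("empty corpus: every document fell below min_doc_tokens")
    counts = counts[keep_docs]
    documents = [d for d, k in zip(documents, keep_docs) if k]
    keep_voc = counts.sum(axis=0) >= 1
    counts = counts[:, keep_voc]
    vocabulary = [g for g, k in zip(vocabulary, keep_voc) if k]
    return Corpus(
        documents=documents,
        vocabulary=vocabulary,
        counts=counts,
        disease_names={d: names[d] for d in documents},
    )
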