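"""Readers and writers for every external artifact the screen consumes.

All formats are plain text. An expression matrix is a TSV with the header
row holding condition (sample) IDs and the first column holding gene (or
probe) IDs; RMA-style log-scale values are assumed but any numeric matrix
is accepted. Companion tables (bait lists, TF-family annotations, BLAST
tabular hits, MapMan-style functional-bin maps, differential-expression
lists, probe-to-gene maps) follow the small TSV contracts documented on
their readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("qcoexp")

__all__ = [
    "ParseError",
    "ValidationError",
    "ExpressionMatrix",
    "GeneAnnotation",
    "BaitSet",
    "BlastHit",
    "FunctionalBinMap",
    "DEGeneList",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_bait_set",
    "write_bait_set",
    "read_blast_tab",
    "write_blast_tab",
    "read_bin_map",
    "write_bin_map",
    "read_de_list",
    "write_de_list",
    "read_annotations",
    "write_annotations",
    "read_probe_map",
]


class ParseError(ValueError):
    """A file does not conform to its documented text format."""


class ValidationError(ValueError):
    """Parsed content violates a data invariant (duplicates, emptiness...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized gene x condition expression values.

    ``values`` is a float DataFrame whose index holds unique gene IDs and
    whose columns hold unique condition IDs. Missing cells are NaN; the
    per-gene missing fraction is available via :meth:`missing_fraction`.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if len(idx) < 1 or len(cols) < 2:
            raise ValidationError(
                f"expression matrix needs >=1 gene and >=2 conditions, "
                f"got {len(idx)} x {len(cols)}"
            )
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate condition IDs: {dups}")
        with np.errstate(invalid="ignore"):
            arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Fraction of missing conditions per gene."""
        return self.values.isna().mean(axis=1)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene metadata: TF family (absent => non-TF), species, display name."""

    gene_id: str
    tf_family: str | None = None
    species: str | None = None
    display_name: str | None = None

    @property
    def is_tf(self) -> bool:
        return self.tf_family is not None


@dataclass(frozen=True)
class BaitSet:
    """An ordered, duplicate-free list of bait (anchor) gene IDs."""

    bait_ids: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.bait_ids:
            raise ValidationError(f"bait set {self.label!r} is empty")
        if len(set(self.bait_ids)) != len(self.bait_ids):
            raise ValidationError(f"bait set {self.label!r} has duplicate IDs")

    def __iter__(self):
        return iter(self.bait_ids)

    def __len__(self) -> int:
        return len(self.bait_ids)


@dataclass(frozen=True)
class BlastHit:
    """One line of BLAST tabular output (-outfmt 6), positional columns."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"negative evalue {self.evalue} for {self.query_id}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )


@dataclass
class FunctionalBinMap:
    """gene_id -> set of functional-bin labels (MapMan-style, overlapping)."""

    bins: dict[str, set[str]] = field(default_factory=dict)

    def genes_in_bin(self, bin_label: str) -> set[str]:
        return {g for g, bs in self.bins.items() if bin_label in bs}

    def bin_labels(self) -> set[str]:
        out: set[str] = set()
        for bs in self.bins.values():
            out |= bs
        return out

    def restrict(self, genes: Iterable[str]) -> "FunctionalBinMap":
        keep = set(genes)
        return FunctionalBinMap({g: set(b) for g, b in self.bins.items() if g in keep})

    def __len__(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class DEGeneList:
    """A differential-expression gene list for one contrast.

    ``direction`` optionally maps gene_id -> "up"/"down".
    """

    label: str
    gene_ids: frozenset[str]
    direction: Mapping[str, str] | None = None


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path,
    missing_token: str = "NA",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes in rows, conditions in columns).

    The first row holds condition IDs, the first column gene IDs. Cells must
    be numeric or equal ``missing_token``. ``transpose=True`` accepts a
    conditions-in-rows file.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, comment=None
    )
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate row IDs {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate column IDs {dups}")

    def _cell(value: str, row: str, col: str) -> float:
        s = value.strip()
        if s == missing_token or s == "":
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric cell {value!r} at row {row!r}, column {col!r}"
            ) from None

    out = pd.DataFrame(
        [[_cell(df.iat[i, j], df.index[i], df.columns[j]) for j in range(df.shape[1])]
         for i in range(df.shape[0])],
        index=df.index,
        columns=df.columns,
        dtype=float,
    )
    if transpose:
        out = out.T
    return ExpressionMatrix(out)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, missing_token: str = "NA"
) -> None:
    """Write a matrix so that a re-read reproduces it to full float precision."""
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep=missing_token, float_format="%.17g")


# ---------------------------------------------------------------------------
# bait lists
# ---------------------------------------------------------------------------


def read_bait_set(path: str | Path, label: str = "") -> BaitSet:
    """Read a bait list: one gene ID per line, '#' starts a comment."""
    path = Path(path)
    seen: dict[str, None] = {}
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line in seen:
            logger.warning("bait list %s: duplicate ID %r collapsed", path, line)
        else:
            seen[line] = None
    if not seen:
        raise ValidationError(f"{path}: bait list contains no gene IDs")
    return BaitSet(tuple(seen), label=label or path.stem)


def write_bait_set(baits: BaitSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{b}\n" for b in baits.bait_ids))


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

_BLAST_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output (``-outfmt 6``), preserving order."""
    path = Path(path)
    hits: list[BlastHit] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != 12:
            raise ParseError(
                f"{path}: line {lineno}: expected 12 tab-separated columns, "
                f"got {len(fields)}"
            )
        try:
            typed = [t(v) for t, v in zip(_BLAST_TYPES, fields)]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        hits.append(BlastHit(*typed))
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:g}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.evalue:g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# functional bins, DE lists, annotations, probe maps
# ---------------------------------------------------------------------------


def _tsv_rows(path: Path, n_min: int, n_max: int):
    """Yield (lineno, fields) for non-comment lines, checking column counts."""
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if not n_min <= len(fields) <= n_max:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_min}"
                + (f"-{n_max}" if n_max != n_min else "")
                + f" columns, got {len(fields)}"
            )
        yield lineno, fields


def read_bin_map(path: str | Path) -> FunctionalBinMap:
    """Read a two-column TSV ``gene_id<TAB>bin_label`` (one bin per line)."""
    path = Path(path)
    bins: dict[str, set[str]] = {}
    for _, (gene, bin_label) in _tsv_rows(path, 2, 2):
        bins.setdefault(gene, set()).add(bin_label)
    return FunctionalBinMap(bins)


def write_bin_map(bin_map: FunctionalBinMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(bin_map.bins):
            for b in sorted(bin_map.bins[gene]):
                fh.write(f"{gene}\t{b}\n")


def read_de_list(path: str | Path, label: str = "") -> DEGeneList:
    """Read a DE gene list: ``gene_id`` or ``gene_id<TAB>up|down`` per line."""
    path = Path(path)
    genes: set[str] = set()
    direction: dict[str, str] = {}
    for lineno, fields in _tsv_rows(path, 1, 2):
        gene = fields[0].strip()
        genes.add(gene)
        if len(fields) == 2:
            d = fields[1].strip().lower()
            if d not in {"up", "down"}:
                raise ParseError(
                    f"{path}: line {lineno}: direction must be 'up' or 'down', got {d!r}"
                )
            direction[gene] = d
    return DEGeneList(
        label=label or path.stem,
        gene_ids=frozenset(genes),
        direction=direction or None,
    )


def write_de_list(de: DEGeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(de.gene_ids):
            if de.direction and gene in de.direction:
                fh.write(f"{gene}\t{de.direction[gene]}\n")
            else:
                fh.write(f"{gene}\n")


def read_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read gene annotations: ``gene_id<TAB>tf_family[<TAB>species[<TAB>name]]``.

    An empty or '-' family field marks a non-TF gene. One record per gene;
    later duplicate lines for a gene are rejected.
    """
    path = Path(path)
    out: dict[str, GeneAnnotation] = {}
    for lineno, fields in _tsv_rows(path, 2, 4):
        gene = fields[0].strip()
        if gene in out:
            raise ValidationError(f"{path}: line {lineno}: duplicate annotation for {gene!r}")
        fam = fields[1].strip()
        out[gene] = GeneAnnotation(
            gene_id=gene,
            tf_family=fam if fam and fam != "-" else None,
            species=fields[2].strip() if len(fields) > 2 and fields[2].strip() else None,
            display_name=fields[3].strip() if len(fields) > 3 and fields[3].strip() else None,
        )
    return out


def write_annotations(annotations: Mapping[str, GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            a = annotations[gene]
            fh.write(
                f"{a.gene_id}\t{a.tf_family or '-'}\t{a.species or ''}\t"
                f"{a.display_name or ''}\n"
            )


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``probe_id<TAB>gene_id`` map (many probes per gene)."""
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, (probe, gene) in _tsv_rows(path, 2, 2):
        if probe in out and out[probe] != gene:
            raise ValidationError(
                f"{path}: line {lineno}: probe {probe!r} mapped to two genes"
            )
        out[probe] = gene
    return out
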