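"""Core domain containers shared across the pipeline.

The analysis operates on a fixed panel of cell lines grouped into three
molecular subtypes of breast cancer (luminal ``Lu``, basal A ``BaA`` and
basal B ``BaB``), gene models anchored at their transcription start site
(TSS), mapped-read intervals from MBDCap-seq (read density proxies DNA
methylation), a log-scale expression matrix, and position weight matrices
for transcription-factor binding-site scanning.

All genomic intervals are stored 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("Lu", "BaA", "BaB")

BIN_SIZE = 100
WINDOW_HALF = 10_000
#: bin indices tiling TSS +/- 10 kb in transcription orientation; bin 0
#: starts at the TSS, negative bins are upstream.
BIN_INDICES = tuple(range(-WINDOW_HALF // BIN_SIZE, WINDOW_HALF // BIN_SIZE))

PROMOTER_LENGTH = 2_000
#: canonical attribute / region naming used throughout (promoter windows are
#: counted in bp upstream of the TSS).
REGION_ORDER = (
    "TSS1-1000",
    "TSS1001-2000",
    "CGI",
    "CGIShore",
    "Exon1",
    "Intron1",
    "Exon2",
)


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violate a domain invariant."""


class UsageError(ValueError):
    """Raised when an operation is invoked with inconsistent arguments."""


@dataclass(frozen=True)
class SubtypeTable:
    """Cell-line panel with molecular subtype labels.

    The subtype is the grouping variable of every protocol; the entropy
    statistic treats it as the phenotype state.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cell_line, subtype in self.entries:
            if subtype not in SUBTYPES:
                raise ValidationError(
                    f"unknown subtype {subtype!r} for cell line {cell_line!r}; "
                    f"expected one of {SUBTYPES}"
                )
            if cell_line in seen:
                raise ValidationError(f"duplicate cell line {cell_line!r}")
            seen.add(cell_line)

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return tuple(cl for cl, _ in self.entries)

    def subtype_of(self, cell_line: str) -> str:
        for cl, st in self.entries:
            if cl == cell_line:
                return st
        raise KeyError(cell_line)

    def members(self, subtype: str) -> tuple[str, ...]:
        if subtype not in SUBTYPES:
            raise UsageError(f"unknown subtype {subtype!r}")
        return tuple(cl for cl, st in self.entries if st == subtype)

    def counts(self) -> dict[str, int]:
        return {st: len(self.members(st)) for st in SUBTYPES}

    def mask(self, cell_lines: Sequence[str], subtype: str) -> np.ndarray:
        """Boolean mask over ``cell_lines`` selecting members of ``subtype``."""
        members = set(self.members(subtype))
        unknown = [cl for cl in cell_lines if cl not in set(self.cell_lines)]
        if unknown:
            raise ValidationError(
                f"cell lines absent from subtype table: {sorted(unknown)}; "
                f"table has {sorted(self.cell_lines)}"
            )
        return np.array([cl in members for cl in cell_lines], dtype=bool)

    def require_all_subtypes(self) -> None:
        empty = [st for st, n in self.counts().items() if n == 0]
        if empty:
            raise ValidationError(f"subtype(s) with no cell lines: {empty}")


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its TSS with exons in transcription order."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: no exons")
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(
                    f"gene {self.gene_id}: empty or inverted exon [{start}, {end})"
                )
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != self.exons:
            raise ValidationError(
                f"gene {self.gene_id}: exons not in transcription order"
            )

    @property
    def tss(self) -> int:
        """Strand-aware transcription start coordinate.

        On '+' the leftmost base of the first exon; on '-' the half-open
        right boundary of the gene span, so the first transcribed base is
        ``tss - 1``.
        """
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[0][1]

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)


@dataclass(frozen=True)
class ReadSet:
    """Mapped-read intervals for one cell line."""

    cell_line_id: str
    reads: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for chrom, start, end in self.reads:
            if start >= end:
                raise ValidationError(
                    f"{self.cell_line_id}: read [{start}, {end}) on {chrom} "
                    "has start >= end"
                )

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class ExpressionMatrix:
    """Gene x cell-line matrix of log-scale abundances.

    ``centered`` records whether every cell-line column has been shifted to
    zero mean.
    """

    data: pd.DataFrame
    centered: bool = False

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dup}")
        if self.centered:
            col_means = self.data.mean(axis=0).to_numpy()
            if np.abs(col_means).max(initial=0.0) > 1e-9:
                raise ValidationError("centered flag set but column means != 0")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass(frozen=True)
class PWM:
    """Position weight matrix as per-position base probabilities (A,C,G,T)."""

    matrix_id: str
    probs: tuple[tuple[float, float, float, float], ...]

    @property
    def width(self) -> int:
        return len(self.probs)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    @property
    def consensus(self) -> str:
        bases = "ACGT"
        return "".join(bases[int(np.argmax(row))] for row in self.probs)


@dataclass(frozen=True)
class PWMSet:
    """Collection of PWMs with unique identifiers."""

    pwms: tuple[PWM, ...]

    def __post_init__(self) -> None:
        ids = [p.matrix_id for p in self.pwms]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate PWM ids: {dup}")

    def __len__(self) -> int:
        return len(self.pwms)

    def __iter__(self):
        return iter(self.pwms)

    def __getitem__(self, matrix_id: str) -> PWM:
        for p in self.pwms:
            if p.matrix_id == matrix_id:
                return p
        raise KeyError(matrix_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p.matrix_id for p in self.pwms)


def normalize_name(name: str) -> str:
    """Canonical cell-line name: whitespace-trimmed, uppercase."""
    return name.strip().upper()


def check_cell_line_consistency(
    names_a: Iterable[str], names_b: Iterable[str], what_a: str, what_b: str
) -> None:
    """Hard error when two files disagree on the cell-line panel."""
    set_a = {normalize_name(n) for n in names_a}
    set_b = {normalize_name(n) for n in names_b}
    if set_a != set_b:
        raise ValidationError(
            f"cell-line sets differ between {what_a} and {what_b}: "
            f"{what_a} only {sorted(set_a - set_b)}, "
            f"{what_b} only {sorted(set_b - set_a)}"
        )
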