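"""Read binning and region-level methylation quantification.

MBDCap-seq enriches methylated fragments, so the number of mapped reads in
a 100 bp bin proxies the methylation level of that bin.  A read increments
every bin it overlaps (fragments span bin boundaries); a midpoint rule is
available behind a flag.  Region levels are overlap-weighted means of bin
densities so regions of different lengths are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BIN_INDICES,
    BIN_SIZE,
    ReadSet,
    SubtypeTable,
    UsageError,
    ValidationError,
)
from .regions import RegionCatalog

RAW_COUNT = "raw_count"
PER_MILLION = "per_million"


@dataclass
class BinnedMethylation:
    """Per (gene, bin) x cell-line read-density matrix."""

    data: pd.DataFrame  # MultiIndex (gene, bin) rows, cell-line columns
    normalization: str = RAW_COUNT
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.normalization not in (RAW_COUNT, PER_MILLION):
            raise UsageError(f"unknown normalization {self.normalization!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("negative methylation values")

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index.get_level_values(0).unique())

    def gene_totals(self) -> pd.DataFrame:
        """Total signal per gene per cell line across the profiled window."""
        return self.data.groupby(level=0, sort=False).sum()


@dataclass(frozen=True)
class DensitySummary:
    """Per-subtype histogram of (truncated, nonzero) methylation levels."""

    bin_edges: np.ndarray
    probabilities: Mapping[str, np.ndarray]
    fraction_above: Mapping[str, Mapping[float, float]]


def bin_reads(
    reads: ReadSet,
    catalog: RegionCatalog,
    normalization: str = RAW_COUNT,
    rule: str = "overlap",
    total_reads: int | None = None,
) -> pd.DataFrame:
    """Count reads per 100 bp bin of every gene window for one cell line.

    Returns a single-column frame indexed by (gene, bin).  With
    ``rule="overlap"`` a read increments every bin it overlaps; with
    ``rule="midpoint"`` only the bin containing the read midpoint.
    ``per_million`` scales by 1e6 / total mapped reads of the cell line
    (``total_reads`` defaults to the size of the read set).
    """
    if rule not in ("overlap", "midpoint"):
        raise UsageError(f"unknown binning rule {rule!r}")
    if not reads.reads:
        warnings.warn(f"cell line {reads.cell_line_id}: empty read set")

    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {r[0] for r in reads.reads}:
        arr = np.array([(s, e) for c, s, e in reads.reads if c == chrom], dtype=np.int64)
        by_chrom[chrom] = arr[np.argsort(arr[:, 0])]

    n_bins = len(BIN_INDICES)
    gene_ids = catalog.gene_ids
    counts = np.zeros((len(gene_ids), n_bins), dtype=float)
    for gi, gene_id in enumerate(gene_ids):
        gr = catalog[gene_id]
        arr = by_chrom.get(gr.chrom)
        if arr is None or not len(arr):
            continue
        w0, w1 = gr.window
        cand = arr[(arr[:, 0] < w1) & (arr[:, 1] > w0)]
        if not len(cand):
            continue
        grid0 = gr.bin_bounds()[:, 0].min()  # leftmost genomic coordinate
        if rule == "midpoint":
            mids = (cand[:, 0] + cand[:, 1]) // 2
            slots = (mids - grid0) // BIN_SIZE
            keep = (slots >= 0) & (slots < n_bins) & (mids >= w0) & (mids < w1)
            np.add.at(counts[gi], slots[keep].astype(int), 1.0)
        else:
            first = np.maximum((cand[:, 0] - grid0) // BIN_SIZE, 0)
            last = np.minimum(-(-(cand[:, 1] - grid0) // BIN_SIZE) - 1, n_bins - 1)
            for f, l in zip(first, last):
                if l >= f:
                    counts[gi, f : l + 1] += 1.0
        if gr.strand == "-":
            counts[gi] = counts[gi][::-1]

    if normalization == PER_MILLION:
        total = total_reads if total_reads is not None else len(reads)
        if total <= 0:
            raise UsageError("per_million normalization needs a positive read total")
        counts *= 1e6 / total

    index = pd.MultiIndex.from_product(
        [gene_ids, list(BIN_INDICES)], names=["gene", "bin"]
    )
    return pd.DataFrame(
        counts.reshape(-1, 1), index=index, columns=[reads.cell_line_id]
    )


def combine_cell_lines(
    columns: Sequence[pd.DataFrame], normalization: str = RAW_COUNT
) -> BinnedMethylation:
    """Assemble per-cell-line bin-count columns into one matrix."""
    if not columns:
        raise UsageError("no cell-line columns to combine")
    data = pd.concat(columns, axis=1)
    if data.isna().any().any():
        raise ValidationError("cell-line columns have mismatched (gene, bin) indices")
    return BinnedMethylation(data, normalization=normalization)


def _region_bin_weights(gr, intervals) -> tuple[np.ndarray, np.ndarray]:
    """Bin indices overlapping a set of intervals and their overlap (bp)."""
    bounds = gr.bin_bounds()
    weights = np.zeros(len(bounds), dtype=float)
    for s, e in intervals:
        ov = np.minimum(bounds[:, 1], e) - np.maximum(bounds[:, 0], s)
        weights += np.clip(ov, 0, None)
    keep = weights > 0
    return np.array(BIN_INDICES)[keep], weights[keep]


def region_level(
    binned: BinnedMethylation, catalog: RegionCatalog, region: str
) -> pd.DataFrame:
    """Per (gene, cell line) methylation level of a named region.

    The level is the overlap-weighted mean of bin densities over the bins
    the region touches.  Genes lacking the region (or whose region lies
    outside the profiled window) are absent from the output.
    """
    from .core import REGION_ORDER

    if region not in REGION_ORDER and not any(
        region in catalog[g].regions for g in catalog.gene_ids
    ):
        raise UsageError(f"unknown region {region!r}; expected one of {REGION_ORDER}")
    rows = {}
    for gene_id in binned.gene_ids:
        if gene_id not in catalog:
            continue
        gr = catalog[gene_id]
        if region not in gr.regions:
            continue
        bins, weights = _region_bin_weights(gr, gr.regions[region])
        if not len(bins):
            continue
        sub = binned.data.loc[gene_id]
        present = [b for b in bins if b in sub.index]
        if not present:
            continue
        w = weights[[list(bins).index(b) for b in present]]
        vals = sub.loc[present].to_numpy()
        rows[gene_id] = (vals * w[:, None]).sum(axis=0) / w.sum()
    if not rows:
        return pd.DataFrame(columns=binned.cell_lines)
    return pd.DataFrame.from_dict(rows, orient="index", columns=binned.cell_lines)


def region_levels(
    binned: BinnedMethylation, catalog: RegionCatalog, regions: Sequence[str]
) -> dict[str, pd.DataFrame]:
    return {r: region_level(binned, catalog, r) for r in regions}


def filter_low_coverage(
    binned: BinnedMethylation, min_reads: int = 3
) -> BinnedMethylation:
    """Drop genes with <= ``min_reads`` total mapped reads (strict '>').

    The filter applies to raw counts summed over the whole profiled window
    and all cell lines, and must precede library-size scaling.
    """
    if binned.normalization != RAW_COUNT:
        raise UsageError("filter_low_coverage requires raw_count normalization")
    totals = binned.gene_totals().sum(axis=1)
    keep = totals[totals > min_reads].index
    data = binned.data.loc[binned.data.index.get_level_values(0).isin(keep)]
    return BinnedMethylation(data, normalization=binned.normalization)


def density_summary(
    levels: pd.DataFrame,
    subtypes: SubtypeTable,
    truncate_at: float = 100.0,
    n_hist_bins: int = 50,
    thresholds: Sequence[float] = (50.0,),
) -> DensitySummary:
    """Subtype-wise density of region methylation levels.

    Levels above ``truncate_at`` are truncated to it (producing the
    characteristic mass at the truncation point); unmethylated regions
    (level exactly 0) are excluded before histogramming.
    """
    if levels.empty:
        raise UsageError("no region levels to summarize")
    edges = np.linspace(0.0, truncate_at, n_hist_bins + 1)
    probs: dict[str, np.ndarray] = {}
    fracs: dict[str, dict[float, float]] = {}
    for st in ("Lu", "BaA", "BaB"):
        members = [cl for cl in levels.columns if cl in subtypes.members(st)]
        vals = levels[members].to_numpy().ravel()
        vals = vals[vals > 0]
        vals = np.minimum(vals, truncate_at)
        if not len(vals):
            raise UsageError(f"subtype {st}: all regions unmethylated")
        hist, _ = np.histogram(vals, bins=edges)
        probs[st] = hist / hist.sum()
        fracs[st] = {t: float((vals >= t).mean()) for t in thresholds}
    return DensitySummary(edges, probs, fracs)


def plot_density_summary(summary: DensitySummary, path: str) -> None:
    """Render the per-subtype density curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (summary.bin_edges[:-1] + summary.bin_edges[1:]) / 2
    fig, ax = plt.subplots(figsize=(6, 4))
    for st, p in summary.probabilities.items():
        ax.plot(centers, p, label=st)
    ax.set_xlabel("methylation level (truncated)")
    ax.set_ylabel("probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
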