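"""Pearson correlation of methylation against expression (protocol 2).

For each called gene, the methylation level of a bin or named region is
paired with the gene's expression level across the cell-line panel and
summarized by the product-moment correlation.  Zero-variance pairs are
masked (NaN) rather than coerced to zero so heatmaps can distinguish
"no signal" from "no data".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, SubtypeTable, UsageError
from .profiles import BinnedMethylation
from .regions import RegionCatalog


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-bin (or per-region) correlation trace for one gene."""

    gene_id: str
    axis: tuple
    r: np.ndarray  # NaN where undefined
    n_pairs: int

    @property
    def undefined_mask(self) -> np.ndarray:
        return np.isnan(self.r)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise UsageError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.size < 3:
        raise UsageError("need at least 3 paired observations")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return float("nan")
    return float((xc * yc).sum() / (sx * sy))


def correlate_gene(
    gene_id: str,
    binned: BinnedMethylation,
    expr: ExpressionMatrix,
    axis: str = "bins",
    catalog: RegionCatalog | None = None,
    regions: Sequence[str] | None = None,
    bins: Sequence[int] | None = None,
) -> CorrelationProfile:
    """Correlation profile of one gene over bins or named regions.

    Pairs are formed over the intersection-ordered cell lines of the two
    matrices (which must coincide as sets).
    """
    from .profiles import region_level

    if axis not in ("bins", "regions"):
        raise UsageError("axis must be 'bins' or 'regions'")
    if gene_id not in expr.genes:
        raise KeyError(f"gene {gene_id!r} absent from expression matrix")
    if gene_id not in binned.gene_ids:
        raise KeyError(f"gene {gene_id!r} absent from methylation matrix")
    cls = [cl for cl in binned.cell_lines if cl in set(expr.cell_lines)]
    if set(cls) != set(binned.cell_lines) or set(cls) != set(expr.cell_lines):
        raise UsageError("cell-line sets of the two matrices differ")
    e = expr.data.loc[gene_id, cls].to_numpy(dtype=float)

    if axis == "bins":
        sub = binned.data.loc[gene_id][cls]
        labels = tuple(int(b) for b in sub.index) if bins is None else tuple(bins)
        if bins is not None:
            sub = sub.loc[list(bins)]
        r = np.array([pearson(row, e) if np.ptp(row) > 0 and np.ptp(e) > 0 else np.nan
                      for row in sub.to_numpy(dtype=float)])
        return CorrelationProfile(gene_id, labels, r, len(cls))

    if catalog is None or regions is None:
        raise UsageError("axis='regions' requires a catalog and region names")
    rs = []
    for name in regions:
        lv = region_level(binned, catalog, name)
        if gene_id not in lv.index:
            rs.append(np.nan)
            continue
        m = lv.loc[gene_id, cls].to_numpy(dtype=float)
        rs.append(pearson(m, e) if np.ptp(m) > 0 and np.ptp(e) > 0 else np.nan)
    return CorrelationProfile(gene_id, tuple(regions), np.array(rs), len(cls))


def exclude_unmethylated(
    binned: BinnedMethylation, gene_ids: Sequence[str], bins: Sequence[int]
) -> list[str]:
    """Drop genes with zero methylation across the given bins in every
    cell line (unmethylated across the whole promoter)."""
    kept = []
    for g in gene_ids:
        if g not in binned.gene_ids:
            continue
        sub = binned.data.loc[g]
        present = [b for b in bins if b in sub.index]
        if present and sub.loc[present].to_numpy().sum() > 0:
            kept.append(g)
    return kept


def heatmap_matrix(
    profiles: Sequence[CorrelationProfile], proximal_first: bool = True
) -> pd.DataFrame:
    """Gene x position matrix of correlations.

    For bin axes the columns are ordered from the TSS outward when
    ``proximal_first`` (upstream bin -1 first, then -2, ...), matching the
    promoter heatmap orientation; region axes keep their given order.
    """
    if not profiles:
        raise UsageError("no profiles")
    axis = profiles[0].axis
    for p in profiles:
        if p.axis != axis:
            raise UsageError("profiles have mixed axes")
    df = pd.DataFrame(
        [p.r for p in profiles], index=[p.gene_id for p in profiles], columns=list(axis)
    )
    if proximal_first and all(isinstance(a, (int, np.integer)) for a in axis):
        order = sorted(df.columns, key=lambda b: (abs(b) if b < 0 else abs(b) + 0.5))
        df = df[order]
    return df


def compare_profiles(
    profiles_a: Sequence[CorrelationProfile],
    profiles_b: Sequence[CorrelationProfile],
    per_bin: bool = True,
) -> pd.DataFrame:
    """Welch t-test of per-gene correlations, group A vs group B.

    Per bin by default; with ``per_bin=False`` each gene is first reduced
    to its mean correlation over the axis and a single test is returned
    (labelled ``aggregate``).  Bins with fewer than two defined values in
    either group are masked.  Benjamini-Hochberg q-values are appended for
    reference; the selection itself uses raw p-values.
    """
    if not profiles_a or not profiles_b:
        raise UsageError("both groups must be non-empty")
    ma = heatmap_matrix(list(profiles_a), proximal_first=False)
    mb = heatmap_matrix(list(profiles_b), proximal_first=False)
    if list(ma.columns) != list(mb.columns):
        raise UsageError("groups have different axes")
    if not per_bin:
        ma = ma.mean(axis=1, skipna=True).to_frame("aggregate")
        mb = mb.mean(axis=1, skipna=True).to_frame("aggregate")

    records = []
    for col in ma.columns:
        a = ma[col].dropna().to_numpy()
        b = mb[col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            records.append((col, np.nan, np.nan, np.nan, np.nan))
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        records.append((col, float(a.mean()), float(b.mean()), float(t), float(p)))
    df = pd.DataFrame.from_records(
        records, columns=["bin", "mean_r_a", "mean_r_b", "t", "p"]
    )
    from statsmodels.stats.multitest import multipletests

    q = np.full(len(df), np.nan)
    defined = df["p"].notna().to_numpy()
    if defined.any():
        q[defined] = multipletests(df.loc[defined, "p"], method="fdr_bh")[1]
    df["bh_q"] = q
    return df
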