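"""Genomic region derivation: promoter windows, CpG islands and shores,
first/second exons, first introns, and the TSS +/- 10 kb bin grid.

Regions per gene
----------------
* ``TSS1-1000``    1-1000 bp upstream of the TSS (strand-aware)
* ``TSS1001-2000`` 1001-2000 bp upstream
* ``CGI``          CpG island(s) overlapping TSS +/- 10 kb
* ``CGIShore``     2 kb flanks of each assigned CGI, minus any CGI overlap
* ``Exon1`` / ``Intron1`` / ``Exon2`` when the gene model supports them

The bin grid tiles TSS +/- 10 kb with 200 bins of 100 bp in transcription
orientation; bin 0 starts at the TSS, negative indices are upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    BIN_INDICES,
    BIN_SIZE,
    GeneModel,
    PROMOTER_LENGTH,
    REGION_ORDER,
    UsageError,
    WINDOW_HALF,
)

Interval = tuple[int, int]

SHORE_WIDTH = 2_000


@dataclass(frozen=True)
class CgiParameters:
    """Criteria defining a CpG island: length > ``min_length`` bp, G+C
    fraction >= ``min_gc`` and observed/expected CpG >= ``min_obs_exp``."""

    min_length: int = 500
    min_gc: float = 0.55
    min_obs_exp: float = 0.65
    window: int = 200
    step: int = 1

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise UsageError("min_length must be positive")
        if not 0 < self.min_gc < 1:
            raise UsageError("min_gc must be in (0, 1)")
        if self.min_obs_exp <= 0:
            raise UsageError("min_obs_exp must be positive")


@dataclass(frozen=True)
class GeneRegions:
    """All analyzed regions of one gene, in genomic coordinates."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    window: Interval
    regions: Mapping[str, tuple[Interval, ...]]

    def bin_interval(self, index: int) -> Interval:
        """Genomic interval of bin ``index`` (transcription-oriented)."""
        if index not in range(BIN_INDICES[0], BIN_INDICES[-1] + 1):
            raise UsageError(f"bin index {index} outside {BIN_INDICES[0]}..{BIN_INDICES[-1]}")
        if self.strand == "+":
            start = self.tss + BIN_SIZE * index
        else:
            start = self.tss - BIN_SIZE * (index + 1)
        return start, start + BIN_SIZE

    def bin_bounds(self) -> np.ndarray:
        """(200, 2) array of genomic bin intervals ordered by bin index."""
        return np.array([self.bin_interval(k) for k in BIN_INDICES])


@dataclass(frozen=True)
class RegionCatalog:
    """Per-gene named regions plus the shared bin-grid convention."""

    genes: Mapping[str, GeneRegions]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneRegions:
        return self.genes[gene_id]

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.genes)

    def regions_of(self, gene_id: str, name: str) -> tuple[Interval, ...]:
        gr = self.genes[gene_id]
        if name not in gr.regions:
            raise UsageError(
                f"unknown region {name!r}; available: {sorted(gr.regions)}"
            )
        return gr.regions[name]


def _subtract(interval: Interval, minus: Sequence[Interval]) -> list[Interval]:
    """Interval minus a union of intervals."""
    pieces = [interval]
    for ms, me in minus:
        next_pieces = []
        for s, e in pieces:
            if me <= s or ms >= e:
                next_pieces.append((s, e))
                continue
            if s < ms:
                next_pieces.append((s, ms))
            if me < e:
                next_pieces.append((me, e))
        pieces = next_pieces
    return [(s, e) for s, e in pieces if e > s]


def build_region_catalog(
    genes: Sequence[GeneModel],
    cgis: Sequence[tuple[str, int, int]] = (),
    chrom_lengths: Mapping[str, int] | None = None,
    promoter_overlapping_cgis_only: bool = False,
) -> RegionCatalog:
    """Derive all named regions and bin grids for a set of gene models.

    CGIs are assigned to a gene when they overlap TSS +/- 10 kb; with
    ``promoter_overlapping_cgis_only`` the assignment is restricted to
    islands overlapping the 2 kb promoter or the gene's first exon.  Shores
    are the 2 kb flanks of each assigned island minus any island overlap.
    Windows extending beyond chromosome bounds are truncated with a warning.
    """
    by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, s, e in cgis:
        by_chrom.setdefault(chrom, []).append((chrom, s, e))

    out: dict[str, GeneRegions] = {}
    for gene in genes:
        tss = gene.tss
        w0, w1 = tss - WINDOW_HALF, tss + WINDOW_HALF
        if chrom_lengths is not None and gene.chrom in chrom_lengths:
            clen = chrom_lengths[gene.chrom]
            if w0 < 0 or w1 > clen:
                warnings.warn(
                    f"gene {gene.gene_id}: TSS +/- {WINDOW_HALF} bp window "
                    f"truncated to chromosome bounds [0, {clen})"
                )
                w0, w1 = max(w0, 0), min(w1, clen)

        regions: dict[str, tuple[Interval, ...]] = {}
        if gene.strand == "+":
            regions["TSS1-1000"] = ((tss - 1000, tss),)
            regions["TSS1001-2000"] = ((tss - 2000, tss - 1000),)
        else:
            regions["TSS1-1000"] = ((tss, tss + 1000),)
            regions["TSS1001-2000"] = ((tss + 1000, tss + 2000),)

        # CGI assignment: overlap with the profiled window (or promoter mode)
        assigned: list[Interval] = []
        cands = by_chrom.get(gene.chrom, [])
        if promoter_overlapping_cgis_only:
            anchor = [regions["TSS1-1000"][0], regions["TSS1001-2000"][0]]
            if len(gene.exons) >= 1:
                anchor.append(gene.exons[0])
        else:
            anchor = [(tss - WINDOW_HALF, tss + WINDOW_HALF)]
        for _, cs, ce in cands:
            if any(cs < ae and ce > as_ for as_, ae in anchor):
                assigned.append((cs, ce))
        assigned.sort()
        if assigned:
            regions["CGI"] = tuple(assigned)
            shores: list[Interval] = []
            for cs, ce in assigned:
                for flank in ((cs - SHORE_WIDTH, cs), (ce, ce + SHORE_WIDTH)):
                    shores.extend(_subtract(flank, assigned))
            regions["CGIShore"] = tuple(sorted(shores))

        if len(gene.exons) >= 1:
            regions["Exon1"] = (gene.exons[0],)
        if len(gene.exons) >= 2:
            e1, e2 = gene.exons[0], gene.exons[1]
            intron = (e1[1], e2[0]) if gene.strand == "+" else (e2[1], e1[0])
            if intron[1] > intron[0]:
                regions["Intron1"] = (intron,)
            regions["Exon2"] = (e2,)

        out[gene.gene_id] = GeneRegions(
            gene.gene_id, gene.chrom, gene.strand, tss, (w0, w1), regions
        )
    return RegionCatalog(out)


def nearest_cgi(gene: GeneRegions) -> Interval | None:
    """The single assigned CGI nearest the TSS (ties: smaller distance,
    then leftmost)."""
    cgis = gene.regions.get("CGI", ())
    if not cgis:
        return None

    def distance(iv: Interval) -> int:
        s, e = iv
        if s <= gene.tss < e:
            return 0
        return min(abs(s - gene.tss), abs(e - gene.tss))

    return sorted(cgis, key=lambda iv: (distance(iv), iv[0]))[0]


# ---------------------------------------------------------------------------
# CpG island detection

_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _island_stats(seq_codes: np.ndarray):
    """Prefix sums enabling O(1) GC / CpG stats for any subinterval."""
    is_c = (seq_codes == 1).astype(np.int64)
    is_g = (seq_codes == 2).astype(np.int64)
    cpg = np.zeros(len(seq_codes), dtype=np.int64)
    if len(seq_codes) > 1:
        cpg[:-1] = (is_c[:-1] & is_g[1:]).astype(np.int64)
    pc = np.concatenate([[0], np.cumsum(is_c)])
    pg = np.concatenate([[0], np.cumsum(is_g)])
    pcpg = np.concatenate([[0], np.cumsum(cpg)])
    return pc, pg, pcpg


def find_cgis(sequence: str, params: CgiParameters = CgiParameters()) -> list[Interval]:
    """Exact maximal CpG islands of a sequence.

    Returns every interval of length >= ``min_length`` that satisfies the
    G+C and observed/expected-CpG criteria and is not contained in a larger
    qualifying interval.  Observed/expected CpG follows the standard
    definition ``#CpG * L / (#C * #G)``.  ``N`` bases count toward length
    but not toward G+C or CpG content, so they dilute both criteria.

    The search evaluates, for each start, every admissible end with
    vectorized prefix sums; it is intended for promoter-scale sequences
    (up to a few tens of kb), not whole chromosomes.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < params.min_length:
        return []
    bad = set(seq) - set("ACGTN")
    if bad:
        raise UsageError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    mapped = np.full(n, 4, dtype=np.int8)
    for base, code in _BASE_CODES.items():
        mapped[codes == ord(base)] = code
    pc, pg, pcpg = _island_stats(mapped)

    # For each start s, the longest qualifying end E(s); interval (s, E(s))
    # is maximal iff no earlier start reaches at least as far.
    results: list[Interval] = []
    best_end_so_far = -1
    ends_all = np.arange(n + 1)
    for s in range(0, n - params.min_length + 1):
        ends = ends_all[s + params.min_length :]
        lengths = ends - s
        c = pc[ends] - pc[s]
        g = pg[ends] - pg[s]
        # CpG dinucleotide count fully inside [s, e): pairs at positions < e-1
        cpg = pcpg[ends - 1] - pcpg[s]
        gc_ok = (c + g) >= params.min_gc * lengths
        denom = c * g
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_exp_ok = cpg * lengths >= params.min_obs_exp * denom
        obs_exp_ok &= denom > 0
        ok = gc_ok & obs_exp_ok
        if not ok.any():
            continue
        e_max = int(ends[ok][-1])
        if e_max > best_end_so_far:
            results.append((s, e_max))
            best_end_so_far = e_max
    return results
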