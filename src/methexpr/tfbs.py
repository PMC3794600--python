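"""TFs whose binding sites fall in subtype-hypermethylated promoter bins
of downregulated genes (protocol 4).

Pipeline: per 100 bp promoter bin of each downregulated target gene, a
one-sided two-sample t-test asks whether methylation is higher in the
called subtype (P < 0.005 by default); cell-line consensus sequences are
built (or sliced) for significant bins; PWMs are scanned on both strands
with thresholds calibrated to a background false-positive rate; TFs whose
own expression differs between the called subtype and the rest are
discarded (their expression, not methylation, could explain the target's
downregulation); and surviving hits are reported with a support rate - the
percentage of same-phenotype cell lines whose consensus contains the site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ExpressionMatrix,
    PROMOTER_LENGTH,
    PWM,
    PWMSet,
    SubtypeTable,
    UsageError,
)
from .profiles import BinnedMethylation

BIN_ALPHA = 0.005
TF_EXPR_ALPHA = 0.05
MIN_SUPPORT_RATE = 50.0
TARGET_FP_RATE = 1e-4

#: promoter bins, TSS-proximal first (bin -1 is 1-100 bp upstream)
PROMOTER_BINS = tuple(range(-1, -(PROMOTER_LENGTH // 100) - 1, -1))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HypermethylatedBin:
    gene_id: str
    bin: int
    subtype: str
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class ConsensusSequence:
    cell_line_id: str
    gene_id: str
    bin: int
    sequence: str
    coverage: tuple[int, ...]


@dataclass(frozen=True)
class TFBSCandidate:
    target_gene: str
    tf_matrix_id: str
    bin: int
    subtype: str
    support_rate: float
    bin_p_value: float
    tf_expression_p: float | None = None


# ---------------------------------------------------------------------------
# step 1: hypermethylated bins

def test_bins(
    binned: BinnedMethylation,
    down_calls: pd.DataFrame,
    subtypes: SubtypeTable,
    alpha: float = BIN_ALPHA,
    bins: Sequence[int] = PROMOTER_BINS,
    equal_var: bool = True,
) -> list[HypermethylatedBin]:
    """One-sided t-test per promoter bin of each downregulated gene.

    The alternative is methylation higher in the called subtype; the
    pooled-variance (Student) test is the default, Welch behind the flag.
    Bins with zero variance in both groups are masked, never significant.
    """
    cell_lines = list(binned.cell_lines)
    out: list[HypermethylatedBin] = []
    for _, call in down_calls.iterrows():
        gene, subtype = call["gene_id"], call["subtype"]
        if gene not in binned.gene_ids:
            continue
        sub = binned.data.loc[gene]
        mask = subtypes.mask(cell_lines, subtype)
        for b in bins:
            if b not in sub.index:
                continue
            row = sub.loc[b].to_numpy(dtype=float)
            a, rest = row[mask], row[~mask]
            if np.ptp(a) == 0 and np.ptp(rest) == 0:
                continue  # degenerate: no evidence either way
            t, p = stats.ttest_ind(
                a, rest, equal_var=equal_var, alternative="greater"
            )
            if p < alpha:
                out.append(HypermethylatedBin(gene, int(b), subtype, float(t), float(p)))
    return out


# ---------------------------------------------------------------------------
# step 2: consensus sequences

def build_consensus(
    reads: Sequence[tuple[int, str]],
    reference: str,
    cell_line_id: str = "",
    gene_id: str = "",
    bin_index: int = 0,
) -> ConsensusSequence:
    """Reference-anchored majority-pileup consensus.

    ``reads`` are (offset, sequence) pairs positioned on the reference of
    the bin.  Each position takes the majority base over covering reads;
    ties and uncovered positions fall back to the reference base.  Reads
    extending beyond the reference are trimmed with a warning.
    """
    n = len(reference)
    counts = np.zeros((n, 5), dtype=int)  # A C G T N
    index = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    for offset, seq in reads:
        if offset < 0 or offset + len(seq) > n:
            warnings.warn(
                f"read at offset {offset} (len {len(seq)}) extends beyond the "
                f"{n} bp reference; trimming"
            )
            seq = seq[max(0, -offset): max(0, n - offset)]
            offset = max(offset, 0)
        for i, base in enumerate(seq.upper()):
            counts[offset + i, index.get(base, 4)] += 1
    bases = "ACGTN"
    consensus = []
    coverage = counts[:, :4].sum(axis=1)
    for pos in range(n):
        if coverage[pos] == 0:
            consensus.append(reference[pos].upper())
            continue
        c = counts[pos, :4]
        top = int(c.max())
        winners = [bases[i] for i in range(4) if c[i] == top]
        ref_base = reference[pos].upper()
        consensus.append(ref_base if len(winners) > 1 and ref_base in winners else winners[0])
    return ConsensusSequence(
        cell_line_id, gene_id, bin_index, "".join(consensus), tuple(int(x) for x in coverage)
    )


def bin_promoter_slice(bin_index: int, flank: int = 10, promoter_length: int = PROMOTER_LENGTH) -> tuple[int, int]:
    """Slice of a transcription-oriented promoter sequence covering an
    upstream bin plus ``flank`` bp on each side.

    The promoter sequence covers positions -promoter_length..-1 relative to
    the TSS, 5'->3' in transcription orientation; bin -k occupies slice
    ``[promoter_length - 100*k, promoter_length - 100*k + 100)``.
    """
    if bin_index >= 0 or -bin_index * 100 > promoter_length:
        raise UsageError(f"bin {bin_index} is not a promoter bin")
    start = promoter_length + 100 * bin_index
    return max(0, start - flank), min(promoter_length, start + 100 + flank)


# ---------------------------------------------------------------------------
# step 3: PWM scanning with calibrated thresholds

def _log_odds(pwm: PWM, background: Sequence[float]) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
        raise UsageError("background must be 4 probabilities summing to 1")
    if (bg <= 0).any():
        raise UsageError("background probabilities must be positive")
    return np.log2(pwm.as_array() / bg)


def _normalize_scores(lo: np.ndarray, s: np.ndarray) -> np.ndarray:
    smin = lo.min(axis=1).sum()
    smax = lo.max(axis=1).sum()
    if smax == smin:
        return np.zeros_like(s)
    # clip: scores outside [0, 1] can only arise from summation rounding
    return np.clip((s - smin) / (smax - smin), 0.0, 1.0)


def calibrate_threshold(
    pwm: PWM,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    target_fp_rate: float = TARGET_FP_RATE,
    seed: int = 0,
    mc_draws: int = 100_000,
    max_exact_width: int = 10,
) -> float:
    """Normalized-score threshold with background hit rate <= target.

    The per-position hit probability on background-composition random
    sequence is computed by exact enumeration of all words for widths up
    to ``max_exact_width`` and by seeded Monte-Carlo otherwise.  The
    threshold is the most permissive normalized score whose exceedance
    probability still meets the target; if even the top score is too
    likely (degenerate PWM), the maximal score is returned with a warning.
    """
    if not 0 < target_fp_rate < 0.5:
        raise UsageError("target_fp_rate must be in (0, 0.5)")
    lo = _log_odds(pwm, background)
    w = pwm.width
    bg = np.asarray(background, dtype=float)
    if w <= max_exact_width:
        scores = np.zeros(1)
        probs = np.ones(1)
        for pos in range(w):
            scores = (scores[:, None] + lo[pos][None, :]).ravel()
            probs = (probs[:, None] * bg[None, :]).ravel()
    else:
        rng = np.random.default_rng(seed)
        draws = rng.choice(4, size=(mc_draws, w), p=bg)
        scores = lo[np.arange(w)[None, :], draws].sum(axis=1)
        probs = np.full(mc_draws, 1.0 / mc_draws)
    # group score classes robustly: summation order must not split a class
    norm = np.round(_normalize_scores(lo, scores), 9)
    order = np.argsort(norm)[::-1]
    norm_sorted = norm[order]
    cum = np.cumsum(probs[order])
    uniq, idx_first = np.unique(-norm_sorted, return_index=True)
    thresholds = -uniq  # descending unique scores
    best = None
    for i, thr in enumerate(thresholds):
        last = idx_first[i + 1] - 1 if i + 1 < len(idx_first) else len(cum) - 1
        p_ge = cum[last]
        if p_ge <= target_fp_rate:
            best = float(thr)  # keep descending until rate exceeded
        else:
            break
    if best is None:
        warnings.warn(
            f"PWM {pwm.matrix_id}: even the maximal score exceeds the target "
            f"false-positive rate; using the maximal score"
        )
        return float(thresholds[0])
    return best


def scan_tfbs(
    sequence: str,
    pwms: PWMSet,
    thresholds: Mapping[str, float],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> list[tuple[str, int, str, float]]:
    """Scan both strands; return (matrix_id, offset, strand, score) hits.

    Offsets refer to the forward sequence.  Overlapping hits of the same
    matrix are deduplicated to the best-scoring offset (ties: leftmost,
    '+' strand first).  Positions containing N never match.
    """
    seq = sequence.upper()
    hits: list[tuple[str, int, str, float]] = []
    for pwm in pwms:
        w = pwm.width
        if len(seq) < w:
            continue
        lo = _log_odds(pwm, background)
        thr = thresholds[pwm.matrix_id]
        raw: list[tuple[float, int, str]] = []
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            codes = np.full(len(s), -1, dtype=int)
            for i, base in enumerate("ACGT"):
                codes[np.frombuffer(s.encode(), dtype=np.uint8) == ord(base)] = i
            for off in range(len(s) - w + 1):
                window = codes[off : off + w]
                if (window < 0).any():
                    continue
                score = float(lo[np.arange(w), window].sum())
                nscore = float(_normalize_scores(lo, np.array([score]))[0])
                if nscore >= thr - 1e-9:
                    fwd_off = off if strand == "+" else len(s) - off - w
                    raw.append((nscore, fwd_off, strand))
        # dedupe overlapping hits of this matrix, best score first
        raw.sort(key=lambda h: (-h[0], h[1], 0 if h[2] == "+" else 1))
        kept: list[tuple[float, int, str]] = []
        for score, off, strand in raw:
            if all(abs(off - k[1]) >= w for k in kept):
                kept.append((score, off, strand))
        hits.extend((pwm.matrix_id, off, strand, score) for score, off, strand in kept)
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


# ---------------------------------------------------------------------------
# step 4/5: filters

def filter_tf_expression(
    candidates: Sequence[TFBSCandidate],
    expr: ExpressionMatrix,
    tf_gene_map: Mapping[str, str],
    subtypes: SubtypeTable,
    alpha: float = TF_EXPR_ALPHA,
) -> list[TFBSCandidate]:
    """Keep TFs whose expression does NOT differ between the called
    subtype and the rest (two-sided t-test, p >= alpha)."""
    cell_lines = list(expr.cell_lines)
    out = []
    for cand in candidates:
        tf_gene = tf_gene_map.get(cand.tf_matrix_id)
        if tf_gene is None:
            warnings.warn(f"matrix {cand.tf_matrix_id} has no TF gene mapping; dropped")
            continue
        if tf_gene not in expr.genes:
            warnings.warn(f"TF gene {tf_gene} absent from expression matrix; dropped")
            continue
        row = expr.data.loc[tf_gene, cell_lines].to_numpy(dtype=float)
        mask = subtypes.mask(cell_lines, cand.subtype)
        a, rest = row[mask], row[~mask]
        if np.ptp(a) == 0 and np.ptp(rest) == 0:
            p = 1.0 if a.mean() == rest.mean() else 0.0
        else:
            _, p = stats.ttest_ind(a, rest, equal_var=False)
        if p >= alpha:
            out.append(
                TFBSCandidate(
                    cand.target_gene,
                    cand.tf_matrix_id,
                    cand.bin,
                    cand.subtype,
                    cand.support_rate,
                    cand.bin_p_value,
                    float(p),
                )
            )
    return out


def support_rate(
    hit_presence: Mapping[str, bool | None],
    subtypes: SubtypeTable,
    phenotype: str,
    min_rate: float = MIN_SUPPORT_RATE,
) -> float | None:
    """Percentage of same-phenotype cell lines whose consensus contains
    the hit.

    ``hit_presence`` maps cell line -> True/False, or None when no
    consensus was computable for that line; the denominator counts only
    computable lines.  Returns the rate, or None when below ``min_rate``.
    """
    members = subtypes.members(phenotype)
    computable = [cl for cl in members if hit_presence.get(cl) is not None]
    if not computable:
        raise UsageError(f"phenotype {phenotype}: no computable consensus")
    n_hit = sum(1 for cl in computable if hit_presence[cl])
    rate = 100.0 * n_hit / len(computable)
    return rate if rate >= min_rate else None


# ---------------------------------------------------------------------------
# end-to-end protocol

def find_blocked_tfs(
    binned: BinnedMethylation,
    down_calls: pd.DataFrame,
    subtypes: SubtypeTable,
    promoter_seqs: Mapping[str, Mapping[str, str]],
    pwms: PWMSet,
    expr: ExpressionMatrix,
    tf_gene_map: Mapping[str, str],
    alpha_bin: float = BIN_ALPHA,
    alpha_tf: float = TF_EXPR_ALPHA,
    min_support: float = MIN_SUPPORT_RATE,
    target_fp_rate: float = TARGET_FP_RATE,
    flank: int = 10,
    background: Sequence[float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run protocol 4 end to end and return a candidate table.

    ``promoter_seqs`` maps cell line -> gene -> 2 kb promoter sequence in
    transcription orientation.  The scanning background defaults to the
    empirical base composition of the available promoter sequences.
    """
    hyper = test_bins(binned, down_calls, subtypes, alpha=alpha_bin)
    if not hyper:
        return _empty_candidates()

    if background is None:
        counts = np.ones(4)  # +1 smoothing keeps all bases positive
        for per_gene in promoter_seqs.values():
            for seq in per_gene.values():
                s = seq.upper()
                for i, b in enumerate("ACGT"):
                    counts[i] += s.count(b)
        background = counts / counts.sum()

    thresholds = {
        p.matrix_id: calibrate_threshold(
            p, background=background, target_fp_rate=target_fp_rate, seed=seed
        )
        for p in pwms
    }

    records = []
    for hb in hyper:
        lo, hi = bin_promoter_slice(hb.bin, flank=flank)
        presence: dict[str, dict[str, bool | None]] = {m: {} for m in pwms.ids}
        for cl in subtypes.members(hb.subtype):
            per_gene = promoter_seqs.get(cl, {})
            seq = per_gene.get(hb.gene_id)
            if seq is None or len(seq) < hi:
                for m in pwms.ids:
                    presence[m][cl] = None
                continue
            window = seq[lo:hi]
            hit_ids = {h[0] for h in scan_tfbs(window, pwms, thresholds, background)}
            for m in pwms.ids:
                presence[m][cl] = m in hit_ids
        for m in pwms.ids:
            rate = support_rate(presence[m], subtypes, hb.subtype, min_rate=min_support)
            if rate is not None and any(v for v in presence[m].values()):
                records.append(
                    TFBSCandidate(hb.gene_id, m, hb.bin, hb.subtype, rate, hb.p_value)
                )

    filtered = filter_tf_expression(records, expr, tf_gene_map, subtypes, alpha=alpha_tf)
    return candidates_to_frame(filtered)


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "target_gene",
            "binding_tf",
            "support_rate",
            "bin",
            "subtype",
            "bin_p_value",
            "tf_expression_p",
        ]
    )


def candidates_to_frame(candidates: Sequence[TFBSCandidate]) -> pd.DataFrame:
    if not candidates:
        return _empty_candidates()
    df = pd.DataFrame(
        [
            (
                c.target_gene,
                c.tf_matrix_id,
                c.support_rate,
                c.bin,
                c.subtype,
                c.bin_p_value,
                c.tf_expression_p,
            )
            for c in candidates
        ],
        columns=[
            "target_gene",
            "binding_tf",
            "support_rate",
            "bin",
            "subtype",
            "bin_p_value",
            "tf_expression_p",
        ],
    )
    return df.sort_values(["target_gene", "binding_tf", "bin"]).reset_index(drop=True)
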