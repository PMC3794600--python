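"""Normalized-entropy screen for phenotype-differential signal (protocol 1).

For a unit *j* (a gene's methylation window or its expression row) the
signal of each cell line is pooled by phenotype: ``t_i`` is the sum over
cell lines of phenotype *i* and ``c = sum_i t_i``.  The phenotype shares
``p_i = t_i / c`` feed the Shannon entropy ``H = -sum p_i log2 p_i`` and
the normalized entropy ``NH = H / log2(n)`` with ``n = 3`` phenotypes.
``NH`` is 1 when signal is spread uniformly across phenotypes and
approaches 0 when one phenotype carries all of it, so *low* NH flags
phenotype-specific methylation or expression.

To keep the entropy defined when a phenotype receives no signal, a small
pseudo-signal proportional to the unit total is added to every phenotype:
``p_i = (t_i + pseudo * c') / (c + n * pseudo * c')`` with
``c' = max(c, 1)``.  The log base cancels in NH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import SUBTYPES, ExpressionMatrix, SubtypeTable, UsageError

N_STATES = len(SUBTYPES)
DEFAULT_PSEUDO = 1e-6

#: entropy thresholds used in the reference analysis
METHYLATION_NH_THRESHOLD = 0.2
EXPRESSION_NH_THRESHOLD = 0.5


class DomainError(ValueError):
    """Negative unit values cannot be pooled into phenotype shares."""


@dataclass(frozen=True)
class EntropyResult:
    unit_id: str
    state_probs: tuple[float, float, float]
    entropy: float  # bits
    normalized_entropy: float


def phenotype_sums(
    values: pd.Series | Sequence[float],
    subtypes: SubtypeTable,
    cell_lines: Sequence[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Pool one unit's per-cell-line values into (t_Lu, t_BaA, t_BaB) and c."""
    if isinstance(values, pd.Series):
        cell_lines = list(values.index)
        arr = values.to_numpy(dtype=float)
    else:
        if cell_lines is None:
            raise UsageError("cell_lines required when values is not a Series")
        arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise DomainError(
            "negative unit values; apply a non-negativity transform first "
            "(see expression_units)"
        )
    sums = np.array(
        [arr[subtypes.mask(cell_lines, st)].sum() for st in SUBTYPES], dtype=float
    )
    return sums, float(sums.sum())


def normalized_entropy(
    sums: Sequence[float], pseudo: float = DEFAULT_PSEUDO, unit_id: str = ""
) -> EntropyResult:
    """Normalized entropy of a triple of phenotype sums."""
    t = np.asarray(sums, dtype=float)
    if t.shape != (N_STATES,):
        raise UsageError(f"expected {N_STATES} phenotype sums, got shape {t.shape}")
    if (t < 0).any():
        raise DomainError("negative phenotype sums")
    c = t.sum()
    if c == 0 and pseudo == 0:
        raise UsageError("all sums zero with pseudo=0: entropy undefined")
    c_prime = max(c, 1.0)
    adj = t + pseudo * c_prime
    p = adj / adj.sum()
    if np.all(adj == adj[0]):
        # uniform states: NH is exactly 1 by definition of the maximum
        probs = tuple(np.full(N_STATES, 1.0 / N_STATES))
        h = float(np.log2(N_STATES))
        return EntropyResult(unit_id, probs, h, 1.0)
    nz = p > 0
    h = float(-(p[nz] * np.log2(p[nz])).sum())
    nh = min(h / np.log2(N_STATES), 1.0)
    return EntropyResult(unit_id, tuple(p), h, nh)


def entropy_screen(
    units: pd.DataFrame,
    subtypes: SubtypeTable,
    threshold: float,
    pseudo: float = DEFAULT_PSEUDO,
) -> pd.DataFrame:
    """Score every unit (row) of a unit x cell-line matrix by NH.

    Returns a frame with columns ``p_Lu, p_BaA, p_BaB, H_bits, NH,
    flagged`` sorted ascending by NH (ties by unit id); units with
    ``NH < threshold`` are flagged as phenotype-differential.
    """
    if not 0 < threshold <= 1:
        raise UsageError(f"threshold must be in (0, 1], got {threshold}")
    subtypes.require_all_subtypes()
    cell_lines = list(units.columns)
    masks = {st: subtypes.mask(cell_lines, st) for st in SUBTYPES}
    vals = units.to_numpy(dtype=float)
    if (vals < 0).any():
        raise DomainError("negative unit values; transform first")
    records = []
    for uid, row in zip(units.index, vals):
        t = np.array([row[masks[st]].sum() for st in SUBTYPES])
        res = normalized_entropy(t, pseudo=pseudo, unit_id=str(uid))
        records.append(
            (
                str(uid),
                res.state_probs[0],
                res.state_probs[1],
                res.state_probs[2],
                res.entropy,
                res.normalized_entropy,
            )
        )
    df = pd.DataFrame.from_records(
        records, columns=["unit_id", "p_Lu", "p_BaA", "p_BaB", "H_bits", "NH"]
    )
    df["flagged"] = df["NH"] < threshold
    df = df.sort_values(["NH", "unit_id"], kind="mergesort").reset_index(drop=True)
    return df


def size_normalized_screen(
    units: pd.DataFrame,
    subtypes: SubtypeTable,
    threshold: float,
    pseudo: float = DEFAULT_PSEUDO,
) -> pd.DataFrame:
    """Variant screen using per-cell-line means per phenotype, removing the
    influence of unequal group sizes on the shares."""
    if not 0 < threshold <= 1:
        raise UsageError(f"threshold must be in (0, 1], got {threshold}")
    cell_lines = list(units.columns)
    scaled = units.copy()
    for st in SUBTYPES:
        mask = subtypes.mask(cell_lines, st)
        cols = [cl for cl, m in zip(cell_lines, mask) if m]
        scaled[cols] = scaled[cols] / max(len(cols), 1)
    return entropy_screen(scaled, subtypes, threshold, pseudo=pseudo)


def expression_units(expr: ExpressionMatrix, offset: float = 1e-3) -> pd.DataFrame:
    """Non-negative unit matrix for the expression entropy screen.

    Entropy shares require non-negative signal, but log abundances can be
    negative (and centered values certainly are), so the uncentered matrix
    is shifted by its global minimum plus ``offset``.  This is an
    interpretation choice: shares then measure relative expression above
    the global floor.
    """
    if expr.centered:
        raise UsageError("use the uncentered expression matrix for the entropy screen")
    data = expr.data
    return data - data.to_numpy().min() + offset


def intersect_screens(methylation_hits: Iterable[str], expression_hits: Iterable[str]) -> set[str]:
    """Genes flagged by both the methylation and the expression screen."""
    return set(methylation_hits) & set(expression_hits)


def flagged_units(screen: pd.DataFrame) -> set[str]:
    return set(screen.loc[screen["flagged"], "unit_id"])
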