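"""Subtype differential-expression calls from median log abundances.

A gene is *down* in subtype *i* when its median log abundance there sits
below the medians of both other subtypes by more than the log-ratio
criterion (1.5 log units by default); *up* mirrors the rule.  Because the
margin is the minimum gap to the other two medians, a gene can satisfy the
rule in at most one subtype per direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SUBTYPES, ExpressionMatrix, SubtypeTable, UsageError, ValidationError

LOG_RATIO_CRITERION = 1.5


def center_expression(
    matrix: ExpressionMatrix, literal_orientation: bool = False
) -> ExpressionMatrix:
    """Mean-adjust each cell line's log abundances to zero column mean.

    The default orientation is ``value - mean``; ``literal_orientation``
    flips every sign (``mean - value``), which inverts up/down semantics
    downstream and exists only for comparison.
    """
    if matrix.centered:
        raise UsageError("matrix is already centered")
    centered = matrix.data - matrix.data.mean(axis=0)
    if literal_orientation:
        centered = -centered
    return ExpressionMatrix(centered, centered=True)


def subtype_medians(matrix: ExpressionMatrix, subtypes: SubtypeTable) -> pd.DataFrame:
    """Per-gene median expression per subtype (columns Lu, BaA, BaB).

    Even-sized groups use the midpoint of the two central values.
    """
    cols = list(matrix.cell_lines)
    out = {}
    for st in SUBTYPES:
        members = [cl for cl in cols if cl in subtypes.members(st)]
        if not members:
            raise ValidationError(f"subtype {st} has no cell lines in the matrix")
        out[st] = matrix.data[members].median(axis=1)
    return pd.DataFrame(out)


def call_differential(
    medians: pd.DataFrame,
    criterion: float = LOG_RATIO_CRITERION,
    direction: str = "down",
) -> pd.DataFrame:
    """Emit per-gene subtype calls from the median triples.

    A *down* call in subtype *i* requires
    ``min_{k != i} (m_k - m_i) > criterion``; *up* swaps the sign.  The
    margin column records that minimum gap.
    """
    if criterion <= 0:
        raise UsageError("criterion must be positive")
    if direction not in ("down", "up"):
        raise UsageError(f"direction must be 'down' or 'up', got {direction!r}")
    missing = [st for st in SUBTYPES if st not in medians.columns]
    if missing:
        raise UsageError(f"medians frame lacks subtype columns {missing}")

    m = medians[list(SUBTYPES)].to_numpy(dtype=float)
    records = []
    for gene, row in zip(medians.index, m):
        for i, st in enumerate(SUBTYPES):
            others = np.delete(row, i)
            margin = (
                float((others - row[i]).min())
                if direction == "down"
                else float((row[i] - others).min())
            )
            if margin > criterion:
                records.append((str(gene), direction, st, *row, margin))
                break  # at most one subtype can satisfy the rule
    return pd.DataFrame.from_records(
        records,
        columns=["gene_id", "direction", "subtype", "m_Lu", "m_BaA", "m_BaB", "margin"],
    )


def calls_for_subtype(calls: pd.DataFrame, subtype: str) -> pd.DataFrame:
    if subtype not in SUBTYPES:
        raise UsageError(f"unknown subtype {subtype!r}")
    return calls[calls["subtype"] == subtype].reset_index(drop=True)
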