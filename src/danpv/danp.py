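"""DANP influential weights from the DEMATEL total-influence matrices.

The criteria matrix T_C is row-normalised block by block (each row of
each dimension-pair block divided by its block sum), transposed into
the unweighted supermatrix W (columns are "influenced-by"
distributions), weighted by the row-normalised dimension matrix T_D,
and raised to its limit.  The limit's identical columns are the global
influential weights (IWs); dimension weights are block sums of the
globals and local weights their within-dimension renormalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .dematel import TotalInfluenceMatrix
from .framework import CriteriaFramework

__all__ = [
    "Supermatrix",
    "WeightSet",
    "ConvergenceError",
    "normalize_tc_blocks",
    "build_unweighted_supermatrix",
    "weight_supermatrix",
    "limit_supermatrix",
    "derive_weight_set",
    "danp_weights",
]

logger = logging.getLogger(__name__)

_STOCH_TOL = 1e-9


class ConvergenceError(RuntimeError):
    """The supermatrix limit did not converge (reducible/periodic input)."""


@dataclass(frozen=True)
class Supermatrix:
    values: np.ndarray
    stage: Literal["unweighted", "weighted", "limit"]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"supermatrix must be square, got {v.shape}")
        if self.stage in ("weighted", "limit"):
            colsums = v.sum(axis=0)
            live = colsums > _STOCH_TOL  # degenerate all-zero columns pass through
            if np.any(np.abs(colsums[live] - 1.0) > 1e-6):
                raise ValueError(f"{self.stage} supermatrix not column-stochastic")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class WeightSet:
    """Global (IW), local and dimension weights, all full precision.

    Invariants (checked to 1e-6): globals sum to 1, dimension weights
    sum to 1, and global = dimension x local for every criterion.
    """

    global_weights: Mapping[str, float]
    local_weights: Mapping[str, float]
    dimension_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, m in (("global", self.global_weights),
                         ("dimension", self.dimension_weights)):
            s = sum(m.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"{label} weights sum to {s}, expected 1")

    def as_frame(self, framework: CriteriaFramework) -> pd.DataFrame:
        rows = []
        for c in framework.criteria:
            rows.append(
                {
                    "criterion": c.code,
                    "dimension": c.dimension_code,
                    "local_weight": self.local_weights[c.code],
                    "global_weight": self.global_weights[c.code],
                    "dimension_weight": self.dimension_weights[c.dimension_code],
                }
            )
        return pd.DataFrame(rows)


def normalize_tc_blocks(
    t_c: TotalInfluenceMatrix | np.ndarray, framework: CriteriaFramework
) -> np.ndarray:
    """Divide every row of every dimension-pair block by its block sum.

    All-zero block rows stay zero (logged: they signal a criterion with
    no influence on that dimension).
    """
    tc = t_c.values if isinstance(t_c, TotalInfluenceMatrix) else np.asarray(t_c, float)
    if tc.shape[0] != framework.n_criteria:
        raise ValueError("T_C shape does not match framework")
    out = np.zeros_like(tc)
    for dp in framework.dimension_codes:
        rows = framework.blocks[dp]
        for dq in framework.dimension_codes:
            cols = framework.blocks[dq]
            block = tc[np.ix_(rows, cols)]
            sums = block.sum(axis=1, keepdims=True)
            zero = sums[:, 0] == 0
            if np.any(zero):
                logger.warning(
                    "all-zero block row(s) in (%s, %s); left as zero", dp, dq
                )
            safe = np.where(sums == 0, 1.0, sums)
            out[np.ix_(rows, cols)] = np.where(zero[:, None], 0.0, block / safe)
    return out


def build_unweighted_supermatrix(normalized_tc: np.ndarray) -> Supermatrix:
    """Transpose the block-normalised T_C: columns become distributions."""
    return Supermatrix(np.asarray(normalized_tc, dtype=float).T, stage="unweighted")


def weight_supermatrix(
    w: Supermatrix, t_d: TotalInfluenceMatrix | np.ndarray, framework: CriteriaFramework
) -> Supermatrix:
    """Scale each (p, q) block of W by normalised T_D entry (q, p)."""
    td = t_d.values if isinstance(t_d, TotalInfluenceMatrix) else np.asarray(t_d, float)
    if td.shape[0] != framework.n_dimensions:
        raise ValueError("T_D shape does not match framework")
    row_sums = td.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        dead = [framework.dimension_codes[i]
                for i in np.flatnonzero(row_sums[:, 0] == 0)]
        raise ValueError(f"zero T_D row for dimension(s) {dead}: disconnected")
    td_norm = td / row_sums
    out = np.zeros_like(w.values)
    for p, dp in enumerate(framework.dimension_codes):
        rows = framework.blocks[dp]
        for q, dq in enumerate(framework.dimension_codes):
            cols = framework.blocks[dq]
            out[np.ix_(rows, cols)] = w.values[np.ix_(rows, cols)] * td_norm[q, p]
    return Supermatrix(out, stage="weighted")


def limit_supermatrix(
    w_weighted: Supermatrix, tol: float = 1e-9, max_squarings: int = 200
) -> Supermatrix:
    """Raise the weighted supermatrix to its limit by repeated squaring.

    Convergence is declared when one squaring changes no entry by more
    than ``tol``.  If the fixed point's columns still differ (period-2
    cycling collapses to distinct even/odd limits), the Cesàro average
    of two consecutive powers is tried before giving up.
    """
    p = w_weighted.values.copy()
    for _ in range(max_squarings):
        nxt = p @ p
        if np.max(np.abs(nxt - p)) < tol:
            p = nxt
            break
        p = nxt
    else:
        raise ConvergenceError(
            f"no fixed point after {max_squarings} squarings "
            f"(residual {np.max(np.abs(p @ p - p)):.3e})"
        )
    if _columns_identical(p, tol=1e-7):
        return Supermatrix(p, stage="limit")
    cesaro = (p + p @ w_weighted.values) / 2.0
    if _columns_identical(cesaro, tol=1e-7):
        return Supermatrix(cesaro, stage="limit")
    raise ConvergenceError(
        "limit columns disagree even after the Cesaro fallback; the "
        "influence network is reducible or periodic beyond period 2 "
        f"(max column spread {np.max(p.max(axis=1) - p.min(axis=1)):.3e})"
    )


def _columns_identical(m: np.ndarray, tol: float) -> bool:
    return bool(np.max(m.max(axis=1) - m.min(axis=1)) < tol)


def derive_weight_set(
    limit: Supermatrix, framework: CriteriaFramework
) -> WeightSet:
    """Read global/local/dimension weights off the limit supermatrix."""
    if limit.stage != "limit":
        raise ValueError("weights must come from a limit supermatrix")
    g = limit.values.mean(axis=1)
    total = g.sum()
    if total <= 0:
        raise ValueError("degenerate limit: global weights sum to zero")
    g = g / total
    codes = framework.criterion_codes
    global_w = {c: float(g[i]) for i, c in enumerate(codes)}
    dim_w: dict[str, float] = {}
    local_w: dict[str, float] = {}
    for d in framework.dimension_codes:
        block = framework.blocks[d]
        dw = float(sum(g[i] for i in block))
        dim_w[d] = dw
        if dw == 0:
            raise ValueError(f"dimension {d} received zero weight; degenerate")
        for i in block:
            local_w[codes[i]] = float(g[i] / dw)
    return WeightSet(global_w, local_w, dim_w)


def danp_weights(
    t_c: TotalInfluenceMatrix,
    t_d: TotalInfluenceMatrix,
    framework: CriteriaFramework,
) -> WeightSet:
    """Full DANP chain: normalise, transpose, weight, limit, extract."""
    w = build_unweighted_supermatrix(normalize_tc_blocks(t_c, framework))
    ww = weight_supermatrix(w, t_d, framework)
    return derive_weight_set(limit_supermatrix(ww), framework)
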