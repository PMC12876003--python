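"""DEMATEL: from expert direct-influence matrices to total influence.

The expert panel's pairwise direct-influence ratings (integers on a
0-4 scale, zero diagonal) are averaged into one direct matrix A, scaled
to D = A / max(max row sum, max column sum), and closed over all
indirect paths with

    T = D (I - D)^(-1) = D + D^2 + D^3 + ...

Row sums r (influence given) and column sums c (influence received)
give each factor's prominence r+c and net causal relation r-c; these
are the coordinates of the influential network relation map (INRM).
The criteria-level matrix T_C is block-averaged into the
dimension-level T_D using the framework partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .framework import CriteriaFramework

__all__ = [
    "DirectMatrix",
    "NormalizedMatrix",
    "TotalInfluenceMatrix",
    "CausalProfile",
    "InrmGraph",
    "RetestReport",
    "aggregate_panel",
    "normalize",
    "total_influence",
    "dimension_total_influence",
    "causal_profile",
    "dimension_priority",
    "build_inrm",
    "retest_consistency",
]

#: condition-number ceiling for the (I - D) solve
_COND_LIMIT = 1e12


@dataclass(frozen=True)
class DirectMatrix:
    """One expert's (or the panel-average) direct-influence ratings."""

    values: np.ndarray
    scale_max: float = 4.0

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"direct matrix must be square, got {a.shape}")
        if np.any(np.diag(a) != 0):
            raise ValueError("direct matrix diagonal must be zero")
        if np.any(a < 0) or np.any(a > self.scale_max):
            raise ValueError(f"ratings outside [0, {self.scale_max}]")
        object.__setattr__(self, "values", a)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class NormalizedMatrix:
    values: np.ndarray


@dataclass(frozen=True)
class TotalInfluenceMatrix:
    values: np.ndarray
    level: Literal["criteria", "dimension"] = "criteria"
    codes: tuple[str, ...] = ()


@dataclass(frozen=True)
class CausalProfile:
    """Per-node influence given (r), received (c), prominence, relation."""

    codes: tuple[str, ...]
    r: np.ndarray
    c: np.ndarray

    @property
    def prominence(self) -> np.ndarray:
        return self.r + self.c

    @property
    def relation(self) -> np.ndarray:
        return self.r - self.c

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": self.codes,
                "r": self.r,
                "c": self.c,
                "prominence": self.prominence,
                "relation": self.relation,
            }
        )


@dataclass(frozen=True)
class InrmGraph:
    """Influential network relation map at both levels.

    Nodes carry (prominence, relation) coordinates; a directed edge
    p -> q is drawn when the total influence of p on q meets the
    threshold rule.
    """

    dimension_graph: nx.DiGraph
    criteria_graph: nx.DiGraph
    dimension_threshold: float
    criteria_threshold: float

    def edge_list(self, level: Literal["dimension", "criteria"] = "dimension") -> pd.DataFrame:
        g = self.dimension_graph if level == "dimension" else self.criteria_graph
        rows = [
            {"from": u, "to": v, "influence": d["weight"]}
            for u, v, d in g.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["from", "to", "influence"])

    def node_table(self, level: Literal["dimension", "criteria"] = "dimension") -> pd.DataFrame:
        g = self.dimension_graph if level == "dimension" else self.criteria_graph
        rows = [
            {"code": n, "prominence": d["prominence"], "relation": d["relation"]}
            for n, d in g.nodes(data=True)
        ]
        return pd.DataFrame(rows, columns=["code", "prominence", "relation"])

    def to_dot(self, level: Literal["dimension", "criteria"] = "dimension") -> str:
        g = self.dimension_graph if level == "dimension" else self.criteria_graph
        lines = [f"digraph inrm_{level} {{"]
        for n, d in g.nodes(data=True):
            lines.append(
                f'  "{n}" [prominence={d["prominence"]:.4f} relation={d["relation"]:.4f}];'
            )
        for u, v, d in g.edges(data=True):
            lines.append(f'  "{u}" -> "{v}" [weight={d["weight"]:.4f}];')
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class RetestReport:
    """Test-retest agreement between two questionnaire rounds."""

    n_pairs: int
    total_abs_diff: float
    mean_abs_diff: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_abs_diff", self.total_abs_diff / self.n_pairs)


def aggregate_panel(matrices: Sequence[DirectMatrix]) -> DirectMatrix:
    """Element-wise arithmetic mean of the expert panel's matrices."""
    if not matrices:
        raise ValueError("empty panel")
    shape = matrices[0].values.shape
    scale = matrices[0].scale_max
    for m in matrices[1:]:
        if m.values.shape != shape:
            raise ValueError(f"shape mismatch: {m.values.shape} vs {shape}")
        if m.scale_max != scale:
            raise ValueError("mixed rating scales in panel")
    mean = np.mean([m.values for m in matrices], axis=0)
    return DirectMatrix(mean, scale_max=scale)


def normalize(a: DirectMatrix) -> NormalizedMatrix:
    """Scale by the larger of the max row sum and max column sum."""
    vals = a.values
    s = max(vals.sum(axis=1).max(), vals.sum(axis=0).max())
    if s == 0:
        return NormalizedMatrix(np.zeros_like(vals))
    return NormalizedMatrix(vals / s)


def total_influence(
    d: NormalizedMatrix,
    codes: Sequence[str] = (),
    level: Literal["criteria", "dimension"] = "criteria",
) -> TotalInfluenceMatrix:
    """Closed form T = D (I - D)^(-1), all direct and indirect paths."""
    dv = d.values
    n = dv.shape[0]
    eye_minus = np.eye(n) - dv
    if np.linalg.cond(eye_minus) > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            "I - D is ill-conditioned; normalization did not damp the matrix"
        )
    t = dv @ np.linalg.inv(eye_minus)
    t[np.abs(t) < 1e-14] = 0.0  # clip solver dust so nonnegativity is exact
    if np.any(t < 0):
        raise np.linalg.LinAlgError("negative total influence; invalid input")
    return TotalInfluenceMatrix(t, level=level, codes=tuple(codes))


def dimension_total_influence(
    t_c: TotalInfluenceMatrix, framework: CriteriaFramework
) -> TotalInfluenceMatrix:
    """Block-average T_C into the dimension-level matrix T_D."""
    if t_c.values.shape[0] != framework.n_criteria:
        raise ValueError("T_C shape does not match framework")
    k = framework.n_dimensions
    t_d = np.empty((k, k))
    for p, dp in enumerate(framework.dimension_codes):
        rows = framework.blocks[dp]
        for q, dq in enumerate(framework.dimension_codes):
            cols = framework.blocks[dq]
            t_d[p, q] = t_c.values[np.ix_(rows, cols)].mean()
    return TotalInfluenceMatrix(
        t_d, level="dimension", codes=tuple(framework.dimension_codes)
    )


def causal_profile(t: TotalInfluenceMatrix) -> CausalProfile:
    """Row/column sums of T: influence given and received per node."""
    codes = t.codes or tuple(str(i) for i in range(t.values.shape[0]))
    return CausalProfile(codes=codes, r=t.values.sum(axis=1), c=t.values.sum(axis=0))


def dimension_priority(profile: CausalProfile) -> list[str]:
    """Codes by net influence (r - c) descending.

    Ties break by prominence descending, then original order, so the
    result is reproducible on degenerate synthetic inputs.
    """
    order = sorted(
        range(len(profile.codes)),
        key=lambda i: (-profile.relation[i], -profile.prominence[i], i),
    )
    return [profile.codes[i] for i in order]


def _threshold(matrix: np.ndarray, rule: float | str) -> float:
    if isinstance(rule, str):
        if rule != "mean-off-diagonal":
            raise ValueError(f"unknown threshold rule {rule!r}")
        off = ~np.eye(matrix.shape[0], dtype=bool)
        return float(matrix[off].mean())
    return float(rule)


def _level_graph(
    t: np.ndarray, codes: Sequence[str], profile: CausalProfile, thr: float
) -> nx.DiGraph:
    g = nx.DiGraph()
    for i, code in enumerate(codes):
        g.add_node(code, prominence=float(profile.prominence[i]),
                   relation=float(profile.relation[i]))
    n = len(codes)
    for i in range(n):
        for j in range(n):
            if i != j and t[i, j] >= thr:
                g.add_edge(codes[i], codes[j], weight=float(t[i, j]))
    return g


def build_inrm(
    t_d: TotalInfluenceMatrix,
    t_c: TotalInfluenceMatrix,
    profile_d: CausalProfile,
    profile_c: CausalProfile,
    threshold_rule: float | str = "mean-off-diagonal",
) -> InrmGraph:
    """Draw the INRM: edges where total influence meets the threshold.

    The default rule thresholds each level at the mean of its own
    off-diagonal entries (inclusive); a numeric rule applies to both
    levels verbatim.
    """
    thr_d = _threshold(t_d.values, threshold_rule)
    thr_c = _threshold(t_c.values, threshold_rule)
    return InrmGraph(
        dimension_graph=_level_graph(t_d.values, profile_d.codes, profile_d, thr_d),
        criteria_graph=_level_graph(t_c.values, profile_c.codes, profile_c, thr_c),
        dimension_threshold=thr_d,
        criteria_threshold=thr_c,
    )


def retest_consistency(m1: np.ndarray | DirectMatrix,
                       m2: np.ndarray | DirectMatrix) -> RetestReport:
    """Sum and mean of |M1 - M2| over all n^2 ordered entry pairs."""
    a = m1.values if isinstance(m1, DirectMatrix) else np.asarray(m1, dtype=float)
    b = m2.values if isinstance(m2, DirectMatrix) else np.asarray(m2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = float(np.abs(a - b).sum())
    return RetestReport(n_pairs=a.size, total_abs_diff=total)
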