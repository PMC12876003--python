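"""Modified VIKOR: aspiration-gap evaluation of a single community.

Instead of ranking alternatives against the best observed one, the
modified method measures every criterion's shortfall from an absolute
aspiration level.  With satisfaction ratings on a 1-10 scale the
aspiration is 10 and the worst level 0, so the gap ratio of a
performance score p is

    gap(p) = (aspiration - p) / (aspiration - worst) = (10 - p) / 10

Gaps aggregate linearly: because the ratio is affine in p, the weighted
gap of an aggregate equals the aggregate of weighted gaps, at dimension
(local weights) and total (global weights) level alike.  Two panels —
residents and external experts — are integrated by valid-respondent
counts: (n_r p_r + n_e p_e) / (n_r + n_e).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .danp import WeightSet
from .framework import CriteriaFramework

__all__ = [
    "SatisfactionSurvey",
    "VikorConfig",
    "IntegrationSpec",
    "PerformanceTable",
    "SampleAdequacy",
    "EvaluationReport",
    "validate_survey",
    "mean_performance",
    "gap_ratio",
    "integrate_panels",
    "dimension_performance",
    "total_performance",
    "build_report",
    "priority_ranking",
    "sample_margin_of_error",
    "round_half_up",
]

RESIDENT = "resident"
EXPERT = "expert"


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding, used only at the reporting layer."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VikorConfig:
    """Aspiration and worst benchmark levels on the rating scale."""

    aspiration: float = 10.0
    worst: float = 0.0

    def __post_init__(self) -> None:
        if not self.aspiration > self.worst:
            raise ValueError("aspiration must exceed worst level")


@dataclass(frozen=True)
class IntegrationSpec:
    """Valid respondent counts used as panel-integration weights."""

    n_resident: int
    n_expert: int

    def __post_init__(self) -> None:
        if self.n_resident < 1 or self.n_expert < 1:
            raise ValueError("panel sizes must be >= 1")


@dataclass(frozen=True)
class SatisfactionSurvey:
    """Long-form satisfaction ratings for one panel.

    ``rows`` has columns respondent_id, criterion_code, rating; ratings
    live on the 1-10 satisfaction scale.
    """

    panel_label: str
    rows: pd.DataFrame
    valid_n: int

    def __post_init__(self) -> None:
        needed = {"respondent_id", "criterion_code", "rating"}
        if not needed <= set(self.rows.columns):
            raise ValueError(f"survey rows need columns {sorted(needed)}")
        r = self.rows["rating"]
        if r.lt(1).any() or r.gt(10).any():
            bad = self.rows[r.lt(1) | r.gt(10)].index[0]
            raise ValueError(f"rating outside [1, 10] at row {bad}")
        if self.valid_n < 1:
            raise ValueError("valid_n must be >= 1")


@dataclass(frozen=True)
class PerformanceTable:
    """Per-criterion panel means, optionally with panel-level aggregates.

    ``criterion`` is indexed by criterion code with one column per panel
    label.  When a report is built from surveys the dimension and total
    aggregates are derived from the weights; a pre-aggregated table (as
    published case studies print them) may carry its own ``dimension``
    frame and ``total`` mapping, which then take precedence.
    """

    criterion: pd.DataFrame
    dimension: pd.DataFrame | None = None
    total: Mapping[str, float] | None = None

    @property
    def panels(self) -> list[str]:
        return list(self.criterion.columns)


@dataclass(frozen=True)
class SampleAdequacy:
    """Cochran margin-of-error check for a proportion-type sample."""

    n: int
    p: float
    confidence: float
    margin_of_error: float


@dataclass(frozen=True)
class EvaluationReport:
    """Full evaluation table: weights, performances and gaps by panel.

    ``frame`` holds full-precision values, one row per dimension,
    criterion and the grand total; :meth:`rounded` mirrors the printed
    3-decimal presentation.
    """

    frame: pd.DataFrame
    integration: IntegrationSpec
    config: VikorConfig

    def rounded(self, ndigits: int = 3) -> pd.DataFrame:
        out = self.frame.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].map(
                    lambda v: round_half_up(v, ndigits) if pd.notna(v) else v
                )
        return out

    def value(self, code: str, column: str) -> float:
        sel = self.frame.loc[self.frame["code"] == code, column]
        if sel.empty:
            raise KeyError(code)
        return float(sel.iloc[0])

    def total_gap(self, panel: str = "integrated") -> float:
        return self.value("TOTAL", f"gap_{panel}")


def validate_survey(
    survey: SatisfactionSurvey,
    framework: CriteriaFramework,
    max_missing_fraction: float = 0.0,
) -> tuple[SatisfactionSurvey, list[str]]:
    """Drop respondents with too many unanswered items.

    A respondent whose fraction of missing framework criteria exceeds
    ``max_missing_fraction`` (default: any missing item) is removed
    whole; remaining missing items are ignored item-wise downstream.
    """
    codes = set(framework.criterion_codes)
    n_items = len(codes)
    dropped: list[str] = []
    keep_ids = []
    for rid, grp in survey.rows.groupby("respondent_id", sort=False):
        answered = len(codes & set(grp["criterion_code"]))
        if (n_items - answered) / n_items > max_missing_fraction:
            dropped.append(rid)
        else:
            keep_ids.append(rid)
    kept = survey.rows[survey.rows["respondent_id"].isin(keep_ids)]
    if not keep_ids:
        raise ValueError("no valid respondents remain after validation")
    return (
        SatisfactionSurvey(survey.panel_label, kept.reset_index(drop=True),
                           valid_n=len(keep_ids)),
        dropped,
    )


def mean_performance(
    survey: SatisfactionSurvey, framework: CriteriaFramework
) -> pd.Series:
    """Arithmetic mean rating per criterion, in framework order."""
    grouped = survey.rows.groupby("criterion_code")["rating"].mean()
    missing = [c for c in framework.criterion_codes if c not in grouped.index]
    if missing:
        raise ValueError(f"criteria with zero ratings: {missing}")
    return grouped.reindex(framework.criterion_codes)


def gap_ratio(performance: float, config: VikorConfig = VikorConfig()) -> float:
    """Normalised shortfall from the aspiration level, in [0, 1]."""
    if not config.worst <= performance <= config.aspiration:
        raise ValueError(
            f"performance {performance} outside "
            f"[{config.worst}, {config.aspiration}]"
        )
    return (config.aspiration - performance) / (config.aspiration - config.worst)


def integrate_panels(
    p_resident: float, n_resident: int, p_expert: float, n_expert: int
) -> float:
    """Respondent-count weighted mean of the two panel values."""
    if n_resident < 1 or n_expert < 1:
        raise ValueError("panel sizes must be >= 1")
    return (n_resident * p_resident + n_expert * p_expert) / (n_resident + n_expert)


def _check_weights(weights: Sequence[float], what: str, tol: float = 0.02) -> None:
    # tol accommodates published weights rounded to reporting precision,
    # whose sum can drift a few thousandths from 1
    s = float(np.sum(weights))
    if abs(s - 1.0) > tol:
        raise ValueError(f"{what} weights sum to {s}, expected 1")


def dimension_performance(
    criterion_means: Sequence[float], local_weights: Sequence[float]
) -> float:
    """Local-weight aggregate of the member criteria's means."""
    _check_weights(local_weights, "local")
    return float(np.dot(local_weights, criterion_means))


def total_performance(
    criterion_means: Sequence[float], global_weights: Sequence[float]
) -> float:
    """Global-weight aggregate over all criteria."""
    _check_weights(global_weights, "global")
    return float(np.dot(global_weights, criterion_means))


def _as_performance_table(
    surveys: Mapping[str, SatisfactionSurvey] | PerformanceTable,
    framework: CriteriaFramework,
) -> PerformanceTable:
    if isinstance(surveys, PerformanceTable):
        return surveys
    if not surveys:
        raise ValueError("no survey panels supplied")
    cols = {
        label: mean_performance(s, framework) for label, s in surveys.items()
    }
    return PerformanceTable(criterion=pd.DataFrame(cols))


def build_report(
    weight_set: WeightSet,
    surveys: Mapping[str, SatisfactionSurvey] | PerformanceTable,
    integration: IntegrationSpec,
    config: VikorConfig = VikorConfig(),
    framework: CriteriaFramework | None = None,
) -> EvaluationReport:
    """Assemble the full evaluation table.

    One row per dimension (weight + aggregated performance/gap), one per
    criterion (local/global weight, per-panel and integrated performance
    and gap), and a TOTAL row.  Expects exactly the two panels named
    ``resident`` and ``expert``.
    """
    if framework is None:
        from .framework import case_framework

        framework = case_framework()
    perf = _as_performance_table(surveys, framework)
    for panel in (RESIDENT, EXPERT):
        if panel not in perf.panels:
            raise ValueError(f"missing panel {panel!r}")
    crit = perf.criterion
    n_r, n_e = integration.n_resident, integration.n_expert

    def integrated(row: pd.Series) -> float:
        return integrate_panels(row[RESIDENT], n_r, row[EXPERT], n_e)

    rows: list[dict] = []
    for d in framework.dimensions:
        members = [c.code for c in framework.criteria_of(d.code)]
        locals_ = [weight_set.local_weights[c] for c in members]
        if perf.dimension is not None and d.code in perf.dimension.index:
            dim_perf = {p: float(perf.dimension.loc[d.code, p])
                        for p in (RESIDENT, EXPERT)}
        else:
            dim_perf = {
                p: dimension_performance(crit.loc[members, p].to_numpy(), locals_)
                for p in (RESIDENT, EXPERT)
            }
        dim_int = integrate_panels(dim_perf[RESIDENT], n_r, dim_perf[EXPERT], n_e)
        rows.append(
            {
                "code": d.code, "name": d.name, "kind": "dimension",
                "dimension": d.code,
                "local_weight": weight_set.dimension_weights[d.code],
                "global_weight": np.nan,
                f"performance_{RESIDENT}": dim_perf[RESIDENT],
                f"gap_{RESIDENT}": gap_ratio(dim_perf[RESIDENT], config),
                f"performance_{EXPERT}": dim_perf[EXPERT],
                f"gap_{EXPERT}": gap_ratio(dim_perf[EXPERT], config),
                "performance_integrated": dim_int,
                "gap_integrated": gap_ratio(dim_int, config),
            }
        )
        for c in framework.criteria_of(d.code):
            p_r = float(crit.loc[c.code, RESIDENT])
            p_e = float(crit.loc[c.code, EXPERT])
            p_i = integrate_panels(p_r, n_r, p_e, n_e)
            rows.append(
                {
                    "code": c.code, "name": c.name, "kind": "criterion",
                    "dimension": d.code,
                    "local_weight": weight_set.local_weights[c.code],
                    "global_weight": weight_set.global_weights[c.code],
                    f"performance_{RESIDENT}": p_r,
                    f"gap_{RESIDENT}": gap_ratio(p_r, config),
                    f"performance_{EXPERT}": p_e,
                    f"gap_{EXPERT}": gap_ratio(p_e, config),
                    "performance_integrated": p_i,
                    "gap_integrated": gap_ratio(p_i, config),
                }
            )
    globals_ = [weight_set.global_weights[c] for c in framework.criterion_codes]
    if perf.total is not None:
        tot = {p: float(perf.total[p]) for p in (RESIDENT, EXPERT)}
    else:
        tot = {
            p: total_performance(
                crit.loc[framework.criterion_codes, p].to_numpy(), globals_
            )
            for p in (RESIDENT, EXPERT)
        }
    tot_int = integrate_panels(tot[RESIDENT], n_r, tot[EXPERT], n_e)
    rows.append(
        {
            "code": "TOTAL", "name": "Total", "kind": "total", "dimension": "",
            "local_weight": np.nan, "global_weight": np.nan,
            f"performance_{RESIDENT}": tot[RESIDENT],
            f"gap_{RESIDENT}": gap_ratio(tot[RESIDENT], config),
            f"performance_{EXPERT}": tot[EXPERT],
            f"gap_{EXPERT}": gap_ratio(tot[EXPERT], config),
            "performance_integrated": tot_int,
            "gap_integrated": gap_ratio(tot_int, config),
        }
    )
    return EvaluationReport(pd.DataFrame(rows), integration, config)


def priority_ranking(report: EvaluationReport) -> list[str]:
    """Criteria by integrated gap descending; ties by global weight."""
    crit = report.frame[report.frame["kind"] == "criterion"]
    ordered = crit.sort_values(
        ["gap_integrated", "global_weight"], ascending=[False, False],
        kind="stable",
    )
    return list(ordered["code"])


def sample_margin_of_error(
    n: int, p: float = 0.5, confidence: float = 0.95
) -> SampleAdequacy:
    """Cochran margin of error for a proportion at the given confidence."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    margin = z * np.sqrt(p * (1 - p) / n)
    return SampleAdequacy(n=n, p=p, confidence=confidence,
                          margin_of_error=float(margin))
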