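"""Synthetic questionnaire panels and the published case fixture.

Raw questionnaires behind the Qianshan case study are not deposited, so
the pipeline is exercised two ways:

* generators that emulate each questionnaire type — satisfaction
  surveys (latent-normal ratings adjusted to hit exact target means),
  DEMATEL direct-influence matrices (0-4 integer ratings with optional
  dimension-level structure), and paired conservative/optimistic fuzzy
  Delphi ratings — all bit-reproducible under an explicit seed;
* :func:`case_fixture`, which embeds the published per-panel criterion
  and dimension performances, the local/dimension influential weights
  and the panel sizes (140 residents, 10 experts) at printed precision.

The greedy mean-matching step nudges individual integer ratings by one
point until each criterion's mean sits within half a rating unit over n
of its target, so a 140-respondent survey reproduces a 3-decimal target
mean essentially exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .danp import WeightSet
from .dematel import DirectMatrix
from .fdm import FdmResponse
from .framework import CriteriaFramework, case_framework
from .vikor import EXPERT, RESIDENT, IntegrationSpec, PerformanceTable, SatisfactionSurvey

__all__ = [
    "GeneratorConfig",
    "gen_satisfaction_survey",
    "gen_dematel_panel",
    "gen_fdm_panel",
    "priority_structure",
    "case_fixture",
    "CASE_LOCAL_WEIGHTS",
    "CASE_DIMENSION_WEIGHTS",
    "CASE_PERFORMANCE",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs shared by the questionnaire generators.

    ``target_means`` maps criterion codes to the mean rating the panel
    should produce; ``dispersion`` is the latent-normal standard
    deviation before rounding; ``missing_rate`` drops individual items
    to exercise respondent-validity handling.
    """

    seed: int
    panel_size: int = 140
    scale_min: int = 1
    scale_max: int = 10
    target_means: Mapping[str, float] = field(default_factory=dict)
    dispersion: float = 1.5
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for code, t in self.target_means.items():
            if not self.scale_min <= t <= self.scale_max:
                raise ValueError(
                    f"target mean {t} for {code} outside "
                    f"[{self.scale_min}, {self.scale_max}]"
                )


def _match_mean(
    ratings: np.ndarray, target: float, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy +/-1 adjustments until sum(ratings) hits round(n * target)."""
    desired = int(round(target * ratings.size))
    desired = min(max(desired, lo * ratings.size), hi * ratings.size)
    out = ratings.copy()
    while out.sum() != desired:
        step = 1 if out.sum() < desired else -1
        room = np.flatnonzero(out < hi) if step > 0 else np.flatnonzero(out > lo)
        out[rng.choice(room)] += step
    return out


def gen_satisfaction_survey(
    config: GeneratorConfig,
    framework: CriteriaFramework,
    panel_label: str = RESIDENT,
) -> SatisfactionSurvey:
    """Integer 1-10 satisfaction ratings hitting each target mean.

    Ratings are latent-normal draws centred on the criterion's target,
    rounded, clipped to scale, then greedily adjusted so the criterion
    mean matches its target to the resolution an integer panel allows
    (|mean - target| <= 0.5/n).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.scale_min, config.scale_max
    default_target = (lo + hi) / 2
    records: list[dict] = []
    respondent_ids = [f"{panel_label}-{i + 1:03d}" for i in range(config.panel_size)]
    for code in framework.criterion_codes:
        target = float(config.target_means.get(code, default_target))
        latent = rng.normal(target, config.dispersion, size=config.panel_size)
        ratings = np.clip(np.rint(latent), lo, hi).astype(int)
        ratings = _match_mean(ratings, target, lo, hi, rng)
        for rid, val in zip(respondent_ids, ratings):
            records.append(
                {"respondent_id": rid, "criterion_code": code, "rating": int(val)}
            )
    rows = pd.DataFrame(records)
    if config.missing_rate > 0:
        keep = rng.random(len(rows)) >= config.missing_rate
        rows = rows[keep].reset_index(drop=True)
    return SatisfactionSurvey(panel_label, rows, valid_n=config.panel_size)


def priority_structure(
    framework: CriteriaFramework,
    ordered_dimensions: Sequence[str],
    low: float = 1.0,
    high: float = 4.0,
) -> dict[tuple[str, str], float]:
    """Dimension-block base ratings realising a net-influence order.

    The first dimension in ``ordered_dimensions`` sends the strongest
    ratings, the last the weakest, so the induced dimension profile's
    relation (r - c) decreases along the given order.
    """
    k = len(ordered_dimensions)
    if set(ordered_dimensions) != set(framework.dimension_codes):
        raise ValueError("ordered_dimensions must permute the framework dimensions")
    levels = np.linspace(high, low, k)
    return {
        (src, dst): float(levels[i])
        for i, src in enumerate(ordered_dimensions)
        for dst in framework.dimension_codes
    }


def gen_dematel_panel(
    config: GeneratorConfig,
    framework: CriteriaFramework,
    structure: Mapping[tuple[str, str], float] | None = None,
    n_experts: int = 9,
    noise: int = 1,
) -> list[DirectMatrix]:
    """Integer 0-4 direct-influence matrices for an expert panel.

    ``structure`` maps (from_dimension, to_dimension) to a base rating;
    every criterion pair in that dimension block starts from it (absent
    blocks default to the scale midpoint).  Each expert then perturbs
    entries by uniform integer noise in [-noise, noise], clipped to the
    0-4 scale, with the diagonal pinned at zero.
    """
    if n_experts < 1:
        raise ValueError("need at least one expert")
    rng = np.random.default_rng(config.seed)
    n = framework.n_criteria
    scale_max = 4.0
    base = np.full((n, n), scale_max / 2.0)
    if structure is not None:
        for (dp, dq), level in structure.items():
            if not 0 <= level <= scale_max:
                raise ValueError(f"structure level {level} outside [0, {scale_max}]")
            base[np.ix_(framework.blocks[dp], framework.blocks[dq])] = level
    np.fill_diagonal(base, 0.0)
    panel: list[DirectMatrix] = []
    for _ in range(n_experts):
        if noise:
            # dithered rounding keeps the panel mean at fractional base
            # levels that plain rounding would collapse onto one integer
            jitter = rng.integers(-noise, noise + 1, size=(n, n))
            vals = np.rint(base + rng.uniform(-0.5, 0.5, size=(n, n))) + jitter
        else:
            vals = np.rint(base)
        vals = np.clip(vals, 0, scale_max)
        np.fill_diagonal(vals, 0.0)
        panel.append(DirectMatrix(vals, scale_max=scale_max))
    return panel


def gen_fdm_panel(
    config: GeneratorConfig,
    framework: CriteriaFramework,
    low_consensus: Sequence[str] = (),
    n_invalid: int = 0,
) -> list[FdmResponse]:
    """Paired conservative/optimistic expert ratings for FDM screening.

    Criteria listed in ``low_consensus`` are rated around the bottom of
    the scale so their consensus lands below the default threshold of 4;
    the rest are rated high.  ``n_invalid`` experts are corrupted (one
    item flipped to conservative >= optimistic or dropped) to exercise
    questionnaire-level invalidation.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.scale_min, config.scale_max
    responses: list[FdmResponse] = []
    for e in range(config.panel_size):
        expert_id = f"expert-{e + 1:02d}"
        corrupt = e < n_invalid
        items: list[FdmResponse] = []
        for code in framework.criterion_codes:
            if code in low_consensus:
                cons = int(rng.integers(lo, lo + 2))        # 1-2
                opt = int(rng.integers(lo + 2, lo + 4))     # 3-4
            else:
                cons = int(rng.integers(5, 8))              # 5-7
                opt = int(rng.integers(8, hi + 1))          # 8-10
            items.append(FdmResponse(expert_id, code, float(cons), float(opt)))
        if corrupt:
            if rng.random() < 0.5:
                bad = items[int(rng.integers(len(items)))]
                items[items.index(bad)] = FdmResponse(
                    expert_id, bad.criterion_code,
                    conservative=bad.optimistic, optimistic=bad.optimistic,
                )
            else:
                items.pop(int(rng.integers(len(items))))
        responses.extend(items)
    return responses


# --------------------------------------------------------------------------
# Published Qianshan case values (per-panel means, weights, panel sizes)
# --------------------------------------------------------------------------

#: local (within-dimension) influential weights per criterion
CASE_LOCAL_WEIGHTS: dict[str, float] = {
    "C11": 0.436, "C12": 0.364, "C13": 0.200,
    "C21": 0.530, "C22": 0.470,
    "C31": 0.608, "C32": 0.392,
    "C41": 0.510, "C42": 0.490,
    "C51": 0.192, "C52": 0.332, "C53": 0.339, "C54": 0.137,
    "C61": 0.345, "C62": 0.216, "C63": 0.439,
}

#: dimension weights (sum to 1.000)
CASE_DIMENSION_WEIGHTS: dict[str, float] = {
    "D1": 0.150, "D2": 0.125, "D3": 0.150,
    "D4": 0.125, "D5": 0.225, "D6": 0.225,
}

#: per-criterion mean satisfaction, (resident panel, expert panel)
CASE_PERFORMANCE: dict[str, tuple[float, float]] = {
    "C11": (7.157, 8.000), "C12": (5.186, 6.300), "C13": (6.157, 7.300),
    "C21": (4.179, 7.200), "C22": (8.036, 8.700),
    "C31": (6.171, 8.000), "C32": (5.171, 7.000),
    "C41": (3.229, 6.200), "C42": (4.164, 5.200),
    "C51": (2.793, 3.900), "C52": (7.164, 7.900),
    "C53": (6.186, 6.900), "C54": (2.157, 2.900),
    "C61": (5.179, 6.900), "C62": (3.236, 6.000), "C63": (2.579, 5.000),
}

#: per-dimension panel aggregates as published (resident, expert)
CASE_DIMENSION_PERFORMANCE: dict[str, tuple[float, float]] = {
    "D1": (6.240, 7.207), "D2": (5.924, 7.854), "D3": (5.767, 7.571),
    "D4": (3.693, 5.717), "D5": (5.346, 6.364), "D6": (3.553, 5.863),
}

#: total performance per panel as published
CASE_TOTAL_PERFORMANCE: dict[str, float] = {RESIDENT: 4.942, EXPERT: 6.534}

CASE_PANEL_SIZES = IntegrationSpec(n_resident=140, n_expert=10)


def case_fixture() -> tuple[WeightSet, PerformanceTable, IntegrationSpec]:
    """The published Qianshan evaluation inputs at printed precision.

    Global weights are reconstructed as dimension x local so the
    weight-set identities hold exactly; the performance table carries
    the printed criterion, dimension and total panel values.
    """
    fw = case_framework()
    global_w = {
        c: CASE_DIMENSION_WEIGHTS[fw.dimension_of(c)] * CASE_LOCAL_WEIGHTS[c]
        for c in fw.criterion_codes
    }
    weights = WeightSet(
        global_weights=global_w,
        local_weights=dict(CASE_LOCAL_WEIGHTS),
        dimension_weights=dict(CASE_DIMENSION_WEIGHTS),
    )
    crit = pd.DataFrame(
        {
            RESIDENT: {c: v[0] for c, v in CASE_PERFORMANCE.items()},
            EXPERT: {c: v[1] for c, v in CASE_PERFORMANCE.items()},
        }
    ).loc[fw.criterion_codes]
    dim = pd.DataFrame(
        {
            RESIDENT: {d: v[0] for d, v in CASE_DIMENSION_PERFORMANCE.items()},
            EXPERT: {d: v[1] for d, v in CASE_DIMENSION_PERFORMANCE.items()},
        }
    ).loc[fw.dimension_codes]
    table = PerformanceTable(
        criterion=crit, dimension=dim, total=dict(CASE_TOTAL_PERFORMANCE)
    )
    return weights, table, CASE_PANEL_SIZES
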