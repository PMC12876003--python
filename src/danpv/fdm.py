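"""Fuzzy Delphi screening of candidate criteria.

Each expert gives every criterion a *conservative* and an *optimistic*
importance rating on a 1-10 scale.  Per criterion the two rating pools
are condensed into triangular fuzzy numbers (min, geometric mean, max);
the overlap between the conservative triangle's upper edge and the
optimistic triangle's lower edge — the gray zone — decides how the
consensus value G is extracted:

* no overlap (Z <= 0): the experts agree; G is the midpoint of the two
  triangle peaks;
* moderate overlap (0 < Z <= M): G is the abscissa of the
  maximum-membership crossing of the descending conservative edge and
  the ascending optimistic edge;
* heavy overlap (Z > M): opinions have not converged; the consensus is
  undefined and the criterion is flagged for expert re-survey.

Criteria whose G meets the screening threshold (inclusive) are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .framework import CriteriaFramework

__all__ = [
    "FdmResponse",
    "TriangularNumber",
    "FdmCriterionResult",
    "FdmConfig",
    "EmptyPanelError",
    "validate_fdm_panel",
    "build_tfn",
    "consensus_value",
    "screen_criteria",
    "run_fdm",
]


class EmptyPanelError(ValueError):
    """No valid expert questionnaires survive validation."""


@dataclass(frozen=True)
class FdmResponse:
    """One expert's paired rating of one criterion."""

    expert_id: str
    criterion_code: str
    conservative: float
    optimistic: float

    def __post_init__(self) -> None:
        for label, v in (("conservative", self.conservative),
                         ("optimistic", self.optimistic)):
            if not 1.0 <= v <= 10.0:
                raise ValueError(f"{label} rating {v} outside [1, 10]")


@dataclass(frozen=True)
class TriangularNumber:
    """Triangular fuzzy number (low, mid, high)."""

    low: float
    mid: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.mid <= self.high:
            raise ValueError(f"not ordered: {(self.low, self.mid, self.high)}")


@dataclass(frozen=True)
class FdmConfig:
    """Screening parameters.

    ``threshold`` is the consensus benchmark on the rating scale;
    criteria with G at or above it are retained.
    """

    threshold: float = 4.0

    def __post_init__(self) -> None:
        if not 1.0 <= self.threshold <= 10.0:
            raise ValueError(f"threshold {self.threshold} outside [1, 10]")


@dataclass(frozen=True)
class FdmCriterionResult:
    criterion_code: str
    conservative_tfn: TriangularNumber
    optimistic_tfn: TriangularNumber
    gray_zone: float
    check_value: float
    consensus: float | None
    retained: bool


def validate_fdm_panel(
    responses: Sequence[FdmResponse],
    framework: CriteriaFramework,
    config: FdmConfig = FdmConfig(),
) -> tuple[list[FdmResponse], list[str]]:
    """Drop whole questionnaires that are incomplete or inconsistent.

    An expert is rejected when any framework criterion is missing from
    their responses or any item has conservative >= optimistic; the
    surviving responses and the rejected expert ids are returned.
    """
    needed = set(framework.criterion_codes)
    by_expert: dict[str, dict[str, FdmResponse]] = {}
    for r in responses:
        if r.criterion_code not in needed:
            raise KeyError(f"unknown criterion {r.criterion_code!r}")
        by_expert.setdefault(r.expert_id, {})[r.criterion_code] = r
    valid: list[FdmResponse] = []
    rejected: list[str] = []
    for expert_id, items in by_expert.items():
        complete = needed <= set(items)
        consistent = all(r.conservative < r.optimistic for r in items.values())
        if complete and consistent:
            valid.extend(items[c] for c in framework.criterion_codes)
        else:
            rejected.append(expert_id)
    if not valid:
        raise EmptyPanelError(
            f"no valid questionnaires remain (rejected {len(rejected)} experts)"
        )
    return valid, rejected


def build_tfn(scores: Iterable[float]) -> TriangularNumber:
    """Condense a rating pool into (min, geometric mean, max)."""
    pool = list(scores)
    if not pool:
        raise ValueError("empty score pool")
    if any(not 1.0 <= s <= 10.0 for s in pool):
        raise ValueError("scores outside [1, 10]")
    gmean = math.exp(sum(math.log(s) for s in pool) / len(pool))
    gmean = min(max(gmean, min(pool)), max(pool))  # guard float roundoff
    return TriangularNumber(min(pool), gmean, max(pool))


def consensus_value(
    cons: TriangularNumber, opt: TriangularNumber
) -> tuple[float, float, float | None]:
    """Gray-zone test and consensus extraction for one criterion.

    Returns ``(Z, M, G)`` where Z = cons.high - opt.low (gray zone),
    M = opt.mid - cons.mid (check value) and G is the consensus on the
    rating scale, or ``None`` when Z > M (no convergence).
    """
    z = cons.high - opt.low
    m = opt.mid - cons.mid
    if z <= 0:
        return z, m, (cons.mid + opt.mid) / 2.0
    if z <= m:
        denom = (cons.high - cons.mid) + (opt.mid - opt.low)
        if denom == 0:  # both triangles vertical at the same abscissa
            return z, m, (cons.mid + opt.mid) / 2.0
        g = (cons.high * opt.mid - opt.low * cons.mid) / denom
        return z, m, g
    return z, m, None


def screen_criteria(
    results: Sequence[FdmCriterionResult], config: FdmConfig = FdmConfig()
) -> list[str]:
    """Criterion codes whose consensus meets the threshold (inclusive).

    Criteria with undefined consensus are never retained here; they are
    flagged on the result objects for re-survey.
    """
    return [
        r.criterion_code
        for r in results
        if r.consensus is not None and r.consensus >= config.threshold
    ]


def run_fdm(
    responses: Sequence[FdmResponse],
    framework: CriteriaFramework,
    config: FdmConfig = FdmConfig(),
) -> tuple[list[FdmCriterionResult], list[str], list[str]]:
    """Full screening round: validate, build TFNs, test consensus, screen.

    Returns (per-criterion results, retained codes, rejected expert ids).
    """
    valid, rejected = validate_fdm_panel(responses, framework, config)
    by_crit: dict[str, list[FdmResponse]] = {}
    for r in valid:
        by_crit.setdefault(r.criterion_code, []).append(r)
    results: list[FdmCriterionResult] = []
    for code in framework.criterion_codes:
        pool = by_crit[code]
        cons = build_tfn([r.conservative for r in pool])
        opt = build_tfn([r.optimistic for r in pool])
        z, m, g = consensus_value(cons, opt)
        results.append(
            FdmCriterionResult(
                criterion_code=code,
                conservative_tfn=cons,
                optimistic_tfn=opt,
                gray_zone=z,
                check_value=m,
                consensus=g,
                retained=g is not None and g >= config.threshold,
            )
        )
    return results, screen_criteria(results, config), rejected
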