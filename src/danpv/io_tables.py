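"""Tabular readers/writers for every questionnaire and result format.

All interchange is comma-separated text with a header row; matrices
travel in long (from, to, value) form so row/column order is never
ambiguous.  Readers validate against the documented schemas and report
offending rows by number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .danp import WeightSet
from .dematel import DirectMatrix
from .fdm import FdmResponse
from .framework import CriteriaFramework
from .vikor import EvaluationReport, SatisfactionSurvey, VikorConfig

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_survey",
    "write_survey",
    "read_fdm_responses",
    "write_fdm_responses",
    "read_dematel_panel",
    "write_dematel_panel",
    "read_weight_set",
    "write_weight_set",
    "write_report",
    "load_run_config",
]


class SchemaError(ValueError):
    """A table does not conform to its documented column schema."""


def _require_columns(table: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _check_range(table: pd.DataFrame, column: str, lo: float, hi: float,
                 what: str) -> None:
    bad = table[(table[column] < lo) | (table[column] > hi)]
    if not bad.empty:
        row = int(bad.index[0]) + 2  # 1-based plus header line
        raise SchemaError(
            f"{what}: {column}={bad[column].iloc[0]} outside [{lo}, {hi}] "
            f"at file row {row}"
        )


def read_survey(path: str | Path, panel_label: str,
                valid_n: int | None = None) -> SatisfactionSurvey:
    table = pd.read_csv(path)
    _require_columns(table, ["respondent_id", "criterion_code", "rating"], str(path))
    _check_range(table, "rating", 1, 10, str(path))
    n = valid_n if valid_n is not None else table["respondent_id"].nunique()
    table["respondent_id"] = table["respondent_id"].astype(str)
    return SatisfactionSurvey(panel_label, table, valid_n=n)


def write_survey(survey: SatisfactionSurvey, path: str | Path) -> None:
    survey.rows.to_csv(path, index=False)


def read_fdm_responses(path: str | Path) -> list[FdmResponse]:
    table = pd.read_csv(path)
    _require_columns(
        table, ["expert_id", "criterion_code", "conservative", "optimistic"],
        str(path),
    )
    _check_range(table, "conservative", 1, 10, str(path))
    _check_range(table, "optimistic", 1, 10, str(path))
    return [
        FdmResponse(str(r.expert_id), str(r.criterion_code),
                    float(r.conservative), float(r.optimistic))
        for r in table.itertuples(index=False)
    ]


def write_fdm_responses(responses: Sequence[FdmResponse], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in responses]).to_csv(path, index=False)


def read_dematel_panel(
    path: str | Path, framework: CriteriaFramework, scale_max: float = 4.0
) -> list[DirectMatrix]:
    """Assemble per-expert matrices from long-form (from, to, rating) rows."""
    table = pd.read_csv(path)
    _require_columns(table, ["expert_id", "from_code", "to_code", "rating"],
                     str(path))
    _check_range(table, "rating", 0, scale_max, str(path))
    codes = framework.criterion_codes
    index = {c: i for i, c in enumerate(codes)}
    unknown = (set(table["from_code"]) | set(table["to_code"])) - set(codes)
    if unknown:
        raise SchemaError(f"{path}: unknown criterion code(s) {sorted(unknown)}")
    panel: list[DirectMatrix] = []
    for _, group in table.groupby("expert_id", sort=False):
        m = np.zeros((len(codes), len(codes)))
        for r in group.itertuples(index=False):
            m[index[r.from_code], index[r.to_code]] = r.rating
        panel.append(DirectMatrix(m, scale_max=scale_max))
    if not panel:
        raise SchemaError(f"{path}: no expert matrices found")
    return panel


def write_dematel_panel(
    panel: Sequence[DirectMatrix], framework: CriteriaFramework, path: str | Path
) -> None:
    codes = framework.criterion_codes
    rows = [
        {"expert_id": f"expert-{k + 1:02d}", "from_code": codes[i],
         "to_code": codes[j], "rating": m.values[i, j]}
        for k, m in enumerate(panel)
        for i in range(len(codes))
        for j in range(len(codes))
        if i != j
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_weight_set(
    weights: WeightSet, framework: CriteriaFramework, path: str | Path
) -> None:
    weights.as_frame(framework).to_csv(path, index=False)


def read_weight_set(path: str | Path) -> WeightSet:
    table = pd.read_csv(path)
    _require_columns(
        table,
        ["criterion", "dimension", "local_weight", "global_weight",
         "dimension_weight"],
        str(path),
    )
    dims = table.drop_duplicates("dimension")
    return WeightSet(
        global_weights=dict(zip(table["criterion"], table["global_weight"])),
        local_weights=dict(zip(table["criterion"], table["local_weight"])),
        dimension_weights=dict(zip(dims["dimension"], dims["dimension_weight"])),
    )


def write_report(report: EvaluationReport, path: str | Path,
                 ndigits: int | None = 3) -> None:
    """Write the evaluation table; ``ndigits=None`` keeps full precision."""
    frame = report.frame if ndigits is None else report.rounded(ndigits)
    frame.to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Paths, benchmarks and run options for the command-line pipeline."""

    framework_path: str | None = None
    resident_survey: str | None = None
    expert_survey: str | None = None
    dematel_panel: str | None = None
    fdm_responses: str | None = None
    aspiration: float = 10.0
    worst: float = 0.0
    inrm_threshold: str | float = "mean-off-diagonal"
    precision: int = 3
    seed: int = 0

    @property
    def vikor(self) -> VikorConfig:
        return VikorConfig(aspiration=self.aspiration, worst=self.worst)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**raw)
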