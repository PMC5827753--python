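"""Trust labels from NASA-TLX assessments.

The mentor rates each procedure on the six NASA-TLX indices (0-20 tick
scale). The performance score PS is inverted into a performance level
PL = 20 − PS, and a procedure is labelled *trustworthy* when PL > 11
(strictly; PL = 11 is *concerning*) — the threshold at which the mentor
considered a trainee qualified to continue on the console. The mental-demand
score doubles as the task-complexity covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

TRUSTWORTHY = "trustworthy"
CONCERNING = "concerning"

#: NASA-TLX columns expected in a performance table.
TLX_COLUMNS = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "performance_score",
    "effort",
    "frustration",
)

PL_THRESHOLD = 11.0
SCALE_MAX = 20.0


def performance_level(ps: float, scale_max: float = SCALE_MAX) -> float:
    """PL = scale_max − PS (default 20 − PS)."""
    if not 0 <= ps <= scale_max:
        raise ValueError(f"performance score {ps} outside the 0-{scale_max} scale")
    return scale_max - ps


def trust_label(pl: float) -> str:
    """'trustworthy' iff PL > 11 (strict); otherwise 'concerning'."""
    return TRUSTWORTHY if pl > PL_THRESHOLD else CONCERNING


@dataclass(frozen=True)
class PerformanceRecord:
    """One procedure's TLX scores with the derived PL and trust label."""

    mental_demand: float
    physical_demand: float
    temporal_demand: float
    performance_score: float
    effort: float
    frustration: float
    task: str

    @property
    def PL(self) -> float:
        return performance_level(self.performance_score)

    @property
    def label(self) -> str:
        return trust_label(self.PL)


def add_trust_columns(table: pd.DataFrame, ps_column: str = "performance_score") -> pd.DataFrame:
    """Append PL and label columns to a TLX score table."""
    if ps_column not in table.columns:
        raise KeyError(f"column {ps_column!r} missing from table")
    out = table.copy()
    out["PL"] = [performance_level(ps) for ps in out[ps_column]]
    out["label"] = [trust_label(pl) for pl in out["PL"]]
    return out


def read_tlx(path, sep: str = ",") -> pd.DataFrame:
    """Read a delimited TLX table (six score columns + task) and label it."""
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in TLX_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"TLX table missing columns: {missing}")
    return add_trust_columns(table)
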