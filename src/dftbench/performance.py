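"""CPU-time normalization for the two bottleneck program stages.

A benchmark run repeatedly invokes two expensive executables: the iterative
SCF solver (Link502) and the two-electron-integral derivative code
(Link703).  Raw logs report the total CPU time and the number of
initializations of each per combination; comparisons are made on the
average time per instance normalized to a single core,

    t_norm = total_cpu_time / (n_instances * n_cores).

Log-derived times carry an uncertainty of roughly 1-2 s per instance,
recorded as :data:`TIMING_UNCERTAINTY_S` metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["STAGES", "TIMING_UNCERTAINTY_S", "PerformanceRecord", "normalize_time", "stage_summary"]

STAGES: tuple[str, ...] = ("link502", "link703")

#: Declared uncertainty of a normalized per-instance time, in seconds.
TIMING_UNCERTAINTY_S: float = 2.0


@dataclass(frozen=True)
class PerformanceRecord:
    combination: tuple[str, str]
    stage: str
    total_cpu_time: float  # seconds
    n_instances: int
    n_cores: int = 1

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.total_cpu_time < 0:
            raise ValueError("total_cpu_time must be non-negative")
        if self.n_instances < 1:
            raise ValueError("n_instances must be at least 1")
        if self.n_cores < 1:
            raise ValueError("n_cores must be at least 1")


def normalize_time(rec: PerformanceRecord) -> float:
    """Average CPU seconds per program instance on one core."""
    return rec.total_cpu_time / (rec.n_instances * rec.n_cores)


def stage_summary(records: Iterable[PerformanceRecord], stages: Sequence[str] = STAGES) -> pd.DataFrame:
    """Tidy per-combination normalized times with per-stage maxima.

    Columns: functional, basis, stage, t_norm, t_max (the per-stage maximum
    that performance scoring compares against).
    """
    records = list(records)
    unknown = sorted({s for s in stages if s not in STAGES})
    if unknown:
        raise ValueError(f"unknown stage label(s): {', '.join(unknown)}")
    rows = [
        {
            "functional": r.combination[0],
            "basis": r.combination[1],
            "stage": r.stage,
            "t_norm": normalize_time(r),
        }
        for r in records
        if r.stage in stages
    ]
    for stage in stages:
        if not any(row["stage"] == stage for row in rows):
            raise ValueError(f"no performance records for stage {stage!r}")
    df = pd.DataFrame(rows).sort_values(["stage", "functional", "basis"], kind="stable").reset_index(drop=True)
    df["t_max"] = df.groupby("stage")["t_norm"].transform("max")
    return df
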