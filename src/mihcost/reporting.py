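"""Result serialization, benchmark comparison, and histogram export.

Monetary values are rounded to whole dollars in human-readable tables
and to cents in machine outputs (CSV/JSON); the simulation itself keeps
full floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .simulation import CostSummary, SimulationResult

__all__ = [
    "BenchmarkSet",
    "DEFAULT_BENCHMARKS",
    "compare_benchmarks",
    "export_histogram",
    "summary_to_dict",
    "summaries_to_dict",
    "iterations_frame",
]


@dataclass(frozen=True)
class BenchmarkSet:
    """Published mean unit costs of comparator care settings (USD).

    Defaults are national literature means for an outpatient clinic
    visit, an emergency department visit and an inpatient admission;
    override per report, since they are external to the cost model.
    """

    outpatient_clinic_visit: float = 160.0
    emergency_department_visit: float = 2715.0
    inpatient_admission: float = 24680.0

    def __post_init__(self) -> None:
        for name in ("outpatient_clinic_visit", "emergency_department_visit",
                     "inpatient_admission"):
            if not getattr(self, name) > 0:
                raise ValueError(f"benchmark {name} must be positive")

    def as_dict(self) -> dict[str, float]:
        return {
            "outpatient_clinic_visit": self.outpatient_clinic_visit,
            "emergency_department_visit": self.emergency_department_visit,
            "inpatient_admission": self.inpatient_admission,
        }


DEFAULT_BENCHMARKS = BenchmarkSet()


def compare_benchmarks(
    summary: CostSummary, benchmarks: BenchmarkSet = DEFAULT_BENCHMARKS
) -> pd.DataFrame:
    """Compare a per-visit cost summary against comparator unit costs.

    Per benchmark: ``difference = benchmark - median`` (positive when
    the benchmark setting is costlier than the MIH visit) and
    ``ratio = median / benchmark`` (> 1 flags the visit as more costly
    than the benchmark).
    """
    rows = []
    for label, unit_cost in benchmarks.as_dict().items():
        ratio = summary.median / unit_cost
        rows.append(
            {
                "benchmark": label,
                "benchmark_usd": round(unit_cost, 2),
                "median_usd": round(summary.median, 2),
                "difference_usd": round(unit_cost - summary.median, 2),
                "ratio": ratio,
                "relation": "more costly" if ratio > 1 else (
                    "equal" if ratio == 1 else "less costly"
                ),
            }
        )
    return pd.DataFrame(rows)


def export_histogram(result: SimulationResult, bins: int = 30) -> pd.DataFrame:
    """Binned per-visit cost counts per stratum (plot-ready).

    Bin edges span [min, max] of each stratum's cost vector; counts sum
    to the iteration count per stratum.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    frames = []
    for stratum, values in (
        ("basic", result.basic_costs), ("advanced", result.advanced_costs)
    ):
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        counts, edges = np.histogram(values, bins=bins)
        frames.append(
            pd.DataFrame(
                {
                    "stratum": stratum,
                    "bin_left": np.round(edges[:-1], 2),
                    "bin_right": np.round(edges[1:], 2),
                    "count": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summary_to_dict(summary: CostSummary) -> dict[str, float]:
    """Machine form of a summary, rounded to cents."""
    return {
        "median": round(summary.median, 2),
        "mean": round(summary.mean, 2),
        "interval_low": round(summary.interval_low, 2),
        "interval_high": round(summary.interval_high, 2),
        "interval_level": summary.interval_level,
        "sd": round(summary.sd, 2),
    }


def summaries_to_dict(
    scenarios: Mapping[str, tuple[CostSummary, CostSummary]],
) -> dict:
    return {
        name: {
            "basic": summary_to_dict(basic),
            "advanced": summary_to_dict(advanced),
        }
        for name, (basic, advanced) in scenarios.items()
    }


def iterations_frame(results: Mapping[str, SimulationResult]) -> pd.DataFrame:
    """Long-form per-iteration export: scenario, stratum, iteration, cost."""
    frames = []
    for scenario, result in results.items():
        for stratum, values in (
            ("basic", result.basic_costs), ("advanced", result.advanced_costs)
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "scenario": scenario,
                        "stratum": stratum,
                        "iteration": np.arange(result.iterations),
                        "cost_usd": np.round(values, 2),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
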