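"""Model/Results interface for the per-visit cost analysis.

:class:`MIHCostModel` wraps a validated program configuration;
``fit()`` runs the Monte Carlo simulation (full and unreimbursed
scenarios under common random numbers) and returns
:class:`MIHCostResults`, which carries the per-iteration cost vectors,
their probabilistic summaries, and presentation helpers
(``summary()``, ``summary_frame()``, benchmark comparison, histogram
export, plotting).

Example
-------
>>> from mihcost import MIHCostModel
>>> from mihcost.synthetic import program_template
>>> res = MIHCostModel(program_template()).fit(seed=1)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import reporting
from .config import ProgramConfig, config_digest, load_config
from .simulation import (
    CostSummary,
    SimulationResult,
    run_scenario_results,
    summarize,
)

__all__ = ["MIHCostModel", "MIHCostResults"]

_SCENARIO_LABEL = {"full": "Full cost", "unreimbursed": "Unreimbursed cost"}


class MIHCostModel:
    """Probabilistic per-visit cost model of an MIH program.

    Parameters
    ----------
    config : ProgramConfig
        Validated cost structure, visit mix and simulation settings.
    """

    def __init__(self, config: ProgramConfig):
        self.config = config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MIHCostModel":
        """Build a model from a YAML/JSON configuration file."""
        return cls(load_config(path))

    @classmethod
    def from_template(cls, seed: int = 1) -> "MIHCostModel":
        """Build a model from the packaged synthetic program template."""
        from .synthetic import program_template

        return cls(program_template(seed))

    @property
    def digest(self) -> str:
        return config_digest(self.config)

    def fit(
        self,
        iterations: int | None = None,
        seed: int | None = None,
        level: float | None = None,
    ) -> "MIHCostResults":
        """Run the Monte Carlo simulation for both scenarios.

        ``iterations``/``seed``/``level`` default to the configuration's
        simulation settings (1,000 iterations, 90% interval).
        """
        if level is None:
            level = self.config.simulation.interval_level
        results = run_scenario_results(self.config, iterations, seed)
        summaries = {
            name: summarize(result, level) for name, result in results.items()
        }
        return MIHCostResults(self, results, summaries, level)


class MIHCostResults:
    """Fitted simulation results for the full and unreimbursed scenarios."""

    def __init__(
        self,
        model: MIHCostModel,
        results: Mapping[str, SimulationResult],
        summaries: Mapping[str, tuple[CostSummary, CostSummary]],
        level: float,
    ):
        self.model = model
        self.results = dict(results)
        self.summaries = dict(summaries)
        self.level = level

    def summary_for(self, scenario: str = "full", stratum: str = "basic") -> CostSummary:
        basic, advanced = self.summaries[scenario]
        return basic if stratum == "basic" else advanced

    def summary_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per (scenario, stratum) with all summary stats."""
        rows = []
        for scenario, (basic, advanced) in self.summaries.items():
            for stratum, s in (("basic", basic), ("advanced", advanced)):
                rows.append(
                    {
                        "scenario": scenario,
                        "stratum": stratum,
                        "median": s.median,
                        "mean": s.mean,
                        "interval_low": s.interval_low,
                        "interval_high": s.interval_high,
                        "sd": s.sd,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable results table (whole dollars)."""
        any_result = next(iter(self.results.values()))
        pct = int(round(self.level * 100))
        lines = [
            "Per-visit cost of mobile integrated health acute care",
            "=" * 68,
            f"Iterations: {any_result.iterations}    Seed: {any_result.seed}"
            f"    Config: {self.model.digest}",
            f"Interval: {pct}% percentile interval of simulated costs",
            "-" * 68,
            f"{'Scenario':<20}{'Stratum':<10}{'Median':>9}{'Mean':>9}"
            f"{'  ' + str(pct) + '% interval':>18}",
            "-" * 68,
        ]
        for scenario, (basic, advanced) in self.summaries.items():
            for stratum, s in (("basic", basic), ("advanced", advanced)):
                interval = f"[{s.interval_low:,.0f}, {s.interval_high:,.0f}]"
                lines.append(
                    f"{_SCENARIO_LABEL.get(scenario, scenario):<20}{stratum:<10}"
                    f"{s.median:>9,.0f}{s.mean:>9,.0f}{interval:>18}"
                )
        lines.append("-" * 68)
        return "\n".join(lines)

    def compare_benchmarks(
        self,
        benchmarks: reporting.BenchmarkSet = reporting.DEFAULT_BENCHMARKS,
        scenario: str = "full",
        stratum: str = "basic",
    ) -> pd.DataFrame:
        return reporting.compare_benchmarks(
            self.summary_for(scenario, stratum), benchmarks
        )

    def histogram(self, bins: int = 30, scenario: str = "full") -> pd.DataFrame:
        return reporting.export_histogram(self.results[scenario], bins)

    def iterations_frame(self) -> pd.DataFrame:
        return reporting.iterations_frame(self.results)

    def to_dict(self) -> dict:
        any_result = next(iter(self.results.values()))
        return {
            "config_digest": self.model.digest,
            "seed": any_result.seed,
            "iterations": any_result.iterations,
            "interval_level": self.level,
            "scenarios": reporting.summaries_to_dict(self.summaries),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def plot(self, bins: int = 30, scenario: str = "full", ax=None):
        """Overlaid basic/advanced cost histograms (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        result = self.results[scenario]
        for stratum, values in (
            ("basic", result.basic_costs), ("advanced", result.advanced_costs)
        ):
            values = np.asarray(values)
            ax.hist(values[~np.isnan(values)], bins=bins, alpha=0.6, label=stratum)
        ax.set_xlabel("Cost per visit (USD)")
        ax.set_ylabel("Iterations")
        ax.set_title(f"Simulated per-visit cost ({_SCENARIO_LABEL.get(scenario, scenario)})")
        ax.legend()
        return ax
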