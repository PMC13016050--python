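"""Deterministic cost-allocation arithmetic for one realization.

Given one sampled value per cost element and a visit split, this module
computes the per-visit cost of basic and advanced encounters:

1. the fixed-cost pool is summed and allocated across strata
   proportionally to (weight x visit count) — with the default unit
   weights this is pure count-proportional allocation, so the per-visit
   fixed share is identical for the two strata;
2. per-visit variable costs accumulate as unit cost x stratum volume;
   per-period variable costs (fuel, vehicle maintenance) scale with
   operations rather than individual encounters and are split across
   strata by the same allocation rule as fixed costs, but stay in the
   variable totals;
3. per-visit cost = (fixed share + variable total) / visit count,
   per stratum.

Every function accepts scalars or equal-length numpy arrays (one entry
per Monte Carlo iteration); the simulation engine relies on the
vectorized path, while the scalar path is the hand-checkable oracle.
Currency is binary floating point throughout; rounding to cents happens
only at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import ProgramConfig

__all__ = [
    "CostRealization",
    "PerVisitCosts",
    "split_visits",
    "allocate_fixed",
    "variable_totals",
    "per_visit_cost",
]


@dataclass(frozen=True)
class CostRealization:
    """Sampled element values plus the realized visit split.

    ``element_values`` maps element id -> sampled USD amount (scalar or
    per-iteration array).  Visit counts are non-negative with
    ``n_basic + n_advanced >= 1``.
    """

    element_values: Mapping[str, float | np.ndarray]
    n_basic: int | np.ndarray
    n_advanced: int | np.ndarray


@dataclass(frozen=True)
class PerVisitCosts:
    """Per-visit cost decomposition for one (vector of) realization(s).

    A stratum with zero visits reports NaN for its per-visit cost; its
    fixed share and variable totals are zero.
    """

    basic: float | np.ndarray
    advanced: float | np.ndarray
    fixed_share_basic: float | np.ndarray
    fixed_share_advanced: float | np.ndarray
    variable_total_basic: float | np.ndarray
    variable_total_advanced: float | np.ndarray


def split_visits(total, prop_basic):
    """Split a total visit count into (n_basic, n_advanced).

    ``n_basic = round(total * prop_basic)`` with round-half-to-even;
    the remainder goes to advanced, so the counts always sum to the
    total.  ``total`` must be >= 1 (element-wise).
    """
    total_arr = np.asarray(total)
    if np.any(total_arr < 1):
        raise ValueError("total visit count must be >= 1")
    if np.any((np.asarray(prop_basic) < 0) | (np.asarray(prop_basic) > 1)):
        raise ValueError("prop_basic must lie in [0, 1]")
    n_basic = np.rint(total_arr * prop_basic).astype(np.int64)
    n_advanced = total_arr.astype(np.int64) - n_basic
    if np.ndim(total) == 0:
        return int(n_basic), int(n_advanced)
    return n_basic, n_advanced


def allocate_fixed(total_fixed, n_basic, n_advanced, *,
                   weight_basic: float = 1.0, weight_advanced: float = 1.0):
    """Allocate the fixed-cost pool across strata.

    Shares are proportional to ``weight * count``; the advanced share is
    computed by subtraction so the two shares sum to ``total_fixed``
    exactly.  With unit weights this is count-proportional allocation.
    """
    nb = np.asarray(n_basic, dtype=float)
    na = np.asarray(n_advanced, dtype=float)
    if np.any(nb + na < 1):
        raise ValueError("at least one visit is required to allocate costs")
    wb = nb * weight_basic
    wa = na * weight_advanced
    share_basic = np.asarray(total_fixed, dtype=float) * wb / (wb + wa)
    share_advanced = np.asarray(total_fixed, dtype=float) - share_basic
    if np.ndim(total_fixed) == 0 and np.ndim(n_basic) == 0:
        return float(share_basic), float(share_advanced)
    return share_basic, share_advanced


def _value_for(realization: CostRealization, element_id: str):
    try:
        return realization.element_values[element_id]
    except KeyError:
        raise KeyError(
            f"realization is missing a sampled value for element '{element_id}'"
        ) from None


def variable_totals(realization: CostRealization, config: ProgramConfig):
    """Accumulate variable costs into per-stratum totals.

    Per-visit elements contribute ``value * n_visits`` to each stratum
    they apply to; per-period variable elements are split like fixed
    costs but remain in the variable totals.
    """
    nb = np.asarray(realization.n_basic, dtype=float)
    na = np.asarray(realization.n_advanced, dtype=float)
    total_basic = np.zeros(np.broadcast(nb, na).shape)
    total_advanced = np.zeros_like(total_basic)
    for e in config.variable_elements:
        value = np.asarray(_value_for(realization, e.id), dtype=float)
        if e.basis == "per_visit":
            if e.applicability in ("all", "basic_only"):
                total_basic = total_basic + value * nb
            if e.applicability in ("all", "advanced_only"):
                total_advanced = total_advanced + value * na
        else:  # per_period: split across strata like the fixed pool
            sb, sa = allocate_fixed(
                value, nb, na,
                weight_basic=config.weight_basic,
                weight_advanced=config.weight_advanced,
            )
            total_basic = total_basic + sb
            total_advanced = total_advanced + sa
    if np.ndim(realization.n_basic) == 0:
        return float(total_basic), float(total_advanced)
    return total_basic, total_advanced


def per_visit_cost(realization: CostRealization, config: ProgramConfig) -> PerVisitCosts:
    """Per-visit cost of basic and advanced encounters for one realization.

    Fixed and variable costs are summed per stratum and divided by the
    stratum's visit count.  A stratum with zero visits reports NaN
    rather than dividing by zero; both strata empty is an error.
    """
    nb = np.asarray(realization.n_basic, dtype=float)
    na = np.asarray(realization.n_advanced, dtype=float)
    if np.any(nb + na < 1):
        raise ValueError("at least one visit is required")
    if np.any(nb < 0) or np.any(na < 0):
        raise ValueError("visit counts must be non-negative")

    total_fixed = np.zeros(np.broadcast(nb, na).shape)
    for e in config.fixed_elements:
        total_fixed = total_fixed + np.asarray(_value_for(realization, e.id), dtype=float)

    fixed_b, fixed_a = allocate_fixed(
        total_fixed, nb, na,
        weight_basic=config.weight_basic,
        weight_advanced=config.weight_advanced,
    )
    var_b, var_a = variable_totals(realization, config)

    with np.errstate(divide="ignore", invalid="ignore"):
        basic = np.where(nb > 0, (np.asarray(fixed_b) + np.asarray(var_b)) / nb, np.nan)
        advanced = np.where(na > 0, (np.asarray(fixed_a) + np.asarray(var_a)) / na, np.nan)

    if np.ndim(realization.n_basic) == 0:
        return PerVisitCosts(
            basic=float(basic), advanced=float(advanced),
            fixed_share_basic=float(np.asarray(fixed_b)),
            fixed_share_advanced=float(np.asarray(fixed_a)),
            variable_total_basic=float(np.asarray(var_b)),
            variable_total_advanced=float(np.asarray(var_a)),
        )
    return PerVisitCosts(
        basic=basic, advanced=advanced,
        fixed_share_basic=np.asarray(fixed_b),
        fixed_share_advanced=np.asarray(fixed_a),
        variable_total_basic=np.asarray(var_b),
        variable_total_advanced=np.asarray(var_a),
    )
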