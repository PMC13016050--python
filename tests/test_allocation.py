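"""Allocation arithmetic: visit splits, fixed pooling, per-visit costs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mihcost.allocation import (
    CostRealization,
    allocate_fixed,
    per_visit_cost,
    split_visits,
    variable_totals,
)

from conftest import element, make_config, point


@pytest.mark.parametrize(
    ("total", "prop", "expected"),
    [
        ((800), 0.6, (480, 320)),
        (1, 1.0, (1, 0)),
        (1, 0.0, (0, 1)),
        (799, 0.6, (479, 320)),  # 479.4 rounds down
        (5, 0.5, (2, 3)),        # 2.5 rounds half-to-even
    ],
)
def test_split_visits_examples(total, prop, expected):
    assert split_visits(total, prop) == expected


def test_split_visits_enumeration():
    """Counts sum to the total and follow round-half-even for all totals."""
    for total in range(1, 1001):
        nb, na = split_visits(total, 0.6)
        assert nb + na == total
        assert nb == round(total * 0.6)  # Python round is half-to-even


def test_split_visits_rejects_bad_arguments():
    with pytest.raises(ValueError):
        split_visits(0, 0.5)
    with pytest.raises(ValueError):
        split_visits(10, 1.5)


@pytest.mark.parametrize(
    ("total_fixed", "nb", "na", "expected"),
    [
        (100_000.0, 480, 320, (60_000.0, 40_000.0)),
        (0.0, 480, 320, (0.0, 0.0)),
        (100_000.0, 800, 0, (100_000.0, 0.0)),
    ],
)
def test_allocate_fixed_examples(total_fixed, nb, na, expected):
    assert allocate_fixed(total_fixed, nb, na) == pytest.approx(expected)


def test_allocate_fixed_shares_sum_exactly():
    sb, sa = allocate_fixed(12345.678, 13, 7)
    assert sb + sa == 12345.678  # advanced share by subtraction, exact


def test_allocate_fixed_rejects_empty_program():
    with pytest.raises(ValueError):
        allocate_fixed(100.0, 0, 0)


def test_allocate_fixed_with_weights():
    # advanced visits weighted 3x: shares proportional to weight*count
    sb, sa = allocate_fixed(1000.0, 50, 50, weight_basic=1.0, weight_advanced=3.0)
    assert sb == pytest.approx(250.0)
    assert sa == pytest.approx(750.0)


def test_variable_totals_examples():
    config = make_config(
        [
            element("fixed_pool", "fixed", "per_period", "all"),
            element("all_elem", applicability="all"),
            element("basic_elem", applicability="basic_only"),
        ]
    )
    real = CostRealization(
        {"all_elem": 10.0, "basic_elem": 5.0, "fixed_pool": 0.0}, 480, 320
    )
    assert variable_totals(real, config) == pytest.approx((480 * 15.0, 320 * 10.0))

    config_adv = make_config(
        [
            element("fixed_pool", "fixed", "per_period", "all"),
            element("adv_elem", applicability="advanced_only"),
        ]
    )
    real_adv = CostRealization({"adv_elem": 120.0, "fixed_pool": 0.0}, 480, 320)
    assert variable_totals(real_adv, config_adv) == pytest.approx((0.0, 38_400.0))


def test_per_period_variable_split_like_fixed():
    config = make_config(
        [
            element("fixed_pool", "fixed", "per_period", "all"),
            element("fuel", "variable", "per_period", "all"),
        ]
    )
    real = CostRealization({"fixed_pool": 0.0, "fuel": 1000.0}, 480, 320)
    vb, va = variable_totals(real, config)
    assert (vb, va) == pytest.approx((600.0, 400.0))


def test_missing_sampled_value_names_element():
    config = make_config(
        [
            element("fixed_pool", "fixed", "per_period", "all"),
            element("meds"),
        ]
    )
    real = CostRealization({"fixed_pool": 1.0}, 480, 320)
    with pytest.raises(KeyError, match="meds"):
        variable_totals(real, config)


def test_per_visit_cost_hand_example(point_mass_config):
    real = CostRealization(
        {"fixed_pool": 100_000.0, "basic_var": 50.0, "advanced_var": 200.0},
        480, 320,
    )
    costs = per_visit_cost(real, point_mass_config)
    assert costs.basic == pytest.approx(175.0)
    assert costs.advanced == pytest.approx(325.0)
    # count-proportional allocation: identical per-visit fixed share
    assert costs.fixed_share_basic / 480 == pytest.approx(costs.fixed_share_advanced / 320)


def test_fixed_only_identity(point_mass_config):
    real = CostRealization(
        {"fixed_pool": 80_000.0, "basic_var": 0.0, "advanced_var": 0.0}, 480, 320
    )
    costs = per_visit_cost(real, point_mass_config)
    assert costs.basic == pytest.approx(100.0)
    assert costs.advanced == pytest.approx(100.0)


def test_homogeneity_degree_one(point_mass_config):
    base = CostRealization(
        {"fixed_pool": 100_000.0, "basic_var": 50.0, "advanced_var": 200.0},
        480, 320,
    )
    doubled = CostRealization(
        {k: 2 * v for k, v in base.element_values.items()}, 480, 320
    )
    c1 = per_visit_cost(base, point_mass_config)
    c2 = per_visit_cost(doubled, point_mass_config)
    assert c2.basic == pytest.approx(2 * c1.basic)
    assert c2.advanced == pytest.approx(2 * c1.advanced)


def test_zero_visit_stratum_reports_nan(point_mass_config):
    real = CostRealization(
        {"fixed_pool": 1000.0, "basic_var": 5.0, "advanced_var": 7.0}, 10, 0
    )
    costs = per_visit_cost(real, point_mass_config)
    assert math.isnan(costs.advanced)
    assert costs.basic == pytest.approx(100.0 + 5.0)
    with pytest.raises(ValueError):
        per_visit_cost(
            CostRealization({"fixed_pool": 1.0, "basic_var": 0.0,
                             "advanced_var": 0.0}, 0, 0),
            point_mass_config,
        )


def test_vectorized_path_matches_scalar(point_mass_config):
    rng = np.random.default_rng(7)
    n = 50
    values = {
        "fixed_pool": rng.uniform(1e4, 2e5, n),
        "basic_var": rng.uniform(0, 100, n),
        "advanced_var": rng.uniform(0, 400, n),
    }
    nb = rng.integers(1, 500, n)
    na = rng.integers(1, 500, n)
    vec = per_visit_cost(CostRealization(values, nb, na), point_mass_config)
    for i in range(n):
        scalar = per_visit_cost(
            CostRealization({k: float(v[i]) for k, v in values.items()},
                            int(nb[i]), int(na[i])),
            point_mass_config,
        )
        assert vec.basic[i] == pytest.approx(scalar.basic, rel=1e-12)
        assert vec.advanced[i] == pytest.approx(scalar.advanced, rel=1e-12)


def _spreadsheet_oracle(values, config, nb, na):
    """Independent brute-force recomputation, spreadsheet style."""
    fixed_total = sum(values[e.id] for e in config.elements
                      if e.classification == "fixed")
    rows_basic = fixed_total * nb / (nb + na)
    rows_adv = fixed_total - rows_basic
    for e in config.elements:
        if e.classification != "variable":
            continue
        v = values[e.id]
        if e.basis == "per_period":
            rows_basic += v * nb / (nb + na)
            rows_adv += v * na / (nb + na)
        else:
            if e.applicability in ("all", "basic_only"):
                rows_basic += v * nb
            if e.applicability in ("all", "advanced_only"):
                rows_adv += v * na
    return rows_basic / nb if nb else float("nan"), rows_adv / na if na else float("nan")


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    fixed=st.floats(0, 1e6),
    fuel=st.floats(0, 1e5),
    v_all=st.floats(0, 500),
    v_adv=st.floats(0, 500),
    nb=st.integers(1, 2000),
    na=st.integers(1, 2000),
)
def test_oracle_equivalence_small_configs(fixed, fuel, v_all, v_adv, nb, na):
    """Point-mass configs of <= 4 elements match the spreadsheet oracle."""
    config = make_config(
        [
            element("fixed_pool", "fixed", "per_period", "all", pert=point(fixed)),
            element("fuel", "variable", "per_period", "all", pert=point(fuel)),
            element("v_all", applicability="all", pert=point(v_all)),
            element("v_adv", applicability="advanced_only", pert=point(v_adv)),
        ]
    )
    values = {"fixed_pool": fixed, "fuel": fuel, "v_all": v_all, "v_adv": v_adv}
    costs = per_visit_cost(CostRealization(values, nb, na), config)
    oracle_b, oracle_a = _spreadsheet_oracle(values, config, nb, na)
    assert costs.basic == pytest.approx(oracle_b, rel=1e-9, abs=1e-9)
    assert costs.advanced == pytest.approx(oracle_a, rel=1e-9, abs=1e-9)
    # conservation: stratum totals recover the whole sampled cost
    total = fixed + fuel + v_all * (nb + na) + v_adv * na
    recovered = costs.basic * nb + costs.advanced * na
    assert recovered == pytest.approx(total, rel=1e-9, abs=1e-6)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    bump=st.sampled_from(["fixed_pool", "basic_var", "advanced_var"]),
    delta=st.floats(0.1, 1e4),
)
def test_monotonicity_in_element_values(bump, delta):
    """Raising any element value never lowers either stratum's cost and
    strictly raises the strata it applies to."""
    point_mass_config = make_config(
        [
            element("fixed_pool", "fixed", "per_period", "all", pert=point(100_000)),
            element("basic_var", applicability="basic_only", pert=point(50.0)),
            element("advanced_var", applicability="advanced_only", pert=point(200.0)),
        ]
    )
    base_values = {"fixed_pool": 50_000.0, "basic_var": 40.0, "advanced_var": 90.0}
    bumped = dict(base_values)
    bumped[bump] += delta
    c0 = per_visit_cost(CostRealization(base_values, 480, 320), point_mass_config)
    c1 = per_visit_cost(CostRealization(bumped, 480, 320), point_mass_config)
    assert c1.basic >= c0.basic and c1.advanced >= c0.advanced
    if bump in ("fixed_pool", "basic_var"):
        assert c1.basic > c0.basic
    if bump in ("fixed_pool", "advanced_var"):
        assert c1.advanced > c0.advanced
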