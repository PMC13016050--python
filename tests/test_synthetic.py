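"""Synthetic encounters, config generation and calibration."""

import numpy as np
import pytest

from mihcost.config import classify_visit
from mihcost.synthetic import (
    AdvancedUtilization,
    BasicUtilization,
    GeneratorSettings,
    calibrate_config,
    encounters_to_utilization,
    generate_config,
    generate_encounters,
    read_encounters_csv,
    program_template,
    write_encounters_csv,
)


def test_generated_records_match_their_stratum_definition():
    records = generate_encounters(GeneratorSettings(seed=1, n_encounters=500))
    for r in records:
        stratum = classify_visit(r)
        if stratum == "basic":
            assert r.iv_therapies == 0
            assert int(r.lab_panels > 0) + int(r.radiology_studies > 0) <= 1
        else:
            assert (r.iv_therapies >= 1
                    or (r.lab_panels > 0 and r.radiology_studies > 0))


def test_complexity_mix_matches_target():
    n = 10_000
    records = generate_encounters(GeneratorSettings(seed=3, n_encounters=n))
    frac = np.mean([classify_visit(r) == "basic" for r in records])
    assert abs(frac - 0.60) < 3 * np.sqrt(0.6 * 0.4 / n)


def test_all_basic_boundary():
    records = generate_encounters(
        GeneratorSettings(seed=2, n_encounters=200, prop_basic_target=1.0)
    )
    assert all(classify_visit(r) == "basic" for r in records)


def test_generation_is_seeded():
    a = generate_encounters(GeneratorSettings(seed=9, n_encounters=50))
    b = generate_encounters(GeneratorSettings(seed=9, n_encounters=50))
    assert a == b


def test_infeasible_settings_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        GeneratorSettings(advanced=AdvancedUtilization(p_iv=0.0, p_both_modalities=0.0))
    with pytest.raises(ValueError, match="one diagnostic modality"):
        GeneratorSettings(basic=BasicUtilization(p_lab=0.7, p_radiology=0.7))
    with pytest.raises(ValueError):
        GeneratorSettings(n_encounters=0)


def test_utilization_summary_hand_example():
    records = generate_encounters(GeneratorSettings(seed=4, n_encounters=40))
    # hand example: 2 basic records with 1 and 0 lab panels
    two = [r for r in records if classify_visit(r) == "basic"][:2]
    from dataclasses import replace

    two = [replace(two[0], lab_panels=1, radiology_studies=0),
           replace(two[1], lab_panels=0, radiology_studies=0)]
    table = encounters_to_utilization(two)
    assert table.loc["basic", "visits"] == 2
    assert table.loc["basic", "mean_lab_panels"] == pytest.approx(0.5)
    assert table.loc["advanced", "visits"] == 0
    assert np.isnan(table.loc["advanced", "mean_lab_panels"])
    # partition: stratum counts sum to the number of records
    full = encounters_to_utilization(records)
    assert int(full["visits"].sum()) == len(records)
    with pytest.raises(ValueError):
        encounters_to_utilization([])


def test_encounter_csv_roundtrip(tmp_path):
    records = generate_encounters(GeneratorSettings(seed=5, n_encounters=30))
    path = tmp_path / "encounters.csv"
    write_encounters_csv(records, path)
    assert read_encounters_csv(path) == records


def test_generate_config_scaling(template):
    identity = generate_config(GeneratorSettings(seed=0), template)
    assert identity.elements == template.elements
    assert identity.visit_mix.annual_visits == template.visit_mix.annual_visits

    scaled = generate_config(
        GeneratorSettings(seed=0, cost_scale={"personnel_paramedics": 2.0}),
        template,
    )
    orig = template.element("personnel_paramedics").pert
    new = scaled.element("personnel_paramedics").pert
    assert (new.minimum, new.most_likely, new.maximum) == (
        2 * orig.minimum, 2 * orig.most_likely, 2 * orig.maximum
    )
    others = [e for e in scaled.elements if e.id != "personnel_paramedics"]
    assert tuple(others) == tuple(
        e for e in template.elements if e.id != "personnel_paramedics"
    )
    with pytest.raises(ValueError, match="unknown"):
        generate_config(GeneratorSettings(seed=0, cost_scale={"nope": 2.0}), template)


def test_generate_config_sets_visit_mix(template):
    config = generate_config(
        GeneratorSettings(seed=0, n_encounters=400, prop_basic_target=0.7),
        template,
    )
    assert config.visit_mix.annual_visits.most_likely == pytest.approx(400)
    assert config.visit_mix.prop_basic == pytest.approx(0.7)


def test_calibration_fixed_point(template):
    """Targets equal to the template's own medians converge immediately
    with unit scales."""
    from mihcost.simulation import run_simulation

    result = run_simulation(template, iterations=500, seed=1)
    targets = {
        "basic_median": float(np.median(result.basic_costs)),
        "advanced_median": float(np.median(result.advanced_costs)),
    }
    cal = calibrate_config(template, targets, tolerance=0.02,
                           iterations=500, seed=1)
    assert cal.converged
    assert (cal.scale_fixed, cal.scale_basic, cal.scale_advanced) == (1.0, 1.0, 1.0)
    assert cal.evaluations <= 2


def test_calibration_is_deterministic(template):
    targets = {"basic_median": 550.0, "advanced_median": 1400.0}
    a = calibrate_config(program_template(), targets, iterations=400, seed=1)
    b = calibrate_config(program_template(), targets, iterations=400, seed=1)
    assert a.config == b.config
    assert (a.scale_fixed, a.scale_basic, a.scale_advanced) == (
        b.scale_fixed, b.scale_basic, b.scale_advanced
    )


def test_calibration_homogeneity(template):
    """Doubling both targets roughly doubles the fixed-pool scale
    (degree-1 homogeneity of the allocation)."""
    targets = {"basic_median": 550.0, "advanced_median": 1400.0}
    one = calibrate_config(template, targets, iterations=400, seed=1)
    two = calibrate_config(
        template,
        {k: 2 * v for k, v in targets.items()},
        iterations=400, seed=1,
    )
    assert two.converged
    assert two.scale_fixed == pytest.approx(2 * one.scale_fixed, rel=0.15)
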