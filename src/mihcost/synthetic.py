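"""Synthetic program data: encounters, configuration templates, calibration.

The study program's actual dollar inputs are not public, so this module
provides three stand-ins that are explicitly labeled synthetic:

* an encounter-level generator producing home-visit records with the
  program's observed complexity mix (60% basic / 40% advanced), built
  constraint-first: each record's stratum is drawn first and its
  service usage (lab panels, radiology studies, IV therapies, oral
  medications) is then sampled *within* that stratum's defining
  constraints, so :func:`mihcost.config.classify_visit` recovers the
  generating stratum by construction;
* a structurally faithful configuration template with the full cost
  taxonomy (personnel at 6.5/1.0/0.5 FTE, administrative costs, durable
  clinical equipment, fuel, vehicle maintenance, laboratory analysis,
  radiology, medications/supplies) whose dollar ranges are placeholder
  orders of magnitude, not the study's data;
* a deterministic calibration utility that rescales the template's
  fixed pool and per-stratum variable costs until the simulated medians
  hit user-supplied targets, producing a demonstration fixture that is
  a *reconstruction*, not the original inputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ProgramConfig, SimulationSettings, VisitMix, classify_visit
from .config import CostElement
from .distributions import PertParams
from .simulation import run_simulation

__all__ = [
    "EncounterRecord",
    "BasicUtilization",
    "AdvancedUtilization",
    "GeneratorSettings",
    "generate_encounters",
    "encounters_to_utilization",
    "write_encounters_csv",
    "read_encounters_csv",
    "program_template",
    "template_path",
    "generate_config",
    "CalibrationResult",
    "calibrate_config",
]

ENCOUNTER_CSV_FIELDS = (
    "encounter_id",
    "lab_panels",
    "radiology_studies",
    "iv_therapies",
    "oral_medications",
    "new_prescription",
)


@dataclass(frozen=True)
class EncounterRecord:
    """One synthetic home visit with its service utilization counts."""

    encounter_id: str
    lab_panels: int
    radiology_studies: int
    iv_therapies: int
    oral_medications: int
    new_prescription: bool

    def __post_init__(self) -> None:
        for name in ("lab_panels", "radiology_studies", "iv_therapies",
                     "oral_medications"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class BasicUtilization:
    """Service-usage rates for basic visits (at most one diagnostic
    modality, no IV).  ``p_lab`` and ``p_radiology`` are the mutually
    exclusive probabilities of using that single modality; the
    remainder is a no-diagnostic visit (evaluation + referral only).
    Rates are placeholders: the study does not publish per-visit
    utilization."""

    p_lab: float = 0.45
    p_radiology: float = 0.25
    extra_lab_panels: float = 0.3
    oral_medication_rate: float = 0.9
    p_new_prescription: float = 0.5

    def validate(self) -> None:
        for name in ("p_lab", "p_radiology", "p_new_prescription"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"basic.{name} must be in [0, 1], got {v}")
        if self.p_lab + self.p_radiology > 1.0 + 1e-12:
            raise ValueError(
                "basic visits use at most one diagnostic modality: "
                "p_lab + p_radiology must not exceed 1"
            )
        if self.extra_lab_panels < 0 or self.oral_medication_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class AdvancedUtilization:
    """Service-usage rates for advanced visits (two or more diagnostic
    modalities and/or any IV therapy).  When a sampled record draws
    neither IV therapy nor both modalities, both modalities are forced
    so the record still satisfies the advanced definition; settings
    with ``p_iv == 0`` and ``p_both_modalities == 0`` are rejected as
    infeasible."""

    p_iv: float = 0.70
    p_both_modalities: float = 0.80
    extra_iv_units: float = 0.4
    extra_lab_panels: float = 0.3
    extra_radiology: float = 0.1
    p_single_lab: float = 0.6
    p_single_radiology: float = 0.3
    oral_medication_rate: float = 0.9
    p_new_prescription: float = 0.6

    def validate(self) -> None:
        for name in ("p_iv", "p_both_modalities", "p_single_lab",
                     "p_single_radiology", "p_new_prescription"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"advanced.{name} must be in [0, 1], got {v}")
        if self.p_iv == 0.0 and self.p_both_modalities == 0.0:
            raise ValueError(
                "infeasible advanced utilization: at least one of p_iv and "
                "p_both_modalities must be positive"
            )
        if self.p_single_lab + self.p_single_radiology > 1.0 + 1e-12:
            raise ValueError("p_single_lab + p_single_radiology must not exceed 1")


@dataclass(frozen=True)
class GeneratorSettings:
    """Settings for the synthetic encounter/config generator."""

    seed: int = 0
    n_encounters: int = 800
    prop_basic_target: float = 0.60
    basic: BasicUtilization = field(default_factory=BasicUtilization)
    advanced: AdvancedUtilization = field(default_factory=AdvancedUtilization)
    cost_scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        if not 0.0 <= self.prop_basic_target <= 1.0:
            raise ValueError("prop_basic_target must be in [0, 1]")
        self.basic.validate()
        self.advanced.validate()
        for k, v in self.cost_scale.items():
            if not v > 0:
                raise ValueError(f"cost_scale['{k}'] must be positive")


def _sample_basic(rng: np.random.Generator, u: BasicUtilization) -> dict:
    r = rng.random()
    labs = rads = 0
    if r < u.p_lab:
        labs = 1 + int(rng.poisson(u.extra_lab_panels))
    elif r < u.p_lab + u.p_radiology:
        rads = 1
    return {
        "lab_panels": labs,
        "radiology_studies": rads,
        "iv_therapies": 0,
        "oral_medications": int(rng.poisson(u.oral_medication_rate)),
        "new_prescription": bool(rng.random() < u.p_new_prescription),
    }


def _sample_advanced(rng: np.random.Generator, u: AdvancedUtilization) -> dict:
    ivs = (1 + int(rng.poisson(u.extra_iv_units))) if rng.random() < u.p_iv else 0
    both = rng.random() < u.p_both_modalities
    if ivs == 0 and not both:
        both = True  # enforce the advanced definition
    if both:
        labs = 1 + int(rng.poisson(u.extra_lab_panels))
        rads = 1 + int(rng.poisson(u.extra_radiology))
    else:
        r = rng.random()
        if r < u.p_single_lab:
            labs, rads = 1 + int(rng.poisson(u.extra_lab_panels)), 0
        elif r < u.p_single_lab + u.p_single_radiology:
            labs, rads = 0, 1
        else:
            labs = rads = 0
    return {
        "lab_panels": labs,
        "radiology_studies": rads,
        "iv_therapies": ivs,
        "oral_medications": int(rng.poisson(u.oral_medication_rate)),
        "new_prescription": bool(rng.random() < u.p_new_prescription),
    }


def generate_encounters(settings: GeneratorSettings) -> list[EncounterRecord]:
    """Generate seeded encounter records with the target complexity mix.

    Each record's stratum is drawn first (basic with probability
    ``prop_basic_target``) and services are sampled within that
    stratum's constraints, so ``classify_visit`` recovers the drawn
    stratum for every record.
    """
    rng = np.random.default_rng(settings.seed)
    records: list[EncounterRecord] = []
    for i in range(settings.n_encounters):
        is_basic = rng.random() < settings.prop_basic_target
        fields = (
            _sample_basic(rng, settings.basic)
            if is_basic
            else _sample_advanced(rng, settings.advanced)
        )
        rec = EncounterRecord(encounter_id=f"E{i + 1:05d}", **fields)
        assert classify_visit(rec) == ("basic" if is_basic else "advanced")
        records.append(rec)
    return records


def encounters_to_utilization(records: Sequence[EncounterRecord]) -> pd.DataFrame:
    """Per-stratum visit counts and mean service units per visit.

    Returns a frame indexed by stratum (``basic``, ``advanced``) with a
    ``visits`` count and mean lab/radiology/IV/oral-medication units,
    ready to be turned into per-visit variable cost elements
    (unit cost x mean units).  Empty strata report 0 visits and NaN
    means.
    """
    if len(records) == 0:
        raise ValueError("cannot compute utilization from zero encounters")
    frame = pd.DataFrame(
        {
            "stratum": [classify_visit(r) for r in records],
            "lab_panels": [r.lab_panels for r in records],
            "radiology_studies": [r.radiology_studies for r in records],
            "iv_therapies": [r.iv_therapies for r in records],
            "oral_medications": [r.oral_medications for r in records],
        }
    )
    grouped = frame.groupby("stratum").agg(
        visits=("stratum", "size"),
        mean_lab_panels=("lab_panels", "mean"),
        mean_radiology_studies=("radiology_studies", "mean"),
        mean_iv_therapies=("iv_therapies", "mean"),
        mean_oral_medications=("oral_medications", "mean"),
    )
    out = grouped.reindex(["basic", "advanced"])
    out["visits"] = out["visits"].fillna(0).astype(int)
    return out


def write_encounters_csv(records: Iterable[EncounterRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ENCOUNTER_CSV_FIELDS)
        for r in records:
            writer.writerow(
                [r.encounter_id, r.lab_panels, r.radiology_studies,
                 r.iv_therapies, r.oral_medications, int(r.new_prescription)]
            )


def read_encounters_csv(path: str | Path) -> list[EncounterRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                EncounterRecord(
                    encounter_id=row["encounter_id"],
                    lab_panels=int(row["lab_panels"]),
                    radiology_studies=int(row["radiology_studies"]),
                    iv_therapies=int(row["iv_therapies"]),
                    oral_medications=int(row["oral_medications"]),
                    new_prescription=bool(int(row["new_prescription"])),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Configuration template and calibration


def _pert(a: float, m: float, b: float) -> PertParams:
    return PertParams(a, m, b)


def template_path() -> Path:
    """Path to the packaged YAML copy of the program template."""
    from importlib.resources import files

    return Path(str(files("mihcost") / "data" / "program_template.yaml"))


def program_template(seed: int = 1) -> ProgramConfig:
    """The packaged program-structure template (synthetic dollar ranges).

    Mirrors the full cost taxonomy of an acute-care MIH program —
    personnel (6.5 FTE paramedics, 1.0 FTE administrator, 0.5 FTE
    physician medical direction), administrative costs, non-disposable
    clinical equipment, fuel, vehicle maintenance, laboratory analysis
    and radiology (both payor-reimbursed), and medications/supplies —
    with ~800 annual visits split 60% basic / 40% advanced.  All dollar
    ranges are placeholder orders of magnitude (public salary and
    equipment figures), not the study program's data; calibrate with
    :func:`calibrate_config` to match published medians.
    """
    elements = (
        CostElement(
            "personnel_paramedics",
            "Personnel salaries with fringe: paramedics (6.5 FTE)",
            "fixed", "per_period", "all", False, _pert(480_000, 552_000, 650_000),
        ),
        CostElement(
            "personnel_administrator",
            "Personnel salaries with fringe: program administrator (1.0 FTE)",
            "fixed", "per_period", "all", False, _pert(70_000, 85_000, 102_000),
        ),
        CostElement(
            "personnel_physician",
            "Personnel salaries with fringe: physician medical direction (0.5 FTE)",
            "fixed", "per_period", "all", False, _pert(90_000, 110_000, 135_000),
        ),
        CostElement(
            "administrative",
            "Administrative: state license fees, paramedic certification fees, "
            "continuing education courses, operational software",
            "fixed", "per_period", "all", False, _pert(15_000, 25_000, 40_000),
        ),
        CostElement(
            "equipment",
            "Non-disposable clinical equipment (annualized): cardiac monitors, "
            "point-of-care blood machine, laptop computers, portable printers, "
            "radios, WIFI hotspot, clinical software",
            "fixed", "per_period", "all", False, _pert(40_000, 60_000, 90_000),
        ),
        CostElement(
            "fuel", "Fuel",
            "variable", "per_period", "all", False, _pert(8_000, 12_000, 18_000),
        ),
        CostElement(
            "vehicle_maintenance", "Vehicle maintenance",
            "variable", "per_period", "all", False, _pert(5_000, 9_000, 15_000),
        ),
        CostElement(
            "laboratory_analysis_basic",
            "Laboratory analysis per basic visit (unit cost x mean panels)",
            "variable", "per_visit", "basic_only", True, _pert(12, 30, 65),
        ),
        CostElement(
            "radiology_basic",
            "Radiology studies and interpretation per basic visit",
            "variable", "per_visit", "basic_only", True, _pert(8, 22, 55),
        ),
        CostElement(
            "medications_supplies_basic",
            "Oral medications, prescriptions and clinical supplies per basic visit",
            "variable", "per_visit", "basic_only", False, _pert(20, 48, 95),
        ),
        CostElement(
            "laboratory_analysis_advanced",
            "Laboratory analysis per advanced visit (unit cost x mean panels)",
            "variable", "per_visit", "advanced_only", True, _pert(120, 250, 450),
        ),
        CostElement(
            "radiology_advanced",
            "Radiology studies and interpretation per advanced visit",
            "variable", "per_visit", "advanced_only", True, _pert(280, 560, 950),
        ),
        CostElement(
            "iv_medications_supplies",
            "IV medications and fluids with administration supplies per advanced visit",
            "variable", "per_visit", "advanced_only", False, _pert(55, 115, 210),
        ),
    )
    return ProgramConfig(
        elements=elements,
        visit_mix=VisitMix(annual_visits=_pert(700, 800, 900)),
        simulation=SimulationSettings(iterations=1000, interval_level=0.90, seed=seed),
    )


def generate_config(settings: GeneratorSettings, template: ProgramConfig) -> ProgramConfig:
    """Rescale a template into a new synthetic program configuration.

    Each element's PERT triple is multiplied by
    ``settings.cost_scale.get(element id, 1.0)`` (uniform scaling can
    never invert the triple), annual volume is recentred on
    ``settings.n_encounters``, and the complexity mix is taken from the
    settings.  The result passes full configuration validation.
    """
    unknown = set(settings.cost_scale) - {e.id for e in template.elements}
    if unknown:
        raise ValueError(f"cost_scale refers to unknown elements: {sorted(unknown)}")
    elements = tuple(
        replace(e, pert=e.pert.scaled(settings.cost_scale.get(e.id, 1.0)))
        if settings.cost_scale.get(e.id, 1.0) != 1.0
        else e
        for e in template.elements
    )
    volume_factor = settings.n_encounters / template.visit_mix.annual_visits.most_likely
    return replace(
        template,
        elements=elements,
        visit_mix=VisitMix(
            annual_visits=template.visit_mix.annual_visits.scaled(volume_factor),
            prop_basic=settings.prop_basic_target,
            prop_advanced=1.0 - settings.prop_basic_target,
        ),
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a calibration search."""

    config: ProgramConfig
    scale_fixed: float
    scale_basic: float
    scale_advanced: float
    basic_median: float
    advanced_median: float
    target_basic: float
    target_advanced: float
    evaluations: int
    converged: bool

    @property
    def relative_errors(self) -> tuple[float, float]:
        return (
            abs(self.basic_median - self.target_basic) / self.target_basic,
            abs(self.advanced_median - self.target_advanced) / self.target_advanced,
        )


def _scale_group(element: CostElement) -> str:
    """Calibration group of an element.

    Elements hitting both strata equally under count-proportional
    allocation (the fixed pool, per-period variable costs, and any
    per-visit element applying to all visits) move with the fixed-pool
    scale; stratum-specific per-visit elements move with their
    stratum's variable scale.
    """
    if element.classification == "variable" and element.basis == "per_visit":
        if element.applicability == "basic_only":
            return "basic"
        if element.applicability == "advanced_only":
            return "advanced"
    return "fixed"


_TINY = 1e-9


def calibrate_config(
    template: ProgramConfig,
    targets: Mapping[str, float],
    tolerance: float = 0.02,
    budget: int = 200,
    *,
    iterations: int = 1000,
    seed: int = 1,
) -> CalibrationResult:
    """Rescale a template until simulated medians hit target medians.

    Searches three multiplicative scale factors — the shared fixed pool,
    basic-only variable costs, advanced-only variable costs — by a
    deterministic staged bisection under common random numbers (every
    candidate is simulated with the same ``seed`` and ``iterations``):

    1. if the shared per-visit base alone already exceeds 80% of the
       basic target, shrink the fixed-pool scale until it equals 80% of
       that target (leaving headroom for the stratum's variable costs);
    2. bisect the basic-variable scale so the basic median hits its
       target (this scale does not touch the advanced stratum);
    3. bisect the advanced-variable scale likewise.

    Returns the best configuration found; ``converged`` is False when
    the evaluation ``budget`` ran out or a target is unreachable within
    it, with the achieved medians reported either way.
    """
    if not (targets.get("basic_median", 0) > 0 and targets.get("advanced_median", 0) > 0):
        raise ValueError("targets must provide positive basic_median and advanced_median")
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    target_b = float(targets["basic_median"])
    target_a = float(targets["advanced_median"])

    groups = {e.id: _scale_group(e) for e in template.elements}
    evals = 0

    def scaled(s_f: float, s_b: float, s_a: float) -> ProgramConfig:
        factors = {"fixed": s_f, "basic": s_b, "advanced": s_a}
        return replace(
            template,
            elements=tuple(
                replace(e, pert=e.pert.scaled(max(factors[groups[e.id]], _TINY)))
                for e in template.elements
            ),
        )

    def medians(s_f: float, s_b: float, s_a: float) -> tuple[float, float]:
        nonlocal evals
        evals += 1
        result = run_simulation(scaled(s_f, s_b, s_a), iterations, seed)
        return (
            float(np.median(result.basic_costs)),
            float(np.median(result.advanced_costs)),
        )

    def make_result(s_f, s_b, s_a) -> CalibrationResult:
        m_b, m_a = medians(s_f, s_b, s_a)
        rel = max(abs(m_b - target_b) / target_b, abs(m_a - target_a) / target_a)
        return CalibrationResult(
            config=scaled(s_f, s_b, s_a),
            scale_fixed=s_f, scale_basic=s_b, scale_advanced=s_a,
            basic_median=m_b, advanced_median=m_a,
            target_basic=target_b, target_advanced=target_a,
            evaluations=evals, converged=rel <= tolerance,
        )

    # Fixed point: the template may already match.
    m_b0, m_a0 = medians(1.0, 1.0, 1.0)
    if (abs(m_b0 - target_b) / target_b <= tolerance
            and abs(m_a0 - target_a) / target_a <= tolerance):
        return make_result(1.0, 1.0, 1.0)

    def bisect(f, lo, hi, target, abs_tol) -> float:
        """Deterministic bisection for the monotone-increasing f."""
        nonlocal evals
        f_lo, f_hi = f(lo), f(hi)
        doubles = 0
        while f_hi < target and evals < budget and doubles < 30:
            lo, f_lo = hi, f_hi
            hi *= 2.0
            f_hi = f(hi)
            doubles += 1
        for _ in range(60):
            if evals >= budget:
                break
            mid = 0.5 * (lo + hi)
            f_mid = f(mid)
            if abs(f_mid - target) <= abs_tol:
                return mid
            if f_mid < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # Stage 1: shared base (fixed pool + per-period variable + any
    # all-visit per-visit elements), measured with stratum scales ~0.
    s_f = 1.0
    base_b, _ = medians(1.0, _TINY, _TINY)
    headroom_target = 0.8 * min(target_b, target_a)
    if base_b > headroom_target:
        s_f = bisect(
            lambda s: medians(s, _TINY, _TINY)[0],
            1e-6, 1.0, headroom_target, 0.005 * headroom_target,
        )

    # Stage 2: basic-variable scale (does not affect the advanced stratum).
    s_b = bisect(
        lambda s: medians(s_f, s, _TINY)[0],
        _TINY, 1.0, target_b, 0.25 * tolerance * target_b,
    )
    # Stage 3: advanced-variable scale (does not affect the basic stratum).
    s_a = bisect(
        lambda s: medians(s_f, s_b, s)[1],
        _TINY, 1.0, target_a, 0.25 * tolerance * target_a,
    )
    return make_result(s_f, s_b, s_a)
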