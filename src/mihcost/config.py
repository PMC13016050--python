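"""Program cost configuration: schema, validation, serialization, scenarios.

A mobile integrated health (MIH) program's cost structure is described
by an ordered list of cost elements, a visit mix, and simulation
settings.  Each element carries:

* ``classification`` — ``fixed`` (independent of encounter volume:
  salaries, licenses, durable equipment) or ``variable`` (scales with
  activity: fuel, diagnostics, medications);
* ``basis`` — ``per_period`` (USD per program year) or ``per_visit``
  (USD per encounter);
* ``applicability`` — which visit stratum the element applies to
  (``all``, ``basic_only``, ``advanced_only``);
* ``reimbursable`` — whether payors already reimburse the element
  (laboratory analysis, radiology studies and interpretation); the
  unreimbursed scenario removes exactly these elements;
* a PERT triple expressing uncertainty in the dollar amount.

Configurations are stored as structured text (YAML primary dialect;
JSON is a subset and parses identically) and validated on load with
per-field error messages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .distributions import DEFAULT_SHAPE, PertParams

__all__ = [
    "ConfigError",
    "CostElement",
    "VisitMix",
    "SimulationSettings",
    "ProgramConfig",
    "load_config",
    "loads_config",
    "config_to_dict",
    "save_config",
    "config_digest",
    "filter_unreimbursed",
    "classify_visit",
    "CLASSIFICATIONS",
    "BASES",
    "APPLICABILITIES",
]

CLASSIFICATIONS = ("fixed", "variable")
BASES = ("per_period", "per_visit")
APPLICABILITIES = ("all", "basic_only", "advanced_only")

PROP_TOL = 1e-9


class ConfigError(ValueError):
    """A configuration failed schema or invariant validation."""


@dataclass(frozen=True)
class CostElement:
    """One named cost line of the program budget."""

    id: str
    label: str
    classification: str
    basis: str
    applicability: str
    reimbursable: bool
    pert: PertParams

    def __post_init__(self) -> None:
        if not self.id:
            raise ConfigError("cost element id must be a non-empty string")
        if self.classification not in CLASSIFICATIONS:
            raise ConfigError(
                f"element '{self.id}': classification must be one of "
                f"{CLASSIFICATIONS}, got '{self.classification}'"
            )
        if self.basis not in BASES:
            raise ConfigError(
                f"element '{self.id}': basis must be one of {BASES}, "
                f"got '{self.basis}'"
            )
        if self.applicability not in APPLICABILITIES:
            raise ConfigError(
                f"element '{self.id}': applicability must be one of "
                f"{APPLICABILITIES}, got '{self.applicability}'"
            )
        if self.classification == "fixed":
            # Fixed costs are a program-period pool allocated across strata.
            if self.basis != "per_period":
                raise ConfigError(
                    f"element '{self.id}': fixed elements must have basis "
                    "'per_period'"
                )
            if self.applicability != "all":
                raise ConfigError(
                    f"element '{self.id}': fixed elements must have "
                    "applicability 'all'"
                )
        if self.pert.minimum < 0:
            raise ConfigError(
                f"element '{self.id}': monetary values must be >= 0"
            )


@dataclass(frozen=True)
class VisitMix:
    """Annual encounter volume (PERT-varied) and complexity proportions.

    The complexity split is a deterministic program characteristic
    (observed 60% basic / 40% advanced) while the annual volume is
    itself an uncertain quantity with its own PERT triple.
    """

    annual_visits: PertParams
    prop_basic: float = 0.60
    prop_advanced: float = 0.40

    def __post_init__(self) -> None:
        if not (0.0 <= self.prop_basic <= 1.0 and 0.0 <= self.prop_advanced <= 1.0):
            raise ConfigError("visit proportions must lie in [0, 1]")
        if abs(self.prop_basic + self.prop_advanced - 1.0) > PROP_TOL:
            raise ConfigError(
                "prop_basic + prop_advanced must equal 1, got "
                f"{self.prop_basic} + {self.prop_advanced}"
            )
        if not self.annual_visits.minimum > 0:
            raise ConfigError("annual_visits minimum must be positive")


@dataclass(frozen=True)
class SimulationSettings:
    iterations: int = 1000
    interval_level: float = 0.90
    seed: int = 0
    pert_shape: float = DEFAULT_SHAPE

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ConfigError(f"iterations must be >= 1, got {self.iterations}")
        if not 0.0 < self.interval_level < 1.0:
            raise ConfigError(
                f"interval_level must be in (0, 1), got {self.interval_level}"
            )
        if not self.pert_shape > 0:
            raise ConfigError(f"pert_shape must be positive, got {self.pert_shape}")


@dataclass(frozen=True)
class ProgramConfig:
    """Full model input: cost elements, visit mix, simulation settings.

    ``weight_basic`` / ``weight_advanced`` are per-stratum allocation
    weights for the fixed-cost pool (and per-period variable costs).
    The default (1, 1) is pure count-proportional allocation, under
    which the per-visit fixed share is identical across strata; unequal
    weights emulate resource-weighted allocation (e.g. by visit
    duration).
    """

    elements: tuple[CostElement, ...]
    visit_mix: VisitMix
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    weight_basic: float = 1.0
    weight_advanced: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        ids = [e.id for e in self.elements]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ConfigError(f"duplicate element ids: {sorted(dupes)}")
        if not any(e.classification == "fixed" for e in self.elements):
            raise ConfigError("config must contain at least one fixed element")
        if not any(e.classification == "variable" for e in self.elements):
            raise ConfigError("config must contain at least one variable element")
        if not (self.weight_basic > 0 and self.weight_advanced > 0):
            raise ConfigError("allocation weights must be positive")

    @property
    def fixed_elements(self) -> tuple[CostElement, ...]:
        return tuple(e for e in self.elements if e.classification == "fixed")

    @property
    def variable_elements(self) -> tuple[CostElement, ...]:
        return tuple(e for e in self.elements if e.classification == "variable")

    def element(self, element_id: str) -> CostElement:
        for e in self.elements:
            if e.id == element_id:
                return e
        raise KeyError(element_id)


# ---------------------------------------------------------------------------
# Serialization


def _pert_to_dict(p: PertParams, default_shape: float) -> dict[str, float]:
    # floats throughout so the serialized form (and its digest) is
    # identical whether the triple was built from ints or from YAML
    d = {"min": float(p.minimum), "mode": float(p.most_likely),
         "max": float(p.maximum)}
    if p.shape != default_shape:
        d["shape"] = float(p.shape)
    return d


def _pert_from_obj(obj: Any, where: str, default_shape: float) -> PertParams:
    """Accept ``{min, mode, max[, shape]}`` or a bare number (point mass)."""
    if isinstance(obj, (int, float)) and not isinstance(obj, bool):
        return PertParams(float(obj), float(obj), float(obj), default_shape)
    if not isinstance(obj, Mapping):
        raise ConfigError(
            f"{where}: PERT triple must be a mapping with min/mode/max "
            f"or a single number, got {type(obj).__name__}"
        )
    missing = {"min", "mode", "max"} - set(obj)
    if missing:
        raise ConfigError(f"{where}: PERT triple missing keys {sorted(missing)}")
    try:
        return PertParams(
            float(obj["min"]),
            float(obj["mode"]),
            float(obj["max"]),
            float(obj.get("shape", default_shape)),
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def config_from_dict(data: Mapping[str, Any]) -> ProgramConfig:
    """Build and validate a :class:`ProgramConfig` from parsed structured text."""
    if not isinstance(data, Mapping):
        raise ConfigError("top level of a config must be a mapping")

    sim_raw = dict(data.get("simulation", {}))
    unknown = set(sim_raw) - {"iterations", "interval_level", "seed", "pert_shape"}
    if unknown:
        raise ConfigError(f"simulation: unknown keys {sorted(unknown)}")
    simulation = SimulationSettings(**sim_raw)
    shape = simulation.pert_shape

    vm_raw = data.get("visit_mix")
    if vm_raw is None:
        raise ConfigError("config missing required section 'visit_mix'")
    try:
        visit_mix = VisitMix(
            annual_visits=_pert_from_obj(
                vm_raw.get("annual_visits"), "visit_mix.annual_visits", shape
            ),
            prop_basic=float(vm_raw.get("prop_basic", 0.60)),
            prop_advanced=float(vm_raw.get("prop_advanced", 0.40)),
        )
    except ConfigError:
        raise
    except (TypeError, AttributeError) as exc:
        raise ConfigError(f"visit_mix: {exc}") from exc

    elements_raw = data.get("elements")
    if not elements_raw:
        raise ConfigError("config missing required section 'elements'")
    elements = []
    for i, raw in enumerate(elements_raw):
        where = f"elements[{i}]" + (f" ('{raw.get('id')}')" if isinstance(raw, Mapping) and raw.get("id") else "")
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{where}: element must be a mapping")
        required = {"id", "classification", "basis", "applicability", "pert"}
        missing = required - set(raw)
        if missing:
            raise ConfigError(f"{where}: missing keys {sorted(missing)}")
        elements.append(
            CostElement(
                id=str(raw["id"]),
                label=str(raw.get("label", raw["id"])),
                classification=str(raw["classification"]),
                basis=str(raw["basis"]),
                applicability=str(raw["applicability"]),
                reimbursable=bool(raw.get("reimbursable", False)),
                pert=_pert_from_obj(raw["pert"], f"{where}.pert", shape),
            )
        )

    alloc = data.get("allocation", {})
    return ProgramConfig(
        elements=tuple(elements),
        visit_mix=visit_mix,
        simulation=simulation,
        weight_basic=float(alloc.get("weight_basic", 1.0)),
        weight_advanced=float(alloc.get("weight_advanced", 1.0)),
    )


def config_to_dict(config: ProgramConfig) -> dict[str, Any]:
    """Serialize to the plain-dict form that round-trips through YAML/JSON."""
    shape = config.simulation.pert_shape
    out: dict[str, Any] = {
        "elements": [
            {
                "id": e.id,
                "label": e.label,
                "classification": e.classification,
                "basis": e.basis,
                "applicability": e.applicability,
                "reimbursable": e.reimbursable,
                "pert": _pert_to_dict(e.pert, shape),
            }
            for e in config.elements
        ],
        "visit_mix": {
            "annual_visits": _pert_to_dict(config.visit_mix.annual_visits, shape),
            "prop_basic": float(config.visit_mix.prop_basic),
            "prop_advanced": float(config.visit_mix.prop_advanced),
        },
        "simulation": {
            "iterations": config.simulation.iterations,
            "interval_level": config.simulation.interval_level,
            "seed": config.simulation.seed,
            "pert_shape": config.simulation.pert_shape,
        },
    }
    if (config.weight_basic, config.weight_advanced) != (1.0, 1.0):
        out["allocation"] = {
            "weight_basic": config.weight_basic,
            "weight_advanced": config.weight_advanced,
        }
    return out


def loads_config(text: str) -> ProgramConfig:
    """Parse a YAML (or JSON) document into a validated config."""
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config: {exc}") from exc
    return config_from_dict(data)


def load_config(path: str | Path) -> ProgramConfig:
    """Load and validate a program configuration file.

    Raises
    ------
    ConfigError
        On parse failure (with line context from the YAML parser) or on
        any invariant violation, naming the offending element/field.
    """
    return loads_config(Path(path).read_text())


def save_config(config: ProgramConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False)
    )


def config_digest(config: ProgramConfig) -> str:
    """Content hash (sha256, first 12 hex chars) of the canonical form."""
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Scenarios and visit classification


def filter_unreimbursed(config: ProgramConfig) -> ProgramConfig:
    """Remove every payor-reimbursed element (lab analysis, radiology).

    Models the total *unreimbursed* program cost: what the program
    itself bears after payors cover diagnostics.  Idempotent; with no
    reimbursable elements this is the identity.
    """
    kept = tuple(e for e in config.elements if not e.reimbursable)
    if len(kept) == len(config.elements):
        return config
    return replace(config, elements=kept)


def classify_visit(encounter: Any) -> str:
    """Classify an encounter as ``"basic"`` or ``"advanced"``.

    A visit is *advanced* when it uses two or more distinct diagnostic
    modalities (laboratory, radiology — multiple lab panels still count
    as one modality) and/or any intravenous therapy including fluids;
    otherwise it is *basic* (paramedic evaluation, telehealth physician
    consult, referral, at most one diagnostic modality, oral medications
    allowed).  Zero-diagnostic, zero-IV visits are basic.

    ``encounter`` is anything with non-negative ``lab_panels``,
    ``radiology_studies`` and ``iv_therapies`` counts.
    """
    labs = encounter.lab_panels
    rads = encounter.radiology_studies
    ivs = encounter.iv_therapies
    if min(labs, rads, ivs) < 0:
        raise ValueError("service counts must be non-negative")
    modalities = int(labs > 0) + int(rads > 0)
    if modalities >= 2 or ivs >= 1:
        return "advanced"
    return "basic"
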