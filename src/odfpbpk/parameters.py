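"""Model input parameters: drug, absorption, disposition and dosing blocks.

Canonical internal units are hours, micrograms, liters (cm for lengths);
all quantities are stored in the units in which they are conventionally
reported (e.g. permeability in cm/s, clearance in L/h/kg) and converted
where they enter the differential equations. Per-kilogram disposition
parameters are scaled by body weight at simulation time, so a parameter
set remains equal to its source table verbatim.
"""

from __future__ import annotations

import enum
import json
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator

__all__ = [
    "CompoundType",
    "Route",
    "DrugProperties",
    "AbsorptionProperties",
    "DispositionProperties",
    "DoseDesign",
    "ParameterSet",
    "beagle_risperidone_fixture",
    "load_config",
    "loads_config",
    "serialize",
    "validate_parameters",
]


class CompoundType(str, enum.Enum):
    monoprotic_base = "monoprotic_base"
    diprotic_base = "diprotic_base"
    acid = "acid"
    neutral = "neutral"


class Route(str, enum.Enum):
    iv = "iv"
    ig = "ig"
    supralingual = "supralingual"
    sublingual = "sublingual"


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class DrugProperties(_Frozen):
    """Physicochemical properties of the compound.

    ``ref_solubility`` is the aqueous solubility (mg/ml) measured at
    ``ref_solubility_ph``; pH-dependent solubility elsewhere is derived
    from it through Henderson-Hasselbalch scaling (:mod:`odfpbpk.dissolution`).
    """

    mol_weight: float            # g/mol
    log_p: float                 # octanol/water partition coefficient
    compound_type: CompoundType
    pka_values: tuple[float, ...]
    blood_plasma_ratio: float    # B/P
    fu_plasma: float             # fraction unbound in plasma
    ref_solubility: float        # mg/ml
    ref_solubility_ph: float
    diffusion_coeff: float       # cm^2/s, aqueous
    particle_density: float      # g/ml
    particle_radius: float       # um
    precipitation_time: float    # s, mean precipitation time constant


class AbsorptionProperties(_Frozen):
    """Intestinal and oromucosal absorption inputs."""

    peff: float                  # effective jejunal permeability, cm/s
    fu_oral_tissue: float        # fraction unbound in oral tissue
    mucosa_diffusivity: float    # oral epithelium diffusivity, cm^2/s


class DispositionProperties(_Frozen):
    """Three-compartment mammillary disposition, micro-constant form.

    ``k12``/``k21``/``k13``/``k31`` are first-order transfer rate constants
    between compartment *amounts*; ``v2`` and ``v3`` are then redundant for
    simulation and retained only for consistency checks (k12*vc == k21*v2).
    Volumes and clearance are per kg body weight.
    """

    first_pass_extraction: float  # fraction of portally absorbed drug removed
    vc: float                     # central volume, L/kg
    cl: float                     # systemic clearance, L/h/kg
    k12: float                    # 1/h
    k21: float                    # 1/h
    k13: float                    # 1/h
    k31: float                    # 1/h
    v2: float                     # L/kg
    v3: float                     # L/kg


class DoseDesign(_Frozen):
    dose: float                  # mg
    body_weight: float           # kg
    route: Route = Route.supralingual
    hold_time: float = 2.0       # min, oral residence (Hold & Swallow)
    sampling_times: tuple[float, ...] = ()  # h

    @field_validator("sampling_times")
    @classmethod
    def _increasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if v and (v[0] < 0 or any(b <= a for a, b in zip(v, v[1:]))):
            raise ValueError("sampling_times must be strictly increasing and nonnegative")
        return v


class ParameterSet(_Frozen):
    drug: DrugProperties
    absorption: AbsorptionProperties
    disposition: DispositionProperties
    design: DoseDesign

    @property
    def dose_ug(self) -> float:
        return self.design.dose * 1000.0

    @property
    def vc_total(self) -> float:
        """Central volume in liters for this animal."""
        return self.disposition.vc * self.design.body_weight

    @property
    def cl_total(self) -> float:
        """Systemic clearance in L/h for this animal."""
        return self.disposition.cl * self.design.body_weight


#: Plasma sampling grid of the crossover study, hours post dose.
STUDY_SAMPLING_TIMES: tuple[float, ...] = (
    0.167, 0.333, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 32.0,
)

_FIXTURE_DEFAULTS: dict = {
    "drug": {
        "mol_weight": 410.49,
        "log_p": 3.04,
        "compound_type": "diprotic_base",
        "pka_values": (8.24, 3.11),
        "blood_plasma_ratio": 0.506,
        "fu_plasma": 0.083,
        "ref_solubility": 0.9,
        "ref_solubility_ph": 6.8,
        "diffusion_coeff": 0.64e-5,
        "particle_density": 1.2,
        "particle_radius": 25.0,
        "precipitation_time": 900.0,
    },
    "absorption": {
        "peff": 5.3894e-4,
        "fu_oral_tissue": 0.15382,
        "mucosa_diffusivity": 9.383e-7,
    },
    "disposition": {
        "first_pass_extraction": 0.51,
        "vc": 0.3139,
        "cl": 0.5903,
        "k12": 16.352,
        "k21": 9.007,
        "k13": 0.4625,
        "k31": 0.4103,
        "v2": 0.56988,
        "v3": 0.35383,
    },
    "design": {
        "dose": 1.0,
        "body_weight": 9.0425,
        "route": "supralingual",
        "hold_time": 2.0,
        "sampling_times": STUDY_SAMPLING_TIMES,
    },
}


def beagle_risperidone_fixture(**overrides) -> ParameterSet:
    """Full beagle/risperidone input record for the orodispersible film study.

    Keyword overrides replace whole blocks or individual fields, e.g.
    ``beagle_risperidone_fixture(design={"route": "iv"})`` keeps every other
    value at its study default.
    """
    blocks = {k: dict(v) for k, v in _FIXTURE_DEFAULTS.items()}
    for key, val in overrides.items():
        if key not in blocks:
            raise KeyError(f"unknown parameter block {key!r}")
        blocks[key].update(val)
    return ParameterSet(
        drug=DrugProperties(**blocks["drug"]),
        absorption=AbsorptionProperties(**blocks["absorption"]),
        disposition=DispositionProperties(**blocks["disposition"]),
        design=DoseDesign(**blocks["design"]),
    )


def validate_parameters(p: ParameterSet) -> list[str]:
    """Collect invariant violations; an empty list means the set is valid.

    Each issue names the offending field, its value and the violated rule.
    """
    issues: list[str] = []

    def positive(block: str, name: str, value: float) -> None:
        if not value > 0:
            issues.append(f"{block}.{name}={value!r}: must be positive")

    def fraction(block: str, name: str, value: float, *, open_low=True, closed_high=True) -> None:
        lo_ok = value > 0 if open_low else value >= 0
        hi_ok = value <= 1 if closed_high else value < 1
        if not (lo_ok and hi_ok):
            issues.append(f"{block}.{name}={value!r}: must lie in the unit interval")

    d = p.drug
    for name in ("mol_weight", "blood_plasma_ratio", "ref_solubility",
                 "diffusion_coeff", "particle_density", "particle_radius",
                 "precipitation_time"):
        positive("drug", name, getattr(d, name))
    fraction("drug", "fu_plasma", d.fu_plasma)
    if not 0 <= d.ref_solubility_ph <= 14:
        issues.append(f"drug.ref_solubility_ph={d.ref_solubility_ph!r}: must lie in [0, 14]")
    if any(pk <= 0 for pk in d.pka_values):
        issues.append(f"drug.pka_values={d.pka_values!r}: must be positive")
    if any(b >= a for a, b in zip(d.pka_values, d.pka_values[1:])):
        issues.append(
            f"drug.pka_values={d.pka_values!r}: must be strictly decreasing (pKa1 > pKa2)"
        )

    a = p.absorption
    positive("absorption", "peff", a.peff)
    positive("absorption", "mucosa_diffusivity", a.mucosa_diffusivity)
    fraction("absorption", "fu_oral_tissue", a.fu_oral_tissue)

    k = p.disposition
    positive("disposition", "vc", k.vc)
    positive("disposition", "cl", k.cl)
    for name in ("k12", "k21", "k13", "k31", "v2", "v3"):
        if getattr(k, name) < 0:
            issues.append(f"disposition.{name}={getattr(k, name)!r}: must be nonnegative")
    if not 0 <= k.first_pass_extraction < 1:
        issues.append(
            f"disposition.first_pass_extraction={k.first_pass_extraction!r}: must lie in [0, 1)"
        )

    g = p.design
    positive("design", "dose", g.dose)
    positive("design", "body_weight", g.body_weight)
    if g.hold_time < 0:
        issues.append(f"design.hold_time={g.hold_time!r}: must be nonnegative")
    return issues


def serialize(p: ParameterSet) -> str:
    """JSON text with blocks [drug], [absorption], [disposition], [design]."""
    return json.dumps(p.model_dump(mode="json"), indent=2)


def loads_config(text: str) -> ParameterSet:
    """Parse a JSON or TOML config into a validated :class:`ParameterSet`.

    Optional fields fall back to the beagle/risperidone fixture defaults;
    validation errors name the offending key.
    """
    data = _parse_structured(text)
    unknown = set(data) - set(_FIXTURE_DEFAULTS)
    if unknown:
        raise KeyError(f"unknown config block(s): {sorted(unknown)}")
    p = beagle_risperidone_fixture(**data)
    issues = validate_parameters(p)
    if issues:
        raise ValueError("invalid parameter set:\n" + "\n".join(issues))
    return p


def load_config(path) -> ParameterSet:
    with open(path, "r", encoding="utf-8") as fh:
        return loads_config(fh.read())


def _parse_structured(text: str) -> dict:
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        pass
    import tomllib

    try:
        return tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ValueError(f"config is neither valid JSON nor TOML: {exc}") from exc
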