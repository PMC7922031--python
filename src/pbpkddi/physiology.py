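"""Virtual individuals: organ volumes and blood flows, tissue composition for
partition-coefficient calculation, glomerular filtration rate and enzyme
expression.

The reference individual is a 30-year-old male European with mean body weight
and height.  Reference organ volumes, blood flows and tissue-composition
fractions are packaged constants derived from published reference-man tables
and are overridable through :func:`load_physiology_config`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

from .errors import ConfigurationError, ValidationError

# Canonical organ identifiers, in state-vector order.
ORGAN_NAMES = (
    "venous blood",
    "arterial blood",
    "lung",
    "liver",
    "kidney",
    "gut wall",
    "adipose",
    "muscle",
    "skin",
    "bone",
    "brain",
    "heart",
    "spleen",
    "rest",
)

BLOOD_COMPARTMENTS = ("venous blood", "arterial blood")
#: organs whose venous outflow drains into the liver (portal circulation)
PORTAL_ORGANS = ("gut wall", "spleen")

ENZYME_NAMES = ("CYP3A4", "CYP2C8", "CYP2B6", "UGT2B7", "EPHX1")

MINUTES_PER_HOUR = 60.0


@dataclass(frozen=True)
class TissueComposition:
    """Volume fractions used by the tissue:plasma partition model.

    ``f_acidic_phospholipids`` (mg/g tissue) is carried for completeness; the
    neutral-species partition equations do not consume it.
    """

    f_extracellular_water: float
    f_intracellular_water: float
    f_neutral_lipids: float
    f_neutral_phospholipids: float
    f_acidic_phospholipids: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "f_extracellular_water",
            "f_intracellular_water",
            "f_neutral_lipids",
            "f_neutral_phospholipids",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")

    @property
    def f_water(self) -> float:
        return self.f_extracellular_water + self.f_intracellular_water


@dataclass(frozen=True)
class OrganSpec:
    name: str
    volume_l: float
    blood_flow_l_min: float
    composition: TissueComposition
    fraction_intracellular: float = 0.8

    def __post_init__(self) -> None:
        if self.name not in ORGAN_NAMES:
            raise ValidationError(f"unknown organ identifier {self.name!r}")
        if self.volume_l <= 0:
            raise ValidationError(f"organ {self.name}: volume must be > 0")
        if self.blood_flow_l_min < 0:
            raise ValidationError(f"organ {self.name}: blood_flow must be >= 0")
        if not 0.0 <= self.fraction_intracellular <= 1.0:
            raise ValidationError(
                f"organ {self.name}: fraction_intracellular must lie in [0, 1]"
            )
        frac_sum = (
            self.composition.f_water
            + self.composition.f_neutral_lipids
            + self.composition.f_neutral_phospholipids
        )
        if frac_sum > 1.0 + 1e-9:
            raise ValidationError(
                f"organ {self.name}: water + lipid fractions exceed the organ volume"
            )

    def subcompartment_volumes(self) -> dict[str, float]:
        """Split the organ volume into water/lipid/residual sub-volumes.

        The residual (proteins, minerals) closes the balance so that the
        sub-volumes sum to ``volume_l`` exactly.
        """
        c = self.composition
        vols = {
            "extracellular_water": c.f_extracellular_water * self.volume_l,
            "intracellular_water": c.f_intracellular_water * self.volume_l,
            "neutral_lipids": c.f_neutral_lipids * self.volume_l,
            "neutral_phospholipids": c.f_neutral_phospholipids * self.volume_l,
        }
        vols["residual"] = self.volume_l - sum(vols.values())
        return vols


@dataclass(frozen=True)
class EnzymeSpec:
    """Baseline enzyme expression and turnover.

    ``organ_concentration`` maps organ name to µmol enzyme per L tissue.
    ``k_deg`` is the default first-order degradation rate constant (1/min);
    ``k_deg_organ`` holds per-organ overrides (e.g. a faster gut turnover).
    """

    name: str
    organ_concentration: Mapping[str, float]
    k_deg: float
    k_deg_organ: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_deg <= 0:
            raise ValidationError(f"enzyme {self.name}: k_deg must be > 0")
        for organ, conc in self.organ_concentration.items():
            if organ not in ORGAN_NAMES:
                raise ValidationError(
                    f"enzyme {self.name}: unknown organ {organ!r}"
                )
            if conc < 0:
                raise ValidationError(
                    f"enzyme {self.name}: concentration in {organ} must be >= 0"
                )
        for organ, k in self.k_deg_organ.items():
            if k <= 0:
                raise ValidationError(
                    f"enzyme {self.name}: k_deg override for {organ} must be > 0"
                )

    def k_deg_in(self, organ: str) -> float:
        return self.k_deg_organ.get(organ, self.k_deg)


@dataclass(frozen=True)
class Individual:
    age_years: float
    sex: str
    ethnicity: str
    body_weight_kg: float
    height_cm: float
    hematocrit: float
    gfr_ml_min: float
    organs: tuple[OrganSpec, ...]
    enzymes: tuple[EnzymeSpec, ...]

    def __post_init__(self) -> None:
        if self.gfr_ml_min <= 0:
            raise ValidationError("GFR must be > 0")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValidationError("hematocrit must lie in (0, 1)")
        names = [o.name for o in self.organs]
        if sorted(names) != sorted(ORGAN_NAMES):
            missing = set(ORGAN_NAMES) - set(names)
            extra = [n for n in names if names.count(n) > 1]
            raise ValidationError(
                f"organ list must contain every identifier exactly once "
                f"(missing={sorted(missing)}, duplicated={sorted(set(extra))})"
            )

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)

    def enzyme(self, name: str) -> EnzymeSpec:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def cardiac_output_l_min(self) -> float:
        """Total systemic arterial flow (equals the lung flow)."""
        return sum(
            o.blood_flow_l_min
            for o in self.organs
            if o.name not in BLOOD_COMPARTMENTS and o.name != "lung"
        )

    @property
    def gfr_l_min(self) -> float:
        return self.gfr_ml_min / 1000.0


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

#: tissue-composition fractions (extracellular water, intracellular water,
#: neutral lipids, neutral phospholipids, acidic phospholipids mg/g)
_REFERENCE_COMPOSITION: dict[str, tuple[float, float, float, float, float]] = {
    "venous blood": (0.945, 0.000, 0.0035, 0.00225, 0.57),
    "arterial blood": (0.945, 0.000, 0.0035, 0.00225, 0.57),
    "lung": (0.336, 0.446, 0.022, 0.0128, 3.91),
    "liver": (0.161, 0.573, 0.0135, 0.0238, 4.56),
    "kidney": (0.273, 0.483, 0.0121, 0.0240, 5.03),
    "gut wall": (0.282, 0.475, 0.0487, 0.0163, 2.41),
    "adipose": (0.135, 0.017, 0.844, 0.0016, 0.40),
    "muscle": (0.118, 0.630, 0.0100, 0.0072, 1.53),
    "skin": (0.382, 0.291, 0.0284, 0.0111, 1.32),
    "bone": (0.100, 0.346, 0.0174, 0.0016, 0.67),
    "brain": (0.162, 0.620, 0.0391, 0.0015, 0.40),
    "heart": (0.320, 0.456, 0.0115, 0.0166, 2.25),
    "spleen": (0.207, 0.579, 0.0077, 0.0113, 3.18),
    "rest": (0.180, 0.521, 0.0400, 0.0100, 1.50),
}

#: reference organ volumes (L) and arterial blood flows (L/min); liver flow is
#: the hepatic artery only (portal inflow arrives via gut wall and spleen)
_REFERENCE_ORGANS: dict[str, tuple[float, float]] = {
    "venous blood": (3.71, 0.0),
    "arterial blood": (1.85, 0.0),
    "lung": (1.05, 0.0),  # flow filled in with the cardiac output
    "liver": (1.80, 0.39),
    "kidney": (0.31, 1.10),
    "gut wall": (1.10, 0.90),
    "adipose": (14.00, 0.32),
    "muscle": (29.00, 0.75),
    "skin": (3.30, 0.30),
    "bone": (10.00, 0.25),
    "brain": (1.45, 0.70),
    "heart": (0.33, 0.24),
    "spleen": (0.18, 0.20),
    "rest": (4.92, 0.35),
}

#: baseline enzyme concentrations, µmol per L tissue
_REFERENCE_ENZYMES: dict[str, dict[str, float]] = {
    # gut-wall CYP3A4 is an effective concentration compensating the
    # perfusion-limited wall model's weak first-pass extraction
    "CYP3A4": {"liver": 4.32, "gut wall": 1.00},
    "CYP2C8": {"liver": 2.52},
    "CYP2B6": {"liver": 1.56},
    "UGT2B7": {"liver": 1.64, "kidney": 0.30, "gut wall": 0.20},
    "EPHX1": {"liver": 1.00},
}

#: enzyme turnover half-lives in hours (with per-organ overrides)
_REFERENCE_ENZYME_HALF_LIVES: dict[str, tuple[float, dict[str, float]]] = {
    "CYP3A4": (36.0, {"gut wall": 23.0}),
    "CYP2C8": (23.0, {}),
    "CYP2B6": (32.0, {}),
    "UGT2B7": (36.0, {}),
    "EPHX1": (36.0, {}),
}

REFERENCE_DEMOGRAPHICS = {
    "age_years": 30.0,
    "sex": "male",
    "ethnicity": "European",
    "body_weight_kg": 73.0,
    "height_cm": 176.0,
    "hematocrit": 0.43,
    "gfr_ml_min": 120.0,
}


def _k_deg_from_half_life_h(half_life_h: float) -> float:
    return math.log(2.0) / (half_life_h * MINUTES_PER_HOUR)


def reference_individual() -> Individual:
    """The packaged 30-year-old male European reference individual."""
    organs = []
    co = sum(
        q for name, (_, q) in _REFERENCE_ORGANS.items() if name != "lung"
    )
    for name in ORGAN_NAMES:
        volume, flow = _REFERENCE_ORGANS[name]
        if name == "lung":
            flow = co
        ew, iw, nl, np_, ap = _REFERENCE_COMPOSITION[name]
        organs.append(
            OrganSpec(
                name=name,
                volume_l=volume,
                blood_flow_l_min=flow,
                composition=TissueComposition(ew, iw, nl, np_, ap),
            )
        )
    enzymes = []
    for name in ENZYME_NAMES:
        half_life, overrides = _REFERENCE_ENZYME_HALF_LIVES[name]
        enzymes.append(
            EnzymeSpec(
                name=name,
                organ_concentration=dict(_REFERENCE_ENZYMES[name]),
                k_deg=_k_deg_from_half_life_h(half_life),
                k_deg_organ={
                    organ: _k_deg_from_half_life_h(h)
                    for organ, h in overrides.items()
                },
            )
        )
    return Individual(organs=tuple(organs), enzymes=tuple(enzymes), **REFERENCE_DEMOGRAPHICS)


def create_individual(
    age_years: float | None = None,
    sex: str | None = None,
    ethnicity: str | None = None,
    body_weight_kg: float | None = None,
    height_cm: float | None = None,
) -> Individual:
    """Construct a virtual individual, defaulting omitted demographics to the
    packaged reference (30-year-old male European).

    Organ volumes scale proportionally with body weight; blood flows and GFR
    scale with weight^0.75 (see :func:`scale_physiology`).
    """
    if age_years is not None and not 0.0 <= age_years <= 120.0:
        raise ValidationError(f"age_years out of range [0, 120]: {age_years}")
    if body_weight_kg is not None and not 20.0 <= body_weight_kg <= 200.0:
        raise ValidationError(
            f"body_weight_kg out of range [20, 200]: {body_weight_kg}"
        )
    if height_cm is not None and not 50.0 <= height_cm <= 250.0:
        raise ValidationError(f"height_cm out of range [50, 250]: {height_cm}")

    ref = reference_individual()
    individual = replace(
        ref,
        age_years=ref.age_years if age_years is None else float(age_years),
        sex=ref.sex if sex is None else sex,
        ethnicity=ref.ethnicity if ethnicity is None else ethnicity,
    )
    weight = ref.body_weight_kg if body_weight_kg is None else float(body_weight_kg)
    height = ref.height_cm if height_cm is None else float(height_cm)
    return scale_physiology(individual, body_weight_kg=weight, height_cm=height)


def scale_physiology(
    reference: Individual, body_weight_kg: float, height_cm: float
) -> Individual:
    """Allometric scaling: volumes with weight ratio (exponent 1), flows and
    GFR with weight ratio^0.75; composition fractions are unchanged."""
    if body_weight_kg <= 0 or height_cm <= 0:
        raise ValidationError("body_weight_kg and height_cm must be > 0")
    ratio = body_weight_kg / reference.body_weight_kg
    organs = tuple(
        replace(
            o,
            volume_l=o.volume_l * ratio,
            blood_flow_l_min=o.blood_flow_l_min * ratio**0.75,
        )
        for o in reference.organs
    )
    return replace(
        reference,
        body_weight_kg=float(body_weight_kg),
        height_cm=float(height_cm),
        gfr_ml_min=reference.gfr_ml_min * ratio**0.75,
        organs=organs,
    )


# ---------------------------------------------------------------------------
# Config override
# ---------------------------------------------------------------------------

def load_physiology_config(path) -> Individual:
    """Load an individual from a YAML/JSON override file.

    Recognised keys: ``gfr_ml_min``, ``hematocrit``, demographic fields,
    ``organs`` (list of ``{name, volume_l, blood_flow_l_min, composition?}``)
    and ``enzymes`` (list of ``{name, organ_concentration, half_life_h?,
    k_deg?}``).  Unspecified entries fall back to the reference individual.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"physiology config {path} must be a mapping")
    ref = reference_individual()
    scalars = {}
    for key in (
        "age_years", "sex", "ethnicity", "body_weight_kg", "height_cm",
        "hematocrit", "gfr_ml_min",
    ):
        if key in raw:
            scalars[key] = raw[key]

    organ_overrides = {entry["name"]: entry for entry in raw.get("organs", [])}
    organs = []
    for o in ref.organs:
        entry = organ_overrides.pop(o.name, None)
        if entry is None:
            organs.append(o)
            continue
        comp = o.composition
        if "composition" in entry:
            comp = TissueComposition(**entry["composition"])
        organs.append(
            replace(
                o,
                volume_l=entry.get("volume_l", o.volume_l),
                blood_flow_l_min=entry.get("blood_flow_l_min", o.blood_flow_l_min),
                composition=comp,
            )
        )
    if organ_overrides:
        raise ConfigurationError(
            f"unknown organs in physiology config: {sorted(organ_overrides)}"
        )

    enzyme_overrides = {entry["name"]: entry for entry in raw.get("enzymes", [])}
    enzymes = []
    for e in ref.enzymes:
        entry = enzyme_overrides.pop(e.name, None)
        if entry is None:
            enzymes.append(e)
            continue
        k_deg = e.k_deg
        if "half_life_h" in entry:
            k_deg = _k_deg_from_half_life_h(entry["half_life_h"])
        if "k_deg" in entry:
            k_deg = entry["k_deg"]
        enzymes.append(
            replace(
                e,
                organ_concentration=dict(
                    entry.get("organ_concentration", e.organ_concentration)
                ),
                k_deg=k_deg,
            )
        )
    for name, entry in enzyme_overrides.items():
        if "half_life_h" in entry:
            entry = dict(entry)
            entry["k_deg"] = _k_deg_from_half_life_h(entry.pop("half_life_h"))
        enzymes.append(EnzymeSpec(**entry))

    return replace(ref, organs=tuple(organs), enzymes=tuple(enzymes), **scalars)
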