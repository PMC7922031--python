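"""Drug-dependent parameter sets.

The carbamazepine and carbamazepine-10,11-epoxide models ship fully
parameterised.  Perpetrator models (erythromycin, alprazolam, simvastatin,
bupropion, efavirenz) are consumed as user-supplied configs; example configs
with approximate, clearly flagged parameter values are packaged under
``pbpkddi/data``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Union

import yaml

from .engine.processes import (
    KNOWN_ENZYMES,
    FormulationSpec,
    HepaticClearance,
    InductionAction,
    InhibitionAction,
    RateLawMM,
    RateLawSpecificCL,
    RenalFiltration,
)
from .errors import SchemaError, ValidationError

Process = Union[RateLawMM, RateLawSpecificCL, HepaticClearance, RenalFiltration]
Interaction = Union[InductionAction, InhibitionAction]

CARBAMAZEPINE = "carbamazepine"
CARBAMAZEPINE_EPOXIDE = "carbamazepine-10,11-epoxide"


@dataclass
class DrugParameters:
    name: str
    molecular_weight: float  # g/mol
    lipophilicity: float  # log units
    solubility: float  # µg/mL
    fraction_unbound: float  # fraction
    intestinal_permeability: float  # cm/s
    partition_method: str = "rodgers-rowland"
    processes: list[Process] = field(default_factory=list)
    interactions: list[Interaction] = field(default_factory=list)
    formulations: dict[str, list[FormulationSpec]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.molecular_weight <= 0:
            raise ValidationError("molecular_weight must be > 0")
        if not 0.0 < self.fraction_unbound <= 1.0:
            raise ValidationError("fraction_unbound must lie in (0, 1]")
        if self.solubility <= 0:
            raise ValidationError("solubility must be > 0")
        if self.intestinal_permeability < 0:
            raise ValidationError("intestinal_permeability must be >= 0")
        n_gfr = 0
        for proc in self.processes:
            if isinstance(proc, (RateLawMM, RateLawSpecificCL)):
                if proc.enzyme not in KNOWN_ENZYMES:
                    raise ValidationError(
                        f"{self.name}: unknown enzyme {proc.enzyme!r}"
                    )
            elif isinstance(proc, RenalFiltration):
                n_gfr += 1
        if n_gfr > 1:
            raise ValidationError(
                f"{self.name}: at most one GFR-fraction entry is allowed"
            )
        for action in self.interactions:
            if action.target_enzyme not in KNOWN_ENZYMES:
                raise ValidationError(
                    f"{self.name}: unknown interaction target "
                    f"{action.target_enzyme!r}"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def metabolite_links(self) -> dict[str, str]:
        """Mapping of process key -> product drug name for linked pathways."""
        links = {}
        for i, proc in enumerate(self.processes):
            product = getattr(proc, "product", None)
            if product is not None:
                links[f"{getattr(proc, 'enzyme', 'process')}[{i}]"] = product
        return links

    @property
    def gfr_fraction(self) -> Optional[float]:
        for proc in self.processes:
            if isinstance(proc, RenalFiltration):
                return proc.gfr_fraction
        return None

    def formulation(self, name: str, food_state: str = "fasted") -> FormulationSpec:
        try:
            specs = self.formulations[name]
        except KeyError:
            raise ValidationError(
                f"{self.name}: unknown formulation {name!r} "
                f"(available: {sorted(self.formulations)})"
            ) from None
        for spec in specs:
            if spec.kind == "dissolved" or spec.food_state == food_state:
                return spec
        raise ValidationError(
            f"{self.name}: formulation {name!r} has no parameters for "
            f"food state {food_state!r}"
        )

    def solubility_um(self) -> float:
        """Solubility in µmol/L (input is µg/mL)."""
        return self.solubility * 1000.0 / self.molecular_weight


def kcat_from_vmax(v_max: float, enzyme_content: float) -> float:
    """Catalytic rate constant from microsomal assay data.

    k_cat = V_max (pmol/min/mg microsomal protein) / enzyme content
    (pmol/mg microsomal protein), yielding 1/min.
    """
    if v_max <= 0 or enzyme_content <= 0:
        raise ValidationError("v_max and enzyme_content must be > 0")
    return v_max / enzyme_content


def carbamazepine_model() -> DrugParameters:
    """The packaged carbamazepine parameter set.

    Five metabolic pathways (two CYP3A4, CYP2C8, CYP2B6, UGT2B7), an
    unspecific hepatic clearance, glomerular filtration with a GFR fraction
    of 0.03, and auto-induction of CYP3A4, CYP2B6 and EPHX1 with a common
    EC50 of 20 µM.  The CYP3A4 and CYP2C8 oxidations feed the
    10,11-epoxide metabolite model mole for mole.
    """
    return DrugParameters(
        name=CARBAMAZEPINE,
        molecular_weight=236.27,
        lipophilicity=2.00,
        solubility=336.0,
        fraction_unbound=0.25,
        intestinal_permeability=4.3e-4,
        processes=[
            RateLawMM("CYP3A4", K_m=248.0, k_cat=0.75, product=CARBAMAZEPINE_EPOXIDE),
            RateLawMM("CYP2C8", K_m=757.0, k_cat=0.67, product=CARBAMAZEPINE_EPOXIDE),
            RateLawMM("CYP3A4", K_m=282.0, k_cat=0.20),
            RateLawMM("CYP2B6", K_m=420.0, k_cat=0.43),
            RateLawMM("UGT2B7", K_m=214.0, k_cat=kcat_from_vmax(0.79, 82.9)),
            HepaticClearance(CL_spec=0.02),
            RenalFiltration(gfr_fraction=0.03),
        ],
        interactions=[
            InductionAction("CYP3A4", EC_50=20.0, E_max=6.00),
            InductionAction("CYP2B6", EC_50=20.0, E_max=17.00),
            InductionAction("EPHX1", EC_50=20.0, E_max=3.25),
        ],
        formulations={
            "solution": [FormulationSpec(kind="dissolved")],
            "suspension": [FormulationSpec(kind="dissolved")],
            # Weibull parameters below are package defaults fitted to
            # qualitative immediate/extended-release behaviour, not literature
            # values; fed-state release is faster, matching the reported food
            # effect on absorption.
            "tablet": [
                FormulationSpec("weibull", t_50=90.0, shape=1.1, lag=10.0,
                                food_state="fasted"),
                FormulationSpec("weibull", t_50=55.0, shape=1.4, lag=0.0,
                                food_state="fed"),
            ],
            "xr tablet": [
                FormulationSpec("weibull", t_50=420.0, shape=1.3, lag=15.0,
                                food_state="fasted"),
                FormulationSpec("weibull", t_50=300.0, shape=1.5, lag=0.0,
                                food_state="fed"),
            ],
        },
    )


def carbamazepine_epoxide_model() -> DrugParameters:
    """The packaged carbamazepine-10,11-epoxide parameter set.

    Cleared by EPHX1 (first-order specific clearance) and glomerular
    filtration with a GFR fraction of 0.21; independently administrable as
    an oral solution.
    """
    return DrugParameters(
        name=CARBAMAZEPINE_EPOXIDE,
        molecular_weight=252.27,
        lipophilicity=1.00,
        solubility=1340.0,
        fraction_unbound=0.518,
        intestinal_permeability=5.0e-3,
        processes=[
            RateLawSpecificCL("EPHX1", CL_spec=0.01),
            RenalFiltration(gfr_fraction=0.21),
        ],
        formulations={
            "solution": [FormulationSpec(kind="dissolved")],
        },
    )


_PACKAGED = {
    CARBAMAZEPINE: carbamazepine_model,
    CARBAMAZEPINE_EPOXIDE: carbamazepine_epoxide_model,
}

#: example perpetrator configs shipped under pbpkddi/data (approximate values)
_EXAMPLE_CONFIGS = {
    "erythromycin": "erythromycin.yaml",
    "alprazolam": "alprazolam.yaml",
    "simvastatin": "simvastatin.yaml",
    "bupropion": "bupropion.yaml",
    "efavirenz": "efavirenz.yaml",
}


def get_drug(name: str) -> DrugParameters:
    """Resolve a drug by name: packaged models first, then example configs."""
    if name in _PACKAGED:
        return _PACKAGED[name]()
    if name in _EXAMPLE_CONFIGS:
        ref = resources.files("pbpkddi.data") / _EXAMPLE_CONFIGS[name]
        with resources.as_file(ref) as path:
            return load_drug_config(path)
    raise KeyError(
        f"unknown drug {name!r}; packaged: {sorted(_PACKAGED)}, "
        f"examples: {sorted(_EXAMPLE_CONFIGS)}"
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

_PROCESS_KINDS = {
    "michaelis-menten": RateLawMM,
    "specific-clearance": RateLawSpecificCL,
    "hepatic-clearance": HepaticClearance,
    "renal-filtration": RenalFiltration,
}
_INTERACTION_KINDS = {
    "induction": InductionAction,
    "inhibition": InhibitionAction,
}

_TOP_KEYS = {"name", "physchem", "processes", "interactions", "formulations"}
_PHYSCHEM_KEYS = {
    "molecular_weight",
    "lipophilicity",
    "solubility",
    "fraction_unbound",
    "intestinal_permeability",
    "partition_method",
}


def _dataclass_fields(cls) -> set[str]:
    return set(cls.__dataclass_fields__)


def serialize_drug(drug: DrugParameters) -> dict:
    """DrugParameters -> plain dict (YAML/JSON friendly)."""

    def proc_entry(proc: Process) -> dict:
        for kind, cls in _PROCESS_KINDS.items():
            if type(proc) is cls:
                entry = {"kind": kind}
                for f in proc.__dataclass_fields__:
                    value = getattr(proc, f)
                    if value is not None:
                        entry[f] = value
                return entry
        raise SchemaError(f"unknown process type {type(proc).__name__}")

    def action_entry(action: Interaction) -> dict:
        kind = "induction" if isinstance(action, InductionAction) else "inhibition"
        entry = {"kind": kind}
        for f in action.__dataclass_fields__:
            value = getattr(action, f)
            if value is not None:
                entry[f] = value
        return entry

    return {
        "name": drug.name,
        "physchem": {
            "molecular_weight": drug.molecular_weight,
            "lipophilicity": drug.lipophilicity,
            "solubility": drug.solubility,
            "fraction_unbound": drug.fraction_unbound,
            "intestinal_permeability": drug.intestinal_permeability,
            "partition_method": drug.partition_method,
        },
        "processes": [proc_entry(p) for p in drug.processes],
        "interactions": [action_entry(a) for a in drug.interactions],
        "formulations": {
            name: [
                {
                    f: getattr(spec, f)
                    for f in spec.__dataclass_fields__
                    if getattr(spec, f) is not None
                }
                for spec in specs
            ]
            for name, specs in drug.formulations.items()
        },
    }


def drug_from_dict(raw: dict) -> DrugParameters:
    """Validate and build DrugParameters from a plain dict; unknown keys are
    rejected with an error listing them."""
    if not isinstance(raw, dict):
        raise SchemaError("drug config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise SchemaError(f"unknown top-level keys: {sorted(unknown)}")
    for key in ("name", "physchem"):
        if key not in raw:
            raise SchemaError(f"missing required key {key!r}")
    physchem = dict(raw["physchem"])
    unknown = set(physchem) - _PHYSCHEM_KEYS
    if unknown:
        raise SchemaError(f"unknown physchem keys: {sorted(unknown)}")

    processes: list[Process] = []
    for entry in raw.get("processes", []):
        entry = dict(entry)
        kind = entry.pop("kind", None)
        if kind not in _PROCESS_KINDS:
            raise SchemaError(f"unknown process kind {kind!r}")
        cls = _PROCESS_KINDS[kind]
        unknown = set(entry) - _dataclass_fields(cls)
        if unknown:
            raise SchemaError(f"unknown keys for process {kind}: {sorted(unknown)}")
        try:
            processes.append(cls(**entry))
        except (TypeError, ValidationError) as exc:
            raise SchemaError(f"invalid process {kind}: {exc}") from exc

    interactions: list[Interaction] = []
    for entry in raw.get("interactions", []):
        entry = dict(entry)
        kind = entry.pop("kind", None)
        if kind not in _INTERACTION_KINDS:
            raise SchemaError(f"unknown interaction kind {kind!r}")
        cls = _INTERACTION_KINDS[kind]
        unknown = set(entry) - _dataclass_fields(cls)
        if unknown:
            raise SchemaError(
                f"unknown keys for interaction {kind}: {sorted(unknown)}"
            )
        try:
            interactions.append(cls(**entry))
        except (TypeError, ValidationError) as exc:
            raise SchemaError(f"invalid interaction {kind}: {exc}") from exc

    formulations: dict[str, list[FormulationSpec]] = {}
    for name, specs in raw.get("formulations", {}).items():
        out = []
        for entry in specs:
            entry = dict(entry)
            unknown = set(entry) - _dataclass_fields(FormulationSpec)
            if unknown:
                raise SchemaError(
                    f"unknown keys for formulation {name}: {sorted(unknown)}"
                )
            try:
                out.append(FormulationSpec(**entry))
            except (TypeError, ValidationError) as exc:
                raise SchemaError(f"invalid formulation {name}: {exc}") from exc
        formulations[name] = out

    try:
        return DrugParameters(
            name=raw["name"],
            processes=processes,
            interactions=interactions,
            formulations=formulations,
            **physchem,
        )
    except (TypeError, ValidationError) as exc:
        raise SchemaError(str(exc)) from exc


def load_drug_config(path) -> DrugParameters:
    """Load and schema-validate a drug config from a YAML/JSON file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return drug_from_dict(raw)


def copy_drug(drug: DrugParameters) -> DrugParameters:
    return copy.deepcopy(drug)
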