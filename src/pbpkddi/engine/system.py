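"""Whole-body ODE system assembly and integration.

Internal units are fixed: time in min, volumes in L, amounts in µmol,
concentrations in µM.  Doses in mg are converted through the molecular
weight at the boundary.

State layout (per drug, in order): 14 organ amounts, four lumen amounts
(stomach solid/dissolved, intestine solid/dissolved), cumulative urine,
cumulative metabolised sink, cumulative faecal loss.  After all drug blocks
follow the enzyme pools, one amount per (enzyme, expressing organ).
Eliminated material is moved into sink states, never destroyed, so the sum
over a drug's block (plus molar transfer to linked metabolites) balances the
administered dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from typing import TYPE_CHECKING

from ..errors import AssemblyError, IntegrationError, ValidationError

if TYPE_CHECKING:  # avoid a circular import; drugs.py consumes this module
    from ..drugs import DrugParameters
from ..physiology import ORGAN_NAMES, Individual
from .partition import rodgers_rowland_kp
from .processes import (
    HepaticClearance,
    InductionAction,
    InhibitionAction,
    RateLawMM,
    RateLawSpecificCL,
    RenalFiltration,
)
from .ratelaws import weibull_hazard

LN2 = math.log(2.0)

# organ indices (match physiology.ORGAN_NAMES)
VEN, ART, LUNG, LIV, KID, GUT = 0, 1, 2, 3, 4, 5
SPL = ORGAN_NAMES.index("spleen")
N_ORGANS = len(ORGAN_NAMES)

# per-drug extra states after the organ block
ST_SOLID, ST_DISS, IN_SOLID, IN_DISS, URINE, METAB, FECES = range(7)
N_EXTRA = 7
N_PER_DRUG = N_ORGANS + N_EXTRA

#: organs draining directly into the venous pool
_DIRECT_IDX = np.array(
    [i for i, n in enumerate(ORGAN_NAMES)
     if n not in ("venous blood", "arterial blood", "lung", "liver",
                  "gut wall", "spleen")]
)
#: organs receiving arterial inflow (everything downstream of the lung)
_TISSUE_IDX = np.array(
    [i for i, n in enumerate(ORGAN_NAMES)
     if n not in ("venous blood", "arterial blood", "lung")]
)


@dataclass(frozen=True)
class SolverConfig:
    """Engine tolerances and absorption-model constants (config-overridable)."""

    rtol: float = 1e-8
    atol: float = 1e-10  # µmol
    method: str = "LSODA"
    max_step: float = np.inf
    stomach_volume_l: float = 0.25
    intestine_volume_l: float = 0.65
    effective_surface_area_cm2: float = 6600.0
    gastric_half_life_fasted_min: float = 15.0
    gastric_half_life_fed_min: float = 60.0
    intestinal_transit_half_life_min: float = 180.0
    #: states below -negative_tolerance raise; values in [-tol, 0] are read as 0
    negative_tolerance: float = 1e-6


@dataclass(frozen=True)
class BoundDose:
    """A dose event bound to a loaded drug model."""

    drug: str
    time_min: float
    amount_mg: float
    formulation: str = "solution"
    food_state: str = "fasted"

    def __post_init__(self) -> None:
        if self.amount_mg < 0:
            raise ValidationError("dose amount must be >= 0")
        if self.time_min < 0:
            raise ValidationError("dose time must be >= 0")


@dataclass
class _MMReaction:
    drug: int
    organ: int
    pool: int
    k_cat: float
    K_m: float
    product: Optional[int]
    stoichiometry: float


@dataclass
class _SpecCLReaction:
    drug: int
    organ: int
    pool: int
    CL_spec: float
    product: Optional[int]
    stoichiometry: float


@dataclass
class _EnzymePool:
    enzyme: str
    organ: int
    E0: float  # µmol
    k_deg: float  # 1/min
    inducers: list[tuple[int, float, float]] = field(default_factory=list)
    inactivators: list[tuple[int, float, float]] = field(default_factory=list)
    competitive: list[tuple[int, float]] = field(default_factory=list)


class ODESystem:
    """Assembled right-hand side with dose events and state bookkeeping."""

    def __init__(
        self,
        individual: Individual,
        drugs: Sequence["DrugParameters"],
        doses: Sequence[BoundDose],
        config: SolverConfig,
    ):
        self.individual = individual
        self.drugs = list(drugs)
        self.config = config
        self.drug_index = {d.name: i for i, d in enumerate(self.drugs)}
        if len(self.drug_index) != len(self.drugs):
            raise AssemblyError("duplicate drug names in system")

        organs = [individual.organ(name) for name in ORGAN_NAMES]
        self.V = np.array([o.volume_l for o in organs])
        self.Q = np.array([o.blood_flow_l_min for o in organs])
        self.CO = individual.cardiac_output_l_min
        self.Q_liver_out = self.Q[LIV] + self.Q[GUT] + self.Q[SPL]

        # partition coefficients per drug per organ
        self.Kp = np.ones((len(self.drugs), N_ORGANS))
        self.fu = np.array([d.fraction_unbound for d in self.drugs])
        self.mw = np.array([d.molecular_weight for d in self.drugs])
        self.sol_um = np.array([d.solubility_um() for d in self.drugs])
        sa = config.effective_surface_area_cm2
        # cm/s * cm^2 -> cm^3/s -> L/min
        self.ka_vol = np.array(
            [d.intestinal_permeability * sa * 60.0 / 1000.0 for d in self.drugs]
        )
        for i, drug in enumerate(self.drugs):
            for j, organ in enumerate(organs):
                self.Kp[i, j] = rodgers_rowland_kp(
                    drug, organ, drug.fraction_unbound, individual.hematocrit
                )

        self._assemble_reactions(organs)

        self.n_states = N_PER_DRUG * len(self.drugs) + len(self.pools)
        self.doses = sorted(doses, key=lambda d: d.time_min)
        for dose in self.doses:
            if dose.drug not in self.drug_index:
                raise AssemblyError(f"dose references unloaded drug {dose.drug!r}")
            # validates the formulation reference early
            self.drugs[self.drug_index[dose.drug]].formulation(
                dose.formulation, dose.food_state
            )

        # mutable absorption context per drug: active formulation, reference
        # time of the most recent solid dose and current gastric emptying rate
        self._ctx = [
            {
                "form": None,
                "t_ref": 0.0,
                "k_ge": LN2 / config.gastric_half_life_fasted_min,
            }
            for _ in self.drugs
        ]

        self.state_labels = self._make_labels()

    # ------------------------------------------------------------------
    def _assemble_reactions(self, organs) -> None:
        enzymes = {e.name: e for e in self.individual.enzymes}

        # collect every enzyme referenced by any loaded drug
        referenced: list[str] = []
        for drug in self.drugs:
            for proc in drug.processes:
                enzyme = getattr(proc, "enzyme", None)
                if enzyme is not None and enzyme not in referenced:
                    referenced.append(enzyme)
            for action in drug.interactions:
                if action.target_enzyme not in referenced:
                    referenced.append(action.target_enzyme)

        self.pools: list[_EnzymePool] = []
        pool_index: dict[tuple[str, int], int] = {}
        for name in referenced:
            spec = enzymes.get(name)
            if spec is None or not any(
                c > 0 for c in spec.organ_concentration.values()
            ):
                raise AssemblyError(
                    f"enzyme {name!r} is referenced but not expressed in the "
                    f"individual"
                )
            for organ_name, conc in spec.organ_concentration.items():
                if conc <= 0:
                    continue
                idx = ORGAN_NAMES.index(organ_name)
                pool = _EnzymePool(
                    enzyme=name,
                    organ=idx,
                    E0=conc * self.V[idx],
                    k_deg=spec.k_deg_in(organ_name),
                )
                pool_index[(name, idx)] = len(self.pools)
                self.pools.append(pool)

        self.mm_reactions: list[_MMReaction] = []
        self.cl_reactions: list[_SpecCLReaction] = []
        self.hepatic_cl = np.zeros(len(self.drugs))
        self.gfr_fraction = np.zeros(len(self.drugs))

        for i, drug in enumerate(self.drugs):
            for proc in drug.processes:
                if isinstance(proc, (RateLawMM, RateLawSpecificCL)):
                    product = getattr(proc, "product", None)
                    if product is not None:
                        if product not in self.drug_index:
                            raise AssemblyError(
                                f"{drug.name}: metabolite {product!r} is not a "
                                f"loaded drug model"
                            )
                        product_idx: Optional[int] = self.drug_index[product]
                    else:
                        product_idx = None
                    for (name, organ_idx), p_idx in pool_index.items():
                        if name != proc.enzyme:
                            continue
                        if isinstance(proc, RateLawMM):
                            self.mm_reactions.append(
                                _MMReaction(
                                    i, organ_idx, p_idx, proc.k_cat, proc.K_m,
                                    product_idx, proc.stoichiometry,
                                )
                            )
                        else:
                            self.cl_reactions.append(
                                _SpecCLReaction(
                                    i, organ_idx, p_idx, proc.CL_spec,
                                    product_idx, proc.stoichiometry,
                                )
                            )
                elif isinstance(proc, HepaticClearance):
                    self.hepatic_cl[i] += proc.CL_spec
                elif isinstance(proc, RenalFiltration):
                    self.gfr_fraction[i] = proc.gfr_fraction

            for action in drug.interactions:
                for pool in self.pools:
                    if pool.enzyme != action.target_enzyme:
                        continue
                    if isinstance(action, InductionAction):
                        pool.inducers.append((i, action.EC_50, action.E_max))
                    elif isinstance(action, InhibitionAction):
                        if action.mode == "mechanism-based":
                            pool.inactivators.append(
                                (i, action.K_I, action.k_inact)
                            )
                        else:
                            pool.competitive.append((i, action.K_i))

    def _make_labels(self) -> list[str]:
        labels = []
        extra = [
            "lumen stomach solid (µmol)",
            "lumen stomach dissolved (µmol)",
            "lumen intestine solid (µmol)",
            "lumen intestine dissolved (µmol)",
            "urine cumulative (µmol)",
            "metabolised sink cumulative (µmol)",
            "faeces cumulative (µmol)",
        ]
        for drug in self.drugs:
            labels += [f"{drug.name}: {name} amount (µmol)" for name in ORGAN_NAMES]
            labels += [f"{drug.name}: {e}" for e in extra]
        labels += [
            f"enzyme {p.enzyme} in {ORGAN_NAMES[p.organ]} (µmol)"
            for p in self.pools
        ]
        return labels

    # ------------------------------------------------------------------
    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        offset = N_PER_DRUG * len(self.drugs)
        for k, pool in enumerate(self.pools):
            y0[offset + k] = pool.E0
        return y0

    def drug_block(self, drug: str) -> slice:
        i = self.drug_index[drug]
        return slice(i * N_PER_DRUG, (i + 1) * N_PER_DRUG)

    def organ_index(self, drug: str, organ: str) -> int:
        return self.drug_index[drug] * N_PER_DRUG + ORGAN_NAMES.index(organ)

    def extra_index(self, drug: str, which: int) -> int:
        return self.drug_index[drug] * N_PER_DRUG + N_ORGANS + which

    def pool_offset(self) -> int:
        return N_PER_DRUG * len(self.drugs)

    def apply_dose(self, y: np.ndarray, dose: BoundDose) -> None:
        i = self.drug_index[dose.drug]
        drug = self.drugs[i]
        spec = drug.formulation(dose.formulation, dose.food_state)
        amount_umol = dose.amount_mg * 1000.0 / drug.molecular_weight
        base = i * N_PER_DRUG + N_ORGANS
        if spec.kind == "dissolved":
            y[base + ST_DISS] += amount_umol
        else:
            y[base + ST_SOLID] += amount_umol
            self._ctx[i]["form"] = spec
            self._ctx[i]["t_ref"] = dose.time_min
        half_life = (
            self.config.gastric_half_life_fed_min
            if dose.food_state == "fed"
            else self.config.gastric_half_life_fasted_min
        )
        self._ctx[i]["k_ge"] = LN2 / half_life

    # ------------------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        nd = len(self.drugs)
        cfg = self.config
        dy = np.zeros_like(y)
        offset = self.pool_offset()
        E = np.maximum(y[offset:], 0.0)

        # plasma-equivalent and unbound concentrations per drug per organ
        Cp = np.empty((nd, N_ORGANS))
        for i in range(nd):
            A = np.maximum(y[i * N_PER_DRUG : i * N_PER_DRUG + N_ORGANS], 0.0)
            Cp[i] = A / self.V / self.Kp[i]
        Cu = Cp * self.fu[:, None]

        k_int = LN2 / cfg.intestinal_transit_half_life_min

        for i in range(nd):
            base = i * N_PER_DRUG
            dA = dy[base : base + N_ORGANS]
            # vascular exchange
            dA[_TISSUE_IDX] += self.Q[_TISSUE_IDX] * Cp[i, ART]
            dA[_DIRECT_IDX] -= self.Q[_DIRECT_IDX] * Cp[i, _DIRECT_IDX]
            dA[GUT] -= self.Q[GUT] * Cp[i, GUT]
            dA[SPL] -= self.Q[SPL] * Cp[i, SPL]
            dA[LIV] += (
                self.Q[GUT] * Cp[i, GUT]
                + self.Q[SPL] * Cp[i, SPL]
                - self.Q_liver_out * Cp[i, LIV]
            )
            dA[VEN] += (
                float(np.dot(self.Q[_DIRECT_IDX], Cp[i, _DIRECT_IDX]))
                + self.Q_liver_out * Cp[i, LIV]
                - self.CO * Cp[i, VEN]
            )
            dA[LUNG] += self.CO * (Cp[i, VEN] - Cp[i, LUNG])
            dA[ART] += self.CO * (Cp[i, LUNG] - Cp[i, ART])

            # renal filtration (from kidney plasma into the urine sink)
            if self.gfr_fraction[i] > 0:
                filt = (
                    self.gfr_fraction[i]
                    * self.individual.gfr_l_min
                    * self.fu[i]
                    * Cp[i, KID]
                )
                dA[KID] -= filt
                dy[base + N_ORGANS + URINE] += filt

            # unspecific hepatic clearance on unbound intracellular liver drug
            if self.hepatic_cl[i] > 0:
                v = self.hepatic_cl[i] * Cu[i, LIV] * self.V[LIV]
                dA[LIV] -= v
                dy[base + N_ORGANS + METAB] += v

            # lumen: release, gastric emptying, absorption, transit
            ctx = self._ctx[i]
            st_solid = max(y[base + N_ORGANS + ST_SOLID], 0.0)
            st_diss = max(y[base + N_ORGANS + ST_DISS], 0.0)
            in_solid = max(y[base + N_ORGANS + IN_SOLID], 0.0)
            in_diss = max(y[base + N_ORGANS + IN_DISS], 0.0)
            k_ge = ctx["k_ge"]
            if ctx["form"] is not None and (st_solid > 0 or in_solid > 0):
                h = weibull_hazard(t - ctx["t_ref"], ctx["form"])
            else:
                h = 0.0
            # dissolution capped by the luminal solubility
            sat_st = max(
                0.0, 1.0 - st_diss / cfg.stomach_volume_l / self.sol_um[i]
            )
            sat_in = max(
                0.0, 1.0 - in_diss / cfg.intestine_volume_l / self.sol_um[i]
            )
            rel_st = h * st_solid * sat_st
            rel_in = h * in_solid * sat_in
            absorbed = self.ka_vol[i] * in_diss / cfg.intestine_volume_l

            dy[base + N_ORGANS + ST_SOLID] += -rel_st - k_ge * st_solid
            dy[base + N_ORGANS + ST_DISS] += rel_st - k_ge * st_diss
            dy[base + N_ORGANS + IN_SOLID] += (
                k_ge * st_solid - rel_in - k_int * in_solid
            )
            dy[base + N_ORGANS + IN_DISS] += (
                k_ge * st_diss + rel_in - absorbed - k_int * in_diss
            )
            dy[base + N_ORGANS + FECES] += k_int * (in_solid + in_diss)
            dA[GUT] += absorbed

        # metabolic reactions
        for r in self.mm_reactions:
            km_app = r.K_m
            pool = self.pools[r.pool]
            for j, k_i in pool.competitive:
                if j != r.drug:
                    km_app *= 1.0 + Cu[j, r.organ] / k_i
            s = Cu[r.drug, r.organ]
            v = E[r.pool] * r.k_cat * s / (km_app + s)
            self._apply_reaction(dy, r, v)

        for r in self.cl_reactions:
            pool = self.pools[r.pool]
            e_norm = E[r.pool] / pool.E0
            s_amount = Cu[r.drug, r.organ] * self.V[r.organ]
            v = e_norm * r.CL_spec * s_amount
            self._apply_reaction(dy, r, v)

        # enzyme turnover with induction and mechanism-based inactivation
        for k, pool in enumerate(self.pools):
            f_ind = 1.0
            for j, ec50, emax in pool.inducers:
                c = Cu[j, pool.organ]
                f_ind *= 1.0 + emax * c / (ec50 + c)
            r_inact = 0.0
            for j, k_I, k_inact in pool.inactivators:
                c = Cu[j, pool.organ]
                r_inact += k_inact * c / (k_I + c)
            dy[offset + k] = (
                pool.k_deg * pool.E0 * f_ind - (pool.k_deg + r_inact) * E[k]
            )

        return dy

    def _apply_reaction(self, dy, r, v: float) -> None:
        base = r.drug * N_PER_DRUG
        dy[base + r.organ] -= v
        if r.product is None:
            dy[base + N_ORGANS + METAB] += v
        else:
            pbase = r.product * N_PER_DRUG
            dy[pbase + r.organ] += r.stoichiometry * v
            if r.stoichiometry < 1.0:
                dy[base + N_ORGANS + METAB] += (1.0 - r.stoichiometry) * v

    # ------------------------------------------------------------------
    def total_drug_equivalents(self, y: np.ndarray) -> float:
        """Sum of all drug states (µmol); conserved at the cumulative dose for
        1:1 molar metabolite links."""
        return float(np.sum(y[: N_PER_DRUG * len(self.drugs)]))


def build_system(
    individual: Individual,
    drugs: Sequence["DrugParameters"],
    doses: Sequence[BoundDose],
    config: SolverConfig | None = None,
) -> ODESystem:
    """Assemble the coupled whole-body system for the loaded drug models.

    Every enzyme referenced by a drug must be expressed in the individual and
    every metabolite product must resolve to a loaded drug model; violations
    raise :class:`AssemblyError` naming the missing reference.
    """
    return ODESystem(individual, drugs, doses, config or SolverConfig())


def integrate(
    system,
    t_grid: np.ndarray,
    rtol: float | None = None,
    atol: float | None = None,
) -> np.ndarray:
    """Integrate ``system`` over ``t_grid`` (min), handling dose events by
    state re-initialisation at the event times.

    ``system`` needs ``rhs``, ``initial_state``, ``doses``, ``apply_dose``
    and a ``config``; degenerate test systems satisfying that contract
    integrate the same way as the full model.

    Returns the trajectory with shape ``(len(t_grid), n_states)``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValidationError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be strictly increasing")
    if t_grid[0] < 0:
        raise ValidationError("t_grid must start at or after time 0")

    cfg = getattr(system, "config", SolverConfig())
    rtol = cfg.rtol if rtol is None else rtol
    atol = cfg.atol if atol is None else atol
    neg_tol = getattr(cfg, "negative_tolerance", 1e-6)

    t_end = t_grid[-1]
    doses = [d for d in getattr(system, "doses", []) if d.time_min < t_end]
    boundaries = sorted({0.0, t_end} | {d.time_min for d in doses})

    y = system.initial_state().astype(float)
    out = np.empty((len(t_grid), len(y)))
    filled = np.zeros(len(t_grid), dtype=bool)

    for seg_idx in range(len(boundaries)):
        t0 = boundaries[seg_idx]
        for dose in doses:
            if dose.time_min == t0:
                system.apply_dose(y, dose)
        if seg_idx + 1 >= len(boundaries):
            break
        t1 = boundaries[seg_idx + 1]
        # record grid points that coincide with the segment start
        at_start = np.isclose(t_grid, t0, rtol=0.0, atol=1e-9) & ~filled
        out[at_start] = y
        filled |= at_start

        mask = (t_grid > t0) & (t_grid <= t1) & ~filled
        t_eval = t_grid[mask]
        sol = solve_ivp(
            system.rhs,
            (t0, t1),
            y,
            method=cfg.method,
            t_eval=t_eval if len(t_eval) else None,
            rtol=rtol,
            atol=atol,
            max_step=cfg.max_step,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed at t = {sol.t[-1]:.6g} min: {sol.message}"
            )
        if len(t_eval):
            traj = sol.y.T
            if traj.min() < -neg_tol:
                bad = np.unravel_index(np.argmin(sol.y), sol.y.shape)
                raise IntegrationError(
                    f"state {bad[0]} fell below -{neg_tol:g} at "
                    f"t = {sol.t[bad[1]]:.6g} min"
                )
            out[mask] = np.clip(traj, 0.0, None)
            filled[mask] = True
        y = sol.y[:, -1].copy()
        if y.min() < -neg_tol:
            raise IntegrationError(
                f"state fell below -{neg_tol:g} at t = {t1:.6g} min"
            )
        y = np.clip(y, 0.0, None)

    at_start = np.isclose(t_grid, t_end, rtol=0.0, atol=1e-9) & ~filled
    out[at_start] = y
    filled |= at_start
    if not filled.all():
        raise IntegrationError("internal error: unevaluated grid points")
    return out
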