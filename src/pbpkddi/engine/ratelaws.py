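"""Elementary rate laws of the whole-body model.

All functions are pure and unit-consistent with the engine's internal unit
system (min, L, µmol, µM).
"""

from __future__ import annotations

import math

from ..errors import ValidationError
from .processes import FormulationSpec

LN2 = math.log(2.0)


def mm_rate(E_amount: float, k_cat: float, S_conc: float, K_m: float) -> float:
    """Michaelis-Menten velocity v = E * k_cat * S / (K_m + S), µmol/min.

    ``E_amount`` is the enzyme amount in µmol, ``S_conc`` the unbound
    substrate concentration in µM.
    """
    if E_amount < 0 or k_cat < 0 or S_conc < 0 or K_m <= 0:
        raise ValidationError("mm_rate requires non-negative inputs and K_m > 0")
    return E_amount * k_cat * S_conc / (K_m + S_conc)


def specific_cl_rate(E_norm: float, CL_spec: float, S_amount: float) -> float:
    """First-order enzymatic clearance v = (E/E0) * CL_spec * S, µmol/min.

    ``E_norm`` is the enzyme amount relative to its baseline, so that at
    baseline expression v = CL_spec * S and induction scales v linearly.
    """
    if E_norm < 0 or CL_spec < 0 or S_amount < 0:
        raise ValidationError("specific_cl_rate requires non-negative inputs")
    return E_norm * CL_spec * S_amount


def induction_factor(C_u: float, EC_50: float, E_max: float) -> float:
    """Synthesis multiplier f = 1 + E_max * C_u / (EC_50 + C_u) in [1, 1+E_max]."""
    if C_u < 0 or EC_50 <= 0 or E_max < 0:
        raise ValidationError(
            "induction_factor requires C_u >= 0, EC_50 > 0, E_max >= 0"
        )
    return 1.0 + E_max * C_u / (EC_50 + C_u)


def enzyme_turnover_rhs(
    E: float, E_0: float, k_deg: float, f_ind: float = 1.0, inact_rate: float = 0.0
) -> float:
    """dE/dt = k_deg * E_0 * f_ind - (k_deg + inact_rate) * E.

    Zero-order synthesis (stimulated by induction) balanced against
    first-order degradation plus mechanism-based inactivation.
    """
    if E < 0 or E_0 < 0 or k_deg <= 0:
        raise ValidationError("enzyme_turnover_rhs requires E, E_0 >= 0, k_deg > 0")
    return k_deg * E_0 * f_ind - (k_deg + inact_rate) * E


def mbi_inactivation_rate(I_u: float, K_I: float, k_inact: float) -> float:
    """Mechanism-based inactivation rate r = k_inact * I_u / (K_I + I_u), 1/min."""
    if I_u < 0 or K_I <= 0 or k_inact < 0:
        raise ValidationError(
            "mbi_inactivation_rate requires I_u >= 0, K_I > 0, k_inact >= 0"
        )
    return k_inact * I_u / (K_I + I_u)


def competitive_km(K_m: float, I_u: float, K_i: float) -> float:
    """Apparent K_m under competitive inhibition: K_m * (1 + I_u / K_i)."""
    if K_i <= 0:
        raise ValidationError("K_i must be > 0")
    if K_m <= 0 or I_u < 0:
        raise ValidationError("competitive_km requires K_m > 0 and I_u >= 0")
    return K_m * (1.0 + I_u / K_i)


def gfr_filtration_rate(
    C_plasma: float, fu: float, GFR: float, gfr_fraction: float
) -> float:
    """Urinary excretion rate = gfr_fraction * GFR * fu * C_plasma, µmol/min.

    ``GFR`` in L/min, ``C_plasma`` in µM.  A gfr_fraction < 1 represents net
    tubular reabsorption after passive glomerular filtration.
    """
    if C_plasma < 0 or fu < 0 or GFR < 0:
        raise ValidationError("gfr_filtration_rate requires non-negative inputs")
    if not 0.0 <= gfr_fraction <= 1.0:
        raise ValidationError("gfr_fraction must lie in [0, 1]")
    return gfr_fraction * GFR * fu * C_plasma


def weibull_release(t: float, spec: FormulationSpec) -> float:
    """Cumulative fraction released at time ``t`` (min) since administration.

    0 for t <= lag, then 1 - exp(-ln2 * ((t - lag)/t_50)^shape), so that half
    the dose is released at lag + t_50.  A dissolved formulation releases
    instantly.
    """
    if t < 0:
        raise ValidationError("t must be >= 0")
    if spec.kind == "dissolved":
        return 1.0
    if t <= spec.lag:
        return 0.0
    return 1.0 - math.exp(-LN2 * ((t - spec.lag) / spec.t_50) ** spec.shape)


def weibull_hazard(t: float, spec: FormulationSpec) -> float:
    """Instantaneous release rate constant (1/min) of the remaining solid.

    h(t) = ln2 * shape * (t - lag)^(shape - 1) / t_50^shape for t > lag,
    the hazard of the Weibull release profile, applied to the undissolved
    amount so that single-dose release reproduces :func:`weibull_release`.
    """
    if spec.kind == "dissolved":
        return 0.0
    tau = t - spec.lag
    if tau <= 0.0:
        return 0.0
    return LN2 * spec.shape * tau ** (spec.shape - 1.0) / spec.t_50**spec.shape
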