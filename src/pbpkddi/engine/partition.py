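"""Tissue:plasma partition coefficients for neutral species.

Implements the neutral-compound form of the Rodgers-Rowland tissue
composition equations: partitioning into tissue water, neutral lipids and
neutral phospholipids.  Ionisation and acidic-phospholipid binding terms are
not needed for neutral drugs (the packaged compounds carry no pKa).
"""

from __future__ import annotations

from ..errors import ConfigurationError, ValidationError
from ..physiology import BLOOD_COMPARTMENTS, OrganSpec

#: log10 transform from octanol:water to vegetable-oil:water partitioning,
#: applied to the neutral-lipid term of adipose tissue
_VO_SLOPE = 1.115
_VO_INTERCEPT = -1.35


def rodgers_rowland_kp(
    drug, organ: OrganSpec, fu: float, hematocrit: float = 0.43
) -> float:
    """Tissue:plasma partition coefficient Kp for a neutral compound.

    ``drug`` must expose a ``lipophilicity`` attribute (log units).  The
    unbound tissue:plasma ratio is

        Kpu = f_EW + f_IW + P * f_NL + (0.3 P + 0.7) * f_NP

    with P = 10^logP (vegetable-oil:water surrogate for adipose), and
    Kp = fu * Kpu.  Blood compartments are plasma pools with Kp = 1.
    ``hematocrit`` is accepted for interface compatibility; red-cell
    partitioning is not modelled for neutral species.
    """
    if not 0.0 < fu <= 1.0:
        raise ValidationError(f"fu must lie in (0, 1], got {fu}")
    logp = getattr(drug, "lipophilicity", None)
    if logp is None:
        raise ConfigurationError("drug record has no lipophilicity")

    if organ.name in BLOOD_COMPARTMENTS:
        return 1.0

    comp = organ.composition
    if comp is None:
        raise ConfigurationError(f"organ {organ.name} has no composition fractions")

    if organ.name == "adipose":
        p_nl = 10.0 ** (_VO_SLOPE * logp + _VO_INTERCEPT)
    else:
        p_nl = 10.0**logp

    kpu = (
        comp.f_extracellular_water
        + comp.f_intracellular_water
        + p_nl * comp.f_neutral_lipids
        + (0.3 * p_nl + 0.7) * comp.f_neutral_phospholipids
    )
    kp = fu * kpu
    if kp <= 0:
        raise ConfigurationError(
            f"non-positive Kp computed for organ {organ.name}"
        )
    return kp
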