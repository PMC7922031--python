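"""Process and interaction descriptors bound into the ODE system."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ..errors import ValidationError

KNOWN_ENZYMES = ("CYP3A4", "CYP2C8", "CYP2B6", "UGT2B7", "EPHX1")


@dataclass
class RateLawMM:
    """Michaelis-Menten metabolism: v = E * k_cat * S / (K_m + S)."""

    enzyme: str
    K_m: float  # µM
    k_cat: float  # 1/min
    product: Optional[str] = None  # metabolite drug name (molar 1:1 by default)
    stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        if self.K_m <= 0:
            raise ValidationError(f"{self.enzyme}: K_m must be > 0")
        if self.k_cat < 0:
            raise ValidationError(f"{self.enzyme}: k_cat must be >= 0")
        if not 0.0 <= self.stoichiometry <= 1.0:
            raise ValidationError("stoichiometry must lie in [0, 1]")


@dataclass
class RateLawSpecificCL:
    """First-order enzymatic clearance: v = (E/E0) * CL_spec * S."""

    enzyme: str
    CL_spec: float  # 1/min
    product: Optional[str] = None
    stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        if self.CL_spec < 0:
            raise ValidationError(f"{self.enzyme}: CL_spec must be >= 0")


@dataclass
class HepaticClearance:
    """Unspecific first-order clearance on unbound intracellular liver drug."""

    CL_spec: float  # 1/min

    def __post_init__(self) -> None:
        if self.CL_spec < 0:
            raise ValidationError("CL_hep must be >= 0")


@dataclass
class RenalFiltration:
    """Passive glomerular filtration with net tubular reabsorption expressed
    as a GFR fraction <= 1."""

    gfr_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gfr_fraction <= 1.0:
            raise ValidationError("gfr_fraction must lie in [0, 1]")


@dataclass
class InductionAction:
    """Maximum-effect stimulation of enzyme synthesis by the unbound inducer
    concentration at the enzyme's location."""

    target_enzyme: str
    EC_50: float  # µM, unbound
    E_max: float  # fold-increase of synthesis at saturation

    def __post_init__(self) -> None:
        if self.EC_50 <= 0:
            raise ValidationError("EC_50 must be > 0")
        if self.E_max < 0:
            raise ValidationError("E_max must be >= 0")


@dataclass
class InhibitionAction:
    """Competitive or mechanism-based enzyme inhibition.

    Competitive mode requires ``K_i``; mechanism-based mode requires ``K_I``
    and ``k_inact``.  Exactly the fields of the declared mode must be set.
    """

    target_enzyme: str
    mode: str  # "competitive" | "mechanism-based"
    K_i: Optional[float] = None  # µM (competitive)
    K_I: Optional[float] = None  # µM (mechanism-based)
    k_inact: Optional[float] = None  # 1/min (mechanism-based)

    def __post_init__(self) -> None:
        if self.mode == "competitive":
            if self.K_i is None or self.K_I is not None or self.k_inact is not None:
                raise ValidationError(
                    "competitive inhibition requires K_i and only K_i"
                )
            if self.K_i <= 0:
                raise ValidationError("K_i must be > 0")
        elif self.mode == "mechanism-based":
            if self.K_I is None or self.k_inact is None or self.K_i is not None:
                raise ValidationError(
                    "mechanism-based inhibition requires K_I and k_inact only"
                )
            if self.K_I <= 0 or self.k_inact <= 0:
                raise ValidationError("K_I and k_inact must be > 0")
        else:
            raise ValidationError(f"unknown inhibition mode {self.mode!r}")


@dataclass
class FormulationSpec:
    """Oral formulation: immediately dissolved, or Weibull-release solid.

    For the Weibull kind, ``t_50`` is the time (min) to 50% cumulative
    release after the lag, with f(lag + t_50) = 0.5 by the ln 2 convention.
    """

    kind: str  # "dissolved" | "weibull"
    t_50: Optional[float] = None  # min
    shape: Optional[float] = None
    lag: float = 0.0  # min
    food_state: str = "fasted"

    def __post_init__(self) -> None:
        if self.kind not in ("dissolved", "weibull"):
            raise ValidationError(f"unknown formulation kind {self.kind!r}")
        if self.food_state not in ("fasted", "fed"):
            raise ValidationError(f"unknown food_state {self.food_state!r}")
        if self.kind == "weibull":
            if self.t_50 is None or self.t_50 <= 0:
                raise ValidationError("weibull formulation requires t_50 > 0")
            if self.shape is None or self.shape <= 0:
                raise ValidationError("weibull formulation requires shape > 0")
            if self.lag < 0:
                raise ValidationError("lag must be >= 0")
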