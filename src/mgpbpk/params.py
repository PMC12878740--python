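"""Parameter sets for the magnesium-implant PBPK model.

The model tracks the "exposed" (exchangeable) Mg(II) pool in four
compartments — serum, bone, bulk tissue, and the small tissue zone
surrounding each implant.  This module defines the physiological
constants for a healthy adult, the implant scaling rules, the renal and
dietary intervention settings, and the homeostatic (pre-implant)
reference state used to normalize every concentration.

Units are fixed throughout the package: days, litres, mmol.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "PhysiologyParams",
    "ImplantConfig",
    "InterventionConfig",
    "HomeostaticState",
    "ParameterError",
    "validate_params",
    "scale_implants",
    "renal_adjust",
    "homeostatic_state",
    "DEFAULT_SIGMA0",
    "DEFAULT_VI0",
]

#: Default per-implant Mg release rate (mmol/day), representative of a
#: 3.2 x 32 mm screw; varies with alloy and implant size.
DEFAULT_SIGMA0 = 0.05
#: Default per-implant affected-tissue volume (L).
DEFAULT_VI0 = 0.00527


class ParameterError(ValueError):
    """A model parameter violates one of its physical invariants."""


@dataclass(frozen=True)
class PhysiologyParams:
    """Physiological constants of the healthy-adult reference model.

    Attributes
    ----------
    Vs, Vr, VN, VTtot
        Volumes (L) of serum, red blood cells, bone, and total tissue.
    phiD
        Dietary Mg intake rate after intestinal absorption (mmol/day).
    gamma
        Urinary excretion rate constant (L/day).
    mu1, mu_1
        Serum->bone and bone->serum exchange rate constants (L/day).
    k1, k_1
        Serum->tissue and tissue->serum exchange rate constants (L/day).
    phi
        Volume fraction of exposed Mg in bone (dimensionless).
    xi1, xi2, xi3
        Equilibrium concentration-ratio constants absorbing the
        unexposed pools (serum, RBC, tissue; dimensionless).
    C_hom, C_hyp, C_sev
        Total serum Mg concentrations (mmol/L): homeostatic level,
        hypermagnesemia threshold, and severe/dangerous level.
    """

    Vs: float = 3.0
    Vr: float = 2.0
    VN: float = 12.3
    VTtot: float = 52.7
    phiD: float = 6.0
    gamma: float = 10.9
    mu1: float = 6.05
    mu_1: float = 0.0775
    k1: float = 138.0
    k_1: float = 34.7
    phi: float = 0.3
    xi1: float = 0.538
    xi2: float = 0.452
    xi3: float = 3.00
    C_hom: float = 0.85
    C_hyp: float = 1.05
    C_sev: float = 2.9

    def __post_init__(self) -> None:
        validate_params(self)

    @property
    def Gamma(self) -> float:
        """Dimensionless kidney-function parameter gamma/k1 (read-only)."""
        return self.gamma / self.k1

    def replace(self, **changes: float) -> "PhysiologyParams":
        return dataclasses.replace(self, **changes)


def validate_params(raw: PhysiologyParams) -> PhysiologyParams:
    """Check every invariant of a parameter set; return it unchanged.

    Raises
    ------
    ParameterError
        Naming the first violated invariant.
    """
    for name in ("Vs", "Vr", "VN", "VTtot", "phiD", "gamma",
                 "mu1", "mu_1", "k1", "k_1"):
        value = getattr(raw, name)
        if not value > 0:
            raise ParameterError(f"{name} must be strictly positive, got {value}")
    if not (0 < raw.phi <= 1):
        raise ParameterError(f"phi must lie in (0, 1], got {raw.phi}")
    for name in ("xi1", "xi2", "xi3"):
        value = getattr(raw, name)
        if value < 0:
            raise ParameterError(f"{name} must be nonnegative, got {value}")
    if not raw.C_hom > 0:
        raise ParameterError(f"C_hom must be strictly positive, got {raw.C_hom}")
    if not (raw.C_hom < raw.C_hyp < raw.C_sev):
        raise ParameterError(
            "threshold ordering C_hom < C_hyp < C_sev violated: "
            f"C_hom={raw.C_hom}, C_hyp={raw.C_hyp}, C_sev={raw.C_sev}"
        )
    return raw


@dataclass(frozen=True)
class ImplantConfig:
    """Total implant source term, built from per-implant quantities.

    ``n`` identical implants each releasing ``sigma0`` mmol/day into a
    local tissue zone of volume ``VI0`` combine linearly (assuming the
    zones do not overlap): ``sigma = n*sigma0``, ``VI = n*VI0`` and
    ``xi = VI/VTtot``.  The same scaling describes a single larger or
    porous implant with ``n`` times the surface area of a screw.
    """

    n: int
    sigma0: float
    VI0: float
    sigma: float
    VI: float
    xi: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError(f"implant count n must be >= 1, got {self.n}")
        # sigma0 = 0 is a valid (inert-implant) configuration of the ODE
        # system; scale_implants additionally requires sigma0 > 0.
        if self.sigma0 < 0:
            raise ParameterError(f"sigma0 must be nonnegative, got {self.sigma0}")
        if not self.VI0 > 0:
            raise ParameterError(f"VI0 must be strictly positive, got {self.VI0}")
        if not (0 < self.xi < 1):
            raise ParameterError(
                f"xi = VI/VTtot must lie in (0, 1) for non-overlapping implant "
                f"zones, got {self.xi}"
            )

    @classmethod
    def from_totals(cls, sigma: float, VI: float,
                    params: PhysiologyParams) -> "ImplantConfig":
        """Build a config directly from total release rate and zone volume.

        Used for implants that are not multiples of the reference screw,
        e.g. a large plate specified by its own affected-tissue volume.
        """
        return cls(n=1, sigma0=sigma, VI0=VI, sigma=sigma, VI=VI,
                   xi=VI / params.VTtot)


def scale_implants(sigma0: float, VI0: float, n: int,
                   params: PhysiologyParams) -> ImplantConfig:
    """Scale per-implant release rate and zone volume to ``n`` implants.

    Raises
    ------
    ParameterError
        If ``n*VI0 >= VTtot`` (implant zones would overlap, xi >= 1) or
        any per-implant quantity is nonpositive.
    """
    if n < 1:
        raise ParameterError(f"implant count n must be >= 1, got {n}")
    if not sigma0 > 0:
        raise ParameterError(f"sigma0 must be strictly positive, got {sigma0}")
    if not VI0 > 0:
        raise ParameterError(f"VI0 must be strictly positive, got {VI0}")
    xi = n * VI0 / params.VTtot
    if xi >= 1:
        raise ParameterError(
            f"total implant-zone volume n*VI0 = {n * VI0} L exceeds the "
            f"tissue volume VTtot = {params.VTtot} L (xi = {xi} >= 1)"
        )
    return ImplantConfig(n=n, sigma0=sigma0, VI0=VI0,
                         sigma=n * sigma0, VI=n * VI0, xi=xi)


@dataclass(frozen=True)
class InterventionConfig:
    """Clinical intervention settings.

    rho scales the external (dietary/drug) Mg intake: 1 is a normal
    diet, 0 is zero external intake.  renal_fraction is gamma/gamma0,
    the kidney excretion constant relative to healthy (1 = healthy).
    """

    rho: float = 1.0
    renal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.rho <= 1):
            raise ParameterError(f"rho must lie in [0, 1], got {self.rho}")
        if not (0 < self.renal_fraction <= 1):
            raise ParameterError(
                f"renal_fraction must lie in (0, 1], got {self.renal_fraction}"
            )


def renal_adjust(params: PhysiologyParams,
                 renal_fraction: float) -> PhysiologyParams:
    """Scale kidney function, preserving pre-implant homeostasis.

    Reduced kidney function is modelled as ``gamma -> f*gamma`` with the
    intake ``phiD -> f*phiD`` covarying, so the homeostatic exposed
    serum level phiD/gamma is unchanged and the patient starts at the
    same equilibrium before the implant is installed.
    """
    if not (0 < renal_fraction <= 1):
        raise ParameterError(
            f"renal_fraction must lie in (0, 1], got {renal_fraction}"
        )
    return params.replace(gamma=renal_fraction * params.gamma,
                          phiD=renal_fraction * params.phiD)


@dataclass(frozen=True)
class HomeostaticState:
    """Pre-implant equilibrium of the exposed pools (the sigma=0, rho=1
    steady state) plus the normalized clinical thresholds.

    Cse = phiD/gamma, CNe = (mu1/mu_1)*Cse, CTe = (k1/k_1)*Cse, all in
    mmol/L; Chyp_star = C_hyp/C_hom and Csev_star = C_sev/C_hom are the
    thresholds on the normalized scale where homeostasis is 1.
    """

    Cse: float
    CNe: float
    CTe: float
    Chyp_star: float
    Csev_star: float


def homeostatic_state(params: PhysiologyParams) -> HomeostaticState:
    """Compute the homeostatic reference state from validated parameters."""
    Cse = params.phiD / params.gamma
    return HomeostaticState(
        Cse=Cse,
        CNe=params.mu1 / params.mu_1 * Cse,
        CTe=params.k1 / params.k_1 * Cse,
        Chyp_star=params.C_hyp / params.C_hom,
        Csev_star=params.C_sev / params.C_hom,
    )
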