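"""Closed-form approximations and derived clinical quantities.

For a small implant-zone fraction xi = VI/VTtot << 1 the model admits
simple exponential approximations.  The systemic compartments (serum,
bone, tissue) rise together toward the new steady state on the single
slow time scale

    TMg = (1/gamma) [ (1+xi1) Vs + xi2 Vr + (mu1/mu_1) phi VN
                      + (1+xi3) (k1/k_1) VTtot ]

(the total effective exposed-Mg capacity of the body divided by the
excretion constant; notably independent of the release rate sigma),
while the implant zone saturates on the fast local scale
T1 = V_T (1+xi3) / k_1.  "Time points" T* mark 63.2% (1 - 1/e) of the
total change.

Several of the derived expressions are ratio products whose reading is
fixed by dimensional analysis and by the reference values they must
reproduce (TMg ~ 104 d, sigma_hyp ~ 1.41 mmol/day, ~8% maximum serum
drop, ~0.8% single-screw rise); each adopted reading is written out
explicitly in the function it belongs to.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import (
    DEFAULT_SIGMA0,
    DEFAULT_VI0,
    ImplantConfig,
    ParameterError,
    PhysiologyParams,
    homeostatic_state,
    scale_implants,
)
from .core import Trajectory, _initial_state

__all__ = [
    "TimeScales",
    "RhoRecommendation",
    "time_scales",
    "sigma_hyp",
    "t_hyp",
    "approx_trajectory",
    "min_serum_normalized",
    "rho_for_target",
    "min_implants_hyper",
]


@dataclass(frozen=True)
class TimeScales:
    """Characteristic times and the capacity decomposition of TMg.

    ``shares`` gives the fractional contribution of the (serum, RBC,
    bone, tissue) capacity terms to the systemic buildup time; with
    healthy-adult values tissue dominates (~74%) followed by bone
    (~25%), which is why systemic accumulation takes months.
    """

    T1: float
    TMg: float
    sigma_hyp: float
    shares: tuple[float, float, float, float]


def time_scales(params: PhysiologyParams, implant: ImplantConfig) -> TimeScales:
    """Local (T1) and systemic (TMg) buildup time points, in days.

    T1 = V_T (1+xi3) / k_1 with V_T = (1-xi) VTtot; TMg as in the
    module docstring.
    """
    VT = (1 - implant.xi) * params.VTtot
    T1 = VT * (1 + params.xi3) / params.k_1
    terms = np.array([
        (1 + params.xi1) * params.Vs,
        params.xi2 * params.Vr,
        params.mu1 / params.mu_1 * params.phi * params.VN,
        (1 + params.xi3) * params.k1 / params.k_1 * params.VTtot,
    ])
    TMg = terms.sum() / params.gamma
    shares = terms / terms.sum()
    return TimeScales(T1=T1, TMg=TMg,
                      sigma_hyp=sigma_hyp(params, implant),
                      shares=tuple(shares))


def sigma_hyp(params: PhysiologyParams, implant: ImplantConfig) -> float:
    """Critical total release rate for eventual hypermagnesemia.

    sigma_hyp = phiD * (C_hyp/C_hom - 1) * (1 - xi): the release rate
    at which the long-run serum rise sigma/((1-xi) phiD) reaches the
    normalized threshold excess C_hyp* - 1.
    """
    Chyp_star = params.C_hyp / params.C_hom
    if Chyp_star <= 1:
        raise ParameterError("sigma_hyp requires C_hyp > C_hom")
    return params.phiD * (Chyp_star - 1) * (1 - implant.xi)


def t_hyp(params: PhysiologyParams, implant: ImplantConfig,
          sigma: float | None = None) -> float | None:
    """Onset time of hypermagnesemia, or None if it is never reached.

    T_hyp = TMg * ln(sigma / (sigma - sigma_hyp)) for sigma >
    sigma_hyp; at or below the critical rate the serum never crosses
    the threshold and None is returned (a distinct outcome, not an
    error).
    """
    if sigma is None:
        sigma = implant.sigma
    s_hyp = sigma_hyp(params, implant)
    if sigma <= s_hyp:
        return None
    return time_scales(params, implant).TMg * math.log(sigma / (sigma - s_hyp))


def approx_trajectory(params: PhysiologyParams, implant: ImplantConfig,
                      rho: float = 1.0,
                      t_grid: np.ndarray | None = None) -> Trajectory:
    """Exponential small-xi approximation of the full trajectory.

    The systemic compartments relax from 1 toward rho +
    sigma/((1-xi) phiD) with time constant TMg (unchanged by rho); the
    implant zone adds the fast local term
    (sigma*gamma/(k1*phiD)) * (V_T/V_I) * (1 - exp(-t/T1)).  The early
    serum dip under intake reduction (see
    :func:`min_serum_normalized`) is not captured by this form.
    """
    if implant.xi > 0.05:
        warnings.warn(
            f"xi = {implant.xi:.3g} > 0.05: the small-xi approximation "
            "may be inaccurate", stacklevel=2)
    if t_grid is None:
        from .core import default_time_grid
        t_grid = default_time_grid()
    t = np.asarray(t_grid, dtype=float)

    ts = time_scales(params, implant)
    target = rho + implant.sigma / ((1 - implant.xi) * params.phiD)
    systemic = target + (1 - target) * np.exp(-t / ts.TMg)
    VT = (1 - implant.xi) * params.VTtot
    local_gain = (implant.sigma * params.gamma / (params.k1 * params.phiD)
                  ) * VT / implant.VI
    CI = systemic + local_gain * (1 - np.exp(-t / ts.T1))

    _, ref = _initial_state(params)
    normalized = np.column_stack([systemic, systemic, systemic, CI])
    return Trajectory(t=t, C=normalized * ref, ref=ref)


def min_serum_normalized(params: PhysiologyParams, rho: float) -> float:
    """Early-dip minimum of the normalized serum level under intake control.

    Cs_min* = 1 + (rho - 1) * gamma/k1: reducing the external intake to
    rho*phiD drops the serum within days to this quasi-plateau, after
    which it is sustained by the tissue and bone reserves.  At rho = 0
    with healthy-adult values the drop is gamma/k1 ~ 8%, comfortably
    above hypomagnesemia.  The value is the global trajectory minimum
    whenever the long-run level rho + sigma/phiD lies above it;
    otherwise the serum continues past the dip toward the lower steady
    state on the TMg scale.
    """
    if not (0 <= rho <= 1):
        raise ParameterError(f"rho must lie in [0, 1], got {rho}")
    return 1 + (rho - 1) * params.gamma / params.k1


@dataclass(frozen=True)
class RhoRecommendation:
    """An intake-control recommendation with feasibility flag.

    ``raw`` is the unclamped factor from the steady-state formula;
    ``rho`` is clamped to [0, 1]; ``feasible`` is False when raw < 0,
    i.e. even zero external intake cannot meet the target by diet
    alone.
    """

    raw: float
    rho: float
    feasible: bool


def rho_for_target(params: PhysiologyParams, implant: ImplantConfig,
                   target: str = "homeostasis") -> RhoRecommendation:
    """Intake factor holding the long-run serum at a clinical target.

    ``"homeostasis"``: rho = 1 - sigma/phiD keeps the long-run
    normalized serum at 1.  ``"avoid_hyper"``: rho = C_hyp* -
    sigma/phiD is the largest intake that still avoids hypermagnesemia
    at steady state.
    """
    if target == "homeostasis":
        raw = 1 - implant.sigma / params.phiD
    elif target == "avoid_hyper":
        raw = params.C_hyp / params.C_hom - implant.sigma / params.phiD
    else:
        raise ValueError(f"unknown target {target!r}")
    return RhoRecommendation(raw=raw, rho=min(max(raw, 0.0), 1.0),
                             feasible=raw >= 0)


def min_implants_hyper(params: PhysiologyParams,
                       sigma0: float = DEFAULT_SIGMA0,
                       VI0: float = DEFAULT_VI0) -> int:
    """Smallest screw count whose steady state reaches hypermagnesemia.

    Direct integer scan for the smallest n with 1 + n*sigma0/phiD >=
    C_hyp/C_hom, i.e. n*sigma0 reaching the critical release rate.

    Raises
    ------
    ParameterError
        If sigma0 <= 0, or the threshold is not reachable before the
        implant zones would fill the entire tissue volume.
    """
    if not sigma0 > 0:
        raise ParameterError(f"sigma0 must be strictly positive, got {sigma0}")
    Chyp_star = params.C_hyp / params.C_hom
    n = 1
    while 1 + n * sigma0 / params.phiD < Chyp_star:
        n += 1
        if n * VI0 >= params.VTtot:
            raise ParameterError(
                "hypermagnesemia not reachable before implant zones overlap "
                f"(n = {n}, n*VI0 >= VTtot)"
            )
    # Consistency: the scan must agree with the scaled implant config.
    scale_implants(sigma0, VI0, n, params)
    return n
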