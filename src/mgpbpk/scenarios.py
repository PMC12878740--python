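"""Named simulation scenarios and parameter sweeps.

Each preset reproduces one of the model's reference experiments as a
tidy long-format table:

``standard``
    a single 3.2 x 32 mm screw (sigma = 0.05 mmol/day) in a healthy
    adult;
``multi_implant``
    screw counts n in {1, 5, 10, 20, 29, 50}, bracketing the smallest
    count (29) whose steady state reaches hypermagnesemia;
``plate``
    a large plate releasing 10 mmol/day into ~1.2 L of affected tissue
    (xi ~ 0.023), the human-scaled analogue of a subcutaneous-plate
    animal experiment;
``diet_control``
    severely reduced kidney function (gamma = gamma0/3) with n = 20
    screws and external-intake factors rho in {1, 0.833, 0.5, 0}.

The sweep functions tabulate derived quantities over kidney function:
steady-state and one-year serum levels against Gamma = gamma/k1
(:func:`sweep_renal`), and the hypermagnesemia onset time against the
release rate (:func:`sweep_thyp`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import (
    DEFAULT_SIGMA0,
    DEFAULT_VI0,
    ImplantConfig,
    InterventionConfig,
    ParameterError,
    PhysiologyParams,
    renal_adjust,
    scale_implants,
)
from .core import COMPARTMENTS, default_time_grid, simulate
from .analytic import sigma_hyp, t_hyp, time_scales

__all__ = [
    "ScenarioSpec",
    "PRESET_NAMES",
    "get_preset",
    "run_scenario",
    "sweep_renal",
    "sweep_thyp",
    "TRAJECTORY_TABLE_COLUMNS",
    "SWEEP_TABLE_COLUMNS",
]

TRAJECTORY_TABLE_COLUMNS = [
    "scenario", "sweep_var", "sweep_value", "t_days",
    "compartment", "C_mmol_per_L", "C_star",
]
SWEEP_TABLE_COLUMNS = [
    "scenario", "renal_fraction_or_Gamma", "n_or_sigma", "quantity", "value",
]

PRESET_NAMES = ("standard", "multi_implant", "plate", "diet_control")


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully parameterized scenario run.

    ``sweep`` optionally names one field ("n" or "rho") and the values
    it takes; each value produces one trajectory in the output table.
    ``implant`` may be given explicitly (e.g. the plate) or is built
    from (sigma0, VI0, n) when None.
    """

    name: str
    params: PhysiologyParams = field(default_factory=PhysiologyParams)
    intervention: InterventionConfig = field(default_factory=InterventionConfig)
    implant: ImplantConfig | None = None
    n: int = 1
    sigma0: float = DEFAULT_SIGMA0
    VI0: float = DEFAULT_VI0
    t_grid: np.ndarray = field(default_factory=default_time_grid)
    sweep: tuple[str, tuple] | None = None


def get_preset(name: str, params: PhysiologyParams | None = None,
               t_end: float = 1095.0) -> ScenarioSpec:
    """Build one of the named preset scenarios (overridable parameters)."""
    if params is None:
        params = PhysiologyParams()
    t_grid = default_time_grid(t_end)
    if name == "standard":
        return ScenarioSpec(name=name, params=params, t_grid=t_grid)
    if name == "multi_implant":
        return ScenarioSpec(name=name, params=params, t_grid=t_grid,
                            sweep=("n", (1, 5, 10, 20, 29, 50)))
    if name == "plate":
        implant = ImplantConfig.from_totals(sigma=10.0, VI=1.2, params=params)
        return ScenarioSpec(name=name, params=params, t_grid=t_grid,
                            implant=implant)
    if name == "diet_control":
        return ScenarioSpec(
            name=name, params=params, t_grid=t_grid, n=20,
            intervention=InterventionConfig(rho=1.0, renal_fraction=1 / 3),
            sweep=("rho", (1.0, 0.833, 0.5, 0.0)))
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def _single_run(spec: ScenarioSpec, n: int, rho: float,
                sweep_var: str, sweep_value: float) -> pd.DataFrame:
    p = renal_adjust(spec.params, spec.intervention.renal_fraction)
    implant = spec.implant
    if implant is None:
        implant = scale_implants(spec.sigma0, spec.VI0, n, p)
    traj = simulate(p, implant, rho=rho, t_grid=spec.t_grid)
    frames = []
    for j, comp in enumerate(COMPARTMENTS):
        frames.append(pd.DataFrame({
            "scenario": spec.name,
            "sweep_var": sweep_var,
            "sweep_value": sweep_value,
            "t_days": traj.t,
            "compartment": comp,
            "C_mmol_per_L": traj.C[:, j],
            "C_star": traj.normalized[:, j],
        }))
    return pd.concat(frames, ignore_index=True)


def run_scenario(spec: ScenarioSpec) -> pd.DataFrame:
    """Run a scenario (with its sweep, if any) into one long table.

    Deterministic: identical specs produce bit-identical tables.
    """
    if spec.sweep is None:
        return _single_run(spec, spec.n, spec.intervention.rho, "", np.nan)
    var, values = spec.sweep
    if var not in ("n", "rho"):
        raise ValueError(f"sweep field must be 'n' or 'rho', got {var!r}")
    frames = []
    for value in values:
        n = int(value) if var == "n" else spec.n
        rho = float(value) if var == "rho" else spec.intervention.rho
        frames.append(_single_run(spec, n, rho, var, float(value)))
    return pd.concat(frames, ignore_index=True)


def sweep_renal(params: PhysiologyParams | None = None,
                implant_counts: Sequence[int] = (0, 1, 5, 10, 15, 20, 29),
                Gamma_grid: np.ndarray | None = None,
                sigma0: float = DEFAULT_SIGMA0,
                VI0: float = DEFAULT_VI0) -> pd.DataFrame:
    """Serum levels versus kidney function Gamma = gamma/k1.

    Each Gamma point scales gamma and phiD together (preserving the
    pre-implant homeostasis phiD/gamma), then tabulates the normalized
    steady-state serum level 1 + sigma/phiD and the one-year level from
    the exponential approximation.  Because phiD falls with gamma, both
    decrease with Gamma and increase with the implant count n.
    """
    if params is None:
        params = PhysiologyParams()
    Gamma0 = params.Gamma
    if Gamma_grid is None:
        Gamma_grid = np.geomspace(Gamma0 / 6, 2 * Gamma0, 25)
    rows = []
    for Gamma in np.asarray(Gamma_grid, dtype=float):
        if Gamma <= 0:
            raise ParameterError(f"Gamma must be strictly positive, got {Gamma}")
        f = Gamma / Gamma0
        p = params.replace(gamma=f * params.gamma, phiD=f * params.phiD)
        for n in implant_counts:
            if n == 0:
                cs_inf = cs_365 = 1.0
            else:
                implant = scale_implants(sigma0, VI0, int(n), p)
                cs_inf = 1 + implant.sigma / p.phiD
                ts = time_scales(p, implant)
                cs_365 = 1 + implant.sigma / ((1 - implant.xi) * p.phiD) * (
                    1 - np.exp(-365.0 / ts.TMg))
            rows.append(("renal_sweep", Gamma, n, "Cs_inf_star", cs_inf))
            rows.append(("renal_sweep", Gamma, n, "Cs_365_star", cs_365))
    return pd.DataFrame(rows, columns=SWEEP_TABLE_COLUMNS)


def sweep_thyp(params: PhysiologyParams | None = None,
               sigma_grid: np.ndarray | None = None,
               renal_fractions: Sequence[float] = (1.0, 2 / 3, 1 / 3),
               sigma0: float = DEFAULT_SIGMA0,
               VI0: float = DEFAULT_VI0) -> pd.DataFrame:
    """Hypermagnesemia onset time against the implant release rate.

    The release-rate grid spans single-screw (0.05 mmol/day) to
    100-screw equivalents; each rate carries the implant-zone volume of
    the equivalent screw count.  Rates at or below the critical rate
    never reach the threshold; those entries carry value NaN ("never").
    """
    if params is None:
        params = PhysiologyParams()
    if sigma_grid is None:
        sigma_grid = np.linspace(sigma0, 100 * sigma0, 100)
    rows = []
    for f in renal_fractions:
        p = renal_adjust(params, f)
        for sigma in np.asarray(sigma_grid, dtype=float):
            implant = ImplantConfig.from_totals(
                sigma=sigma, VI=sigma / sigma0 * VI0, params=p)
            s_hyp = sigma_hyp(p, implant)
            onset = t_hyp(p, implant)
            rows.append(("thyp_curve", f, sigma, "sigma_hyp", s_hyp))
            rows.append(("thyp_curve", f, sigma, "T_hyp",
                         np.nan if onset is None else onset))
    return pd.DataFrame(rows, columns=SWEEP_TABLE_COLUMNS)
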