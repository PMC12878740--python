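"""Flat key-value configuration files.

A config file is plain text with one ``key = value`` pair per line;
``#`` starts a comment and blank lines are ignored.  The accepted keys
are exactly the model's inputs (physiology, implant, intervention);
missing keys fall back to the healthy-adult defaults and every applied
default is logged, unknown keys are an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .params import (
    DEFAULT_SIGMA0,
    DEFAULT_VI0,
    ImplantConfig,
    InterventionConfig,
    PhysiologyParams,
    scale_implants,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "write_config", "CONFIG_KEYS"]

log = logging.getLogger("mgpbpk")

_PHYS_KEYS = ("Vs", "Vr", "VN", "VTtot", "phiD", "gamma", "mu1", "mu_1",
              "k1", "k_1", "phi", "xi1", "xi2", "xi3",
              "C_hom", "C_hyp", "C_sev")
_INT_KEYS = ("n",)
_FLOAT_KEYS = _PHYS_KEYS + ("VI0", "sigma0", "rho", "renal_fraction")
CONFIG_KEYS = _FLOAT_KEYS + _INT_KEYS


class ConfigError(ValueError):
    """A config file could not be parsed into a valid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """A resolved run configuration: model inputs plus run plumbing."""

    scenario: str = "standard"
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = dict(_defaults())
        for key in self.values:
            if key not in full:
                raise ConfigError(f"unknown key {key!r}")
        full.update(self.values)
        object.__setattr__(self, "values", full)

    def physiology(self) -> PhysiologyParams:
        return PhysiologyParams(**{k: self.values[k] for k in _PHYS_KEYS})

    def implant(self, params: PhysiologyParams | None = None) -> ImplantConfig:
        if params is None:
            params = self.physiology()
        return scale_implants(self.values["sigma0"], self.values["VI0"],
                              self.values["n"], params)

    def intervention(self) -> InterventionConfig:
        return InterventionConfig(rho=self.values["rho"],
                                  renal_fraction=self.values["renal_fraction"])


def _defaults() -> dict:
    base = PhysiologyParams()
    values = {k: getattr(base, k) for k in _PHYS_KEYS}
    values.update(sigma0=DEFAULT_SIGMA0, VI0=DEFAULT_VI0, n=1,
                  rho=1.0, renal_fraction=1.0)
    return values


def load_config(path) -> RunConfig:
    """Parse a flat key-value config file into a :class:`RunConfig`.

    Raises
    ------
    ConfigError
        On parse failure, an unknown key, or an un-coercible value —
        always naming the offending key or line.
    """
    values: dict = {}
    with open(path) as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(
                    f"line {lineno}: expected 'key = value', got {line!r}")
            key, _, raw_value = (part.strip() for part in line.partition("="))
            if key not in CONFIG_KEYS:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
            if key in values:
                raise ConfigError(f"line {lineno}: duplicate key {key!r}")
            try:
                values[key] = (int(raw_value) if key in _INT_KEYS
                               else float(raw_value))
            except ValueError:
                raise ConfigError(
                    f"line {lineno}: cannot coerce {key} = {raw_value!r}"
                ) from None
    for key, default in _defaults().items():
        if key not in values:
            log.debug("config %s: using default %s = %r", path, key, default)
    return RunConfig(values=values)


def write_config(config: RunConfig, path) -> None:
    """Write a config so that ``load_config`` round-trips it exactly."""
    with open(path, "w") as fh:
        for key in CONFIG_KEYS:
            fh.write(f"{key} = {config.values[key]!r}\n")
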