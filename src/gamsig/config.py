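"""Run configuration: schema, validation and defaults.

A run is described by a YAML (or JSON) document with four blocks::

    experiment: equilibrium          # equilibrium | invade | grid | sweep |
                                     # linkage | landscape
    seed: 1
    out: results/
    kinetics:
      k_on: 1.0
      k_off: 1.0
      gamma: 0.1                     # shared degradation rate, or give
      # deg_L / deg_R / deg_LR       # the three rates individually
      k_between: null                # default: k_on / k_off
      n_cost: 1
    evolution:
      N: 1000                        # M defaults to N/2
      mu: 0.01
      sigma: 0.1
      ...
    spec:                            # experiment-specific block (required)
      ...

Unknown keys anywhere are rejected, and all physical bounds are validated
before any simulation starts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .evolution import ConvergenceCriterion, EvolutionParams
from .kinetics import KineticParams

__all__ = ["RunConfig", "ConfigError", "load_config", "parse_config"]

EXPERIMENTS = ("equilibrium", "invade", "grid", "sweep", "linkage", "landscape")


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


def _check_keys(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _kinetics_from(block: Mapping[str, Any]) -> KineticParams:
    allowed = {
        "k_on", "k_off", "k_between", "gamma", "deg_L", "deg_R", "deg_LR",
        "n_cost", "K_sat",
    }
    _check_keys(block, allowed, "kinetics")
    if "k_on" not in block:
        raise ConfigError("kinetics.k_on is required")
    k_on = float(block["k_on"])
    k_off = float(block.get("k_off", 1.0))
    if "gamma" in block and any(k in block for k in ("deg_L", "deg_R", "deg_LR")):
        raise ConfigError("give kinetics.gamma or the three deg_* rates, not both")
    if "gamma" in block:
        gL = gR = gLR = float(block["gamma"])
    else:
        try:
            gL = float(block["deg_L"])
            gR = float(block["deg_R"])
            gLR = float(block["deg_LR"])
        except KeyError as exc:
            raise ConfigError(f"kinetics.{exc.args[0]} is required") from None
    kb = block.get("k_between")
    if kb is None:
        if k_off <= 0:
            raise ConfigError("kinetics.k_off must be positive to default k_between")
        kb = k_on / k_off
    try:
        return KineticParams(
            k_on=k_on,
            k_off=k_off,
            k_between=float(kb),
            deg_L=gL,
            deg_R=gR,
            deg_LR=gLR,
            n_cost=float(block.get("n_cost", 1.0)),
            K_sat=None if block.get("K_sat") is None else float(block["K_sat"]),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid kinetics block: {exc}") from None


def _convergence_from(block: Mapping[str, Any]) -> ConvergenceCriterion:
    allowed = {"epsilon_s", "window", "epsilon_rho", "report_window"}
    _check_keys(block, allowed, "evolution.convergence")
    kwargs = {k: block[k] for k in allowed if k in block and block[k] is not None}
    try:
        return ConvergenceCriterion(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"invalid convergence block: {exc}") from None


def _evolution_from(block: Mapping[str, Any]) -> EvolutionParams:
    allowed = {
        "N", "M", "mu", "sigma", "mu_rho", "sigma_rho", "alpha",
        "max_generations", "convergence", "mate_attempt_cap",
    }
    _check_keys(block, allowed, "evolution")
    kwargs: dict[str, Any] = {
        k: block[k] for k in allowed - {"convergence"} if k in block and block[k] is not None
    }
    if "convergence" in block and block["convergence"] is not None:
        kwargs["convergence"] = _convergence_from(block["convergence"])
    try:
        return EvolutionParams(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid evolution block: {exc}") from None


@dataclass(frozen=True)
class RunConfig:
    """Fully validated description of one simulation run."""

    experiment: str
    kin: KineticParams
    params: EvolutionParams
    spec: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    outdir: Path = Path("results")
    log_level: str = "INFO"

    def describe(self) -> str:
        """Human-readable dump of the resolved parameters (for --dry-run)."""
        lines = [
            f"experiment : {self.experiment}",
            f"seed       : {self.seed}",
            f"outdir     : {self.outdir}",
            f"kinetics   : {self.kin}",
            f"evolution  : {self.params}",
            f"spec       : {self.spec}",
        ]
        return "\n".join(lines)


def parse_config(doc: Mapping[str, Any]) -> RunConfig:
    """Validate a parsed configuration mapping into a :class:`RunConfig`."""
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration must be a mapping")
    allowed = {"experiment", "kinetics", "evolution", "spec", "seed", "out", "log_level"}
    _check_keys(doc, allowed, "top level")
    experiment = doc.get("experiment")
    if not experiment:
        raise ConfigError("experiment block is required (empty or missing)")
    if experiment not in EXPERIMENTS:
        raise ConfigError(
            f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}"
        )
    if "kinetics" not in doc:
        raise ConfigError("kinetics block is required")
    kin = _kinetics_from(doc["kinetics"])
    params = _evolution_from(doc.get("evolution", {}) or {})
    spec = doc.get("spec", {}) or {}
    if not isinstance(spec, Mapping):
        raise ConfigError("spec must be a mapping")
    seed = doc.get("seed")
    return RunConfig(
        experiment=str(experiment),
        kin=kin,
        params=params,
        spec=dict(spec),
        seed=None if seed is None else int(seed),
        outdir=Path(doc.get("out", "results")),
        log_level=str(doc.get("log_level", "INFO")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if doc is None:
        raise ConfigError(f"{path}: empty configuration")
    return parse_config(doc)
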