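"""Scenario drivers for the evolutionary experiments.

Each driver builds a population, runs the individual-based engine and
returns a result object carrying the trajectory, steady-state summaries and
the full parameterization (so any run can be reproduced from its metadata).

Drivers
-------
``equilibrium_experiment``
    Recurrent mutation from a monomorphic start, optionally with a fixed
    recombination rate; reports the steady-state symmetry s*.
``invasion_experiment`` / ``invasibility_grid``
    Adaptive-dynamics style: rare mutants introduced at frequency p with
    recurrent mutation switched off, followed to a stable outcome.
``recombination_sweep`` / ``equilibrium_sweep``
    Steady state as a function of the recombination rate or of a kinetic
    parameter, with replicate management.
``linkage_coevolution``
    The recombination modifier evolves jointly with the signaling loci,
    starting from free recombination with a drift-only warm-up phase.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .evolution import (
    ConvergenceCriterion,
    EvolutionParams,
    EvolutionResult,
    PopulationState,
    run_to_steady_state,
    step_generation,
    symmetry_statistic,
)
from .kinetics import KineticParams, calibrate_K

__all__ = [
    "InvasionSpec",
    "SweepSpec",
    "EquilibriumResult",
    "InvasionResult",
    "LinkageResult",
    "equilibrium_experiment",
    "invasion_experiment",
    "invasibility_grid",
    "recombination_sweep",
    "equilibrium_sweep",
    "linkage_coevolution",
    "bin_genotypes",
    "threshold_from_sweep",
    "GENOTYPE_ARCHETYPES",
]

# reference genotypes used to summarize which cell types dominate a population
GENOTYPE_ARCHETYPES: dict[str, tuple[float, float, float, float]] = {
    "(1,1,0,0)": (1.0, 1.0, 0.0, 0.0),
    "(0,0,1,1)": (0.0, 0.0, 1.0, 1.0),
    "(1,0,0,1)": (1.0, 0.0, 0.0, 1.0),
    "(0,1,1,0)": (0.0, 1.0, 1.0, 0.0),
    "(1,0.5,0,0.5)": (1.0, 0.5, 0.0, 0.5),
    "(0,0.5,1,0.5)": (0.0, 0.5, 1.0, 0.5),
    "(0.5,1,0.5,0)": (0.5, 1.0, 0.5, 0.0),
    "(0.5,0,0.5,1)": (0.5, 0.0, 0.5, 1.0),
}
_ARCHETYPE_RADIUS = 0.25


def bin_genotypes(nu: np.ndarray) -> pd.Series:
    """Frequency of cells near each archetype genotype.

    Cells are assigned to the nearest archetype by Euclidean distance in
    production-rate space; cells farther than 0.25 from every archetype are
    binned as ``other``.
    """
    nu = np.atleast_2d(np.asarray(nu, dtype=float))
    names = list(GENOTYPE_ARCHETYPES)
    centers = np.array([GENOTYPE_ARCHETYPES[k] for k in names])  # (8, 4)
    d = np.linalg.norm(nu[:, None, :] - centers[None, :, :], axis=-1)  # (N, 8)
    nearest = d.argmin(axis=1)
    within = d[np.arange(len(nu)), nearest] <= _ARCHETYPE_RADIUS
    labels = np.where(within, np.array(names)[nearest], "other")
    counts = pd.Series(labels).value_counts()
    return counts.reindex(names + ["other"], fill_value=0) / len(nu)


def _spawn_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Deterministic independent substreams so replicate r is reproducible alone."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def _resolve_K(kin: KineticParams, alpha: float) -> float:
    return kin.K_sat if kin.K_sat is not None else calibrate_K(kin, alpha=alpha)


def _json_ready(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _json_ready(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    return obj


@dataclass
class EquilibriumResult:
    """Outcome of an equilibrium run under recurrent mutation."""

    run: EvolutionResult
    K: float
    kin: KineticParams
    params: EvolutionParams
    init: tuple[float, ...]
    rho_init: float
    seed: int | None

    @property
    def s_star(self) -> float:
        return self.run.s_star

    @property
    def rho_star(self) -> float:
        return self.run.rho_star

    @property
    def trajectory(self) -> pd.DataFrame:
        return self.run.trajectory

    def genotype_frequencies(self) -> pd.Series:
        return bin_genotypes(self.run.final_nu)

    def metadata(self) -> dict:
        return {
            "experiment": "equilibrium",
            "kinetics": _json_ready(self.kin),
            "evolution": _json_ready(self.params),
            "K": self.K,
            "init": list(self.init),
            "rho_init": self.rho_init,
            "seed": self.seed,
            "converged": self.run.converged,
            "reason": self.run.reason,
            "generations": self.run.generations,
            "s_star": self.s_star,
            "rho_star": self.rho_star,
        }

    def summary(self) -> str:
        freqs = self.genotype_frequencies()
        top = freqs[freqs > 0.01].sort_values(ascending=False)
        lines = [
            "Equilibrium experiment",
            f"  K (saturation)  : {self.K:.6g}",
            self.run.summary(),
            "  dominant genotype bins:",
        ]
        for name, f in top.items():
            lines.append(f"    {name:<16s} {f:6.3f}")
        return "\n".join(lines)

    def save(self, outdir: str | Path, name: str = "equilibrium") -> None:
        save_result(outdir, name, {"trajectory": self.trajectory}, self.metadata(),
                    snapshot=pd.DataFrame(self.run.final_nu,
                                          columns=["nu_L", "nu_R", "nu_l", "nu_r"])
                    .assign(rho=self.run.final_rho))


def save_result(
    outdir: str | Path,
    name: str,
    tables: dict[str, pd.DataFrame],
    metadata: dict,
    snapshot: pd.DataFrame | None = None,
) -> None:
    """Write tidy CSV tables plus a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, df in tables.items():
        df.to_csv(outdir / f"{name}_{key}.csv", index=False)
    if snapshot is not None:
        snapshot.to_csv(outdir / f"{name}_snapshot.csv", index=False)
    with open(outdir / f"{name}_metadata.json", "w") as fh:
        json.dump(_json_ready(metadata), fh, indent=2, default=str)


def equilibrium_experiment(
    kin: KineticParams,
    params: EvolutionParams,
    init: Sequence[float] = (1.0, 1.0, 0.0, 0.0),
    rho_fixed: float = 0.0,
    seed: int | None = None,
    K: float | None = None,
    min_generations: int = 0,
) -> EquilibriumResult:
    """Evolve a monomorphic population under recurrent mutation.

    ``rho_fixed`` sets the (non-evolving) recombination rate between the
    ligand and receptor loci; modifier mutation is disabled unless the
    supplied ``params`` request it explicitly.
    """
    K = _resolve_K(kin, params.alpha) if K is None else K
    pop = PopulationState.monomorphic(init, params.N, rho=rho_fixed, seed=seed)
    run = run_to_steady_state(pop, kin, K, params, min_generations=min_generations)
    return EquilibriumResult(
        run=run, K=K, kin=kin, params=params, init=tuple(float(v) for v in init),
        rho_init=rho_fixed, seed=seed,
    )


@dataclass(frozen=True)
class InvasionSpec:
    """Adaptive-dynamics scenario: rare mutants facing a common resident.

    The mutants are introduced at the given initial frequencies; recurrent
    mutation is off, so the only evolutionary forces are the mating lottery,
    recombination (at ``rho``) and drift.
    """

    resident: tuple[float, ...]
    mutants: tuple[tuple[float, ...], ...]
    frequencies: tuple[float, ...]
    rho: float = 0.0
    criterion: ConvergenceCriterion = field(
        default_factory=lambda: ConvergenceCriterion(epsilon_s=1e-7)
    )

    def __post_init__(self) -> None:
        if len(self.mutants) != len(self.frequencies):
            raise ValueError("one frequency per mutant required")
        if any(not 0.0 <= f < 1.0 for f in self.frequencies):
            raise ValueError("initial frequencies must be in [0, 1)")
        if sum(self.frequencies) >= 1.0:
            raise ValueError("mutant frequencies must sum below 1")


@dataclass
class InvasionResult:
    """Final-state frequencies of resident, mutants and recombinants."""

    run: EvolutionResult
    spec: InvasionSpec
    resident_freq: float
    mutant_freqs: tuple[float, ...]
    other_freq: float
    K: float
    seed: int | None

    @property
    def s_star(self) -> float:
        return self.run.s_star

    def metadata(self) -> dict:
        return {
            "experiment": "invasion",
            "spec": _json_ready(self.spec),
            "K": self.K,
            "seed": self.seed,
            "converged": self.run.converged,
            "generations": self.run.generations,
            "s_star": self.s_star,
            "resident_freq": self.resident_freq,
            "mutant_freqs": list(self.mutant_freqs),
            "other_freq": self.other_freq,
        }

    def summary(self) -> str:
        lines = [
            "Invasion experiment",
            f"  resident {self.spec.resident}: final frequency {self.resident_freq:.3f}",
        ]
        for g, f in zip(self.spec.mutants, self.mutant_freqs):
            lines.append(f"  mutant   {g}: final frequency {f:.3f}")
        lines.append(f"  recombinant/other frequency {self.other_freq:.3f}")
        lines.append(f"  steady-state s* = {self.s_star:.4f} ({self.run.reason})")
        return "\n".join(lines)


def _genotype_frequency(nu: np.ndarray, genotype: Sequence[float]) -> float:
    match = np.all(np.isclose(nu, np.asarray(genotype, float), atol=1e-12), axis=1)
    return float(match.mean())


def invasion_experiment(
    spec: InvasionSpec,
    kin: KineticParams,
    params: EvolutionParams,
    seed: int | None = None,
    K: float | None = None,
) -> InvasionResult:
    """Follow rare mutants (no recurrent mutation) to a stable outcome."""
    K = _resolve_K(kin, params.alpha) if K is None else K
    params = replace(params, mu=0.0, mu_rho=0.0)
    genotypes = (spec.resident, *spec.mutants)
    freqs = (1.0 - sum(spec.frequencies), *spec.frequencies)
    pop = PopulationState.from_frequencies(
        genotypes, freqs, params.N, rho=spec.rho, seed=seed
    )
    run = run_to_steady_state(pop, kin, K, params, criterion=spec.criterion)
    res_f = _genotype_frequency(run.final_nu, spec.resident)
    mut_f = tuple(_genotype_frequency(run.final_nu, g) for g in spec.mutants)
    return InvasionResult(
        run=run,
        spec=spec,
        resident_freq=res_f,
        mutant_freqs=mut_f,
        other_freq=max(0.0, 1.0 - res_f - sum(mut_f)),
        K=K,
        seed=seed,
    )


def invasibility_grid(
    dx_grid: Sequence[float],
    dy_grid: Sequence[float],
    kin: KineticParams,
    params: EvolutionParams,
    p: float = 0.01,
    replicates: int = 20,
    seed: int | None = None,
    rho: float = 0.0,
    resident_family: Callable[[float, float], Sequence[float]] | None = None,
    mutant_families: Sequence[Callable[[float, float], Sequence[float]]] | None = None,
    K: float | None = None,
) -> pd.DataFrame:
    """Steady-state outcome over a grid of mutant deviations (dx, dy).

    Defaults reproduce the two-mutant setup: resident (1, 1, 0, 0) invaded by
    (1-dx, 1, dx, 0) and (1, 1-dy, 0, dy), each introduced at frequency p.
    Returns a long-format table with one row per grid point and replicate,
    including the per-run seed entropy so any single cell of a heatmap can
    be rerun in isolation.
    """
    if resident_family is None:
        resident_family = lambda dx, dy: (1.0, 1.0, 0.0, 0.0)  # noqa: E731
    if mutant_families is None:
        mutant_families = (
            lambda dx, dy: (1.0 - dx, 1.0, dx, 0.0),
            lambda dx, dy: (1.0, 1.0 - dy, 0.0, dy),
        )
    K = _resolve_K(kin, params.alpha) if K is None else K
    points = [(dx, dy) for dx in dx_grid for dy in dy_grid]
    rows = []
    ss = np.random.SeedSequence(seed)
    for (dx, dy), point_ss in zip(points, ss.spawn(len(points))):
        child_seeds = point_ss.generate_state(replicates)
        for rep in range(replicates):
            rep_seed = int(child_seeds[rep]) % (2**31)
            spec = InvasionSpec(
                resident=tuple(float(v) for v in resident_family(dx, dy)),
                mutants=tuple(
                    tuple(float(v) for v in fam(dx, dy)) for fam in mutant_families
                ),
                frequencies=tuple(p for _ in mutant_families),
                rho=rho,
            )
            out = invasion_experiment(spec, kin, params, seed=rep_seed, K=K)
            rows.append(
                {
                    "dx": dx,
                    "dy": dy,
                    "replicate": rep,
                    "seed": rep_seed,
                    "s_star": out.s_star,
                    "f_res": out.resident_freq,
                    **{f"f_mut{i+1}": f for i, f in enumerate(out.mutant_freqs)},
                    "f_other": out.other_freq,
                    "generations": out.run.generations,
                }
            )
    return pd.DataFrame(rows)


def recombination_sweep(
    rho_grid: Sequence[float],
    kin: KineticParams,
    params: EvolutionParams,
    init: Sequence[float] = (1.0, 1.0, 0.0, 0.0),
    replicates: int = 1,
    seed: int | None = None,
    K: float | None = None,
) -> pd.DataFrame:
    """Steady-state symmetry s* as a function of a fixed recombination rate."""
    K = _resolve_K(kin, params.alpha) if K is None else K
    rows = []
    ss = np.random.SeedSequence(seed)
    for rho, point_ss in zip(rho_grid, ss.spawn(len(rho_grid))):
        child_seeds = point_ss.generate_state(replicates)
        for rep in range(replicates):
            rep_seed = int(child_seeds[rep]) % (2**31)
            out = equilibrium_experiment(
                kin, params, init=init, rho_fixed=float(rho), seed=rep_seed, K=K
            )
            rows.append(
                {
                    "rho": float(rho),
                    "replicate": rep,
                    "seed": rep_seed,
                    "s_star": out.s_star,
                    "generations": out.run.generations,
                    "converged": out.run.converged,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter sweep: which knob to vary, over which grid."""

    parameter: str  # one of k_on, gamma, k_between, n_cost, rho, alpha
    grid: tuple[float, ...]
    replicates: int = 1
    tie_k_between: bool = True  # keep k_between = k_on / k_off while sweeping k_on

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("sweep grid must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _kin_with(kin: KineticParams, parameter: str, value: float, tie_kb: bool) -> KineticParams:
    if parameter == "k_on":
        kb = value / kin.k_off if tie_kb else kin.k_between
        return replace(kin, k_on=value, k_between=kb, K_sat=None)
    if parameter == "gamma":
        return replace(kin, deg_L=value, deg_R=value, deg_LR=value, K_sat=None)
    if parameter in ("k_between", "n_cost"):
        return replace(kin, **{parameter: value}, K_sat=None)
    raise ValueError(f"unsupported kinetic sweep parameter: {parameter}")


def equilibrium_sweep(
    spec: SweepSpec,
    kin: KineticParams,
    params: EvolutionParams,
    init: Sequence[float] = (1.0, 1.0, 0.0, 0.0),
    rho_fixed: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Equilibrium s* along a grid of one parameter, with replicates.

    K is recalibrated at every kinetic grid point, since the feasible
    maximum of the interaction strength moves with the kinetics.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for value, point_ss in zip(spec.grid, ss.spawn(len(spec.grid))):
        if spec.parameter == "rho":
            kin_v, rho_v, params_v = kin, float(value), params
        elif spec.parameter == "alpha":
            kin_v, rho_v = replace(kin, K_sat=None), rho_fixed
            params_v = replace(params, alpha=float(value))
        else:
            kin_v = _kin_with(kin, spec.parameter, float(value), spec.tie_k_between)
            rho_v, params_v = rho_fixed, params
        K = _resolve_K(kin_v, params_v.alpha)
        child_seeds = point_ss.generate_state(spec.replicates)
        for rep in range(spec.replicates):
            rep_seed = int(child_seeds[rep]) % (2**31)
            out = equilibrium_experiment(
                kin_v, params_v, init=init, rho_fixed=rho_v, seed=rep_seed, K=K
            )
            rows.append(
                {
                    spec.parameter: float(value),
                    "replicate": rep,
                    "seed": rep_seed,
                    "K": K,
                    "s_star": out.s_star,
                    "generations": out.run.generations,
                    "converged": out.run.converged,
                }
            )
    return pd.DataFrame(rows)


def threshold_from_sweep(df: pd.DataFrame, parameter: str = "k_on") -> float:
    """Transition point of an E1-to-E2 sweep.

    Returns the grid midpoint between the last parameter value whose mean
    s* exceeds 0.9 (symmetric equilibrium) and the first whose mean s* falls
    below 0.1 (asymmetric equilibrium).  Requires a single transition along
    the grid.
    """
    means = df.groupby(parameter)["s_star"].mean().sort_index()
    high = means[means > 0.9]
    low = means[means < 0.1]
    if high.empty or low.empty:
        raise ValueError("sweep does not span both equilibria")
    last_high = high.index.max()
    first_low = low[low.index > last_high].index.min()
    if not np.isfinite(first_low):
        raise ValueError("no E2 point beyond the last E1 point; not a single transition")
    return float((last_high + first_low) / 2.0)


@dataclass
class LinkageResult:
    """Joint evolution of signaling symmetry and the recombination modifier."""

    run: EvolutionResult  # phase 2 (signaling mutation enabled)
    drift_trajectory: pd.DataFrame  # phase 1 (modifier drift only)
    K: float
    kin: KineticParams
    params: EvolutionParams
    seed: int | None

    @property
    def s_star(self) -> float:
        return self.run.s_star

    @property
    def rho_star(self) -> float:
        return self.run.rho_star

    @property
    def trajectory(self) -> pd.DataFrame:
        """Full (drift + coevolution) trajectory of s and mean rho."""
        return pd.concat(
            [self.drift_trajectory, self.run.trajectory.iloc[1:]], ignore_index=True
        )

    def metadata(self) -> dict:
        return {
            "experiment": "linkage_coevolution",
            "kinetics": _json_ready(self.kin),
            "evolution": _json_ready(self.params),
            "K": self.K,
            "seed": self.seed,
            "converged": self.run.converged,
            "reason": self.run.reason,
            "generations": int(self.trajectory["generation"].iloc[-1]),
            "s_star": self.s_star,
            "rho_star": self.rho_star,
        }

    def summary(self) -> str:
        return "\n".join(
            [
                "Linkage coevolution experiment",
                f"  K (saturation)        : {self.K:.6g}",
                f"  steady-state s*       : {self.s_star:.4f}",
                f"  steady-state rho*     : {self.rho_star:.4f}",
                f"  termination           : {self.run.reason}",
            ]
        )

    def save(self, outdir: str | Path, name: str = "linkage") -> None:
        save_result(outdir, name, {"trajectory": self.trajectory}, self.metadata())


def linkage_coevolution(
    kin: KineticParams,
    params: EvolutionParams,
    init: Sequence[float] = (1.0, 1.0, 0.0, 0.0),
    rho_init: float = 0.5,
    drift_generations: int = 1000,
    seed: int | None = None,
    K: float | None = None,
) -> LinkageResult:
    """Coevolve the recombination modifier with the signaling loci.

    Phase 1: the population starts monomorphic at ``init`` with free
    recombination (rho = 0.5 for all cells) and only the modifier mutates,
    drifting for ``drift_generations``.  Phase 2: production-rate mutation is
    switched on and the run continues until the joint convergence criterion
    on s and mean rho, or the generation cap.
    """
    K = _resolve_K(kin, params.alpha) if K is None else K
    pop = PopulationState.monomorphic(init, params.N, rho=rho_init, seed=seed)

    # phase 1: modifier drift only, run for its full length (no early stop)
    drift_params = replace(params, mu=0.0, max_generations=drift_generations)
    s0 = [symmetry_statistic(pop.nu)]
    rho0 = [float(pop.rho.mean())]
    for _ in range(drift_generations):
        step_generation(pop, kin, K, drift_params)
        s0.append(symmetry_statistic(pop.nu))
        rho0.append(float(pop.rho.mean()))
    drift_traj = pd.DataFrame(
        {"generation": np.arange(len(s0)), "s": s0, "mean_rho": rho0}
    )

    crit = params.convergence
    if crit.epsilon_rho is None:
        crit = ConvergenceCriterion(
            epsilon_s=crit.epsilon_s,
            window=crit.window,
            epsilon_rho=crit.epsilon_s,
            report_window=crit.report_window,
        )
    run = run_to_steady_state(pop, kin, K, params, criterion=crit)
    return LinkageResult(
        run=run, drift_trajectory=drift_traj, K=K, kin=kin, params=params, seed=seed
    )
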