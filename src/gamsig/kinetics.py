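"""Ligand-receptor binding kinetics and between-cell signaling.

Each cell displays membrane-bound ligand and receptor molecules belonging to
two mutually incompatible pairs, (L, R) and (l, r).  Within a cell, free
ligand and receptor of the same pair bind reversibly (rates ``k_on`` /
``k_off``) and all species degrade at first order.  Because production,
binding and turnover are fast relative to cell encounters, each cell sits at
the deterministic steady state of its own kinetics when it meets a partner.

The steady state feeds a between-cell signal strength: the signal cell 1
receives from cell 2 is, per pair,

    W12 = kb * [L2]* [R1]* * (1 - [LR1]*/([LR1]* + kb [L2]* [R1]*))**n

summed over the two pairs.  Self-bound complex [LR1]* corrupts the readout
of the incoming signal when the cost exponent ``n >= 1`` and merely depletes
free molecules when ``n = 0``.  Two cells mate with probability

    P = W12 W21 / (K + W12 W21)

where the saturation constant K is calibrated to the maximum of W12*W21 over
the feasible genotype space, so P <= 1/2 and is near-linear in W12*W21.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "KineticParams",
    "ProductionRates",
    "PairSteadyState",
    "CellSignalState",
    "solve_pair_steady_state",
    "cell_signal_state",
    "incoming_signal",
    "mating_probability",
    "calibrate_K",
    "invasion_fitness",
    "invasion_landscape",
]

_FLUX_RTOL = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """Physical constants of the ligand-receptor system.

    Parameters
    ----------
    k_on : float
        Within-cell binding rate constant (concentration^-1 time^-1).
    k_off : float
        Unbinding rate of the within-cell complex (time^-1).
    k_between : float
        Between-cell ligand-receptor affinity.  When within- and
        between-cell affinities coincide this equals ``k_on / k_off``.
    deg_L, deg_R, deg_LR : float
        First-order degradation rates of free ligand, free receptor and
        bound complex (time^-1).  Must be strictly positive.
    n_cost : float
        Exponent of the self-signaling cost; 0 means self-binding only
        depletes molecules, >= 1 additionally corrupts signal readout.
    K_sat : float or None
        Saturation constant of the mating-probability function.  ``None``
        until calibrated (see :func:`calibrate_K`).
    """

    k_on: float
    k_off: float
    k_between: float
    deg_L: float
    deg_R: float
    deg_LR: float
    n_cost: float = 1.0
    K_sat: float | None = None

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0 or self.k_between < 0:
            raise ValueError("rate constants must be nonnegative")
        if min(self.deg_L, self.deg_R, self.deg_LR) <= 0:
            raise ValueError("degradation rates must be strictly positive")
        if self.n_cost < 0:
            raise ValueError("n_cost must be nonnegative")
        if self.K_sat is not None and self.K_sat <= 0:
            raise ValueError("K_sat must be positive once set")

    @classmethod
    def symmetric(
        cls,
        k_on: float,
        k_off: float = 1.0,
        gamma: float = 0.5,
        k_between: float | None = None,
        n_cost: float = 1.0,
        K_sat: float | None = None,
    ) -> "KineticParams":
        """Common-gamma parameterization used throughout the evolutionary model.

        All three degradation rates are set to ``gamma``; ``k_between``
        defaults to ``k_on / k_off`` (equal within- and between-cell
        affinity).
        """
        if k_between is None:
            if k_off == 0:
                raise ValueError("k_off must be > 0 to default k_between")
            k_between = k_on / k_off
        return cls(
            k_on=k_on,
            k_off=k_off,
            k_between=k_between,
            deg_L=gamma,
            deg_R=gamma,
            deg_LR=gamma,
            n_cost=n_cost,
            K_sat=K_sat,
        )

    def with_K(self, K: float) -> "KineticParams":
        return replace(self, K_sat=K)


@dataclass(frozen=True)
class ProductionRates:
    """A cell's genotype: production rates of the four signaling genes.

    ``nu_L``/``nu_l`` are the two ligand genes (one locus), ``nu_R``/``nu_r``
    the two receptor genes (another locus).  Each rate lies in [0, alpha] and
    the two genes at a locus share a production budget:
    ``nu_L + nu_l <= alpha`` and ``nu_R + nu_r <= alpha``.
    """

    nu_L: float
    nu_R: float
    nu_l: float
    nu_r: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        rates = (self.nu_L, self.nu_R, self.nu_l, self.nu_r)
        if any(v < 0 or v > self.alpha for v in rates):
            raise ValueError(f"production rates must lie in [0, {self.alpha}]")
        tol = 1e-12
        if self.nu_L + self.nu_l > self.alpha + tol:
            raise ValueError("ligand locus exceeds production cap")
        if self.nu_R + self.nu_r > self.alpha + tol:
            raise ValueError("receptor locus exceeds production cap")

    def as_array(self) -> np.ndarray:
        return np.array([self.nu_L, self.nu_R, self.nu_l, self.nu_r])

    @classmethod
    def from_sequence(cls, seq: Sequence[float], alpha: float = 1.0) -> "ProductionRates":
        nu_L, nu_R, nu_l, nu_r = seq
        return cls(nu_L, nu_R, nu_l, nu_r, alpha=alpha)


@dataclass(frozen=True)
class PairSteadyState:
    """Steady-state concentrations for one ligand-receptor pair in one cell."""

    L_free: float
    R_free: float
    LR_bound: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.L_free, self.R_free, self.LR_bound)


@dataclass(frozen=True)
class CellSignalState:
    """Steady states of both (mutually incompatible) pairs in one cell."""

    pair_LR: PairSteadyState
    pair_lr: PairSteadyState

    def free_ligand(self) -> np.ndarray:
        return np.array([self.pair_LR.L_free, self.pair_lr.L_free])

    def free_receptor(self) -> np.ndarray:
        return np.array([self.pair_LR.R_free, self.pair_lr.R_free])

    def bound(self) -> np.ndarray:
        return np.array([self.pair_LR.LR_bound, self.pair_lr.LR_bound])


def steady_state_arrays(
    nu_ligand: np.ndarray, nu_receptor: np.ndarray, kin: KineticParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized steady-state solver for one ligand-receptor pair.

    Sets the mass-action production/binding/degradation dynamics

        d[L]/dt  = nu_L - k_on [R][L] + k_off [LR] - deg_L [L]
        d[R]/dt  = nu_R - k_on [R][L] + k_off [LR] - deg_R [R]
        d[LR]/dt = k_on [R][L] - k_off [LR] - deg_LR [LR]

    to zero.  Eliminating [LR] = k_on [L][R] / (k_off + deg_LR) leaves a
    quadratic in [L] with a unique nonnegative root; [R] and [LR] follow.
    Returns arrays ``(L_free, R_free, LR_bound)`` broadcast over the inputs.
    """
    nu_L = np.asarray(nu_ligand, dtype=float)
    nu_R = np.asarray(nu_receptor, dtype=float)
    if np.any(nu_L < 0) or np.any(nu_R < 0):
        raise ValueError("production rates must be nonnegative")

    gL, gR, gLR = kin.deg_L, kin.deg_R, kin.deg_LR
    # effective removal of free molecules through the complex channel
    c = kin.k_on * gLR / (kin.k_off + gLR)

    if c == 0.0:
        L = nu_L / gL
        R = nu_R / gR
        LR = np.zeros(np.broadcast(L, R).shape)
        return (
            np.broadcast_to(L, LR.shape).copy(),
            np.broadcast_to(R, LR.shape).copy(),
            LR,
        )

    # gL*c*L^2 + (gL*gR + c*(nu_R - nu_L))*L - nu_L*gR = 0, positive root.
    # Use the cancellation-free form 2*nu_L*gR/(b + sqrt(disc)) when b > 0
    # (relevant when the complex channel is weak, c -> 0).
    a = gL * c
    b = gL * gR + c * (nu_R - nu_L)
    disc = np.sqrt(b * b + 4.0 * a * nu_L * gR)
    L = np.where(
        b > 0.0,
        np.divide(2.0 * nu_L * gR, b + disc, out=np.zeros_like(disc + nu_L), where=(b + disc) > 0),
        (disc - b) / (2.0 * a),
    )
    L = np.maximum(L, 0.0)  # guard round-off at nu_L == 0
    R = nu_R / (gR + c * L)
    LR = kin.k_on * L * R / (kin.k_off + gLR)
    return L, R, LR


def _check_flux_balance(
    nu_L: float, nu_R: float, L: float, R: float, LR: float, kin: KineticParams
) -> None:
    res_L = kin.deg_L * L + kin.deg_LR * LR - nu_L
    res_R = kin.deg_R * R + kin.deg_LR * LR - nu_R
    scale_L = max(abs(nu_L), 1.0)
    scale_R = max(abs(nu_R), 1.0)
    if abs(res_L) > 1e-7 * scale_L or abs(res_R) > 1e-7 * scale_R:
        raise ArithmeticError(
            "steady-state solution violates flux balance "
            f"(residuals {res_L:.3e}, {res_R:.3e}); parameter pathology?"
        )


def solve_pair_steady_state(
    nu_ligand: float, nu_receptor: float, kin: KineticParams
) -> PairSteadyState:
    """Steady state of one ligand-receptor pair in one cell.

    The returned concentrations zero the mass-action dynamics; they are the
    unique all-nonnegative root of the equilibrium system.  At equilibrium
    production balances degradation for each molecule:
    ``nu_L = deg_L [L]* + deg_LR [LR]*`` and likewise for the receptor.
    """
    L, R, LR = steady_state_arrays(float(nu_ligand), float(nu_receptor), kin)
    L, R, LR = float(L), float(R), float(LR)
    if min(L, R, LR) < 0:
        raise ArithmeticError("negative steady-state concentration")
    _check_flux_balance(float(nu_ligand), float(nu_receptor), L, R, LR, kin)
    return PairSteadyState(L, R, LR)


def cell_signal_state(g: ProductionRates, kin: KineticParams) -> CellSignalState:
    """Solve both pairs of a cell independently (no cross-pair binding)."""
    return CellSignalState(
        pair_LR=solve_pair_steady_state(g.nu_L, g.nu_R, kin),
        pair_lr=solve_pair_steady_state(g.nu_l, g.nu_r, kin),
    )


def signal_terms(
    L_sender: np.ndarray,
    R_receiver: np.ndarray,
    LR_receiver: np.ndarray,
    kin: KineticParams,
) -> np.ndarray:
    """Per-pair contribution to the incoming signal, vectorized.

    ``kb * L2 * R1 * (1 - LR1/(LR1 + kb*L2*R1))**n``.  When the prefactor
    ``kb*L2*R1`` is zero the contribution is zero (the 0/0 case at
    ``LR1 == 0`` is resolved by its continuous limit).
    """
    pref = kin.k_between * np.asarray(L_sender) * np.asarray(R_receiver)
    denom = np.asarray(LR_receiver) + pref
    ratio = np.divide(
        pref, denom, out=np.zeros(np.broadcast(pref, denom).shape), where=denom > 0
    )
    return pref * ratio**kin.n_cost


def incoming_signal(
    receiver: CellSignalState, sender: CellSignalState, kin: KineticParams
) -> float:
    """Strength W12 of the signal the receiver reads from the sender.

    Sum over the two incompatible pairs of the sender's free ligand bound by
    the receiver's free receptor, discounted by the receiver's self-bound
    complex raised to the cost exponent.
    """
    w = signal_terms(
        sender.free_ligand(), receiver.free_receptor(), receiver.bound(), kin
    )
    return float(np.sum(w))


def mating_probability(w12: float, w21: float, K: float) -> float:
    """Probability that a cell pair mates given their mutual signals.

    ``P = W12*W21 / (K + W12*W21)``; monotone in each signal, in [0, 1).
    """
    if K <= 0:
        raise ValueError("saturation constant K must be positive")
    if w12 < 0 or w21 < 0:
        raise ValueError("signals must be nonnegative")
    prod = w12 * w21
    return prod / (K + prod)


def _interaction_strength(
    g1: np.ndarray, g2: np.ndarray, kin: KineticParams
) -> np.ndarray:
    """W12*W21 for genotype arrays of shape (..., 4) = (nu_L, nu_R, nu_l, nu_r)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    L1, R1, C1 = steady_state_arrays(g1[..., [0, 2]], g1[..., [1, 3]], kin)
    L2, R2, C2 = steady_state_arrays(g2[..., [0, 2]], g2[..., [1, 3]], kin)
    w12 = signal_terms(L2, R1, C1, kin).sum(axis=-1)
    w21 = signal_terms(L1, R2, C2, kin).sum(axis=-1)
    return w12 * w21


def interaction_strength(
    g1: Sequence[float], g2: Sequence[float], kin: KineticParams
) -> float:
    """W12*W21 between two genotypes given as (nu_L, nu_R, nu_l, nu_r)."""
    return float(_interaction_strength(np.asarray(g1), np.asarray(g2), kin))


def _locus_grid(alpha: float, step: float) -> np.ndarray:
    """All (a, b) with a, b in [0, alpha] on a grid and a + b <= alpha."""
    vals = np.arange(0.0, alpha + step / 2, step)
    a, b = np.meshgrid(vals, vals, indexing="ij")
    keep = a + b <= alpha + 1e-12
    return np.column_stack([a[keep], b[keep]])


def calibrate_K(
    kin: KineticParams,
    alpha: float = 1.0,
    grid_step: float = 0.125,
    refine: bool = True,
    full_output: bool = False,
):
    """Saturation constant K = max of W12*W21 over feasible genotype pairs.

    Calibrating K this way makes the mating probability at most 1/2 and
    near-linear in W12*W21 over the whole genotype space, so only relative
    interaction strength matters for selection.

    The maximum is located by a coarse grid search over both cells' genotypes
    (respecting the per-locus production caps), refined locally with
    Nelder-Mead, and always compared against the fully asymmetric
    complementary pair (alpha,0,0,alpha) vs (0,alpha,alpha,0), which attains
    the analytic upper bound ``k_between**2 * alpha**4 / (deg_L*deg_R)**2``
    whenever self-binding is costly.

    Returns K (float), or ``(K, info_dict)`` when ``full_output`` is true.
    """
    if kin.k_between == 0:
        raise ValueError("k_between must be positive to calibrate K")

    # coarse grid over genotype pairs
    locus = _locus_grid(alpha, grid_step)  # (m, 2) per-locus combos
    m = len(locus)
    # genotype = (nu_L, nu_R, nu_l, nu_r) from ligand-locus (nu_L, nu_l)
    # and receptor-locus (nu_R, nu_r) combos
    li, ri = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    genos = np.column_stack(
        [
            locus[li.ravel(), 0],
            locus[ri.ravel(), 0],
            locus[li.ravel(), 1],
            locus[ri.ravel(), 1],
        ]
    )  # (m*m, 4)
    n_g = len(genos)
    i1, i2 = np.meshgrid(np.arange(n_g), np.arange(n_g), indexing="ij")
    vals = _interaction_strength(genos[i1.ravel()], genos[i2.ravel()], kin)
    best = int(np.argmax(vals))
    best_val = float(vals[best])
    best_pair = (genos[i1.ravel()[best]].copy(), genos[i2.ravel()[best]].copy())

    if refine:

        def neg(x: np.ndarray) -> float:
            g1, g2 = _project_genotype(x[:4], alpha), _project_genotype(x[4:], alpha)
            return -float(_interaction_strength(g1, g2, kin))

        x0 = np.concatenate(best_pair)
        res = optimize.minimize(neg, x0, method="Nelder-Mead", options={"maxiter": 2000})
        if -res.fun > best_val:
            best_val = -float(res.fun)
            best_pair = (
                _project_genotype(res.x[:4], alpha),
                _project_genotype(res.x[4:], alpha),
            )

    # explicit check of the conjectured maximizer
    g_a = np.array([alpha, 0.0, 0.0, alpha])
    g_b = np.array([0.0, alpha, alpha, 0.0])
    asym_val = interaction_strength(g_a, g_b, kin)
    if asym_val >= best_val:
        best_val = asym_val
        best_pair = (g_a, g_b)

    if not full_output:
        return best_val
    return best_val, {
        "K": best_val,
        "maximizer": (best_pair[0].tolist(), best_pair[1].tolist()),
        "grid_step": grid_step,
        "asymmetric_pair_value": asym_val,
    }


def _project_genotype(x: np.ndarray, alpha: float) -> np.ndarray:
    """Clip to [0, alpha] and rescale each locus onto its budget simplex."""
    g = np.clip(np.asarray(x, dtype=float), 0.0, alpha)
    for locus in ((0, 2), (1, 3)):
        s = g[locus[0]] + g[locus[1]]
        if s > alpha:
            g[locus[0]] *= alpha / s
            g[locus[1]] *= alpha / s
    return g


def invasion_fitness(
    res: Sequence[float] | ProductionRates,
    mut: Sequence[float] | ProductionRates,
    kin: KineticParams,
) -> float:
    """Signed fitness of a rare mutant interacting with a common resident.

    ``[W12*W21]_{res<->mut} - [W12*W21]_{res<->res}``: positive values mean
    the mutant pairs with the resident more effectively than the resident
    pairs with itself, so the mutant can spread.
    """
    g_res = res.as_array() if isinstance(res, ProductionRates) else np.asarray(res, float)
    g_mut = mut.as_array() if isinstance(mut, ProductionRates) else np.asarray(mut, float)
    return interaction_strength(g_res, g_mut, kin) - interaction_strength(
        g_res, g_res, kin
    )


def invasion_landscape(
    res: Sequence[float] | ProductionRates,
    kin: KineticParams,
    grid_resolution: int = 21,
    mutant_family: Callable[[float, float], Sequence[float]] | None = None,
    dx_range: tuple[float, float] = (0.0, 1.0),
    dy_range: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Invasion-fitness surface over a (dx, dy) grid of mutant deviations.

    The default mutant family shifts production toward the second pair:
    ``mut = (1-dx, 1-dy, dx, dy)``.  Returns a long-format DataFrame with
    columns ``dx``, ``dy``, ``fitness_difference``.
    """
    if mutant_family is None:
        mutant_family = lambda dx, dy: (1.0 - dx, 1.0 - dy, dx, dy)  # noqa: E731
    g_res = res.as_array() if isinstance(res, ProductionRates) else np.asarray(res, float)
    dxs = np.linspace(*dx_range, grid_resolution)
    dys = np.linspace(*dy_range, grid_resolution)
    res_res = interaction_strength(g_res, g_res, kin)
    rows = []
    for dx in dxs:
        for dy in dys:
            g_mut = np.asarray(mutant_family(dx, dy), dtype=float)
            fit = interaction_strength(g_res, g_mut, kin) - res_res
            rows.append((dx, dy, fit))
    return pd.DataFrame(rows, columns=["dx", "dy", "fitness_difference"])
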