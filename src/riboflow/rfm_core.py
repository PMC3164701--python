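"""The ribosome flow model: dynamics, steady states and limits.

The model coarse-grains an mRNA into ``n`` sites of ``C`` codons and
tracks the occupancy probability ``p_i(t)`` of each site.  Ribosomes
enter the first site at initiation rate ``lam`` when it is free, hop from
site ``i`` to ``i+1`` at rate ``lam_i`` attenuated by the occupancy of
the target site (a mean-field treatment of steric exclusion), and leave
from the last site at its own rate:

    dp_1/dt = lam (1 - p_1)          - lam_1 p_1 (1 - p_2)
    dp_i/dt = lam_{i-1} p_{i-1} (1 - p_i) - lam_i p_i (1 - p_{i+1})
    dp_n/dt = lam_{n-1} p_{n-1} (1 - p_n) - lam_n p_n

At steady state every junction carries the same flow, the protein
production rate ``R = lam_n pbar_n``, which is bounded by the slowest
rate in the system: ``R <= min(lam, lam_1, ..., lam_n)``.

Two independent solvers are provided: direct time integration from an
empty strand, and an exact algebraic route through an equivalent
tridiagonal eigenvalue problem.  They agree to solver tolerance and
serve as mutual oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp
from scipy.linalg import eigh_tridiagonal

__all__ = [
    "RFMInstance",
    "SteadyState",
    "rfm_rhs",
    "solve_steady_state_ode",
    "solve_steady_state_algebraic",
    "elongation_capacity",
    "rate_vs_lambda_curve",
    "solve_with_abortion",
    "finite_horizon_mean_rate",
]


@dataclass(frozen=True)
class RFMInstance:
    """Initiation rate, site transition rates and site size metadata."""

    lam: float
    rates: np.ndarray
    C: int = 25

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if self.lam <= 0:
            raise ValueError(f"initiation rate must be positive, got {self.lam}")
        if rates.ndim != 1 or rates.size < 1:
            raise ValueError("rates must be a non-empty 1-D vector")
        if np.any(rates <= 0):
            raise ValueError("all site rates must be positive")

    @property
    def n(self) -> int:
        return int(self.rates.size)


@dataclass
class SteadyState:
    """Steady-state occupancies, production rate and solver diagnostics."""

    occupancies: np.ndarray
    rate: float
    residual: float
    horizon: float

    @property
    def mean_density(self) -> float:
        """Mean site occupancy, the model's ribosome-density readout."""
        return float(np.mean(self.occupancies))


def rfm_rhs(
    p: np.ndarray, instance: RFMInstance, gamma: float = 0.0
) -> np.ndarray:
    """Occupancy time-derivatives of the flow model.

    With ``gamma > 0`` each interior junction additionally loses
    ``gamma * lam_i * p_i * p_{i+1}`` from both adjacent sites: the
    fraction of ribosome-ribosome collisions in which both colliding
    ribosomes abort and detach.
    """
    p = np.asarray(p, dtype=float)
    lam, rates, n = instance.lam, instance.rates, instance.n
    if p.shape != (n,):
        raise ValueError(f"state has shape {p.shape}, expected ({n},)")
    # inflow[i]: flow into site i; outflow[i]: flow out of site i
    inter = rates[:-1] * p[:-1] * (1.0 - p[1:])  # junction flows i -> i+1
    inflow = np.concatenate(([lam * (1.0 - p[0])], inter))
    outflow = np.concatenate((inter, [rates[-1] * p[-1]]))
    dp = inflow - outflow
    if gamma != 0.0:
        loss = gamma * rates[:-1] * p[:-1] * p[1:]
        dp[:-1] -= loss
        dp[1:] -= loss
    return dp


def _integrate_to_steady(
    instance: RFMInstance,
    tolerance: float,
    max_horizon: float | None,
    gamma: float = 0.0,
) -> SteadyState:
    n = instance.n
    rhs = lambda t, p: rfm_rhs(p, instance, gamma=gamma)
    # natural relaxation scale: sites divided by the slowest rate
    t_scale = n / min(instance.lam, float(instance.rates.min()))
    if max_horizon is None:
        max_horizon = 1e6 * t_scale
    p = np.zeros(n)
    t0, t1 = 0.0, 10.0 * t_scale
    residual = float(np.max(np.abs(rhs(0.0, p))))
    while t0 < max_horizon:
        sol = solve_ivp(
            rhs, (t0, t1), p, method="LSODA", rtol=1e-10, atol=1e-12
        )
        if not sol.success:  # pragma: no cover - LSODA failure is exotic here
            raise RuntimeError(f"integration failed: {sol.message}")
        p = sol.y[:, -1]
        residual = float(np.max(np.abs(rhs(t1, p))))
        if residual < tolerance:
            p = np.clip(p, 0.0, 1.0)
            return SteadyState(
                occupancies=p,
                rate=float(instance.rates[-1] * p[-1]),
                residual=residual,
                horizon=t1,
            )
        t0, t1 = t1, t1 * 4.0
    raise RuntimeError(
        f"no steady state within horizon {max_horizon:g}; last residual {residual:g}"
    )


def solve_steady_state_ode(
    instance: RFMInstance,
    tolerance: float = 1e-9,
    max_horizon: float | None = None,
) -> SteadyState:
    """Integrate the dynamics from an empty strand until the flow balances.

    Integration proceeds over geometrically growing horizons until the
    max-norm of the right-hand side drops below ``tolerance``.
    """
    return _integrate_to_steady(instance, tolerance, max_horizon)


def solve_steady_state_algebraic(
    instance: RFMInstance, tolerance: float = 1e-9
) -> SteadyState:
    """Steady state by an exact spectral method, independent of the ODE.

    Unrolling the steady-state flow balance as a continued fraction shows
    that ``1/sqrt(R)`` is the largest eigenvalue of the (n+2)-dimensional
    symmetric tridiagonal matrix with zero diagonal and off-diagonal
    entries ``1/sqrt(lam), 1/sqrt(lam_1), ..., 1/sqrt(lam_n)``, and that
    the occupancies follow from consecutive ratios of the corresponding
    (positive) eigenvector ``v``:

        p_i = sqrt(R) * lam_i**-0.5 * v[i+1] / v[i].

    This is numerically stable for any chain, unlike one-directional
    back-substitution of the balance equations, which amplifies rounding
    error through its non-contracting region.  ``tolerance`` bounds the
    accepted max-norm residual of the flow balance (relative to R).
    """
    lam, rates, n = instance.lam, instance.rates, instance.n
    c = 1.0 / np.sqrt(np.concatenate(([lam], rates)))
    w, v = eigh_tridiagonal(
        np.zeros(n + 2), c, select="i", select_range=(n + 1, n + 1)
    )
    zeta = float(w[0])
    vec = v[:, 0]
    if vec[0] < 0:
        vec = -vec
    R = 1.0 / zeta**2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.sqrt(R) * c[1:] * vec[2:] / vec[1:-1]
    # On long initiation-limited chains the eigenvector decays
    # exponentially and underflows downstream; that region is dilute, so
    # backward substitution of the flow balance is stable there.
    # (and, symmetrically, toward the entry when slow interior sites
    # localize the eigenvector: that head is dense, where the forward
    # recursion is the stable one)
    # components much smaller than the largest are numerically meaningless
    # (the eigenvector is computed to absolute, not relative, accuracy)
    tiny = 1e-13 * float(np.max(np.abs(vec)))
    bad = (
        ~np.isfinite(p)
        | (np.abs(vec[1:-1]) < tiny)
        | (np.abs(vec[2:]) < tiny)
    )
    if bad.all():  # pragma: no cover - eigenvector is normalized
        raise RuntimeError("degenerate eigenvector in spectral steady state")
    if bad.any():
        good = np.flatnonzero(~bad)
        first, last = int(good[0]), int(good[-1])
        if last < n - 1:  # dilute tail: backward substitution from the exit
            p[-1] = min(R / rates[-1], 1.0)
            for i in range(n - 2, last, -1):
                denom = rates[i] * (1.0 - p[i + 1])
                p[i] = min(R / denom, 1.0) if denom > 0 else 1.0
        if first > 0:  # dense head: forward substitution from the entry
            p[0] = max(1.0 - R / lam, 0.0)
            for i in range(1, first):
                p[i] = max(1.0 - R / (rates[i - 1] * p[i - 1]), 0.0)
    p = np.clip(p, 0.0, 1.0)
    residual = float(np.max(np.abs(rfm_rhs(p, instance))))
    if residual > 1e-14 * max(R, 1.0):
        # Newton polish from the (already accurate) spectral solution
        sol = optimize.root(lambda q: rfm_rhs(q, instance), p, method="hybr")
        res_new = float(np.max(np.abs(sol.fun)))
        if res_new < residual and np.all(sol.x > -1e-9) and np.all(sol.x < 1 + 1e-9):
            p = np.clip(sol.x, 0.0, 1.0)
            R = float(rates[-1] * p[-1])
            residual = res_new
    if residual > tolerance * max(R, 1.0):
        raise RuntimeError(
            f"steady state inconsistent: residual {residual:g} for R={R:g}"
        )
    return SteadyState(occupancies=p, rate=float(R), residual=residual, horizon=np.inf)


def elongation_capacity(
    rates: Sequence[float] | np.ndarray,
    lam_large: float | None = None,
    tolerance: float = 1e-3,
    grid_points: int = 60,
) -> tuple[float, float]:
    """Maximal translation rate of a transcript and its saturation onset.

    The capacity ``R_inf`` is the initiation-saturated limit of the
    steady-state rate, computed exactly from the site rates alone, and
    verified reachable: the rate at ``10 * lam_large`` (default
    ``lam_large = 1e3 * max lam_i``) must agree within ``tolerance``
    relative.  The threshold ``lam_0`` is the smallest lambda on a log
    grid reaching ``(1 - tolerance) * R_inf``.
    """
    rates = np.asarray(rates, dtype=float)
    if lam_large is None:
        lam_large = 1e3 * float(rates.max())
    # exact initiation-saturated limit: dropping the entry row of the
    # spectral form leaves the n+1 Jacobi matrix of the site rates alone
    c = 1.0 / np.sqrt(rates)
    n = rates.size
    w = eigh_tridiagonal(
        np.zeros(n + 1), c, select="i", select_range=(n, n), eigvals_only=True
    )
    R_inf = 1.0 / float(w[0]) ** 2
    R_check = solve_steady_state_algebraic(RFMInstance(10.0 * lam_large, rates)).rate
    if abs(R_check - R_inf) > tolerance * R_inf:
        raise RuntimeError(
            f"capacity not converged at lam={lam_large:g}: "
            f"limit={R_inf:g}, R({10 * lam_large:g})={R_check:g}"
        )
    grid = np.geomspace(1e-3 * float(rates.min()), lam_large, grid_points)
    lam0 = lam_large
    for lam in grid:
        R = solve_steady_state_algebraic(RFMInstance(float(lam), rates)).rate
        if R >= (1.0 - tolerance) * R_inf:
            lam0 = float(lam)
            break
    return float(R_inf), lam0


def rate_vs_lambda_curve(
    rates: Sequence[float] | np.ndarray,
    lam_grid: Sequence[float] | np.ndarray,
    solver: Callable[[RFMInstance], SteadyState] | None = None,
) -> list[tuple[float, float, float]]:
    """(lambda, R, mean density) along an increasing initiation-rate grid."""
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size < 1 or np.any(lam_grid <= 0) or np.any(np.diff(lam_grid) <= 0):
        raise ValueError("lam_grid must be positive and strictly increasing")
    solve = solver or solve_steady_state_algebraic
    out: list[tuple[float, float, float]] = []
    prev_R = -np.inf
    for lam in lam_grid:
        ss = solve(RFMInstance(float(lam), rates))
        if ss.rate < prev_R - 1e-9:
            raise AssertionError(
                f"translation rate decreased along lambda grid at lam={lam:g}"
            )
        prev_R = ss.rate
        out.append((float(lam), ss.rate, ss.mean_density))
    return out


def solve_with_abortion(
    instance: RFMInstance,
    gamma: float,
    tolerance: float = 1e-9,
    max_horizon: float | None = None,
) -> SteadyState:
    """Steady state of the model with collision-induced abortion.

    ``gamma`` is the probability that a ribosome-ribosome collision makes
    both colliding ribosomes detach; ``gamma = 0`` recovers the plain
    model (the regime the data favor).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"abortion probability must be in [0, 1], got {gamma}")
    return _integrate_to_steady(instance, tolerance, max_horizon, gamma=gamma)


def finite_horizon_mean_rate(instance: RFMInstance, horizon: float) -> float:
    """Mean production rate over [0, T] starting from an empty strand.

    Models a transcript whose lifetime (set by mRNA half-life) is too
    short for the steady-state assumption: the production flux
    ``lam_n p_n(t)`` is integrated alongside the occupancies and divided
    by the horizon.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    n = instance.n

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dp = rfm_rhs(y[:n], instance)
        return np.concatenate((dp, [instance.rates[-1] * y[n - 1]]))

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        np.zeros(n + 1),
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"integration failed: {sol.message}")
    produced = sol.y[n, -1]
    return float(produced / horizon)
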