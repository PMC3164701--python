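"""Event-driven simulation of ribosome traffic on a single mRNA.

The model is a generalized totally asymmetric simple exclusion process
(TASEP): ribosomes are extended particles covering ``l`` codons (``l``
odd; the codon under translation sits at the ribosome's middle), they
attach at codon 1 with rate ``lam`` when the first ``(l+1)/2`` codons are
uncovered, hop codon-by-codon with codon-specific rates, never overlap,
and terminate on the jump off the last codon.  Near the 3' end a ribosome
bulges off the strand and its moves are never blocked.

Events (initiation, jump or termination attempts) are drawn by the
Gillespie direct method — equivalent to taking the minimum of the
competing exponential clocks — and blocked attempts consume time without
changing the configuration.  A deterministic-dwell variant keeps the
exponential initiation clock but replaces each codon's exponential dwell
with its exact expectation ``1/lam_i``, rescheduling blocked ribosomes
after a further full dwell.

The production rate is the number of terminations divided by the elapsed
time of the measurement phase, after a burn-in from an empty strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .codon_rates import CodonTimeTable, Transcript, site_rates
from .rfm_core import RFMInstance, solve_steady_state_algebraic

__all__ = ["TASEPInstance", "SimulationResult", "simulate", "compare_rfm_tasep"]


@dataclass(frozen=True)
class TASEPInstance:
    """Per-codon jump rates, initiation rate and ribosome footprint."""

    lam: float
    rates: np.ndarray
    footprint: int = 11

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if self.footprint < 1 or self.footprint % 2 == 0:
            raise ValueError(
                f"footprint must be odd and >= 1, got {self.footprint}"
            )
        if self.lam < 0:
            raise ValueError("initiation rate must be non-negative")
        if rates.ndim != 1 or rates.size < 1 or np.any(rates <= 0):
            raise ValueError("rates must be a non-empty positive vector")

    @property
    def n_codons(self) -> int:
        return int(self.rates.size)


@dataclass
class SimulationResult:
    """Measured production rate, occupancy profile and bookkeeping."""

    rate: float
    occupancy: np.ndarray
    n_events: int
    n_terminations: int
    elapsed_time: float
    seed: int


@njit(cache=True)
def _run_kernel(rates, lam, l, burn_in, measure, seed, deterministic):
    """Core event loop.

    positions[k] is the (1-based) translated codon of the k-th ribosome,
    sorted ascending (index m-1 is closest to the 3' end).  Exclusion:
    consecutive translated codons differ by at least l.  Returns
    (terminations, measured time, time-weighted occupancy, min spacing
    seen, total events).
    """
    N = rates.size
    max_m = N // l + 2
    positions = np.zeros(max_m, dtype=np.int64)
    next_time = np.zeros(max_m, dtype=np.float64)  # deterministic mode only
    m = 0
    np.random.seed(seed)
    t = 0.0
    occ = np.zeros(N, dtype=np.float64)
    terms = 0
    t_measure = 0.0
    min_spacing = np.int64(N + l)
    t_init = 0.0
    if deterministic and lam > 0.0:
        t_init = -np.log(np.random.random()) / lam
    total_events = burn_in + measure
    for ev in range(total_events):
        measuring = ev >= burn_in
        if not deterministic:
            # Gillespie direct: total rate of all competing clocks
            total = lam
            for k in range(m):
                total += rates[positions[k] - 1]
            if total <= 0.0:
                break
            dt = -np.log(np.random.random()) / total
            t_new = t + dt
            event_is_init = False
            k_sel = -1
            r = np.random.random() * total
            if r < lam:
                event_is_init = True
            else:
                r -= lam
                for k in range(m):
                    r -= rates[positions[k] - 1]
                    if r < 0.0:
                        k_sel = k
                        break
                if k_sel < 0:
                    k_sel = m - 1
        else:
            # next scheduled event among ribosome dwell expiries and initiation
            t_new = t_init if lam > 0.0 else np.inf
            event_is_init = True
            k_sel = -1
            for k in range(m):
                if next_time[k] < t_new:
                    t_new = next_time[k]
                    event_is_init = False
                    k_sel = k
            if not np.isfinite(t_new):
                break
            dt = t_new - t
        if measuring:
            t_measure += dt
            for k in range(m):
                occ[positions[k] - 1] += dt
        t = t_new
        if event_is_init:
            if deterministic:
                t_init = t - np.log(np.random.random()) / lam
            # attach at codon 1 if the first (l+1)/2 codons are uncovered
            if m == 0 or positions[0] > l:
                for k in range(m, 0, -1):
                    positions[k] = positions[k - 1]
                    next_time[k] = next_time[k - 1]
                positions[0] = 1
                next_time[0] = t + 1.0 / rates[0]
                m += 1
        else:
            i = positions[k_sel]
            if k_sel == m - 1:
                # nothing ahead: move freely; jump off codon N terminates
                if i == N:
                    for k in range(k_sel, m - 1):
                        positions[k] = positions[k + 1]
                        next_time[k] = next_time[k + 1]
                    m -= 1
                    if measuring:
                        terms += 1
                else:
                    positions[k_sel] = i + 1
                    next_time[k_sel] = t + 1.0 / rates[i]
            else:
                gap = positions[k_sel + 1] - i
                if gap > l:
                    positions[k_sel] = i + 1
                    next_time[k_sel] = t + 1.0 / rates[i]
                elif deterministic:
                    # blocked: retry after another full dwell
                    next_time[k_sel] = t + 1.0 / rates[i - 1]
        for k in range(m - 1):
            sp = positions[k + 1] - positions[k]
            if sp < min_spacing:
                min_spacing = sp
    return terms, t_measure, occ, min_spacing, total_events


def simulate(
    instance: TASEPInstance,
    burn_in_events: int = 250_000,
    measure_events: int = 1_000_000,
    seed: int = 0,
    dwell_mode: str = "exponential",
) -> SimulationResult:
    """Simulate the exclusion process and measure the production rate.

    The strand starts empty; ``burn_in_events`` events relax it toward
    the stationary regime, then ``measure_events`` events are tracked.
    ``dwell_mode`` selects exponential codon dwell times (the stochastic
    model) or deterministic ones (fixed dwell ``1/lam_i`` per codon).
    """
    if burn_in_events < 0 or measure_events < 0:
        raise ValueError("event counts must be non-negative")
    if dwell_mode not in ("exponential", "deterministic"):
        raise ValueError(f"unknown dwell_mode {dwell_mode!r}")
    terms, t_measure, occ, min_spacing, n_events = _run_kernel(
        instance.rates,
        float(instance.lam),
        instance.footprint,
        burn_in_events,
        measure_events,
        np.uint32(seed),
        dwell_mode == "deterministic",
    )
    if min_spacing < instance.footprint:  # pragma: no cover - invariant guard
        raise AssertionError(
            f"exclusion violated: spacing {min_spacing} < footprint {instance.footprint}"
        )
    rate = terms / t_measure if t_measure > 0 else 0.0
    occupancy = occ / t_measure if t_measure > 0 else occ
    return SimulationResult(
        rate=float(rate),
        occupancy=occupancy,
        n_events=int(n_events),
        n_terminations=int(terms),
        elapsed_time=float(t_measure),
        seed=int(seed),
    )


@dataclass
class ModelComparison:
    """Paired rates from the flow model and the exclusion process."""

    gene_ids: list[str]
    rfm_rates: np.ndarray
    tasep_rates: np.ndarray
    pearson_r: float
    spearman_r: float


def compare_rfm_tasep(
    transcripts: Sequence[Transcript],
    time_table: CodonTimeTable,
    C: int,
    lam: float,
    seed: int = 0,
    footprint: int = 11,
    burn_in_events: int = 250_000,
    measure_events: int = 1_000_000,
    rfm_solver: str = "algebraic",
) -> ModelComparison:
    """Run both models on shared dwell-time inputs and correlate the rates.

    The exclusion process runs at codon resolution with per-codon rates
    ``1/tau_i``; the flow model runs on the same transcript after
    coarse-graining into sites of ``C`` codons (``rfm_solver`` selects the
    algebraic or the time-integration route).  Each transcript gets an
    independent simulation seed derived from ``seed``.
    """
    import warnings

    from scipy import stats

    from .rfm_core import solve_steady_state_ode

    solvers = {
        "algebraic": solve_steady_state_algebraic,
        "ode": solve_steady_state_ode,
    }
    if rfm_solver not in solvers:
        raise ValueError(f"unknown rfm_solver {rfm_solver!r}")
    solve = solvers[rfm_solver]
    if len(transcripts) < 3:
        raise ValueError("need at least 3 transcripts to correlate models")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(transcripts))
    rfm_rates = np.empty(len(transcripts))
    tasep_rates = np.empty(len(transcripts))
    ids = []
    for k, tr in enumerate(transcripts):
        ids.append(tr.gene_id)
        codon_rates = np.array(
            [1.0 / time_table.time_of(c) for c in tr.coding_codons()]
        )
        rfm_rates[k] = solve(
            RFMInstance(lam, site_rates(tr, C, time_table), C=C)
        ).rate
        tasep_rates[k] = simulate(
            TASEPInstance(lam, codon_rates, footprint),
            burn_in_events=burn_in_events,
            measure_events=measure_events,
            seed=int(sub_seeds[k]),
        ).rate
    if np.ptp(rfm_rates) == 0 or np.ptp(tasep_rates) == 0:
        warnings.warn("degenerate (constant) rates: correlation undefined")
        pearson = spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(rfm_rates, tasep_rates).statistic)
        spearman = float(stats.spearmanr(rfm_rates, tasep_rates).statistic)
    return ModelComparison(ids, rfm_rates, tasep_rates, pearson, spearman)
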