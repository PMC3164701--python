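"""Derived analyses built on the flow model.

Codon-order dependence (DTCO/DPCO) quantifies how much a transcript's
predicted translation rate — and, through a log-log regressor, its
predicted protein abundance — changes under random shuffles of its codon
order, a signal invisible to content-only indices such as the tAI.

Working-point inference asks at which initiation rate a cell operates: a
global ``lambda*`` maximizing the rank correlation between predicted
rates and measured protein abundance defines the fraction ``Q%`` of the
elongation capacity attained there, and per-gene initiation rates are
then read off as the ``lambda`` where each gene reaches ``Q%`` of its
own capacity.

Also here: translation cost (proteins per unit time per working
ribosome), fold-change between sequence variants averaged over an
initiation-rate grid, permutation-based empirical p-values for Spearman
correlations, and a jackknife over genes assessing the robustness of the
inferred optimal coarse-graining size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .codon_rates import CodonTimeTable, Transcript, site_rates
from .rfm_core import RFMInstance, elongation_capacity, solve_steady_state_algebraic

__all__ = [
    "PermutationReport",
    "WorkingPoint",
    "rfm_rate",
    "dtco",
    "fit_loglog_abundance_regressor",
    "dpco",
    "global_working_point",
    "gene_working_point",
    "translation_cost",
    "fold_change",
    "empirical_spearman_p",
    "jackknife_site_size",
]


def rfm_rate(
    transcript: Transcript, table: CodonTimeTable, C: int, lam: float
) -> float:
    """Steady-state translation rate of a transcript at initiation rate lam."""
    rates = site_rates(transcript, C, table)
    return solve_steady_state_algebraic(RFMInstance(lam, rates, C=C)).rate


@dataclass
class PermutationReport:
    gene_id: str
    n_perm: int
    original_rate: float
    permuted_rates: np.ndarray
    dtco: float
    seed: int


@dataclass
class WorkingPoint:
    lam_star: float
    q_percent: float
    correlations: np.ndarray
    lam_grid: np.ndarray


def _permuted_rates(
    transcript: Transcript,
    table: CodonTimeTable,
    C: int,
    lam: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    codons = list(transcript.coding_codons())
    rates = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = list(codons)
        rng.shuffle(shuffled)
        perm = Transcript(f"{transcript.gene_id}|perm{k}", tuple(shuffled))
        rates[k] = rfm_rate(perm, table, C, lam)
    return rates


def dtco(
    transcript: Transcript,
    table: CodonTimeTable,
    C: int,
    lam: float,
    n_perm: int = 10,
    seed: int = 0,
) -> PermutationReport:
    """Dependence of the translation rate on codon order, in percent.

    The codon order is shuffled uniformly at random ``n_perm`` times
    (whole codons; the multiset, and hence any content-only index, is
    preserved), the rate recomputed per shuffle, and the sample standard
    deviation (n-1 denominator) normalized by the unpermuted rate.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations for a standard deviation")
    rng = np.random.default_rng(seed)
    r0 = rfm_rate(transcript, table, C, lam)
    rates = _permuted_rates(transcript, table, C, lam, n_perm, rng)
    value = 100.0 * float(np.std(rates, ddof=1)) / r0
    return PermutationReport(transcript.gene_id, n_perm, r0, rates, value, seed)


def fit_loglog_abundance_regressor(
    rates: Sequence[float], abundances: Sequence[float]
) -> tuple[float, float]:
    """Least-squares line of log(abundance) on log(rate).

    Protein abundance against predicted translation rate is close to
    linear on a log-log scale, so a power law is the natural calibration.
    """
    rates = np.asarray(rates, dtype=float)
    abundances = np.asarray(abundances, dtype=float)
    if rates.size != abundances.size or rates.size < 3:
        raise ValueError("need >= 3 paired rate/abundance values")
    if np.any(rates <= 0) or np.any(abundances <= 0):
        raise ValueError("rates and abundances must be positive")
    res = stats.linregress(np.log(rates), np.log(abundances))
    return float(res.slope), float(res.intercept)


def dpco(
    transcript: Transcript,
    regressor: tuple[float, float],
    table: CodonTimeTable,
    C: int,
    lam: float,
    n_perm: int = 10,
    seed: int = 0,
) -> float:
    """Dependence of predicted protein abundance on codon order (%).

    Each permuted rate is mapped through the fitted log-log regressor to
    a predicted abundance; the standard deviation over permutations is
    normalized by the predicted abundance of the original transcript.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations for a standard deviation")
    slope, intercept = regressor
    rng = np.random.default_rng(seed)
    r0 = rfm_rate(transcript, table, C, lam)
    rates = _permuted_rates(transcript, table, C, lam, n_perm, rng)
    predict = lambda r: np.exp(slope * np.log(r) + intercept)
    abundances = predict(rates)
    return 100.0 * float(np.std(abundances, ddof=1)) / float(predict(r0))


def global_working_point(
    gene_rates: Sequence[np.ndarray],
    abundances: Sequence[float],
    lam_grid: Sequence[float],
) -> WorkingPoint:
    """Infer the organism-wide initiation rate and its capacity fraction.

    ``gene_rates`` are per-gene site-rate vectors.  For every lambda on
    the grid, steady-state rates are computed for all genes and rank-
    correlated with abundance; ``lambda*`` is the grid argmax.  ``Q`` is
    the percentage of the mean elongation capacity attained by the mean
    rate at ``lambda*``.
    """
    abundances = np.asarray(abundances, dtype=float)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if len(gene_rates) < 10:
        raise ValueError("need >= 10 genes with abundance")
    if np.ptp(abundances) == 0:
        raise ValueError("abundances are constant; correlation undefined")
    R = np.empty((lam_grid.size, len(gene_rates)))
    for i, lam in enumerate(lam_grid):
        for j, rates in enumerate(gene_rates):
            R[i, j] = solve_steady_state_algebraic(
                RFMInstance(float(lam), rates)
            ).rate
    corrs = np.array(
        [stats.spearmanr(R[i], abundances).statistic for i in range(lam_grid.size)]
    )
    i_star = int(np.nanargmax(corrs))
    capacities = np.array([elongation_capacity(r)[0] for r in gene_rates])
    q = 100.0 * float(np.mean(R[i_star]) / np.mean(capacities))
    return WorkingPoint(float(lam_grid[i_star]), q, corrs, lam_grid)


def gene_working_point(rates: np.ndarray, Q: float) -> float:
    """The lambda at which a gene attains Q% of its elongation capacity.

    ``R(lambda)`` is monotone increasing and saturates at the capacity,
    so the equation ``R(lambda) = (Q/100) * capacity`` has a unique root,
    found by bracketed root search.
    """
    if not 0.0 < Q < 100.0:
        raise ValueError(f"Q must lie in (0, 100), got {Q}")
    rates = np.asarray(rates, dtype=float)
    cap, _ = elongation_capacity(rates)
    target = (Q / 100.0) * cap

    def f(log_lam: float) -> float:
        ss = solve_steady_state_algebraic(RFMInstance(np.exp(log_lam), rates))
        return ss.rate - target

    lo = np.log(1e-6 * float(rates.min()))
    hi = np.log(1e6 * float(rates.max()))
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12)))


def translation_cost(rate: float, mean_density: float) -> float:
    """Proteins produced per unit time per working ribosome.

    The ratio of the translation rate to the mean ribosome density on
    the transcript: a cost-efficiency readout of the translation
    machinery.
    """
    if mean_density <= 0:
        raise ValueError("mean density must be positive")
    return rate / mean_density


def fold_change(
    native: Transcript,
    variant: Transcript,
    table: CodonTimeTable,
    C: int = 25,
    lam_grid: Sequence[float] | None = None,
) -> float:
    """Mean predicted rate ratio variant/native over an initiation grid.

    The default grid, 41 equally spaced values of lambda in
    [0.0002, 0.0094], spans the physiologically relevant initiation-
    limited range used for heterologous-expression comparisons.
    """
    if lam_grid is None:
        lam_grid = np.linspace(0.0002, 0.0094, 41)
    lam_grid = np.asarray(lam_grid, dtype=float)
    r_nat = site_rates(native, C, table)
    r_var = site_rates(variant, C, table)
    ratios = [
        solve_steady_state_algebraic(RFMInstance(float(l), r_var)).rate
        / solve_steady_state_algebraic(RFMInstance(float(l), r_nat)).rate
        for l in lam_grid
    ]
    return float(np.mean(ratios))


def empirical_spearman_p(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation with a permutation-based empirical p-value.

    p is the fraction of random permutations of ``y`` whose correlation
    with ``x`` strictly exceeds the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    higher = 0
    for _ in range(n_perm):
        rho_p = stats.spearmanr(x, rng.permutation(y)).statistic
        if rho_p > rho:
            higher += 1
    return rho, higher / n_perm


def jackknife_site_size(
    transcripts: Sequence[Transcript],
    abundances: Sequence[float],
    table: CodonTimeTable,
    C_candidates: Sequence[int],
    lam: float,
    subsample_fraction: float = 0.8,
    reps: int = 100,
    seed: int = 0,
) -> dict[int, int]:
    """Robustness of the inferred optimal site size under gene subsampling.

    Repeatedly subsample ``subsample_fraction`` of the genes, find the
    candidate site size maximizing the rank correlation between the
    predicted rates and abundance, and count how often each candidate
    wins.
    """
    abundances = np.asarray(abundances, dtype=float)
    if len(C_candidates) < 1 or reps < 1:
        raise ValueError("need >= 1 candidate site sizes and >= 1 repetition")
    if np.ptp(abundances) == 0:
        raise ValueError("abundances are constant; correlation undefined")
    C_candidates = list(C_candidates)
    # precompute rates per candidate C for all genes
    R = np.empty((len(C_candidates), len(transcripts)))
    for i, C in enumerate(C_candidates):
        for j, tr in enumerate(transcripts):
            R[i, j] = rfm_rate(tr, table, C, lam)
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample_fraction * len(transcripts))))
    counts = {C: 0 for C in C_candidates}
    for _ in range(reps):
        idx = rng.choice(len(transcripts), size=n_sub, replace=False)
        corrs = [
            stats.spearmanr(R[i, idx], abundances[idx]).statistic
            for i in range(len(C_candidates))
        ]
        counts[C_candidates[int(np.nanargmax(corrs))]] += 1
    return counts
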