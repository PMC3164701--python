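"""Baseline sequence predictors and ribosome-density profile tools.

These are the codon-content summaries the flow model is compared
against: the gene-level tRNA adaptation index (geometric mean of codon
coupling probabilities), the bottleneck (reciprocal time of the slowest
fixed-size codon window) and the mean per-codon speed.  All three depend
only on codon content, not order.

Profile utilities aggregate per-gene occupancy vectors into a genomic
mean density profile aligned at the 5' end, and compare competing
predicted profiles against an observed one with a paired Wilcoxon
signed-rank test on per-position distances.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .codon_rates import CodonTimeTable, Transcript

__all__ = [
    "gene_tai",
    "bottleneck",
    "mean_speed",
    "density_profile",
    "profile_distance_test",
]


def gene_tai(transcript: Transcript, table: CodonTimeTable) -> float:
    """Gene-level tAI: geometric mean of per-codon coupling probabilities."""
    codons = transcript.coding_codons()
    if not codons:
        raise ValueError(f"{transcript.gene_id}: empty transcript")
    logs = [np.log(table.p[c]) if c in table.p else None for c in codons]
    missing = [c for c, v in zip(codons, logs) if v is None]
    if missing:
        raise KeyError(f"codons missing from table: {sorted(set(missing))}")
    return float(np.exp(np.mean([v for v in logs if v is not None])))


def bottleneck(
    transcript: Transcript, table: CodonTimeTable, window: int = 15
) -> tuple[float, int, float]:
    """Slowest window of a gene, as a rate-like score.

    Returns ``(score, position, worst_time)`` where ``worst_time`` is the
    largest summed dwell time over any ``window`` consecutive codons,
    ``score = 1/worst_time`` (larger = faster, like the other
    predictors) and ``position`` is the 1-based codon index where the
    worst window starts.
    """
    codons = transcript.coding_codons()
    if len(codons) < window:
        raise ValueError(
            f"{transcript.gene_id}: length {len(codons)} < window {window}; "
            "use a smaller window"
        )
    taus = np.array([table.time_of(c) for c in codons])
    window_times = np.convolve(taus, np.ones(window), mode="valid")
    pos = int(np.argmax(window_times))
    worst = float(window_times[pos])
    return 1.0 / worst, pos + 1, worst


def mean_speed(transcript: Transcript, table: CodonTimeTable) -> float:
    """Arithmetic mean of per-codon translation rates ``1/tau``."""
    codons = transcript.coding_codons()
    if not codons:
        raise ValueError(f"{transcript.gene_id}: empty transcript")
    return float(np.mean([1.0 / table.time_of(c) for c in codons]))


def density_profile(
    occupancies: Sequence[np.ndarray],
    profile_site_size: int = 15,
    normalize_mean_to: float | None = None,
) -> np.ndarray:
    """Genomic mean ribosome-density profile, aligned at the 5' end.

    Each gene contributes its occupancy vector up to its own length;
    position-wise means are taken over the genes covering that position.
    ``profile_site_size`` is metadata describing the coarse-graining of
    the inputs (per-site occupancy vectors are averaged as given).  If
    ``normalize_mean_to`` is set, the profile is rescaled to that mean —
    competing profiles are compared shape-wise after equalizing means.
    """
    if len(occupancies) == 0:
        raise ValueError("no occupancy vectors given")
    max_len = max(len(o) for o in occupancies)
    total = np.zeros(max_len)
    count = np.zeros(max_len)
    for occ in occupancies:
        occ = np.asarray(occ, dtype=float)
        total[: len(occ)] += occ
        count[: len(occ)] += 1
    profile = total / count
    if normalize_mean_to is not None:
        profile = profile * (normalize_mean_to / profile.mean())
    return profile


def profile_distance_test(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    observed: np.ndarray,
) -> dict:
    """Which of two predicted profiles is closer to the observed one?

    Per-position absolute distances to the observed profile are computed
    for both predictions and compared with a two-sided paired Wilcoxon
    signed-rank test.  Returns the mean distances, the test statistic
    and p-value, and which profile is closer on average (``'A'``,
    ``'B'`` or ``'tie'``).
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if not (a.shape == b.shape == obs.shape):
        raise ValueError(
            f"profile lengths differ: {a.shape}, {b.shape}, {obs.shape}"
        )
    dist_a = np.abs(a - obs)
    dist_b = np.abs(b - obs)
    diffs = dist_a - dist_b
    if np.allclose(diffs, 0.0):
        statistic, pvalue = 0.0, 1.0
    else:
        res = stats.wilcoxon(dist_a, dist_b, alternative="two-sided")
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    mean_a, mean_b = float(dist_a.mean()), float(dist_b.mean())
    closer = "tie" if mean_a == mean_b else ("A" if mean_a < mean_b else "B")
    return {
        "mean_distance_a": mean_a,
        "mean_distance_b": mean_b,
        "statistic": statistic,
        "pvalue": pvalue,
        "closer": closer,
    }
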