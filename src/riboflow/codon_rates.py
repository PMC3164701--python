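"""Codon dwell times from tRNA adaptation.

Per-codon expected translation times are derived from the composition of
the cellular tRNA pool: a codon recognized by many abundant, well-paired
tRNAs is translated quickly, a codon served by rare or wobble-paired tRNAs
slowly.  The construction follows the tRNA adaptation index (tAI): each
codon gets an absolute adaptiveness ``W_i`` summing the gene copy numbers
of its recognizing tRNAs discounted by the wobble selective constraint
``S_ij``; normalizing by the best codon gives a tRNA-coupling probability
``p_i`` and an expected dwell time ``tau_i = 1/p_i`` (arbitrary time
units).

Coding sequences are then coarse-grained into consecutive sites of ``C``
codons; the transition rate of a site is the reciprocal of the summed
dwell times of its codons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

__all__ = [
    "STOP_CODONS",
    "TRNAEntry",
    "TRNAPool",
    "CodonTimeTable",
    "Transcript",
    "absolute_adaptiveness",
    "coupling_probabilities",
    "cga_sensitivity_fix",
    "build_time_table",
    "site_rates",
]


@dataclass(frozen=True)
class TRNAEntry:
    """One tRNA species recognizing a codon."""

    trna_id: str
    copy_number: int
    wobble_class: str

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError(
                f"negative copy number {self.copy_number} for tRNA {self.trna_id!r}"
            )


@dataclass
class TRNAPool:
    """Codon -> recognizing tRNAs, plus the wobble S-vector.

    ``entries`` maps each sense codon to the tRNA species able to decode
    it (gene copy number and codon:anticodon wobble pairing class).
    ``s_vector`` holds the selective constraint ``S in [0, 1]`` per wobble
    class; Watson-Crick pairings conventionally have ``S = 0``.
    """

    entries: dict[str, list[TRNAEntry]]
    s_vector: dict[str, float]

    def __post_init__(self) -> None:
        for codon, recs in self.entries.items():
            for rec in recs:
                if rec.wobble_class not in self.s_vector:
                    raise ValueError(
                        f"wobble class {rec.wobble_class!r} (codon {codon}) "
                        "has no S-vector entry"
                    )
        for cls, s in self.s_vector.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"S value for {cls!r} must lie in [0, 1], got {s}")

    @property
    def codons(self) -> list[str]:
        return list(self.entries)


@dataclass
class CodonTimeTable:
    """Per-codon adaptiveness, coupling probability and expected time.

    For pool-derived tables ``max(p) == 1`` and hence ``tau >= 1``; tables
    built from explicit times (:meth:`from_times`) keep the times as given.
    Stop codons carry no entry: termination is not a dwell step.
    """

    weights: dict[str, float]
    p: dict[str, float]
    tau: dict[str, float]

    @classmethod
    def from_times(cls, times: Mapping[str, float]) -> "CodonTimeTable":
        """Build a table directly from expected per-codon times."""
        bad = {c: t for c, t in times.items() if t <= 0}
        if bad:
            raise ValueError(f"non-positive codon times: {bad}")
        tau = dict(times)
        p = {c: 1.0 / t for c, t in tau.items()}
        return cls(weights=dict(p), p=p, tau=tau)

    def time_of(self, codon: str) -> float:
        try:
            return self.tau[codon]
        except KeyError:
            raise KeyError(f"codon {codon!r} not present in time table") from None


@dataclass(frozen=True)
class Transcript:
    """An in-frame coding sequence, stored as a codon list."""

    gene_id: str
    codons: tuple[str, ...]

    def __post_init__(self) -> None:
        for c in self.codons:
            if len(c) != 3:
                raise ValueError(f"codon {c!r} in {self.gene_id} is not a triplet")

    @classmethod
    def from_sequence(cls, gene_id: str, seq: str) -> "Transcript":
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise ValueError(
                f"{gene_id}: sequence length {len(seq)} not divisible by 3"
            )
        if set(seq) - set("ACGT"):
            raise ValueError(f"{gene_id}: non-ACGT characters in sequence")
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        return cls(gene_id, codons)

    def __len__(self) -> int:
        return len(self.codons)

    def coding_codons(self) -> tuple[str, ...]:
        """Codons with stop codons removed."""
        return tuple(c for c in self.codons if c not in STOP_CODONS)


def absolute_adaptiveness(codon: str, pool: TRNAPool) -> float:
    """Absolute adaptiveness ``W = sum_j (1 - S_ij) * tCGN_ij``.

    The sum runs over the tRNA species recognizing the codon, weighting
    each gene copy number by one minus the wobble selective constraint.
    A codon with no recognition gets ``W = 0`` (imputed downstream).
    """
    if codon not in pool.entries:
        raise KeyError(f"codon {codon!r} not present in the tRNA pool")
    w = 0.0
    for rec in pool.entries[codon]:
        w += (1.0 - pool.s_vector[rec.wobble_class]) * rec.copy_number
    return w


def cga_sensitivity_fix(
    pool: TRNAPool,
    weights: Mapping[str, float],
    codons: Iterable[str] = ("CGA",),
    perturbation: float = 0.5,
) -> dict[str, float]:
    """Stabilize S-sensitive codons by averaging over S perturbations.

    For each listed codon, its adaptiveness is replaced by the mean of
    ``W`` recomputed under every combination of +/-``perturbation`` applied
    to the S-vector entries affecting it, each perturbed S clamped to
    [0, 1].  The canonical target is CGA, whose adaptiveness (decoded
    almost exclusively through I:A wobble) is orders of magnitude more
    sensitive to the S-values than any other codon.
    """
    out = dict(weights)
    for codon in codons:
        if codon not in pool.entries:
            continue
        classes = sorted({rec.wobble_class for rec in pool.entries[codon]})
        if not classes:
            continue
        variants = []
        for deltas in itertools.product((-perturbation, +perturbation), repeat=len(classes)):
            s_pert = dict(pool.s_vector)
            for cls, d in zip(classes, deltas):
                s_pert[cls] = min(1.0, max(0.0, s_pert[cls] + d))
            w = 0.0
            for rec in pool.entries[codon]:
                w += (1.0 - s_pert[rec.wobble_class]) * rec.copy_number
            variants.append(w)
        out[codon] = float(np.mean(variants))
    return out


def coupling_probabilities(weights: Mapping[str, float]) -> CodonTimeTable:
    """Normalize adaptiveness to coupling probabilities and dwell times.

    ``p_i = W_i / max(W)`` so the best-adapted codon couples a tRNA with
    probability one; the expected dwell time is ``tau_i = 1/p_i``.
    Zero-weight codons (no recognizing tRNA) are imputed the smallest
    positive ``p`` so they remain finite-time; this is logged.
    """
    w_max = max(weights.values(), default=0.0)
    if w_max <= 0:
        raise ValueError("all codon weights are zero; cannot normalize")
    p = {c: w / w_max for c, w in weights.items() if w > 0}
    p_min = min(p.values())
    zero = [c for c, w in weights.items() if w <= 0]
    if zero:
        logger.warning(
            "codons with zero adaptiveness imputed minimal p=%g: %s", p_min, zero
        )
        for c in zero:
            p[c] = p_min
    tau = {c: 1.0 / v for c, v in p.items()}
    full_w = {c: float(weights[c]) for c in p}
    return CodonTimeTable(weights=full_w, p=p, tau=tau)


def build_time_table(
    pool: TRNAPool,
    cga_fix: bool = True,
    fix_codons: Iterable[str] = ("CGA",),
) -> CodonTimeTable:
    """Full pipeline: pool -> adaptiveness (-> CGA fix) -> time table."""
    weights = {c: absolute_adaptiveness(c, pool) for c in pool.codons}
    if cga_fix:
        weights = cga_sensitivity_fix(pool, weights, codons=fix_codons)
    return coupling_probabilities(weights)


def site_rates(
    transcript: Transcript, C: int, times: CodonTimeTable
) -> np.ndarray:
    """Coarse-grain a transcript into sites of ``C`` codons and rate them.

    Stop codons are removed first (termination is the last site's exit
    flow, not a dwell).  The codon list is partitioned into consecutive
    chunks of ``C`` codons, the last chunk possibly shorter; the rate of
    site ``i`` is the reciprocal of the summed codon times in chunk ``i``.
    """
    if C < 1:
        raise ValueError(f"site size C must be >= 1, got {C}")
    codons = transcript.coding_codons()
    if not codons:
        raise ValueError(f"{transcript.gene_id}: no coding codons after stop removal")
    taus = np.array([times.time_of(c) for c in codons], dtype=float)
    n = int(np.ceil(len(taus) / C))
    rates = np.empty(n)
    for i in range(n):
        rates[i] = 1.0 / taus[i * C : (i + 1) * C].sum()
    return rates
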