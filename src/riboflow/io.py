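"""Input readers, output writers and the synthetic fixture generator.

File dialects
-------------
* CDS input: FASTA, one record per gene, in-frame nucleotide sequence
  (lowercase and RNA accepted; normalized to uppercase DNA).  Records
  whose length is not a multiple of three or that contain non-ACGT
  characters are skipped with a logged reason.
* tRNA pool: TSV with columns ``codon``, ``trna_id``, ``copy_number``,
  ``wobble_class``; duplicate (codon, tRNA) rows have their copy numbers
  summed.  The wobble S-vector lives in a YAML/key-value config mapping
  each wobble class to its selective constraint in [0, 1].
* Outputs: TSV with 6 significant digits plus a JSON sidecar holding the
  full-precision parameters and seed; codon and site indices are 1-based.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .codon_rates import (
    CodonTimeTable,
    Transcript,
    TRNAEntry,
    TRNAPool,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_cds_fasta",
    "read_trna_table",
    "read_s_vector",
    "generate_fixture_transcripts",
    "write_table",
]

SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


def read_cds_fasta(path: str | Path) -> tuple[list[Transcript], int]:
    """Read in-frame coding sequences; returns (transcripts, n_skipped)."""
    path = Path(path)
    transcripts: list[Transcript] = []
    skipped = 0
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            transcripts.append(Transcript.from_sequence(record.id, str(record.seq)))
        except ValueError as exc:
            logger.warning("skipping record %s: %s", record.id, exc)
            skipped += 1
    if not transcripts:
        raise ValueError(f"no valid CDS records in {path}")
    return transcripts, skipped


def read_s_vector(path: str | Path) -> dict[str, float]:
    """Wobble class -> S value config (YAML mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"S-vector config {path} must be a mapping")
    return {str(k): float(v) for k, v in data.items()}


def read_trna_table(path: str | Path, s_vector_path: str | Path) -> TRNAPool:
    """Read the tRNA pool TSV and its S-vector config into a TRNAPool."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"codon", "trna_id", "copy_number", "wobble_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tRNA table {path} missing columns: {sorted(missing)}")
    df["copy_number"] = df["copy_number"].astype(int)
    if (df["copy_number"] < 0).any():
        bad = df.loc[df["copy_number"] < 0, "trna_id"].tolist()
        raise ValueError(f"negative copy numbers for tRNAs: {bad}")
    dup = df.duplicated(subset=["codon", "trna_id"], keep=False)
    if dup.any():
        logger.warning(
            "duplicate (codon, tRNA) rows summed: %s",
            df.loc[dup, ["codon", "trna_id"]].drop_duplicates().to_dict("records"),
        )
        df = (
            df.groupby(["codon", "trna_id", "wobble_class"], as_index=False)[
                "copy_number"
            ].sum()
        )
    s_vector = read_s_vector(s_vector_path)
    entries: dict[str, list[TRNAEntry]] = {}
    for row in df.itertuples(index=False):
        entries.setdefault(row.codon.upper(), []).append(
            TRNAEntry(row.trna_id, int(row.copy_number), row.wobble_class)
        )
    return TRNAPool(entries=entries, s_vector=s_vector)


def generate_fixture_transcripts(
    n_genes: int,
    length_codons: int,
    codon_alphabet_size: int = 61,
    tau_range: tuple[float, float] = (1.0, 10.0),
    seed: int = 0,
) -> tuple[list[Transcript], TRNAPool, CodonTimeTable]:
    """Synthetic transcripts with a matching synthetic tRNA pool.

    Per-codon expected times are drawn log-uniform over ``tau_range``
    for a ``codon_alphabet_size``-codon alphabet; a one-tRNA-per-codon
    pool with integer copy numbers proportional to ``1/tau`` realizes
    those times (to rounding).  Transcripts are i.i.d. uniform draws
    over the alphabet.  The returned time table carries the drawn times
    exactly, in the units they were drawn in.
    """
    if n_genes < 1 or length_codons < 1 or codon_alphabet_size < 1:
        raise ValueError("sizes must be positive")
    if codon_alphabet_size > len(SENSE_CODONS):
        raise ValueError(f"alphabet size capped at {len(SENSE_CODONS)} sense codons")
    lo, hi = tau_range
    if not 0 < lo <= hi:
        raise ValueError(f"invalid tau_range {tau_range}")
    rng = np.random.default_rng(seed)
    alphabet = list(SENSE_CODONS[:codon_alphabet_size])
    taus = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(alphabet)))
    # integer copy numbers ~ 1/tau at high resolution so the realized
    # dwell times match the drawn ones to rounding error
    scale = 10**6
    entries = {
        codon: [TRNAEntry(f"tRNA-{codon}", int(round(scale / t)), "WC")]
        for codon, t in zip(alphabet, taus)
    }
    pool = TRNAPool(entries=entries, s_vector={"WC": 0.0})
    table = CodonTimeTable.from_times(dict(zip(alphabet, taus)))
    transcripts = [
        Transcript(
            f"synth{g + 1:04d}",
            tuple(rng.choice(alphabet, size=length_codons)),
        )
        for g in range(n_genes)
    ]
    return transcripts, pool, table


def write_table(
    df: pd.DataFrame,
    out_path: str | Path,
    params: dict | None = None,
) -> None:
    """Write a TSV (6 significant digits) plus a JSON parameter sidecar."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    if params is not None:
        sidecar = out_path.with_suffix(out_path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(params, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
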