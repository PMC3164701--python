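import numpy as np
import pytest

from riboflow.codon_rates import CodonTimeTable, Transcript, TRNAEntry, TRNAPool


@pytest.fixture
def two_codon_table() -> CodonTimeTable:
    """Fast codon GCT (tau=1) and slow codon CCG (tau=2)."""
    return CodonTimeTable.from_times({"GCT": 1.0, "CCG": 2.0})


@pytest.fixture
def small_pool() -> TRNAPool:
    return TRNAPool(
        entries={
            "GCT": [TRNAEntry("tA1", 4, "WC")],
            "CCG": [TRNAEntry("tP1", 2, "WC")],
            "CGA": [TRNAEntry("tR1", 1, "I:A")],
        },
        s_vector={"WC": 0.0, "I:A": 0.9},
    )


@pytest.fixture
def random_instances():
    """Random flow-model instances: (lam, rates) with log-uniform rates."""
    rng = np.random.default_rng(12345)
    instances = []
    for _ in range(30):
        n = int(rng.integers(1, 41))
        rates = np.exp(rng.uniform(np.log(1e-2), np.log(1e2), size=n))
        lam = float(np.exp(rng.uniform(np.log(1e-2), np.log(1e2))))
        instances.append((lam, rates))
    return instances


def make_transcript(codons, gene_id="g"):
    return Transcript(gene_id, tuple(codons))


@pytest.fixture
def heterogeneous_transcript(two_codon_table) -> Transcript:
    rng = np.random.default_rng(3)
    codons = rng.choice(["GCT", "CCG"], size=30, p=[0.5, 0.5])
    return Transcript("het", tuple(codons))
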