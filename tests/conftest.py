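import numpy as np
import pytest

from popdiv import SimParams, alignment_from_sequences, simulate_dataset


@pytest.fixture(scope="session")
def panmictic_loci():
    """500 panmictic loci at the study's design point (n=14/11, θ=5, L=1200)."""
    return simulate_dataset(SimParams(tau=0.0, n_loci=500, seed=20260101))


@pytest.fixture()
def two_pop_toy():
    """Fixed difference between populations, no within variation."""
    return alignment_from_sequences(
        ["AAAA", "AAAA", "TAAA", "TAAA"],
        populations=["GA", "GA", "MA", "MA"],
    )


def random_alignment(rng: np.random.Generator, n=None, length=None,
                     labeled=True):
    """Small random alignment over {A,C,G,T,N,-} for oracle comparisons."""
    n = n or int(rng.integers(3, 9))
    length = length or int(rng.integers(4, 30))
    alphabet = np.array(list("ACGT"))
    seqs = ["".join(rng.choice(alphabet, size=length)) for _ in range(n)]
    if rng.random() < 0.5:  # sprinkle missing data
        seqs = [
            "".join(
                c if rng.random() > 0.08 else rng.choice(["N", "-"])
                for c in s
            )
            for s in seqs
        ]
    pops = None
    if labeled:
        n1 = int(rng.integers(1, n))
        pops = ["P1"] * n1 + ["P2"] * (n - n1)
    return alignment_from_sequences(seqs, populations=pops)
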