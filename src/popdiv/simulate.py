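"""Two-deme split-model coalescent simulator over haploid sequences.

The generator produces labeled FASTA loci with the statistical structure the
analysis assumes. Backwards in time, lineages within each deme coalesce at
rate C(k,2); at the split time ``tau`` the two demes merge into a single
ancestral pool (equal deme sizes, no migration after the split) and
coalescence continues to the MRCA. Time is in coalescent units of 2N
generations per deme. Mutations are dropped on the genealogy under the
infinite-sites model restricted to ``L`` columns: the count is
Poisson(theta/2 × total branch length) with ``theta`` the per-locus (not
per-site) population mutation rate, and each mutation lands on its own
uniformly chosen column. Ancestral bases are uniform over {A,C,G,T} and the
derived base is uniform over the three alternatives.

``tau = 0`` is the panmictic null: the labels then carry no information and
the expected S_nn is about one half. Defaults (n1=14, n2=11, L=1200,
theta=5) mirror the study design the package reproduces: 14 Georgia and 11
Massachusetts haplotypes per locus with loci around 1.2 kb.

Seed contract: locus ``i`` of a dataset is generated from
``numpy.random.default_rng((seed, i))``, so a dataset is byte-identical for
a given seed and loci are independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignio import LabeledAlignment, write_alignment, write_popmap

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    n1: int = 14
    n2: int = 11
    L: int = 1200
    theta: float = 5.0
    tau: float = 0.0
    n_loci: int = 1
    seed: int = 0
    missing_fraction: float = 0.0
    #: sample indices the missingness is applied to; None means every sample
    missing_samples: tuple[int, ...] | None = None
    pop_names: tuple[str, str] = ("GA", "MA")

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.L < 1:
            raise ValueError("locus length must be >= 1")
        if self.theta < 0 or self.tau < 0:
            raise ValueError("theta and tau must be non-negative")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")


@dataclass(frozen=True)
class Genealogy:
    """Branches as (descendant leaf set, length) plus summary quantities."""

    n_leaves: int
    branches: tuple[tuple[frozenset, float], ...]
    tmrca: float
    total_length: float
    #: time of the first coalescence joining lineages from the two demes
    first_cross_time: float


@dataclass(frozen=True)
class SimulatedLocus:
    alignment: LabeledAlignment
    true_params: SimParams
    tmrca: float
    total_branch_length: float
    n_mutations: int


def simulate_genealogy(
    params: SimParams, rng: np.random.Generator
) -> Genealogy:
    """One realization of the two-deme structured coalescent."""
    n = params.n1 + params.n2
    # lineage: (leaf set, birth time); demes hold indices into `lineages`
    lineages: list[tuple[frozenset, float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    demes: list[list[int]] = [list(range(params.n1)),
                              list(range(params.n1, n))]
    merged = params.tau == 0
    if merged:
        demes = [demes[0] + demes[1]]
    t = 0.0
    branches: list[tuple[frozenset, float]] = []
    deme0_leaves = frozenset(range(params.n1))
    first_cross = [np.inf]

    def coalesce(deme: list[int], time: float) -> None:
        i, j = rng.choice(len(deme), size=2, replace=False)
        a, b = deme[i], deme[j]
        la, lb = lineages[a], lineages[b]
        branches.append((la[0], time - la[1]))
        branches.append((lb[0], time - lb[1]))
        joined = la[0] | lb[0]
        if joined & deme0_leaves and joined - deme0_leaves:
            first_cross[0] = min(first_cross[0], time)
        lineages.append((joined, time))
        new = len(lineages) - 1
        deme[max(i, j)] = new
        del deme[min(i, j)]

    while sum(len(d) for d in demes) > 1:
        rates = [len(d) * (len(d) - 1) / 2.0 for d in demes]
        total = sum(rates)
        if total == 0:
            # one lineage per deme: nothing can happen before the merge
            t = params.tau
        else:
            t += rng.exponential(1.0 / total)
        if not merged and t >= params.tau:
            t = max(t, params.tau) if total == 0 else params.tau
            demes = [demes[0] + demes[1]]
            merged = True
            continue
        if total == 0:
            continue
        u = rng.uniform(0, total)
        which = 0 if u < rates[0] or len(demes) == 1 else 1
        coalesce(demes[which], t)

    return Genealogy(
        n_leaves=n,
        branches=tuple(branches),
        tmrca=t,
        total_length=sum(length for _, length in branches),
        first_cross_time=float(first_cross[0]),
    )


def drop_mutations(
    genealogy: Genealogy,
    theta: float,
    L: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Infinite-sites mutations on distinct columns; returns (n, L) array.

    The array holds base codes 0..3; the caller renders it to letters.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    n_mut = int(rng.poisson(theta / 2.0 * genealogy.total_length))
    if n_mut > L:
        raise ValueError("locus length too short for theta")
    anc = rng.integers(0, 4, size=L)
    arr = np.tile(anc, (genealogy.n_leaves, 1))
    if n_mut > 0:
        cols = rng.choice(L, size=n_mut, replace=False)
        lengths = np.array([b[1] for b in genealogy.branches])
        probs = lengths / lengths.sum()
        branch_idx = rng.choice(len(lengths), size=n_mut, p=probs)
        for col, bi in zip(cols, branch_idx):
            leaves = sorted(genealogy.branches[bi][0])
            derived = (anc[col] + rng.integers(1, 4)) % 4
            arr[leaves, col] = derived
    return arr, n_mut


def _render_alignment(
    codes: np.ndarray, params: SimParams, locus_id: str,
    rng: np.random.Generator,
) -> LabeledAlignment:
    arr = _BASE_CODES[codes]
    n = params.n1 + params.n2
    if params.missing_fraction > 0:
        targets = (range(n) if params.missing_samples is None
                   else params.missing_samples)
        n_mask = int(round(params.missing_fraction * params.L))
        for i in targets:
            cols = rng.choice(params.L, size=n_mask, replace=False)
            arr[i, cols] = ord("N")
    p1, p2 = params.pop_names
    ids = ([f"{p1}{i + 1:02d}" for i in range(params.n1)]
           + [f"{p2}{i + 1:02d}" for i in range(params.n2)])
    pops = (p1,) * params.n1 + (p2,) * params.n2
    return LabeledAlignment(
        locus_id=locus_id, sample_ids=tuple(ids),
        populations=pops, seq_array=arr,
    )


def simulate_locus(params: SimParams, locus_index: int = 0) -> SimulatedLocus:
    """One labeled locus; deterministic in (params.seed, locus_index)."""
    rng = np.random.default_rng((params.seed, locus_index))
    gen = simulate_genealogy(params, rng)
    codes, n_mut = drop_mutations(gen, params.theta, params.L, rng)
    aln = _render_alignment(codes, params, f"locus_{locus_index:04d}", rng)
    return SimulatedLocus(
        alignment=aln, true_params=params, tmrca=gen.tmrca,
        total_branch_length=gen.total_length, n_mutations=n_mut,
    )


def simulate_dataset(
    params: SimParams, out_dir: str | Path | None = None
) -> list[SimulatedLocus]:
    """Generate ``params.n_loci`` independent loci; optionally write files.

    With ``out_dir`` set, writes one FASTA per locus, a shared
    ``popmap.tsv``, and ``truth.tsv`` with per-locus genealogy summaries.
    """
    loci = [simulate_locus(params, i) for i in range(params.n_loci)]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for loc in loci:
            write_alignment(loc.alignment, out / f"{loc.alignment.locus_id}.fa")
        aln0 = loci[0].alignment
        write_popmap(
            {sid: pop for sid, pop in zip(aln0.sample_ids, aln0.populations)},
            out / "popmap.tsv",
        )
        with open(out / "truth.tsv", "w", encoding="utf-8") as fh:
            fh.write("locus_id\ttheta\ttau\ttmrca\ttotal_branch_length\tn_mutations\n")
            for loc in loci:
                fh.write(
                    f"{loc.alignment.locus_id}\t{params.theta}\t{params.tau}\t"
                    f"{loc.tmrca:.6f}\t{loc.total_branch_length:.6f}\t"
                    f"{loc.n_mutations}\n"
                )
    return loci
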