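"""Two-population divergence: D_xy, Nei's net divergence d_A, Hudson F_ST
and Hudson's nearest-neighbor statistic S_nn.

S_nn measures how often each sequence's most similar sequences come from its
own population: for sequence j the tie set T_j holds every other sequence at
the minimum distance to j, X_j is the fraction of T_j sharing j's label, and
S_nn is the mean of the X_j. It is 0.5 in expectation for two equally sized
panmictic groups and 1 under complete separation. Ties are handled by the
fractional tie-set rule, so the statistic is deterministic.

F_ST here is the Hudson–Slatkin–Maddison sequence version 1 − H_w/H_b with
H_w the unweighted mean of the two within-population π values and H_b = D_xy.
Negative F_ST and d_A are legal sampling outcomes and are never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignio import LabeledAlignment, SiteMask
from .diversity import (
    mean_pairwise_differences,
    mean_pairwise_per_site,
    nucleotide_diversity,
    pairwise_difference_counts,
)


@dataclass(frozen=True)
class NearestNeighborDetail:
    """Per-sequence nearest-neighbor fractions X_j and tie-set sizes."""

    x: np.ndarray
    tie_set_size: np.ndarray


@dataclass(frozen=True)
class DivergenceStats:
    n1: int
    n2: int
    sites: int
    pi1: float
    pi2: float
    dxy: float
    da: float
    hw: float
    hb: float
    fst: float | None
    snn: float


def _two_pop_indices(aln: LabeledAlignment) -> tuple[str, str, np.ndarray, np.ndarray]:
    pops = aln.population_set()
    if len(pops) != 2:
        raise ValueError("two populations required")
    p1, p2 = pops
    return p1, p2, aln.population_indices(p1), aln.population_indices(p2)


def _cross_pair_mean(ndiff: np.ndarray, nshared: np.ndarray,
                     idx1: np.ndarray, idx2: np.ndarray,
                     mode: str, sites: int) -> float:
    block_d = ndiff[np.ix_(idx1, idx2)]
    if mode == "complete":
        return float(block_d.mean()) / sites
    block_s = nshared[np.ix_(idx1, idx2)]
    if np.any(block_s == 0):
        raise ValueError("a sequence pair shares no analyzable sites")
    return float((block_d / block_s).mean())


def dxy(aln: LabeledAlignment, mask: SiteMask) -> float:
    """Mean per-site difference over all between-population pairs."""
    _, _, i1, i2 = _two_pop_indices(aln)
    if len(i1) < 1 or len(i2) < 1:
        raise ValueError("two populations required")
    if mask.n_sites == 0:
        raise ValueError("no analyzable sites")
    ndiff, nshared = pairwise_difference_counts(aln, mask)
    return _cross_pair_mean(ndiff, nshared, i1, i2, mask.deletion_mode, mask.n_sites)


def net_divergence(aln: LabeledAlignment, mask: SiteMask) -> float:
    """Nei's d_A = D_xy − (π1 + π2)/2; negative values are reported as-is."""
    _, _, i1, i2 = _two_pop_indices(aln)
    if len(i1) < 2 or len(i2) < 2:
        raise ValueError("within-population diversity undefined")
    pi1 = nucleotide_diversity(aln, mask, i1)
    pi2 = nucleotide_diversity(aln, mask, i2)
    return dxy(aln, mask) - (pi1 + pi2) / 2.0


def hudson_fst(aln: LabeledAlignment, mask: SiteMask) -> float | None:
    """1 − H_w/H_b; ``None`` when H_b = 0 (no between-population differences)."""
    _, _, i1, i2 = _two_pop_indices(aln)
    if len(i1) < 2 or len(i2) < 2:
        raise ValueError("within-population diversity undefined")
    hw = (nucleotide_diversity(aln, mask, i1)
          + nucleotide_diversity(aln, mask, i2)) / 2.0
    hb = dxy(aln, mask)
    if hb == 0:
        return None
    return 1.0 - hw / hb


def distance_matrix(aln: LabeledAlignment, mask: SiteMask) -> np.ndarray:
    """Pairwise distances used by S_nn.

    Complete deletion: integer mismatch counts over kept columns (exact tie
    detection). Pairwise deletion: per-pair per-site mismatch fractions.
    """
    ndiff, nshared = pairwise_difference_counts(aln, mask)
    if mask.deletion_mode == "complete":
        return ndiff.astype(float)
    if np.any((nshared == 0) & ~np.eye(len(nshared), dtype=bool)):
        raise ValueError("a sequence pair shares no analyzable sites")
    with np.errstate(invalid="ignore"):
        d = ndiff / nshared
    np.fill_diagonal(d, 0.0)
    return d


def snn_from_distances(
    dist: np.ndarray, labels: np.ndarray
) -> tuple[float, NearestNeighborDetail]:
    """S_nn from a precomputed distance matrix and label vector.

    Factored out so permutation testing can relabel without recomputing
    distances (labels never change pairwise distances).
    """
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    dmin = d.min(axis=1)
    ties = d == dmin[:, None]
    same = labels[:, None] == labels[None, :]
    tie_sizes = ties.sum(axis=1)
    x = (ties & same).sum(axis=1) / tie_sizes
    return float(x.mean()), NearestNeighborDetail(x=x, tie_set_size=tie_sizes)


def snn(
    aln: LabeledAlignment, mask: SiteMask
) -> tuple[float, NearestNeighborDetail]:
    """Hudson's nearest-neighbor statistic with per-sequence detail.

    Works for any number of populations ≥ 1 present in the labels.
    """
    if aln.n < 2:
        raise ValueError("need at least two sequences")
    labels = np.array([p if p is not None else "" for p in aln.populations])
    return snn_from_distances(distance_matrix(aln, mask), labels)


def divergence_stats(aln: LabeledAlignment, mask: SiteMask) -> DivergenceStats:
    """Full two-population battery; components share one pass over pairs."""
    p1, p2, i1, i2 = _two_pop_indices(aln)
    if len(i1) < 2 or len(i2) < 2:
        raise ValueError("within-population diversity undefined")
    if mask.n_sites == 0:
        raise ValueError("no analyzable sites")
    ndiff, nshared = pairwise_difference_counts(aln, mask)
    if mask.deletion_mode == "complete":
        pi1 = mean_pairwise_differences(ndiff, i1) / mask.n_sites
        pi2 = mean_pairwise_differences(ndiff, i2) / mask.n_sites
    else:
        pi1 = mean_pairwise_per_site(ndiff, nshared, i1)
        pi2 = mean_pairwise_per_site(ndiff, nshared, i2)
    dxy_val = _cross_pair_mean(ndiff, nshared, i1, i2,
                               mask.deletion_mode, mask.n_sites)
    hw = (pi1 + pi2) / 2.0
    hb = dxy_val
    fst = None if hb == 0 else 1.0 - hw / hb
    snn_val, _ = snn(aln, mask)
    return DivergenceStats(
        n1=len(i1), n2=len(i2), sites=mask.n_sites,
        pi1=pi1, pi2=pi2, dxy=dxy_val, da=dxy_val - hw,
        hw=hw, hb=hb, fst=fst, snn=snn_val,
    )
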