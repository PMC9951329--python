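"""Within-sample diversity: S, π per site, Watterson's θ, Tajima's D.

All statistics operate on a :class:`~popdiv.alignio.LabeledAlignment`
restricted to the columns of a :class:`~popdiv.alignio.SiteMask`. Under
complete deletion every retained column is fully observed, so a pairwise
difference is simply a base mismatch; under pairwise deletion each sequence
pair is compared over its own shared non-missing columns and per-site values
are averaged per pair (which keeps π ≤ 1 for every pair).

Tajima's D follows the standard variance-normalized difference between the
pairwise (π) and segregating-site (θ_W) estimators of the population
mutation rate; it is undefined (``None``) when S = 0, matching the practice
of omitting invariant loci rather than reporting 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignio import LabeledAlignment, SiteMask, _missing_matrix


# ---------------------------------------------------------------------------
# pairwise difference machinery (shared with the divergence module)
# ---------------------------------------------------------------------------

def pairwise_difference_counts(
    aln: LabeledAlignment, mask: SiteMask
) -> tuple[np.ndarray, np.ndarray]:
    """(n, n) matrices of pairwise mismatch counts and shared-site counts.

    Only non-missing bases in both members of a pair are compared. Under
    complete deletion the shared-site count is the mask size for every pair.
    """
    arr = aln.seq_array[:, mask.kept_columns]
    n = arr.shape[0]
    miss = _missing_matrix(arr)
    if mask.deletion_mode == "complete":
        ndiff = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        nshared = np.full((n, n), arr.shape[1], dtype=int)
    else:
        ok = ~miss
        shared = ok[:, None, :] & ok[None, :, :]
        ndiff = ((arr[:, None, :] != arr[None, :, :]) & shared).sum(axis=2)
        nshared = shared.sum(axis=2)
    np.fill_diagonal(ndiff, 0)
    return ndiff, nshared


def _upper_pairs(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(len(idx), k=1)
    return idx[i], idx[j]


def mean_pairwise_differences(
    ndiff: np.ndarray, idx: np.ndarray
) -> float:
    """Mean raw mismatch count over unordered pairs within ``idx`` (Π)."""
    if len(idx) < 2:
        raise ValueError("need at least two sequences")
    a, b = _upper_pairs(np.asarray(idx))
    return float(ndiff[a, b].mean())


def mean_pairwise_per_site(
    ndiff: np.ndarray, nshared: np.ndarray, idx: np.ndarray
) -> float:
    """Mean of per-pair per-site difference fractions within ``idx``."""
    a, b = _upper_pairs(np.asarray(idx))
    shared = nshared[a, b]
    if np.any(shared == 0):
        raise ValueError("a sequence pair shares no analyzable sites")
    return float((ndiff[a, b] / shared).mean())


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityStats:
    n: int
    sites: int
    S: int
    pi_per_site: float
    theta_w_per_site: float
    tajimas_d: float | None
    constants: dict


def tajima_constants(n: int) -> dict:
    """The a1..e2 coefficients of Tajima's variance normalization."""
    if n < 2:
        raise ValueError("need at least two sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _masked_array(aln: LabeledAlignment, mask: SiteMask,
                  subset: Sequence[int] | None) -> np.ndarray:
    arr = aln.seq_array
    if subset is not None:
        arr = arr[np.asarray(subset, dtype=int)]
    return arr[:, mask.kept_columns]


def segregating_sites(
    aln: LabeledAlignment, mask: SiteMask, subset: Sequence[int] | None = None
) -> int:
    """Count of kept columns with at least two distinct non-missing bases."""
    arr = _masked_array(aln, mask, subset)
    if arr.shape[0] < 2:
        raise ValueError("need at least two sequences")
    miss = _missing_matrix(arr)
    count = 0
    for col in range(arr.shape[1]):
        bases = arr[~miss[:, col], col]
        if bases.size >= 2 and len(np.unique(bases)) >= 2:
            count += 1
    return count


def nucleotide_diversity(
    aln: LabeledAlignment, mask: SiteMask, subset: Sequence[int] | None = None
) -> float:
    """π per site: mean pairwise differences divided by analyzed sites."""
    idx = np.arange(aln.n) if subset is None else np.asarray(subset, dtype=int)
    if len(idx) < 2:
        raise ValueError("need at least two sequences")
    if mask.n_sites == 0:
        raise ValueError("no analyzable sites")
    ndiff, nshared = pairwise_difference_counts(aln, mask)
    if mask.deletion_mode == "complete":
        return mean_pairwise_differences(ndiff, idx) / mask.n_sites
    return mean_pairwise_per_site(ndiff, nshared, idx)


def wattersons_theta(
    aln: LabeledAlignment, mask: SiteMask, subset: Sequence[int] | None = None
) -> float:
    """θ_W per site = S / (a1 · sites)."""
    idx = np.arange(aln.n) if subset is None else np.asarray(subset, dtype=int)
    if mask.n_sites == 0:
        raise ValueError("no analyzable sites")
    s = segregating_sites(aln, mask, subset)
    a1 = tajima_constants(len(idx))["a1"]
    return s / (a1 * mask.n_sites)


def tajimas_d(
    aln: LabeledAlignment, mask: SiteMask, subset: Sequence[int] | None = None
) -> float | None:
    """Tajima's D; ``None`` when there are no segregating sites.

    D = (Π − S/a1) / sqrt(e1·S + e2·S·(S−1)) with Π the total (not
    per-site) mean pairwise difference count.
    """
    idx = np.arange(aln.n) if subset is None else np.asarray(subset, dtype=int)
    if len(idx) < 2:
        raise ValueError("need at least two sequences")
    s = segregating_sites(aln, mask, subset)
    if s == 0:
        return None
    ndiff, _ = pairwise_difference_counts(aln, mask)
    pi_total = mean_pairwise_differences(ndiff, idx)
    k = tajima_constants(len(idx))
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        # degenerate at n=2, where c1 = c2 = 0 and the numerator also
        # vanishes (Π = S, a1 = 1): report undefined rather than 0/0
        return None
    return (pi_total - s / k["a1"]) / math.sqrt(var)


def diversity_stats(
    aln: LabeledAlignment, mask: SiteMask, subset: Sequence[int] | None = None
) -> DiversityStats:
    """The full within-sample battery on one (sub)sample."""
    idx = np.arange(aln.n) if subset is None else np.asarray(subset, dtype=int)
    s = segregating_sites(aln, mask, subset)
    return DiversityStats(
        n=len(idx),
        sites=mask.n_sites,
        S=s,
        pi_per_site=nucleotide_diversity(aln, mask, subset),
        theta_w_per_site=wattersons_theta(aln, mask, subset),
        tajimas_d=tajimas_d(aln, mask, subset),
        constants=tajima_constants(len(idx)),
    )
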