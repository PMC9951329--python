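"""Nei–Gojobori codon-level divergence (Ka/Ks, equivalently dN/dS).

The method decomposes each sense codon into fractional synonymous and
nonsynonymous sites (per position, the fraction of the three possible
single-base changes that preserve the amino acid; changes creating a stop
count as nonsynonymous). Differences between a codon pair are classified by
averaging over all single-step mutational pathways between the codons,
excluding pathways that pass through a stop codon; if every pathway is
blocked, stop-crossing pathways are admitted as a fallback. Proportions are
corrected for multiple hits with the Jukes–Cantor transform
d = −(3/4)·ln(1 − 4p/3).

Counts are averaged across the selected pair set first and the transform
applied to the averages (the original counting order); a per-pair-then-
average mode is exposed for sensitivity checks. A locus where no synonymous
difference is observed gets ``ratio=None`` with the ``ks_zero`` flag instead
of an infinite ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

from .alignio import LabeledAlignment

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon → amino acid (one-letter), stops mapped to '*'
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
GENETIC_CODE.update({c: "*" for c in _STANDARD.stop_codons})

_BASES = "ACGT"


def _aa(codon: str, code: dict[str, str]) -> str:
    return code[codon]


@dataclass(frozen=True)
class CodonDivergence:
    syn_sites: float
    nonsyn_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: float
    dn: float
    ratio: float | None
    ks_zero: bool
    n_codons: int
    n_pairs: int = 1
    #: a proportion reached the JC singularity (p >= 3/4); the affected
    #: distance is NaN and the ratio undefined, but counts stay valid
    saturated: bool = False


def ng_site_counts(
    codon: str, code: dict[str, str] | None = None
) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    The two always sum to 3 for a sense codon.
    """
    code = GENETIC_CODE if code is None else code
    codon = codon.upper()
    if any(b not in _BASES for b in codon) or len(codon) != 3:
        raise ValueError(f"ambiguous or malformed codon: {codon}")
    aa = _aa(codon, code)
    if aa == "*":
        raise ValueError("stop codon has no site decomposition")
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            # mutations to stop codons count as nonsynonymous
            if _aa(mutant, code) == aa:
                n_syn += 1
        syn += n_syn / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over mutational pathways.

    Pathways through stop codons are excluded; if all pathways are blocked
    the average falls back to including them (stop-crossing steps counted
    nonsynonymous).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            aa_from, aa_to = _aa(cur, GENETIC_CODE), _aa(nxt, GENETIC_CODE)
            if aa_to == "*" and nxt != c2:
                through_stop = True
            if aa_from == aa_to:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd, through_stop

    paths = [walk(order) for order in permutations(diff_pos)]
    valid = [(s, n) for s, n, blocked in paths if not blocked]
    if not valid:  # fallback: average over everything
        valid = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def _jc(p: float) -> float:
    """Jukes–Cantor correction; NaN past the singularity at p = 3/4
    ("distance saturated, JC correction undefined")."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _divergence_from_counts(
    syn_sites: float, nonsyn_sites: float, sd: float, nd: float,
    n_codons: int, n_pairs: int,
) -> CodonDivergence:
    if syn_sites + nonsyn_sites <= 0:
        raise ValueError("no valid codons")
    # zero sites of one class forces zero differences of that class
    ps = sd / syn_sites if syn_sites > 0 else 0.0
    pn = nd / nonsyn_sites if nonsyn_sites > 0 else 0.0
    ds, dn = _jc(ps), _jc(pn)
    saturated = math.isnan(ds) or math.isnan(dn)
    ks_zero = sd == 0
    ratio = None if (saturated or ds == 0) else dn / ds
    return CodonDivergence(
        syn_sites=syn_sites, nonsyn_sites=nonsyn_sites, sd=sd, nd=nd,
        ps=ps, pn=pn, ds=ds, dn=dn, ratio=ratio, ks_zero=ks_zero,
        n_codons=n_codons, n_pairs=n_pairs, saturated=saturated,
    )


def _codon_ok(codon: str) -> bool:
    return all(b in _BASES for b in codon)


def _pair_counts(seq1: str, seq2: str) -> tuple[float, float, float, float, int]:
    """Raw (syn_sites, nonsyn_sites, Sd, Nd, codons used) for one pair.

    Codons with missing/ambiguous bases in either sequence, or that are stop
    codons in either sequence, are skipped for this pair only.
    """
    syn_sites = nonsyn_sites = sd = nd = 0.0
    used = 0
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k:k + 3], seq2[k:k + 3]
        if len(c1) < 3 or not (_codon_ok(c1) and _codon_ok(c2)):
            continue
        if _aa(c1, GENETIC_CODE) == "*" or _aa(c2, GENETIC_CODE) == "*":
            continue
        s1, n1 = ng_site_counts(c1)
        s2, n2 = ng_site_counts(c2)
        syn_sites += (s1 + s2) / 2.0
        nonsyn_sites += (n1 + n2) / 2.0
        psd, pnd = _pathway_counts(c1, c2)
        sd += psd
        nd += pnd
        used += 1
    return syn_sites, nonsyn_sites, sd, nd, used


def _in_frame(seq: str, frame: int, revcomp: bool) -> str:
    if revcomp:
        comp = str.maketrans("ACGTN-", "TGCAN-")
        seq = seq.translate(comp)[::-1]
    seq = seq[frame:]
    return seq[: len(seq) - len(seq) % 3]


def ng_pairwise(
    seq1: str, seq2: str, frame: int = 0, revcomp: bool = False
) -> CodonDivergence:
    """Nei–Gojobori divergence between two in-frame coding sequences."""
    if len(seq1) != len(seq2):
        raise ValueError("unequal sequence lengths")
    if (len(seq1) - frame) % 3 != 0:
        raise ValueError("sequence length (after frame offset) not divisible by 3")
    s1 = _in_frame(seq1.upper(), frame, revcomp)
    s2 = _in_frame(seq2.upper(), frame, revcomp)
    syn_sites, nonsyn_sites, sd, nd, used = _pair_counts(s1, s2)
    if used == 0:
        raise ValueError("no valid codons")
    return _divergence_from_counts(syn_sites, nonsyn_sites, sd, nd, used, 1)


def kaks_locus(
    aln: LabeledAlignment,
    mode: str = "between_pops",
    frame: int = 0,
    revcomp: bool = False,
    per_pair: bool = False,
) -> CodonDivergence:
    """Locus-level Ka/Ks averaged over a pair set.

    ``mode='between_pops'`` uses every cross-population pair (two labeled
    populations required); ``mode='all_pairs'`` uses every unordered pair.
    Default averaging pools the raw site and difference counts over the
    pair set before forming proportions; ``per_pair=True`` instead averages
    per-pair dN and dS and reports their ratio.
    """
    if mode not in ("between_pops", "all_pairs"):
        raise ValueError(f"unknown mode: {mode}")
    seqs = aln.sequences
    if mode == "between_pops":
        pops = aln.population_set()
        if len(pops) != 2:
            raise ValueError("two populations required")
        i1 = aln.population_indices(pops[0])
        i2 = aln.population_indices(pops[1])
        pairs = [(a, b) for a in i1 for b in i2]
    else:
        pairs = [(a, b) for a in range(aln.n) for b in range(a + 1, aln.n)]
    if not pairs:
        raise ValueError("no valid pairs")

    if per_pair:
        ds_vals, dn_vals = [], []
        tot_sd = 0.0
        codons = 0
        for a, b in pairs:
            cd = ng_pairwise(seqs[a], seqs[b], frame=frame, revcomp=revcomp)
            ds_vals.append(cd.ds)
            dn_vals.append(cd.dn)
            tot_sd += cd.sd
            codons = max(codons, cd.n_codons)
        ds = sum(ds_vals) / len(ds_vals)
        dn = sum(dn_vals) / len(dn_vals)
        saturated = math.isnan(ds) or math.isnan(dn)
        ks_zero = tot_sd == 0
        return CodonDivergence(
            syn_sites=float("nan"), nonsyn_sites=float("nan"),
            sd=float("nan"), nd=float("nan"), ps=float("nan"), pn=float("nan"),
            ds=ds, dn=dn, ratio=None if (saturated or ds == 0) else dn / ds,
            ks_zero=ks_zero, n_codons=codons, n_pairs=len(pairs),
            saturated=saturated,
        )

    syn_sites = nonsyn_sites = sd = nd = 0.0
    codons = 0
    valid_pairs = 0
    for a, b in pairs:
        s1 = _in_frame(seqs[a], frame, revcomp)
        s2 = _in_frame(seqs[b], frame, revcomp)
        if len(s1) == 0:
            raise ValueError("no complete codons in frame")
        ss, ns, psd, pnd, used = _pair_counts(s1, s2)
        if used == 0:
            continue
        syn_sites += ss
        nonsyn_sites += ns
        sd += psd
        nd += pnd
        codons = max(codons, used)
        valid_pairs += 1
    if valid_pairs == 0:
        raise ValueError("no valid pairs")
    # averaging the counts over pairs; constant factor cancels in p = d/sites
    return _divergence_from_counts(
        syn_sites / valid_pairs, nonsyn_sites / valid_pairs,
        sd / valid_pairs, nd / valid_pairs, codons, valid_pairs,
    )
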