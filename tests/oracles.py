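"""Independent brute-force re-implementations used only as test oracles.

Everything here is written with explicit pair loops and no shared code with
the package internals, so agreement is an actual cross-check.
"""

from __future__ import annotations

import math
from itertools import permutations

MISSING = {"-", "N"}


def kept_columns_complete(seqs: list[str]) -> list[int]:
    return [
        c for c in range(len(seqs[0]))
        if all(s[c] not in MISSING for s in seqs)
    ]


def pair_diff(s1: str, s2: str, cols) -> tuple[int, int]:
    """(mismatches, shared sites) over the given columns, pairwise deletion."""
    nd = ns = 0
    for c in cols:
        a, b = s1[c], s2[c]
        if a in MISSING or b in MISSING:
            continue
        ns += 1
        if a != b:
            nd += 1
    return nd, ns


def snn_brute(
    seqs: list[str], labels: list[str], mode: str = "complete"
) -> tuple[float, list[float]]:
    """Hudson's S_nn by explicit O(n^2 L) loops with fractional tie sets.

    Returns the statistic and the per-sequence fractions X_j.
    """
    n = len(seqs)
    cols = (kept_columns_complete(seqs) if mode == "complete"
            else list(range(len(seqs[0]))))
    dist = {}
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            nd, ns = pair_diff(seqs[j], seqs[k], cols)
            dist[(j, k)] = nd if mode == "complete" else nd / ns
    xs = []
    for j in range(n):
        dmin = min(dist[(j, k)] for k in range(n) if k != j)
        tie = [k for k in range(n) if k != j and dist[(j, k)] == dmin]
        same = sum(1 for k in tie if labels[k] == labels[j])
        xs.append(same / len(tie))
    return sum(xs) / n, xs


def pi_brute(seqs: list[str]) -> float:
    """π per site, complete deletion, explicit pair loop."""
    cols = kept_columns_complete(seqs)
    n = len(seqs)
    tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += pair_diff(seqs[i], seqs[j], cols)[0]
    return tot / (n * (n - 1) / 2) / len(cols)


def tajimas_d_direct(seqs: list[str]) -> float | None:
    """Tajima's D transcribed directly from the 1989 formulas."""
    cols = kept_columns_complete(seqs)
    n = len(seqs)
    s = sum(1 for c in cols if len({seq[c] for seq in seqs}) > 1)
    if s == 0:
        return None
    npairs = n * (n - 1) / 2
    k_hat = sum(
        pair_diff(seqs[i], seqs[j], cols)[0]
        for i in range(n) for j in range(i + 1, n)
    ) / npairs
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


# --- Nei–Gojobori enumeration oracle ---------------------------------------

def _code():
    from Bio.Data import CodonTable
    t = CodonTable.unambiguous_dna_by_id[1]
    code = dict(t.forward_table)
    code.update({c: "*" for c in t.stop_codons})
    return code


_CODE = _code()


def ng_pair_oracle(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair by exhaustive pathway enumeration."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODE[nxt] == "*" and nxt != c2:
                ok = False
            if _CODE[nxt] == _CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, ok))
    usable = [(s, n) for s, n, ok in results if ok]
    if not usable:
        usable = [(s, n) for s, n, _ in results]
    return (sum(s for s, _ in usable) / len(usable),
            sum(n for _, n in usable) / len(usable))


def ng_sites_oracle(codon: str) -> float:
    """Synonymous site count by direct mutation enumeration."""
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if _CODE[mut] == _CODE[codon]:
                syn += 1 / 3
    return syn
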