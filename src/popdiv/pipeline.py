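"""Multi-locus orchestration: per-locus statistic tables, distribution
summaries, and the top-5% d_A ∩ S_nn outlier-selection rule.

Every input locus produces exactly one table row. Loci failing the curation
gates (missingness filter, then the ≥15 total / ≥5 per population rule) stay
in the table as flagged rows with NA statistics so sample bookkeeping stays
auditable; undefined statistics are carried as NA markers, never dropped.
Tajima's D in the main column is computed on the pooled two-population
sample; per-population D is reported alongside.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import alignio, codon, divergence, diversity, resample

TABLE_COLUMNS = [
    "locus_id", "n1", "n2", "sites", "S",
    "pi_pop1", "pi_pop2", "pi_pooled",
    "tajd_pooled", "tajd_pop1", "tajd_pop2",
    "dxy", "da", "fst", "snn", "snn_p", "kaks", "flags",
]


@dataclass(frozen=True)
class BatteryOptions:
    deletion_mode: str = "complete"
    max_missing_fraction: float = 0.20
    min_total: int = 15
    min_per_pop: int = 5
    snn_permutations: int = 1000
    seed: int = 0
    compute_kaks: bool = False
    kaks_mode: str = "between_pops"
    frame: int = 0


@dataclass(frozen=True)
class OutlierReport:
    top_da: frozenset
    top_snn: frozenset
    intersection: frozenset
    q: float
    da_threshold: float
    snn_threshold: float


def _locus_row(
    aln: alignio.LabeledAlignment, options: BatteryOptions
) -> dict:
    row: dict = {c: np.nan for c in TABLE_COLUMNS}
    row["locus_id"] = aln.locus_id
    flags: list[str] = []
    try:
        aln, dropped = alignio.filter_missingness(
            aln, options.max_missing_fraction
        )
    except ValueError:
        row["flags"] = "all_samples_dropped"
        return row
    if dropped:
        flags.append(f"dropped:{len(dropped)}")
    ok, reason = alignio.check_eligibility(
        aln, options.min_total, options.min_per_pop
    )
    counts = aln.population_counts()
    pops = aln.population_set()
    if len(pops) == 2:
        row["n1"] = counts.get(pops[0], 0)
        row["n2"] = counts.get(pops[1], 0)
    if not ok:
        flags.append(f"ineligible:{reason}")
        row["flags"] = ";".join(flags)
        return row

    mask = alignio.build_site_mask(aln, options.deletion_mode)
    i1 = aln.population_indices(pops[0])
    i2 = aln.population_indices(pops[1])
    if mask.n_sites == 0:
        flags.append("no_analyzable_sites")
        row["flags"] = ";".join(flags)
        return row

    row["sites"] = mask.n_sites
    row["S"] = diversity.segregating_sites(aln, mask)
    row["pi_pop1"] = diversity.nucleotide_diversity(aln, mask, i1)
    row["pi_pop2"] = diversity.nucleotide_diversity(aln, mask, i2)
    row["pi_pooled"] = diversity.nucleotide_diversity(aln, mask)
    for col, subset in (
        ("tajd_pooled", None), ("tajd_pop1", i1), ("tajd_pop2", i2)
    ):
        d = diversity.tajimas_d(aln, mask, subset)
        row[col] = np.nan if d is None else d
        if d is None:
            flags.append(f"{col}_undefined")

    dstats = divergence.divergence_stats(aln, mask)
    row["dxy"] = dstats.dxy
    row["da"] = dstats.da
    row["fst"] = np.nan if dstats.fst is None else dstats.fst
    if dstats.fst is None:
        flags.append("fst_undefined")
    row["snn"] = dstats.snn
    perm = resample.permutation_test(
        aln, "snn", B=options.snn_permutations,
        seed=options.seed, mask=mask,
    )
    row["snn_p"] = perm.p_value

    if options.compute_kaks:
        try:
            cd = codon.kaks_locus(aln, mode=options.kaks_mode,
                                  frame=options.frame)
            if cd.ks_zero:
                flags.append("ks_zero")
            row["kaks"] = np.nan if cd.ratio is None else cd.ratio
        except ValueError as exc:
            flags.append(f"kaks_failed:{exc}")
    row["flags"] = ";".join(flags) if flags else ""
    return row


def run_locus_battery(
    fasta_paths: Sequence[str | Path],
    popmap: Mapping[str, str],
    options: BatteryOptions | None = None,
) -> pd.DataFrame:
    """Curation gates plus the full statistic battery per locus."""
    options = options or BatteryOptions()
    rows = []
    for path in fasta_paths:
        aln = alignio.read_alignment(path)
        aln = alignio.assign_populations(aln, popmap)
        rows.append(_locus_row(aln, options))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if len(table) and table["snn"].notna().sum() == 0:
        print("[popdiv] warning: zero eligible loci", file=sys.stderr)
    return table


def battery_from_alignments(
    alignments: Sequence[alignio.LabeledAlignment],
    options: BatteryOptions | None = None,
) -> pd.DataFrame:
    """Same battery over already-labeled in-memory alignments."""
    options = options or BatteryOptions()
    return pd.DataFrame(
        [_locus_row(aln, options) for aln in alignments],
        columns=TABLE_COLUMNS,
    )


_SUMMARY_COLUMNS = [
    "pi_pop1", "pi_pop2", "pi_pooled", "tajd_pooled",
    "tajd_pop1", "tajd_pop2", "dxy", "da", "fst", "snn",
]


def summarize_distributions(table: pd.DataFrame) -> dict:
    """Per-column mean/min/max/count plus the two K-S population contrasts."""
    summary: dict = {}
    for col in _SUMMARY_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce").dropna()
        if len(vals) == 0:
            summary[col] = {"defined": 0, "all_undefined": True}
        else:
            summary[col] = {
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "defined": int(len(vals)),
            }
    for name, a, b in (
        ("ks_pi", "pi_pop1", "pi_pop2"),
        ("ks_tajd", "tajd_pop1", "tajd_pop2"),
    ):
        x = pd.to_numeric(table[a], errors="coerce").dropna().to_numpy()
        y = pd.to_numeric(table[b], errors="coerce").dropna().to_numpy()
        if len(x) and len(y):
            summary[name] = {
                "D": resample.ks_two_sample(x, y),
                "p_asymptotic": resample.ks_two_sample_pvalue(x, y),
            }
        else:
            summary[name] = {"all_undefined": True}
    return summary


def _top_quantile(values: pd.Series, q: float) -> tuple[frozenset, float]:
    """Loci in the upper q-quantile of defined values, ties included.

    The threshold is the k-th largest defined value with k = ceil(q·N); every
    locus ≥ the threshold is kept, so ties may enlarge the set.
    """
    defined = values.dropna()
    k = max(1, math.ceil(q * len(defined)))
    threshold = float(defined.sort_values(ascending=False).iloc[k - 1])
    keep = defined[defined >= threshold]
    return frozenset(keep.index), threshold


def select_outliers(table: pd.DataFrame, q: float = 0.05) -> OutlierReport:
    """Top-q loci for d_A and S_nn and their intersection (rank-based)."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    indexed = table.set_index("locus_id")
    da = pd.to_numeric(indexed["da"], errors="coerce")
    snn = pd.to_numeric(indexed["snn"], errors="coerce")
    minimum = math.ceil(1.0 / q)
    n_defined = int((da.notna() & snn.notna()).sum())
    if n_defined < minimum:
        raise ValueError(
            f"need at least {minimum} loci with defined da and snn "
            f"(have {n_defined})"
        )
    top_da, thr_da = _top_quantile(da, q)
    top_snn, thr_snn = _top_quantile(snn, q)
    return OutlierReport(
        top_da=top_da, top_snn=top_snn,
        intersection=frozenset(top_da & top_snn),
        q=q, da_threshold=thr_da, snn_threshold=thr_snn,
    )


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """TSV with undefined values serialized as NA (byte-stable)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA",
                 float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
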