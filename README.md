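# popdiv

Per-locus diversity and divergence statistics for two-population collections
of aligned haploid sequences (e.g. per-individual transcript haplotypes or
Sanger haplotypes from two geographic samples), with permutation-based
significance, codon-level Ka/Ks, distribution contrasts, an outlier-locus
selection rule, and a two-deme coalescent simulator for calibration.

It is aimed at population geneticists asking a simple question of a panel of
locus alignments: *which loci are divergent between two population samples,
and is that divergence more than label noise?*

## Statistics

For an alignment of n sequences over the analyzed sites (complete deletion
by default: columns containing `-`/`N` are excluded):

- **S** — segregating sites; **π** — mean pairwise differences per site;
  **θ_W = S/a₁** per site, a₁ = Σ_{i<n} 1/i.
- **Tajima's D** = (Π − S/a₁) / √(e₁S + e₂S(S−1)), Π the total mean pairwise
  difference count; undefined when S = 0 and at n ≤ 3, where the variance
  coefficients vanish exactly.
- **D_xy** — mean per-site differences over all between-population pairs;
  **d_A = D_xy − (π₁+π₂)/2** (Nei's net divergence; may be negative in
  samples and is reported as-is).
- **F_ST** (Hudson–Slatkin–Maddison) = 1 − H_w/H_b with H_w = (π₁+π₂)/2 and
  H_b = D_xy; undefined when H_b = 0.
- **S_nn** (Hudson 2000) — for each sequence j, the fraction of its
  minimum-distance tie set that shares j's population label, averaged over
  sequences. ≈ 0.5 under panmixia for two groups, 1 under complete
  separation. Ties are handled fractionally, so the value is deterministic.
- **Ka/Ks** — Nei–Gojobori codon counting: fractional synonymous /
  nonsynonymous sites, differences averaged over mutational pathways
  (stop-crossing pathways excluded), Jukes–Cantor correction, ratio dN/dS.
  A locus with no synonymous differences is flagged `ks_zero` instead of
  reporting an infinite ratio.

Significance of a divergence statistic is a one-sided permutation test:
population labels are reshuffled without replacement (group sizes
preserved), the statistic recomputed B times (default 1000), and
p = (1 + #{null ≥ observed}) / (B + 1); the raw percentile rule
(observed > 95th percentile of the null) is reported alongside.

Curation gates mirror common practice for transcript panels: samples missing
more than 20% of the alignment are dropped, and a locus is analyzed only
with ≥ 15 sequences and ≥ 5 per population.

## Worked example

Simulate six diverged loci (split time τ = 2 coalescent units, per-locus
θ = 5) and run the battery:

```sh
popdiv sim --n-loci 6 --tau 2.0 --theta 5 --seed 7 --out-dir loci
popdiv battery --fasta-dir loci --popmap loci/popmap.tsv \
    --nperm 1000 --seed 1 --out table.tsv
popdiv stats --fasta loci/locus_0000.fa --popmap loci/popmap.tsv
```

The per-locus statistics for the first locus print as:

```
locus_id    pop      n   sites  S   pi          theta_w     tajD
locus_0000  pooled   25  1200   23  0.00487222  0.00507597  -0.147
locus_0000  GA       14  1200   11  0.00203297  0.00288248  -1.16159
locus_0000  MA       11  1200   9   0.00239394  0.00256063  -0.27357
locus_0000  between  25  1200   -   dxy=0.00743506;da=0.00522161;fst=0.702295;snn=1
```

Reading this: within-population diversity is low (π ≈ 0.002 per site in
each sample) while between-population divergence is not (D_xy ≈ 0.0074,
d_A ≈ 0.0052 per site after netting out within-sample diversity), F_ST ≈ 0.70
says ~70% of the pairwise diversity lies between the groups, and S_nn = 1
means every sequence's nearest neighbors are from its own population —
complete lineage sorting, as expected two coalescent units after a split.
In `table.tsv` the same locus carries `snn_p = 0.000999…` (= 1/1001): none
of 1000 label permutations reached the observed S_nn.

`popdiv outliers --table table.tsv --q 0.05` reports the loci in the top 5%
of both d_A and S_nn; `popdiv summarize --table table.tsv` prints per-column
means/extremes and the two-population Kolmogorov–Smirnov contrasts of the π
and Tajima's D distributions.

## Archived data

Two end-to-end checks in `tests/test_acceptance.py` reproduce published
values from archived datasets and need a one-time download:

- `data/coi/coi_alignment.fasta` + `data/coi/popmap.tsv` — the mitochondrial
  COI Sanger haplotypes (NCBI accessions OL893108–OL893127), aligned, with
  GA/MA labels. Expected: S_nn = 0.7563, Hudson F_ST = 0.229.
- `data/curated/{amylase,lysin}.fasta` + matching `*_popmap.tsv` — the
  curated trimmed alignments archived at doi:10.6084/m9.figshare.20813707.
  Expected: amylase S_nn = 0.947, d_A = 0.01522, Ka/Ks = 0.136, pooled
  Tajima's D = 1.852; lysin S_nn = 0.78947.

Without these files the two tests fail with a message describing the
download; everything else runs offline.
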