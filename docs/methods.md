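# Methods

## Unit of analysis and conventions

A locus is an equal-length multi-FASTA alignment of haploid sequences over
{A,C,G,T,N,-}, case-insensitive (normalized to upper case on read), with
population labels attached from a two-column TSV. Sequences are treated as
haplotypes throughout; if they are assembled per-individual transcripts they
are "synthetic haplotypes" that do not represent within-individual
heterozygosity, and nothing here corrects for that — distribution-level
results on such data should be read with that caveat.

Both `-` and `N` count as missing everywhere: for the per-sample missingness
rule, and for site masking. The default deletion convention is **complete
(listwise) deletion** — a column containing any missing character in any
retained sequence is excluded before any statistic — which is what the
"analyzed bases" counts of standard desktop tools reflect. **Pairwise
deletion** is available behind a flag: every column is kept and each
sequence pair is compared over its own shared non-missing columns, with π
then the mean of per-pair per-site values (keeping each pair's value ≤ 1).
Coordinates are 0-based half-open internally; every user-facing number is a
length or a per-site value, so there is no off-by-one surface.

Curation gates (in order): samples missing strictly more than
`max_missing_fraction` (default 0.20) of the columns are dropped — a sample
at exactly the threshold is kept; then a locus is eligible only with at
least `min_total` (15) sequences and at least `min_per_pop` (5) per
population, the per-population condition reported first when both fail.
Ineligible loci stay in the output table as flagged rows with NA statistics
so that sample bookkeeping remains auditable.

## Diversity and divergence statistics

π, S and θ_W are the standard Nei–Li / Watterson estimators computed on the
masked columns. Multi-allelic columns count once toward S; a pairwise
difference is any base mismatch regardless of allele count.

Tajima's D uses Π, the *total* mean pairwise difference count (not
per-site), and the usual a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ coefficients. Two
degenerate regimes are reported as undefined (`None`, serialized NA) rather
than zero or ±∞: S = 0, and n ≤ 3 — at n = 2 and n = 3 the variance
coefficients c₁ and c₂ vanish *exactly*, so D is 0/0 (tskit returns NaN/−inf
in the same situations; we prefer an explicit undefined marker). In the
multi-locus table, the headline D column is computed on the pooled
two-population sample — the regime in which extreme values flag loci where
the combined sample carries intermediate-frequency variants — with
per-population D in adjacent columns. Under pairwise deletion D uses raw
per-pair mismatch counts over the all-columns mask; the complete-deletion
default is the convention the reproduced tables use.

D_xy is the mean per-site difference over all n₁·n₂ cross-population pairs;
d_A = D_xy − (π₁+π₂)/2 (the identity d_A + (π₁+π₂)/2 = D_xy holds to
machine precision and is property-tested). F_ST is fixed to the
Hudson–Slatkin–Maddison sequence form 1 − H_w/H_b with H_w the *unweighted*
mean of the two within-population π values and H_b = D_xy; undefined when
H_b = 0. Negative d_A and F_ST are legitimate sampling outcomes and are
never clamped.

S_nn uses, under complete deletion, integer mismatch counts as distances, so
tie detection is exact; under pairwise deletion, per-pair per-site
fractions. Self-distances are excluded; duplicated haplotypes enter tie sets
naturally at distance 0 (no haplotype collapsing). Ties at the minimum are
resolved by the fractional tie-set rule, making the statistic deterministic;
with k > 2 labels the definition generalizes unchanged (F_ST and d_A remain
pairwise-only). For an all-identical alignment with group sizes n₁, n₂ every
sequence ties with all others and
S_nn = (n₁(n₁−1) + n₂(n₂−1)) / ((n−1)·n), the analytic reference used in
tests.

## Nei–Gojobori Ka/Ks

Standard genetic code (code table injectable). Per sense codon, each
position contributes the fraction of its three single-base changes that are
synonymous (changes to stops count nonsynonymous); synonymous + nonsynonymous
sites sum to 3 exactly. Codon pairs differing at k positions average their
difference counts over all k! single-step pathways, excluding pathways that
pass through a stop codon; if all pathways are blocked the average falls
back to including them. Codons with missing data, or that are stop codons,
in either member of a pair are skipped for that pair only (pairwise, not
listwise, maximizing usable codons in ragged transcript alignments).

Locus-level values average the raw site and difference counts over the pair
set (all pairs, or between-population pairs) *before* forming proportions
and applying the Jukes–Cantor transform d = −(3/4)ln(1 − 4p/3) — the
original counting order; a per-pair-then-average mode is exposed for
sensitivity checks. Reading frame defaults to 0 with `--frame 0/1/2` and a
reverse-complement flag, since archived alignments rarely state frame;
trailing partial codons are trimmed. Two non-fatal flags replace infinities:
`ks_zero` (no synonymous differences → ratio undefined) and `saturated`
(p ≥ 3/4, past the JC singularity → the affected distance is NaN, counts
remain valid). The saturation flag, rather than an exception, is what lets
single-codon examples return their pathway-averaged counts.

## Permutation significance

The null reassigns population labels to sequences uniformly at random
without replacement, preserving group sizes — the standard null for S_nn;
"resampling each population" phrasing in the field is ambiguous between this
and a bootstrap, so a bootstrap mode (labels drawn with replacement from the
observed pool) exists behind a flag for sensitivity analysis only. Labels
never change pairwise distances, so the distance/count matrices are computed
once per locus and each replicate only regroups pairs; a dedicated test
verifies the fast path equals recomputing the statistic on an explicitly
relabeled alignment.

p = (1 + #{null ≥ observed}) / (B + 1), one-sided (greater), never zero;
`significant_at_95` separately applies the raw rule "observed strictly
greater than the 95th percentile of the null draws", so tables that print
p = 0 under the raw rule remain interpretable. Replicate i draws from
`numpy.random.default_rng((seed, i))` — a documented counter scheme giving
bit-identical, order-independent, platform-stable results. Pooled Tajima's D
is label-invariant, so its permutation p-value is 1 by construction; the
option exists for interface completeness.

The two-sample Kolmogorov–Smirnov statistic (used for between-population
contrasts of per-locus π and D distributions) is the exact sup-difference of
the two ECDFs, delegated to `scipy.stats.ks_2samp`; only D is first-class,
with the asymptotic p-value available and labeled as an approximation.

## Multi-locus table and outlier rule

One row per input locus with stable columns (counts, per-population and
pooled diversity, divergence, S_nn with its permutation p, optional Ka/Ks,
flags); NA marks undefined values. Output TSV is byte-stable for identical
inputs and seed. The outlier rule takes the upper q-quantile (default
q = 0.05) of the *defined* values of d_A and of S_nn — the threshold is the
⌈qN⌉-th largest value and ties at the threshold are included, so a locus
equal to the cutoff is never silently excluded — and reports both top sets
and their intersection. The rule is rank-based: invariant to row order and
to monotone rescaling of either statistic.

## The simulator

A calibration instrument, not a demographic inference: two demes of equal
size with no migration after a split at time τ (coalescent units of 2N
generations per deme), chosen as the minimal model spanning the panmictic
null (τ = 0) and clean divergence. Within a deme, k lineages coalesce at
rate C(k,2); at τ the demes merge and coalescence continues to the MRCA.
Mutations follow infinite-sites restricted to L columns: count ~
Poisson(θ/2 × total branch length) with θ the *per-locus* (not per-site)
population mutation rate, each mutation on its own uniformly chosen column
(error if mutations exceed L), ancestral base uniform, derived base uniform
over the three alternatives. Keeping infinite sites (no recurrent mutation)
makes the analytic expectations exact — E[S] = θ·a₁ under panmixia,
E[d_A] = θτ/L under the split — which the tests use for calibration.

Defaults are the design point of a two-population transcript survey: n₁ = 14,
n₂ = 11, L = 1200 (typical transcript-alignment length), θ = 5 per locus
(giving π per site of a few × 10⁻³, matching the observed order of
magnitude), τ = 0. Optional missingness masks an exact fraction of bases to
N in designated samples, used to exercise the curation filter. Locus i of a
dataset draws from `numpy.random.default_rng((seed, i))`, so datasets are
byte-identical under a seed and loci are order-independent.

What the simulator does **not** emulate: recombination, selection, diploid
genotypes, migration after the split, unequal deme sizes, length variation
across loci, alignment error, and the synthetic-haplotype distortions of
assembled transcripts. Tests passing on simulated data therefore validate
the statistics and their null calibration, not the upstream assembly and
alignment pipeline of any real dataset.

## Problem sizes in tests

Calibration tests use 500 panmictic loci (mean S_nn within 0.5 ± 0.03; type-I
error of the percentile rule with B = 200 in [0.02, 0.09]; Tajima's D mean
in [−0.35, 0.1], the small negative bias being expected under neutrality),
200 loci per τ for the monotonicity of S_nn and d_A over
τ ∈ {0, 0.5, 1, 2, 4}, 100 msprime/tskit loci for the independent-oracle
agreement at 1e−8, and 50 random small instances each for exact agreement
with in-repo brute-force S_nn and codon-pathway enumerators. The whole suite
runs in well under a minute on one CPU.

## Known limitations

- No multiple-testing correction across loci (by design; the permutation p
  values are per-locus).
- K-S p-values are asymptotic approximations when reported at all.
- Ka/Ks is the counting method: no ML codon models, no codon-usage or
  transition/transversion corrections.
- Tajima's D under pairwise deletion mixes per-pair site sets; prefer
  complete deletion when comparing against desktop-tool output.
- The 20% missingness rule is applied to the alignment as given; any
  upstream end-trimming changes what "20%" refers to.
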