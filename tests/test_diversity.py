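import numpy as np
import pytest

from popdiv import (
    SimParams,
    alignment_from_sequences,
    build_site_mask,
    diversity_stats,
    nucleotide_diversity,
    segregating_sites,
    simulate_dataset,
    tajima_constants,
    tajimas_d,
    wattersons_theta,
)
from conftest import random_alignment
from oracles import pi_brute, tajimas_d_direct


def _mask(aln, mode="complete"):
    return build_site_mask(aln, mode)


class TestSegregatingSites:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["ACGT", "ACGA", "ACGT"], 1),
            (["AC-T", "ACGT"], 0),  # the variant-bearing column is masked
            (["ACGT", "ACGT", "ACGT"], 0),
        ],
    )
    def test_examples(self, seqs, expected):
        aln = alignment_from_sequences(seqs)
        assert segregating_sites(aln, _mask(aln)) == expected

    def test_single_sequence_rejected(self):
        aln = alignment_from_sequences(["ACGT"])
        with pytest.raises(ValueError, match="at least two"):
            segregating_sites(aln, _mask(aln))

    def test_multiallelic_site_counts_once(self):
        aln = alignment_from_sequences(["A", "C", "G"])
        assert segregating_sites(aln, _mask(aln)) == 1


class TestNucleotideDiversity:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["ACGT", "ACGA"], 0.25),
            (["AAA", "AAT", "AAT"], 2 / 9),
            (["ACGT", "ACGT"], 0.0),
        ],
    )
    def test_examples(self, seqs, expected):
        aln = alignment_from_sequences(seqs)
        assert nucleotide_diversity(aln, _mask(aln)) == pytest.approx(expected)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            aln = random_alignment(rng, labeled=False)
            mask = _mask(aln)
            if mask.n_sites == 0:
                continue
            assert nucleotide_diversity(aln, mask) == pytest.approx(
                pi_brute(list(aln.sequences)), abs=1e-12
            )

    def test_invariant_under_reordering_and_base_relabeling(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            aln = random_alignment(rng, labeled=False)
            mask = _mask(aln)
            if mask.n_sites == 0:
                continue
            pi = nucleotide_diversity(aln, mask)
            theta = wattersons_theta(aln, mask)
            perm = rng.permutation(aln.n)
            shuffled = aln.subset(perm)
            m2 = _mask(shuffled)
            assert nucleotide_diversity(shuffled, m2) == pytest.approx(pi)
            assert wattersons_theta(shuffled, m2) == pytest.approx(theta)
            # permute the alphabet A<->T, C<->G
            table = str.maketrans("ACGT", "TGCA")
            relabeled = alignment_from_sequences(
                [s.translate(table) for s in aln.sequences]
            )
            m3 = _mask(relabeled)
            assert nucleotide_diversity(relabeled, m3) == pytest.approx(pi)

    def test_pairwise_deletion_keeps_pair_pi_bounded(self):
        aln = alignment_from_sequences(["AC-T", "TGGA", "TG-A"])
        pi = nucleotide_diversity(aln, _mask(aln, "pairwise"))
        assert 0 <= pi <= 1


class TestWattersonsTheta:
    def test_examples(self):
        aln = alignment_from_sequences(["ACGT", "ACGA"])
        assert wattersons_theta(aln, _mask(aln)) == pytest.approx(0.25)
        aln3 = alignment_from_sequences(["AAAAAAAAAT", "AAAAAAAATT", "AAAAAAAAAA"])
        # n=3, S=2, 10 sites, a1 = 1.5
        assert wattersons_theta(aln3, _mask(aln3)) == pytest.approx(2 / 15)

    def test_zero_when_invariant(self):
        aln = alignment_from_sequences(["ACGT"] * 4)
        assert wattersons_theta(aln, _mask(aln)) == 0.0


class TestTajimasD:
    def test_undefined_when_no_variation(self):
        aln = alignment_from_sequences(["ACGT"] * 5)
        assert tajimas_d(aln, _mask(aln)) is None

    def test_n2_degenerate(self):
        # for n=2, Π = S and a1 = 1 so the numerator vanishes, and the
        # variance constants c1 = c2 = 0: D is 0/0 and reported undefined
        aln = alignment_from_sequences(["ACGTACGT", "ACGAACGA"])
        from popdiv import nucleotide_diversity, segregating_sites

        mask = _mask(aln)
        s = segregating_sites(aln, mask)
        assert nucleotide_diversity(aln, mask) * mask.n_sites == pytest.approx(s)
        assert tajimas_d(aln, mask) is None

    def test_matches_independent_transcription(self):
        # fixed 6-sequence, 500-site alignment with a deterministic
        # genotype pattern; compared against a second, independently
        # written transcription of the published formula
        rng = np.random.default_rng(99)
        base = "".join(rng.choice(list("ACGT"), size=500))
        seqs = []
        for i in range(6):
            s = list(base)
            for col in rng.choice(500, size=12, replace=False):
                s[col] = "T" if s[col] != "T" else "A"
            seqs.append("".join(s))
        aln = alignment_from_sequences(seqs)
        mine = tajimas_d(aln, _mask(aln))
        oracle = tajimas_d_direct(list(aln.sequences))
        assert mine == pytest.approx(oracle, abs=1e-12)

    def test_constants_positive(self):
        # strictly positive from n=4 up; at n=2 and n=3 the variance
        # coefficients c1, c2 (hence e1, e2) vanish exactly, so D is the
        # degenerate 0/0 there and reported undefined
        for n in range(4, 40):
            assert all(v > 0 for v in tajima_constants(n).values())
        for n in (2, 3):
            k = tajima_constants(n)
            assert k["a1"] > 0 and k["b1"] > 0
            assert k["c1"] == pytest.approx(0, abs=1e-15)
            assert k["c2"] == pytest.approx(0, abs=1e-15)

    def test_n3_degenerate_is_undefined(self):
        aln = alignment_from_sequences(["ACGT", "ACGA", "ATGT"])
        assert tajimas_d(aln, _mask(aln)) is None

    def test_panmictic_mean_near_zero(self, panmictic_loci):
        """Neutral panmictic loci: mean D mildly negative, distribution
        brackets zero."""
        ds = []
        for loc in panmictic_loci:
            mask = build_site_mask(loc.alignment, "complete")
            d = tajimas_d(loc.alignment, mask)
            if d is not None:
                ds.append(d)
        ds = np.array(ds)
        assert len(ds) > 400
        assert -0.35 <= ds.mean() <= 0.1
        assert ds.min() < 0 < ds.max()


class TestDiversityStats:
    def test_bundle_consistency(self):
        aln = alignment_from_sequences(
            ["ACGTAC", "ACGAAC", "ATGTAC", "ACGTAT"]
        )
        mask = _mask(aln)
        st = diversity_stats(aln, mask)
        assert st.S == segregating_sites(aln, mask)
        assert st.pi_per_site == nucleotide_diversity(aln, mask)
        assert st.theta_w_per_site == wattersons_theta(aln, mask)
        assert st.tajimas_d == tajimas_d(aln, mask)
        assert st.n == 4 and st.sites == 6
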