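import numpy as np
import pytest

from popdiv import (
    alignment_from_sequences,
    build_site_mask,
    divergence_stats,
    dxy,
    hudson_fst,
    net_divergence,
    nucleotide_diversity,
    snn,
)
from conftest import random_alignment
from oracles import snn_brute


def _labeled(seqs, pops):
    return alignment_from_sequences(seqs, populations=pops)


def _mask(aln, mode="complete"):
    return build_site_mask(aln, mode)


class TestDxy:
    def test_fixed_difference(self):
        aln = _labeled(["AAAA", "AAAA", "TAAA", "TAAA"], ["X", "X", "Y", "Y"])
        assert dxy(aln, _mask(aln)) == pytest.approx(0.25)

    def test_identical_composition(self):
        aln = _labeled(["AAAA", "AAAT", "AAAA", "AAAT"], ["X", "X", "Y", "Y"])
        assert dxy(aln, _mask(aln)) == pytest.approx(0.125)

    def test_identical_single_sequences(self):
        aln = _labeled(["ACGT", "ACGT"], ["X", "Y"])
        assert dxy(aln, _mask(aln)) == 0.0

    def test_one_population_rejected(self):
        aln = _labeled(["ACGT", "ACGT"], ["X", "X"])
        with pytest.raises(ValueError, match="two populations"):
            dxy(aln, _mask(aln))


class TestNetDivergence:
    def test_fixed_difference_equals_dxy(self, two_pop_toy):
        assert net_divergence(two_pop_toy, _mask(two_pop_toy)) == pytest.approx(0.25)

    def test_negative_values_are_legal(self):
        aln = _labeled(["AAAA", "AAAT", "AAAA", "AAAT"], ["X", "X", "Y", "Y"])
        assert net_divergence(aln, _mask(aln)) == pytest.approx(-0.125)

    def test_small_population_rejected(self):
        aln = _labeled(["AAAA", "AAAT", "AAAA"], ["X", "X", "Y"])
        with pytest.raises(ValueError, match="within-population diversity"):
            net_divergence(aln, _mask(aln))

    def test_conservation_identity(self):
        # da + (pi1 + pi2)/2 = dxy exactly
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 25:
            aln = random_alignment(rng, n=8)
            if min(len(aln.population_indices(p))
                   for p in aln.population_set()) < 2:
                continue
            mask = _mask(aln)
            if mask.n_sites == 0:
                continue
            i1 = aln.population_indices("P1")
            i2 = aln.population_indices("P2")
            pi1 = nucleotide_diversity(aln, mask, i1)
            pi2 = nucleotide_diversity(aln, mask, i2)
            da = net_divergence(aln, mask)
            assert da + (pi1 + pi2) / 2 == pytest.approx(
                dxy(aln, mask), abs=1e-15
            )
            checked += 1


class TestHudsonFst:
    def test_fixed_difference_gives_one(self, two_pop_toy):
        assert hudson_fst(two_pop_toy, _mask(two_pop_toy)) == pytest.approx(1.0)

    def test_negative_fst_reported(self):
        aln = _labeled(["AAAA", "AAAT", "AAAA", "AAAT"], ["X", "X", "Y", "Y"])
        assert hudson_fst(aln, _mask(aln)) == pytest.approx(-1.0)

    def test_undefined_when_no_between_differences(self):
        aln = _labeled(["AAAA"] * 4, ["X", "X", "Y", "Y"])
        assert hudson_fst(aln, _mask(aln)) is None


class TestSnn:
    def test_fully_diverged_gives_one(self):
        aln = _labeled(
            ["AAAA", "AAAA", "TTTT", "TTTT"], ["X", "X", "Y", "Y"]
        )
        value, detail = snn(aln, _mask(aln))
        assert value == 1.0
        assert np.all(detail.x == 1.0)

    def test_all_identical_tie_formula(self):
        aln = _labeled(["ACGT"] * 25, ["GA"] * 14 + ["MA"] * 11)
        value, detail = snn(aln, _mask(aln))
        expected = (14 * 13 / 24 + 11 * 10 / 24) / 25
        assert value == pytest.approx(expected)
        assert np.all(detail.tie_set_size == 24)

    def test_single_sequence_rejected(self):
        aln = _labeled(["ACGT"], ["X"])
        with pytest.raises(ValueError, match="at least two"):
            snn(aln, _mask(aln))

    def test_label_swap_invariance_equal_sizes(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            aln = random_alignment(rng, n=8)
            pops = ["X"] * 4 + ["Y"] * 4
            aln = _labeled(list(aln.sequences), pops)
            mask = _mask(aln)
            if mask.n_sites == 0:
                continue
            v1, _ = snn(aln, mask)
            swapped = _labeled(list(aln.sequences),
                               ["Y"] * 4 + ["X"] * 4)
            v2, _ = snn(swapped, mask)
            assert v1 == pytest.approx(v2)

    def test_bounded_and_mean_of_xj(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            aln = random_alignment(rng)
            mask = _mask(aln)
            if mask.n_sites == 0:
                continue
            value, detail = snn(aln, mask)
            assert 0.0 <= value <= 1.0
            assert value == pytest.approx(float(detail.x.mean()))

    @pytest.mark.parametrize("mode", ["complete", "pairwise"])
    def test_matches_brute_force(self, mode):
        rng = np.random.default_rng(41)
        checked = 0
        while checked < 50:
            aln = random_alignment(rng)
            mask = _mask(aln, mode)
            if mask.n_sites == 0:
                continue
            if mode == "pairwise":
                from popdiv.diversity import pairwise_difference_counts
                _, nshared = pairwise_difference_counts(aln, mask)
                off_diag = nshared[~np.eye(aln.n, dtype=bool)]
                if np.any(off_diag == 0):
                    continue
            mine, detail = snn(aln, mask)
            brute_mean, brute_x = snn_brute(
                list(aln.sequences), [p or "" for p in aln.populations], mode
            )
            # per-sequence fractions are exact; the mean may differ only in
            # float summation order
            assert list(detail.x) == brute_x
            assert mine == pytest.approx(brute_mean, abs=1e-12)
            checked += 1


class TestDivergenceStatsBundle:
    def test_components_agree_with_individual_functions(self):
        rng = np.random.default_rng(43)
        checked = 0
        while checked < 15:
            aln = random_alignment(rng, n=9)
            if min((len(aln.population_indices(p))
                    for p in aln.population_set()), default=0) < 2:
                continue
            mask = _mask(aln)
            if mask.n_sites == 0:
                continue
            st = divergence_stats(aln, mask)
            assert st.dxy == pytest.approx(dxy(aln, mask))
            assert st.da == pytest.approx(net_divergence(aln, mask))
            fst = hudson_fst(aln, mask)
            if fst is None:
                assert st.fst is None
            else:
                assert st.fst == pytest.approx(fst)
            assert st.snn == pytest.approx(snn(aln, mask)[0])
            checked += 1
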