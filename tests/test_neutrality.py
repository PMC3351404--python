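import math

import numpy as np
import pytest

from caryogeo.errors import NotCalculable
from caryogeo.neutrality import (
    coalescent_null_pvalue,
    ewens_pmf,
    fit_expansion,
    fus_fs,
    mismatch_expected,
    mismatch_observed,
    mk_counts,
    raggedness_index,
    raggedness_pvalue,
    tajimas_d,
)
from caryogeo.seq_data import Alignment

from _oracles import tajimas_d_oracle
from conftest import random_alignment


class TestTajimasD:
    def test_worked_quartet(self, quartet):
        d, comp = tajimas_d(quartet)
        assert comp["S"] == 3
        assert math.isclose(comp["kbar"], 10 / 6)
        assert math.isclose(d, tajimas_d_oracle(list(quartet.sequences)))
        assert round(d, 3) == 0.168

    def test_monomorphic_not_calculable(self):
        aln = Alignment.from_records([(f"s{i}", "ACGT") for i in range(5)])
        with pytest.raises(NotCalculable):
            tajimas_d(aln)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 12))
            aln = random_alignment(rng, n, 40)
            expected = tajimas_d_oracle(list(aln.sequences))
            if expected is None:
                continue
            d, _ = tajimas_d(aln)
            assert abs(d - expected) < 1e-9
            checked += 1


class TestEwensAndFs:
    def test_n2_closed_form(self):
        p = ewens_pmf(2, 1.0)
        assert np.allclose(p, [0.5, 0.5])
        # general closed form: Pr(K=1) = 1/(theta+1)
        for theta in (0.1, 1.0, 10.0):
            assert math.isclose(ewens_pmf(2, theta)[0], 1 / (theta + 1))

    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("n", [5, 20, 50, 100])
    def test_normalizes(self, n, theta):
        assert math.isclose(float(ewens_pmf(n, theta).sum()), 1.0,
                            abs_tol=1e-12)

    def test_small_theta_concentrates_on_one_haplotype(self):
        p = ewens_pmf(10, 1e-6)
        assert p[0] > 0.999

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            ewens_pmf(5, 0.0)

    def test_fs_two_sequences_one_difference_is_zero(self):
        aln = Alignment.from_records([("a", "ACGT"), ("b", "ACGA")])
        assert math.isclose(fus_fs(aln), 0.0, abs_tol=1e-12)

    def test_fs_single_haplotype_not_calculable(self):
        aln = Alignment.from_records([(f"s{i}", "ACGT") for i in range(5)])
        with pytest.raises(NotCalculable):
            fus_fs(aln)

    def test_fs_negative_for_star_like_excess_haplotypes(self):
        # many singleton haplotypes, each one step from a common core
        base = list("A" * 30)
        recs = [("c0", "".join(base)), ("c1", "".join(base))]
        for i in range(8):
            s = base.copy()
            s[i] = "C"
            recs.append((f"x{i}", "".join(s)))
        aln = Alignment.from_records(recs)
        assert fus_fs(aln) < 0


class TestNullPvalues:
    def test_deterministic_under_seed(self, quartet):
        rng_args = dict(reps=200, seed=99)
        a = coalescent_null_pvalue(quartet, "D", **rng_args)
        b = coalescent_null_pvalue(quartet, "D", **rng_args)
        assert a.p == b.p

    def test_null_median_statistic_p_near_half(self):
        # a neutral draw's D should sit well inside the null distribution
        rng = np.random.default_rng(8)
        aln = random_alignment(rng, 12, 60, n_var=8)
        res = coalescent_null_pvalue(aln, "D", reps=400, seed=1)
        assert 0.02 < res.p < 0.98

    def test_theta_conditioning_runs(self, quartet):
        res = coalescent_null_pvalue(quartet, "Fs", reps=150, seed=5,
                                     condition_on="theta")
        assert 0.0 < res.p <= 1.0


class TestMismatch:
    def test_identical_sequences_single_class(self):
        aln = Alignment.from_records([(f"s{i}", "ACGT") for i in range(4)])
        assert np.allclose(mismatch_observed(aln), [1.0])

    def test_worked_quartet_distribution(self, quartet):
        assert np.allclose(mismatch_observed(quartet),
                           [0.0, 3 / 6, 2 / 6, 1 / 6])

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(2)
        aln = random_alignment(rng, 9, 40)
        assert math.isclose(float(mismatch_observed(aln).sum()), 1.0)

    def test_constant_model_closed_form(self):
        f = mismatch_expected("constant", 1.0, 3)
        assert np.allclose(f, [0.5, 0.25, 0.125, 0.0625])

    def test_constant_model_normalizes_geometrically(self):
        f = mismatch_expected("constant", 2.0, 400)
        assert math.isclose(float(f.sum()), 1.0, abs_tol=1e-12)

    def test_tau_zero_reduces_to_constant(self):
        f0 = mismatch_expected("sudden-expansion", (0.0, 1.5, math.inf), 8)
        fc = mismatch_expected("constant", 1.5, 8)
        assert np.allclose(f0, fc)

    def test_expansion_fit_recovers_peak_location(self):
        tau, th0 = 4.0, 0.2
        x = mismatch_expected("sudden-expansion", (tau, th0, math.inf), 20)
        x = x / x.sum()
        tau_hat, _ = fit_expansion(x)
        assert abs(tau_hat - tau) < 0.5


class TestRaggedness:
    def test_worked_examples(self):
        assert math.isclose(raggedness_index([0.25, 0.5, 0.25]), 0.1875)
        assert math.isclose(raggedness_index([1.0]), 1.0)

    def test_smooth_beats_jagged_permutation(self):
        smooth = [0.05, 0.15, 0.3, 0.3, 0.15, 0.05]
        jagged = [0.3, 0.05, 0.3, 0.05, 0.15, 0.15]
        assert raggedness_index(smooth) < raggedness_index(jagged)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            raggedness_index([])

    def test_pvalue_deterministic_and_bounded(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, 15, 80, n_var=12)
        r1 = raggedness_pvalue(aln, reps=120, seed=3)
        r2 = raggedness_pvalue(aln, reps=120, seed=3)
        assert r1[1] == r2[1]
        assert 0.0 < r1[1] <= 1.0


class TestMcDonaldKreitman:
    def test_toy_leucine_phenylalanine(self):
        a = Alignment.from_records([("a1", "TTT"), ("a2", "TTC")])
        b = Alignment.from_records([("b1", "TTA")])
        mk = mk_counts(a, b, frame=0)
        assert (mk.Ps, mk.Pn, mk.Ms, mk.Mn) == (1.0, 0.0, 0.0, 1.0)

    def test_identical_alignments_all_zero(self):
        a = Alignment.from_records([("a1", "ATGTTTAAA")])
        b = Alignment.from_records([("b1", "ATGTTTAAA")])
        mk = mk_counts(a, b, frame=0)
        assert (mk.Ps, mk.Pn, mk.Ms, mk.Mn) == (0.0, 0.0, 0.0, 0.0)

    def test_fixed_synonymous_difference(self):
        # GGA vs GGG: both glycine, fixed between species
        a = Alignment.from_records([("a1", "GGA"), ("a2", "GGA")])
        b = Alignment.from_records([("b1", "GGG"), ("b2", "GGG")])
        mk = mk_counts(a, b, frame=0)
        assert (mk.Ps, mk.Pn, mk.Ms, mk.Mn) == (0.0, 0.0, 1.0, 0.0)
        # no fixed non-synonymous differences -> never flagged
        assert not mk.positive_selection_indicated

    def test_shared_polymorphism_is_not_fixed(self):
        # both species segregate A/G at third position: polymorphic twice
        a = Alignment.from_records([("a1", "GGA"), ("a2", "GGG")])
        b = Alignment.from_records([("b1", "GGA"), ("b2", "GGG")])
        mk = mk_counts(a, b, frame=0)
        assert mk.Ms == 0.0 and mk.Mn == 0.0 and mk.Ps == 2.0
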