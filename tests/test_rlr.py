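import itertools
import math

import dendropy
import numpy as np
import pytest

from caryogeo.errors import TreeError
from caryogeo.rlr import (
    TreeSample,
    bayes_factor,
    fitch_root_states,
    harmonic_mean_log_ml,
    pool_localities,
    read_tree_sample,
    rps_scores,
)

from _oracles import all_rooted_topologies, mpr_root_states, tree_to_newick


def dtree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


class TestFitch:
    def test_cherry_split(self):
        rw = fitch_root_states(dtree("(A,B);"),
                               {"A": frozenset({"X"}), "B": frozenset({"Y"})})
        assert rw.states == frozenset({"X", "Y"})
        assert rw.n == 2 and rw.weight == 0.5

    def test_three_tips_against_enumeration(self):
        # ((A:{X},B:{X}),C:{Y}): root=X (change on C edge) and root=Y
        # (change on the internal edge) both cost 1 -> MPR set {X, Y}
        tips = {"A": frozenset({"X"}), "B": frozenset({"X"}),
                "C": frozenset({"Y"})}
        expected = mpr_root_states((("A", "B"), "C"), tips, ["X", "Y"])
        rw = fitch_root_states(dtree("((A,B),C);"), tips)
        assert rw.states == expected == frozenset({"X", "Y"})

    def test_multistate_tips_against_enumeration(self):
        tips = {"A": frozenset({"X", "Y"}), "B": frozenset({"Y"}),
                "C": frozenset({"Z"})}
        expected = mpr_root_states((("A", "B"), "C"), tips, ["X", "Y", "Z"])
        rw = fitch_root_states(dtree("((A,B),C);"), tips)
        assert rw.states == expected == frozenset({"Y", "Z"})

    def test_empty_tip_set_rejected(self):
        with pytest.raises(TreeError):
            fitch_root_states(dtree("(A,B);"),
                              {"A": frozenset(), "B": frozenset({"X"})})

    def test_exhaustive_small_topologies(self):
        """Fitch root sets equal MPR enumeration on all rooted binary
        topologies with up to 5 tips and up to 4 states."""
        rng = np.random.default_rng(123)
        states = ["W", "X", "Y", "Z"]
        for n in range(2, 6):
            labels = tuple("ABCDE"[:n])
            for topo in all_rooted_topologies(labels):
                for _ in range(3):
                    tips = {
                        lab: frozenset(rng.choice(states,
                                                  size=rng.integers(1, 3),
                                                  replace=False).tolist())
                        for lab in labels
                    }
                    expected = mpr_root_states(topo, tips, states)
                    got = fitch_root_states(dtree(tree_to_newick(topo) + ";"),
                                            tips)
                    assert got.states == expected, (topo, tips)

    def test_sampled_six_tip_topologies(self):
        rng = np.random.default_rng(7)
        states = ["W", "X", "Y", "Z"]
        labels = tuple("ABCDEF")
        topos = list(all_rooted_topologies(labels))
        for i in rng.choice(len(topos), size=40, replace=False):
            topo = topos[i]
            tips = {lab: frozenset({rng.choice(states)}) for lab in labels}
            expected = mpr_root_states(topo, tips, states)
            got = fitch_root_states(dtree(tree_to_newick(topo) + ";"), tips)
            assert got.states == expected


class TestRps:
    def _sample(self, newicks, tips):
        trees = tuple(dtree(nw) for nw in newicks)
        return TreeSample(trees=trees, tip_states=tips)

    def test_unanimous_root(self):
        tips = {"A": frozenset({"X"}), "B": frozenset({"X"}),
                "C": frozenset({"Y"})}
        s = self._sample(["(C,(A,B));"] * 4, tips)
        # every tree roots to {X, Y} equally -> 50/50
        res = rps_scores(s)
        assert math.isclose(res.scores["X"], 50.0)
        assert math.isclose(sum(res.scores.values()), 100.0)

    def test_weighted_mixture(self):
        # 1 tree rooting {X}, 3 rooting {X,Y}: RPS_X = 100*(1+1.5)/4
        tips_a = {"A": frozenset({"X"}), "B": frozenset({"X"}),
                  "C": frozenset({"X"})}
        tips_b = {"A": frozenset({"X"}), "B": frozenset({"Y"}),
                  "C": frozenset({"Y"})}
        sa = self._sample(["((A,B),C);"], tips_a)
        sb = self._sample(["((A,B),C);"] * 3, tips_b)
        ra = rps_scores(sa)
        assert ra.scores["X"] == 100.0
        rb = rps_scores(sb)
        # each tree: A:{X} vs {Y} at the cherry -> union {X,Y}; root with
        # C:{Y} -> {Y}; so every weight goes to Y
        assert rb.scores["Y"] == 100.0

    def test_scores_conserved_and_relabeling_invariant(self):
        rng = np.random.default_rng(3)
        tips = {lab: frozenset({rng.choice(["P", "Q", "R"])})
                for lab in "ABCDE"}
        s = self._sample(["((A,(B,C)),(D,E));"] * 5, tips)
        res = rps_scores(s)
        assert math.isclose(sum(res.scores.values()), 100.0)
        ren = {"P": "P2", "Q": "Q2", "R": "R2"}
        tips2 = {k: frozenset(ren[x] for x in v) for k, v in tips.items()}
        res2 = rps_scores(self._sample(["((A,(B,C)),(D,E));"] * 5, tips2))
        for c, v in res.scores.items():
            assert math.isclose(res2.scores[ren[c]], v)


class TestTreeSampleIO:
    def _write(self, tmp_path, n=20):
        p = tmp_path / "trees.nwk"
        p.write_text("".join("((A,B),C);\n" for _ in range(n)))
        return p

    def test_burnin_and_subsample(self, tmp_path):
        p = self._write(tmp_path, n=100)
        s = read_tree_sample(p, burnin_fraction=0.1, subsample=25, seed=4)
        assert len(s) == 25

    def test_subsample_all_preserves_order(self, tmp_path):
        p = self._write(tmp_path, n=10)
        s = read_tree_sample(p, subsample=10, seed=0)
        assert len(s) == 10

    def test_oversubsample_rejected(self, tmp_path):
        p = self._write(tmp_path, n=5)
        with pytest.raises(TreeError):
            read_tree_sample(p, subsample=10)

    def test_unrooted_tree_rejected(self, tmp_path):
        p = tmp_path / "trees.nwk"
        p.write_text("(A,B,C);\n")  # basal trifurcation, unrooted shape
        with pytest.raises(TreeError):
            read_tree_sample(p)

    def test_subsample_deterministic(self, tmp_path):
        p = self._write(tmp_path, n=50)
        a = read_tree_sample(p, subsample=10, seed=7)
        b = read_tree_sample(p, subsample=10, seed=7)
        assert [t.as_string(schema="newick") for t in a.trees] == \
            [t.as_string(schema="newick") for t in b.trees]


class TestPooling:
    def test_pooled_characters(self):
        m = pool_localities({"GA": "GA+TO", "TO": "GA+TO"},
                            codes=["GA", "TO"])
        assert m == {"GA": "GA+TO", "TO": "GA+TO"}

    def test_identity_map(self):
        m = pool_localities({"A": "A", "B": "B"}, codes=["A", "B"])
        assert m == {"A": "A", "B": "B"}

    def test_missing_code_rejected(self):
        with pytest.raises(TreeError):
            pool_localities({"A": "A"}, codes=["A", "B"])


class TestBayesFactors:
    def test_constant_trace_recovers_value(self):
        assert math.isclose(harmonic_mean_log_ml([3.7] * 10), 3.7)

    def test_harmonic_mean_of_one_and_three(self):
        est = harmonic_mean_log_ml([math.log(1.0), math.log(3.0)])
        assert math.isclose(est, math.log(1.5))

    def test_permutation_invariant(self):
        tr = [-10.0, -12.0, -9.5, -11.0]
        assert harmonic_mean_log_ml(tr) == harmonic_mean_log_ml(tr[::-1])

    @pytest.mark.parametrize("log10_bf,call", [
        (2.099, "decisive"), (6.482, "decisive"),
        (0.7, "substantial"), (1.5, "strong"), (0.0, "none"), (0.3, "none"),
    ])
    def test_jeffreys_grades(self, log10_bf, call):
        res = bayes_factor(log10_bf * math.log(10.0), 0.0)
        assert res.call == call
        assert math.isclose(res.log10_bf, log10_bf)

    def test_sign_points_to_favored_model(self):
        res = bayes_factor(0.0, 10.0, labels=("const", "growth"))
        assert res.favored == "growth" and res.log10_bf < 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(float("inf"), 0.0)
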