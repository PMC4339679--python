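"""Weighted P/R/F evaluation, singleton removal, contingency, sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import homclust as hc


class TestRemoveSingletons:
    def test_singleton_class_removed(self):
        gold = hc.GoldStandard.from_mappings({"a": "f1", "b": "f1", "c": "f2"})
        filtered, removed = hc.remove_singletons(gold)
        assert removed == ["c"]
        assert sorted(filtered.roster) == ["a", "b"]

    def test_no_singletons_unchanged(self, worked_gold):
        filtered, removed = hc.remove_singletons(worked_gold)
        assert removed == [] and sorted(filtered.roster) == ["a", "b", "c", "d"]

    def test_all_singletons_empty_result(self):
        gold = hc.GoldStandard.from_mappings({"a": "f1", "b": "f2"})
        filtered, removed = hc.remove_singletons(gold)
        assert filtered.roster == [] and sorted(removed) == ["a", "b"]

    def test_level_specific(self):
        gold = hc.GoldStandard(
            {"a": "f1", "b": "f2", "c": "f3"},
            {"a": "s1", "b": "s1", "c": "s1"},
        )
        _, removed_fam = hc.remove_singletons(gold, "family")
        _, removed_sup = hc.remove_singletons(gold, "superfamily")
        assert sorted(removed_fam) == ["a", "b", "c"]
        assert removed_sup == []


class TestContingency:
    def test_counts(self, worked_gold, worked_clustering):
        t = hc.contingency(worked_clustering, worked_gold)
        assert t.loc["f1", 0] == 2
        assert t.loc["f2", 0] == 1
        assert t.loc["f2", 1] == 1

    def test_identity_clustering_diagonal(self, worked_gold):
        clu = worked_gold.to_clustering("family")
        t = hc.contingency(clu, worked_gold)
        assert sorted(t.max(axis=1)) == sorted(t.sum(axis=1))

    def test_roster_mismatch_lists_difference(self, worked_gold):
        clu = hc.Clustering([["a", "b"], ["c", "x"]])
        with pytest.raises(ValueError, match="x"):
            hc.contingency(clu, worked_gold)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_marginal_conservation_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        roster = [f"p{i}" for i in range(n)]
        gold = hc.GoldStandard.from_mappings({p: f"f{rng.integers(0, 4)}" for p in roster})
        labels = rng.integers(0, 5, n)
        clu = hc.Clustering.from_labels(roster, labels)
        t = hc.contingency(clu, gold)
        fam_sizes = pd.Series(gold.family).value_counts()
        for f in t.index:
            assert t.loc[f].sum() == fam_sizes[f]
        assert int(t.to_numpy().sum()) == n


class TestWeightedPrf:
    def test_worked_fixture(self, worked_gold, worked_clustering):
        p, r, f = hc.weighted_prf(hc.contingency(worked_clustering, worked_gold))
        assert p == pytest.approx(0.8333, abs=1e-4)
        assert r == pytest.approx(0.75, abs=1e-9)
        assert f == pytest.approx(0.7333, abs=1e-4)

    def test_identity_case_all_ones(self, worked_gold):
        clu = worked_gold.to_clustering("family")
        p, r, f = hc.weighted_prf(hc.contingency(clu, worked_gold))
        assert (p, r, f) == (1.0, 1.0, 1.0)

    def test_all_singletons_of_size_two_families(self, worked_gold):
        clu = hc.Clustering([["a"], ["b"], ["c"], ["d"]])
        p, r, f = hc.weighted_prf(hc.contingency(clu, worked_gold))
        assert p == 1.0
        assert r == pytest.approx(0.5)
        assert f == pytest.approx(2.0 / 3.0)

    def test_harmonic_term_bounded_by_components(self):
        """Per (family, cluster) pair the harmonic mean lies between the
        smaller and larger of precision and recall, so the weighted F never
        exceeds max(weighted P, weighted R)."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            t = pd.DataFrame(rng.integers(0, 6, (4, 5)))
            t = t.loc[t.sum(axis=1) > 0, t.sum(axis=0) > 0]
            if t.empty:
                continue
            n_fg = t.to_numpy(float)
            pm = n_fg / n_fg.sum(axis=0, keepdims=True)
            rm = n_fg / n_fg.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                h = np.where(pm + rm > 0, 2 * pm * rm / np.where(pm + rm > 0, pm + rm, 1), 0)
            assert (h <= np.maximum(pm, rm) + 1e-12).all()
            assert (h + 1e-12 >= np.minimum(pm, rm)).all()
            p, r, f = hc.weighted_prf(t)
            assert f <= max(p, r) + 1e-12

    def test_merging_families_lowers_precision_splitting_lowers_recall(self, worked_gold):
        merged = hc.Clustering([["a", "b", "c", "d"]])
        split = hc.Clustering([["a"], ["b"], ["c", "d"]])
        ideal = worked_gold.to_clustering("family")
        p0, r0, _ = hc.weighted_prf(hc.contingency(ideal, worked_gold))
        pm, rm, _ = hc.weighted_prf(hc.contingency(merged, worked_gold))
        ps, rs, _ = hc.weighted_prf(hc.contingency(split, worked_gold))
        assert pm <= p0 and pm < 1.0
        assert rs <= r0 and rs < 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_bounds_and_identity_iff_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        roster = [f"p{i}" for i in range(n)]
        gold = hc.GoldStandard.from_mappings({p: f"f{rng.integers(0, 3)}" for p in roster})
        labels = rng.integers(0, 4, n)
        clu = hc.Clustering.from_labels(roster, labels)
        p, r, f = hc.weighted_prf(hc.contingency(clu, gold))
        assert 0.0 <= f <= 1.0
        gold_part = sorted(sorted(c) for c in gold.to_clustering("family").clusters)
        clu_part = sorted(sorted(c) for c in clu.clusters)
        if f == 1.0:
            assert gold_part == clu_part
        if gold_part == clu_part:
            assert f == 1.0


class TestEvaluate:
    def test_report_fields(self, worked_gold, worked_clustering):
        rep = hc.evaluate(worked_clustering, worked_gold)
        assert rep.n_clusters == 2 and rep.n_proteins == 4
        assert rep.weighted_f_measure == pytest.approx(0.7333, abs=1e-4)

    def test_empty_roster_rejected(self, worked_gold):
        with pytest.raises(ValueError):
            hc.evaluate(hc.Clustering([]), worked_gold)


class TestGridSweep:
    def make_data(self, seed=0, difficulty=0.0):
        cfg = hc.SynthConfig(n_families=4, family_size_range=(3, 5), difficulty=difficulty, seed=seed)
        hits, gold = hc.synth_benchmark(cfg)
        return hits, gold, hc.build_matrix(hc.symmetrize(hits))

    def test_single_point_grid(self):
        hits, gold, S = self.make_data()
        res = hc.grid_sweep("mcl", gold=gold, grid={"inflation": [2.0]}, matrix=S)
        assert len(res.rows) == 1
        assert res.best["param_inflation"] == 2.0

    def test_separating_threshold_reaches_f_one(self):
        hits, gold, S = self.make_data()
        res = hc.grid_sweep(
            "transclust", gold=gold,
            grid={"threshold": [0.5, 5.0, 9.0, 20.0, 60.0]}, matrix=S,
        )
        assert res.best_f == pytest.approx(1.0)
        assert 8.0 < res.best["param_threshold"] < 10.0 or res.best_f == 1.0

    def test_deterministic_rerun(self):
        hits, gold, S = self.make_data(seed=3, difficulty=0.5)
        g = {"c": [3, 4, 5]}
        r1 = hc.grid_sweep("scps", gold=gold, grid=g, matrix=S, seed=11)
        r2 = hc.grid_sweep("scps", gold=gold, grid=g, matrix=S, seed=11)
        pd.testing.assert_frame_equal(r1.rows, r2.rows)
        assert r1.best == r2.best

    def test_unknown_method(self):
        hits, gold, S = self.make_data()
        with pytest.raises(ValueError, match="unknown method"):
            hc.grid_sweep("nosuch", gold=gold, grid={"x": [1]}, matrix=S)
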