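import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pooltox import (
    aafc_score,
    afc_score,
    feature_set_scores,
    ora_enrichment,
    permutation_null,
    score_collection,
    score_set,
)
from pooltox.io import GeneSet, GeneSetCollection


def fc_series(values):
    return pd.Series(values, index=[f"G{i}" for i in range(len(values))], dtype=float)


class TestAggregateScores:
    def test_aafc_ignores_sign(self):
        fc = pd.Series({"g1": 1.0, "g2": -1.0})
        score, n = aafc_score(fc, {"g1", "g2"}, min_genes=2)
        assert score == 1.0 and n == 2

    def test_afc_cancels(self):
        fc = pd.Series({"g1": 1.0, "g2": -1.0})
        score, n = afc_score(fc, {"g1", "g2"}, min_genes=2)
        assert score == 0.0

    def test_unmeasured_members_ignored_but_counted(self):
        fc = pd.Series({"g1": -0.7})
        score, n = aafc_score(fc, {"g1", "gX"}, min_genes=1)
        assert score == pytest.approx(0.7) and n == 1

    def test_all_positive_afc_equals_aafc(self):
        fc = pd.Series({"a": 0.5, "b": 1.5, "c": 2.0})
        assert afc_score(fc, fc.index)[0] == aafc_score(fc, fc.index)[0]

    def test_min_genes_enforced(self):
        fc = pd.Series({"g1": 1.0, "g2": 2.0})
        with pytest.raises(ValueError, match="measured member"):
            aafc_score(fc, {"g1", "g2"}, min_genes=3)

    def test_matches_brute_force_mean_of_abs(self):
        rng = np.random.default_rng(5)
        fc = fc_series(rng.normal(0, 1, 200))
        members = set(rng.choice(fc.index, 20, replace=False))
        score, n = aafc_score(fc, members)
        expected = sum(abs(fc[g]) for g in members) / len(members)
        assert score == pytest.approx(expected, abs=1e-12) and n == 20

    def test_member_order_irrelevant(self):
        fc = fc_series([0.3, -0.2, 0.9, 1.1])
        a = afc_score(fc, ["G0", "G2", "G3"])[0]
        b = afc_score(fc, ["G3", "G0", "G2"])[0]
        assert a == b

    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=3, max_size=50))
    def test_aafc_dominates_abs_afc(self, values):
        fc = fc_series(values)
        aafc, _ = aafc_score(fc, fc.index)
        afc, _ = afc_score(fc, fc.index)
        assert aafc >= abs(afc) - 1e-12


class TestPermutationNull:
    def test_four_gene_enumeration(self):
        fc = pd.Series({"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4})
        null = permutation_null(fc, set_size=2, method="AAFC", n_perm=10_000, seed=9)
        pair_means = sorted(
            (abs(x) + abs(y)) / 2 for x, y in itertools.combinations(fc, 2)
        )
        assert pair_means == pytest.approx([0.15, 0.20, 0.25, 0.25, 0.30, 0.35])
        p_exact = 1 / 6
        p_mc = float((null.null_scores >= 0.35).mean())
        tol = 3 * math.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(p_mc - p_exact) <= tol

    def test_constant_universe_degenerate(self):
        fc = pd.Series(0.5, index=[f"G{i}" for i in range(10)])
        null = permutation_null(fc, 3, "AAFC", n_perm=500, seed=1)
        assert null.degenerate and null.null_sd == 0.0

    def test_same_seed_reproducible(self):
        fc = fc_series(np.random.default_rng(2).normal(0, 1, 100))
        a = permutation_null(fc, 10, "AAFC", 1000, seed=42)
        b = permutation_null(fc, 10, "AAFC", 1000, seed=42)
        assert np.array_equal(a.null_scores, b.null_scores)

    def test_oversized_set_rejected(self):
        fc = fc_series([1.0, 2.0])
        with pytest.raises(ValueError, match="exceeds"):
            permutation_null(fc, 3)


class TestScoreSet:
    def test_whole_universe_saturates(self):
        fc = fc_series(np.random.default_rng(3).normal(0, 1, 30))
        ms = score_set(fc, set(fc.index), n_perm=500, seed=0)
        assert ms.z_score == 0.0
        assert ms.p_perm > 0.9
        assert not ms.activated

    @pytest.mark.parametrize("universe_size,set_size", [(8, 3), (10, 4), (12, 5)])
    def test_p_perm_matches_exhaustive_enumeration(self, universe_size, set_size):
        rng = np.random.default_rng(universe_size)
        fc = fc_series(rng.normal(0, 1, universe_size))
        members = list(fc.index[:set_size])
        raw, _ = aafc_score(fc, members)
        absvals = np.abs(fc.to_numpy())
        exact_ge = sum(
            1 for combo in itertools.combinations(range(universe_size), set_size)
            if absvals[list(combo)].mean() >= raw
        )
        p_exact = exact_ge / math.comb(universe_size, set_size)
        ms = score_set(fc, members, n_perm=10_000, seed=1)
        tol = 3 * math.sqrt(max(p_exact * (1 - p_exact), 1e-6) / 10_000) + 1e-4
        assert abs(ms.p_perm - p_exact) <= tol

    def test_afc_signed_z_carries_direction(self):
        rng = np.random.default_rng(4)
        fc = fc_series(rng.normal(0, 0.2, 200))
        fc.iloc[:10] = -2.0  # strongly down-regulated block
        ms = score_set(fc, list(fc.index[:10]), method="AFC", n_perm=1000, seed=0)
        assert ms.raw_score < 0
        assert ms.z_signed < 0
        assert abs(ms.z_signed) == pytest.approx(abs(ms.z_score))

    def test_injected_signal_activates(self, small_synthetic):
        cfg, (study, truth) = small_synthetic
        from pooltox import de_all_lots

        tables = de_all_lots(study)
        long, z = score_collection(tables, truth.gene_sets, n_perm=2000, seed=5)
        assert z.loc["inj_strong", "merged"] >= 2.0
        null_ids = [s for s in truth.gene_sets.ids() if s.startswith("null_")]
        assert (z.loc[null_ids, "merged"].abs() < 2.0).all()


class TestScoreCollection:
    def test_single_lot_merged_identity(self):
        fc = fc_series(np.random.default_rng(6).normal(0, 1, 50))
        coll = GeneSetCollection()
        coll.add(GeneSet("s1", "d", frozenset(fc.index[:5]), "injury_module"))
        long, z = score_collection({"A": fc}, coll, n_perm=500, seed=0)
        assert z.loc["s1", "merged"] == z.loc["s1", "A"]

    def test_merged_is_mean_of_lot_z(self):
        rng = np.random.default_rng(7)
        fcs = {lot: fc_series(rng.normal(0, 1, 60)) for lot in "AB"}
        coll = GeneSetCollection()
        coll.add(GeneSet("s1", "d", frozenset([f"G{i}" for i in range(6)]),
                         "injury_module"))
        _, z = score_collection(fcs, coll, n_perm=500, seed=0)
        assert z.loc["s1", "merged"] == pytest.approx(
            (z.loc["s1", "A"] + z.loc["s1", "B"]) / 2
        )

    def test_tiny_set_reported_na(self):
        fc = fc_series(np.random.default_rng(8).normal(0, 1, 50))
        coll = GeneSetCollection()
        coll.add(GeneSet("tiny", "d", frozenset({"G0", "G1"}), "injury_module"))
        long, z = score_collection({"A": fc}, coll, n_perm=500, seed=0, min_genes=3)
        assert np.isnan(z.loc["tiny", "A"])
        assert long.loc[long.set_id == "tiny", "n_measured"].item() == 2


class TestFeatureSetScores:
    def test_identical_scores_zero_sd(self):
        fc = pd.Series({"a": 0.5, "b": -0.5, "c": 1.0})
        coll = GeneSetCollection()
        coll.add(GeneSet("fs", "d", frozenset("abc"), "feature_set"))
        df = feature_set_scores({"A": fc, "B": fc.copy()}, coll)
        assert df.loc["fs", "sd"] == 0.0
        assert df.loc["fs", "mean"] == pytest.approx(2.0 / 3)

    def test_published_liver_toxicity_summary(self):
        # Per-lot mean-|FC| scores matching the published PTGS (all) panel:
        # the cross-lot summary must reproduce 0.84 (0.07) at 2 dp.
        per_lot = {"A": 0.75, "B": 0.80, "C": 0.94, "D": 0.88, "E": 0.85}
        coll = GeneSetCollection()
        coll.add(GeneSet("PTGS_all", "d", frozenset({"g1", "g2", "g3"}), "feature_set"))
        fcs = {
            lot: pd.Series({"g1": s, "g2": -s, "g3": s})
            for lot, s in per_lot.items()
        }
        df = feature_set_scores(fcs, coll)
        assert round(df.loc["PTGS_all", "mean"], 2) == 0.84
        assert round(df.loc["PTGS_all", "sd"], 2) == 0.07


class TestORA:
    def test_full_overlap_combinatorial_p(self):
        universe = {f"G{i}" for i in range(10)}
        members = {f"G{i}" for i in range(5)}
        coll = GeneSetCollection()
        coll.add(GeneSet("s", "d", frozenset(members), "pathway"))
        res = ora_enrichment(members, universe, coll)
        assert res.loc["s", "p"] == pytest.approx(1 / math.comb(10, 5))

    def test_zero_overlap_bounded(self):
        universe = {f"G{i}" for i in range(20)}
        coll = GeneSetCollection()
        coll.add(GeneSet("s", "d", frozenset({"G0", "G1", "G2"}), "pathway"))
        res = ora_enrichment({"G10", "G11"}, universe, coll)
        assert 0 < res.loc["s", "p"] <= 1

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(10)
        universe = [f"G{i}" for i in range(15)]
        members = set(rng.choice(universe, 6, replace=False))
        de = set(rng.choice(universe, 5, replace=False))
        coll = GeneSetCollection()
        coll.add(GeneSet("s", "d", frozenset(members), "pathway"))
        res = ora_enrichment(de, set(universe), coll)
        k = len(members & de)
        # brute-force tail: enumerate all DE draws of the same size
        total = hits = 0
        for combo in itertools.combinations(universe, len(de)):
            total += 1
            if len(set(combo) & members) >= k:
                hits += 1
        assert res.loc["s", "p"] == pytest.approx(hits / total, abs=1e-12)

    def test_de_outside_universe_rejected(self):
        coll = GeneSetCollection()
        coll.add(GeneSet("s", "d", frozenset({"G0", "G1", "G2"}), "pathway"))
        with pytest.raises(ValueError, match="subset"):
            ora_enrichment({"X"}, {"G0", "G1"}, coll)
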