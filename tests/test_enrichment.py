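from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diffsen import (
    ConfigError,
    DiffSenVector,
    aggregate_ranks,
    cellline_enrichment,
    importance_scores,
    rank_features_per_model,
    transporter_enrichment,
)
from diffsen.enrichment import RankedFeatureList
from diffsen.modeling import FeatureSelection


def _selection(corrs: dict[str, float]) -> FeatureSelection:
    ranked = sorted(corrs.items(), key=lambda kv: (-kv[1], kv[0]))
    return FeatureSelection(
        drug_id="d",
        ranked_features=[(f, r, 0.5) for f, r in ranked],
        selected=[f for f, _ in ranked],
    )


def _ranked(order: list[str], scope="d") -> RankedFeatureList:
    return RankedFeatureList(
        scope=scope,
        entries=[(f, float(i + 1)) for i, f in enumerate(order)],
        n_models_integrated=1,
    )


class TestRanking:
    def test_rank_one_is_most_positive_correlation(self):
        ranks = rank_features_per_model(_selection({"a": 0.9, "b": 0.1, "c": -0.5}))
        assert list(ranks[["a", "b", "c"]]) == [1.0, 2.0, 3.0]

    def test_ties_get_average_ranks(self):
        ranks = rank_features_per_model(_selection({"a": 0.7, "b": 0.7, "c": 0.1}))
        assert ranks["a"] == ranks["b"] == 1.5
        assert ranks["c"] == 3.0

    def test_rank_vector_sums_conserved(self, rng):
        n = 57
        corrs = {f"f{i}": float(r) for i, r in enumerate(rng.normal(size=n))}
        ranks = rank_features_per_model(_selection(corrs))
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2)


class TestAggregation:
    def test_single_model_is_identity(self):
        rv = rank_features_per_model(_selection({"a": 0.9, "b": 0.5, "c": 0.1}))
        agg = aggregate_ranks([rv], scope="d")
        assert agg.universe == ["a", "b", "c"]
        assert [mr for _, mr in agg.entries] == [1.0, 2.0, 3.0]

    def test_reversed_rankings_tie_everything(self):
        fwd = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        rev = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        agg = aggregate_ranks([fwd, rev], scope="d")
        assert all(mr == 2.0 for _, mr in agg.entries)

    def test_order_of_models_is_irrelevant(self, rng):
        vs = [pd.Series(rng.permutation(10) + 1.0, index=[f"f{i}" for i in range(10)])
              for _ in range(4)]
        a = aggregate_ranks(vs, "d")
        b = aggregate_ranks(vs[::-1], "d")
        assert a.entries == b.entries

    def test_restricted_to_common_universe(self):
        v1 = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        v2 = pd.Series([1.0, 2.0, 3.0], index=["b", "c", "d"])
        agg = aggregate_ranks([v1, v2], "d")
        assert set(agg.universe) == {"b", "c"}


class TestTransporterEnrichment:
    def test_exact_p_matches_enumeration_oracle(self):
        """2 annotated features at the top of a 10-feature list: exhaustive
        placement gives p = 1/45."""
        ranked = _ranked([f"f{i}" for i in range(10)])
        res = transporter_enrichment(ranked, {"f0", "f1"})
        positions = np.arange(1, 11)
        count = sum(1 for s in combinations(positions, 2) if sum(s) <= 3)
        assert count / 45 == pytest.approx(1 / 45)
        assert res.method == "exact_permutation"
        assert res.p == pytest.approx(1 / 45)

    def test_exact_p_for_arbitrary_placement_matches_oracle(self):
        ranked = _ranked([f"f{i}" for i in range(11)])
        annotated = {"f2", "f5", "f9"}  # positions 3, 6, 10 -> sum 19
        res = transporter_enrichment(ranked, annotated)
        count = sum(1 for s in combinations(range(1, 12), 3) if sum(s) <= 19)
        from math import comb
        assert res.p == pytest.approx(count / comb(11, 3))

    def test_annotated_equals_universe_has_no_contrast(self):
        ranked = _ranked(["a", "b", "c"])
        res = transporter_enrichment(ranked, {"a", "b", "c"})
        assert res.p == 1.0

    def test_disjoint_annotation_is_untestable(self):
        res = transporter_enrichment(_ranked(["a", "b"]), {"zz"})
        assert res.untestable and np.isnan(res.p)

    def test_null_p_uniform(self, rng):
        """Random placement of 5 annotated among 300 features: p uniform
        (1000 draws, KS at 0.01)."""
        universe = [f"f{i:03d}" for i in range(300)]
        ps = []
        for _ in range(1000):
            order = list(rng.permutation(universe))
            ps.append(transporter_enrichment(_ranked(order), set(universe[:5])).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_normal_approximation_agrees_with_exact_decision(self, rng):
        """On small universes the asymptotic rank-sum and the exhaustive
        permutation agree in their alpha=0.05 decision >= 95% of the time."""
        agree = 0
        n_inst = 200
        for _ in range(n_inst):
            n = int(rng.integers(8, 13))
            m = int(rng.integers(1, min(5, n - 1) + 1))
            order = [f"f{i}" for i in rng.permutation(n)]
            annotated = set(rng.choice([f"f{i}" for i in range(n)], size=m, replace=False))
            ranked = _ranked(order)
            exact = transporter_enrichment(ranked, annotated).p
            mean_ranks = ranked.to_series()
            ann = sorted(annotated)
            rest = [f for f in ranked.universe if f not in annotated]
            approx = stats.mannwhitneyu(
                mean_ranks[ann], mean_ranks[rest], alternative="less",
                method="asymptotic",
            ).pvalue
            agree += (exact < 0.05) == (approx < 0.05)
        assert agree / n_inst >= 0.95


class TestCelllineEnrichment:
    def _vec(self, values, cells):
        return DiffSenVector("d", "ds", list(cells), np.asarray(values, float))

    def test_expression_identical_to_diffsen(self, rng):
        cells = [f"c{i:02d}" for i in range(50)]
        y = rng.normal(size=50)
        expr = pd.Series(y, index=cells)
        res = cellline_enrichment(expr, self._vec(y, cells), top_n=10)
        # oracle: perfectly separated top-10 vs rest is the minimal p
        ref = stats.mannwhitneyu(
            np.sort(y)[-10:], np.sort(y)[:-10], alternative="greater",
            method="asymptotic",
        ).pvalue
        assert res["p_high"] == pytest.approx(ref)
        assert res["p_low"] > 0.9

    def test_independent_expression_is_uniform(self, rng):
        cells = [f"c{i:02d}" for i in range(60)]
        ps_high, ps_low = [], []
        for _ in range(300):
            y = rng.normal(size=60)
            expr = pd.Series(rng.normal(size=60), index=cells)
            res = cellline_enrichment(expr, self._vec(y, cells), top_n=10)
            ps_high.append(res["p_high"])
            ps_low.append(res["p_low"])
        assert stats.kstest(ps_high, "uniform").pvalue > 0.01
        assert stats.kstest(ps_low, "uniform").pvalue > 0.01

    def test_oversized_tail_rejected(self, rng):
        cells = [f"c{i}" for i in range(30)]
        expr = pd.Series(rng.normal(size=30), index=cells)
        with pytest.raises(ConfigError):
            cellline_enrichment(expr, self._vec(rng.normal(size=30), cells), top_n=15)


class TestImportance:
    def test_score_bounds_and_ordering(self):
        ranked = _ranked(["a", "b", "c", "d"], scope="g1")
        scores = importance_scores({"g1": ranked}, {"g1": ["drugA"]})["drugA"]
        assert scores["a"] == 1.0
        assert scores["d"] == pytest.approx(1 / 4)
        assert list(scores.index) == ["a", "b", "c", "d"]
        assert scores.is_monotonic_decreasing
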