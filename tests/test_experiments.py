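"""Comparative-study pipeline: aggregation, asymmetry, normalization,
ranking, and extraction accounting."""

import math

import numpy as np
import pandas as pd
import pytest

from netbackbone import experiments
from netbackbone.corrections import extract_backbone
from netbackbone.experiments import PValueCache
from netbackbone.filters import compute_pvalues
from netbackbone.synth import fixture, gen_heterogeneous

from conftest import random_network


@pytest.fixture(scope="module")
def nets():
    return [
        gen_heterogeneous(n=60, mean_degree=4.0, seed=s, weight_model="poisson_shifted")
        for s in (0, 1)
    ]


class TestSimilarity:
    def test_self_similarity_unit_diagonal(self, nets):
        mu, sigma, _ = experiments.similarity_study(nets, ["df", "mlf"])
        assert mu.loc["df", "df"] == pytest.approx(1.0)
        assert mu.loc["mlf", "mlf"] == pytest.approx(1.0)
        assert sigma.loc["df", "df"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_matrix(self, nets):
        mu, _, _ = experiments.similarity_study(nets, ["df", "lans", "mlf"])
        for a in mu.index:
            for b in mu.columns:
                assert mu.loc[a, b] == pytest.approx(mu.loc[b, a])

    def test_df_pf_strongly_similar_nulls(self):
        # at a=1 the Pólya null is the finite-strength analogue of the
        # disparity null, so their p-value rankings nearly coincide
        net = gen_heterogeneous(n=120, seed=5)
        mu, _, _ = experiments.similarity_study([net], ["df", "pf"])
        assert mu.loc["df", "pf"] >= 0.9

    def test_mean_and_population_sd_aggregation(self, nets):
        _, _, rec = experiments.similarity_study(nets, ["df", "mlf"])
        pair = rec[(rec.method_a == "df") & (rec.method_b == "mlf")]
        rs = pair.spearman.to_numpy()
        mu, sigma, _ = experiments.similarity_study(nets, ["df", "mlf"])
        assert mu.loc["df", "mlf"] == pytest.approx(rs.mean())
        assert sigma.loc["df", "mlf"] == pytest.approx(np.std(rs, ddof=0))


class TestOverlap:
    def test_identical_methods_full_overlap(self, nets):
        mu, _, _ = experiments.overlap_study(
            nets, ["mlf"], alpha=0.3, correction="none"
        )
        assert mu.loc["mlf", "mlf"] == pytest.approx(1.0)

    def test_containment_asymmetry_direct_sets(self, nets):
        # validate against direct set arithmetic per network
        cache = PValueCache()
        mu, _, rec = experiments.overlap_study(
            nets, ["df", "mlf"], alpha=0.1, correction="none", cache=cache
        )
        for net in nets:
            bbs = {
                m: extract_backbone(net, cache.get(net, m), 0.1, "none").edges
                for m in ("df", "mlf")
            }
            row = rec[
                (rec.network == net.name)
                & (rec.method_a == "df")
                & (rec.method_b == "mlf")
            ]
            if not bbs["df"]:
                assert row.empty
                continue
            expected = len(bbs["df"] & bbs["mlf"]) / len(bbs["df"])
            assert row.overlap.iloc[0] == pytest.approx(expected)


class TestLocalProperties:
    def test_gloss_marginal_perfectly_anticorrelated_with_weight(self):
        net = gen_heterogeneous(n=80, seed=3)
        cache = PValueCache(method_params={"gloss": {"mode": "marginal"}})
        rec = experiments.local_property_study(
            [net], ["gloss"], properties=("weight",), cache=cache
        )
        assert rec.spearman.iloc[0] == pytest.approx(-1.0)

    def test_constant_pvalues_recorded_missing(self):
        # equal-weight 4-cycle: every method's p-values are constant
        from netbackbone.graph import WeightedNetwork

        cyc = WeightedNetwork.from_edges(
            [("a", "b", 2), ("b", "c", 2), ("c", "d", 2), ("a", "d", 2)],
            name="cycle",
        )
        rec = experiments.local_property_study(
            [cyc], ["pf"], properties=("weight",)
        )
        assert math.isnan(rec.spearman.iloc[0])

    def test_df_negative_weight_correlation(self):
        net = gen_heterogeneous(n=200, seed=0)
        rec = experiments.local_property_study(
            [net], ["df"], properties=("weight",)
        )
        assert rec.spearman.iloc[0] <= -0.5


class TestGlobalProperties:
    def test_full_backbone_normalizes_to_one(self, nets):
        rec = experiments.global_property_study(
            nets[:1], ["lans"], alpha=0.9999999, corrections=("none",)
        )
        # at alpha ~ 1 LANS keeps every edge: all ratios 1
        vals = rec[rec.property != "components"].normalized
        assert all(v == pytest.approx(1.0) for v in vals.dropna())

    def test_empty_backbone_zero_fractions(self):
        tri = fixture("triangle_unit")
        rec = experiments.global_property_study(
            [tri], ["mlf"], alpha=0.05, corrections=("none",)
        )
        frac = rec[rec.property.isin(["edge_fraction", "node_fraction", "weight_fraction"])]
        assert all(v == 0.0 for v in frac.normalized)
        rest = rec[~rec.property.isin(["edge_fraction", "node_fraction", "weight_fraction"])]
        assert all(math.isnan(v) for v in rest.normalized)

    def test_lans_preserves_all_nodes(self, nets):
        rec = experiments.global_property_study(
            nets, ["lans"], alpha=0.05, corrections=("none",)
        )
        nf = rec[rec.property == "node_fraction"].normalized
        assert all(v == 1.0 for v in nf)

    def test_ccdf_is_proper_tail_function(self, nets):
        rec = experiments.global_property_study(
            nets, ["df", "mlf"], alpha=0.05, corrections=("none",)
        )
        ccdf = experiments.ccdf_table(rec)
        for _, group in ccdf.groupby(["method", "correction", "property"]):
            vals = group.sort_values("value")
            tf = vals.tail_fraction.to_numpy()
            assert tf[0] == pytest.approx(1.0)
            assert all(a >= b for a, b in zip(tf, tf[1:]))


class TestDistributionRanks:
    def test_ranks_are_average_tie_permutation(self):
        nets_big = [gen_heterogeneous(n=400, mean_degree=7.0, seed=s) for s in (0,)]
        rec = experiments.distribution_rank_study(
            nets_big, ["df", "mlf", "lans"], alpha=0.05, min_edges=500
        )
        for (_, _), group in rec.groupby(["network", "distribution"]):
            expected = group.ks.rank(method="average")
            assert np.allclose(group["rank"], expected)

    def test_small_networks_excluded(self):
        tri = fixture("triangle_unit")
        rec = experiments.distribution_rank_study(
            [tri], ["df"], min_edges=1000
        )
        assert rec.empty

    def test_full_backbone_has_rank_one(self):
        net = gen_heterogeneous(n=400, mean_degree=7.0, seed=2)
        rec = experiments.distribution_rank_study(
            net and [net], ["lans", "mlf"], alpha=0.999999, min_edges=100
        )
        # at alpha ~ 1 both methods keep everything: KS = 0, tied rank
        assert all(rec.ks == 0.0)
        assert all(rec["rank"] == 1.5)


class TestExtractionRates:
    def test_proper_backbone_accounting(self, nets):
        rates = experiments.extraction_rate_table(
            nets, ["mlf", "lans"], alpha=0.05, corrections=("none",)
        )
        assert set(rates.extraction_pct) <= {0.0, 50.0, 100.0}

    def test_keep_everything_counts_zero(self):
        # at alpha ~ 1 every method keeps all edges: not a proper backbone
        nets_ = [gen_heterogeneous(n=60, seed=4)]
        rates = experiments.extraction_rate_table(
            nets_, ["lans"], alpha=0.9999999, corrections=("none",)
        )
        assert rates.extraction_pct.iloc[0] == 0.0

    def test_failed_method_counts_against_rate(self):
        tri = fixture("triangle_unit")  # ecm saturates here
        good = gen_heterogeneous(
            n=30, mean_degree=4.0, weight_model="poisson_shifted", seed=0
        )
        rates = experiments.extraction_rate_table(
            [tri, good], ["ecm"], alpha=0.5, corrections=("none",)
        )
        assert rates.extraction_pct.iloc[0] <= 50.0
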