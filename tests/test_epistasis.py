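"""Epistasis scoring, calling, binning, and summary comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nudixmap.epistasis import (
    KnockdownPanel,
    bin_scores,
    build_network,
    call_interactions,
    canonical_pair,
    compare_bins,
    compute_epistasis,
    normalize_to_controls,
    overlap_counts,
    pairwise_spearman,
)


class TestNormalizeToControls:
    def test_per_batch_division(self):
        raw = pd.DataFrame(
            {
                "gene_a": ["control", "g1", "control", "g1"],
                "gene_b": ["", "", "", ""],
                "batch": [0, 0, 1, 1],
                "replicate_1": [2.0, 1.0, 4.0, 1.0],
                "replicate_2": [2.0, 1.0, 4.0, 1.0],
            }
        )
        panel = normalize_to_controls(raw)
        # same raw sample, controls 2.0 and 4.0 -> 0.5 and 0.25
        np.testing.assert_allclose(sorted(panel.single_viability["g1"]), [0.25, 0.25, 0.5, 0.5])
        assert abs(panel.control_viability.mean() - 1.0) < 1e-12

    def test_sample_equal_to_control_is_one(self):
        raw = pd.DataFrame(
            {
                "gene_a": ["control", "g1"],
                "gene_b": ["", ""],
                "replicate_1": [3.0, 3.0],
                "replicate_2": [3.0, 3.0],
            }
        )
        panel = normalize_to_controls(raw)
        np.testing.assert_allclose(panel.single_viability["g1"], 1.0)

    def test_nonpositive_control_names_batch(self):
        raw = pd.DataFrame(
            {
                "gene_a": ["control", "g1"],
                "gene_b": ["", ""],
                "batch": ["plateX", "plateX"],
                "replicate_1": [0.0, 1.0],
            }
        )
        with pytest.raises(ValueError, match="plateX"):
            normalize_to_controls(raw)


class TestComputeEpistasis:
    @pytest.mark.parametrize(
        "w_a,w_b,w_ab,expected_e,expected_eps",
        [
            (0.8, 0.5, 0.4, 0.40, 0.0),
            (1.0, 1.0, 0.7, 1.00, -0.30),
            (0.9, 0.9, 0.95, 0.81, 0.14),
        ],
    )
    def test_multiplicative_null_arithmetic(self, w_a, w_b, w_ab, expected_e, expected_eps):
        panel = KnockdownPanel(
            genes=["a", "b"],
            single_viability={"a": np.array([w_a] * 2), "b": np.array([w_b] * 2)},
            double_viability={("a", "b"): np.array([w_ab] * 2)},
        )
        res = compute_epistasis(panel)
        assert res.expected[("a", "b")] == pytest.approx(expected_e)
        assert res.epsilon[("a", "b")] == pytest.approx(expected_eps)

    def test_symmetric_in_gene_order(self, planted_panel):
        panel, _ = planted_panel
        res = compute_epistasis(panel)
        for (a, b) in list(panel.double_viability)[:20]:
            assert canonical_pair(b, a) == (a, b)
            assert res.epsilon[(a, b)] == res.epsilon[canonical_pair(b, a)]

    def test_missing_single_raises(self):
        with pytest.raises(ValueError, match="missing|without"):
            KnockdownPanel(
                genes=["a", "b"],
                single_viability={"a": np.array([0.8, 0.8])},
                double_viability={("a", "b"): np.array([0.4, 0.4])},
            )


class TestZTestCaller:
    def test_zero_difference_gives_no_call(self, tiny_panel):
        res = call_interactions(compute_epistasis(tiny_panel), tiny_panel, alpha=0.05, var_mode="per-pair")
        pair = ("a", "b")  # W_ab = 0.40 = 0.8*0.5 exactly, zero variance
        assert res.epsilon[pair] == 0.0
        assert res.call[pair] == "none"

    def test_against_direct_formula_oracle(self):
        # doubles (0.40, 0.42, 0.38) vs expected 0.8*0.9 = 0.72 with exact singles
        panel = KnockdownPanel(
            genes=["a", "b"],
            single_viability={"a": np.array([0.8, 0.8, 0.8]), "b": np.array([0.9, 0.9, 0.9])},
            double_viability={("a", "b"): np.array([0.40, 0.42, 0.38])},
        )
        res = call_interactions(compute_epistasis(panel), panel, alpha=0.05, var_mode="per-pair")
        # oracle: difference 0.40 - 0.72; only the double contributes variance
        se = np.sqrt(np.var([0.40, 0.42, 0.38], ddof=1) / 3)
        z_expect = (0.40 - 0.72) / se
        p_expect = 2 * stats.norm.sf(abs(z_expect))
        assert res.z[("a", "b")] == pytest.approx(z_expect)
        assert res.z[("a", "b")] == pytest.approx(-27.7128, abs=1e-3)
        assert res.p[("a", "b")] == pytest.approx(p_expect)
        assert res.call[("a", "b")] == "aggravating"

    def test_degenerate_zero_variance_flagged(self):
        panel = KnockdownPanel(
            genes=["a", "b"],
            single_viability={"a": np.array([0.8, 0.8]), "b": np.array([0.9, 0.9])},
            double_viability={("a", "b"): np.array([0.5, 0.5])},
        )
        res = call_interactions(compute_epistasis(panel), panel, var_mode="per-pair")
        assert ("a", "b") in res.degenerate
        assert res.call[("a", "b")] == "aggravating"  # called by sign, not by infinite z

    def test_calibration_converges_to_alpha(self):
        # averaged over three independent 1,000-pair null screens to tighten
        # the Monte-Carlo error on the empirical rate
        from nudixmap.simulate import GeneratorConfig, gen_null_pair_panel

        rates05, rates10 = [], []
        for seed in (0, 1, 2):
            panel = gen_null_pair_panel(1000, GeneratorConfig(seed=seed))
            res = compute_epistasis(panel)
            rates05.append(len(call_interactions(res, panel, alpha=0.05).significant_pairs()) / 1000)
            rates10.append(len(call_interactions(res, panel, alpha=0.10).significant_pairs()) / 1000)
        assert abs(np.mean(rates05) - 0.05) <= 0.015
        assert abs(np.mean(rates10) - 0.10) <= 0.020


class TestDensityCaller:
    def test_matches_brute_force_percentiles(self):
        rng = np.random.default_rng(11)
        eps = rng.standard_normal(100)
        genes = [f"g{i}" for i in range(101)]
        pairs = [canonical_pair(genes[i], genes[i + 1]) for i in range(100)]
        panel_like = type("R", (), {})  # density mode needs no panel
        from nudixmap.epistasis import EpistasisResult

        res = EpistasisResult(expected={p: 0.0 for p in pairs}, epsilon=dict(zip(pairs, eps)))
        called = call_interactions(res, alpha=0.1, method="density", coverage=0.90)
        lo, hi = np.percentile(eps, [5, 95], method="midpoint")
        expected_sig = {p for p, e in zip(pairs, eps) if e < lo or e > hi}
        assert called.significant_pairs() == expected_sig

    def test_coverage_fraction(self):
        from nudixmap.simulate import GeneratorConfig, gen_null_pair_panel

        panel = gen_null_pair_panel(2000, GeneratorConfig(seed=5))
        res = call_interactions(compute_epistasis(panel), panel, method="density", coverage=0.90)
        inside = 1 - len(res.significant_pairs()) / 2000
        assert inside == pytest.approx(0.90, abs=0.01)

    def test_needs_enough_pairs(self, tiny_panel):
        with pytest.raises(ValueError, match="20"):
            call_interactions(compute_epistasis(tiny_panel), method="density")


class TestNullAndPower:
    def test_exact_null_all_zero(self, null_panel_clean):
        panel, _ = null_panel_clean
        res = compute_epistasis(panel)
        assert all(e == 0.0 for e in res.epsilon.values())
        for alpha in (0.05, 0.1):
            called = call_interactions(res, panel, alpha=alpha)
            assert not called.significant_pairs()

    def test_planted_recovery_and_sign(self, planted_panel):
        from nudixmap.simulate import precision_recall

        panel, truth = planted_panel
        called = call_interactions(compute_epistasis(panel), panel, alpha=0.05)
        _, recall = precision_recall(truth, called.significant_pairs())
        assert recall >= 0.9
        for pair in called.significant_pairs() & truth.planted_pairs:
            assert called.call[pair] == truth.planted_sign(pair)


class TestBinsAndSummaries:
    def _result_with_eps(self, eps_values):
        from nudixmap.epistasis import EpistasisResult

        pairs = [canonical_pair(f"g{i}", f"h{i}") for i in range(len(eps_values))]
        return EpistasisResult(expected={p: 0 for p in pairs}, epsilon=dict(zip(pairs, eps_values))), pairs

    def test_equal_width_edges(self):
        res, _ = self._result_with_eps(np.linspace(-0.5, 0.5, 11))
        bins = bin_scores(res, n_bins=5)
        np.testing.assert_allclose(bins.edges[1:-1], [-0.3, -0.1, 0.1, 0.3])

    def test_boundary_rule(self):
        res, pairs = self._result_with_eps([-0.5, -0.3, 0.5])
        bins = bin_scores(res, n_bins=5)
        assert bins.labels[pairs[0]] == 1  # minimum in bin 1
        assert bins.labels[pairs[1]] == 1  # interior edge is right-inclusive
        assert bins.labels[pairs[2]] == 5  # maximum in last bin

    def test_partition_sums(self):
        res, _ = self._result_with_eps(np.random.default_rng(0).uniform(-1, 1, 10))
        bins = bin_scores(res, n_bins=5)
        assert len(bins.labels) == 10

    def test_compare_bins_quartiles(self):
        res, pairs = self._result_with_eps([-0.4, -0.35, -0.3, 0.4])
        bins = bin_scores(res, n_bins=2)
        summary = compare_bins(bins, {pairs[0]: 1.0, pairs[1]: 2.0, pairs[2]: 3.0, pairs[3]: 9.0})
        row = summary.loc[1]
        assert row["median"] == 2.0
        assert row["q1"] == 1.5 and row["q3"] == 2.5  # linear-interpolation quartile rule
        assert row["n"] == 3

    def test_monotone_covariate_gives_monotone_medians(self):
        eps = np.linspace(-0.5, 0.5, 40)
        res, pairs = self._result_with_eps(eps)
        bins = bin_scores(res, n_bins=5)
        summary = compare_bins(bins, {p: 2 * e + 3 for p, e in zip(pairs, eps)})
        med = summary["median"].to_numpy()
        assert np.all(np.diff(med) > 0)


class TestSpearmanAndVenn:
    def test_self_and_negation(self):
        from nudixmap.epistasis import EpistasisResult

        pairs = [canonical_pair(f"g{i}", f"h{i}") for i in range(30)]
        eps = np.random.default_rng(2).normal(size=30)
        r1 = EpistasisResult(expected={}, epsilon=dict(zip(pairs, eps)))
        r2 = EpistasisResult(expected={}, epsilon=dict(zip(pairs, -eps)))
        mat = pairwise_spearman({"x": r1, "y": r2, "x2": r1})
        assert mat.loc["x", "x"] == 1.0
        assert mat.loc["x", "x2"] == pytest.approx(1.0)
        assert mat.loc["x", "y"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        from nudixmap.epistasis import EpistasisResult

        rng = np.random.default_rng(8)
        pairs = [canonical_pair(f"g{i}", f"h{i}") for i in range(50)]
        x = rng.normal(size=50)
        y = np.tanh(x) + 0.3 * rng.normal(size=50)
        mat = pairwise_spearman(
            {
                "x": EpistasisResult(expected={}, epsilon=dict(zip(pairs, x))),
                "y": EpistasisResult(expected={}, epsilon=dict(zip(pairs, y))),
            }
        )
        rank_x = stats.rankdata(x)
        rank_y = stats.rankdata(y)
        oracle = np.corrcoef(rank_x, rank_y)[0, 1]
        assert mat.loc["x", "y"] == pytest.approx(oracle, abs=1e-12)

    def test_venn_small_cases(self):
        counts = overlap_counts({"L1": {"AB", "BC"}, "L2": {"BC", "CD"}})
        assert counts[("L1", "L2")] == 1
        assert counts[("L1",)] == 1 and counts[("L2",)] == 1

    def test_venn_triple_identical(self):
        s = {"p1", "p2", "p3", "p4"}
        counts = overlap_counts({"a": set(s), "b": set(s), "c": set(s)})
        assert counts[("a", "b", "c")] == 4
        assert all(v == 0 for k, v in counts.items() if k != ("a", "b", "c"))

    def test_venn_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        universe = [f"p{i}" for i in range(40)]
        sets = {name: {p for p in universe if rng.random() < 0.4} for name in "ABC"}
        counts = overlap_counts(sets)
        for members, count in counts.items():
            expected = sum(
                1
                for p in universe
                if all(p in sets[m] for m in members) and all(p not in sets[m] for m in sets if m not in members)
            )
            assert count == expected


class TestNetworkExport:
    def test_tiers_nested_and_signed(self, planted_panel):
        panel, _ = planted_panel
        res = compute_epistasis(panel)
        strict = call_interactions(res, panel, alpha=0.05)
        loose = call_interactions(res, panel, alpha=0.10)
        net = build_network(strict, loose, nodes=panel.genes)
        frame = net.to_frame()
        strict_edges = set(map(tuple, frame.loc[frame.tier == "strict", ["gene_a", "gene_b"]].to_numpy()))
        all_edges = set(map(tuple, frame[["gene_a", "gene_b"]].to_numpy()))
        assert strict_edges <= all_edges
        assert strict_edges == strict.significant_pairs()
        assert all_edges == loose.significant_pairs() | strict.significant_pairs()
        for _, row in frame.iterrows():
            assert row["sign"] == ("-" if row["weight"] < 0 else "+")

    def test_empty_network_keeps_nodes(self, null_panel_clean):
        panel, _ = null_panel_clean
        res = call_interactions(compute_epistasis(panel), panel, alpha=0.05)
        net = build_network(res, res, nodes=panel.genes)
        assert net.edges == []
        assert net.nodes == panel.genes
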