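"""Correlation-change test, differential network construction, export."""

import numpy as np
import pandas as pd
import pytest

from diffcornet import (
    PlantedChange,
    build_differential_network,
    correlation_change_test,
    display_width,
    export_network,
    get_partition,
    ground_truth_edges,
    pairwise_correlations,
    simulate_table,
)
from diffcornet.diffnet import read_edge_csv
from diffcornet.errors import DataValidationError, SaturatedCorrelationError
from diffcornet.synthetic import DesignCell, SyntheticSpec, two_group_design

from conftest import make_table


class TestChangeTest:
    def test_no_change_gives_q_zero_p_one(self):
        q, p = correlation_change_test(0.4, 25, 0.4, 250)
        assert q == 0.0
        assert p == 1.0

    def test_hand_computed_oracle(self):
        # q = (atanh(0.8) - atanh(0.2)) / sqrt(2/37)
        q, p = correlation_change_test(0.2, 40, 0.8, 40)
        expect_q = (np.arctanh(0.8) - np.arctanh(0.2)) / np.sqrt(2.0 / 37.0)
        assert q == pytest.approx(expect_q, abs=1e-12)
        assert q == pytest.approx(3.853, abs=1e-3)
        assert p == pytest.approx(1.17e-4, rel=1e-2)

    def test_subset_swap_negates_q_keeps_p(self):
        q1, p1 = correlation_change_test(0.2, 40, 0.8, 40)
        q2, p2 = correlation_change_test(0.8, 40, 0.2, 40)
        assert q2 == pytest.approx(-q1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-15)

    def test_small_n_rejected(self):
        with pytest.raises(DataValidationError, match="n > 3"):
            correlation_change_test(0.2, 3, 0.8, 40)

    def test_saturated_r_rejected(self):
        with pytest.raises(SaturatedCorrelationError):
            correlation_change_test(1.0, 40, 0.5, 40)


class TestDisplayWidth:
    @pytest.mark.parametrize(
        "mag,expect",
        [(0.1, 1.0), (0.7, 7.0), (0.4, 4.0), (0.0, 1.0), (2.0, 7.0)],
    )
    def test_anchors_midpoint_and_clamping(self, mag, expect):
        assert display_width(mag) == pytest.approx(expect, abs=1e-12)

    def test_monotone_non_decreasing(self):
        mags = np.linspace(0, 1.5, 200)
        widths = display_width(mags)
        assert np.all(np.diff(widths) >= 0)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            display_width(-0.1)


def _planted_two_group_spec(seed=0, n=100, k=20, delta_pairs=None):
    mets = tuple(f"M{i:02d}" for i in range(k))
    planted = tuple(
        PlantedChange(pair, r_a, r_b, "polyamine")
        for pair, r_a, r_b in (delta_pairs or [])
    )
    return SyntheticSpec(
        metabolites=mets, groups={m: "other" for m in mets},
        design=tuple(two_group_design(n, n)),
        base_correlation=np.eye(k), planted=planted, seed=seed,
    )


def _two_sets(table, n_min=4):
    scheme = get_partition("polyamine")
    ids_a, ids_b = scheme.apply(table)
    return (
        pairwise_correlations(table, ids_a, label="low", n_min=n_min),
        pairwise_correlations(table, ids_b, label="high", n_min=n_min),
    )


class TestBuildNetwork:
    def test_identical_subsets_give_zero_edges(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.normal(size=(30, 4)), [f"M{i}" for i in range(4)])
        cs = pairwise_correlations(t, t.sample_ids, label="same")
        net = build_differential_network(cs, cs)
        assert net.edges == []
        assert net.n_tested == len(cs.pairs)

    def test_planted_changes_recovered_false_positives_bounded(self):
        delta = [(("M00", "M01"), 0.1, 0.7),
                 (("M02", "M03"), -0.2, 0.4),
                 (("M04", "M05"), 0.2, 0.8)]
        spec = _planted_two_group_spec(seed=17, delta_pairs=delta)
        table = simulate_table(spec)
        set_a, set_b = _two_sets(table)
        net = build_differential_network(set_a, set_b, partition="polyamine")
        found = {e.pair for e in net.edges}
        truth = {ch.pair for ch in ground_truth_edges(spec, "polyamine")}
        assert truth <= found
        # 187 null pairs at alpha = 0.05: binomial 99% interval
        from scipy.stats import binom

        fp = len(found - truth)
        assert binom.ppf(0.005, 187, 0.05) <= fp <= binom.ppf(0.995, 187, 0.05)

    def test_bh_edge_set_is_subset_of_raw(self):
        spec = _planted_two_group_spec(
            seed=21, delta_pairs=[(("M00", "M01"), 0.1, 0.7)]
        )
        table = simulate_table(spec)
        set_a, set_b = _two_sets(table)
        raw = build_differential_network(set_a, set_b, multiplicity="none")
        bh = build_differential_network(set_a, set_b, multiplicity="bh")
        assert {e.pair for e in bh.edges} <= {e.pair for e in raw.edges}

    def test_reversed_subsets_flip_every_direction(self):
        spec = _planted_two_group_spec(
            seed=29, delta_pairs=[(("M00", "M01"), 0.1, 0.7),
                                  (("M02", "M03"), 0.6, -0.1)]
        )
        table = simulate_table(spec)
        set_a, set_b = _two_sets(table)
        fwd = build_differential_network(set_a, set_b)
        rev = build_differential_network(set_b, set_a)
        assert {e.pair for e in fwd.edges} == {e.pair for e in rev.edges}
        rev_by_pair = {e.pair: e for e in rev.edges}
        for e in fwd.edges:
            o = rev_by_pair[e.pair]
            assert o.delta_z == pytest.approx(-e.delta_z, abs=1e-12)
            assert {e.direction, o.direction} == {"increase", "decrease"}

    def test_column_and_row_order_invariance(self):
        spec = _planted_two_group_spec(
            seed=31, k=6, delta_pairs=[(("M00", "M01"), 0.1, 0.7)]
        )
        table = simulate_table(spec)
        set_a, set_b = _two_sets(table)
        base = build_differential_network(set_a, set_b)
        rng = np.random.default_rng(0)
        cols = list(table.values.columns)
        rows = list(table.values.index)
        rng.shuffle(cols)
        rng.shuffle(rows)
        from diffcornet import MetaboliteTable

        shuffled = MetaboliteTable(
            table.values.loc[rows, cols], table.factors.loc[rows],
            table.registry, table.factor_registry,
        )
        set_a2, set_b2 = _two_sets(shuffled)
        other = build_differential_network(set_a2, set_b2)
        assert [e.pair for e in base.edges] == [e.pair for e in other.edges]
        np.testing.assert_allclose(
            [e.q for e in base.edges], [e.q for e in other.edges], atol=1e-12
        )

    def test_mismatched_rosters_rejected(self):
        rng = np.random.default_rng(1)
        t1 = make_table(rng.normal(size=(20, 3)), ["M0", "M1", "M2"])
        t2 = make_table(rng.normal(size=(20, 3)), ["M0", "M1", "M9"])
        cs1 = pairwise_correlations(t1, t1.sample_ids)
        cs2 = pairwise_correlations(t2, t2.sample_ids)
        with pytest.raises(DataValidationError, match="roster"):
            build_differential_network(cs1, cs2)

    def test_pairs_missing_from_one_subset_are_skipped(self):
        rng = np.random.default_rng(2)
        vals_a = rng.normal(size=(20, 3))
        vals_b = rng.normal(size=(20, 3))
        vals_b[:, 2] = 5.0  # constant in subset B: pair excluded there
        t = make_table(
            np.vstack([vals_a, vals_b]), ["M0", "M1", "M2"],
            genotypes=["2"] * 20 + ["8"] * 20,
        )
        set_a, set_b = _two_sets(t)
        net = build_differential_network(set_a, set_b)
        tested = {tuple(p) for p, _ in net.skipped}
        assert ("M0", "M2") in tested and ("M1", "M2") in tested
        assert net.n_tested == 1


class TestExport:
    def _net(self, seed=37):
        spec = _planted_two_group_spec(
            seed=seed, k=8,
            delta_pairs=[(("M00", "M01"), 0.1, 0.7), (("M02", "M03"), 0.7, 0.1)],
        )
        table = simulate_table(spec)
        set_a, set_b = _two_sets(table)
        return build_differential_network(set_a, set_b, partition="polyamine")

    def test_empty_network_writes_header_only(self, tmp_path):
        rng = np.random.default_rng(3)
        t = make_table(rng.normal(size=(25, 3)), ["M0", "M1", "M2"])
        cs = pairwise_correlations(t, t.sample_ids)
        net = build_differential_network(cs, cs)
        path = export_network(net, tmp_path / "empty.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("source,target,r_a,r_b,delta_r,delta_z")

    def test_edge_csv_round_trip_and_width_consistency(self, tmp_path):
        net = self._net()
        assert len(net.edges) >= 2
        path = export_network(net, tmp_path / "edges.csv")
        back = read_edge_csv(path)
        assert len(back) == len(net.edges)
        for _, row in back.iterrows():
            assert row["width"] == pytest.approx(
                display_width(abs(row["delta_r"])), abs=1e-9
            )
            expect_color = "blue" if row["direction"] == "increase" else "red"
            assert row["color"] == expect_color

    def test_swap_colors_flag(self, tmp_path):
        net = self._net()
        path = export_network(net, tmp_path / "sw.csv", swap_colors=True)
        back = read_edge_csv(path)
        inc = back[back["direction"] == "increase"]
        assert (inc["color"] == "red").all()

    def test_byte_identical_re_export(self, tmp_path):
        net = self._net()
        p1 = export_network(net, tmp_path / "a.csv")
        p2 = export_network(net, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_graphml_carries_attributes(self, tmp_path):
        import networkx as nx

        net = self._net()
        path = export_network(net, tmp_path / "net.graphml", format="graphml")
        g = nx.read_graphml(path)
        assert g.number_of_edges() == len(net.edges)
        edge = next(iter(g.edges(data=True)))[2]
        assert {"delta_z", "p", "direction", "color", "width"} <= set(edge)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(DataValidationError, match="format"):
            export_network(self._net(), tmp_path / "x.bin", format="edgelist")


def test_null_rejection_rate_and_p_uniformity():
    """Type-I calibration: empirical size near alpha, p-values uniform."""
    from scipy.stats import kstest

    from diffcornet.calibration import null_rejection_simulation

    sim = null_rejection_simulation(rho=0.3, n=40, reps=2000, seed=12345)
    assert 0.038 <= sim["rejection_rate"] <= 0.063
    assert kstest(sim["p_values"], "uniform").pvalue > 0.01


def test_power_matches_normal_approximation():
    """Power at (0.2 vs 0.8, n=40) matches the closed form within 3 MC SE."""
    from diffcornet import change_test_power
    from diffcornet.calibration import power_simulation

    theory = change_test_power(0.2, 40, 0.8, 40)
    assert theory == pytest.approx(0.971, abs=5e-4)
    sim = power_simulation(0.2, 0.8, n=40, reps=1000, seed=54321)
    assert sim["rejection_rate"] == pytest.approx(theory, abs=3 * max(sim["mc_se"], 1e-3))
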