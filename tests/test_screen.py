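"""Screen scoring: normalization, Z-scores, hit calling, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resistkit import screen
from resistkit.screen import (
    ScreenStats,
    aggregate_gene,
    call_hits,
    enrich,
    intersect_gene_lists,
    normalize_wells,
    score_screen,
    sirna_log2_ratio,
    zscore,
)


def make_wells(rows):
    return pd.DataFrame(rows, columns=["plate", "well", "arm", "sirna_id", "signal", "is_control"])


class TestNormalization:
    def test_wells_equal_to_control_median_normalize_to_one(self):
        wells = make_wells(
            [
                ("P1", "A01", "drug", "", 200.0, True),
                ("P1", "A02", "drug", "s1", 200.0, False),
                ("P1", "A03", "drug", "s2", 200.0, False),
            ]
        )
        out = normalize_wells(wells)
        assert np.allclose(out["norm"], 1.0)

    def test_scale_invariance_within_plate(self):
        base = make_wells(
            [
                ("P1", "A01", "drug", "", 100.0, True),
                ("P1", "A02", "drug", "s1", 150.0, False),
                ("P1", "A03", "drug", "s2", 50.0, False),
            ]
        )
        doubled = base.assign(signal=base["signal"] * 2)
        assert np.allclose(normalize_wells(base)["norm"], normalize_wells(doubled)["norm"])

    def test_two_plate_batch_effect_removed(self):
        # plate P2 carries a 2x multiplicative effect on every well;
        # oracle: fraction-of-control is 1.5 and 0.5 on both plates
        rows = []
        for plate, factor in (("P1", 1.0), ("P2", 2.0)):
            rows += [
                (plate, "A01", "drug", "", 100.0 * factor, True),
                (plate, "A02", "drug", "hi", 150.0 * factor, False),
                (plate, "A03", "drug", "lo", 50.0 * factor, False),
            ]
        out = normalize_wells(make_wells(rows))
        samples = out[~out["is_control"]].set_index(["plate", "sirna_id"])["norm"]
        for plate in ("P1", "P2"):
            assert samples[(plate, "hi")] == pytest.approx(1.5)
            assert samples[(plate, "lo")] == pytest.approx(0.5)

    def test_missing_controls_error_names_plate(self):
        wells = make_wells(
            [
                ("P1", "A01", "drug", "", 100.0, True),
                ("P1", "A02", "drug", "s1", 80.0, False),
                ("P7", "A02", "drug", "s2", 80.0, False),
            ]
        )
        with pytest.raises(ValueError, match="P7"):
            normalize_wells(wells)


class TestExperimentalValue:
    def make_norm(self, drug, vehicle):
        wells = make_wells(
            [
                ("P1", "A01", "drug", "", 100.0, True),
                ("P1", "A01", "vehicle", "", 100.0, True),
                ("P1", "A02", "drug", "s1", drug, False),
                ("P1", "A02", "vehicle", "s1", vehicle, False),
            ]
        )
        return normalize_wells(wells)

    def test_equal_arms_give_zero(self):
        x = sirna_log2_ratio(self.make_norm(80.0, 80.0))
        assert x["s1"] == pytest.approx(0.0)

    def test_quarter_viability_gives_minus_two(self):
        x = sirna_log2_ratio(self.make_norm(20.0, 80.0))
        assert x["s1"] == pytest.approx(-2.0)

    def test_zero_vehicle_excluded_not_crashed(self, caplog):
        with caplog.at_level("WARNING", logger="resistkit.screen"):
            x = sirna_log2_ratio(self.make_norm(20.0, 0.0))
        assert "s1" not in x.index
        assert "excluded 1" in caplog.text

    def test_planted_sensitizer_effect_recovered_in_x(self):
        """Mean ratio-mode x of planted sensitizers matches the planted effect."""
        from resistkit.simulate import ScreenSimConfig, simulate_screen

        cfg = ScreenSimConfig(
            n_genes=200, n_sensitizers=20, sensitizer_effect=-3.0, noise_sd=0.3, seed=1
        )
        design, wells, truth = simulate_screen(cfg)
        x = sirna_log2_ratio(normalize_wells(wells), mode="ratio")
        genes = design.set_index("sirna_id")["gene_id"]
        sens = {g for g, l in truth.true_hit_labels.items() if l == "sensitizer"}
        mean_x = x[genes.reindex(x.index).isin(sens).to_numpy()].mean()
        assert mean_x == pytest.approx(-3.0, abs=0.15)


class TestZScore:
    def test_median_value_scores_zero(self):
        z, stats = zscore(pd.Series([1.0, 2, 3, 4, 5]))
        assert z.iloc[2] == 0.0
        assert stats.mu == 3.0

    def test_extreme_value_matches_brute_force_sd(self):
        vals = [1.0, 2, 3, 4, 5]
        # brute-force sample sd
        mean = sum(vals) / 5
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 4)
        z, _ = zscore(pd.Series(vals))
        assert z.iloc[4] == pytest.approx((5 - 3) / sd)

    def test_location_shift_invariance(self, rng):
        vals = pd.Series(rng.normal(size=50))
        z1, _ = zscore(vals)
        z2, _ = zscore(vals + 17.3)
        assert np.allclose(z1, z2)

    def test_median_of_scores_is_exactly_zero(self, rng):
        z, _ = zscore(pd.Series(rng.normal(size=101)))
        assert float(z.median()) == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="sigma|identical"):
            zscore(pd.Series([2.0, 2.0, 2.0]))
        with pytest.raises(ValueError, match=">= 3"):
            zscore(pd.Series([1.0, 2.0]))
        with pytest.raises(ValueError):
            ScreenStats(mu=0.0, sigma=0.0)


class TestGeneAggregation:
    design = pd.DataFrame(
        {
            "gene_id": ["gA", "gA", "gA", "gB"],
            "sirna_id": ["a1", "a2", "a3", "b1"],
            "plate": "P1",
            "well": ["A01", "A02", "A03", "A04"],
        }
    )

    def test_median_of_three(self):
        vals = pd.Series({"a1": -4.0, "a2": -4.0, "a3": 0.0, "b1": 1.0})
        out = aggregate_gene(vals, self.design)
        assert out["gA"] == -4.0

    def test_single_sirna_passes_through(self):
        vals = pd.Series({"a1": -4.0, "a2": -4.0, "a3": 0.0, "b1": 1.25})
        for method in ("median", "mean", "second_best"):
            assert aggregate_gene(vals, self.design, method)["gB"] == 1.25

    def test_unknown_method_rejected(self):
        vals = pd.Series({"a1": 0.0, "a2": 0.0, "a3": 0.0, "b1": 0.0})
        with pytest.raises(ValueError, match="unknown aggregation"):
            aggregate_gene(vals, self.design, "best")

    def test_unmapped_sirna_rejected(self):
        with pytest.raises(ValueError, match="missing from design"):
            aggregate_gene(pd.Series({"zz": 1.0}), self.design)


class TestHitCalling:
    def scores(self, zs):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(zs))], "z": zs})

    def test_threshold_is_inclusive(self):
        sens, res = call_hits(self.scores([2.5, -2.5, 0.0]))
        assert sens == ["g0"] and res == ["g1"]

    def test_all_interior_gives_empty_lists(self):
        sens, res = call_hits(self.scores([2.49, -2.49, 1.0]))
        assert sens == [] and res == []

    def test_partition_into_three_classes(self, small_screen):
        _, design, wells, _ = small_screen
        scored = score_screen(wells, design)
        sens, res = call_hits(scored)
        neutral = scored[scored["hit_class"] == "neutral"]
        assert len(sens) + len(res) + len(neutral) == len(scored)
        assert set(sens) == set(scored.loc[scored["hit_class"] == "sensitive", "gene_id"])

    @given(st.floats(min_value=2.5, max_value=6.0))
    @settings(max_examples=25, deadline=None)
    def test_hit_calling_monotone_in_threshold(self, thr):
        """Raising the threshold never adds hits."""
        zs = list(np.linspace(-5, 5, 41))
        base_s, base_r = call_hits(self.scores(zs), threshold=2.5)
        s, r = call_hits(self.scores(zs), threshold=thr)
        assert set(s) <= set(base_s) and set(r) <= set(base_r)

    def test_planted_hits_rank_in_extreme_tail(self, small_screen):
        _, design, wells, truth = small_screen
        scored = score_screen(wells, design)
        top = scored.head(5)["gene_id"]  # sorted by z descending
        assert all(truth.true_hit_labels[g] == "sensitizer" for g in top)
        bottom = scored.tail(5)["gene_id"]
        assert all(truth.true_hit_labels[g] == "resistor" for g in bottom)


def enumeration_pvalue(universe, gene_set, hits):
    """Exhaustive oracle: P(overlap >= observed) over all hit subsets."""
    k_obs = len(set(hits) & set(gene_set))
    n = len(hits)
    total = 0
    extreme = 0
    for combo in itertools.combinations(sorted(universe), n):
        total += 1
        if len(set(combo) & set(gene_set)) >= k_obs:
            extreme += 1
    return extreme / total


class TestEnrichment:
    def test_exact_three_of_three_in_set(self):
        universe = [f"g{i}" for i in range(10)]
        sets = {"S": universe[:5]}
        res = enrich(universe[:3], sets, universe)
        expected = math.comb(5, 3) / math.comb(10, 3)
        assert res.loc[0, "p_value"] == pytest.approx(expected)

    def test_hit_list_equal_to_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        res = enrich(universe, {"S": universe[:4]}, universe)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_set_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = enrich(universe[:3], {"S": universe[5:]}, universe)
        assert res.loc[0, "n_hits_in_set"] == 0
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_small_universes(self, rng):
        for trial in range(10):
            m = int(rng.integers(6, 13))
            universe = [f"g{i}" for i in range(m)]
            set_size = int(rng.integers(1, m))
            n_hits = int(rng.integers(1, min(m, 6)))
            gene_set = list(rng.choice(universe, size=set_size, replace=False))
            hits = list(rng.choice(universe, size=n_hits, replace=False))
            res = enrich(hits, {"S": gene_set}, universe)
            assert res.loc[0, "p_value"] == pytest.approx(
                enumeration_pvalue(universe, gene_set, hits)
            )

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            enrich([], {"S": ["a"]}, ["a", "b"])
        with pytest.raises(ValueError):
            enrich(["a"], {"S": ["a"]}, [])
        with pytest.raises(ValueError, match="not in universe"):
            enrich(["zz"], {"S": ["a"]}, ["a", "b"])


class TestIntersection:
    def test_three_way_example(self):
        assert intersect_gene_lists(["A", "B", "C"], ["B", "C", "D"], ["C", "B"]) == ["B", "C"]

    def test_any_empty_list_gives_empty(self):
        assert intersect_gene_lists(["A", "B"], []) == []

    def test_matches_brute_force_scan(self, rng):
        pool = [f"g{i}" for i in range(30)]
        for _ in range(10):
            lists = [
                list(rng.choice(pool, size=int(rng.integers(1, 20)), replace=False))
                for _ in range(3)
            ]
            oracle = [g for g in dict.fromkeys(lists[0]) if all(g in l for l in lists[1:])]
            assert intersect_gene_lists(*lists) == oracle
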