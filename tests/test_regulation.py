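"""The z-score decision rule: transforms, statistics, classification, combination."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silacdiff import (
    Direction,
    ProteinRecord,
    QuantTable,
    Thresholds,
    Tier,
    classify_protein,
    combine_replicates,
    log2_ratios,
    population_stats,
    rank_top,
    score_replicate,
    z_scores,
)
from silacdiff.errors import DegeneratePopulationError, InputError


def make_table(ratios, prefix="P"):
    records = [
        ProteinRecord(f"{prefix}{i:04d}", f"g{i}", "", float(r))
        for i, r in enumerate(ratios, start=1)
    ]
    return QuantTable(records=records, comparison="X H/M", replicate="r1",
                      channel_scheme="heavy_over_medium")


class TestLog2Ratios:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (1.0, 0.0),
            # the most extreme up- and down-validated ratios of the study design
            (171.5, math.log2(171.5)),   # ≈ 7.422
            (0.52, math.log2(0.52)),     # ≈ -0.943
        ],
    )
    def test_matches_direct_arithmetic(self, ratio, expected):
        lr = log2_ratios(make_table([ratio, 2.0]))
        assert lr.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_extreme_ratio_values(self):
        lr = log2_ratios(make_table([171.5, 0.52]))
        assert lr.iloc[0] == pytest.approx(7.422, abs=5e-4)
        assert lr.iloc[1] == pytest.approx(-0.943, abs=5e-4)

    def test_unfiltered_table_rejected(self, small_table):
        with pytest.raises(InputError, match="P00006"):
            log2_ratios(small_table)


class TestPopulationStats:
    def test_constant_population(self):
        s = population_stats(np.zeros(4))
        assert (s.mean_log2, s.sd_log2, s.n) == (0.0, 0.0, 4)

    def test_hand_computed_example(self):
        # sum of squared deviations 12.8 over n-1 = 4
        s = population_stats(np.array([0.0, 0.0, 0.0, 0.0, 4.0]))
        assert s.mean_log2 == pytest.approx(0.8)
        assert s.sd_log2 == pytest.approx(math.sqrt(12.8 / 4), abs=1e-12)
        assert s.sd_log2 == pytest.approx(1.78885, abs=1e-5)

    def test_mean_is_log2_of_geometric_mean(self):
        ratios = np.array([0.5, 1.0, 2.0, 171.5])
        s = population_stats(np.log2(ratios))
        gm = float(np.prod(ratios) ** (1 / len(ratios)))
        assert s.geometric_mean_ratio == pytest.approx(gm, rel=1e-12)

    def test_too_few_values(self):
        with pytest.raises(InputError):
            population_stats(np.array([1.0]))


class TestZScores:
    def test_centering_and_derived_example(self):
        lr = pd.Series([0.0, 0.0, 0.0, 0.0, 4.0],
                       index=[f"P{i}" for i in range(5)], name="log2_ratio")
        stats = population_stats(lr)
        z = z_scores(lr, stats)["z"]
        # (4 - 0.8) / 1.78885 from hand arithmetic
        assert z.iloc[4] == pytest.approx(3.2 / math.sqrt(12.8 / 4), abs=1e-12)
        assert z.iloc[4] == pytest.approx(1.7889, abs=1e-4)

    def test_zero_sd_rejected(self):
        lr = pd.Series([1.0, 1.0, 1.0], name="log2_ratio")
        with pytest.raises(DegeneratePopulationError):
            z_scores(lr, population_stats(lr))

    def test_brute_force_agreement_on_random_populations(self):
        """Vectorized z-scores match an element-wise loop to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 5000))
            vals = rng.normal(rng.normal(0, 2), rng.uniform(0.1, 3), n)
            lr = pd.Series(vals, index=[f"P{i}" for i in range(n)], name="log2_ratio")
            stats = population_stats(lr)
            z = z_scores(lr, stats)["z"].to_numpy()
            mean = sum(vals) / n
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
            expected = np.array([(v - mean) / sd for v in vals])
            np.testing.assert_allclose(z, expected, atol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-8, 8), min_size=5, max_size=200),
           st.floats(0.01, 10))
    def test_standardization_and_scale_equivariance(self, values, scale_factor):
        """z-scores have mean 0 / sd 1 and are invariant to rescaling all ratios."""
        values = np.asarray(values)
        if np.std(values, ddof=1) < 1e-6:
            return
        lr = pd.Series(values, index=[f"P{i}" for i in range(len(values))],
                       name="log2_ratio")
        z = z_scores(lr, population_stats(lr))["z"]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        # multiplying every raw ratio by c shifts log2 by log2(c): z unchanged
        shifted = lr + math.log2(scale_factor)
        z2 = z_scores(shifted, population_stats(shifted))["z"]
        np.testing.assert_allclose(z.to_numpy(), z2.to_numpy(), atol=1e-7)


class TestClassifyProtein:
    @pytest.mark.parametrize(
        "log2_ratio, z, direction, tier",
        [
            (0.0, 0.0, Direction.UNCHANGED, Tier.NONE),
            # fold criterion is strictly > 0.58: the boundary fails
            (0.58, 3.0, Direction.UNCHANGED, Tier.NONE),
            # z criterion is >=: the boundary passes
            (0.59, 1.960, Direction.UP, Tier.CI95),
            (7.42, 5.0, Direction.UP, Tier.CI999),
            (-0.943, -2.1, Direction.DOWN, Tier.CI95),
            (-0.943, -2.576, Direction.DOWN, Tier.CI99),
            # sign-inconsistent z never yields a call
            (-0.943, 2.5, Direction.UNCHANGED, Tier.NONE),
            (0.59, -2.5, Direction.UNCHANGED, Tier.NONE),
        ],
    )
    def test_dual_criterion_and_tiers(self, log2_ratio, z, direction, tier):
        assert classify_protein(log2_ratio, z) == (direction, tier)

    def test_tier_monotone_in_z(self):
        """For a fixed passing fold change, growing z never weakens the call."""
        order = [Tier.NONE, Tier.CI95, Tier.CI99, Tier.CI999]
        last = -1
        for z in np.linspace(1.96, 6.0, 50):
            d, tier = classify_protein(1.0, float(z))
            assert d is Direction.UP
            assert order.index(tier) >= last
            last = order.index(tier)

    def test_custom_thresholds_validated(self):
        with pytest.raises(InputError):
            Thresholds(z_cut=3.0, z_tier99=2.0)
        with pytest.raises(InputError):
            Thresholds(log2_cut=-1)


def scored_frame(rows):
    """Build a per-replicate scored frame from (accession, ratio, log2, z, direction, tier)."""
    df = pd.DataFrame(rows, columns=["accession", "ratio", "log2_ratio", "z",
                                     "direction", "tier"]).set_index("accession")
    df.insert(0, "gene_name", df.index.str.lower())
    return df


class TestCombineReplicates:
    def test_direction_requires_agreement_in_both(self):
        r1 = scored_frame([
            ("P1", 4.0, 2.0, 3.0, "up", "ci99"),
            ("P2", 4.0, 2.0, 3.0, "up", "ci999"),
            ("P3", 4.0, 2.0, 3.0, "up", "ci95"),
            ("P4", 0.25, -2.0, -3.0, "down", "ci99"),
        ])
        r2 = scored_frame([
            ("P1", 4.0, 2.0, 3.5, "up", "ci999"),
            ("P2", 1.0, 0.0, 0.0, "unchanged", "none"),
            ("P3", 0.25, -2.0, -3.0, "down", "ci999"),
            ("P4", 0.25, -2.0, -2.0, "down", "ci95"),
        ])
        calls = combine_replicates({"rep1": r1, "rep2": r2})
        assert calls.loc["P1", "direction"] == "up"          # up + up
        assert calls.loc["P2", "direction"] == "unchanged"   # up + unchanged
        assert calls.loc["P3", "direction"] == "unchanged"   # up + down conflict
        assert calls.loc["P4", "direction"] == "down"        # down + down
        # combined tier is the weaker of the two replicates
        assert calls.loc["P1", "tier"] == "ci99"
        assert calls.loc["P4", "tier"] == "ci95"
        assert calls.loc["P2", "tier"] == "none"

    def test_average_ratio_is_geometric_mean(self):
        r1 = scored_frame([("P1", 2.0, 1.0, 3.0, "up", "ci99")])
        r2 = scored_frame([("P1", 8.0, 3.0, 3.0, "up", "ci99")])
        calls = combine_replicates({"rep1": r1, "rep2": r2})
        assert calls.loc["P1", "average_ratio"] == pytest.approx(4.0)  # sqrt(2*8)

    def test_protein_absent_from_one_replicate_is_unchanged(self):
        r1 = scored_frame([("P1", 4.0, 2.0, 3.0, "up", "ci99"),
                           ("P2", 4.0, 2.0, 3.0, "up", "ci99")])
        r2 = scored_frame([("P1", 4.0, 2.0, 3.0, "up", "ci99")])
        calls = combine_replicates({"rep1": r1, "rep2": r2})
        assert calls.loc["P2", "direction"] == "unchanged"
        assert np.isnan(calls.loc["P2", "average_ratio"])

    def test_final_up_set_subset_of_each_replicate(self):
        rng = np.random.default_rng(7)
        tabs = {r: make_table(2 ** rng.normal(0, 1, 300), prefix=f"Q")
                for r in ("rep1", "rep2")}
        scored = {r: score_replicate(t) for r, t in tabs.items()}
        calls = combine_replicates(scored)
        final_up = set(calls.index[calls["direction"] == "up"])
        for r, s in scored.items():
            assert final_up <= set(s.index[s["direction"] == "up"])

    def test_requires_exactly_two_replicates(self):
        r1 = scored_frame([("P1", 2.0, 1.0, 3.0, "up", "ci99")])
        with pytest.raises(InputError, match="2 replicates"):
            combine_replicates({"rep1": r1})


class TestRankTop:
    def make_calls(self, rows):
        df = pd.DataFrame(rows, columns=["accession", "direction", "average_ratio"])
        return df.set_index("accession")

    def test_up_descending_down_ascending(self):
        calls = self.make_calls([
            ("P1", "up", 2.0), ("P2", "up", 4.0), ("P3", "up", 3.0),
            ("P4", "down", 0.5), ("P5", "down", 0.2),
        ])
        top_up = rank_top(calls, "up", 2)
        assert list(top_up["average_ratio"]) == [4.0, 3.0]
        top_down = rank_top(calls, "down", 5)
        assert list(top_down["average_ratio"]) == [0.2, 0.5]

    def test_n_larger_than_available_returns_all(self):
        calls = self.make_calls([("P1", "up", 2.0)])
        assert len(rank_top(calls, "up", 10)) == 1

    def test_ties_broken_by_accession(self):
        calls = self.make_calls([("PB", "up", 2.0), ("PA", "up", 2.0)])
        assert list(rank_top(calls, "up", 2).index) == ["PA", "PB"]
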