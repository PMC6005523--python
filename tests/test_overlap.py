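"""Pianka's index, seasonal overlap and the bootstrap null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietpulse.core_data import ValidationError
from dietpulse.overlap import (
    PiankaObserved,
    bootstrap_null,
    classify_significance,
    pianka,
    seasonal_overlap,
)
from dietpulse.simulate import SimConfig, generate

from conftest import make_table


class TestPianka:
    def test_identical_profiles_full_overlap(self):
        p = np.array([0.2, 0.3, 0.5])
        assert pianka(p, p) == pytest.approx(1.0)

    def test_disjoint_supports_no_overlap(self):
        assert pianka(np.array([0.5, 0.5, 0]), np.array([0, 0, 1.0])) == 0.0

    def test_hand_value(self):
        assert pianka(np.array([0.5, 0.5, 0.0]),
                      np.array([0.0, 0.5, 0.5])) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            pianka(np.zeros(3), np.array([0.5, 0.5, 0.0]))

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=10),
        st.integers(0, 10**6),
    )
    def test_symmetric_and_bounded(self, raw, seed):
        rng = np.random.default_rng(seed)
        a = np.asarray(raw) + 1e-9
        b = rng.uniform(size=len(a)) + 1e-9
        a, b = a / a.sum(), b / b.sum()
        o1, o2 = pianka(a, b), pianka(b, a)
        assert o1 == o2
        assert -1e-12 <= o1 <= 1 + 1e-12


class TestSeasonalOverlap:
    def test_pairs_times_seasons(self):
        table, _ = generate(SimConfig(cell_sizes=6, seed=0))
        out = seasonal_overlap(table)
        assert len(out) == 3  # 3 species pairs
        assert all(len(o.by_season) == 4 for o in out)

    def test_disjoint_item_pools_zero_everywhere(self):
        vocab = ["fish_1", "insects_1"]
        cmap = {"fish_1": "fish", "insects_1": "insects"}
        rows = []
        for se in ("wet", "dry"):
            for i in range(3):
                rows.append((f"a{se}{i}", "spA", se, "L1", {"fish_1": 1}))
                rows.append((f"b{se}{i}", "spB", se, "L1", {"insects_1": 1}))
        t = make_table(rows, vocab, cmap)
        t.seasons = ("wet", "dry")
        for obs in seasonal_overlap(t):
            assert all(v == 0.0 for v in obs.by_season.values())

    def test_same_generating_vector_high_overlap(self):
        cfg = SimConfig(n_species=2, n_locations=1, cell_sizes=300,
                        empty_prob=0.0, overlap_share=1.0, season_shift=0.0,
                        items_per_stomach=1.0, seed=1)
        table, _ = generate(cfg)
        for obs in seasonal_overlap(table):
            assert all(v > 0.95 for v in obs.by_season.values())

    def test_empty_cell_named(self):
        rows = [("a1", "spA", "wet", "L1", {"fish_1": 1}),
                ("a2", "spA", "dry", "L1", {"fish_1": 1}),
                ("b1", "spB", "wet", "L1", {"fish_1": 1}),
                ("b2", "spB", "dry", "L1", {})]
        t = make_table(rows, ["fish_1"], {"fish_1": "fish"})
        t.seasons = ("wet", "dry")
        with pytest.raises(ValidationError, match="spB.*dry"):
            seasonal_overlap(t)


class TestBootstrapNull:
    def test_fixed_seed_reproducible(self):
        table, _ = generate(SimConfig(n_species=2, cell_sizes=10, seed=2))
        a = bootstrap_null(table, ("sp1", "sp2"), n_boot=50, seed=9)
        b = bootstrap_null(table, ("sp1", "sp2"), n_boot=50, seed=9)
        np.testing.assert_array_equal(a.null_values, b.null_values)

    def test_degenerate_single_shared_item(self):
        rows = []
        for se in ("wet", "dry"):
            for i in range(4):
                rows.append((f"a{se}{i}", "spA", se, "L1", {"fish_1": 1}))
                rows.append((f"b{se}{i}", "spB", se, "L1", {"fish_1": 1}))
        t = make_table(rows, ["fish_1"], {"fish_1": "fish"})
        t.seasons = ("wet", "dry")
        res = bootstrap_null(t, ("spA", "spB"), n_boot=100, seed=0)
        assert (res.null_values == 1.0).all()
        assert res.ci == (1.0, 1.0)

    def test_resample_size_modes(self):
        table, _ = generate(SimConfig(n_species=2, cell_sizes=10,
                                      empty_prob=0.0, seed=3))
        res = bootstrap_null(table, ("sp1", "sp2"), n_boot=20, seed=0)
        # mean per-season non-empty count: 4 seasons x 4 locations x 10 / 4
        assert res.resample_size == {"sp1": 40, "sp2": 40}
        pooled = bootstrap_null(table, ("sp1", "sp2"), n_boot=20,
                                resample_size="pooled_n", seed=0)
        assert pooled.resample_size == {"sp1": 160, "sp2": 160}
        explicit = bootstrap_null(table, ("sp1", "sp2"), n_boot=20,
                                  resample_size={"sp1": 5, "sp2": 7}, seed=0)
        assert explicit.resample_size == {"sp1": 5, "sp2": 7}

    def test_tiny_resample_rejected(self):
        table, _ = generate(SimConfig(n_species=2, cell_sizes=10, seed=4))
        with pytest.raises(ValidationError, match="resample size"):
            bootstrap_null(table, ("sp1", "sp2"), n_boot=10,
                           resample_size={"sp1": 1, "sp2": 5}, seed=0)


class TestClassification:
    def _null(self, values, observed):
        from dietpulse.overlap import PiankaNull

        values = np.asarray(values, float)
        lo, hi = np.percentile(values, [2.5, 97.5])
        return PiankaNull(
            pair=("A", "B"), null_values=values, mean=float(values.mean()),
            ci=(lo, hi), level=0.95, observed=observed,
            flags={}, n_boot=len(values), resample_size={"A": 5, "B": 5},
            seed=0,
        )

    def test_observed_at_null_mean_is_inside(self):
        rng = np.random.default_rng(0)
        values = rng.beta(5, 5, size=1000)
        null = self._null(values, {})
        obs = PiankaObserved(("A", "B"), {"wet": float(values.mean())})
        assert classify_significance(obs, null)["wet"] == "inside"

    def test_observed_one_above_truncated_ci(self):
        rng = np.random.default_rng(1)
        values = rng.beta(2, 5, size=1000)
        null = self._null(values, {})
        obs = PiankaObserved(("A", "B"), {"wet": 1.0})
        assert classify_significance(obs, null)["wet"] == "above"

    def test_wider_level_never_stricter(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            values = rng.beta(2, 2, size=400)
            null = self._null(values, {})
            obs = PiankaObserved(("A", "B"), {"wet": float(rng.uniform())})
            f95 = classify_significance(obs, null, level=0.95)["wet"]
            f99 = classify_significance(obs, null, level=0.99)["wet"]
            if f95 == "inside":
                assert f99 == "inside"
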