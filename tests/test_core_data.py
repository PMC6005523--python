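"""Stomach-table construction, I/O, tallies and FOC profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietpulse import fixtures
from dietpulse.core_data import (
    CountTable,
    SchemaError,
    StomachRecord,
    StomachTable,
    ValidationError,
    build_community_matrix,
    category_importance,
    empty_stomach_summary,
    foc_profiles,
    read_stomach_table,
    tally_by,
    write_stomach_table,
)

from conftest import make_table


class TestRecordsAndTable:
    def test_is_empty_iff_no_positive_counts(self):
        assert StomachRecord("s", "sp", "wet", "L", items={}).is_empty
        assert StomachRecord("s", "sp", "wet", "L", items={"a": 0}).is_empty
        assert not StomachRecord("s", "sp", "wet", "L", items={"a": 1}).is_empty

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            StomachRecord("s", "sp", "wet", "L", items={"a": -1})

    def test_items_must_belong_to_vocabulary(self):
        with pytest.raises(ValidationError, match="outside the"):
            make_table([("s1", "sp", "wet", "L", {"zz": 1})], ["a"])

    def test_category_map_must_cover_vocabulary(self):
        with pytest.raises(ValidationError, match="cover"):
            StomachTable(
                [StomachRecord("s", "sp", "wet", "L", items={"a": 1})],
                ["a", "b"],
                {"a": "fish"},
            )


class TestIO:
    def test_read_derives_emptiness(self, tmp_path, tiny_table):
        path = tmp_path / "t.csv"
        write_stomach_table(tiny_table, path)
        back = read_stomach_table(path, category_map=tiny_table.category_map)
        assert len(back) == 3
        assert [r.is_empty for r in back.records] == [False, False, True]

    def test_round_trip_identity(self, tmp_path, tiny_table):
        path = tmp_path / "t.csv"
        write_stomach_table(tiny_table, path)
        back = read_stomach_table(path, category_map=tiny_table.category_map)
        pd.testing.assert_frame_equal(back.to_dataframe(), tiny_table.to_dataframe())
        assert back.item_vocabulary == tiny_table.item_vocabulary

    def test_missing_mandatory_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"specimen_id": ["a"], "species": ["x"]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="season"):
            read_stomach_table(path)

    def test_negative_count_in_file_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "specimen_id": ["a"],
                "species": ["x"],
                "season": ["wet"],
                "location": ["L"],
                "item1": [-2],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="negative"):
            read_stomach_table(path)

    def test_columns_outside_vocabulary_reported(self, tmp_path, tiny_table):
        path = tmp_path / "t.csv"
        write_stomach_table(tiny_table, path)
        with pytest.warns(UserWarning, match="outside the item"):
            read_stomach_table(path, vocabulary=["a"], category_map={"a": "fish"})


class TestTally:
    def test_empty_table_all_zero(self):
        table = StomachTable([], [], {})
        assert tally_by(table, "species", "season").to_frame().empty

    def test_uniform_fill(self):
        rows = [
            (f"s{i}{sp}{se}", sp, se, "L1", {})
            for sp in ("A", "B")
            for se in ("wet", "dry")
            for i in range(2)
        ]
        ct = make_table(rows, [])
        tt = tally_by(ct, "species", "season")
        assert (tt.to_frame().values == 2).all()
        assert (tt.row_margin == 4).all() and (tt.col_margin == 4).all()

    def test_transpose_symmetry(self, tiny_table):
        a = tally_by(tiny_table, "species", "season").to_frame()
        b = tally_by(tiny_table, "season", "species").to_frame()
        a = a.sort_index().sort_index(axis=1)
        b = b.T.sort_index().sort_index(axis=1)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_factor_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="unknown factor"):
            tally_by(tiny_table, "species", "weight")

    def test_table1_fixture_reproduces_published_margins(self):
        table = fixtures.table1_stomach_table()
        loc = tally_by(table, "species", "location").to_frame()
        for sp, expect in fixtures.TABLE1_LOCATION_COUNTS.items():
            for l, n in expect.items():
                assert loc.loc[sp, l] == n
        assert loc.loc["Anabas testudineus"].sum() == 236
        assert loc.loc["Boesemania microlepis"].sum() == 179
        assert loc.loc["Notopterus notopterus"].sum() == 208
        assert loc.values.sum() == 623

    def test_margin_report_flags_inconsistent_species_only(self):
        reports = fixtures.margin_report()
        assert reports, "the inconsistent published margin must be reported"
        assert all("Notopterus" in r for r in reports)


class TestEmptySummary:
    def test_all_empty_gives_ones(self):
        t = make_table([("s1", "A", "wet", "L", {}), ("s2", "A", "dry", "L", {})], [])
        assert (empty_stomach_summary(t).values == 1.0).all()

    def test_no_empty_gives_zeros(self):
        t = make_table(
            [("s1", "A", "wet", "L", {"a": 1}), ("s2", "A", "dry", "L", {"a": 1})],
            ["a"],
        )
        assert (empty_stomach_summary(t).values == 0.0).all()

    def test_direct_division(self):
        rows = [(f"e{i}", "A", "wet", "L", {}) for i in range(3)]
        rows += [(f"f{i}", "A", "wet", "L", {"a": 1}) for i in range(17)]
        t = make_table(rows, ["a"])
        assert empty_stomach_summary(t).loc["A", "wet"] == pytest.approx(0.15)

    def test_absent_cell_is_nan_not_zero(self):
        t = make_table(
            [("s1", "A", "wet", "L", {"a": 1}), ("s2", "B", "dry", "L", {"a": 1})],
            ["a"],
        )
        out = empty_stomach_summary(t)
        assert np.isnan(out.loc["A", "dry"])


class TestCommunityMatrix:
    def test_binarization(self):
        t = make_table([("s1", "A", "wet", "L", {"a": 2, "b": 1})], ["a", "b"])
        m = build_community_matrix(t, binarize=True)
        assert m.values.tolist() == [[1.0, 1.0]]

    def test_category_sum(self):
        t = make_table(
            [("s1", "A", "wet", "L", {"fishA": 1, "fishB": 1})],
            ["fishA", "fishB"],
            {"fishA": "fish", "fishB": "fish"},
        )
        m = build_community_matrix(t, level="category", binarize=False)
        assert m.item_labels == ["fish"]
        assert m.values.tolist() == [[2.0]]

    def test_empty_stomachs_excluded(self):
        rows = [(f"s{i}", "A", "wet", "L", {"a": 1}) for i in range(3)]
        rows += [(f"e{i}", "A", "wet", "L", {}) for i in range(2)]
        m = build_community_matrix(make_table(rows, ["a"]))
        assert m.n_units == 3

    def test_all_empty_is_error(self):
        t = make_table([("s1", "A", "wet", "L", {})], ["a"])
        with pytest.raises(ValidationError, match="no non-empty"):
            build_community_matrix(t)

    def test_item_matrix_aggregates_to_category_matrix(self):
        rng = np.random.default_rng(0)
        vocab = [f"fish_{i}" for i in range(3)] + [f"insects_{i}" for i in range(2)]
        cmap = {v: v.split("_")[0] for v in vocab}
        rows = []
        for i in range(10):
            items = {v: int(rng.integers(0, 3)) for v in vocab}
            if sum(items.values()) == 0:
                items[vocab[0]] = 1
            rows.append((f"s{i}", "A", "wet", "L1", items))
        t = make_table(rows, vocab, cmap)
        mi = build_community_matrix(t, binarize=False)
        mc = build_community_matrix(t, level="category", binarize=False)
        agg = np.zeros_like(mc.values)
        for j, item in enumerate(mi.item_labels):
            agg[:, mc.item_labels.index(cmap[item])] += mi.values[:, j]
        np.testing.assert_allclose(agg, mc.values)


class TestFOC:
    def test_uniform_split(self):
        t = make_table([("s1", "A", "wet", "L", {"a": 1, "b": 1})], ["a", "b"])
        prof = foc_profiles(build_community_matrix(t))[("A", "wet")]
        np.testing.assert_allclose(prof.p, [0.5, 0.5])

    def test_hand_count(self):
        t = make_table(
            [
                ("s1", "A", "wet", "L", {"a": 1}),
                ("s2", "A", "wet", "L", {"a": 3, "b": 2}),
            ],
            ["a", "b"],
        )
        prof = foc_profiles(build_community_matrix(t))[("A", "wet")]
        np.testing.assert_allclose(prof.p, [2 / 3, 1 / 3])
        assert prof.n_stomachs == 2

    def test_requires_binarized_matrix(self, tiny_table):
        m = build_community_matrix(tiny_table, binarize=False)
        with pytest.raises(ValidationError, match="binarize"):
            foc_profiles(m)

    @settings(deadline=None, max_examples=25)
    @given(st.data())
    def test_profiles_normalized_and_nonnegative(self, data):
        n = data.draw(st.integers(2, 8))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        rows = []
        for i in range(n):
            items = {f"i{j}": int(rng.integers(0, 2)) for j in range(5)}
            if sum(items.values()) == 0:
                items["i0"] = 1
            rows.append((f"s{i}", "A", rng.choice(["wet", "dry"]), "L1", items))
        t = make_table(rows, [f"i{j}" for j in range(5)])
        for prof in foc_profiles(build_community_matrix(t)).values():
            assert prof.p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (prof.p >= 0).all()


class TestCategoryImportance:
    def test_single_category_degenerate(self):
        t = make_table([("s1", "A", "wet", "L", {"a": 1, "b": 1})], ["a", "b"])
        profs = foc_profiles(build_community_matrix(t))
        imp = category_importance(profs, {"a": "fish", "b": "fish"})
        assert imp.values.tolist() == [[1.0]]

    def test_renormalization(self):
        # two categories whose average item FOC are 0.3 and 0.1
        from dietpulse.core_data import FOCProfile

        # category means: c1 -> (0.4+0.2)/2 = 0.3, c2 -> 0.4/4 = 0.1
        prof = FOCProfile(
            group=("A", "wet"),
            items=("c1_a", "c1_b", "c2_a", "c2_b", "c2_c", "c2_d"),
            p=np.array([0.4, 0.2, 0.15, 0.05, 0.1, 0.1]),
            n_stomachs=5,
        )
        cmap = {"c1_a": "c1", "c1_b": "c1", "c2_a": "c2", "c2_b": "c2",
                "c2_c": "c2", "c2_d": "c2"}
        imp = category_importance([prof], cmap)
        assert imp.loc[("A", "wet"), "c1"] == pytest.approx(0.75)
        assert imp.loc[("A", "wet"), "c2"] == pytest.approx(0.25)

    def test_dominant_category_ranks_first(self):
        rng = np.random.default_rng(3)
        vocab = [f"fish_{i}" for i in range(3)] + [f"plants_{i}" for i in range(3)]
        cmap = {v: v.split("_")[0] for v in vocab}
        rows = []
        for i in range(40):
            items = {}
            for v in vocab:
                p = 0.8 if v.startswith("fish") else 0.2
                if rng.uniform() < p:
                    items[v] = 1
            if not items:
                items["fish_0"] = 1
            rows.append((f"s{i}", "A", "wet", "L1", items))
        t = make_table(rows, vocab, cmap)
        imp = category_importance(foc_profiles(build_community_matrix(t)), cmap)
        row = imp.loc[("A", "wet")]
        assert row.idxmax() == "fish"


def test_count_table_margins_match_recomputed_sums(tiny_table):
    ct = tally_by(tiny_table, "species", "season")
    assert (ct.row_margin == ct.to_frame().sum(axis=1)).all()
    assert (ct.col_margin == ct.to_frame().sum(axis=0)).all()
    assert ct.total == len(tiny_table)


def test_bundled_fixture_file_matches_programmatic_table():
    bundled = fixtures.load_bundled_table1()
    programmatic = fixtures.table1_stomach_table()
    pd.testing.assert_frame_equal(
        bundled.to_dataframe(), programmatic.to_dataframe()
    )
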