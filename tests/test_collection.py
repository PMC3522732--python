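"""Collections, medium application, batch FBA, normalization, correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import fluxcompare as fc
from fluxcompare.collection import (
    MISSING_OBJECTIVE,
    ComparativeResultTable,
    exchange_influx,
)
from fluxcompare.errors import MediumError, StatisticsError
from fluxcompare.model import DEFAULT_BIG

from oracles import naive_pearson_r2


def chain_collection(uptakes=(5.0, 10.0, 20.0)):
    members = []
    for i, u in enumerate(uptakes):
        m = fc.fixtures.make_chain(k=3, uptake=u, model_id=f"org{i}")
        members.append(m)
    return fc.ModelCollection(name="chains", members=members)


class TestApplyMedium:
    def test_influx_capped_at_medium_value(self):
        """Minimal-medium style entry: glucose influx capped at 10."""
        model = fc.fixtures.make_chain(k=3, uptake=DEFAULT_BIG)
        medium = fc.Medium(entries={"glc_e": 10.0})
        constrained = fc.apply_medium(model, medium)
        assert fc.solve_fba(constrained, "export").objective_value == pytest.approx(10.0)

    def test_empty_medium_nothing_enters(self, chain_model):
        constrained = fc.apply_medium(chain_model, fc.Medium(entries={}))
        assert fc.solve_fba(constrained, "export").objective_value == pytest.approx(
            0.0, abs=1e-9
        )

    def test_doubling_binding_entry_doubles_optimum(self):
        model = fc.fixtures.make_chain(k=2, uptake=DEFAULT_BIG)
        for value in (4.0, 8.0):
            constrained = fc.apply_medium(model, fc.Medium(entries={"glc_e": value}))
            assert fc.solve_fba(constrained, "export").objective_value == pytest.approx(
                value
            )

    def test_original_model_unchanged(self, chain_model):
        snapshot = chain_model.copy()
        fc.apply_medium(chain_model, fc.Medium(entries={"glc_e": 1.0}))
        assert chain_model == snapshot

    def test_idempotent(self, chain_model):
        medium = fc.Medium(entries={"glc_e": 3.0})
        once = fc.apply_medium(chain_model, medium)
        twice = fc.apply_medium(once, medium)
        assert once == twice

    def test_secretion_stays_unbounded(self, chain_model):
        constrained = fc.apply_medium(chain_model, fc.Medium(entries={"glc_e": 5.0}))
        ex_prod = constrained.get_reaction("EX_prod")
        # forward direction of EX_prod (prod_e ->) is secretion
        assert ex_prod.upper_bound == DEFAULT_BIG

    def test_exchange_autocreated_when_absent(self):
        model = fc.fixtures.make_chain(k=2, uptake=DEFAULT_BIG)
        model.reactions = [r for r in model.reactions if r.id != "EX_glc"]
        constrained = fc.apply_medium(model, fc.Medium(entries={"glc_e": 7.0}))
        assert fc.solve_fba(constrained, "export").objective_value == pytest.approx(7.0)

    def test_unknown_medium_key_raises(self, chain_model):
        coll = fc.ModelCollection(name="one", members=[chain_model])
        with pytest.raises(MediumError, match="mystery"):
            fc.apply_medium(chain_model, fc.Medium(entries={"mystery": 1.0}), coll)

    def test_negative_influx_rejected(self):
        with pytest.raises(MediumError):
            fc.Medium(entries={"glc_e": -1.0})

    def test_medium_tsv_roundtrip(self, tmp_path):
        medium = fc.Medium(entries={"glc_e": 10.0, "nh3_e": 6.0})
        medium.to_tsv(tmp_path / "medium.tsv")
        assert fc.Medium.from_tsv(tmp_path / "medium.tsv") == medium


class TestBatchFba:
    def test_column_of_optima_in_collection_order(self):
        coll = chain_collection()
        table = fc.batch_fba(coll, "export")
        frame = table.to_frame()
        assert list(frame.index) == ["org0", "org1", "org2"]
        assert list(frame["export"]) == pytest.approx([5.0, 10.0, 20.0])

    def test_missing_objective_token_not_exception(self):
        coll = chain_collection()
        coll.members[1].reactions = [
            r for r in coll.members[1].reactions if r.id != "export"
        ]
        table = fc.batch_fba(coll, "export")
        assert table.cells[("org1", "export")] == MISSING_OBJECTIVE
        assert table.cells[("org0", "export")] == pytest.approx(5.0)

    def test_equals_memberwise_apply_medium_plus_solve(self):
        coll = chain_collection()
        medium = fc.Medium(entries={"glc_e": 7.0})
        table = fc.batch_fba(coll, "export", medium=medium)
        for member in coll.members:
            prepared = fc.apply_medium(member, medium, coll)
            expected = fc.solve_fba(prepared, "export").objective_value
            assert table.cells[(member.id, "export")] == pytest.approx(expected)

    def test_multi_objective_grid_matches_individual_solves(self):
        coll = chain_collection((5.0, 10.0, 20.0, 40.0))
        objectives = {"production": "export", "uptake_rate": "uptake", "entry": "EX_glc"}
        table = fc.batch_fba(coll, objectives)
        assert len(table.cells) == 12
        for member in coll.members:
            for label, rxn in objectives.items():
                expected = fc.solve_fba(member, rxn).objective_value
                assert table.cells[(member.id, label)] == pytest.approx(expected)

    def test_table_tsv_roundtrip(self, tmp_path):
        table = fc.batch_fba(chain_collection(), "export")
        table.to_tsv(tmp_path / "table.tsv")
        back = ComparativeResultTable.from_tsv(tmp_path / "table.tsv")
        assert back.model_ids == table.model_ids
        for key, value in table.cells.items():
            assert back.cells[key] == pytest.approx(value)


class TestRelativeFluxMatrix:
    def test_column_scaled_to_percent_of_max(self):
        table = ComparativeResultTable(
            model_ids=["a", "b", "c"],
            objective_labels=["obj"],
            cells={("a", "obj"): 5.0, ("b", "obj"): 10.0, ("c", "obj"): 20.0},
        )
        out = fc.relative_flux_matrix(table)
        assert list(out["obj"]) == pytest.approx([25.0, 50.0, 100.0])

    def test_all_zero_column_maps_to_zeros_not_nan(self):
        table = ComparativeResultTable(
            model_ids=["a", "b"],
            objective_labels=["obj"],
            cells={("a", "obj"): 0.0, ("b", "obj"): 0.0},
        )
        out = fc.relative_flux_matrix(table)
        assert list(out["obj"]) == [0.0, 0.0]

    def test_status_cells_are_absent(self):
        table = ComparativeResultTable(
            model_ids=["a", "b"],
            objective_labels=["obj"],
            cells={("a", "obj"): 8.0, ("b", "obj"): MISSING_OBJECTIVE},
        )
        out = fc.relative_flux_matrix(table)
        assert out.loc["a", "obj"] == 100.0
        assert math.isnan(out.loc["b", "obj"])

    @given(st.integers(0, 100), st.floats(0.01, 100.0))
    def test_invariant_under_positive_column_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 50, size=4)
        ids = [f"m{i}" for i in range(4)]
        t1 = ComparativeResultTable(
            ids, ["o"], {(mid, "o"): float(v) for mid, v in zip(ids, values)}
        )
        t2 = ComparativeResultTable(
            ids, ["o"], {(mid, "o"): float(v * scale) for mid, v in zip(ids, values)}
        )
        pd.testing.assert_frame_equal(
            fc.relative_flux_matrix(t1), fc.relative_flux_matrix(t2)
        )

    def test_column_max_is_exactly_100(self):
        rng = np.random.default_rng(7)
        ids = [f"m{i}" for i in range(6)]
        cells = {(mid, "o"): float(rng.uniform(0.1, 9.0)) for mid in ids}
        out = fc.relative_flux_matrix(ComparativeResultTable(ids, ["o"], cells))
        assert out["o"].max() == 100.0


class TestPresenceFluxCorrelation:
    def test_perfect_correlation(self):
        coll, _ = fc.fixtures.make_random_collection(
            n_models=4, presence_prob=1.0, seed=0
        )
        # drop unlock_x from two members by hand -> presence (1,1,0,0)
        for member in coll.members[2:]:
            member.reactions = [r for r in member.reactions if r.id != "unlock_x"]
        fluxes = {"model_00": 5.0, "model_01": 5.0, "model_02": 0.0, "model_03": 0.0}
        frame = fc.presence_flux_correlation(coll, fluxes)
        row = frame[frame.reaction_id == "unlock_x"].iloc[0]
        assert row.r_squared == pytest.approx(1.0)
        assert row.n_present == 2

    def test_constant_presence_is_undefined_marker(self):
        coll, _ = fc.fixtures.make_random_collection(
            n_models=4, presence_prob=1.0, seed=0
        )
        fluxes = {m: float(i) for i, m in enumerate(coll.member_ids())}
        frame = fc.presence_flux_correlation(coll, fluxes)
        # every reaction present everywhere: zero presence variance
        assert frame.r_squared.isna().all()

    def test_matches_naive_two_pass_pearson(self):
        coll, presence = fc.fixtures.make_random_collection(
            n_models=6, presence_prob=0.5, seed=3
        )
        fluxes = {m: float(i * i) for i, m in enumerate(coll.member_ids())}
        frame = fc.presence_flux_correlation(coll, fluxes).set_index("reaction_id")
        y = [fluxes[m] for m in coll.member_ids()]
        for rid in presence.columns:
            x = list(presence[rid])
            expected = naive_pearson_r2(x, y)
            got = frame.loc[rid, "r_squared"]
            if expected is None:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_sorted_by_r2_desc_then_id(self):
        coll, _ = fc.fixtures.make_random_collection(
            n_models=6, presence_prob=0.5, seed=3
        )
        fluxes = {m: float(i) for i, m in enumerate(coll.member_ids())}
        frame = fc.presence_flux_correlation(coll, fluxes)
        defined = frame.dropna(subset=["r_squared"])
        values = list(defined.r_squared)
        assert values == sorted(values, reverse=True)
        for _, group in defined.groupby("r_squared"):
            ids = list(group.reaction_id)
            assert ids == sorted(ids)

    def test_fewer_than_three_members_rejected(self):
        coll, _ = fc.fixtures.make_random_collection(
            n_models=2, presence_prob=1.0, seed=0
        )
        with pytest.raises(StatisticsError):
            fc.presence_flux_correlation(coll, {"model_00": 1.0, "model_01": 2.0})

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_r2_invariant_under_positive_affine_flux_transform(self, slope, shift):
        coll, _ = fc.fixtures.make_random_collection(
            n_models=6, presence_prob=0.5, seed=3
        )
        base = {m: float(i * 2 + (i % 2)) for i, m in enumerate(coll.member_ids())}
        transformed = {m: slope * v + shift for m, v in base.items()}
        f1 = fc.presence_flux_correlation(coll, base)
        f2 = fc.presence_flux_correlation(coll, transformed)
        pd.testing.assert_series_equal(
            f1.set_index("reaction_id").r_squared.sort_index(),
            f2.set_index("reaction_id").r_squared.sort_index(),
            atol=1e-9,
        )
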