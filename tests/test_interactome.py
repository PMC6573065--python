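"""Interactor-calling rules, checked against an independent exhaustive oracle."""

import dataclasses

import numpy as np
import pytest

from mediascape.interactome import (
    CONTROL_OF,
    MEDIATOR_ROLES,
    ROLES,
    ApmsRow,
    FilterConfig,
    call_interactors,
    chromatin_independent,
    edge_weight_category,
    endogenous_overlap,
    passes_inclusion,
    rows_from_table,
    subtract_core_subunits,
)


def make_row(pid="p", empai=None, mascot=None, **flags):
    base_e = {r: 0.0 for r in ROLES}
    base_m = {r: 0.0 for r in ROLES}
    base_e.update(empai or {})
    base_m.update(mascot or {})
    return ApmsRow(pid, base_m, base_e, **flags)


def passing_row(pid="p"):
    return make_row(
        pid,
        empai={r: 1.0 for r in MEDIATOR_ROLES},
        mascot={r: 200.0 for r in MEDIATOR_ROLES},
    )


def oracle_pass(row: ApmsRow, cfg: FilterConfig) -> bool:
    """Direct restatement of the rule conjunction, kept independent of the
    implementation's helper structure."""

    def enriched(s, c, fold):
        return (c == 0 and s > 0) or (c > 0 and s / c >= fold - 1e-12)

    for role in MEDIATOR_ROLES:
        ctrl = CONTROL_OF[role]
        if row.mascot[role] < cfg.mascot_min:
            return False
        if not enriched(row.empai[role], row.empai[ctrl], cfg.empai_fold_min):
            return False
        if not enriched(row.mascot[role], row.mascot[ctrl], cfg.mascot_fold_min):
            return False
    if row.is_cyto:
        return False
    u = row.empai["untreated"]
    for treated in ("benzonase", "etbr"):
        t = row.empai[treated]
        if u > 0 and (t == 0 or u / t >= cfg.treatment_drop_fold - 1e-12):
            return False
    if any(row.empai[r] == 0 for r in MEDIATOR_ROLES):
        return False
    return True


class TestInclusionRules:
    def test_mascot_just_below_threshold_fails(self):
        row = passing_row()
        row = dataclasses.replace(row, mascot={**row.mascot, "untreated": 49.0})
        ok, reasons = passes_inclusion(row, "untreated", "control_exp1")
        assert not ok and reasons == ["mascot_min"]

    def test_zero_control_counts_as_infinite_enrichment(self):
        row = make_row(empai={"untreated": 0.3}, mascot={"untreated": 80.0})
        ok, reasons = passes_inclusion(row, "untreated", "control_exp1")
        assert ok and reasons == []

    def test_enrichment_just_below_fivefold_fails(self):
        row = make_row(
            empai={"untreated": 0.5, "control_exp1": 0.11},
            mascot={"untreated": 300.0, "control_exp1": 10.0},
        )
        ok, reasons = passes_inclusion(row, "untreated", "control_exp1")
        assert not ok and reasons == ["empai_fold"]

    def test_cyto_flag_fails(self):
        row = dataclasses.replace(passing_row(), is_cyto=True)
        ok, reasons = passes_inclusion(row, "untreated", "control_exp1")
        assert not ok and "cyto" in reasons

    def test_unknown_role_rejected(self):
        with pytest.raises(KeyError):
            passes_inclusion(passing_row(), "untreated", "mock")


class TestChromatinIndependence:
    @pytest.mark.parametrize(
        "untreated,treated,expected",
        [
            (1.0, 0.5, False),   # exactly two-fold lower: dependent
            (1.0, 0.51, True),   # just inside the boundary
            (0.0, 0.2, True),    # no untreated detection: no drop definable
            (0.3, 0.0, False),   # lost under treatment
            (1.0, 2.0, True),
        ],
    )
    def test_two_fold_drop_boundary(self, untreated, treated, expected):
        assert chromatin_independent(untreated, treated) is expected

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            chromatin_independent(-1.0, 0.5)


class TestCallInteractors:
    def test_planted_fixture_matches_exhaustive_oracle(self, apms_default):
        cfg = FilterConfig()
        rows = rows_from_table(apms_default.table)
        calls = {c.protein_id: c for c in call_interactors(rows, cfg)}
        for row in rows:
            assert calls[row.protein_id].passed == oracle_pass(row, cfg), row.protein_id

    def test_random_small_tables_match_oracle(self):
        rng = np.random.default_rng(42)
        cfg = FilterConfig()
        for _ in range(60):
            rows = []
            for i in range(20):
                empai = {r: float(rng.choice([0.0, 0.05, 0.3, 1.0, 2.5])) for r in ROLES}
                mascot = {r: float(rng.choice([0.0, 30.0, 60.0, 150.0, 400.0])) for r in ROLES}
                rows.append(
                    make_row(f"p{i}", empai, mascot, is_cyto=bool(rng.random() < 0.1))
                )
            calls = {c.protein_id: c for c in call_interactors(rows, cfg)}
            for row in rows:
                assert calls[row.protein_id].passed == oracle_pass(row, cfg)

    def test_all_zero_table_passes_nothing(self):
        rows = [make_row(f"p{i}") for i in range(5)]
        assert not any(c.passed for c in call_interactors(rows))

    def test_passing_and_failing_partition_with_reasons(self, apms_default):
        calls = call_interactors(rows_from_table(apms_default.table))
        for c in calls:
            assert c.passed == (len(c.failure_reasons) == 0)

    def test_sorted_by_mean_empai_descending(self, apms_default):
        calls = call_interactors(rows_from_table(apms_default.table))
        empais = [c.mean_empai for c in calls]
        assert empais == sorted(empais, reverse=True)

    def test_raising_any_threshold_never_enlarges_passing_set(self):
        rng = np.random.default_rng(7)
        base = FilterConfig()
        for _ in range(100):
            rows = []
            for i in range(12):
                empai = {r: float(rng.uniform(0, 2) * (rng.random() < 0.8)) for r in ROLES}
                mascot = {r: float(rng.uniform(0, 300) * (rng.random() < 0.9)) for r in ROLES}
                rows.append(make_row(f"p{i}", empai, mascot))
            passing = {c.protein_id for c in call_interactors(rows, base) if c.passed}
            for field, delta in [
                ("mascot_min", 40.0),
                ("empai_fold_min", 2.0),
                ("mascot_fold_min", 2.0),
                ("treatment_drop_fold", -0.7),
            ]:
                # a larger treatment_drop_fold is a LAXER rule; tightening
                # means lowering it, hence the negative delta
                stricter = dataclasses.replace(
                    base, **{field: getattr(base, field) + delta}
                )
                if field == "treatment_drop_fold":
                    stricter_set = {
                        c.protein_id for c in call_interactors(rows, stricter) if c.passed
                    }
                    assert stricter_set <= passing
                else:
                    stricter_set = {
                        c.protein_id for c in call_interactors(rows, stricter) if c.passed
                    }
                    assert stricter_set <= passing


class TestDownstreamOps:
    def test_core_subtraction_counts(self, apms_default):
        calls = [c for c in call_interactors(rows_from_table(apms_default.table)) if c.passed]
        core = set(apms_default.core_ids)
        kept = subtract_core_subunits(calls, core)
        assert len(calls) == len(kept) + len({c.protein_id for c in calls} & core)
        assert subtract_core_subunits(calls, set()) == calls
        assert subtract_core_subunits(calls, {c.protein_id for c in calls}) == []

    @pytest.mark.parametrize(
        "empai,cat",
        [(1.6, 4), (1.5, 3), (0.76, 3), (0.75, 2), (0.26, 2), (0.25, 1), (0.0, 1)],
    )
    def test_edge_weight_boundaries(self, empai, cat):
        assert edge_weight_category(empai) == cat

    def test_edge_weight_rejects_negative(self):
        with pytest.raises(ValueError):
            edge_weight_category(-0.1)

    def test_endogenous_overlap_set_semantics(self):
        assert endogenous_overlap({"a", "b"}, {"c"}) == (0, [])
        n, ids = endogenous_overlap({"a", "b", "c"}, {"c", "a", "z"})
        assert n == 2 and ids == ["a", "c"]
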