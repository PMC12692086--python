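import itertools
import json

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dicscore.cohort import Cohort, Subgroup
from dicscore.scoring import (
    SCORE_DEFINITIONS,
    Component,
    ComponentMissingError,
    ScoreId,
    component_points,
    compute_score,
    definitions_to_json,
    pt_prolongation,
    score_all,
    _RULES,
)

from _oracles import ORACLE_THRESHOLDS, oracle_score


class TestPtProlongation:
    @pytest.mark.parametrize(
        "pt,expected",
        [(13.80, pytest.approx(0.30)), (13.5, 0.0), (20.0, 6.5), (11.0, 0.0)],
    )
    def test_seconds_over_upper_normal_floored_at_zero(self, pt, expected):
        assert pt_prolongation(pt) == expected

    def test_configurable_baseline(self):
        assert pt_prolongation(15.0, baseline=14.0) == 1.0


class TestComponentPoints:
    @pytest.mark.parametrize(
        "component,value,expected",
        [
            # D-dimer (ng/mL): moderate increase = 2, strong = 3; both
            # published limits fall in the moderate bin
            (Component.D_DIMER, 13500.0, 3),
            (Component.D_DIMER, 499.999, 0),
            (Component.D_DIMER, 500.0, 2),
            (Component.D_DIMER, 4000.0, 2),
            (Component.D_DIMER, 4000.001, 3),
            # fibrinogen: exactly 100 goes to the lower-risk bin
            (Component.FIBRINOGEN, 100.0, 0),
            (Component.FIBRINOGEN, 99.9, 1),
            # platelets: 100 -> 0, 50 -> 1 (boundary to lower-risk bin)
            (Component.PLATELET, 30.6, 2),
            (Component.PLATELET, 50.0, 1),
            (Component.PLATELET, 100.0, 0),
            # PT prolongation: exactly 3 s -> 0, exactly 6 s -> 1
            (Component.PT_PROLONGATION, 3.0, 0),
            (Component.PT_PROLONGATION, 6.0, 1),
            (Component.PT_PROLONGATION, 6.5, 2),
            # LDH: published as >=, so the threshold itself scores
            (Component.LDH400, 400.0, 1),
            (Component.LDH400, 399.9, 0),
            (Component.LDH800, 800.0, 1),
            (Component.LDH800, 799.9, 0),
            # INR <=1.2 -> 0; Hgb >=7 -> 0
            (Component.INR, 1.2, 0),
            (Component.INR, 1.201, 1),
            (Component.HGB, 7.0, 0),
            (Component.HGB, 6.99, 1),
            (Component.GENETICS, True, 1),
            (Component.GENETICS, False, 0),
        ],
    )
    def test_bin_assignment(self, component, value, expected):
        assert component_points(_RULES[component], value) == expected

    def test_missing_value_raises(self):
        with pytest.raises(ComponentMissingError, match="d_dimer"):
            component_points(_RULES[Component.D_DIMER], None)


class TestComputeScore:
    def test_overt_dic_panel_original_score(self, make_record):
        # PT 6.5 s prolonged -> 2, D-dimer strong increase -> 3,
        # fibrinogen < 100 -> 1, platelets < 50 -> 2
        rec = make_record(pt_seconds=20.0, d_dimer_ng_ml=5000.0,
                          fibrinogen_mg_dl=90.0, platelet_1e9_l=40.0)
        res = compute_score(rec, ScoreId.ORIGINAL)
        assert res.component_points == {
            Component.PT_PROLONGATION: 2,
            Component.D_DIMER: 3,
            Component.FIBRINOGEN: 1,
            Component.PLATELET: 2,
        }
        assert res.total == 8 and res.positive

    @pytest.mark.parametrize("score_id", list(ScoreId))
    def test_all_normal_labs_score_zero(self, make_record, score_id):
        res = compute_score(make_record(), score_id)
        assert res.total == 0 and not res.positive

    def test_m7_without_d_dimer(self, make_record):
        rec = make_record(d_dimer_ng_ml=None, platelet_1e9_l=80.0, ldh=850.0,
                          genetic_positive=True)
        res = compute_score(rec, ScoreId.M7)
        assert res.total == 0 + 0 + 1 + 1 + 1 == 3
        assert not res.positive  # threshold 5

    def test_missing_required_component_names_score_and_patient(self, make_record):
        rec = make_record(patient_id="px", d_dimer_ng_ml=None)
        with pytest.raises(ComponentMissingError, match="ORIGINAL.*px"):
            compute_score(rec, ScoreId.ORIGINAL)

    def test_subgroup_does_not_alter_scoring(self, make_record):
        kwargs = dict(pt_seconds=18.0, d_dimer_ng_ml=600.0, platelet_1e9_l=60.0)
        a = compute_score(make_record(subgroup=Subgroup.M3, **kwargs), ScoreId.M3)
        b = compute_score(make_record(subgroup=Subgroup.NON_M3, **kwargs), ScoreId.M3)
        assert a.total == b.total and a.positive == b.positive


class TestScoreDefinitions:
    @pytest.mark.parametrize(
        "score_id,threshold,max_total",
        [
            (ScoreId.ORIGINAL, 5, 8),
            (ScoreId.M1, 6, 9), (ScoreId.M2, 6, 9), (ScoreId.M3, 6, 9),
            (ScoreId.M4, 6, 9), (ScoreId.M5, 6, 9),
            (ScoreId.M6, 5, 7), (ScoreId.M7, 5, 7),
            (ScoreId.M8, 4, 6),
        ],
    )
    def test_thresholds_and_max_totals(self, score_id, threshold, max_total):
        d = SCORE_DEFINITIONS[score_id]
        assert d.positivity_threshold == threshold
        assert d.max_total == max_total

    def test_json_export_is_machine_readable(self):
        doc = json.loads(definitions_to_json())
        assert set(doc) == {s.value for s in ScoreId}
        orig = doc["ORIGINAL"]
        assert orig["positivity_threshold"] == 5
        dd = next(c for c in orig["components"] if c["component"] == "d_dimer")
        assert [b["points"] for b in dd["bins"]] == [0, 2, 3]
        assert dd["bins"][0]["upper"] == 500.0

    def test_bins_partition_without_gap_or_overlap(self):
        probe = [0.0, 0.1, 2.9, 3, 6, 7, 49.9, 50, 99.9, 100, 399.9, 400,
                 500, 799.9, 800, 4000, 4000.1, 1e9]
        for comp, rule in _RULES.items():
            if comp == Component.GENETICS:
                continue
            for v in probe:
                hits = [b for b in rule.bins if b.contains(v)]
                assert len(hits) == 1, (comp, v)


# grids straddling every published threshold (including exact values)
_GRIDS = {
    "pt": [12.0, 13.5, 16.4, 16.5, 16.6, 19.4, 19.5, 19.6, 25.0],
    "dd": [100.0, 499.9, 500.0, 500.1, 3999.9, 4000.0, 4000.1, 10000.0],
    "fib": [50.0, 99.9, 100.0, 100.1, 300.0],
    "plt": [10.0, 49.9, 50.0, 50.1, 99.9, 100.0, 100.1, 250.0],
    "ldh": [200.0, 399.9, 400.0, 400.1, 799.9, 800.0, 800.1, 1000.0],
    "hgb": [5.0, 6.9, 7.0, 7.1, 10.0],
    "inr": [1.0, 1.19, 1.2, 1.21, 2.0],
    "gen": [False, True],
}

_SCORE_AXES = {
    "ORIGINAL": ("pt", "dd", "fib", "plt"),
    "M1": ("pt", "dd", "fib", "plt", "ldh"),
    "M2": ("pt", "dd", "fib", "plt", "ldh"),
    "M3": ("pt", "dd", "fib", "plt", "gen"),
    "M4": ("pt", "dd", "fib", "plt", "hgb"),
    "M5": ("pt", "dd", "fib", "plt", "inr"),
    "M6": ("pt", "fib", "plt", "ldh", "gen"),
    "M7": ("pt", "fib", "plt", "ldh", "gen"),
    "M8": ("pt", "fib", "plt", "gen"),
}

_FIELD = {"pt": "pt_seconds", "dd": "d_dimer_ng_ml", "fib": "fibrinogen_mg_dl",
          "plt": "platelet_1e9_l", "ldh": "ldh", "hgb": "hemoglobin_g_dl",
          "inr": "inr", "gen": "genetic_positive"}


@pytest.mark.parametrize("score_id", list(_SCORE_AXES))
def test_engine_matches_nested_conditional_oracle_on_threshold_grid(
        make_record, score_id):
    """Exhaustive grid over each score's own components, straddling every
    threshold, compared against an independently hand-coded oracle."""
    axes = _SCORE_AXES[score_id]
    for combo in itertools.product(*(_GRIDS[a] for a in axes)):
        kwargs = {_FIELD[a]: v for a, v in zip(axes, combo)}
        res = compute_score(make_record(**kwargs), ScoreId(score_id))
        named = dict(zip(axes, combo))
        expected = oracle_score(score_id, **named)
        assert res.total == expected, (score_id, named)
        assert res.positive == (expected >= ORACLE_THRESHOLDS[score_id])


_RISK_DELTAS = {
    # field -> a shift toward higher risk
    "pt_seconds": +2.0,
    "d_dimer_ng_ml": +1500.0,
    "fibrinogen_mg_dl": -60.0,
    "platelet_1e9_l": -40.0,
    "ldh": +300.0,
    "hemoglobin_g_dl": -2.0,
    "inr": +0.5,
}


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    pt=st.floats(6, 40), dd=st.floats(0, 20000), fib=st.floats(0, 800),
    plt=st.floats(0, 500), ldh=st.floats(0, 3000), hgb=st.floats(3, 18),
    inr=st.floats(0.6, 5), gen=st.booleans(),
    field=st.sampled_from(list(_RISK_DELTAS) + ["genetic_positive"]),
)
def test_risk_direction_monotonicity(pt, dd, fib, plt, ldh, hgb, inr, gen, field):
    """Moving exactly one value in the risk direction never lowers any total."""
    from dicscore.cohort import PatientRecord

    base = dict(patient_id="h", subgroup=Subgroup.M3, pt_seconds=pt,
                d_dimer_ng_ml=dd, fibrinogen_mg_dl=fib, platelet_1e9_l=plt,
                ldh=ldh, hemoglobin_g_dl=hgb, inr=inr, genetic_positive=gen,
                bleeding=False)
    worse = dict(base)
    if field == "genetic_positive":
        worse[field] = True
    else:
        worse[field] = max(base[field] + _RISK_DELTAS[field], 1e-6)
        if field == "pt_seconds":
            worse[field] = min(worse[field], 119.0)
        if field == "inr":
            worse[field] = min(worse[field], 19.0)
    r0, r1 = PatientRecord(**base), PatientRecord(**worse)
    for sid in ScoreId:
        assert compute_score(r1, sid).total >= compute_score(r0, sid).total


class TestScoreAll:
    def test_cardinality(self, make_record):
        cohort = Cohort(records=[make_record(patient_id="a"),
                                 make_record(patient_id="b")])
        table = score_all(cohort, [ScoreId.ORIGINAL, ScoreId.M7])
        assert len(table.results) == 4 and not table.failures

    def test_empty_cohort(self):
        table = score_all(Cohort(records=[]), [ScoreId.ORIGINAL])
        assert table.results == [] and table.failures == []

    def test_missing_d_dimer_fails_original_but_not_m8(self, make_record):
        cohort = Cohort(records=[make_record(d_dimer_ng_ml=None)])
        table = score_all(cohort, [ScoreId.ORIGINAL, ScoreId.M8])
        assert len(table.results) == 1
        assert table.results[0].score_id == ScoreId.M8
        assert len(table.failures) == 1
        assert table.failures[0].score_id == ScoreId.ORIGINAL

    def test_order_invariance_of_totals(self, make_record):
        recs = [make_record(patient_id=f"p{i}", platelet_1e9_l=v)
                for i, v in enumerate([20.0, 80.0, 150.0])]
        fwd = score_all(Cohort(records=recs), [ScoreId.ORIGINAL])
        rev = score_all(Cohort(records=recs[::-1]), [ScoreId.ORIGINAL])
        totals_fwd = {r.patient_id: r.total for r in fwd.results}
        totals_rev = {r.patient_id: r.total for r in rev.results}
        assert totals_fwd == totals_rev

    def test_to_frame_layout(self, make_record):
        table = score_all(Cohort(records=[make_record()]), [ScoreId.M7])
        df = table.to_frame()
        assert list(df["score_id"]) == ["M7"]
        assert df.loc[0, "total"] == 0
        assert pd.isna(df.loc[0, "d_dimer"])
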