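"""Index engine: availability, dynamic weights, quality values, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wqikit import (
    MISSING,
    CriteriaSet,
    NoUsableParametersError,
    ParameterSpec,
    SampleRecord,
    WQIError,
    classify_wqi,
    compute_many,
    compute_wqi,
    default_criteria,
    dynamic_weights,
    quality_value_generic,
    quality_value_ph,
    resolve_availability,
)

from conftest import naive_wqi

TABLE_WEIGHT_SUM = 46  # 4+2+2+3+4+4+4+5+4+4+3+3+4 over the 13 default parameters


# ---------------------------------------------------------------------------
# types

class TestCriteriaValidation:
    def test_default_criteria_shape(self, criteria):
        assert len(criteria.included_names) == 13
        assert sum(p.weight for p in criteria if p.included) == TABLE_WEIGHT_SUM
        assert criteria["pH"].limit_kind == "band"
        assert not criteria["total_hardness"].included

    def test_duplicate_names_rejected(self):
        p = ParameterSpec("x", 1, limit=1)
        with pytest.raises(WQIError, match="duplicate"):
            CriteriaSet((p, p))

    def test_size_cap(self):
        params = tuple(ParameterSpec(f"p{i}", 1, limit=1) for i in range(41))
        with pytest.raises(WQIError, match="max"):
            CriteriaSet(params)

    def test_two_band_parameters_rejected(self):
        with pytest.raises(WQIError, match="band"):
            CriteriaSet(
                (
                    ParameterSpec("a", 1, "band", band_low=1, band_high=2),
                    ParameterSpec("b", 1, "band", band_low=1, band_high=2),
                )
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(weight=0, limit=1),
            dict(weight=1, limit=-5),
            dict(weight=1, limit_kind="band", band_low=9, band_high=7),
        ],
    )
    def test_bad_parameter_spec(self, kwargs):
        with pytest.raises(WQIError):
            ParameterSpec("x", **kwargs)

    def test_bad_selection_code(self):
        with pytest.raises(WQIError, match="selection code"):
            SampleRecord("s", {"a": 1.0}, overrides={"a": 2})


# ---------------------------------------------------------------------------
# availability

class TestAvailability:
    def test_all_present_all_used(self, criteria, at_limit_record):
        used, skipped = resolve_availability(at_limit_record, criteria)
        assert set(used) == set(criteria.included_names)
        assert skipped == {"total_hardness": "excluded_globally"}

    def test_override_and_missing_reasons(self, criteria, at_limit_record):
        """An excluded-by-code parameter and an absent value get distinct reasons."""
        rec = at_limit_record
        rec.overrides["nitrate"] = -1
        rec.values["ammonium"] = MISSING
        rec.values["iron"] = float("nan")
        rec.overrides["tds"] = 0
        used, skipped = resolve_availability(rec, criteria)
        assert len(used) == 9
        assert skipped["nitrate"] == "excluded_override"
        assert skipped["ammonium"] == "no_data"
        assert skipped["iron"] == "no_data"
        assert skipped["tds"] == "no_data"

    def test_global_exclusion_beats_record_code(self, criteria, at_limit_record):
        rec = at_limit_record
        rec.values["total_hardness"] = 100.0
        rec.overrides["total_hardness"] = 1
        used, skipped = resolve_availability(rec, criteria)
        assert "total_hardness" not in used
        assert skipped["total_hardness"] == "excluded_globally"

    def test_twenty_one_parameter_scenario(self):
        """21 selected, one excluded by code, one value absent -> 19 usable.

        Mirrors the per-record selection-code workflow: total hardness is
        struck with -1 and ammonium simply has no data.
        """
        specs = [ParameterSpec(f"p{i}", 1, limit=10.0) for i in range(19)]
        specs += [
            ParameterSpec("total_hardness", 2, limit=500.0),
            ParameterSpec("ammonium", 3, limit=1.5),
        ]
        crit = CriteriaSet(tuple(specs))
        values = {p.name: 1.0 for p in specs}
        del values["ammonium"]
        rec = SampleRecord("fig", values, overrides={"total_hardness": -1})
        used, skipped = resolve_availability(rec, crit)
        assert len(used) == 19
        assert skipped == {"total_hardness": "excluded_override", "ammonium": "no_data"}

    def test_all_missing_is_error(self, criteria):
        rec = SampleRecord("empty", {})
        with pytest.raises(NoUsableParametersError, match="empty"):
            resolve_availability(rec, criteria)


# ---------------------------------------------------------------------------
# weights

class TestDynamicWeights:
    def test_single_parameter(self, criteria):
        assert dynamic_weights(criteria, ["nitrate"]) == {"nitrate": 1.0}

    def test_all_thirteen(self, criteria):
        w = dynamic_weights(criteria, criteria.included_names)
        assert w["nitrate"] == pytest.approx(5 / TABLE_WEIGHT_SUM)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)

    def test_pair(self, criteria):
        w = dynamic_weights(criteria, ["pH", "nitrate"])
        assert w == {"pH": pytest.approx(4 / 9), "nitrate": pytest.approx(5 / 9)}

    def test_empty_used_is_error(self, criteria):
        with pytest.raises(WQIError):
            dynamic_weights(criteria, [])

    @settings(max_examples=200, deadline=None)
    @given(st.sets(st.sampled_from(list(default_criteria().included_names)), min_size=1))
    def test_weights_sum_to_one(self, used):
        w = dynamic_weights(default_criteria(), sorted(used))
        assert math.isclose(sum(w.values()), 1.0, abs_tol=1e-9)
        assert all(0 < v <= 1 for v in w.values())


# ---------------------------------------------------------------------------
# quality values

class TestQualityValues:
    @pytest.mark.parametrize(
        "ph,w,expected",
        [
            (7.0, 0.3, 0.0),
            (6.5, 1.0, 0.0),
            (8.5, 1.0, 0.0),
            (6.0, 0.5, 6.5 / 6.0 * 100 * 0.5),  # 54.1667
            (9.0, 1.0, 9.0 / 8.5 * 100),  # 105.882
        ],
    )
    def test_ph_band_rule(self, ph, w, expected):
        assert quality_value_ph(ph, w) == pytest.approx(expected, abs=1e-9)

    def test_ph_domain(self):
        with pytest.raises(WQIError):
            quality_value_ph(0.0, 1.0)
        with pytest.raises(WQIError):
            quality_value_ph(-1.0, 1.0)

    @pytest.mark.parametrize(
        "conc,limit,w,expected",
        [(250.0, 250.0, 1.0, 100.0), (0.0, 5.0, 0.7, 0.0), (25.0, 50.0, 0.5, 25.0)],
    )
    def test_generic_rule(self, conc, limit, w, expected):
        assert quality_value_generic(conc, limit, w) == pytest.approx(expected)

    def test_generic_domain(self):
        with pytest.raises(WQIError):
            quality_value_generic(-1.0, 5.0, 1.0)
        with pytest.raises(WQIError):
            quality_value_generic(1.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# classification

class TestClassification:
    @pytest.mark.parametrize(
        "wqi,label",
        [
            (0.0, "Excellent water quality"),
            (49.99, "Excellent water quality"),
            (50.0, "Good water quality"),
            (99.999, "Good water quality"),
            (100.0, "Poor water quality"),
            (162.08, "Poor water quality"),
            (200.0, "Very poor water quality"),
            (300.0, "Unsuitable for drinking"),
            (1e9, "Unsuitable for drinking"),
        ],
    )
    def test_bands(self, wqi, label):
        assert classify_wqi(wqi) == label

    def test_negative_rejected(self):
        with pytest.raises(WQIError):
            classify_wqi(-0.1)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    def test_total_and_exhaustive(self, wqi):
        assert classify_wqi(wqi) in {
            "Excellent water quality",
            "Good water quality",
            "Poor water quality",
            "Very poor water quality",
            "Unsuitable for drinking",
        }


# ---------------------------------------------------------------------------
# full index

class TestComputeWQI:
    def test_all_at_limit_scale_anchor(self, criteria, at_limit_record):
        """With pH mid-band, the anchor is 100 * (1 - w_pH); without pH, exactly 100."""
        res = compute_wqi(at_limit_record, criteria)
        w_ph = res.dynamic_weights["pH"]
        assert res.wqi == pytest.approx(100 * (1 - w_ph), abs=1e-9)

        at_limit_record.overrides["pH"] = -1
        res2 = compute_wqi(at_limit_record, criteria)
        assert res2.wqi == pytest.approx(100.0, abs=1e-9)

    def test_single_nitrate(self, criteria):
        res = compute_wqi(SampleRecord("s", {"nitrate": 10.0}), criteria)
        assert res.wqi == pytest.approx(20.0)
        assert res.class_label == "Excellent water quality"
        assert res.used == ["nitrate"]

    def test_result_invariants(self, criteria, at_limit_record):
        res = compute_wqi(at_limit_record, criteria)
        assert sum(res.dynamic_weights[n] for n in res.used) == pytest.approx(1.0, abs=1e-9)
        assert res.wqi == pytest.approx(sum(res.quality_values[n] for n in res.used), abs=1e-9)

    def test_all_missing_errors_with_sample_id(self, criteria):
        with pytest.raises(NoUsableParametersError, match="sparse-1"):
            compute_wqi(SampleRecord("sparse-1", {}), criteria)

    def test_ph_only_in_band_warns(self, criteria):
        res = compute_wqi(SampleRecord("p", {"pH": 7.2}), criteria)
        assert res.wqi == 0.0
        assert res.class_label == "Excellent water quality"
        assert res.warnings

    def test_monotonic_in_each_concentration(self, criteria, rng):
        """Raising any non-pH concentration never lowers the index."""
        base = {
            p.name: (7.0 if p.limit_kind == "band" else p.limit * rng.uniform(0.2, 1.5))
            for p in criteria
            if p.included
        }
        w0 = compute_wqi(SampleRecord("m", dict(base)), criteria).wqi
        for name in criteria.included_names:
            if criteria[name].limit_kind == "band":
                continue
            bumped = dict(base)
            bumped[name] *= 1.5
            assert compute_wqi(SampleRecord("m", bumped), criteria).wqi >= w0 - 1e-12

    def test_missing_data_consistency(self, criteria, rng):
        """Dropping a parameter whose ratio equals the weighted mean of the
        rest leaves the renormalized index unchanged."""
        names = [n for n in criteria.included_names if n != "pH"]
        keep, probe = names[:-1], names[-1]
        ratios = {n: rng.uniform(0.1, 2.0) for n in keep}
        wsum = sum(criteria[n].weight for n in keep)
        mean_ratio = sum(criteria[n].weight * ratios[n] for n in keep) / wsum
        values = {n: ratios[n] * criteria[n].limit for n in keep}
        values[probe] = mean_ratio * criteria[probe].limit
        with_probe = compute_wqi(SampleRecord("c", dict(values)), criteria).wqi
        del values[probe]
        without_probe = compute_wqi(SampleRecord("c", values), criteria).wqi
        assert with_probe == pytest.approx(without_probe, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_oracle_equivalence(self, data):
        """Engine output matches the naive one-shot formula on random
        records with random missingness."""
        criteria = default_criteria()
        names = list(criteria.included_names)
        present = data.draw(
            st.sets(st.sampled_from(names), min_size=1), label="present"
        )
        values = {}
        for n in sorted(present):
            if criteria[n].limit_kind == "band":
                values[n] = data.draw(
                    st.floats(min_value=1.0, max_value=13.0), label=n
                )
            else:
                values[n] = data.draw(
                    st.floats(min_value=0.0, max_value=criteria[n].limit * 4),
                    label=n,
                )
        res = compute_wqi(SampleRecord("h", values), criteria)
        assert res.wqi == pytest.approx(
            naive_wqi(criteria, values, sorted(present)), abs=1e-9
        )

    def test_compute_many_skip_mode(self, criteria):
        records = [
            SampleRecord("a", {"nitrate": 10.0}),
            SampleRecord("b", {}),
        ]
        with pytest.raises(NoUsableParametersError):
            compute_many(records, criteria)
        results = compute_many(records, criteria, on_error="skip")
        assert [r.sample_id for r in results] == ["a"]
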