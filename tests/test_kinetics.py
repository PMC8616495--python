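import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggremap import kinetics as kin
from aggremap import synth
from aggremap.imaging.types import AggregateObject, FrameMeasurement


def measurement(areas_and_circs, time_index=0):
    objs = [
        AggregateObject(label=i + 1, area_px=a, area_um2=a * 0.645**2,
                        perimeter_px=100.0, circularity=c, centroid=(0, 0),
                        bbox=(0, 0, 1, 1))
        for i, (a, c) in enumerate(areas_and_circs)
    ]
    return FrameMeasurement(time_index=time_index, n_aggregates=len(objs),
                            total_area_px=sum(a for a, _ in areas_and_circs),
                            objects=objs)


def model_curve(a_inf=0.4, k=1.0, duration=24.0, interval=0.25, well_id="w"):
    model = synth.KineticsModel(a_inf=a_inf, k=k)
    geom = synth.AcquisitionGeometry(duration=duration, frame_interval=interval)
    times, values = synth.simulate_kinetics(model, geom)
    return kin.AggregationCurve(times=times, normalized_area=values,
                                well_id=well_id)


class TestBuildCurve:
    def test_definition(self):
        ms = [measurement([(a, 0.5)], i) for i, a in enumerate([1000, 800, 600])]
        curve = kin.build_curve(ms, 0.25)
        assert np.allclose(curve.normalized_area, [1.0, 0.8, 0.6])
        assert np.allclose(curve.times, [0, 0.25, 0.5])

    def test_constant_area(self):
        ms = [measurement([(500, 0.5)], i) for i in range(5)]
        curve = kin.build_curve(ms, 0.25)
        assert np.allclose(curve.normalized_area, 1.0)

    def test_zero_initial_area_raises(self):
        ms = [measurement([], 0), measurement([(100, 0.5)], 1)]
        with pytest.raises(ValueError, match="zero"):
            kin.build_curve(ms, 0.25)

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError):
            kin.AggregationCurve(times=[0, 1], normalized_area=[0.9, 0.8])
        with pytest.raises(ValueError):
            kin.AggregationCurve(times=[0, 1, 1.5], normalized_area=[1, 0.9, 0.8])


class TestAreaAt:
    def test_at_zero(self):
        assert kin.area_at(model_curve(), 0.0) == 1.0

    def test_exponential_at_2h(self):
        expected = 0.4 + 0.6 * math.exp(-2.0)
        assert kin.area_at(model_curve(), 2.0) == pytest.approx(expected, abs=1e-12)

    def test_boundary(self):
        curve = model_curve(duration=6.0)
        assert kin.area_at(curve, 6.0) == curve.normalized_area[-1]

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            kin.area_at(model_curve(duration=6.0), 7.0)

    def test_off_grid_warns(self):
        with pytest.warns(UserWarning, match="off the sampling grid"):
            kin.area_at(model_curve(), 2.1)


class TestComputeAuc:
    def test_constant_one_24h(self):
        curve = model_curve(a_inf=1.0, duration=24.0)
        assert kin.compute_auc(curve, 24.0) == pytest.approx(24.0, abs=1e-12)

    def test_constant_one_6h(self):
        curve = model_curve(a_inf=1.0, duration=24.0)
        assert kin.compute_auc(curve, 6.0) == pytest.approx(6.0, abs=1e-12)

    def test_exponential_closed_form(self):
        # closed form: 0.4*24 + 0.6*(1 - e^-24)/1 = 10.2 (trapezoid error
        # at 15-min sampling is < 0.5%)
        curve = model_curve(a_inf=0.4, k=1.0, duration=24.0)
        closed = 0.4 * 24 + 0.6 * (1 - math.exp(-24.0))
        auc = kin.compute_auc(curve, 24.0)
        assert auc == pytest.approx(closed, rel=0.005)

    def test_window_exceeds_curve(self):
        with pytest.raises(ValueError):
            kin.compute_auc(model_curve(duration=6.0), 6.5)

    @given(a_inf=st.floats(0.05, 1.0), k=st.floats(0.0, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_auc_bounds(self, a_inf, k):
        curve = model_curve(a_inf=a_inf, k=k, duration=6.0)
        auc = kin.compute_auc(curve, 6.0)
        assert 0 < auc <= 6.0 + 1e-9
        if a_inf == 1.0 or k == 0.0:
            assert auc == pytest.approx(6.0)

    def test_pointwise_lower_curve_has_lower_auc_and_area2h(self):
        hi = model_curve(a_inf=0.6, k=1.0, duration=6.0)
        lo = model_curve(a_inf=0.3, k=1.0, duration=6.0)
        assert np.all(lo.normalized_area <= hi.normalized_area)
        assert kin.compute_auc(lo, 6.0) < kin.compute_auc(hi, 6.0)
        assert kin.area_at(lo, 2.0) < kin.area_at(hi, 2.0)


class TestEndCircularity:
    def test_mean_of_two(self):
        fm = measurement([(200, 0.6), (300, 0.8)])
        assert kin.end_circularity(fm) == pytest.approx(0.7)

    def test_single_disk_near_one(self):
        fm = measurement([(10_000, 0.997)])
        assert kin.end_circularity(fm) == pytest.approx(0.997)

    def test_no_objects_sentinel(self):
        with pytest.warns(UserWarning, match="no retained aggregates"):
            assert math.isnan(kin.end_circularity(measurement([])))


class TestSummarizeCondition:
    def test_single_replicate(self):
        curve = model_curve(duration=6.0)
        summary = kin.summarize_condition("ctrl", [curve],
                                          [measurement([(300, 0.7)])], 6.0)
        assert summary.n_replicates == 1
        assert summary.sds["auc"] == 0.0
        assert summary.means["auc"] == pytest.approx(
            kin.compute_auc(curve, 6.0))

    def test_two_replicate_arithmetic(self):
        reps = [
            kin.WellParameters(area_2h=0.5, auc=6.0, circularity_end=0.6,
                               window_h=24.0),
            kin.WellParameters(area_2h=0.7, auc=8.0, circularity_end=0.8,
                               window_h=24.0),
        ]
        summary = kin.ConditionSummary(label="x", replicates=reps)
        assert summary.means["auc"] == pytest.approx(7.0)
        # sample SD (ddof=1): sqrt(((6-7)^2 + (8-7)^2)/1) = sqrt(2)
        assert summary.sds["auc"] == pytest.approx(math.sqrt(2.0))

    def test_thirty_replicates_match_closed_form(self):
        model = synth.KineticsModel(a_inf=0.4, k=1.0)
        geom = synth.AcquisitionGeometry(duration=24.0)
        times, curves = synth.simulate_replicate_curves(model, geom, 30, seed=0)
        crv = [kin.AggregationCurve(times=times, normalized_area=c,
                                    well_id=f"w{i}")
               for i, c in enumerate(curves)]
        summary = kin.summarize_condition("c", crv, None, 24.0)
        assert summary.means["auc"] == pytest.approx(model.auc(24.0), rel=0.02)

    def test_mixed_intervals_rejected(self):
        a = model_curve(duration=6.0, interval=0.25)
        b = model_curve(duration=6.0, interval=0.5)
        with pytest.raises(ValueError, match="mixed frame intervals"):
            kin.summarize_condition("x", [a, b], None, 6.0)


def exact_mannwhitney_p(x, y):
    """Brute-force two-sided p by enumerating all rank arrangements."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    combined = x + y
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    u_obs = min(u_obs, n * m - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(n + m) if i not in idx]
        u = sum(1 for xi in xs for yj in ys if xi > yj) \
            + 0.5 * sum(1 for xi in xs for yj in ys if xi == yj)
        u = min(u, n * m - u)
        total += 1
        if u <= u_obs + 1e-9:
            count += 1
    return count / total


def summary_from_aucs(label, aucs):
    reps = [kin.WellParameters(area_2h=0.5, auc=a, circularity_end=0.5,
                               window_h=6.0) for a in aucs]
    return kin.ConditionSummary(label=label, replicates=reps)


class TestCompareConditions:
    def test_identical_sets_no_effect(self):
        a = summary_from_aucs("a", [6.0, 7.0, 8.0, 9.0])
        b = summary_from_aucs("b", [6.0, 7.0, 8.0, 9.0])
        res = kin.compare_conditions(a, b, "auc")
        assert res.p_value >= 0.99

    def test_separated_samples_exact_p(self):
        # {1,2,3} vs {10,11,12}: U = 0, two-sided p = 2/20 = 0.1 by
        # enumeration of all C(6,3) arrangements
        a = summary_from_aucs("a", [1, 2, 3])
        b = summary_from_aucs("b", [10, 11, 12])
        res = kin.compare_conditions(a, b, "auc")
        assert res.u_statistic in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1, abs=1e-9)
        assert res.p_value == pytest.approx(exact_mannwhitney_p([1, 2, 3],
                                                                [10, 11, 12]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 8, size=2)
        x = rng.normal(0, 1, sizes[0])
        y = rng.normal(0.8, 1, sizes[1])
        res = kin.compare_conditions(summary_from_aucs("a", x),
                                     summary_from_aucs("b", y), "auc")
        assert res.p_value == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-9)
        assert res.method == "exact"

    def test_unknown_parameter(self):
        a = summary_from_aucs("a", [1, 2, 3])
        with pytest.raises(KeyError):
            kin.compare_conditions(a, a, "slope")

    def test_plateau_shift_detected(self):
        # one seeded instance of the treated-vs-control power experiment
        geom = synth.AcquisitionGeometry(duration=6.0)
        _, ctrl = synth.simulate_replicate_curves(
            synth.KineticsModel(a_inf=0.35, k=1.0), geom, 60, seed=10)
        times, trt = synth.simulate_replicate_curves(
            synth.KineticsModel(a_inf=0.45, k=1.0), geom, 60, seed=11)
        mk = lambda label, mat: kin.summarize_condition(
            label,
            [kin.AggregationCurve(times=times, normalized_area=c,
                                  well_id=str(i)) for i, c in enumerate(mat)],
            None, 6.0)
        res = kin.compare_conditions(mk("ctrl", ctrl), mk("trt", trt), "auc")
        assert res.p_value < 1e-4
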