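"""Sequential and joint parameter estimation from longitudinal data."""

import numpy as np
import pytest

from adcascade import (ExclusionError, LongitudinalRecord, analytic_abeta,
                       calibrate, fit_abeta, fit_joint, fit_stage, joint_sse,
                       read_records, relative_error, sequential_fit, simulate,
                       write_records)
from adcascade.calibration import default_bounds


def _record_from(params, schedules, subject_id="S1", rng=None, cv=0.0):
    """Noiseless (or noisy) samples of the model trajectory."""
    t_end = max(a[-1] for a in schedules.values())
    traj = simulate(params, params.T0, t_end, step=0.01)
    series = {}
    for bm, ages in schedules.items():
        vals = np.interp(ages, traj.times, traj.series(bm))
        if cv > 0:
            vals = vals * (1 + cv * rng.standard_normal(vals.size))
        series[bm] = (np.asarray(ages, float), vals)
    return LongitudinalRecord(subject_id, series)


def _full_schedule(base=54.0):
    return {
        "Abeta": base + 2.0 * np.arange(6),
        "taup": base + 2.0 * np.arange(6),
        "tauo": base + 2.0 * np.arange(6),
        "N": base + 1.0 * np.arange(11),
        "C": base + 0.5 * np.arange(21),
    }


class TestFitAbeta:
    def test_exact_recovery_from_noiseless_logistic(self, slow_params):
        truth = slow_params.with_(lambda_Abeta=0.18, K_Abeta=260.0, A0=36.0)
        ages = np.arange(54.0, 65.0, 2.0)
        rec = LongitudinalRecord("S1", {
            "Abeta": (ages, analytic_abeta(ages, truth))})
        fit = fit_abeta(rec)
        assert fit.values["lambda_Abeta"] == pytest.approx(0.18, rel=0.01)
        assert fit.values["K_Abeta"] == pytest.approx(260.0, rel=0.01)
        assert fit.values["A0"] == pytest.approx(36.0, rel=0.01)

    def test_constant_series_yields_zero_growth(self):
        ages = np.array([54.0, 56.0, 58.0])
        rec = LongitudinalRecord("S1", {"Abeta": (ages, np.full(3, 80.0))})
        fit = fit_abeta(rec)
        assert fit.values["lambda_Abeta"] == 0.0
        assert not fit.identifiable

    def test_two_points_excluded_with_reason(self):
        rec = LongitudinalRecord("S1", {
            "Abeta": (np.array([54.0, 56.0]), np.array([70.0, 90.0]))})
        with pytest.raises(ExclusionError, match="at least 3"):
            fit_abeta(rec)


class TestFitStage:
    def test_linear_tauo_recovered_exactly(self):
        # slope 1.5/yr, value 30 at age 54 -> tauo0 = 24 at T0 = 50
        ages = np.array([54.0, 57.0, 60.0, 64.0])
        rec = LongitudinalRecord("S1", {"tauo": (ages, 30 + 1.5 * (ages - 54))})
        fit = fit_stage("tauo", rec, fixed={})
        assert fit.values["lambda_tauo"] == pytest.approx(1.5, abs=1e-6)
        assert fit.values["tauo0"] == pytest.approx(24.0, abs=1e-6)

    def test_neurodegeneration_stage_recovery(self, slow_params):
        sched = _full_schedule()
        rec = _record_from(slow_params, {"N": sched["N"]})
        upstream = {n: getattr(slow_params, n) for n in
                    ("lambda_Abeta", "K_Abeta", "A0", "lambda_tau", "K_taup",
                     "taup0", "lambda_tauo", "tauo0")}
        fit = fit_stage("N", rec, fixed=upstream)
        for name in ("lambda_N_tauo", "lambda_N_taup", "K_N", "N0"):
            assert fit.values[name] == pytest.approx(
                getattr(slow_params, name), rel=0.02), name

    def test_saturated_series_flagged_not_guessed(self, slow_params):
        ages = np.array([60.0, 61.0, 62.0, 63.0])
        rec = LongitudinalRecord("S1", {"N": (ages, np.full(4, 1.0))})
        upstream = {n: getattr(slow_params, n) for n in
                    ("lambda_Abeta", "K_Abeta", "A0", "lambda_tau", "K_taup",
                     "taup0", "lambda_tauo", "tauo0")}
        fit = fit_stage("N", rec, fixed=upstream)
        assert not fit.identifiable
        assert fit.values["lambda_N_tauo"] == 0.0
        assert fit.values["lambda_N_taup"] == 0.0

    def test_missing_upstream_parameters_rejected(self, slow_params):
        rec = _record_from(slow_params, {"taup": np.array([54.0, 56, 58.0])})
        with pytest.raises(ValueError, match="upstream"):
            fit_stage("taup", rec, fixed={})


class TestJoint:
    def test_noiseless_record_recovered_and_never_worsened(self, slow_params):
        rec = _record_from(slow_params, _full_schedule())
        init, stages = sequential_fit(rec)
        j_init = joint_sse(init, rec)
        params, j, flags = fit_joint(rec, init)
        assert j <= j_init + 1e-9
        for name in ("lambda_Abeta", "K_Abeta", "lambda_tau", "K_taup",
                     "lambda_tauo", "lambda_N_tauo", "lambda_N_taup", "K_N",
                     "lambda_CN", "lambda_Ctau", "K_C",
                     "A0", "taup0", "tauo0", "N0", "C0"):
            assert getattr(params, name) == pytest.approx(
                getattr(slow_params, name), rel=0.02), name

    def test_optimal_init_is_fixed_point(self, slow_params):
        rec = _record_from(slow_params, _full_schedule())
        params, j, flags = fit_joint(rec, slow_params)
        assert j <= joint_sse(slow_params, rec) + 1e-9
        for name in ("lambda_Abeta", "K_C", "N0"):
            assert getattr(params, name) == pytest.approx(
                getattr(slow_params, name), rel=1e-4)

    def test_sequential_then_joint_dominance_under_noise(self, slow_params,
                                                         rng):
        rec = _record_from(slow_params, _full_schedule(), rng=rng, cv=0.05)
        res_seq = calibrate(rec, joint=False)
        res = calibrate(rec, joint=True)
        assert res.joint_objective <= res_seq.joint_objective + 1e-9

    def test_reported_relative_errors_match_recomputation(self, slow_params,
                                                          rng):
        rec = _record_from(slow_params, _full_schedule(), rng=rng, cv=0.05)
        res = calibrate(rec)
        t_end = rec.max_age()
        traj = simulate(res.params, res.params.T0, t_end, step=0.01)
        for bm in rec.series:
            pred = np.interp(rec.ages(bm), traj.times, traj.series(bm))
            expect = relative_error(pred, rec.values(bm))
            assert res.relative_errors[bm] == pytest.approx(expect, rel=1e-9)


def test_relative_error_forms():
    assert relative_error([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert relative_error([2.0], [1.0]) == pytest.approx(1.0)
    assert relative_error([1.1, 0.9], [1.0, 1.0]) == pytest.approx(0.1)
    assert relative_error([1.1, 0.9], [1.0, 1.0],
                          form="rmsre") == pytest.approx(0.1)
    with pytest.raises(ValueError):
        relative_error([1.0], [0.0])
    with pytest.raises(ValueError):
        relative_error([1.0, 2.0], [1.0])


def test_datapoint_order_does_not_affect_fit(rng):
    ages = np.arange(54.0, 65.0, 2.0)
    vals = 260 / (1 + (260 / 36 - 1) * np.exp(-0.18 * (ages - 50)))
    fit1 = fit_abeta(LongitudinalRecord("A", {"Abeta": (ages, vals)}))
    perm = rng.permutation(len(ages))
    fit2 = fit_abeta(LongitudinalRecord("A", {"Abeta": (ages[perm],
                                                        vals[perm])}))
    assert fit1.values == fit2.values


def test_records_tidy_roundtrip(slow_params, tmp_path):
    recs = [_record_from(slow_params, _full_schedule(), subject_id=f"S{i}")
            for i in (1, 2)]
    path = tmp_path / "records.csv"
    write_records(recs, path)
    again = read_records(path)
    assert [r.subject_id for r in again] == ["S1", "S2"]
    for a, b in zip(recs, again):
        for bm in a.series:
            np.testing.assert_allclose(a.values(bm), b.values(bm))


def test_unknown_biomarker_rejected():
    with pytest.raises(ValueError, match="unknown biomarker"):
        LongitudinalRecord("S1", {"ptau181": (np.array([54.0, 55, 56]),
                                              np.array([1.0, 2, 3]))})


def test_capacity_bounds_bracket_observed_maximum(slow_params):
    rec = _record_from(slow_params, _full_schedule())
    b = default_bounds(rec)
    m = float(np.max(rec.values("C")))
    assert b["K_C"] == (pytest.approx(m), pytest.approx(10 * m))
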