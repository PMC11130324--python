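"""Objective, pattern search, parameter recovery and translation policy."""

import numpy as np
import pandas as pd
import pytest

from her2qsp.calibration import (
    CalibrationDataset,
    FitSpec,
    PolicyViolationError,
    fit,
    objective,
    pattern_search,
    predictions,
    translate_in_vivo,
)
from her2qsp.protocols import Regimen, RegimenArm, XenograftProtocol
from her2qsp.params import ParameterSet


def _toy_dataset(means, sds=None):
    n = len(means)
    return CalibrationDataset(pd.DataFrame({
        "condition": ["c"] * n, "time": np.arange(n, dtype=float),
        "readout": ["y"] * n, "mode": ["none"] * n,
        "mean": means, "sd": sds if sds is not None else [np.nan] * n,
    }))


def _toy_simulators(fn):
    """Simulator returning a (time, y) frame computed from the parameters."""

    def sim(params):
        t = np.arange(10.0)
        return pd.DataFrame({"time": t, "y": fn(params, t)})

    return {"c": sim}


def test_objective_zero_at_truth():
    sims = _toy_simulators(lambda p, t: p["a"] * t)
    truth = ParameterSet({"a": 2.0})
    ds = _toy_dataset(list(2.0 * np.arange(5.0)))
    assert objective(truth, ds, sims) == pytest.approx(0.0)


def test_objective_one_sd_off_equals_one():
    sims = _toy_simulators(lambda p, t: np.full_like(t, p["a"]))
    ds = _toy_dataset([4.0], sds=[1.0])
    assert objective(ParameterSet({"a": 5.0}), ds, sims) == pytest.approx(1.0)


def test_objective_matches_hand_summed_residuals(rng):
    sims = _toy_simulators(lambda p, t: p["a"] * t + p["b"])
    means = rng.normal(3.0, 1.0, 5)
    sds = rng.uniform(0.5, 2.0, 5)
    ds = _toy_dataset(list(means), sds=list(sds))
    p = ParameterSet({"a": 1.3, "b": 0.4})
    pred = 1.3 * np.arange(5.0) + 0.4
    expected = np.sum(((pred - means) / sds) ** 2)
    assert objective(p, ds, sims) == pytest.approx(expected)


def test_sd_imputation_rule():
    ds = _toy_dataset([10.0, 20.0], sds=[np.nan, 2.0])
    np.testing.assert_allclose(ds.weighting_sd(), [1.0, 2.0])  # 10% of mean
    np.testing.assert_allclose(ds.resampling_sd(), [1.0, 2.0])
    ds0 = _toy_dataset([10.0], sds=[0.0])
    assert ds0.weighting_sd()[0] == 1.0  # positive for weighting
    assert ds0.resampling_sd()[0] == 0.0  # noiseless data resample exactly


def test_dataset_roundtrip(tmp_path):
    ds = _toy_dataset([1.0, 2.0], sds=[0.1, 0.2])
    path = tmp_path / "ds.tsv"
    ds.to_csv(path)
    back = CalibrationDataset.from_csv(path)
    pd.testing.assert_frame_equal(back.frame[["mean", "sd"]], ds.frame[["mean", "sd"]])


def test_pattern_search_on_convex_quadratic():
    """GPS converges to the analytic minimum of a convex quadratic and its
    incumbent trace is monotone non-increasing."""
    target = np.array([0.3, 0.7])
    f = lambda x: float(np.sum((x - target) ** 2))
    x, fx, trace, n_evals, converged = pattern_search(f, np.array([0.9, 0.1]),
                                                      max_iter=400)
    assert converged
    np.testing.assert_allclose(x, target, atol=1e-5)
    assert np.all(np.diff(trace) <= 0)


def test_fit_returns_start_when_already_optimal():
    sims = _toy_simulators(lambda p, t: p["a"] * t)
    ds = _toy_dataset(list(2.0 * np.arange(5.0)), sds=[0.1] * 5)
    base = ParameterSet({"a": 2.0})
    res = fit(FitSpec(free={"a": (0.5, 8.0)}, n_starts=1, max_iter=50), ds,
              sims, base)
    assert res.loss == pytest.approx(0.0, abs=1e-12)
    assert res.fitted["a"] == pytest.approx(2.0, rel=1e-6)


def test_fit_is_deterministic():
    sims = _toy_simulators(lambda p, t: p["a"] * t + p["b"])
    ds = _toy_dataset(list(1.7 * np.arange(5.0) + 0.9), sds=[0.05] * 5)
    base = ParameterSet({"a": 1.0, "b": 1.0})
    spec = dict(free={"a": (0.2, 5.0), "b": (0.2, 5.0)}, seed=7, max_iter=150)
    r1 = fit(FitSpec(**spec), ds, sims, base)
    r2 = fit(FitSpec(**spec), ds, sims, base)
    assert r1.fitted == r2.fitted


def test_recovers_growth_parameters_from_xenograft(vivo_full):
    """Noiseless control-arm volumes identify umax and dmax within 5%."""
    from her2qsp.synthetic import FixtureSpec, generate

    truth = {"umax": vivo_full.params["umax"], "dmax": vivo_full.params["dmax"]}
    days = np.arange(0.0, 22.0, 3.0)
    # a cytotoxic arm scales with dmax and breaks the growth/death ridge
    arms = {"control": Regimen(()),
            "tdm1": Regimen((RegimenArm("T-DM1", 15.0, "q3w", route="iv"),))}
    ds, _ = generate(vivo_full, FixtureSpec("tumor_volume",
                                            design={"arms": arms, "days": days},
                                            noise=0.0))
    sims = vivo_full.xenograft_simulators(arms, XenograftProtocol(follow_up_days=21.0))
    base = vivo_full.params.override({"umax": ("x", 1.4), "dmax": ("x", 0.6)})
    res = fit(FitSpec(free={"umax": (truth["umax"] / 4, truth["umax"] * 4),
                            "dmax": (truth["dmax"] / 4, truth["dmax"] * 4)},
                      n_starts=1, max_iter=150), ds, sims, base)
    assert res.fitted["umax"] == pytest.approx(truth["umax"], rel=0.05)
    assert res.fitted["dmax"] == pytest.approx(truth["dmax"], rel=0.05)


def test_translation_policy(vivo_full):
    """In vivo translation frees only growth/death parameters; a control-only
    dataset re-estimates umax alone; signaling stays bit-identical."""
    with pytest.raises(PolicyViolationError):
        translate_in_vivo(vivo_full.params, _toy_dataset([1.0]), {}, free=["k8on"])

    # empty dataset -> identity
    res = translate_in_vivo(vivo_full.params, None)
    assert dict(res.params) == dict(vivo_full.params)

    from her2qsp.synthetic import FixtureSpec, generate

    days = np.arange(0.0, 16.0, 3.0)
    arms = {"control": Regimen(())}
    truth_umax = vivo_full.params["umax"] * 1.2
    shifted = vivo_full.with_overrides({"umax": truth_umax})
    ds, _ = generate(shifted, FixtureSpec("tumor_volume",
                                          design={"arms": arms, "days": days},
                                          noise=0.0))
    sims = vivo_full.xenograft_simulators(arms, XenograftProtocol(follow_up_days=15.0))
    res = translate_in_vivo(vivo_full.params, ds, sims, free=["umax", "dmax"],
                            max_iter=80, n_starts=1)
    # control-only data: policy restricts to umax
    assert set(res.fitted) == {"umax"}
    assert res.fitted["umax"] == pytest.approx(truth_umax, rel=0.05)
    for name, val in vivo_full.params.items():
        if name != "umax":
            assert res.params[name] == val


def test_prediction_normalization_modes():
    t = np.arange(4.0)
    sim = {"c": lambda p: pd.DataFrame({"time": t, "y": np.array([1.0, 2.0, 4.0, 2.0])})}
    frame = pd.DataFrame({
        "condition": ["c"] * 4, "time": t, "readout": ["y"] * 4,
        "mode": ["max"] * 4, "mean": [0.25, 0.5, 1.0, 0.5],
    })
    pred = predictions(ParameterSet(), CalibrationDataset(frame), sim)
    np.testing.assert_allclose(pred, [0.25, 0.5, 1.0, 0.5])
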