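"""LHS stratification, PRCC, Sobol indices and bootstrap uncertainty."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from her2qsp.calibration import CalibrationDataset, FitSpec
from her2qsp.params import ParameterSet
from her2qsp.sensitivity import (
    SensitivitySpec,
    UncertaintySpec,
    bootstrap_uncertainty,
    lhs_sample,
    prcc,
    relative_values,
    sobol_total,
)


def test_lhs_one_point_per_stratum():
    spec = SensitivitySpec(parameters=["p"], n=4, fold_range=(1.0, 2.0), seed=0)
    s = lhs_sample(spec, {"p": 1.0})["p"].to_numpy()
    # exactly one point in each quartile of [1, 2]
    counts, _ = np.histogram(s, bins=[1.0, 1.25, 1.5, 1.75, 2.0])
    assert list(counts) == [1, 1, 1, 1]


def test_lhs_marginals_close_to_uniform():
    """Column-wise Kolmogorov distance to uniform stays below the stratified-
    sampling bound 1/n + Dn for plain KS at n samples."""
    n = 256
    spec = SensitivitySpec(parameters=["a", "b", "c"], n=n, fold_range=(0.5, 2.0), seed=1)
    base = {"a": 1.0, "b": 10.0, "c": 0.1}
    df = lhs_sample(spec, base)
    for name, b in base.items():
        u = (df[name] / b - 0.5) / 1.5  # back to [0, 1]
        d = stats.kstest(u, "uniform").statistic
        assert d <= 1.0 / n + 1e-9  # stratification bounds KS at 1/n


def test_lhs_deterministic_given_seed():
    spec = SensitivitySpec(parameters=["a", "b"], n=16, seed=5)
    df1 = lhs_sample(spec, {"a": 1.0, "b": 2.0})
    df2 = lhs_sample(spec, {"a": 1.0, "b": 2.0})
    pd.testing.assert_frame_equal(df1, df2)


def _linear_samples(rng, n=400):
    X = pd.DataFrame({"x1": rng.uniform(0.5, 2, n), "x2": rng.uniform(0.5, 2, n),
                      "dummy": rng.uniform(0.5, 2, n)})
    y = 3.0 * X["x1"].to_numpy() - 1.0 * X["x2"].to_numpy()
    return X, y


def test_prcc_identifies_monotone_driver(rng):
    X, y = _linear_samples(rng)
    res = prcc(X, y)
    assert res.table.loc["x1", "prcc"] > 0.95
    assert res.table.loc["x2", "prcc"] < -0.95
    assert abs(res.table.loc["dummy", "prcc"]) < 0.05
    assert not res.table.loc["dummy", "significant"]


def test_prcc_invariant_under_monotone_output_transform(rng):
    """Rank-based PRCC is unchanged by a strictly monotone transform."""
    X, y = _linear_samples(rng)
    r1 = prcc(X, y).table["prcc"]
    r2 = prcc(X, np.exp(0.3 * y)).table["prcc"]
    np.testing.assert_allclose(r1, r2, atol=1e-12)


def test_prcc_constant_output_raises(rng):
    X, _ = _linear_samples(rng, n=50)
    with pytest.raises(RuntimeError):
        prcc(X, np.ones(50))


def test_prcc_drops_failed_runs(rng):
    X, y = _linear_samples(rng, n=200)
    y = y.copy()
    y[:5] = np.nan
    res = prcc(X, y)
    assert res.n_failed == 5
    assert res.n_used == 195
    y[:40] = np.nan
    with pytest.raises(RuntimeError):
        prcc(X, y)  # > 5% failures


def test_sobol_additive_toy_matches_analytic():
    """For f = a1 x1 + a2 x2 on independent uniforms the total-order indices
    equal the closed-form variance shares; an inert input scores ~0."""
    a1, a2 = 2.0, 1.0
    bounds = {"x1": (0.0, 1.0), "x2": (0.0, 1.0), "x3": (0.0, 1.0)}
    f = lambda x: a1 * x[0] + a2 * x[1]
    res = sobol_total(f, bounds, base_n=1024, seed=2)
    v1, v2 = a1**2 / 12, a2**2 / 12
    assert res.loc["x1", "S_T"] == pytest.approx(v1 / (v1 + v2), abs=0.03)
    assert res.loc["x2", "S_T"] == pytest.approx(v2 / (v1 + v2), abs=0.03)
    assert res.loc["x3", "S_T"] == pytest.approx(0.0, abs=0.02)
    assert res.loc["x1", "lo"] <= res.loc["x1", "S_T"] <= res.loc["x1", "hi"]


def test_sobol_rank_agrees_with_prcc_on_toy(rng):
    """Qualitative rank agreement between the two global methods."""
    f = lambda x: 3.0 * x[0] + 1.0 * x[1] + 0.1 * x[2]
    bounds = {f"x{i}": (0.5, 2.0) for i in range(3)}
    st_idx = sobol_total(f, bounds, base_n=256, seed=3)["S_T"]
    n = 300
    X = pd.DataFrame({f"x{i}": rng.uniform(0.5, 2, n) for i in range(3)})
    y = 3.0 * X["x0"] + 1.0 * X["x1"] + 0.1 * X["x2"]
    pr = prcc(X, y.to_numpy()).table["prcc"].abs()
    assert list(st_idx.sort_values(ascending=False).index) == \
        list(pr.sort_values(ascending=False).index)


# ---------------------------------------------------------------------------
# bootstrap uncertainty (cheap synthetic simulator, no ODEs)
# ---------------------------------------------------------------------------


def _line_problem(noise_sd):
    t = np.arange(8.0)
    truth = ParameterSet({"slope": 2.0, "offset": 1.0})
    means = truth["slope"] * t + truth["offset"]
    frame = pd.DataFrame({"condition": "c", "time": t, "readout": "y",
                          "mode": "none", "mean": means, "sd": noise_sd})
    sims = {"c": lambda p: pd.DataFrame({"time": t, "y": p["slope"] * t + p["offset"]})}
    return CalibrationDataset(frame), sims, truth


def test_bootstrap_zero_dispersion_degenerates():
    """Noiseless data yield identical estimates in every resample."""
    ds, sims, truth = _line_problem(noise_sd=0.0)
    spec = UncertaintySpec(parameters=["slope", "offset"], n_resamples=5,
                           seed=0, max_iter=60)
    table = bootstrap_uncertainty(spec, ds, sims, truth)
    assert table["slope"].nunique() == 1
    assert table["offset"].nunique() == 1


def test_bootstrap_covers_truth():
    ds, sims, truth = _line_problem(noise_sd=0.3)
    spec = UncertaintySpec(parameters=["slope", "offset"], n_resamples=24,
                           seed=1, max_iter=80)
    table = bootstrap_uncertainty(spec, ds, sims, truth)
    rel = relative_values(table, truth)
    for p in ("slope", "offset"):
        lo, hi = np.quantile(table[p].dropna(), [0.05, 0.95])
        assert lo <= truth[p] <= hi
        assert 0.5 < rel[p].median() < 1.5


def test_bootstrap_missing_sd_uses_imputation(rng):
    """With the sd column absent, resampling applies the 10%-of-mean rule."""
    t = np.arange(5.0)
    frame = pd.DataFrame({"condition": "c", "time": t, "readout": "y",
                          "mode": "none", "mean": 10.0 * np.ones(5)})
    ds = CalibrationDataset(frame)
    np.testing.assert_allclose(ds.resampling_sd(), 1.0)
    draws = ds.resampled(rng).frame["mean"]
    assert draws.std() > 0.2  # noise actually injected
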