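"""Compartmental PK: closed forms, metabolite cascade, mass balance."""

import numpy as np
import pytest

from her2qsp import ConfigError, DoseEvent, PKParams, capecitabine_cascade, simulate_pk, tumor_exposure
from her2qsp.params import dose_to_nmol


def test_no_doses_all_zero():
    df = simulate_pk(PKParams.lapatinib(), [], duration=24.0)
    assert np.all(df["central_nM"] == 0.0)
    assert np.all(df["peripheral_nM"] == 0.0)


def test_one_compartment_closed_form():
    """With Q = 0 a single IV bolus decays as (D/Vc) exp(-CL/Vc t)."""
    p = PKParams("drugx", route="iv", Vc=2.0, Vp=1.0, CL=1.0, Q=0.0, Kp=1.0, mw=500.0)
    dose = 10.0  # mg/kg
    df = simulate_pk(p, [DoseEvent("drugx", dose, 0.0, "iv")], duration=12.0)
    t = df["time_h"].to_numpy()
    c0 = dose_to_nmol("drugx", dose, mw=500.0) / (p.Vc * 0.020)
    expected = c0 * np.exp(-(p.CL / p.Vc) * t)
    # the t = 0 sample is recorded before the bolus lands
    np.testing.assert_allclose(df["central_nM"][1:], expected[1:], rtol=1e-5)


def test_mass_balance():
    """Eliminated + remaining equals administered to 1e-6 relative."""
    p = PKParams.lapatinib()
    doses = [DoseEvent("lapatinib", 100.0, 24.0 * d, "oral") for d in range(3)]
    df = simulate_pk(p, doses, duration=96.0)
    administered = 3 * dose_to_nmol("lapatinib", 100.0)
    total = df["eliminated_nmol"] + df["remaining_nmol"]
    np.testing.assert_allclose(total.iloc[-1], administered, rtol=1e-6)


def test_dose_proportionality_and_superposition():
    p = PKParams.pyrotinib()
    one = simulate_pk(p, [DoseEvent("pyrotinib", 10.0, 0.0, "oral")], 48.0)
    two = simulate_pk(p, [DoseEvent("pyrotinib", 20.0, 0.0, "oral")], 48.0)
    np.testing.assert_allclose(2 * one["central_nM"], two["central_nM"], rtol=1e-6)
    both = simulate_pk(p, [DoseEvent("pyrotinib", 10.0, 0.0, "oral"),
                           DoseEvent("pyrotinib", 10.0, 24.0, "oral")], 48.0,
                       n_points=481)
    one = simulate_pk(p, [DoseEvent("pyrotinib", 10.0, 0.0, "oral")], 48.0,
                      n_points=481)
    t = one["time_h"].to_numpy()
    shifted = np.interp(t - 24.0, t, one["central_nM"], left=0.0)
    np.testing.assert_allclose(both["central_nM"], one["central_nM"] + shifted,
                               rtol=1e-5, atol=1e-4)


def test_nonnegative_compartments():
    p = PKParams.tdm1()
    df = simulate_pk(p, [DoseEvent("T-DM1", 3.0, 0.0, "iv")], 21 * 24.0)
    assert (df.drop(columns="time_h") >= -1e-12).all().all()


def test_tdm1_biexponential_decline():
    """Two-compartment ADC PK declines biexponentially: the late log-slope is
    shallower than the early one."""
    df = simulate_pk(PKParams.tdm1(), [DoseEvent("T-DM1", 3.0, 0.0, "iv")], 21 * 24.0)
    t, c = df["time_h"].to_numpy(), df["central_nM"].to_numpy()
    early = (np.log(c[2]) - np.log(c[1])) / (t[2] - t[1])
    sel = t > 300
    late = np.polyfit(t[sel], np.log(c[sel]), 1)[0]
    assert early < late < 0


def test_capecitabine_cascade_bateman():
    """Sequential first-order chain agrees with the matrix-exponential
    solution and metabolite Tmax values are ordered parent -> 5-FU."""
    from scipy.linalg import expm

    p = PKParams.capecitabine()
    dose = 755.0
    df = capecitabine_cascade(p, [DoseEvent("capecitabine", dose, 0.0, "oral")],
                              duration=12.0, n_points=200)
    ka = p.ka
    k1, k2, k3, k4 = p.cap_chain
    A = np.array([
        [-ka, 0, 0, 0, 0],
        [ka, -k1, 0, 0, 0],
        [0, k1, -k2, 0, 0],
        [0, 0, k2, -k3, 0],
        [0, 0, 0, k3, -k4],
    ])
    a0 = np.array([dose_to_nmol("capecitabine", dose), 0, 0, 0, 0])
    cols = ["capecitabine_nM", "dfcr_nM", "dfur_nM", "fu5_nM"]
    vols = [p.Vc, p.V_met, p.V_met, p.V_met]
    for i, t in enumerate(df["time_h"]):
        exact = expm(A * t) @ a0
        for j, (col, v) in enumerate(zip(cols, vols)):
            assert df[col].iloc[i] == pytest.approx(exact[j + 1] / (v * 0.020),
                                                    rel=1e-6, abs=1e-6)
    tmax = [df["time_h"].iloc[df[c].idxmax()] for c in cols]
    assert tmax == sorted(tmax)  # each metabolite peaks at or after its precursor


def test_cascade_without_conversion_gives_no_fu():
    p = PKParams("capecitabine", route="oral", ka=2.0, Vc=2.0, CL=0.0, Q=0.0,
                 Kp=1.0, cap_chain=(0.0, 0.0, 0.0, 1.0), mw=359.0)
    df = capecitabine_cascade(p, [DoseEvent("capecitabine", 400.0, 0.0, "oral")], 24.0)
    assert np.all(df["fu5_nM"] == 0.0)


def test_tumor_exposure_partition():
    p = PKParams.lapatinib()
    df = simulate_pk(p, [DoseEvent("lapatinib", 60.0, 0.0, "oral")], 24.0)
    full = tumor_exposure(df, p)
    np.testing.assert_allclose(full["tumor_nM"], p.Kp * df["central_nM"])
    p0 = PKParams("lapatinib", route="oral", ka=1.0, Vc=4.0, Vp=2.0, CL=1.6,
                  Q=0.1, Kp=0.0, mw=581.0)
    assert np.all(tumor_exposure(df, p0)["tumor_nM"] == 0.0)


def test_adc_tumor_influx_integral():
    """Cumulative first-order tumor influx matches a trapezoid-rule oracle on
    a fine plasma grid."""
    p = PKParams.tdm1()
    df = simulate_pk(p, [DoseEvent("T-DM1", 3.0, 0.0, "iv")], 240.0, n_points=2000)
    exp = tumor_exposure(df, p)
    t = df["time_h"].to_numpy()
    amount = df["central_nM"].to_numpy() * p.Vc * 0.020
    oracle = np.trapezoid(p.k_tu * amount[: len(t)], t)
    assert exp["cumulative_influx_nM"].iloc[-1] == pytest.approx(oracle, rel=1e-6)


def test_event_drug_mismatch():
    with pytest.raises(ConfigError):
        simulate_pk(PKParams.lapatinib(), [DoseEvent("pyrotinib", 10.0, 0.0, "oral")], 24.0)
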