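"""Cell-level drug mechanisms: TKI inhibition, ligand rescue, ADC payload."""

import numpy as np
import pytest

from her2qsp import DrugMechanism, TumorGrowthModel, adc_bath, bath, ligand_bath
from her2qsp.network import NM_PER_MOLECULE
from her2qsp.simulate import simulate_timecourse


@pytest.fixture(scope="module")
def baseline(skbr3_lap, skbr3_lap_ss):
    traj = skbr3_lap.simulate(1.0, y0=skbr3_lap_ss)
    return traj.final("pERK"), traj.final("pAKT"), traj.final("tHER3")


def test_lapatinib_shuts_down_pathway(skbr3_lap, baseline):
    """100 nM lapatinib alone drives pERK and pAKT below 5% of baseline at 1 h."""
    pERK0, pAKT0, _ = baseline
    traj = skbr3_lap.simulate(1.0, events=[bath("lapatinib", 100.0)])
    assert traj.final("pERK") / pERK0 < 0.05
    assert traj.final("pAKT") / pAKT0 < 0.05


def test_zero_concentration_is_no_op(skbr3_lap, skbr3_lap_ss):
    ref = skbr3_lap.simulate(6.0, y0=skbr3_lap_ss)
    zero = skbr3_lap.simulate(6.0, y0=skbr3_lap_ss, events=[bath("lapatinib", 0.0)])
    np.testing.assert_allclose(zero.states[-1], ref.states[-1], rtol=1e-6, atol=1e-9)


def test_nrg1_rescues_signaling_at_high_lapatinib(skbr3_lap, baseline):
    """NRG1 keeps pERK/pAKT above 20% of baseline even at 1000 nM lapatinib."""
    pERK0, pAKT0, _ = baseline
    traj = skbr3_lap.simulate(24.0, events=[bath("lapatinib", 1000.0),
                                            ligand_bath("NRG1", 50.0)])
    assert traj.final("pERK") / pERK0 > 0.20
    assert traj.final("pAKT") / pAKT0 > 0.20


def test_nrg1_downregulates_her3(skbr3_lap, baseline):
    """Ligand-induced internalization lowers total HER3 after 24 h of NRG1."""
    *_, tHER3_0 = baseline
    traj = skbr3_lap.simulate(24.0, events=[ligand_bath("NRG1", 50.0)])
    assert traj.final("tHER3") < tHER3_0


def test_lapatinib_upregulates_her3(skbr3_lap, baseline):
    """AKT shutdown de-represses FOXO-driven HER3 synthesis."""
    *_, tHER3_0 = baseline
    traj = skbr3_lap.simulate(24.0, events=[bath("lapatinib", 100.0)])
    assert traj.final("tHER3") > tHER3_0


def test_pyrotinib_receptor_regulation():
    """Pyrotinib lowers total HER2 but leaves total HER3 at or above control."""
    m = TumorGrowthModel.skbr3(drugs=["pyrotinib"])
    ctrl = m.simulate(24.0)
    pyr = m.simulate(24.0, events=[bath("pyrotinib", 20.0)])
    assert pyr.final("tHER2") < ctrl.final("tHER2")
    assert pyr.final("tHER3") >= ctrl.final("tHER3")


def test_tki_inhibition_is_monotone_in_dose(skbr3_lap):
    """Steady-window pERK and pAKT are non-increasing over a 10-point log grid."""
    perk, pakt = [], []
    for c in np.logspace(0, 3, 10):
        traj = skbr3_lap.simulate(24.0, events=[bath("lapatinib", c)])
        perk.append(traj.final("pERK"))
        pakt.append(traj.final("pAKT"))
    assert np.all(np.diff(perk) <= 1e-6)
    assert np.all(np.diff(pakt) <= 1e-6)


def test_adc_requires_internalization(skbr3_vitro_full):
    """With kint_ADC = 0 no payload accumulates."""
    m = skbr3_vitro_full
    params = m.params.override({"T-DM1.kint_ADC": 0.0})
    traj = simulate_timecourse(m.network, params, m.steady_state(), 48.0,
                               events=[adc_bath("T-DM1", 10.0)])
    assert np.all(traj.species("PL_in:T-DM1") == 0.0)


def test_dm1_payload_cannot_reenter(skbr3_vitro_full):
    """The effluxed DM1 pool only grows and never refills the cell."""
    m = skbr3_vitro_full
    traj = simulate_timecourse(m.network, m.params, m.steady_state(), 48.0,
                               events=[adc_bath("T-DM1", 10.0)])
    ple = traj.species("PL_ex:T-DM1")
    assert np.all(np.diff(ple) >= -1e-9)
    # wiring check: no reaction consumes the DM1 extracellular pool
    for r in m.network.reactions:
        consumed = r.stoich.get("PL_ex:T-DM1", 0)
        c = consumed[0] if isinstance(consumed, tuple) else consumed
        assert c >= 0 or not r.name.startswith("perm")


def test_dxd_payload_permeates_both_ways(skbr3_vitro_full):
    """DXd exchanges across the membrane: an extracellular payload bath loads
    the cell even without any ADC."""
    m = skbr3_vitro_full
    net = m.network
    y0 = m.steady_state().copy()
    y0[net.sidx["PL_ex:T-DXd"]] = 50.0
    traj = simulate_timecourse(net, m.params, y0, 4.0)
    assert traj.final("PL_in:T-DXd") > 1.0  # bystander re-entry
    y0b = m.steady_state().copy()
    y0b[net.sidx["PL_ex:T-DM1"]] = 50.0
    trajb = simulate_timecourse(net, m.params, y0b, 4.0)
    assert trajb.final("PL_in:T-DM1") == 0.0  # DM1 cannot re-enter


def test_payload_cascade_matches_analytic_chain(skbr3_vitro_full):
    """Single-cell payload mass balance agrees with the hand-integrated
    internalization -> processing -> payload chain (Bateman-type oracle)."""
    m = skbr3_vitro_full
    net = m.network
    p = dict(m.params)
    kint, kproc, krec = p["T-DM1.kint_ADC"], p["T-DM1.kdeg_ADC_2"], p["T-DM1.k_recycle"]
    kloss = p["T-DM1.kout_PL"] + p["T-DM1.kdeg_PL"]
    dar = p["T-DM1.DAR"]
    # freeze binding so the chain starts from a bolus of surface complexes
    params = m.params.override({"T-DM1.kon_ADC": 0.0, "T-DM1.koff_ADC": 0.0,
                                "T-DM1.kclr_PLex": 0.0})
    y0 = np.zeros(net.n_species)
    c0 = 1.0e5
    y0[net.sidx["ADC:HER2:T-DM1"]] = c0
    traj = simulate_timecourse(net, params, y0, 24.0,
                               t_eval=np.linspace(0, 24, 25), turnover_off=False)

    t = traj.times
    k2 = kproc + krec
    cah = c0 * np.exp(-kint * t)
    cint = c0 * kint / (k2 - kint) * (np.exp(-kint * t) - np.exp(-k2 * t))
    np.testing.assert_allclose(traj.species("ADC:HER2:T-DM1"), cah, rtol=1e-5, atol=1e-3)
    np.testing.assert_allclose(traj.species("ADCint:T-DM1"), cint, rtol=1e-4, atol=1e-2)
    # payload: three-stage Bateman chain with source kproc*cint and loss kloss
    def bateman(t, k_in, rates, amps):
        return sum(a * np.exp(-r * t) for r, a in zip(rates, amps))

    # solve the linear chain exactly via eigen-decomposition of the 3x3 system
    A = np.array([[-kint, 0, 0], [kint, -k2, 0],
                  [0, kproc * dar * NM_PER_MOLECULE, -kloss]])
    from scipy.linalg import expm

    for i, ti in enumerate(t):
        exact = expm(A * ti) @ np.array([c0, 0.0, 0.0])
        assert traj.species("PL_in:T-DM1")[i] == pytest.approx(exact[2], rel=1e-4, abs=1e-6)
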