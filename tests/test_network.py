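"""Structure, conservation and oracle checks of the reaction network."""

import numpy as np
import pytest
from scipy.linalg import expm

from her2qsp import (
    CellLineConfig,
    ConfigError,
    DrugMechanism,
    GrowthDeathParams,
    SignalingParams,
    TumorGrowthModel,
    adc_bath,
    bath,
    build_network,
    ligand_bath,
    simulate_timecourse,
)
from her2qsp.network import MA, Reaction, ReactionNetwork, Species
from her2qsp.simulate import initialize_steady_state

DIMERS = {"D1", "D2", "D3", "D4", "D5"}


def test_structural_budget(vivo_full):
    """Full model with PK for all five drugs stays within 60 species / 80 reactions."""
    net = vivo_full.network
    assert net.n_species <= 60
    assert net.n_reactions <= 80


def test_dimer_inventory(skbr3_lap):
    """Exactly the five canonical dimers; HER3 homodimers absent (kinase-dead)."""
    names = {s.name for s in skbr3_lap.network.species}
    assert DIMERS <= names
    assert not any(n.startswith("D3x") or n == "D_HER3_HER3" for n in names)
    # every dimer contains HER2 (no HER3-HER3 pairing possible)
    for s in skbr3_lap.network.species:
        if s.name in DIMERS:
            assert s.monomers.get("HER2", 0) >= 1


def test_cell_line_presets():
    skbr3 = CellLineConfig.skbr3()
    assert skbr3.receptors_per_cell == {
        "EGFR": 150_000.0, "HER2": 1_500_000.0, "HER3": 40_000.0, "HER4": 2_000.0}
    assert CellLineConfig.nci_n87().receptor("HER2") == 0.5e6
    assert CellLineConfig.zr75_1().receptor("HER2") == 0.1e6
    with pytest.raises(ConfigError):
        CellLineConfig("bad", {"EGFR": -1, "HER2": 1, "HER3": 1, "HER4": 1})
    with pytest.raises(ConfigError):
        CellLineConfig("bad", {"EGFR": 1, "HER2": 1, "HER3": 1, "HER5": 1})


def test_initial_amounts(skbr3_lap, vivo_full):
    net = skbr3_lap.network
    y0 = net.pack(skbr3_lap.params).y0
    assert y0[net.sidx["HER2"]] == 1_500_000.0
    m = TumorGrowthModel.from_ihc("2+")
    assert m.network.pack(m.params).y0[m.network.sidx["HER2"]] == 500_000.0


def test_zero_receptors_zero_phospho():
    """A receptor-null configuration produces identically zero phospho-species."""
    cell = CellLineConfig("null", {r: 0.0 for r in ("EGFR", "HER2", "HER3", "HER4")},
                          growth=GrowthDeathParams())
    m = TumorGrowthModel(cell)
    traj = m.simulate(24.0, y0=m.network.pack(m.params).y0,
                      events=[ligand_bath("EGF", 100.0), ligand_bath("NRG1", 50.0)])
    for d in DIMERS:
        assert np.all(traj.species("p" + d) == 0.0)
    assert np.all(traj.readout("pHER2") == 0.0)


def test_negative_rate_rejected():
    with pytest.raises(ConfigError):
        SignalingParams(k8on=-1.0)
    with pytest.raises(ConfigError):
        GrowthDeathParams(umax=0.1, dmax=0.2)  # shrinkage baseline is invalid


def test_receptor_conservation(skbr3_vitro_full):
    """With turnover fluxes disabled, receptor monomer totals are conserved to
    1e-6 relative along a stimulated, drug-treated trajectory."""
    m = skbr3_vitro_full
    ss = m.steady_state()
    traj = simulate_timecourse(
        m.network, m.params, ss, 48.0,
        events=[ligand_bath("EGF", 100.0), bath("lapatinib", 50.0),
                adc_bath("T-DM1", 1.0)],
        turnover_off=True)
    t0 = m.network.monomer_totals(traj.states[0])
    t1 = m.network.monomer_totals(traj.states[-1])
    for rec, total in t0.items():
        if total > 0:
            assert abs(t1[rec] - total) / total < 1e-6


def test_rhs_matches_naive_interpreter(skbr3_vitro_full, rng):
    """Packed-kernel RHS equals the per-reaction Python interpreter at 100
    random states (independent evaluation paths)."""
    m = skbr3_vitro_full
    net = m.network
    packed = net.pack(m.params)
    u0 = np.zeros(len(net.inputs))
    u0[net.uidx["EGF"]] = 5.0
    u0[net.uidx["lapatinib"]] = 30.0
    u0[net.uidx["5-FU"]] = 500.0
    f = packed.rhs(u0)
    scales = np.array([s.scale for s in net.species])
    for _ in range(100):
        y = rng.uniform(0.0, 1.0, net.n_species) * scales
        expected = net.naive_rhs(y, u0, m.params)
        got = f(0.0, y)
        np.testing.assert_allclose(got, expected, rtol=1e-9,
                                   atol=1e-9 * np.abs(expected).max())


def _toy_network(species, reactions, params):
    cell = CellLineConfig("toy", {r: 0.0 for r in ("EGFR", "HER2", "HER3", "HER4")},
                          growth=GrowthDeathParams())
    species = list(species) + [Species("N", "cells", 1.0, 1.0)]
    net = ReactionNetwork(species, reactions, ["x"], {}, "in_vitro", cell, [])
    return net, dict(params)


def test_toy_dimer_equilibrium():
    """Monomer-dimer system with synthesis/degradation reaches the equilibrium
    solved independently from the algebraic balance equations."""
    ks, kd, kon, koff = 50.0, 0.5, 1e-3, 2.0
    net, params = _toy_network(
        [Species("M", "a", 10.0, 100.0), Species("D", "a", 0.0, 100.0)],
        [
            Reaction("syn", MA, {"M": 1}, k="ks"),
            Reaction("deg", MA, {"M": -1}, k="kd", A="M"),
            Reaction("dim", MA, {"M": -2, "D": 1}, k="kon", A="M", B="M",
                     reversible=True, kr="koff", RA="D"),
        ],
        {"ks": ks, "kd": kd, "kon": kon, "koff": koff},
    )
    ss = initialize_steady_state(net, params, tol=1e-10)
    m_star = ks / kd  # synthesis/degradation balance fixes the monomer
    d_star = kon * m_star**2 / koff
    assert ss[net.sidx["M"]] == pytest.approx(m_star, rel=1e-6)
    assert ss[net.sidx["D"]] == pytest.approx(d_star, rel=1e-6)


def test_toy_linear_matches_matrix_exponential():
    """Two-species interconversion agrees with the closed-form expm solution."""
    k1, k2 = 0.7, 0.3
    net, params = _toy_network(
        [Species("A", "a", 10.0, 10.0), Species("B", "a", 0.0, 10.0)],
        [Reaction("fwd", MA, {"A": -1, "B": 1}, k="k1", A="A",
                  reversible=True, kr="k2", RA="B")],
        {"k1": k1, "k2": k2},
    )
    y0 = net.pack(params).y0
    traj = simulate_timecourse(net, params, y0, 5.0, t_eval=np.linspace(0, 5, 11))
    A = np.array([[-k1, k2], [k1, -k2]])
    for i, t in enumerate(traj.times):
        exact = expm(A * t) @ y0[:2]
        np.testing.assert_allclose(traj.states[i, :2], exact, rtol=1e-5, atol=1e-8)


def test_network_tables_export(vivo_full, tmp_path):
    sp, rx = vivo_full.network.to_tables()
    assert len(sp) == vivo_full.network.n_species
    assert len(rx) == vivo_full.network.n_reactions
    sp.to_csv(tmp_path / "species.tsv", sep="\t", index=False)
    rx.to_csv(tmp_path / "reactions.tsv", sep="\t", index=False)
    assert (tmp_path / "reactions.tsv").exists()
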