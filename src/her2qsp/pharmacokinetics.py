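"""Mouse plasma PK: compartment models, capecitabine cascade, tumor coupling.

Amounts are carried in nmol; concentrations reported in nM (amount divided by
compartment volume x 20 g body weight).  The same PK blocks are embedded in
the full in vivo network; this module exposes them stand-alone, with explicit
elimination sink species so mass balance can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .network import ReactionNetwork, Species, build_network, derived_pk_rates, _add_pk_block
from .params import (
    ADC,
    CellLineConfig,
    ConfigError,
    DRUG_PRESETS,
    DrugMechanism,
    GrowthDeathParams,
    MOUSE_BODY_WEIGHT_KG,
    ParameterSet,
    PKParams,
    SignalingParams,
    dose_to_nmol,
)
from . import simulate as _sim


@dataclass(frozen=True)
class DoseEvent:
    """One administration: drug, mg/kg amount, time (h), route."""

    drug: str
    amount: float
    time: float
    route: str = "oral"

    def __post_init__(self):
        if self.amount < 0:
            raise ConfigError("dose amount must be >= 0")


def _pk_only_network(params: PKParams, mech: DrugMechanism | None = None,
                     sinks: bool = True) -> ReactionNetwork:
    """A network containing just one drug's PK block (plus sinks)."""
    dn = params.drug
    if mech is None:
        preset = DRUG_PRESETS.get(dn)
        mech = preset() if preset else DrugMechanism(dn, "chemo_payload")
    sp: list[Species] = []
    rx: list = []
    u_coupl: dict = {}
    _add_pk_block(sp, rx, u_coupl, params, dn, mech, sinks)
    # ADC blocks reference the tumor pool species
    if mech.kind == ADC:
        sp.append(Species(f"ADC_tu:{dn}", "nM", 0.0, 1.0))
    cell = CellLineConfig("none", {r: 0.0 for r in ("EGFR", "HER2", "HER3", "HER4")},
                          growth=GrowthDeathParams())
    inputs = ["EGF", "NRG1", "lapatinib", "pyrotinib", "T-DM1",
              "T-DXd", "5-FU", "PL:T-DM1", "PL:T-DXd"]
    if dn not in inputs:
        inputs.append(dn)
    net = ReactionNetwork(sp, rx, inputs, {}, "in_vivo", cell, [mech], {dn: params})
    net.u_couplings = u_coupl
    return net


def _pk_parameter_set(params: PKParams, mech: DrugMechanism) -> ParameterSet:
    ps = ParameterSet.from_components(SignalingParams(), GrowthDeathParams(),
                                      {mech.name: mech}, {params.drug: params})
    return derived_pk_rates(ps)


def simulate_pk(
    params: PKParams,
    events: Iterable[DoseEvent],
    duration: float,
    n_points: int = 400,
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Concentration-time table for one drug's compartments.

    IV doses enter the central compartment as boluses; oral doses pass through
    a first-order absorption depot.  Returns a wide table with one
    ``<compartment>_nM`` column per compartment plus nmol bookkeeping columns.
    """
    events = sorted(events, key=lambda e: e.time)
    for e in events:
        if e.drug != params.drug:
            raise ConfigError(f"event drug {e.drug!r} does not match {params.drug!r}")
    mech = DRUG_PRESETS.get(params.drug, lambda: DrugMechanism(params.drug, "chemo_payload"))()
    net = _pk_only_network(params, mech, sinks=True)
    ps = _pk_parameter_set(params, mech)
    sim_events = [_sim.Event(e.time, "dose", e.drug, e.amount) for e in events]
    t_eval = np.linspace(0.0, duration, n_points)
    traj = _sim.simulate_timecourse(net, ps, net.pack(ps).y0, duration,
                                    events=sim_events, t_eval=t_eval, rtol=rtol)
    return _pk_frame(traj, params)


def _pk_frame(traj: _sim.Trajectory, params: PKParams) -> pd.DataFrame:
    dn = params.drug
    bw = MOUSE_BODY_WEIGHT_KG
    out = {"time_h": traj.times}
    names = {s.name for s in traj.network.species}

    def conc(spname, vol):
        return traj.species(spname) / (vol * bw)

    if params.cap_chain:
        out["capecitabine_nM"] = conc(f"A_cap:{dn}", params.Vc)
        out["dfcr_nM"] = conc(f"A_dfcr:{dn}", params.V_met)
        out["dfur_nM"] = conc(f"A_dfur:{dn}", params.V_met)
        out["fu5_nM"] = conc(f"A_5fu:{dn}", params.V_met)
    else:
        out["central_nM"] = conc(f"Ac:{dn}", params.Vc)
        out["peripheral_nM"] = conc(f"Ap:{dn}", params.Vp)
        if f"APLc:{dn}" in names:
            out["payload_central_nM"] = conc(f"APLc:{dn}", params.Vc_star)
            out["payload_peripheral_nM"] = conc(f"APLp:{dn}", params.Vp_star)
        if f"ADC_tu:{dn}" in names:
            out["tumor_nM"] = traj.species(f"ADC_tu:{dn}")
    if f"Gut:{dn}" in names:
        out["gut_nmol"] = traj.species(f"Gut:{dn}")
    if f"Elim:{dn}" in names:
        out["eliminated_nmol"] = traj.species(f"Elim:{dn}")
    out["remaining_nmol"] = _remaining_nmol(traj, dn)
    return pd.DataFrame(out)


def _remaining_nmol(traj: _sim.Trajectory, dn: str) -> np.ndarray:
    """Total drug-derived material still in PK compartments (nmol)."""
    total = np.zeros(len(traj.times))
    for s in traj.network.species:
        if s.name.endswith(f":{dn}") and s.unit == "nmol" and not s.name.startswith("Elim"):
            if s.name.startswith(("APLc", "APLp")):
                continue  # payload counted in payload mass units, not antibody
            total += traj.species(s.name)
    return total


def capecitabine_cascade(
    params: PKParams, events: Iterable[DoseEvent], duration: float,
    n_points: int = 400, rtol: float = 1e-10,
) -> pd.DataFrame:
    """Parent + metabolite (5'DFCR, 5'DFUR, 5-FU) concentration table."""
    if not params.cap_chain:
        raise ConfigError("capecitabine_cascade requires cap_chain rate constants")
    for e in events:
        if e.route != "oral":
            raise ConfigError("capecitabine is dosed orally")
    return simulate_pk(params, events, duration, n_points, rtol=rtol)


def tumor_exposure(plasma: pd.DataFrame, params: PKParams) -> pd.DataFrame:
    """Tumor-compartment drug input derived from a plasma table.

    Small molecules partition instantaneously (``Kp`` x central concentration);
    ADCs enter first-order in the central amount with no back-flux, reported
    here as the influx rate and its running integral.
    """
    t = plasma["time_h"].to_numpy()
    if params.Kp is not None:
        col = "fu5_nM" if "fu5_nM" in plasma else "central_nM"
        return pd.DataFrame({"time_h": t, "tumor_nM": params.Kp * plasma[col].to_numpy()})
    if "central_nM" not in plasma:
        raise ConfigError("plasma table lacks a central_nM column")
    amount = plasma["central_nM"].to_numpy() * params.Vc * MOUSE_BODY_WEIGHT_KG
    influx = params.k_tu * amount
    from scipy.integrate import cumulative_trapezoid

    cum = np.concatenate([[0.0], cumulative_trapezoid(influx, t)])
    return pd.DataFrame({"time_h": t, "influx_nM_per_h": influx,
                         "cumulative_influx_nM": cum})
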