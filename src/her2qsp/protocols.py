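"""Simulated experiments: signaling assays, dose-viability, xenograft studies.

In vitro assays bypass PK entirely (drugs are constant baths, with 5-FU
standing in for capecitabine); in vivo studies expand dosing regimens into
events on the embedded PK model, start from an 80 mm^3 tumor at treatment day
0 and cap volume logistically at 2000 mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ReactionNetwork
from .params import ADC, CHEMO_PAYLOAD, ConfigError
from .pharmacokinetics import DoseEvent
from .simulate import Event, Trajectory, adc_bath, bath, initialize_steady_state, simulate_timecourse

CYCLE_DAYS = 21


# ---------------------------------------------------------------------------
# regimens
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegimenArm:
    """One drug line of a regimen: dose in mg/kg and a schedule tag.

    Schedule tags: ``qd`` (daily), ``q3w`` (day 1 of each 21-day cycle),
    ``d1-d14`` (days 1-14 of each 21-day cycle), ``single`` (one dose at
    ``start_day``) or an explicit tuple of day numbers (0-based).
    """

    drug: str
    dose: float
    schedule: object = "qd"
    route: str = "oral"
    start_day: float = 0.0


@dataclass(frozen=True)
class Regimen:
    arms: tuple = ()

    def expand(self, n_days: float) -> list[DoseEvent]:
        """Deterministically expand schedule tags into a sorted dose-event list."""
        events: list[DoseEvent] = []
        for arm in self.arms:
            days: Iterable[float]
            if isinstance(arm.schedule, (tuple, list)):
                days = [float(d) for d in arm.schedule]
            elif arm.schedule == "qd":
                days = np.arange(arm.start_day, n_days)
            elif arm.schedule == "q3w":
                days = np.arange(arm.start_day, n_days, CYCLE_DAYS)
            elif arm.schedule == "d1-d14":
                days = [c + d for c in np.arange(arm.start_day, n_days, CYCLE_DAYS)
                        for d in range(14) if c + d < n_days]
            elif arm.schedule == "single":
                days = [arm.start_day]
            else:
                raise ConfigError(f"unknown schedule tag {arm.schedule!r}")
            events.extend(DoseEvent(arm.drug, arm.dose, 24.0 * d, arm.route)
                          for d in days if d < n_days)
        return sorted(events, key=lambda e: (e.time, e.drug))


def control_regimen() -> Regimen:
    return Regimen(())


# ---------------------------------------------------------------------------
# in vitro viability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViabilityAssay:
    """Dose-viability assay: drug (or drug pair) on a concentration grid.

    ``doses`` maps drug name -> concentrations (nM); a grid is formed from the
    cartesian product when two drugs are given.  ``ligands`` are optional
    constant baths in ng/mL applied throughout.
    """

    doses: Mapping[str, Sequence[float]]
    duration_h: float = 72.0
    ligands: Mapping[str, float] = field(default_factory=dict)


def _drug_events(net: ReactionNetwork, drug: str, conc: float) -> list[Event]:
    mech = {d.name: d for d in net.drugs}.get(drug)
    if mech is None:
        raise ConfigError(f"drug {drug!r} not wired into this network")
    if mech.kind == ADC:
        return [adc_bath(drug, conc)]
    if mech.kind == CHEMO_PAYLOAD:
        return [bath("5-FU", conc)]
    return [bath(drug, conc)]


def run_viability(net: ReactionNetwork, params: Mapping[str, float],
                  assay: ViabilityAssay, y_ss: np.ndarray | None = None) -> pd.DataFrame:
    """Viability = treated / untreated cell count after the same elapsed time.

    Returns a tidy table with one row per dose combination; the zero-dose
    point is exactly 1 by construction.
    """
    if net.mode != "in_vitro":
        raise ConfigError("viability assays run on in vitro networks")
    if y_ss is None:
        y_ss = initialize_steady_state(net, params)
    lig_events = [Event(0.0, "input", lig, _ngml(lig, v))
                  for lig, v in assay.ligands.items()]
    t = assay.duration_h

    def cells(drug_events):
        traj = simulate_timecourse(net, params, y_ss, t, events=lig_events + drug_events,
                                   t_eval=np.array([0.0, t]))
        return traj.final("cells")

    # reference: untreated, unstimulated cells over the same elapsed time
    n_control_ref = simulate_timecourse(net, params, y_ss, t,
                                        t_eval=np.array([0.0, t])).final("cells")
    drugs = list(assay.doses)
    rows = []
    if len(drugs) == 1:
        combos = [(c,) for c in assay.doses[drugs[0]]]
    elif len(drugs) == 2:
        combos = [(a, b) for a in assay.doses[drugs[0]] for b in assay.doses[drugs[1]]]
    else:
        raise ConfigError("viability assays support one or two drugs")
    for combo in combos:
        ev: list[Event] = []
        for d, c in zip(drugs, combo):
            if c > 0:
                ev.extend(_drug_events(net, d, c))
        row = {f"conc_{d}_nM": c for d, c in zip(drugs, combo)}
        row["viability"] = (1.0 if not ev and not lig_events
                            else cells(ev) / n_control_ref)
        rows.append(row)
    return pd.DataFrame(rows)


def _ngml(ligand, v):
    from .params import ngml_to_nM

    return ngml_to_nM(ligand, v)


# ---------------------------------------------------------------------------
# xenograft studies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class XenograftProtocol:
    """Mouse xenograft study design: dosing starts once the tumor reaches
    ``start_volume`` (treatment day 0), follow-up in days, output daily."""

    start_volume: float = 80.0
    follow_up_days: float = 62.0
    extra_events: tuple = ()  # stimulus events, e.g. a constant NRG1 bath


def run_xenograft(net: ReactionNetwork, params: Mapping[str, float],
                  regimen: Regimen, protocol: XenograftProtocol = XenograftProtocol(),
                  y_ss: np.ndarray | None = None, rtol: float = 1e-6) -> pd.DataFrame:
    """Tumor-volume time series (mm^3, daily cadence) under a regimen."""
    if net.mode != "in_vivo":
        raise ConfigError("xenograft studies run on in vivo networks")
    doses = regimen.expand(protocol.follow_up_days)
    have_pk = set(net.pk)
    for d in doses:
        if d.drug not in have_pk:
            raise ConfigError(f"regimen drug {d.drug!r} has no PK parameters in this network")
    if y_ss is None:
        y_ss = initialize_steady_state(net, params)
    y0 = y_ss.copy()
    y0[net.sidx["N"]] = protocol.start_volume * params["cells_per_mm3"]
    duration = protocol.follow_up_days * 24.0
    events = [Event(d.time, "dose", d.drug, d.amount) for d in doses]
    events += list(protocol.extra_events)
    t_eval = np.arange(0.0, protocol.follow_up_days + 1e-9) * 24.0
    traj = simulate_timecourse(net, params, y0, duration, events=events,
                               t_eval=t_eval, rtol=rtol)
    vol = traj.readout("volume")
    return pd.DataFrame({"day": traj.times / 24.0, "volume_mm3": vol})


def compute_tgi(treated: pd.DataFrame, control: pd.DataFrame, day: float,
                baseline_corrected: bool = True) -> float:
    """Percent tumor growth inhibition at ``day``.

    Default (baseline-corrected): ``100 * (1 - (Vt - V0)/(Vc - V0))``, clipped
    at 100 so regression below baseline reads as complete inhibition.  The
    ratio form ``100 * (1 - Vt/Vc)`` is available via
    ``baseline_corrected=False``.
    """
    for df in (treated, control):
        if day > df["day"].max() + 1e-9:
            raise ValueError(f"series does not cover day {day}")
    vt = float(np.interp(day, treated["day"], treated["volume_mm3"]))
    vc = float(np.interp(day, control["day"], control["volume_mm3"]))
    if not baseline_corrected:
        return 100.0 * (1.0 - vt / vc)
    v0 = float(control["volume_mm3"].iloc[0])
    if vc <= v0:
        raise ValueError("control arm has not grown beyond baseline; TGI undefined")
    return min(100.0, 100.0 * (1.0 - (vt - v0) / (vc - v0)))


def normalize_readout(values, mode: str, control: float | None = None) -> np.ndarray:
    """Normalize a readout series to its maximum or to a control value."""
    values = np.asarray(values, float)
    if mode == "max":
        ref = float(np.max(values))
    elif mode == "control":
        ref = float(values[0]) if control is None else float(control)
    elif mode in ("none", None):
        return values
    else:
        raise ConfigError(f"unknown normalization mode {mode!r}")
    if ref <= 0:
        raise ValueError("normalization reference must be > 0")
    return values / ref
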