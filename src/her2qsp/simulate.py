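"""Time-course integration, steady-state initialization and trajectories.

Stimuli are piecewise-constant events applied at stated times: bath inputs
(ligands and in vitro drug concentrations, nM), bolus/oral doses (in vivo, as
additions to the PK depot or central compartment, nmol) and direct species
(re)settings.  Integration proceeds segment by segment between event times
with a stiff-capable solver (LSODA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import ReactionNetwork
from .params import ConfigError, dose_to_nmol, ngml_to_nM


class IntegrationError(RuntimeError):
    """Solver failure; carries the last successfully reached time."""

    def __init__(self, msg, last_time=None):
        super().__init__(msg)
        self.last_time = last_time


class SteadyStateError(RuntimeError):
    """No steady state within the allowed horizon."""


@dataclass(frozen=True)
class Event:
    """One stimulus action at ``time`` (h)."""

    time: float
    kind: str  # 'input' | 'dose' | 'species_set' | 'species_add'
    target: str
    value: float


def bath(name: str, conc_nM: float, time: float = 0.0) -> Event:
    """Constant-bath input (drug or ligand) set to ``conc_nM`` from ``time`` on."""
    if conc_nM < 0:
        raise ConfigError("bath concentration must be >= 0")
    return Event(time, "input", name, conc_nM)


def ligand_bath(ligand: str, ng_per_ml: float, time: float = 0.0) -> Event:
    """Ligand bath given in the assay's ng/mL units (EGF 6.2 kDa, NRG1 7.5 kDa)."""
    return bath(ligand, ngml_to_nM(ligand, ng_per_ml), time)


def adc_bath(drug: str, conc_nM: float, time: float = 0.0) -> Event:
    """In vitro ADC bath: the tumor-compartment ADC species is held at conc."""
    return Event(time, "species_set", f"ADC_tu:{drug}", conc_nM)


class Trajectory:
    """Time-indexed state matrix with named readout extraction."""

    def __init__(self, network: ReactionNetwork, params: Mapping[str, float],
                 times: np.ndarray, states: np.ndarray, events: Sequence[Event] = ()):
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.network = network
        self.params = dict(params)
        self.times = np.asarray(times, float)
        self.states = np.asarray(states, float)
        self.events = list(events)

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.network.sidx[name]]

    def readout(self, name: str) -> np.ndarray:
        """Phospho/total readouts mirroring the immunoblot conventions."""
        net = self.network
        if name in net.sidx:
            return self.species(name)
        if name == "pEGFR":
            return self.species("pD1")
        if name == "pHER2":
            return (self.species("pD1") + 2 * self.species("pD2") + self.species("pD3")
                    + self.species("pD4") + self.species("pD5"))
        if name == "pHER3":
            return self.species("pD3") + self.species("pD4")
        if name == "pHER4":
            return self.species("pD5")
        if name in ("tEGFR", "tHER2", "tHER3", "tHER4"):
            rec = name[1:]
            out = np.zeros(len(self.times))
            for s in net.species:
                c = s.monomers.get(rec, 0)
                if c:
                    out += c * self.species(s.name)
            return out
        if name == "cells":
            return self.species("N")
        if name == "volume":
            return self.species("N") / self.params["cells_per_mm3"]
        raise KeyError(f"unknown readout {name!r}")

    def at(self, t: float, name: str) -> float:
        return float(np.interp(t, self.times, self.readout(name)))

    def final(self, name: str) -> float:
        return float(self.readout(name)[-1])

    def to_frame(self):
        """Tidy (time, species, value, unit) table."""
        import pandas as pd

        rows = []
        for s in self.network.species:
            col = self.species(s.name)
            rows.append(pd.DataFrame({"time_h": self.times, "species": s.name,
                                      "value": col, "unit": s.unit}))
        return pd.concat(rows, ignore_index=True)


def _apply_event(net: ReactionNetwork, ev: Event, y: np.ndarray, u0: np.ndarray):
    if ev.kind == "input":
        if ev.target not in net.uidx:
            raise ConfigError(f"unknown input {ev.target!r}")
        u0[net.uidx[ev.target]] = ev.value
    elif ev.kind == "species_set":
        y[net.sidx[ev.target]] = ev.value
    elif ev.kind == "species_add":
        y[net.sidx[ev.target]] += ev.value
    elif ev.kind == "dose":
        if ev.target not in net.pk:
            raise ConfigError(f"no PK parameters for drug {ev.target!r}")
        p = net.pk[ev.target]
        amount = dose_to_nmol(ev.target, ev.value, mw=p.mw)
        if p.route == "oral" or p.cap_chain:
            y[net.sidx[f"Gut:{ev.target}"]] += amount
        else:
            y[net.sidx[f"Ac:{ev.target}"]] += amount
    else:
        raise ConfigError(f"unknown event kind {ev.kind!r}")


def simulate_timecourse(
    net: ReactionNetwork,
    params: Mapping[str, float],
    y0: np.ndarray,
    duration: float,
    events: Iterable[Event] = (),
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-6,
    turnover_off: bool = False,
) -> Trajectory:
    """Integrate the network for ``duration`` hours applying stimulus events.

    Returns a :class:`Trajectory`; states are clamped non-negative at solver
    tolerance on output.
    """
    y0 = np.asarray(y0, float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    packed = net.pack(params, turnover_off=turnover_off)
    events = sorted(events, key=lambda e: e.time)
    if any(e.time < 0 or e.time > duration for e in events):
        raise ConfigError("event outside the simulated horizon")
    if t_eval is None:
        t_eval = np.linspace(0.0, duration, 201)
    t_eval = np.asarray(t_eval, float)

    cuts = sorted({0.0, duration, *[e.time for e in events]})
    y = y0.copy()
    u0 = np.zeros(max(len(net.inputs), 1))
    times_out = [np.array([0.0])]
    states_out = [y.copy()[None, :]]

    eidx = 0
    for a, b in zip(cuts[:-1], cuts[1:]):
        while eidx < len(events) and events[eidx].time <= a:
            _apply_event(net, events[eidx], y, u0)
            eidx += 1
        seg_eval = t_eval[(t_eval > a) & (t_eval < b)]
        seg_t = np.concatenate([seg_eval, [b]])
        sol = solve_ivp(packed.rhs(u0.copy()), (a, b), y, method="LSODA",
                        t_eval=seg_t, rtol=rtol, atol=packed.atol)
        if not sol.success:
            raise IntegrationError(
                f"integrator failed in [{a}, {b}] h: {sol.message}",
                last_time=sol.t[-1] if sol.t.size else a)
        times_out.append(sol.t)
        states_out.append(sol.y.T)
        y = sol.y[:, -1].copy()
    while eidx < len(events):  # events exactly at the end
        _apply_event(net, events[eidx], y, u0)
        eidx += 1

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    keep = np.concatenate([[True], np.diff(times) > 0])
    states = np.maximum(states[keep], 0.0)
    return Trajectory(net, params, times[keep], states, events)


def initialize_steady_state(
    net: ReactionNetwork,
    params: Mapping[str, float],
    tol: float = 1e-8,
    max_hours: float = 10_000.0,
) -> np.ndarray:
    """Equilibrate the drug- and ligand-free network; return the steady state.

    The tumor-size state ``N`` is excluded from the convergence criterion (it
    grows indefinitely by design) and is reset to its configured initial value
    in the returned vector.  Raises :class:`SteadyStateError` if the maximum
    relative derivative stays above ``tol`` (1/h) within ``max_hours``.
    """
    packed = net.pack(params)
    y = packed.y0.copy()
    u0 = np.zeros(max(len(net.inputs), 1))
    f = packed.rhs(u0)
    n_idx = net.sidx["N"]
    mask = np.ones(net.n_species, bool)
    mask[n_idx] = False

    t, chunk = 0.0, 200.0
    while t < max_hours:
        chunk = min(chunk, max_hours - t)
        sol = solve_ivp(f, (0.0, chunk), y, method="LSODA", rtol=1e-8,
                        atol=packed.atol * 1e-2)
        if not sol.success:
            raise IntegrationError("steady-state equilibration failed", last_time=t)
        y = np.maximum(sol.y[:, -1], 0.0)
        t += chunk
        dy = f(0.0, y)
        rel = np.abs(dy[mask]) / (np.abs(y[mask]) + packed.atol[mask] / 1e-3)
        if float(np.max(rel)) < tol:
            y[n_idx] = packed.y0[n_idx]
            return y
        chunk = min(chunk * 2.0, 2000.0)
    raise SteadyStateError(
        f"no steady state within {max_hours} h (max rel. derivative "
        f"{float(np.max(rel)):.3g}/h)")
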