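"""Model/Results facade over the reaction network and protocols.

:class:`TumorGrowthModel` is constructed from a cell-line configuration and a
drug list (statsmodels-style: the model holds design and data, ``fit``
returns a results object).  It owns the assembled :class:`ReactionNetwork`,
the flat parameter set, a cached signaling steady state and convenience
runners for the simulated experiments.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import calibration as _cal
from . import protocols as _prot
from .network import build_network, derived_pk_rates
from .params import (
    CellLineConfig,
    ConfigError,
    DRUG_PRESETS,
    DrugMechanism,
    IN_VIVO_GROWTH,
    PK_PRESETS,
    PKParams,
    ParameterSet,
    SignalingParams,
)
from .simulate import Event, Trajectory, initialize_steady_state, simulate_timecourse

ALL_DRUGS = ("lapatinib", "pyrotinib", "capecitabine", "T-DM1", "T-DXd")


def _as_mechs(drugs: Iterable, in_vivo: bool) -> list[DrugMechanism]:
    out = []
    for d in drugs:
        if isinstance(d, DrugMechanism):
            out.append(d)
            continue
        if d == "capecitabine" and not in_vivo:
            d = "5-FU"  # 5-FU substitutes for capecitabine in vitro
        if d not in DRUG_PRESETS:
            raise ConfigError(f"unknown drug {d!r}")
        out.append(DRUG_PRESETS[d]())
    return out


class TumorGrowthModel:
    """Mechanistic HER2+ tumor model for one cell line and drug panel.

    Parameters
    ----------
    cell_line : CellLineConfig
        Receptor copy numbers and growth/death law.
    drugs : iterable of str or DrugMechanism
        Therapeutics wired into the network.
    in_vivo : bool
        In vivo mode embeds compartmental PK and the logistic volume cap and
        applies the in vivo growth/death baseline.
    """

    def __init__(self, cell_line: CellLineConfig, drugs: Iterable = (),
                 in_vivo: bool = False, signaling: SignalingParams | None = None,
                 pk: Mapping[str, PKParams] | None = None,
                 params: ParameterSet | None = None):
        self.cell_line = cell_line
        self.in_vivo = bool(in_vivo)
        self.signaling = signaling or SignalingParams()
        mechs = _as_mechs(drugs, self.in_vivo)
        growth = cell_line.growth
        if self.in_vivo:
            growth = replace(growth, **IN_VIVO_GROWTH)
        self.drug_mechs = mechs
        if self.in_vivo:
            self.pk = dict(pk) if pk else {
                m.name: PK_PRESETS[m.name]() for m in mechs if m.name in PK_PRESETS}
        else:
            self.pk = {}
        self.network = build_network(cell_line, self.signaling, mechs,
                                     mode="in_vivo" if self.in_vivo else "in_vitro",
                                     pk=self.pk)
        if params is None:
            params = ParameterSet.from_components(
                self.signaling, growth, {m.name: m for m in mechs}, self.pk)
            params = derived_pk_rates(params)
        self.params = params
        self._ss_cache: dict = {}

    # -- constructors -------------------------------------------------------

    @classmethod
    def skbr3(cls, drugs: Iterable = (), in_vivo: bool = False, **kw) -> "TumorGrowthModel":
        return cls(CellLineConfig.skbr3(), drugs, in_vivo=in_vivo, **kw)

    @classmethod
    def from_ihc(cls, level: str, drugs: Iterable = (), in_vivo: bool = False,
                 **kw) -> "TumorGrowthModel":
        return cls(CellLineConfig.from_ihc(f"IHC{level}", level), drugs,
                   in_vivo=in_vivo, **kw)

    # -- simulation ---------------------------------------------------------

    def with_overrides(self, overrides: Mapping) -> "TumorGrowthModel":
        m = TumorGrowthModel.__new__(TumorGrowthModel)
        m.__dict__.update(self.__dict__)
        m.params = self.params.override(overrides)
        m._ss_cache = {}
        return m

    def steady_state(self, params: Mapping[str, float] | None = None) -> np.ndarray:
        """Drug-free signaling steady state (cached for the model's params)."""
        if params is None:
            params = self.params
        key = id(params) if params is self.params else None
        if key is not None and key in self._ss_cache:
            return self._ss_cache[key]
        ss = initialize_steady_state(self.network, params)
        if key is not None:
            self._ss_cache[key] = ss
        return ss

    def simulate(self, duration_h: float, events: Sequence[Event] = (),
                 params: Mapping[str, float] | None = None,
                 y0: np.ndarray | None = None, **kw) -> Trajectory:
        params = self.params if params is None else params
        if y0 is None:
            y0 = self.steady_state(params)
        return simulate_timecourse(self.network, params, y0, duration_h,
                                   events=events, **kw)

    def viability(self, assay: _prot.ViabilityAssay,
                  params: Mapping[str, float] | None = None) -> pd.DataFrame:
        params = self.params if params is None else params
        return _prot.run_viability(self.network, params, assay,
                                   y_ss=self.steady_state(params))

    def xenograft(self, regimen: _prot.Regimen,
                  protocol: _prot.XenograftProtocol = _prot.XenograftProtocol(),
                  params: Mapping[str, float] | None = None) -> pd.DataFrame:
        params = self.params if params is None else params
        return _prot.run_xenograft(self.network, params, regimen, protocol,
                                   y_ss=self.steady_state(params))

    def tgi(self, regimen: _prot.Regimen, day: float,
            protocol: _prot.XenograftProtocol | None = None,
            params: Mapping[str, float] | None = None) -> float:
        """Percent TGI of a regimen vs the vehicle arm at ``day``."""
        protocol = protocol or _prot.XenograftProtocol(follow_up_days=max(day, 21.0))
        treated = self.xenograft(regimen, protocol, params=params)
        control = self.xenograft(_prot.control_regimen(), protocol, params=params)
        return _prot.compute_tgi(treated, control, day)

    # -- estimation ---------------------------------------------------------

    def xenograft_simulators(self, regimens: Mapping[str, _prot.Regimen],
                             protocol: _prot.XenograftProtocol = _prot.XenograftProtocol(),
                             rtol: float = 1e-6) -> _cal.Simulators:
        """Condition -> simulator mapping (volume vs day) for calibration."""

        def make(reg):
            def sim(params):
                return _prot.run_xenograft(self.network, params, reg, protocol,
                                           rtol=rtol)

            return sim

        return {cond: make(reg) for cond, reg in regimens.items()}

    def fit(self, dataset: _cal.CalibrationDataset, simulators: _cal.Simulators,
            free: Mapping[str, tuple], **spec_kw) -> "TumorGrowthResults":
        spec = _cal.FitSpec(free=free, **spec_kw)
        res = _cal.fit(spec, dataset, simulators, self.params)
        return TumorGrowthResults(self, res, dataset)


class TumorGrowthResults:
    """Fit results: estimates, loss trace and a summary table."""

    def __init__(self, model: TumorGrowthModel, fit_result: _cal.FitResult,
                 dataset: _cal.CalibrationDataset):
        self.model = model
        self.fit_result = fit_result
        self.dataset = dataset
        self.params = fit_result.params
        self.estimates = pd.Series(fit_result.fitted, name="estimate")
        self.loss = fit_result.loss
        self.trace = fit_result.trace

    def fitted_model(self) -> TumorGrowthModel:
        m = self.model.with_overrides({})
        m.params = self.params
        return m

    def summary(self) -> str:
        head = (f"TumorGrowthModel fit | cell line {self.model.cell_line.name} | "
                f"{'in vivo' if self.model.in_vivo else 'in vitro'}\n"
                f"n points: {len(self.dataset)}   loss: {self.loss:.6g}   "
                f"evals: {self.fit_result.n_evals}\n")
        tbl = self.estimates.to_string(float_format=lambda v: f"{v:.5g}")
        tail = "" if self.fit_result.warning is None else f"\nwarning: {self.fit_result.warning}"
        return head + tbl + tail
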