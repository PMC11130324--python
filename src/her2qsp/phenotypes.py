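"""Named parameter-override presets generating heterogeneous response
phenotypes and resistance scenarios, and the phenotype x regimen TGI grid.

The four response phenotypes mirror the standard heterogeneity panel:
``sensitive`` (the calibrated baseline), ``tdm1_resistant`` (payload efflux
up), ``lapatinib_resistant`` (faster growth plus hyperactive Raf) and
``pan_resistant`` (growth further increased).  The exact multipliers are
reconstructions chosen to reproduce the qualitative response patterns; they
are configurable per phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .params import ConfigError, ParameterSet
from .protocols import Regimen, RegimenArm, XenograftProtocol, compute_tgi, run_xenograft
from .simulate import Event, initialize_steady_state, ligand_bath

#: default override multipliers (documented reconstructions, not published values)
PHENOTYPE_DEFAULTS: dict[str, dict] = {
    "sensitive": {},
    "tdm1_resistant": {"T-DM1.kout_PL": ("x", 50.0)},
    "lapatinib_resistant": {"umax": ("x", 1.6), "kon_Raf": ("x", 5.0)},
    "pan_resistant": {"umax": ("x", 2.6), "kon_Raf": ("x", 6.0)},
    "nrg1_over": {},
    "her3_mab": {"k8on": 0.0},  # NRG1-HER3 binding blocked (HER3 antibody)
    "pi3k_inhibited": {"k_pi3k_act": ("x", 0.2)},
    "pik3ca_dependent": {"wAKT": ("x", 4.0), "w11": ("x", 0.25), "km_pi3k": ("x", 0.01)},
}

#: ng/mL constant bath representing NRG1 overexpression
NRG1_OVER_NGML = 50.0


@dataclass(frozen=True)
class Phenotype:
    """Parameter overrides (multipliers or absolute values) plus stimuli."""

    name: str
    overrides: Mapping[str, object] = field(default_factory=dict)
    stimuli: tuple = ()

    def apply(self, params: ParameterSet) -> ParameterSet:
        return params.override(self.overrides) if self.overrides else ParameterSet(params)

    def combined(self, other: "Phenotype") -> "Phenotype":
        """Stack another phenotype's overrides/stimuli on top of this one."""
        ov = dict(self.overrides)
        ov.update(other.overrides)
        return Phenotype(f"{self.name}+{other.name}", ov, self.stimuli + other.stimuli)


def make_phenotype(name: str, multipliers: Mapping[str, float] | None = None) -> Phenotype:
    """Build a named phenotype preset; unknown names list the options."""
    if name not in PHENOTYPE_DEFAULTS:
        raise ConfigError(
            f"unknown phenotype {name!r}; presets: {sorted(PHENOTYPE_DEFAULTS)}")
    overrides = dict(PHENOTYPE_DEFAULTS[name])
    if multipliers:
        for k, m in multipliers.items():
            overrides[k] = ("x", m)
    stimuli = (ligand_bath("NRG1", NRG1_OVER_NGML),) if name == "nrg1_over" else ()
    return Phenotype(name, overrides, stimuli)


# ---------------------------------------------------------------------------
# the 13-arm regimen panel (single-cycle doses)
# ---------------------------------------------------------------------------

_L = lambda: RegimenArm("lapatinib", 100.0, "qd")
_P = lambda: RegimenArm("pyrotinib", 30.0, "qd")
_C = lambda: RegimenArm("capecitabine", 400.0, "d1-d14")
_M = lambda: RegimenArm("T-DM1", 30.0, "q3w", route="iv")
_X = lambda: RegimenArm("T-DXd", 10.0, "q3w", route="iv")

#: arm order is stable and documented: singles, classic doubles, TKI+ADC
#: doubles, lapatinib triples, pyrotinib triples
STANDARD_ARMS: tuple[tuple[str, Regimen], ...] = (
    ("lapatinib", Regimen((_L(),))),
    ("pyrotinib", Regimen((_P(),))),
    ("capecitabine", Regimen((_C(),))),
    ("T-DM1", Regimen((_M(),))),
    ("T-DXd", Regimen((_X(),))),
    ("lap+cap", Regimen((_L(), _C()))),
    ("pyr+cap", Regimen((_P(), _C()))),
    ("pyr+T-DM1", Regimen((_P(), _M()))),
    ("pyr+T-DXd", Regimen((_P(), _X()))),
    ("lap+cap+T-DM1", Regimen((_L(), _C(), _M()))),
    ("lap+cap+T-DXd", Regimen((_L(), _C(), _X()))),
    ("pyr+cap+T-DM1", Regimen((_P(), _C(), _M()))),
    ("pyr+cap+T-DXd", Regimen((_P(), _C(), _X()))),
)


def phenotype_regimen_grid(model, phenotypes: Sequence[Phenotype],
                           arms: Sequence[tuple] = STANDARD_ARMS,
                           day: float = 20.0) -> pd.DataFrame:
    """TGI (%) of each regimen arm in each phenotype, measured at ``day``.

    ``model`` must be an in vivo model carrying all five drugs.  Each
    phenotype re-equilibrates its own steady state and control arm.
    """
    rows = {}
    for ph in phenotypes:
        params = ph.apply(model.params)
        protocol = XenograftProtocol(follow_up_days=day, extra_events=ph.stimuli)
        ss = initialize_steady_state(model.network, params)
        control = run_xenograft(model.network, params, Regimen(()), protocol, y_ss=ss)
        vals = {}
        for arm_name, reg in arms:
            treated = run_xenograft(model.network, params, reg, protocol, y_ss=ss)
            vals[arm_name] = compute_tgi(treated, control, day)
        rows[ph.name] = vals
    return pd.DataFrame(rows).T
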