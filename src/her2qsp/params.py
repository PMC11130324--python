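"""Parameter containers for the HER2+ breast-cancer cell and pharmacokinetic model.

Conventions
-----------
* Intracellular species are counted in molecules/cell; ligands and drugs in the
  medium (or tumor interstitium) in nM; pharmacokinetic amounts in nmol.
* All rate constants are stored in per-hour units internally, except the tumor
  growth/death rates which are conventionally quoted per day
  (:class:`GrowthDeathParams`) and converted at network-packing time.
* A flat ``name -> value`` mapping (:class:`ParameterSet`) is the currency the
  reaction network, the optimizer and the sensitivity machinery exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np

HOURS_PER_DAY = 24.0

RECEPTORS = ("EGFR", "HER2", "HER3", "HER4")

#: HER2 copy number implied by each immunohistochemistry grade (molecules/cell).
IHC_HER2_LEVELS = {"3+": 1.5e6, "2+": 0.5e6, "1+": 0.1e6}

#: molecular weights used for ng/mL -> nM and mg/kg -> nmol conversions (g/mol)
MOLECULAR_WEIGHTS = {
    "EGF": 6200.0,
    "NRG1": 7500.0,
    "lapatinib": 581.0,
    "pyrotinib": 583.0,
    "capecitabine": 359.0,
    "5-FU": 130.0,
    "T-DM1": 148_000.0,
    "T-DXd": 148_000.0,
    "DM1": 738.0,
    "DXd": 493.0,
}

#: mouse body weight assumed for mg/kg -> absolute-dose conversion (kg)
MOUSE_BODY_WEIGHT_KG = 0.020


class ConfigError(ValueError):
    """Raised for inconsistent cell-line / drug / network configuration."""


def hill(x, km, n):
    """Saturating Hill function ``x^n / (x^n + km^n)``, clipped at zero."""
    x = np.maximum(x, 0.0)
    xn = x**n
    return xn / (xn + km**n)


# ---------------------------------------------------------------------------
# growth / death
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthDeathParams:
    """Tumor-cell proliferation/death law parameters.

    ``dN/dt = N * [umax * H(S; km13, n13) * (1 - V/Vmax)
                   - dmax * (1 + w14*H(payload; km14, n14) + w15*H(FU; km10, n10))]``

    where ``S`` is the integrated pro-growth signal from pERK/pAKT, ``payload``
    the intracellular ADC payload concentration and ``FU`` the 5-FU exposure.
    Rates are per day; the ``1 - V/Vmax`` logistic factor applies in vivo only.
    """

    umax: float = 0.80  # max proliferation rate (1/day)
    dmax: float = 0.12  # basal death rate (1/day)
    km13: float = 0.30  # half-saturation of growth signal on proliferation
    n13: float = 2.0
    w14: float = 12.0  # max fold-stimulation of death by ADC payload
    km14: float = 12.0  # nM intracellular payload
    n14: float = 1.0
    w15: float = 8.0  # max fold-stimulation of death by 5-FU
    km10: float = 3000.0  # nM 5-FU
    n10: float = 1.0
    s_basal: float = 0.0  # ErbB-independent additive growth-signal offset
    Vmax: float = 2000.0  # carrying capacity, mm^3 (in vivo only)
    cells_per_mm3: float = 1.0e6

    def __post_init__(self):
        if self.umax <= self.dmax:
            raise ConfigError("umax must exceed dmax for a growing baseline")
        for name in ("w14", "w15"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("n13", "n14", "n10"):
            if getattr(self, name) < 1:
                raise ConfigError(f"Hill exponent {name} must be >= 1")


#: in vivo re-estimated growth/death baseline (SKBR3 xenograft scale).
IN_VIVO_GROWTH = dict(umax=0.38, dmax=0.11, w14=2.0, w15=1.5)


# ---------------------------------------------------------------------------
# cell line
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellLineConfig:
    """Receptor copy numbers and growth/death parameters for one cell line."""

    name: str
    receptors_per_cell: Mapping[str, float]
    ihc_level: str | None = None
    growth: GrowthDeathParams = field(default_factory=GrowthDeathParams)

    def __post_init__(self):
        for rec, count in self.receptors_per_cell.items():
            if rec not in RECEPTORS:
                raise ConfigError(f"unknown receptor {rec!r}; expected one of {RECEPTORS}")
            if count < 0:
                raise ConfigError(f"receptor count for {rec} must be >= 0")
        for rec in RECEPTORS:
            if rec not in self.receptors_per_cell:
                raise ConfigError(f"missing receptor count for {rec}")

    def receptor(self, name: str) -> float:
        return float(self.receptors_per_cell[name])

    @staticmethod
    def skbr3(**growth_overrides) -> "CellLineConfig":
        """SKBR3 (IHC 3+): 150k EGFR, 1.5M HER2, 40k HER3, 2k HER4 per cell."""
        g = replace(GrowthDeathParams(), **growth_overrides) if growth_overrides else GrowthDeathParams()
        return CellLineConfig(
            "SKBR3",
            {"EGFR": 150_000.0, "HER2": 1_500_000.0, "HER3": 40_000.0, "HER4": 2_000.0},
            ihc_level="3+",
            growth=g,
        )

    @staticmethod
    def from_ihc(name: str, level: str, **growth_overrides) -> "CellLineConfig":
        """Generic HER2 line by IHC grade (3+/2+/1+ -> 1.5e6/0.5e6/0.1e6 HER2/cell)."""
        if level not in IHC_HER2_LEVELS:
            raise ConfigError(f"unknown IHC level {level!r}")
        # lower-HER2 lines grow through ErbB-independent drivers (e.g. ER
        # signaling in luminal lines); the per-line recalibration is expressed
        # as a basal growth-signal offset
        over = {"s_basal": {"3+": 0.0, "2+": 0.25, "1+": 0.5}[level]}
        over.update(growth_overrides)
        g = replace(GrowthDeathParams(), **over)
        return CellLineConfig(
            name,
            {"EGFR": 150_000.0, "HER2": IHC_HER2_LEVELS[level], "HER3": 40_000.0, "HER4": 2_000.0},
            ihc_level=level,
            growth=g,
        )

    @staticmethod
    def bt474() -> "CellLineConfig":
        return CellLineConfig.from_ihc("BT-474", "3+")

    @staticmethod
    def nci_n87() -> "CellLineConfig":
        return CellLineConfig.from_ihc("NCI-N87", "2+")

    @staticmethod
    def zr75_1() -> "CellLineConfig":
        return CellLineConfig.from_ihc("ZR-75-1", "1+")


# ---------------------------------------------------------------------------
# signaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalingParams:
    """Rates of the ErbB ligand-binding / dimerization / cascade network.

    Bimolecular ligand and drug binding rates are 1/(nM h); membrane
    dimerization rates are 1/((molecules/cell) h); first-order rates 1/h.
    The downstream tiers (Raf->ERK with MEK lumped in, and PI3K->AKT with PI3K
    lumped into the AKT activation step) operate on normalized 0..1 activities.
    """

    # ligand binding (k8on/k8off: NRG1-HER3, the sensitivity-relevant pair)
    k1on: float = 0.5
    k1off: float = 1.0
    k8on: float = 0.5
    k8off: float = 4.0
    k9on: float = 0.5
    k9off: float = 0.5
    kint_lig: float = 0.4  # ligand-induced internalization of bound monomers

    # dimerization (d1 EGF:EGFR-HER2, d2 HER2-HER2, d3 HER2-HER3 ligand-free,
    # d4 NRG1:HER3-HER2, d5 NRG1:HER4-HER2)
    kd1on: float = 8.0e-6
    kd1off: float = 8.0
    kd2on: float = 3.0e-7
    kd2off: float = 30.0
    kd3on: float = 3.6e-6
    kd3off: float = 30.0
    kd4on: float = 8.0e-5
    kd4off: float = 4.0
    kd5on: float = 4.0e-5
    kd5off: float = 4.0

    # transphosphorylation / dephosphorylation
    kphos: float = 200.0
    kdeph: float = 100.0
    f_phos_d3: float = 0.7  # relative phospho rate of the ligand-free HER2-HER3 dimer

    # phospho-receptor pool weights feeding the two cascades
    we_d1: float = 1.0
    we_d2: float = 1.0
    we_d3: float = 0.3
    we_d4: float = 3.0
    we_d5: float = 0.15
    wa_d1: float = 0.3
    wa_d2: float = 0.65
    wa_d3: float = 0.12
    wa_d4: float = 6.0
    wa_d5: float = 0.15

    # Raf/MAPK tier
    kon_Raf: float = 24.0
    koff_Raf: float = 24.0
    w7: float = 1.0  # max drive of the phospho-receptor pool on Raf
    km7: float = 5.0e3
    n7: float = 1.5
    kon_ERK: float = 24.0
    koff_ERK: float = 12.0
    w8: float = 1.0  # max drive of pRaf on ERK
    km8: float = 0.4
    n8: float = 2.0

    # PI3K/AKT tier
    k_pi3k_act: float = 24.0
    k_pi3k_deact: float = 18.0
    km_pi3k: float = 4.0e4
    n_pi3k: float = 2.0

    # growth-signal integration S = (w11 H(pERK) + wAKT H(pAKT)) / (w11 + wAKT)
    w11: float = 1.0  # pERK weight in the growth signal
    km11: float = 0.35
    n11: float = 2.0
    wAKT: float = 1.0
    kmA: float = 0.30
    nA: float = 2.0

    # FOXO feedback: low pAKT de-represses HER3 synthesis
    f_foxo: float = 4.0  # max fold-induction of HER3 synthesis
    km_foxo: float = 0.30  # pAKT half-saturation of FOXO inactivation
    n_foxo: float = 2.0
    pakt_ref: float = 0.40  # reference pAKT at which synthesis is normalized

    # receptor turnover
    kdeg_R: float = 0.25  # basal receptor degradation (1/h, t1/2 ~ 14 h)

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ConfigError(f"signaling rate {f.name} must be >= 0")
        for name in ("n7", "n8", "n_pi3k", "n11", "nA", "n_foxo"):
            if getattr(self, name) < 1:
                raise ConfigError(f"Hill exponent {name} must be >= 1")


# ---------------------------------------------------------------------------
# drug mechanisms
# ---------------------------------------------------------------------------

TKI_REVERSIBLE = "TKI_reversible"
TKI_IRREVERSIBLE = "TKI_irreversible"
ADC = "ADC"
CHEMO_PAYLOAD = "chemo_payload"


@dataclass(frozen=True)
class DrugMechanism:
    """Cell-level mechanism of one therapeutic agent.

    ``kind`` selects the wiring: reversible/irreversible kinase inhibition of
    ``targets`` with enhanced degradation of the bound receptor; HER2-directed
    ADC with internalization, lysosomal processing and payload kinetics; or a
    chemotherapy payload acting through the 5-FU death stimulus.
    """

    name: str
    kind: str
    targets: tuple[str, ...] = ()
    # TKI
    kon: float = 0.0  # 1/(nM h); reversible association or covalent inactivation
    koff: float = 0.0  # 1/h (reversible only)
    fdeg: float = 1.0  # fold-enhancement of degradation of the bound receptor
    # ADC
    kon_ADC: float = 0.37
    koff_ADC: float = 1.0
    kint_ADC: float = 0.10  # internalization of the ADC:HER2 complex (1/h)
    kdeg_ADC_2: float = 0.10  # lysosomal processing of internalized complex (1/h)
    k_recycle: float = 0.10  # recycling/exocytosis of internalized complex without payload release (1/h)
    DAR: float = 0.0  # payload molecules released per processed ADC
    kout_PL: float = 0.0  # payload efflux, no re-entry (DM1)
    kper_PL: float = 0.0  # bidirectional membrane permeation (DXd)
    payload_reentry: bool = False
    kdeg_PL: float = 0.04  # intracellular payload inactivation (1/h)
    kclr_PLex: float = 0.20  # clearance of extracellular payload pool (1/h)
    death_potency: float = 1.0  # scales w14 for this ADC's payload

    def __post_init__(self):
        if self.kind not in (TKI_REVERSIBLE, TKI_IRREVERSIBLE, ADC, CHEMO_PAYLOAD):
            raise ConfigError(f"unknown drug kind {self.kind!r}")
        for rec in self.targets:
            if rec not in RECEPTORS:
                raise ConfigError(f"unknown receptor target {rec!r}")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and v < 0:
                raise ConfigError(f"negative rate {f.name} for {self.name}")
        if self.kind == ADC and self.payload_reentry and self.kout_PL > 0:
            raise ConfigError("re-entering payloads use kper_PL, not kout_PL")

    @staticmethod
    def lapatinib(**over) -> "DrugMechanism":
        """Reversible EGFR/HER2 TKI (Kd = koff/kon ~ 10 nM)."""
        kw = dict(kon=1.0, koff=5.0, fdeg=3.0)
        kw.update(over)
        return DrugMechanism("lapatinib", TKI_REVERSIBLE, ("EGFR", "HER2"), **kw)

    @staticmethod
    def pyrotinib(**over) -> "DrugMechanism":
        """Irreversible pan-ErbB (EGFR/HER2/HER4) TKI."""
        kw = dict(kon=0.3, fdeg=5.0)
        kw.update(over)
        return DrugMechanism("pyrotinib", TKI_IRREVERSIBLE, ("EGFR", "HER2", "HER4"), **kw)

    @staticmethod
    def tdm1(**over) -> "DrugMechanism":
        """Trastuzumab emtansine: DM1 payload is effluxed and cannot re-enter."""
        kw = dict(DAR=3.5, kout_PL=0.55, payload_reentry=False, death_potency=1.0)
        kw.update(over)
        return DrugMechanism("T-DM1", ADC, ("HER2",), **kw)

    @staticmethod
    def tdxd(**over) -> "DrugMechanism":
        """Trastuzumab deruxtecan: membrane-permeant DXd payload (bystander-capable)."""
        kw = dict(DAR=8.0, kper_PL=1.0, payload_reentry=True, death_potency=0.85)
        kw.update(over)
        return DrugMechanism("T-DXd", ADC, ("HER2",), **kw)

    @staticmethod
    def fluorouracil() -> "DrugMechanism":
        """5-FU (the in vitro surrogate of capecitabine): direct death stimulus."""
        return DrugMechanism("5-FU", CHEMO_PAYLOAD)

    @staticmethod
    def capecitabine() -> "DrugMechanism":
        """Capecitabine: prodrug; tumoricidal only after conversion to 5-FU."""
        return DrugMechanism("capecitabine", CHEMO_PAYLOAD)


DRUG_PRESETS = {
    "lapatinib": DrugMechanism.lapatinib,
    "pyrotinib": DrugMechanism.pyrotinib,
    "T-DM1": DrugMechanism.tdm1,
    "T-DXd": DrugMechanism.tdxd,
    "5-FU": DrugMechanism.fluorouracil,
    "capecitabine": DrugMechanism.capecitabine,
}


# ---------------------------------------------------------------------------
# pharmacokinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PKParams:
    """Mouse compartmental PK of one drug.

    Two-compartment disposition (Vc/Vp, CL, Q) for TKIs and ADCs, with an oral
    first-order depot when ``route='oral'``.  ADCs carry a deconjugated-payload
    disposition block (starred volumes) and enter the tumor interstitium
    first-order in the central amount (``k_tu``); small molecules partition
    instantaneously with coefficient ``Kp``.  Capecitabine uses the sequential
    cap -> 5'DFCR -> 5'DFUR -> 5-FU metabolite chain instead of Vp.
    Volumes L/kg, clearances L/(h kg), rates 1/h.
    """

    drug: str
    route: str = "oral"
    ka: float = 1.0
    Vc: float = 4.0
    Vp: float = 4.0
    CL: float = 1.4
    Q: float = 0.5
    # tumor coupling: exactly one of Kp (instantaneous partition) or k_tu
    Kp: float | None = 1.0
    k_tu: float | None = None  # nM tumor per (nmol central · h)
    kclr_tumor: float = 0.1  # clearance of the ADC tumor pool (1/h)
    # ADC payload disposition
    k_release: float = 0.0  # plasma deconjugation (1/h)
    Vc_star: float = 2.0
    Vp_star: float = 2.0
    CL_star: float = 0.5
    Q_star: float = 0.2
    # capecitabine metabolite chain
    cap_chain: tuple[float, ...] = ()  # (k cap->DFCR, DFCR->DFUR, DFUR->5FU, 5FU elim)
    V_met: float = 2.0
    mw: float = 500.0

    def __post_init__(self):
        if self.route not in ("oral", "iv"):
            raise ConfigError(f"unknown route {self.route!r}")
        if (self.Kp is None) == (self.k_tu is None):
            raise ConfigError("exactly one tumor-coupling mode (Kp or k_tu) per drug")
        for name in ("Vc", "Vp", "Vc_star", "Vp_star", "V_met"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"volume {name} must be > 0")

    @staticmethod
    def lapatinib() -> "PKParams":
        return PKParams("lapatinib", route="oral", ka=1.0, Vc=4.0, Vp=2.0, CL=1.6,
                        Q=0.1, Kp=0.007, mw=MOLECULAR_WEIGHTS["lapatinib"])

    @staticmethod
    def pyrotinib() -> "PKParams":
        return PKParams("pyrotinib", route="oral", ka=1.0, Vc=5.0, Vp=5.0, CL=2.5,
                        Q=0.5, Kp=0.045, mw=MOLECULAR_WEIGHTS["pyrotinib"])

    @staticmethod
    def capecitabine() -> "PKParams":
        return PKParams("capecitabine", route="oral", ka=2.0, Vc=2.0, Vp=2.0, CL=0.0,
                        Q=0.0, Kp=1.0, cap_chain=(1.5, 1.5, 1.0, 2.0), V_met=2.0,
                        mw=MOLECULAR_WEIGHTS["capecitabine"])

    @staticmethod
    def tdm1() -> "PKParams":
        return PKParams("T-DM1", route="iv", Vc=0.085, Vp=0.060, CL=0.0006, Q=0.003,
                        Kp=None, k_tu=0.04, k_release=0.005,
                        Vc_star=2.0, Vp_star=2.0, CL_star=0.5, Q_star=0.2,
                        mw=MOLECULAR_WEIGHTS["T-DM1"])

    @staticmethod
    def tdxd() -> "PKParams":
        return PKParams("T-DXd", route="iv", Vc=0.085, Vp=0.060, CL=0.0006, Q=0.003,
                        Kp=None, k_tu=0.04, k_release=0.005,
                        Vc_star=2.0, Vp_star=2.0, CL_star=0.5, Q_star=0.2,
                        mw=MOLECULAR_WEIGHTS["T-DXd"])


PK_PRESETS = {
    "lapatinib": PKParams.lapatinib,
    "pyrotinib": PKParams.pyrotinib,
    "capecitabine": PKParams.capecitabine,
    "T-DM1": PKParams.tdm1,
    "T-DXd": PKParams.tdxd,
}


def dose_to_nmol(drug: str, mg_per_kg: float, mw: float | None = None) -> float:
    """Convert a mg/kg mouse dose to nmol (20 g body weight)."""
    if mw is None:
        mw = MOLECULAR_WEIGHTS.get(drug, 500.0)
    return mg_per_kg * MOUSE_BODY_WEIGHT_KG / mw * 1.0e6


def ngml_to_nM(ligand: str, ng_per_ml: float) -> float:
    """Convert a ligand bath from ng/mL to nM using configured molecular weights."""
    if ligand not in ("EGF", "NRG1"):
        raise ConfigError(f"unknown ligand {ligand!r}")
    return ng_per_ml / MOLECULAR_WEIGHTS[ligand] * 1.0e3


# ---------------------------------------------------------------------------
# flat parameter set
# ---------------------------------------------------------------------------


class ParameterSet(dict):
    """Flat ``name -> value`` mapping with multiplier-style overrides.

    Overrides accept either absolute values or ``("x", m)`` tuples meaning
    "multiply the baseline by m" (the phenotype-library convention).
    """

    def override(self, overrides: Mapping[str, object]) -> "ParameterSet":
        new = ParameterSet(self)
        for name, val in overrides.items():
            if name not in new:
                raise ConfigError(f"unknown parameter {name!r} in overrides")
            if isinstance(val, tuple) and len(val) == 2 and val[0] in ("x", "*"):
                new[name] = new[name] * float(val[1])
            else:
                new[name] = float(val)  # type: ignore[arg-type]
        return new

    @staticmethod
    def from_components(
        signaling: SignalingParams,
        growth: GrowthDeathParams,
        drugs: Mapping[str, DrugMechanism] = (),
        pk: Mapping[str, PKParams] = (),
    ) -> "ParameterSet":
        ps = ParameterSet()
        for f in fields(signaling):
            ps[f.name] = float(getattr(signaling, f.name))
        for f in fields(growth):
            ps[f.name] = float(getattr(growth, f.name))
        for dname, mech in dict(drugs).items():
            for f in fields(mech):
                v = getattr(mech, f.name)
                if isinstance(v, (int, float)) and not isinstance(v, bool):
                    ps[f"{dname}.{f.name}"] = float(v)
        for dname, p in dict(pk).items():
            for f in fields(p):
                v = getattr(p, f.name)
                if isinstance(v, (int, float)) and not isinstance(v, bool):
                    ps[f"pk.{dname}.{f.name}"] = float(v)
            if p.cap_chain:
                for i, k in enumerate(p.cap_chain):
                    ps[f"pk.{dname}.kmet{i}"] = float(k)
            if p.Kp is not None:
                ps[f"pk.{dname}.Kp"] = float(p.Kp)
            if p.k_tu is not None:
                ps[f"pk.{dname}.k_tu"] = float(p.k_tu)
        return ps
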