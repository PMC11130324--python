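"""Reaction-network representation of the HER2+ tumor-cell / PK model.

The model is held as an explicit list of :class:`Species` and :class:`Reaction`
objects (mass-action and Hill-type rate laws) from which two evaluation paths
are derived:

* a packed array form evaluated by a numba-compiled kernel (the production
  right-hand side used by the integrator), and
* a naive per-reaction Python interpreter (:meth:`ReactionNetwork.naive_rhs`)
  kept deliberately simple so it can serve as an independent cross-check.

Reversible binding/distribution processes are represented as single reactions
with forward and reverse rates (the usual convention of ODE modeling tools);
each reaction contributes one or two unidirectional fluxes internally.

External concentrations enter as a vector of inputs ``u = u0 + Cu @ y``: in
vitro, baths are constants in ``u0``; in vivo, the same inputs are linear
read-outs of the PK species (partition coefficients folded into ``Cu``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .params import (
    ADC,
    CHEMO_PAYLOAD,
    TKI_IRREVERSIBLE,
    TKI_REVERSIBLE,
    MOUSE_BODY_WEIGHT_KG,
    CellLineConfig,
    ConfigError,
    DrugMechanism,
    GrowthDeathParams,
    HOURS_PER_DAY,
    ParameterSet,
    PKParams,
    RECEPTORS,
    SignalingParams,
    hill,
)

#: nM of intracellular concentration per molecule/cell (2 pL cell volume)
NM_PER_MOLECULE = 1.0e9 / (6.022e23 * 2.0e-12)

# law identifiers
MA, SYNFB, HILLACT, GROWTH, DEATH = 0, 1, 2, 3, 4

_IN_VITRO, _IN_VIVO = "in_vitro", "in_vivo"


@dataclass
class Species:
    """One state variable: name, unit, initial value and conservation content.

    ``monomers`` maps receptor names to how many monomer equivalents of that
    receptor the species carries (used by the conservation invariant).
    """

    name: str
    unit: str
    init: float = 0.0
    scale: float = 1.0
    monomers: Mapping[str, int] = field(default_factory=dict)


@dataclass
class Reaction:
    """A (possibly reversible) reaction with a tagged rate law.

    ``stoich`` is the net stoichiometry of the forward flux; coefficients may
    be ``(const, param_name)`` pairs resolved at packing time (payload release
    uses ``DAR * nM-conversion``).  ``k``/``k2`` name rate parameters that are
    multiplied together with the constant ``const``; ``A``/``B`` are species
    operands, ``U`` an input operand, ``X`` the Hill driver (species name or
    ``"obs:<pool>"``).  ``extra`` carries law-specific parameter names and
    ``stimuli`` the death-law stimulus list.  Reverse flux (mass action) uses
    ``kr`` on operand ``RA``.
    """

    name: str
    law: int
    stoich: dict
    k: str | None = None
    k2: str | None = None
    const: float = 1.0
    A: str | None = None
    B: str | None = None
    U: str | None = None
    X: str | None = None
    extra: dict = field(default_factory=dict)
    stimuli: tuple = ()
    reversible: bool = False
    kr: str | None = None
    RA: str | None = None
    turnover: bool = False


@dataclass
class PackedNetwork:
    """Array form of the network for one concrete parameter set."""

    y0: np.ndarray
    S: np.ndarray  # species x fluxes stoichiometry
    law: np.ndarray
    ia: np.ndarray
    ib: np.ndarray
    iu: np.ndarray
    ix: np.ndarray
    xobs: np.ndarray
    PP: np.ndarray
    W: np.ndarray  # observable pools (n_obs x n_species)
    Cu_base: np.ndarray  # state-coupled part of the inputs
    n_inputs: int
    atol: np.ndarray

    def rhs(self, u0: np.ndarray):
        """Return an ``f(t, y)`` callable for a fixed constant-input vector."""
        S, law, ia, ib, iu, ix, xobs, PP, W, Cu = (
            self.S, self.law, self.ia, self.ib, self.iu, self.ix,
            self.xobs, self.PP, self.W, self.Cu_base,
        )

        def f(t, y):
            return _rhs_kernel(y, u0, Cu, W, S, law, ia, ib, iu, ix, xobs, PP)

        return f

    def fluxes(self, y: np.ndarray, u0: np.ndarray) -> np.ndarray:
        return _flux_kernel(
            np.asarray(y, float), u0, self.Cu_base, self.W, self.law,
            self.ia, self.ib, self.iu, self.ix, self.xobs, self.PP,
        )


# ---------------------------------------------------------------------------
# kernels (numba-compiled when available)
# ---------------------------------------------------------------------------


def _flux_py(y, u0, Cu, W, law, ia, ib, iu, ix, xobs, PP):
    yc = np.maximum(y, 0.0)
    u = u0 + Cu @ yc
    o = W @ yc
    nf = law.shape[0]
    rates = np.empty(nf)
    for i in range(nf):
        L = law[i]
        if L == 0:  # mass action / zero order, optional input factor
            r = PP[i, 0] * PP[i, 1]
            if ia[i] >= 0:
                r *= yc[ia[i]]
            if ib[i] >= 0:
                r *= yc[ib[i]]
            if iu[i] >= 0:
                r *= u[iu[i]]
        elif L == 1:  # synthesis with FOXO-type inhibitory feedback
            p = yc[ia[i]]
            km = PP[i, 2]
            n = PP[i, 3]
            h = p**n / (p**n + km**n) if p > 0.0 else 0.0
            ref = PP[i, 4]
            href = ref**n / (ref**n + km**n)
            fb = 1.0 + PP[i, 1] * (1.0 - h)
            fb0 = 1.0 + PP[i, 1] * (1.0 - href)
            r = PP[i, 0] * fb / fb0
        elif L == 2:  # Hill-driven activation of a normalized activity
            x = o[ix[i]] if xobs[i] == 1 else yc[ix[i]]
            km = PP[i, 2]
            n = PP[i, 3]
            h = x**n / (x**n + km**n) if x > 0.0 else 0.0
            r = PP[i, 0] * PP[i, 1] * h * (PP[i, 4] - yc[ia[i]])
        elif L == 3:  # logistic proliferation driven by integrated signal
            perk = yc[ib[i]]
            pakt = yc[ix[i]]
            h11 = perk ** PP[i, 5] / (perk ** PP[i, 5] + PP[i, 4] ** PP[i, 5]) if perk > 0 else 0.0
            hA = pakt ** PP[i, 8] / (pakt ** PP[i, 8] + PP[i, 7] ** PP[i, 8]) if pakt > 0 else 0.0
            sg = (PP[i, 3] * h11 + PP[i, 6] * hA) / (PP[i, 3] + PP[i, 6]) + PP[i, 10]
            h13 = sg ** PP[i, 2] / (sg ** PP[i, 2] + PP[i, 1] ** PP[i, 2]) if sg > 0 else 0.0
            r = PP[i, 0] * h13 * (1.0 - yc[ia[i]] * PP[i, 9]) * yc[ia[i]]
        else:  # death with up to three saturable stimuli
            # stimulus inputs are packed as indices in ix (s1), iu (s2), ib (s3)
            stim = 1.0
            for j in range(3):
                if j == 0:
                    idx = ix[i]
                elif j == 1:
                    idx = iu[i]
                else:
                    idx = ib[i]
                w = PP[i, 1 + 3 * j]
                if idx >= 0 and w > 0.0:
                    x = u[idx]
                    km = PP[i, 2 + 3 * j]
                    n = PP[i, 3 + 3 * j]
                    h = x**n / (x**n + km**n) if x > 0.0 else 0.0
                    stim += w * h
            r = PP[i, 0] * stim * yc[ia[i]]
        rates[i] = r
    return rates


def _rhs_py(y, u0, Cu, W, S, law, ia, ib, iu, ix, xobs, PP):
    return S @ _flux_py(y, u0, Cu, W, law, ia, ib, iu, ix, xobs, PP)


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _flux_kernel = numba.njit(cache=True, fastmath=False)(_flux_py)

    @numba.njit(cache=True, fastmath=False)
    def _rhs_kernel(y, u0, Cu, W, S, law, ia, ib, iu, ix, xobs, PP):
        return S @ _flux_kernel(y, u0, Cu, W, law, ia, ib, iu, ix, xobs, PP)

except Exception:  # pragma: no cover
    _flux_kernel = _flux_py
    _rhs_kernel = _rhs_py


# ---------------------------------------------------------------------------
# the network object
# ---------------------------------------------------------------------------


class ReactionNetwork:
    """Species + reactions defining the ODE right-hand side."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        inputs: Sequence[str],
        obs_defs: Mapping[str, Sequence[tuple]],
        mode: str,
        cell_line: CellLineConfig,
        drugs: Sequence[DrugMechanism],
        pk: Mapping[str, PKParams] | None = None,
    ):
        self.species = list(species)
        self.reactions = list(reactions)
        self.inputs = list(inputs)
        self.obs_defs = dict(obs_defs)
        self.mode = mode
        self.cell_line = cell_line
        self.drugs = list(drugs)
        self.pk = dict(pk or {})
        self.sidx = {s.name: i for i, s in enumerate(self.species)}
        self.uidx = {u: i for i, u in enumerate(self.inputs)}
        self.oidx = {o: i for i, o in enumerate(self.obs_defs)}
        for r in self.reactions:
            for sp in r.stoich:
                if sp not in self.sidx:
                    raise ConfigError(f"reaction {r.name}: unknown species {sp}")

    # -- structure ----------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def stoichiometry(self) -> np.ndarray:
        """Net forward stoichiometry (species x reactions); DAR-type entries
        use the constant part of their coefficient."""
        S = np.zeros((self.n_species, self.n_reactions))
        for j, r in enumerate(self.reactions):
            for sp, c in r.stoich.items():
                S[self.sidx[sp], j] = c[0] if isinstance(c, tuple) else c
        return S

    def parameter_names(self) -> set:
        names: set = set()
        for r in self.reactions:
            for n in (r.k, r.k2, r.kr):
                if n:
                    names.add(n)
            names.update(v for v in r.extra.values() if isinstance(v, str))
            for stim in r.stimuli:
                names.update(x for x in stim[:-1] if isinstance(x, str))
            for c in r.stoich.values():
                if isinstance(c, tuple) and isinstance(c[1], str):
                    names.add(c[1])
        for pool in self.obs_defs.values():
            names.update(w for _, w in pool)
        return names

    def to_tables(self):
        """Tidy species/reactions tables (for export and eyeballing)."""
        import pandas as pd

        sp = pd.DataFrame(
            [(s.name, s.unit, s.init, dict(s.monomers)) for s in self.species],
            columns=["species", "unit", "init", "monomer_content"],
        )
        law_names = {MA: "mass_action", SYNFB: "synthesis_feedback",
                     HILLACT: "hill_activation", GROWTH: "growth", DEATH: "death"}
        rx = pd.DataFrame(
            [
                (r.name, law_names[r.law], r.reversible, r.turnover,
                 ";".join(f"{k}:{v if not isinstance(v, tuple) else v}" for k, v in r.stoich.items()),
                 r.k, r.kr)
                for r in self.reactions
            ],
            columns=["reaction", "law", "reversible", "turnover", "stoichiometry", "k", "kr"],
        )
        return sp, rx

    # -- packing ------------------------------------------------------------

    def _resolve(self, params: Mapping[str, float], name, default=1.0) -> float:
        if name is None:
            return default
        if isinstance(name, (int, float)):
            return float(name)
        try:
            return float(params[name])
        except KeyError:
            raise ConfigError(f"parameter {name!r} missing from parameter set") from None

    def pack(self, params: Mapping[str, float], turnover_off: bool = False) -> PackedNetwork:
        """Resolve parameter names into the packed array form."""
        rows = []  # (law, ia, ib, iu, ix, xobs, PP, stoich_col)
        gv = lambda n, d=1.0: self._resolve(params, n, d)
        si = lambda n: -1 if n is None else self.sidx[n]

        def xref(x):
            if x is None:
                return -1, 0
            if isinstance(x, str) and x.startswith("obs:"):
                return self.oidx[x[4:]], 1
            return self.sidx[x], 0

        for r in self.reactions:
            dead = turnover_off and r.turnover
            col = np.zeros(self.n_species)
            for sp, c in r.stoich.items():
                v = c[0] * gv(c[1]) if isinstance(c, tuple) else c
                col[self.sidx[sp]] = v
            PP = np.zeros(12)
            ia = si(r.A)
            ib = si(r.B)
            iu = -1 if r.U is None else self.uidx[r.U]
            ix, xo = -1, 0
            if r.law == MA:
                PP[0] = 0.0 if dead else gv(r.k) * r.const
                PP[1] = gv(r.k2)
            elif r.law == SYNFB:
                PP[0] = 0.0 if dead else gv(r.k) * r.const
                PP[1] = gv(r.extra["fmax"])
                PP[2] = gv(r.extra["km"])
                PP[3] = gv(r.extra["n"])
                PP[4] = gv(r.extra["ref"])
            elif r.law == HILLACT:
                PP[0] = gv(r.k) * r.const
                PP[1] = gv(r.extra.get("w"))
                PP[2] = gv(r.extra["km"])
                PP[3] = gv(r.extra["n"])
                PP[4] = r.extra.get("total", 1.0)
                ix, xo = xref(r.X)
            elif r.law == GROWTH:
                PP[0] = gv(r.k) / HOURS_PER_DAY
                PP[1] = gv(r.extra["km13"])
                PP[2] = gv(r.extra["n13"])
                PP[3] = gv(r.extra["w11"])
                PP[4] = gv(r.extra["km11"])
                PP[5] = gv(r.extra["n11"])
                PP[6] = gv(r.extra["wAKT"])
                PP[7] = gv(r.extra["kmA"])
                PP[8] = gv(r.extra["nA"])
                if self.mode == _IN_VIVO:
                    PP[9] = 1.0 / (gv(r.extra["Vmax"]) * gv(r.extra["rho"]))
                PP[10] = gv(r.extra.get("s0"), 0.0)
                ib = self.sidx[r.B]
                ix, xo = self.sidx[r.X], 0
            elif r.law == DEATH:
                PP[0] = gv(r.k) / HOURS_PER_DAY
                idxs = [-1, -1, -1]
                for j, stim in enumerate(r.stimuli[:3]):
                    wnames, km, n, uname = stim
                    w = 1.0
                    for wn in (wnames if isinstance(wnames, tuple) else (wnames,)):
                        w *= gv(wn)
                    PP[1 + 3 * j] = w
                    PP[2 + 3 * j] = gv(km)
                    PP[3 + 3 * j] = gv(n)
                    idxs[j] = self.uidx[uname]
                ix, iu, ib = idxs  # stimulus input slots
            rows.append((r.law, ia, ib, iu, ix, xo, PP, col))
            if r.reversible:
                PPr = np.zeros(12)
                PPr[0] = 0.0 if dead else gv(r.kr)
                PPr[1] = 1.0
                rows.append((MA, self.sidx[r.RA], -1, -1, -1, 0, PPr, -col))

        nf = len(rows)
        law = np.array([x[0] for x in rows], dtype=np.int64)
        ia = np.array([x[1] for x in rows], dtype=np.int64)
        ib = np.array([x[2] for x in rows], dtype=np.int64)
        iu = np.array([x[3] for x in rows], dtype=np.int64)
        ix = np.array([x[4] for x in rows], dtype=np.int64)
        xo = np.array([x[5] for x in rows], dtype=np.int64)
        PP = np.vstack([x[6] for x in rows])
        S = np.column_stack([x[7] for x in rows]) if nf else np.zeros((self.n_species, 0))

        W = np.zeros((max(len(self.obs_defs), 1), self.n_species))
        for o, pool in self.obs_defs.items():
            for spname, wname in pool:
                W[self.oidx[o], self.sidx[spname]] = gv(wname)

        Cu = np.zeros((max(len(self.inputs), 1), self.n_species))
        for uname, (spname, coef) in getattr(self, "u_couplings", {}).items():
            c = coef[0] * gv(coef[1]) if isinstance(coef, tuple) else coef
            Cu[self.uidx[uname], self.sidx[spname]] = c

        y0 = np.array([s.init for s in self.species])
        atol = np.array([max(s.scale * 1e-9, 1e-12) for s in self.species])
        return PackedNetwork(y0, S, law, ia, ib, iu, ix, xo, PP, W, Cu,
                             len(self.inputs), atol)

    # -- naive oracle -------------------------------------------------------

    def naive_rhs(self, y, u0, params: Mapping[str, float], turnover_off=False):
        """Independent per-reaction interpreter: evaluates every rate law from
        the reaction objects with plain Python/numpy and sums stoichiometry."""
        y = np.maximum(np.asarray(y, float), 0.0)
        gv = lambda n, d=1.0: self._resolve(params, n, d)
        u = np.array(u0, float)
        for uname, (spname, coef) in getattr(self, "u_couplings", {}).items():
            c = coef[0] * gv(coef[1]) if isinstance(coef, tuple) else coef
            u[self.uidx[uname]] += c * y[self.sidx[spname]]
        obs = {}
        for o, pool in self.obs_defs.items():
            obs[o] = sum(gv(w) * y[self.sidx[sp]] for sp, w in pool)
        dy = np.zeros_like(y)

        def val(ref):
            if ref is None:
                return 1.0
            if isinstance(ref, str) and ref.startswith("obs:"):
                return obs[ref[4:]]
            return y[self.sidx[ref]]

        for r in self.reactions:
            dead = turnover_off and r.turnover
            if r.law == MA:
                rate = 0.0 if dead else gv(r.k) * r.const * gv(r.k2) * val(r.A) * val(r.B)
                if r.U is not None:
                    rate *= u[self.uidx[r.U]]
            elif r.law == SYNFB:
                p = y[self.sidx[r.A]]
                fb = 1.0 + gv(r.extra["fmax"]) * (1.0 - hill(p, gv(r.extra["km"]), gv(r.extra["n"])))
                fb0 = 1.0 + gv(r.extra["fmax"]) * (
                    1.0 - hill(gv(r.extra["ref"]), gv(r.extra["km"]), gv(r.extra["n"])))
                rate = 0.0 if dead else gv(r.k) * r.const * fb / fb0
            elif r.law == HILLACT:
                x = val(r.X)
                rate = (gv(r.k) * r.const * gv(r.extra.get("w"))
                        * hill(x, gv(r.extra["km"]), gv(r.extra["n"]))
                        * (r.extra.get("total", 1.0) - y[self.sidx[r.A]]))
            elif r.law == GROWTH:
                s_g = (gv(r.extra["w11"]) * hill(y[self.sidx[r.B]], gv(r.extra["km11"]), gv(r.extra["n11"]))
                       + gv(r.extra["wAKT"]) * hill(y[self.sidx[r.X]], gv(r.extra["kmA"]), gv(r.extra["nA"])))
                s_g /= gv(r.extra["w11"]) + gv(r.extra["wAKT"])
                if r.extra.get("s0"):
                    s_g += gv(r.extra["s0"], 0.0)
                cap = 1.0
                if self.mode == _IN_VIVO:
                    cap = 1.0 - y[self.sidx[r.A]] / (gv(r.extra["Vmax"]) * gv(r.extra["rho"]))
                rate = (gv(r.k) / HOURS_PER_DAY * hill(s_g, gv(r.extra["km13"]), gv(r.extra["n13"]))
                        * cap * y[self.sidx[r.A]])
            elif r.law == DEATH:
                stim = 1.0
                for wnames, km, n, uname in r.stimuli:
                    w = 1.0
                    for wn in (wnames if isinstance(wnames, tuple) else (wnames,)):
                        w *= gv(wn)
                    stim += w * hill(u[self.uidx[uname]], gv(km), gv(n))
                rate = gv(r.k) / HOURS_PER_DAY * stim * y[self.sidx[r.A]]
            else:  # pragma: no cover
                raise ConfigError(f"unknown law {r.law}")
            for sp, c in r.stoich.items():
                cv = c[0] * gv(c[1]) if isinstance(c, tuple) else c
                dy[self.sidx[sp]] += cv * rate
            if r.reversible:
                rr = 0.0 if dead else gv(r.kr) * y[self.sidx[r.RA]]
                for sp, c in r.stoich.items():
                    cv = c[0] * gv(c[1]) if isinstance(c, tuple) else c
                    dy[self.sidx[sp]] -= cv * rr
        return dy

    def monomer_totals(self, y) -> dict:
        """Total monomer equivalents of each receptor across all species."""
        y = np.asarray(y, float)
        out = {}
        for rec in RECEPTORS:
            tot = 0.0
            for s in self.species:
                c = s.monomers.get(rec, 0)
                if c:
                    tot += c * y[self.sidx[s.name]]
            out[rec] = tot
        return out


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

#: canonical input slots
INPUT_NAMES = ("EGF", "NRG1", "lapatinib", "pyrotinib", "T-DM1", "T-DXd", "5-FU",
               "PL:T-DM1", "PL:T-DXd")


def build_network(
    cell_line: CellLineConfig,
    signaling: SignalingParams | None = None,
    drugs: Iterable[DrugMechanism] = (),
    mode: str = _IN_VITRO,
    pk: Mapping[str, PKParams] | None = None,
    include_pk_sinks: bool = False,
) -> ReactionNetwork:
    """Assemble the ErbB signaling + growth (+ drug, + PK) reaction network.

    The dimer inventory is fixed: EGF:EGFR-HER2, HER2-HER2, ligand-independent
    HER2-HER3, NRG1:HER3-HER2 and NRG1:HER4-HER2 (HER3 homodimers are absent:
    HER3 is kinase-dead).  In vivo mode adds compartmental PK species for every
    drug with PK parameters and couples tumor exposure through ``Cu``.
    """
    signaling = signaling or SignalingParams()
    drugs = list(drugs)
    pk = dict(pk or {})
    if mode not in (_IN_VITRO, _IN_VIVO):
        raise ConfigError(f"unknown mode {mode!r}")
    if mode == _IN_VIVO:
        for d in drugs:
            if d.name not in pk and d.kind != CHEMO_PAYLOAD:
                raise ConfigError(f"in vivo network requires PK parameters for {d.name}")

    R0 = {r: cell_line.receptor(r) for r in RECEPTORS}
    sp: list[Species] = []
    rx: list[Reaction] = []
    u_coupl: dict = {}

    def add(s):
        sp.append(s)

    # receptors and ligand-bound monomers
    for r in RECEPTORS:
        add(Species(r, "molecules/cell", R0[r], max(R0[r], 1.0), {r: 1}))
    add(Species("EGF:EGFR", "molecules/cell", 0.0, max(R0["EGFR"], 1.0), {"EGFR": 1}))
    add(Species("NRG1:HER3", "molecules/cell", 0.0, max(R0["HER3"], 1.0), {"HER3": 1}))
    add(Species("NRG1:HER4", "molecules/cell", 0.0, max(R0["HER4"], 1.0), {"HER4": 1}))

    dimers = [
        ("D1", {"EGFR": 1, "HER2": 1}),  # EGF:EGFR-HER2
        ("D2", {"HER2": 2}),  # HER2-HER2
        ("D3", {"HER2": 1, "HER3": 1}),  # ligand-independent HER2-HER3
        ("D4", {"HER2": 1, "HER3": 1}),  # NRG1:HER3-HER2
        ("D5", {"HER2": 1, "HER4": 1}),  # NRG1:HER4-HER2
    ]
    dscale = max(R0["HER2"] / 50.0, 1.0)
    for name, mono in dimers:
        add(Species(name, "molecules/cell", 0.0, dscale, mono))
        add(Species("p" + name, "molecules/cell", 0.0, dscale, mono))

    add(Species("pRaf", "fraction", 0.0, 1.0))
    add(Species("pERK", "fraction", 0.0, 1.0))
    add(Species("pAKT", "fraction", 0.0, 1.0))
    # in vivo the tumor state is counted in cells (~1e7-1e9); in vitro it is a
    # normalized relative cell number of order 1-1000
    add(Species("N", "cells", 1.0, 1.0e7 if mode == _IN_VIVO else 1.0))

    g = cell_line.growth

    # --- ligand binding ----------------------------------------------------
    rx.append(Reaction("EGF+EGFR", MA, {"EGFR": -1, "EGF:EGFR": 1}, k="k1on",
                       A="EGFR", U="EGF", reversible=True, kr="k1off", RA="EGF:EGFR"))
    rx.append(Reaction("NRG1+HER3", MA, {"HER3": -1, "NRG1:HER3": 1}, k="k8on",
                       A="HER3", U="NRG1", reversible=True, kr="k8off", RA="NRG1:HER3"))
    rx.append(Reaction("NRG1+HER4", MA, {"HER4": -1, "NRG1:HER4": 1}, k="k9on",
                       A="HER4", U="NRG1", reversible=True, kr="k9off", RA="NRG1:HER4"))

    # --- dimerization ------------------------------------------------------
    dim_rx = [
        ("dim1", "EGF:EGFR", "HER2", "D1", "kd1on", "kd1off", {"EGF:EGFR": -1, "HER2": -1, "D1": 1}),
        ("dim2", "HER2", "HER2", "D2", "kd2on", "kd2off", {"HER2": -2, "D2": 1}),
        ("dim3", "HER2", "HER3", "D3", "kd3on", "kd3off", {"HER2": -1, "HER3": -1, "D3": 1}),
        ("dim4", "NRG1:HER3", "HER2", "D4", "kd4on", "kd4off", {"NRG1:HER3": -1, "HER2": -1, "D4": 1}),
        ("dim5", "NRG1:HER4", "HER2", "D5", "kd5on", "kd5off", {"NRG1:HER4": -1, "HER2": -1, "D5": 1}),
    ]
    for name, a, b, d, kon, koff, st in dim_rx:
        rx.append(Reaction(name, MA, st, k=kon, A=a, B=b, reversible=True, kr=koff, RA=d))

    # --- transphosphorylation ---------------------------------------------
    for i, (dname, _) in enumerate(dimers, start=1):
        k2 = "f_phos_d3" if dname == "D3" else None
        rx.append(Reaction(f"phos_{dname}", MA, {dname: -1, "p" + dname: 1},
                           k="kphos", k2=k2, A=dname,
                           reversible=True, kr="kdeph", RA="p" + dname))

    # --- cascades ----------------------------------------------------------
    rx.append(Reaction("raf_cycle", HILLACT, {"pRaf": 1}, k="kon_Raf", A="pRaf",
                       X="obs:erk_pool", extra={"w": "w7", "km": "km7", "n": "n7"},
                       reversible=True, kr="koff_Raf", RA="pRaf"))
    rx.append(Reaction("erk_cycle", HILLACT, {"pERK": 1}, k="kon_ERK", A="pERK",
                       X="pRaf", extra={"w": "w8", "km": "km8", "n": "n8"},
                       reversible=True, kr="koff_ERK", RA="pERK"))
    rx.append(Reaction("akt_cycle", HILLACT, {"pAKT": 1}, k="k_pi3k_act", A="pAKT",
                       X="obs:akt_pool", extra={"w": None, "km": "km_pi3k", "n": "n_pi3k"},
                       reversible=True, kr="k_pi3k_deact", RA="pAKT"))

    # --- receptor turnover -------------------------------------------------
    for r in RECEPTORS:
        if r == "HER3":
            rx.append(Reaction("syn_HER3", SYNFB, {"HER3": 1}, k="kdeg_R", const=R0[r],
                               A="pAKT",
                               extra={"fmax": "f_foxo", "km": "km_foxo", "n": "n_foxo",
                                      "ref": "pakt_ref"},
                               turnover=True))
        elif R0[r] > 0:
            rx.append(Reaction(f"syn_{r}", MA, {r: 1}, k="kdeg_R", const=R0[r], turnover=True))
        rx.append(Reaction(f"deg_{r}", MA, {r: -1}, k="kdeg_R", A=r, turnover=True))
    for b in ("EGF:EGFR", "NRG1:HER3", "NRG1:HER4"):
        rx.append(Reaction(f"int_{b}", MA, {b: -1}, k="kint_lig", A=b, turnover=True))
    # ligand-induced endocytosis of active ligand-bound dimers (the classical
    # receptor-downregulation route; ligand-independent dimers recycle)
    for d in ("pD1", "pD4", "pD5"):
        rx.append(Reaction(f"int_{d}", MA, {d: -1}, k="kint_lig", A=d, turnover=True))

    # --- drug mechanisms ---------------------------------------------------
    obs_defs = {
        "erk_pool": [(f"pD{i}", f"we_d{i}") for i in range(1, 6)],
        "akt_pool": [(f"pD{i}", f"wa_d{i}") for i in range(1, 6)],
    }

    death_stimuli = []
    for d in drugs:
        dn = d.name
        if d.kind in (TKI_REVERSIBLE, TKI_IRREVERSIBLE):
            for tgt in d.targets:
                if tgt not in R0:
                    raise ConfigError(f"{dn}: unknown target {tgt}")
                if R0[tgt] <= 0:
                    continue
                bname = f"{tgt}:{dn}"
                add(Species(bname, "molecules/cell", 0.0, max(R0[tgt], 1.0), {tgt: 1}))
                rev = d.kind == TKI_REVERSIBLE
                rx.append(Reaction(f"bind_{bname}", MA, {tgt: -1, bname: 1},
                                   k=f"{dn}.kon", A=tgt, U=dn,
                                   reversible=rev, kr=f"{dn}.koff" if rev else None,
                                   RA=bname if rev else None))
                rx.append(Reaction(f"deg_{bname}", MA, {bname: -1},
                                   k="kdeg_R", k2=f"{dn}.fdeg", A=bname, turnover=True))
        elif d.kind == ADC:
            if R0["HER2"] <= 0:
                continue  # ADC on a HER2-null line: payload flux identically zero
            at, cah, cin = f"ADC_tu:{dn}", f"ADC:HER2:{dn}", f"ADCint:{dn}"
            pli, ple = f"PL_in:{dn}", f"PL_ex:{dn}"
            add(Species(at, "nM", 0.0, 1.0))
            add(Species(cah, "molecules/cell", 0.0, max(R0["HER2"], 1.0), {"HER2": 1}))
            add(Species(cin, "molecules/cell", 0.0, max(R0["HER2"], 1.0), {"HER2": 1}))
            add(Species(pli, "nM", 0.0, 1.0))
            add(Species(ple, "nM", 0.0, 1.0))
            rx.append(Reaction(f"bind_{dn}", MA, {"HER2": -1, cah: 1},
                               k=f"{dn}.kon_ADC", A="HER2", B=at,
                               reversible=True, kr=f"{dn}.koff_ADC", RA=cah))
            rx.append(Reaction(f"int_{dn}", MA, {cah: -1, cin: 1}, k=f"{dn}.kint_ADC", A=cah))
            rx.append(Reaction(f"proc_{dn}", MA,
                               {cin: -1, pli: (NM_PER_MOLECULE, f"{dn}.DAR")},
                               k=f"{dn}.kdeg_ADC_2", A=cin, turnover=True))
            # competing recycling/exocytosis: complex cleared without payload
            rx.append(Reaction(f"recyc_{dn}", MA, {cin: -1},
                               k=f"{dn}.k_recycle", A=cin, turnover=True))
            if d.payload_reentry:
                rx.append(Reaction(f"perm_{dn}", MA, {pli: -1, ple: 1},
                                   k=f"{dn}.kper_PL", A=pli,
                                   reversible=True, kr=f"{dn}.kper_PL", RA=ple))
            else:
                rx.append(Reaction(f"efflux_{dn}", MA, {pli: -1, ple: 1},
                                   k=f"{dn}.kout_PL", A=pli))
            rx.append(Reaction(f"degPL_{dn}", MA, {pli: -1}, k=f"{dn}.kdeg_PL", A=pli))
            if d.payload_reentry:
                # effluxed non-re-entering payload is a terminal pool and needs
                # no clearance; the exchanging pool does
                rx.append(Reaction(f"clrPLex_{dn}", MA, {ple: -1}, k=f"{dn}.kclr_PLex", A=ple))
            u_coupl[f"PL:{dn}"] = (pli, 1.0)
            death_stimuli.append((("w14", f"{dn}.death_potency"),
                                  "km14", "n14", f"PL:{dn}"))
        elif d.kind == CHEMO_PAYLOAD:
            death_stimuli.append(("w15", "km10", "n10", "5-FU"))

    # ADCs bind the HER2 ectodomain regardless of kinase-site TKI occupancy:
    # TKI-bound HER2 can still be captured into the ADC:HER2 complex
    existing = {s.name for s in sp}
    for d in drugs:
        if d.kind != ADC or R0["HER2"] <= 0:
            continue
        for tki in drugs:
            if d.kind != ADC or "HER2" not in tki.targets:
                continue
            bname = f"HER2:{tki.name}"
            if bname in existing:
                rx.append(Reaction(
                    f"bind_{d.name}_{bname}", MA,
                    {bname: -1, f"ADC:HER2:{d.name}": 1},
                    k=f"{d.name}.kon_ADC", A=bname, B=f"ADC_tu:{d.name}"))

    # --- growth and death --------------------------------------------------
    rx.append(Reaction("growth", GROWTH, {"N": 1}, k="umax", A="N", B="pERK", X="pAKT",
                       extra={"km13": "km13", "n13": "n13", "w11": "w11", "km11": "km11",
                              "n11": "n11", "wAKT": "wAKT", "kmA": "kmA", "nA": "nA",
                              "Vmax": "Vmax", "rho": "cells_per_mm3", "s0": "s_basal"}))
    rx.append(Reaction("death", DEATH, {"N": -1}, k="dmax", A="N",
                       stimuli=tuple(death_stimuli)))

    # --- PK ---------------------------------------------------------------
    if mode == _IN_VIVO:
        for d in drugs:
            dn = d.name
            if dn not in pk:
                continue
            # the plasma-deconjugation payload block is observationally inert
            # for tumor outcomes (plasma catabolites do not enter the tumor)
            # and is carried by the stand-alone PK module instead
            _add_pk_block(sp, rx, u_coupl, pk[dn], dn, d, include_pk_sinks,
                          payload_plasma=False)

    inputs = list(INPUT_NAMES)
    net = ReactionNetwork(sp, rx, inputs, obs_defs, mode, cell_line, drugs, pk)
    net.u_couplings = u_coupl
    return net


def _add_pk_block(sp, rx, u_coupl, p: PKParams, dn: str, mech: DrugMechanism,
                  sinks: bool, payload_plasma: bool = True):
    """Compartmental PK reactions for one drug (amounts in nmol)."""
    pfx = f"pk.{dn}."
    bw = MOUSE_BODY_WEIGHT_KG

    def S(name, init=0.0):
        sp.append(Species(name, "nmol", init, 1.0e3))

    ac, ap = f"Ac:{dn}", f"Ap:{dn}"
    if p.drug == "capecitabine" or p.cap_chain:
        gut, met = f"Gut:{dn}", [f"A_cap:{dn}", f"A_dfcr:{dn}", f"A_dfur:{dn}", f"A_5fu:{dn}"]
        S(gut)
        for m in met:
            S(m)
        rx.append(Reaction(f"abs_{dn}", MA, {gut: -1, met[0]: 1}, k=pfx + "ka", A=gut))
        for i in range(3):
            rx.append(Reaction(f"met{i}_{dn}", MA, {met[i]: -1, met[i + 1]: 1},
                               k=pfx + f"kmet{i}", A=met[i]))
        st = {met[3]: -1}
        if sinks:
            S(f"Elim:{dn}")
            st[f"Elim:{dn}"] = 1
        rx.append(Reaction(f"elim5fu_{dn}", MA, st, k=pfx + "kmet3", A=met[3]))
        # tumor 5-FU exposure: Kp x central 5-FU concentration
        u_coupl["5-FU"] = (met[3], (1.0 / (p.V_met * bw), pfx + "Kp"))
        return

    S(ac)
    S(ap)
    if p.route == "oral":
        gut = f"Gut:{dn}"
        S(gut)
        rx.append(Reaction(f"abs_{dn}", MA, {gut: -1, ac: 1}, k=pfx + "ka", A=gut))
    st = {ac: -1}
    if sinks:
        S(f"Elim:{dn}")
        st[f"Elim:{dn}"] = 1
    rx.append(Reaction(f"elim_{dn}", MA, st, k=pfx + "kel", A=ac))
    rx.append(Reaction(f"dist_{dn}", MA, {ac: -1, ap: 1}, k=pfx + "k12", A=ac,
                       reversible=True, kr=pfx + "k21", RA=ap))

    if mech.kind == ADC:
        if payload_plasma:
            plc, plp = f"APLc:{dn}", f"APLp:{dn}"
            S(plc)
            S(plp)
            st_dec = {ac: -1, plc: (1.0, f"{dn}.DAR")}
            if sinks:
                st_dec[f"Elim:{dn}"] = 1  # antibody leaving the intact-ADC ledger
            rx.append(Reaction(f"deconj_{dn}", MA, st_dec, k=pfx + "k_release", A=ac))
            stp = {plc: -1}
            if sinks:
                S(f"ElimPL:{dn}")
                stp[f"ElimPL:{dn}"] = 1
            rx.append(Reaction(f"elimPL_{dn}", MA, stp, k=pfx + "kel_star", A=plc))
            rx.append(Reaction(f"distPL_{dn}", MA, {plc: -1, plp: 1}, k=pfx + "k12_star",
                               A=plc, reversible=True, kr=pfx + "k21_star", RA=plp))
        # first-order tumor entry from the central amount; no back-flux, and the
        # tumor dose is negligible relative to body burden so Ac is not depleted
        rx.append(Reaction(f"tumor_in_{dn}", MA, {f"ADC_tu:{dn}": 1}, k=pfx + "k_tu", A=ac))
        rx.append(Reaction(f"tumor_clr_{dn}", MA, {f"ADC_tu:{dn}": -1},
                           k=pfx + "kclr_tumor", A=f"ADC_tu:{dn}"))
    else:
        # small molecule: instantaneous tumor partition, Kp x central conc
        u_coupl[dn] = (ac, (1.0 / (p.Vc * bw), pfx + "Kp"))


def derived_pk_rates(ps: ParameterSet) -> ParameterSet:
    """Append kel/k12/k21-style rate constants derived from CL/V PK fields."""
    out = ParameterSet(ps)
    drugs = {n.split(".")[1] for n in ps if n.startswith("pk.")}
    for d in drugs:
        pfx = f"pk.{d}."
        if pfx + "CL" in ps and ps.get(pfx + "Vc", 0) > 0:
            out[pfx + "kel"] = ps[pfx + "CL"] / ps[pfx + "Vc"]
            out[pfx + "k12"] = ps[pfx + "Q"] / ps[pfx + "Vc"]
            out[pfx + "k21"] = ps[pfx + "Q"] / ps[pfx + "Vp"]
        if pfx + "CL_star" in ps:
            out[pfx + "kel_star"] = ps[pfx + "CL_star"] / ps[pfx + "Vc_star"]
            out[pfx + "k12_star"] = ps[pfx + "Q_star"] / ps[pfx + "Vc_star"]
            out[pfx + "k21_star"] = ps[pfx + "Q_star"] / ps[pfx + "Vp_star"]
    return out
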