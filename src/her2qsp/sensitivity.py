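"""Global sensitivity (PRCC over Latin hypercube samples, total-order Sobol)
and bootstrap parameter uncertainty.

PRCC follows the standard partial-rank-correlation recipe: rank-transform the
sample matrix and output, regress each parameter column and the output on all
remaining columns, and correlate the residuals; significance comes from the
t-statistic of the residual correlation with a Bonferroni-corrected
threshold.  Sobol total-order indices use Saltelli sampling with the Jansen
estimator.  The model output of interest is tumor volume at day 20 of a
xenograft simulation under a named input condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .calibration import CalibrationDataset, FitSpec, Simulators, fit
from .params import ConfigError, ParameterSet
from .protocols import Regimen, RegimenArm, XenograftProtocol, run_xenograft
from .simulate import Event, initialize_steady_state, ligand_bath

PRCC_THRESHOLD = 0.05  # |PRCC| above this (and significant) counts as influential
P_THRESHOLD = 0.01  # Bonferroni-corrected over parameters

#: NRG1 bath for the overexpression *sensitivity* condition (ng/mL).  Probed
#: in the receptor-binding-limited autocrine regime, where the NRG1-HER3
#: association rate is rate-determining; the resistance phenotype simulations
#: use a saturating 50 ng/mL exposure instead.
NRG1_OVER_SENSITIVITY_NGML = 2.0

#: parameters sampled under every condition
CORE_PARAMETERS = (
    "umax", "dmax", "km13", "n13", "kon_Raf", "koff_Raf", "kon_ERK", "koff_ERK",
    "w7", "w8", "w11", "wAKT", "k_pi3k_act", "k8on", "k1on", "kphos", "kdeph",
    "kdeg_R", "f_foxo", "km_pi3k",
)

#: standard single-cycle doses used for the sensitivity input conditions
CONDITION_REGIMENS: dict[str, tuple] = {
    "none": ((), Regimen(())),
    "NRG1_over": ((), Regimen(())),
    "lap+cap": (("lapatinib", "capecitabine"),
                Regimen((RegimenArm("lapatinib", 100.0, "qd"),
                         RegimenArm("capecitabine", 400.0, "d1-d14")))),
    "pyr+cap": (("pyrotinib", "capecitabine"),
                Regimen((RegimenArm("pyrotinib", 30.0, "qd"),
                         RegimenArm("capecitabine", 400.0, "d1-d14")))),
    "TDM1": (("T-DM1",), Regimen((RegimenArm("T-DM1", 30.0, "q3w", route="iv"),))),
    "TDXd": (("T-DXd",), Regimen((RegimenArm("T-DXd", 10.0, "q3w", route="iv"),))),
}


def condition_parameters(condition: str) -> list[str]:
    """Default sampled-parameter list for one input condition."""
    extra: list[str] = []
    if condition in ("lap+cap", "pyr+cap"):
        drug = "lapatinib" if condition.startswith("lap") else "pyrotinib"
        extra += [f"{drug}.kon", "w15", "km10"]
    elif condition == "TDM1":
        extra += ["T-DM1.kint_ADC", "T-DM1.kdeg_ADC_2", "T-DM1.kout_PL", "w14", "km14"]
    elif condition == "TDXd":
        extra += ["T-DXd.kint_ADC", "T-DXd.kdeg_ADC_2", "T-DXd.kper_PL", "w14", "km14"]
    return list(CORE_PARAMETERS) + extra


@dataclass
class SensitivitySpec:
    """LHS/PRCC design: condition, sampled parameters, fold range, size."""

    condition: str = "none"
    parameters: Sequence[str] | None = None
    fold_range: tuple = (0.5, 2.0)
    n: int = 5000
    day: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.parameters is None:
            self.parameters = condition_parameters(self.condition)
        if self.fold_range[0] <= 0 or self.fold_range[1] <= self.fold_range[0]:
            raise ConfigError("fold_range must be positive and increasing")


@dataclass
class SensitivityResult:
    """PRCC values with p-values and the significant set."""

    table: pd.DataFrame  # index: parameter; columns: prcc, p, significant
    n_used: int
    n_failed: int

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def ranked(self) -> pd.DataFrame:
        return self.table.reindex(self.table["prcc"].abs().sort_values(ascending=False).index)


def lhs_sample(spec: SensitivitySpec, baseline: Mapping[str, float]) -> pd.DataFrame:
    """Latin-hypercube sample of the parameters, uniform on fold x baseline.

    Each parameter's marginal places exactly one point per equal-probability
    stratum; deterministic for a given seed.
    """
    names = list(spec.parameters)
    if spec.n < len(names):
        raise ConfigError("need at least one sample per parameter")
    for nm in names:
        if nm not in baseline:
            raise ConfigError(f"parameter {nm!r} not in baseline set")
    unit = qmc.LatinHypercube(d=len(names), seed=spec.seed).random(spec.n)
    lo, hi = spec.fold_range
    base = np.array([baseline[nm] for nm in names])
    vals = base * (lo + unit * (hi - lo))
    return pd.DataFrame(vals, columns=names)


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def prcc(samples: pd.DataFrame, outputs: np.ndarray,
         p_threshold: float = P_THRESHOLD, bonferroni: bool = True,
         min_valid_fraction: float = 0.95) -> SensitivityResult:
    """Partial rank correlation of each sampled parameter with the output."""
    X = samples.to_numpy(float)
    y = np.asarray(outputs, float)
    ok = np.isfinite(y)
    n_failed = int((~ok).sum())
    if ok.mean() < min_valid_fraction:
        raise RuntimeError(f"only {ok.mean():.0%} of model evaluations finite")
    X, y = X[ok], y[ok]
    n, k = X.shape
    if np.ptp(y) == 0:
        raise RuntimeError("constant output: PRCC undefined")
    Xr = _rank(X)
    yr = _rank(y[:, None])[:, 0]
    thr = p_threshold / k if bonferroni else p_threshold
    rows = []
    ones = np.ones((n, 1))
    for j in range(k):
        Z = np.column_stack([ones, np.delete(Xr, j, axis=1)])
        beta_x, *_ = np.linalg.lstsq(Z, Xr[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(Z, yr, rcond=None)
        rx = Xr[:, j] - Z @ beta_x
        ry = yr - Z @ beta_y
        denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
        if denom == 0:
            rows.append((np.nan, np.nan, False))
            continue
        r = float(np.sum(rx * ry) / denom)
        dof = n - 2 - (k - 1)
        t = r * np.sqrt(dof / max(1e-12, 1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), dof)
        rows.append((r, p, abs(r) > PRCC_THRESHOLD and p < thr))
    table = pd.DataFrame(rows, index=list(samples.columns),
                         columns=["prcc", "p", "significant"])
    return SensitivityResult(table, n, n_failed)


def condition_output_fn(model, condition: str, day: float = 20.0,
                        ss_tol: float = 1e-6) -> Callable[[Mapping[str, float]], float]:
    """Tumor volume at ``day`` as a function of the parameter set.

    ``model`` must be an in vivo :class:`~her2qsp.model.TumorGrowthModel`
    carrying the condition's drugs; the NRG1-overexpression condition applies
    a constant 50 ng/mL NRG1 bath.
    """
    _, regimen = CONDITION_REGIMENS[condition]
    extra = (ligand_bath("NRG1", NRG1_OVER_SENSITIVITY_NGML),) if condition == "NRG1_over" else ()
    protocol = XenograftProtocol(follow_up_days=day, extra_events=extra)

    def f(params: Mapping[str, float]) -> float:
        ss = initialize_steady_state(model.network, params, tol=ss_tol, max_hours=4000)
        df = run_xenograft(model.network, params, regimen, protocol, y_ss=ss)
        return float(df["volume_mm3"].iloc[-1])

    return f


def run_prcc(model, spec: SensitivitySpec, baseline: Mapping[str, float] | None = None,
             output_fn: Callable | None = None) -> tuple[SensitivityResult, pd.DataFrame, np.ndarray]:
    """LHS + model evaluation + PRCC for one condition; returns the result,
    the sample matrix and the raw outputs (failures as NaN)."""
    baseline = dict(model.params if baseline is None else baseline)
    samples = lhs_sample(spec, baseline)
    if output_fn is None:
        output_fn = condition_output_fn(model, spec.condition, day=spec.day)
    outputs = np.empty(len(samples))
    base = ParameterSet(baseline)
    for i, row in enumerate(samples.itertuples(index=False)):
        try:
            outputs[i] = output_fn(base.override(dict(zip(samples.columns, row)))
                                   )
        except Exception:
            outputs[i] = np.nan
    return prcc(samples, outputs), samples, outputs


# ---------------------------------------------------------------------------
# Sobol total-order indices
# ---------------------------------------------------------------------------


def sobol_total(func: Callable[[np.ndarray], float], bounds: Mapping[str, tuple],
                base_n: int = 512, seed: int = 0, n_boot: int = 200,
                ci: float = 0.95) -> pd.DataFrame:
    """Total-order Sobol indices by Saltelli sampling and the Jansen estimator.

    ``func`` maps a parameter vector (ordered as ``bounds``) to a scalar.
    Returns a table with ``S_T`` and bootstrap confidence bounds; the sample
    budget is ``(k + 2) * base_n`` model evaluations.
    """
    names = list(bounds)
    k = len(names)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    base = sampler.random(base_n)
    A = lo + base[:, :k] * (hi - lo)
    B = lo + base[:, k:] * (hi - lo)

    fA = np.array([func(x) for x in A])
    fB = np.array([func(x) for x in B])
    fAB = np.empty((base_n, k))
    for j in range(k):
        AB = A.copy()
        AB[:, j] = B[:, j]
        fAB[:, j] = [func(x) for x in AB]

    f_all = np.concatenate([fA, fB])
    var = np.var(f_all, ddof=1)
    if var <= 0:
        raise RuntimeError("zero output variance: Sobol indices undefined")

    def jansen(idx):
        v = np.var(np.concatenate([fA[idx], fB[idx]]), ddof=1)
        return 0.5 * np.mean((fA[idx, None] - fAB[idx]) ** 2, axis=0) / v

    st = jansen(np.arange(base_n))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, k))
    for b in range(n_boot):
        boots[b] = jansen(rng.integers(0, base_n, base_n))
    alpha = (1.0 - ci) / 2.0
    return pd.DataFrame(
        {"S_T": st,
         "lo": np.quantile(boots, alpha, axis=0),
         "hi": np.quantile(boots, 1 - alpha, axis=0)},
        index=names)


# ---------------------------------------------------------------------------
# bootstrap uncertainty
# ---------------------------------------------------------------------------


@dataclass
class UncertaintySpec:
    """Bootstrap design: parameters, resample count, per-estimate bounds."""

    parameters: Sequence[str]
    n_resamples: int = 50
    bounds_fold: float = 10.0  # estimates range over [0.1x, 10x] baseline
    seed: int = 0
    max_iter: int = 60
    n_starts: int = 1
    mesh0: float = 0.25  # warm-started refits can use a smaller initial mesh


def bootstrap_uncertainty(spec: UncertaintySpec, dataset: CalibrationDataset,
                          simulators: Simulators, base_params: ParameterSet,
                          fit_fn: Callable | None = None) -> pd.DataFrame:
    """Refit the selected parameters on resampled datasets.

    Each resample redraws datapoint means from Normal(mean, sd) with the
    10%-of-mean dispersion imputation; failed fits are recorded as NaN rows
    rather than dropped.  Returns the resample x parameter estimate table with
    a ``loss`` column; relative-to-baseline values via :func:`relative_values`.
    ``fit_fn(dataset) -> {name: estimate, ...}`` replaces the default joint
    pattern-search refit when a staged estimation protocol is wanted.
    """
    rng = np.random.default_rng(spec.seed)
    free = {p: (base_params[p] / spec.bounds_fold, base_params[p] * spec.bounds_fold)
            for p in spec.parameters}
    rows = []
    for i in range(spec.n_resamples):
        ds = dataset.resampled(rng)
        try:
            if fit_fn is not None:
                rows.append(dict(fit_fn(ds)))
            else:
                res = fit(FitSpec(free=free, seed=spec.seed + i,
                                  max_iter=spec.max_iter,
                                  n_starts=spec.n_starts, mesh0=spec.mesh0),
                          ds, simulators, base_params)
                rows.append({**res.fitted, "loss": res.loss})
        except Exception:
            rows.append({p: np.nan for p in spec.parameters} | {"loss": np.nan})
    return pd.DataFrame(rows)


def relative_values(estimates: pd.DataFrame, base_params: Mapping[str, float]) -> pd.DataFrame:
    cols = [c for c in estimates.columns if c != "loss"]
    return estimates[cols] / pd.Series({c: base_params[c] for c in cols})
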