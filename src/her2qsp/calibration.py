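"""Parameter estimation against calibration datasets.

The loss is variance-weighted least squares over normalized readouts; the
optimizer is a derivative-free generalized pattern search (mesh/poll with
expansion 2 and contraction 0.5) run multi-start over log-scaled boxes, which
guarantees a monotone non-increasing incumbent loss and deterministic results
for a given seed.

In vitro -> in vivo translation follows a strict policy: signaling,
drug-target and intracellular processing parameters are frozen; only the
growth/death parameters (umax, dmax, w14, w15, n14, km14) may be re-estimated,
and for a new control arm only umax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ConfigError, ParameterSet

SD_IMPUTATION_FRACTION = 0.10  # sd = 10% of mean when dispersion is missing

TRANSLATABLE = ("umax", "dmax", "w14", "w15", "n14", "km14")

REQUIRED_COLUMNS = ("condition", "time", "readout", "mode", "mean")


class PolicyViolationError(ConfigError):
    """A translation step tried to free a frozen (signaling) parameter."""


class CalibrationDataset:
    """Observed datapoints with normalization semantics and dispersion.

    Backed by a DataFrame with columns ``condition, time, readout, mode, mean``
    and optional ``sd, n, weight``; ``source`` tags calibration vs validation.
    """

    def __init__(self, frame: pd.DataFrame, source: str = "calibration"):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigError(f"dataset missing columns {missing}")
        self.frame = frame.reset_index(drop=True).copy()
        if "sd" not in self.frame:
            self.frame["sd"] = np.nan
        if "weight" not in self.frame:
            self.frame["weight"] = 1.0
        if "n" not in self.frame:
            self.frame["n"] = 3
        self.source = source

    def __len__(self):
        return len(self.frame)

    def conditions(self):
        return list(dict.fromkeys(self.frame["condition"]))

    def weighting_sd(self) -> np.ndarray:
        """Strictly positive dispersion for residual weighting: missing or
        non-positive values fall back to 10% of the mean (with a small floor
        for zero-mean points)."""
        sd = self.frame["sd"].to_numpy(float).copy()
        mean = self.frame["mean"].to_numpy(float)
        bad = ~np.isfinite(sd) | (sd <= 0)
        sd[bad] = SD_IMPUTATION_FRACTION * np.abs(mean[bad])
        sd[sd <= 0] = 1e-6  # zero-mean points still need a positive dispersion
        return sd

    def resampling_sd(self) -> np.ndarray:
        """Dispersion used when redrawing datapoint means: missing values get
        the 10%-of-mean imputation; an explicit zero stays zero (noiseless
        data resample to themselves)."""
        sd = self.frame["sd"].to_numpy(float).copy()
        mean = self.frame["mean"].to_numpy(float)
        missing = ~np.isfinite(sd)
        sd[missing] = SD_IMPUTATION_FRACTION * np.abs(mean[missing])
        return sd

    def resampled(self, rng: np.random.Generator) -> "CalibrationDataset":
        """Bootstrap replicate: means redrawn from Normal(mean, sd)."""
        new = self.frame.copy()
        new["mean"] = rng.normal(self.frame["mean"].to_numpy(float), self.resampling_sd())
        return CalibrationDataset(new, source=self.source)

    def to_csv(self, path):
        self.frame.assign(source=self.source).to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_csv(path) -> "CalibrationDataset":
        df = pd.read_csv(path, sep="\t")
        source = df.pop("source").iloc[0] if "source" in df else "calibration"
        return CalibrationDataset(df, source=source)


#: a simulator maps a parameter set to one condition's Trajectory
Simulators = Mapping[str, Callable[[Mapping[str, float]], object]]


def predictions(params: Mapping[str, float], dataset: CalibrationDataset,
                simulators: Simulators) -> np.ndarray:
    """Model predictions for every dataset row, normalized per the row's mode.

    Normalization groups are (condition, readout): ``max`` divides by the
    group's maximum predicted value, ``control`` by the prediction at the
    group's earliest time point, ``none`` leaves raw values.
    """
    df = dataset.frame
    out = np.full(len(df), np.nan)
    for cond, gidx in df.groupby("condition").groups.items():
        if cond not in simulators:
            raise ConfigError(f"no simulator registered for condition {cond!r}")
        traj = simulators[cond](params)
        sub = df.loc[gidx]
        for readout, ridx in sub.groupby("readout").groups.items():
            rows = df.loc[ridx]
            times = rows["time"].to_numpy(float)
            if hasattr(traj, "readout"):
                series = np.interp(times, traj.times, traj.readout(readout))
            else:  # plain frames (first column is the axis: day, dose, ...)
                series = np.interp(times, traj.iloc[:, 0].to_numpy(),
                                   traj[readout].to_numpy())
            mode = rows["mode"].iloc[0]
            if mode == "max":
                ref = np.max(series)
                series = series / ref if ref > 0 else series
            elif mode == "control":
                ref = series[np.argmin(times)]
                series = series / ref if ref > 0 else series
            out[np.asarray(ridx)] = series
    return out


def objective(params: Mapping[str, float], dataset: CalibrationDataset,
              simulators: Simulators, penalty: float = 1e8) -> float:
    """Sum of weighted squared standardized residuals; simulation failures map
    to a large finite penalty."""
    try:
        pred = predictions(params, dataset, simulators)
    except Exception:
        return penalty
    if not np.all(np.isfinite(pred)):
        return penalty
    res = (pred - dataset.frame["mean"].to_numpy(float)) / dataset.weighting_sd()
    w = dataset.frame["weight"].to_numpy(float)
    return float(np.sum(w * res**2))


# ---------------------------------------------------------------------------
# pattern search
# ---------------------------------------------------------------------------


@dataclass
class FitSpec:
    """Free parameters with (lower, upper) bounds plus optimizer settings."""

    free: Mapping[str, tuple]
    fixed: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    max_iter: int = 200
    n_starts: int = 8
    log_scale: bool = True
    mesh0: float = 0.25
    mesh_tol: float = 1e-6

    def __post_init__(self):
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ConfigError(f"parameters both free and fixed: {sorted(overlap)}")
        for name, (lo, hi) in dict(self.free).items():
            if not (0 < lo < hi) or not np.isfinite(hi):
                raise ConfigError(f"bounds for {name} must be finite and positive")


@dataclass
class FitResult:
    params: ParameterSet
    fitted: dict
    loss: float
    trace: list
    n_evals: int
    converged: bool
    warning: str | None = None

    def summary(self) -> str:
        lines = [f"pattern-search fit: loss={self.loss:.6g}, "
                 f"{self.n_evals} evaluations, converged={self.converged}"]
        for k, v in self.fitted.items():
            lines.append(f"  {k:>12s} = {v:.6g}")
        return "\n".join(lines)


def pattern_search(f: Callable[[np.ndarray], float], x0: np.ndarray,
                   max_iter: int = 200, mesh0: float = 0.25,
                   mesh_tol: float = 1e-6) -> tuple:
    """Generalized pattern search on the unit box (coordinates in [0, 1]).

    Opportunistic coordinate poll with direction memory (the last successful
    direction is polled first); successful polls expand the mesh (x2, capped),
    failures contract (x0.5); terminates when the mesh drops below
    ``mesh_tol`` or the iteration budget is exhausted.  Deterministic.
    """
    x = np.clip(np.asarray(x0, float), 0.0, 1.0)
    fx = f(x)
    trace = [fx]
    mesh = mesh0
    n_evals = 1
    d = len(x)
    # coordinate directions plus pairwise diagonals: the diagonals rescue the
    # search in narrow correlated valleys where axis polls all point uphill
    dirs: list[np.ndarray] = []
    for i in range(d):
        for s in (+1.0, -1.0):
            v = np.zeros(d)
            v[i] = s
            dirs.append(v)
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    for i in range(d):
        for j in range(i + 1, d):
            for si in (+1.0, -1.0):
                for sj in (+1.0, -1.0):
                    v = np.zeros(d)
                    v[i], v[j] = si * inv_sqrt2, sj * inv_sqrt2
                    dirs.append(v)
    last_good = 0
    for _ in range(max_iter):
        if mesh < mesh_tol:
            break
        improved = False
        order = list(range(last_good, len(dirs))) + list(range(last_good))
        for k in order:
            xt = np.clip(x + mesh * dirs[k], 0.0, 1.0)
            if np.all(xt == x):
                continue
            ft = f(xt)
            n_evals += 1
            if ft < fx:
                x, fx = xt, ft
                improved = True
                last_good = k
                break
        mesh = min(mesh * 2.0, 0.5) if improved else mesh * 0.5
        trace.append(fx)
    return x, fx, trace, n_evals, mesh < mesh_tol


def fit(spec: FitSpec, dataset: CalibrationDataset, simulators: Simulators,
        base_params: ParameterSet) -> FitResult:
    """Estimate the free parameters of ``spec`` against a dataset.

    Multi-start pattern search in (log-scaled) bounded coordinates; the best
    incumbent over all starts is returned with its monotone loss trace.
    """
    names = list(spec.free)
    lo = np.array([spec.free[n][0] for n in names], float)
    hi = np.array([spec.free[n][1] for n in names], float)
    if spec.log_scale:
        zlo, zhi = np.log(lo), np.log(hi)
    else:
        zlo, zhi = lo, hi

    base = base_params.override(dict(spec.fixed)) if spec.fixed else ParameterSet(base_params)

    def decode(t: np.ndarray) -> dict:
        z = zlo + t * (zhi - zlo)
        vals = np.exp(z) if spec.log_scale else z
        return dict(zip(names, vals))

    def loss_of(t: np.ndarray) -> float:
        return objective(base.override(decode(t)), dataset, simulators)

    starts = []
    x_base = np.array([base.get(n, np.sqrt(lo[i] * hi[i])) for i, n in enumerate(names)])
    z_base = np.log(np.clip(x_base, lo, hi)) if spec.log_scale else np.clip(x_base, lo, hi)
    starts.append((z_base - zlo) / (zhi - zlo))
    if spec.n_starts > 1:
        from scipy.stats import qmc

        extra = qmc.LatinHypercube(d=len(names), seed=spec.seed).random(spec.n_starts - 1)
        starts.extend(extra)

    best = None
    total_evals = 0
    for s in starts:
        x, fx, trace, n_ev, conv = pattern_search(
            loss_of, s, max_iter=spec.max_iter, mesh0=spec.mesh0, mesh_tol=spec.mesh_tol)
        total_evals += n_ev
        if best is None or fx < best[1]:
            best = (x, fx, trace, conv)
    x, fx, trace, conv = best
    fitted = decode(x)
    warning = None if conv else "iteration budget exhausted before mesh convergence"
    return FitResult(base.override(fitted), fitted, fx, trace, total_evals, conv, warning)


# ---------------------------------------------------------------------------
# in vitro -> in vivo translation policy
# ---------------------------------------------------------------------------


def translate_in_vivo(cell_params: ParameterSet, dataset: CalibrationDataset | None,
                      simulators: Simulators | None = None,
                      free: Sequence[str] = ("umax", "dmax"),
                      bounds_fold: float = 10.0, seed: int = 0,
                      max_iter: int = 120, n_starts: int = 4,
                      control_only: bool | None = None) -> FitResult:
    """Re-estimate only growth/death parameters against in vivo data.

    Signaling/drug-processing parameters are returned bit-identical.  For a
    dataset containing only a control arm, policy restricts the free set to
    ``umax`` alone.
    """
    illegal = [n for n in free if n not in TRANSLATABLE]
    if illegal:
        raise PolicyViolationError(
            f"cannot free signaling/processing parameters in vivo: {illegal}")
    if dataset is None or len(dataset) == 0:
        return FitResult(ParameterSet(cell_params), {}, 0.0, [0.0], 0, True)
    if control_only is None:
        control_only = set(dataset.frame["condition"]) <= {"control", "vehicle"}
    if control_only:
        free = ["umax"]
    spec = FitSpec(
        free={n: (cell_params[n] / bounds_fold, cell_params[n] * bounds_fold) for n in free},
        seed=seed, max_iter=max_iter, n_starts=n_starts)
    result = fit(spec, dataset, simulators, cell_params)
    for name in cell_params:
        if name not in result.fitted:
            assert result.params[name] == cell_params[name]
    return result
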