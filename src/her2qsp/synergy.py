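"""Bliss-independence expected effects and synergy classification.

The Bliss null model for two independently acting drugs with fractional
effects Ya and Yb is ``Yab = Ya + Yb - Ya*Yb``; a dose pair whose simulated
combination effect exceeds Yab is classified synergistic.  For in vivo
surfaces the effect scale is fractional TGI (TGI/100 clipped to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

SYNERGISTIC, ADDITIVE, ANTAGONISTIC, UNDEFINED = "synergistic", "additive", "antagonistic", "undefined"


def bliss_expected(ya: float, yb: float) -> float:
    """Bliss-independence expected combination effect ``ya + yb - ya*yb``."""
    ya_a, yb_a = np.asarray(ya, float), np.asarray(yb, float)
    if np.any((ya_a < 0) | (ya_a > 1) | (yb_a < 0) | (yb_a > 1)):
        raise ValueError("fractional effects must lie in [0, 1]")
    # algebraically identical to ya + yb - ya*yb but exact at the fixed
    # points ya = 1 and yb = 0 in floating point
    return ya_a + yb_a * (1.0 - ya_a)


@dataclass
class SynergySurface:
    """Dose-grid synergy surface with model, Bliss and classification matrices."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    model_effect: np.ndarray
    bliss_effect: np.ndarray
    classification: np.ndarray
    drug_a: str = "A"
    drug_b: str = "B"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, da in enumerate(self.doses_a):
            for j, db in enumerate(self.doses_b):
                rows.append((da, db, self.model_effect[i, j], self.bliss_effect[i, j],
                             self.classification[i, j]))
        return pd.DataFrame(rows, columns=[f"dose_{self.drug_a}", f"dose_{self.drug_b}",
                                           "model_effect", "bliss_effect", "class"])

    def n_synergistic(self) -> int:
        return int(np.sum(self.classification == SYNERGISTIC))


def classify_surface(doses_a: Sequence[float], doses_b: Sequence[float],
                     effect_fn: Callable[[float, float], float],
                     tol: float = 0.01, drug_a: str = "A", drug_b: str = "B",
                     ) -> SynergySurface:
    """Classify every dose pair against the Bliss expectation.

    ``effect_fn(a, b)`` must return a fractional effect in [0, 1] (viability
    loss or TGI/100).  Single-agent effects come from the zero-dose calls;
    cells within ``tol`` of the Bliss value are labeled additive, and
    non-finite effects are marked undefined rather than raising.
    """
    doses_a = np.asarray(doses_a, float)
    doses_b = np.asarray(doses_b, float)
    ya = np.array([effect_fn(a, 0.0) for a in doses_a])
    yb = np.array([effect_fn(0.0, b) for b in doses_b])
    na, nb = len(doses_a), len(doses_b)
    model = np.empty((na, nb))
    blis = np.empty((na, nb))
    cls = np.empty((na, nb), dtype=object)
    for i, a in enumerate(doses_a):
        for j, b in enumerate(doses_b):
            if a == 0.0:
                eff = yb[j]
            elif b == 0.0:
                eff = ya[i]
            else:
                eff = effect_fn(a, b)
            model[i, j] = eff
            if not (np.isfinite(ya[i]) and np.isfinite(yb[j]) and np.isfinite(eff)):
                blis[i, j] = np.nan
                cls[i, j] = UNDEFINED
                continue
            expected = bliss_expected(np.clip(ya[i], 0, 1), np.clip(yb[j], 0, 1))
            blis[i, j] = expected
            if a == 0.0 or b == 0.0:
                cls[i, j] = ADDITIVE  # single-agent rows are additive by definition
            elif eff > expected + tol:
                cls[i, j] = SYNERGISTIC
            elif eff < expected - tol:
                cls[i, j] = ANTAGONISTIC
            else:
                cls[i, j] = ADDITIVE
    return SynergySurface(doses_a, doses_b, model, blis, cls, drug_a, drug_b)
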