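"""Accuracy-curve fitting and training-size extrapolation.

Predictive ability r(ĝ,y) converts to predictive accuracy r(ĝ,g) by
dividing by h = sqrt(h²).  Accuracy as a function of training size N follows
the deterministic curve

    r(ĝ,g) = sqrt(N h² / (N h² + M)),

where M is the effective number of independent loci.  Linearizing with
y = (1 - r²)/r² and x = 1/N gives a zero-intercept line y = k x with
k = M/h², fitted by least squares through the origin; M = k h², and the
training size needed for a target accuracy r* is N* = (r*²/(1 - r*²)) k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError


@dataclass
class AccuracyCurveFit:
    h2: float
    points: pd.DataFrame   # N, ability, accuracy, x, y
    k: float               # zero-intercept slope = M / h2
    M: float               # effective number of independent loci
    rss: float


def ability_to_accuracy(ability: float, h2: float) -> float:
    """r(ĝ,g) = r(ĝ,y) / sqrt(h²); errors if the result reaches 1.

    Accuracy at or above 1 leaves the domain of the accuracy curve (the
    transform (1-r²)/r² hits 0) and indicates ability inconsistent with the
    supplied heritability.
    """
    if not 0 < h2 <= 1:
        raise ConfigurationError(f"h2={h2} outside (0, 1]")
    acc = ability / math.sqrt(h2)
    if acc >= 1:
        raise DomainError(
            f"accuracy {acc:.4f} >= 1: outside the accuracy-curve domain "
            f"(ability {ability} with h2 {h2})"
        )
    return acc


def fit_curve(points, h2: float) -> AccuracyCurveFit:
    """Zero-intercept least squares of (1-r²)/r² on 1/N; returns k and M = k h².

    ``points`` is a sequence of (N, ability) pairs, at least two with
    distinct N; every implied accuracy must lie strictly in (0, 1).
    """
    pts = [(float(n), float(a)) for n, a in points]
    if len(pts) < 2 or len({n for n, _ in pts}) < 2:
        raise ConfigurationError("need >= 2 points with distinct N")
    rows = []
    for n, ability in pts:
        if n <= 0:
            raise ConfigurationError(f"training size {n} must be positive")
        acc = ability / math.sqrt(h2)
        if not 0 < acc < 1:
            raise DomainError(
                f"point (N={n:g}, ability={ability}) gives accuracy {acc:.4f} "
                f"outside (0, 1)"
            )
        rows.append((n, ability, acc, 1.0 / n, (1 - acc**2) / acc**2))
    df = pd.DataFrame(rows, columns=["N", "ability", "accuracy", "x", "y"])
    k = float((df["x"] * df["y"]).sum() / (df["x"] ** 2).sum())
    rss = float(((df["y"] - k * df["x"]) ** 2).sum())
    return AccuracyCurveFit(h2=h2, points=df, k=k, M=k * h2, rss=rss)


def predict_accuracy(N: float, h2: float, M: float) -> float:
    """sqrt(N h² / (N h² + M))."""
    if N <= 0 or not 0 < h2 < 1 or M <= 0:
        raise ConfigurationError("require N > 0, h2 in (0, 1), M > 0")
    return math.sqrt(N * h2 / (N * h2 + M))


def required_training_size(target_accuracy: float, fit: AccuracyCurveFit) -> int:
    """Smallest N reaching the target accuracy on the fitted curve.

    N* = (r²/(1-r²)) k, rounded half-up to the nearest integer.
    """
    r = target_accuracy
    if not 0 < r < 1:
        raise ConfigurationError(f"target accuracy {r} outside (0, 1)")
    n_star = (r**2 / (1 - r**2)) * fit.k
    return int(math.floor(n_star + 0.5))


def curve_table(fits: dict, targets=(0.8,)) -> pd.DataFrame:
    """Summary table over {(trait, method): AccuracyCurveFit} with equations."""
    rows = []
    for (trait, method), fit in fits.items():
        row = {
            "trait": trait, "method": method, "h2": fit.h2,
            "k": fit.k, "M": fit.M,
            "equation": f"r = sqrt({fit.h2:g}*N/({fit.h2:g}*N+{fit.M:.2f}))",
        }
        for tgt in targets:
            row[f"required_N@{tgt:g}"] = required_training_size(tgt, fit)
        rows.append(row)
    return pd.DataFrame(rows)
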