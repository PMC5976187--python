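"""Centerline evaluation: curve distances, failure criterion, model selection.

Curves are compared on their delta-sampled points (no segment projection):
with both curves sampled at 0.1 mm the sampling error is negligible
against the 3.5 mm failure threshold.

* D(x, C)   - distance from a point to the closest sampled curve point;
* H(A, B)   - symmetric Hausdorff distance between two curves;
* CAD       - per-artery distance: max of the ICA and ECA Hausdorff
              distances between automatic and manual centerlines; a
              detection counts as failed when CAD exceeds 3.5 mm
              (strictly), about the mean artery radius.

``select_omega_loo`` reproduces the leave-one-case-out selection of the
smoothness constant omega (fewest failures, then lowest mean CAD), and
``mcnemar_exact`` the exact binomial McNemar test on discordant failure
counts between two methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import binom

from .volumes import Centerline

__all__ = [
    "EvaluationReport",
    "point_to_path",
    "hausdorff",
    "cad",
    "select_omega_loo",
    "mcnemar_exact",
    "FAILURE_THRESHOLD_MM",
]

FAILURE_THRESHOLD_MM = 3.5


@dataclass(frozen=True)
class EvaluationReport:
    """Per-artery distances and the failure flag."""

    H_ica: float
    H_eca: float
    CAD: float
    failed: bool
    threshold: float = FAILURE_THRESHOLD_MM


def _points(c) -> np.ndarray:
    return c.points if isinstance(c, Centerline) else np.asarray(c, dtype=float)


def point_to_path(x, c) -> float:
    """min over sampled path points of the Euclidean distance to x."""
    pts = _points(c)
    return float(np.linalg.norm(pts - np.asarray(x, dtype=float), axis=1).min())


def hausdorff(c_a, c_b) -> float:
    """Symmetric Hausdorff distance max{max_x D(x,B), max_y D(y,A)}."""
    a = _points(c_a)
    b = _points(c_b)
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def cad(
    auto_ica,
    auto_eca,
    manual_ica,
    manual_eca,
    threshold: float = FAILURE_THRESHOLD_MM,
) -> EvaluationReport:
    """Centerline Artery Distance report for one artery.

    ``failed`` is True only for CAD strictly above the threshold.
    """
    h_i = hausdorff(manual_ica, auto_ica)
    h_e = hausdorff(manual_eca, auto_eca)
    c = max(h_i, h_e)
    return EvaluationReport(h_i, h_e, c, failed=bool(c > threshold), threshold=threshold)


def select_omega_loo(
    cad_table: pd.DataFrame, threshold: float = FAILURE_THRESHOLD_MM
) -> pd.Series:
    """Leave-one-case-out selection of the smoothness constant omega.

    ``cad_table`` holds CAD values with one row per case and one column per
    omega value.  For each held-out case, omega is chosen on the remaining
    cases as the value minimising (failure count, mean CAD, omega).
    Returns the selected omega per case.
    """
    table = pd.DataFrame(cad_table).astype(float)
    if table.isna().any().any():
        raise ValueError("CAD table is incomplete")
    if table.shape[1] == 0:
        raise ValueError("omega grid is empty")
    selected = {}
    for case in table.index:
        train = table.drop(index=case)
        failures = (train > threshold).sum(axis=0)
        means = train.mean(axis=0)
        ranked = sorted(
            table.columns, key=lambda w: (int(failures[w]), float(means[w]), float(w))
        )
        selected[case] = ranked[0]
    return pd.Series(selected, name="omega")


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided binomial McNemar p-value from discordant counts.

    ``b`` and ``c`` count cases where only the first / only the second
    method failed; p = min(1, 2 * P[Binom(b+c, 1/2) <= min(b, c)]).  With
    no discordant pairs, p = 1 by convention.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * binom.cdf(min(b, c), n, 0.5)))
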