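"""Detectability and length-error models fitted from matched vessels.

Two empirical relationships drive the dark-fleet estimate:

* **Detection curve α** — probability that a vessel of a given true length
  shows up in a radar scene. Below a 60 m knot the rate rises roughly
  linearly with length (fitted as a τ = 0.5 quantile regression on
  per-vessel detection fractions); above the knot it plateaus at the
  pooled detection rate of the large vessels (≈ 0.91 in the data these
  models emulate). Binned to 1 m over 0–400 m: a vector of 400 values.

* **Length-error matrix L** — L[i, j] is the probability that a vessel with
  true length in bin j is reported by the radar as length bin i. Columns
  are discretized lognormal densities whose parameters come from τ = 1/3
  and 2/3 quantile regressions of radar length on true length: the two
  predicted quantiles identify the lognormal's log-mean and log-sd in
  closed form. Each column is renormalized to sum to 1, so applying L
  conserves counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.quantile_regression import QuantReg

N_BINS = 400
KNOT_M = 60.0
#: Standard-normal quantile at 2/3; the lognormal log-sd is the half-gap of
#: the log quantiles divided by this.
Z_TWO_THIRDS = float(stats.norm.ppf(2.0 / 3.0))


def bin_centers() -> np.ndarray:
    return np.arange(N_BINS) + 0.5


@dataclass
class QuantileLine:
    """Polynomial quantile fit, coefficients in ascending degree order."""

    coefs: np.ndarray
    tau: float

    def predict(self, x) -> np.ndarray:
        return np.polyval(self.coefs[::-1], np.asarray(x, dtype=float))


@dataclass
class DetectionCurve:
    alpha: np.ndarray            # 400 probabilities, 1 m bins
    knot_m: float = KNOT_M
    plateau: float = 1.0
    line: Optional[QuantileLine] = None

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (N_BINS,):
            raise ValueError(f"alpha must have {N_BINS} bins")
        if (self.alpha < 0).any() or (self.alpha > 1).any():
            raise ValueError("alpha values must lie in [0, 1]")

    def at_length(self, length_m) -> np.ndarray:
        idx = np.clip(np.asarray(length_m, dtype=float).astype(int), 0, N_BINS - 1)
        return self.alpha[idx]


@dataclass
class LengthErrorMatrix:
    L: np.ndarray                # 400×400, column-stochastic
    q13_fit: Optional[QuantileLine] = None
    q23_fit: Optional[QuantileLine] = None

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (N_BINS, N_BINS):
            raise ValueError(f"L must be {N_BINS}×{N_BINS}")
        if (self.L < 0).any():
            raise ValueError("L entries must be non-negative")


class FittingError(ValueError):
    """Not enough data to fit a model."""


def _quantreg(y: np.ndarray, x: np.ndarray, tau: float, degree: int = 1) -> QuantileLine:
    X = np.vander(x, degree + 1, increasing=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = QuantReg(y, X).fit(q=tau, max_iter=5000)
    return QuantileLine(coefs=np.asarray(res.params, dtype=float), tau=tau)


def fit_detection_curve(records: pd.DataFrame, knot_m: float = KNOT_M) -> DetectionCurve:
    """Fit α from per-vessel (true length, detection fraction) records.

    ``records`` needs columns ``length_m`` and ``detection_fraction``
    (vessels seen in several scenes have fractional rates). Requires at
    least 10 records below the knot and 5 at or above it.

    Below the knot α follows the median (τ = 0.5) quantile-regression line
    of fraction on length, clipped to [0, 1] and to non-decreasing; at and
    above the knot it is the pooled detection rate of the large vessels.
    """
    lengths = np.asarray(records["length_m"], dtype=float)
    frac = np.asarray(records["detection_fraction"], dtype=float)
    below = lengths < knot_m
    if below.sum() < 10 or (~below).sum() < 5:
        raise FittingError(
            f"need ≥10 records below {knot_m} m and ≥5 at/above it, "
            f"got {int(below.sum())} and {int((~below).sum())}"
        )
    line = _quantreg(frac[below], lengths[below], tau=0.5)
    if line.coefs[-1] < 0:
        warnings.warn("detection rate decreasing in length; flattening to the median fraction")
        line = QuantileLine(coefs=np.array([float(np.median(frac[below])), 0.0]), tau=0.5)
    plateau = float(np.clip(frac[~below].mean(), 0.0, 1.0))
    centers = bin_centers()
    alpha = np.clip(line.predict(centers), 0.0, 1.0)
    alpha = np.maximum.accumulate(alpha)  # enforce non-decreasing below knot
    alpha[centers >= knot_m] = plateau
    return DetectionCurve(alpha=alpha, knot_m=knot_m, plateau=plateau, line=line)


def plateau_rate(n_detected: int, n_total: int) -> float:
    """Pooled detection rate for the above-knot plateau (e.g. 42 of 46
    large vessels detected → 0.913)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return n_detected / n_total


def fit_length_quantiles(
    pairs: pd.DataFrame, degree: int = 1
) -> tuple[QuantileLine, QuantileLine]:
    """Fit the τ = 1/3 and 2/3 quantile lines of radar length on true length.

    ``pairs`` needs columns ``true_length_m`` and ``sar_length_m``; at
    least 20 pairs spanning more than 30 m of true length. If the fitted
    lines cross inside the data range they are refitted as a
    location-shift model (common median slope, intercepts from residual
    quantiles), which cannot cross.
    """
    x = np.asarray(pairs["true_length_m"], dtype=float)
    y = np.asarray(pairs["sar_length_m"], dtype=float)
    if len(x) < 20:
        raise FittingError(f"need ≥20 matched pairs, got {len(x)}")
    if x.max() - x.min() <= 30.0:
        raise FittingError("matched pairs must span more than 30 m of true length")
    q13 = _quantreg(y, x, tau=1.0 / 3.0, degree=degree)
    q23 = _quantreg(y, x, tau=2.0 / 3.0, degree=degree)
    grid = np.linspace(x.min(), x.max(), 64)
    if np.any(q23.predict(grid) < q13.predict(grid)):
        warnings.warn("quantile lines cross; refitting as a location-shift model")
        med = _quantreg(y, x, tau=0.5, degree=degree)
        resid = y - med.predict(x)
        lo, hi = np.quantile(resid, [1.0 / 3.0, 2.0 / 3.0])
        c13, c23 = med.coefs.copy(), med.coefs.copy()
        c13[0] += lo
        c23[0] += hi
        q13 = QuantileLine(coefs=c13, tau=1.0 / 3.0)
        q23 = QuantileLine(coefs=c23, tau=2.0 / 3.0)
    return q13, q23


def lognormal_from_quantiles(q13: float, q23: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose 1/3 and 2/3 quantiles are (q13, q23).

    By symmetry of the normal quantiles around the median,
    mu = (ln q13 + ln q23)/2 and sigma = (ln q23 − ln q13)/(2 z) with
    z = Φ⁻¹(2/3). Equal quantiles give sigma = 0 (a point mass).
    """
    if not 0 < q13 <= q23:
        raise ValueError(f"need 0 < q13 ≤ q23, got ({q13}, {q23})")
    mu = 0.5 * (np.log(q13) + np.log(q23))
    sigma = (np.log(q23) - np.log(q13)) / (2.0 * Z_TWO_THIRDS)
    return float(mu), float(sigma)


def build_L(q13_line: QuantileLine, q23_line: QuantileLine) -> LengthErrorMatrix:
    """Assemble the 400×400 length-error matrix from the quantile lines.

    Column j uses the lognormal implied by the predicted quantiles at the
    true-length bin centre; densities are integrated across each 1 m radar
    bin (not point-evaluated) and renormalized, so L is column-stochastic
    and count-conserving by construction. Degenerate columns (sigma = 0,
    or all mass beyond the binned range) collapse to a point mass at the
    median bin.
    """
    centers = bin_centers()
    eps = 1e-6
    q13 = np.maximum(q13_line.predict(centers), eps)
    q23 = np.maximum(q23_line.predict(centers), q13)
    mu = 0.5 * (np.log(q13) + np.log(q23))
    sigma = (np.log(q23) - np.log(q13)) / (2.0 * Z_TWO_THIRDS)
    edges = np.arange(N_BINS + 1, dtype=float)[:, None]
    pos = sigma > 0
    L = np.zeros((N_BINS, N_BINS))
    if pos.any():
        z = (np.log(np.maximum(edges, 1e-300)) - mu[None, pos]) / sigma[None, pos]
        cdf = stats.norm.cdf(z)
        cdf[0, :] = 0.0
        L[:, pos] = np.diff(cdf, axis=0)
    sums = L.sum(axis=0)
    degenerate = sums <= 0
    ok = ~degenerate
    L[:, ok] /= sums[ok]
    if degenerate.any():
        idx = np.clip(np.floor(np.exp(mu[degenerate])).astype(int), 0, N_BINS - 1)
        for j, i in zip(np.flatnonzero(degenerate), idx):
            L[:, j] = 0.0
            L[i, j] = 1.0
    return LengthErrorMatrix(L=L, q13_fit=q13_line, q23_fit=q23_line)


# --------------------------------------------------------------------------
# Serialization (fitted models are reused by the estimator CLI)


def save_models(path, curve: DetectionCurve, lmat: LengthErrorMatrix) -> None:
    doc = {
        "version": 1,
        "n_bins": N_BINS,
        "z_two_thirds": Z_TWO_THIRDS,
        "detection_curve": {
            "knot_m": curve.knot_m,
            "plateau": curve.plateau,
            "line_coefs": None if curve.line is None else list(curve.line.coefs),
            "alpha": list(curve.alpha),
        },
        "length_error": {
            "q13_coefs": list(lmat.q13_fit.coefs),
            "q23_coefs": list(lmat.q23_fit.coefs),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_models(path) -> tuple[DetectionCurve, LengthErrorMatrix]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != 1 or doc.get("n_bins") != N_BINS:
        raise ValueError("unsupported model file")
    dc = doc["detection_curve"]
    curve = DetectionCurve(
        alpha=np.asarray(dc["alpha"]),
        knot_m=dc["knot_m"],
        plateau=dc["plateau"],
        line=None
        if dc["line_coefs"] is None
        else QuantileLine(coefs=np.asarray(dc["line_coefs"]), tau=0.5),
    )
    le = doc["length_error"]
    q13 = QuantileLine(coefs=np.asarray(le["q13_coefs"]), tau=1.0 / 3.0)
    q23 = QuantileLine(coefs=np.asarray(le["q23_coefs"]), tau=2.0 / 3.0)
    return curve, build_L(q13, q23)
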