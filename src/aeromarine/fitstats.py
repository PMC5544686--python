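"""Distance binning, exponential distance-decay fits and AIC selection.

The central empirical result the pipeline reproduces is that airborne
abundance (or its terrestrial excess, or the column load) decays as
y = a exp(-b D) with distance to the nearest land mass D (km).  Fits are
nonlinear least squares seeded by a log-linear regression on the positive
responses; R^2 is always computed on the untransformed response, and
AIC = n ln(RSS/n) + 2k with k counting the error variance as a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecayFit",
    "LinearFit",
    "bin_by_distance",
    "fit_exponential_decay",
    "fit_linear",
    "aic_select",
    "evaluate_decay",
    "fraction_remaining",
]


@dataclass(frozen=True)
class DecayFit:
    """Fitted exponential decay y = a exp(-b D)."""

    amplitude: float        # a, units of y
    rate: float             # b, km^-1 (sign free)
    r_squared: float
    aic: float
    n: int
    fit_target: str = "abundance"   # abundance | excess | load
    binned: bool = False
    n_params: int = 3       # a, b, error variance

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a decay fit needs n >= 3")

    def predict(self, D):
        return self.amplitude * np.exp(-self.rate * np.asarray(D, float))


@dataclass(frozen=True)
class LinearFit:
    """Straight-line alternative y = intercept + slope D for AIC contests."""

    intercept: float
    slope: float
    r_squared: float
    aic: float
    n: int
    n_params: int = 3       # intercept, slope, error variance

    def predict(self, D):
        return self.intercept + self.slope * np.asarray(D, float)


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)  # guard perfect fits
    return n * math.log(rss / n) + 2 * k


def bin_by_distance(D, y, n_bins: int = 8, scheme: str = "quantile"
                    ) -> pd.DataFrame:
    """Group stations into distance bins; returns per-bin mean D, mean y,
    SEM (NaN for single-member bins) and count.

    ``scheme`` is "quantile" (equal-count, the default) or "width"
    (equal-width in D).
    """
    D = np.asarray(D, float)
    y = np.asarray(y, float)
    if D.size < n_bins:
        raise ValueError(
            f"only {D.size} stations for {n_bins} bins; reduce n_bins")
    if scheme == "quantile":
        edges = np.quantile(D, np.linspace(0.0, 1.0, n_bins + 1))
    elif scheme == "width":
        edges = np.linspace(D.min(), D.max(), n_bins + 1)
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    edges = np.unique(edges)
    if edges.size - 1 < n_bins:
        raise ValueError("degenerate bin edges; too many tied distances")
    idx = np.clip(np.searchsorted(edges, D, side="right") - 1,
                  0, n_bins - 1)
    rows = []
    for i in range(n_bins):
        sel = idx == i
        cnt = int(sel.sum())
        yi = y[sel]
        rows.append({
            "distance_km": D[sel].mean() if cnt else np.nan,
            "mean": yi.mean() if cnt else np.nan,
            "sem": yi.std(ddof=1) / math.sqrt(cnt) if cnt > 1 else np.nan,
            "count": cnt,
        })
    return pd.DataFrame(rows)


def fit_exponential_decay(D, y, fit_target: str = "abundance",
                          weights: str | np.ndarray | None = None,
                          binned: bool = False) -> DecayFit:
    """Least-squares fit of y = a exp(-b D).

    weights
        ``None`` (ordinary least squares, the default), ``"relative"``
        (iteratively reweighted with sigma proportional to the fitted value,
        appropriate for multiplicative noise), or an array of per-point
        sigmas.
    """
    D = np.asarray(D, float)
    y = np.asarray(y, float)
    if D.size != y.size:
        raise ValueError("D and y must have equal length")
    if D.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(y, y[0]):
        raise ValueError("response is constant; decay is undefined")

    p0 = _log_linear_seed(D, y)
    model = lambda x, a, b: a * np.exp(-b * x)
    try:
        if isinstance(weights, str) and weights == "relative":
            popt = p0
            floor = max(1e-12, 1e-3 * np.abs(y).max())
            for _ in range(4):
                sigma = np.maximum(np.abs(model(D, *popt)), floor)
                popt, _ = curve_fit(model, D, y, p0=popt, sigma=sigma,
                                    maxfev=20000)
        else:
            sigma = None if weights is None else np.asarray(weights, float)
            popt, _ = curve_fit(model, D, y, p0=p0, sigma=sigma, maxfev=20000)
    except RuntimeError as exc:
        grid = _grid_search(D, y)
        raise RuntimeError(
            f"exponential fit did not converge; grid-search fallback "
            f"a={grid[0]:.6g}, b={grid[1]:.6g}") from exc

    resid = y - model(D, *popt)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return DecayFit(amplitude=float(popt[0]), rate=float(popt[1]),
                    r_squared=min(max(r2, 0.0), 1.0),
                    aic=_aic(rss, y.size, 3), n=int(y.size),
                    fit_target=fit_target, binned=binned)


def _log_linear_seed(D, y) -> list[float]:
    pos = y > 0
    if pos.sum() >= 2:
        coef = np.polyfit(D[pos], np.log(y[pos]), 1)
        return [float(np.exp(coef[1])), float(-coef[0])]
    return [float(np.abs(y).max()), 1.0e-3]


def _grid_search(D, y):
    span = max(D.max() - D.min(), 1.0)
    best = (y.max(), 0.0, np.inf)
    for b in np.geomspace(1e-5, 10.0 / span, 60):
        e = np.exp(-b * D)
        a = float(y @ e / (e @ e))
        rss = float(((y - a * e) ** 2).sum())
        if rss < best[2]:
            best = (a, b, rss)
    return best[:2]


def fit_linear(D, y) -> LinearFit:
    """Ordinary least-squares straight line, the AIC alternative model."""
    D = np.asarray(D, float)
    y = np.asarray(y, float)
    slope, intercept = np.polyfit(D, y, 1)
    resid = y - (intercept + slope * D)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return LinearFit(intercept=float(intercept), slope=float(slope),
                     r_squared=1.0 - rss / tss if tss > 0 else 0.0,
                     aic=_aic(rss, y.size, 3), n=int(y.size))


def aic_select(fits):
    """Return (best_fit, delta_table) among candidate fits on the same data.

    delta_table is a DataFrame with each candidate's AIC and delta-AIC from
    the minimum.  Ties break toward the model with fewer parameters.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no candidate fits given")
    if len({f.n for f in fits}) != 1:
        raise ValueError("candidates were not fitted on identical data")
    order = sorted(range(len(fits)),
                   key=lambda i: (fits[i].aic, fits[i].n_params))
    best = fits[order[0]]
    table = pd.DataFrame({
        "model": [type(f).__name__ for f in fits],
        "aic": [f.aic for f in fits],
        "delta_aic": [f.aic - best.aic for f in fits],
        "n_params": [f.n_params for f in fits],
    })
    return best, table


def evaluate_decay(fit: DecayFit, D) -> float | np.ndarray:
    """Fitted response a exp(-b D) at distance D (km)."""
    out = fit.predict(D)
    return float(out) if np.isscalar(D) else out


def fraction_remaining(fit: DecayFit, D) -> float | np.ndarray:
    """Amplitude-normalised fraction exp(-b D) surviving at distance D."""
    out = np.exp(-fit.rate * np.asarray(D, float))
    return float(out) if np.isscalar(D) else out
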