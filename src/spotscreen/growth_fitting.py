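"""Log2-biomass transformation, QC filtering and Gompertz growth fitting.

Each spot's biomass is estimated as size x opacity and log2-transformed.
Trajectories with fewer than five usable timepoints are excluded; at most
the first 20 timepoints are used.  Growth is modelled with the
three-parameter Gompertz curve

    y(t) = A * exp(-exp(-k * (t - t_i)))

with asymptote ``A`` (log2-biomass units), growth-rate parameter ``k``
(1/h) and inflection time ``t_i`` (h); note y(t_i) = A/e.  Fits are
screened by per-parameter significance: a two-sided Wald test per
parameter (the square of a Wald z is chi-square with 1 df, so this matches
a "chi-square p" report), all three required below alpha.  An automated
residual screen (max |standardized residual| > 4) stands in for manual
curve curation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .plate_io import position_label

__all__ = [
    "STATUS_ACCEPTED",
    "STATUS_REJECTED_QC",
    "STATUS_REJECTED_SIGNIFICANCE",
    "STATUS_REJECTED_VISUAL",
    "SpotTimeSeries",
    "GrowthFit",
    "gompertz",
    "compute_biomass",
    "qc_filter",
    "fit_gompertz",
    "validate_fit",
    "fit_series_table",
]

STATUS_ACCEPTED = "accepted"
STATUS_REJECTED_QC = "rejected_qc"
STATUS_REJECTED_SIGNIFICANCE = "rejected_significance"
STATUS_REJECTED_VISUAL = "rejected_visual"

MIN_POINTS = 5
MAX_POINTS = 20


def gompertz(t, A, k, t_i):
    """Three-parameter Gompertz curve ``A * exp(-exp(-k*(t - t_i)))``."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        return A * np.exp(-np.exp(-k * (t - t_i)))


def compute_biomass(size, opacity):
    """log2 biomass from spot size and opacity.

    Biomass is the product size x opacity, floored at 1 before the log2
    transform so that an empty spot maps to biomass 0 rather than -inf.

    Raises
    ------
    ValueError
        If any size or opacity is negative.
    """
    size = np.asarray(size, dtype=float)
    opacity = np.asarray(opacity, dtype=float)
    if np.any(size < 0) or np.any(opacity < 0):
        raise ValueError("size and opacity must be non-negative")
    return np.log2(np.maximum(size * opacity, 1.0))


@dataclass
class SpotTimeSeries:
    """One spot's measurement trajectory.

    ``times`` must be strictly increasing; ``biomass`` is derived from
    ``size`` and ``opacity`` on construction.
    """

    plate_id: str
    position: tuple[int, int]
    times: np.ndarray
    size: np.ndarray
    opacity: np.ndarray
    biomass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        self.opacity = np.asarray(self.opacity, dtype=float)
        if not (len(self.times) == len(self.size) == len(self.opacity)):
            raise ValueError("times, size and opacity must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.biomass is None:
            self.biomass = compute_biomass(self.size, self.opacity)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def label(self) -> str:
        return f"{self.plate_id}:{position_label(*self.position)}"


@dataclass
class GrowthFit:
    """Fitted Gompertz parameters and their significance screen."""

    plate_id: str
    position: tuple[int, int]
    A: float
    k: float
    t_i: float
    p_A: float
    p_k: float
    p_ti: float
    status: str
    n_points: int
    rmse: float = float("nan")
    max_std_resid: float = float("nan")

    @property
    def converged(self) -> bool:
        return np.isfinite(self.A)

    def predict(self, t):
        return gompertz(t, self.A, self.k, self.t_i)


def qc_filter(
    series: SpotTimeSeries,
    min_points: int = MIN_POINTS,
    max_points: int = MAX_POINTS,
) -> tuple[bool, SpotTimeSeries, str | None]:
    """Apply the point-count QC rule.

    Returns ``(passed, filtered_series, reason)``.  A series fails iff it
    has fewer than ``min_points`` timepoints with defined biomass; a series
    longer than ``max_points`` is truncated to its first ``max_points``
    timepoints.
    """
    mask = np.isfinite(series.biomass)
    n = int(mask.sum())
    if n < min_points:
        return False, series, f"only {n} data points (< {min_points})"
    idx = np.flatnonzero(mask)[:max_points]
    if len(idx) != len(series):
        series = SpotTimeSeries(
            plate_id=series.plate_id,
            position=series.position,
            times=series.times[idx],
            size=series.size[idx],
            opacity=series.opacity[idx],
            biomass=series.biomass[idx],
        )
    return True, series, None


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a0 = max(float(np.max(y)), 1e-6)
    dy = np.diff(y)
    dt = np.diff(t)
    slopes = dy / dt
    j = int(np.argmax(slopes))
    ti0 = 0.5 * (t[j] + t[j + 1])
    # max slope of the curve is A*k/e, attained at t_i
    k0 = max(float(slopes[j]) * np.e / a0, 1e-3)
    return np.array([a0, k0, ti0])


def fit_gompertz(
    series: SpotTimeSeries,
    alpha: float = 0.05,
    max_std_resid: float = 4.0,
    n_starts: int = 3,
    seed: int = 0,
) -> GrowthFit:
    """Least-squares fit of the three-parameter Gompertz model to one spot.

    Per-parameter p-values come from two-sided Wald tests
    (estimate / standard error against N(0, 1)).  Nonconvergence and
    undefined p-values yield a rejected fit, never an exception.  Fits with
    all three p-values below ``alpha`` that also pass the residual screen
    are ``accepted``.

    Raises
    ------
    ValueError
        If the series has fewer than :data:`MIN_POINTS` points (it must
        have passed :func:`qc_filter`).
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.biomass, dtype=float)
    if len(t) < MIN_POINTS:
        raise ValueError("series must pass qc_filter before fitting")

    p0 = _initial_guess(t, y)
    rng = np.random.default_rng(seed)
    starts = [p0]
    for _ in range(n_starts - 1):
        starts.append(p0 * rng.uniform(0.5, 1.5, size=3))

    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for start in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    gompertz, t, y, p0=start, maxfev=10_000
                )
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            continue
        ssr = float(np.sum((y - gompertz(t, *popt)) ** 2))
        if best is None or ssr < best[2] - 1e-12:
            best = (popt, pcov, ssr)
        if best is not None and start is starts[0]:
            break  # first start converged; no need for jittered restarts

    def _rejected(status: str) -> GrowthFit:
        return GrowthFit(
            plate_id=series.plate_id,
            position=series.position,
            A=np.nan,
            k=np.nan,
            t_i=np.nan,
            p_A=np.nan,
            p_k=np.nan,
            p_ti=np.nan,
            status=status,
            n_points=len(t),
        )

    if best is None:
        return _rejected(STATUS_REJECTED_SIGNIFICANCE)
    popt, pcov, ssr = best
    a_hat, k_hat, ti_hat = (float(v) for v in popt)

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.diag(pcov))
        z = popt / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    # a perfect (zero-residual) fit has se == 0 -> z = inf -> p = 0
    pvals = np.where(np.isfinite(popt) & (se == 0), 0.0, pvals)

    dof = len(t) - 3
    resid = y - gompertz(t, *popt)
    s = np.sqrt(ssr / dof) if dof > 0 else 0.0
    # below the numerical noise floor the fit is effectively exact
    max_sr = float(np.max(np.abs(resid)) / s) if s > 1e-8 else 0.0
    rmse = float(np.sqrt(ssr / len(t)))

    if not np.all(np.isfinite(popt)) or a_hat <= 0 or k_hat <= 0:
        status = STATUS_REJECTED_SIGNIFICANCE
    elif np.any(~np.isfinite(pvals)) or np.any(pvals >= alpha):
        status = STATUS_REJECTED_SIGNIFICANCE
    elif max_sr > max_std_resid:
        status = STATUS_REJECTED_VISUAL
    else:
        status = STATUS_ACCEPTED

    return GrowthFit(
        plate_id=series.plate_id,
        position=series.position,
        A=a_hat,
        k=k_hat,
        t_i=ti_hat,
        p_A=float(pvals[0]),
        p_k=float(pvals[1]),
        p_ti=float(pvals[2]),
        status=status,
        n_points=len(t),
        rmse=rmse,
        max_std_resid=max_sr,
    )


def validate_fit(fit: GrowthFit, alpha: float = 0.05) -> str:
    """Significance screen: accepted iff all three parameter p-values < alpha.

    Undefined p-values (singular covariance) reject the fit.
    """
    ps = np.array([fit.p_A, fit.p_k, fit.p_ti])
    if np.any(~np.isfinite(ps)):
        return "rejected"
    return "accepted" if float(np.max(ps)) < alpha else "rejected"


def fit_series_table(
    series_list: Iterable[SpotTimeSeries],
    alpha: float = 0.05,
    min_points: int = MIN_POINTS,
    max_points: int = MAX_POINTS,
    max_std_resid: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """QC-filter and fit a collection of spot series.

    Returns one row per input series with fitted parameters, p-values and a
    status column; series failing QC appear with ``rejected_qc``.
    """
    rows = []
    for series in series_list:
        ok, filtered, reason = qc_filter(series, min_points, max_points)
        if not ok:
            rows.append(
                {
                    "plate_id": series.plate_id,
                    "row": series.position[0],
                    "col": series.position[1],
                    "position": position_label(*series.position),
                    "A": np.nan,
                    "k": np.nan,
                    "t_i": np.nan,
                    "p_A": np.nan,
                    "p_k": np.nan,
                    "p_ti": np.nan,
                    "n_points": len(series),
                    "rmse": np.nan,
                    "status": STATUS_REJECTED_QC,
                    "qc_reason": reason,
                }
            )
            continue
        fit = fit_gompertz(
            filtered, alpha=alpha, max_std_resid=max_std_resid, seed=seed
        )
        rows.append(
            {
                "plate_id": fit.plate_id,
                "row": fit.position[0],
                "col": fit.position[1],
                "position": position_label(*fit.position),
                "A": fit.A,
                "k": fit.k,
                "t_i": fit.t_i,
                "p_A": fit.p_A,
                "p_k": fit.p_k,
                "p_ti": fit.p_ti,
                "n_points": fit.n_points,
                "rmse": fit.rmse,
                "status": fit.status,
                "qc_reason": None,
            }
        )
    return pd.DataFrame(rows)
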