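"""Integrated fitness, robust plate centering and replicate-noise scale.

Integrated fitness (IF) is the area under the fitted Gompertz curve from
inoculation to ``t_max`` (default 72 h).  Plate-to-plate variation is
removed by subtracting a robust location estimate (Huber M-estimate,
c = 1.345) from every IF value on a plate.  The replicate-noise scale is
the median, across isolates, of the standard deviation of IF over each
isolate's replicate spots — border positions excluded (MSD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

from .growth_fitting import GrowthFit, gompertz

__all__ = [
    "MSDStat",
    "gompertz_auc",
    "integrated_fitness",
    "huber_location",
    "center_plate",
    "compute_msd",
    "fitness_table",
]

HUBER_C = 1.345


@dataclass
class MSDStat:
    """Median replicate standard deviation of integrated fitness."""

    msd: float
    n_isolates_used: int
    scope: str = "dataset"


def gompertz_auc(A: float, k: float, t_i: float, t_max: float = 72.0) -> float:
    """Area under ``A*exp(-exp(-k*(t - t_i)))`` over [0, t_max].

    Adaptive quadrature at absolute tolerance 1e-8.  The integral is linear
    in ``A``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if A == 0:
        return 0.0
    value, _ = integrate.quad(
        gompertz, 0.0, t_max, args=(A, k, t_i), epsabs=1e-8, limit=200
    )
    return float(value)


def integrated_fitness(fit: GrowthFit, t_max: float = 72.0) -> float:
    """Integrated fitness of an accepted fit: AUC of its curve over [0, t_max]."""
    return gompertz_auc(fit.A, fit.k, fit.t_i, t_max=t_max)


def huber_location(
    values, c: float = HUBER_C, tol: float = 1e-8, max_iter: int = 200
) -> float:
    """Huber M-estimate of location with MAD scale.

    Iteratively reweighted mean with weights ``min(1, c*s/|x - mu|)`` where
    ``s`` is the normalized median absolute deviation.  Falls back to the
    median when the MAD is zero (a majority of identical values).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values")
    mu = float(np.median(x))
    s = 1.4826 * float(np.median(np.abs(x - mu)))
    if s == 0:
        return mu
    for _ in range(max_iter):
        r = x - mu
        w = np.ones_like(r)
        big = np.abs(r) > c * s
        w[big] = c * s / np.abs(r[big])
        mu_new = float(np.sum(w * x) / np.sum(w))
        if abs(mu_new - mu) < tol:
            return mu_new
        mu = mu_new
    return mu


def center_plate(values, method: str = "huber") -> np.ndarray:
    """Center one plate's IF values on a robust location estimate.

    ``method`` is ``"huber"`` (default) or ``"median"``.  NaNs are ignored
    for the location and preserved in the output.

    Raises
    ------
    ValueError
        If the plate has no finite value, or the method is unknown.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        raise ValueError("cannot center a plate with no finite IF values")
    if method == "huber":
        loc = huber_location(finite)
    elif method == "median":
        loc = float(np.median(finite))
    else:
        raise ValueError(f"unknown centering method: {method!r}")
    return x - loc


def compute_msd(
    records: pd.DataFrame,
    value_col: str = "IF_centered",
    isolate_col: str = "isolate",
    border_col: str = "border",
    min_replicates: int = 2,
    scope: str = "dataset",
) -> MSDStat:
    """Median of per-isolate replicate standard deviations of IF.

    ``records`` holds one row per replicate spot with the isolate id, the
    IF value and a border flag.  Border spots are excluded before anything
    else; per-isolate sample SDs (n-1 denominator) are computed for sets
    with at least ``min_replicates`` finite values, and the MSD is the
    median of those SDs.

    Raises
    ------
    ValueError
        If no replicate set is usable.
    """
    df = records
    if border_col in df.columns:
        df = df[~df[border_col].astype(bool)]
    df = df[np.isfinite(df[value_col].astype(float))]
    sds = []
    for _, grp in df.groupby(isolate_col):
        if len(grp) >= min_replicates:
            sds.append(float(grp[value_col].std(ddof=1)))
    if not sds:
        raise ValueError("no replicate set with enough non-border values")
    return MSDStat(msd=float(np.median(sds)), n_isolates_used=len(sds), scope=scope)


def fitness_table(
    fits: pd.DataFrame,
    layouts: dict[str, "object"],
    t_max: float = 72.0,
    center_method: str = "huber",
) -> pd.DataFrame:
    """Per-spot fitness records from a fit table.

    Adds ``IF_raw`` (AUC of accepted fits, NaN otherwise), ``IF_centered``
    (per-plate robust centering), ``border``, the occupant isolate id(s)
    and the medium, using the :class:`~spotscreen.plate_io.PlateLayout`
    for each ``plate_id``.
    """
    from .growth_fitting import STATUS_ACCEPTED

    df = fits.copy()
    if_raw = np.full(len(df), np.nan)
    for i, rec in enumerate(df.itertuples(index=False)):
        if rec.status == STATUS_ACCEPTED:
            if_raw[i] = gompertz_auc(rec.A, rec.k, rec.t_i, t_max=t_max)
    df["IF_raw"] = if_raw

    centered = np.full(len(df), np.nan)
    for plate_id, idx in df.groupby("plate_id").groups.items():
        vals = df.loc[idx, "IF_raw"].to_numpy(dtype=float)
        if np.any(np.isfinite(vals)):
            centered[df.index.get_indexer(idx)] = center_plate(
                vals, method=center_method
            )
    df["IF_centered"] = centered

    borders, occupants, media, roles = [], [], [], []
    for rec in df.itertuples(index=False):
        layout = layouts[rec.plate_id]
        pos = (int(rec.row), int(rec.col))
        borders.append(layout.is_border(pos))
        occ = layout.occupants.get(pos, ())
        occupants.append("+".join(occ))
        media.append(layout.medium)
        roles.append(layout.role)
    df["border"] = borders
    df["occupants"] = occupants
    df["medium"] = media
    df["role"] = roles
    return df
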