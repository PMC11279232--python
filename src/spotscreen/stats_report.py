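"""Contingency-table statistics and results-style summary tables.

The likelihood-ratio ("G") test of independence, Fisher's exact test for
2x2 tables, half-up-rounded proportion summaries and Venn region counts —
the statistical layer that turns classified records into the experiment's
headline tables.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "GTestResult",
    "g_test",
    "fisher_exact",
    "round_half_up",
    "proportion_summary",
    "venn_counts",
    "summarize_interactions",
]


@dataclass
class ContingencyTable:
    """Labeled non-negative count matrix."""

    row_labels: Sequence[str]
    col_labels: Sequence[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match the count matrix shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ContingencyTable":
        return cls(
            row_labels=list(frame.index.astype(str)),
            col_labels=list(frame.columns.astype(str)),
            counts=frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass
class GTestResult:
    g: float
    df: int
    p_value: float


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return np.asarray(table.counts, dtype=float)
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def g_test(table) -> GTestResult:
    """Likelihood-ratio (G) test of independence.

    ``G = 2 * sum(observed * ln(observed / expected))`` with zero cells
    contributing nothing; ``df = (r - 1) * (c - 1)``; p from the
    chi-square upper tail.

    Raises
    ------
    ValueError
        If any row or column marginal is zero (expected counts undefined).
    """
    obs = _as_counts(table)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("g_test needs an r x c table with r, c >= 2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal: drop empty rows/columns first")
    total = obs.sum()
    expected = np.outer(row, col) / total
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return GTestResult(g=g, df=df, p_value=float(stats.chi2.sf(g, df)))


def fisher_exact(table, side: str = "two_sided") -> float:
    """Fisher's exact test p-value for a 2x2 table.

    ``side`` is ``"two_sided"`` (sum of all fixed-margin tables whose
    hypergeometric probability does not exceed the observed one) or
    ``"right"`` (upper tail of the first cell).

    Raises
    ------
    ValueError
        On non-2x2 input, non-integer counts or a zero marginal.
    """
    obs = _as_counts(table)
    if obs.shape != (2, 2):
        raise ValueError("fisher_exact needs a 2x2 table")
    if not np.allclose(obs, np.round(obs)):
        raise ValueError("fisher_exact needs integer counts")
    obs = np.round(obs).astype(int)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate margin: a row or column sums to zero")
    alternative = {"two_sided": "two-sided", "right": "greater"}.get(side)
    if alternative is None:
        raise ValueError(f"unknown side: {side!r}")
    return float(stats.fisher_exact(obs, alternative=alternative).pvalue)


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero at a fixed number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def proportion_summary(
    records: pd.DataFrame,
    value: str,
    by: str | Sequence[str] | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Counts and half-up-rounded percentages of each class, per group.

    ``records`` holds one row per classified record; ``value`` names the
    class column (boolean flags or categorical labels).  With ``by`` the
    summary is computed within each group; without it over all records.
    Output columns: group keys (if any), ``class``, ``count``,
    ``denominator``, ``percent``.

    Raises
    ------
    ValueError
        If the table (or any group) is empty.
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")

    def _one(group: pd.DataFrame) -> pd.DataFrame:
        denom = len(group)
        if denom == 0:
            raise ValueError("empty group")
        counts = group[value].value_counts()
        out = pd.DataFrame(
            {
                "class": counts.index,
                "count": counts.to_numpy(),
                "denominator": denom,
            }
        )
        out["percent"] = [
            round_half_up(100.0 * c / denom, decimals) for c in out["count"]
        ]
        return out

    if by is None:
        return _one(records).reset_index(drop=True)
    keys = [by] if isinstance(by, str) else list(by)
    pieces = []
    for key_vals, group in records.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        piece = _one(group)
        for k, v in zip(keys, key_vals):
            piece.insert(0, k, v)
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


def venn_counts(flag_sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for 2 or 3 overlapping sets.

    Keys of the result are sorted tuples of set names; the regions
    partition the union of all sets, so the counts sum to the number of
    elements carrying at least one flag.
    """
    names = sorted(flag_sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_counts supports 2 or 3 sets")
    universe = set().union(*flag_sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for element in universe:
        member = tuple(n for n in names if element in flag_sets[n])
        regions[member] = regions.get(member, 0) + 1
    # make every region explicit, including empty ones
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions.setdefault(combo, 0)
    return dict(sorted(regions.items()))


# ---------------------------------------------------------------------------
# results-style report
# ---------------------------------------------------------------------------


def summarize_interactions(
    interactions: pd.DataFrame,
    decimals: int = 1,
) -> dict[str, pd.DataFrame]:
    """Headline tables from a long interaction frame.

    Produces, where the inputs allow: ecological-class proportions (overall
    and per medium), functional-class proportions (per target, overall and
    per medium), paired antifungal rates per medium, and cross-media
    stability matrices for every medium pair sharing an identical pair set.
    Unscored records are excluded from all denominators.
    """
    out: dict[str, pd.DataFrame] = {}

    eco = interactions.drop_duplicates("pair_id")
    eco = eco[eco["eco_class"].isin(("cooperation", "competition", "neutral"))]
    if len(eco):
        out["eco_overall"] = proportion_summary(eco, "eco_class", decimals=decimals)
        out["eco_by_medium"] = proportion_summary(
            eco, "eco_class", by="medium", decimals=decimals
        )

    func = interactions[
        interactions["func_class"].isin(("induction", "suppression", "neutral"))
    ]
    if len(func):
        out["func_by_target"] = proportion_summary(
            func, "func_class", by="target", decimals=decimals
        )
        out["func_by_medium_target"] = proportion_summary(
            func, "func_class", by=["medium", "target"], decimals=decimals
        )
        pair_halo = func.dropna(subset=["halo_pair"]).copy()
        pair_halo["halo_pair"] = pair_halo["halo_pair"].astype(bool)
        out["pair_antifungal_by_medium_target"] = proportion_summary(
            pair_halo, "halo_pair", by=["medium", "target"], decimals=decimals
        )

    # cross-media stability on the shared pair key (plate index + position + pair)
    eco_all = interactions.drop_duplicates("pair_id").copy()
    eco_all["pair_key"] = [
        f"{pid.split('-')[-1]}:{pos}:{a}+{b}"
        for pid, pos, a, b in zip(
            eco_all["plate_id"],
            eco_all["position"],
            eco_all["isolate_1"],
            eco_all["isolate_2"],
        )
    ]
    media = sorted(eco_all["medium"].unique())
    stab_rows = []
    for i, ma in enumerate(media):
        for mb in media[i + 1 :]:
            da = _scored_map(eco_all, ma)
            db = _scored_map(eco_all, mb)
            shared = set(da) & set(db)
            if not shared:
                continue
            from .interaction_scoring import stability_matrix

            counts, diag = stability_matrix(
                {k: da[k] for k in shared},
                {k: db[k] for k in shared},
                labels=("cooperation", "competition", "neutral"),
            )
            counts.index.name = ma
            counts.columns.name = mb
            out[f"stability_{ma}_vs_{mb}"] = counts
            stab_rows.append(
                {
                    "medium_a": ma,
                    "medium_b": mb,
                    "n_pairs": len(shared),
                    "percent_same": round_half_up(diag, decimals),
                }
            )
    if stab_rows:
        out["stability_summary"] = pd.DataFrame(stab_rows)
    return out


def _scored_map(eco_all: pd.DataFrame, medium: str) -> dict[str, str]:
    sub = eco_all[
        (eco_all["medium"] == medium)
        & eco_all["eco_class"].isin(("cooperation", "competition", "neutral"))
    ]
    return dict(zip(sub["pair_key"], sub["eco_class"]))
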