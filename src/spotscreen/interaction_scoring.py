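"""Classification of pairwise ecological and functional interactions.

Ecological outcome of a pair instance, from integrated fitness (IF):

* cooperation — pair IF strictly greater than both individual IFs plus
  twice the replicate-noise scale (2 x MSD);
* competition — pair IF strictly smaller than both individual IFs minus
  2 x MSD;
* neutral — anything in between (ties at the boundary are neutral).

Functional outcome of a pair instance, from presence/absence halo flags:

* induction — the pair is antifungal although neither individual is;
* suppression — the pair is not antifungal although an individual is
  (by default either-or-both individuals; ``strict_one_sided`` restricts
  to exactly one);
* neutral — no qualitative change.

Higher-level labels: per-isolate behavior profiles (counts of cooperative
and competitive outcomes over its three partner pairs), antifungal
spectrum classes (intrafamily vs interfamily activity across the three
target yeasts), and the stability of per-pair classes across media.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import plate_io
from .plate_io import PlateLayout, match_pair_to_individuals, position_label

__all__ = [
    "ECO_CLASSES",
    "FUNC_CLASSES",
    "BehaviorProfile",
    "classify_ecological",
    "classify_functional",
    "behavior_profile",
    "spectrum_class",
    "stability_matrix",
    "score_interactions",
    "behavior_profiles_table",
]

ECO_CLASSES = ("cooperation", "competition", "neutral")
FUNC_CLASSES = ("induction", "suppression", "neutral")
UNSCORED = "unscored"


def classify_ecological(
    if_pair: float, if_ind1: float, if_ind2: float, msd: float
) -> str:
    """Ecological class of one pair instance from its three IF values.

    Strict inequalities; any non-finite input yields ``"unscored"``.
    """
    if msd < 0:
        raise ValueError("msd must be non-negative")
    vals = (if_pair, if_ind1, if_ind2)
    if not all(math.isfinite(v) for v in vals):
        return UNSCORED
    if if_pair > max(if_ind1, if_ind2) + 2.0 * msd:
        return "cooperation"
    if if_pair < min(if_ind1, if_ind2) - 2.0 * msd:
        return "competition"
    return "neutral"


def classify_functional(
    halo_pair: bool | None,
    halo_ind1: bool | None,
    halo_ind2: bool | None,
    strict_one_sided: bool = False,
) -> str:
    """Functional class of one pair instance from its three halo flags.

    ``strict_one_sided`` restricts suppression to exactly one antifungal
    individual; by default a pair losing the activity of either or both
    individuals counts as suppression.  ``None`` flags yield ``"unscored"``.
    """
    flags = (halo_pair, halo_ind1, halo_ind2)
    if any(f is None for f in flags):
        return UNSCORED
    pair, i1, i2 = (bool(f) for f in flags)
    if pair and not i1 and not i2:
        return "induction"
    if not pair:
        active = int(i1) + int(i2)
        if strict_one_sided:
            if active == 1:
                return "suppression"
        elif active >= 1:
            return "suppression"
    return "neutral"


@dataclass
class BehaviorProfile:
    """Counts of cooperative/competitive outcomes over an isolate's partner pairs."""

    isolate_id: str
    n_interactions: int
    n_cooperative: int
    n_competitive: int
    antifungal: bool
    incomplete: bool


def behavior_profile(
    isolate_id: str,
    eco_classes: Sequence[str],
    antifungal: bool,
    expected: int = 3,
) -> BehaviorProfile:
    """Profile one isolate from the ecological classes of its partner pairs.

    ``eco_classes`` lists the outcomes of the isolate's non-self pair
    instances; a profile built from fewer than ``expected`` scored outcomes
    is flagged incomplete.
    """
    scored = [c for c in eco_classes if c in ECO_CLASSES]
    return BehaviorProfile(
        isolate_id=isolate_id,
        n_interactions=len(scored),
        n_cooperative=sum(c == "cooperation" for c in scored),
        n_competitive=sum(c == "competition" for c in scored),
        antifungal=bool(antifungal),
        incomplete=len(scored) < expected,
    )


def spectrum_class(kl: bool, sc: bool, cb: bool) -> str:
    """Antifungal spectrum from per-target halo flags.

    Parameters are the flags against *K. lactis*, *S. cerevisiae* and
    *C. boidinii*.  Activity spanning into *C. boidinii*'s family
    (``cb`` together with at least one of the other two, or all three) is
    ``"interfamily"``; activity against both same-family targets only is
    ``"intrafamily"``; single-target or no activity is ``"none"``.
    """
    kl, sc, cb = bool(kl), bool(sc), bool(cb)
    if cb and (kl or sc):
        return "interfamily"
    if kl and sc and not cb:
        return "intrafamily"
    return "none"


def stability_matrix(
    classes_a: Mapping[object, str],
    classes_b: Mapping[object, str],
    labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate per-pair class labels under two conditions.

    Both mappings must cover the same pair set.  Returns the square count
    table (rows: condition A, columns: condition B) and the percentage of
    pairs scored the same (diagonal sum / total, one decimal not applied —
    raw float).

    Raises
    ------
    ValueError
        If the two pair sets differ.
    """
    if set(classes_a) != set(classes_b):
        raise ValueError("pair sets differ between the two conditions")
    if not classes_a:
        raise ValueError("empty pair set")
    if labels is None:
        labels = sorted(set(classes_a.values()) | set(classes_b.values()))
    counts = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for key, la in classes_a.items():
        lb = classes_b[key]
        counts.loc[la, lb] += 1
    total = int(counts.to_numpy().sum())
    diag = int(np.trace(counts.to_numpy()))
    return counts, 100.0 * diag / total


# ---------------------------------------------------------------------------
# experiment-level scoring
# ---------------------------------------------------------------------------


def score_interactions(
    layouts: Sequence[PlateLayout],
    fitness: pd.DataFrame,
    msd: float,
    halos: pd.DataFrame | None = None,
    include_self_pairs: bool = False,
    strict_one_sided: bool = False,
    align_pairs: bool = True,
    value_col: str = "IF_raw",
) -> pd.DataFrame:
    """Build one interaction record per pair instance (and per halo target).

    For every interaction plate, the pair at each position is matched with
    the individual values from the same position on the medium's MSP and on
    the RSP the interaction plate was built from (interaction plate ``i``
    pairs with ``RSP i``; plates are matched by the trailing index in their
    ids).  Functional classes use the halo flags of the pair plate and of
    the two source plates.  Records missing any component are kept with
    class ``"unscored"``.  Self-pairs are recorded but left unscored
    ecologically/functionally unless ``include_self_pairs``.

    With ``align_pairs`` (the default) each interaction plate is normalized
    against its own reference plates before the +-2 x MSD rule is applied:
    the Huber location of ``IF_pair - max(IF_ind1, IF_ind2)`` over the
    plate's complete records (self-pairs included — they are neutral
    anchors by construction) is subtracted from every pair IF.  This
    removes plate-level offsets *and* the systematic elevation of
    pair-plate values that arises because pairs track their dominant
    partner, which a per-plate location centering cannot distinguish from a
    plate effect.  Plain per-plate centered values (``value_col
    "IF_centered"``, ``align_pairs=False``) remain available.

    Returns a long frame: one row per (pair instance, target); when no halo
    data exists for a pair instance a single row with ``target`` NaN is
    emitted.
    """
    by_id = {p.plate_id: p for p in layouts}
    fit_key = fitness.set_index(["plate_id", "row", "col"])

    def _if_at(plate_id: str, pos: tuple[int, int]) -> float:
        try:
            rec = fit_key.loc[(plate_id, pos[0], pos[1])]
        except KeyError:
            return float("nan")
        if rec["status"] != "accepted":
            return float("nan")
        return float(rec[value_col])

    halo_key = None
    if halos is not None and len(halos):
        halo_key = halos.set_index(["plate_id", "row", "col", "target"])["antifungal"]

    def _halo_at(plate_id: str, pos: tuple[int, int], target: str):
        if halo_key is None:
            return None
        try:
            return bool(halo_key.loc[(plate_id, pos[0], pos[1], target)])
        except KeyError:
            return None

    rows = []
    for medium, plates in _group_by_medium(by_id.values()).items():
        msp = _single_role(plates, "main_source", medium)
        rsps = _indexed_role(plates, "replicate_source")
        ints = _indexed_role(plates, "interaction")
        for i, inter in ints.items():
            if i not in rsps:
                raise plate_io.LayoutError(
                    f"{inter.plate_id}: no replicate-source plate with index {i}"
                )
            rsp = rsps[i]
            pairing = match_pair_to_individuals(inter, msp, rsp)
            offset = 0.0
            if align_pairs:
                deltas = []
                for pos, (mpos, rpos) in pairing.items():
                    trip = (
                        _if_at(inter.plate_id, pos),
                        _if_at(msp.plate_id, mpos),
                        _if_at(rsp.plate_id, rpos),
                    )
                    if all(math.isfinite(v) for v in trip):
                        deltas.append(trip[0] - max(trip[1], trip[2]))
                if deltas:
                    from .fitness import huber_location

                    offset = huber_location(deltas)
            for pos, (mpos, rpos) in sorted(pairing.items()):
                iso1, iso2 = inter.occupants[pos]
                is_self = iso1 == iso2
                if_pair = _if_at(inter.plate_id, pos)
                if_1 = _if_at(msp.plate_id, mpos)
                if_2 = _if_at(rsp.plate_id, rpos)
                if is_self and not include_self_pairs:
                    eco = UNSCORED
                else:
                    eco = classify_ecological(if_pair - offset, if_1, if_2, msd)
                base = {
                    "pair_id": f"{inter.plate_id}:{position_label(*pos)}",
                    "medium": medium,
                    "plate_id": inter.plate_id,
                    "position": position_label(*pos),
                    "row": pos[0],
                    "col": pos[1],
                    "isolate_1": iso1,
                    "isolate_2": iso2,
                    "is_self": is_self,
                    "IF_pair": if_pair,
                    "IF_ind1": if_1,
                    "IF_ind2": if_2,
                    "pair_offset": offset,
                    "IF_pair_aligned": if_pair - offset,
                    "eco_class": eco,
                }
                targets = []
                if halo_key is not None:
                    targets = [
                        tgt
                        for tgt in plate_io.TARGET_YEASTS
                        if _halo_at(inter.plate_id, pos, tgt) is not None
                        or _halo_at(msp.plate_id, mpos, tgt) is not None
                        or _halo_at(rsp.plate_id, rpos, tgt) is not None
                    ]
                if not targets:
                    rows.append(
                        {**base, "target": None, "halo_pair": None,
                         "halo_ind1": None, "halo_ind2": None,
                         "func_class": UNSCORED}
                    )
                    continue
                for tgt in targets:
                    hp = _halo_at(inter.plate_id, pos, tgt)
                    h1 = _halo_at(msp.plate_id, mpos, tgt)
                    h2 = _halo_at(rsp.plate_id, rpos, tgt)
                    if is_self and not include_self_pairs:
                        func = UNSCORED
                    else:
                        func = classify_functional(
                            hp, h1, h2, strict_one_sided=strict_one_sided
                        )
                    rows.append(
                        {**base, "target": tgt, "halo_pair": hp,
                         "halo_ind1": h1, "halo_ind2": h2, "func_class": func}
                    )
    return pd.DataFrame(rows)


def behavior_profiles_table(
    interactions: pd.DataFrame,
    antifungal_by_isolate: Mapping[str, bool],
    expected: int = 3,
) -> pd.DataFrame:
    """Behavior profile of every isolate appearing in the interaction records.

    Each isolate is profiled against its distinct partners.  In the
    replicate-community design every unordered pair is tested twice (two
    instances on different plates); the per-partner outcome is cooperative
    if any scored instance is cooperative and none competitive, competitive
    symmetrically, and neutral otherwise (including disagreement).
    Partners with no scored instance are dropped, which flags the profile
    incomplete when fewer than ``expected`` partners remain.
    """
    eco = interactions.drop_duplicates("pair_id")
    eco = eco[~eco["is_self"].astype(bool)]
    per_partner: dict[tuple[str, str], list[str]] = {}
    for rec in eco.itertuples(index=False):
        for iso, other in (
            (rec.isolate_1, rec.isolate_2),
            (rec.isolate_2, rec.isolate_1),
        ):
            per_partner.setdefault((iso, other), []).append(rec.eco_class)
    per_isolate: dict[str, list[str]] = {}
    for (iso, _other), classes in per_partner.items():
        scored = [c for c in classes if c in ECO_CLASSES]
        if not scored:
            continue
        has_coop = "cooperation" in scored
        has_comp = "competition" in scored
        if has_coop and not has_comp:
            outcome = "cooperation"
        elif has_comp and not has_coop:
            outcome = "competition"
        else:
            outcome = "neutral"
        per_isolate.setdefault(iso, []).append(outcome)
    rows = []
    for iso in sorted(per_isolate):
        prof = behavior_profile(
            iso,
            per_isolate[iso],
            antifungal=bool(antifungal_by_isolate.get(iso, False)),
            expected=expected,
        )
        rows.append(
            {
                "isolate_id": prof.isolate_id,
                "n_interactions": prof.n_interactions,
                "n_cooperative": prof.n_cooperative,
                "n_competitive": prof.n_competitive,
                "antifungal": prof.antifungal,
                "incomplete": prof.incomplete,
            }
        )
    return pd.DataFrame(rows)


def _group_by_medium(plates: Iterable[PlateLayout]) -> dict[str, list[PlateLayout]]:
    out: dict[str, list[PlateLayout]] = {}
    for p in plates:
        out.setdefault(p.medium, []).append(p)
    return out


def _single_role(plates: Sequence[PlateLayout], role: str, medium: str) -> PlateLayout:
    found = [p for p in plates if p.role == role]
    if len(found) != 1:
        raise plate_io.LayoutError(
            f"medium {medium}: expected exactly one {role} plate, got {len(found)}"
        )
    return found[0]


def _indexed_role(plates: Sequence[PlateLayout], role: str) -> dict[int, PlateLayout]:
    out = {}
    for p in plates:
        if p.role != role:
            continue
        m = re.search(r"(\d+)$", p.plate_id)
        out[int(m.group(1)) if m else len(out) + 1] = p
    return out
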