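"""Plate layouts, position arithmetic and tabular I/O.

This module owns the experiment's physical model: 96- and 384-array
plates, the condensation of four 96-array source plates into one 384-array
main source plate (MSP), the replication of a single 96-array plate into a
four-quadrant replicate source plate (RSP), and the pairing of MSP and RSP
occupants on interaction plates.  It also reads and writes the tabular
formats used throughout the pipeline:

* colony quantification tables — tab-separated, ``#``-prefixed metadata
  lines (``#plate_id=``, ``#array_format=``, ``#time_h=``), then columns
  ``row``, ``column``, ``size``, ``opacity``; one file per plate and
  timepoint;
* inhibition-halo score tables — CSV with columns ``plate_id``,
  ``position``, ``target``, ``antifungal`` (0/1);
* layout bundles — JSON (or YAML) listing every plate and its occupants.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ARRAY_GEOMETRY",
    "MEDIA",
    "ROLES",
    "TARGET_YEASTS",
    "PlateLayout",
    "QuantTable",
    "LayoutError",
    "QuantFormatError",
    "position_label",
    "parse_position",
    "is_border",
    "iter_positions",
    "condense_well",
    "assemble_layouts",
    "match_pair_to_individuals",
    "read_quant_table",
    "write_quant_table",
    "read_halo_scores",
    "write_halo_scores",
    "write_layouts",
    "read_layouts",
]

#: rows x columns for the supported array densities
ARRAY_GEOMETRY = {96: (8, 12), 384: (16, 24)}

MEDIA = ("LM17", "PCA", "SALN")
ROLES = (
    "preculture",
    "main_source",
    "replicate_source",
    "interaction",
    "antifungal_lawn",
    "growth_control",
)
TARGET_YEASTS = ("K_lactis", "C_boidinii", "S_cerevisiae")

_ROW_LETTERS = string.ascii_uppercase
_POSITION_RE = re.compile(r"^([A-P])(\d{1,2})$")


class LayoutError(ValueError):
    """Raised when a plate layout violates the experiment's geometry."""


class QuantFormatError(ValueError):
    """Raised when a quantification table cannot be parsed."""


def position_label(row: int, col: int) -> str:
    """0-based ``(row, col)`` -> letter/number label, e.g. ``(0, 0) -> 'A1'``."""
    if row < 0 or col < 0 or row >= 16 or col >= 24:
        raise ValueError(f"position out of range: ({row}, {col})")
    return f"{_ROW_LETTERS[row]}{col + 1}"


def parse_position(label: str) -> tuple[int, int]:
    """Letter/number label -> 0-based ``(row, col)``; inverse of :func:`position_label`."""
    m = _POSITION_RE.match(label.strip().upper())
    if m is None:
        raise ValueError(f"invalid position label: {label!r}")
    return _ROW_LETTERS.index(m.group(1)), int(m.group(2)) - 1


def is_border(row: int, col: int, array_format: int) -> bool:
    """True iff the position lies in the outermost row or column of the array."""
    n_rows, n_cols = ARRAY_GEOMETRY[array_format]
    return row in (0, n_rows - 1) or col in (0, n_cols - 1)


def iter_positions(array_format: int) -> Iterable[tuple[int, int]]:
    """All positions of an array in row-major order."""
    n_rows, n_cols = ARRAY_GEOMETRY[array_format]
    for r in range(n_rows):
        for c in range(n_cols):
            yield r, c


def condense_well(row: int, col: int, quadrant: int) -> tuple[int, int]:
    """Map a 96-array well to its 384-array position for a given quadrant.

    The four 96-arrays are interleaved: quadrant ``q`` occupies positions
    ``(2r + q // 2, 2c + q % 2)``, the standard pinning geometry of a
    96 -> 384 condensation.
    """
    if quadrant not in (0, 1, 2, 3):
        raise ValueError("quadrant must be in 0..3")
    return 2 * row + quadrant // 2, 2 * col + quadrant % 2


@dataclass
class PlateLayout:
    """One physical plate: geometry, role and occupant map.

    Parameters
    ----------
    plate_id
        Unique identifier of the plate.
    array_format
        96 or 384.
    medium
        Culture medium (``LM17``, ``PCA`` or ``SALN``).
    role
        One of :data:`ROLES`.
    occupants
        Map of 0-based ``(row, col)`` to a tuple of isolate ids: exactly one
        id on every plate except interaction plates, which carry exactly two
        (a self-pair repeats the same id).
    quadrant_of
        Optional map of position to the id of the 96-array source plate the
        occupant was pinned from.
    target_yeast
        For ``antifungal_lawn`` plates only: the yeast spread as the lawn.
    """

    plate_id: str
    array_format: int
    medium: str
    role: str
    occupants: dict[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)
    quadrant_of: dict[tuple[int, int], str] = field(default_factory=dict)
    target_yeast: str | None = None

    def __post_init__(self) -> None:
        if self.array_format not in ARRAY_GEOMETRY:
            raise LayoutError(f"unsupported array format: {self.array_format}")
        if self.role not in ROLES:
            raise LayoutError(f"unknown plate role: {self.role!r}")
        if self.target_yeast is not None and self.target_yeast not in TARGET_YEASTS:
            raise LayoutError(f"unknown target yeast: {self.target_yeast!r}")
        n_rows, n_cols = ARRAY_GEOMETRY[self.array_format]
        expected = 2 if self.role == "interaction" else 1
        for pos, occ in self.occupants.items():
            r, c = pos
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                raise LayoutError(
                    f"{self.plate_id}: position {pos} outside a "
                    f"{self.array_format}-array"
                )
            if len(occ) != expected:
                raise LayoutError(
                    f"{self.plate_id}: position {position_label(r, c)} has "
                    f"{len(occ)} occupants, expected {expected} for role "
                    f"{self.role!r}"
                )

    def is_border(self, pos: tuple[int, int]) -> bool:
        return is_border(pos[0], pos[1], self.array_format)

    @property
    def border_positions(self) -> list[tuple[int, int]]:
        return [p for p in iter_positions(self.array_format) if self.is_border(p)]

    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "array_format": self.array_format,
            "medium": self.medium,
            "role": self.role,
            "target_yeast": self.target_yeast,
            "occupants": {
                position_label(r, c): list(occ)
                for (r, c), occ in sorted(self.occupants.items())
            },
            "quadrant_of": {
                position_label(r, c): src
                for (r, c), src in sorted(self.quadrant_of.items())
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlateLayout":
        return cls(
            plate_id=d["plate_id"],
            array_format=int(d["array_format"]),
            medium=d["medium"],
            role=d["role"],
            target_yeast=d.get("target_yeast"),
            occupants={
                parse_position(k): tuple(v) for k, v in d.get("occupants", {}).items()
            },
            quadrant_of={
                parse_position(k): v for k, v in d.get("quadrant_of", {}).items()
            },
        )


# ---------------------------------------------------------------------------
# layout assembly
# ---------------------------------------------------------------------------


def assemble_layouts(precultures: Sequence[PlateLayout]) -> dict[str, list[PlateLayout]]:
    """Build the source and interaction plates from 96-array precultures.

    ``precultures`` must contain exactly four 96-array plates per medium.
    For every medium the returned mapping holds, in order:

    * one 384-array main source plate (``{medium}-MSP``) condensing the four
      precultures, plate ``i`` in quadrant ``i``;
    * four replicate source plates (``{medium}-RSP1..4``), RSP ``i``
      replicating preculture ``i`` into all four quadrants (four replicates
      per isolate);
    * four interaction plates (``{medium}-INT1..4``), pairing the MSP
      occupant with the corresponding RSP occupant at every position.

    Raises
    ------
    LayoutError
        If a medium does not have exactly four 96-array precultures, or two
        precultures collide on a 384 position.
    """
    by_medium: dict[str, list[PlateLayout]] = {}
    for p in precultures:
        if p.array_format != 96:
            raise LayoutError(f"{p.plate_id}: preculture plates must be 96-array")
        by_medium.setdefault(p.medium, []).append(p)

    out: dict[str, list[PlateLayout]] = {}
    for medium, plates in by_medium.items():
        if len(plates) != 4:
            raise LayoutError(
                f"medium {medium}: need exactly 4 preculture plates, "
                f"got {len(plates)}"
            )
        msp_occ: dict[tuple[int, int], tuple[str, ...]] = {}
        msp_src: dict[tuple[int, int], str] = {}
        for q, plate in enumerate(plates):
            for (r, c), occ in plate.occupants.items():
                pos = condense_well(r, c, q)
                if pos in msp_occ:
                    raise LayoutError(
                        f"medium {medium}: occupant collision at "
                        f"{position_label(*pos)}"
                    )
                msp_occ[pos] = occ
                msp_src[pos] = plate.plate_id
        msp = PlateLayout(
            plate_id=f"{medium}-MSP",
            array_format=384,
            medium=medium,
            role="main_source",
            occupants=msp_occ,
            quadrant_of=msp_src,
        )

        rsps = []
        for i, plate in enumerate(plates, start=1):
            occ: dict[tuple[int, int], tuple[str, ...]] = {}
            src: dict[tuple[int, int], str] = {}
            for q in range(4):
                for (r, c), o in plate.occupants.items():
                    pos = condense_well(r, c, q)
                    occ[pos] = o
                    src[pos] = plate.plate_id
            rsps.append(
                PlateLayout(
                    plate_id=f"{medium}-RSP{i}",
                    array_format=384,
                    medium=medium,
                    role="replicate_source",
                    occupants=occ,
                    quadrant_of=src,
                )
            )

        ints = []
        for i, rsp in enumerate(rsps, start=1):
            occ = {}
            for pos, msp_o in msp.occupants.items():
                rsp_o = rsp.occupants.get(pos)
                if rsp_o is None:
                    continue
                occ[pos] = (msp_o[0], rsp_o[0])
            ints.append(
                PlateLayout(
                    plate_id=f"{medium}-INT{i}",
                    array_format=384,
                    medium=medium,
                    role="interaction",
                    occupants=occ,
                )
            )
        out[medium] = [msp, *rsps, *ints]
    return out


def match_pair_to_individuals(
    interaction: PlateLayout, msp: PlateLayout, rsp: PlateLayout
) -> dict[tuple[int, int], tuple[tuple[int, int], tuple[int, int]]]:
    """Map every pair position to the positions of its two individuals.

    The mapping is the identity on positions — the individual values for a
    pair are read from the *same* position on the MSP and RSP plates, which
    cancels positional bias.  Every occupied interaction position gets an
    entry even when the same unordered pair occurs elsewhere; downstream
    each instance keeps its own record.
    """
    for other in (msp, rsp):
        if other.array_format != interaction.array_format:
            raise LayoutError(
                f"geometry mismatch: {interaction.plate_id} is "
                f"{interaction.array_format}-array, {other.plate_id} is "
                f"{other.array_format}-array"
            )
    return {pos: (pos, pos) for pos in interaction.occupants}


# ---------------------------------------------------------------------------
# quantification tables
# ---------------------------------------------------------------------------


@dataclass
class QuantTable:
    """One plate's colony quantification at a single timepoint."""

    plate_id: str
    time_h: float
    array_format: int
    data: pd.DataFrame  # columns: row, col (0-based int), size, opacity (float)


_QUANT_COLUMNS = ["row", "column", "size", "opacity"]


def read_quant_table(path: str | Path, time_h: float | None = None) -> QuantTable:
    """Read a colony quantification table.

    Metadata lines start with ``#``; ``#key=value`` pairs declare
    ``plate_id``, ``array_format`` and ``time_h``.  The header row names at
    least ``row``, ``column``, ``size`` and ``opacity``; ``row`` and
    ``column`` are 1-based in the file and 0-based in the returned frame.
    Spots missing from the file are simply absent (the imaging software does
    not detect every spot at every timepoint).

    Raises
    ------
    QuantFormatError
        On a malformed row (with its line number) or a duplicated
        ``(row, column)``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    records: list[tuple[int, int, float, float]] = []
    seen: set[tuple[int, int]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in _QUANT_COLUMNS if c not in header]
                if missing:
                    raise QuantFormatError(
                        f"{path}:{lineno}: missing column(s) {missing}"
                    )
                continue
            row_map = dict(zip(header, fields))
            try:
                r = int(row_map["row"])
                c = int(row_map["column"])
                size = float(row_map["size"])
                opacity = float(row_map["opacity"])
            except (KeyError, ValueError) as exc:
                raise QuantFormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if size < 0 or opacity < 0:
                raise QuantFormatError(
                    f"{path}:{lineno}: negative size/opacity"
                )
            key = (r, c)
            if key in seen:
                raise QuantFormatError(
                    f"{path}:{lineno}: duplicate spot at row={r}, column={c}"
                )
            seen.add(key)
            records.append((r - 1, c - 1, size, opacity))
    if header is None:
        raise QuantFormatError(f"{path}: no header row found")

    array_format = int(meta.get("array_format", 384))
    if time_h is None:
        if "time_h" not in meta:
            raise QuantFormatError(f"{path}: no '#time_h=' header and no time given")
        time_h = float(meta["time_h"])
    n_rows, n_cols = ARRAY_GEOMETRY[array_format]
    for r, c, _, _ in records:
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise QuantFormatError(
                f"{path}: spot ({r + 1}, {c + 1}) outside declared "
                f"{array_format}-array geometry"
            )
    data = pd.DataFrame(records, columns=["row", "col", "size", "opacity"])
    return QuantTable(
        plate_id=meta.get("plate_id", path.stem),
        time_h=float(time_h),
        array_format=array_format,
        data=data,
    )


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Write a quantification table in the dialect read by :func:`read_quant_table`."""
    path = Path(path)
    lines = [
        "# colony quantification",
        f"#plate_id={table.plate_id}",
        f"#array_format={table.array_format}",
        f"#time_h={table.time_h:g}",
        "\t".join(_QUANT_COLUMNS),
    ]
    for rec in table.data.itertuples(index=False):
        lines.append(
            f"{int(rec.row) + 1}\t{int(rec.col) + 1}\t{rec.size:.6f}\t{rec.opacity:.6f}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# halo scores
# ---------------------------------------------------------------------------


def read_halo_scores(path: str | Path) -> pd.DataFrame:
    """Read qualitative inhibition-halo scores.

    CSV columns: ``plate_id``, ``position`` (e.g. ``B7``), ``target``,
    ``antifungal`` (0/1).  Returns a frame with 0-based ``row``/``col``
    added and ``antifungal`` as bool; one record per (plate, position,
    target) is enforced.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "position": str})
    required = {"plate_id", "position", "target", "antifungal"}
    missing = required - set(df.columns)
    if missing:
        raise QuantFormatError(f"{path}: halo table missing columns {sorted(missing)}")
    bad = ~df["antifungal"].isin([0, 1, True, False])
    if bad.any():
        raise QuantFormatError(
            f"{path}: non-boolean antifungal score at row(s) "
            f"{df.index[bad].tolist()}"
        )
    unknown = ~df["target"].isin(TARGET_YEASTS)
    if unknown.any():
        raise QuantFormatError(
            f"{path}: unknown target(s) {sorted(df.loc[unknown, 'target'].unique())}"
        )
    dup = df.duplicated(subset=["plate_id", "position", "target"])
    if dup.any():
        raise QuantFormatError(
            f"{path}: duplicate (plate, position, target) records at row(s) "
            f"{df.index[dup].tolist()}"
        )
    rc = df["position"].map(parse_position)
    df = df.assign(
        row=[p[0] for p in rc],
        col=[p[1] for p in rc],
        antifungal=df["antifungal"].astype(bool),
    )
    return df


def write_halo_scores(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["plate_id", "position", "target", "antifungal"]].copy()
    out["antifungal"] = out["antifungal"].astype(int)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# layout bundles
# ---------------------------------------------------------------------------


def write_layouts(layouts: Iterable[PlateLayout], path: str | Path) -> None:
    """Serialize layouts to JSON (or YAML when the suffix is .yml/.yaml)."""
    path = Path(path)
    payload = {"plates": [p.to_dict() for p in layouts]}
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_layouts(path: str | Path) -> list[PlateLayout]:
    path = Path(path)
    text = path.read_text()
    payload = (
        yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    )
    return [PlateLayout.from_dict(d) for d in payload["plates"]]
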