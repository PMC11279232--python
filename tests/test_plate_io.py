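import pytest
from hypothesis import given
from hypothesis import strategies as st

from spotscreen import plate_io
from spotscreen.plate_io import (
    LayoutError,
    PlateLayout,
    QuantFormatError,
    QuantTable,
    assemble_layouts,
    condense_well,
    is_border,
    iter_positions,
    match_pair_to_individuals,
    parse_position,
    position_label,
    read_halo_scores,
    read_layouts,
    read_quant_table,
    write_halo_scores,
    write_layouts,
    write_quant_table,
)

import pandas as pd


def make_96(plate_id="P1", medium="LM17", n=96, prefix="iso"):
    positions = list(iter_positions(96))[:n]
    return PlateLayout(
        plate_id=plate_id,
        array_format=96,
        medium=medium,
        role="preculture",
        occupants={pos: (f"{prefix}{i:03d}",) for i, pos in enumerate(positions)},
    )


def four_precultures(medium="LM17"):
    return [
        make_96(f"{medium}-PRE{i + 1}", medium, prefix=f"p{i}_") for i in range(4)
    ]


class TestPositions:
    def test_label_round_trip(self):
        assert position_label(0, 0) == "A1"
        assert position_label(15, 23) == "P24"
        assert parse_position("B7") == (1, 6)

    @given(st.integers(0, 15), st.integers(0, 23))
    def test_parse_inverts_label(self, r, c):
        assert parse_position(position_label(r, c)) == (r, c)

    def test_invalid_labels(self):
        with pytest.raises(ValueError):
            parse_position("Q1")
        with pytest.raises(ValueError):
            parse_position("11")

    def test_border_counts(self):
        n384 = sum(is_border(r, c, 384) for r, c in iter_positions(384))
        assert n384 == 2 * 24 + 2 * 16 - 4 == 76
        n96 = sum(is_border(r, c, 96) for r, c in iter_positions(96))
        assert n96 == 2 * 12 + 2 * 8 - 4


class TestCondensation:
    def test_quadrants_tile_the_384_array(self):
        seen = {
            condense_well(r, c, q)
            for q in range(4)
            for r, c in iter_positions(96)
        }
        assert seen == set(iter_positions(384))

    def test_bad_quadrant(self):
        with pytest.raises(ValueError):
            condense_well(0, 0, 4)


class TestPlateLayout:
    def test_occupant_count_enforced(self):
        with pytest.raises(LayoutError):
            PlateLayout(
                plate_id="X",
                array_format=384,
                medium="LM17",
                role="interaction",
                occupants={(0, 0): ("a",)},  # pairs need 2
            )
        with pytest.raises(LayoutError):
            PlateLayout(
                plate_id="X",
                array_format=96,
                medium="LM17",
                role="preculture",
                occupants={(0, 0): ("a", "b")},
            )

    def test_position_range_enforced(self):
        with pytest.raises(LayoutError):
            PlateLayout(
                plate_id="X",
                array_format=96,
                medium="LM17",
                role="preculture",
                occupants={(8, 0): ("a",)},
            )

    def test_dict_round_trip(self):
        plate = make_96()
        again = PlateLayout.from_dict(plate.to_dict())
        assert again.occupants == plate.occupants
        assert again.plate_id == plate.plate_id


class TestAssembleLayouts:
    def test_msp_has_384_distinct_occupants(self):
        plates = assemble_layouts(four_precultures())["LM17"]
        msp = plates[0]
        assert msp.role == "main_source"
        occ = [o[0] for o in msp.occupants.values()]
        assert len(occ) == 384 and len(set(occ)) == 384

    def test_rsp_is_four_copies_of_its_source(self):
        pres = four_precultures()
        plates = assemble_layouts(pres)["LM17"]
        rsp1 = plates[1]
        assert rsp1.role == "replicate_source"
        from collections import Counter

        rsp_counts = Counter(o[0] for o in rsp1.occupants.values())
        src_counts = Counter(o[0] for o in pres[0].occupants.values())
        assert rsp_counts == {iso: 4 * n for iso, n in src_counts.items()}

    def test_interaction_pairs_msp_with_rsp(self):
        plates = assemble_layouts(four_precultures())["LM17"]
        msp, rsp2, int2 = plates[0], plates[2], plates[6]
        for pos, pair in int2.occupants.items():
            assert pair == (msp.occupants[pos][0], rsp2.occupants[pos][0])

    def test_self_pairs_occur_once_per_isolate_per_plate(self):
        pres = four_precultures()
        plates = assemble_layouts(pres)["LM17"]
        int1 = plates[5]
        selfs = [p for p in int1.occupants.values() if p[0] == p[1]]
        # quadrant 0 of INT1 pairs preculture 1 against itself
        assert len(selfs) == 96

    def test_wrong_plate_count_rejected(self):
        with pytest.raises(LayoutError):
            assemble_layouts(four_precultures()[:3])

    def test_non_96_rejected(self):
        plate = PlateLayout(
            plate_id="X", array_format=384, medium="LM17", role="preculture",
            occupants={(0, 0): ("a",)},
        )
        with pytest.raises(LayoutError):
            assemble_layouts([plate])


class TestPairMatching:
    def test_identity_mapping(self):
        plates = assemble_layouts(four_precultures())["LM17"]
        msp, rsp1, int1 = plates[0], plates[1], plates[5]
        mapping = match_pair_to_individuals(int1, msp, rsp1)
        assert mapping[(1, 6)] == ((1, 6), (1, 6))
        assert set(mapping) == set(int1.occupants)

    def test_geometry_mismatch(self):
        plates = assemble_layouts(four_precultures())["LM17"]
        small = make_96()
        with pytest.raises(LayoutError):
            match_pair_to_individuals(plates[5], small, plates[1])


class TestQuantTables:
    def make_table(self, n=4):
        data = pd.DataFrame(
            {
                "row": range(n),
                "col": range(n),
                "size": [100.0 + i for i in range(n)],
                "opacity": [50.0 + i for i in range(n)],
            }
        )
        return QuantTable(plate_id="PLATE", time_h=24.0, array_format=384, data=data)

    def test_round_trip(self, tmp_path):
        table = self.make_table()
        path = tmp_path / "t.tsv"
        write_quant_table(table, path)
        again = read_quant_table(path)
        assert again.plate_id == "PLATE"
        assert again.time_h == 24.0
        pd.testing.assert_frame_equal(again.data, table.data)

    def test_missing_spot_simply_absent(self, tmp_path):
        table = self.make_table(4)
        table.data = table.data.iloc[[0, 2, 3]].reset_index(drop=True)
        path = tmp_path / "t.tsv"
        write_quant_table(table, path)
        again = read_quant_table(path)
        assert len(again.data) == 3
        assert (1, 1) not in set(zip(again.data["row"], again.data["col"]))

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#time_h=2\nrow\tcolumn\tsize\topacity\n1\t1\tabc\t5\n"
        )
        with pytest.raises(QuantFormatError, match=":3"):
            read_quant_table(path)

    def test_duplicate_spot_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "#time_h=2\nrow\tcolumn\tsize\topacity\n"
            "1\t1\t10\t5\n1\t1\t11\t6\n"
        )
        with pytest.raises(QuantFormatError, match="duplicate"):
            read_quant_table(path)

    def test_missing_time_rejected(self, tmp_path):
        path = tmp_path / "nt.tsv"
        path.write_text("row\tcolumn\tsize\topacity\n1\t1\t10\t5\n")
        with pytest.raises(QuantFormatError, match="time"):
            read_quant_table(path)
        assert read_quant_table(path, time_h=4.0).time_h == 4.0

    def test_geometry_check(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "#time_h=2\n#array_format=96\nrow\tcolumn\tsize\topacity\n9\t1\t1\t1\n"
        )
        with pytest.raises(QuantFormatError, match="geometry"):
            read_quant_table(path)


class TestHaloScores:
    def make_frame(self):
        return pd.DataFrame(
            {
                "plate_id": ["P", "P"],
                "position": ["A1", "B2"],
                "target": ["K_lactis", "S_cerevisiae"],
                "antifungal": [True, False],
            }
        )

    def test_round_trip(self, tmp_path):
        path = tmp_path / "h.csv"
        write_halo_scores(self.make_frame(), path)
        again = read_halo_scores(path)
        assert list(again["antifungal"]) == [True, False]
        assert list(again["row"]) == [0, 1]

    def test_duplicate_rejected(self, tmp_path):
        frame = pd.concat([self.make_frame()] * 2, ignore_index=True)
        path = tmp_path / "h.csv"
        write_halo_scores(frame, path)
        with pytest.raises(QuantFormatError, match="duplicate"):
            read_halo_scores(path)

    def test_non_boolean_rejected(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("plate_id,position,target,antifungal\nP,A1,K_lactis,2\n")
        with pytest.raises(QuantFormatError, match="non-boolean"):
            read_halo_scores(path)

    def test_unknown_target_rejected(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("plate_id,position,target,antifungal\nP,A1,E_coli,1\n")
        with pytest.raises(QuantFormatError, match="unknown target"):
            read_halo_scores(path)


@pytest.mark.parametrize("suffix", ["json", "yaml"])
def test_layout_bundle_round_trip(tmp_path, suffix):
    plates = assemble_layouts(four_precultures())["LM17"]
    path = tmp_path / f"layouts.{suffix}"
    write_layouts(plates, path)
    again = read_layouts(path)
    assert [p.plate_id for p in again] == [p.plate_id for p in plates]
    assert again[0].occupants == plates[0].occupants
    assert again[5].occupants == plates[5].occupants
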