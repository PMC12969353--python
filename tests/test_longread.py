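"""Barcode extraction, part identification and the association rules."""

import numpy as np
import pytest

from oripool.longread import (
    STATUS_CONFLICT,
    STATUS_ERROR_NEIGHBOR,
    STATUS_INSUFFICIENT,
    STATUS_MAPPED,
    UNASSIGNED,
    UNMAPPED,
    BarcodeObservation,
    LongRead,
    PartHit,
    backbone_confounded_ids,
    build_association,
    extract_barcode,
    identify_parts,
    summarize_map,
)
from oripool.parts import assemble_plasmid
from oripool.simulate import make_default_design, mutate_sequence

BC = "ACGT" * 5


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture(scope="module")
def design():
    return make_default_design(seed=7)


@pytest.fixture(scope="module")
def plasmid(design):
    return assemble_plasmid(
        design, {"origin": "ori02", "promoter": "P01", "resistance": "kanR1"}, BC
    )


class TestExtractBarcode:
    def test_exact_cassette(self, design):
        read = LongRead("r1", "ACCA" * 30 + design.flank_left + BC + design.flank_right + "TGGT" * 30)
        assert extract_barcode(read, design) == BC

    def test_reverse_complement_gives_canonical_barcode(self, design):
        seq = "ACCA" * 30 + design.flank_left + BC + design.flank_right + "TGGT" * 30
        assert extract_barcode(LongRead("r1", _revcomp(seq)), design) == BC

    def test_wrong_length_is_dropped(self, design):
        read = LongRead("r1", "ACCA" * 30 + design.flank_left + BC[:19] + design.flank_right + "TG" * 40)
        assert extract_barcode(read, design) is None

    def test_tolerates_two_flank_mismatches(self, design):
        fl = list(design.flank_left)
        fl[3], fl[11] = ("C" if fl[3] != "C" else "G"), ("A" if fl[11] != "A" else "T")
        read = LongRead("r1", "ACCA" * 30 + "".join(fl) + BC + design.flank_right + "TGGT" * 30)
        assert extract_barcode(read, design) == BC

    def test_two_distinct_cassettes_are_ambiguous(self, design):
        other = "TTTTGGGGCCCCAAAATTTT"
        seq = (
            "ACCA" * 20
            + design.flank_left + BC + design.flank_right
            + "GTCA" * 20
            + design.flank_left + other + design.flank_right
            + "TGGT" * 20
        )
        assert extract_barcode(LongRead("r1", seq), design) is None

    def test_missing_flanks(self, design):
        assert extract_barcode(LongRead("r1", "ACGT" * 200), design) is None


class TestIdentifyParts:
    def test_error_free_read_hits_every_category_at_identity_one(self, design, plasmid):
        hits = identify_parts(LongRead("r1", plasmid.sequence), design)
        assert hits["origin"].part_id == "ori02" and hits["origin"].identity == 1.0
        assert hits["promoter"].part_id == "P01" and not hits["promoter"].ambiguous
        assert hits["resistance"].part_id == "kanR1"

    def test_backbone_confounded_promoter_flagged_ambiguous(self, design):
        # promoter variant 4 shares a 160 bp block with the backbone
        assert backbone_confounded_ids(design) == frozenset({"P04"})
        p = assemble_plasmid(
            design, {"origin": "ori01", "promoter": "P04", "resistance": "kanR1"}, BC
        )
        hits = identify_parts(LongRead("r1", p.sequence), design)
        assert hits["promoter"] is not None and hits["promoter"].ambiguous

    def test_heavily_mutated_read_has_no_hit(self, design):
        ori = design.get_part("ori05").body_seq
        rng = np.random.default_rng(42)
        mutated = mutate_sequence(ori, sub_rate=0.12, indel_rate=0.0, rng=rng)
        read = LongRead("r1", "ACCA" * 25 + mutated + "TGGT" * 25)
        hits = identify_parts(read, design)
        assert hits["origin"] is None  # expected identity ~0.88 < 0.90

    def test_minus_strand_read(self, design, plasmid):
        hits = identify_parts(LongRead("r1", _revcomp(plasmid.sequence)), design)
        assert hits["origin"].part_id == "ori02"


def obs(read_id, barcode, origin=None, promoter=None, resistance=None):
    hits = {}
    if origin:
        hits["origin"] = PartHit(origin, 1.0)
    if promoter:
        hits["promoter"] = PartHit(promoter, 1.0)
    if resistance:
        hits["resistance"] = PartHit(resistance, 1.0)
    return BarcodeObservation(read_id, barcode, hits)


B1 = "A" * 20
B2 = "C" * 20


class TestBuildAssociation:
    def test_two_reads_map(self):
        table = build_association([obs("r1", B1, "O1"), obs("r2", B1, "O1")])
        row = table.df.iloc[0]
        assert row["status"] == STATUS_MAPPED and row["part1"] == "O1" and row["support1"] == 2

    def test_single_read_is_insufficient(self):
        table = build_association([obs("r1", B1, "O1")])
        row = table.df.iloc[0]
        assert row["status"] == STATUS_INSUFFICIENT and row["part1"] == UNASSIGNED

    def test_dual_support_is_eliminated(self):
        table = build_association(
            [obs(f"r{i}", B1, "O1") for i in (1, 2)] + [obs(f"r{i}", B1, "O2") for i in (3, 4)]
        )
        assert table.df.iloc[0]["status"] == STATUS_CONFLICT

    def test_duplicate_read_ids_count_once(self):
        table = build_association([obs("r1", B1, "O1"), obs("r1", B1, "O1")])
        assert table.df.iloc[0]["status"] == STATUS_INSUFFICIENT

    def test_part2_may_stay_unmapped_on_mapped_row(self):
        table = build_association(
            [obs("r1", B1, "O1", promoter="P1"), obs("r2", B1, "O1")]
        )
        row = table.df.iloc[0]
        assert row["status"] == STATUS_MAPPED and row["part2"] == UNMAPPED and row["support2"] == 1

    def test_order_independence(self):
        reads = (
            [obs(f"r{i}", B1, "O1", promoter="P1") for i in range(3)]
            + [obs(f"s{i}", B2, "O2") for i in range(2)]
            + [obs("t0", B2, "O3")]
        )
        t1 = build_association(reads)
        t2 = build_association(list(reversed(reads)))
        assert t1.df.equals(t2.df)

    def test_no_barcode_maps_to_two_origins(self):
        rng = np.random.default_rng(0)
        reads = []
        for i in range(200):
            bc = "".join(rng.choice(list("ACGT"), 20))
            for j in range(2):
                reads.append(obs(f"r{i}_{j}", bc, f"O{rng.integers(5)}"))
        table = build_association(reads)
        mapped = table.mapped()
        assert mapped.groupby("barcode")["part1"].nunique().le(1).all()

    def test_error_neighbor_suppressed(self):
        near = B1[:-1] + "T"  # one edit from B1
        reads = [obs(f"r{i}", B1, "O1") for i in range(8)] + [
            obs(f"e{i}", near, "O1") for i in range(2)
        ]
        table = build_association(reads)
        by_bc = table.df.set_index("barcode")
        assert by_bc.loc[B1, "status"] == STATUS_MAPPED
        assert by_bc.loc[near, "status"] == STATUS_ERROR_NEIGHBOR
        # with the guard off, the phantom would map
        off = build_association(reads, merge_near_duplicates=False)
        assert off.df.set_index("barcode").loc[near, "status"] == STATUS_MAPPED

    def test_empty_observations_warn(self):
        with pytest.warns(UserWarning):
            table = build_association([])
        assert len(table.df) == 0


class TestSummarize:
    def test_per_origin_counts(self):
        reads = [obs(f"a{i}", f"{b}AAAAAAAAAAAAAAAAAAA", "O1") for b in "CGT" for i in (1, 2)]
        reads += [obs(f"b{i}", "G" * 20, "O2") for i in (1, 2)]
        per_origin, status = summarize_map(build_association(reads))
        assert dict(zip(per_origin["origin"], per_origin["n_barcodes"])) == {"O1": 3, "O2": 1}
        assert status[STATUS_MAPPED] == 4

    def test_all_conflict(self):
        reads = [obs(f"r{i}", B1, o) for o in ("O1", "O2") for i in (f"{o}a", f"{o}b")]
        per_origin, status = summarize_map(build_association(reads))
        assert len(per_origin) == 0 and status[STATUS_CONFLICT] == 1
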