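"""Deconvolution of pooled-library long reads into a barcode -> parts map.

Each whole-plasmid long read (Nanopore/PacBio) is searched for the N20
barcode cassette (the random barcode between its two fixed priming sites)
and for the best-matching variant in each variable part category.  Reads
are then tallied per barcode: a barcode is assigned an origin only when at
least ``min_support`` distinct reads agree, and barcodes supported for two
or more variants of the same category are eliminated from all downstream
analysis (they indicate barcode collisions or chimeric assemblies).

Alignment is edlib infix alignment (edit distance); identity for a part
hit is 1 - edit_distance / len(part body).
"""

from __future__ import annotations

import functools
import gzip
import warnings
from dataclasses import dataclass, field

import edlib
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .parts import LibraryDesign, VARIABLE_CATEGORIES

UNASSIGNED = "UNASSIGNED"
UNMAPPED = "UNMAPPED"

STATUS_MAPPED = "mapped"
STATUS_INSUFFICIENT = "insufficient_support"
STATUS_CONFLICT = "conflict_eliminated"
STATUS_ERROR_NEIGHBOR = "error_neighbor"


@dataclass(frozen=True)
class LongRead:
    read_id: str
    sequence: str
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id} has empty sequence")


@dataclass
class PartHit:
    part_id: str
    identity: float
    ambiguous: bool = False
    interval: tuple[int, int] | None = None


@dataclass
class BarcodeObservation:
    """What one read contributes: its barcode (canonical strand) and at most
    one retained part hit per variable category."""

    read_id: str
    barcode: str | None
    part_hits: dict[str, PartHit | None] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return self.barcode is not None and all(
            self.part_hits.get(c) is not None and not self.part_hits[c].ambiguous
            for c in VARIABLE_CATEGORIES
        )


def read_fastx(path) -> list[LongRead]:
    """Read FASTQ/FASTA (gz-transparent) into LongRead records."""
    p = str(path)
    opener = gzip.open if p.endswith(".gz") else open
    stem = p[:-3] if p.endswith(".gz") else p
    fmt = "fastq" if stem.endswith(("fastq", "fq")) else "fasta"
    with opener(p, "rt") as fh:
        return [LongRead(r.id, str(r.seq).upper(), source=p) for r in SeqIO.parse(fh, fmt)]


# ---------------------------------------------------------------------------
# barcode extraction


def _flank_matches(flank: str, seq: str, k: int) -> list[tuple[int, int]]:
    """Best-scoring infix matches of ``flank`` in ``seq`` within edit distance k.

    Returns (start, end) half-open intervals; co-optimal shifted locations
    are all reported.
    """
    res = edlib.align(flank, seq, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return []
    out = []
    for s, e in res["locations"]:
        out.append((s if s is not None else 0, e + 1))
    return sorted(set(out))


def _extract_barcode_stranded(
    read: LongRead, design: LibraryDesign, max_flank_mismatches: int = 2, length_tolerance: int = 0
) -> tuple[str | None, str | None]:
    """Locate the barcode cassette on either strand.

    Returns (barcode, strand); barcode is reported on the canonical strand
    (the one where flank_left precedes the barcode).  Returns (None, None)
    if the cassette is absent, the intervening segment has the wrong
    length (strict by default: indel-shifted barcodes are dropped, not
    corrected), or several distinct cassettes are found (ambiguous read).
    """
    L = design.barcode_length
    candidates: set[tuple[str, str]] = set()
    for strand, seq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
        lefts = _flank_matches(design.flank_left, seq, max_flank_mismatches)
        if not lefts:
            continue
        rights = _flank_matches(design.flank_right, seq, max_flank_mismatches)
        for _, le in lefts:
            for rs, _ in rights:
                gap = rs - le
                if abs(gap - L) <= length_tolerance and gap > 0:
                    candidates.add((seq[le:rs], strand))
    barcodes = {b for b, _ in candidates}
    if len(barcodes) != 1:
        return None, None  # absent, wrong length, or ambiguous (multiple cassettes)
    (barcode, strand) = sorted(candidates)[0]
    return barcode, strand


def extract_barcode(
    read: LongRead, design: LibraryDesign, max_flank_mismatches: int = 2, length_tolerance: int = 0
) -> str | None:
    """Extract the canonical-strand barcode from a read, or None."""
    barcode, _ = _extract_barcode_stranded(read, design, max_flank_mismatches, length_tolerance)
    return barcode


# ---------------------------------------------------------------------------
# part identification


@functools.lru_cache(maxsize=8)
def _backbone_confounded_ids(design_key: int, min_identity: float, min_block: int = 100) -> frozenset[str]:
    """Part ids sharing a >= min_block nt block with the backbone at
    >= min_identity (the part 2.4 confound).  Cached per design object."""
    design = _DESIGN_CACHE[design_key]
    backbone = design.backbone.body_seq
    confounded = set()
    k = int(min_block * (1.0 - min_identity))
    for cat in VARIABLE_CATEGORIES:
        for p in design.parts(cat):
            body = p.body_seq
            if len(body) < min_block:
                continue
            step = max(1, min_block // 5)
            for i in range(0, len(body) - min_block + 1, step):
                window = body[i : i + min_block]
                if edlib.align(window, backbone, mode="HW", k=k)["editDistance"] >= 0:
                    confounded.add(p.part_id)
                    break
    return frozenset(confounded)


_DESIGN_CACHE: dict[int, LibraryDesign] = {}


def backbone_confounded_ids(design: LibraryDesign, min_identity: float = 0.90) -> frozenset[str]:
    _DESIGN_CACHE[id(design)] = design
    return _backbone_confounded_ids(id(design), min_identity)


def _best_infix(query: str, target: str, k: int):
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    return res["editDistance"], (s if s is not None else 0, e + 1)


def identify_parts(
    read: LongRead,
    design: LibraryDesign,
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
    strand: str | None = None,
) -> dict[str, PartHit | None]:
    """Best-matching variant per variable category for one read.

    A part scores a hit when its whole body aligns into the read at
    >= min_identity with a matched interval covering >= min_coverage of the
    body.  Two distinct passing variants of the same category at
    non-overlapping read positions (a chimeric-read signature) cancel each
    other: the category votes for neither.  A hit on a part that shares a
    >=100 nt block with the backbone at >= min_identity is flagged
    ambiguous and its category reported unmapped (the part 2.4 confound).

    ``strand``: "+"/"-" restricts the search to that read strand (used by
    the pipeline once the barcode cassette fixes the orientation); None
    searches both.
    """
    confounded = backbone_confounded_ids(design, min_identity)
    targets = []
    if strand in (None, "+"):
        targets.append(read.sequence)
    if strand in (None, "-"):
        targets.append(reverse_complement(read.sequence))

    hits: dict[str, PartHit | None] = {}
    for cat in VARIABLE_CATEGORIES:
        passing: list[PartHit] = []
        for p in design.parts(cat):
            k = int(len(p.body_seq) * (1.0 - min_identity))
            best = None
            for t in targets:
                r = _best_infix(p.body_seq, t, k)
                if r is not None and (best is None or r[0] < best[0]):
                    best = r
            if best is None:
                continue
            ed, (s, e) = best
            identity = 1.0 - ed / len(p.body_seq)
            if identity >= min_identity and (e - s) >= min_coverage * len(p.body_seq):
                passing.append(PartHit(p.part_id, identity, interval=(s, e)))
        if not passing:
            hits[cat] = None
            continue
        passing.sort(key=lambda h: (-h.identity, h.part_id))
        best_hit = passing[0]
        conflict = False
        for other in passing[1:]:
            s1, e1 = best_hit.interval
            s2, e2 = other.interval
            overlap = max(0, min(e1, e2) - max(s1, s2))
            if overlap < 0.5 * min(e1 - s1, e2 - s2):
                conflict = True  # two different variants at distinct loci
                break
            if other.identity == best_hit.identity and other.part_id != best_hit.part_id:
                conflict = True  # exact tie between distinct variants
                break
        if conflict:
            hits[cat] = None
            continue
        if best_hit.part_id in confounded:
            best_hit.ambiguous = True
        hits[cat] = best_hit
    return hits


def observe_reads(
    reads,
    design: LibraryDesign,
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
    max_flank_mismatches: int = 2,
) -> list[BarcodeObservation]:
    """Run barcode extraction + part identification over a read set.

    Reads without an extractable barcode contribute nothing downstream and
    are returned with ``barcode=None``; part search is skipped for them.
    """
    out = []
    for read in reads:
        barcode, strand = _extract_barcode_stranded(read, design, max_flank_mismatches)
        if barcode is None:
            out.append(BarcodeObservation(read.read_id, None))
            continue
        hits = identify_parts(read, design, min_identity, min_coverage, strand=strand)
        out.append(BarcodeObservation(read.read_id, barcode, hits))
    return out


# ---------------------------------------------------------------------------
# association table


@dataclass
class AssociationTable:
    """Barcode -> (part1, part2, part3) map with per-association read support.

    One row per barcode; ``status`` is mapped / insufficient_support /
    conflict_eliminated.  Only mapped rows enter downstream analysis.
    """

    df: pd.DataFrame

    COLUMNS = ("barcode", "part1", "part2", "part3", "support1", "support2", "support3", "status")

    def mapped(self) -> pd.DataFrame:
        return self.df[self.df["status"] == STATUS_MAPPED]

    def barcode_to_origin(self) -> dict[str, str]:
        m = self.mapped()
        return dict(zip(m["barcode"], m["part1"]))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AssociationTable":
        df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
        return cls(df)


_CAT_TO_COL = dict(zip(VARIABLE_CATEGORIES, ("part1", "part2", "part3")))


def _error_neighbor_barcodes(obs_counts: dict[str, int]) -> set[str]:
    """Barcodes within edit distance 1 of a strictly better-observed
    barcode: almost always sequencing-error variants of that neighbor
    (random 20-mers essentially never collide at distance 1)."""
    phantoms: set[str] = set()
    ranked = sorted(obs_counts, key=lambda b: (-obs_counts[b], b))
    for i, b in enumerate(ranked):
        for better in ranked[:i]:
            if obs_counts[better] <= obs_counts[b]:
                break
            if edlib.align(b, better, mode="NW", k=1)["editDistance"] >= 0:
                phantoms.add(b)
                break
    return phantoms


def build_association(
    observations, min_support: int = 2, merge_near_duplicates: bool = True
) -> AssociationTable:
    """Tally read support per (barcode, category, part) and apply the
    support/conflict rules.

    Support is the number of *distinct* read_ids backing a candidate.  Per
    barcode: any category with two or more candidates reaching
    ``min_support`` eliminates the barcode (conflict); a unique supported
    part1 makes the row mapped; part2/part3 stay unmapped on a mapped row
    when no unique candidate reaches support.  Tallying is order
    independent, so identical read sets in any order give identical tables.

    ``merge_near_duplicates`` suppresses barcodes one edit away from a
    strictly better-observed barcode (status ``error_neighbor``), the
    standard guard against recurrent single-error phantom barcodes in
    barcode-counting pipelines; their reads are not reassigned.
    """
    if not observations:
        warnings.warn("empty observation list; returning empty association table")
        return AssociationTable(pd.DataFrame(columns=list(AssociationTable.COLUMNS)))

    support: dict[str, dict[str, dict[str, set[str]]]] = {}
    obs_counts: dict[str, int] = {}
    for obs in observations:
        if obs.barcode is None:
            continue
        obs_counts[obs.barcode] = obs_counts.get(obs.barcode, 0) + 1
        bc = support.setdefault(obs.barcode, {c: {} for c in VARIABLE_CATEGORIES})
        for cat in VARIABLE_CATEGORIES:
            hit = obs.part_hits.get(cat)
            if hit is None or hit.ambiguous:
                continue
            bc[cat].setdefault(hit.part_id, set()).add(obs.read_id)

    phantoms = _error_neighbor_barcodes(obs_counts) if merge_near_duplicates else set()

    rows = []
    for barcode in sorted(support):
        tallies = support[barcode]
        assigned: dict[str, str] = {}
        sup: dict[str, int] = {}
        conflict = False
        for cat in VARIABLE_CATEGORIES:
            counts = {pid: len(rids) for pid, rids in tallies[cat].items()}
            candidates = sorted(
                (pid for pid, n in counts.items() if n >= min_support),
                key=lambda pid: (-counts[pid], pid),
            )
            if len(candidates) >= 2:
                conflict = True
            if candidates:
                assigned[cat] = candidates[0]
                sup[cat] = counts[candidates[0]]
            else:
                assigned[cat] = UNMAPPED
                sup[cat] = max(counts.values(), default=0)
        if barcode in phantoms:
            status = STATUS_ERROR_NEIGHBOR
        elif conflict:
            status = STATUS_CONFLICT
        elif assigned["origin"] != UNMAPPED:
            status = STATUS_MAPPED
        else:
            status = STATUS_INSUFFICIENT
        part1 = assigned["origin"] if status == STATUS_MAPPED else UNASSIGNED
        part2 = assigned["promoter"] if status == STATUS_MAPPED else UNMAPPED
        part3 = assigned["resistance"] if status == STATUS_MAPPED else UNMAPPED
        rows.append(
            {
                "barcode": barcode,
                "part1": part1,
                "part2": part2,
                "part3": part3,
                "support1": sup["origin"],
                "support2": sup["promoter"],
                "support3": sup["resistance"],
                "status": status,
            }
        )
    return AssociationTable(pd.DataFrame(rows, columns=list(AssociationTable.COLUMNS)))


def summarize_map(table: AssociationTable) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-origin tallies of mapped barcodes (and their total read support),
    plus counts of each row status."""
    mapped = table.mapped()
    if len(mapped):
        per_origin = (
            mapped.groupby("part1")
            .agg(n_barcodes=("barcode", "nunique"), total_support=("support1", "sum"))
            .rename_axis("origin")
            .reset_index()
            .sort_values("origin", ignore_index=True)
        )
    else:
        per_origin = pd.DataFrame(columns=["origin", "n_barcodes", "total_support"])
    status_counts = table.df["status"].value_counts().to_dict() if len(table.df) else {}
    for s in (STATUS_MAPPED, STATUS_INSUFFICIENT, STATUS_CONFLICT, STATUS_ERROR_NEIGHBOR):
        status_counts.setdefault(s, 0)
    return per_origin, status_counts
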