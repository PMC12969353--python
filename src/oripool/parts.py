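"""Model of the combinatorial ("magic pool") plasmid library.

A library member is assembled from four golden-gate positions: an origin of
replication (part 1), a resistance-gene promoter+RBS (part 2), a resistance
CDS (part 3) and the barcoded backbone (part 4, carrying the conditional
cloning origin and the N20 barcode cassette).  Junctions are modelled as
abstract 4-nt overhang labels: a chain of parts is assemblable iff the
downstream overhang of each part equals the upstream overhang of the next,
around the circle part1 -> part2 -> part3 -> part4 -> part1.  Restriction
chemistry (BsbI/BbsI site placement, digestion) is deliberately out of
scope: the pipeline needs junction validity, not enzymology.

Coordinates are 0-based half-open on the canonical linearization, which
starts at the first base of the left barcode-flanking priming site so that
barcode coordinates are stable across rotations.  Strand "+" is the strand
carrying flank_left -> barcode -> flank_right.
"""

from __future__ import annotations

import csv
import itertools
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("origin", "promoter", "resistance", "backbone")
#: assembly order around the circle; the backbone closes back onto part 1
CATEGORY_ORDER = ("origin", "promoter", "resistance", "backbone")
VARIABLE_CATEGORIES = ("origin", "promoter", "resistance")

_DNA = set("ACGT")


class AssemblyError(ValueError):
    """A junction in the part chain has mismatched overhangs."""


class PartLookupError(KeyError):
    """A selection names a part_id that is not in the design."""


def _check_dna(seq: str, what: str, allow_empty: bool = False) -> None:
    if not allow_empty and not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class Part:
    """One sequence part with its golden-gate junction labels.

    ``body_seq`` excludes the overhangs; the assembled sequence is the
    concatenation of bodies joined at shared overhangs, each shared
    overhang appearing exactly once.
    """

    part_id: str
    category: str
    body_seq: str
    upstream_overhang: str
    downstream_overhang: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        _check_dna(self.body_seq, f"part {self.part_id} body_seq")
        if self.body_seq != self.body_seq.upper():
            raise ValueError(f"part {self.part_id} body_seq must be uppercase")
        for name, oh in (("upstream", self.upstream_overhang), ("downstream", self.downstream_overhang)):
            _check_dna(oh, f"part {self.part_id} {name} overhang")
            if len(oh) != 4:
                raise ValueError(f"part {self.part_id} {name} overhang must be 4 nt")


@dataclass
class LibraryDesign:
    """Registry of all part variants plus the barcode cassette geometry.

    ``flank_left``/``flank_right`` are the common PCR priming sites that
    flank the random N20 barcode; the backbone body must contain
    ``flank_left + flank_right`` exactly once, and assembly inserts the
    barcode between them.
    """

    parts_by_category: dict[str, list[Part]]
    flank_left: str
    flank_right: str
    barcode_length: int = 20

    def __post_init__(self) -> None:
        _check_dna(self.flank_left, "flank_left")
        _check_dna(self.flank_right, "flank_right")
        if self.barcode_length < 8:
            raise ValueError("barcode_length must be >= 8")
        backbones = self.parts_by_category.get("backbone", [])
        if len(backbones) != 1:
            raise ValueError(f"design must have exactly one backbone part, got {len(backbones)}")
        seen: set[str] = set()
        for parts in self.parts_by_category.values():
            for p in parts:
                if p.part_id in seen:
                    raise ValueError(f"duplicate part_id {p.part_id!r}")
                seen.add(p.part_id)
        cassette = self.flank_left + self.flank_right
        if self.backbone.body_seq.count(cassette) != 1:
            raise ValueError(
                "backbone body must contain flank_left + flank_right (the empty "
                "barcode cassette) exactly once"
            )

    @property
    def backbone(self) -> Part:
        return self.parts_by_category["backbone"][0]

    def get_part(self, part_id: str) -> Part:
        for parts in self.parts_by_category.values():
            for p in parts:
                if p.part_id == part_id:
                    return p
        raise PartLookupError(part_id)

    def parts(self, category: str) -> list[Part]:
        return list(self.parts_by_category.get(category, []))


@dataclass
class AssembledPlasmid:
    """A circular library member on its canonical rotation.

    ``sequence`` is the linearization starting at the first base of
    ``flank_left``; all rotations are equivalent representations of the
    same molecule.  ``feature_annotations`` are (label, start, end, strand)
    in 0-based half-open coordinates on ``sequence`` ("+" carries
    flank_left -> barcode -> flank_right).
    """

    plasmid_id: str
    barcode: str
    part_ids: dict[str, str]
    sequence: str
    feature_annotations: list[tuple[str, int, int, str]] = field(default_factory=list)
    circular: bool = True


def canonical_rotation(circular_seq: str, anchor: str) -> str:
    """Rotate a circular sequence to start at the first occurrence of ``anchor``."""
    doubled = circular_seq + circular_seq
    i = doubled.find(anchor)
    if i < 0 or i >= len(circular_seq):
        raise ValueError("anchor not found on the given strand of the circular sequence")
    return doubled[i : i + len(circular_seq)]


def assemble_plasmid(
    design: LibraryDesign,
    selection: dict[str, str],
    barcode: str,
    plasmid_id: str | None = None,
) -> AssembledPlasmid:
    """Assemble one circular plasmid from a per-category part selection.

    The chain part1 -> part2 -> part3 -> part4 -> part1 must have matching
    overhangs at every junction; each shared overhang contributes 4 nt to
    the circle exactly once.  The barcode is inserted between the
    backbone's flanking priming sites.
    """
    _check_dna(barcode, "barcode")
    if len(barcode) != design.barcode_length:
        raise ValueError(
            f"barcode length {len(barcode)} != design barcode_length {design.barcode_length}"
        )
    chain: list[Part] = []
    for cat in CATEGORY_ORDER:
        if cat == "backbone":
            chain.append(design.backbone)
            continue
        if cat not in selection:
            raise PartLookupError(f"selection missing category {cat!r}")
        part = design.get_part(selection[cat])
        if part.category != cat:
            raise PartLookupError(f"part {part.part_id!r} is not a {cat}")
        chain.append(part)

    for a, b in zip(chain, chain[1:] + chain[:1]):
        if a.downstream_overhang != b.upstream_overhang:
            raise AssemblyError(
                f"overhang mismatch at junction ({a.part_id}, {b.part_id}): "
                f"{a.downstream_overhang} != {b.upstream_overhang}"
            )

    # circle = sum over parts of (body + downstream overhang); the upstream
    # overhang of each part is the downstream overhang of its predecessor.
    pieces: list[str] = []
    spans: list[tuple[str, int, int]] = []
    pos = 0
    for part in chain:
        body = part.body_seq
        if part.category == "backbone":
            cassette = design.flank_left + design.flank_right
            k = body.index(cassette)
            body = body[: k + len(design.flank_left)] + barcode + body[k + len(design.flank_left) :]
        spans.append((part.part_id, pos, pos + len(body)))
        pieces.append(body)
        pos += len(body)
        pieces.append(part.downstream_overhang)
        pos += 4
    raw = "".join(pieces)

    seq = canonical_rotation(raw, design.flank_left)
    shift = (raw + raw).find(design.flank_left)
    n = len(raw)

    # a feature crossing the rotation point (always the backbone, since the
    # canonical start is inside its barcode cassette) gets end > n, meaning
    # it wraps around the circular origin
    annotations: list[tuple[str, int, int, str]] = []
    for label, s, e in spans:
        s2, e2 = (s - shift) % n, (e - shift) % n
        if e2 <= s2:
            e2 += n
        annotations.append((label, s2, e2, "+"))
    bc_start = len(design.flank_left)
    annotations.append(("barcode", bc_start, bc_start + len(barcode), "+"))
    annotations.sort(key=lambda t: (t[1], t[0]))

    if plasmid_id is None:
        plasmid_id = "_".join(selection[c] for c in VARIABLE_CATEGORIES) + "_" + barcode[:8]
    return AssembledPlasmid(
        plasmid_id=plasmid_id,
        barcode=barcode,
        part_ids={**{c: selection[c] for c in VARIABLE_CATEGORIES}, "backbone": design.backbone.part_id},
        sequence=seq,
        feature_annotations=annotations,
    )


def enumerate_design_space(design: LibraryDesign):
    """Count and enumerate all part1 x part2 x part3 selections.

    Returns ``(count, iterator)``; the iterator yields each selection
    exactly once in registry order (deterministic).
    """
    lists = []
    for cat in VARIABLE_CATEGORIES:
        parts = design.parts(cat)
        if not parts:
            warnings.warn(f"category {cat!r} has no variants; design space is empty")
            return 0, iter(())
        lists.append([p.part_id for p in parts])
    count = 1
    for l in lists:
        count *= len(l)
    it = (dict(zip(VARIABLE_CATEGORIES, combo)) for combo in itertools.product(*lists))
    return count, it


# ---------------------------------------------------------------------------
# serialization


def _to_seqrecord(p: AssembledPlasmid) -> SeqRecord:
    rec = SeqRecord(Seq(p.sequence), id=p.plasmid_id, name=p.plasmid_id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if p.circular else "linear"
    n = len(p.sequence)
    for label, start, end, strand in p.feature_annotations:
        s = 1 if strand == "+" else -1
        if end > n:  # wraps the circular origin: join (start..n) + (0..end-n)
            loc = FeatureLocation(start, n, strand=s) + FeatureLocation(0, end - n, strand=s)
        else:
            loc = FeatureLocation(start, end, strand=s)
        rec.features.append(SeqFeature(loc, type="misc_feature", qualifiers={"label": [label]}))
    return rec


def _from_seqrecord(rec: SeqRecord) -> AssembledPlasmid:
    annotations = []
    barcode = ""
    n = len(rec.seq)
    for f in rec.features:
        label = f.qualifiers.get("label", [f.type])[0]
        parts_ = sorted(f.location.parts, key=lambda l: int(l.start))
        if len(parts_) == 2 and int(parts_[1].end) == n and int(parts_[0].start) == 0:
            s, e = int(parts_[1].start), int(parts_[0].end) + n  # rejoin wrap
        else:
            s, e = int(f.location.start), int(f.location.end)
        annotations.append((label, s, e, "+" if (f.location.strand or 1) >= 0 else "-"))
        if label == "barcode":
            barcode = str(rec.seq[s:e])
    return AssembledPlasmid(
        plasmid_id=rec.id,
        barcode=barcode,
        part_ids={},
        sequence=str(rec.seq),
        feature_annotations=sorted(annotations, key=lambda t: (t[1], t[0])),
        circular=rec.annotations.get("topology", "linear") == "circular",
    )


def serialize_library(plasmids, path, format: str = "genbank") -> None:
    """Write assembled plasmids to a multi-record GenBank or FASTA file."""
    if format not in ("genbank", "fasta"):
        raise ValueError(f"unknown format {format!r}")
    records = [_to_seqrecord(p) for p in plasmids]
    SeqIO.write(records, path, format)


def read_library(path, format: str = "genbank") -> list[AssembledPlasmid]:
    """Inverse of :func:`serialize_library` (FASTA drops annotations/topology)."""
    if format not in ("genbank", "fasta"):
        raise ValueError(f"unknown format {format!r}")
    from Bio import BiopythonParserWarning

    try:
        with warnings.catch_warnings():
            # Biopython downgrades truncation to a warning; treat it as fatal
            warnings.simplefilter("error", BiopythonParserWarning)
            records = list(SeqIO.parse(path, format))
    except (ValueError, BiopythonParserWarning) as exc:
        raise ValueError(f"parse error while reading {path}: {exc}") from exc
    return [_from_seqrecord(r) for r in records]


def write_parts_tsv(design: LibraryDesign, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["part_id", "category", "upstream_overhang", "downstream_overhang", "body_seq"])
        for cat in CATEGORY_ORDER:
            for p in design.parts(cat):
                w.writerow([p.part_id, p.category, p.upstream_overhang, p.downstream_overhang, p.body_seq])
        w.writerow(["#flank_left", "meta", "", "", design.flank_left])
        w.writerow(["#flank_right", "meta", "", "", design.flank_right])
        w.writerow(["#barcode_length", "meta", "", "", str(design.barcode_length)])


def read_parts_tsv(path, flank_left: str | None = None, flank_right: str | None = None,
                   barcode_length: int | None = None) -> LibraryDesign:
    """Load a parts registry TSV (columns part_id, category, upstream_overhang,
    downstream_overhang, body_seq).  Flank sequences may come from ``#flank_*``
    metadata rows or be supplied by the caller (user-supplied priming sites
    override file metadata)."""
    parts: dict[str, list[Part]] = {c: [] for c in CATEGORIES}
    meta: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "part_id" not in reader.fieldnames:
            raise ValueError(f"parse error in {path}: missing header with part_id column")
        for i, row in enumerate(reader, start=2):
            pid = (row.get("part_id") or "").strip()
            if not pid:
                raise ValueError(f"parse error in {path} line {i}: empty part_id")
            if pid.startswith("#"):
                meta[pid.lstrip("#")] = row["body_seq"].strip()
                continue
            parts[row["category"]].append(
                Part(pid, row["category"], row["body_seq"].strip().upper(),
                     row["upstream_overhang"].strip().upper(), row["downstream_overhang"].strip().upper())
            )
    return LibraryDesign(
        parts_by_category=parts,
        flank_left=flank_left or meta.get("flank_left", ""),
        flank_right=flank_right or meta.get("flank_right", ""),
        barcode_length=barcode_length or int(meta.get("barcode_length", 20)),
    )
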