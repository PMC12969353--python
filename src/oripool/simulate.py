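"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* a combinatorial 4-part library with log-normally skewed barcode
  abundances and a high-copy origin whose members are disproportionately
  abundant in the pool;
* error-bearing long reads of the circular plasmids (random rotation and
  strand, per-base substitutions/indels, a small chimera rate);
* multinomial BarSeq counts: ~5,000 colony founders under host-specific
  origin fitness, serial liquid passages with a bottleneck, and a
  geometrically decaying donor-carryover term proportional to pool
  abundance;
* qPCR amplification curves (exponential phase saturating into a plateau)
  generated so that the delta-Ct/efficiency equations recover the true
  copy number at zero noise.

Everything is reproducible from (config, seed): the seed is recorded in
the GroundTruth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barseq import CountTable, SampleMeta
from .longread import STATUS_MAPPED, AssociationTable, LongRead
from .parts import (
    VARIABLE_CATEGORIES,
    AssembledPlasmid,
    LibraryDesign,
    Part,
    assemble_plasmid,
)
from .qpcr import AmplificationCurve

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: invented 20-nt priming sites flanking the N20 barcode (synthetic; the
#: real sites live in the prior barcoding literature and are user-supplied)
DEFAULT_FLANK_LEFT = "CAGTGAACTGGACTTCAGCA"
DEFAULT_FLANK_RIGHT = "TCCTGAAGTCGACCATGGAT"


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n).tobytes().decode()


def make_default_design(
    seed: int = 0,
    n_origins: int = 38,
    n_promoters: int = 10,
    n_resistance: int = 2,
    origin_len: int = 700,
    promoter_len: int = 200,
    resistance_len: int = 800,
    backbone_len: int = 2000,
    promoter_backbone_overlap: int = 160,
    barcode_length: int = 20,
) -> LibraryDesign:
    """Synthetic parts registry shaped like the screening library:
    38 origins x 10 promoters x 2 resistance CDSs on one barcoded backbone.

    One promoter variant shares a ``promoter_backbone_overlap``-nt block
    with the backbone, reproducing the confound in which that variant
    cannot be distinguished from backbone sequence.
    """
    rng = np.random.default_rng(seed)
    overhangs = []
    while len(overhangs) < 4:
        oh = _random_dna(rng, 4)
        if oh not in overhangs:
            overhangs.append(oh)
    o1, o2, o3, o4 = overhangs

    backbone_seq = _random_dna(rng, backbone_len)
    mid = backbone_len // 2
    backbone_seq = backbone_seq[:mid] + DEFAULT_FLANK_LEFT + DEFAULT_FLANK_RIGHT + backbone_seq[mid:]

    parts = {
        "origin": [
            Part(f"ori{i + 1:02d}", "origin", _random_dna(rng, origin_len), o4, o1)
            for i in range(n_origins)
        ],
        "promoter": [
            Part(f"P{i + 1:02d}", "promoter", _random_dna(rng, promoter_len), o1, o2)
            for i in range(n_promoters)
        ],
        "resistance": [
            Part(f"kanR{i + 1}", "resistance", _random_dna(rng, resistance_len), o2, o3)
            for i in range(n_resistance)
        ],
        "backbone": [Part("backbone", "backbone", backbone_seq, o3, o4)],
    }
    if promoter_backbone_overlap and n_promoters >= 4:
        # promoter variant 4 carries a backbone block (the part 2.4 confound)
        k = min(promoter_backbone_overlap, promoter_len - 20, backbone_len // 4)
        block = backbone_seq[100 : 100 + k]
        old = parts["promoter"][3]
        body = old.body_seq[:10] + block + old.body_seq[10 + k :]
        parts["promoter"][3] = Part(old.part_id, "promoter", body, o1, o2)
    return LibraryDesign(parts, DEFAULT_FLANK_LEFT, DEFAULT_FLANK_RIGHT, barcode_length)


@dataclass
class LibraryMember:
    barcode: str
    selection: dict[str, str]
    abundance: float

    @property
    def origin(self) -> str:
        return self.selection["origin"]


@dataclass
class GroundTruth:
    """Hidden state of a simulated experiment, for recovery tests."""

    library: list[LibraryMember]
    seed: int
    host_profiles: dict[str, dict[str, float]] = field(default_factory=dict)  # host -> origin -> w
    artifact_barcodes: dict[str, tuple[str, float]] = field(default_factory=dict)  # host -> (barcode, w)
    carryover_fraction: dict[str, float] = field(default_factory=dict)  # origin -> pool-share carryover
    true_copy_numbers: dict[str, float] = field(default_factory=dict)
    high_copy_origins: frozenset[str] = frozenset()
    w_neutral: float = 1.0

    def functional_origins(self, host: str) -> set[str]:
        return {o for o, w in self.host_profiles.get(host, {}).items() if w > self.w_neutral}

    def barcode_to_origin(self) -> dict[str, str]:
        return {m.barcode: m.origin for m in self.library}

    def origin_abundance(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for m in self.library:
            out[m.origin] = out.get(m.origin, 0.0) + m.abundance
        return out

    def association_table(self) -> AssociationTable:
        """The true barcode -> parts map in association-table form
        (as if deconvolution were perfect)."""
        rows = [
            {
                "barcode": m.barcode,
                "part1": m.selection["origin"],
                "part2": m.selection["promoter"],
                "part3": m.selection["resistance"],
                "support1": 2, "support2": 2, "support3": 2,
                "status": STATUS_MAPPED,
            }
            for m in sorted(self.library, key=lambda m: m.barcode)
        ]
        return AssociationTable(pd.DataFrame(rows, columns=list(AssociationTable.COLUMNS)))


def simulate_library(
    design: LibraryDesign,
    n_barcodes: int = 200,
    skew_sigma: float = 0.5,
    high_copy_origins: set[str] | None = None,
    boost: float = 10.0,
    seed: int = 0,
) -> tuple[list[AssembledPlasmid], GroundTruth]:
    """Draw a barcoded library: unique random N20s, uniformly random part
    selections, log-normal(0, sigma) abundances with a ``boost`` factor on
    members of high-copy origins (then renormalized)."""
    if n_barcodes < 1:
        raise ValueError("n_barcodes must be >= 1")
    rng = np.random.default_rng(seed)
    if high_copy_origins is None:
        high_copy_origins = {design.parts("origin")[0].part_id}

    barcodes: set[str] = set()
    attempts = 0
    while len(barcodes) < n_barcodes:
        attempts += 1
        if attempts > 100 * n_barcodes:
            raise RuntimeError("barcode collision rate too high; n_barcodes too large for length")
        barcodes.add(_random_dna(rng, design.barcode_length))
    barcode_list = sorted(barcodes)
    rng.shuffle(barcode_list)

    ids = {cat: [p.part_id for p in design.parts(cat)] for cat in VARIABLE_CATEGORIES}
    members: list[LibraryMember] = []
    plasmids: list[AssembledPlasmid] = []
    raw = rng.lognormal(mean=0.0, sigma=skew_sigma, size=n_barcodes)
    for i, bc in enumerate(barcode_list):
        selection = {cat: ids[cat][rng.integers(len(ids[cat]))] for cat in VARIABLE_CATEGORIES}
        w = raw[i] * (boost if selection["origin"] in high_copy_origins else 1.0)
        members.append(LibraryMember(bc, selection, w))
        plasmids.append(assemble_plasmid(design, selection, bc, plasmid_id=f"pl{i:05d}"))
    total = sum(m.abundance for m in members)
    for m in members:
        m.abundance /= total
    truth = GroundTruth(library=members, seed=seed, high_copy_origins=frozenset(high_copy_origins))
    return plasmids, truth


def assign_host_profiles(
    truth: GroundTruth,
    hosts=("hostA", "hostB"),
    n_functional: int = 4,
    w_range: tuple[float, float] = (1.2, 2.0),
    artifact_w: float = 2.5,
    carryover_c0: float = 0.02,
    min_barcodes: int = 5,
    seed: int = 0,
) -> GroundTruth:
    """Attach host-specific fitness profiles and planted artifacts.

    Per host, ``n_functional`` origins with at least ``min_barcodes``
    library members (excluding the high-copy/carryover origins) get a
    fitness advantage w > 1; every other origin is nonfunctional (w = 0).
    One barcode of a nonfunctional low-diversity origin is planted as a
    single-barcode artifact with fitness ``artifact_w`` (a hitchhiker
    behaving like a functional replicon).  Per-origin carryover fractions
    are ``carryover_c0`` times the origin's pool share.
    """
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for m in truth.library:
        counts[m.origin] = counts.get(m.origin, 0) + 1
    eligible = sorted(
        o for o, n in counts.items() if n >= min_barcodes and o not in truth.high_copy_origins
    )
    if len(eligible) < n_functional:
        raise ValueError("library too small: not enough origins with the required barcode diversity")
    for host in hosts:
        chosen = sorted(rng.choice(eligible, size=n_functional, replace=False))
        ws = rng.uniform(*w_range, size=n_functional)
        profile = {o: 0.0 for o in counts}
        profile.update(dict(zip(chosen, ws)))
        truth.host_profiles[host] = profile
        # artifact: one barcode of a nonfunctional non-boosted low-diversity
        # origin behaves like a functional replicon (a mis-associated
        # hitchhiker).  The plant must be a barcode abundant enough to show
        # up under selection -- that detectability is what defines the
        # phenomenon -- so among the lowest-diversity eligible origins the
        # one with the most abundant top barcode is used.
        candidates = [
            o for o in sorted(counts)
            if o not in chosen and o not in truth.high_copy_origins and counts[o] >= 1
        ]
        top_member = {
            o: max((m.abundance for m in truth.library if m.origin == o), default=0.0)
            for o in candidates
        }
        fewest = min(counts[o] for o in candidates)
        low_diversity = [o for o in candidates if counts[o] <= fewest + 1]
        art_origin = max(low_diversity, key=lambda o: (top_member[o], o))
        art_members = [m for m in truth.library if m.origin == art_origin]
        art_bc = max(art_members, key=lambda m: m.abundance).barcode
        truth.artifact_barcodes[host] = (art_bc, artifact_w)
    abund = truth.origin_abundance()
    truth.carryover_fraction = {o: carryover_c0 * a for o, a in abund.items()}
    return truth


def make_ground_truth(
    design: LibraryDesign | None = None,
    n_barcodes: int = 200,
    hosts=("hostA", "hostB"),
    seed: int = 0,
    profile_kwargs: dict | None = None,
    **library_kwargs,
) -> tuple[LibraryDesign, list[AssembledPlasmid], GroundTruth]:
    """Convenience: default design -> library -> host profiles."""
    if design is None:
        design = make_default_design(seed=seed)
    plasmids, truth = simulate_library(design, n_barcodes=n_barcodes, seed=seed, **library_kwargs)
    truth = assign_host_profiles(truth, hosts=hosts, seed=seed + 1, **(profile_kwargs or {}))
    return design, plasmids, truth


# ---------------------------------------------------------------------------
# long reads

_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _IDX[_b] = _i


def mutate_sequence(seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    """Apply per-base substitutions and indels (half insertions, half
    deletions; inserted bases are random)."""
    idx = _IDX[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    n = len(idx)
    sub_mask = rng.random(n) < sub_rate
    idx[sub_mask] = (idx[sub_mask] + rng.integers(1, 4, size=int(sub_mask.sum()))) % 4
    r = rng.random(n)
    reps = np.ones(n, dtype=np.int64)
    reps[r < indel_rate / 2] = 0  # deletion
    reps[(r >= indel_rate / 2) & (r < indel_rate)] = 2  # insertion
    out_src = np.repeat(np.arange(n), reps)
    out = idx[out_src]
    inserted = np.nonzero(np.diff(out_src) == 0)[0] + 1
    if len(inserted):
        out[inserted] = rng.integers(0, 4, size=len(inserted))
    return _BASES[out].tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_long_reads(
    plasmids: list[AssembledPlasmid],
    truth: GroundTruth,
    depth_per_barcode: float = 10.0,
    sub_rate: float = 0.01,
    indel_rate: float = 0.005,
    chimera_rate: float = 0.02,
    seed: int = 0,
    weight_by_abundance: bool = False,
) -> list[LongRead]:
    """Whole-plasmid long reads of the pool.

    Each read takes the full circular sequence at a uniform random
    rotation and strand and applies per-base errors; with probability
    ``chimera_rate`` the first half is spliced onto the second half of a
    different plasmid.  By default each barcode receives Poisson(depth)
    reads; with ``weight_by_abundance`` the same expected total is
    allocated proportionally to pool abundance instead.
    """
    if not (0.0 <= sub_rate <= 0.2 and 0.0 <= indel_rate <= 0.2 and 0.0 <= chimera_rate <= 1.0):
        raise ValueError("substitution/indel rates must be in [0, 0.2], chimera rate in [0, 1]")
    rng = np.random.default_rng(seed)
    by_barcode = {p.barcode: p for p in plasmids}
    members = [m for m in truth.library if m.barcode in by_barcode]
    if weight_by_abundance:
        total = rng.poisson(depth_per_barcode * len(members))
        probs = np.array([m.abundance for m in members])
        counts = rng.multinomial(total, probs / probs.sum())
    else:
        counts = rng.poisson(depth_per_barcode, size=len(members))

    reads: list[LongRead] = []
    k = 0
    for m, c in zip(members, counts):
        seq = by_barcode[m.barcode].sequence
        for _ in range(int(c)):
            rot = int(rng.integers(len(seq)))
            template = seq[rot:] + seq[:rot]
            source = m.barcode
            if rng.random() < chimera_rate and len(plasmids) > 1:
                other = plasmids[int(rng.integers(len(plasmids)))]
                if other.barcode != m.barcode:
                    orot = int(rng.integers(len(other.sequence)))
                    oseq = other.sequence[orot:] + other.sequence[:orot]
                    template = template[: len(template) // 2] + oseq[len(oseq) // 2 :]
                    source = f"{m.barcode}|chimera:{other.barcode}"
            if rng.random() < 0.5:
                template = _revcomp(template)
            mutated = mutate_sequence(template, sub_rate, indel_rate, rng)
            reads.append(LongRead(f"read{k:07d}", mutated, source=source))
            k += 1
    return reads


def write_fastq(reads: list[LongRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# BarSeq counts


def simulate_barseq(
    truth: GroundTruth,
    hosts=None,
    n_colonies: int = 5000,
    reads_per_sample: int = 100_000,
    passages: int = 4,
    bottleneck_size: int = 100_000,
    carryover_decay: float = 0.3,
    seed: int = 0,
) -> CountTable:
    """Multinomial BarSeq counts for plate, plate-outgrowth and four
    liquid-passage samples per host.

    Founders (~5,000 colonies) are drawn multinomially from the viable
    members (functional origin in the host, or a planted artifact);
    liquid passages update frequencies by p <- p*w / sum(p*w) with a
    binomial bottleneck.  A carryover term proportional to pool abundance
    decays geometrically (rate ``carryover_decay`` per passage) and is
    the only route by which nonfunctional-origin barcodes persist.
    Column sums equal ``reads_per_sample`` exactly.
    """
    rng = np.random.default_rng(seed)
    hosts = list(hosts) if hosts is not None else sorted(truth.host_profiles)
    members = truth.library
    abund = np.array([m.abundance for m in members])
    abund = abund / abund.sum()
    barcodes = [m.barcode for m in members]
    origin_carryover = truth.carryover_fraction or {}
    abund_by_origin = truth.origin_abundance()
    # per-barcode carryover weight: the origin-level carryover fraction
    # split proportionally to member abundance
    c_bc = np.array(
        [
            origin_carryover.get(m.origin, 0.0) * (m.abundance / abund_by_origin[m.origin])
            for m in members
        ]
    )
    c0 = float(c_bc.sum())
    c_shape = c_bc / c0 if c0 > 0 else np.zeros_like(c_bc)
    retention = 1.0 - carryover_decay

    rows = []
    samples: dict[str, SampleMeta] = {}

    def emit(sample_id: str, meta: SampleMeta, viable_freq: np.ndarray, t: int) -> None:
        ct = c0 * retention**t
        mix = (1.0 - ct) * viable_freq + ct * c_shape
        counts = rng.multinomial(reads_per_sample, mix / mix.sum())
        for bc, n in zip(barcodes, counts):
            if n > 0:
                rows.append({"sample_id": sample_id, "barcode": bc, "count": int(n)})
        samples[sample_id] = meta

    for host in hosts:
        profile = truth.host_profiles[host]
        w = np.array([profile.get(m.origin, 0.0) for m in members])
        art = truth.artifact_barcodes.get(host)
        if art is not None:
            art_bc, art_w = art
            w[barcodes.index(art_bc)] = art_w
        viable_p = abund * (w > 0)
        if viable_p.sum() <= 0:
            raise ValueError(f"host {host}: no viable founders (all selection probabilities zero)")
        viable_p = viable_p / viable_p.sum()

        founders = rng.multinomial(n_colonies, viable_p)
        emit(f"{host}_plate", SampleMeta(f"{host}_plate", host, "plate"), founders / n_colonies, 0)

        grown = founders * w
        emit(
            f"{host}_outgrowth",
            SampleMeta(f"{host}_outgrowth", host, "plate_outgrowth"),
            grown / grown.sum(),
            1,
        )

        liquid_founders = rng.multinomial(n_colonies, viable_p)
        pop = liquid_founders.astype(float)
        for t in range(1, passages + 1):
            sel = pop * w
            sel_freq = sel / sel.sum()
            pop = rng.multinomial(bottleneck_size, sel_freq).astype(float)
            emit(
                f"{host}_T{t}",
                SampleMeta(f"{host}_T{t}", host, "liquid", timepoint=t),
                pop / pop.sum(),
                t,
            )

    return CountTable(pd.DataFrame(rows, columns=["sample_id", "barcode", "count"]), samples)


# ---------------------------------------------------------------------------
# qPCR curves


def simulate_qpcr(
    true_cn: float,
    a_gdna: float = 2.0,
    a_plasmid: float = 2.0,
    f0_gdna: float = 0.002,
    plateau: float = 10000.0,
    ct_noise_sd: float = 0.15,
    cycles: int = 40,
    seed: int = 0,
    sample: str = "sample",
    n_replicates: int = 3,
    dilutions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125),
    n_tech: int = 3,
    baseline: float = 50.0,
    baseline_sd: float = 0.5,
    mult_noise: float = 0.01,
    threshold: float = 1000.0,
) -> list[AmplificationCurve]:
    """Paired gDNA/plasmid amplification curves for one colony sample
    (default: 3 biological replicates x 4 dilutions, reactions in
    technical triplicate).

    Curves grow exponentially at the primer pair's per-cycle factor and
    saturate logistically at ``plateau``.  When the two primer pairs have
    different efficiencies a delta-Ct is threshold-dependent, so curves
    are anchored to ``threshold``: at zero noise the efficiency-corrected
    delta-Ct pipeline recovers ``true_cn`` exactly there.  Ct jitter is
    injected as an F0 perturbation of ``ct_noise_sd`` cycles per well.
    """
    if not true_cn > 0:
        raise ValueError("true_cn must be positive")
    for a in (a_gdna, a_plasmid):
        if not (1.0 < a <= 2.2):
            raise ValueError(f"amplification factor {a} outside (1, 2.2]")
    rng = np.random.default_rng(seed)
    n = np.arange(1, cycles + 1, dtype=float)
    curves: list[AmplificationCurve] = []
    for rep in range(1, n_replicates + 1):
        for dil in dilutions:
            ct_g_ideal = float(np.log(threshold / (f0_gdna * dil)) / np.log(a_gdna))
            ct_p_ideal = ct_g_ideal - float(np.log2(true_cn * a_plasmid / a_gdna))
            dlabel = "1" if dil == 1.0 else f"1/{round(1 / dil)}"
            for tech in range(1, n_tech + 1):
                for target, a, ct_ideal in (
                    ("gDNA", a_gdna, ct_g_ideal),
                    ("plasmid", a_plasmid, ct_p_ideal),
                ):
                    ct = ct_ideal + rng.normal(0.0, ct_noise_sd)
                    f0 = threshold * a ** (-ct)
                    signal = plateau / (1.0 + ((plateau - f0) / f0) * a ** (-n))
                    obs = (
                        baseline
                        + signal * (1.0 + rng.normal(0.0, mult_noise, size=cycles))
                        + rng.normal(0.0, baseline_sd, size=cycles)
                    )
                    curves.append(
                        AmplificationCurve(
                            f"{sample}_r{rep}_d{dlabel.replace('/', '-')}_t{tech}_{target}",
                            target, sample, dlabel, rep, n.copy(), obs, tech_rep=tech,
                        )
                    )
    return curves


def simulate_colony_qpcr_dataset(
    true_copy_numbers: dict[str, float], seed: int = 0, **kwargs
) -> tuple[list[AmplificationCurve], GroundTruth]:
    """Full colony-qPCR dataset over several samples (one true copy number
    each); a synthetic stand-in for an instrument export."""
    curves: list[AmplificationCurve] = []
    for i, (sample, cn) in enumerate(sorted(true_copy_numbers.items())):
        curves.extend(simulate_qpcr(cn, seed=seed + i, sample=sample, **kwargs))
    truth = GroundTruth(library=[], seed=seed, true_copy_numbers=dict(true_copy_numbers))
    return curves, truth
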