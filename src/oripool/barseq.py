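"""BarSeq enrichment analysis and origin classification.

Per-sample barcode counts (one sample = host x selection mode x timepoint)
are filtered at a minimum count, joined to the barcode -> origin map, and
summarized as per-origin count fractions and unique-barcode diversity --
the quantities behind the screening heatmap.  Classification then labels
each (origin, host) pair:

* ``functional`` -- several distinct barcodes of the origin jointly reach a
  high count fraction in a plate-mode sample, or in a liquid sample whose
  time series is not strictly declining.  Plate evidence stands on its own:
  in serial liquid passage every origin except the fittest declines in
  relative terms, so a liquid decline must not veto plate-based evidence
  (an origin can be functional yet outcompeted in liquid).
* ``artifact_single_barcode`` -- a high fraction driven by exactly one
  barcode in every sample where the origin is enriched.
* ``carryover`` -- fractions that stay low and strictly decline over the
  liquid series, for an origin that is highly abundant in the donor pool:
  residual donor-strain plasmid rather than replication in the recipient.
* ``not_detected`` -- everything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

SELECTION_MODES = ("plate", "plate_outgrowth", "liquid")
PLATE_MODES = ("plate", "plate_outgrowth")

CALL_FUNCTIONAL = "functional"
CALL_CARRYOVER = "carryover"
CALL_ARTIFACT = "artifact_single_barcode"
CALL_NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one BarSeq sample.  Liquid timepoints 1-4 correspond to
    24/48/72/96 h of serial outgrowth; plate-derived samples have none."""

    sample_id: str
    host: str
    selection: str
    timepoint: int | None = None

    def __post_init__(self) -> None:
        if self.selection not in SELECTION_MODES:
            raise ValueError(f"unknown selection mode {self.selection!r}")
        if self.selection == "liquid":
            if self.timepoint not in (1, 2, 3, 4):
                raise ValueError("liquid samples need timepoint in {1,2,3,4}")
        elif self.timepoint is not None:
            raise ValueError("plate-derived samples must not carry a timepoint")


@dataclass
class CountTable:
    """Long-format per-sample barcode counts with attached sample metadata."""

    df: pd.DataFrame  # columns: sample_id, barcode, count
    samples: dict[str, SampleMeta]

    def __post_init__(self) -> None:
        if len(self.df):
            if (self.df["count"] < 0).any():
                raise ValueError("counts must be non-negative")
            if self.df.duplicated(["sample_id", "barcode"]).any():
                raise ValueError("(sample_id, barcode) must be unique")

    def to_tsv(self, counts_path, samples_path=None) -> None:
        self.df.to_csv(counts_path, sep="\t", index=False)
        if samples_path is not None:
            rows = [
                {"sample_id": m.sample_id, "host": m.host, "selection": m.selection,
                 "timepoint": "" if m.timepoint is None else m.timepoint}
                for m in self.samples.values()
            ]
            pd.DataFrame(rows).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountTable":
        df = pd.read_csv(counts_path, sep="\t", dtype={"barcode": str})
        sdf = pd.read_csv(samples_path, sep="\t")
        samples = {}
        for _, r in sdf.iterrows():
            tp = r.get("timepoint")
            tp = None if pd.isna(tp) or tp == "" else int(tp)
            samples[str(r["sample_id"])] = SampleMeta(str(r["sample_id"]), str(r["host"]), str(r["selection"]), tp)
        return cls(df, samples)


def filter_counts(table: CountTable, min_count: int = 6) -> tuple[CountTable, pd.Series]:
    """Drop rows with count < min_count ("below 6" boundary: 5 removed, 6 kept).

    Returns the filtered table and the per-sample retained fraction of the
    total counts.  Idempotent by construction.
    """
    df = table.df
    totals = df.groupby("sample_id")["count"].sum()
    kept = df[df["count"] >= min_count].reset_index(drop=True)
    kept_totals = kept.groupby("sample_id")["count"].sum()
    retained = (kept_totals.reindex(totals.index, fill_value=0) / totals).astype(float)
    retained.name = "retained_fraction"
    for sid, frac in retained.items():
        if frac == 0.0:
            warnings.warn(f"sample {sid} is empty after filtering (retained_fraction 0)")
    return CountTable(kept, table.samples), retained


@dataclass
class EnrichmentMatrix:
    """Per (origin, sample) count fraction and unique-barcode diversity.

    ``fraction`` uses all filtered counts of the sample as denominator,
    including barcodes absent from the association map; those contribute
    to ``unmapped_fraction`` so that per-sample fractions plus the
    unmapped fraction sum to 1.
    """

    df: pd.DataFrame  # columns: origin, sample_id, fraction, n_barcodes
    unmapped_fraction: pd.Series  # index sample_id
    samples: dict[str, SampleMeta]
    retained_fraction: pd.Series | None = None

    def fraction(self, origin: str, sample_id: str) -> float:
        m = self.df[(self.df["origin"] == origin) & (self.df["sample_id"] == sample_id)]
        return float(m["fraction"].iloc[0]) if len(m) else 0.0

    def n_barcodes(self, origin: str, sample_id: str) -> int:
        m = self.df[(self.df["origin"] == origin) & (self.df["sample_id"] == sample_id)]
        return int(m["n_barcodes"].iloc[0]) if len(m) else 0

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, samples: dict[str, SampleMeta] | None = None) -> "EnrichmentMatrix":
        df = pd.read_csv(path, sep="\t")
        totals = df.groupby("sample_id")["fraction"].sum()
        return cls(df, (1.0 - totals).clip(lower=0.0), samples or {})


def origin_enrichment(filtered: CountTable, assoc) -> EnrichmentMatrix:
    """Join filtered counts to the barcode -> origin map and compute, per
    sample, each origin's count fraction and number of distinct detected
    barcodes."""
    bc2origin = assoc.barcode_to_origin() if not isinstance(assoc, dict) else assoc
    df = filtered.df.copy()
    df["origin"] = df["barcode"].map(bc2origin)
    totals = df.groupby("sample_id")["count"].sum().astype(float)

    mapped = df.dropna(subset=["origin"])
    grouped = (
        mapped.groupby(["origin", "sample_id"])
        .agg(count=("count", "sum"), n_barcodes=("barcode", "nunique"), top=("count", "max"))
        .reset_index()
    )
    grouped["fraction"] = grouped["count"] / grouped["sample_id"].map(totals)
    # share of the origin's counts carried by its single biggest barcode:
    # ~1 flags single-barcode enrichment (association artifacts)
    grouped["top_barcode_share"] = grouped["top"] / grouped["count"]

    # all mapped origins x all samples, zero-filled, for stable layout
    origins = sorted(set(bc2origin.values()))
    sample_ids = list(totals.index)
    full = pd.MultiIndex.from_product([origins, sample_ids], names=["origin", "sample_id"])
    out = (
        grouped.set_index(["origin", "sample_id"])[["fraction", "n_barcodes", "top_barcode_share"]]
        .reindex(full, fill_value=0)
        .reset_index()
    )
    out["n_barcodes"] = out["n_barcodes"].astype(int)

    mapped_totals = mapped.groupby("sample_id")["count"].sum().reindex(totals.index, fill_value=0)
    unmapped = 1.0 - mapped_totals / totals
    unmapped.name = "unmapped_fraction"
    return EnrichmentMatrix(out, unmapped, filtered.samples)


def strictly_declining(series) -> bool | None:
    """True iff each successive value is strictly smaller; None (abstain)
    with fewer than 3 points."""
    vals = list(series)
    if len(vals) < 3:
        return None
    return all(b < a for a, b in zip(vals, vals[1:]))


@dataclass
class ClassifierParams:
    min_fraction: float = 0.05
    min_diversity: int = 2
    abundance_quantile: float = 0.75  # top quartile of pool abundance
    #: an enrichment is a single-barcode artifact when one barcode carries
    #: at least this share of the origin's counts in every enriched sample
    artifact_dominance: float = 0.90


@dataclass
class OriginCall:
    origin: str
    host: str
    call: str
    evidence: dict = field(default_factory=dict)
    partial_evidence: bool = False


def classify_origins(
    matrix: EnrichmentMatrix,
    pool_abundance,
    params: ClassifierParams | None = None,
) -> list[OriginCall]:
    """Call each (origin, host) functional / carryover / single-barcode
    artifact / not detected.

    ``pool_abundance`` maps origin -> abundance in the donor pool (any
    consistent measure; the pipeline passes total supporting-read mass
    from the association summary).  Hosts are classified independently.
    Hosts without a liquid series (or with < 3 timepoints) get calls on
    plate evidence alone, flagged ``partial_evidence``.
    """
    params = params or ClassifierParams()
    if hasattr(pool_abundance, "items"):
        abundance = dict(pool_abundance.items())
    else:
        abundance = dict(pool_abundance)
    origins = sorted(set(matrix.df["origin"]))
    hosts = sorted({m.host for m in matrix.samples.values()})
    abundances = pd.Series({o: float(abundance.get(o, 0.0)) for o in origins})
    cutoff = abundances.quantile(params.abundance_quantile) if len(abundances) else 0.0

    calls = []
    for host in hosts:
        host_samples = [m for m in matrix.samples.values() if m.host == host]
        plate = [m for m in host_samples if m.selection in PLATE_MODES]
        liquid = sorted(
            (m for m in host_samples if m.selection == "liquid"), key=lambda m: m.timepoint
        )
        if not plate or not liquid:
            warnings.warn(f"host {host}: missing plate-mode or liquid samples; partial-evidence calls")
        sub = matrix.df
        dom_lookup = {
            (o, s): d
            for o, s, d in zip(sub["origin"], sub["sample_id"], sub.get("top_barcode_share", pd.Series(dtype=float)))
        }
        for origin in origins:
            frac = {m.sample_id: matrix.fraction(origin, m.sample_id) for m in host_samples}
            nbar = {m.sample_id: matrix.n_barcodes(origin, m.sample_id) for m in host_samples}
            dom = {m.sample_id: float(dom_lookup.get((origin, m.sample_id), 0.0)) for m in host_samples}
            liquid_series = [frac[m.sample_id] for m in liquid]
            decline = strictly_declining(liquid_series)
            partial = not plate or decline is None

            enriched = [m for m in host_samples if frac[m.sample_id] >= params.min_fraction]
            plate_evidence = any(
                frac[m.sample_id] >= params.min_fraction and nbar[m.sample_id] >= params.min_diversity
                for m in plate
            )
            liquid_evidence = decline is not True and any(
                frac[m.sample_id] >= params.min_fraction and nbar[m.sample_id] >= params.min_diversity
                for m in liquid
            )
            max_frac = max(frac.values(), default=0.0)
            top_abundance = len(abundances) > 0 and abundances.get(origin, 0.0) >= cutoff

            single_barcode = bool(enriched) and all(
                nbar[m.sample_id] == 1 or dom[m.sample_id] >= params.artifact_dominance
                for m in enriched
            )
            if single_barcode:
                call = CALL_ARTIFACT
            elif plate_evidence or liquid_evidence:
                call = CALL_FUNCTIONAL
            elif max_frac < params.min_fraction and decline is True and top_abundance:
                call = CALL_CARRYOVER
            else:
                call = CALL_NOT_DETECTED

            calls.append(
                OriginCall(
                    origin,
                    host,
                    call,
                    evidence={
                        "max_plate_fraction": max((frac[m.sample_id] for m in plate), default=0.0),
                        "max_liquid_fraction": max(liquid_series, default=0.0),
                        "max_diversity": max(nbar.values(), default=0),
                        "max_enriched_dominance": max(
                            (dom[m.sample_id] for m in enriched), default=0.0
                        ),
                        "liquid_strictly_declining": decline,
                        "pool_abundance": abundances.get(origin, 0.0),
                        "top_quartile_abundance": bool(top_abundance),
                    },
                    partial_evidence=partial,
                )
            )
    return calls


def calls_to_frame(calls: list[OriginCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"origin": c.origin, "host": c.host, "call": c.call, "partial_evidence": c.partial_evidence}
        row.update(c.evidence)
        rows.append(row)
    return pd.DataFrame(rows)


def render_matrix(
    matrix: EnrichmentMatrix,
    calls: list[OriginCall] | None,
    path,
    predicted_origins: set[str] | None = None,
    heatmap_path=None,
) -> pd.DataFrame:
    """Write the fraction/diversity matrix as TSV (origins ordered by name),
    flagging predicted origins and attaching host-level calls; optionally
    render a heatmap figure."""
    df = matrix.df.sort_values(["origin", "sample_id"], ignore_index=True).copy()
    df["predicted_origin"] = df["origin"].isin(predicted_origins or set())
    if calls:
        call_map = {(c.origin, c.host): c.call for c in calls}
        hosts = {sid: m.host for sid, m in matrix.samples.items()}
        df["call"] = [
            call_map.get((o, hosts.get(s, "")), "") for o, s in zip(df["origin"], df["sample_id"])
        ]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if heatmap_path is not None:
        _render_heatmap(matrix, heatmap_path)
    return df


def _render_heatmap(matrix: EnrichmentMatrix, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = matrix.df.pivot(index="origin", columns="sample_id", values="fraction")
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(pivot.columns)), max(4, 0.18 * len(pivot))))
    im = ax.imshow(pivot.values, aspect="auto", cmap="viridis", vmin=0.0)
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="fraction of barcode counts")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
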