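"""Relative plasmid copy number from colony qPCR.

The copy number of a plasmid per genome copy is estimated from the
quantification-cycle difference between a plasmid amplicon and a
single-copy chromosomal amplicon,

    CN         = 2 ** -(Ct_plasmid - Ct_gDNA)
    CN_adjusted = CN * (E_gDNA / E_plasmid)

where E is the per-cycle amplification factor of each primer pair
(perfect doubling: E = 2), estimated per well from the exponential phase
of the raw fluorescence curve by log-linear regression.  E here is the
multiplication factor per cycle, not a percent efficiency; this keeps the
ratio correction dimensionally coherent with the base-2 delta-Ct term.

A colony experiment pairs plasmid and gDNA wells within each (biological
replicate, dilution) stratum -- technical triplicates are averaged first
-- and aggregates the per-pairing adjusted copy numbers into median,
quartiles, mean, SD and a nearest-integer estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TARGET_GDNA = "gDNA"
TARGET_PLASMID = "plasmid"


class NoAmplificationError(ValueError):
    """Fluorescence never crosses the quantification threshold."""


class InvalidThresholdError(ValueError):
    """Threshold at or below the starting (baseline) fluorescence."""


class InsufficientExponentialPhaseError(ValueError):
    """Fewer than the minimum number of usable exponential-phase points."""


@dataclass
class AmplificationCurve:
    """Raw per-cycle fluorescence of one well."""

    well_id: str
    target: str  # gDNA | plasmid
    sample: str
    dilution: str  # "1", "1/2", "1/4", "1/8", ...
    replicate: int
    cycles: np.ndarray
    values: np.ndarray
    tech_rep: int = 1

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.cycles) != len(self.values):
            raise ValueError("cycles and values must have equal length")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycles must be strictly increasing")


@dataclass
class WellRecord:
    well_id: str
    target: str
    sample: str
    dilution: str
    replicate: int
    ct: float
    efficiency: float
    tech_rep: int = 1

    def __post_init__(self) -> None:
        if not self.ct > 0:
            raise ValueError("Ct must be positive")
        if not (1.0 < self.efficiency <= 2.2):
            raise ValueError(f"amplification factor {self.efficiency} outside (1, 2.2]")


@dataclass
class EfficiencyFit:
    efficiency: float
    window: tuple[int, int]  # [start, end) indices into the curve
    r_squared: float
    low_confidence: bool


@dataclass
class CopyNumberEstimate:
    """Aggregated relative copy number for one sample.

    ``sd`` is across all pairings; ``sd_replicates`` across per-biological-
    replicate means (both are reported because a figure-style spread may
    refer to either).
    """

    sample: str
    values: pd.DataFrame  # one row per (replicate, dilution) pairing
    median: float
    q1: float
    q3: float
    mean: float
    sd: float
    sd_replicates: float
    rounded: int
    n_pairings: int
    degenerate: bool = False  # single pairing: SD reported as 0
    flags: list[str] = field(default_factory=list)


def copy_number_raw(ct_plasmid: float, ct_gdna: float) -> float:
    """CN = 2^-(Ct_plasmid - Ct_gDNA); equal Cts give 1 copy per genome."""
    if not (math.isfinite(ct_plasmid) and math.isfinite(ct_gdna)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_plasmid - ct_gdna))


def copy_number_adjusted(cn: float, a_gdna: float, a_plasmid: float) -> float:
    """Efficiency-corrected copy number: CN * (E_gDNA / E_plasmid)."""
    for a in (a_gdna, a_plasmid):
        if not (1.0 < a <= 2.2):
            raise ValueError(f"amplification factor {a} outside (1, 2.2]")
    return cn * (a_gdna / a_plasmid)


def compute_ct(curve: AmplificationCurve, threshold: float) -> float:
    """Fractional cycle of the first threshold crossing, by linear
    interpolation between the bracketing cycles."""
    v, c = curve.values, curve.cycles
    if threshold <= v[0]:
        raise InvalidThresholdError(
            f"threshold {threshold} not above starting fluorescence {v[0]:.3g}"
        )
    above = np.nonzero(v >= threshold)[0]
    if len(above) == 0:
        raise NoAmplificationError(f"well {curve.well_id}: curve never crosses {threshold}")
    i = int(above[0])
    frac = (threshold - v[i - 1]) / (v[i] - v[i - 1])
    return float(c[i - 1] + frac * (c[i] - c[i - 1]))


def _baseline(values: np.ndarray, n_baseline: int = 5) -> tuple[float, float]:
    """Estimate baseline level and noise from the first cycles.

    If the early cycles already show clear growth (no flat baseline, e.g.
    a pure exponential trace), the baseline is taken as zero.
    """
    head = values[:n_baseline]
    lo = max(float(head[0]), 1e-12)
    if float(head[-1]) / lo > 2.0:
        return 0.0, 0.0
    return float(np.median(head)), float(np.std(head))


def estimate_efficiency(
    curve: AmplificationCurve,
    n_baseline: int = 5,
    max_window: int = 6,
    min_window: int = 4,
    takeoff_fraction: float = 0.001,
    bend_fraction: float = 0.25,
    r2_warn: float = 0.98,
) -> EfficiencyFit:
    """Per-well amplification factor from the exponential phase.

    The window opens at the first baseline-subtracted point exceeding
    max(3 x baseline SD, ``takeoff_fraction`` of the dynamic range) and
    closes after ``max_window`` points or when fluorescence reaches
    ``bend_fraction`` of the curve maximum (onset of plateau curvature),
    whichever is first.  log(fluorescence) vs cycle is fit by least
    squares; the factor is exp(slope).  The window and R^2 are returned
    for auditability; R^2 below ``r2_warn`` sets a low-confidence flag.
    """
    if len(curve.values) < 10:
        raise InsufficientExponentialPhaseError("need >= 10 cycles for curve-based estimation")
    base, sd = _baseline(curve.values, n_baseline)
    f = curve.values - base
    span = float(np.max(f))
    if span <= 0:
        raise InsufficientExponentialPhaseError(f"well {curve.well_id}: flat curve")
    takeoff_level = max(3.0 * sd, takeoff_fraction * span)
    candidates = np.nonzero(f > takeoff_level)[0]
    if len(candidates) == 0:
        raise InsufficientExponentialPhaseError(f"well {curve.well_id}: no exponential takeoff")
    i0 = int(candidates[0])
    bend = np.nonzero(f >= bend_fraction * span)[0]
    i_end = int(bend[0]) if len(bend) else len(f)
    i_end = min(i_end, i0 + max_window)
    idx = np.arange(i0, i_end)
    idx = idx[f[idx] > 0]
    if len(idx) < min_window:
        raise InsufficientExponentialPhaseError(
            f"well {curve.well_id}: exponential window has {len(idx)} points (< {min_window})"
        )
    x = curve.cycles[idx]
    y = np.log(f[idx])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    a = float(np.exp(slope))
    return EfficiencyFit(a, (int(idx[0]), int(idx[-1]) + 1), r2, low_confidence=r2 < r2_warn)


def auto_threshold(curves: list[AmplificationCurve], fraction: float = 0.10) -> float:
    """Common quantification threshold for a plate: ``fraction`` of the
    median baseline-subtracted dynamic range."""
    spans = []
    for c in curves:
        base, _ = _baseline(c.values)
        spans.append(float(np.max(c.values) - base))
    return fraction * float(np.median(spans))


def wells_from_curves(
    curves: list[AmplificationCurve], threshold: float | str = "auto"
) -> tuple[pd.DataFrame, float]:
    """Reduce raw curves to per-well (Ct, efficiency) records.

    Ct is computed on the baseline-subtracted signal against a common
    plate threshold (so scaling all fluorescence rescales nothing that
    matters).  Returns the audit table and the threshold used.
    """
    thr = auto_threshold(curves) if threshold == "auto" else float(threshold)
    rows = []
    for c in curves:
        base, _ = _baseline(c.values)
        sub = AmplificationCurve(
            c.well_id, c.target, c.sample, c.dilution, c.replicate,
            c.cycles, c.values - base, tech_rep=c.tech_rep,
        )
        fit = estimate_efficiency(c)
        rows.append(
            {
                "well_id": c.well_id,
                "target": c.target,
                "sample": c.sample,
                "replicate": c.replicate,
                "dilution": c.dilution,
                "tech_rep": c.tech_rep,
                "ct": compute_ct(sub, thr),
                "efficiency": fit.efficiency,
                "eff_window_start": fit.window[0],
                "eff_window_end": fit.window[1],
                "eff_r2": fit.r_squared,
                "low_confidence": fit.low_confidence,
            }
        )
    return pd.DataFrame(rows), thr


def aggregate_copy_number(wells: pd.DataFrame) -> list[CopyNumberEstimate]:
    """Aggregate per-well Ct/efficiency into per-sample copy numbers.

    Technical replicates (rows sharing sample/replicate/dilution/target)
    are arithmetically averaged first; plasmid and gDNA are then paired
    within each (replicate, dilution) stratum.  Unpaired strata are
    excluded with a warning.  Quartiles use the linear-interpolation
    convention; the point estimate is the nearest integer of the mean.
    """
    required = {"target", "sample", "replicate", "dilution", "ct", "efficiency"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")

    averaged = (
        wells.groupby(["sample", "replicate", "dilution", "target"], as_index=False)
        .agg(ct=("ct", "mean"), efficiency=("efficiency", "mean"))
    )
    estimates = []
    for sample, sdf in averaged.groupby("sample"):
        pair_rows = []
        for (rep, dil), pdf in sdf.groupby(["replicate", "dilution"]):
            by_target = {t: r for t, r in zip(pdf["target"], pdf.itertuples())}
            if TARGET_GDNA not in by_target or TARGET_PLASMID not in by_target:
                warnings.warn(
                    f"sample {sample}, replicate {rep}, dilution {dil}: unpaired wells excluded"
                )
                continue
            g, p = by_target[TARGET_GDNA], by_target[TARGET_PLASMID]
            cn = copy_number_raw(p.ct, g.ct)
            cn_adj = copy_number_adjusted(cn, g.efficiency, p.efficiency)
            pair_rows.append(
                {
                    "sample": sample, "replicate": rep, "dilution": dil,
                    "ct_plasmid": p.ct, "ct_gdna": g.ct,
                    "eff_plasmid": p.efficiency, "eff_gdna": g.efficiency,
                    "cn": cn, "cn_adjusted": cn_adj,
                }
            )
        if not pair_rows:
            warnings.warn(f"sample {sample}: no complete plasmid/gDNA pairings")
            continue
        values = pd.DataFrame(pair_rows)
        v = values["cn_adjusted"].to_numpy()
        degenerate = len(v) == 1
        rep_means = values.groupby("replicate")["cn_adjusted"].mean().to_numpy()
        mean = float(np.mean(v))
        estimates.append(
            CopyNumberEstimate(
                sample=str(sample),
                values=values,
                median=float(np.median(v)),
                q1=float(np.percentile(v, 25)),
                q3=float(np.percentile(v, 75)),
                mean=mean,
                sd=0.0 if degenerate else float(np.std(v, ddof=1)),
                sd_replicates=0.0 if len(rep_means) < 2 else float(np.std(rep_means, ddof=1)),
                rounded=int(math.floor(mean + 0.5)),
                n_pairings=len(v),
                degenerate=degenerate,
                flags=["single_value_sd_undefined"] if degenerate else [],
            )
        )
    return estimates


def estimate_copy_number_from_curves(
    curves: list[AmplificationCurve], threshold: float | str = "auto"
) -> tuple[list[CopyNumberEstimate], pd.DataFrame]:
    """Full raw-curve entry path: curves -> per-well Ct/efficiency ->
    paired, efficiency-corrected, aggregated copy numbers."""
    wells, _ = wells_from_curves(curves, threshold)
    return aggregate_copy_number(wells), wells


def read_wells_csv(path) -> pd.DataFrame:
    """Instrument-export entry path: CSV with columns well_id, target,
    sample, replicate, dilution, Ct (or ct), efficiency."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() if c.strip().lower() in ("ct",) else c.strip() for c in df.columns]
    if "Ct" in df.columns:
        df = df.rename(columns={"Ct": "ct"})
    return df


def read_curves_csv(curves_path, annotation_path) -> list[AmplificationCurve]:
    """Raw-fluorescence entry path: long-format CSV (well_id, cycle, value)
    plus a well-annotation CSV (well_id, target, sample, replicate,
    dilution[, tech_rep])."""
    long_df = pd.read_csv(curves_path)
    ann = pd.read_csv(annotation_path).set_index("well_id")
    curves = []
    for well_id, wdf in long_df.groupby("well_id"):
        wdf = wdf.sort_values("cycle")
        if well_id not in ann.index:
            raise ValueError(f"well {well_id} has curves but no annotation")
        a = ann.loc[well_id]
        curves.append(
            AmplificationCurve(
                str(well_id), str(a["target"]), str(a["sample"]), str(a["dilution"]),
                int(a["replicate"]), wdf["cycle"].to_numpy(), wdf["value"].to_numpy(),
                tech_rep=int(a.get("tech_rep", 1)),
            )
        )
    return curves


def estimates_to_frame(estimates: list[CopyNumberEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": e.sample, "rounded": e.rounded, "mean": e.mean, "median": e.median,
                "q1": e.q1, "q3": e.q3, "sd": e.sd, "sd_replicates": e.sd_replicates,
                "n_pairings": e.n_pairings, "flags": ";".join(e.flags),
            }
            for e in estimates
        ]
    )
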