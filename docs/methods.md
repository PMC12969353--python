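# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, the assumptions of the synthetic-data generators, and
what passing the test suite does and does not establish about real data.

## Library model and in-silico assembly

Golden-gate junctions are modelled as abstract 4-nt overhang labels: a
selection of parts is assemblable iff the downstream overhang of each
part equals the upstream overhang of the next, around the circle
part1 → part2 → part3 → part4 → part1. Restriction chemistry (enzyme
site placement, digestion, ligation fidelity) is deliberately not
simulated: for deconvolution and screening the pipeline needs junction
validity and the final sequence, not enzymology. Each shared overhang
contributes its 4 nt exactly once, so assembled length is the sum of
part bodies plus 16 nt of junctions plus the barcode.

Circular sequences are canonicalized by rotating to the first base of
the left barcode-flanking priming site, which keeps barcode coordinates
stable (always `[len(flank_left), len(flank_left)+20)`); coordinates are
0-based half-open, and a feature crossing the rotation point is stored
with `end > len(sequence)` (written to GenBank as a joined
origin-spanning location). The priming-site sequences shipped with the
default registry are invented placeholders (the real sites belong to the
prior barcoding literature); every reader accepts user-supplied flanks.

## Long-read deconvolution

Barcode extraction finds both priming sites by edit-distance infix
alignment (edlib), allowing ≤ 2 edits per flank, on either strand;
the intervening segment must be exactly 20 nt (indel-shifted barcodes
are dropped, not corrected — no error-correction rule is assumed; a
length tolerance is exposed but defaults to 0). Reads with several
distinct candidate cassettes (e.g. chimeras) are discarded as ambiguous.

Part identification aligns each registry part body into the read
(oriented by the cassette when available) and accepts the best variant
per category at ≥ 90% identity over ≥ 90% of the body. Two passing
variants of one category at distinct, non-overlapping read loci are a
chimera signature: the read votes for neither. A part sharing a
≥ 100 nt block with the backbone at ≥ 90% identity cannot be
distinguished from backbone sequence, so its hits are flagged ambiguous
and the category reported unmapped; this confound is detected once per
registry (part-vs-backbone windows) and cached.

The association rules: support is the number of *distinct* reads
backing a (barcode, part) pair; a barcode is mapped when exactly one
part 1 reaches ≥ 2 supporting reads; a barcode with two supported
variants in any category is eliminated outright; part 2/part 3 may stay
unmapped on an otherwise mapped row. In addition, a barcode within edit
distance 1 of a strictly better-observed barcode is suppressed as a
sequencing-error phantom (`error_neighbor`). This guard is on by
default: at a 1% substitution rate and 10× coverage, roughly 3–4
single-substitution variants per 200 barcodes recur on two reads and
would otherwise satisfy the support rule, and random 20-mers essentially
never collide at distance 1, so the suppression costs no real barcodes.
Set `merge_near_duplicates=False` for strict exact-key behavior.

Identity thresholds (0.90/0.90) are declared defaults, config-exposed;
they are not derived from any published pipeline.

## BarSeq enrichment and classification

Counts below 6 are removed per sample; the per-sample retained fraction
of total counts is reported. Fractions use *all* filtered counts of the
sample as denominator (barcodes absent from the association map
contribute to an explicit unmapped fraction), so per-sample fractions
plus the unmapped fraction sum to 1 — the conservative choice, since
mapped fractions can only shrink; a mapped-only denominator is a
one-line change on the caller side. Diversity is the number of distinct
detected (post-filter) barcodes per origin per sample; the matrix also
records the share of each origin's counts carried by its single biggest
barcode.

Classification per (origin, host), in precedence order:

1. **artifact_single_barcode** — the origin reaches the enrichment
   threshold somewhere, and in every such sample a single barcode
   carries ≥ 90% of its counts (or the origin has exactly one detected
   barcode). Single-barcode enrichments indicate mis-associated or
   chimeric library members rather than a replicating origin.
2. **functional** — ≥ 2 barcodes jointly at fraction ≥ 0.05 in a
   plate-mode sample, or in a liquid sample whose series is not strictly
   declining. Plate evidence stands on its own: in serial passage every
   origin except the fittest declines in relative abundance, so a liquid
   decline is evidence about competition, not about replication ability,
   and must not veto plate-based evidence. The decline test only
   discounts liquid-only evidence.
3. **carryover** — fractions below 0.05 everywhere, strictly declining
   across the liquid timepoints, and the origin in the top quartile of
   donor-pool abundance. Both legs are required: the decline alone also
   matches rare noise, and high abundance alone also matches functional
   origins.
4. **not_detected** — everything else.

The decline test abstains with < 3 liquid timepoints, and calls made
without a full series carry a `partial_evidence` flag. `min_fraction`
(0.05) and `min_diversity` (2) are declared defaults: the diversity
requirement is qualitative in origin-screening practice and no numeric
fraction threshold is standard, so both are config-exposed. Pool
abundance may be supplied as mapped-barcode counts or (pipeline default)
total supporting-read mass per origin, which tracks pool abundance even
when barcode counts per origin are flat. Hosts are classified
independently; no multiple-testing correction is applied.

## Colony qPCR copy number

Quantification cycle (Ct) is the fractional cycle at which
baseline-subtracted fluorescence first crosses a common plate threshold
(default: 10% of the median dynamic range), interpolated linearly
between bracketing cycles. The baseline is the median of the first five
cycles; if those cycles already show clear growth the curve is treated
as pre-subtracted. Both Ct and the efficiency estimate are invariant to
rescaling all fluorescence values (with the threshold rescaled equally).

Per-well amplification efficiency is the per-cycle multiplication
factor `A = exp(slope)` of a least-squares fit of log fluorescence vs
cycle over the exponential phase. The window opens at the first point
exceeding max(3 × baseline SD, 0.1% of the dynamic range) — the floor
matters because at instrument-scale additive noise the 3-SD point sits
where relative noise is tens of percent — and closes after at most 6
points or at 25% of the curve maximum (onset of plateau curvature),
whichever comes first; fewer than 4 usable points is an error, and
R² < 0.98 sets a low-confidence flag. Window bounds and R² are reported
per well for audit. `E` in the correction formula is this factor, not a
percent efficiency, which keeps `CN × (E_gDNA/E_plasmid)`
dimensionally coherent with the base-2 ΔCt term.

Aggregation: technical triplicate Cts (and efficiencies) are
arithmetically averaged first; plasmid/gDNA wells are paired within each
(biological replicate, dilution) stratum; dilutions are treated as
independent estimates of the same ratio (ΔCt is dilution-invariant in
expectation), so no dilution-series regression is fitted. Summaries use
linear-interpolation quartiles, the sample SD over all pairings and over
per-replicate means (a published ± spread may refer to either), and a
nearest-integer point estimate of the mean. A single pairing reports
SD 0 with a degenerate flag; unpaired strata are excluded with a
warning.

## Synthetic-data generators

The generators encode the qualitative structure the analysis assumes,
with defaults fixed once:

* **Library** — unique random N20 barcodes, uniformly random part
  selections, log-normal(0, σ = 0.5) abundances. σ = 0.5 reflects the
  modest skew of a pooled assembly from equimolar part mixes; the large
  skew seen in real pools is modelled separately by a ×10 abundance
  boost on members of designated high-copy origins (default: the first
  origin), mimicking a high-copy replicon over-represented in the
  cloning host.
* **Long reads** — full circular sequence at uniform random rotation and
  strand; per-base substitutions (1%), indels (0.5%, half insertions with
  random bases), 2% chimeras splicing the halves of two members. Each
  barcode receives Poisson(10) reads by default; abundance-weighted
  sampling is available (`weight_by_abundance=True`) for realism but is
  not the default, so that stated per-barcode coverage actually holds
  per barcode. Realistic platform error profiles (homopolymer-aware ONT
  or PacBio error structure) are out of scope.
* **BarSeq** — ~5,000 colony founders drawn multinomially from viable
  members (functional origin in the host, or a planted artifact
  barcode); serial passages update frequencies by p ← p·w / Σp·w with a
  binomial bottleneck (default 10⁵, abstracting the back-dilution);
  counts are multinomial with 10⁵ reads per sample (a scaled-down stand-
  in for multi-million-read runs; column sums are exact). Donor
  carryover is a passive term proportional to pool abundance, starting
  at 2% of a sample and decaying at rate 0.3 per passage — the minimal
  mechanism producing low, declining signal for nonfunctional origins;
  whether real carryover is persisting plasmid or surviving donor cells
  is not resolved by this model. Per host, 4 origins with ≥ 5 barcodes
  get fitness w ∈ [1.2, 2.0]; one barcode of a low-diversity
  nonfunctional origin is planted as an artifact with w = 2.5 (a
  mis-associated hitchhiker; its barcode is chosen abundant enough to
  show up under selection, since detectability is what defines the
  phenomenon).
* **qPCR** — logistic curves (exponential at the primer pair's factor,
  saturating at a plateau of 10⁴ RFU over a 50-RFU baseline) with 1%
  multiplicative noise and per-well Ct jitter of 0.15 cycles injected
  through the starting fluorescence. When the two primer pairs differ
  in efficiency a ΔCt is inherently threshold-dependent, so curves are
  anchored to the analysis threshold: at zero noise the
  ΔCt/efficiency-correction pipeline recovers the programmed copy
  number exactly there. This makes the generator the exact generative
  model of the correction formula rather than a mechanistic PCR model.

All generators are reproducible from (parameters, seed); the seed is
recorded in the ground-truth object.

## What the tests show — and what they cannot

Recovery tests demonstrate that the implementation inverts its own
generative model at realistic noise: barcode→origin deconvolution at
precision ≥ 0.99 / recall ≥ 0.95 (200 barcodes, 10×, 1% + 0.5% + 2%
errors), correct functional/carryover/artifact calls in ≥ 95% of seeded
screens, copy-number MAE ≤ 1 over true values 1–38. They do not
validate platform-specific error structure, PCR amplification bias in
BarSeq library prep, host biology (satellite colonies, mobilization), or
the interpretation of carryover.

One statistical ceiling is worth stating explicitly: with 0.15-cycle
per-well Ct noise, technical triplicates and 12 pairings, the aggregate
copy-number estimate has a standard error near 2.5% of CN, so
*nearest-integer* recovery of copy numbers ≥ 22 cannot be highly
reliable (the ±0.5 rounding band is narrower than the sampling spread);
recovery at CN ≤ 9 and the MAE ≤ 1 bound are the robust claims at this
noise level.

## Scale choices

Test and acceptance runs use 200-barcode libraries, 10× long-read
coverage, 10⁵ BarSeq reads per sample and 30–50 seeded replicates per
stochastic claim — sizes chosen so the whole suite completes in well
under a minute per stage while keeping binomial confidence bands
narrow relative to the asserted margins. Full-scale settings
(thousands of barcodes, 4×10⁶ reads per sample) are plain parameter
changes on the same code paths.
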