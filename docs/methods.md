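# Methods

## Extracellular-flux bioenergetics

A mito-stress-test trace is a per-well OCR/ECAR time series over four
phases: basal (4 measurement cycles by default), then 3 cycles after
each of oligomycin, FCCP, and rotenone/antimycin A. Each cycle is 30 s
of mixing followed by 3 min of acquisition; a phase value is the mean
OCR over the phase's cycles (an alternative `mode="last"` uses only the
final cycle of a post-injection phase, useful when the post-oligomycin
plateau is slow to settle — the default mean matches the convention
that each data point is itself a per-cycle mean rate).

Derived quantities: mitochondrial respiration `OCR_mito = basal −
rot/AA`; *coupled* (ATP-synthase-linked) respiration is defined as
basal minus post-oligomycin OCR — the standard mito-stress-test
convention and the only definition consistent with the injection order;
proton leak is post-oligomycin minus rot/AA, so coupled + leak =
OCR_mito exactly. Spare respiratory capacity is maximal/basal × 100;
maximal is the post-FCCP mean *even when it falls below basal*, so SRC
< 100% is representable rather than clamped.

ATP-rate partitioning uses the stoichiometric framework in the README.
Total acidification has two sources — lactate export and CO₂ hydration
from TCA-cycle flux — so the glycolytic proton production rate
subtracts the CO₂ term (`OCR_mito · maxH⁺/O₂ · 10^(pH−pK₁)/(1+10^…)`).
A negative PPR_glyc is *returned with a flag, never clamped*: clamping
would silently mask a mis-calibrated buffering power.

Parameters (all in `BioenergeticConstants`, all overridable, all
recorded in outputs): medium pH 7.4 (HEPES-buffered assay medium),
carbonic-acid pK₁ 6.093 at 37 °C, buffering power 0.1 mpH per pmol H⁺
in the measurement volume, max H⁺/O₂ 1.0, P/O_oxphos 2.486, P/O_TCA
0.121, P/O_glyc 0.167, ATP/lactate 1.0 — the conventional
glucose-oxidation stoichiometries. They are defaults for a typical
glucose/pyruvate medium, not measured truths; any real assay should
supply its own.

Normalization by a cell-number proxy (nuclei-stain signal) divides each
rate column by `signal / mean(signal)`, with the mean taken over the
plate or per comparison group (both modes exist because either may be
the lab's practice). Dimensionless ratios (SRC %) are left untouched:
they are invariant to cell number by construction, and dividing a
percentage by a cell-count factor would change its meaning.

## Mitochondrial morphometry

Segmentation is deliberately parameter-light: Gaussian smoothing (sd
1 px) → Otsu threshold (or a fixed value) → 8-connected components →
area filter (default 9–10000 px²) → border-touching particles removed
(their axes are truncated, so they are not clearly identifiable).
Otsu on a constant (blank) image is undefined; a blank image returns an
empty label map rather than an error.

Axes come from the moment-equivalent ellipse (second central moments),
matching the definition used by the common GUI tools, so the printed
roundness formula stays consistent: `roundness = 4·area/(π·major²)`,
`aspect = major/minor`. For an ideal ellipse the product
roundness·aspect equals 1; pixelation moves it a few percent, which is
why fixtures assert the product in [0.8, 1.2] rather than exactly 1.
A 1-px-wide component has a zero minor-axis moment; its minor axis is
floored at 1 px and the particle flagged `degenerate`. Coordinates are
0-based row-major; lengths are pixels unless `um_per_px` is set.

Group summaries report mean ± SEM of both descriptors and flag groups
with fewer than 500 particles as under-sampled — the sample size at
which per-group means of these descriptors are stable in practice.

## Puncta and tandem-reporter classification

Detection is multi-scale Laplacian-of-Gaussian (scales 1–3 px sd, 5
steps) with a threshold *relative to the in-cell maximum response*
(default 0.3): each cell ROI is cropped and detected independently, so
dim cells are not dominated by bright neighbours. With no cell mask a
single global pass is made and detections carry cell id "unassigned".
Cell ROIs in synthetic fixtures are rectangular tiles — per-cell
aggregation needs only a partition, not realistic cell outlines.

The tandem reporter's topology (GFP⁺ ⟹ RFP⁺) makes the literal counting
rule primary: autophagosomes = green count, autolysosomes = red − green
per cell. A cell where green exceeds red (detection asymmetry) has its
autolysosome count clamped to 0 and is flagged, preserving
auditability. A secondary per-vesicle mode pairs each green detection
with the nearest red detection within 3 px and reports the paired
count alongside; when detection is perfect the two modes agree exactly,
and summaries always use the primary rule.

Synthetic puncta are rendered as Gaussian spots (sd 1.5 px) over
background noise — the diffraction-limited appearance blob detection
assumes — with ≥ 8 spot-sd centroid spacing inside each tile so planted
counts are unambiguous. Detection fidelity is scored by greedy
one-to-one matching of detections to planted centroids within 3 px
(precision/recall/F1).

## Cytometry and normalized ratios

Percent-above-threshold gating takes the threshold as the q-quantile
(default 0.95) of a positive-control sample that collapses the signal
(e.g. FCCP for a membrane-potential dye), then reports 100 × the
fraction of sample events strictly above it — a per-event statistic,
invariant under any monotone transform applied to both samples. The
0.95 default is the conventional positive-control gate; it is
configuration. Note the calibration identity: a mixture with
fraction π of positive events reads π·100 + (1−π)·(1−q)·100 on average
(the negative component contributes its own tail).

Event statistics report mean, median, and geometric mean; the geometric
mean uses positive events only (no pseudo-offset) and reports the zero
count. Ratio readouts (plate reader, densitometry) divide signal by its
normalizer per well/lane, summarize per group, and can rescale so a
named reference group's mean is 1. Densitometry inputs are
already-integrated band intensities; background subtraction and band
finding are out of scope.

## Statistics

One-way fixed-effects ANOVA is computed from the classical sums of
squares; zero within-group variance with unequal means is reported as
F = ∞, p = 0 with a degenerate flag. The Newman–Keuls procedure orders
the group means (ties broken by label), and tests the pair spanning
`p` ordered means with `q = |Δmean| / √(MS_within/ñ)` against the
studentized-range quantile `q(α; p, df_within)`, where ñ is the
harmonic mean of the two group sizes (the standard unequal-n
extension). Testing proceeds from the widest span inward; every
sub-range of a non-significant range is declared non-significant
without testing. Critical values come from an established
studentized-range distribution routine — no embedded tables. α defaults
to 0.05. Groups with n < 2 are excluded from post-hoc testing with a
warning. At the complete null the procedure's family-wise error is
controlled by the widest-span test alone, which the null simulation
(4 groups, n = 10, 2000 replicates) verifies empirically.

## Synthetic data: what it does and does not emulate

Generators are seeded (`numpy.random.default_rng`) and bit-reproducible.
Flux noise is additive i.i.d. Gaussian per cycle — the simplest model
matching replicate-well scatter and sufficient for recovery testing; no
well-to-well variance structure is claimed to be realistic, and default
noise (5% of basal) is chosen for test power. Ellipses are
non-overlapping by construction to isolate measurement accuracy from
segmentation-merging; images have flat background plus Gaussian noise,
with no PSF beyond the Gaussian spot model, no photobleaching, no
uneven illumination. Cytometry events are a two-component log-normal
mixture with no spillover or compensation structure. Passing recovery
tests therefore demonstrates the *computational* pipeline is unbiased
and correctly calibrated under its stated model — not that segmentation
or detection would reach the same fidelity on real micrographs.

## Problem sizes and numerical choices

The validation suite runs 96-well flux recovery at 5% noise, 50
morphometry images (8 particles each), 20 tandem-reporter frames of 4
cells (10 red / 4 green planted per cell, SNR ≈ 10 over sd-3 noise),
10⁴-event gating samples (50 seeds), and 2000-replicate null
simulations — sizes chosen so each check has clear statistical power
while the whole suite stays fast. Recovery of the flux plate is
assessed on plate-mean estimates against 3 analytic standard deviations
of the corresponding estimator (derived from the cycle structure), and
SRC against a 5-percentage-point band. Studentized-range quantiles are
cached per (α, span, df). Report JSON is written with sorted keys and
no timestamps, so identical configuration and seed give byte-identical
files.

## Known limitations

No 3-D morphometry or network/branching analysis; no live-cell
tracking or per-vesicle intensity flux ratios; no FCS binary parsing
(events come as CSV); no oxygen-diffusion or temperature-drift
corrections for flux plates; Newman–Keuls is the only post-hoc
procedure offered (by design, it is the analysis layer this pipeline
standardizes on), and it is known not to control the family-wise error
rate strongly under partial-null configurations — a property inherent
to the procedure, not to this implementation.
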