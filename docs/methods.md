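# Methods

This note documents the models implemented in `aggscan`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions a user should know about.

## The phenotype

The unit of measurement is one micrograph pair: a slightly off-focus DIC
image in which yeast cells appear as bright objects, and a GFP image of a
polyQ reporter. Per field, the pipeline counts cells, decides which are
fluorescent, and counts which fluorescent cells contain at least one
punctate focus (read as a protein aggregate). The strain phenotype is

    percent_foci = 100 · n_with_foci / n_fluorescent,

averaged without weighting over replicate clones. Normalising by
*fluorescent* cells (rather than all cells) makes the statistic robust to
transformation efficiency and expression differences between strains;
`diffuse_vs_foci_correlation` quantifies the residual association between
expression level (mean diffuse intensity, foci pixels excluded) and the
phenotype. When a replicate contains no fluorescent cells its value is
*undefined* and is excluded from the strain mean — propagating it as 0
would bias low-expressing strains toward artificially low aggregation.

## Imaging pipeline

**Cell detection.** The DIC proxy is binarised with a locally adaptive
rule: a pixel is foreground iff its intensity exceeds the mean plus
`local_offset_k` standard deviations of its square `local_window`
neighbourhood (reflected padding at borders). The rule is invariant to
adding a constant to the image. Connected components with area outside
[`min_cell_area`, `max_cell_area`] = [4, 80] µm² are discarded. Defaults
(window 61 px, k = 1.25 at 0.2 µm/px) keep the threshold between
background and cell interior as long as cells occupy well under half of
any window; at confluency above roughly 30% of the frame the local
statistics are dominated by the cells themselves and detection degrades —
fields should be imaged (or rendered) at moderate density. A small
absolute guard (10⁻⁸ of the intensity scale) prevents float round-off in
the running means from promoting numerically flat background to
foreground. Cells touching the image border are kept by default
(`keep_border_cells`); exclusion would bias counts in dense fields.

**Puncta versus diffuse.** The GFP image is high-pass filtered by
subtracting a Gaussian smoothing at `highpass_scale` = 0.8 µm (sigma) and
clipping negatives — a difference-of-scales filter that removes constant
offsets exactly, passes sub-micron puncta nearly unattenuated, and
attenuates features much broader than the scale. The filtered image gets
a light matched smoothing (`puncta_smooth_px` = 1 px) and the same locally
adaptive binarisation (window 31 px, offset `puncta_offset_k` = 5.0). Each
connected component is then classified by its equivalent diameter
2·√(area/π): at or below `puncta_max_diameter` = 2 µm it is a focus,
above it is diffuse fluorescence. This size dichotomy — not the filter
alone — is what rejects broad bright structures: a 3 µm blob may survive
binarisation, but its detected extent always exceeds the 2 µm rule.
Components below `min_focus_area` = 0.1 µm² are discarded as noise
specks. A focus is assigned to the cell containing its centroid, which
also settles foci straddling two masks.

A cell is *fluorescent* iff its low-passed GFP signal (Gaussian sigma
`lowpass_scale` = 1.2 µm) exceeds the fluorescence threshold over at least
half of its mask, or it contains a focus. The threshold is either Otsu's
threshold of the low-passed image (default) or a calibrated absolute
value. `diffuse_mean_intensity` is the mean raw GFP over the cell mask
minus each focus with a `focus_guard_px` = 2 px ring, so focus tails do
not inflate the diffuse estimate.

**Calibration.** `calibrate_thresholds` derives both sensitivities from a
high-aggregating positive control: the fluorescence threshold is the 10%
quantile of within-cell low-passed intensity (valid when essentially all
control cells are fluorescent — the quantile then falls between
background and the diffuse level), and the puncta offset is chosen from
the focus-count-versus-sensitivity curve. That curve falls steeply while
noise hits vanish, sits on a plateau where exactly the real foci are
counted, and decays as real foci are lost; the chosen offset is the
largest k on the widest stable stretch (successive counts within 5%).
Both choices are deterministic given the control. The iterative
optimisation used with proprietary acquisition software is not specified
anywhere in a reproducible form; this fixed surrogate is documented as
such and achieves self-recovery of a known control within 5 percentage
points in the test suite.

**Human-cell arm.** `max_project` takes the per-pixel maximum over a
z-stack; `segment_aggregates` is a global-Otsu + connected-components
segmentation of the projected aggregate channel; `bin_aggregate_sizes`
reports the fraction of aggregates smaller than a 50 µm² cutoff, with
areas exactly at the cutoff counted as large (the boundary rule is a
convention; planted test areas keep a ≥ 20% margin from it).
`rank_sum_test` computes the Mann–Whitney U from midranks; for small
samples (both n ≤ 8, or n₁+n₂ ≤ 12) the two-sided p is computed by exact
enumeration of all label assignments, defining p as the probability of a
U at least as far from its null mean as observed (valid under ties);
larger samples use the normal approximation with the standard tie
correction and no continuity correction.

## Cross simulation

Genotypes: each chromosome of each haploid segregant is a two-state
Markov chain over {lab, vineyard}; the first marker is a fair coin and
each adjacent-marker interval switches parent with probability
`recomb_prob`. Entries are then set missing independently at
`missing_rate`. Marker positions are an integer grid (the scan uses only
ordering, never genetic distance) and the real cross's recombination map
is unknown, so `recomb_prob` is a free knob: 0.2–0.3 gives the
between-marker decorrelation of a sparse marker map, 0.01–0.05 produces
the tight LD blocks that exercise the pruning rules.

Phenotypes: percent = baseline + Σ effectₑ·1[allele = lab] + N(0, σ),
clamped to [0, 100]. Effects are signed (negative = vineyard-increasing);
with antagonistic effects the segregant range strictly contains both
parental values (transgressive segregation). A strain missing the
genotype at a QTL receives no contribution from that locus, keeping the
simulated panel size stable; the scan handles missingness separately. In
variance units, a biallelic QTL with effect e at allele frequency ½
contributes e²/4, so planting expected single-locus R² values is exact
arithmetic: e = 2·√(R²·V) with V the target total variance (the test
suite plants R² = 0.38 and 0.16 this way with V = 100).

## Field rendering

Cells are random non-overlapping axis-aligned ellipses (radii 1.5–2.5 µm
at 0.2 µm/px). The DIC proxy renders each as a bright blob (contrast 300
over background 100, 1 px edge smoothing) — a detection target, not an
optical DIC model, since the detection contract only needs cells brighter
than background. The GFP channel adds a diffuse fill (level 60 over
background 20) for fluorescent cells with a smoother 2.5 px edge (real
cytoplasmic fluorescence falls off smoothly; a sharp edge would ring
through the high-pass filter), plus an isotropic Gaussian per planted
focus whose full width at half maximum equals the planted diameter
(default 0.8–1.4 µm, peak 150). Both channels receive independent
Gaussian noise; peak/noise_sd is the SNR quoted in the tests (SNR 5 means
noise sd 30). `sample_field_truth` rounds the fluorescent and
foci-bearing counts so the planted percent-foci value is exact, and
plants foci within 40% of the cell centre so they never interact with the
boundary.

What the renderer does **not** emulate: optical point-spread functions,
DIC shear artefacts, uneven illumination, autofluorescence, touching or
budding cells, multiple or clustered foci per cell, and focus drift.
Passing the recovery tests therefore demonstrates that the segmentation
logic and statistics are correct under the stated image model, not that
the pipeline is robust to every artefact of real microscopy.

The aggregate-field renderer places non-overlapping bright disks with
requested areas (µm²) and returns the true label map; the number of
aggregates is simply the length of the request list.

## Linkage analysis

**Marker QC.** Within each chromosome, markers are pruned left-to-right:
the candidate marker is compared by squared Pearson correlation (over
pairwise-complete strains, alleles coded 0/1) against the last retained
marker; when R² > 0.90 the *earlier* member is removed and the candidate
is re-checked against the new tail. This greedy pass guarantees the
endpoint property that every adjacent pair of surviving markers has
R² ≤ 0.90. An immediate-neighbour variant (each original adjacent pair
compared once, no re-check) is available as `mode="neighbor"` for
sensitivity analysis. Correlation pruning runs first, then markers with
more than `max_missing` = 1 missing entries or minor-allele frequency
below `maf_min` = 0.25 are removed; every removed marker is logged with
exactly one reason, so kept + removed always equals the input count. A
pair with fewer than two complete strains, or constant on its complete
subset, gets R² = 0 (never pruned on that account); markers with fewer
than two non-missing entries are removed outright as `insufficient_data`.
Note the interaction between the missingness filter and panel size: at ~1%
random missingness a 120-strain panel loses about a third of its markers
to the ≤ 1-missing rule, so the demo simulates 0.2% missingness.

**Scan.** Per marker, strains with missing genotype there are dropped,
and phenotype is regressed on the 0/1 allele code; the two-sided p for
slope = 0 comes from the t distribution with n−2 degrees of freedom. For
a binary predictor this is algebraically the pooled-variance two-sample
t-test, which the test suite verifies to 10⁻¹⁰. Monomorphic markers,
markers with under 3 complete strains, and zero phenotype variance are
flagged undefined (NaN statistics) rather than dropped; exact fits report
p = 0. The scan is vectorised across markers, so the 100-permutation FDR
on 1000 markers × 200 strains runs in about a second. Strain-mean
phenotypes (not replicate values) enter the regression.

**Permutation FDR.** Phenotype values are shuffled across strains with
genotypes fixed, preserving the LD structure of the panel. At each
threshold t, FDR(t) = mean over permutations of #{p ≤ t} divided by the
observed #{p ≤ t}; the ratio is undefined (NaN) when the real count is
zero, and undefined marker tests are excluded from both counts so the
numerator and denominator stay comparable. The default threshold grid is
the sorted distinct observed p-values, which makes the FDR step function
exact without arbitrary gridding; counts use p ≤ t so each grid threshold
includes its defining marker. Permutations are seeded; a tiny-panel
exhaustive mode enumerates all n! permutations for oracle tests. Under
the null the FDR sits near 1 wherever the real count is large enough for
the ratio to be stable; at the most extreme thresholds the defining order
statistic itself fluctuates by a factor of order 1 (the k-th smallest of
N uniform p-values is Gamma(k)-distributed around k/N), which is a
property of the estimand, not an implementation artefact.

**Variance explained and peaks.** `variance_explained` fits additive
least-squares models (intercept + coded alleles) by pseudoinverse on the
strains complete at every named marker, reporting single-locus R² on the
same subset so nested models are comparable, plus the design rank for
collinear marker sets. `call_peaks` takes the largest threshold with
defined FDR at or below the ceiling and collapses runs of adjacent
significant markers per chromosome to their best marker; `merge_gap` > 0
additionally bridges runs separated by at most that many non-significant
markers, so an LD flank split off a peak by one weak marker is not
reported as a second locus (default 0, i.e. strict adjacency). Note that
an FDR ceiling of q with m significant markers *expects* about q·m false
hits — calling "exactly the planted peaks" in simulation needs a strict
ceiling (≤ 0.005 in the tests), not the conventional 5–12% reporting
threshold.

## Pipeline

`run_pipeline` chains simulate → quantify → prune → scan → FDR → peaks.
The single global seed is expanded via `SeedSequence.spawn` into
independent per-stage substreams, so each stage is individually
reproducible. When the imaging stage is enabled (`n_fields` > 0), each
strain's simulated phenotype sets the fraction of foci-bearing cells in
`n_fields` rendered fields, which are then quantified — the mapped
phenotype is a *measured* value carrying binomial counting noise, as in a
real screen; with `n_fields = 0` the simulated values are mapped
directly. Every output table carries the seed, package version and a
hash of the scientific configuration (output paths excluded) in `#`
header lines, and `manifest.json` records per-stage checksums and wall
times. The bundled demo maps two antagonistic QTL (+10 / −8 percentage
points, baseline 12%, noise 2%) in 120 segregants × 150 markers with 8
fields of 40 cells per strain; the acceptance script runs it with 4
fields per strain to stay fast, which leaves the planted chromosomes
comfortably recoverable.

## Numerical conventions and edge cases

- Alleles are int8 with lab = 0, vineyard = 1, missing = −1; text codes
  L/V/N in TSV files.
- All thresholds use strict `>` against local statistics; equal-to-mean
  pixels in flat regions are background.
- `percent_foci` with zero fluorescent cells is None/NaN ("undefined"),
  never 0, and undefined values propagate as missing through replicate
  means, phenotype tables and the scan.
- Phenotype clamping to [0, 100] slightly distorts planted variances when
  baseline ± 3σ leaves the percent scale; the test configurations keep
  planted distributions well inside it.
- Determinism: identical seeds give bit-identical genotypes, phenotypes,
  rendered images, permutations and pipeline outputs.

## Problem sizes used in the tests and acceptance script

Scan oracle: 50 datasets of 20–60 strains × 12 markers. Null
calibration: 200 strains × 1000 markers, 100 permutations. QTL recovery:
20 replicates of 500 strains × 300 markers on 16 chromosomes. Imaging:
10 noisy fields of 200 cells at 768×768 px (≈ 14% confluency) plus
noiseless 40-cell fields; controls of 100 cells. Pipeline demo: 120
strains × 150 markers with 4 rendered fields per strain. These sizes were
chosen so the whole suite completes in well under a minute while keeping
Monte-Carlo noise far inside the stated tolerances.

## Known limitations

- The image model is a rendering contract, not an optics simulation (see
  above); real-data performance depends on artefacts the generator does
  not produce.
- Single-marker regression only: no interval mapping, no epistasis, no
  genetic-map estimation, haploid biallelic genotypes only.
- The calibration surrogate assumes a nearly fully fluorescent positive
  control and a focus-count plateau; controls violating either assumption
  need manually set thresholds.
- `detect_cells` assumes moderate confluency; heavily clumped fields need
  a different segmentation strategy (e.g. watershed splitting), which is
  out of scope.
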