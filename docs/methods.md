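# Methods

## The problem and the approach

Data-independent acquisition (DIA/SWATH) co-fragments every precursor inside
each isolation window, so fragment spectra must be computationally assigned
to precursors. The usual approach matches chromatographic peak shapes within
a single run, which fails when peak shapes are distorted by non-selective
analyte–stationary-phase interactions or when isomers co-elute. The approach
implemented here instead acquires a pooled QC sample under **nine different
LC gradient programs** and uses the *retention behaviour* — the vector of
retention times across the gradient family — as the assignment signature:
a fragment belongs to a precursor only if the two RT vectors agree. The
deconvolved feature list is then searched in targeted mode in every
individual sample (acquired under the reference gradient G5 only), which
keeps per-sample instrument time at one run per mode and column.

Downstream, the package reproduces the sensory-guided discovery chain:
panel scores → outlier screen → PCA grouping → differential (abundant ion
feature) selection → spectral-library annotation → standard confirmation →
standard-addition quantification → validation-formula composition.

## Retention model

Analyte migration follows the linear-solvent-strength (LSS) law
`log10 k(φ) = log k0 − S·φ`, with φ the organic fraction for RPLC. HILIC is
modelled with the same law on the aqueous fraction `(1 − φ)`; consequently
the default HILIC programs ramp the organic fraction *down* (0.98 → 0) so
analytes are retained at the start and eluted by increasing water. The
retention time solves `∫ dt / (t0·k(φ(t))) = 1` on a uniform 10 ms grid with
trapezoidal accumulation and linear interpolation in the crossing step;
under isocratic conditions this reduces to `t_R = t0(1 + k)` exactly (unit
tested against a 1 ms brute-force oracle). A compound whose cumulative
migration never reaches 1 raises a non-eluting error rather than being
clipped.

The published study shows its nine gradient programs only graphically, so
the default family is a configurable stand-in: linear ramps from organic
fraction 0.02 to 1.0 with ramp durations 10–30 min in nine even steps plus
a 5 min hold; G5 (20 min ramp) is the reference. Dead time 1 min.

## Synthetic study generator

The generator's defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| samples | 57: 24 T, 5 N1, 24 N2, 4 N3 | study design |
| assessors × metrics | 6 × 5 (scores 0–50; aroma 0–100) | study design |
| MS1 range / dwell | 70–1200 Da / 150 ms | instrument method |
| SWATH windows | 12 variable, 50 ms each; duty cycle 750 ms | instrument method |
| window widths | quantiles of the panel's precursor m/z density, 0.5 Da overlap each side | "variable windows" equalise ions per window; fixed-width fallback provided |
| peak shape | Gaussian, σ = 0.05 min per column | typical 7 s FWHM UPLC peak; value not printed in the study, configurable |
| noise | 3 ppm mass jitter, 0.005 min RT jitter, 5% intensity CV, noise floor 50 counts, ~2 random centroids/scan | moderate TOF-like noise |
| response | 10⁴ counts/ppm at apex, unit response | makes standard-addition truth exact; per-compound factors configurable |
| panel masses | uniform 90–800 Da | differential features in this domain are mostly < 500 Da |
| fragments | 4–10 per compound, base peak = water loss | generic ESI fragmentation template |
| concentrations | log-normal, median 20 ppm, sample CV 20%; 25% of compounds enriched 4–32× in N1, 25% in N2&T | spans the reported ppm range; planted folds straddle the FC > 2 gate |
| sensory baselines | §-averaged group scores (T: aroma 84.9, astringency 32.3, moistening 32.6; N1: 33.6/34.2; N3: 23.8/23.5, …) | group radar averages; the source also cites higher per-sample N1 ranges (39–40) — the averaged values were chosen and the discrepancy left unreconciled |

Each compound carries one ionisation mode (≈50/50 positive/negative), LSS
parameters per column (log k0 ∈ [1.0, 2.8] RPLC / [0.8, 2.2] HILIC,
S ∈ [3, 7]), and flags for library membership and standard availability.
A configurable fraction (default 5%) of compounds is arranged in **planted
co-elution pairs**: the partner's `log k0` is solved (Brent's method) so both
elute within 0.02 min under G5-RPLC while their different slopes `S` separate
them under every other gradient — the exact failure case single-run
deconvolution cannot resolve. QC concentrations are the equal-volume pool
(mean over samples), so the noise-free QC area equals the mean sample area
by construction.

Sensory scores are `group baseline + Σ_c w(c, metric)·log1p(conc) +
assessor bias + N(0, noise_sd)`, truncated to the metric range. Driver
weights default to zero (the group baselines already encode the planted
pattern); they exist to couple scores to compound concentrations when a
metabolite-driven panel is wanted.

Library export draws a seeded `coverage_fraction` subset (emulating the low
coverage of natural products in public libraries) plus isomer decoys that
copy any panel compound's spectrum and precursor m/z but carry a standard RT
displaced by 0.6–2.0 min. Decoy parents are drawn from the whole panel, not
just covered compounds: a feature whose true compound is absent from the
library can then hit *only* the decoy, which the standard-RT check must
expose.

## Deconvolution

Peak picking mirrors common DIA-software settings: triangular (linear
weighted) moving average of level 3, minimum height 1000 counts, minimum
width 5 s. Peak bounds are walked outward on the smoothed trace to the first
local minimum or 0.5% of apex; the width gate is applied to the *raw* trace's
contiguous above-baseline span (so smoothing cannot promote one-scan spikes);
the area integrates the raw trace between the smoothed bounds (trapezoid).

Linking clusters peaks by m/z (gap > 10 ppm splits) and resolves same-m/z
isomers by **within-gradient elution rank**: the i-th earliest peak in every
gradient forms the i-th feature. Rationale: elution order is far more stable
across gradient programs than absolute RT. Features need detections in ≥ 7
of 9 gradients and a G5 detection (G5 anchors the targeted re-search; the
source does not state how features absent from G5 were handled, so the
requirement is a parameter).

Fragment assignment applies two gates: (a) co-elution with the precursor
within `rt_tol` = 0.05 min in *every* shared gradient (≥ 4 shared required),
and (b) Pearson correlation of the RT vectors ≥ 0.99. The published
description gives the principle, not thresholds; the defaults were chosen so
that noise-free truth passes and the degenerate control fails, and all are
configurable. **Degenerate-input convention:** when a vector's retention
spread does not exceed `rt_tol`, its correlation is meaningless (jitter
against jitter), so gate (b) is waived and only co-elution decides. This is
what makes the nine-identical-gradients negative control behave as expected:
the method degrades to single-run co-elution grouping and planted co-eluting
pairs are no longer split (their fragments cross-assign), demonstrating why
nine *distinct* gradients are needed.

Targeted re-search extracts the XIC at each feature m/z in each sample run
and integrates the largest peak within ±0.2 min of the G5 reference RT.
Undetected-in-window is 0 and enters statistics; a missing run is NaN and is
excluded — conflating the two would manufacture fold changes.

## Statistics

Differential selection: enriched in A iff `mean_A/mean_B > 2` (strict) and
Welch's t-test p < 0.05, on raw areas (log1p transform available but off —
the workflow this replicates reports arithmetic fold changes up to ~200
alongside Welch p-values). No multiple-testing correction is applied,
matching that workflow; this is statistically liberal and the selected set
should be read as candidates. Zero group means are replaced by half the
smallest positive area in the table, keeping fold changes finite without
inventing an intensity scale. Welch's statistic uses Satterthwaite degrees
of freedom, clamped at 1; zero-variance groups with unequal means map to
t = ±∞, p = 0 (documented convention; cross-checked against
`scipy.stats.ttest_ind(equal_var=False)`).

Grouping: profiles are per-sample assessor means after a Tukey-fence outlier
screen (hinge quartiles, k = 1.5, unit = (sample, metric) across assessors;
flags annotate, never delete; cells with < 4 scores are skipped). The
published subgrouping was expert-visual on a PCA plot; it is codified here
as seeded k-means (50 restarts) on the first two PC scores of the natural
samples, with the labelling rule: nearest-to-tobacco centroid → N2, highest
mean astringency + nasal moistening → N1, remainder → N3. Caveat: PCA
autoscaling inflates metrics that carry no group structure to unit variance,
so recovery is exact only when the planted separation dominates most
metrics — with study-like baselines plus a ≥ 3-point effect at score noise
SD ≤ 1 the planted partition is recovered with ARI 1.0 across 20 seeds; an
effect planted on two metrics alone over flat baselines occasionally loses
boundary samples.

## Annotation and quantification

The spectral dot product pairs peaks greedily by ascending m/z gap within
0.025 Da and takes the cosine over the union vector (unpaired peaks
contribute zeros). Plain cosine on relative intensities is the default; the
weighting variant used by any particular study is rarely stated, so
square-root/m/z-weighted variants are left to configuration. Level 2
requires mass error < 10 ppm (strict) and DP > 0.4 (strict); candidates are
ranked by DP, ties by smaller mass error; one best annotation per feature is
retained for counting. Level 1 additionally requires |feature RT − standard
RT| ≤ 0.1 min under the same gradient and column; |ΔRT| > 0.5 min sets the
isomer flag.

Standard addition is single-point (`C_s = C_std·A/(A_spiked − A)`), exact
under linear response and invariant to a shared matrix-effect factor. Under
5% independent area noise at an equal-magnitude spike, first-order
propagation gives a relative SD of √8·5% ≈ 14% and a median absolute
relative error near 9.5% — the pipeline's observed ~2% is lower because
integration averages many scans. The pipeline spikes all standards in one
simulated pass at the QC-mean concentration ("same magnitude as the
analyte"). Group-average concentrations are arithmetic means with
non-detects included as zeros (averaging rule unstated in the source;
configurable). Formulas partition the level-1 set into all/majors/minors,
majors defaulting to the three highest group-mean concentrations.

## Pipeline, determinism, problem sizes

Stages exchange tables, feature lists, spectra and reports as files
(CSV/MSP/JSON) for stage-wise testing and re-entry; raw scan data stays in
memory by default, with mzML export behind a `write_mzml` flag (a full
57-sample × 4-dataset study is ~260 runs of ~26 000 spectra each — exported
on demand rather than always). Every random draw derives from the config
seed through per-run `SeedSequence` children in a fixed order, so equal
configs give bit-identical runs and reports; deconvolution output is
invariant to scan order and gradient relabelling.

Default problem sizes: the test suite and the acceptance script run the
full 200-compound scenario for deconvolution recovery but QC-only and
RPLC-only (the four-dataset version is exercised at 24–60 compounds),
chosen to keep a complete run on one CPU in the low minutes while leaving
every per-feature quantity well populated.

## What the generator does not emulate

Profile-mode spectra, isotope envelopes beyond M+0, adduct multiplicity and
in-source fragmentation chemistry, charge states > 1, peak-shape distortions
(EMG tailing is available but off by default), retention drift between QC
and sample batches, ion suppression that varies *within* a run, and real
MS/MS fragmentation logic (templates are random). Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms under
the stated noise model — not instrument-grade performance on real extracts.
Known limitations: the correlation gate needs ≥ 4 shared gradients and an
informative retention spread; annotation recall is bounded by library
coverage by construction; and raw-p differential selection inflates the
candidate set on weakly powered contrasts (N3 has only 4 samples).
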