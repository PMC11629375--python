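# Methods

`glycoquant` implements an integrated targeted-MS1 workflow for measuring,
in one LC-MS run, the absolute plasma concentration and the Fc glycosylation
profile of antigen-specific IgG1 (optionally IgG3), using a spiked
stable-isotope-labeled (SIL) recombinant IgG1 standard. This note documents
the model, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## The measurement model

A fixed mass `m_SIL` (default 2 ng) of a ¹³C/¹⁵N-Lys/Arg-labeled IgG1 is
added to each immunosorbent eluate captured from a fixed plasma volume `V`
(default 0.02 mL). After tryptic digestion, every natural (glyco)peptide has
a SIL counterpart shifted by exactly one labeled C-terminal residue:
+8.0142 Da for Lys peptides (6×(¹³C−¹²C) + 2×(¹⁵N−¹⁴N)) and +10.0083 Da for
Arg peptides (6 C + 4 N). Natural and SIL isotopologues are chemically
identical in ionization and recovery, so the plasma concentration follows
from summed MS1 intensities alone:

    c = (Σ I_natural / Σ I_SIL) · m_SIL / V        [ng/mL]

With the defaults, a unit ratio corresponds to exactly 100 ng/mL. The
concentration is computed independently from (i) the summed IgG1 Fc
glycopeptides (backbone `EEQYNSTYR`; SIL panel restricted to the standard's
three abundant glycoforms G0/G0F/G1F), (ii) the proteotypic peptide
`GPSVFPLAPSSK` (GPS) and (iii) optionally `TTPPVLDSDGSFFLYSK` (TTP, excluded
from the composite by default because of its interference liability). The
reported value is the median of the enabled classes. LLOQ/ULOQ (100 /
10 000 ng/mL) are reporting flags, not truncation. IgG3 (backbone
`EEQYNSTFR`, six glycoforms) can be quantified against the IgG1 standard;
the result is tagged with the cross-subclass caveat that equal response
factors are assumed.

Mass-based (ng) units are used throughout; molar conversion is out of scope.
Capture efficiency is not corrected for (it cannot be, with a post-capture
spike), so accuracy is relative by design.

## Isotopologue patterns

All mass math is built on elemental compositions, with `C13`/`N15`
pseudo-elements (isotopically pure) for the labeled atoms; label impurity is
not modeled. Isotopologue distributions are aggregated by neutron-count
offset above the monoisotopic peak — not isotope fine structure — because
0.04 Th integration windows see a time-of-flight cluster as one peak per
nominal offset. The distribution is computed by per-element convolution with
binary exponentiation; each offset's exact mass is the abundance-weighted
mean of its fine structure. Trailing probability below 1e-14 of the total is
truncated at each convolution, keeping the result within total-variation
1e-9 of exhaustive enumeration for compositions of several hundred atoms
(verified in the tests against an independent multinomial enumeration
oracle). Pattern truncation for integration keeps the most abundant offsets
whose fractions sum to at least the configured minimum (0.95 for
glycopeptides, 0.8 for peptides), and the integrated area is divided by that
summed fraction ("coverage correction") to estimate the full cluster
abundance.

## Spectra and integration

Input is centroided MS1 data (mzXML, or a TSV peak-list dialect for text
fixtures). Scans inside a retention window are merged on a fixed 0.002 Th
grid (intensities summed per cell, cell m/z = intensity-weighted mean) — an
order of magnitude finer than the narrowest integration window, so merging
cannot move signal across window boundaries. Retention windows are
per-analyte configuration, not auto-detected: they are instrument facts.

Each analyte charge state is integrated in windows of ±0.04 Th
(glycopeptides) or ±0.065 Th (non-glycosylated peptides) around the
theoretical m/z of each selected isotopologue. Quality metrics per
extraction:

* **S/N** — apex intensity of the most abundant isotopologue over the local
  noise standard deviation.
* **ppm error** — theoretical-abundance-weighted mean of per-isotopologue
  apex deviations (apex = most intense grid cell in the window, ties broken
  toward the window center).
* **IPQ** — L1 distance between observed and theoretical normalized
  isotopologue intensities.

**Background and noise.** The local background is the mean, and the noise
the standard deviation, of the lowest-intensity 20% of observed grid peaks
within ±10 Th of the cluster, excluding 99.99% of the theoretical pattern of
every targeted analyte (excluding only the integrated 95% subset lets faint
cluster tails of large analytes masquerade as baseline and biases small
clusters low). Background is subtracted once per *observed* peak inside an
integration window, not per grid cell: centroided spectra are sparse, and
per-cell subtraction would over-subtract roughly the ratio of grid capacity
to peak density and clip weak clusters to zero. Negative per-isotopologue
areas after subtraction are clipped to zero. A region with no usable peaks
yields background 0 and a flagged noise stand-in (smallest positive
intensity in the spectrum). This estimator is a documented stand-in — the
processing convention this workflow descends from does not publish its exact
variant — and is configurable; only the S/N cutoff (9) is fixed by the
method.

**Calibration.** The six SIL glycopeptide charge states (G0/G0F/G1F at
z=2,3) are candidate calibrants: the most intense peak within ±30 ppm of
the theoretical monoisotopic m/z is matched, and matches with S/N ≥ 9 become
calibration points. The observed ppm error is fitted as a polynomial in m/z,
tiered by point count (≥5 quadratic, 3–4 linear, 1–2 constant, 0 none →
sample flagged uncalibrated) so the model degrades gracefully.
Glycopeptides are integrated in the calibrated frame (implemented by mapping
theoretical positions into the observed frame, which leaves intensities
untouched); non-glycosylated peptides are always integrated uncalibrated,
matching the method's processing rule.

## Curation

**Spectral curation.** Per sample, the ratio of total natural IgG1
glycopeptide intensity over total SIL intensity is compared with the 95th
percentile of that ratio among ≥3 antibody-deficient negative controls.
Samples at or below the cutoff are excluded; negative controls themselves
are always excluded from quantitation; a sample with zero SIL signal fails
with "standard absent" (spike or digestion failure). The percentile uses
the conservative order-statistic ("higher") definition rather than linear
interpolation: for any continuous ratio distribution at n=28 this bounds
the expected fraction of negatives above their own cutoff at 1/28 ≈ 3.6%
(interpolating definitions give 2/28 ≈ 7.1%, breaking the ≤5% design goal
of a 95th-percentile background cutoff). Corrected (coverage- and
charge-summed) areas are used, consistent with quantitation.

**Consensus list.** A natural glycopeptide enters the consensus panel iff
it passes the QC rule (defaults: S/N ≥ 9, |ppm error| ≤ 20, IPQ ≤ 0.25,
after charge merging — conventional defaults, all configurable) in at least
80% (inclusive) of the curated case spectra of *every* biological group; a
switch allows the weaker any-group reading. Raising the cutoff can only
shrink the list (monotone).

## Profiling

Relative glycoform abundances are corrected areas normalized over the
consensus panel of one subclass; SIL analytes never enter the natural
profile. Traits use the antenna-normalized convention for biantennary IgG
Fc glycans: fucosylation and bisection are summed abundances of forms with
core fucose / a fifth HexNAc; galactosylation and sialylation count residues
per antenna (Hex−3 clipped to [0,2], NeuAc, each divided by 2).
Hybrid/high-mannose forms are outside the supported short-name grammar and
would be reported separately rather than entering antenna-normalized traits.

## Synthetic data generator

The generator emulates the cohort structure the method was designed for:
cases with true concentrations log-uniform over 100–10 000 ng/mL, 28
negative controls whose residual natural/SIL ratio is log-normal (median
0.005, σ=0.5 — chosen so the percentile cutoff exercise is non-degenerate),
and 19 pooled replicates at 5.4 µg/mL. Per-sample glycoform profiles are
Dirichlet draws around a ten-form default panel (a documented stand-in for
an assay-specific panel; override via the analyte table to reproduce a
specific assay). Intensity response is linear (1000 units/ng shared by
natural and SIL species); glycopeptide charge is split 60/40 between z=2
and z=3; each isotopologue peak receives an independent mean-one log-normal
factor (default cv 5%); clusters are spread over 10 scans per retention
window by a fixed triangular profile (integration operates on sum spectra,
so peak shape is immaterial); spectra are shifted by a linear-in-m/z ppm
miscalibration (default +3 ppm constant); and a noise floor of exponential
centroids (mean 3 units, 1 peak/Th/scan) plus occasional persistent
contaminant peaks completes the spectrum. Identical seed and configuration
give byte-identical output; every downstream module can be scored from the
truth table alone.

**What passing the synthetic benchmark shows — and what it does not.** The
generator realizes the method's own premises: exactly equal natural/SIL
response, linear detectors, known retention windows, well-separated
clusters, and white noise. Recovery on this benchmark therefore validates
the processing algebra (integration, coverage correction, calibration,
curation, ratio quantitation) — noiseless samples recover truth to <0.5%,
and the residual there is a real property of the chemistry (the faint tail
of the SIL fucosylated cluster overlaps the windows of the natural
afucosylated one-more-galactose form, ≲0.8% of the SIL cluster). It does
not validate robustness to ionization suppression, retention drift,
digestion variability, isotope-label impurity, or capture-efficiency
variation, none of which are simulated.

## Problem sizes and defaults used in the checks

The packaged checks run the full pipeline at cohort sizes chosen to keep
the whole suite fast while leaving the statistics meaningful: 10 samples
for the noiseless identity, 50 cases for noisy recovery (median |relative
error| < 10% at 5% multiplicative noise) and for the default-cohort
Spearman check (ρ > 0.95), 19 pool replicates for profile stability
(per-glycoform sd < 1 percentage point for forms > 5%), and 1000 replicated
n=28 negative-control sets for the curation pass-rate bound (≤5%).

## Known limitations

* Only centroided MS1 input; profile data must be centroided upstream.
* No untargeted peak detection, deisotoping, or chimera deconvolution
  beyond window-based exclusion.
* O-glycans, non-tryptic/missed-cleavage peptides (more than one labeled
  residue) and isotope fine structure are unsupported.
* The background/noise estimator is a documented stand-in; pipelines aiming
  at bit-exact agreement with a specific legacy toolchain must verify it.
* IgG3 quantitation against the IgG1 standard assumes equal response and
  carries no independent reference.
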