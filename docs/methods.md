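# Methods

This note documents the models and procedures serapept implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions made where the design was
genuinely open.

## Study design being emulated

The pipeline targets three-group serum peptidome studies: healthy controls,
non-metastatic and metastatic cancer patients, profiled by MALDI-TOF MS on
the C18-captured low-molecular-weight serum fraction. Default cohort
structure: 19 / 80 / 92 samples per group, four technical replicates
(target spots) per sample, each replicate a spectrum averaged from 15
consecutive scans, acquisition range m/z 800–3000. Controls are younger than
patients (mean 54 vs 71 years) and gender proportions differ — which is why
the covariate-adjusted regression exists.

## Quality gate (fpA degradation score)

Fibrinopeptide A is the canonical serum-degradation reporter: physico-
chemical stress converts the intact high-mass fragments (m/z 1350.6,
1465.63) into low-mass fragments (m/z 905.46, 1077.53). For a sample peak
list and a reference peak list of assessed quality, the score components
are:

* overall fraction = (sum of sample fpA-fragment abundances within the match
  tolerance) / (same sum in the reference);
* high-/low-mass percentages over the sample's fpA abundance only (not the
  whole-spectrum TIC — the criteria are stated as fractions *of fpA
  fragments*).

Selection requires, with strict `>` comparisons, overall fraction > 1/3 and
high-mass % > (2/3) × low-mass %. Defaults: match tolerance 0.3 Da
(instrument-resolution scale; no canonical value exists). The reference is
user-supplied; in simulation it is a pristine (zero-degradation, zero-noise)
rendering of the panel. Scores are computed on raw replicate-averaged
abundances; whether one should normalize first is an open question in the
underlying procedure — raw scoring is used and recorded here.

## Peak detection

Two steps, as in standard linear-MALDI practice:

1. candidates = strict local maxima (a point higher than both neighbours;
   plateau ties are not candidates; endpoints never qualify);
2. keep a candidate iff (apex − baseline) / max(noise, ε) ≥ SNR, where
   baseline is the median of the window ±half_window points around the
   candidate (truncated at spectrum bounds) and noise is the MAD of that
   window around the baseline scaled by 1.4826.

Defaults: half-window 20 points, SNR 2.5. The literature the parameters come
from does not state whether noise was estimated globally or per window;
per-window is implemented (and flagged here) because it adapts to the strong
baseline heteroscedasticity of serum spectra. Peak m/z is reported at the
apex grid point; no centroid interpolation. An SNR of 2.5 is deliberately
liberal — isolated noise maxima that survive it are removed downstream by
the replicate-presence threshold.

## Preprocessing and alignment

* **Normalization / recalibration.** Abundances are divided by the internal
  standard's abundance; all m/z are shifted by one constant so the standard
  sits exactly at its reference position. The spiked standard has MW
  1419.76; what a positive-mode spectrum shows is the singly protonated ion,
  so the default reference m/z is 1420.77 (configurable, recorded in
  provenance). A constant additive offset is the simplest recalibration
  consistent with single-point referencing. Normalization is idempotent.
* **Isotope summing.** Maximal chains spaced 1.00335 Da (tolerance 0.05 Da,
  up to 5 members) collapse onto their lowest-mass member with abundance
  equal to the chain sum (abundance-conserving). Chain heads are chosen
  greedily from low m/z; only +1 charge is considered (linear MALDI of
  peptides).
* **Replicate averaging.** Peaks matched across the four replicates within
  the alignment tolerance; a signal is kept iff present in ≥ 3 of 4
  replicates; abundance and m/z are means over the replicates where present.
* **Cross-sample alignment.** Single-linkage clustering of all
  representative peaks (clusters split where the m/z gap exceeds the
  tolerance, default 0.3 Da). Clusters spanning ≥ 5 samples become table
  rows labelled by the cluster mean m/z. The threshold 5 is deliberately
  low: it protects signals private to the smallest group (19 controls).
  Absent entries are 0 — a presence/absence signal model, not missing-value
  imputation. If a cluster holds two peaks of one sample, the peak nearest
  the cluster mean is kept with a warning.
* **Exclusion.** Rows matching fpA/fpB masses are removed because those
  fragments selected the samples (testing them would be circular), as is the
  m/z 1051.71 polypropylene/polyethylene polymer contaminant. The default
  exclusion list is the four quality-gate fpA masses plus the contaminant; an
  extended, configurable ladder (`fpa_fpb_exclusion_masses`) enumerates
  [M+H]⁺ of every C-terminal suffix of fibrinopeptide A (ADSGEGDFLAEGGGVR)
  and B (QGVNDNEEGFFSAR) down to 5 residues — serum aminopeptidase
  degradation proceeds by N-terminal truncation, and the ladder reproduces
  the conventional fragment masses (e.g. des-A fpA 1465.65, des-AD 1350.63)
  to ~0.02 Da.

## SAM differential analysis

Two-class unpaired SAM on unlogged abundances (the workflow normalizes but
never log-transforms; a log2 flag exists):

    d_i = (mean_cases − mean_controls) / (s_i + s0)
    s_i = sqrt[(1/n1 + 1/n2) · (SS1 + SS2) / (n1 + n2 − 2)]

* **s0** by percentile search: candidates are the 0,5,…,100th percentiles of
  s; for each, the coefficient of variation of a windowed MAD of d across
  quantile bins of s is computed; the candidate minimising it wins. A fixed
  s0 can be supplied instead (used by the exhaustive-oracle tests).
* **Null distribution** from group-label permutations: exhaustive
  enumeration when the number of distinct splits ≤ n_permutations (default
  1000), else seeded Monte Carlo; s0 is held at its original-data value.
  Per-signal p-values are the fraction of permutations with |d*| ≥ |d|
  (for Monte Carlo, with the +1 correction).
* **q-values**: at each cutoff c = |d_(i)|, called = #{|d| ≥ c} and the
  expected false count is the *mean* over permutations of #{|d*| ≥ c}; q =
  false/called clipped to [0,1], then made monotone non-decreasing in rank
  (running minimum from the least-significant end, as in
  Benjamini–Hochberg). The median-count variant is available
  (`false_count_estimator="median"`) but is not the default: the median of a
  count that is zero in just over half the permutations is zero regardless
  of its mean, so the median variant assigns q = 0 to the top-ranked signal
  in roughly half of *null* datasets — measured at ~16/30 here — which
  destroys type-I behaviour. No π₀ shrinkage is applied (π₀ = 1,
  conservative).
* **Fold change** = ratio of raw group means, cases over controls, so values
  above 1 read as elevated in patients.

Degenerate inputs: a signal with zero scatter in both groups gets d via s0
alone (clamped to a tiny positive value if the search returned 0) and is
flagged `zero_scatter`.

## Bootstrap occurrence validation

100 datasets (default) are built by resampling samples with replacement
*within each group* to the original group sizes — stratified resampling is
the only scheme that conserves the group-size ratio exactly, which the
procedure requires. A draw that collapses a group onto one unique sample is
redrawn (it would have zero scatter). SAM is re-run per dataset; a candidate
signal scores an occurrence when it meets the significance rule *and* its
effect direction matches the original analysis. The default rule is the
permutation p < 0.05 (the rule under which occurrence counts are
conventionally reported); q ≤ threshold is available as an option.

A caveat worth stating: bootstrap replicates condition on the observed group
difference, so under a true null the occurrence rate is ~2–3× the nominal α
(measured ~0.16 at n = 12/20 with α = 0.05), not α itself. Occurrence counts
are a *stability* measure, not a second significance test.

## Covariate-adjusted regression

For each signature signal and comparison, ordinary least squares on
*abundance = β₀ + β·group + γ·covariate*, with age and gender adjusted in
separate models (two sub-analyses; a joint flag exists but is off by
default). β estimates the covariate-adjusted difference in mean abundance
between patients and controls. Because group sizes are small and abundances
heavy-tailed, the SE of β comes from a non-parametric case-resampling
bootstrap (default 1000 refits); the 95% CI is β ± 1.96·SE with a two-sided
normal p-value. A constant covariate is dropped with a warning, reducing β
to the raw difference of means. Parameter recovery: with planted β = 3 under
age confounding (controls mean 54 vs cases 71), the 95% CI covers the true β
in ≥ 90% of 50 simulated cohorts (92–94% measured).

## Adduct annotation and peptide masses

CHCA matrix adducts displace peptide ions by multiples of 189.04 Da. All
ordered signal pairs whose spacing is within tolerance (default 0.05 Da) of
k × 189.04 (k ≤ 2) are annotated with their mass error; when several parents
explain one adduct, the smallest |error| wins. Theoretical [M+zH]ᶻ⁺ values
use a hard-coded 5-decimal monoisotopic residue table (IUPAC/Unimod standard
values; proton 1.00728, water 18.01056), cross-checked in the tests against
an independent mass library. The known ~0.02 Da discrepancy between the
theoretical C3f mass (2021.104 for SSKITHRIHWESASLLR) and the observed
2021.084 signal is reported, never "corrected": annotation operates on
observed masses only.

## Synthetic-cohort generator

The generator produces what the analysis assumes, with ground truth stored
on every sample (and never read by any analysis stage):

* **Panel** (default 108 signals): 98 null analytes at fixed pseudo-random
  m/z, the internal standard (base 100, the normalization anchor), four fpA
  fragments (high-mass bases 60+60, low-mass 40+40, so the high/low ratio is
  1.5 when pristine and the quality gate flips at degradation ≈ 1/3), the
  1051.71 contaminant (folds 2.5/2.7 — planted so the exclusion filter has
  something real to remove), and four differential signals: 1561.72 (folds
  16.4 / 17.8 in non-metastatic / metastatic), 2021.084 (2.63 / 2.92),
  2399.165 (6.7 / 6.9) and 2210.13 (a single-CHCA adduct that tracks its
  2021.084 parent's effect and biological noise, as a true adduct would).
  After the exclusion filter the aligned table holds 103 signals.
* **Noise**: per-sample biological log-normal σ = 0.5 per signal (typical
  MALDI serum dispersion); per-replicate spot-intensity log-normal σ = 0.3
  applied to all peaks jointly (cancelled exactly by internal-standard
  normalization); per-peak replicate log-normal σ = 0.15; per-replicate
  constant m/z calibration offset sd 0.05 Da (cancelled by recalibration);
  per-peak m/z jitter sd 0.01 Da. The internal standard is spiked, so it
  carries no biological noise. All fpA/fpB fragments of a sample share one
  biological factor (σ = 0.2): they derive from one parent molecule, so the
  high/low ratio the quality gate reads reflects degradation, not
  independent fragment noise.
* **Degradation** is mass transfer: a sample at level δ moves a fraction δ
  of its high-mass fpA abundance onto the low-mass fragments
  (proportionally to their bases), strictly decreasing the high/low ratio.
  Default per-sample level ~ U(0, 0.15), i.e. cohorts that pass the gate —
  the default group sizes are the *post*-QC sizes of the emulated design.
* **Covariates**: ages truncated-normal per group (controls 54 ± 8 on
  [40, 67]; non-metastatic 71 ± 10 on [44, 89]; metastatic 71 ± 12 on
  [34, 93]); gender Bernoulli with the emulated proportions.
* **Profiles** on demand: each centroid becomes a Gaussian whose integral
  equals its abundance; scans differ only by additive baseline noise.
* Abundance units and dynamic range are arbitrary (the real instrument's are
  unspecified); both are exposed in the configs rather than fixed.

What the generator does **not** emulate: chemical/ionisation suppression,
detector saturation, correlated biological covariance structure between
analytes (each null signal is independent), mass-dependent resolution,
spectrum-level baseline drift, or batch effects. Passing tests therefore
demonstrate correct *statistical* behaviour of the pipeline under the
assumed noise model, not robustness to every artefact of real spectra.

## Problem sizes used in tests and the acceptance script

Simulation checks run at the emulated study's group sizes (19/80/92) with
the full peak-list path for signature recovery (20 seeds in the test suite,
10 in the acceptance script), ground-truth abundance tables for the 50-seed
type-I and bootstrap-saturation checks (the table path isolates the
statistics from rendering cost while keeping the identical between-sample
structure), 1000 permutations for headline runs and 300–500 inside
resampling loops. These sizes were chosen so the whole suite exercises every
stage at full cohort scale while remaining comfortable to run repeatedly
during development.

## Known limitations

* The SAM variant is two-class unpaired only; no multiclass, paired or
  survival modes.
* No charge-state deconvolution beyond +1; no wavelet or model-fitting peak
  shapes; no vendor raw-format support (mzML or 2-column text only).
* The exact extended fpA/fpB exclusion set of the emulated study is not
  published; the suffix-ladder default is a principled reconstruction, and
  the 122 → 103 reduction is reproduced on fixtures built to contain 19
  matching columns.
* Permutation p-values have resolution 1/(P+1) under Monte Carlo; q-values
  inherit permutation noise of order 1/√P.
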