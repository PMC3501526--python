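# Methods

## The measurement model

A SELDI-TOF acquisition is modelled as intensity over an m/z grid: a
decaying-exponential chemical baseline plus Gaussian peaks plus additive
grid noise.  Three laser-energy tiers are acquired per sample, optimised for
small (2–10 kDa), medium (5–30 kDa) and large (20–200 kDa) species; the
ranges overlap, so one molecule can legitimately appear in two tiers — the
pipeline treats such re-acquisitions as peaks to be merged during alias
resolution, as the vendor's clustering step does.

Peak shape is Gaussian with FWHM = m/z / R, R = 400 (linear-TOF-like
resolution, constant within a tier).  The grid is uniform in m/z with
spacing FWHM(tier start)/6, giving at least six samples across any peak.
Baseline: amplitude 2.0 decaying over a third of the tier span plus offset
0.1; grid noise σ = 0.05 (all in the arbitrary µA-like intensity units of
the study).

## The cohort generator

Cohort sizes default to the study's: P30 13/11, P60 16/16, P90 22/23
exposed/control.  Each protein has a base intensity, a lognormal biological
coefficient of variation, an optional developmental baseline per age, an
exposure effect (ENU/control ratio) per age, optional charge-state/dimer
satellites (z2 at (m+1)/2, z3 at (m+2)/3, dimer at 2m−1, each with a
relative abundance and 10% ionization jitter), and optional proteoforms
(adduct label, mass shift, per-group fraction).  Suppression is
`observed = true × (1 − s·S)` with S the suppressor's per-sample intensity
scaled to its cohort maximum — the simplest model producing a near-linear
inverse relation between suppressor and target.

The default panel anchors four named proteins to the study's measured
values and fills the rest with anonymous proteins until ~247 rendered peaks:

* **albumin-like**, 66 110 Da, high tier, control mean 13.1, cv 0.20,
  satellites z2/z3/dimer (0.32/0.042/0.034), exposure ratio 1.02/1.15/1.30
  by age, and a developmental rise (0.4/0.7/1.0) reflecting the strong age
  dependence of CSF protein composition (the reason normalization is
  age-grouped, and the driver of the pooled-age suppression regression).
* **transthyretin-like family**, base 13 601 Da, six proteoforms
  (unmodified, sulfo, cysteinyl, Cys-Gly, glutathionyl, γGlu-Cys) with
  fractions taken from the measured control/exposed means; both fraction
  vectors sum to 1, so exposure redistributes mass (away from the
  glutathionylated form) while conserving the per-sample total.  cv 0.15
  with 5% per-form jitter; z2 satellites (abundance 0.2) and weak dimers.
* **PGD2S-like**, 22 893 Da, control mean 23, cv 0.06 (an abundant, tightly
  regulated brain-derived protein), no true exposure effect; its *apparent*
  decrease is entirely the albumin-like suppression at strength 0.6 —
  the planted artifact.  Pooled over ages this yields r ≈ −0.90
  (cf. the study's −0.945).
* **fragment peptide**, 3 493 Da, low tier, cv 0.5, ratio up to 1.87 at P90.

Twenty-eight fillers carry exposure effects: the P90 fold change is drawn
uniformly from 1.4–1.9 (40% decreased), realised progressively with age
(~5% of the log effect at P30, 25–60% at P60) — the age-growing signal that
produces the discovery gradient.  Filler cv is uniform on 0.15–0.30,
intensities log-uniform on 0.4–30.

Peaks whose expected control-group apex falls below 0.30 (6× grid noise)
are not rendered: sub-noise satellites are not observable and would never
survive detection, so "planted" peaks are by construction detectable.

A fast path (`simulate_peak_matrix`) produces the quantified peaks×samples
matrix directly from the latent intensities (5% read-out error plus a
half-normal noise floor of 0.05), skipping spectrum rendering.  It is the
input contract of the statistics and classification stages and keeps
permutation and subsampling studies cheap; the rendering path is exercised
separately by the detection/quantification round-trip tests.

**What the generator does not emulate:** isotope structure, calibration
drift and peak-position jitter across spectra, detector saturation,
heavy-tailed or correlated biological variation beyond the planted
structures, and matrix-region artifacts.  Passing tests therefore show the
*pipeline logic* is sound under the stated statistical structure, not that
real spectra meet that structure.

## Preprocessing

Baseline: morphological opening (rolling minimum then maximum) with window
2% of local m/z, approximated piecewise over six log-m/z segments with
linear blending; peaks (FWHM 0.25% of m/z) are ~8× narrower than the
window, so apex heights survive within 5%.  Noise: 1.4826·MAD of first
differences /√2 per segment (insensitive to smooth baseline and sparse
peaks).  Normalization: each spectrum scaled so its TIC (above m/z 1500)
matches the median TIC of its (age, tier) group — within age because
composition differs strongly by age.  Blood QC: samples whose globin-window
(m/z 15216 ± 0.3%) apex exceeds 3× the cohort median are flagged.

## Peak detection, quantification, aliases

Detection runs per tier on the mean of all preprocessed spectra, but SNR is
referenced to the *individual*-acquisition noise (median per-spectrum noise
profile): a peak must be measurable in single spectra, not merely in the
101-fold average.  Local maxima need height ≥ 5× that noise, prominence
≥ 2.5×, and ≥ 3-point width; windows are apex ± 0.3% m/z, trimmed at
midpoints so they partition disjointly.  Quantification is apex height
(window maximum minus the smaller window-edge value, clipped at zero) — the
study reports peak heights, not areas.

Alias resolution must break a genuine symmetry: a = z2-of-m and
m = dimer-of-a are the same arithmetic.  The rules, in order: (1) merge
cross-tier duplicates at 0.15% tolerance (re-acquisitions agree far more
tightly than charge-conversion arithmetic; a looser merge would fuse
proteoform satellites interleaved across tiers), keeping the tier whose
range centre is nearest in log-m/z; (2) enumerate candidate edges at 0.5%
tolerance; (3) gate on intensity (a satellite cannot out-shine its parent;
unknown intensities pass) and, when per-sample data exist, on Pearson
correlation ≥ 0.5 with the parent; (4) each alias keeps its
minimum-deviation parent; (5) remaining two-cycles resolve in favour of the
charge-state reading, then toward the less intense member as the alias.
Adduct ladders use 0.1% tolerance (same-tier, better calibrated) against
the fixed table {cysteinyl 119.004, Cys-Gly 176.026, glutathionyl 305.068,
sulfo 79.957, γGlu-Cys 248.047 Da}; the γGlu-Cys entry covers the
glutamyl-cysteinyl proteoform whose z2 satellite is a top-ranked marker.

## Statistics

Mann-Whitney *U*, two-sided: exact enumeration when n₁+n₂ ≤ 12 and the
pooled sample is tie-free, otherwise the tie-corrected normal approximation
with continuity correction; identical pooled values give p = 1.

Permutations shuffle animal identities *within* an age stratum (group sizes
preserved by construction), 100 by default, seeded.  The global FDR curve
compares observed discovery counts with the mean permuted count on a grid
of thresholds up to 0.05.  The local FDR of peak *i* is the expected
permuted count of p-values in the window [pᵢ/c, pᵢ·c] (c = 2; widened until
it holds ≥ 5 observed p-values) divided by the observed count there, with
the null pooled across all peaks — a per-peak-only null at 100 permutations
cannot resolve local FDRs of order 10⁻³.  Values are clipped to [0, 1] and
monotonized (running maximum along increasing p), so a discovery can never
look more credible than one with a smaller p.

Diagnostics: Pearson chi-square homogeneity for the pathology incidence
table; ordinary least squares of target on suppressor, all ages pooled, for
ion suppression; the proteoform-sum test applies the Mann-Whitney test to
per-sample family totals.

## Marker selection

The homotopy path of min_β ½‖y − Xβ‖² + λ‖β‖₁ is traced from
λ = max|Xᵀy| downward on column-standardized X and centred ±1 labels;
features join when their correlation with the residual reaches the active
level, drop when a coefficient crosses zero, and exact duplicate columns
resolve to the lower index (columns are m/z-ordered).  The path is
piecewise linear in λ and is verified against an independent
coordinate-descent LASSO to 10⁻⁶ on random problems.

The size-k classifier is the solution at the *end* of the first path
segment with k active features.  Cross-validation draws 36 of the 45
oldest-age animals group-proportionally (18/18), standardizes using the
training fold only, fits the path to k_max, and scores every k on the 9
held-out animals.  Held-out scoring uses the LARS-OLS hybrid: the path
chooses the size-k marker set and an unpenalized least-squares refit on
those markers makes the prediction.  With the path's shrunken coefficients
the error curve plateaus or keeps falling past the true marker count —
relief of shrinkage on informative features masks the cost of noise
features — and the characteristic error minimum at the planted size does
not appear; the refit restores it while leaving selection frequencies
(active-set membership) untouched.  Selection frequency is the fraction of
repeats in which a peak sits in the five-marker active set; aliased peaks
are *not* collapsed before selection (correlated satellites legitimately
split the vote), but the report joins alias annotations afterwards.

## Benchmarks, problem sizes and thresholds

The test suite runs the simulation-based checks at stated sizes chosen as
this package's benchmark conditions: 20 cohort seeds for null calibration
and planted-effect recovery (100 permutations each; 1000 for the
null-curve convergence check), and 10 experiment replications × 200
subsample repeats for the five-marker benchmark (ratio 1.7, cv 0.2,
5 informative among 247).  Expectations: ≥ 80% of strongly planted peaks
(fold ≥ 1.3) below local FDR 0.05 at P90 with null peaks' median ≥ 0.25;
null discovery counts inside the central 95% binomial band in ≥ 80% of
seeds (alias correlation makes counts mildly overdispersed, so the band is
applied across seeds rather than to every seed); the error-minimizing
marker count in {4, 5, 6} and the planted peaks atop the frequency table in
≥ 80% of replications.  All thresholds were fixed from pilot runs of the
generator defaults before the tests were frozen.

## Numerical and design choices

* Seeds: every stochastic operation takes an explicit seed; pipeline stages
  derive theirs from the config seed by fixed offsets, so reruns are
  byte-identical.
* Degenerate inputs: constant peaks give p = 1 and local FDR 1; zero-TIC
  spectra are excluded from normalization with a NaN factor; zero-variance
  columns are inert under standardization; empty alias windows widen until
  populated.
* mzML can be read (via pyteomics) but spectra are persisted as long-form
  CSV; no mzML writer exists in the dependency set.
* Known limitations: no peak alignment/warping across spectra, no
  deisotoping, no cross-tier intensity reconciliation beyond duplicate
  merging, logistic-loss LASSO intentionally out of scope.
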