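# Methods

## Mass arithmetic

Peptide neutral monoisotopic mass is the sum of residue masses (standard
monoisotopic values fixed to five decimals), one water (18.010565 Da) for
the termini, and modification deltas: Amadori/fructosamine +162.052824 Da
(one hexose on K), carbamidomethyl +57.021464 Da (on C), oxidation
+15.994915 Da (on M). Ion m/z is `(M + z·m_p)/z` with the proton mass
m_p = 1.00727646 Da. With constants at this precision, theoretical m/z is
reproducible to well below 1 ppm; agreement with externally observed values
is asserted at 10 ppm because reported observed m/z carry instrument jitter
of a few ppm (two charge states of the same observed peptide can imply
neutral masses differing by ~1 mDa).

Charge-state enumeration runs from z = 2 (singly charged tryptic ions are
rarely informative in ESI annotation) to one more than the count of basic
sites (R, H, K without Amadori, N-terminus), capped at z = 5, the largest
charge state observed in practice for this peptide class.

In-silico tryptic digestion cleaves after K/R, suppressed before proline
and, by default, at glycated lysines — the Amadori adduct blocks trypsin,
which is why glycated tryptic peptides carry internal modified lysines.
Up to 3 missed cleavages are generated by default. Pyrylium/furylium
diagnostic fragment masses are not hard-coded (no canonical values exist);
callers supply their own m/z lists where needed.

## XIC quantification

An XIC sums centroid intensities within ±0.02 Th of the target m/z per
scan. Peak integration: the apex is the trace maximum within ±0.5 min of
the expected retention time (consistent with retention-time RSDs < 1%); a
local linear baseline is interpolated between the window edges; the area is
the trapezoidal integral of the contiguous above-baseline region around the
apex. The noise estimate for S/N is 1.4826 × the median absolute deviation
of the trace outside the window (σ-equivalent under normality); a peak is
"detected" iff S/N ≥ 3. On sparse centroided traces the out-of-window
baseline can be identically zero, in which case a positive peak reports
infinite S/N; this is deliberate (the detection rule, not the S/N value, is
the contract). The reference integration algorithm was vendor software;
only the ±0.02 window and the S/N ≥ 3 rule are prescribed, so baseline and
noise estimators here are the simplest testable choices.

## Feature-table assembly

Peak areas are normalized per sample by `reference / concentration`, the
reference defaulting to the cohort median plasma protein concentration
(robust, and invariant to a common rescaling of all concentrations).
Areas of a peptide's charge states are arithmetically averaged after
normalization (both operations are linear, so the order is immaterial; we
normalize first). Undetected abundances are imputed as half the feature's
minimum detected value before statistics.

## Univariate screening

Each feature is tested with the two-sided Mann–Whitney U test, U reported
in the min-of-groups convention. P-values are exact (permutation
distribution) for tie-free groups below 8 per side, otherwise the
tie-corrected normal approximation. Family-wise error over the panel is
controlled with Holm–Bonferroni step-down at α = 0.01.

Per-feature Ac/Sp/Sn are computed at the in-sample accuracy-maximizing
abundance threshold (candidates: midpoints between distinct pooled values;
samples above the threshold are called cases, matching the upregulated
direction of glycation; accuracy ties break toward higher specificity, then
the lower threshold). This is an optimistic in-sample bound, flagged as
such in the API documentation; it reproduces the arithmetic identity
`Ac = (Sn·n_cases + Sp·n_controls)/n` that ties the three percentages to
the 20/18 cohort sizes.

## Feature selection

`VIF_i = 1/(1 − R_i²)`, with R_i² from an intercept-including least-squares
regression of feature i on the remaining features; perfectly collinear
features report `inf`. The randomized filter starts each run from a random
feature pair, adds the remaining features in random order, and after every
addition removes the largest-VIF feature (recomputing VIFs after each
single removal) until the subset's maximum VIF is at or below the cutoff
(5 or 10, the conventional critical values corresponding to 80%/90% shared
variance). Because the surviving subset depends on the test order, the run
is repeated (1000 times by default) under a seeded generator and subsets
are tallied; reporting exposes the full frequency table, the top subset,
and all subsets above a representation fraction (default 0.70). If a
subset's size ever reaches the sample count, the newest feature is removed
outright — the regression would be underdetermined, meaning the feature is
perfectly predictable from the rest.

PCA is computed on standardized features (correlation-matrix convention;
raw peak areas span orders of magnitude and centered-only PCA would be
dominated by the largest features). The minimal number of leading
components whose cumulative explained variance reaches 95% is retained;
zero-variance features are dropped with a warning.

## LDA and validation

The Fisher discriminant uses the unbiased pooled within-class covariance;
weights `w = S⁻¹(μ_case − μ_control)`, threshold at the midpoint of the
projected class means (equal priors: the generated training sets are
balanced and the original cohort nearly so). If the covariance condition
number exceeds 1e10, a ridge of `1e-6 · trace/d` is added and flagged on
the model.

Leave-one-out cross-validation refits the discriminant n times, each time
scoring the held-out sample; the confusion matrix accumulates over held-out
predictions only.

Sub-sample training draws each coordinate of each synthetic training vector
independently from the corresponding class's empirical per-feature value
pool, and rejects candidates sharing ≥ 25% of their coordinate values
(exact matches — well defined since values come from the originals' pools)
with any original sample. "Shared" is counted against all originals of both
classes. For feature sets of ≤ 4 features the 25% limit permits zero
matches, which pool-drawn vectors cannot achieve (each coordinate exactly
matches its source sample); the constraint is then disabled with a warning
rather than failing, so degenerate low-dimensional models remain usable.
If the constraint is satisfiable but pools are too degenerate (e.g. all
rows of a class identical), generation aborts with a diagnostic after a
bounded number of redraws. The trained model scores all original samples
as an untouched verification set.

## Synthetic cohort generator

The generator emulates the target study design: 20 cases vs 18 controls
over 42 non-negative features. Log-abundances are multivariate normal with
block-equicorrelated correlation — default blocks (27, 6, 5, 4) mirroring
the protein groupings of the annotated panel (27 albumin peptides, 6
serotransferrin, remaining proteins pooled), within-block r = 0.8 (the
reference data show strong multicollinearity but no quantified correlation
values; r is a free parameter). Per-feature log-means are uniform over
[ln 1e4, ln 1e6] (typical XIC peak-area magnitudes), within-feature log-SD
0.5. Cases receive a configurable log-scale shift on the differential
feature set — by default all 42 features at +1.0 (≈ e-fold, i.e. two
within-feature SDs), matching a panel in which every member is
significantly upregulated. Plasma protein concentrations are drawn per
group at 58.8 ± 9.85 (cases) and 61.9 ± 13.5 mg/mL (controls), clipped
at 10 mg/mL.

What the generator does **not** emulate: heavy-tailed or batch-structured
intensity noise, missingness correlated with abundance, retention-time
drift, inter-protein correlation, or any real biological link between
glycation sites and disease. Tests passing on these cohorts demonstrate
the correctness and calibration of the statistical machinery under the
declared model, not clinical performance on real plasma data.

The chromatogram generator renders each target as a Gaussian elution peak
(width σ_t = 0.1 min, 2-s scans) whose amplitude encodes the requested
area, an optional log-normal run-to-run area jitter (`area_cv`), and a flat
baseline of random centroids with exponential intensities across the
acquisition m/z range.

## Numerical and testing choices

- Problem sizes in the statistical test-suite (500 null cohorts for the
  family-wise-error check, 25 replicates for power, 200 filter runs for the
  end-to-end check) are chosen so each property is measured with useful
  binomial resolution while the whole suite stays interactive.
- The family-wise error bound is asserted at the nominal 1% plus three
  binomial standard deviations over 500 replicates.
- Mass computations are cross-checked against pyteomics as an independent
  oracle; VIF against statsmodels; LDA direction against scikit-learn.
- Packaged reference tables are integrity-checked by SHA-256 before
  parsing. Four rows of the glycopeptide panel carry sensitivity and
  specificity transposed (the accuracy identity only holds with the two
  swapped); the tables are stored verbatim and the consistency test
  accepts either orientation for those rows.

## Known limitations

- The in-sample per-feature threshold scan overstates single-marker
  accuracy; use the cross-validated multivariate reports for performance
  claims.
- The randomized VIF filter's subset frequencies depend on the seed and the
  number of runs; frequencies stabilize by ~1000 runs at this panel size.
- The exact-match definition of "shared values" in sub-sample training is
  meaningful only for values drawn from finite empirical pools; after any
  continuous transformation of the table it degenerates to no sharing.
- mzML ingestion reads centroided MS1 scans only; profile-mode data must be
  centroided upstream.
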