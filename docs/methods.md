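# Methods

## Model and assumptions

The pipeline treats a bait protein's interactome as a superposition of
*modules*: groups of proteins (and bait phospho-proteoforms) that co-migrate
as one band under native electrophoresis.  The generative picture is

* each module `m` migrates as a Gaussian band with apex fraction `a_m` and a
  shared width (FWHM, with `σ = FWHM / 2.355`);
* a member protein's migration profile is the weighted sum of the bands of
  every module it belongs to (multi-assembly proteins contribute several
  peaks);
* a bait phosphopeptide attached to module `m` co-migrates with `m` and, in
  addition, scales with the bait's own level per fraction — which is why
  phosphopeptide profiles are divided by the bait protein profile before
  analysis;
* measurement noise on MS1 intensities is multiplicative log-normal, and
  individual fraction values can drop out (missing, never zero).

Under this model, splitting each profile at detected peaks and clustering
single-peak traces by correlation distance identifies the modules; the
phosphosites whose traces land in a module's cluster are its
*phosphosignature*.

## Stage parameters (defaults)

| Stage | Parameter | Default | Meaning |
|---|---|---|---|
| apms | `saint_threshold` | 0.90 | interactor kept iff score strictly above |
| apms | `top_n_peptides` | 2 | protein = sum of top-n unique peptide intensities |
| apms | `impute_percentile` | 5 (1 for mutant/DIA-style panels) | center of left-censored imputation, percentile of the run's observed log2 intensities |
| apms | `max_single_missing_per_condition` | 1 | up to this many missing replicates are median-imputed |
| kinetics | `n_clusters`, `fuzzifier` | 3, 2.0 | fuzzy c-means c and m (three response clusters; both exposed) |
| peaks | `min_norm_intensity_protein` / `_phospho` | 0.2 / 0.3 | smoothed-peak height gates on max-scaled profiles |
| peaks | `width` | 2 fractions | FWHM of the smoothing kernel and the peak-merge radius |
| peaks | `loc_any_fraction` / `loc_per_fraction` | 0.8 / 0.5 | two-level phosphosite localization filter |
| clustering | `linkage`, `k_min..k_max` | average, 2..15 | silhouette-chosen k on the correlation-distance matrix |
| integration | `fc_down`, `fc_up`, `p_max` | −1, +1, 0.05 (strict) | association classes against site-null mutants |
| prm | `rt_tolerance_fraction` | 0.05 of gradient | RT match window |
| prm | `min_dotp` | 0.75 (strict >) | observed/library fragment cosine |
| prm | `min_sn`, `quant_top_fragments` | 5 (strict <, removed), 3 | fragment S/N gate, top-n area sum |

An alternative peak gate of 0.4 (used in some graphical summaries of this
kind of data) is available through the config; 0.2/0.3 are the analysis
defaults.

## Synthetic-data generator

The generator's defaults define the study conditions used by the tests and
the acceptance script:

* **BN-PAGE**: 9 modules of 3–8 members over 64 fractions, FWHM 2, apexes
  at least 2 × FWHM apart, log-normal stoichiometry weights (σ = 0.3),
  multiplicative noise σ = 0.2, dropout 5%, localization scores drawn in
  (0.8, 1.0) on the peak support and (0.5, 1.0) elsewhere so the two-level
  filter is exercised but true sites pass.
* **AP-MS**: 2–5 peptides per protein, log-normal intensities (replicate
  σ = 0.2 on log2), planted per-condition log2 fold changes, 5%
  missingness, scores ≥ 0.95 for true interactors and < 0.5 for background.
* **PRM**: 6 fragments per peptide with geometrically decaying library
  intensities (ratio 0.45 with ±20% jitter — steep patterns with one or two
  dominant fragments, as in real assay libraries), multiplicative noise
  σ = 0.1, RT jitter σ = 1% of the gradient.  Decoys are either RT-shifted
  by 7–25% of the gradient or have deranged fragment ratios.  With these
  settings the stated acceptance rules (5% RT window, cosine > 0.75)
  separate true peaks from decoys, which is the regime the thresholds were
  designed for.

What the generator does **not** emulate: correlated noise across fractions,
peak tailing/asymmetry, co-eluting interferences in PRM traces, intensity-
dependent missingness, shared peptides between proteins, and any form of
identification error (the spectra-to-peptide step is upstream of this
package).  Passing the synthetic benchmarks therefore demonstrates that the
numerics and decision rules behave as specified under the assumed model —
not that the thresholds are optimal for any particular instrument or
sample.

## Numerical choices

* **Top-n peptides** are combined by *sum* (monotone, robust for
  single-peptide proteins, scale-consistent).
* **Differential tests** are Welch (unequal variance) by default with a
  pooled-variance switch; with zero variance in both groups the p-value is
  defined as 1 for equal means.  BH correction is applied within each
  contrast, not globally.
* **Imputation**: exactly one missing replicate per condition takes the
  observed within-condition median; more missing values draw from a normal
  centered at the run's `impute_percentile` log2 quantile with sd equal to
  the median within-condition replicate sd.
* **Neighbour imputation** of migration profiles: interior single gaps take
  the mean of the two flanking fractions; edge gaps take the single
  available neighbour; longer runs stay missing and count as zero signal in
  detection.
* **Peak detection** operates on the Gaussian-smoothed profile
  (σ = width/2.355, zero-padded ends); maxima closer than `width` are merged
  keeping the higher; splitting cuts at the smoothed minimum between
  adjacent apexes, with the valley fraction assigned to the left (higher
  mass) trace so the traces partition the profile exactly.
* **Peak distance** is Pearson-based on the union of supports: disjoint
  supports → 2, constant trace on the union → 1.  Silhouette model
  selection runs on that same distance matrix by default (a Euclidean
  variant on the trace vectors is available; on the synthetic benchmark
  both select the planted k).  Ties in silhouette go to the smaller k; if
  all distances vanish, k = 1 is reported as a degenerate case.
* **Molecular weight** is interpolated linearly in log10(kDa) versus
  fraction; out-of-range apexes extrapolate from the nearest segment and
  are flagged.
* **Fuzzy c-means** runs on row-z-scored profiles with seeded random
  memberships and 10 restarts, keeping the lowest objective; the objective
  is non-increasing within a run by construction.
* **Recall background**: the comparison distribution resamples, per module,
  200 random member sets of the same size from the interactor universe
  (excluding the bait); the alternative — a single pooled background value —
  would make the t-test ill-defined.
* **PCA** for KO panels is computed by SVD of the column-centered,
  unscaled replicate-level log2 fold-change matrix (entities are already on
  a common log scale); variance ratios always sum to 1.

## Design notes

* "Median of biological replicates" for imputation is read as the median of
  the *observed replicates in that condition*, not across conditions.
* An association between an interactor and a phosphosite requires
  co-migration in *some* module, and the mutant effect may come from any
  module (the matrix records the module multiplicity).
* Whether smoothing precedes or follows apex normalization is fixed as:
  normalize to max 1, then smooth for detection; split traces keep the
  unsmoothed values so partition is exact.
* The problem sizes used by the test suite and acceptance script (20
  simulation seeds for module recovery, 100 for PRM gatekeeping and
  differential recovery, 1,000 instances for the statistical oracles) are
  the package's benchmark conditions; all complete in well under a minute
  per block on one CPU.

## Known limitations

* Overlapping modules closer than ~2 × FWHM are not deconvolved (no mixture
  fitting); they merge into one module or split unstably.
* Localization filtering censors fractions rather than re-assigning
  ambiguous phosphopeptides to alternative sites.
* The recall t-test treats module recalls as independent observations; with
  very few modules the Shapiro–Wilk normality check has little power.
* PRM S/N is taken from the input table (or a pluggable strategy); the
  package does not re-derive noise from raw chromatograms.
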