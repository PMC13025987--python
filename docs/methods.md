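# Methods

This note documents the models behind `aromastages`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Data model and units

Abundance tables carry a unit tag tracing the semi-quantification
chain: `raw_area` (detector counts) → `is_normalized` (µg/g after
internal-standard scaling) → `percent` (per-sample relative content).
The internal-standard step implements

    value'(s, c) = value(s, c) / IS_area(s) × m_IS / m_sample

with defaults m_IS = 0.5 µg (a 10 µL spike of a 50 µg/mL deuterated
hexanone solution) and m_sample = 0.5 g. Relative content divides each
sample by its own total and multiplies by 100, so rows sum to 100
exactly; it is invariant to any positive rescaling of the raw data.
Missing cells are disallowed — an explicit 0 means "not detected" and
is handled downstream by a pseudo-count (default: half the smallest
positive value in the table) in log2 fold changes.

Stage labels are fixed to the process order RM → IF → FF (raw
material, intermediate, final fermentation); every ordered output uses
it. Files are UTF-8 delimited text, tab by default with comma
auto-detection, because chemical names routinely contain commas.
Whether published relative contents are percent-of-total or
internal-standard-scaled varies between studies; the unit tag makes
the state explicit instead of guessing, and the rOAV step requires
`percent` under the default configuration.

## Univariate statistics

One-way ANOVA uses the classical between/within decomposition; the
degenerate all-constant input is defined as F = 0, p = 1. Duncan's
multiple range test ranks group means descending and compares each
stretch of p consecutive means against the critical range

    R_p = q(1 − α_p, p, df_err) · sqrt(MSE / n_h),
    α_p = 1 − (1 − α)^(p−1),

with q the studentized-range quantile (computed from
`scipy.stats.studentized_range`, not printed tables), MSE the ANOVA
error mean square and n_h the harmonic mean group size. Ranges nested
inside a non-significant wider range are declared non-significant
(step-down shielding), and letters are assigned per maximal
non-separated stretch. At k = 2 the procedure reduces to the pooled
two-sample t-test decision, which the test suite checks.

Volcano classification is a pure function: increased iff
log2FC ≥ log2(fc_threshold) and p < p_threshold (defaults 2 and 0.05,
both configurable), decreased symmetrically, else unchanged. p-values
are reported raw by default — matching common practice in targeted
flavor profiling — with optional Benjamini–Hochberg adjustment.
Class-composition percentages are rounded half-up to two decimals, the
convention of published inventory tables.

## PCA and OPLS-DA

Both are implemented in-repo. PCA is the SVD of the scaled matrix with
a deterministic sign convention (largest-|loading| element positive).

Scaling defaults to unit variance (autoscaling) with the *population*
standard deviation, so a two-point column (0, 2) scales to (−1, 1);
Pareto and center-only modes are available. Constant columns are
flagged and left at zero rather than dropped, with a float-tolerant
constancy test (a repeated 4.2 has sd ≈ 1e-15 after mean subtraction).

OPLS-DA (two classes, one predictive component, `n_ortho` orthogonal
components, default 1) follows the orthogonal-signal-correction
factorization: the predictive weight is w ∝ X'y; each orthogonal round
takes the loading p of the current predictive score, removes its
y-predictive part (w_o ∝ p − (w'p)w), deflates X by t_o p_o', and
re-derives w on the filtered matrix. With n_ortho = 0 the fit is
exactly a one-component PLS1, which the tests verify against an
independently coded NIPALS loop and against scikit-learn's
`PLSRegression`. Predictive scores are oriented so positive values
mean the second (later-stage) class — swapping labels negates scores
and leaves R²Y/Q² unchanged; orthogonal weight vectors use the
largest-element-positive convention. There is no random
initialization: identical inputs give bit-identical models.

VIP uses the standard PLS formulation over the model's retained
components, weighted by the response sum of squares each score
explains; orthogonal components explain ≈ 0 of the response by
construction, so the ranking is driven by the predictive weights and
mean(VIP²) = 1 holds identically. OPLS-specific VIP variants (e.g.
separate predictive/orthogonal importances) are out of scope.

Q² = 1 − PRESS/SS_y over held-out predictions with stratified,
seed-deterministic folds (default 7, falling back to leave-one-out
when n < 2 × folds). Fold assignment depends only on the class
partition, never on which class is coded 0 or 1. The permutation test
refits R²Y and Q² under `n_perm` label shuffles (default 200) and
reports the add-one empirical p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm+1),
keeping all permuted values for the usual validation plot. With 3
replicates per group only 20 distinct labelings exist, so the
empirical p has a floor near 0.1; the calibration tests therefore use
9-per-class geometries, where pure-noise false-positive rates stay at
or below the nominal level.

## Differential screening

A compound is differential for a contrast iff VIP > 1.0 AND p < 0.05,
both strict inequalities; the thresholds are configurable and the
selection is monotone in both. Contrasts are within-batch stage
comparisons (later stage coded positive). The Venn partition is the
exact membership-bitmask decomposition over any number of contrasts;
"common differential compounds" is the full-intersection cell, which
is also the aggregation the recovery experiment uses: a planted
compound counts as recovered when selected in all four batch-stage
contrasts, mirroring how cross-batch-consistent compounds are
prioritized in stage-resolved studies.

## rOAV

Odor activity of compound i is its content-to-threshold ratio
C_i / T_i; rOAV rescales so the most active compound scores exactly
100:

    rOAV_i = (C_i / C_max)(T_max / T_i) · 100
           = (C_i / T_i) / (C_max / T_max) · 100.

The two algebraic forms agree to 1e-12 and the statistic is invariant
to positive rescaling of contents and to compound order (ties in the
reference argmax break lexicographically). The reference scope
defaults to `global` — one reference for the whole dataset, computed
from mean activity over all samples — so rOAVs are comparable across
stages and batches, which cross-stage trajectories require;
`per_sample` and `per_group` scopes exist because "the sample" is
ambiguous in informal usage. rOAVs are computed per replicate and
summarized as mean ± SD per (batch, stage); computing on group-mean
contents instead is a caller choice (pass group-averaged tables).

Contribution bands: key if rOAV ≥ 1, contributor if 0.1 ≤ rOAV < 1,
minor below. The ≥ 1 boundary (rather than a strict >) is the
documented convention here and is boundary-tested; compounds without a
literature threshold are reported as `no_threshold`, never silently
dropped, and are excluded from reference selection.

## Flavor wheel

Key compounds (any group-mean rOAV ≥ 1) join exactly one of seven
sensory categories via their annotated aroma category; when the
annotation is missing, the first descriptor that names a wheel sector
decides, with a warning — multi-descriptor aromas still get a single
sector, keeping cumulative sums free of double counting. Cumulative
category scores are sums of member group-mean rOAVs. Batch comparisons
are two-sided Welch t-tests on replicate-level category totals (not
group means), so the test has genuine degrees of freedom; the star
scale is ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 / 0.0001.
The *** level is included even though some published captions skip it,
to keep the mapping monotone. JSON export is deterministic: canonical
category order, members by descending average rOAV.

## Synthetic data generator

The generator emulates a two-batch, three-stage, three-replicate
design with 134 volatiles in 10 chemical classes (33 hydrocarbons, 22
alcohols, 15 ketones, 13 esters, 13 aldehydes, 12 heterocyclics, 8
aromatics, 6 phenols, 5 acids, 7 others). The expected abundance is

    E[x(s, c)] = baseline_c · stage_factor_c(stage) · batch_factor_c(batch, stage)

with log-normal replicate noise at CV 0.20 (GC-MS peak areas are
positive and right-skewed, hence the log-normal choice throughout).
Baselines are log-normal (ln-mean 13, ln-sd 1.5, i.e. peak areas around
4×10⁵ counts). Class-level stage trends default to alcohols declining
(×0.75, ×0.80 across the two transitions) and esters/aromatics rising
(×1.25, ×1.2), the qualitative pattern of pile fermentation. The batch
signature is exp(sd_stage · z_{c,batch}) with one latent z per
(compound, batch) and sd halving per stage (0.30 → 0.15 → 0.075): the
two batches start apart and converge, as stage-trajectory ordinations
show, while the signature largely cancels within a batch so the
within-batch null calibration stays honest. A pseudo-compound spiked
at a constant amount (with injection noise a tenth of the replicate
CV) provides the internal-standard channel, exercising the
normalization path end-to-end. Odor thresholds draw log-uniformly from
0.1–1000 µg/kg; aroma categories and descriptors come from a built-in
seven-category lexicon.

Twenty planted differential compounds receive a stage multiplier of at
least |log2| = 2 (4-fold, random sign, applied from IF onward), drawn
across all classes, and are recorded with their true multipliers in an
exportable ground-truth file. The recovery experiment switches the
class-level trends off (all multipliers 1) so that non-planted
compounds are genuinely null — with trends active, the screen
*correctly* detects trend-following compounds, which would be
miscounted as false discoveries against the planted-only truth. Under
those conditions the test suite requires the screen to recover planted
effects with sensitivity ≥ 0.9 at FDR ≤ 0.15, pooled over 20 seeds.

What the generator does not emulate: chromatographic artifacts
(co-elution, retention drift), censoring at the detection limit,
within-pile spatial heterogeneity (absorbed into replicate noise),
correlated compound families beyond class trends, and heavy-tailed
contamination. Passing recovery tests therefore demonstrate the
pipeline's correctness under its stated statistical model, not
robustness to every failure mode of real instruments.

## Problem sizes and determinism

Default analyses run on 18 × 134 tables in well under a second per
contrast; permutation validation at 200 shuffles with 7-fold (or LOO)
cross-validation takes a few seconds. The test suite's calibration
studies use 12–18-sample matrices with 15–40 variables and 20–50
seeds, sizes chosen so the full suite completes in well under a
minute while keeping Monte-Carlo noise far from the asserted margins.
Every stochastic step (generator, folds, permutations) flows from an
explicit integer seed; the pipeline manifest records the package
version, a config hash, the seed and per-stage counts, and re-running
a pipeline with identical inputs and config is byte-identical.

## Known limitations

- Two-class OPLS-DA only (one predictive component); no multi-class
  extension, O2PLS or kernel variants, and no automatic selection of
  the orthogonal-component count.
- The nested design (replicates within batch within stage) is analyzed
  with fixed-effect contrasts per batch, not mixed models.
- Nonparametric alternatives (Kruskal–Wallis) are not provided.
- Odor thresholds are taken as given; matrix effects on perception and
  threshold uncertainty are not propagated into rOAV.
- The permutation p floor on 3-replicate groups (above) is a property
  of the design, not of the implementation.
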