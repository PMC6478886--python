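# Methods

`partglm` implements the classical partitioned-error analysis of
group-level repeated measurements inside a single-error-term GLM
framework: symbolic expected-mean-squares (EMS) derivation, exact
error-term selection, a multi-model plan with data averaging, Type III
contrasts derived from design-matrix rows, stratum-matched covariates,
sphericity diagnostics, and a vectorised mass-univariate executor.

## The model family

The supported designs have one random *unit* factor (subjects), any
number of fixed within-subject factors fully crossed with the subjects,
and fixed between-subjects factors in which the subjects may be nested.
The full model for two within factors (A, B) and one between factor (C)
is

    y_ijkl = mu + a_i + b_j + g_k + (ab)_ij + (ag)_ik + (bg)_jk
             + (abg)_ijk + S_l(k) + (Sa)_il(k) + (Sb)_jl(k) + e_ijkl

with S ~ N(0, s_s^2), (SW) ~ N(0, s_sW^2), e ~ N(0, s^2).  The random
subject terms partition the error into strata: subject,
subject-by-within-factor, and the residual (which equals the highest
subject-by-within interaction).  Purely between-subjects designs (no
unit factor, n replicates per cell) are also supported; designs with
several random unit factors (e.g. subjects *and* items) are out of scope
and refused, as is replication under the subject factor.

## EMS derivation and error-term selection

EMS are derived by the tabular (Cornfield–Tukey / Kutner) rules in the
**restricted-model** convention: one row per term, one column per
subscript; a bracketed nesting index contributes 1, a live index 0 for a
fixed factor and 1 for a random one, an absent index its level count.
Term U contributes to EMS(T) when U's subscripts contain T's, with
coefficient the product of U's entries over the indices outside T.
Coefficients are kept as sympy products of level-count symbols, so the
balanced-template tables can be rendered and asserted literally;
numeric designs substitute integers on demand.

The exact denominator for an effect is the unique stratum whose EMS
equals the effect's EMS minus its own component.  If no stratum matches
(e.g. a fixed factor crossed with two random factors), the engine raises
a quasi-F-required error naming the unmatched variance components —
Satterthwaite pooling is deliberately not constructed.  If several
strata matched (impossible in the supported family), it raises an
ambiguity error rather than choosing.

*Restricted vs unrestricted.*  Under the restricted convention the
subject-by-within effects sum to zero over the fixed factor's levels for
each subject, and s_sW^2 is the variance parameter of that convention
(the marginal variance of a draw is (l-1)/l times it).  The synthetic
generator draws accordingly (iid Gaussians centered within subject), so
the EMS tables are the exact expectations of the mean squares —
this is what `monte_carlo_ems_check` verifies.  F-ratios are identical
under the unrestricted convention, because the extra components appear
in numerator and denominator EMS alike.

## The multi-model plan

A single-error-term GLM always tests against the residual of whatever
model it is given.  To test an effect against the stratum its EMS
demands, the data are averaged over the within-subject factors absent
from that stratum; the stratum then becomes perfectly collinear with the
residuals of the averaged model and *is* its error term.  The plan
therefore contains one sub-model per distinct error stratum: for the
2 x 3 x 2 example, four sub-models (between model averaging over both
within factors; one model per within factor averaging over the other;
the full model).  Averaging divides all sums of squares by the product
of the averaged level counts; since numerator and denominator scale
together, F is invariant — the package reports the averaged-scale SS and
the invariant F.

## Degrees of freedom

For fixed effects, df is the product of (levels − 1) over the effect's
factors.  Subject-derived strata use

    df(S x V) = (sum_k n_k − g − c) * prod_{w in V} (l_w − 1)

with actual per-group sizes n_k, g between-subjects groups and c
covariates; the balanced-template EMS logic is applied to unbalanced
designs only to identify error terms, while df always use the real
group sizes.  Each covariate absorbs one subject-level degree of
freedom, and the reduction is inherited multiplicatively by every
stratum derived from the subjects — the split-plot ANCOVA accounting
(for the example design with one within covariate: 27, 27, 54, 54).
The fitted sub-models report these nominal df; MS_error is the residual
sum of squares divided by the nominal df, which for covariate models is
marginally conservative relative to the rank-based residual df.

## Contrast weights

Overparameterized design matrices (indicator columns per level, subject
blocks last, fitted by pseudoinverse) make individual parameters
non-estimable; only combinations of design-matrix rows are.  Marginal
mean weights are row averages; main effects are differences of marginal
means, interactions differences of differences of cell means, simple
effects differences of cell means at fixed levels of the other factors.
All weight arithmetic is exact (`fractions.Fraction`), so the familiar
vectors of halves and quarters are reproduced bit-for-bit; treatment,
sigma-restricted and cell-means codings are supported and span the same
row space, hence identical F statistics.

Weights that retain non-zero entries on subject-containing blocks flag
`subject_zero=False` with the required error stratum attached; `f_test`
refuses to test such a contrast against a sub-model residual, because
the subject variance would inflate the numerator but not the
denominator.  Manually zeroing the subject entries instead produces a
non-estimable function and is likewise refused — both failure modes of
published contrast recipes are guarded against.  For simple effects the
required stratum is inferred from the surviving random blocks and may
differ from the omnibus test's stratum; a between-subjects simple effect
needs a separate between-subjects model on the selected data subset.

Estimability uses `max |L − L X⁻ X| < 1e-8` with a relative
pseudoinverse cutoff of 1e-10 (numpy ≥ 2 retains near-null singular
values by default, which breaks row-space projections; the explicit
cutoff restores standard rank-deficient behaviour).

## Covariates

A covariate measured per within-subject cell is decomposed into one
regressor per error stratum: the subject mean, a per-level subject mean
for each subject-by-factor stratum, and the raw values.  Columns that
are identical after averaging (covariates constant over some factor) are
redundant and dropped; every surviving column enters every sub-model it
remains expressible in (duplicates after sub-model averaging are merged)
but is *tested* only in the sub-model of its own stratum, with 1
numerator df.  Covariates are grand-mean centered by default (switchable)
so the intercept keeps its grand-mean interpretation; slope estimates
are unaffected.  A covariate aliased with factor columns (e.g. a group
indicator) raises an error naming the sub-model.  As an opt-in
(`covariate_interactions=True`), each stratum's covariate column is
additionally interacted with the stratum's within factor and the
interaction tested in the same sub-model, matching the convention of
classical repeated-measures ANCOVA software; covariate-by-group
interactions are not modelled.

## Sphericity

Within-subject F tests are exact only if all pairwise difference
variances are equal.  Per stratum, the subject-by-cell means are
projected through a Kronecker transform (orthonormal Helmert contrasts
for the stratum's factors, averaging rows for the rest), the covariance
is pooled within between-subjects groups, and the report carries the
pairwise difference variances, Mauchly's W with its chi-square
approximation ((N−g)·f·(−ln W), f the Box correction), the
Greenhouse–Geisser epsilon tr(S)^2 / (d tr(S^2)) and the Huynh–Feldt
epsilon ((N−g+1) d e − 2) / (d (N−g − d e)) capped at 1.  Corrections
multiply both df of the affected tests by epsilon and recompute p.
Epsilons are per-response (per-voxel); no pooling across voxels is
performed — an intentional divergence from pooled-voxel estimators,
whose voxel-selection step is a documented source of instability.

## Mass-univariate execution

The plan is compiled once — averaging operators, sub-model
pseudoinverses, contrast quadratic forms — and applied to an
observations x voxels matrix with BLAS-level operations, so runtime is
linear in voxel count; the same engine powers the tabular pipeline
(one column), the voxel-wise pipeline, and all Monte-Carlo loops
(replicates as columns).  Inputs are one summary volume per subject per
within-cell with a shared geometry; averaged sub-model responses are
computed internally from the loaded stack.  Non-finite voxels are
masked with a warning.  Outputs are per-effect F/p (optionally
BH-FDR-adjusted p and per-voxel epsilon) volumes plus a JSON sidecar
with the design, plan and df.  Voxel-wise multiple-comparison control is
BH-FDR only; random-field and permutation inference are out of scope.

## The synthetic generator

`simulate_dataset` builds responses by the variance-component
construction above (mode `spherical`), or draws each subject's
within-cell noise from a compound-symmetric or AR(1) covariance to
exercise the sphericity module (AR(1) runs over the flattened
within-cell index; it is intended for single-within-factor designs).
Fixed-effect arrays must sum to zero along every axis.  All randomness
flows through `numpy` generators seeded by (seed, voxel), so voxel v of
`simulate_images` equals `simulate_dataset(spec, voxel=v)` exactly and
identical seeds give identical bytes.  Voxels are independent: no
spatial smoothness or temporal autocorrelation is emulated, so passing
image-pipeline tests demonstrates correctness of the per-voxel
statistics and calibration, not robustness to the spatial noise
structure of real acquisitions.  Missing within-cells are an error, not
imputed — the averaging construction requires complete crossings;
marginal (sandwich-estimator) or multivariate approaches are the
appropriate tools for incomplete data.

## Problem sizes used in validation

The test suite validates statistical calibration with 2000 simulated
datasets of a 2 x 2 mixed design (8 subjects per group), EMS recovery
with 2000 replicates of the 3 x 2 x 20 design and 1200 of a 2 x 3 x 2
design (6 per group), and the image pipeline on an 8 x 8 x 8 stack with
30 subjects x 6 cells (180 volumes); these sizes give binomial
99%-confidence bands of about ±1.3 percentage points around the nominal
5% level and keep the full suite under a minute.  Independent oracles:
a hand-written full-partition sums-of-squares decomposition, pingouin's
mixed ANOVA and sphericity statistics, statsmodels' AnovaRM, and R's
`aov` with `Error()` strata.

## Known limitations

- Exactly one random unit factor; quasi-F designs are detected and
  refused, not approximated.
- Complete within-subject crossings are required.
- Type III hypotheses only (via estimable contrasts on the
  overparameterized matrix); no sequential SS.
- GLS/whitening-based marginal modelling is not implemented; sphericity
  handling is limited to the classical df corrections above.
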