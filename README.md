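# partglm

Partitioned-error repeated-measures ANOVA/ANCOVA for mass-univariate
(voxel-wise) group analyses — the classical multi-model procedure that
single-error-term GLM software (SPM/FSL-style) needs to test
within-subject designs correctly, implemented as a library and CLI.

## Why

Group-level repeated measurements carry several layers of random
variation: between subjects, subject-by-condition, and residual.  A
valid F-ratio divides an effect's mean square by the mean square whose
*expected* value differs only by that effect — and for most effects in a
mixed design that denominator is **not** the overall residual.  Software
that derives its error implicitly from the model residuals will test
between-subjects effects against the wrong stratum, inflating F (the
between effect plus the subject variance ends up in the numerator but
not the denominator).  The cure is one sub-model per error stratum, with
the data averaged over the within-subject factors that stratum does not
test, plus contrast weights derived carefully from the rows of the
(rank-deficient) design matrix.

`partglm` automates the whole procedure:

- **EMS engine** — symbolic expected mean squares by the tabular
  (Cornfield–Tukey) rules; exact error-term selection per effect
  (quasi-F designs are detected and refused); the multi-model plan; df
  for balanced and unbalanced designs.
- **Contrasts** — overparameterized / treatment / sigma-restricted /
  cell-means design matrices; estimable Type III main-effect,
  interaction and simple-effect weights in exact rational arithmetic,
  with subject-cancellation diagnostics and required-error metadata.
- **Fitting** — pseudoinverse OLS per sub-model, contrast F tests,
  a unified ANOVA table; stratum-decomposed within/between covariates;
  Mauchly / Greenhouse–Geisser / Huynh–Feldt sphericity handling.
- **Mass-univariate** — the same pipeline compiled once and applied to
  NIfTI image stacks voxel-wise, with per-voxel epsilon maps and BH-FDR.
- **Synthetic data** — a generator with the exact variance-component
  structure of the models, for testing and calibration without any
  external data.

For the expected mean squares of, e.g., the three-way mixed model
(within factors A, B; between factor C; subjects S nested in C):

    EMS_A  = σ² + b·σ²_SA + bcn·Σα²/(a−1)        → F_A  = MS_A / MS_SA
    EMS_C  = σ² + ab·σ²_S + abn·Σγ²/(c−1)        → F_C  = MS_C / MS_S
    EMS_AB = σ² + cn·Σ(αβ)²/((a−1)(b−1))         → F_AB = MS_AB / MS_E

## Worked example

A 2 × 3 × 2 mixed design: within-subject factors Location (2) and
Texture (3), between-subjects factor Drink (2), subjects nested in
Drink with groups of 14 and 16:

```python
from partglm import (DesignSpec, FactorSpec, SimulationSpec,
                     run_partitioned_anova, simulate_dataset)

design = DesignSpec(factors=(
    FactorSpec("Location", 2, scope="within"),
    FactorSpec("Texture", 3, scope="within"),
    FactorSpec("Drink", 2, scope="between"),
    FactorSpec("Subject", 16, kind="random", scope="unit",
               nested_in=("Drink",)),
), group_sizes=(14, 16))

spec = SimulationSpec(
    design=design,
    effects={"Location": [0.5, -0.5], "Texture": [0.3, 0.0, -0.3]},
    variances={"sigma2": 1.0, "sigma2_s": 2.0,
               "sigma2_s:Location": 0.5, "sigma2_s:Texture": 0.5},
    seed=1,
)
data = simulate_dataset(spec)
table = run_partitioned_anova(data, design)
print(table.frame[["Effect", "SS", "df", "F", "p", "ErrorTerm"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
```

prints

```
                          Effect      SS  df       F      p                 ErrorTerm
                           Drink  1.4694   1  1.1555 0.2916            Subject(Drink)
           Error: Subject(Drink) 35.6075  28     NaN    NaN            Subject(Drink)
                        Location 13.4003   1 14.8842 0.0006 Subject(Drink) × Location
                Location × Drink  1.4378   1  1.5970 0.2168 Subject(Drink) × Location
Error: Subject(Drink) × Location 25.2086  28     NaN    NaN Subject(Drink) × Location
                         Texture 11.8853   2  9.8588 0.0002  Subject(Drink) × Texture
                 Texture × Drink  2.1401   2  1.7752 0.1788  Subject(Drink) × Texture
 Error: Subject(Drink) × Texture 33.7556  56     NaN    NaN  Subject(Drink) × Texture
              Location × Texture  5.1797   2  2.8899 0.0639                     Error
      Location × Texture × Drink  0.7816   2  0.4361 0.6487                     Error
                    Error: Error 50.1848  56     NaN    NaN                     Error
```

Four sub-models were fitted (one per error stratum).  Drink — a
between-subjects effect — is tested on 1 and 28 df against the
Subject(Drink) stratum, not against the overall residual; the injected
Location and Texture effects are detected against their own
subject-by-factor strata (F = 14.88 on 1,28 df and F = 9.86 on 2,56 df);
the null interactions are not.  The df column (1, 28, 1, 1, 28, 2, 2,
56, 2, 2, 56) is the classical partitioned-error table for groups of 14
and 16 subjects.  Note the SS are on the averaged-data scale of each
sub-model (smaller than a full-decomposition table by the product of the
averaged level counts); F and p are invariant to that scaling.

The same analysis runs from the shell, including voxel-wise over NIfTI
stacks, with the design in a small YAML file:

```yaml
# design.yaml
factors:
  - {name: Location, levels: 2, scope: within}
  - {name: Texture,  levels: 3, scope: within}
  - {name: Drink,    levels: 2, scope: between}
subject: {name: Subject, nested_in: [Drink]}
group_sizes: [14, 16]
```

```sh
partglm plan design.yaml
partglm fit --design design.yaml --images-dir imgs/ --obs obs.csv \
        --mask mask.nii.gz --correction gg --fdr 0.05 --out results/
```

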