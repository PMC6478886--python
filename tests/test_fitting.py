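"""Multi-model fitting: averaging, sub-models, F tests, assembled tables."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from partglm import (
    LongDataset,
    PlanFitter,
    SimulationSpec,
    average_over,
    build_design_matrix,
    derive_effect_contrast,
    derive_ems,
    f_test,
    fit_submodel,
    plan_models,
    run_partitioned_anova,
    simulate_dataset,
    DesignSpec,
    FactorSpec,
)
from partglm.errors import (
    IncompleteDataError,
    InvalidErrorTermError,
    NonEstimableError,
)

from conftest import make_mixed_2way, make_mixed_3way, make_pure_within
from oracles import mixed_3way_oracle

CODINGS = ["overparameterized", "treatment", "sigma_restricted", "cell_means"]


def taste_dataset(n1=4, n2=4, seed=42, **kw):
    design = make_mixed_3way(n1, n2)
    spec = SimulationSpec(
        design=design,
        effects={"Location": [0.5, -0.5], "Texture": [0.3, 0.0, -0.3],
                 "Drink": [0.2, -0.2],
                 "Location:Drink": [[0.1, -0.1], [-0.1, 0.1]]},
        variances={"sigma2": 1.0, "sigma2_s": 2.0,
                   "sigma2_s:Location": 0.5, "sigma2_s:Texture": 0.8},
        seed=seed, **kw,
    )
    return simulate_dataset(spec), design


class TestAveraging:
    def test_average_over_nothing_is_identity(self):
        ds, design = taste_dataset()
        out = average_over(ds, [])
        pd.testing.assert_frame_equal(out.frame, ds.frame)

    def test_full_averaging_leaves_one_record_per_subject(self):
        ds, design = taste_dataset()
        out = average_over(ds, ["Location", "Texture"])
        assert len(out.frame) == ds.n_subjects
        subj = ds.frame[ds.frame["Subject"] == 1]["value"].mean()
        got = out.frame.loc[out.frame["Subject"] == 1, "value"].iloc[0]
        assert np.isclose(got, subj)

    def test_averaging_two_level_factor_halves_records(self):
        ds, _ = taste_dataset()
        out = average_over(ds, ["Location"])
        assert len(out.frame) == len(ds.frame) // 2

    def test_missing_cell_raises(self):
        ds, design = taste_dataset()
        broken = ds.frame.drop(index=0)
        with pytest.raises(IncompleteDataError):
            LongDataset(frame=broken, design=design)

    def test_non_within_factor_rejected(self):
        ds, _ = taste_dataset()
        with pytest.raises(ValueError):
            average_over(ds, ["Drink"])


class TestSubmodelFits:
    def test_residual_dfs_match_plan(self):
        """Fitted residual df reproduce the planned error df for every
        sub-model of the 14/16-subject design."""
        ds, design = taste_dataset(14, 16)
        plan = plan_models(derive_ems(design), design)
        expected = {"Subject(Drink)": 28, "Subject(Drink) × Location": 28,
                    "Subject(Drink) × Texture": 56, "Error": 56}
        for entry in plan:
            avg = average_over(ds, entry.average_over)
            fit = fit_submodel(avg, entry, design)
            assert fit.df_resid == expected[entry.label] == entry.df_error

    def test_two_subject_paired_design_df(self):
        design = DesignSpec(factors=(
            FactorSpec("A", 2, scope="within"),
            FactorSpec("S", 2, kind="random", scope="unit"),
        ))
        spec = SimulationSpec(design=design, seed=1)
        ds = simulate_dataset(spec)
        plan = plan_models(derive_ems(design), design)
        fit = fit_submodel(ds, plan.entries[0], design)
        assert fit.df_resid == 1

    def test_f_equals_squared_t_for_rank_one_contrast(self):
        design = make_mixed_2way(a=2, b=2, n=4)
        spec = SimulationSpec(design=design,
                              variances={"sigma2": 1.0, "sigma2_s": 1.0},
                              seed=3)
        ds = simulate_dataset(spec)
        plan = plan_models(derive_ems(design), design)
        entry = next(e for e in plan if e.error_term.is_error)
        fit = fit_submodel(ds, entry, design)
        cw = derive_effect_contrast(fit.X, ("A",))
        F, r, dfd, p = f_test(fit, cw)
        assert r == 1
        # independent t: paired-style contrast via the projected estimate
        G = fit.pinv @ fit.pinv.T
        L = np.zeros((1, fit.Xf.shape[1]))
        L[0, : cw.as_float().shape[1]] = cw.as_float()
        se = np.sqrt(float((L @ G @ L.T).item()) * fit.rss / fit.df_resid)
        t = float((L @ fit.beta).item()) / se
        assert np.isclose(F, t ** 2)

    def test_wrong_error_term_refused(self):
        """A between-subjects contrast with surviving subject weights must
        not be tested against a sub-model residual (the F-inflation trap)."""
        ds, design = taste_dataset()
        plan = plan_models(derive_ems(design), design)
        entry = next(e for e in plan if e.error_term.is_error)
        fit = fit_submodel(ds, entry, design)
        cw = derive_effect_contrast(fit.X, ("Drink",))
        assert not cw.subject_zero
        with pytest.raises(InvalidErrorTermError):
            f_test(fit, cw)

    def test_non_estimable_contrast_refused(self):
        ds, design = taste_dataset()
        plan = plan_models(derive_ems(design), design)
        entry = next(e for e in plan if e.error_term.is_error)
        fit = fit_submodel(ds, entry, design)
        L = np.zeros(fit.Xf.shape[1])
        L[1] = 1.0  # a bare level indicator is not estimable
        with pytest.raises(NonEstimableError):
            f_test(fit, L)


class TestPipeline:
    def test_df_column_matches_classical_table(self):
        ds, design = taste_dataset(14, 16)
        table = run_partitioned_anova(ds, design)
        assert table.df_column == [1, 28, 1, 1, 28, 2, 2, 56, 2, 2, 56]

    def test_matches_full_partition_oracle(self):
        ds, design = taste_dataset()
        table = run_partitioned_anova(ds, design)
        oracle = mixed_3way_oracle(ds.frame)
        pairs = {
            "Location": "A", "Texture": "B", "Drink": "C",
            "Location × Texture": "AB", "Location × Drink": "AC",
            "Texture × Drink": "BC", "Location × Texture × Drink": "ABC",
        }
        for label, key in pairs.items():
            F = float(table.row(label)["F"])
            assert abs(F - oracle["F"][key]) <= 1e-8 * oracle["F"][key]

    def test_ss_scaling_law(self):
        """Averaged sub-model SS times the averaged level count equals the
        full-decomposition SS; the F-ratio is unchanged."""
        ds, design = taste_dataset()
        table = run_partitioned_anova(ds, design)
        oracle = mixed_3way_oracle(ds.frame)
        # Texture sub-model averages over the 2-level Location factor
        assert np.isclose(2 * float(table.row("Texture")["SS"]),
                          oracle["SS"]["B"])
        assert np.isclose(2 * float(table.row("Texture")["ErrorSS"]),
                          oracle["SS"]["SB"])
        # Location sub-model averages over the 3-level Texture factor
        assert np.isclose(3 * float(table.row("Location")["SS"]),
                          oracle["SS"]["A"])
        # the between model averages over both (factor 6)
        assert np.isclose(6 * float(table.row("Drink")["SS"]),
                          oracle["SS"]["C"])
        assert np.isclose(6 * float(table.row("Drink")["ErrorSS"]),
                          oracle["SS"]["S"])

    @pytest.mark.parametrize("coding", CODINGS[1:])
    def test_f_invariant_to_design_coding(self, coding):
        """All codings span the same row space, so every F is identical."""
        ds, design = taste_dataset()
        base = run_partitioned_anova(ds, design, coding="overparameterized")
        other = run_partitioned_anova(ds, design, coding=coding)
        for label in base.frame["Effect"]:
            if label.startswith("Error"):
                continue
            assert np.isclose(float(base.row(label)["F"]),
                              float(other.row(label)["F"]),
                              rtol=1e-8), (coding, label)

    def test_zero_within_variance_gives_infinite_f(self):
        design = make_mixed_2way(a=2, b=2, n=3)
        spec = SimulationSpec(design=design,
                              effects={"A": [1.0, -1.0]},
                              variances={"sigma2": 0.0, "sigma2_s": 1.0},
                              seed=5)
        ds = simulate_dataset(spec)
        table = run_partitioned_anova(ds, design)
        assert np.isinf(float(table.row("A")["F"]))

    def test_unbalanced_groups_supported(self):
        ds, design = taste_dataset(3, 5, seed=9)
        table = run_partitioned_anova(ds, design)
        assert table.df_column == [1, 6, 1, 1, 6, 2, 2, 12, 2, 2, 12]
        assert np.isfinite(table.frame["F"].iloc[0])


class TestIndependentReferences:
    def test_against_pingouin_mixed_anova(self):
        """Two-way mixed design: F-ratios and df must match pingouin's
        dedicated mixed ANOVA implementation."""
        pg = pytest.importorskip("pingouin")
        design = make_mixed_2way(a=3, b=2, n=10)
        spec = SimulationSpec(design=design,
                              effects={"A": [0.4, 0.0, -0.4]},
                              variances={"sigma2": 1.0, "sigma2_s": 2.0},
                              seed=21)
        ds = simulate_dataset(spec)
        table = run_partitioned_anova(ds, design)
        ref = pg.mixed_anova(ds.frame.rename(columns={"S": "subj"}),
                             dv="value", within="A", between="B",
                             subject="subj").set_index("Source")
        assert np.isclose(float(table.row("A")["F"]), ref.loc["A", "F"])
        assert np.isclose(float(table.row("B")["F"]), ref.loc["B", "F"])
        assert np.isclose(float(table.row("A × B")["F"]),
                          ref.loc["Interaction", "F"])
        assert table.row("A")["Errordf"] == ref.loc["A", "DF2"]

    def test_against_statsmodels_anovarm(self):
        """Single-group two-within design vs statsmodels AnovaRM."""
        from statsmodels.stats.anova import AnovaRM

        design = make_pure_within(a=2, b=3, n=10)
        spec = SimulationSpec(design=design,
                              effects={"A": [0.3, -0.3]},
                              variances={"sigma2": 1.0, "sigma2_s": 1.0,
                                         "sigma2_s:A": 0.4,
                                         "sigma2_s:B": 0.4},
                              seed=13)
        ds = simulate_dataset(spec)
        table = run_partitioned_anova(ds, design)
        ref = AnovaRM(ds.frame, "value", "Subject",
                      within=["A", "B"]).fit().anova_table
        assert np.isclose(float(table.row("A")["F"]), ref.loc["A", "F Value"])
        assert np.isclose(float(table.row("B")["F"]), ref.loc["B", "F Value"])
        assert np.isclose(float(table.row("A × B")["F"]),
                          ref.loc["A:B", "F Value"])

    def test_against_r_aov_error_strata(self, tmp_path):
        """Balanced 2x3x2 mixed design vs R's aov with Error(S/(A*B))."""
        ds, design = taste_dataset(3, 3, seed=77)
        csv = tmp_path / "data.csv"
        ds.frame.to_csv(csv, index=False)
        out = tmp_path / "f.json"
        rcode = f"""
        df <- read.csv("{csv}")
        for (col in c("Location","Texture","Drink","Subject"))
            df[[col]] <- as.factor(df[[col]])
        m <- aov(value ~ Location*Texture*Drink +
                 Error(Subject/(Location*Texture)), data=df)
        s <- summary(m)
        res <- list()
        for (stratum in names(s)) {{
            tab <- s[[stratum]][[1]]
            for (rn in rownames(tab)) {{
                key <- trimws(rn)
                if (key != "Residuals")
                    res[[key]] <- tab[rn, "F value"]
            }}
        }}
        writeLines(jsonlite::toJSON(res, auto_unbox=TRUE, digits=12), "{out}")
        """
        subprocess.run(["Rscript", "-e", rcode], check=True,
                       capture_output=True)
        ref = json.loads(out.read_text())
        table = run_partitioned_anova(ds, design)
        pairs = {
            "Location": "Location", "Texture": "Texture", "Drink": "Drink",
            "Location × Drink": "Location:Drink",
            "Texture × Drink": "Texture:Drink",
            "Location × Texture": "Location:Texture",
            "Location × Texture × Drink": "Location:Texture:Drink",
        }
        for mine, theirs in pairs.items():
            assert np.isclose(float(table.row(mine)["F"]), ref[theirs],
                              rtol=1e-6), mine
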