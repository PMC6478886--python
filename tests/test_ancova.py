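"""Stratum-matched covariate decomposition and ANCOVA testing."""

from dataclasses import replace

import numpy as np
import pytest

from partglm import (
    CovariateModel,
    CovariateSpec,
    LongDataset,
    PlanFitter,
    SimulationSpec,
    decompose_covariate,
    derive_ems,
    plan_models,
    run_partitioned_anova,
    simulate_dataset,
)
from partglm.errors import CollinearCovariateError
from partglm.simulate import simulate_response_matrix

from conftest import make_mixed_3way


def with_covariate(design, varies_over):
    return replace(design, covariates=(
        CovariateSpec("x", varies_over=tuple(varies_over)),))


def taste_ancova_dataset(n1=14, n2=16, varies_over=("Location", "Texture"),
                         slopes=None, seed=5):
    design = with_covariate(make_mixed_3way(n1, n2), varies_over)
    spec = SimulationSpec(
        design=design,
        effects={"Location": [0.4, -0.4], "Texture": [0.2, 0.0, -0.2]},
        variances={"sigma2": 1.0, "sigma2_s": 2.0,
                   "sigma2_s:Location": 0.5, "sigma2_s:Texture": 0.5},
        covariate=CovariateModel(slopes=slopes or {}, sd=1.0),
        seed=seed,
    )
    return simulate_dataset(spec), design


class TestDecomposition:
    def test_between_covariate_reduces_to_subject_mean(self):
        ds, design = taste_ancova_dataset(4, 4, varies_over=())
        plan = plan_models(derive_ems(design), design)
        cols = decompose_covariate(ds.frame, design.covariates[0], design,
                                   plan)
        assert [c.stratum.label for c in cols] == ["Subject(Drink)"]

    def test_full_within_covariate_gives_four_columns(self):
        ds, design = taste_ancova_dataset(4, 4)
        plan = plan_models(derive_ems(design), design)
        cols = decompose_covariate(ds.frame, design.covariates[0], design,
                                   plan)
        assert [c.stratum.label for c in cols] == [
            "Subject(Drink)", "Subject(Drink) × Location",
            "Subject(Drink) × Texture", "Error"]
        # the raw column is the last one and differs from the averages
        assert not np.allclose(cols[-1].values, cols[0].values)

    def test_partially_varying_covariate_drops_redundant_columns(self):
        """A covariate varying over Location but constant over Texture:
        the per-Texture means equal the subject means and the raw values
        equal the per-Location means, leaving two columns."""
        ds, design = taste_ancova_dataset(4, 4, varies_over=("Location",))
        plan = plan_models(derive_ems(design), design)
        cols = decompose_covariate(ds.frame, design.covariates[0], design,
                                   plan)
        assert [c.stratum.label for c in cols] == [
            "Subject(Drink)", "Subject(Drink) × Location"]

    def test_constant_covariate_rejected(self):
        ds, design = taste_ancova_dataset(4, 4)
        frame = ds.frame.assign(x=1.0)
        plan = plan_models(derive_ems(design), design)
        with pytest.raises(CollinearCovariateError, match="constant"):
            decompose_covariate(frame, design.covariates[0], design, plan)


class TestAncovaTable:
    def test_error_df_match_split_block_accounting(self):
        """With one within-subject covariate the four error strata lose
        one subject-level df each, inherited multiplicatively:
        27, 27, 54, 54 for groups of 14 and 16."""
        ds, design = taste_ancova_dataset(14, 16)
        table = run_partitioned_anova(ds, design)
        err = [int(r["df"]) for _, r in table.frame.iterrows()
               if r["Effect"].startswith("Error")]
        assert err == [27, 27, 54, 54]
        assert table.df_column == [1, 1, 27, 1, 1, 1, 27, 1, 2, 2, 54,
                                   1, 2, 2, 54]

    def test_covariate_rows_have_unit_df_and_own_stratum(self):
        ds, design = taste_ancova_dataset(4, 4)
        table = run_partitioned_anova(ds, design)
        covrows = table.frame[table.frame["Effect"].str.startswith("x.")]
        assert list(covrows["df"]) == [1, 1, 1, 1]
        assert list(covrows["ErrorTerm"]) == [
            "Subject(Drink)", "Subject(Drink) × Location",
            "Subject(Drink) × Texture", "Error"]

    def test_between_covariate_tested_only_in_between_model(self):
        ds, design = taste_ancova_dataset(6, 6, varies_over=())
        table = run_partitioned_anova(ds, design)
        covrows = table.frame[table.frame["Effect"] == "x.mean"]
        assert len(covrows) == 1
        assert covrows.iloc[0]["ErrorTerm"] == "Subject(Drink)"

    def test_group_indicator_covariate_is_aliased(self):
        ds, design = taste_ancova_dataset(4, 4, varies_over=())
        frame = ds.frame.copy()
        frame["x"] = (frame["Drink"] == 1).astype(float)
        with pytest.raises(CollinearCovariateError, match="aliased"):
            run_partitioned_anova(LongDataset(frame=frame, design=design),
                                  design)


class TestRecoveryAndCalibration:
    def test_between_slope_recovered(self):
        """Known subject-level slope: the estimated coefficient from the
        between sub-model lands within the Monte-Carlo interval."""
        slopes = {"mean": 1.5}
        ests = []
        for seed in range(12):
            ds, design = taste_ancova_dataset(10, 10, varies_over=(),
                                              slopes=slopes, seed=100 + seed)
            fitter = PlanFitter(design, obs=ds.frame)
            ests.append(fitter.covariate_slopes(ds.values)["x.mean"])
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 1.5) < 4 * se + 1e-9

    def test_raw_slope_recovered(self):
        slopes = {"raw": 0.8}
        ests = []
        for seed in range(12):
            ds, design = taste_ancova_dataset(8, 8, slopes=slopes,
                                              seed=300 + seed)
            fitter = PlanFitter(design, obs=ds.frame)
            ests.append(fitter.covariate_slopes(ds.values)["x.raw"])
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.8) < 4 * se + 1e-9

    def test_null_covariate_keeps_type_one_error_calibrated(self):
        """A zero-slope covariate reduces the error df but must leave the
        effect tests' rejection rates at the nominal level."""
        ds, design = taste_ancova_dataset(8, 8, slopes={}, seed=1)
        null_design = design
        spec = SimulationSpec(design=make_mixed_3way(8, 8),
                              variances={"sigma2": 1.0, "sigma2_s": 1.0,
                                         "sigma2_s:Location": 0.5,
                                         "sigma2_s:Texture": 0.5},
                              seed=2)
        obs, Y = simulate_response_matrix(spec, 1200)
        obs = obs.assign(x=ds.frame["x"].to_numpy())
        fitter = PlanFitter(null_design, obs=obs)
        res = fitter.analyze(Y)
        assert res.entries[0]["df"] == 13  # 16 - 2 - 1
        for row in res.effects:
            if row["is_covariate"]:
                continue
            rate = float(np.mean(row["p"] < 0.05))
            assert 0.025 < rate < 0.075, (row["label"], rate)

    def test_noise_explaining_covariate_increases_power(self):
        """A raw covariate that soaks up residual noise raises the average
        F of the residual-stratum effects when a true effect is present."""
        design = with_covariate(make_mixed_3way(8, 8),
                                ("Location", "Texture"))
        base = SimulationSpec(
            design=design,
            effects={"Location:Texture": [[0.3, 0.0, -0.3],
                                          [-0.3, 0.0, 0.3]]},
            variances={"sigma2": 0.25, "sigma2_s": 1.0},
            covariate=CovariateModel(slopes={"raw": 1.0}, sd=1.0),
            seed=11,
        )
        f_with, f_without = [], []
        for seed in range(15):
            spec = replace(base, seed=500 + seed)
            ds = simulate_dataset(spec)
            t1 = run_partitioned_anova(ds, design)
            t0 = run_partitioned_anova(
                LongDataset(frame=ds.frame.drop(columns=["x"]),
                            design=make_mixed_3way(8, 8)),
                make_mixed_3way(8, 8))
            f_with.append(float(t1.row("Location × Texture")["F"]))
            f_without.append(float(t0.row("Location × Texture")["F"]))
        assert np.mean(f_with) > np.mean(f_without)

    def test_covariate_by_within_interaction_opt_in(self):
        """With the opt-in enabled, each within stratum gains a
        covariate-by-factor interaction row with (levels - 1) df."""
        ds, design = taste_ancova_dataset(8, 8, slopes={"raw": 0.5},
                                          seed=71)
        table = run_partitioned_anova(ds, design,
                                      covariate_interactions=True)
        row_loc = table.row("x × Location")
        row_tex = table.row("x × Texture")
        assert row_loc["df"] == 1 and row_loc["ErrorTerm"] == (
            "Subject(Drink) × Location")
        assert row_tex["df"] == 2 and row_tex["ErrorTerm"] == (
            "Subject(Drink) × Texture")
        # the plain effect rows are still present and finite
        assert np.isfinite(table.row("Texture")["F"])

    def test_subject_constant_within_covariate_matches_between_path(self):
        """A covariate declared within but constant per subject decomposes
        exactly like a between-subjects covariate."""
        ds, design = taste_ancova_dataset(4, 4, varies_over=())
        frame = ds.frame
        within_design = with_covariate(make_mixed_3way(4, 4),
                                       ("Location", "Texture"))
        plan_w = plan_models(derive_ems(within_design), within_design)
        cols_w = decompose_covariate(frame, within_design.covariates[0],
                                     within_design, plan_w)
        assert [c.stratum.label for c in cols_w] == ["Subject(Drink)"]
        t_between = run_partitioned_anova(ds, design)
        t_within = run_partitioned_anova(
            LongDataset(frame=frame, design=within_design), within_design)
        pd_cols = ["Effect", "SS", "df", "F"]
        assert t_between.frame[pd_cols].equals(t_within.frame[pd_cols])
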