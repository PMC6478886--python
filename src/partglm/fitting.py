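"""Execution of the multi-model plan on data.

Each error stratum gets its own sub-model: the within-subject factors the
stratum does not test are averaged out of the data, the remaining design is
fitted by ordinary least squares through the pseudoinverse, and every
effect assigned to the stratum is tested with a Type III contrast against
the sub-model's residual mean square.  Because averaging removes the
lower-order random terms' separate existence, the intended stratum becomes
the sub-model residual and the resulting F-ratios are exact.

Sums of squares from averaged sub-models are smaller than the classical
full-decomposition values by the product of the averaged level counts; the
F-ratios are invariant to this scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ancova import CovariateColumn, decompose_covariate
from .contrasts import (
    ContrastWeights,
    DesignMatrix,
    build_design_matrix,
    canonical_observation_table,
    check_estimable,
    derive_effect_contrast,
)
from .design import DesignSpec, ModelTerm
from .ems import ModelPlan, PlanEntry, compute_df, derive_ems, plan_models
from .errors import (
    CollinearCovariateError,
    DegenerateFitError,
    IncompleteDataError,
    InvalidErrorTermError,
    NonEstimableError,
)

__all__ = [
    "LongDataset",
    "AnovaTable",
    "PlanFitter",
    "SubmodelFit",
    "average_over",
    "fit_submodel",
    "f_test",
    "run_partitioned_anova",
]

RANK_TOL = 1e-8


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class LongDataset:
    """Long-format responses: one row per (subject, within-cell).

    Column conventions: the subject column is named after the design's unit
    factor, one column per factor holds 1-based level codes, ``value``
    holds the response, and covariate columns carry their declared names.
    """

    frame: pd.DataFrame
    design: DesignSpec
    value_col: str = "value"

    def __post_init__(self):
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    @classmethod
    def from_frame(cls, frame, design, value="value", subject=None):
        frame = frame.copy()
        unit = design.unit_factor
        if subject and unit is not None and subject != unit.name:
            frame = frame.rename(columns={subject: unit.name})
        if value != "value":
            frame = frame.rename(columns={value: "value"})
        return cls(frame=frame, design=design)

    def validate(self) -> None:
        design, frame = self.design, self.frame
        needed = [f.name for f in design.factors if f.scope != "unit"]
        unit = design.unit_factor
        if unit is not None:
            needed.append(unit.name)
        missing = [c for c in needed + [self.value_col] if c not in frame.columns]
        if missing:
            raise ValueError(f"data is missing columns {missing}")
        if unit is None:
            return
        withins = [f.name for f in design.within_factors]
        n_cells = 1
        for w in withins:
            n_cells *= int(design.factor(w).n_levels)
        for subj, grp in frame.groupby(unit.name, sort=False):
            cells = grp[withins].apply(tuple, axis=1) if withins else None
            if len(grp) != n_cells or (withins and cells.nunique() != n_cells):
                raise IncompleteDataError(
                    f"subject {subj!r} has {len(grp)} rows; expected one per "
                    f"within-subject cell ({n_cells})"
                )
            betweens = [f.name for f in design.between_factors]
            if betweens and grp[betweens].drop_duplicates().shape[0] != 1:
                raise IncompleteDataError(
                    f"subject {subj!r} appears in more than one "
                    "between-subjects group"
                )

    @property
    def values(self) -> np.ndarray:
        return self.frame[self.value_col].to_numpy(dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.frame[self.design.unit_factor.name].nunique()


def average_over(data: LongDataset, factors) -> LongDataset:
    """Average the responses (and covariates) over within-subject factors.

    Each subject's records are reduced to the arithmetic mean per retained
    within-subject cell; covariate columns are averaged identically.
    Averaging over nothing returns an equivalent dataset.
    """
    factors = list(factors)
    design = data.design
    withins = {f.name for f in design.within_factors}
    bad = [f for f in factors if f not in withins]
    if bad:
        raise ValueError(f"cannot average over non-within factors {bad}")
    if not factors:
        return LongDataset(frame=data.frame.copy(), design=design,
                           value_col=data.value_col)
    unit = design.unit_factor.name
    keep = [unit] + [f.name for f in design.between_factors] + [
        w for w in (f.name for f in design.within_factors) if w not in factors
    ]
    numeric = [data.value_col] + [c.name for c in design.covariates
                                  if c.name in data.frame.columns]
    out = (
        data.frame.groupby(keep, sort=False)[numeric]
        .mean()
        .reset_index()
    )
    return LongDataset(frame=out, design=_drop_withins(design, factors),
                       value_col=data.value_col)


def _drop_withins(design: DesignSpec, factors) -> DesignSpec:
    kept = tuple(f for f in design.factors
                 if not (f.scope == "within" and f.name in factors))
    covs = tuple(c for c in design.covariates)
    return DesignSpec(kept, design.replicates_per_cell, design.group_sizes, covs)


# ---------------------------------------------------------------------------
# ANOVA table
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Assembled effect rows (SS, df, MS, F, p) with their error strata."""

    frame: pd.DataFrame
    design: DesignSpec | None = None

    def __repr__(self):
        return repr(self.frame)

    def row(self, effect: str) -> pd.Series:
        sel = self.frame[self.frame["Effect"] == effect]
        if sel.empty:
            raise KeyError(effect)
        return sel.iloc[0]

    @property
    def df_column(self) -> list:
        return list(self.frame["df"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        payload = self.frame.to_dict(orient="records")
        if path is None:
            return json.dumps(payload, indent=2, default=float)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# vectorised plan execution
# ---------------------------------------------------------------------------

@dataclass
class _EffectOp:
    effect: ModelTerm | None
    label: str
    L: np.ndarray        # (r, p) float, padded to the fitted column count
    Minv: np.ndarray     # inverse of L (X'X)^- L'
    rank: int
    is_covariate: bool = False


@dataclass
class _EntryOp:
    entry: PlanEntry
    averager: np.ndarray          # (m, n_obs) row-averaging operator
    X: DesignMatrix
    Xf: np.ndarray                # fitted matrix incl. covariate columns
    pinv: np.ndarray
    rank: int
    scale: int                    # product of averaged level counts
    df_error: int
    effects: list
    cov_idx: dict = field(default_factory=dict)


class PlanFitter:
    """Pre-compiled multi-model pipeline for one design.

    All averaging operators, sub-model pseudoinverses and contrast
    quadratic forms are computed once; :meth:`analyze` then maps a response
    matrix (observations x columns) to per-effect statistics.  Columns may
    be voxels, simulation replicates, or a single data vector.
    """

    def __init__(
        self,
        design: DesignSpec,
        obs: pd.DataFrame | None = None,
        coding: str = "overparameterized",
        covariate_interactions: bool = False,
    ):
        self.design = design
        self.coding = coding
        self.covariate_interactions = covariate_interactions
        self.ems = derive_ems(design)
        self.plan = plan_models(self.ems, design)
        self.dfmap = compute_df(design)
        if obs is None:
            obs = canonical_observation_table(design)
        self.obs = obs.reset_index(drop=True)
        self.cov_columns: list[CovariateColumn] = []
        for cov in design.covariates:
            self.cov_columns.extend(
                decompose_covariate(self.obs, cov, design, self.plan)
            )
        self.entries = [self._compile_entry(e) for e in self.plan.entries]

    # -- compilation ---------------------------------------------------
    def _compile_entry(self, entry: PlanEntry) -> _EntryOp:
        design = self.design
        unit = design.unit_factor
        withins = [f.name for f in design.within_factors]
        kept = [w for w in withins if w not in entry.average_over]
        keys = ([unit.name] if unit else []) + [
            f.name for f in design.between_factors
        ] + kept
        gids = self.obs.groupby(keys, sort=False).ngroup().to_numpy()
        m = int(gids.max()) + 1
        counts = np.bincount(gids, minlength=m).astype(float)
        A = np.zeros((m, len(self.obs)))
        A[gids, np.arange(len(self.obs))] = 1.0 / counts[gids]
        first = np.zeros(m, dtype=int)
        seen = np.zeros(m, dtype=bool)
        for i, g in enumerate(gids):
            if not seen[g]:
                seen[g] = True
                first[g] = i
        avg_rows = self.obs.iloc[first].reset_index(drop=True)

        X = build_design_matrix(design, self.coding, rows=avg_rows,
                                withins_present=kept)
        Xf = X.as_float()
        # averaged covariate columns, deduplicated within this sub-model
        # (averaging collapses higher-stratum columns onto lower ones)
        cov_cols, cov_idx, kept = [], {}, []
        for cc in self.cov_columns:
            col = A @ cc.values
            for vals, j in kept:
                if np.allclose(col, vals, atol=1e-12):
                    cov_idx[cc.name] = j
                    break
            else:
                j = Xf.shape[1] + len(cov_cols)
                kept.append((col, j))
                cov_cols.append(col)
                cov_idx[cc.name] = j
        if cov_cols:
            Xf = np.column_stack([Xf] + cov_cols)
        # opt-in covariate-by-within-factor interactions, tested in the
        # same sub-model as the interacting within factor
        interactions = []
        stratum_withins = [w for w in withins
                           if w in entry.error_term.subscripts]
        if (self.covariate_interactions and self.cov_columns
                and len(stratum_withins) == 1
                and not entry.error_term.is_error):
            w = stratum_withins[0]
            lev = int(design.factor(w).n_levels)
            wcodes = avg_rows[w].to_numpy()
            for cc in self.cov_columns:
                if cc.stratum == entry.error_term:
                    base = Xf[:, cov_idx[cc.name]]
                    cols = [base * (wcodes == j) for j in range(1, lev + 1)]
                    start = Xf.shape[1]
                    Xf = np.column_stack([Xf] + cols)
                    interactions.append(
                        (cc.name, f"{cc.covariate} × {w}", start, lev))
        pinv = np.linalg.pinv(Xf, rcond=RANK_TOL)
        rank = int(np.linalg.matrix_rank(Xf, tol=None))
        df_error = entry.df_error
        if df_error is None or not isinstance(df_error, (int, np.integer)):
            df_error = X.n_rows - rank
        if df_error <= 0:
            raise DegenerateFitError(
                f"sub-model for stratum {entry.label!r} has no residual "
                "degrees of freedom"
            )
        G = pinv @ pinv.T

        ops: list[_EffectOp] = []
        for cc in self.cov_columns:
            if cc.stratum == entry.error_term:
                Lf = np.zeros((1, Xf.shape[1]))
                Lf[0, cov_idx[cc.name]] = 1.0
                for name, _, start, lev in interactions:
                    if name == cc.name:
                        # with per-level slope columns present, the main
                        # slope is the average of the per-level slopes
                        Lf[0, start:start + lev] = 1.0 / lev
                if not check_estimable(Xf, Lf):
                    raise CollinearCovariateError(
                        f"covariate column {cc.name!r} is aliased with the "
                        f"design of the {entry.label!r} sub-model"
                    )
                ops.append(self._effect_op(None, cc.name, Lf, G, Xf,
                                           is_covariate=True))
        for eff in entry.effects_tested:
            cw = derive_effect_contrast(X, eff, self.ems)
            if not cw.subject_zero:
                raise InvalidErrorTermError(
                    f"contrast for {eff.label!r} retains subject weights in "
                    f"the {entry.label!r} sub-model"
                )
            Lf = np.zeros((cw.weights.shape[0], Xf.shape[1]))
            Lf[:, : X.n_cols] = cw.as_float()
            ops.append(self._effect_op(eff, eff.label, Lf, G, Xf))
        for _, label, start, lev in interactions:
            Lf = np.zeros((lev - 1, Xf.shape[1]))
            for i in range(lev - 1):
                Lf[i, start + i] = 1.0
                Lf[i, start + i + 1] = -1.0
            ops.append(self._effect_op(None, label, Lf, G, Xf,
                                       is_covariate=True))
        scale = 1
        for w in entry.average_over:
            scale *= int(design.factor(w).n_levels)
        return _EntryOp(entry=entry, averager=A, X=X, Xf=Xf, pinv=pinv,
                        rank=rank, scale=scale, df_error=int(df_error),
                        effects=ops, cov_idx=cov_idx)

    def _effect_op(self, eff, label, Lf, G, Xf, is_covariate=False):
        if not check_estimable(Xf, Lf):
            raise NonEstimableError(
                f"derived contrast for {label!r} is not estimable"
            )
        M = Lf @ G @ Lf.T
        r = int(np.linalg.matrix_rank(Lf))
        Minv = np.linalg.pinv(M, rcond=RANK_TOL)
        return _EffectOp(effect=eff, label=label, L=Lf, Minv=Minv, rank=r,
                         is_covariate=is_covariate)

    def covariate_slopes(self, y: np.ndarray) -> dict:
        """Estimated regression coefficient of each covariate column in
        the sub-model of its own stratum (an estimable coefficient, hence
        invariant to the choice of generalized inverse)."""
        y = np.asarray(y, dtype=float)
        out = {}
        for eop in self.entries:
            beta = eop.pinv @ (eop.averager @ y)
            for cc in self.cov_columns:
                if cc.stratum == eop.entry.error_term:
                    out[cc.name] = float(beta[eop.cov_idx[cc.name]])
        return out

    # -- execution -----------------------------------------------------
    def analyze(self, Y: np.ndarray) -> "AnovaResults":
        """Run the full plan on a response matrix (n_obs x n_columns)."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        effect_rows, entry_rows = [], []
        for eop in self.entries:
            Ya = eop.averager @ Y
            B = eop.pinv @ Ya
            resid = Ya - eop.Xf @ B
            rss = np.einsum("ij,ij->j", resid, resid)
            entry_rows.append(
                {"entry": eop.entry, "rss": rss, "df": eop.df_error,
                 "scale": eop.scale}
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                mse = rss / eop.df_error
                # a residual that is zero to machine precision (degenerate
                # within-subject variance) must yield an infinite F, not an
                # enormous finite one
                scale = np.einsum("ij,ij->j", Ya, Ya) / max(Ya.shape[0], 1)
                mse = np.where(mse < 1e-12 * np.maximum(scale, 1e-300),
                               0.0, mse)
                for op in eop.effects:
                    LB = op.L @ B
                    ss = np.einsum("ij,ij->j", LB, op.Minv @ LB)
                    F = (ss / op.rank) / mse
                    p = stats.f.sf(F, op.rank, eop.df_error)
                    effect_rows.append(
                        {
                            "effect": op.effect,
                            "label": op.label,
                            "SS": ss,
                            "df": op.rank,
                            "F": F,
                            "p": p,
                            "entry": eop.entry,
                            "scale": eop.scale,
                            "error_df": eop.df_error,
                            "rss": rss,
                            "is_covariate": op.is_covariate,
                        }
                    )
        return AnovaResults(fitter=self, effects=effect_rows,
                            entries=entry_rows)


@dataclass
class AnovaResults:
    """Vectorised results; ``table(j)`` extracts one column's ANOVA table."""

    fitter: PlanFitter
    effects: list
    entries: list

    def effect(self, label: str) -> dict:
        for row in self.effects:
            if row["label"] == label:
                return row
        raise KeyError(label)

    @property
    def effect_labels(self) -> list:
        return [r["label"] for r in self.effects]

    def table(self, column: int = 0) -> AnovaTable:
        rows = []
        for ent in self.entries:
            entry = ent["entry"]
            block = [r for r in self.effects if r["entry"] is entry]
            block.sort(key=lambda r: (not r["is_covariate"],))
            for r in block:
                ss = float(r["SS"][column])
                rows.append(
                    {
                        "Effect": r["label"],
                        "SS": ss,
                        "df": r["df"],
                        "MS": ss / r["df"],
                        "F": float(r["F"][column]),
                        "p": float(r["p"][column]),
                        "ErrorTerm": entry.label,
                        "ErrorSS": float(ent["rss"][column]),
                        "Errordf": ent["df"],
                    }
                )
            rss = float(ent["rss"][column])
            rows.append(
                {
                    "Effect": f"Error: {entry.label}",
                    "SS": rss,
                    "df": ent["df"],
                    "MS": rss / ent["df"],
                    "F": np.nan,
                    "p": np.nan,
                    "ErrorTerm": entry.label,
                    "ErrorSS": rss,
                    "Errordf": ent["df"],
                }
            )
        return AnovaTable(frame=pd.DataFrame(rows), design=self.fitter.design)


# ---------------------------------------------------------------------------
# single sub-model interface
# ---------------------------------------------------------------------------

@dataclass
class SubmodelFit:
    """One fitted sub-model (pseudoinverse OLS)."""

    X: DesignMatrix
    Xf: np.ndarray
    pinv: np.ndarray
    beta: np.ndarray
    rss: float
    df_resid: int
    rank: int
    y: np.ndarray


def fit_submodel(
    data: LongDataset,
    entry: PlanEntry,
    design: DesignSpec | None = None,
    coding: str = "overparameterized",
) -> SubmodelFit:
    """Fit one plan entry's sub-model to already-averaged data.

    The design includes the intercept, the surviving fixed terms and the
    subject blocks that are not collinear with the residuals; the residual
    degrees of freedom equal the entry's planned error degrees of freedom.
    """
    design = design or data.design
    withins = [f.name for f in design.within_factors]
    kept = [w for w in withins if w not in entry.average_over]
    X = build_design_matrix(design, coding, rows=data.frame,
                            withins_present=kept)
    Xf = X.as_float()
    pinv = np.linalg.pinv(Xf, rcond=RANK_TOL)
    y = data.values
    beta = pinv @ y
    resid = y - Xf @ beta
    rank = int(np.linalg.matrix_rank(Xf))
    df_resid = X.n_rows - rank
    if df_resid <= 0:
        raise DegenerateFitError(
            f"sub-model for stratum {entry.label!r} has no residual "
            "degrees of freedom"
        )
    return SubmodelFit(X=X, Xf=Xf, pinv=pinv, beta=beta,
                       rss=float(resid @ resid), df_resid=df_resid,
                       rank=rank, y=y)


def f_test(fit: SubmodelFit, L) -> tuple:
    """F test of a contrast against the sub-model residual.

    ``F = [(Lb)' (L (X'X)^- L')^{-1} (Lb) / rank(L)] / MS_residual`` with
    numerator df ``rank(L)`` and denominator df the residual df.  Refuses
    contrasts that are non-estimable or that retain subject-block weights
    (testing those against the residual would add the subject variance to
    the numerator but not the denominator, inflating F).
    """
    if isinstance(L, ContrastWeights):
        if not L.subject_zero:
            raise InvalidErrorTermError(
                f"contrast {L.target!r} has non-zero subject weights; "
                "testing it against the sub-model residual would inflate F. "
                f"It requires the {L.required_error.label!r} error stratum."
            )
        Lf = L.as_float()
    else:
        Lf = np.atleast_2d(np.asarray(L, dtype=float))
    if Lf.shape[1] < fit.Xf.shape[1]:
        Lf = np.pad(Lf, ((0, 0), (0, fit.Xf.shape[1] - Lf.shape[1])))
    if not check_estimable(fit.Xf, Lf):
        raise NonEstimableError("contrast is not estimable in this sub-model")
    G = fit.pinv @ fit.pinv.T
    M = Lf @ G @ Lf.T
    r = int(np.linalg.matrix_rank(Lf))
    Lb = Lf @ fit.beta
    ss = float(Lb @ np.linalg.pinv(M, rcond=RANK_TOL) @ Lb)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss / r) / (fit.rss / fit.df_resid)
    p = float(stats.f.sf(F, r, fit.df_resid))
    return float(F), r, fit.df_resid, p


# ---------------------------------------------------------------------------
# top-level pipeline
# ---------------------------------------------------------------------------

def run_partitioned_anova(
    data,
    design: DesignSpec,
    coding: str = "overparameterized",
    sphericity: str = "none",
    covariate_interactions: bool = False,
) -> AnovaTable:
    """Full partitioned-error ANOVA/ANCOVA of a long-format dataset.

    Derives the EMS, plans one sub-model per error stratum, averages the
    within-subject data per sub-model, fits by pseudoinverse OLS, tests
    Type III contrasts, and assembles the unified table.  ``sphericity``
    may be ``"none"``, ``"gg"`` or ``"hf"`` to apply per-stratum
    Greenhouse-Geisser / Huynh-Feldt df corrections.
    ``covariate_interactions`` additionally models and tests each
    covariate's interaction with the within-subject factor of its
    stratum (the convention of classical repeated-measures ANCOVA
    software).
    """
    if isinstance(data, pd.DataFrame):
        data = LongDataset(frame=data, design=design)
    fitter = PlanFitter(design, obs=data.frame, coding=coding,
                        covariate_interactions=covariate_interactions)
    res = fitter.analyze(data.values)
    table = res.table(0)
    if sphericity != "none":
        from .sphericity import adjust_df, assess_sphericity, stratum_reports

        reports = stratum_reports(data)
        table = adjust_df(table, reports, method=sphericity)
    return table
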