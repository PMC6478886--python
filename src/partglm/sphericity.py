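"""Sphericity assessment and degrees-of-freedom corrections.

Within-subject F-tests are exact only under sphericity: the variances of
all pairwise differences of the repeated measurements are equal,

    Var(y_i - y_j) = sigma_i^2 + sigma_j^2 - 2 sigma_ij = lambda
    for all i != j.

Departures are assessed per error stratum on the orthonormalized
within-subject covariance: Mauchly's W test, the Greenhouse-Geisser
epsilon (the eigenvalue-dispersion measure) and the Huynh-Feldt epsilon
(its less-biased, capped variant).  Corrections multiply the numerator and
denominator degrees of freedom of the affected tests by epsilon.

Epsilons here are per-response (per-voxel) quantities; no pooling across
voxels is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert

from .design import DesignSpec
from .errors import SingularCovarianceError

__all__ = [
    "SphericityReport",
    "assess_sphericity",
    "stratum_reports",
    "adjust_df",
]


@dataclass
class SphericityReport:
    """Sphericity diagnostics for one within-subject error stratum."""

    stratum: str
    factors: tuple
    pair_variances: dict
    mauchly_W: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    epsilon_gg: float
    epsilon_hf: float
    lambda_check: float
    n_subjects: int
    n_groups: int

    #: dimension of the stratum's orthonormal contrast space
    dims: int = 1


def _cell_mean_matrix(frame: pd.DataFrame, design: DesignSpec):
    """Subjects x within-cells response matrix (first factor fastest),
    plus per-subject group codes."""
    unit = design.unit_factor.name
    withins = [f.name for f in design.within_factors]
    levels = [int(design.factor(w).n_levels) for w in withins]
    stride = 1
    cell = np.zeros(len(frame), dtype=int)
    for w, lv in zip(withins, levels):
        cell += (frame[w].to_numpy() - 1) * stride
        stride *= lv
    work = frame.assign(__cell=cell)
    pivot = work.pivot_table(index=unit, columns="__cell", values="value")
    pivot = pivot[list(range(stride))]
    betweens = [f.name for f in design.between_factors]
    if betweens:
        ginfo = frame.drop_duplicates(subset=[unit]).set_index(unit)[betweens]
        ginfo = ginfo.loc[pivot.index]
        groups = pd.factorize(ginfo.apply(tuple, axis=1))[0]
    else:
        groups = np.zeros(len(pivot), dtype=int)
    return pivot.to_numpy(dtype=float), groups, levels, withins


def _within_transform(withins, levels, V, orthonormal=True):
    """Kronecker transform picking out the stratum's contrast space.

    Factors in ``V`` contribute orthonormal (Helmert) contrasts, the rest
    an averaging row.  Cell order has the first factor fastest, so the
    Kronecker product runs over the factors in reverse."""
    mats = []
    for w, lv in zip(withins, levels):
        if w in V:
            mats.append(helmert(lv, full=False) if orthonormal
                        else np.eye(lv))
        else:
            mats.append(np.full((1, lv), 1.0 / lv))
    out = np.array([[1.0]])
    for m in reversed(mats):
        out = np.kron(out, m)
    return out


def _pooled_cov(Z: np.ndarray, groups: np.ndarray):
    """Within-group covariance of the transformed variables."""
    uniq = pd.unique(groups)
    n, d = Z.shape
    g = len(uniq)
    if n - g < d:
        raise SingularCovarianceError(
            f"{n} subjects in {g} group(s) cannot estimate a {d}-dimensional "
            "within-subject covariance"
        )
    resid = Z.copy()
    for u in uniq:
        sel = groups == u
        resid[sel] -= Z[sel].mean(axis=0)
    return resid.T @ resid / (n - g), n, g


def _epsilons(S: np.ndarray, n: int, g: int):
    d = S.shape[0]
    if d == 1:
        return 1.0, 1.0
    tr = np.trace(S)
    gg = tr ** 2 / (d * np.trace(S @ S))
    num = (n - g + 1) * d * gg - 2.0
    den = d * ((n - g) - d * gg)
    hf = num / den if den > 0 else 1.0
    return float(gg), float(min(hf, 1.0))


def _mauchly(S: np.ndarray, n: int, g: int):
    d = S.shape[0]
    if d == 1:
        return 1.0, 0.0, 0, 1.0
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise SingularCovarianceError("singular within-subject covariance")
    logW = logdet - d * np.log(np.trace(S) / d)
    W = float(np.exp(logW))
    ne = n - g
    f = 1.0 - (2.0 * d ** 2 + d + 2.0) / (6.0 * d * ne)
    chi2 = -ne * f * logW
    dof = d * (d + 1) // 2 - 1
    return W, float(chi2), int(dof), float(stats.chi2.sf(chi2, dof))


def assess_sphericity(data, within=None) -> SphericityReport:
    """Sphericity diagnostics for the stratum spanned by ``within``.

    ``data`` is a :class:`~partglm.fitting.LongDataset`; ``within`` lists
    the within-subject factor(s) of the stratum (default: all of them, the
    residual stratum).  Requires at least two within levels and more
    subjects (minus groups) than contrast dimensions.
    """
    design = data.design
    if within is None:
        within = tuple(f.name for f in design.within_factors)
    V = (within,) if isinstance(within, str) else tuple(within)
    # normalize to declaration order
    V = tuple(f.name for f in design.within_factors if f.name in V)
    Ymat, groups, levels, withins = _cell_mean_matrix(data.frame, design)
    d = int(np.prod([lv - 1 for w, lv in zip(withins, levels) if w in V]))
    if d < 1:
        raise ValueError("the stratum has no within-subject contrast space")

    M = _within_transform(withins, levels, V)
    Z = Ymat @ M.T
    S, n, g = _pooled_cov(Z, groups)
    gg, hf = _epsilons(S, n, g)
    W, chi2, dof, p = _mauchly(S, n, g)

    # pairwise difference variances over the stratum's cell crossing
    P = _within_transform(withins, levels, V, orthonormal=False)
    # rows of P index the V-crossing cells (V factors, first fastest)
    U = Ymat @ P.T
    vlevels = [lv for w, lv in zip(withins, levels) if w in V]
    cells = _v_cells(withins, levels, V)
    pair_vars = {}
    for (i, ci), (j, cj) in combinations(list(enumerate(cells)), 2):
        diff = U[:, i] - U[:, j]
        resid = diff.copy()
        for u in pd.unique(groups):
            sel = groups == u
            resid[sel] -= diff[sel].mean()
        pair_vars[(ci, cj)] = float(resid @ resid / (n - g))
    vals = np.array(list(pair_vars.values()))
    lam = float(np.abs(vals - vals.mean()).max()) if len(vals) else 0.0

    rep = SphericityReport(
        stratum=" × ".join(V),
        factors=V,
        pair_variances=pair_vars,
        mauchly_W=W,
        mauchly_chi2=chi2,
        mauchly_df=dof,
        mauchly_p=p,
        epsilon_gg=gg,
        epsilon_hf=hf,
        lambda_check=lam,
        n_subjects=n,
        n_groups=g,
        dims=d,
    )
    return rep


def _v_cells(withins, levels, V):
    from .contrasts import _cells

    vlv = [lv for w, lv in zip(withins, levels) if w in V]
    vnames = [w for w in withins if w in V]
    return [tuple(zip(vnames, c)) for c in _cells(vlv)]


def stratum_reports(data) -> dict:
    """Reports for every within-subject error stratum, keyed by the
    stratum's ANOVA-table label."""
    design = data.design
    unit = design.unit_factor
    withins = tuple(f.name for f in design.within_factors)
    out = {}
    from .design import ModelTerm

    for size in range(1, len(withins)):
        for V in combinations(withins, size):
            term = ModelTerm((unit.name,) + V, unit.nested_in, "random")
            out[term.label] = assess_sphericity(data, V)
    if withins:
        out["Error"] = assess_sphericity(data, withins)
    return out


def adjust_df(table, report, method: str = "gg"):
    """Sphericity-correct an ANOVA table's within-subject tests.

    Multiplies the numerator and denominator degrees of freedom of every
    test whose error stratum has a report by the stratum's epsilon, and
    recomputes the p-values.  ``method="none"`` returns the table
    unchanged.
    """
    from .fitting import AnovaTable

    if method == "none":
        return AnovaTable(frame=table.frame.copy(), design=table.design)
    if method not in ("gg", "hf"):
        raise ValueError(f"unknown correction method {method!r}")
    if isinstance(report, SphericityReport):
        reports = {report.stratum: report}
        design = table.design
        if design is not None and design.unit_factor is not None:
            from .design import ModelTerm

            unit = design.unit_factor
            withins_all = tuple(f.name for f in design.within_factors)
            if set(report.factors) == set(withins_all):
                reports["Error"] = report
            else:
                term = ModelTerm((unit.name,) + report.factors,
                                 unit.nested_in, "random")
                reports[term.label] = report
    else:
        reports = dict(report)
    frame = table.frame.copy()
    frame["df"] = frame["df"].astype(float)
    frame["Errordf"] = frame["Errordf"].astype(float)
    for idx, row in frame.iterrows():
        rep = reports.get(row["ErrorTerm"])
        if rep is None:
            continue
        eps = rep.epsilon_gg if method == "gg" else rep.epsilon_hf
        d1 = row["df"] * eps
        d2 = row["Errordf"] * eps
        frame.at[idx, "df"] = d1
        frame.at[idx, "Errordf"] = d2
        if np.isfinite(row["F"]):
            frame.at[idx, "p"] = float(stats.f.sf(row["F"], d1, d2))
        frame.at[idx, "MS"] = row["SS"] / d1
    return AnovaTable(frame=frame, design=table.design)
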