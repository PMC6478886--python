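"""Stratum-matched decomposition of continuous covariates.

In a partitioned-error analysis there are as many regression coefficients
as there are error strata: a covariate measured per within-subject cell is
split into

* the per-subject mean (adjusts the between-subjects stratum),
* one per-within-factor-level subject mean for every subject-by-factor
  stratum, and
* the raw values (adjust the residual stratum),

each tested against its matching error term.  Columns that are identical
after averaging (a covariate constant over some within factor) are
redundant and dropped; the surviving columns enter every sub-model they
remain expressible in, but each is *tested* only in the sub-model of its
own stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CovariateSpec, DesignSpec, ModelTerm
from .ems import ModelPlan
from .errors import CollinearCovariateError, UnsupportedDesignError

__all__ = ["CovariateColumn", "decompose_covariate"]


@dataclass
class CovariateColumn:
    """One derived covariate regressor, tagged by its error stratum."""

    covariate: str
    stratum: ModelTerm
    name: str
    values: np.ndarray


def _stratum_within_sets(plan: ModelPlan):
    """Per error stratum, the within factors spanning it (residual = all)."""
    design = plan.design
    withins = tuple(f.name for f in design.within_factors)
    out = []
    for entry in plan.entries:
        term = entry.error_term
        if term.kind == "residual":
            out.append((term, withins))
        else:
            out.append((term, tuple(w for w in withins if w in term.subscripts)))
    return out


def decompose_covariate(
    obs: pd.DataFrame,
    cov: CovariateSpec,
    design: DesignSpec,
    plan: ModelPlan,
) -> list:
    """Split a covariate into stratum-matched regressors.

    ``obs`` is the long-format observation table (one row per observation,
    with the subject and factor-level columns and the raw covariate
    column).  Returns the non-redundant :class:`CovariateColumn` list in
    stratum order (between stratum first, residual last).
    """
    unit = design.unit_factor
    if unit is None:
        raise UnsupportedDesignError("covariates require a subject factor")
    x = obs[cov.name].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise CollinearCovariateError(
            f"covariate {cov.name!r} is constant (zero variance)"
        )
    if cov.centering == "grand_mean":
        x = x - x.mean()
    work = obs.copy()
    work["__x"] = x
    columns: list[CovariateColumn] = []
    for stratum, wset in _stratum_within_sets(plan):
        keys = [unit.name] + list(wset)
        col = work.groupby(keys, sort=False)["__x"].transform("mean").to_numpy()
        if any(np.allclose(col, prev.values, atol=1e-12) for prev in columns):
            continue
        suffix = "mean" if not wset else (
            "raw" if len(wset) == len(design.within_factors) and stratum.kind == "residual"
            else "by_" + "_".join(wset)
        )
        columns.append(
            CovariateColumn(
                covariate=cov.name,
                stratum=stratum,
                name=f"{cov.name}.{suffix}",
                values=col,
            )
        )
    return columns
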