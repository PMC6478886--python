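"""Expected mean squares, error-term selection and multi-model planning.

The engine derives, for every term of a mixed-measures ANOVA model, its
expected mean square (EMS) as a symbolic linear combination of variance
components and fixed-effect quadratic forms, using the tabular
Cornfield-Tukey rules (restricted-model convention):

* build one row per model term and one column per subscript index;
* the entry for a bracketed (nesting) index is 1; for a live index it is 0
  when the index belongs to a fixed factor and 1 when it belongs to a random
  factor; for an absent index it is the index's level count;
* a term U contributes to EMS(T) whenever U's subscripts contain T's, with
  coefficient equal to the product of U's entries over the indices outside
  T's subscripts.

An exact F-ratio for an effect divides its mean square by the mean square
of the unique term whose EMS differs from the effect's only by the effect's
own component.  When within-subject factors are present this denominator is
generally not the overall residual, which is why a single-error-term GLM
needs one sub-model per error stratum, with the within-subject factors that
the stratum does not test averaged out of the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import pandas as pd
import sympy

from .design import (
    RANDOM,
    REP_INDEX,
    UNIT,
    DesignSpec,
    FactorSpec,
    ModelTerm,
)
from .errors import (
    AmbiguousErrorTermError,
    DegenerateDesignError,
    QuasiFRequiredError,
    UnsupportedDesignError,
)

__all__ = [
    "EMSTable",
    "ModelPlan",
    "PlanEntry",
    "enumerate_terms",
    "derive_ems",
    "select_error_term",
    "plan_models",
    "compute_df",
]


# ---------------------------------------------------------------------------
# model terms
# ---------------------------------------------------------------------------

def enumerate_terms(design: DesignSpec) -> list[ModelTerm]:
    """All terms of the full model for ``design``, residual last.

    Fixed (and crossed random) terms are every non-empty subset of the
    non-unit factors.  With a unit factor the random strata are the unit
    term and its interactions with every proper subset of the
    within-subject factors; the interaction with all of them is the
    residual.
    """
    crossed = design.crossed_factors
    unit = design.unit_factor
    if unit is not None and any(f.kind == RANDOM for f in crossed):
        raise UnsupportedDesignError(
            "random factors crossed with the subject factor are not "
            "supported (multiple random unit factors would require quasi-F "
            "ratios)"
        )
    if unit is not None:
        reps = design.replicates_per_cell
        if isinstance(reps, int) and reps != 1:
            raise UnsupportedDesignError(
                "replicated observations per subject/cell are not supported; "
                "supply per-cell subject summaries"
            )

    terms: list[ModelTerm] = []
    names = [f.name for f in crossed]
    kinds = {f.name: f.kind for f in crossed}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            kind = RANDOM if any(kinds[c] == RANDOM for c in combo) else "fixed"
            terms.append(ModelTerm(combo, (), kind))

    withins = [f.name for f in design.within_factors]
    if unit is not None:
        for size in range(0, len(withins)):  # proper subsets only
            for combo in combinations(withins, size):
                terms.append(
                    ModelTerm((unit.name,) + combo, unit.nested_in, RANDOM)
                )
        nested = tuple(n for n in names)
        terms.append(ModelTerm((unit.name,), nested, "residual"))
    else:
        terms.append(ModelTerm((REP_INDEX,), tuple(names), "residual"))
    return terms


def term_sort_key(term: ModelTerm, design: DesignSpec):
    """Output order: main effects in declaration order, interactions by
    ascending order, random strata (fewest within factors first), residual
    last -- the layout of the printed ANOVA tables."""
    pos = {f.name: i for i, f in enumerate(design.factors)}
    if term.kind == "residual":
        return (3, ())
    positions = tuple(pos.get(f, 99) for f in term.factors)
    if term.is_random:
        return (2, len(term.factors), positions)
    return (1, len(term.factors), positions)


# ---------------------------------------------------------------------------
# EMS derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EMSTable:
    """Per model term, the EMS as ``{component term: coefficient}``.

    Coefficients are :mod:`sympy` expressions (products of level counts);
    component terms map to variance components (random terms, residual
    ``sigma2``) or fixed-effect quadratic forms.
    """

    design: DesignSpec
    terms: tuple
    rows: dict

    def __iter__(self):
        return iter(self.terms)

    def term(self, label: str) -> ModelTerm:
        for t in self.terms:
            if t.label == label:
                return t
        raise KeyError(label)

    def ems(self, term: ModelTerm) -> dict:
        return dict(self.rows[term])

    def own_component(self, term: ModelTerm):
        return self.rows[term][term]

    def ems_expr(self, term: ModelTerm) -> sympy.Expr:
        """The EMS as a single sympy expression over component symbols."""
        return sympy.Add(
            *(
                coeff * sympy.Symbol(comp.component_name, positive=True)
                for comp, coeff in self.rows[term].items()
            )
        )

    @property
    def strata(self) -> tuple:
        """Random strata (potential error terms), residual last."""
        out = [t for t in self.terms if t.is_random]
        out.sort(key=lambda t: term_sort_key(t, self.design))
        return tuple(out)

    @property
    def fixed_effects(self) -> tuple:
        out = [t for t in self.terms if t.kind == "fixed"]
        out.sort(key=lambda t: term_sort_key(t, self.design))
        return tuple(out)

    def evaluate(self, term: ModelTerm, components: dict) -> float:
        """Numeric EMS value given ``{component name: value}``.

        Quadratic-form values (``Q_*``) should be supplied as
        sum-of-squared-effects divided by the term's degrees of freedom;
        missing components count as 0.
        """
        total = 0.0
        for comp, coeff in self.rows[term].items():
            total += float(coeff) * float(components.get(comp.component_name, 0.0))
        return total

    def to_frame(self) -> pd.DataFrame:
        """Render the EMS table (terms x components, string coefficients)."""
        order = sorted(self.terms, key=lambda t: term_sort_key(t, self.design))
        cols: list[ModelTerm] = [t for t in order]
        data = {}
        for comp in cols:
            col = []
            for t in order:
                coeff = self.rows[t].get(comp)
                col.append("" if coeff is None else str(coeff))
            data[comp.component_name] = col
        return pd.DataFrame(data, index=[t.label for t in order])

    def f_assignments(self) -> pd.DataFrame:
        """Numerator/denominator mean squares for every fixed effect."""
        rows = []
        for eff in self.fixed_effects:
            err = select_error_term(self, eff)
            rows.append(
                {
                    "Effect": eff.label,
                    "Test": f"MS({eff.label}) / MS({err.label})",
                    "Error": err.label,
                }
            )
        return pd.DataFrame(rows)


def _index_info(design: DesignSpec):
    indices = [f.name for f in design.factors]
    is_random = {
        f.name: f.kind == RANDOM or f.scope == UNIT for f in design.factors
    }
    levels = {f.name: f.level_expr() for f in design.factors}
    if design.unit_factor is None:
        indices.append(REP_INDEX)
        is_random[REP_INDEX] = True
        levels[REP_INDEX] = sympy.sympify(design.replicates_per_cell)
    return indices, is_random, levels


def _ct_entry(term: ModelTerm, idx: str, is_random: dict, levels: dict):
    if idx in term.nested:
        return sympy.Integer(1)
    if idx in term.factors:
        return sympy.Integer(1) if is_random[idx] else sympy.Integer(0)
    return levels[idx]


def derive_ems(design: DesignSpec) -> EMSTable:
    """Derive the EMS table for every term of the full model.

    Raises :class:`UnsupportedDesignError` for designs outside the supported
    family (more than one unit factor, random factors crossed with the
    subject factor, replicated cells under a subject factor).
    """
    terms = enumerate_terms(design)
    indices, is_random, levels = _index_info(design)
    rows: dict[ModelTerm, dict[ModelTerm, sympy.Expr]] = {}
    for t in terms:
        row: dict[ModelTerm, sympy.Expr] = {}
        for u in terms:
            if not t.subscripts <= u.subscripts:
                continue
            coeff = sympy.Integer(1)
            for idx in indices:
                if idx in t.subscripts:
                    continue
                coeff = coeff * _ct_entry(u, idx, is_random, levels)
            coeff = sympy.expand(coeff)
            if coeff != 0:
                row[u] = coeff
        rows[t] = row
    return EMSTable(design=design, terms=tuple(terms), rows=rows)


# ---------------------------------------------------------------------------
# error-term selection
# ---------------------------------------------------------------------------

def _rows_equal(a: dict, b: dict) -> bool:
    if set(a) != set(b):
        return False
    return all(sympy.expand(a[k] - b[k]) == 0 for k in a)


def select_error_term(ems: EMSTable, effect: ModelTerm) -> ModelTerm:
    """The unique term whose EMS equals EMS(effect) minus the effect's own
    component -- the exact F-ratio denominator.

    Raises :class:`QuasiFRequiredError` when no stratum matches (never
    silently falls back to the residual) and
    :class:`AmbiguousErrorTermError` if more than one matches.
    """
    if effect.is_error:
        raise ValueError("the residual has no error term")
    target = {u: c for u, c in ems.rows[effect].items() if u != effect}
    candidates = [
        t
        for t in ems.terms
        if t is not effect and t.is_random and _rows_equal(ems.rows[t], target)
    ]
    if not candidates:
        unmatched = [u.component_name for u in target if u.kind != "residual"]
        raise QuasiFRequiredError(effect.label, unmatched)
    if len(candidates) > 1:
        raise AmbiguousErrorTermError(
            f"effect {effect.label!r} has multiple matching error strata: "
            f"{[c.label for c in candidates]}"
        )
    return candidates[0]


# ---------------------------------------------------------------------------
# degrees of freedom
# ---------------------------------------------------------------------------

def _within_levels(design: DesignSpec, names: Iterable[str]):
    return [design.factor(n).level_expr() for n in names]


def stratum_df_expr(design: DesignSpec, stratum: ModelTerm, n_cov: int = 0):
    """Degrees of freedom of a subject-derived error stratum.

    ``(sum_k n_k - g - c) * prod(levels - 1)`` over the stratum's
    within-subject factors, where ``g`` is the number of between-subjects
    groups and ``c`` the number of covariates.  A covariate absorbs one
    subject-level degree of freedom; the reduction is inherited by every
    stratum derived from the subjects (the split-plot ANCOVA accounting).
    """
    unit = design.unit_factor
    if unit is None:
        raise ValueError("stratum df requires a unit factor")
    g = sympy.Integer(1)
    for f in design.between_factors:
        g *= f.level_expr()
    if design.group_sizes is not None:
        n_total = sympy.Integer(int(sum(design.group_sizes)))
    else:
        n_total = g * unit.level_expr()
    base = n_total - g - sympy.Integer(n_cov)
    withins_in = [
        f.name for f in design.within_factors if f.name in stratum.subscripts
    ]
    df = base
    for lev in _within_levels(design, withins_in):
        df *= lev - 1
    return sympy.expand(df)


def compute_df(
    design: DesignSpec,
    plan: "ModelPlan | None" = None,
    n_covariates: int | None = None,
) -> dict:
    """Integer degrees of freedom for every model term.

    Fixed effects use the product of (levels - 1) over their subscripts;
    subject-derived strata use :func:`stratum_df_expr` with the actual
    per-group sizes, which is valid for unbalanced designs.  Covariates
    (from the design, or ``n_covariates``) each remove one subject-level
    degree of freedom.
    """
    if not design.is_numeric:
        raise ValueError("compute_df requires numeric level counts")
    c = len(design.covariates) if n_covariates is None else int(n_covariates)
    terms = plan.ems.terms if plan is not None else enumerate_terms(design)
    out: dict[ModelTerm, int] = {}
    for t in terms:
        if t.kind == "residual" and design.unit_factor is None:
            continue
        if t.is_random and design.unit_factor is not None:
            df = int(stratum_df_expr(design, t, n_cov=c))
        else:
            df = 1
            for name in t.factors:
                df *= int(design.factor(name).level_expr()) - 1
        out[t] = df
    if design.unit_factor is None:
        n_obs = design.replicates_per_cell
        for f in design.crossed_factors:
            n_obs *= int(f.level_expr())
        residual = next(t for t in terms if t.kind == "residual")
        out[residual] = int(n_obs) - 1 - sum(
            out[t] for t in terms if t.kind != "residual"
        )
    bad = [t.label for t, v in out.items() if v <= 0]
    if bad:
        raise DegenerateDesignError(
            f"non-positive degrees of freedom for terms: {bad}"
        )
    return out


# ---------------------------------------------------------------------------
# model planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanEntry:
    """One sub-model: an enforced error stratum, the within-subject factors
    averaged over to enforce it, and the effects it tests."""

    error_term: ModelTerm
    average_over: tuple
    effects_tested: tuple
    df_error: object  # int for numeric designs, sympy expression otherwise

    @property
    def label(self) -> str:
        return self.error_term.label


@dataclass(frozen=True)
class ModelPlan:
    entries: tuple
    design: DesignSpec
    ems: EMSTable

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def entry_for(self, effect: ModelTerm) -> PlanEntry:
        for e in self.entries:
            if effect in e.effects_tested:
                return e
        raise KeyError(effect.label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "ErrorTerm": e.error_term.label,
                    "AverageOver": ", ".join(e.average_over) or "-",
                    "EffectsTested": ", ".join(t.label for t in e.effects_tested),
                    "dfError": e.df_error,
                }
            )
        return pd.DataFrame(rows)


def plan_models(ems: EMSTable, design: DesignSpec) -> ModelPlan:
    """Group the fixed effects by their exact error stratum.

    One entry per distinct stratum.  The within-subject factors absent from
    a stratum's subscripts are averaged over before fitting that sub-model:
    after averaging, the stratum becomes perfectly collinear with the
    residuals and is thereby enforced as that model's error term.
    """
    withins = [f.name for f in design.within_factors]
    by_stratum: dict[ModelTerm, list[ModelTerm]] = {}
    for eff in ems.fixed_effects:
        err = select_error_term(ems, eff)
        by_stratum.setdefault(err, []).append(eff)
    entries = []
    for stratum in sorted(by_stratum, key=lambda t: term_sort_key(t, design)):
        avg = tuple(w for w in withins if w not in stratum.subscripts)
        effs = tuple(
            sorted(by_stratum[stratum], key=lambda t: term_sort_key(t, design))
        )
        if design.unit_factor is not None:
            df = stratum_df_expr(design, stratum, n_cov=len(design.covariates))
            if design.is_numeric:
                df = int(df)
        else:
            df = compute_df(design)[stratum] if design.is_numeric else None
        entries.append(
            PlanEntry(
                error_term=stratum,
                average_over=avg,
                effects_tested=effs,
                df_error=df,
            )
        )
    return ModelPlan(entries=tuple(entries), design=design, ems=ems)
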