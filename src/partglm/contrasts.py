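"""Design matrices and estimable contrast weights.

In overparameterized ANOVA design matrices (one indicator column per factor
level, fitted by generalized inverse) individual parameters are not
estimable; only linear combinations of design-matrix rows are.  Contrast
weights are therefore derived from the rows themselves:

* a *marginal mean* weight vector is the average of the rows selected by a
  level condition (always estimable, being an average of estimable
  functions);
* a *main effect* is spanned by differences of marginal-mean weight
  vectors, an *interaction* by differences of differences of cell-mean
  weight vectors, and a *simple effect* by differences of cell means at
  fixed levels of the other factors.

Weight vectors retain non-zero entries on the random subject blocks
whenever the subject effects do not cancel in the numerator; such contrasts
must not be tested against the overall residual (the ``subject_zero``
flag and ``required_error`` metadata carry this diagnosis).

All weight arithmetic is exact (:class:`fractions.Fraction`), so printed
vectors of halves and quarters are reproduced bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd

from .design import DesignSpec, ModelTerm, RANDOM
from .ems import EMSTable, select_error_term, term_sort_key
from .errors import NonEstimableError

__all__ = [
    "DesignMatrix",
    "ContrastWeights",
    "build_design_matrix",
    "canonical_observation_table",
    "reduce_unique_rows",
    "marginal_mean_weights",
    "derive_effect_contrast",
    "derive_simple_effect_contrast",
    "check_estimable",
]

CODINGS = ("overparameterized", "treatment", "sigma_restricted", "cell_means")

#: default estimability tolerance on unit-scaled matrices
ESTIMABILITY_TOL = 1e-8

#: relative singular-value cutoff for rank-deficient pseudoinverses
PINV_RCOND = 1e-10


def _cells(level_counts):
    """Level-index tuples for a factor crossing, first factor fastest."""
    if not level_counts:
        return [()]
    rev = [range(1, c + 1) for c in reversed(level_counts)]
    return [tuple(reversed(t)) for t in product(*rev)]


def _factor_codes(n_levels: int, coding: str) -> np.ndarray:
    """Level -> code-row matrix (n_levels x n_columns), integer valued."""
    eye = np.eye(n_levels, dtype=int)
    if coding in ("overparameterized", "cell_means"):
        return eye
    if coding == "treatment":  # reference = last level
        return eye[:, :-1]
    if coding == "sigma_restricted":
        out = np.vstack([np.eye(n_levels - 1, dtype=int), -np.ones((1, n_levels - 1), dtype=int)])
        return out
    raise ValueError(f"unknown coding {coding!r}")


@dataclass
class DesignMatrix:
    """An integer-valued design matrix with labelled column blocks.

    ``blocks`` maps a block label (e.g. ``"Location"``, ``"Subject(Drink)"``)
    to a column slice; ``block_terms`` maps it to the corresponding
    :class:`ModelTerm`.  ``row_info`` holds, per row, the subject label and
    the 1-based factor levels the row predicts.
    """

    values: np.ndarray
    col_labels: list
    blocks: dict
    block_terms: dict
    coding: str
    row_info: pd.DataFrame
    design: DesignSpec
    withins_present: tuple

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def as_float(self) -> np.ndarray:
        return self.values.astype(float)

    @property
    def subject_blocks(self) -> list:
        unit = self.design.unit_factor
        if unit is None:
            return []
        return [
            lab
            for lab, term in self.block_terms.items()
            if term is not None and unit.name in term.factors
        ]

    @property
    def subject_column_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_cols, dtype=bool)
        for lab in self.subject_blocks:
            mask[self.blocks[lab]] = True
        return mask

    def column_subset(self, cols) -> "DesignMatrix":
        cols = np.asarray(cols)
        keep = np.flatnonzero(cols) if cols.dtype == bool else cols
        labels = [self.col_labels[i] for i in keep]
        return DesignMatrix(
            values=self.values[:, keep],
            col_labels=labels,
            blocks={},
            block_terms={},
            coding=self.coding,
            row_info=self.row_info,
            design=self.design,
            withins_present=self.withins_present,
        )


def canonical_observation_table(
    design: DesignSpec, withins_present=None
) -> pd.DataFrame:
    """One row per observation for the full (or averaged) design.

    Rows are ordered group-major, then subject, then within-subject cells
    with the first within factor varying fastest.  Factor levels are
    1-based integers; subjects are numbered 1..N across groups.
    """
    unit = design.unit_factor
    betweens = design.between_factors
    withins = [
        f
        for f in design.within_factors
        if withins_present is None or f.name in withins_present
    ]
    rows = []
    if unit is None:
        cells = _cells([int(f.n_levels) for f in design.crossed_factors])
        names = [f.name for f in design.crossed_factors]
        for cell in cells:
            for rep in range(1, int(design.replicates_per_cell) + 1):
                rows.append(dict(zip(names, cell)))
        return pd.DataFrame(rows)
    group_cells = _cells([int(f.n_levels) for f in betweens])
    wcells = _cells([int(f.n_levels) for f in withins])
    subj = 0
    for gi, gcell in enumerate(group_cells):
        for _ in range(design.group_size(gi)):
            subj += 1
            for wcell in wcells:
                row = {unit.name: subj}
                row.update({f.name: l for f, l in zip(betweens, gcell)})
                row.update({f.name: l for f, l in zip(withins, wcell)})
                rows.append(row)
    return pd.DataFrame(rows)


def _subject_order(design: DesignSpec, rows: pd.DataFrame):
    """Subjects grouped by between-subjects cell, first-appearance order."""
    unit = design.unit_factor
    betweens = [f.name for f in design.between_factors]
    info = rows.drop_duplicates(subset=[unit.name])[[unit.name] + betweens]
    group_cells = _cells([int(f.n_levels) for f in design.between_factors])
    ordered, groups = [], []
    for gcell in group_cells:
        sel = info
        for name, lvl in zip(betweens, gcell):
            sel = sel[sel[name] == lvl]
        subs = list(sel[unit.name])
        ordered.extend(subs)
        groups.append(subs)
    if len(ordered) != len(info):
        raise ValueError("subjects with inconsistent between-group levels")
    return ordered, groups


def _subject_codes(design, rows, coding):
    """Subject -> code-row mapping (dict) and number of code columns."""
    ordered, groups = _subject_order(design, rows)
    n = len(ordered)
    if coding in ("overparameterized", "cell_means"):
        mat = np.eye(n, dtype=int)
        cols = ordered
    else:
        # one indicator per subject, last subject of each group dropped
        kept = [s for grp in groups for s in grp[:-1]]
        mat = np.zeros((n, len(kept)), dtype=int)
        for j, s in enumerate(kept):
            mat[ordered.index(s), j] = 1
        cols = kept
    return {s: mat[i] for i, s in enumerate(ordered)}, cols


def build_design_matrix(
    design: DesignSpec,
    coding: str = "overparameterized",
    rows: pd.DataFrame | None = None,
    withins_present=None,
) -> DesignMatrix:
    """Design matrix for the full model (or an averaged sub-model).

    Column layout: intercept, factor main-effect blocks in declaration
    order, interaction blocks by ascending order, then the random subject
    blocks (subject, and subject-by-within for every proper subset of the
    within factors present).  Cell-means coding replaces the fixed blocks
    by one indicator per cell of the full fixed crossing.
    """
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}")
    if withins_present is None:
        withins_present = tuple(f.name for f in design.within_factors)
    else:
        withins_present = tuple(withins_present)
    if rows is None:
        rows = canonical_observation_table(design, withins_present)
    rows = rows.reset_index(drop=True)

    crossed = [f for f in design.crossed_factors if f.scope != "within" or f.name in withins_present]
    unit = design.unit_factor

    values_cols: list[np.ndarray] = []
    col_labels: list[str] = []
    blocks: dict[str, slice] = {}
    block_terms: dict[str, ModelTerm | None] = {}

    def add_block(label, term, cols, labels):
        start = len(col_labels)
        values_cols.extend(cols)
        col_labels.extend(labels)
        blocks[label] = slice(start, start + len(labels))
        block_terms[label] = term

    def factor_block_columns(subset, fcoding):
        codes = {f.name: _factor_codes(int(f.n_levels), fcoding) for f in subset}
        ncols = {f.name: codes[f.name].shape[1] for f in subset}
        combos = _cells([ncols[f.name] for f in subset])
        cols, labels = [], []
        for combo in combos:
            col = np.ones(len(rows), dtype=int)
            parts = []
            for f, j in zip(subset, combo):
                lev = rows[f.name].to_numpy()
                col = col * codes[f.name][lev - 1, j - 1]
                parts.append(f"{f.name}{j}")
            cols.append(col)
            labels.append(":".join(parts))
        return cols, labels

    if coding == "cell_means":
        cols, labels = factor_block_columns(crossed, "overparameterized")
        add_block("cells", None, cols, labels)
    else:
        add_block("mu", None, [np.ones(len(rows), dtype=int)], ["mu"])
        fixed_terms = []
        for size in range(1, len(crossed) + 1):
            from itertools import combinations

            for subset in combinations(crossed, size):
                kinds = [f.kind for f in subset]
                term = ModelTerm(
                    tuple(f.name for f in subset),
                    (),
                    RANDOM if RANDOM in kinds else "fixed",
                )
                fixed_terms.append((term, subset))
        fixed_terms.sort(key=lambda p: term_sort_key(p[0], design))
        for term, subset in fixed_terms:
            cols, labels = factor_block_columns(subset, coding)
            add_block(term.label, term, cols, labels)

    if unit is not None:
        scodes, scols = _subject_codes(design, rows, coding)
        subj_code_rows = np.vstack([scodes[s] for s in rows[unit.name]])
        from itertools import combinations

        wfacs = [design.factor(w) for w in withins_present]
        for size in range(0, len(wfacs)):
            for wsub in combinations(wfacs, size):
                term = ModelTerm(
                    (unit.name,) + tuple(f.name for f in wsub),
                    unit.nested_in,
                    RANDOM,
                )
                if size == 0:
                    cols = [subj_code_rows[:, j] for j in range(subj_code_rows.shape[1])]
                    labels = [f"{unit.name}{s}" for s in scols]
                else:
                    fcod = "overparameterized" if coding == "cell_means" else coding
                    wcols, wlabels = factor_block_columns(
                        wsub, "overparameterized" if coding in ("overparameterized", "cell_means") else "treatment"
                    )
                    cols, labels = [], []
                    for wc, wl in zip(wcols, wlabels):
                        for j, s in enumerate(scols):
                            cols.append(subj_code_rows[:, j] * wc)
                            labels.append(f"{unit.name}{s}:{wl}")
                add_block(term.label, term, cols, labels)

    values = np.column_stack(values_cols) if values_cols else np.zeros((len(rows), 0), int)
    return DesignMatrix(
        values=values,
        col_labels=col_labels,
        blocks=blocks,
        block_terms=block_terms,
        coding=coding,
        row_info=rows,
        design=design,
        withins_present=withins_present,
    )


def reduce_unique_rows(X: DesignMatrix, drop_subject_columns: bool = False) -> DesignMatrix:
    """Unique rows in first-occurrence (stable) order, optionally after
    removing the subject blocks."""
    if drop_subject_columns:
        X = X.column_subset(~X.subject_column_mask)
    seen: dict[tuple, int] = {}
    keep = []
    for i in range(X.n_rows):
        key = tuple(X.values[i])
        if key not in seen:
            seen[key] = i
            keep.append(i)
    return DesignMatrix(
        values=X.values[keep],
        col_labels=X.col_labels,
        blocks=X.blocks,
        block_terms=X.block_terms,
        coding=X.coding,
        row_info=X.row_info.iloc[keep].reset_index(drop=True),
        design=X.design,
        withins_present=X.withins_present,
    )


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def marginal_mean_weights(X: DesignMatrix, condition: dict) -> np.ndarray:
    """Exact (Fraction) average of the design-matrix rows selected by
    ``condition`` -- ``{factor: level}`` entries select, ``"average"`` (or
    omission) averages over that factor."""
    mask = np.ones(X.n_rows, dtype=bool)
    for name, lvl in condition.items():
        if lvl == "average":
            continue
        mask &= (X.row_info[name] == lvl).to_numpy()
    count = int(mask.sum())
    if count == 0:
        raise ValueError(f"no design rows match condition {condition!r}")
    sums = X.values[mask].sum(axis=0)
    return np.array([Fraction(int(s), count) for s in sums], dtype=object)


@dataclass
class ContrastWeights:
    """A rank-r weight matrix over design columns with diagnostics."""

    weights: np.ndarray  # (r, p) object array of Fractions
    target: str
    estimable: bool
    subject_zero: bool
    required_error: ModelTerm | None

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.as_float()))

    def as_float(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def row(self, i: int = 0) -> list:
        return list(self.weights[i])

    def to_tsv(self, path, col_labels=None) -> None:
        """One weight row per line, exact fractions, optional header."""
        with open(path, "w") as fh:
            if col_labels is not None:
                fh.write("\t".join(col_labels) + "\n")
            for row in self.weights:
                fh.write("\t".join(str(w) for w in row) + "\n")


def check_estimable(X, L, tol: float = ESTIMABILITY_TOL) -> bool:
    """True iff every row of ``L`` lies in the row space of ``X``
    (``L == L X^- X`` within ``tol``)."""
    Xf = X.as_float() if isinstance(X, DesignMatrix) else np.asarray(X, float)
    Lf = np.atleast_2d(np.asarray(L, dtype=float))
    if Lf.shape[1] != Xf.shape[1]:
        raise ValueError("column counts of L and X differ")
    proj = Lf @ np.linalg.pinv(Xf, rcond=PINV_RCOND) @ Xf
    return bool(np.max(np.abs(Lf - proj)) < tol)


def _difference_matrix(n: int) -> np.ndarray:
    """(n-1) x n adjacent-difference operator."""
    D = np.zeros((n - 1, n), dtype=object)
    for i in range(n - 1):
        D[i, i] = Fraction(1)
        D[i, i + 1] = Fraction(-1)
    return D


def _kron(mats):
    out = np.array([[Fraction(1)]], dtype=object)
    for m in mats:
        out = np.kron(out, m)
    return out


def _surviving_error(X: DesignMatrix, W: np.ndarray) -> ModelTerm:
    """Error stratum implied by the random blocks whose weights survive."""
    survivors = []
    for lab in X.subject_blocks:
        block = W[:, X.blocks[lab]]
        if any(w != 0 for w in np.ravel(block)):
            survivors.append(X.block_terms[lab])
    if not survivors:
        names = tuple(f.name for f in X.design.crossed_factors)
        unit = X.design.unit_factor
        if unit is None:
            from .design import REP_INDEX

            return ModelTerm((REP_INDEX,), names, "residual")
        return ModelTerm((unit.name,), names, "residual")
    survivors.sort(key=lambda t: len(t.factors))
    return survivors[0]


def _contrast_from_cells(X, factors, fixed_at, target):
    """Differences (of differences ...) of cell-mean weights."""
    fspecs = [X.design.factor(f) for f in factors]
    levels = [int(f.n_levels) for f in fspecs]
    cell_combos = list(product(*[range(1, l + 1) for l in levels]))
    G = []
    for combo in cell_combos:
        cond = dict(fixed_at)
        cond.update({f: l for f, l in zip(factors, combo)})
        G.append(marginal_mean_weights(X, cond))
    G = np.vstack(G)
    D = _kron([_difference_matrix(l) for l in levels])
    L = D @ G
    subject_zero = not np.any(
        np.asarray(L[:, X.subject_column_mask], dtype=float)
    ) if X.subject_column_mask.any() else True
    return ContrastWeights(
        weights=L,
        target=target,
        estimable=check_estimable(X, np.asarray(L, dtype=float)),
        subject_zero=bool(subject_zero),
        required_error=_surviving_error(X, L),
    )


def derive_effect_contrast(
    X: DesignMatrix, effect, ems: EMSTable | None = None
) -> ContrastWeights:
    """Type III contrast for a main effect or interaction, derived from the
    design-matrix rows.

    Main effects are spanned by differences of marginal-mean weight
    vectors; interactions by differences of differences of cell-mean
    weights.  If an :class:`EMSTable` is supplied the ``required_error`` is
    taken from the exact EMS match, otherwise it is inferred from the
    surviving subject-block weights.
    """
    factors = effect.factors if isinstance(effect, ModelTerm) else tuple(effect)
    label = " × ".join(factors)
    cw = _contrast_from_cells(X, factors, {}, label)
    if ems is not None:
        term = next(
            (t for t in ems.terms if t.kind == "fixed" and set(t.factors) == set(factors)),
            None,
        )
        if term is not None:
            cw.required_error = select_error_term(ems, term)
    return cw


def derive_simple_effect_contrast(
    X: DesignMatrix, factor: str, at: dict
) -> ContrastWeights:
    """Simple (follow-up) effect of ``factor`` at fixed levels of the other
    factors.

    The error term appropriate for a follow-up test is not necessarily the
    one used for the omnibus effect: the returned ``required_error`` and
    ``subject_zero`` flags report which stratum the surviving random-effect
    weights demand.  A between-subjects simple effect (``subject_zero``
    False) needs a separate between-subjects model fitted to the selected
    subset of the data.
    """
    label = f"{factor} at " + ", ".join(f"{k}={v}" for k, v in at.items())
    return _contrast_from_cells(X, (factor,), dict(at), label)
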