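"""Declarative specification of factorial designs with repeated measurements.

A design is a list of factors.  Each factor is fixed or random and lives on
one of three scopes:

``between``
    varies across subjects only (e.g. treatment group);
``within``
    varies inside each subject (repeated measurements);
``unit``
    the observational unit itself (the subject factor), always random,
    optionally nested in the between-subjects factors.

The :class:`DesignSpec` is the single source of truth consumed by the EMS
engine, the design-matrix/contrast builder, the model-fitting pipeline and
the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import sympy

from .errors import UnsupportedDesignError

FIXED = "fixed"
RANDOM = "random"

WITHIN = "within"
BETWEEN = "between"
UNIT = "unit"

#: reserved index name for pure-replication error terms
REP_INDEX = "_rep"


@dataclass(frozen=True)
class FactorSpec:
    """One factor of the design.

    Parameters
    ----------
    name
        Identifier, unique within the design.
    n_levels
        Number of levels.  May be a :mod:`sympy` symbol for symbolic EMS
        derivation.  For the unit factor this is the number of subjects per
        between-subjects group (the balanced template); actual per-group
        sizes are supplied through :attr:`DesignSpec.group_sizes`.
    kind
        ``"fixed"`` or ``"random"``.  The unit factor must be random.
    scope
        ``"within"``, ``"between"`` or ``"unit"``.
    nested_in
        Names of the factors this factor is nested in (e.g. the subject
        factor nested in the group factor).
    symbol
        Name of the level-count symbol used in symbolic EMS output.
        Defaults to the lower-cased first letter of ``name`` (``n`` for the
        unit factor).
    """

    name: str
    n_levels: object
    kind: str = FIXED
    scope: str = BETWEEN
    nested_in: tuple = ()
    symbol: str | None = None

    def __post_init__(self):
        if self.kind not in (FIXED, RANDOM):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.scope not in (WITHIN, BETWEEN, UNIT):
            raise ValueError(f"unknown factor scope {self.scope!r}")
        object.__setattr__(self, "nested_in", tuple(self.nested_in))
        if self.scope == UNIT and self.kind != RANDOM:
            raise UnsupportedDesignError(
                f"unit factor {self.name!r} must be random"
            )
        if isinstance(self.n_levels, int) and self.n_levels < 1:
            raise ValueError(f"factor {self.name!r} needs >= 1 level")

    @property
    def is_symbolic(self) -> bool:
        return not isinstance(self.n_levels, (int,))

    def level_expr(self) -> sympy.Expr:
        return sympy.sympify(self.n_levels)

    def default_symbol(self) -> str:
        if self.scope == UNIT:
            return "n"
        return (self.symbol or self.name[0].lower())


@dataclass(frozen=True)
class CovariateSpec:
    """A continuous covariate attached to a design.

    ``varies_over`` lists the within-subject factors the covariate genuinely
    varies over; an empty tuple declares a between-subjects (constant,
    one-value-per-subject) covariate.  Grand-mean centering is applied by
    default so the intercept keeps its grand-mean interpretation.
    """

    name: str
    varies_over: tuple = ()
    centering: str = "grand_mean"

    def __post_init__(self):
        object.__setattr__(self, "varies_over", tuple(self.varies_over))
        if self.centering not in ("grand_mean", "none"):
            raise ValueError(f"unknown centering {self.centering!r}")


@dataclass(frozen=True)
class DesignSpec:
    """A complete design: factors, replication and optional covariates."""

    factors: tuple
    replicates_per_cell: object = 1
    group_sizes: tuple | None = None
    covariates: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.group_sizes is not None:
            object.__setattr__(self, "group_sizes", tuple(self.group_sizes))
        self._validate()

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        if REP_INDEX in names:
            raise ValueError(f"factor name {REP_INDEX!r} is reserved")
        known = set(names)
        for f in self.factors:
            for parent in f.nested_in:
                if parent not in known:
                    raise ValueError(
                        f"factor {f.name!r} nested in undeclared {parent!r}"
                    )
        self._check_no_nesting_cycles()
        units = [f for f in self.factors if f.scope == UNIT]
        if len(units) > 1:
            raise UnsupportedDesignError(
                "designs with more than one unit (subject) factor are not "
                "supported"
            )
        if self.within_factors and not units:
            raise UnsupportedDesignError(
                "within-subject factors require a unit (subject) factor"
            )
        if units:
            unit = units[0]
            for parent in unit.nested_in:
                if self.factor(parent).scope != BETWEEN:
                    raise UnsupportedDesignError(
                        "the unit factor may only be nested in "
                        "between-subjects factors"
                    )
        if self.group_sizes is not None:
            if not units:
                raise ValueError("group_sizes requires a unit factor")
            if len(self.group_sizes) != self.n_groups:
                raise ValueError(
                    f"group_sizes has {len(self.group_sizes)} entries but the "
                    f"design has {self.n_groups} between-subjects groups"
                )
        seen = set()
        for cov in self.covariates:
            if cov.name in seen or cov.name in known:
                raise ValueError(f"duplicate covariate name {cov.name!r}")
            seen.add(cov.name)
            for w in cov.varies_over:
                if w not in {f.name for f in self.within_factors}:
                    raise ValueError(
                        f"covariate {cov.name!r} varies over {w!r}, which is "
                        "not a within-subject factor"
                    )

    def _check_no_nesting_cycles(self) -> None:
        graph = {f.name: set(f.nested_in) for f in self.factors}
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            if state.get(node) == 1:
                raise ValueError(f"nesting cycle involving factor {node!r}")
            if state.get(node) == 2:
                return
            state[node] = 1
            for parent in graph[node]:
                visit(parent)
            state[node] = 2

        for name in graph:
            visit(name)

    # -- accessors -----------------------------------------------------
    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def within_factors(self) -> tuple:
        return tuple(f for f in self.factors if f.scope == WITHIN)

    @property
    def between_factors(self) -> tuple:
        return tuple(f for f in self.factors if f.scope == BETWEEN)

    @property
    def unit_factor(self) -> FactorSpec | None:
        for f in self.factors:
            if f.scope == UNIT:
                return f
        return None

    @property
    def crossed_factors(self) -> tuple:
        """All non-unit factors, in declaration order."""
        return tuple(f for f in self.factors if f.scope != UNIT)

    @property
    def n_groups(self) -> int:
        g = 1
        for f in self.between_factors:
            if f.is_symbolic:
                raise ValueError("numeric between-factor levels required")
            g *= f.n_levels
        return g

    @property
    def n_subjects_total(self) -> int:
        if self.unit_factor is None:
            raise ValueError("design has no unit factor")
        if self.group_sizes is not None:
            return int(sum(self.group_sizes))
        n = self.unit_factor.n_levels
        if not isinstance(n, int):
            raise ValueError("numeric subject count required")
        return n * self.n_groups

    @property
    def balanced(self) -> bool:
        if self.group_sizes is None:
            return True
        return len(set(self.group_sizes)) <= 1

    @property
    def is_numeric(self) -> bool:
        ok = all(not f.is_symbolic for f in self.factors)
        return ok and isinstance(self.replicates_per_cell, int)

    def group_size(self, group_index: int) -> int:
        if self.group_sizes is not None:
            return int(self.group_sizes[group_index])
        return int(self.unit_factor.n_levels)

    def symbolic(self) -> "DesignSpec":
        """Return a copy with all level counts replaced by symbols, for
        literal symbolic EMS output (the balanced template)."""
        factors = tuple(
            replace(f, n_levels=sympy.Symbol(f.default_symbol(), positive=True))
            for f in self.factors
        )
        reps = self.replicates_per_cell
        if isinstance(reps, int) and reps > 1:
            reps = sympy.Symbol("n", positive=True)
        return DesignSpec(factors, reps, None, self.covariates)

    # -- construction from config --------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict) -> "DesignSpec":
        """Build a design from a plain config mapping (the YAML dialect).

        Expected keys: ``factors`` (list of factor blocks with ``name``,
        ``levels``, optional ``kind``/``scope``/``nested_in``), optional
        ``subject`` block (``name``, ``nested_in``), ``group_sizes``,
        ``replicates_per_cell`` and ``covariates``.
        """
        factors = [
            FactorSpec(
                name=b["name"],
                n_levels=int(b["levels"]),
                kind=b.get("kind", FIXED),
                scope=b.get("scope", BETWEEN),
                nested_in=tuple(b.get("nested_in", ())),
            )
            for b in cfg["factors"]
        ]
        group_sizes = cfg.get("group_sizes")
        subj = cfg.get("subject")
        if subj is not None:
            nested = tuple(subj.get("nested_in", ()))
            n_per_group = subj.get("n")
            if n_per_group is None:
                if not group_sizes:
                    raise ValueError("subject block needs 'n' or group_sizes")
                n_per_group = max(group_sizes)
            factors.append(
                FactorSpec(
                    name=subj.get("name", "Subject"),
                    n_levels=int(n_per_group),
                    kind=RANDOM,
                    scope=UNIT,
                    nested_in=nested,
                )
            )
        covs = tuple(
            CovariateSpec(
                name=b["name"],
                varies_over=tuple(b.get("varies_over", ())),
                centering=b.get("centering", "grand_mean"),
            )
            for b in cfg.get("covariates", ())
        )
        return cls(
            factors=tuple(factors),
            replicates_per_cell=int(cfg.get("replicates_per_cell", 1)),
            group_sizes=tuple(group_sizes) if group_sizes else None,
            covariates=covs,
        )

    @classmethod
    def from_yaml(cls, path) -> "DesignSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ModelTerm:
    """A term of the ANOVA model, identified by its subscripts.

    ``factors`` are the live subscripts, ``nested`` the bracketed nesting
    subscripts (e.g. the subject term S_l(k) has ``factors=("Subject",)``
    and ``nested=("Drink",)``).  ``kind`` is ``"fixed"``, ``"random"`` or
    ``"residual"``.
    """

    factors: tuple
    nested: tuple = ()
    kind: str = FIXED

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "nested", tuple(self.nested))

    @property
    def subscripts(self) -> frozenset:
        return frozenset(self.factors) | frozenset(self.nested)

    @property
    def is_error(self) -> bool:
        return self.kind == "residual"

    @property
    def is_random(self) -> bool:
        return self.kind in ("random", "residual")

    def contains(self, other: "ModelTerm") -> bool:
        return other.subscripts <= self.subscripts

    @property
    def label(self) -> str:
        if self.kind == "residual":
            return "Error"
        if self.nested:
            head = f"{self.factors[0]}({', '.join(self.nested)})"
            rest = self.factors[1:]
            return " × ".join((head,) + rest)
        return " × ".join(self.factors)

    @property
    def component_name(self) -> str:
        """Identifier of the variance component / quadratic form symbol."""
        if self.kind == "residual":
            return "sigma2"
        stem = "_".join(self.factors)
        if self.kind == "random":
            return f"sigma2_{stem}"
        return f"Q_{stem}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label
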