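import numpy as np
import pytest
import sympy

from partglm import DesignSpec, FactorSpec


def make_mixed_3way(n1=14, n2=16, symbolic=False):
    """Two within factors (2 and 3 levels), one between factor (2 levels),
    subjects nested in the between factor -- the taste-study layout."""
    if symbolic:
        a, b, c, n = sympy.symbols("a b c n", positive=True)
        return DesignSpec(factors=(
            FactorSpec("A", a, scope="within"),
            FactorSpec("B", b, scope="within"),
            FactorSpec("C", c, scope="between"),
            FactorSpec("S", n, kind="random", scope="unit", nested_in=("C",)),
        ))
    return DesignSpec(factors=(
        FactorSpec("Location", 2, scope="within"),
        FactorSpec("Texture", 3, scope="within"),
        FactorSpec("Drink", 2, scope="between"),
        FactorSpec("Subject", max(n1, n2), kind="random", scope="unit",
                   nested_in=("Drink",)),
    ), group_sizes=(n1, n2))


def make_mixed_2way(a=2, b=2, n=2, symbolic=False):
    """One within factor crossed with one between factor."""
    if symbolic:
        sa, sb, sn = sympy.symbols("a b n", positive=True)
        a, b, n = sa, sb, sn
    return DesignSpec(factors=(
        FactorSpec("A", a, scope="within"),
        FactorSpec("B", b, scope="between"),
        FactorSpec("S", n, kind="random", scope="unit", nested_in=("B",)),
    ))


def make_between_2way(a=2, b=2, n=2, symbolic=False):
    if symbolic:
        a, b, n = sympy.symbols("a b n", positive=True)
    return DesignSpec(factors=(
        FactorSpec("A", a),
        FactorSpec("B", b),
    ), replicates_per_cell=n)


def make_pure_within(a=2, b=3, n=8):
    """Single group, two within factors."""
    return DesignSpec(factors=(
        FactorSpec("A", a, scope="within"),
        FactorSpec("B", b, scope="within"),
        FactorSpec("Subject", n, kind="random", scope="unit"),
    ))


@pytest.fixture
def mixed_2x2():
    return make_mixed_2way()


@pytest.fixture
def taste_design():
    return make_mixed_3way()


@pytest.fixture
def taste_design_balanced():
    return make_mixed_3way(4, 4)
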