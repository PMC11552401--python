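import numpy as np
import pytest

import fusionaudit as fa
from fusionaudit import Fixed, Free, SemModelSpec


@pytest.fixture(scope="session")
def compact():
    return fa.compact_scenario()


@pytest.fixture(scope="session")
def compact_sigma(compact):
    return fa.population_sigma(compact)


@pytest.fixture(scope="session")
def care_aide():
    return fa.care_aide_scenario()


@pytest.fixture(scope="session")
def care_aide_sigma(care_aide):
    return fa.population_sigma(care_aide)


def one_factor_spec():
    """Single factor, four indicators (first loading fixed for scale)."""
    return SemModelSpec(
        observed_names=("y1", "y2", "y3", "y4"),
        latent_names=("L", "e1", "e2", "e3", "e4"),
        loadings=tuple((f"y{i}", "L", Fixed(1.0) if i == 1 else Free(f"l{i}", 1.0))
                       for i in (1, 2, 3, 4))
        + tuple((f"y{i}", f"e{i}", Fixed(1.0)) for i in (1, 2, 3, 4)),
        psi=(("L", "L", Free("phi", 1.0)),)
        + tuple((f"e{i}", f"e{i}", Free(f"t{i}", 0.5)) for i in (1, 2, 3, 4)),
    )


ONE_FACTOR_TRUTH = {"l2": 0.8, "l3": 1.2, "l4": 0.9, "phi": 1.0,
                    "t1": 0.5, "t2": 0.6, "t3": 0.4, "t4": 0.7}


def saturated_spec(names):
    """All observed moments free: fits any PD matrix exactly."""
    lat = tuple(f"ts_{n}" for n in names)
    psi = []
    for i, a in enumerate(names):
        psi.append((f"ts_{a}", f"ts_{a}", Free(f"v_{a}", 1.0)))
        for b in names[i + 1:]:
            psi.append((f"ts_{a}", f"ts_{b}", Free(f"c_{a}_{b}")))
    return SemModelSpec(
        observed_names=tuple(names), latent_names=lat,
        loadings=tuple((n, f"ts_{n}", Fixed(1.0)) for n in names),
        psi=tuple(psi))


def path_toy_spec():
    """Recursive path model: x1, x2 exogenous; y1 <- x1, x2; y2 <- x1, x2, y1.

    Saturated structure (every earlier variable may affect every later one),
    no measurement error, so ML coefficients must equal per-equation OLS.
    """
    names = ("x1", "x2", "y1", "y2")
    lat = tuple(f"ts_{n}" for n in names)
    return SemModelSpec(
        observed_names=names, latent_names=lat,
        loadings=tuple((n, f"ts_{n}", Fixed(1.0)) for n in names),
        paths=(("ts_x1", "ts_y1", Free("b11")), ("ts_x2", "ts_y1", Free("b21")),
               ("ts_x1", "ts_y2", Free("b12")), ("ts_x2", "ts_y2", Free("b22")),
               ("ts_y1", "ts_y2", Free("byy"))),
        psi=(("ts_x1", "ts_x1", Free("v1", 1.0)), ("ts_x2", "ts_x2", Free("v2", 1.0)),
             ("ts_x1", "ts_x2", Free("c12")),
             ("ts_y1", "ts_y1", Free("d1", 1.0)), ("ts_y2", "ts_y2", Free("d2", 1.0))),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250919)
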