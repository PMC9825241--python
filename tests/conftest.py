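import numpy as np
import pandas as pd
import pytest

from vasca import DesignTable, ModelTerms, build_coding, fit_glm, full_factorial


@pytest.fixture
def eq3_design() -> DesignTable:
    """Three temperatures x two pH levels, two replicates per condition."""
    temps = [10, 10, 20, 20, 30, 30] * 2
    ph = [4.0] * 6 + [6.0] * 6
    return DesignTable.from_frame(pd.DataFrame({"temp": temps, "pH": ph}))


@pytest.fixture
def eq3_coding(eq3_design):
    terms = ModelTerms.from_string("temp + pH + temp:pH")
    return build_coding(eq3_design, terms)


@pytest.fixture
def four_obs():
    """One 2-level factor, X = [1,3,5,7]: cell means 2 and 6, grand mean 4."""
    design = DesignTable.from_frame(pd.DataFrame({"g": [1, 1, 2, 2]}))
    coding = build_coding(design, ModelTerms(("g",)))
    X = np.array([[1.0], [3.0], [5.0], [7.0]])
    return X, design, coding


def random_balanced_problem(rng, levels=(3, 2), replicates=2, n_vars=3,
                            interaction=False):
    design = full_factorial(levels, replicates, names=["A", "B"][: len(levels)])
    terms = ModelTerms(
        tuple(design.factors),
        (("A", "B"),) if interaction and len(levels) == 2 else (),
    )
    coding = build_coding(design, terms)
    X = rng.standard_normal((design.n_obs, n_vars))
    return X, design, coding


@pytest.fixture
def balanced_decomp():
    rng = np.random.default_rng(42)
    X, design, coding = random_balanced_problem(rng, n_vars=8)
    return X, coding, fit_glm(X - X.mean(axis=0), coding)
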