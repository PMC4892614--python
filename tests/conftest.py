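import numpy as np
import pytest

from fuzzystage.fis import GaussianMF, Rule, SugenoFIS
from fuzzystage.preprocessing import normalize_cohort
from fuzzystage.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded synthetic study cohort (n=399)."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def default_grouped(default_cohort):
    return normalize_cohort(default_cohort)


def make_1d_fis(c1, w1, c2, w2, f1=1.0, f2=2.0):
    """A 1-input, 2-rule Sugeno system with constant consequents."""
    return SugenoFIS(
        input_names=("x",), input_ranges={"x": (0.0, 10.0)},
        rules=[Rule([GaussianMF(c1, w1)], np.array([f1, 0.0]), "OCD"),
               Rule([GaussianMF(c2, w2)], np.array([f2, 0.0]), "ED")])


def make_5d_fis():
    """A known 2-rule system on the five grouped clinical inputs."""
    def rule(centers, widths, coef, tag):
        return Rule([GaussianMF(c, w) for c, w in zip(centers, widths)],
                    np.array(coef), tag)
    return SugenoFIS(rules=[
        rule([3.2, 3.4, 2.5, 7.0, 1.5], [0.6, 0.6, 1.2, 1.6, 1.0],
             [1.0, 0.02, 0.01, 0.0, 0.0, 0.03], "OCD"),
        rule([3.9, 4.1, 4.5, 9.5, 3.5], [0.6, 0.7, 1.3, 1.5, 1.3],
             [1.6, 0.05, 0.04, 0.0, 0.0, 0.05], "ED")])
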