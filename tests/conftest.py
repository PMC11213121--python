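import numpy as np
import pytest

from ulv.io import ClusteredExpression
from ulv.simulate import FeatureSubjectParams, SimDesign, simulate_counts


@pytest.fixture(scope="session")
def small_study():
    """A small two-group ZINB study: 40 features, 10+10 subjects, 60 cells
    each; the first 10 features carry a two-fold case increase."""
    rng = np.random.default_rng(11)
    F, S = 40, 20
    params = FeatureSubjectParams(
        mu=rng.uniform(2.0, 10.0, (F, S)),
        phi=rng.uniform(0.5, 1.5, (F, S)),
        z=rng.uniform(0.0, 0.4, (F, S)),
        sigma=rng.uniform(0.0, 1.0, (F, S)),
    )
    design = SimDesign(
        n_case=10,
        n_control=10,
        cells_per_subject=60,
        n_features=F,
        r=2.0,
        de_fraction=0.25,
        seed=11,
    )
    sim = simulate_counts(params, design)
    return sim


@pytest.fixture(scope="session")
def small_expression(small_study) -> ClusteredExpression:
    return small_study.to_clustered_expression()
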