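import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20180927)


def random_composition(rng, s):
    from gradcoda.simplex import Composition

    return Composition(np.exp(rng.normal(0.0, 1.5, s)))


@pytest.fixture
def random_compositions():
    """Factory: n random s-part compositions from a log-normal cloud."""

    def make(n, s, seed=0):
        r = np.random.default_rng(seed)
        return [random_composition(r, s) for _ in range(n)]

    return make


@pytest.fixture(scope="session")
def dock_fit():
    """One reduced-settings fit of the dock-like synthetic data, shared by
    the model and summary tests (the sampler is the slow part)."""
    from gradcoda.model import ModelSpec, SamplerSpec, fit
    from gradcoda.synthetic import default_dock_like_spec, generate

    spec = default_dock_like_spec(seed=11)
    table, truth = generate(spec)
    mspec = ModelSpec(
        degree=2, sampler=SamplerSpec(chains=2, warmup=500, draws=400, seed=5)
    )
    draws = fit(table, mspec, on_bad_fit="warn")
    return {"spec": spec, "table": table, "truth": truth, "draws": draws}


@pytest.fixture(scope="session")
def dock_curves(dock_fit):
    from gradcoda.model import predict_expected_curve

    return predict_expected_curve(dock_fit["draws"])
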