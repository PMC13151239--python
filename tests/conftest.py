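import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cv():
    """One small end-to-end cross-validation run shared across tests.

    30 diseases x 30 miRNAs, 3 blocks, short training -- enough to produce
    real FoldResults, layer states and a trained scorer quickly.
    """
    from mirmoment.model import ModelConfig
    from mirmoment.synthetic import SyntheticSpec, generate, holdout_eval, synthetic_embed_config

    spec = SyntheticSpec(n_diseases=30, n_mirnas=30, n_blocks=3, seed=7)
    cfg = ModelConfig(lr=1e-3, epochs=12, patience=12, seed=1234, hidden_dim=32)
    result = holdout_eval(spec, cfg, embed=synthetic_embed_config())
    return {"spec": spec, "cfg": cfg, "result": result, "data": generate(spec)}


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_normalized_graph(rng, n, p=0.4):
    """Symmetric 0/1 graph with D^{-1/2} A D^{-1/2} normalization."""
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    deg = a.sum(1)
    inv = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-12)), 0.0)
    return a, a * inv[:, None] * inv[None, :]
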