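import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from priddg import (
    ModelConfig,
    MutationDataset,
    MutationRecord,
    SyntheticSpec,
    WindowConfig,
    generate_synthetic_study,
    reverse_augment,
)
from priddg.features import build_features

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_config():
    """Narrow network for fast unit tests (same architecture, small dims)."""
    return ModelConfig(
        d_model=16, num_heads=4, encoder_out_dim=8, ffn_dim=32,
        conv_map_dim=16, conv_channels=(2, 3, 4), conv_out_dim=12,
        head_widths=(8, 4, 1), dropout_rate=0.1, l2_reg=0.0, lr=1e-3,
        esm_dim=12, pt_dim=10, window_len=21,
    )


@pytest.fixture
def toy_dataset():
    """Three hand-written forward records on two synthetic chains."""
    seq_a = "MKT" + "A" * 20 + "Q" + "G" * 26  # Q at position 24
    seq_b = "GG" + "W" * 10 + "K" + "L" * 30  # K at position 13
    records = [
        MutationRecord("1XYZ", "A", "Q", 24, "E", 1.5),
        MutationRecord("1XYZ", "A", "A", 5, "G", -0.4),
        MutationRecord("2ABC", "B", "K", 13, "A", 0.0),
    ]
    return MutationDataset(records, {"1XYZ_A": seq_a, "2ABC_B": seq_b})


@pytest.fixture(scope="session")
def small_study():
    """Compact planted-signal study shared across tests."""
    spec = SyntheticSpec(n_complexes=8, n_forward_mutations=40,
                         seq_len_range=(60, 120), esm_dim=12, pt_dim=10, seed=3)
    return generate_synthetic_study(spec)


@pytest.fixture(scope="session")
def small_features(small_study):
    ds = reverse_augment(small_study.dataset)
    return build_features(ds, small_study.esm_provider, small_study.pt_provider,
                          WindowConfig(flank=10))


@pytest.fixture(scope="session")
def small_features_config():
    return ModelConfig.desk_scale(esm_dim=12, pt_dim=10, window_len=21)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar-valued f with respect to x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        v = x[i]
        x[i] = v + eps
        fp = f()
        x[i] = v - eps
        fm = f()
        x[i] = v
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
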