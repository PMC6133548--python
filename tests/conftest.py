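import numpy as np
import pytest

from fasciq import BundleSpec, generate_bundle_traces


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced phantom (shorter bundle, fewer bins) that renders quickly."""
    return BundleSpec(
        n_positions=120, n_bins=60, length_um=30.0,
        order_model="fixed", middle_label="AFD", snr=10.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return generate_bundle_traces(small_spec)


def random_smooth_triplet(seed: int, n: int = 80):
    """Three gently winding, mutually offset polylines for geometry tests."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n)
    center = np.column_stack([
        t * 30.0,
        2 + np.sin(2 * np.pi * t * rng.uniform(0.5, 1.5) + rng.uniform(0, 6)),
        2 + np.cos(2 * np.pi * t * rng.uniform(0.5, 1.5) + rng.uniform(0, 6)),
    ])
    offsets = rng.normal(0, 0.6, size=(3, 3))
    offsets[:, 0] = 0.0
    from fasciq.tracing import DendriteTrace

    return tuple(
        DendriteTrace(points=center + off, label=lab)
        for off, lab in zip(offsets, ("AWA", "AFD", "ASE"))
    )
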