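import numpy as np
import pytest

from frbain.clustering import KernelBank
from frbain.network import build_model
from frbain.signal import Signal, SignalDataset
from frbain.synthetic import GeneratorSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_generated():
    """A small well-separated 2-class dataset with known truth."""
    spec = GeneratorSpec(K=2, subclasses_per_class=(2, 1), n_total=36,
                         base_length=32, n_channels=2, seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def toy_bank():
    """A tiny hand-built kernel bank: 2 classes x 2 centers, 1 channel."""
    t = np.linspace(0, 1, 16)
    centers = [
        Signal(np.sin(2 * np.pi * t)[None, :], record_id="a1", label="A"),
        Signal(np.sin(4 * np.pi * t)[None, :], record_id="a2", label="A"),
        Signal((t * 4)[None, :], record_id="b1", label="B"),
        Signal((4 - 4 * t)[None, :], record_id="b2", label="B"),
    ]
    return KernelBank(centers=centers, class_index=np.array([0, 0, 1, 1]),
                      subclass_index=np.array([0, 1, 0, 1]),
                      class_order=["A", "B"])


@pytest.fixture(scope="session")
def toy_model(toy_bank):
    return build_model(toy_bank, seed=3)


def make_dataset(values_list, labels, n_channels=1):
    sigs = []
    for i, (v, lab) in enumerate(zip(values_list, labels)):
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 1:
            arr = np.tile(arr, (n_channels, 1))
        sigs.append(Signal(arr, record_id=f"s{i}", label=lab))
    return SignalDataset(sigs)
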