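import numpy as np
import pytest

from cortexflow import Connectome, SynthConfig, censor, compute_distances, generate


@pytest.fixture
def toy_connectome():
    """4 areas, handmade weights and coordinates; B and C are measured."""
    labels = ["A", "B", "C", "D"]
    W = np.zeros((4, 4))
    W[0, 1] = 2.0  # A -> B
    W[0, 2] = 0.5  # A -> C
    W[1, 2] = 1.0  # B -> C
    W[3, 1] = 4.0  # D -> B
    coords = np.array(
        [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0], [0.0, 0.0, 2.0], [1.0, 1.0, 1.0]]
    )
    c = Connectome(
        labels=labels,
        W=W,
        weight_kind="LNe",
        measured=np.array([False, True, True, False]),
        coords=coords,
    )
    return compute_distances(c)


@pytest.fixture
def synth_small():
    """A small censored synthetic connectome with ground truth."""
    cfg = SynthConfig(n_nodes=30, n_measured=14, n_modules=3, seed=42)
    c, gt = generate(cfg)
    return censor(c, gt.measured_set), gt


def set_partitions(n):
    """Enumerate all set partitions of range(n) as assignment lists
    (restricted-growth strings); independent oracle for the codelength
    optimiser."""
    if n <= 1:
        yield [0] * n
        return
    a = [0] * n

    def rec(i, k):
        if i == n:
            yield list(a)
            return
        for m in range(k + 1):
            a[i] = m
            yield from rec(i + 1, max(k, m + 1))

    yield from rec(1, 1)


def random_connectome(rng, n=12, density=0.4, measured_frac=0.6):
    """Helper: random LNe connectome with coordinates and distances."""
    W = (rng.uniform(size=(n, n)) < density) * rng.lognormal(1.0, 1.0, (n, n))
    np.fill_diagonal(W, 0.0)
    n_meas = max(1, int(round(measured_frac * n)))
    measured = np.zeros(n, dtype=bool)
    measured[rng.choice(n, n_meas, replace=False)] = True
    W[:, ~measured] = 0.0
    c = Connectome(
        labels=[f"n{i:02d}" for i in range(n)],
        W=W,
        weight_kind="LNe",
        measured=measured,
        coords=rng.uniform(0, 10, size=(n, 3)),
    )
    return compute_distances(c)
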