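import numpy as np
import pandas as pd
import pytest

from pbcrt import PBCRTData


def make_data(clusters):
    """Build a PBCRTData from {cluster: (sequence, baseline list, follow-up list)}."""
    rows = []
    for cl, (seq, base, fol) in clusters.items():
        for y in base:
            rows.append((cl, 0, seq, float(y)))
        for y in fol:
            rows.append((cl, 1, seq, float(y)))
    return PBCRTData(pd.DataFrame(rows, columns=["cluster", "period", "sequence", "y"]))


@pytest.fixture
def toy_c():
    """Two treated clusters with baseline 0 and follow-up diffs 2 (K=1) and 6 (K=3);
    two control clusters identically zero."""
    return make_data({
        1: (1, [0], [2]),
        2: (1, [0, 0, 0], [6, 6, 6]),
        3: (0, [0], [0]),
        4: (0, [0, 0, 0], [0, 0, 0]),
    })


@pytest.fixture
def random_trial():
    """A small random trial with equal within-cluster cell sizes."""
    rng = np.random.default_rng(7)
    clusters = {}
    for cl in range(8):
        K = int(rng.integers(1, 6))
        seq = cl % 2
        base = rng.normal(1.0, 1.0, size=K)
        fol = rng.normal(1.2 + 0.35 * seq, 1.0, size=K)
        clusters[cl] = (seq, base, fol)
    return make_data(clusters)


@pytest.fixture
def random_trial_unequal():
    """Random trial where cluster-period sizes differ between periods."""
    rng = np.random.default_rng(11)
    clusters = {}
    for cl in range(8):
        k0, k1 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        seq = cl % 2
        clusters[cl] = (seq, rng.normal(size=k0), rng.normal(0.4 * seq, 1, size=k1))
    return make_data(clusters)
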