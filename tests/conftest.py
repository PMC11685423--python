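import numpy as np
import pytest

from regcode.enhancer_classification import classify_enhancers
from regcode.synthetic_data import SyntheticConfig, generate_dataset

SMALL_CLASS_COUNTS = {
    "K4me1+:bidirectional": 10,
    "K4me1+:unidirectional": 10,
    "K4me1+:none": 10,
    "K4me1-:bidirectional": 10,
    "K4me1-:unidirectional": 10,
    "K4me1-:none": 10,
}


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle: 600 distal peaks, 100 per class, seed 1."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def records(bundle):
    return classify_enhancers(bundle.k27ac_distal, bundle.k4me1, bundle.rna)


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced bundle for fast unit tests."""
    cfg = SyntheticConfig(
        seed=7,
        class_counts=dict(SMALL_CLASS_COUNTS),
        n_extra_gene_slots=30,
        n_tes=20,
        n_loops=20,
        n_local_peaks=15,
        n_srna_clusters=10,
        n_hairpin_clusters=3,
        n_ref_degs=100,
        deg_counts={"pollen": (8, 5), "ear": (3, 2), "CN": (0, 4)},
        n_distractor_genes=10,
        n_target_extra_degs=30,
        srna_totals={21: 3000, 22: 9000, 24: 18000},
    )
    return generate_dataset(cfg)


def dense_integral(arr: np.ndarray, x: float, y: float) -> float:
    """Brute-force integral of a per-bp step function over [x, y)."""
    x = max(0.0, x)
    y = min(float(len(arr)), y)
    if y <= x:
        return 0.0
    cums = np.concatenate([[0.0], np.cumsum(arr)])

    def at(t):
        i = int(np.floor(t))
        return cums[i] + (t - i) * (arr[i] if i < len(arr) else 0.0)

    return at(y) - at(x)
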