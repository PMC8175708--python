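import numpy as np
import pytest

from kronbind.io import InteractionTable, PredictionSet
from kronbind.kernels import KernelMatrix
from kronbind.synthetic import SyntheticSpec, generate


def random_pd_kernel(n: int, seed: int, ids=None) -> KernelMatrix:
    """Random strictly positive definite kernel with unit diagonal."""
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(n, n))
    K = B @ B.T + n * np.eye(n)
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)
    if ids is None:
        ids = tuple(f"e{i}" for i in range(n))
    return KernelMatrix(tuple(ids), K)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic benchmark (shared, read-only)."""
    return generate(
        SyntheticSpec(
            n_compounds=12,
            n_proteins=8,
            n_compound_clusters=3,
            n_protein_families=3,
            fp_bits=128,
            seq_length=80,
            bilinear_rank=3,
            noise_sd=0.2,
            frac_observed=0.5,
            seed=11,
        )
    )


@pytest.fixture()
def toy_measured():
    rng = np.random.default_rng(42)
    pairs = [(f"C{i:02d}", f"P{i % 5}") for i in range(40)]
    truth = rng.uniform(4.0, 10.0, size=len(pairs))
    return InteractionTable.from_rows(
        [(c, p, float(t)) for (c, p), t in zip(pairs, truth)]
    )


def noisy_prediction(measured: InteractionTable, sd: float, seed: int, model_id="m"):
    rng = np.random.default_rng(seed)
    return PredictionSet(
        model_id,
        {
            (c, p): float(v + rng.normal(0.0, sd))
            for c, p, v in measured.frame.itertuples(index=False)
        },
    )
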