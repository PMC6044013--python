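import numpy as np
import pytest

from combatkit import ExpressionMatrix, StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values, gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{gene_prefix}{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
    )


def two_batch_design(n1, n2, covariates=None, reference=None):
    return StudyDesign(
        np.array(["A"] * n1 + ["B"] * n2),
        covariates=covariates,
        reference_batch=reference,
    )


@pytest.fixture
def random_study(rng):
    """60 genes x 24 samples, two batches with mild mean/variance effects."""
    n_genes, n1, n2 = 60, 10, 14
    base = rng.normal(5.0, 1.0, (n_genes, n1 + n2))
    base[:, n1:] += rng.normal(0.8, 0.3, (n_genes, 1))   # per-gene additive shift
    base[:, n1:] *= 1.2
    Y = make_matrix(base)
    design = two_batch_design(n1, n2)
    return Y, design
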