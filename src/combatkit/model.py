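"""Location-scale model core: data containers, design matrices, standardization.

The model for log-scale expression of gene ``g`` in sample ``j`` of batch
``i`` is

    Y_ijg = alpha_g + X_ij beta_g + gamma_ig + delta_ig * eps_ijg

with ``eps_ijg ~ N(0, sigma_g^2)``.  ``alpha_g`` is the overall expression
level of the gene, ``X`` a design matrix of biological covariates,
``gamma_ig`` the additive and ``delta_ig`` the multiplicative batch effect.
This module fits the per-gene regression by ordinary least squares and
produces the standardized residual matrix

    Z_ijg = (Y_ijg - alpha_hat_g - X_ij beta_hat_g) / sigma_hat_g

which still carries the batch effects (they are deliberately *not* part of
the subtracted mean) and on which all downstream estimation and diagnostics
operate.

Two standardization modes exist:

* ``pooled`` — alpha_hat is the sample-size-weighted average of the fitted
  batch means and sigma_hat^2 the mean squared residual over all samples.
* ``reference`` — alpha_hat and sigma_hat come from a designated reference
  batch only (beta_hat is still taken from the joint fit so covariate
  effects remain estimable when a condition is absent from the reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfoundedDesignError,
    DimensionError,
    SingletonBatchError,
    ZeroVarianceGeneError,
)

logger = logging.getLogger(__name__)

#: genes with sigma_hat below RTOL * (max|Y| + 1) are rejected
ZERO_VARIANCE_RTOL = 1e-8


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A gene-by-sample matrix of continuous (log-scale) expression values.

    Genes are rows, samples are columns.  Values must be finite; ids must be
    unique.  Use :meth:`from_dataframe` / :meth:`to_dataframe` to move in and
    out of pandas.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise DimensionError("expression values must be a 2-D gene x sample array")
        n_g, n_s = self.values.shape
        if n_g != len(self.gene_ids) or n_s != len(self.sample_ids):
            raise DimensionError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        if n_g < 2 or n_s < 2:
            raise DimensionError("need at least 2 genes and 2 samples")
        if len(set(self.gene_ids)) != n_g:
            raise DimensionError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_s:
            raise DimensionError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            g, s = bad[0]
            raise DimensionError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r} ({len(bad)} total)"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return ExpressionMatrix(self.values[:, mask].copy(), list(self.gene_ids), ids)


@dataclass
class StudyDesign:
    """Per-sample batch labels plus an optional biological covariate matrix.

    ``covariates`` is numeric, one row per sample (use
    :func:`expand_categorical` to treatment-code categorical covariates).
    ``reference_batch``, if set, must be one of the batch levels.
    """

    batch: np.ndarray
    covariates: Optional[np.ndarray] = None
    covariate_names: Optional[list[str]] = None
    reference_batch: Optional[str] = None

    def __post_init__(self) -> None:
        self.batch = np.asarray([str(b) for b in np.asarray(self.batch).ravel()], dtype=object)
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.n_samples:
                if self.covariates.shape[1] == self.n_samples:
                    self.covariates = self.covariates.T
                else:
                    raise DimensionError(
                        f"covariate rows ({self.covariates.shape[0]}) != "
                        f"number of samples ({self.n_samples})"
                    )
            if self.covariate_names is None:
                self.covariate_names = [f"covariate_{i}" for i in range(self.covariates.shape[1])]
        if self.reference_batch is not None:
            self.reference_batch = str(self.reference_batch)
            if self.reference_batch not in self.batch_levels:
                raise DimensionError(
                    f"reference batch {self.reference_batch!r} is not a batch level "
                    f"(levels: {self.batch_levels})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.batch)

    @property
    def batch_levels(self) -> list[str]:
        # order of first appearance, stable across permutation-free operations
        seen: dict[str, None] = {}
        for b in self.batch:
            seen.setdefault(b, None)
        return list(seen)

    @property
    def n_batches(self) -> int:
        return len(self.batch_levels)

    @property
    def batch_sizes(self) -> np.ndarray:
        return np.array([int(np.sum(self.batch == b)) for b in self.batch_levels])

    def batch_mask(self, level: str) -> np.ndarray:
        return self.batch == str(level)

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    def require_min_batch_size(self, n_min: int) -> None:
        small = [b for b, n in zip(self.batch_levels, self.batch_sizes) if n < n_min]
        if small:
            raise SingletonBatchError(
                f"batch(es) {small} have fewer than {n_min} samples; "
                "variance-adjusting modes require n_i >= 2 per batch "
                "(use mean_only for singleton batches)"
            )

    def permuted(self, order: Sequence[int]) -> "StudyDesign":
        order = np.asarray(order)
        return StudyDesign(
            self.batch[order],
            None if self.covariates is None else self.covariates[order],
            self.covariate_names,
            self.reference_batch,
        )


@dataclass
class StandardizedFit:
    """Per-gene least-squares estimates and the standardized matrix Z.

    ``alpha`` and ``sigma`` are per-gene; ``beta`` is (n_genes, n_covariates).
    In ``reference`` mode alpha and sigma are estimated from the reference
    batch only.  ``batch_means`` keeps the fitted per-batch gene means from
    the joint fit (used for adjustment and inspection).
    """

    alpha: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    Z: np.ndarray
    mode: str
    gene_ids: list[str]
    sample_ids: list[str]
    batch_means: np.ndarray = field(repr=False, default=None)  # (n_batches, n_genes)

    @property
    def n_genes(self) -> int:
        return self.Z.shape[0]

    @property
    def n_samples(self) -> int:
        return self.Z.shape[1]

    def stand_mean(self, design: StudyDesign) -> np.ndarray:
        """The subtracted mean surface alpha_g + X_ij beta_g, genes x samples."""
        mean = np.repeat(self.alpha[:, None], self.n_samples, axis=1)
        if design.covariates is not None and self.beta.size:
            mean = mean + self.beta @ design.covariates.T
        return mean


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def expand_categorical(values: Sequence, name: str = "covariate") -> tuple[np.ndarray, list[str]]:
    """Treatment-code a categorical covariate, dropping the first level.

    Returns an (n_samples, n_levels - 1) indicator matrix and column names.
    """
    values = [str(v) for v in values]
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    levels = list(seen)
    cols = levels[1:]
    mat = np.column_stack([[1.0 if v == lev else 0.0 for v in values] for lev in cols]) \
        if cols else np.empty((len(values), 0))
    return mat, [f"{name}[{lev}]" for lev in cols]


def build_design(design: StudyDesign, n_samples: int) -> np.ndarray:
    """Batch-indicator columns followed by covariate columns, full rank.

    One indicator per batch (cell-means coding, no global intercept), so the
    fitted coefficients of the first block are the per-batch gene means.
    Raises :class:`ConfoundedDesignError` when covariates are linearly
    dependent with batch membership and :class:`DimensionError` on row-count
    mismatch.
    """
    if design.n_samples != n_samples:
        raise DimensionError(
            f"design has {design.n_samples} samples, expression has {n_samples}"
        )
    levels = design.batch_levels
    X = np.column_stack([design.batch_mask(b).astype(float) for b in levels])
    if design.covariates is not None and design.covariates.shape[1]:
        X = np.column_stack([X, design.covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ConfoundedDesignError(
            "design matrix is rank deficient: batch is confounded with the "
            f"covariates (rank {rank} < {X.shape[1]} columns)"
        )
    return X


# ---------------------------------------------------------------------------
# fitting / standardization
# ---------------------------------------------------------------------------

def fit_location_scale(
    Y: ExpressionMatrix,
    design: StudyDesign,
    mode: str = "pooled",
) -> StandardizedFit:
    """Per-gene OLS fit of the location-scale model and standardization.

    Parameters
    ----------
    Y
        Expression matrix (genes x samples).
    design
        Batch labels and covariates, aligned with ``Y.sample_ids``.
    mode
        ``"pooled"``: alpha_hat_g is the n_i/N-weighted average of the fitted
        batch means and sigma_hat_g^2 the mean squared residual over all N
        samples (denominator N — the target is unit-variance standardized
        data, not an unbiased variance estimate).
        ``"reference"``: alpha_hat_g is the reference-batch mean and
        sigma_hat_g^2 the mean squared residual over reference-batch samples
        only; requires ``design.reference_batch``.

    Raises
    ------
    ZeroVarianceGeneError
        If any gene's residual scale falls below
        ``ZERO_VARIANCE_RTOL * (max|Y| + 1)``.
    """
    if mode not in ("pooled", "reference"):
        raise ValueError(f"unknown standardization mode {mode!r}")
    if mode == "reference" and design.reference_batch is None:
        raise DimensionError("reference mode requires design.reference_batch")

    X = build_design(design, Y.n_samples)
    k = design.n_batches
    # OLS for all genes at once: coefs is (k + p, n_genes)
    coefs, *_ = np.linalg.lstsq(X, Y.values.T, rcond=None)
    batch_means = coefs[:k]                      # (k, n_genes)
    beta = coefs[k:].T                           # (n_genes, p)

    fitted = (X @ coefs).T                       # (n_genes, n_samples)
    resid = Y.values - fitted

    if mode == "pooled":
        weights = design.batch_sizes / design.n_samples
        alpha = weights @ batch_means
        sigma2 = np.mean(resid**2, axis=1)
    else:
        ref_idx = design.batch_levels.index(design.reference_batch)
        ref_mask = design.batch_mask(design.reference_batch)
        alpha = batch_means[ref_idx]
        sigma2 = np.mean(resid[:, ref_mask] ** 2, axis=1)

    sigma = np.sqrt(sigma2)
    tol = ZERO_VARIANCE_RTOL * (np.max(np.abs(Y.values)) + 1.0)
    flat = sigma < tol
    if np.any(flat):
        raise ZeroVarianceGeneError([g for g, f in zip(Y.gene_ids, flat) if f])

    stand_mean = np.repeat(alpha[:, None], Y.n_samples, axis=1)
    if design.covariates is not None and beta.size:
        stand_mean = stand_mean + beta @ design.covariates.T
    Z = (Y.values - stand_mean) / sigma[:, None]

    return StandardizedFit(
        alpha=alpha,
        beta=beta,
        sigma=sigma,
        Z=Z,
        mode=mode,
        gene_ids=list(Y.gene_ids),
        sample_ids=list(Y.sample_ids),
        batch_means=batch_means,
    )
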