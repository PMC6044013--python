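"""Synthetic studies and evaluation harnesses.

Two generators are provided, each emulating a canonical two-batch scenario:

* :func:`simulate_pathway_study` — a pathway-signature profiling study.
  Batch 1 is a small, clean perturbation experiment (200 genes x 6 samples:
  three replicates before and three after pathway activation; the first 100
  genes are signature genes that move from N(0, 0.1) to N(1, 0.1), the rest
  stay at N(0, 0.1)).  Batch 2 is a large, noisy patient-like cohort (200 x
  600: six equal subgroups with graded activation; signature genes
  N(mu, 10) with mu in {0.5, 0.7, ..., 1.5}, controls N(0.5, 10)).  The
  Gaussian scale parameter is read as a STANDARD DEVIATION by default
  (the convention of R's ``rnorm``, under which the study's qualitative
  contract holds — see docs/methods.md); ``scale_param_is_variance=True``
  flips to the variance reading.  Signature recovery is scored by k-means over gene vectors
  (:func:`kmeans_signature_accuracy`), and
  :func:`run_pathway_benchmark` compares unadjusted, original-mode, and
  reference-mode (reference = batch 1) adjustment.

* :func:`simulate_de_study` — a two-batch, two-condition differential
  expression study with three batch-effect regimes (none, mean-only, mean
  and variance), scored by type-I error and power of a per-gene pooled
  two-sample t-test (:func:`evaluate_type1_power`).

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .adjust import combat
from .errors import DimensionError
from .model import ExpressionMatrix, StudyDesign

logger = logging.getLogger(__name__)

PATHWAY_N_GENES = 200
PATHWAY_N_SIGNATURE = 100
PATHWAY_BATCH1_N = 6
PATHWAY_BATCH2_N = 600
PATHWAY_ACTIVATIONS = (0.5, 0.7, 0.9, 1.1, 1.3, 1.5)


@dataclass
class SimulatedStudy:
    """A generated expression study with ground truth attached."""

    expression: ExpressionMatrix
    design: StudyDesign
    gene_truth: np.ndarray          # 'signature' / 'control' per gene
    sample_groups: np.ndarray       # biological group label per sample
    pathway_activation: np.ndarray  # numeric activation per sample
    seed: int

    @property
    def signature_mask(self) -> np.ndarray:
        return self.gene_truth == "signature"

    def batch_columns(self, batch: str) -> np.ndarray:
        return self.design.batch_mask(batch)


def _scale_to_sd(param: float, scale_param_is_variance: bool) -> float:
    return float(np.sqrt(param)) if scale_param_is_variance else float(param)


def simulate_pathway_study(
    seed: int,
    scale_param_is_variance: bool = False,
) -> SimulatedStudy:
    """Two-batch pathway-signature study (batch 1: 200x6, batch 2: 200x600).

    ``pathway_activation`` is 0/1 (before/after) in batch 1 and the subgroup
    mean mu in batch 2; it is usable as a biological covariate during
    adjustment.  Regeneration with the same seed is bit-identical.
    """
    rng = np.random.default_rng(seed)
    sd_b1 = _scale_to_sd(0.1, scale_param_is_variance)
    sd_b2 = _scale_to_sd(10.0, scale_param_is_variance)
    n_sig = PATHWAY_N_SIGNATURE
    n_ctl = PATHWAY_N_GENES - n_sig

    # batch 1: 3 before + 3 after
    b1 = np.empty((PATHWAY_N_GENES, PATHWAY_BATCH1_N))
    b1[:n_sig, :3] = rng.normal(0.0, sd_b1, (n_sig, 3))
    b1[:n_sig, 3:] = rng.normal(1.0, sd_b1, (n_sig, 3))
    b1[n_sig:, :] = rng.normal(0.0, sd_b1, (n_ctl, PATHWAY_BATCH1_N))

    # batch 2: six equal subgroups with graded activation
    per_group = PATHWAY_BATCH2_N // len(PATHWAY_ACTIVATIONS)
    b2 = np.empty((PATHWAY_N_GENES, PATHWAY_BATCH2_N))
    for g_idx, mu in enumerate(PATHWAY_ACTIVATIONS):
        cols = slice(g_idx * per_group, (g_idx + 1) * per_group)
        b2[:n_sig, cols] = rng.normal(mu, sd_b2, (n_sig, per_group))
    b2[n_sig:, :] = rng.normal(0.5, sd_b2, (n_ctl, PATHWAY_BATCH2_N))

    values = np.hstack([b1, b2])
    gene_ids = [f"gene_{i + 1:03d}" for i in range(PATHWAY_N_GENES)]
    sample_ids = [f"b1_s{j + 1}" for j in range(PATHWAY_BATCH1_N)] + [
        f"b2_s{j + 1:03d}" for j in range(PATHWAY_BATCH2_N)
    ]
    batch = np.array(["batch1"] * PATHWAY_BATCH1_N + ["batch2"] * PATHWAY_BATCH2_N)
    groups = np.array(
        ["before"] * 3
        + ["after"] * 3
        + [f"group{g + 1}" for g in range(len(PATHWAY_ACTIVATIONS)) for _ in range(per_group)]
    )
    activation = np.array(
        [0.0] * 3
        + [1.0] * 3
        + [mu for mu in PATHWAY_ACTIVATIONS for _ in range(per_group)]
    )
    truth = np.array(["signature"] * n_sig + ["control"] * n_ctl, dtype=object)

    expr = ExpressionMatrix(values, gene_ids, sample_ids)
    design = StudyDesign(
        batch,
        covariates=activation[:, None],
        covariate_names=["pathway_activation"],
    )
    return SimulatedStudy(expr, design, truth, groups, activation, int(seed))


def kmeans_signature_accuracy(
    values,
    gene_truth,
    k: int = 2,
    n_restarts: int = 25,
    seed: int = 0,
) -> float:
    """Fraction of genes whose k-means cluster matches their truth label.

    Genes are clustered as points (dimension = number of samples) with
    Euclidean k-means (``n_restarts`` independent initializations, best
    within-cluster sum of squares kept); the accuracy is the maximum over
    the two cluster-to-label assignments, so it cannot fall below 0.5 for
    balanced truth.
    """
    if isinstance(values, ExpressionMatrix):
        values = values.values
    values = np.asarray(values, dtype=float)
    gene_truth = np.asarray(gene_truth)
    if values.shape[0] != gene_truth.size:
        raise DimensionError("one truth label per gene (row) required")
    if values.shape[0] < k:
        raise DimensionError(f"need at least k={k} genes to cluster")
    km = KMeans(
        n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**31), tol=1e-8,
        max_iter=300,
    )
    labels = km.fit_predict(values)
    truth_bin = (gene_truth == gene_truth[0]).astype(int)
    acc = max(
        float(np.mean((labels == c) == truth_bin.astype(bool))) for c in (0, 1)
    )
    return acc


def run_pathway_benchmark(
    seed: int,
    use_covariates: bool = True,
    scale_param_is_variance: bool = False,
    n_restarts: int = 25,
) -> pd.DataFrame:
    """Signature-recovery accuracies for three adjustments x three views.

    Rows: ``unadjusted``, ``original``, ``reference`` (reference = batch 1).
    Columns: ``batch1``, ``batch2``, ``combined``.  The pathway activation
    level is used as a covariate when ``use_covariates`` (the headline
    configuration); without covariates the activation signal is hidden from
    the adjustment, emulating the realistic case where it is unknown.
    """
    rng = np.random.default_rng(int(seed))
    study = simulate_pathway_study(seed, scale_param_is_variance)
    design = StudyDesign(
        study.design.batch,
        covariates=study.pathway_activation[:, None] if use_covariates else None,
        covariate_names=["pathway_activation"] if use_covariates else None,
        reference_batch="batch1",
    )
    matrices = {"unadjusted": study.expression}
    matrices["original"] = combat(study.expression, design, mode="original").adjusted
    matrices["reference"] = combat(study.expression, design, mode="reference").adjusted

    b1 = study.batch_columns("batch1")
    b2 = study.batch_columns("batch2")
    rows = {}
    for name, M in matrices.items():
        km_seed = int(rng.integers(2**31))
        rows[name] = {
            "batch1": kmeans_signature_accuracy(
                M.values[:, b1], study.gene_truth, n_restarts=n_restarts, seed=km_seed
            ),
            "batch2": kmeans_signature_accuracy(
                M.values[:, b2], study.gene_truth, n_restarts=n_restarts, seed=km_seed + 1
            ),
            "combined": kmeans_signature_accuracy(
                M.values, study.gene_truth, n_restarts=n_restarts, seed=km_seed + 2
            ),
        }
    return pd.DataFrame(rows).T[["batch1", "batch2", "combined"]]


# ---------------------------------------------------------------------------
# differential-expression study
# ---------------------------------------------------------------------------

BATCH_EFFECT_REGIMES = ("none", "mean_only", "mean_and_variance")


def simulate_de_study(
    seed: int,
    batch_effect: str = "none",
    n_genes: int = 1000,
    n_de: int = 100,
    n_per_group: int = 10,
    effect_size: float = 1.0,
    gamma_shift: float = 1.0,
    delta2_factor: float = 4.0,
) -> SimulatedStudy:
    """Two batches x two conditions, balanced, with a chosen batch regime.

    Baseline expression is N(0, 1); the first ``n_de`` genes gain
    ``effect_size`` in condition 2.  Batch 2 is perturbed by an additive
    ``gamma_shift`` under the mean regimes and its residual scale is
    multiplied by sqrt(``delta2_factor``) under the mean-and-variance
    regime.
    """
    if batch_effect not in BATCH_EFFECT_REGIMES:
        raise ValueError(f"batch_effect must be one of {BATCH_EFFECT_REGIMES}")
    if not 0 <= n_de <= n_genes:
        raise ValueError("need 0 <= n_de <= n_genes")
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    rng = np.random.default_rng(int(seed))
    n_samples = 4 * n_per_group
    batch = np.repeat(["batch1", "batch2"], 2 * n_per_group)
    condition = np.tile(np.repeat(["ctrl", "case"], n_per_group), 2)

    noise_sd = np.ones(n_samples)
    if batch_effect == "mean_and_variance":
        noise_sd[batch == "batch2"] = np.sqrt(delta2_factor)
    values = rng.normal(0.0, 1.0, (n_genes, n_samples)) * noise_sd[None, :]
    values[:n_de, condition == "case"] += effect_size
    if batch_effect in ("mean_only", "mean_and_variance"):
        values[:, batch == "batch2"] += gamma_shift

    gene_ids = [f"gene_{i + 1:04d}" for i in range(n_genes)]
    sample_ids = [f"{b}_{c}_{j + 1}" for j, (b, c) in enumerate(zip(batch, condition))]
    cond_numeric = (condition == "case").astype(float)
    truth = np.array(["signature"] * n_de + ["control"] * (n_genes - n_de), dtype=object)
    expr = ExpressionMatrix(values, gene_ids, sample_ids)
    design = StudyDesign(batch, covariates=cond_numeric[:, None], covariate_names=["condition"])
    return SimulatedStudy(expr, design, truth, condition, cond_numeric, int(seed))


def pooled_ttest(x: np.ndarray, y: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample equal-variance t-test, implemented in-house.

    t = (mean(x) - mean(y)) / sqrt(sp2 (1/nx + 1/ny)) with the pooled
    variance sp2 and nx + ny - 2 degrees of freedom; two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.shape[axis], y.shape[axis]
    if nx < 2 or ny < 2:
        raise DimensionError("need >= 2 observations per group")
    mx, my = x.mean(axis=axis), y.mean(axis=axis)
    ssx = np.sum((x - np.expand_dims(mx, axis)) ** 2, axis=axis)
    ssy = np.sum((y - np.expand_dims(my, axis)) ** 2, axis=axis)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def evaluate_type1_power(
    seed: int,
    batch_effect: str = "none",
    combat_mode: Optional[str] = None,
    n_reps: int = 50,
    alpha: float = 0.05,
    **sim_kwargs,
) -> tuple[float, float]:
    """Type-I error and power of per-gene DE testing, with/without adjustment.

    Per replicate: simulate with :func:`simulate_de_study`, optionally run
    batch adjustment (``combat_mode`` in {None, 'original', 'mean_only'}),
    then test each gene between conditions with the in-house pooled t-test
    at ``alpha``.  Returns (mean rejection fraction among non-DE genes,
    mean rejection fraction among DE genes) over ``n_reps`` replicates.
    """
    rng = np.random.default_rng(int(seed))
    type1, power = [], []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31))
        study = simulate_de_study(rep_seed, batch_effect=batch_effect, **sim_kwargs)
        values = study.expression.values
        if combat_mode is not None:
            values = combat(study.expression, study.design, mode=combat_mode).adjusted.values
        case = study.sample_groups == "case"
        _, p = pooled_ttest(values[:, case], values[:, ~case], axis=1)
        reject = p < alpha
        sig = study.signature_mask
        if np.any(~sig):
            type1.append(float(np.mean(reject[~sig])))
        if np.any(sig):
            power.append(float(np.mean(reject[sig])))
    return (
        float(np.mean(type1)) if type1 else float("nan"),
        float(np.mean(power)) if power else float("nan"),
    )


# ---------------------------------------------------------------------------
# standardized-scale panel (EB recovery experiments)
# ---------------------------------------------------------------------------

def simulate_standardized_batches(
    seed: int,
    n_genes: int = 100,
    batch_sizes: tuple[int, ...] = (10, 10),
    gamma_mean: float = 0.5,
    gamma_var: float = 0.2,
    delta2_shape: float = 3.0,
    delta2_scale: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw standardized data directly from the hierarchical batch model.

    gamma_ig ~ N(gamma_mean, gamma_var), delta2_ig ~ InvGamma(shape, scale),
    Z_ijg ~ N(gamma_ig, delta2_ig).  Returns (Z, batch_labels, gamma_true,
    delta2_true) with Z genes x samples and the truths (n_batches, n_genes).
    Used to measure shrinkage dominance of the EB posteriors.
    """
    rng = np.random.default_rng(int(seed))
    k = len(batch_sizes)
    gamma = rng.normal(gamma_mean, np.sqrt(gamma_var), (k, n_genes))
    delta2 = stats.invgamma.rvs(
        delta2_shape, scale=delta2_scale, size=(k, n_genes), random_state=rng
    )
    cols = []
    labels = []
    for i, n_i in enumerate(batch_sizes):
        eps = rng.normal(0.0, 1.0, (n_genes, n_i))
        cols.append(gamma[i][:, None] + np.sqrt(delta2[i])[:, None] * eps)
        labels.extend([f"batch{i + 1}"] * n_i)
    Z = np.hstack(cols)
    return Z, np.asarray(labels, dtype=object), gamma, delta2
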