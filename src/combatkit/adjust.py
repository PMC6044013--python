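"""Empirical Bayes batch-effect estimation and the three adjustment modes.

On the standardized scale each batch/gene cell has an additive effect
``gamma_ig`` (the batch mean of Z) and a multiplicative effect
``delta_ig^2`` (the batch variance of Z).  The EB machinery assumes the
per-gene effects within a batch are exchangeable draws from batch-level
hyper-distributions — ``gamma_ig ~ N(gamma_bar_i, tau2_i)`` and
``delta_ig^2 ~ InverseGamma(lambda_i, theta_i)`` — estimates the
hyperparameters by the method of moments across genes, and shrinks each
cell's raw estimate toward the batch prior by iterating the conditional
posterior means to a fixed point.

Three modes are provided:

* ``original`` — shrink and remove both the additive and multiplicative
  effects; every batch is pulled to the pooled mean/variance profile.
* ``mean_only`` — shrink and remove only the additive effect (closed form;
  delta*^2 is fixed at 1 so within-batch variances are untouched).
* ``reference`` — standardize against a designated reference batch, adjust
  every other batch to the reference's mean/variance profile, and return
  the reference batch bit-identical to its input.  Because the adjustment of
  each non-reference batch depends only on itself and the reference, adding
  or removing other batches never changes already-adjusted data ("set bias"
  is avoided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .errors import (
    DegeneratePriorError,
    DimensionError,
    NonConvergenceError,
    SingleBatchError,
    SingletonBatchError,
)
from .model import ExpressionMatrix, StandardizedFit, StudyDesign, fit_location_scale

logger = logging.getLogger(__name__)

MODES = ("original", "mean_only", "reference")

#: relative tolerance for the posterior fixed-point iteration
CONVERGENCE_TOL = 1e-4
MAX_ITER = 100


@dataclass
class HyperPriors:
    """Per-batch hyperparameters of the EB priors.

    ``gamma_bar``/``tau2_bar`` are the cross-gene mean and (unbiased)
    variance of the raw additive estimates.  ``lam``/``theta`` are the
    inverse-gamma shape/scale for delta^2 from the method of moments; they
    are NaN for batches whose cross-gene variance of delta2_hat is zero
    (degenerate prior — no shrinkage applied there).
    """

    batches: list[str]
    gamma_bar: np.ndarray
    tau2_bar: np.ndarray
    lam: np.ndarray
    theta: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        return ~np.isfinite(self.lam)


@dataclass
class BatchEffectModel:
    """Raw and shrunken batch-effect estimates for every (batch, gene) cell."""

    batches: list[str]
    gamma_hat: np.ndarray       # (n_batches, n_genes)
    delta2_hat: Optional[np.ndarray]
    hyper: Optional[HyperPriors]
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    mode: str
    n_iter: Optional[np.ndarray] = None   # per batch, variance modes only


class CombatResult(NamedTuple):
    adjusted: ExpressionMatrix
    model: BatchEffectModel
    fit: StandardizedFit


# ---------------------------------------------------------------------------
# raw estimates
# ---------------------------------------------------------------------------

def estimate_batch_effects(
    fit: StandardizedFit,
    design: StudyDesign,
    with_variance: bool = True,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Per-(batch, gene) mean and unbiased variance of the standardized data.

    gamma_hat_ig is the mean of Z over the samples of batch i; delta2_hat_ig
    the (n_i - 1)-denominator variance.  With ``with_variance`` a singleton
    batch raises :class:`SingletonBatchError`; zero variances are floored at
    1e-3 times the batch's smallest positive estimate (logged) so that
    shrinkage remains defined.
    """
    if fit.n_samples != design.n_samples:
        raise DimensionError("fit and design disagree on the number of samples")
    levels = design.batch_levels
    gamma_hat = np.empty((len(levels), fit.n_genes))
    delta2_hat = np.empty_like(gamma_hat) if with_variance else None
    if with_variance:
        design.require_min_batch_size(2)
    for i, b in enumerate(levels):
        Zi = fit.Z[:, design.batch_mask(b)]
        gamma_hat[i] = Zi.mean(axis=1)
        if with_variance:
            delta2_hat[i] = Zi.var(axis=1, ddof=1)
            zero = delta2_hat[i] <= 0.0
            if np.any(zero):
                positive = delta2_hat[i][~zero]
                floor = (positive.min() if positive.size else 1.0) * 1e-3
                logger.warning(
                    "batch %s: %d gene(s) constant within batch; "
                    "flooring delta2_hat at %.3g", b, int(zero.sum()), floor
                )
                delta2_hat[i][zero] = floor
    return gamma_hat, delta2_hat


# ---------------------------------------------------------------------------
# hyperpriors
# ---------------------------------------------------------------------------

def fit_hyperpriors(
    gamma_hat: np.ndarray,
    delta2_hat: Optional[np.ndarray],
    batches: Optional[list[str]] = None,
    on_degenerate: str = "raise",
) -> HyperPriors:
    """Method-of-moments hyperparameters per batch.

    gamma_bar_i / tau2_bar_i are the mean and unbiased variance over genes of
    gamma_hat.  With Vbar_i = mean(delta2_hat) and S2_i = var(delta2_hat)
    over genes, matching the first two moments of an inverse gamma gives

        lambda_i = (2 S2 + Vbar^2) / S2
        theta_i  = (Vbar S2 + Vbar^3) / S2

    ``on_degenerate="raise"`` raises :class:`DegeneratePriorError` when
    S2_i == 0; ``"fallback"`` marks the batch with NaN hyperparameters so
    the posterior solver skips delta shrinkage there.
    """
    gamma_hat = np.atleast_2d(gamma_hat)
    k = gamma_hat.shape[0]
    if batches is None:
        batches = [str(i) for i in range(k)]
    gamma_bar = gamma_hat.mean(axis=1)
    tau2_bar = gamma_hat.var(axis=1, ddof=1)
    lam = np.full(k, np.nan)
    theta = np.full(k, np.nan)
    if delta2_hat is not None:
        delta2_hat = np.atleast_2d(delta2_hat)
        vbar = delta2_hat.mean(axis=1)
        s2 = delta2_hat.var(axis=1, ddof=1)
        degenerate = s2 <= 0.0
        if np.any(degenerate):
            names = [b for b, d in zip(batches, degenerate) if d]
            if on_degenerate == "raise":
                raise DegeneratePriorError(
                    f"cross-gene variance of delta2_hat is zero in batch(es) {names}; "
                    "cannot fit an inverse-gamma prior (fall back to no shrinkage)"
                )
            logger.warning(
                "degenerate delta2 prior in batch(es) %s; variance shrinkage disabled there",
                names,
            )
        ok = ~degenerate
        lam[ok] = (2.0 * s2[ok] + vbar[ok] ** 2) / s2[ok]
        theta[ok] = (vbar[ok] * s2[ok] + vbar[ok] ** 3) / s2[ok]
    return HyperPriors(list(batches), gamma_bar, tau2_bar, lam, theta)


# ---------------------------------------------------------------------------
# posteriors
# ---------------------------------------------------------------------------

def _postmean(gamma_hat, gamma_bar, n, delta2, tau2):
    return (n * tau2 * gamma_hat + delta2 * gamma_bar) / (n * tau2 + delta2)


def solve_posteriors(
    gamma_hat: np.ndarray,
    delta2_hat: Optional[np.ndarray],
    hyper: HyperPriors,
    fit: StandardizedFit,
    design: StudyDesign,
    mode: str = "original",
    tol: float = CONVERGENCE_TOL,
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shrunken (posterior) batch effects gamma*_ig, delta*^2_ig.

    Variance modes iterate the coupled conditional posterior means per batch

        gamma* <- (n tau2 gamma_hat + delta*^2 gamma_bar) / (n tau2 + delta*^2)
        delta*^2 <- (theta + 0.5 sum_j (Z_ijg - gamma*)^2) / (n/2 + lambda - 1)

    from (gamma_hat, delta2_hat) until the maximum absolute relative change
    drops below ``tol``.  ``mean_only`` uses the closed form with delta*^2
    fixed at 1.  In ``reference`` mode the reference batch's row is forced to
    exactly (0, 1).  Returns (gamma_star, delta2_star, n_iter_per_batch).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    levels = design.batch_levels
    k = len(levels)
    n_sizes = design.batch_sizes.astype(float)
    gamma_star = np.array(gamma_hat, dtype=float, copy=True)
    delta2_star = np.ones_like(gamma_star)
    n_iter = np.zeros(k, dtype=int)

    if mode == "mean_only":
        for i in range(k):
            gamma_star[i] = _postmean(
                gamma_hat[i], hyper.gamma_bar[i], n_sizes[i], 1.0, hyper.tau2_bar[i]
            )
        return gamma_star, delta2_star, n_iter

    if delta2_hat is None:
        raise DimensionError("variance modes need delta2_hat estimates")
    delta2_star = np.array(delta2_hat, dtype=float, copy=True)

    ref_idx = None
    if mode == "reference":
        if design.reference_batch is None:
            raise DimensionError("reference mode requires design.reference_batch")
        ref_idx = levels.index(design.reference_batch)

    for i in range(k):
        if i == ref_idx:
            gamma_star[i] = 0.0
            delta2_star[i] = 1.0
            continue
        Zi = fit.Z[:, design.batch_mask(levels[i])]
        n = n_sizes[i]
        tau2, gbar = hyper.tau2_bar[i], hyper.gamma_bar[i]
        lam, theta = hyper.lam[i], hyper.theta[i]
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        if hyper.degenerate[i]:
            # no variance shrinkage; gamma posterior is closed-form given delta2
            gamma_star[i] = _postmean(gamma_hat[i], gbar, n, d_old, tau2)
            delta2_star[i] = d_old
            continue
        for it in range(1, max_iter + 1):
            g_new = _postmean(gamma_hat[i], gbar, n, d_old, tau2)
            sum2 = np.sum((Zi - g_new[:, None]) ** 2, axis=1)
            d_new = (theta + 0.5 * sum2) / (n / 2.0 + lam - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        else:
            raise NonConvergenceError(
                f"posterior iteration for batch {levels[i]} did not converge "
                f"in {max_iter} iterations (last relative change {change:.3g})"
            )
        n_iter[i] = it
        gamma_star[i] = g_old
        delta2_star[i] = d_old
    return gamma_star, delta2_star, n_iter


# ---------------------------------------------------------------------------
# adjustment
# ---------------------------------------------------------------------------

def apply_adjustment(
    Y: ExpressionMatrix,
    fit: StandardizedFit,
    model: BatchEffectModel,
    design: StudyDesign,
) -> ExpressionMatrix:
    """Remove the shrunken batch effects and restore the original scale.

    original / reference:  Y*_ijg = sigma_g (Z_ijg - gamma*_ig) / delta*_ig
                                     + alpha_g + X_ij beta_g
    mean_only:             Y*_ijg = sigma_g (Z_ijg - gamma*_ig)
                                     + alpha_g + X_ij beta_g

    In reference mode the reference batch's samples are copied from the
    input, so they are bit-identical (not merely numerically close).
    """
    if Y.values.shape != fit.Z.shape:
        raise DimensionError("expression and fit shapes differ")
    adjusted = np.empty_like(Y.values)
    stand_mean = fit.stand_mean(design)
    for i, b in enumerate(model.batches):
        mask = design.batch_mask(b)
        Zadj = fit.Z[:, mask] - model.gamma_star[i][:, None]
        if model.mode in ("original", "reference"):
            Zadj = Zadj / np.sqrt(model.delta2_star[i])[:, None]
        adjusted[:, mask] = fit.sigma[:, None] * Zadj + stand_mean[:, mask]
    if model.mode == "reference":
        ref_mask = design.batch_mask(design.reference_batch)
        adjusted[:, ref_mask] = Y.values[:, ref_mask]
    return ExpressionMatrix(adjusted, list(Y.gene_ids), list(Y.sample_ids))


def combat(
    Y: ExpressionMatrix,
    design: StudyDesign,
    mode: str = "original",
    tol: float = CONVERGENCE_TOL,
    max_iter: int = MAX_ITER,
) -> CombatResult:
    """End-to-end batch adjustment: fit, estimate, shrink, apply.

    Parameters
    ----------
    Y
        Gene x sample expression matrix (log scale).
    design
        Batch labels, covariates, and (for ``mode="reference"``) the
        reference batch.
    mode
        ``"original"`` (mean and variance), ``"mean_only"``, or
        ``"reference"``.

    Returns
    -------
    CombatResult
        ``(adjusted, model, fit)`` — the corrected matrix, the fitted
        :class:`BatchEffectModel` (raw + shrunken effects, hyperpriors), and
        the :class:`~combatkit.model.StandardizedFit`.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if design.n_batches < 2:
        raise SingleBatchError("need at least two batches to adjust")
    if mode == "reference" and design.reference_batch is None:
        raise DimensionError("mode='reference' requires design.reference_batch")

    with_variance = mode != "mean_only"
    fit = fit_location_scale(Y, design, mode="reference" if mode == "reference" else "pooled")
    gamma_hat, delta2_hat = estimate_batch_effects(fit, design, with_variance=with_variance)
    hyper = fit_hyperpriors(
        gamma_hat, delta2_hat, design.batch_levels, on_degenerate="fallback"
    )
    gamma_star, delta2_star, n_iter = solve_posteriors(
        gamma_hat, delta2_hat, hyper, fit, design, mode=mode, tol=tol, max_iter=max_iter
    )
    model = BatchEffectModel(
        batches=design.batch_levels,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        hyper=hyper,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        mode=mode,
        n_iter=n_iter,
    )
    adjusted = apply_adjustment(Y, fit, model, design)
    return CombatResult(adjusted, model, fit)
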