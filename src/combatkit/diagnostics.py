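"""Moment-based batch-effect diagnostics.

After standardization, each batch's standardized data are assumed to come
from a distribution with mean gamma_ig, variance delta_ig^2, skewness
eta_ig and kurtosis phi_ig, themselves exchangeable draws from cross-gene
hyper-distributions.  Two families of tests probe whether those moments
differ across batches:

* **sample-level** — each sample j contributes one estimate of each moment,
  computed over its n_g gene values (e.g. the sample mean
  (1/n_g) sum_g Z_ijg); estimates are grouped by the sample's batch.
  Robust at small sample sizes; blind on quantile-normalized data, where
  every sample has identical moments by construction.
* **gene-level** — each (gene, batch) cell contributes one estimate,
  computed over the batch's n_i samples; there are n_g x n_batches
  estimates in total.  More sensitive at large sample sizes, and the right
  tool for quantile-normalized data.

Each moment table is compared across batches with a one-way ANOVA F-test,
and with a *robust* variant that divides the F statistic by a variance
inflation factor VIF = max(1, M / n0) and caps the denominator degrees of
freedom at n0, counteracting the collapse of p-values when the number of
moment estimates M (= n_g x n_batches for the gene-level test) is very
large.  The exact inflation factor is a documented, pluggable choice; it
reduces to the standard test whenever M <= n0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateGroupsError, InsufficientObservationsError
from .model import ExpressionMatrix, StandardizedFit, StudyDesign, fit_location_scale

logger = logging.getLogger(__name__)

MOMENTS = ("mean", "variance", "skewness", "kurtosis")
LEVELS = ("sample", "gene")
#: minimum observations per unit for each moment estimator
_MIN_OBS = {"mean": 1, "variance": 2, "skewness": 3, "kurtosis": 4}
#: default reference size for the robust F-test
DEFAULT_N0 = 100

SCHEMA_VERSION = "1"


def _moment_estimates(values: np.ndarray, moment: str, axis: int) -> np.ndarray:
    """mean, unbiased variance, g1 skewness, g2 excess kurtosis along axis."""
    if moment == "mean":
        return values.mean(axis=axis)
    if moment == "variance":
        return values.var(axis=axis, ddof=1)
    if moment == "skewness":
        return stats.skew(values, axis=axis, bias=True)
    if moment == "kurtosis":
        return stats.kurtosis(values, axis=axis, fisher=True, bias=True)
    raise ValueError(f"unknown moment {moment!r}")


@dataclass
class MomentTable:
    """One moment's estimates, one per unit, each tagged with a batch label.

    Sample level: one unit per sample (N estimates).  Gene level: one unit
    per (gene, batch) cell (n_g x n_batches estimates).
    """

    level: str
    moment: str
    estimates: np.ndarray
    batch_of_unit: np.ndarray

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.batch_of_unit = np.asarray(self.batch_of_unit, dtype=object)
        if self.estimates.shape != self.batch_of_unit.shape:
            raise ValueError("estimates and batch labels differ in length")

    @property
    def n_units(self) -> int:
        return self.estimates.size

    def groups(self) -> list[np.ndarray]:
        seen: dict = {}
        for b in self.batch_of_unit:
            seen.setdefault(b, None)
        return [self.estimates[self.batch_of_unit == b] for b in seen]


def compute_moments(
    fit: StandardizedFit,
    design: StudyDesign,
    level: str,
    moments: tuple[str, ...] = MOMENTS,
    on_insufficient: str = "raise",
) -> dict[str, MomentTable]:
    """Moment tables of the standardized data at one level.

    Sample level: for each sample, the mean / unbiased variance / g1
    skewness / g2 excess kurtosis over its genes.  Gene level: the same four
    estimators over the samples within each (gene, batch) cell.

    ``on_insufficient="raise"`` raises
    :class:`InsufficientObservationsError` when a unit has too few
    observations for a requested moment (variance 2, skewness 3, kurtosis
    4); ``"skip"`` silently drops that moment from the result.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    out: dict[str, MomentTable] = {}
    if level == "sample":
        n_obs = fit.n_genes
        for m in moments:
            if n_obs < _MIN_OBS[m]:
                if on_insufficient == "raise":
                    raise InsufficientObservationsError(
                        f"{m} needs >= {_MIN_OBS[m]} genes; have {n_obs}"
                    )
                continue
            out[m] = MomentTable(
                level, m, _moment_estimates(fit.Z, m, axis=0), np.asarray(design.batch)
            )
    else:
        levels_ = design.batch_levels
        sizes = dict(zip(levels_, design.batch_sizes))
        for m in moments:
            small = [b for b in levels_ if sizes[b] < _MIN_OBS[m]]
            if small:
                if on_insufficient == "raise":
                    raise InsufficientObservationsError(
                        f"{m} needs >= {_MIN_OBS[m]} samples per batch; "
                        f"batch(es) {small} are smaller"
                    )
                continue
            ests, labels = [], []
            for b in levels_:
                ests.append(_moment_estimates(fit.Z[:, design.batch_mask(b)], m, axis=1))
                labels.extend([b] * fit.n_genes)
            out[m] = MomentTable(level, m, np.concatenate(ests), np.asarray(labels, dtype=object))
    return out


# ---------------------------------------------------------------------------
# F-tests
# ---------------------------------------------------------------------------

def _anova_ss(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    """Between/within sums of squares and degrees of freedom."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    k = len(groups)
    M = all_vals.size
    return float(ssb), float(ssw), k, M


def moment_anova(table: MomentTable) -> tuple[float, float]:
    """One-way ANOVA F across batches on the moment estimates.

    Returns (F, p) with p from F(k - 1, M - k).  When neither between- nor
    within-group variation exists (all estimates identical, as for
    quantile-normalized data at the sample level) the test is vacuous and
    (0, 1) is returned by convention.
    """
    groups = table.groups()
    if len(groups) < 2:
        raise DegenerateGroupsError("need at least two batches to compare")
    if any(len(g) < 1 for g in groups) or sum(len(g) for g in groups) <= len(groups):
        raise DegenerateGroupsError("need more estimates than batches")
    ssb, ssw, k, M = _anova_ss(groups)
    scale = max(1.0, float(np.mean(np.concatenate(groups) ** 2)))
    if (ssb + ssw) <= 1e-12 * scale * M:
        return 0.0, 1.0
    msb = ssb / (k - 1)
    msw = ssw / (M - k)
    if msw == 0.0:
        return float("inf"), 0.0
    F = msb / msw
    p = float(stats.f.sf(F, k - 1, M - k))
    return float(F), p


def robust_moment_anova(table: MomentTable, n0: int = DEFAULT_N0) -> tuple[float, float]:
    """Variance-inflated F-test robust to very large numbers of estimates.

    F_r = F / VIF with VIF = max(1, M / n0); p is computed from
    F(k - 1, min(M, n0) - k).  Identical to :func:`moment_anova` whenever
    M <= n0.  ``n0`` acts as an effective reference sample size (default
    100).
    """
    groups = table.groups()
    k = len(groups)
    M = sum(len(g) for g in groups)
    if n0 < k + 1:
        raise ValueError(f"n0 must be at least n_batches + 1 = {k + 1}")
    F, p = moment_anova(table)
    vif = max(1.0, M / float(n0))
    if not np.isfinite(F):
        return F, p
    F_r = F / vif
    df2 = min(M, n0) - k
    if F == 0.0 and p == 1.0:
        return 0.0, 1.0
    p_r = float(stats.f.sf(F_r, k - 1, df2))
    return float(F_r), p_r


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    """Table-shaped grid of batch-effect p-values plus a recommendation.

    ``pvalues`` maps (level, moment, test) -> p; ``statistics`` holds the
    matching F statistics.  ``recommendation`` is one of
    ``"mean/variance"``, ``"mean-only"``, ``"no adjustment indicated"``.
    """

    adjustment_label: str
    pvalues: dict[tuple[str, str, str], float]
    statistics: dict[tuple[str, str, str], float] = field(default_factory=dict)
    alpha: float = 0.05
    n0: int = DEFAULT_N0
    recommendation: str = ""

    def p(self, level: str, moment: str, test: str = "robust") -> float:
        return self.pvalues[(level, moment, test)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            for test in ("standard", "robust"):
                row = {"adjustment": self.adjustment_label, "level": level, "test": test}
                for m in MOMENTS:
                    row[m] = self.pvalues.get((level, m, test), float("nan"))
                rows.append(row)
        return pd.DataFrame(rows)

    def to_table_row(self) -> pd.DataFrame:
        """One row per adjustment state: 8 cells x 2 test variants, wide."""
        cells = {"adjustment": self.adjustment_label}
        for level in LEVELS:
            for m in MOMENTS:
                for test in ("standard", "robust"):
                    cells[f"{level}_{m}_{test}"] = self.pvalues.get(
                        (level, m, test), float("nan")
                    )
        return pd.DataFrame([cells])

    def to_json(self) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "adjustment": self.adjustment_label,
            "alpha": self.alpha,
            "n0": self.n0,
            "recommendation": self.recommendation,
            "pvalues": [
                {"level": lv, "moment": m, "test": t, "p": p}
                for (lv, m, t), p in sorted(self.pvalues.items())
            ],
            "statistics": [
                {"level": lv, "moment": m, "test": t, "F": f}
                for (lv, m, t), f in sorted(self.statistics.items())
            ],
        }
        return json.dumps(payload, indent=2, allow_nan=True)

    def to_tsv(self, path) -> None:
        self.to_table_row().to_csv(path, sep="\t", index=False)


def _recommend(pvalues: dict, alpha: float) -> str:
    """Decision rule: mean/variance correction if any variance test is
    significant at either level; otherwise mean-only if any mean test is;
    otherwise no adjustment.  Skewness/kurtosis are reported but cannot be
    adjusted by these models, so they do not enter the rule."""
    def sig(moment: str) -> bool:
        return any(
            pvalues.get((lv, moment, "robust"), 1.0) < alpha for lv in LEVELS
        )
    if sig("variance"):
        return "mean/variance"
    if sig("mean"):
        return "mean-only"
    return "no adjustment indicated"


def batch_diagnostics(
    Y: ExpressionMatrix,
    design: StudyDesign,
    adjustment_label: str = "None",
    alpha: float = 0.05,
    n0: int = DEFAULT_N0,
    robust_test: Optional[Callable[[MomentTable, int], tuple[float, float]]] = None,
) -> DiagnosticsReport:
    """Full Table-shaped diagnostics for one (possibly pre-adjusted) matrix.

    Standardizes ``Y`` in pooled mode, computes sample- and gene-level
    tables for all four moments, runs the standard and robust F-tests on
    each, and applies the decision rule at ``alpha``.  Moments that cannot
    be estimated (e.g. gene-level kurtosis with n_i < 4) appear as NaN.
    ``robust_test`` allows plugging a different inflation scheme.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    robust = robust_test or robust_moment_anova
    fit = fit_location_scale(Y, design, mode="pooled")
    pvalues: dict[tuple[str, str, str], float] = {}
    statistics: dict[tuple[str, str, str], float] = {}
    for level in LEVELS:
        tables = compute_moments(fit, design, level, on_insufficient="skip")
        for m, table in tables.items():
            F, p = moment_anova(table)
            pvalues[(level, m, "standard")] = p
            statistics[(level, m, "standard")] = F
            F_r, p_r = robust(table, n0)
            pvalues[(level, m, "robust")] = p_r
            statistics[(level, m, "robust")] = F_r
    report = DiagnosticsReport(
        adjustment_label=adjustment_label,
        pvalues=pvalues,
        statistics=statistics,
        alpha=alpha,
        n0=n0,
    )
    report.recommendation = _recommend(pvalues, alpha)
    return report
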