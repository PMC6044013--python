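"""Exception hierarchy.

Every error raised by combatkit derives from :class:`CombatKitError`, so
callers (and the CLI) can catch the whole family and map each subclass to a
distinct exit code.
"""

from __future__ import annotations


class CombatKitError(Exception):
    """Base class for all combatkit errors."""


# ---------------------------------------------------------------------------
# data / parsing
# ---------------------------------------------------------------------------

class ParseError(CombatKitError):
    """A cell in an input table could not be parsed; message names (row, column)."""


class DuplicateIdError(CombatKitError):
    """Duplicate gene or sample identifiers in an input table."""


class MissingSampleError(CombatKitError):
    """Sample ids present in one input file but not the other."""


class MissingColumnError(CombatKitError):
    """A required metadata column is absent."""


class DimensionError(CombatKitError):
    """Mismatched shapes between expression, design, or model objects."""


# ---------------------------------------------------------------------------
# design / fitting
# ---------------------------------------------------------------------------

class ConfoundedDesignError(CombatKitError):
    """Batch indicators are linearly dependent with the covariates.

    A batch fully confounded with a biological condition makes the additive
    batch effect unidentifiable; the combined design matrix is rank deficient.
    """


class ZeroVarianceGeneError(CombatKitError):
    """Genes whose residual scale is numerically zero.

    Carries the offending gene ids in :attr:`genes` so the caller can drop
    them and retry.
    """

    def __init__(self, genes: list[str]):
        self.genes = list(genes)
        preview = ", ".join(self.genes[:10])
        more = "" if len(self.genes) <= 10 else f" (+{len(self.genes) - 10} more)"
        super().__init__(
            f"{len(self.genes)} gene(s) have (near-)zero residual variance: {preview}{more}"
        )


class SingleBatchError(CombatKitError):
    """Fewer than two batches: nothing to adjust."""


class SingletonBatchError(CombatKitError):
    """A batch with a single sample in a variance-adjusting mode."""


class DegeneratePriorError(CombatKitError):
    """All per-gene variance estimates in a batch are identical.

    The inverse-gamma method of moments divides by the cross-gene variance of
    the delta-squared estimates; when that is zero no prior can be fit and the
    caller should fall back to unshrunken variance estimates.
    """


class NonConvergenceError(CombatKitError):
    """Posterior fixed-point iteration exceeded the iteration budget."""


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

class DegenerateGroupsError(CombatKitError):
    """Moment estimates carry no variation at all (within or between batches)."""


class InsufficientObservationsError(CombatKitError):
    """Too few observations per unit for the requested moment.

    Variance needs >= 2 observations, skewness >= 3, kurtosis >= 4.
    """
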