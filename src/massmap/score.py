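"""Null trait models, single-taxon score statistics and permutation p-values.

The score statistic for a taxon is the inner product of the null-model
residuals with the taxon's abundance vector.  P-values come from residual
permutation: residuals are permuted (the null model is NOT re-fitted per
permutation) and compared two-sided on the absolute statistic, with the
(1 + b) / (1 + B) estimator so p-values are bounded below by 1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data import TraitData, ValidationError


class FitError(RuntimeError):
    """Null model failed to fit (non-convergence or perfect separation)."""


@dataclass
class NullFit:
    """Fitted null trait model shared by all tests on a dataset."""

    trait_type: str
    beta0_hat: float
    alpha_hat: np.ndarray
    y_hat: np.ndarray
    residuals: np.ndarray

    @property
    def n(self) -> int:
        return len(self.residuals)


def fit_null(trait: TraitData) -> NullFit:
    """Fit the covariate-only null model (intercept always included).

    Continuous traits use least squares; binary traits use logistic MLE via
    iteratively reweighted optimization.
    """
    y = trait.y
    design = np.column_stack([np.ones(trait.n), trait.X])
    if trait.trait_type == "continuous":
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        y_hat = design @ coef
    else:
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise FitError(f"logistic null fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise FitError("logistic null fit did not converge")
        coef = res.params
        y_hat = res.predict(design)
        if np.any(y_hat <= 1e-10) or np.any(y_hat >= 1 - 1e-10):
            raise FitError("fitted probabilities at the boundary (separation?)")
    return NullFit(
        trait_type=trait.trait_type,
        beta0_hat=float(coef[0]),
        alpha_hat=np.asarray(coef[1:], dtype=float),
        y_hat=y_hat,
        residuals=y - y_hat,
    )


@dataclass(frozen=True)
class PermutationSet:
    """A reusable ensemble of sample-order permutations.

    One shared ensemble drives every permutation test in a run so that
    component p-values are comparable and the run is reproducible from a
    single seed.
    """

    indices: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        idx = np.asarray(self.indices)
        if idx.ndim != 2:
            raise ValidationError("permutation indices must be a B x N matrix")
        expected = np.arange(idx.shape[1])
        if not np.all(np.sort(idx, axis=1) == expected):
            raise ValidationError("each row must be a permutation of 0..N-1")
        object.__setattr__(self, "indices", idx)

    @property
    def B(self) -> int:
        return self.indices.shape[0]

    @property
    def n(self) -> int:
        return self.indices.shape[1]

    @classmethod
    def generate(cls, n_samples: int, n_perm: int, seed: int | None = None) -> "PermutationSet":
        if n_perm < 1:
            raise ValidationError("number of permutations must be >= 1")
        rng = np.random.default_rng(seed)
        base = np.tile(np.arange(n_samples), (n_perm, 1))
        return cls(rng.permuted(base, axis=1), seed=seed)


def score_statistic(null: NullFit, z: np.ndarray) -> float:
    """Inner product of null residuals with one abundance vector."""
    z = np.asarray(z, dtype=float).ravel()
    if len(z) != null.n:
        raise ValidationError(f"abundance length {len(z)} != sample count {null.n}")
    return float(null.residuals @ z)


def permuted_residuals(null: NullFit, perms: PermutationSet) -> np.ndarray:
    """B x N matrix of residuals under each permutation."""
    if perms.n != null.n:
        raise ValidationError("permutation width does not match sample count")
    return null.residuals[perms.indices]


def permutation_pvalues(
    null: NullFit, Z: np.ndarray, perms: PermutationSet, sided: str = "two_sided"
) -> np.ndarray:
    """Residual-permutation p-values for each column of ``Z``.

    ``p_j = (1 + #{b : |U*_jb| >= |U_j|}) / (B + 1)``, ties counted as
    extreme.  All columns share the permutation ensemble.
    """
    if sided != "two_sided":
        raise ValidationError("only two_sided p-values are supported")
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != null.n:
        raise ValidationError("abundance rows do not match sample count")
    # Column-centering leaves U unchanged in exact arithmetic (residuals sum
    # to zero with an intercept) but makes ties for constant columns exact.
    Zc = Z - Z.mean(axis=0)
    u = np.abs(null.residuals @ Zc)
    u_star = np.abs(permuted_residuals(null, perms) @ Zc)
    # ties counted as extreme, at a tolerance relative to the statistic's
    # natural magnitude so float noise cannot break exact-arithmetic ties
    tol = 1e-12 * (np.abs(null.residuals) @ np.abs(Z))
    return (1 + (u_star >= u - tol).sum(axis=0)) / (perms.B + 1)
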