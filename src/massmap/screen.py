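"""Group-level association tests at the screening rank.

Implements the adaptive sum-of-powered-score test (aSPU), kernel
quadratic-form tests over ecological/phylogenetic distances (an OMiRKAT-style
omnibus), their minP combination (OMiAT) and the shared-coefficient
aggregated test.

All components are calibrated against one shared permutation ensemble.  The
minP combination uses a single-layer scheme: every component statistic is
converted to a p-value against the ensemble, each permutation's own
component statistics are ranked within the ensemble, and the observed
minimum p-value is then ranked against the permutation minima.  With a
single component this reduces exactly to that component's permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .data import AbundanceMatrix, PhyloTree, TaxonomyMap, TraitData, ValidationError
from .score import NullFit, PermutationSet, fit_null, permutation_pvalues, permuted_residuals

GAMMA_DEFAULT = (1, 2, 3, 4, 5, 6, 7, 8, np.inf)
KERNELS_DEFAULT = ("bray_curtis",)
KERNELS_WITH_TREE = (
    "bray_curtis",
    "unifrac_unweighted",
    "unifrac_weighted",
    "unifrac_generalized_0.5",
)


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SPU statistics
# ---------------------------------------------------------------------------


def spu_statistics(U: np.ndarray, gammas=GAMMA_DEFAULT) -> dict:
    """Powered-sum statistics T(gamma) = sum_j U_j^gamma; T(inf) = max |U_j|."""
    gammas = tuple(gammas)
    if not gammas:
        raise ValidationError("empty gamma set")
    U = np.asarray(U, dtype=float).ravel()
    if U.size < 1:
        raise ValidationError("score vector must have at least one entry")
    out = {}
    for g in gammas:
        if np.isinf(g):
            out[g] = float(np.abs(U).max())
        else:
            out[g] = float(np.sum(U ** g))
    return out


def _spu_matrix(scores: np.ndarray, gammas) -> np.ndarray:
    """Rows of scores (m,) -> columns of powered-sum statistics (one per gamma)."""
    cols = []
    for g in gammas:
        if np.isinf(g):
            cols.append(np.abs(scores).max(axis=1))
        else:
            cols.append(np.sum(scores ** g, axis=1))
    return np.column_stack(cols)


def _gamma_tails(gammas) -> list:
    # odd finite powers keep sign -> two-sided on |T|; even powers and the
    # max statistic are nonnegative-leaning -> upper tail
    tails = []
    for g in gammas:
        if np.isinf(g) or int(g) % 2 == 0:
            tails.append("upper")
        else:
            tails.append("two_sided")
    return tails


# ---------------------------------------------------------------------------
# Shared minP machinery
# ---------------------------------------------------------------------------


def _tail_pvalues(t_obs: np.ndarray, t_perm: np.ndarray, tails, scale=None) -> tuple:
    """Component p-values for observed statistics and for each permutation.

    Observed: (1 + #extreme)/(B + 1), ties counted as extreme at a tolerance
    of 1e-12 relative to ``scale`` (the statistic's natural magnitude).
    Per-permutation: the fraction of the ensemble at least as extreme, used
    only for minP ranking.
    """
    B = t_perm.shape[0]
    t_obs = np.array(t_obs, dtype=float)
    t_perm = np.array(t_perm, dtype=float)
    for c, tail in enumerate(tails):
        if tail == "two_sided":
            t_obs[c] = abs(t_obs[c])
            t_perm[:, c] = np.abs(t_perm[:, c])
    tol = 0.0 if scale is None else 1e-12 * np.abs(np.asarray(scale, dtype=float))
    p_obs = (1 + (t_perm >= t_obs - tol).sum(axis=0)) / (B + 1)
    # count of ensemble values >= each permutation's own value
    ranks = rankdata(t_perm, axis=0, method="min")
    p_perm = (B - ranks + 1) / B
    return p_obs, p_perm


@dataclass
class _MinPResult:
    p: float                      # permutation p-value of the minP statistic
    component_p: dict             # name -> observed component p-value
    statistics: dict              # name -> observed component statistic
    perm_p: np.ndarray            # (B,) per-permutation p analog for nesting


def _minp_layer(p_obs: np.ndarray, p_perm: np.ndarray) -> tuple:
    B = p_perm.shape[0]
    m_obs = p_obs.min()
    m_perm = p_perm.min(axis=1)
    p = (1 + (m_perm <= m_obs).sum()) / (B + 1)
    perm_p = rankdata(m_perm, method="max") / B
    return float(p), perm_p


def _scores(null: NullFit, Zg: np.ndarray, perms: PermutationSet) -> tuple:
    Zg = np.asarray(Zg, dtype=float)
    if Zg.ndim == 1:
        Zg = Zg[:, None]
    if Zg.shape[0] != null.n:
        raise ValidationError("group abundance rows do not match sample count")
    # centered columns: identical scores in exact arithmetic, exact ties for
    # constant columns (see permutation_pvalues)
    Zc = Zg - Zg.mean(axis=0)
    U = null.residuals @ Zc
    U_star = permuted_residuals(null, perms) @ Zc
    return U, U_star


def _aspu_internal(
    null: NullFit,
    Zg: np.ndarray,
    perms: PermutationSet,
    gammas=GAMMA_DEFAULT,
    standardize: bool = True,
) -> _MinPResult:
    gammas = tuple(gammas)
    if not gammas:
        raise ValidationError("empty gamma set")
    Zg = np.asarray(Zg, dtype=float)
    if Zg.ndim == 1:
        Zg = Zg[:, None]
    U, U_star = _scores(null, Zg, perms)
    # tie tolerance scale from the raw data magnitude (a constant column has
    # near-zero scores but O(1) natural scale)
    u_scale = np.abs(null.residuals) @ np.abs(Zg)
    if standardize:
        sd = U_star.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        U = U / sd
        U_star = U_star / sd
        u_scale = u_scale / sd
    t_obs = _spu_matrix(U[None, :], gammas)[0]
    t_perm = _spu_matrix(U_star, gammas)
    t_scale = _spu_matrix(u_scale[None, :], gammas)[0]
    p_obs, p_perm = _tail_pvalues(t_obs, t_perm, _gamma_tails(gammas), scale=t_scale)
    p, perm_p = _minp_layer(p_obs, p_perm)
    names = [f"spu_{g}" for g in gammas]
    return _MinPResult(
        p=p,
        component_p=dict(zip(names, p_obs)),
        statistics=dict(zip(names, t_obs)),
        perm_p=perm_p,
    )


def aspu_test(
    null: NullFit,
    Zg: np.ndarray,
    perms: PermutationSet,
    gammas=GAMMA_DEFAULT,
    standardize: bool = True,
) -> float:
    """Adaptive SPU p-value: permutation p of the minimum per-gamma p."""
    return _aspu_internal(null, Zg, perms, gammas, standardize).p


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


def _bray_curtis(Z: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(Z, metric="braycurtis"))
    D[np.isnan(D)] = 0.0  # pairs of all-zero samples
    return D


def _unifrac(Z: np.ndarray, lengths: np.ndarray, inc: np.ndarray, kind: str) -> np.ndarray:
    """Pairwise UniFrac family distances from per-branch abundance profiles."""
    N = Z.shape[0]
    D = np.zeros((N, N))
    if inc.shape[0] == 0:  # no branches (single-taxon group): no variation
        return D
    P = Z @ inc.T  # (N, E) abundance descending from each branch
    if kind == "unweighted":
        A = (P > 0).astype(float)
        for i in range(N - 1):
            diff = np.abs(A[i] - A[i + 1:])
            union = np.maximum(A[i], A[i + 1:])
            num = diff @ lengths
            den = union @ lengths
            d = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
            D[i, i + 1:] = D[i + 1:, i] = d
        return D
    alpha = 1.0 if kind == "weighted" else float(kind.split("_")[-1])
    for i in range(N - 1):
        s = P[i] + P[i + 1:]
        diff = np.abs(P[i] - P[i + 1:])
        ratio = np.divide(diff, s, out=np.zeros_like(diff), where=s > 0)
        w = np.where(s > 0, s ** alpha, 0.0)
        num = (w * ratio) @ lengths
        den = w @ lengths
        d = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        D[i, i + 1:] = D[i + 1:, i] = d
    return D


def kernel_from_distance(D: np.ndarray) -> np.ndarray:
    """Gower-centered kernel -1/2 J D^2 J with negative eigenvalues clipped."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    K = -0.5 * J @ (D ** 2) @ J
    K = (K + K.T) / 2
    w, V = eigh(K)
    if w.min() < -1e-8 * max(1.0, abs(w).max()):
        # distances far from Euclidean-embeddable; still repair but loudly
        pass
    w = np.clip(w, 0.0, None)
    K = (V * w) @ V.T
    return (K + K.T) / 2


def build_kernels(
    Zg: np.ndarray,
    tree: PhyloTree | None = None,
    kinds=KERNELS_DEFAULT,
    taxon_ids=None,
    renormalize: bool = False,
) -> dict:
    """Named PSD similarity kernels from sample-pair distances over a group.

    UniFrac kinds require ``tree`` and ``taxon_ids`` (column labels of
    ``Zg`` mapping to tree leaves).
    """
    kinds = tuple(kinds)
    if not kinds:
        raise ValidationError("empty kernel kind list")
    Zg = np.asarray(Zg, dtype=float)
    if Zg.ndim == 1:
        Zg = Zg[:, None]
    if renormalize:
        sums = Zg.sum(axis=1, keepdims=True)
        Zg = np.divide(Zg, sums, out=np.zeros_like(Zg), where=sums > 0)
    branch = None
    kernels = {}
    for kind in kinds:
        if kind == "bray_curtis":
            D = _bray_curtis(Zg)
        elif kind.startswith("unifrac_"):
            if tree is None:
                raise ConfigurationError(f"kernel {kind!r} requires a phylogenetic tree")
            if taxon_ids is None:
                raise ConfigurationError(f"kernel {kind!r} requires taxon_ids for Zg columns")
            if branch is None:
                branch = tree.branch_matrix(list(taxon_ids))
            D = _unifrac(Zg, *branch, kind=kind.removeprefix("unifrac_"))
        else:
            raise ConfigurationError(f"unknown kernel kind {kind!r}")
        kernels[kind] = kernel_from_distance(D)
    return kernels


def kernel_statistic(null: NullFit, K: np.ndarray) -> float:
    """Variance-component quadratic form r' K r."""
    K = np.asarray(K, dtype=float)
    if K.shape != (null.n, null.n):
        raise ValidationError("kernel dimensions do not match sample count")
    r = null.residuals
    return float(r @ K @ r)


def _omirkat_internal(null: NullFit, kernels: dict, perms: PermutationSet) -> _MinPResult:
    if not kernels:
        raise ValidationError("empty kernel set")
    Rp = permuted_residuals(null, perms)
    names = list(kernels)
    q_obs = np.array([kernel_statistic(null, kernels[k]) for k in names])
    q_perm = np.column_stack([((Rp @ kernels[k]) * Rp).sum(axis=1) for k in names])
    r_abs = np.abs(null.residuals)
    q_scale = np.array([r_abs @ np.abs(kernels[k]) @ r_abs for k in names])
    p_obs, p_perm = _tail_pvalues(q_obs, q_perm, ["upper"] * len(names), scale=q_scale)
    p, perm_p = _minp_layer(p_obs, p_perm)
    return _MinPResult(
        p=p,
        component_p=dict(zip(names, p_obs)),
        statistics=dict(zip(names, q_obs)),
        perm_p=perm_p,
    )


def omirkat_test(null: NullFit, kernels: dict, perms: PermutationSet) -> float:
    """minP over kernel quadratic-form permutation p-values."""
    return _omirkat_internal(null, kernels, perms).p


# ---------------------------------------------------------------------------
# OMiAT and the aggregated test
# ---------------------------------------------------------------------------


def _omiat_internal(
    null: NullFit,
    Zg: np.ndarray,
    perms: PermutationSet,
    tree: PhyloTree | None = None,
    gammas=GAMMA_DEFAULT,
    kinds=KERNELS_DEFAULT,
    taxon_ids=None,
    standardize: bool = True,
    renormalize: bool = False,
) -> _MinPResult:
    parts = []
    component_p: dict = {}
    statistics: dict = {}
    if gammas:
        a = _aspu_internal(null, Zg, perms, gammas, standardize)
        parts.append(("aspu", a))
    if kinds:
        kernels = build_kernels(Zg, tree, kinds, taxon_ids, renormalize)
        parts.append(("omirkat", _omirkat_internal(null, kernels, perms)))
    if not parts:
        raise ValidationError("OMiAT needs at least one component (gammas or kernels)")
    for name, res in parts:
        component_p[name] = res.p
        component_p.update(res.component_p)
        statistics.update(res.statistics)
    p_obs = np.array([res.p for _, res in parts])
    p_perm = np.column_stack([res.perm_p for _, res in parts])
    p, perm_p = _minp_layer(p_obs, p_perm)
    return _MinPResult(p=p, component_p=component_p, statistics=statistics, perm_p=perm_p)


def omiat_test(
    null: NullFit,
    Zg: np.ndarray,
    perms: PermutationSet,
    tree: PhyloTree | None = None,
    gammas=GAMMA_DEFAULT,
    kinds=KERNELS_DEFAULT,
    taxon_ids=None,
    standardize: bool = True,
    renormalize: bool = False,
) -> float:
    """Omnibus group p-value: minP of the aSPU and kernel components."""
    return _omiat_internal(
        null, Zg, perms, tree, gammas, kinds, taxon_ids, standardize, renormalize
    ).p


def aggregated_test(null: NullFit, Zg: np.ndarray, perms: PermutationSet) -> float:
    """Shared-coefficient test: sum group columns, then the score test."""
    Zg = np.asarray(Zg, dtype=float)
    if Zg.ndim == 1:
        Zg = Zg[:, None]
    return float(permutation_pvalues(null, Zg.sum(axis=1), perms)[0])


# ---------------------------------------------------------------------------
# Rank-level screening
# ---------------------------------------------------------------------------


@dataclass
class GroupScreenResult:
    """Raw group p-values at the screening rank with per-component traces."""

    group_ids: list
    group_members: list          # list of member taxon-id lists, same order
    p_values: np.ndarray
    component_pvalues: list      # per group: component name -> p
    statistic_trace: list        # per group: component name -> observed stat
    method: str


def screen_rank(
    ab: AbundanceMatrix,
    tax: TaxonomyMap,
    trait: TraitData | None,
    rank: str,
    perms: PermutationSet,
    method: str = "omiat",
    tree: PhyloTree | None = None,
    null: NullFit | None = None,
    target_rank: str = "species",
    gammas=GAMMA_DEFAULT,
    kinds=KERNELS_DEFAULT,
    standardize: bool = True,
    renormalize: bool = False,
    pool_unassigned: bool = False,
) -> GroupScreenResult:
    """Apply the chosen group test to every group at ``rank``."""
    from .data import rank_index

    if rank_index(rank) >= rank_index(target_rank):
        raise ConfigurationError(
            f"screening rank {rank!r} must be above target rank {target_rank!r}"
        )
    if null is None:
        if trait is None:
            raise ValidationError("either a TraitData or a NullFit must be supplied")
        null = fit_null(trait)
    groups = tax.partition(rank, taxa=ab.taxon_ids, pool_unassigned=pool_unassigned)
    group_ids, members, pvals, comp_ps, traces = [], [], [], [], []
    for gid, taxa in groups.items():
        Zg = ab.values[:, [ab.taxon_ids.index(t) for t in taxa]]
        if method == "omiat":
            res = _omiat_internal(
                null, Zg, perms, tree, gammas, kinds, taxa, standardize, renormalize
            )
            p, comp, stat = res.p, res.component_p, res.statistics
        elif method == "aggregated":
            p = aggregated_test(null, Zg, perms)
            comp, stat = {"aggregated": p}, {"aggregated": score_sum(null, Zg)}
        else:
            raise ConfigurationError(f"unknown screening method {method!r}")
        group_ids.append(gid)
        members.append(list(taxa))
        pvals.append(p)
        comp_ps.append(comp)
        traces.append(stat)
    return GroupScreenResult(
        group_ids=group_ids,
        group_members=members,
        p_values=np.asarray(pvals),
        component_pvalues=comp_ps,
        statistic_trace=traces,
        method=method,
    )


def score_sum(null: NullFit, Zg: np.ndarray) -> float:
    """Observed aggregated score statistic (residuals . row-sums of Zg)."""
    return float(null.residuals @ np.asarray(Zg, dtype=float).sum(axis=1))
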