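"""Synthetic benchmark: Dirichlet-multinomial abundance, medoid-clustered
signal assignment, trait generation and empirical FDR/TPR/ROC evaluation.

The shipped benchmark data (taxonomy, tree, proportion means) are generated
deterministically from a frozen internal seed, so every stage is testable
without downloads; users with real data can pass their own parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import PhyloTree, TaxonomyMap, TraitData, ValidationError, RANKS
from .fdr import HypothesisTree, hbh, one_stage_bh, sst
from .score import PermutationSet, fit_null, permutation_pvalues
from .screen import GAMMA_DEFAULT, _omiat_internal, aggregated_test

logger = logging.getLogger(__name__)

_FROZEN_SEED = 20180725  # seed of the versioned benchmark fixture


@dataclass
class DMParams:
    """Dirichlet-multinomial parameters for count generation."""

    pi: np.ndarray
    theta: float = 0.01
    reads_per_sample: int = 15_000

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi <= 0):
            raise ValidationError("pi must be strictly positive")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValidationError("pi must sum to 1")
        if not 0 <= self.theta < 1:
            raise ValidationError("theta must lie in [0, 1)")

    @property
    def n_taxa(self) -> int:
        return len(self.pi)


@dataclass
class SimulationTruth:
    """Ground truth of one replicate: which taxa carry signal, and how."""

    lambda_indices: np.ndarray
    lambda_ids: list
    beta: np.ndarray
    scenario: str                # same_direction | mixed_direction
    effect_high: float = 2.0
    pam_k: int = 10

    def __post_init__(self):
        self.lambda_indices = np.asarray(self.lambda_indices, dtype=int)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.lambda_indices.size < 1:
            raise ValidationError("at least one associated taxon required")
        if self.scenario == "same_direction" and np.any(self.beta < 0):
            raise ValidationError("same-direction scenario requires nonnegative effects")


@dataclass
class Benchmark:
    """A self-contained simulation universe: DM parameters, taxonomy, tree."""

    params: DMParams
    taxonomy: TaxonomyMap
    tree: PhyloTree
    taxon_ids: list


# ---------------------------------------------------------------------------
# Frozen benchmark fixture
# ---------------------------------------------------------------------------


def _nested_counts(n_leaves: int, targets: Sequence[int], rng) -> list:
    """Random nested partition sizes for each rank (phylum..genus)."""
    levels = []
    for t in targets:
        t = min(max(2, t), n_leaves)
        levels.append(t)
    return levels


def _random_split(items: list, k: int, rng) -> list:
    """Split items into k non-empty contiguous chunks at random cut points."""
    n = len(items)
    k = min(k, n)
    if k == 1:
        return [items]
    cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
    bounds = [0, *cuts.tolist(), n]
    return [items[bounds[i]:bounds[i + 1]] for i in range(k)]


def default_benchmark(
    n_taxa: int = 174,
    theta: float = 0.01,
    reads_per_sample: int = 15_000,
    seed: int = _FROZEN_SEED,
) -> Benchmark:
    """Deterministic benchmark with a 7-rank taxonomy (~5 phyla -> ~30
    families at the reference size), a congruent random tree with branch
    lengths, and long-tailed stick-breaking proportion means."""
    rng = np.random.default_rng(seed)
    taxon_ids = [f"otu{i + 1:04d}" for i in range(n_taxa)]

    # nested taxonomy, target widths scaled from the reference 174-leaf layout
    scale = n_taxa / 174
    widths = [max(2, round(w * scale)) for w in (5, 8, 15, 30, 60)]
    lineage = {t: ["Bacteria"] for t in taxon_ids}
    chunks = [list(taxon_ids)]
    label_count = 0
    rank_letters = ["P", "C", "O", "F", "G"]
    for level, width in enumerate(widths):
        new_chunks = []
        # distribute the target number of groups over current chunks
        extra = width - len(chunks)
        per_chunk = [1] * len(chunks)
        big = sorted(range(len(chunks)), key=lambda i: -len(chunks[i]))
        i = 0
        while extra > 0:
            c = big[i % len(big)]
            if per_chunk[c] < len(chunks[c]):
                per_chunk[c] += 1
                extra -= 1
            i += 1
            if i > 10 * width:
                break
        for chunk, k in zip(chunks, per_chunk):
            for part in _random_split(chunk, k, rng):
                label_count += 1
                name = f"{rank_letters[level]}{label_count:03d}"
                for t in part:
                    lineage[t].append(name)
                new_chunks.append(part)
        chunks = new_chunks
    for i, t in enumerate(taxon_ids):
        lineage[t].append(f"S{i + 1:04d}")
    taxonomy = TaxonomyMap({t: tuple(v) for t, v in lineage.items()})

    # tree congruent with the taxonomy: nest newick groups genus-up
    def newick_for(taxa: list, rank_i: int) -> str:
        if rank_i == len(RANKS) - 1 or len(taxa) == 1:
            return ",".join(
                f"{t}:{rng.uniform(0.02, 0.3):.6f}" for t in taxa
            )
        by_child: dict = {}
        for t in taxa:
            by_child.setdefault(lineage[t][rank_i + 1], []).append(t)
        parts = []
        for sub in by_child.values():
            inner = newick_for(sub, rank_i + 1)
            if len(sub) == 1:
                parts.append(inner)
            else:
                parts.append(f"({inner}):{rng.uniform(0.05, 0.5):.6f}")
        return ",".join(parts)

    tree = PhyloTree.from_newick(f"({newick_for(list(taxon_ids), 0)});")

    # long-tailed proportion means via stick breaking; floored at 0.1% to
    # mimic a mean-relative-abundance pre-filter on the retained taxa
    v = rng.beta(1.0, 5.0, size=n_taxa)
    remaining = np.concatenate([[1.0], np.cumprod(1 - v[:-1])])
    pi = v * remaining
    pi = np.maximum(pi, 1e-3)
    rng.shuffle(pi)
    pi = pi / pi.sum()

    params = DMParams(pi=pi, theta=theta, reads_per_sample=reads_per_sample)
    return Benchmark(params=params, taxonomy=taxonomy, tree=tree, taxon_ids=taxon_ids)


# ---------------------------------------------------------------------------
# DM sampling
# ---------------------------------------------------------------------------


def sample_dm_counts(params: DMParams, n_samples: int, seed: int | None = None) -> np.ndarray:
    """Counts with per-sample total exactly ``reads_per_sample``.

    Proportions are drawn from Dirichlet(pi (1 - theta) / theta) and then a
    multinomial; theta = 0 short-circuits to a plain multinomial.
    """
    rng = np.random.default_rng(seed)
    n_reads = params.reads_per_sample
    if params.theta == 0:
        return rng.multinomial(n_reads, params.pi, size=n_samples)
    alpha = params.pi * (1 - params.theta) / params.theta
    out = np.empty((n_samples, params.n_taxa), dtype=np.int64)
    for i in range(n_samples):
        out[i] = rng.multinomial(n_reads, rng.dirichlet(alpha))
    return out


# ---------------------------------------------------------------------------
# PAM clustering
# ---------------------------------------------------------------------------


def pam_cluster(D: np.ndarray, k: int, seed: int | None = None) -> tuple:
    """Partitioning around medoids (BUILD + SWAP) on a distance matrix.

    Fully deterministic: ties are broken by lowest index, so ``seed`` is
    accepted only for interface stability.  Tiny instances (<= 2000 medoid
    subsets) are solved exactly by enumeration, since greedy SWAP can stall
    in a local optimum there.  Returns (labels, medoids).
    """
    import math
    from itertools import combinations

    D = np.asarray(D, dtype=float)
    M = D.shape[0]
    if D.shape != (M, M):
        raise ValidationError("distance matrix must be square")
    if k < 1 or k > M:
        raise ValidationError("k must lie in 1..M")
    if k == M:
        return np.arange(M), np.arange(M)
    if math.comb(M, k) <= 2000:
        best_cost, best = np.inf, None
        for combo in combinations(range(M), k):
            cost = D[:, combo].min(axis=1).sum()
            if cost < best_cost - 1e-15:
                best_cost, best = cost, combo
        medoids = np.asarray(best)
        return np.argmin(D[:, medoids], axis=1), medoids

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP: repeat best improving (medoid, candidate) swap until none helps
    medoids = sorted(medoids)
    while True:
        dist_med = D[:, medoids]
        order = np.argsort(dist_med, axis=1)
        d1 = dist_med[np.arange(M), order[:, 0]]
        nearest = order[:, 0]
        d2 = dist_med[np.arange(M), order[:, 1]] if k > 1 else np.full(M, np.inf)
        cost = d1.sum()
        best = (0.0, None, None)
        non_med = np.setdiff1d(np.arange(M), medoids)
        for mi in range(k):
            base = np.where(nearest == mi, d2, d1)
            new_costs = np.minimum(base[:, None], D[:, non_med]).sum(axis=0)
            j = int(np.argmin(new_costs))
            delta = new_costs[j] - cost
            if delta < best[0] - 1e-12:
                best = (delta, mi, int(non_med[j]))
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)
    medoids = np.asarray(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids


def assign_associated(
    tree: PhyloTree | np.ndarray,
    n_assoc: int,
    pam_k: int = 10,
    seed: int | None = None,
    taxon_ids: Sequence | None = None,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Pick ``n_assoc`` phylogenetically clustered taxon indices.

    Medoid-clusters the cophenetic distances into ``pam_k`` groups, draws two
    groups at random, keeps drawing without replacement while the pooled size
    is below ``n_assoc``, then samples ``n_assoc`` members uniformly from the
    pool.  ``tree`` may be a PhyloTree (with ``taxon_ids`` giving column
    order) or a precomputed distance matrix; precomputed ``labels`` skip the
    clustering step.
    """
    if labels is None:
        if isinstance(tree, PhyloTree):
            D = tree.cophenetic(taxon_ids)
        else:
            D = np.asarray(tree, dtype=float)
        labels, _ = pam_cluster(D, pam_k)
    labels = np.asarray(labels)
    M = labels.size
    if n_assoc > M:
        raise ValidationError("n_assoc exceeds the number of taxa")
    rng = np.random.default_rng(seed)
    group_order = rng.permutation(np.unique(labels))
    pool: list = []
    taken = 0
    for g in group_order:
        pool.extend(np.flatnonzero(labels == g).tolist())
        taken += 1
        if taken >= 2 and len(pool) >= n_assoc:
            break
    return np.sort(rng.choice(np.asarray(pool), size=n_assoc, replace=False))


# ---------------------------------------------------------------------------
# Trait generation
# ---------------------------------------------------------------------------


def generate_trait(
    Z: np.ndarray,
    truth: SimulationTruth,
    trait_type: str = "binary",
    seed: int | None = None,
) -> TraitData:
    """Trait from the standardized abundances of the associated taxa.

    Continuous: Y = sum_j beta_j scale(Z_j) + N(0,1) noise; binary: Bernoulli
    with logit equal to the same linear predictor.  Zero-variance associated
    columns are dropped (logged).
    """
    rng = np.random.default_rng(seed)
    Z = np.asarray(Z, dtype=float)
    idx = truth.lambda_indices
    cols = Z[:, idx]
    sd = cols.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        logger.warning("dropping %d zero-variance associated columns", (~keep).sum())
    if not np.any(keep):
        raise ValidationError("all associated columns have zero variance")
    scaled = (cols[:, keep] - cols[:, keep].mean(axis=0)) / sd[keep]
    eta = scaled @ truth.beta[keep]
    if trait_type == "continuous":
        y = eta + rng.standard_normal(len(eta))
    elif trait_type == "binary":
        from scipy.special import expit

        y = rng.binomial(1, expit(eta)).astype(float)
    else:
        raise ValidationError(f"unknown trait_type {trait_type!r}")
    return TraitData(y=y, X=np.empty((len(y), 0)), trait_type=trait_type)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_replicate(result, truth: SimulationTruth) -> tuple:
    """(false discovery proportion, true positive rate) for one replicate.

    ``result`` may be a MassMapResult, an FdrOutcome, or an iterable of
    rejected taxon ids.  FDP is 0 when nothing is rejected.
    """
    if hasattr(result, "fdr"):
        rejected = set(result.fdr.rejected_taxa)
    elif hasattr(result, "rejected_taxa"):
        rejected = set(result.rejected_taxa)
    else:
        rejected = set(result)
    lam = set(truth.lambda_ids)
    n_rej = len(rejected)
    fdp = len(rejected - lam) / max(n_rej, 1)
    tpr = len(rejected & lam) / len(lam)
    return fdp, tpr


def group_truth(group_members: list, lambda_ids: Sequence) -> np.ndarray:
    """A group is truly associated iff it contains >= 1 associated taxon."""
    lam = set(lambda_ids)
    return np.array([bool(lam & set(m)) for m in group_members])


# ---------------------------------------------------------------------------
# Benchmark loop
# ---------------------------------------------------------------------------

PRESETS = {
    "scenario1_small": dict(scenario="same_direction", effect_high=2.0),
    "scenario1_modest": dict(scenario="same_direction", effect_high=3.0),
    "scenario1_large": dict(scenario="same_direction", effect_high=4.0),
    "scenario2_small": dict(scenario="mixed_direction", effect_high=2.0),
    "scenario2_modest": dict(scenario="mixed_direction", effect_high=3.0),
    "scenario2_large": dict(scenario="mixed_direction", effect_high=4.0),
    "sensitivity_5pct": dict(scenario="same_direction", effect_high=3.0, frac_assoc=0.05),
    "sensitivity_pam50": dict(scenario="same_direction", effect_high=3.0, pam_k=50),
}


def run_benchmark(
    n_reps: int = 10,
    seed: int = 0,
    scenario: str = "same_direction",
    effect_high: float = 2.0,
    trait_type: str = "binary",
    methods: Sequence[str] = ("bh", "omiat_hbh", "omiat_sst", "agg_hbh", "agg_sst"),
    screening_rank: str = "family",
    n_taxa: int = 174,
    n_samples: int = 200,
    n_permutations: int = 999,
    q: float = 0.05,
    frac_assoc: float = 0.1,
    pam_k: int = 10,
    theta: float = 0.01,
    reads_per_sample: int = 15_000,
    gammas=GAMMA_DEFAULT,
    kinds=("bray_curtis",),
    benchmark: Benchmark | None = None,
    strict: bool = True,
) -> tuple:
    """Monte-Carlo benchmark over replicates.

    ``methods`` entries: ``bh`` (one-stage), ``omiat_hbh``, ``omiat_sst``,
    ``agg_hbh``, ``agg_sst``, plus screening-only entries ``omiat``/``agg``
    which contribute AUC but no target-rank testing.

    Returns ``(summary DataFrame, detail dict)``; the detail dict maps
    method -> per-replicate arrays of fdp / tpr / auc.
    """
    if benchmark is None:
        benchmark = default_benchmark(n_taxa=n_taxa, theta=theta, reads_per_sample=reads_per_sample)
    bench = benchmark
    M = len(bench.taxon_ids)
    n_assoc = max(1, round(frac_assoc * M))
    D_coph = bench.tree.cophenetic(bench.taxon_ids)
    pam_labels, _ = pam_cluster(D_coph, pam_k)
    groups = bench.taxonomy.partition(screening_rank, taxa=bench.taxon_ids)
    group_ids = list(groups)
    members = [groups[g] for g in group_ids]
    member_idx = [[bench.taxon_ids.index(t) for t in m] for m in members]

    need_screen_omiat = any(m.startswith("omiat") for m in methods)
    need_screen_agg = any(m.startswith("agg") for m in methods)
    need_target = any(m in ("bh", "omiat_hbh", "omiat_sst", "agg_hbh", "agg_sst") for m in methods)

    master = np.random.SeedSequence(seed)
    child_seeds = master.spawn(n_reps)
    detail: dict = {m: {"fdp": [], "tpr": [], "auc": []} for m in methods}

    from sklearn.metrics import roc_auc_score

    for rep in range(n_reps):
        ss = child_seeds[rep]
        s_counts, s_lambda, s_beta, s_trait, s_perm = ss.generate_state(5).tolist()
        counts = sample_dm_counts(bench.params, n_samples, seed=s_counts)
        Z = counts / bench.params.reads_per_sample
        lam_idx = assign_associated(
            D_coph, n_assoc, pam_k=pam_k, seed=s_lambda, labels=pam_labels
        )
        rng_beta = np.random.default_rng(s_beta)
        if scenario == "same_direction":
            beta = rng_beta.uniform(0, effect_high, size=n_assoc)
        elif scenario == "mixed_direction":
            beta = rng_beta.uniform(-effect_high, effect_high, size=n_assoc)
        else:
            raise ValidationError(f"unknown scenario {scenario!r}")
        truth = SimulationTruth(
            lambda_indices=lam_idx,
            lambda_ids=[bench.taxon_ids[i] for i in lam_idx],
            beta=beta,
            scenario=scenario,
            effect_high=effect_high,
            pam_k=pam_k,
        )
        # redraw a degenerate binary trait (all one class) with shifted seeds
        for attempt in range(20):
            try:
                trait = generate_trait(Z, truth, trait_type, seed=s_trait + attempt)
                break
            except ValidationError:
                continue
        else:
            raise ValidationError("could not generate a non-degenerate trait")
        null = fit_null(trait)
        perms = PermutationSet.generate(n_samples, n_permutations, seed=s_perm)

        p_taxa = permutation_pvalues(null, Z, perms) if need_target else None
        g_true = group_truth(members, truth.lambda_ids)

        screen_p: dict = {}
        if need_screen_omiat:
            screen_p["omiat"] = np.array(
                [
                    _omiat_internal(
                        null, Z[:, idx], perms, bench.tree, gammas, kinds,
                        [bench.taxon_ids[i] for i in idx],
                    ).p
                    for idx in member_idx
                ]
            )
        if need_screen_agg:
            screen_p["agg"] = np.array(
                [aggregated_test(null, Z[:, idx], perms) for idx in member_idx]
            )

        for method in methods:
            if method == "bh":
                out = one_stage_bh(p_taxa, q, ids=bench.taxon_ids, strict=strict)
                fdp, tpr = evaluate_replicate(out, truth)
                detail[method]["fdp"].append(fdp)
                detail[method]["tpr"].append(tpr)
                detail[method]["auc"].append(np.nan)
                continue
            screen_key = "omiat" if method.startswith("omiat") else "agg"
            pv = screen_p[screen_key]
            auc = (
                roc_auc_score(g_true, -pv)
                if 0 < g_true.sum() < len(g_true)
                else np.nan
            )
            detail[method]["auc"].append(auc)
            if method in ("omiat", "agg"):
                continue
            tree_h = HypothesisTree(
                group_ids=group_ids,
                screening_pvalues=pv,
                target_ids=members,
                target_pvalues=[p_taxa[idx] for idx in member_idx],
            )
            proc = hbh if method.endswith("hbh") else sst
            out = proc(tree_h, q, strict=strict)
            fdp, tpr = evaluate_replicate(out, truth)
            detail[method]["fdp"].append(fdp)
            detail[method]["tpr"].append(tpr)

    rows = []
    for method in methods:
        d = detail[method]
        auc = np.asarray(d["auc"], dtype=float)
        rows.append(
            {
                "method": method,
                "scenario": scenario,
                "effect": effect_high,
                "screen_rank": screening_rank,
                "fdr": float(np.mean(d["fdp"])) if d["fdp"] else np.nan,
                "tpr": float(np.mean(d["tpr"])) if d["tpr"] else np.nan,
                "auc": float(np.nanmean(auc)) if auc.size and not np.all(np.isnan(auc)) else np.nan,
                "n_reps": n_reps,
            }
        )
        for key in d:
            d[key] = np.asarray(d[key], dtype=float)
    return pd.DataFrame(rows), detail
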