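import itertools

import numpy as np
import pytest

from massmap.data import PhyloTree, TraitData, ValidationError
from massmap.score import PermutationSet, fit_null, permutation_pvalues
from massmap.screen import (
    ConfigurationError,
    aggregated_test,
    aspu_test,
    build_kernels,
    kernel_from_distance,
    kernel_statistic,
    omiat_test,
    omirkat_test,
    screen_rank,
    spu_statistics,
)


@pytest.fixture
def small_null(rng):
    n = 16
    y = rng.normal(size=n)
    trait = TraitData(y=y, X=np.empty((n, 0)), trait_type="continuous")
    return fit_null(trait)


@pytest.fixture
def small_perms(small_null):
    return PermutationSet.generate(small_null.n, 499, seed=11)


class TestSpuStatistics:
    def test_direct_arithmetic(self):
        stats = spu_statistics([1.0, -2.0], gammas=(1, 2, np.inf))
        assert stats[1] == pytest.approx(-1.0)
        assert stats[2] == pytest.approx(5.0)
        assert stats[np.inf] == pytest.approx(2.0)

    def test_all_zero(self):
        stats = spu_statistics(np.zeros(4))
        assert all(v == 0 for v in stats.values())

    def test_loop_oracle(self, rng):
        u = rng.normal(size=10)
        stats = spu_statistics(u, gammas=(3,))
        expected = sum(x**3 for x in u)
        assert stats[3] == pytest.approx(expected)

    def test_empty_gamma_set(self):
        with pytest.raises(ValidationError):
            spu_statistics([1.0], gammas=())


class TestAspu:
    def test_single_gamma_equals_permutation_p(self, rng, small_null, small_perms):
        # gamma=1: T is the plain score-sum, two-sided; must equal the
        # aggregated (sum of columns) permutation p exactly
        Zg = rng.uniform(size=(small_null.n, 3))
        p_aspu = aspu_test(small_null, Zg, small_perms, gammas=(1,), standardize=False)
        p_agg = aggregated_test(small_null, Zg, small_perms)
        assert p_aspu == pytest.approx(p_agg)

    def test_single_member_exhaustive(self, rng):
        # m_g = 1, gamma=1: aSPU is the single-taxon score test; verify
        # against full enumeration at N=4
        n = 4
        y = rng.normal(size=n)
        trait = TraitData(y=y, X=np.empty((n, 0)), trait_type="continuous")
        null = fit_null(trait)
        z = rng.uniform(size=(n, 1))
        perms = PermutationSet(np.array(list(itertools.permutations(range(n)))))
        p = aspu_test(null, z, perms, gammas=(1,))
        assert p == pytest.approx(permutation_pvalues(null, z, perms)[0])

    def test_constant_group_gives_one(self, small_null, small_perms):
        Zg = np.full((small_null.n, 3), 0.1)
        assert aspu_test(small_null, Zg, small_perms) == pytest.approx(1.0)

    def test_p_within_bounds(self, rng, small_null, small_perms):
        Zg = rng.uniform(size=(small_null.n, 4))
        p = aspu_test(small_null, Zg, small_perms)
        assert 1 / (small_perms.B + 1) <= p <= 1.0


class TestKernels:
    def test_identical_samples_zero_distance(self, small_null):
        Z = np.tile([0.2, 0.3, 0.5], (4, 1))
        K = build_kernels(Z, kinds=("bray_curtis",))["bray_curtis"]
        assert np.allclose(K, 0.0, atol=1e-12)

    def test_bray_curtis_disjoint_support(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        from massmap.screen import _bray_curtis

        assert _bray_curtis(Z)[0, 1] == pytest.approx(1.0)

    def test_weighted_unifrac_manual_oracle(self):
        # 3-leaf tree ((a:1,b:2):0.5,c:3); branches: a=1, b=2, (ab)=0.5, c=3
        tree = PhyloTree.from_newick("((a:1.0,b:2.0):0.5,c:3.0);")
        Z = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, 1.0, 0.0],
                [0.0, 0.0, 1.0],
                [0.5, 0.5, 0.0],
            ]
        )
        from massmap.screen import _unifrac

        lengths, inc = tree.branch_matrix(["a", "b", "c"])
        D = _unifrac(Z, lengths, inc, "weighted")

        def manual(pa, pb):
            # per-branch abundances: a, b, ab-clade, c
            br = [
                (1.0, pa[0], pb[0]),
                (2.0, pa[1], pb[1]),
                (0.5, pa[0] + pa[1], pb[0] + pb[1]),
                (3.0, pa[2], pb[2]),
            ]
            num = sum(l * abs(x - y) for l, x, y in br)
            den = sum(l * (x + y) for l, x, y in br)
            return num / den

        for i in range(4):
            for j in range(4):
                if i != j:
                    assert D[i, j] == pytest.approx(manual(Z[i], Z[j]))

    def test_unweighted_unifrac_presence_only(self):
        tree = PhyloTree.from_newick("((a:1.0,b:2.0):0.5,c:3.0);")
        Z = np.array([[0.9, 0.1, 0.0], [0.5, 0.5, 0.0]])
        from massmap.screen import _unifrac

        lengths, inc = tree.branch_matrix(["a", "b", "c"])
        D = _unifrac(Z, lengths, inc, "unweighted")
        assert D[0, 1] == pytest.approx(0.0)  # same support

    def test_unifrac_requires_tree(self):
        Z = np.random.default_rng(0).uniform(size=(4, 3))
        with pytest.raises(ConfigurationError):
            build_kernels(Z, tree=None, kinds=("unifrac_weighted",))

    def test_kernel_psd_after_repair(self, rng):
        Z = rng.uniform(size=(10, 5))
        for K in build_kernels(Z, kinds=("bray_curtis",)).values():
            w = np.linalg.eigvalsh(K)
            assert w.min() >= -1e-10
            assert np.allclose(K, K.T)

    def test_gower_centering_known_case(self):
        # two points at distance d: kernel eigenvalue d^2/2
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        K = kernel_from_distance(D)
        assert np.allclose(K, [[0.25, -0.25], [-0.25, 0.25]])


class TestKernelStatistic:
    def test_identity_kernel(self, small_null):
        K = np.eye(small_null.n)
        assert kernel_statistic(small_null, K) == pytest.approx(
            np.sum(small_null.residuals**2)
        )

    def test_zero_residuals(self, small_null):
        import dataclasses

        null0 = dataclasses.replace(small_null, residuals=np.zeros(small_null.n))
        assert kernel_statistic(null0, np.eye(small_null.n)) == 0.0

    def test_double_loop_oracle(self, rng, small_null):
        A = rng.normal(size=(small_null.n, small_null.n))
        K = A @ A.T
        r = small_null.residuals
        expected = sum(
            r[i] * K[i, j] * r[j] for i in range(len(r)) for j in range(len(r))
        )
        assert kernel_statistic(small_null, K) == pytest.approx(expected)

    def test_dimension_mismatch(self, small_null):
        with pytest.raises(ValidationError):
            kernel_statistic(small_null, np.eye(3))


class TestOmirkat:
    def test_single_kernel_equality(self, rng, small_null, small_perms):
        Zg = rng.uniform(size=(small_null.n, 3))
        kernels = build_kernels(Zg, kinds=("bray_curtis",))
        p_multi = omirkat_test(small_null, kernels, small_perms)
        # independent single-kernel permutation p
        from massmap.score import permuted_residuals

        K = kernels["bray_curtis"]
        q = small_null.residuals @ K @ small_null.residuals
        Rp = permuted_residuals(small_null, small_perms)
        q_star = ((Rp @ K) * Rp).sum(axis=1)
        expected = (1 + (q_star >= q - 1e-12 * abs(q)).sum()) / (small_perms.B + 1)
        assert p_multi == pytest.approx(expected)

    def test_duplicated_kernel_invariance(self, rng, small_null, small_perms):
        Zg = rng.uniform(size=(small_null.n, 3))
        K = build_kernels(Zg, kinds=("bray_curtis",))["bray_curtis"]
        p1 = omirkat_test(small_null, {"a": K}, small_perms)
        p2 = omirkat_test(small_null, {"a": K, "b": K.copy()}, small_perms)
        assert p1 == pytest.approx(p2)

    def test_empty_kernelset_errors(self, small_null, small_perms):
        with pytest.raises(ValidationError):
            omirkat_test(small_null, {}, small_perms)

    def test_exhaustive_small_n(self, rng):
        n = 4
        y = rng.normal(size=n)
        trait = TraitData(y=y, X=np.empty((n, 0)), trait_type="continuous")
        null = fit_null(trait)
        Zg = rng.uniform(size=(n, 2))
        perms = PermutationSet(np.array(list(itertools.permutations(range(n)))))
        kernels = build_kernels(Zg, kinds=("bray_curtis",))
        p = omirkat_test(null, kernels, perms)
        # enumeration oracle
        K = kernels["bray_curtis"]
        r = null.residuals
        q = r @ K @ r
        count = sum(
            1
            for perm in itertools.permutations(range(n))
            if r[list(perm)] @ K @ r[list(perm)] >= q - 1e-12 * abs(q)
        )
        assert p == pytest.approx((1 + count) / (perms.B + 1))


def _oracle_omiat(null, Zg, perms, gammas, K, standardize=False):
    """Literal nested-loop reimplementation of the single-layer minP scheme."""
    r = null.residuals
    B = perms.B
    Zc = Zg - Zg.mean(axis=0)
    m = Zg.shape[1]

    def spu(scores):
        out = []
        for g in gammas:
            if np.isinf(g):
                out.append(max(abs(s) for s in scores))
            else:
                out.append(sum(s**g for s in scores))
        return out

    obs_scores = [sum(r[i] * Zc[i, j] for i in range(len(r))) for j in range(m)]
    perm_scores = [
        [sum(r[perms.indices[b, i]] * Zc[i, j] for i in range(len(r))) for j in range(m)]
        for b in range(B)
    ]
    if standardize:
        for j in range(m):
            col = [perm_scores[b][j] for b in range(B)]
            mean = sum(col) / B
            sd = (sum((x - mean) ** 2 for x in col) / (B - 1)) ** 0.5 or 1.0
            obs_scores[j] /= sd
            for b in range(B):
                perm_scores[b][j] /= sd
    t_obs = spu(obs_scores)
    t_perm = [spu(s) for s in perm_scores]
    # transform two-sided components
    for c, g in enumerate(gammas):
        if not np.isinf(g) and int(g) % 2 == 1:
            t_obs[c] = abs(t_obs[c])
            for b in range(B):
                t_perm[b][c] = abs(t_perm[b][c])
    eps = 1e-9
    p_obs = [
        (1 + sum(t_perm[b][c] >= t_obs[c] - eps for b in range(B))) / (B + 1)
        for c in range(len(gammas))
    ]
    p_perm = [
        [
            sum(t_perm[b2][c] >= t_perm[b][c] for b2 in range(B)) / B
            for c in range(len(gammas))
        ]
        for b in range(B)
    ]
    aspu_obs = min(p_obs)
    aspu_perm_min = [min(p_perm[b]) for b in range(B)]
    p_aspu = (1 + sum(mp <= aspu_obs for mp in aspu_perm_min)) / (B + 1)
    aspu_perm_p = [
        sum(aspu_perm_min[b2] <= aspu_perm_min[b] for b2 in range(B)) / B for b in range(B)
    ]

    q_obs = r @ K @ r
    q_perm = [r[perms.indices[b]] @ K @ r[perms.indices[b]] for b in range(B)]
    pk_obs = (1 + sum(qp >= q_obs - eps for qp in q_perm)) / (B + 1)
    pk_perm = [sum(q_perm[b2] >= q_perm[b] for b2 in range(B)) / B for b in range(B)]
    p_kern = (1 + sum(pp <= pk_obs for pp in pk_perm)) / (B + 1)
    kern_perm_p = [sum(pk_perm[b2] <= pk_perm[b] for b2 in range(B)) / B for b in range(B)]

    m_obs = min(p_aspu, p_kern)
    m_perm = [min(a, k) for a, k in zip(aspu_perm_p, kern_perm_p)]
    return (1 + sum(mp <= m_obs for mp in m_perm)) / (B + 1)


class TestOmiat:
    def test_tree_absent_bray_curtis_only(self, rng, small_null, small_perms):
        Zg = rng.uniform(size=(small_null.n, 3))
        p = omiat_test(small_null, Zg, small_perms, kinds=("bray_curtis",))
        assert 0 < p <= 1

    def test_single_component_reduces_to_aspu(self, rng, small_null, small_perms):
        Zg = rng.uniform(size=(small_null.n, 3))
        p_only_aspu = omiat_test(small_null, Zg, small_perms, kinds=())
        assert p_only_aspu == pytest.approx(aspu_test(small_null, Zg, small_perms))

    def test_single_component_reduces_to_omirkat(self, rng, small_null, small_perms):
        Zg = rng.uniform(size=(small_null.n, 3))
        p_only_kernel = omiat_test(small_null, Zg, small_perms, gammas=())
        kernels = build_kernels(Zg, kinds=("bray_curtis",))
        assert p_only_kernel == pytest.approx(
            omirkat_test(small_null, kernels, small_perms)
        )

    @pytest.mark.parametrize("standardize", [False, True])
    def test_matches_nested_loop_oracle(self, rng, standardize):
        n, m, B = 6, 2, 199
        y = rng.normal(size=n)
        trait = TraitData(y=y, X=np.empty((n, 0)), trait_type="continuous")
        null = fit_null(trait)
        Zg = rng.uniform(size=(n, m))
        perms = PermutationSet.generate(n, B, seed=77)
        gammas = (1, 2)
        kernels = build_kernels(Zg, kinds=("bray_curtis",))
        p = omiat_test(
            null, Zg, perms, gammas=gammas, kinds=("bray_curtis",), standardize=standardize
        )
        p_oracle = _oracle_omiat(
            null, Zg, perms, gammas, kernels["bray_curtis"], standardize=standardize
        )
        assert p == pytest.approx(p_oracle)

    def test_type_one_error_controlled(self):
        # simulated global null; empirical rejection rate at alpha=.05
        n, B, reps = 40, 199, 200
        hits = 0
        master = np.random.SeedSequence(99)
        for ss in master.spawn(reps):
            rng = np.random.default_rng(ss)
            y = rng.normal(size=n)
            Zg = rng.dirichlet(np.ones(5), size=n)
            trait = TraitData(y=y, X=np.empty((n, 0)), trait_type="continuous")
            null = fit_null(trait)
            perms = PermutationSet.generate(n, B, seed=int(rng.integers(2**31)))
            if omiat_test(null, Zg, perms, kinds=("bray_curtis",)) < 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.08


class TestAggregated:
    def test_single_member_equals_score_test(self, rng, small_null, small_perms):
        z = rng.uniform(size=(small_null.n, 1))
        p_agg = aggregated_test(small_null, z, small_perms)
        assert p_agg == pytest.approx(permutation_pvalues(small_null, z, small_perms)[0])

    def test_signal_cancellation(self, small_null, small_perms, rng):
        z1 = rng.uniform(size=small_null.n)
        Zg = np.column_stack([z1, 0.8 - z1])  # columns sum to a constant
        assert aggregated_test(small_null, Zg, small_perms) == pytest.approx(1.0)

    def test_manual_sum_then_test_oracle(self, rng, small_null, small_perms):
        Zg = rng.uniform(size=(small_null.n, 4))
        p = aggregated_test(small_null, Zg, small_perms)
        manual = permutation_pvalues(small_null, Zg.sum(axis=1)[:, None], small_perms)[0]
        assert p == pytest.approx(manual)


class TestScreenRank:
    def test_group_bookkeeping(self, toy_abundance, toy_taxonomy, binary_trait, rng):
        ab = toy_abundance
        # widen toy abundance to the binary trait's sample count
        values = rng.dirichlet(np.ones(5), size=binary_trait.n)
        from massmap.data import AbundanceMatrix

        ab = AbundanceMatrix(
            [f"s{i}" for i in range(binary_trait.n)], ab.taxon_ids, values
        )
        perms = PermutationSet.generate(binary_trait.n, 99, seed=5)
        res = screen_rank(
            ab, toy_taxonomy, binary_trait, rank="family", perms=perms, method="omiat"
        )
        groups = toy_taxonomy.partition("family", taxa=ab.taxon_ids)
        assert res.group_ids == list(groups)
        assert len(res.p_values) == len(groups)
        res2 = screen_rank(
            ab, toy_taxonomy, binary_trait, rank="family", perms=perms, method="aggregated"
        )
        assert res2.group_ids == res.group_ids

    def test_rank_order_validated(self, toy_abundance, toy_taxonomy, binary_trait):
        perms = PermutationSet.generate(4, 9, seed=5)
        with pytest.raises(ConfigurationError):
            screen_rank(
                toy_abundance,
                toy_taxonomy,
                None,
                rank="species",
                perms=perms,
                target_rank="species",
            )

    def test_associated_group_attains_min_p(self):
        # planted strong signal in one family
        from massmap.simulate import default_benchmark, sample_dm_counts

        bench = default_benchmark(n_taxa=40)
        n = 80
        counts = sample_dm_counts(bench.params, n, seed=3)
        Z = counts / bench.params.reads_per_sample
        groups = bench.taxonomy.partition("family", taxa=bench.taxon_ids)
        # choose the largest family and drive the trait with its members
        gid = max(groups, key=lambda g: len(groups[g]))
        idx = [bench.taxon_ids.index(t) for t in groups[gid]]
        rng = np.random.default_rng(8)
        cols = Z[:, idx]
        sd = cols.std(axis=0)
        keep = sd > 0
        eta = ((cols[:, keep] - cols[:, keep].mean(0)) / sd[keep]) @ np.full(keep.sum(), 2.0)
        y = eta + rng.normal(size=n)
        trait = TraitData(y=y, X=np.empty((n, 0)), trait_type="continuous")
        perms = PermutationSet.generate(n, 2000, seed=4)
        res = screen_rank(
            bench.taxonomy and bench_ab(Z, bench),
            bench.taxonomy,
            trait,
            rank="family",
            perms=perms,
            method="omiat",
            tree=bench.tree,
        )
        assert res.group_ids[int(np.argmin(res.p_values))] == gid

    def test_aggregated_auc_increases_down_ranks_same_direction(self):
        # same-direction signals: aggregated screening discriminates better
        # at lower (more homogeneous) ranks
        from massmap.simulate import run_benchmark

        aucs = {}
        for rank in ("phylum", "genus"):
            _, detail = run_benchmark(
                n_reps=40,
                seed=123,
                scenario="same_direction",
                effect_high=4.0,
                trait_type="continuous",
                methods=("agg",),
                screening_rank=rank,
                n_taxa=50,
                n_samples=100,
                n_permutations=199,
            )
            aucs[rank] = np.nanmean(detail["agg"]["auc"])
        assert aucs["genus"] > aucs["phylum"]


def bench_ab(Z, bench):
    from massmap.data import AbundanceMatrix

    return AbundanceMatrix(
        [f"s{i}" for i in range(Z.shape[0])], bench.taxon_ids, Z
    )
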