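"""Cluster permutation machinery, JZS Bayes factors, FDR and lateralisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import cauchy, nct
from scipy.stats import t as t_dist

from megword import features, stats, synthgen


class TestCriticalT:
    def test_printed_threshold_for_18_participants(self):
        assert round(stats.critical_t(18, 0.05), 1) == 2.1

    def test_independent_quantile_oracle(self):
        assert stats.critical_t(11, 0.05) == pytest.approx(2.228, abs=5e-4)

    def test_alpha_one_limit_is_zero(self):
        assert stats.critical_t(18, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            stats.critical_t(1)


def jzs_ttest_oracle(t: float, n: int, scale: float = 0.707) -> float:
    """Independent route: marginal over effect size delta ~ Cauchy(0, scale),
    likelihood from the non-central t density."""
    nu = n - 1

    def integrand(delta):
        return nct.pdf(t, nu, delta * np.sqrt(n)) * cauchy.pdf(delta, 0.0, scale)

    num, _ = quad(integrand, -np.inf, np.inf, epsabs=0.0, epsrel=1e-10, limit=400)
    return num / t_dist.pdf(t, nu)


class TestJzsBayesFactorTtest:
    def test_null_favoured_at_t_zero(self):
        assert stats.jzs_bf_ttest(0.0, 18).bf10 < 1.0

    @pytest.mark.parametrize("t,n", [(3.0, 18), (2.66, 18), (0.5, 10), (4.4, 15)])
    def test_matches_independent_quadrature_oracle(self, t, n):
        bf = stats.jzs_bf_ttest(t, n).bf10
        assert bf == pytest.approx(jzs_ttest_oracle(t, n), rel=1e-6)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        ours = stats.jzs_bf_ttest(3.0, 18).bf10
        theirs = float(pingouin.bayesfactor_ttest(3.0, 18, paired=True, r=0.707))
        assert ours == pytest.approx(theirs, rel=1e-4)

    def test_strictly_increasing_in_abs_t(self):
        bfs = [stats.jzs_bf_ttest(t, 12).bf10 for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert np.all(np.diff(bfs) > 0)
        assert stats.jzs_bf_ttest(-3.0, 12).bf10 == pytest.approx(
            stats.jzs_bf_ttest(3.0, 12).bf10, rel=1e-12
        )

    def test_verdict_thresholds(self):
        assert stats.BayesResult(5.0).verdict == "H1"
        assert stats.BayesResult(0.2).verdict == "H0"
        assert stats.BayesResult(1.0).verdict == "inconclusive"

    def test_non_finite_t_rejected(self):
        with pytest.raises(ValueError):
            stats.jzs_bf_ttest(np.inf, 10)


def jzs_correlation_oracle(r: float, n: int) -> float:
    """Same marginal, integrated on the compactified variable u = g/(1+g)."""
    u = np.linspace(1e-9, 1 - 1e-9, 200_001)
    g = u / (1.0 - u)
    logf = (
        0.5 * (n - 2) * np.log1p(g)
        - 0.5 * (n - 1) * np.log1p((1.0 - r * r) * g)
        - 1.5 * np.log(g)
        - n / (2.0 * g)
        - 2.0 * np.log1p(-u)  # Jacobian dg/du = 1/(1-u)^2
    )
    val = np.trapezoid(np.exp(logf), u)
    return float(np.sqrt(n / 2.0) / np.sqrt(np.pi) * val)


class TestJzsBayesFactorCorrelation:
    def test_null_favoured_at_r_zero(self):
        assert stats.jzs_bf_correlation(0.0, 20).bf10 < 1.0

    def test_strong_correlation_supported(self):
        assert stats.jzs_bf_correlation(0.8, 30).bf10 > 3.0

    def test_monotone_in_abs_r(self):
        bfs = [stats.jzs_bf_correlation(r, 25).bf10 for r in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize("r,n", [(0.3, 20), (0.8, 30), (0.0, 15)])
    def test_matches_quadrature_oracle(self, r, n):
        assert stats.jzs_bf_correlation(r, n).bf10 == pytest.approx(
            jzs_correlation_oracle(r, n), rel=1e-4
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.jzs_bf_correlation(1.0, 20)
        with pytest.raises(ValueError):
            stats.jzs_bf_correlation(0.5, 2)


def fdr_oracle(p: np.ndarray, q: float) -> np.ndarray:
    """Brute-force step-up: largest k with p_(k) <= k q / m."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestFdrBH:
    def test_step_up_hand_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        assert np.array_equal(stats.fdr_bh(p, 0.05), [True, True, True, False])

    def test_none_rejected_above_q(self):
        assert not stats.fdr_bh(np.array([0.2, 0.6, 0.9]), 0.05).any()

    @pytest.mark.parametrize("p,expect", [(0.04, True), (0.06, False)])
    def test_single_p(self, p, expect):
        assert stats.fdr_bh(np.array([p]), 0.05)[0] == expect

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
        q=st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_matches_bruteforce_oracle(self, p, q):
        p = np.asarray(p)
        assert np.array_equal(stats.fdr_bh(p, q), fdr_oracle(p, q))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.fdr_bh(np.array([0.5, 1.2]))


def flood_fill_oracle(mask, neighbours):
    """BFS connected components over the supra-threshold set."""
    todo = set(np.flatnonzero(mask))
    comps = []
    while todo:
        frontier = [todo.pop()]
        comp = set(frontier)
        while frontier:
            node = frontier.pop()
            for nb in neighbours[node]:
                if nb in todo:
                    todo.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(frozenset(comp))
    return set(comps)



@pytest.fixture(scope="module")
def lattice125():
    grid = synthgen.make_grid(6.0, 24.0)  # 125 points
    adjacency = stats.grid_adjacency(grid)
    pos = grid.positions
    dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    neighbours = [
        np.flatnonzero(np.abs(dist[i] - 6.0) < 1e-9) for i in range(len(pos))
    ]
    return grid, adjacency, neighbours


@pytest.fixture(scope="module")
def lateral_setting():
    grid = synthgen.make_grid(6.0, 24.0)
    mirror = features.mirror_index(grid)
    left = np.flatnonzero(grid.positions[:, 0] < 0)
    cluster = stats.ClusterResult(
        members=left[:20], t_sum=20.0, p=0.01, peak=int(left[0])
    )
    return grid, mirror, cluster


class TestClusterFinding:

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_flood_fill_oracle(self, lattice125, seed):
        grid, adjacency, neighbours = lattice125
        rng = np.random.default_rng(seed)
        mask = rng.random(grid.n_points) < 0.4
        values = rng.standard_normal(grid.n_points)
        found = stats.find_clusters(values, mask, adjacency, min_size=1)
        got = {frozenset(m.tolist()) for m, _, _ in found}
        assert got == flood_fill_oracle(mask, neighbours)
        for members, t_sum, peak in found:
            assert t_sum == pytest.approx(values[members].sum())
            assert peak in members

    def test_minimum_size_of_ten_blocks_nine_points(self, lattice125):
        grid, adjacency, _ = lattice125
        # 9 collinear supra-threshold points: below the minimal cluster size
        axis_line = np.flatnonzero(
            (grid.positions[:, 1] == 0) & (grid.positions[:, 2] == 0)
        )  # 5 points; build a 9-point L-shape instead
        arm = np.flatnonzero(
            (grid.positions[:, 0] == 0) & (grid.positions[:, 2] == 0)
        )
        nine = np.unique(np.concatenate([axis_line, arm]))[:9]
        mask = np.zeros(grid.n_points, dtype=bool)
        mask[nine] = True
        values = mask.astype(float)
        assert stats.find_clusters(values, mask, adjacency, min_size=10) == []
        found = stats.find_clusters(values, mask, adjacency, min_size=9)
        assert len(found) == 1 and found[0][0].size == 9


def _block_members(grid, predicate):
    return np.flatnonzero(predicate(grid.positions))


class TestClusterPermutationT:
    def test_subthreshold_map_yields_empty_result(self, lattice125):
        grid, adjacency, _ = lattice125
        t_map = np.full(grid.n_points, 1.0)
        t_perms = np.zeros((120, grid.n_points))
        assert (
            stats.cluster_perm_t(t_map, t_perms, adjacency, first_level_t=2.0) == []
        )

    def test_permutation_p_matches_hand_count(self, lattice125):
        # single constant cluster; 20 permutations, 5 of them exceeding:
        # p = (1 + 5) / (1 + 20)
        grid, adjacency, _ = lattice125
        block = _block_members(grid, lambda p: p[:, 0] <= -6)  # 50 points
        t_map = np.zeros(grid.n_points)
        t_map[block] = 3.0
        t_perms = np.zeros((20, grid.n_points))
        t_perms[:5, block] = 4.0  # exceed the observed T_sum
        with pytest.warns(UserWarning, match="coarse"):
            clusters = stats.cluster_perm_t(
                t_map, t_perms, adjacency, first_level_t=2.0
            )
        assert len(clusters) == 1
        assert clusters[0].t_sum == pytest.approx(3.0 * block.size)
        assert clusters[0].p == pytest.approx(6.0 / 21.0)

    def test_negative_clusters_handled_separately(self, lattice125):
        grid, adjacency, _ = lattice125
        left = _block_members(grid, lambda p: p[:, 0] <= -6)
        right = _block_members(grid, lambda p: p[:, 0] >= 6)
        t_map = np.zeros(grid.n_points)
        t_map[left] = 3.0
        t_map[right] = -3.0
        t_perms = np.zeros((150, grid.n_points))
        clusters = stats.cluster_perm_t(t_map, t_perms, adjacency, first_level_t=2.0)
        assert len(clusters) == 2
        signs = sorted(np.sign(c.t_sum) for c in clusters)
        assert signs == [-1.0, 1.0]

    def test_planted_effect_detected_with_overlap(self, lattice125):
        # 30-point planted block among null maps: significant overlapping cluster
        grid, adjacency, _ = lattice125
        rng = np.random.default_rng(3)
        planted = _block_members(
            grid, lambda p: (p[:, 0] <= -6) & (p[:, 2] <= 0)
        )[:30]
        n_part = 10
        maps = 0.2 * rng.standard_normal((n_part, grid.n_points))
        maps[:, planted] += 1.0
        t_obs = neurobehav_t(maps)
        flips = rng.choice([-1.0, 1.0], size=(500, n_part, 1))
        t_perms = neurobehav_t(maps[None] * flips)
        clusters = stats.cluster_perm_t(
            t_obs, t_perms, adjacency, first_level_t=stats.critical_t(n_part)
        )
        assert clusters and clusters[0].p < 0.05
        overlap = len(set(planted) & set(clusters[0].members.tolist()))
        assert overlap >= 0.8 * planted.size


def neurobehav_t(maps: np.ndarray) -> np.ndarray:
    """One-sample t along the participant axis (vectorised, supports stacks)."""
    n = maps.shape[-2]
    mean = maps.mean(axis=-2)
    sd = maps.std(axis=-2, ddof=1)
    return mean / (sd / np.sqrt(n))


class TestClusterPermutationClassification:
    def test_planted_performance_cluster_detected(self, lattice125):
        grid, adjacency, _ = lattice125
        rng = np.random.default_rng(5)
        planted = _block_members(grid, lambda p: p[:, 0] >= 6)[:30]
        n_part, n_perm = 10, 300
        maps = 0.25 + 0.02 * rng.standard_normal((n_part, grid.n_points))
        maps[:, planted] += 0.05
        perm_maps = 0.25 + 0.02 * rng.standard_normal((n_perm, n_part, grid.n_points))
        clusters = stats.cluster_perm_classification(
            maps, perm_maps, adjacency, min_size=10, percentile=99.95
        )
        assert clusters and clusters[0].p < 0.05
        assert set(planted) <= set(clusters[0].members.tolist())

    def test_null_maps_yield_no_low_p_cluster(self, lattice125):
        grid, adjacency, _ = lattice125
        rng = np.random.default_rng(6)
        all_maps = 0.25 + 0.02 * rng.standard_normal((301, 10, grid.n_points))
        clusters = stats.cluster_perm_classification(
            all_maps[0], all_maps[1:], adjacency
        )
        assert all(c.p >= 0.05 for c in clusters)

    def test_few_permutations_warn(self, lattice125):
        grid, adjacency, _ = lattice125
        rng = np.random.default_rng(7)
        with pytest.warns(UserWarning, match="unstable"):
            stats.cluster_perm_classification(
                rng.random((4, grid.n_points)),
                rng.random((50, 4, grid.n_points)),
                adjacency,
            )


class TestLateralisation:
    def test_symmetric_maps_give_zero_difference(self, lateral_setting):
        grid, mirror, cluster = lateral_setting
        rng = np.random.default_rng(8)
        half = rng.standard_normal((5, grid.n_points))
        values = (half + half[:, mirror]) / 2.0  # mirror-symmetric by construction
        rows = stats.lateralisation_test(values, [cluster], mirror)
        assert np.isnan(rows[0]["t"]) or abs(rows[0]["t"]) < 1e-10

    def test_left_planted_effect_detected(self, lateral_setting):
        grid, mirror, cluster = lateral_setting
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            values = 0.3 * rng.standard_normal((12, grid.n_points))
            values[:, cluster.members] += 1.0
            rows = stats.lateralisation_test(values, [cluster], mirror)
            hits += rows[0]["t"] > 0 and rows[0]["p_fdr"] < 0.05
        assert hits >= 18

    def test_single_cluster_fdr_equals_raw(self, lateral_setting):
        grid, mirror, cluster = lateral_setting
        rng = np.random.default_rng(10)
        values = rng.standard_normal((8, grid.n_points))
        rows = stats.lateralisation_test(values, [cluster], mirror)
        assert rows[0]["p_fdr"] == pytest.approx(rows[0]["p"])

    def test_unmapped_members_flagged(self):
        grid = synthgen.SourceGrid(
            positions=np.array(
                [[-6.0, 0.0, 0.0], [0.0, 0.0, 0.0], [6.0, 0.0, 0.0], [12.0, 0.0, 0.0]]
            ),
            spacing=6.0,
        )
        mirror = features.mirror_index(grid)
        cluster = stats.ClusterResult(
            members=np.array([2, 3]), t_sum=1.0, p=0.5, peak=2
        )
        values = np.random.default_rng(11).standard_normal((4, 4))
        rows = stats.lateralisation_test(values, [cluster], mirror)
        assert rows[0]["n_unmapped"] == 1
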