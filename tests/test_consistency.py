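import itertools

import numpy as np
import pytest

from sdcornet.consistency import (
    consistency_profile,
    corrected_edge_similarity,
    default_theta_grid,
    expected_overlap_beta,
    make_split_plan,
    select_threshold,
)
from sdcornet.dataio import ExpressionMatrix, generate_synthetic_expression
from sdcornet.netbuild import UnweightedNetwork


def _net(node_count, pairs):
    return UnweightedNetwork([f"n{i}" for i in range(node_count)], set(pairs))


def _random_net(node_count, n_edges, rng):
    pairs = list(itertools.combinations(range(node_count), 2))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    return _net(node_count, [pairs[i] for i in chosen])


class TestSplitPlan:
    def test_published_sample_size_arithmetic(self):
        plan = make_split_plan(54, 0)
        assert len(plan.indices_a) == 40 and len(plan.indices_b) == 40
        shared = set(plan.indices_a.tolist()) & set(plan.indices_b.tolist())
        assert len(shared) == 27 == plan.shared_count
        assert len(set(plan.indices_a.tolist()) - shared) == 13
        used = set(plan.indices_a.tolist()) | set(plan.indices_b.tolist())
        assert len(used) == 53  # one sample left out

    def test_minimal_n(self):
        plan = make_split_plan(4, 1)
        assert len(plan.indices_a) == 3
        assert plan.shared_count == 2

    def test_indices_unique_within_each_side(self, rng):
        for n in (5, 9, 20, 54):
            plan = make_split_plan(n, rng)
            assert len(set(plan.indices_a.tolist())) == len(plan.indices_a)
            assert len(set(plan.indices_b.tolist())) == len(plan.indices_b)

    def test_deterministic_under_fixed_seed(self):
        p1, p2 = make_split_plan(30, 42), make_split_plan(30, 42)
        np.testing.assert_array_equal(p1.indices_a, p2.indices_a)
        np.testing.assert_array_equal(p1.indices_b, p2.indices_b)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_split_plan(3, 0)


class TestExpectedOverlapBeta:
    def test_both_empty_gives_zero(self):
        assert expected_overlap_beta(_net(5, []), _net(5, []), 0) == 0.0

    def test_one_empty_term_is_zero(self, rng):
        g = _random_net(8, 6, rng)
        beta = expected_overlap_beta(g, _net(8, []), 0)
        # the term over the empty graph's edges vanishes and the term over
        # g's edges vanishes too because the empty graph has all-zero degrees
        assert beta == 0.0

    def test_complete_graphs_closed_form(self):
        # regular degrees: edge-sum over ordered-all-pairs-sum = 1/2,
        # so each directional term is |E|/2 and beta = |E|
        m = 7
        full = list(itertools.combinations(range(m), 2))
        g = _net(m, full)
        beta = expected_overlap_beta(g, g, 0)
        assert beta == pytest.approx(len(full))

    def test_beta_bounded_by_mean_edge_count(self, rng):
        for _ in range(30):
            g1 = _random_net(12, int(rng.integers(1, 60)), rng)
            g2 = _random_net(12, int(rng.integers(1, 60)), rng)
            beta = expected_overlap_beta(g1, g2, rng)
            assert beta <= (g1.n_edges + g2.n_edges) / 2 + 1e-9

    def test_matches_sampled_configuration_overlap(self, rng):
        """beta approximates the mean overlap of one graph with random
        graphs drawn edge-by-edge proportional to permuted-degree products
        (equal edge counts, so both directional terms estimate the same
        expectation)."""
        m, n_edges = 30, 45
        g1 = _random_net(m, n_edges, rng)
        g2 = _random_net(m, n_edges, rng)
        pairs = list(itertools.combinations(range(m), 2))
        e1 = g1.edges

        mc_rng = np.random.default_rng(7)
        overlaps = []
        d2 = g2.degrees()
        for _ in range(400):
            d2p = mc_rng.permutation(d2)
            w = np.array([d2p[i] * d2p[j] for i, j in pairs], float)
            # one directional half: overlap of E1 with a degree-weighted
            # random graph of |E2| edges
            idx = mc_rng.choice(len(pairs), size=n_edges, replace=False, p=w / w.sum())
            overlaps.append(sum(1 for k in idx if pairs[k] in e1))
        mc_half = np.mean(overlaps)

        betas = [expected_overlap_beta(g1, g2, np.random.default_rng(s)) for s in range(400)]
        assert np.mean(betas) == pytest.approx(mc_half, rel=0.15)


class TestCorrectedSimilarity:
    def test_identical_networks_with_beta_zero_is_one(self, rng):
        g = _random_net(10, 8, rng)
        res = corrected_edge_similarity(g, g, 0, beta=0.0)
        assert res.similarity == 1.0

    def test_identical_sparse_networks_near_one(self, rng):
        g = _random_net(40, 12, rng)
        res = corrected_edge_similarity(g, g, 0)
        assert res.similarity > 0.8

    def test_edge_disjoint_networks_negative(self):
        g1 = _net(6, [(0, 1), (2, 3)])
        g2 = _net(6, [(0, 2), (1, 3)])
        res = corrected_edge_similarity(g1, g2, 0)
        assert res.intersection == 0
        assert res.similarity < 0

    def test_bounded_on_random_pairs(self, rng):
        for trial in range(60):
            m = int(rng.integers(5, 25))
            max_e = m * (m - 1) // 2
            g1 = _random_net(m, int(rng.integers(0, max_e + 1)), rng)
            g2 = _random_net(m, int(rng.integers(0, max_e + 1)), rng)
            if g1.n_edges == 0 and g2.n_edges == 0:
                continue
            res = corrected_edge_similarity(g1, g2, rng)
            assert -1 / 3 - 1e-9 <= res.similarity <= 1 + 1e-9

    def test_identical_complete_graphs_score_zero(self):
        """A complete graph is indistinguishable from its own configuration
        randomization, so the corrected similarity carries no signal."""
        g = _net(6, itertools.combinations(range(6), 2))
        res = corrected_edge_similarity(g, g, 0)
        assert res.beta == pytest.approx(res.union)
        assert res.similarity == pytest.approx(0.0)

    def test_both_empty_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning, match="empty"):
            res = corrected_edge_similarity(_net(4, []), _net(4, []), 0)
        assert res.similarity == 0.0

    def test_symmetric_under_mirrored_seeds(self, rng):
        g1 = _random_net(12, 10, rng)
        g2 = _random_net(12, 14, rng)
        a = [corrected_edge_similarity(g1, g2, np.random.default_rng(s)).similarity for s in range(200)]
        b = [corrected_edge_similarity(g2, g1, np.random.default_rng(s)).similarity for s in range(200)]
        assert np.mean(a) == pytest.approx(np.mean(b), abs=0.01)

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError, match="node set"):
            corrected_edge_similarity(_net(4, []), _net(5, []), 0)


@pytest.fixture(scope="module")
def noise_matrix():
    rng = np.random.default_rng(17)
    return ExpressionMatrix(
        rng.standard_normal((30, 40)),
        [f"g{i}" for i in range(30)],
        [f"s{j}" for j in range(40)],
    )


class TestConsistencyProfile:
    def test_pure_noise_never_scores_like_structure(self, noise_matrix):
        with pytest.warns(RuntimeWarning):
            prof = consistency_profile(
                noise_matrix, "pearson", thetas=np.arange(0.1, 0.95, 0.1),
                n_repetitions=5, seed=1,
            )
        # no consistent structure: the score stays far below what modular
        # fixtures reach (>0.8); the similarity average stays in its range
        assert prof.scores.max() < 0.3
        assert (prof.s_values >= -1 / 3 - 1e-9).all()
        assert (prof.s_values <= 1 + 1e-9).all()

    def test_strong_modules_recovered(self):
        M, truth = generate_synthetic_expression(
            n_modules=2, genes_per_module=10, n_background=80, n_samples=30,
            noise_sd=0.05, seed=9,
        )
        prof = consistency_profile(
            M, "signed_distance", thetas=np.arange(0.2, 0.96, 0.05),
            n_repetitions=5, seed=2,
        )
        theta, score, density = select_threshold(prof)
        from sdcornet.correlations import compute_correlation
        from sdcornet.netbuild import threshold_network
        from sdcornet.preprocess import preprocess

        S = compute_correlation(preprocess(M), "signed_distance")
        edges = set(threshold_network(S, theta).edge_ids())
        tp = {tuple(p) for p in truth.true_pairs}
        assert len(edges & tp) / len(tp) >= 0.9
        assert len(edges & tp) / len(edges) >= 0.9

    def test_bit_reproducible_for_fixed_seed(self, noise_matrix):
        kwargs = dict(thetas=[0.3, 0.6], n_repetitions=3, seed=5)
        p1 = consistency_profile(noise_matrix, "pearson", **kwargs)
        p2 = consistency_profile(noise_matrix, "pearson", **kwargs)
        np.testing.assert_array_equal(p1.s_values, p2.s_values)

    def test_densities_non_increasing_and_score_bounded_by_s(self, noise_matrix):
        prof = consistency_profile(
            noise_matrix, "pearson", thetas=np.arange(0.0, 0.9, 0.15),
            n_repetitions=3, seed=3,
        )
        assert (np.diff(prof.densities) <= 1e-12).all()
        assert (prof.scores <= prof.s_values + 1e-12).all()

    def test_across_seed_stability_of_s(self):
        """With strong structure, s(theta) varies little across seeds."""
        M, _ = generate_synthetic_expression(
            n_modules=2, genes_per_module=10, n_background=60, n_samples=40,
            noise_sd=0.1, seed=4,
        )
        values = [
            consistency_profile(
                M, "signed_distance", thetas=[0.6], n_repetitions=10, seed=s
            ).s_values[0]
            for s in (1, 2, 3)
        ]
        assert np.std(values) < 0.05

    def test_unsorted_thetas_rejected(self, noise_matrix):
        with pytest.raises(ValueError, match="sorted"):
            consistency_profile(noise_matrix, "pearson", thetas=[0.5, 0.1], n_repetitions=1)


class TestSelectThreshold:
    def _profile(self, thetas, scores, densities=None):
        from sdcornet.consistency import ConsistencyProfile

        thetas = np.asarray(thetas, float)
        scores = np.asarray(scores, float)
        densities = np.zeros_like(scores) if densities is None else np.asarray(densities)
        return ConsistencyProfile(
            thetas, scores + densities, densities, scores, 1, 0, "pearson"
        )

    def test_argmax_selected(self):
        prof = self._profile([0.1, 0.2, 0.3], [0.1, 0.5, 0.2])
        theta, score, _ = select_threshold(prof)
        assert (theta, score) == (0.2, 0.5)

    def test_ties_broken_toward_larger_theta(self):
        prof = self._profile([0.1, 0.2, 0.3], [0.5, 0.5, 0.1])
        assert select_threshold(prof)[0] == 0.2

    def test_all_equal_warns_and_returns_largest(self):
        prof = self._profile([0.1, 0.2], [0.3, 0.3])
        with pytest.warns(RuntimeWarning, match="largest"):
            assert select_threshold(prof)[0] == 0.2

    def test_single_point_profile(self):
        assert select_threshold(self._profile([0.4], [0.2]))[0] == 0.4

    def test_default_grid_covers_unit_interval(self):
        grid = default_theta_grid()
        assert grid[0] == 0.0 and grid[-1] == 0.99 and len(grid) == 100
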