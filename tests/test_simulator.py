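"""GPA growth: attractiveness, angle selection, linking, and ensemble limits."""

import math

import numpy as np
import pytest
from scipy import stats

from gpanet.geometry import (
    angular_distance,
    birth_radius,
    hyperbolic_distance_approx,
    hyperbolic_distance_exact,
    updated_radius,
)
from gpanet.simulator import (
    GPANetwork,
    ModelParams,
    attractiveness,
    attractiveness_profile,
    expected_edge_count,
    follower_probability,
    grow_network,
    sample_angle,
    select_candidate,
)

TWO_PI = 2 * math.pi


def brute_force_attractiveness(phi, t, existing, beta, mode):
    """Reference count: explicit distance from (r_t, phi) to every node."""
    r_t = birth_radius(t)
    count = 0
    for s in range(1, t):
        r_s = updated_radius(s, t, beta)
        dt = angular_distance(phi, existing[s - 1])
        if mode == "approx":
            d = -np.inf if dt == 0 else hyperbolic_distance_approx((r_t, phi), (r_s, existing[s - 1]))
        else:
            d = hyperbolic_distance_exact((r_t, phi), (r_s, existing[s - 1]))
        count += d <= r_t
    return count


class TestModelParams:
    @pytest.mark.parametrize(
        "kw",
        [dict(n=0), dict(n=5, m=0), dict(n=5, beta=0.0), dict(n=5, beta=1.2),
         dict(n=5, lambda_schedule=-1.0), dict(n=5, distance_mode="flat"),
         dict(n=5, zero_weight_policy="retry")],
    )
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)

    def test_implied_exponent(self):
        assert ModelParams(n=10, beta=2 / 3).gamma == pytest.approx(2.5)

    def test_negative_schedule_value_rejected_at_use(self):
        p = ModelParams(n=3, lambda_schedule=lambda t: -1.0)
        with pytest.raises(ValueError):
            grow_network(p)


class TestAttractiveness:
    def test_no_existing_nodes(self):
        assert attractiveness(1.0, 1, [], beta=0.5) == 0

    def test_worked_three_node_example_exact_mode(self):
        # node 1 at distance 1.4648 <= r_3 = 2.1972; node 2 at 3.8538 outside
        a = attractiveness(0.0, 3, [0.0, math.pi], beta=2 / 3, distance_mode="exact")
        assert a == 1

    def test_node_at_probe_location_increments(self):
        # the same state with the last node moved onto the probe location
        # counts exactly one more (distance 0 <= r_t; the antipode is outside)
        rng = np.random.default_rng(2)
        existing = list(rng.uniform(0, TWO_PI, 5))
        phi = 1.2345
        on_probe = attractiveness(phi, 7, existing + [phi], beta=0.6)
        off_probe = attractiveness(phi, 7, existing + [phi + math.pi], beta=0.6)
        assert on_probe == off_probe + 1

    @pytest.mark.parametrize("mode", ["approx", "exact"])
    def test_matches_brute_force(self, mode):
        rng = np.random.default_rng(4)
        for _ in range(40):
            t = int(rng.integers(2, 50))
            beta = rng.uniform(0.3, 1.0)
            existing = rng.uniform(0, TWO_PI, t - 1)
            phis = rng.uniform(0, TWO_PI, 5)
            fast = attractiveness_profile(phis, t, existing, beta, mode)
            slow = [brute_force_attractiveness(p, t, existing, beta, mode) for p in phis]
            assert list(fast) == slow

    def test_inconsistent_state_rejected(self):
        with pytest.raises(ValueError):
            attractiveness(0.0, 3, [0.0], beta=0.5)


class TestAngleSelection:
    def test_first_node_uniform(self):
        rng = np.random.default_rng(10)
        draws = [sample_angle(1, 1.0, [], rng, beta=0.5) for _ in range(10_000)]
        assert stats.kstest(np.array(draws) / TWO_PI, "uniform").pvalue > 0.01

    def test_infinite_lambda_limit_is_uniform(self):
        # Lambda -> inf: every candidate equally likely, so the angle marginal
        # is uniform regardless of the existing configuration (the PS model)
        rng = np.random.default_rng(12)
        existing = np.array([0.1, 0.11, 0.12, 0.13, 0.14])  # tight cluster
        draws = [sample_angle(6, 1e9, existing, rng, beta=2 / 3) for _ in range(10_000)]
        assert stats.kstest(np.array(draws) / TWO_PI, "uniform").pvalue > 0.01

    def test_selection_probabilities(self):
        # weights (2+1, 0+1) -> probabilities (0.75, 0.25)
        rng = np.random.default_rng(13)
        picks = np.array([select_candidate(np.array([2, 0]), 1.0, rng.random())
                          for _ in range(100_000)])
        p0 = np.mean(picks == 0)
        assert abs(p0 - 0.75) < 4 * math.sqrt(0.75 * 0.25 / 100_000)

    def test_degenerate_zero_weights_uniform(self):
        rng = np.random.default_rng(14)
        picks = [select_candidate(np.zeros(4), 0.0, rng.random()) for _ in range(20_000)]
        freq = np.bincount(picks, minlength=4) / 20_000
        assert stats.chisquare(np.bincount(picks, minlength=4)).pvalue > 0.01
        assert freq.max() < 0.3

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            select_candidate(np.array([1.0]), -0.5, 0.5)

    def test_two_path_equivalence_with_follower_decomposition(self):
        """Direct weight-proportional selection vs the follower decomposition
        (with probability p_f pick proportionally to A, else uniformly) give
        the same selection law on a frozen candidate set."""
        attract = np.array([3, 0, 1, 0, 2])
        t, lam = 5, 1.0
        n_draws = 100_000
        rng = np.random.default_rng(15)
        direct = np.array([select_candidate(attract, lam, rng.random()) for _ in range(n_draws)])

        p_f = follower_probability(t, lam, attract)
        probs_follow = attract / attract.sum()
        rng2 = np.random.default_rng(16)
        is_follower = rng2.random(n_draws) < p_f
        decomposed = np.where(
            is_follower,
            rng2.choice(len(attract), size=n_draws, p=probs_follow),
            rng2.integers(0, len(attract), size=n_draws),
        )
        table = np.vstack([np.bincount(direct, minlength=5), np.bincount(decomposed, minlength=5)])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01


class TestFollowerProbability:
    def test_limits_and_values(self):
        assert follower_probability(3, 0.0, [1, 2, 0]) == 1.0
        assert follower_probability(3, 2.0, [0, 0, 0]) == 0.0
        assert follower_probability(10, 1.0, [1] * 10) == pytest.approx(0.5)

    def test_degenerate_case_raises(self):
        with pytest.raises(ZeroDivisionError):
            follower_probability(1, 0.0, [0])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            follower_probability(3, 1.0, [0, 1])


class TestGrowth:
    def test_small_complete_graph(self):
        net = grow_network(ModelParams(n=3, m=3, seed=1))
        assert sorted(map(tuple, net.edges)) == [(1, 2), (1, 3), (2, 3)]

    @pytest.mark.parametrize("mode", ["approx", "exact"])
    def test_edge_count_and_structure(self, mode):
        net = grow_network(ModelParams(n=300, m=3, beta=2 / 3, lambda_schedule=1.0,
                                       seed=21, distance_mode=mode))
        assert len(net.edges) == expected_edge_count(300, 3) == 3 + 3 * 297
        assert np.all(net.edges[:, 0] < net.edges[:, 1])  # no self-loops
        assert len({tuple(e) for e in net.edges}) == len(net.edges)  # no duplicates
        assert np.all((net.angles >= 0) & (net.angles < TWO_PI))
        deg = net.degrees()
        assert deg.min() >= 3
        assert deg.mean() == pytest.approx(2 * len(net.edges) / 300)

    def test_reproducible_given_seed(self):
        a = grow_network(ModelParams(n=150, m=2, seed=33))
        b = grow_network(ModelParams(n=150, m=2, seed=33))
        assert np.array_equal(a.angles, b.angles)
        assert np.array_equal(a.edges, b.edges)

    def test_lambda_schedule_callable(self):
        sched = lambda t: 2.0 if t < 50 else 0.0
        net = grow_network(ModelParams(n=100, m=2, lambda_schedule=sched, seed=8))
        assert net.n == 100
        assert len(net.edges) == expected_edge_count(100, 2)

    def test_pure_density_following_runs(self):
        # Lambda = 0 exercises the degenerate-weight resampling path
        net = grow_network(ModelParams(n=100, m=3, lambda_schedule=0.0, seed=9))
        assert len(net.edges) == expected_edge_count(100, 3)

    def test_degree_sequence_invariant_under_lambda(self, small_ensembles):
        """The degree distribution is a function of m and beta only: pooled
        degrees at Lambda = 0.1 and Lambda = 10 are KS-indistinguishable."""
        pooled = {
            lam: np.concatenate([net.degrees() for net in small_ensembles[lam]])
            for lam in (0.1, 10.0)
        }
        p = stats.ks_2samp(pooled[0.1], pooled[10.0]).pvalue
        assert p > 0.01

    def test_radii_match_update_rule(self):
        net = grow_network(ModelParams(n=50, m=2, seed=3))
        expected = [updated_radius(s, 50, net.params.beta) for s in range(1, 51)]
        assert np.allclose(net.radii(), expected)
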