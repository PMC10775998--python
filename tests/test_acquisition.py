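"""Acquisition math: Pareto extraction, hypervolume, EHVI, penalty, fitness."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from idpdesign.acquisition import (FitnessContext, ParetoArchive, ehvi_batch,
                                   fitness, hypervolume, pareto_front, psi,
                                   similarity_penalty,
                                   similarity_penalty_batch)


def brute_force_front(pts):
    """O(n^2) dominance scan; first-seen wins on exact ties."""
    keep = []
    for i, p in enumerate(pts):
        dominated = False
        for j, q in enumerate(pts):
            if j == i:
                continue
            if (q[0] >= p[0] and q[1] >= p[1]) and (q[0] > p[0] or q[1] > p[1]):
                dominated = True
                break
            if q[0] == p[0] and q[1] == p[1] and j < i:
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep


def grid_hypervolume(pts, ref, n=2000):
    """Brute-force dominated-area estimate on a fine rectangular grid."""
    pts = np.asarray(pts, dtype=float)
    hi0, hi1 = pts[:, 0].max(), pts[:, 1].max()
    xs = np.linspace(ref[0], hi0, n)
    ys = np.linspace(ref[1], hi1, n)
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    xc = xs[:-1] + 0.5 * (xs[1] - xs[0])
    yc = ys[:-1] + 0.5 * (ys[1] - ys[0])
    covered = np.zeros((n - 1, n - 1), dtype=bool)
    for p in pts:
        covered |= (xc[:, None] <= p[0]) & (yc[None, :] <= p[1])
    return covered.sum() * cell


class TestParetoFront:
    def test_single_point(self):
        assert pareto_front([[1.0, 2.0]]).tolist() == [0]

    def test_mutually_nondominated_chain(self):
        pts = [[1, 4], [2, 3], [3, 2], [4, 1]]
        assert pareto_front(pts).tolist() == [0, 1, 2, 3]

    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 1, (200, 2))
            assert sorted(pareto_front(pts).tolist()) == sorted(brute_force_front(pts))

    def test_exact_ties_keep_first_seen(self):
        pts = [[1.0, 1.0], [1.0, 1.0], [0.5, 0.5]]
        assert pareto_front(pts).tolist() == [0]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pareto_front([[np.inf, 0.0]])


class TestHypervolume:
    def test_single_rectangle(self):
        assert hypervolume([[1.0, 1.0]], (0.0, 0.0)) == pytest.approx(1.0)

    def test_two_point_union(self):
        assert hypervolume([[1, 2], [2, 1]], (0, 0)) == pytest.approx(3.0)

    def test_matches_grid_oracle(self, rng):
        for _ in range(3):
            pts = rng.uniform(0.2, 1.0, (12, 2))
            hv = hypervolume(pts, (0.0, 0.0))
            assert hv == pytest.approx(grid_hypervolume(pts, (0.0, 0.0)), rel=0.01)

    def test_point_below_reference_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            hv = hypervolume([[1, 1], [-1, 5]], (0, 0))
        assert hv == pytest.approx(1.0)

    def test_adding_nondominated_point_increases_hv(self, rng):
        pts = rng.uniform(0.1, 1.0, (20, 2))
        front = pts[pareto_front(pts)]
        hv = hypervolume(front, (0, 0))
        new = front[np.argmax(front[:, 0])] + np.array([0.05, 0.0])
        assert hypervolume(np.vstack([front, new]), (0, 0)) > hv


class TestPsi:
    @pytest.mark.parametrize("a,b,mu,sigma", [
        (1.0, 0.0, 0.0, 1.0), (0.5, 1.5, -0.3, 0.7), (-1.0, 2.0, 0.4, 2.0),
    ])
    def test_matches_numerical_quadrature(self, a, b, mu, sigma):
        val, _ = quad(lambda z: (a - z) / sigma * norm.pdf((z - mu) / sigma),
                      mu - 12 * sigma, b)
        assert psi(a, b, mu, sigma) == pytest.approx(val, abs=1e-8)

    def test_empty_integration_range(self):
        assert psi(1.0, -40.0, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_sigma_step(self):
        assert psi(2.0, 1.0, 0.5, 0.0) == pytest.approx(1.5)
        assert psi(2.0, 1.0, 1.5, 0.0) == 0.0


def mc_ehvi(mu1, s1, mu2, s2, front, ref, n, rng):
    """Monte-Carlo EHVI oracle: average geometric hypervolume gain over
    Gaussian draws, using the sweep-based hypervolume routine per draw."""
    y1 = rng.normal(mu1, s1, n)
    y2 = rng.normal(mu2, s2, n)
    base = hypervolume(front, ref)
    gains = np.empty(n)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            gains[i] = hypervolume(np.vstack([front, [[y1[i], y2[i]]]]), ref) - base
    return gains.mean(), gains.std(ddof=1) / np.sqrt(n)


class TestEHVI:
    def test_dominated_deterministic_candidate_zero(self):
        v = ehvi_batch([0.2], [0.0], [0.2], [0.0], [[1, 1]], (0, 0))
        assert v[0] == 0.0

    def test_dominating_deterministic_candidate_equals_hv_gain(self):
        front = np.array([[1.0, 1.0], [0.5, 1.5]])
        v = ehvi_batch([2.0], [0.0], [2.0], [0.0], front, (0, 0))
        gain = hypervolume(np.vstack([front, [[2, 2]]]), (0, 0)) - hypervolume(front, (0, 0))
        assert v[0] == pytest.approx(gain)

    def test_always_nonnegative(self, rng):
        for _ in range(50):
            nf = rng.integers(1, 6)
            front = rng.uniform(0, 2, (nf, 2))
            v = ehvi_batch(rng.normal(1, 2, 4), rng.uniform(0, 1, 4),
                           rng.normal(1, 2, 4), rng.uniform(0, 1, 4),
                           front, (-0.5, -0.5))
            assert np.all(v >= 0)

    def test_matches_monte_carlo(self, rng):
        for _ in range(6):
            nf = int(rng.integers(1, 6))
            front = rng.uniform(0.3, 2.0, (nf, 2))
            front = front[pareto_front(front)]
            mu1, mu2 = rng.uniform(0, 2.2, 2)
            s1, s2 = rng.uniform(0.1, 0.8, 2)
            exact = ehvi_batch([mu1], [s1], [mu2], [s2], front, (0, 0))[0]
            m, se = mc_ehvi(mu1, s1, mu2, s2, front, (0, 0), 20000, rng)
            assert abs(exact - m) <= max(3 * se, 1e-3)

    def test_small_sd_limit_approaches_deterministic_gain(self):
        front = np.array([[1.0, 1.0]])
        gain = hypervolume(np.vstack([front, [[1.5, 1.5]]]), (0, 0)) - 1.0
        v = ehvi_batch([1.5], [1e-9], [1.5], [1e-9], front, (0, 0))
        assert v[0] == pytest.approx(gain, rel=1e-6)


class TestParetoArchive:
    def test_add_and_monotone_hypervolume(self, rng):
        arch = ParetoArchive(reference_point=(0.0, 0.0))
        hv_prev = 0.0
        for i in range(10):
            pts = rng.uniform(0.1, 1.0, (5, 2))
            arch.add([f"s{i}_{j}" for j in range(5)], pts)
            hv = arch.hypervolume()
            assert hv >= hv_prev - 1e-12
            hv_prev = hv
        assert len(pareto_front(arch.points)) == len(arch.points)

    def test_json_round_trip(self, rng):
        arch = ParetoArchive(reference_point=(0.0, 0.0))
        arch.add(["a", "b", "c"], np.array([[1, 3], [2, 2], [3, 1]]))
        arch2 = ParetoArchive.from_json(arch.to_json(iteration=4))
        assert arch2.ids == arch.ids
        np.testing.assert_allclose(arch2.points, arch.points)
        assert arch2.hypervolume() == pytest.approx(arch.hypervolume())


class TestSimilarityPenalty:
    def test_empty_history(self):
        assert similarity_penalty(np.array([1.0, 0.0]), []) == 1.0

    def test_identical_history_entry_zero(self):
        x = np.array([0.3, 0.7, 0.1])
        assert similarity_penalty(x, [x.copy()]) == 0.0

    def test_hand_computed_harmonic_mean(self):
        """Cosines 0 and 0.5 -> dissimilarities 0.5, 0.25 -> alpha = 1/3."""
        cand = np.array([1.0, 0.0])
        h1 = np.array([0.0, 1.0])           # cos 0
        h2 = np.array([1.0, np.sqrt(3.0)])  # cos 0.5
        assert similarity_penalty(cand, [h1, h2]) == pytest.approx(1.0 / 3.0)

    def test_permutation_invariance_and_bounds(self, rng):
        cand = rng.uniform(0, 1, 8)
        hist = [rng.uniform(0, 1, 8) for _ in range(6)]
        a1 = similarity_penalty(cand, hist)
        a2 = similarity_penalty(cand, hist[::-1])
        assert a1 == pytest.approx(a2)
        assert 0.0 <= a1 <= 1.0

    def test_batch_matches_scalar(self, rng):
        hist = [rng.uniform(0, 1, 8) for _ in range(5)]
        X = rng.uniform(0, 1, (7, 8))
        batch = similarity_penalty_batch(X, hist)
        for i in range(7):
            assert batch[i] == pytest.approx(similarity_penalty(X[i], hist))


class _StubGP:
    """Deterministic stand-in exposing the surrogate prediction surface."""

    def __init__(self, fn, sd=0.1):
        self.fn, self.sd = fn, sd

    def predict(self, X):
        from idpdesign.surrogates import SurrogatePrediction
        m = np.array([self.fn(x) for x in np.atleast_2d(X)])
        return SurrogatePrediction(mean=m, sd=np.full(len(m), self.sd))

    def predict_mean(self, X):
        return self.predict(X).mean


class _StubClassifier:
    def __init__(self, val):
        self.val = val

    def label(self, X):
        return np.full(len(np.atleast_2d(X)), self.val, dtype=int)


class TestFitness:
    def _ctx(self, k, clf_val=1):
        return FitnessContext(
            k=k, k_final=8,
            gp_b2=_StubGP(lambda x: x[0]),        # predicts B2~ = first feature
            gp_d=_StubGP(lambda x: x[1]),
            classifier=_StubClassifier(clf_val),
            front=np.array([[0.0, 0.0]]),
            reference_point=(-2.0, -2.0),
        )

    def test_stage0_ranks_by_negative_b2_prediction(self, rng):
        X = rng.uniform(0, 1, (10, 2))
        f = fitness(X, self._ctx(0))
        assert np.array_equal(np.argsort(f), np.argsort(-X[:, 0]))

    def test_classifier_gate_zeroes_ehvi_stage(self, rng):
        X = rng.uniform(0, 1, (6, 2))
        assert np.all(fitness(X, self._ctx(3, clf_val=0)) == 0.0)
        assert np.any(fitness(X, self._ctx(3, clf_val=1)) > 0.0)

    def test_final_stage_hand_values(self):
        # -B2~ + D~: (-0.3 + 1.5) = 1.2 preferred over (-0.8 + 1.5) = 0.7
        X = np.array([[0.3, 1.5], [0.8, 1.5]])
        f = fitness(X, self._ctx(8))
        assert f[0] == pytest.approx(1.2)
        assert f[1] == pytest.approx(0.7)
        assert f[0] > f[1]

    def test_missing_model_raises(self):
        ctx = FitnessContext(k=3, gp_b2=_StubGP(lambda x: x[0]))
        with pytest.raises(ValueError, match="EHVI stage requires"):
            fitness(np.zeros((1, 2)), ctx)
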