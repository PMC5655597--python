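import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcatsim.mgrm import (
    ItemParameters,
    category_probabilities,
    item_information,
    response_log_likelihood,
    simulate_response,
)

from .conftest import make_bank, make_item, random_item


def psi(x):
    """Independent logistic oracle used throughout this file."""
    return math.exp(x) / (1.0 + math.exp(x)) if x < 30 else 1.0


def oracle_probs(item, theta_d):
    """Three-branch category probabilities, written out by hand."""
    z = item.alpha * theta_d
    cum = [psi(z - b) for b in item.betas]
    probs = [1.0 - cum[0]]
    probs += [cum[j] - cum[j + 1] for j in range(len(cum) - 1)]
    probs.append(cum[-1])
    return np.array(probs)


class TestItemParameters:
    def test_non_increasing_betas_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ItemParameters("x", 1, 1.0, (0.0, 0.0))
        with pytest.raises(ValueError, match="strictly increasing"):
            ItemParameters("x", 1, 1.0, (1.0, -1.0))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            ItemParameters("x", 1, 0.0, (0.0,))

    @pytest.mark.parametrize("betas", [(), (0.0,) * 0, (-2, -1, 0, 1, 2)])
    def test_category_count_bounds(self, betas):
        with pytest.raises(ValueError):
            ItemParameters("x", 1, 1.0, betas)

    def test_n_categories(self):
        assert make_item(betas=(-1, 0, 1)).n_categories == 4


class TestBankValidation:
    def test_bad_correlation_rejected(self):
        item = make_item()
        bad = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            make_bank([item], n_dimensions=2, correlation=bad)
        with pytest.raises(ValueError, match="unit diagonal"):
            make_bank([item], n_dimensions=2,
                      correlation=np.array([[2.0, 0.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="positive definite"):
            make_bank([item], n_dimensions=2,
                      correlation=np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_domain_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_bank([make_item(domain=3)], n_dimensions=2)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_bank([make_item("a"), make_item("a")])


class TestCategoryProbabilities:
    def test_binary_item_at_threshold_is_half(self):
        # alpha * theta_d = beta_1  =>  linear predictor 0  =>  Psi(0) = 0.5
        item = make_item(alpha=2.0, betas=(1.0,))
        p = category_probabilities(item, np.array([0.5]))
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-12)

    def test_symmetric_four_category_item(self):
        item = make_item(alpha=1.7, betas=(-1.0, 0.0, 1.0))
        p = category_probabilities(item, np.zeros(1))
        assert p[0] == pytest.approx(p[3], abs=1e-12)
        assert p[1] == pytest.approx(p[2], abs=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        # frozen from the logistic: P_0 = 1 - Psi(1), P_1 = Psi(1) - Psi(0)
        assert p[0] == pytest.approx(0.2689414213699951, abs=1e-12)
        assert p[1] == pytest.approx(0.2310585786300049, abs=1e-12)

    def test_only_own_dimension_matters(self):
        item = make_item(domain=2)
        theta_a = np.array([5.0, 0.3, -4.0])
        theta_b = np.array([-1.0, 0.3, 2.0])
        np.testing.assert_allclose(
            category_probabilities(item, theta_a),
            category_probabilities(item, theta_b),
        )

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="theta"):
            category_probabilities(make_item(domain=3), np.zeros(2))

    def test_normalization_and_positivity_random(self, rng):
        for _ in range(1000):
            item = random_item(rng)
            theta = rng.uniform(-4, 4, size=1)
            p = category_probabilities(item, theta)
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p > 0)

    def test_matches_hand_oracle(self, rng):
        for _ in range(50):
            item = random_item(rng)
            theta_d = float(rng.uniform(-4, 4))
            np.testing.assert_allclose(
                category_probabilities(item, np.array([theta_d])),
                oracle_probs(item, theta_d),
                atol=1e-12,
            )


class TestSimulateResponse:
    def test_degenerate_low_theta(self, rng):
        item = make_item(alpha=3.0, betas=(0.0, 1.0))
        draws = [simulate_response(item, np.array([-8.0]), rng) for _ in range(200)]
        assert all(d == 0 for d in draws)

    def test_empirical_frequencies_match_probabilities(self):
        item = make_item(alpha=1.3, betas=(-0.8, 0.2, 1.1))
        theta = np.array([0.4])
        p = category_probabilities(item, theta)
        n = 100_000
        rng = np.random.default_rng(7)
        draws = np.array([simulate_response(item, theta, rng) for _ in range(n)])
        freqs = np.bincount(draws, minlength=item.n_categories) / n
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(freqs - p) < 3 * se)

    def test_identical_seeds_identical_draws(self):
        item = make_item()
        theta = np.array([0.2])
        r1, r2 = np.random.default_rng(42), np.random.default_rng(42)
        s1 = [simulate_response(item, theta, r1) for _ in range(50)]
        s2 = [simulate_response(item, theta, r2) for _ in range(50)]
        assert s1 == s2


class TestLogLikelihood:
    def test_single_binary_item_at_threshold(self):
        item = make_item(alpha=1.0, betas=(0.0,))
        bank = make_bank([item])
        ll = response_log_likelihood(bank, [("i1", 1)], np.zeros(1))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_empty_pattern_is_zero(self, small_bank):
        assert response_log_likelihood(small_bank, [], np.zeros(2)) == 0.0

    def test_additivity(self, small_bank):
        theta = np.array([0.3, -0.2])
        a = [("s0", 1)]
        b = [("s1", 0)]
        assert response_log_likelihood(small_bank, a + b, theta) == pytest.approx(
            response_log_likelihood(small_bank, a, theta)
            + response_log_likelihood(small_bank, b, theta)
        )

    def test_brute_force_oracle_random_patterns(self, small_bank, rng):
        for _ in range(20):
            theta = rng.uniform(-2, 2, size=2)
            pattern = []
            expected = 0.0
            for item in small_bank.items:
                if rng.uniform() < 0.4:
                    continue
                cat = int(rng.integers(item.n_categories))
                pattern.append((item.item_id, cat))
                expected += math.log(oracle_probs(item, theta[item.domain - 1])[cat])
            got = response_log_likelihood(small_bank, pattern, theta)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_invalid_category_rejected(self, small_bank):
        item = small_bank.items[0]
        with pytest.raises(ValueError, match="out of range"):
            response_log_likelihood(
                small_bank, [(item.item_id, item.n_categories)], np.zeros(2)
            )


def numeric_expected_neg_hessian(item, theta_d, h=1e-4):
    """E[-d2 log P / d theta_d^2] by central finite differences."""
    probs = oracle_probs(item, theta_d)
    total = 0.0
    for c, p in enumerate(probs):
        lp = [
            math.log(oracle_probs(item, theta_d + dx)[c])
            for dx in (-h, 0.0, h)
        ]
        d2 = (lp[0] - 2 * lp[1] + lp[2]) / h**2
        total += p * (-d2)
    return total


class TestItemInformation:
    def test_structure_only_own_diagonal(self, rng):
        item = random_item(rng, domain=2)
        info = item_information(item, np.zeros(4))
        expected = np.zeros((4, 4))
        expected[1, 1] = info[1, 1]
        np.testing.assert_array_equal(info, expected)
        assert info[1, 1] > 0

    def test_numeric_hessian_oracle(self, rng):
        for k in range(5):
            item = random_item(rng, item_id=f"h{k}")
            for theta_d in np.linspace(-3, 3, 10):
                info = item_information(item, np.array([theta_d]))
                want = numeric_expected_neg_hessian(item, theta_d)
                assert info[0, 0] == pytest.approx(want, abs=1e-4), (item, theta_d)

    def test_binary_reduces_to_2pl(self, rng):
        for _ in range(10):
            item = random_item(rng, n_categories=2)
            theta_d = float(rng.uniform(-3, 3))
            p1 = category_probabilities(item, np.array([theta_d]))[1]
            info = item_information(item, np.array([theta_d]))
            assert info[0, 0] == pytest.approx(item.alpha**2 * p1 * (1 - p1), rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        theta_d=st.floats(-5, 5),
        domain=st.integers(1, 4),
    )
    def test_psd_property(self, seed, theta_d, domain):
        item = random_item(np.random.default_rng(seed), domain=domain)
        theta = np.zeros(4)
        theta[domain - 1] = theta_d
        info = item_information(item, theta)
        assert np.linalg.eigvalsh(info).min() >= -1e-10
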