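"""Unit and property tests for the Shannon/THC entropy family and the
batch losses: worked examples, limit equivalence at alpha -> 1,
nonnegativity, generator consistency and the analytic gradient."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thcpred import (
    AlphaParam,
    BinaryBatch,
    ProbabilityVector,
    VolumePair,
    binary_shannon_loss,
    binary_thc_loss,
    binary_thc_loss_gradient,
    h_alpha,
    mse_reconstruction_loss,
    shannon_cross_entropy,
    shannon_entropy,
    thc_cross_entropy,
    thc_entropy,
    total_loss,
)
from thcpred.entropy import EPS, InvalidDistributionError, ParameterError


def random_distribution(rng, k):
    p = rng.dirichlet(np.ones(k))
    return p / p.sum()


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "p, expected",
    [
        ([1.0, 0.0], 0.0),
        ([0.5, 0.5], np.log(2)),
        ([0.9, 0.1], 0.325083),
    ],
)
def test_shannon_entropy_examples(p, expected):
    assert shannon_entropy(p) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize(
    "q, p, expected",
    [
        ([0.8, 0.2], [1.0, 0.0], -np.log(0.8)),
        ([0.5, 0.5], [0.5, 0.5], np.log(2)),
    ],
)
def test_shannon_cross_entropy_examples(q, p, expected):
    assert shannon_cross_entropy(q, p) == pytest.approx(expected, abs=1e-6)


def test_shannon_cross_entropy_minimum_at_clamped_dirac():
    val = shannon_cross_entropy([1.0 - EPS, EPS], [1.0, 0.0])
    assert 0.0 <= val < 2 * EPS


@pytest.mark.parametrize(
    "u, alpha, expected",
    [
        (1.0, 0.7, 0.0),
        (1.0, 2.0, 0.0),
        (0.5, 2.0, -0.25),
        (0.25, 0.5, -0.5),
    ],
)
def test_h_alpha_examples(u, alpha, expected):
    assert h_alpha(u, alpha) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "p, alpha, expected, tol",
    [
        ([1.0, 0.0], 2.0, 0.0, 1e-12),
        ([1.0, 0.0], 0.5, 0.0, 1e-12),
        ([0.5, 0.5], 2.0, 0.5, 1e-12),
        ([0.9, 0.1], 1.0 + 1e-4, 0.325083, 2e-4),
        ([0.9, 0.1], 1.0 - 1e-4, 0.325083, 2e-4),
    ],
)
def test_thc_entropy_examples(p, alpha, expected, tol):
    assert thc_entropy(p, alpha) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize(
    "q, p, alpha, expected",
    [
        ([0.8, 0.2], [1.0, 0.0], 2.0, 0.2),
        ([0.25, 0.75], [1.0, 0.0], 0.5, 2.0),
    ],
)
def test_thc_cross_entropy_examples(q, p, alpha, expected):
    assert thc_cross_entropy(q, p, alpha) == pytest.approx(expected, abs=1e-6)


def test_thc_cross_entropy_zero_on_matching_dirac():
    for alpha in (0.5, 2.0, 3.5):
        val = thc_cross_entropy([1.0, 0.0], [1.0, 0.0], alpha)
        assert val == pytest.approx(0.0, abs=1e-5)


@pytest.mark.parametrize(
    "labels, preds, alpha, expected",
    [
        ([1], [0.5], None, np.log(2)),        # None -> Shannon
        ([1, 0], [0.9, 0.1], None, 0.105361),
        ([1], [0.8], 2.0, 0.2),
        ([1, 0], [0.8, 0.2], 2.0, 0.2),
    ],
)
def test_binary_loss_examples(labels, preds, alpha, expected):
    batch = BinaryBatch(labels, preds)
    if alpha is None:
        val = binary_shannon_loss(batch)
    else:
        val = binary_thc_loss(batch, alpha)
    assert val == pytest.approx(expected, abs=1e-6)


def test_binary_shannon_loss_perfect_prediction_near_zero():
    assert binary_shannon_loss(BinaryBatch([1], [1.0 - EPS])) < 1e-6


@pytest.mark.parametrize(
    "labels, preds, alpha, expected",
    [
        ([1], [0.8], 2.0, [-1.0]),
        ([0], [0.5], 2.0, [1.0]),
    ],
)
def test_binary_thc_gradient_examples(labels, preds, alpha, expected):
    grad = binary_thc_loss_gradient(BinaryBatch(labels, preds), alpha)
    assert grad == pytest.approx(expected, abs=1e-9)


def test_mse_reconstruction_loss_examples():
    y = np.array([[1.0, 2.0]]).reshape(1, 2, 1)
    zero = np.zeros_like(y)
    assert mse_reconstruction_loss([VolumePair(y, y)]) == 0.0
    assert mse_reconstruction_loss([VolumePair(y, zero)]) == pytest.approx(5.0)
    a = np.zeros((2, 1, 1))
    b = np.zeros((2, 1, 1))
    pair_5 = VolumePair(np.sqrt([[ [5.0]], [[0.0]]]), a)
    pair_3 = VolumePair(np.sqrt([[[3.0]], [[0.0]]]), b)
    assert mse_reconstruction_loss([pair_5, pair_3]) == pytest.approx(4.0)


def test_total_loss_is_exact_sum():
    assert total_loss(0.0, 0.0).total == 0.0
    assert total_loss(5.0, 0.2).total == 5.2
    lb = total_loss(3.25, 0.0)
    assert lb.total == lb.rec == 3.25


# ---------------------------------------------------------------------------
# Validation errors
# ---------------------------------------------------------------------------


def test_invalid_distributions_rejected():
    with pytest.raises(InvalidDistributionError):
        ProbabilityVector([0.5, 0.6])
    with pytest.raises(InvalidDistributionError):
        ProbabilityVector([-0.1, 1.1])
    with pytest.raises(ValueError):
        shannon_cross_entropy([0.5, 0.5], [0.3, 0.3, 0.4])
    with pytest.raises(ParameterError):
        AlphaParam(0.0)
    with pytest.raises(ParameterError):
        thc_entropy([0.5, 0.5], -1.0)
    with pytest.raises(ValueError):
        BinaryBatch([], [])
    with pytest.raises(ValueError):
        BinaryBatch([1, 2], [0.5, 0.5])
    with pytest.raises(ValueError):
        VolumePair(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


# ---------------------------------------------------------------------------
# Invariants
# ---------------------------------------------------------------------------


def test_limit_equivalence_alpha_near_one():
    """THC reduces to Shannon within 1e-3 at alpha = 1 +/- 1e-4.

    Distributions are drawn with a small uniform admixture: the
    second-order term of the expansion in (alpha - 1) grows like
    p (log q)^2, so the stated bound presumes probabilities away from 0.
    """
    rng = np.random.default_rng(42)
    for _ in range(1000):
        k = int(rng.integers(2, 6))
        p = 0.85 * random_distribution(rng, k) + 0.15 / k
        q = 0.85 * random_distribution(rng, k) + 0.15 / k
        n = int(rng.integers(1, 8))
        labels = rng.integers(0, 2, n).astype(float)
        preds = rng.uniform(0.01, 0.99, n)
        batch = BinaryBatch(labels, preds)
        for alpha in (1.0 - 1e-4, 1.0 + 1e-4):
            assert abs(thc_entropy(p, alpha) - shannon_entropy(p)) < 1e-3
            assert abs(
                thc_cross_entropy(q, p, alpha) - shannon_cross_entropy(q, p)
            ) < 1e-3
            assert abs(
                binary_thc_loss(batch, alpha) - binary_shannon_loss(batch)
            ) < 1e-3


def test_nonnegativity_of_thc_family():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        k = int(rng.integers(2, 7))
        p = random_distribution(rng, k)
        q = random_distribution(rng, k)
        alpha = float(rng.uniform(1e-3, 4.0))
        assert thc_entropy(p, alpha) >= 0.0
        assert thc_cross_entropy(q, p, alpha) >= -1e-12


def test_generator_consistency():
    """thc_entropy(p) == -sum_i h_alpha(p_i) to 1e-12."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        k = int(rng.integers(2, 7))
        p = random_distribution(rng, k)
        alpha = float(rng.uniform(0.1, 4.0))
        direct = thc_entropy(p, alpha)
        via_generator = -sum(h_alpha(u, alpha) for u in p)
        assert direct == pytest.approx(via_generator, abs=1e-12)


def test_dirac_zero_for_all_four():
    dirac = [1.0, 0.0, 0.0]
    for alpha in (0.5, 2.0, 3.0):
        assert thc_entropy(dirac, alpha) == pytest.approx(0.0, abs=1e-6)
        assert thc_cross_entropy(dirac, dirac, alpha) == pytest.approx(0.0, abs=1e-5)
    assert shannon_entropy(dirac) == 0.0
    assert shannon_cross_entropy(dirac, dirac) == pytest.approx(0.0, abs=1e-6)


def test_uniform_closed_form():
    """thc_entropy(uniform_k) == (1 - k^(1-alpha))/(alpha-1), against the
    direct-summation oracle."""
    for k in range(2, 11):
        uniform = np.full(k, 1.0 / k)
        for alpha in (0.5, 2.0, 3.0):
            closed = (1.0 - k ** (1.0 - alpha)) / (alpha - 1.0)
            oracle = (1.0 - np.sum(uniform**alpha)) / (alpha - 1.0)
            assert thc_entropy(uniform, alpha) == pytest.approx(closed, abs=1e-12)
            assert closed == pytest.approx(oracle, abs=1e-12)


def _finite_difference_gradient(labels, preds, alpha, step=1e-6):
    grads = []
    for i in range(len(preds)):
        up = np.array(preds, dtype=float)
        dn = np.array(preds, dtype=float)
        up[i] += step
        dn[i] -= step
        f_up = binary_thc_loss(BinaryBatch(labels, up), alpha)
        f_dn = binary_thc_loss(BinaryBatch(labels, dn), alpha)
        grads.append((f_up - f_dn) / (2 * step))
    return np.array(grads)


@pytest.mark.parametrize("alpha", [0.3, 0.5, 1.0, 1.5, 2.3, 3.5])
def test_gradient_matches_finite_differences(alpha):
    """Analytic dL/dq_n vs central differences, rel. error < 1e-5 on a
    grid of prediction values."""
    qs = np.round(np.arange(0.01, 1.0, 0.07), 2)
    labels = np.tile([1.0, 0.0], len(qs))[: len(qs)]
    analytic = binary_thc_loss_gradient(BinaryBatch(labels, qs), alpha)
    numeric = _finite_difference_gradient(labels, qs, alpha)
    rel = np.abs(analytic - numeric) / np.maximum(np.abs(numeric), 1e-12)
    assert rel.max() < 1e-5


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    st.floats(0.05, 4.0),
)
def test_thc_entropy_nonnegative_and_below_uniform(weights, alpha):
    p = np.array(weights) / np.sum(weights)
    if abs(np.sum(p) - 1.0) > 1e-12:
        p[-1] = 1.0 - np.sum(p[:-1])
    h = thc_entropy(p, alpha)
    h_uniform = thc_entropy(np.full(p.size, 1.0 / p.size), alpha)
    assert h >= -1e-12
    assert h <= h_uniform + 1e-9


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.sampled_from([0.0, 1.0]), min_size=1, max_size=10),
    st.floats(0.05, 4.0),
    st.integers(0, 2**31 - 1),
)
def test_binary_thc_loss_nonnegative_and_zero_at_truth(labels, alpha, seed):
    rng = np.random.default_rng(seed)
    preds = rng.uniform(0.01, 0.99, len(labels))
    batch = BinaryBatch(labels, preds)
    assert binary_thc_loss(batch, alpha) >= -1e-12
    perfect = BinaryBatch(labels, np.array(labels))
    assert binary_thc_loss(perfect, alpha) == pytest.approx(0.0, abs=1e-5)
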