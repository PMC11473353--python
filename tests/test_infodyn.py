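"""Entropy, ApEn, AMI and transfer-entropy estimators against oracles."""

import numpy as np
import pytest

from socimotor import errors
from socimotor.infodyn import (
    approximate_entropy,
    auto_template_length,
    average_mutual_information,
    entropy_rate_decomposition,
    local_transfer_entropy,
    shannon_entropy,
    transfer_entropy,
)


@pytest.mark.parametrize("counts,expected", [
    ({0: 1, 1: 1}, 1.0),
    ({"a": 5}, 0.0),
    ({"a": 1, "b": 1, "c": 1, "d": 1}, 2.0),
])
def test_shannon_entropy(counts, expected):
    assert shannon_entropy(counts, base=2) == pytest.approx(expected)


def test_shannon_entropy_rejects_empty():
    with pytest.raises(errors.InputError):
        shannon_entropy({0: 0, 1: 0})


def _apen_oracle(x, m, r, base=2.0):
    """Literal double-loop template-count formulation."""
    x = np.asarray(x, float)
    N = len(x)
    nt = N - m
    total = 0.0
    for i in range(nt):
        cm = sum(
            max(abs(x[i + d] - x[j + d]) for d in range(m)) < r
            for j in range(nt))
        cm1 = sum(
            max(abs(x[i + d] - x[j + d]) for d in range(m + 1)) < r
            for j in range(nt))
        total += np.log(cm / cm1)
    return total / nt / np.log(base)


def test_apen_constant_is_exactly_zero():
    assert approximate_entropy(np.ones(200), m=3, r=0.5).value == 0.0


def test_apen_periodic_binary_near_zero():
    x = np.tile([0, 1], 500)
    assert approximate_entropy(x, m=2, r=0.5).value <= 0.01


def test_apen_iid_fair_bits_near_one(rng):
    x = rng.integers(0, 2, 10_000)
    est = approximate_entropy(x, m=2, r=0.5)
    assert est.value == pytest.approx(1.0, abs=0.05)
    # alphabet bound for binary data
    assert est.value <= 1.0 + 0.02


@pytest.mark.parametrize("m", [1, 2, 3])
def test_apen_matches_exhaustive_oracle(rng, m):
    x = rng.integers(0, 2, 200)
    est = approximate_entropy(x, m=m, r=0.5)
    assert est.value == pytest.approx(_apen_oracle(x, m, 0.5), abs=1e-12)


def test_apen_continuous_path_matches_oracle(rng):
    x = rng.normal(size=120)
    est = approximate_entropy(x, m=2, r=0.4)
    assert est.value == pytest.approx(_apen_oracle(x, 2, 0.4), abs=1e-12)


def test_apen_contracts():
    with pytest.raises(errors.InputError):
        approximate_entropy(np.zeros(4), m=3, r=0.5)
    with pytest.raises(errors.InputError):
        approximate_entropy(np.zeros(100), m=2, r=0.0)


def test_auto_template_length():
    bits = np.zeros(100, np.uint8)
    bits[[10, 16, 22]] = 1  # mean ISI 6
    assert auto_template_length(bits) == 6
    bits2 = np.zeros(100, np.uint8)
    bits2[[0, 90]] = 1
    assert auto_template_length(bits2) == 10  # capped
    assert auto_template_length(np.zeros(50, np.uint8)) == 1


def _ami_oracle(x, tau, n_bins=16):
    """Direct histogram MI between x_t and x_{t+tau}, in bits."""
    a, b = x[:-tau], x[tau:]
    h, _, _ = np.histogram2d(a, b, bins=n_bins,
                             range=[[x.min(), x.max()]] * 2)
    p = h / h.sum()
    pa, pb = p.sum(1), p.sum(0)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / np.outer(pa, pb)[nz])).sum())


def test_ami_iid_noise_near_zero(rng):
    x = rng.random(10_000)
    ed = average_mutual_information(x, max_lag=20)
    assert np.all(ed.ami_curve < 0.05)
    assert 1 <= ed.delay <= 3
    # matches the direct-count oracle at a few lags
    for tau in (1, 5, 10):
        assert ed.ami_curve[tau - 1] == pytest.approx(
            _ami_oracle(x, tau), abs=1e-9)


def test_ami_sine_quarter_period_minimum():
    """Quarter-period AMI minimum for a 1 Hz sine at 128 Hz (8 bins)."""
    t = np.arange(10_000) / 128
    x = np.sin(2 * np.pi * t)
    ed = average_mutual_information(x, max_lag=40, n_bins=8)
    assert abs(int(np.argmin(ed.ami_curve)) + 1 - 32) <= 2


def test_ami_period_five_structure(rng):
    base = rng.integers(0, 4, 5).astype(float)
    base[0] += 10  # ensure non-constant
    x = np.tile(base, 2000)
    ed = average_mutual_information(x, max_lag=12)
    # AMI peaks at multiples of 5 and the first local minimum is below 5
    assert ed.ami_curve[4] == max(ed.ami_curve)
    assert ed.delay < 5


def test_ami_constant_rejected():
    with pytest.raises(errors.DegenerateDataError):
        average_mutual_information(np.ones(1000), max_lag=10)


def _copy_pair(rng, n, flip_p=0.0):
    x = rng.integers(0, 2, n)
    y = np.empty(n, dtype=int)
    y[0] = 0
    y[1:] = x[:-1]
    if flip_p:
        flips = rng.random(n) < flip_p
        y[1:] ^= flips[1:].astype(int)
    return x, y


def test_te_independent_near_zero(rng):
    x = rng.integers(0, 2, 100_000)
    z = rng.integers(0, 2, 100_000)
    assert transfer_entropy(z, x, k=1, l=1).value <= 0.01


def test_te_deterministic_copy_one_bit(rng):
    x, y = _copy_pair(rng, 100_000)
    assert transfer_entropy(y, x, k=1, l=1).value == pytest.approx(1.0, abs=0.01)


def test_te_noisy_copy_binary_channel(rng):
    x, y = _copy_pair(rng, 100_000, flip_p=0.1)
    expected = 1.0 - (-0.1 * np.log2(0.1) - 0.9 * np.log2(0.9))
    assert transfer_entropy(y, x, k=1, l=1).value == pytest.approx(
        expected, abs=0.02)


def test_local_te_mean_equals_average(rng):
    x = rng.integers(0, 2, 5000)
    y = rng.integers(0, 2, 5000)
    loc = local_transfer_entropy(y, x, k=2, l=2)
    te = transfer_entropy(y, x, k=2, l=2)
    assert np.mean(loc) == pytest.approx(te.value, abs=1e-9)
    # independent processes: mean near zero, individual values signed
    assert abs(np.mean(loc)) < 0.01
    assert np.min(loc) < 0 < np.max(loc)


def test_local_te_deterministic_copy_all_one_bit(rng):
    x, y = _copy_pair(rng, 20_000)
    loc = local_transfer_entropy(y, x, k=1, l=1)
    np.testing.assert_allclose(loc, 1.0, atol=0.05)


def test_entropy_rate_decomposition_identity(rng):
    for seed in range(3):
        r = np.random.default_rng(seed)
        x = r.integers(0, 2, 4000)
        y = (np.roll(x, 1) ^ (r.random(4000) < 0.2)).astype(int)
        h_x, h_xy, te = entropy_rate_decomposition(y, x, k=2, l=2)
        te_direct = transfer_entropy(y, x, k=2, l=2)
        assert te.value == pytest.approx(h_x - h_xy, abs=1e-9)
        assert te.value == pytest.approx(te_direct.value, abs=1e-9)
        loc = local_transfer_entropy(y, x, k=2, l=2)
        assert np.mean(loc) == pytest.approx(te.value, abs=1e-9)


def test_decomposition_copy_and_independent(rng):
    x, y = _copy_pair(rng, 50_000)
    h_x, h_xy, _ = entropy_rate_decomposition(y, x, k=1, l=1)
    assert h_x == pytest.approx(1.0, abs=0.01)
    assert h_xy == pytest.approx(0.0, abs=0.01)
    z = rng.integers(0, 2, 50_000)
    h_x2, h_xy2, _ = entropy_rate_decomposition(z, x, k=1, l=1)
    assert h_xy2 == pytest.approx(h_x2, abs=0.01)


def test_te_non_negative_and_shuffle_null(rng):
    """Shuffling the source keeps TE at or below the shuffle null tail."""
    x = rng.integers(0, 2, 8000)
    y = (np.roll(x, 2) ^ (rng.random(8000) < 0.3)).astype(int)
    te = transfer_entropy(y, x, k=3, l=3)
    assert te.value >= -1e-12
    null = []
    for s in range(100):
        r2 = np.random.default_rng(1000 + s)
        null.append(transfer_entropy(y, r2.permutation(x), k=3, l=3).value)
    shuffled = transfer_entropy(y, np.random.default_rng(7).permutation(x),
                                k=3, l=3)
    assert shuffled.value <= np.percentile(null, 95)
    assert te.value > np.percentile(null, 95)  # true coupling detected


def test_te_shuffle_correction_clips_at_zero(rng):
    x = rng.integers(0, 2, 3000)
    z = rng.integers(0, 2, 3000)
    est = transfer_entropy(z, x, k=2, l=2, shuffle_correct=True, seed=3)
    assert est.value >= 0.0
    assert est.estimator == "plugin_shuffle_corrected"


def test_te_pooled_segments_respect_boundaries(rng):
    """Pooling windows must not count transitions across window edges."""
    x = rng.integers(0, 2, 2000)
    y = rng.integers(0, 2, 2000)
    whole = transfer_entropy(y, x, k=1, l=1)
    halves = transfer_entropy(None, None, k=1, l=1,
                              pairs=[(y[:1000], x[:1000]),
                                     (y[1000:], x[1000:])])
    # one transition per boundary is dropped, not relabelled
    assert halves.n_eff == whole.n_eff - 1


def test_te_history_too_long_rejected(rng):
    with pytest.raises(errors.InputError):
        transfer_entropy(rng.integers(0, 2, 10), rng.integers(0, 2, 10),
                         k=20, l=20)
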