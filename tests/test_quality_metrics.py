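import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbobhe import (
    GrayImage,
    MetricConfig,
    ambe,
    asd,
    compute_histogram,
    entropy,
    make_ramp,
    mean_brightness,
    nrms_contrast,
    rbd,
    rcd,
)


def gray(values, levels=256):
    return GrayImage(np.asarray(values), levels)


class TestMoments:
    def test_mean_brightness_examples(self):
        assert mean_brightness(np.full((3, 3), 0.5)) == 0.5
        assert mean_brightness(np.array([[0.0, 1.0]])) == 0.5
        assert mean_brightness(np.array([[0.0, 0.2], [0.4, 0.6]])) == pytest.approx(0.3)

    def test_nrms_contrast_examples(self):
        assert nrms_contrast(np.full((4, 4), 0.3)) == 0.0
        assert nrms_contrast(np.array([[0.0, 1.0]])) == 0.5
        assert nrms_contrast(np.array([[0.0, 0.5], [1.0, 0.5]])) == pytest.approx(
            np.sqrt(0.125)
        )

    def test_integer_path_matches_float_path(self, phantom):
        from mbobhe import normalize

        assert mean_brightness(phantom) == pytest.approx(
            mean_brightness(normalize(phantom)), abs=1e-14
        )
        assert nrms_contrast(phantom) == pytest.approx(
            nrms_contrast(normalize(phantom)), abs=1e-14
        )


class TestRelativeDifferences:
    def test_identity_fingerprint(self, phantom):
        assert rbd(phantom, phantom) == 1.0
        assert rcd(phantom, phantom) == 0.0
        assert asd(phantom, phantom) == 1.0
        assert ambe(phantom, phantom) == 0.0

    def test_rbd_worked_value(self):
        x = np.full((1, 2), 0.5)
        y = np.full((1, 2), 0.6)
        assert rbd(x, y) == pytest.approx(np.exp(-0.1 / 0.500001), rel=1e-12)
        assert rbd(x, y) == pytest.approx(0.81873, abs=5e-6)

    def test_rbd_black_input_is_finite(self):
        x = np.zeros((2, 2))
        y = np.full((2, 2), 0.5)
        v = rbd(x, y)
        assert np.isfinite(v) and v == pytest.approx(0.0, abs=1e-12)

    def test_rbd_signed_variant(self):
        cfg = MetricConfig(signed_rbd=True)
        x = np.full((1, 2), 0.5)
        y = np.full((1, 2), 0.6)
        assert rbd(x, y, cfg) == pytest.approx(np.exp(0.1 / 0.500001))
        assert rbd(y, x, MetricConfig(signed_rbd=True)) < 1.0

    def test_rcd_worked_value(self):
        # sigma_x = 0.2, sigma_y = 0.3 via two-point images
        x = np.array([[0.3, 0.7]])  # mean .5, sd .2
        y = np.array([[0.2, 0.8]])  # mean .5, sd .3
        assert rcd(x, y) == pytest.approx(1 - np.exp(-0.1 / 0.200001), rel=1e-12)
        assert rcd(x, y) == pytest.approx(0.39347, abs=5e-6)

    def test_rcd_constant_input_saturates_finite(self):
        x = np.full((2, 2), 0.5)
        y = np.array([[0.4, 0.6], [0.4, 0.6]])  # sd 0.1
        v = rcd(x, y)
        assert np.isfinite(v) and v == pytest.approx(1.0, abs=1e-12)

    def test_ambe_symmetric(self):
        x = np.full((1, 2), 0.3)
        y = np.full((1, 2), 0.45)
        assert ambe(x, y) == pytest.approx(0.15)
        assert ambe(x, y) == ambe(y, x)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbd(np.zeros((2, 2)), np.zeros((2, 3)))


class TestASD:
    def test_mean_reflection_scores_zero(self):
        x = np.array([[0.2, 0.8], [0.1, 0.9]])
        y = 1.0 - x  # reflects each pixel across the (equal) means
        assert asd(x, y) == 0.0

    def test_half_preserved(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert asd(x, y) == 0.5

    def test_pixels_at_mean_count_as_preserved(self):
        x = np.full((2, 2), 0.5)
        y = np.array([[0.1, 0.9], [0.2, 0.8]])
        assert asd(x, y) == 1.0  # d = 0 everywhere on x's side

    def test_same_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 4))
        y = rng.random((4, 4))
        perm = rng.permutation(16)
        xp = x.ravel()[perm].reshape(4, 4)
        yp = y.ravel()[perm].reshape(4, 4)
        assert asd(x, y) == asd(xp, yp)


class TestEntropy:
    def test_known_values(self):
        assert entropy(compute_histogram(GrayImage(np.full((3, 3), 5)))) == 0.0
        assert entropy(compute_histogram(make_ramp(1, 256))) == 8.0
        two = GrayImage(np.array([[0, 1]]), 256)
        assert entropy(compute_histogram(two)) == 1.0


@settings(deadline=None, max_examples=250, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), m=st.integers(1, 8), n=st.integers(1, 8))
def test_metric_bounds_hold_for_random_pairs(seed, m, n):
    """RBD in (0,1], RCD in [0,1), ASD in [0,1] for arbitrary image pairs."""
    rng = np.random.default_rng(seed)
    x = GrayImage(rng.integers(0, 256, (m, n)), 256)
    y = GrayImage(rng.integers(0, 256, (m, n)), 256)
    r, c, a = rbd(x, y), rcd(x, y), asd(x, y)
    assert 0.0 <= r <= 1.0
    assert 0.0 <= c <= 1.0
    assert 0.0 <= a <= 1.0
    assert ambe(x, y) >= 0.0
    # the open ends of (0, 1] / [0, 1) are exact except where exp saturates
    # double precision (exponent magnitude beyond ~36 collapses 1 - exp(-t)
    # to 1.0; beyond ~745 exp(-t) underflows to 0.0)
    if r == 0.0:
        assert ambe(x, y) / (mean_brightness(x) + 1e-6) > 700
    if c == 1.0:
        assert abs(nrms_contrast(y) - nrms_contrast(x)) / (nrms_contrast(x) + 1e-6) > 36
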