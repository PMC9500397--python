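import math

import numpy as np
import pytest

from vesselseg import ConfigurationError, ParameterError
from vesselseg.bcosfire import (
    CosfireFilter,
    CosfireTuple,
    DoGParams,
    blur_shift_response,
    combined_vessel_response,
    configure_filter,
    dog_kernel,
    dog_response,
    filter_response,
    make_prototype,
    rotate_filter,
    rotation_tolerant_response,
)
from vesselseg.synthetic import generate_bar_image

from .oracles import naive_filter_response


class TestDogKernel:
    def test_center_value_closed_form(self):
        # 1/(2*pi*1.44) - 1/(2*pi*5.76) for sigma = 2.4
        k = dog_kernel(DoGParams(2.4))
        c = k.shape[0] // 2
        assert k[c, c] == pytest.approx(0.082893, abs=1e-5)

    def test_two_unit_gaussians_cancel(self):
        k = dog_kernel(DoGParams(2.4))
        assert abs(k.sum()) < 1e-3 * k.max()

    def test_radial_symmetry(self):
        k = dog_kernel(DoGParams(1.7))
        np.testing.assert_array_equal(k, k[::-1, ::-1])
        np.testing.assert_array_equal(k, k.T)

    def test_as_printed_sign_flips(self):
        params = DoGParams(2.0)
        flipped = DoGParams(2.0, sign="as_printed")
        np.testing.assert_array_equal(dog_kernel(params), -dog_kernel(flipped))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ParameterError):
            DoGParams(0.0)


class TestDogResponse:
    def test_constant_image_gives_zero(self):
        resp = dog_response(np.full((32, 32), 0.7), DoGParams(2.4))
        assert resp.max() < 1e-12

    def test_rectification_nonnegative(self, rng):
        resp = dog_response(rng.random((32, 32)), DoGParams(1.5))
        assert (resp >= 0).all()

    def test_bright_line_peaks_on_line(self):
        img = np.zeros((41, 41))
        img[:, 20] = 1.0
        resp = dog_response(img, DoGParams(2.4))
        assert (resp.argmax(axis=1)[5:-5] == 20).all()


class TestPrototype:
    def test_symmetric_bar_columns(self):
        proto = make_prototype("symmetric", 3, 101)
        assert (proto[:, 49:52] == 1).all()
        proto[:, 49:52] = 0
        assert not proto.any()

    def test_asymmetric_lower_half_only(self):
        proto = make_prototype("asymmetric", 3, 101)
        assert (proto[50:, 49:52] == 1).all()
        assert not proto[:50, :].any()

    @pytest.mark.parametrize("kind", ["symmetric", "asymmetric"])
    def test_mirror_symmetry(self, kind):
        proto = make_prototype(kind, 3, 41)
        np.testing.assert_array_equal(proto, proto[:, ::-1])

    def test_even_size_rejected(self):
        with pytest.raises(ParameterError):
            make_prototype("symmetric", 3, 100)


class TestConfigure:
    def test_symmetric_bar_tuple_geometry(self):
        f = configure_filter(make_prototype("symmetric", 3, 101), 2.4, [0, 2])
        rho0 = [t for t in f.tuples if t.rho == 0]
        rho2 = sorted(math.degrees(t.phi) for t in f.tuples if t.rho == 2)
        assert len(rho0) == 1 and len(rho2) == 2
        assert rho2[0] == pytest.approx(90, abs=5)
        assert rho2[1] == pytest.approx(270, abs=5)

    def test_asymmetric_bar_one_sided(self):
        f = configure_filter(
            make_prototype("asymmetric", 3, 101), 2.4, [0, 2], kind="asymmetric"
        )
        assert len(f.tuples) == 2
        (t2,) = [t for t in f.tuples if t.rho == 2]
        # lower-half bar: the point sits below the center, at 3*pi/2
        assert math.degrees(t2.phi) == pytest.approx(270, abs=5)

    def test_constant_prototype_rejected(self):
        with pytest.raises(ConfigurationError, match="no structure"):
            configure_filter(np.full((41, 41), 0.5), 2.4, [0, 2])


class TestBlurShift:
    def test_rho_zero_impulse_keeps_unit_peak(self):
        c = np.zeros((21, 21))
        c[10, 10] = 1.0
        out = blur_shift_response(c, CosfireTuple(2.4, 0.0, 0.0), sigma0_prime=2.0)
        assert out[10, 10] == pytest.approx(1.0)
        assert out.argmax() == np.ravel_multi_index((10, 10), out.shape)

    def test_shift_is_exact_translation_of_rho_zero_result(self):
        c = np.zeros((31, 31))
        c[15, 15] = 1.0
        base = blur_shift_response(c, CosfireTuple(2.4, 0.0, 0.0), sigma0_prime=2.0, alpha=0.0)
        shifted = blur_shift_response(c, CosfireTuple(2.4, 4.0, 0.0), sigma0_prime=2.0, alpha=0.0)
        # phi = 0: the tuple sits 4 columns toward +x; its response moves back
        # onto the center, so the map reads 4 columns toward +x
        np.testing.assert_allclose(shifted[:, :-4], base[:, 4:], atol=1e-15)
        assert not shifted[:, -4:].any()

    def test_bounded_by_input_maximum(self, rng):
        c = rng.random((24, 24))
        out = blur_shift_response(c, CosfireTuple(1.5, 3.0, 1.1))
        assert (out >= 0).all() and out.max() <= c.max() + 1e-12


def _random_filter(rng, max_tuples=6):
    n = int(rng.integers(1, max_tuples + 1))
    tuples = [CosfireTuple(float(rng.uniform(1.0, 2.5)), 0.0, 0.0)]
    for _ in range(n - 1):
        tuples.append(
            CosfireTuple(
                float(rng.uniform(1.0, 2.5)),
                float(rng.uniform(0.5, 6.0)),
                float(rng.uniform(0.0, 2 * math.pi)),
            )
        )
    return CosfireFilter(
        tuples=tuple(tuples),
        sigma0_prime=float(rng.uniform(2.0, 3.0)),
        alpha=float(rng.uniform(0.4, 0.8)),
        weight_sigma=float(rng.uniform(1.5, 4.0)),
        t=float(rng.choice([0.0, 0.2])),
    )


class TestFilterResponse:
    def test_single_tuple_identity(self, rng):
        img = rng.random((32, 32))
        tp = CosfireTuple(1.8, 2.0, math.pi / 3)
        f = CosfireFilter(tuples=(tp,), t=0.0)
        c = dog_response(img, DoGParams(1.8))
        np.testing.assert_allclose(
            filter_response(img, f), blur_shift_response(c, tp, f.sigma0_prime, f.alpha),
            atol=1e-12,
        )

    def test_zero_subresponse_zeroes_output(self):
        # far from an isolated impulse every sub-response is exactly 0, so the
        # AND-type geometric mean is exactly 0 there
        img = np.zeros((48, 48))
        img[24, 24] = 1.0
        f = CosfireFilter(
            tuples=(CosfireTuple(1.5, 0.0, 0.0), CosfireTuple(1.5, 2.0, 0.0)),
            sigma0_prime=2.0, alpha=0.5,
        )
        resp = filter_response(img, f)
        assert resp[24, 24] > 0
        assert resp[0, 0] == 0.0 and resp[-1, -1] == 0.0

    def test_constant_image_response_vanishes(self):
        f = CosfireFilter(tuples=(CosfireTuple(1.5, 0.0, 0.0), CosfireTuple(1.5, 2.0, 0.0)))
        assert filter_response(np.full((24, 24), 0.3), f).max() < 1e-9

    def test_matches_naive_rederivation(self, rng):
        for _ in range(3):
            img = rng.random((32, 32))
            f = _random_filter(rng)
            np.testing.assert_allclose(
                filter_response(img, f), naive_filter_response(img, f), atol=1e-9
            )

    def test_homogeneity_in_image_intensity(self, rng):
        img = rng.random((32, 32))
        f = _random_filter(rng)
        f = CosfireFilter(tuples=f.tuples, sigma0_prime=f.sigma0_prime, alpha=f.alpha,
                          weight_sigma=f.weight_sigma, t=0.0)
        base = filter_response(img, f)
        for c in (0.5, 2.0):
            np.testing.assert_allclose(filter_response(c * img, f), c * base, atol=1e-9)

    def test_equivariance_under_quarter_turn(self, rng):
        img = rng.random((33, 33))
        f = _random_filter(rng)
        rot_resp = filter_response(np.rot90(img), rotate_filter(f, math.pi / 2))
        np.testing.assert_allclose(rot_resp, np.rot90(filter_response(img, f)), atol=1e-12)


class TestRotation:
    def test_identity_and_inverse(self):
        f = configure_filter(make_prototype("symmetric", 3, 101), 2.4, [0, 2, 4])
        same = rotate_filter(f, 0.0)
        assert same.tuples == f.tuples
        back = rotate_filter(rotate_filter(f, 0.7), -0.7)
        for a, b in zip(back.tuples, f.tuples):
            assert math.isclose((a.phi - b.phi) % (2 * math.pi), 0.0, abs_tol=1e-12)

    def test_half_turn_preserves_symmetric_tuple_multiset(self):
        f = configure_filter(make_prototype("symmetric", 3, 101), 2.4, [0, 2, 4])
        rotated = rotate_filter(f, math.pi)
        orig = sorted((t.sigma, t.rho, round(t.phi % (2 * math.pi), 9)) for t in f.tuples)
        rot = sorted((t.sigma, t.rho, round(t.phi % (2 * math.pi), 9)) for t in rotated.tuples)
        assert orig == rot

    def test_single_orientation_equals_plain_response(self, rng):
        img = rng.random((32, 32))
        f = _random_filter(rng)
        np.testing.assert_array_equal(
            rotation_tolerant_response(img, f, 1), filter_response(img, f)
        )

    def test_max_dominates_each_orientation(self, rng):
        img = rng.random((32, 32))
        f = _random_filter(rng)
        out = rotation_tolerant_response(img, f, 4)
        for k in range(4):
            resp = filter_response(img, rotate_filter(f, k * math.pi / 4))
            assert (out >= resp - 1e-15).all()


class TestCombined:
    def test_symmetric_only_degenerate_combination(self, configured_filters):
        f_sym, _ = configured_filters
        img = generate_bar_image(60, 3, 0.4, size=101)
        comb = combined_vessel_response(img, f_sym, None, 12)
        assert comb.max() <= 1.0 + 1e-12 and comb.min() >= 0.0

    def test_output_range_within_zero_two(self, configured_filters):
        f_sym, f_asym = configured_filters
        img = generate_bar_image(60, 3, 1.2, size=101)
        comb = combined_vessel_response(img, f_sym, f_asym, 12)
        assert comb.min() >= 0.0 and comb.max() <= 2.0 + 1e-12

    def test_asymmetric_term_lifts_bar_ending(self, configured_filters):
        f_sym, f_asym = configured_filters
        # vertical bar occupying the lower half: its free end is at the center
        img = np.zeros((101, 101))
        img[50:, 49:52] = 1.0
        sym_only = combined_vessel_response(img, f_sym, None, 12)
        both = combined_vessel_response(img, f_sym, f_asym, 12)
        end = (50, 50)
        assert both[end] - sym_only[end] > 0.1
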