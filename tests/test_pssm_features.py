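"""Pseudo-Zernike numerics: coefficients, basis, moments, descriptors."""

import math
from fractions import Fraction

import numpy as np
import pytest

from ncrpi import (
    Pssm,
    PzmBasisCache,
    image_from_grid,
    normalize_pssm,
    pseudo_zernike_moment,
    pzm_basis,
    pzm_feature_vector,
    radial_coefficient,
    radial_polynomial,
    read_psiblast_pssm,
    to_unit_disk,
)
from ncrpi.pssm_features import basis_matrix, disk_grid, feature_length, moment_pairs


def exact_radial_coefficient(alpha: int, beta_abs: int, t: int) -> Fraction:
    """Independent oracle: exact integer-factorial arithmetic."""
    f = math.factorial
    return Fraction(
        (-1) ** t * f(2 * alpha + 1 - t),
        f(t) * f(alpha - beta_abs - t) * f(alpha + beta_abs + 1 - t),
    )


class TestRadialCoefficient:
    @pytest.mark.parametrize(
        "alpha,beta_abs,t,expected", [(0, 0, 0, 1.0), (1, 0, 0, 3.0), (1, 0, 1, -2.0)]
    )
    def test_low_order_values(self, alpha, beta_abs, t, expected):
        assert radial_coefficient(alpha, beta_abs, t) == pytest.approx(expected)

    def test_matches_exact_factorial_oracle_up_to_order_15(self):
        for alpha in range(16):
            for beta_abs in range(alpha + 1):
                for t in range(alpha - beta_abs + 1):
                    exact = float(exact_radial_coefficient(alpha, beta_abs, t))
                    got = radial_coefficient(alpha, beta_abs, t)
                    assert got == pytest.approx(exact, rel=1e-10)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            radial_coefficient(2, 3, 0)
        with pytest.raises(ValueError):
            radial_coefficient(2, 0, 3)


class TestRadialPolynomial:
    def test_constant_for_order_zero(self, rng):
        for rho in rng.uniform(0, 1, size=10):
            assert radial_polynomial(0, 0, rho) == pytest.approx(1.0)

    def test_diagonal_case_is_pure_power(self):
        assert radial_polynomial(2, 2, 0.7) == pytest.approx(0.49)
        assert radial_polynomial(5, 5, 0.9) == pytest.approx(0.9**5)

    def test_two_term_expansion(self):
        assert radial_polynomial(1, 0, 0.5) == pytest.approx(-0.5)

    def test_matches_coefficient_sum_oracle(self, rng):
        """Direct evaluation from exact coefficients at random points."""
        for _ in range(50):
            alpha = int(rng.integers(0, 9))
            beta_abs = int(rng.integers(0, alpha + 1))
            rho = float(rng.uniform(0, 1))
            expected = sum(
                float(exact_radial_coefficient(alpha, beta_abs, t)) * rho ** (alpha - t)
                for t in range(alpha - beta_abs + 1)
            )
            assert radial_polynomial(alpha, beta_abs, rho) == pytest.approx(
                expected, abs=1e-10
            )


class TestBasis:
    def test_order_zero_is_one_everywhere(self, rng):
        for _ in range(10):
            x, y = rng.uniform(-0.7, 0.7, size=2)
            assert pzm_basis(0, 0, x, y) == pytest.approx(1.0)

    def test_zero_repetition_is_real(self, rng):
        for _ in range(10):
            x, y = rng.uniform(-0.7, 0.7, size=2)
            assert pzm_basis(3, 0, x, y).imag == 0.0

    def test_v11_at_known_point(self):
        # rho = 0.5, theta = pi/2: R_{1,1} = rho, phase = e^{j pi/2} = j
        value = pzm_basis(1, 1, 0.0, 0.5)
        assert value == pytest.approx(0.5j, abs=1e-12)

    def test_point_outside_disk_rejected(self):
        with pytest.raises(ValueError):
            pzm_basis(1, 1, 0.9, 0.9)


class TestUnitDiskMapping:
    def test_square_grid_corners_on_unit_circle(self):
        image = to_unit_disk(Pssm(np.zeros((20, 20))))
        radii = np.hypot(image.x, image.y)
        assert radii.max() == pytest.approx(1.0)
        assert np.sum(np.isclose(radii, 1.0)) == 4

    def test_central_cell_of_odd_grid_near_origin(self):
        image = to_unit_disk(Pssm(np.zeros((21, 20))))
        d = math.hypot(20, 19)
        assert np.min(np.hypot(image.x, image.y)) <= math.sqrt(2) / d

    @pytest.mark.parametrize("r", [1, 2, 7, 100, 2000])
    def test_all_radii_inside_disk(self, r):
        image = to_unit_disk(Pssm(np.zeros((r, 20))))
        assert np.all(image.x**2 + image.y**2 <= 1.0 + 1e-12)

    def test_pixel_area_matches_cell_spacing(self):
        image = to_unit_disk(Pssm(np.zeros((30, 20))))
        d = math.hypot(29, 19)
        assert image.pixel_area == pytest.approx((2 / d) ** 2)


class TestMoments:
    def test_zero_image_gives_zero_moments(self):
        image = image_from_grid(np.zeros((15, 20)))
        for alpha in range(4):
            for beta in range(alpha + 1):
                assert pseudo_zernike_moment(image, alpha, beta) == 0.0

    def test_constant_disk_image_m00_converges_to_one(self):
        m00 = pseudo_zernike_moment(disk_grid(200), 0, 0)
        assert abs(m00 - 1.0) < 0.01

    def test_magnitude_symmetric_in_repetition_sign(self, rng):
        image = image_from_grid(rng.uniform(0, 1, size=(18, 20)))
        for alpha in range(1, 6):
            for beta in range(1, alpha + 1):
                plus = abs(pseudo_zernike_moment(image, alpha, beta))
                minus = abs(pseudo_zernike_moment(image, alpha, -beta))
                assert abs(plus - minus) < 1e-12

    @pytest.mark.parametrize("quarter_turns", [1, 2, 3])
    def test_rotation_invariance_on_square_grids(self, rng, quarter_turns):
        values = rng.uniform(0, 1, size=(24, 24))
        base = image_from_grid(values)
        rotated = image_from_grid(np.rot90(values, quarter_turns))
        for alpha in range(1, 6):
            for beta in range(alpha + 1):
                m0 = abs(pseudo_zernike_moment(base, alpha, beta))
                m1 = abs(pseudo_zernike_moment(rotated, alpha, beta))
                assert abs(m0 - m1) < 1e-9

    def test_discrete_orthogonality_low_orders(self):
        """Gram matrix of the basis approximates pi/(alpha+1) * identity."""
        grid = disk_grid(200)
        pairs = [(a, b) for a in range(5) for b in range(-a, a + 1)]
        stacked = basis_matrix(pairs, grid.x, grid.y)
        gram = (stacked.conj() @ stacked.T) * grid.pixel_area
        norms = np.array([math.pi / (a + 1) for a, _ in pairs])
        normalized = gram / np.sqrt(np.outer(norms, norms))
        assert np.abs(normalized - np.eye(len(pairs))).max() < 0.01


class TestFeatureVector:
    def test_length_formula(self):
        assert feature_length(10) == 65
        assert len(moment_pairs(10)) == 65
        fv = pzm_feature_vector(Pssm(np.zeros((12, 20))), alpha_max=10)
        assert fv.magnitudes.size == 65

    def test_constant_pssms_share_descriptor(self):
        a = pzm_feature_vector(Pssm(np.zeros((9, 20))), alpha_max=6)
        b = pzm_feature_vector(Pssm(np.full((9, 20), 0.0)), alpha_max=6)
        assert np.array_equal(a.magnitudes, b.magnitudes)

    def test_cached_and_uncached_paths_agree_bitwise(self, rng):
        pssm = Pssm(rng.normal(size=(40, 20)))
        cache = PzmBasisCache()
        warm = pzm_feature_vector(pssm, 8, cache)  # populate
        cached = pzm_feature_vector(pssm, 8, cache)
        fresh = pzm_feature_vector(pssm, 8, None)
        assert np.array_equal(warm.magnitudes, cached.magnitudes)
        assert np.array_equal(cached.magnitudes, fresh.magnitudes)

    def test_90_degree_symmetric_square_profiles_agree(self, rng):
        """Rotating a square score grid leaves the descriptor unchanged."""
        values = rng.normal(size=(20, 20))
        a = pzm_feature_vector(Pssm(values), 6)
        b = pzm_feature_vector(Pssm(np.rot90(values)), 6)
        assert np.allclose(a.magnitudes, b.magnitudes, atol=1e-9)


class TestNormalize:
    def test_logistic_fixed_points(self):
        pssm = normalize_pssm(Pssm(np.array([[0.0] * 20])))
        assert np.allclose(pssm.scores, 0.5)

    def test_saturation_never_nan(self):
        pssm = normalize_pssm(Pssm(np.full((3, 20), -1e6)))
        assert np.all(np.isfinite(pssm.scores))
        assert np.all(pssm.scores >= 0)

    def test_monotone(self, rng):
        raw = rng.normal(size=(5, 20))
        out = normalize_pssm(Pssm(raw)).scores
        order_in = np.argsort(raw.ravel())
        assert np.all(np.diff(out.ravel()[order_in]) >= 0)


class TestPsiblastParser:
    def test_row_with_19_fields_rejected(self, tmp_path):
        from ncrpi.pssm_features import AA_ORDER

        path = tmp_path / "bad.pssm"
        header = " " * 11 + "  ".join(AA_ORDER)
        row = "    1 M " + " ".join(["1"] * 19)
        path.write_text(f"\nmatrix\n{header}\n{row}\n")
        with pytest.raises(ValueError, match="line 4"):
            read_psiblast_pssm(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "noheader.pssm"
        path.write_text("not a pssm at all\n")
        with pytest.raises(ValueError, match="header"):
            read_psiblast_pssm(path)

    def test_row_count_matches_sequence_length(self, tmp_path):
        from ncrpi import ProteinRecord, synthesize_pssm, write_psiblast_pssm

        rec = ProteinRecord("p", "MKVLA")
        path = tmp_path / "p.pssm"
        write_psiblast_pssm(synthesize_pssm(rec, seed=0), rec.sequence, path)
        assert read_psiblast_pssm(path).length == 5
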