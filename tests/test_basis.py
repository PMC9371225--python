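"""Basis evaluation, kernel integrals, and moment computation."""

import numpy as np
import pytest
from scipy import integrate, special

from zeromark import (
    BasisSpec,
    compute_moments,
    frghp_eval,
    grid_coords,
    hermite_eval,
    kernel_integrals,
    reconstruct,
    validate_basis,
    zeroth_order_moments,
)
from zeromark.basis import MomentSet, frghp_matrix


class TestHermite:
    def test_matches_scipy_hermite(self, rng):
        x = rng.uniform(-3, 3, size=20)
        for p in range(11):
            np.testing.assert_allclose(
                hermite_eval(p, x), special.eval_hermite(p, x), rtol=1e-12
            )

    @pytest.mark.parametrize(
        "p, x, expected", [(0, 3.7, 1.0), (1, 1.0, 2.0), (2, 1.0, 2.0)]
    )
    def test_low_degree_values(self, p, x, expected):
        assert hermite_eval(p, x) == pytest.approx(expected)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            hermite_eval(-1, 0.0)


class TestFrGHP:
    def test_matches_high_precision_explicit_form(self):
        """Recurrence route agrees with the factorial explicit form evaluated
        in 50-digit arithmetic, to at least 10 significant digits."""
        import sympy as sp

        spec = BasisSpec(grid_n=16, nmax=6)
        p, tval, alpha, sigma = 5, sp.Rational(37, 100), sp.Rational(19, 10), sp.Rational(105, 1000)
        u = (2 * tval**alpha - 1) / sigma
        poly = sp.factorial(p) * sum(
            (-1) ** m * (2 * u) ** (p - 2 * m)
            / (sp.factorial(m) * sp.factorial(p - 2 * m))
            for m in range(p // 2 + 1)
        )
        norm = 1 / sp.sqrt(2**p * sp.factorial(p) * sigma * sp.sqrt(sp.pi))
        jac = sp.sqrt(2 * alpha * tval ** (alpha - 1))
        exact = float((jac * norm * sp.exp(-(u**2) / 2) * poly).evalf(50))
        got = frghp_eval(5, 0.37, BasisSpec(grid_n=16, nmax=6, alpha=1.9, sigma=0.105))
        assert got == pytest.approx(exact, rel=1e-10)
        del spec

    @pytest.mark.parametrize("p", [0, 3, 6])
    def test_unit_norm_on_unit_interval(self, small_spec, p):
        val, _ = integrate.quad(
            lambda t: frghp_eval(p, t, small_spec) ** 2, 0, 1, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_alpha_one_reduces_to_scaled_gaussian(self):
        spec = BasisSpec(grid_n=16, nmax=2, alpha=1.0, sigma=0.2)
        t = 0.31
        x = 2 * t - 1
        gauss = np.exp(-(x**2) / (2 * spec.sigma**2)) / np.sqrt(
            spec.sigma * np.sqrt(np.pi)
        )
        assert frghp_eval(0, t, spec) == pytest.approx(np.sqrt(2.0) * gauss, rel=1e-12)

    def test_domain_errors(self, small_spec):
        with pytest.raises(ValueError):
            frghp_eval(0, 1.2, small_spec)
        with pytest.raises(ValueError):
            frghp_eval(0, -0.1, small_spec)
        singular = BasisSpec(grid_n=16, nmax=2, alpha=0.5)
        with pytest.raises(ValueError):
            frghp_eval(0, 0.0, singular)
        with pytest.raises(ValueError):
            frghp_eval(7, 0.5, small_spec)  # beyond nmax


class TestGrid:
    @pytest.mark.parametrize(
        "n, expected",
        [(2, [0.25, 0.75]), (4, [0.125, 0.375, 0.625, 0.875])],
    )
    def test_pixel_centers(self, n, expected):
        np.testing.assert_allclose(grid_coords(n), expected)

    @pytest.mark.parametrize("n", [1, 3, 17, 256])
    def test_subintervals_tile_unit_interval(self, n):
        c = grid_coords(n)
        edges = np.concatenate([c - 0.5 / n, [c[-1] + 0.5 / n]])
        np.testing.assert_allclose(edges, np.linspace(0, 1, n + 1), atol=1e-15)

    def test_invalid_side(self):
        with pytest.raises(ValueError):
            grid_coords(0)


class TestKernelIntegrals:
    def test_column_sums_match_adaptive_quadrature(self):
        spec = BasisSpec(grid_n=32, nmax=10)
        ker = kernel_integrals(spec)
        for p in range(11):
            ref, _ = integrate.quad(
                lambda t: frghp_eval(p, t, spec), 0, 1, limit=400
            )
            assert ker.ix[:, p].sum() == pytest.approx(ref, abs=1e-8)

    def test_self_convergence_doubling_quad_order(self):
        lo = kernel_integrals(BasisSpec(grid_n=32, nmax=10, quad_order=8))
        hi = kernel_integrals(BasisSpec(grid_n=32, nmax=10, quad_order=16))
        assert np.max(np.abs(lo.ix - hi.ix)) < 1e-10

    def test_ix_equals_iy_on_square_grid(self, small_spec):
        ker = kernel_integrals(small_spec)
        np.testing.assert_array_equal(ker.ix, ker.iy)
        assert np.all(np.isfinite(ker.ix))


def _brute_force_moments(image, spec):
    """Literal quadruple-loop double sum over pixels — the independent oracle."""
    ker = kernel_integrals(spec)
    n = spec.grid_n
    mfg = np.zeros((3, spec.nmax + 1, spec.nmax + 1))
    for c in range(3):
        for p in range(spec.nmax + 1):
            for q in range(spec.nmax + 1):
                acc = 0.0
                for i in range(n):  # column / x
                    for j in range(n):  # row / y
                        acc += ker.ix[i, p] * ker.iy[j, q] * float(image[j, i, c])
                mfg[c, p, q] = acc
    return mfg


class TestMoments:
    def test_zero_image_annihilated(self, small_spec):
        ker = kernel_integrals(small_spec)
        z = np.zeros((16, 16, 3))
        assert np.all(compute_moments(z, ker).mfg == 0)
        assert np.all(zeroth_order_moments(z, small_spec).mfg == 0)

    def test_linearity(self, small_spec, rng):
        ker = kernel_integrals(small_spec)
        a = rng.uniform(0, 120, size=(16, 16, 3))
        b = rng.uniform(0, 120, size=(16, 16, 3))
        lhs = compute_moments(a + b, ker).mfg
        rhs = compute_moments(a, ker).mfg + compute_moments(b, ker).mfg
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_matches_brute_force_double_sum(self, rng):
        spec = BasisSpec(grid_n=8, nmax=4)
        image = rng.integers(0, 256, size=(8, 8, 3)).astype(float)
        fast = compute_moments(image, kernel_integrals(spec)).mfg
        np.testing.assert_allclose(fast, _brute_force_moments(image, spec), atol=1e-12)

    def test_size_mismatch_rejected(self, small_spec):
        ker = kernel_integrals(small_spec)
        with pytest.raises(ValueError):
            compute_moments(np.zeros((8, 8, 3)), ker)

    def test_kernel_route_beats_zeroth_order_on_constant_image(self):
        """On a constant image the exact moments are products of exact basis
        integrals; the kernel route reproduces them while the midpoint route
        carries an O(1e-3) discretization error at every index."""
        spec = BasisSpec(grid_n=32, nmax=4)
        const = np.full((32, 32, 3), 200.0)
        # dense-quadrature reference: 200 * int(FH_p) * int(FH_q)
        ints = np.array(
            [integrate.quad(lambda t: frghp_eval(p, t, spec), 0, 1, limit=400)[0]
             for p in range(spec.nmax + 1)]
        )
        ref = 200.0 * np.outer(ints, ints)
        err_kernel = np.abs(compute_moments(const, kernel_integrals(spec)).mfg[0] - ref)
        err_zeroth = np.abs(zeroth_order_moments(const, spec).mfg[0] - ref)
        assert err_kernel.max() < 1e-8
        assert np.all(err_kernel <= err_zeroth + 1e-12)
        assert err_zeroth.max() > 100 * err_kernel.max()
        assert err_zeroth.max() < 1e-2

    def test_zeroth_order_error_grows_faster_with_degree(self):
        """The midpoint route's worst-case error versus the quadrature
        reference grows with nmax faster than the kernel route's."""
        const = np.full((32, 32, 3), 200.0)
        gaps = []
        for nmax in (2, 6, 10):
            spec = BasisSpec(grid_n=32, nmax=nmax)
            ints = np.array(
                [integrate.quad(lambda t: frghp_eval(p, t, spec), 0, 1, limit=400)[0]
                 for p in range(nmax + 1)]
            )
            ref = 200.0 * np.outer(ints, ints)
            ek = np.abs(compute_moments(const, kernel_integrals(spec)).mfg[0] - ref).max()
            ez = np.abs(zeroth_order_moments(const, spec).mfg[0] - ref).max()
            gaps.append((ez, ek))
        zeroth_errors = [g[0] for g in gaps]
        kernel_errors = [g[1] for g in gaps]
        assert zeroth_errors == sorted(zeroth_errors)
        assert all(ek < ez for ez, ek in gaps)
        assert all(e < 1e-8 for e in kernel_errors)


class TestReconstruction:
    def test_single_basis_function_image(self):
        """An image proportional to FH_3(x) FH_2(y) concentrates its energy in
        the (3,2) moment; reconstruction returns the image."""
        n = 128
        spec = BasisSpec(grid_n=n, nmax=6)
        phi = frghp_matrix(grid_coords(n), spec)
        g = np.outer(phi[:, 2], phi[:, 3])  # rows = y -> degree 2, cols = x -> degree 3
        scale = 100.0 / np.abs(g).max()
        base = np.full((n, n, 3), 120.0)
        img = base + scale * g[:, :, None]
        assert img.min() >= 0 and img.max() <= 255
        ker = kernel_integrals(spec)
        diff = MomentSet(
            compute_moments(img, ker).mfg - compute_moments(base, ker).mfg, spec
        )
        m = diff.mfg[0]
        # tolerances reflect the O(h^2) discretization of sampling the
        # basis product on a 128-point grid
        assert m[3, 2] == pytest.approx(scale, rel=3e-2)
        rest = m.copy()
        rest[3, 2] = 0.0
        assert np.abs(rest).max() < 2e-2 * scale
        # Parseval: single coefficient carries the discrete energy
        energy = np.sum((scale * g) ** 2) / n**2
        assert np.sum(m**2) == pytest.approx(energy, rel=5e-2)
        # reconstruction of the bump matches the input bump
        recon = reconstruct(diff)[:, :, 0]
        rel_rmse = np.sqrt(np.mean((recon - scale * g) ** 2)) / np.sqrt(
            np.mean((scale * g) ** 2)
        )
        assert rel_rmse < 5e-2

    def test_zero_moments_reconstruct_to_zero(self, small_spec):
        zeros = MomentSet(np.zeros((3, 7, 7)), small_spec)
        assert np.all(reconstruct(zeros) == 0)

    def test_rmse_decreases_with_degree(self):
        from zeromark import PhantomSpec, make_phantom

        img = make_phantom(PhantomSpec(side=128, seed=3, noise_sd=0.0)).astype(float)
        errs = []
        for nmax in (5, 10, 20, 30):
            spec = BasisSpec(grid_n=128, nmax=nmax)
            rec = reconstruct(compute_moments(img, kernel_integrals(spec)))
            errs.append(float(np.sqrt(np.mean((rec - img) ** 2))))
        assert errs == sorted(errs, reverse=True)


class TestValidateBasis:
    def test_default_spec_is_orthonormal(self):
        report = validate_basis(BasisSpec(grid_n=256))
        assert report.ok
        assert report.defect < 1e-4

    def test_degree_zero_gram_is_unit(self):
        report = validate_basis(BasisSpec(grid_n=16, nmax=0))
        assert report.gram.shape == (1, 1)
        assert report.gram[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_oversized_sigma_is_flagged(self):
        report = validate_basis(BasisSpec(grid_n=256, sigma=1.05))
        assert not report.ok
        assert report.defect > 1e-2


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"grid_n": 0},
            {"grid_n": 16, "nmax": -1},
            {"grid_n": 16, "alpha": 0.0},
            {"grid_n": 16, "sigma": -1.0},
            {"grid_n": 16, "quad_order": 0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BasisSpec(**kwargs)

    def test_hash_distinguishes_specs(self):
        a = BasisSpec(grid_n=64).spec_hash()
        b = BasisSpec(grid_n=64, nmax=11).spec_hash()
        assert a != b
        assert BasisSpec(grid_n=64).spec_hash() == a
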