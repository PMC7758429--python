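"""Collocation, per-batch pipeline algebra, and the end-to-end integrator
against dense and finite-difference oracles."""
import numpy as np
import pytest

from xcquad.basis import ShellTemplate, build_basis
from xcquad.functionals import XCEval
from xcquad.geometry import Atom
from xcquad.integrator import (REFERENCE_GUARD, accumulate, batch_density,
                               batch_vxc, batch_zmat, eval_collocation,
                               integrate_xc, reference_integrate)
from xcquad.fixtures import fixture_system, random_density


def _single_s_basis(alpha=1.0):
    atoms = [Atom("H", 1, np.zeros(3))]
    tpl = {"H": [ShellTemplate(0, np.array([alpha]), np.array([1.0]))]}
    return atoms, build_basis(atoms, tpl)


class TestCollocation:
    def test_p_shell_vanishes_at_center(self):
        atoms = [Atom("H", 1, np.array([0.5, -0.2, 0.1]))]
        tpl = {"H": [ShellTemplate(1, np.array([0.8]), np.array([1.0]))]}
        basis = build_basis(atoms, tpl)
        phi, _ = eval_collocation(atoms[0].position[None, :], basis,
                                  np.array([0]))
        np.testing.assert_array_equal(phi[:, 0], 0.0)

    def test_normalized_s_at_center(self):
        _, basis = _single_s_basis()
        phi, _ = eval_collocation(np.zeros((1, 3)), basis, np.array([0]))
        assert phi[0, 0] == pytest.approx((2 / np.pi) ** 0.75, rel=1e-14)

    @pytest.mark.parametrize("basis_name, pure",
                             [("sto-min", False), ("s+d", False),
                              ("s+d", True)])
    def test_gradient_vs_finite_differences(self, basis_name, pure, rng):
        atoms, basis = fixture_system("HeH", basis_name, pure=pure)
        pts = rng.uniform(-2, 2, (40, 3))
        sel = np.arange(len(basis))
        phi, dphi = eval_collocation(pts, basis, sel)
        h = 1e-5
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            pp, _ = eval_collocation(pts + e, basis, sel)
            pm, _ = eval_collocation(pts - e, basis, sel)
            fd = (pp - pm) / (2 * h)
            np.testing.assert_allclose(dphi[ax], fd, atol=1e-6)

    def test_empty_shell_list(self):
        _, basis = _single_s_basis()
        phi, dphi = eval_collocation(np.zeros((4, 3)), basis,
                                     np.empty(0, int))
        assert phi.shape == (0, 4) and dphi.shape == (3, 0, 4)


class TestBatchDensity:
    def test_zero_density_matrix(self, rng):
        phi = rng.standard_normal((3, 10))
        dphi = rng.standard_normal((3, 3, 10))
        X, rho, grad = batch_density(np.zeros((3, 3)), phi, dphi)
        assert np.all(rho == 0) and np.all(grad == 0)

    def test_single_s_density_at_center(self):
        _, basis = _single_s_basis()
        phi, dphi = eval_collocation(np.zeros((1, 3)), basis,
                                     np.array([0]))
        _, rho, _ = batch_density(np.array([[2.0]]), phi, dphi)
        assert rho[0] == pytest.approx(2 * (2 / np.pi) ** 1.5, rel=1e-14)

    def test_psd_density_matrix_gives_nonnegative_rho(self, rng):
        n = 5
        C = rng.standard_normal((n, 2))
        P = 2 * C @ C.T
        phi = rng.standard_normal((n, 50))
        dphi = rng.standard_normal((3, n, 50))
        _, rho, _ = batch_density(P, phi, dphi)
        assert np.all(rho >= -1e-14)

    def test_gradient_factor_two(self, rng):
        """grad rho = 2 sum_mu gradPhi X, checked against a scalar loop."""
        n, npts = 4, 7
        P = rng.standard_normal((n, n))
        P = P + P.T
        phi = rng.standard_normal((n, npts))
        dphi = rng.standard_normal((3, n, npts))
        X, rho, grad = batch_density(P, phi, dphi)
        for i in range(npts):
            assert rho[i] == pytest.approx(phi[:, i] @ X[:, i], rel=1e-13)
            for ax in range(3):
                assert grad[i, ax] == pytest.approx(
                    2 * dphi[ax, :, i] @ X[:, i], rel=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            batch_density(np.zeros((2, 2)), np.zeros((3, 5)),
                          np.zeros((3, 3, 5)))


class TestZmatAndVxc:
    def test_zero_channels_give_zero_z(self, rng):
        phi = rng.standard_normal((4, 6))
        dphi = rng.standard_normal((3, 4, 6))
        xce = XCEval(eps=np.zeros(6), vrho=np.zeros(6), vsigma=np.zeros(6))
        Z = batch_zmat(xce, phi, dphi, rng.standard_normal((6, 3)))
        assert np.all(Z == 0)

    def test_lda_structural_reduction(self, rng):
        """With vsigma = 0, Z = 1/2 vrho Phi exactly."""
        phi = rng.standard_normal((4, 6))
        dphi = rng.standard_normal((3, 4, 6))
        vrho = rng.standard_normal(6)
        xce = XCEval(eps=np.zeros(6), vrho=vrho, vsigma=np.zeros(6))
        Z = batch_zmat(xce, phi, dphi, np.zeros((6, 3)))
        np.testing.assert_allclose(Z, 0.5 * vrho[None, :] * phi,
                                   rtol=1e-15)

    def test_zmat_matches_scalar_loop(self, rng):
        n, npts = 5, 8
        phi = rng.standard_normal((n, npts))
        dphi = rng.standard_normal((3, n, npts))
        grad = rng.standard_normal((npts, 3))
        xce = XCEval(eps=rng.standard_normal(npts),
                     vrho=rng.standard_normal(npts),
                     vsigma=rng.standard_normal(npts))
        Z = batch_zmat(xce, phi, dphi, grad)
        for mu in range(n):
            for i in range(npts):
                want = (0.5 * xce.vrho[i] * phi[mu, i]
                        + 2.0 * xce.vsigma[i]
                        * (grad[i] @ dphi[:, mu, i]))
                assert Z[mu, i] == pytest.approx(want, abs=1e-13)

    def test_vxc_symmetric_and_matches_loop(self, rng):
        n, npts = 4, 9
        Z = rng.standard_normal((n, npts))
        phi = rng.standard_normal((n, npts))
        V = batch_vxc(Z, phi)
        np.testing.assert_array_equal(V, V.T)
        dense = np.zeros((n, n))
        for mu in range(n):
            for nu in range(n):
                dense[mu, nu] = sum(Z[mu, i] * phi[nu, i]
                                    + phi[mu, i] * Z[nu, i]
                                    for i in range(npts))
        np.testing.assert_allclose(V, dense, atol=1e-12)

    def test_zero_z_gives_zero_v(self):
        assert np.all(batch_vxc(np.zeros((3, 5)), np.ones((3, 5))) == 0)


class TestAccumulate:
    def test_zero_batches(self, h2_sto):
        _, basis = h2_sto
        res = accumulate([], basis)
        assert res.exc == 0.0 and np.all(res.vxc == 0)

    def test_batch_order_permutation_stable(self, heh_sp, heh_density_fg):
        atoms, basis = heh_sp
        res, grid, batches = integrate_xc(
            atoms, basis, heh_density_fg, "FG", "PBE", return_batches=True)
        from xcquad.integrator import integrate_batches, process_batch
        rev = integrate_batches(batches[::-1], grid, basis,
                                heh_density_fg, "PBE")
        assert abs(rev.exc - res.exc) <= 1e-12
        np.testing.assert_allclose(rev.vxc, res.vxc, atol=1e-12)


class TestIntegrateXC:
    def test_electron_count(self, h2_sto, h2_density):
        """Doubly occupied orbital integrates to 2 electrons on UFG."""
        atoms, basis = h2_sto
        res = integrate_xc(atoms, basis, h2_density, "UFG", "PBE")
        assert res.n_el == pytest.approx(2.0, abs=1e-6)

    def test_lda_closed_form_single_gaussian(self):
        """Exchange-only LDA for rho = 2 |phi|^2 with a single normalized
        s primitive (alpha = 1): Exc has an analytic value."""
        atoms, basis = _single_s_basis(alpha=1.0)
        res = integrate_xc(atoms, basis, np.array([[2.0]]), "SFG", "LDA")
        exact = (-(3 / 4) * (3 / np.pi) ** (1 / 3) * 2 ** (4 / 3)
                 * (2 / np.pi) ** 2 * (3 * np.pi / 8) ** 1.5)
        assert res.exc == pytest.approx(exact, rel=1e-7)

    def test_variational_identity(self, heh_sp, heh_density_fg):
        """V_munu equals the symmetrized finite difference of Exc with
        respect to P entries -- the strongest end-to-end check."""
        atoms, basis = heh_sp
        P = heh_density_fg
        res = integrate_xc(atoms, basis, P, "FG", "PBE")
        delta = 1e-5
        for (m, n) in [(0, 0), (0, 3), (2, 5), (4, 6)]:
            E = np.zeros_like(P)
            E[m, n] += delta
            E[n, m] += delta
            ep = integrate_xc(atoms, basis, P + E, "FG", "PBE").exc
            em = integrate_xc(atoms, basis, P - E, "FG", "PBE").exc
            fd = (ep - em) / (2 * delta)
            expect = 2 * res.vxc[m, n] if m != n else 2 * res.vxc[m, m]
            assert fd == pytest.approx(expect, abs=1e-6)

    def test_batch_size_invariance(self, h2_sto, h2_density):
        atoms, basis = h2_sto
        base = integrate_xc(atoms, basis, h2_density, "FG", "PBE",
                            max_pts=512)
        for mp in (64, 128):
            other = integrate_xc(atoms, basis, h2_density, "FG", "PBE",
                                 max_pts=mp)
            assert abs(other.exc - base.exc) <= 1e-12
            assert np.abs(other.vxc - base.vxc).max() <= 1e-12

    def test_group_size_invariance(self, h2_sto, h2_density):
        atoms, basis = h2_sto
        a = integrate_xc(atoms, basis, h2_density, "FG", "PBE",
                         group_size=1)
        b = integrate_xc(atoms, basis, h2_density, "FG", "PBE",
                         group_size=64)
        assert a.exc == b.exc
        np.testing.assert_array_equal(a.vxc, b.vxc)

    def test_asymmetric_density_rejected(self, h2_sto):
        _, basis = h2_sto
        atoms, _ = h2_sto
        P = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            integrate_xc(atoms, basis, P)


class TestReferenceOracle:
    @pytest.mark.parametrize("molecule, basis_name, nel",
                             [("H2", "sto-min", 2), ("HeH", "s+p", 4)])
    def test_screened_matches_dense(self, molecule, basis_name, nel):
        """Screening at eta = 1e-10 changes Exc by < 1e-8 and Vxc entries
        by < 1e-9 relative to the dense unscreened evaluation."""
        atoms, basis = fixture_system(molecule, basis_name)
        P = random_density(atoms, basis, nel, seed=11, grid_spec="FG")
        res = integrate_xc(atoms, basis, P, "UFG", "PBE")
        ref = reference_integrate(atoms, basis, P, "UFG", "PBE")
        assert abs(res.exc - ref.exc) <= 1e-8
        assert np.abs(res.vxc - ref.vxc).max() <= 1e-9

    def test_vxc_symmetric(self, h2_sto, h2_density):
        atoms, basis = h2_sto
        ref = reference_integrate(atoms, basis, h2_density, "FG", "PBE")
        np.testing.assert_allclose(ref.vxc, ref.vxc.T, atol=1e-12)

    def test_memory_guard(self, h2_sto, h2_density):
        atoms, basis = h2_sto
        import xcquad.integrator as integ
        old = integ.REFERENCE_GUARD
        try:
            integ.REFERENCE_GUARD = 10
            with pytest.raises(MemoryError):
                reference_integrate(atoms, basis, h2_density, "FG", "PBE")
        finally:
            integ.REFERENCE_GUARD = old
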