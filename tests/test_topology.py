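"""Model-density topology: analytic derivatives, NCI, ELF/LOL, BCPs."""
import math

import numpy as np
import pytest

from fullersense import (
    FieldSample,
    Geometry,
    PromolecularModel,
    elf,
    energy_densities,
    evaluate_grid,
    find_bcps,
    kinetic_density,
    lol,
    promolecular_field,
    rdg,
    signed_density,
    total_energy_density,
)
from fullersense.constants import BOHR_PER_ANGSTROM, C_TF

# one-exponential toy element for closed-form checks
C_SHELL, ZETA = 0.4, 0.7
ONE_SHELL = PromolecularModel({"H": [(C_SHELL, ZETA)],
                               "C": [(C_SHELL, ZETA)],
                               "N": [(C_SHELL, ZETA)]})


def sample_at(rho, grad=(0.0, 0.0, 0.0), hessian=None):
    h = np.zeros((3, 3)) if hessian is None else np.asarray(hessian)
    return FieldSample(np.zeros(3), rho, np.asarray(grad, float), h)


class TestPromolecularField:
    def test_density_at_nucleus_is_coefficient_sum(self):
        field = promolecular_field(Geometry([("H", 0.0, 0.0, 0.0)]), ONE_SHELL)
        s = field.sample([0.0, 0.0, 0.0])
        assert s.rho == pytest.approx(C_SHELL, rel=1e-8)

    def test_single_shell_gradient_norm_is_rho_over_zeta(self):
        field = promolecular_field(Geometry([("H", 0.0, 0.0, 0.0)]), ONE_SHELL)
        for r in (0.5, 1.0, 2.5):
            s = field.sample([r, 0.0, 0.0])
            assert s.grad_norm == pytest.approx(s.rho / ZETA, rel=1e-10)

    def test_unsupported_element_rejected(self):
        with pytest.raises(ValueError, match="not in promolecular model"):
            promolecular_field(Geometry([("H", 0, 0, 0)]),
                               PromolecularModel({"C": [(1.0, 0.5)]}))

    def test_derivatives_match_finite_differences(self):
        """Analytic gradient and Hessian agree with central differences to
        1e-6 at random off-nucleus points of a heteronuclear trimer."""
        geom = Geometry([("C", 0.0, 0.0, 0.0), ("N", 0.0, 0.0, 1.4),
                         ("H", 0.9, 0.0, 0.7)])
        field = promolecular_field(geom)
        rng = np.random.default_rng(42)
        h = 1e-4
        eye = np.eye(3)
        for _ in range(8):
            x = rng.uniform(-2.0, 4.0, 3)
            s = field.sample(x)
            for i in range(3):
                rp = field.sample(x + h * eye[i]).rho
                rm = field.sample(x - h * eye[i]).rho
                assert s.grad[i] == pytest.approx((rp - rm) / (2 * h),
                                                  abs=1e-6)
                gp = field.sample(x + h * eye[i]).grad
                gm = field.sample(x - h * eye[i]).grad
                np.testing.assert_allclose(s.hessian[i], (gp - gm) / (2 * h),
                                           atol=1e-6)

    def test_laplacian_is_eigenvalue_sum(self):
        field = promolecular_field(
            Geometry([("C", 0, 0, 0), ("N", 0, 0, 1.4)]))
        s = field.sample([0.3, 0.2, 0.8])
        assert s.laplacian == pytest.approx(float(np.sum(s.eigenvalues)),
                                            abs=1e-10)


class TestRDG:
    def test_stationary_point_gives_zero(self):
        assert rdg(0.1, 0.0) == 0.0

    def test_closed_form_value(self):
        assert rdg(0.1, 0.2) == pytest.approx(0.6964, abs=1e-3)

    def test_single_shell_radial_form(self):
        """For a one-exponential atom s(r) = rho^(-1/3)/(2(3pi^2)^(1/3) zeta),
        growing as the density decays."""
        field = promolecular_field(Geometry([("H", 0.0, 0.0, 0.0)]), ONE_SHELL)
        pref = 2 * (3 * math.pi**2) ** (1 / 3)
        prev = 0.0
        for r in (1.0, 2.0, 3.0):
            s = field.sample([0.0, 0.0, r])
            expected = s.rho ** (-1 / 3) / (pref * ZETA)
            val = rdg(s.rho, s.grad_norm)
            assert val == pytest.approx(expected, rel=1e-10)
            assert val > prev
            prev = val

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            rdg(0.0, 0.1)


class TestNCI:
    def test_spherical_atom_off_nucleus_is_attractive_signed(self):
        """Off-nucleus the tangential curvatures rho'/r are negative, so
        lambda_2 < 0 and the signed density is negative."""
        field = promolecular_field(Geometry([("H", 0.0, 0.0, 0.0)]), ONE_SHELL)
        s = field.sample([0.0, 0.0, 0.8])
        p = signed_density(s)
        assert s.eigenvalues[1] < 0
        assert p.signed_rho == pytest.approx(-s.rho)
        assert p.nci_class == "attractive"  # rho well above the 0.01 cut

    def test_zero_lambda2_is_vdw(self):
        p = signed_density(sample_at(0.5))
        assert p.signed_rho == 0.0
        assert p.nci_class == "vdw"

    def test_weak_dimer_midpoint_is_vdw(self):
        geom = Geometry([("H", 0, 0, 0), ("H", 0, 0, 4.0)])
        field = promolecular_field(geom, ONE_SHELL)
        mid = field.sample([0.0, 0.0, 2.0 * BOHR_PER_ANGSTROM])
        p = signed_density(mid)
        assert p.nci_class == "vdw"
        assert abs(p.signed_rho) <= 0.01


class TestKineticAndLocalization:
    def test_thomas_fermi_value(self):
        assert kinetic_density(sample_at(1.0), "tf") == pytest.approx(
            2.8712, abs=1e-4)

    def test_weizsaecker_vanishes_at_zero_gradient(self):
        s = sample_at(0.3)
        assert kinetic_density(s, "tfw") == kinetic_density(s, "tf")

    def test_weizsaecker_term_nonnegative(self):
        s = sample_at(0.3, grad=(0.1, -0.2, 0.05))
        assert kinetic_density(s, "tfw") >= kinetic_density(s, "tf")

    def test_elf_reference_values(self):
        s = sample_at(1.0)  # grad 0: D = tau, D_h = C_TF
        assert elf(s, C_TF) == pytest.approx(0.5)
        assert elf(s, 0.0) == pytest.approx(1.0)
        assert elf(s, 2 * C_TF) == pytest.approx(0.2)

    def test_elf_clamps_below_weizsaecker_bound(self):
        s = sample_at(1.0, grad=(1.0, 0.0, 0.0))  # W = 1/8
        assert elf(s, 0.05) == 1.0  # D clamped to 0

    def test_lol_reference_values(self):
        s = sample_at(1.0)
        tau_tf = C_TF
        assert lol(s, tau_tf) == pytest.approx(0.5)
        assert lol(s, 3 * tau_tf) == pytest.approx(0.25)

    def test_lol_monotone_decreasing_in_tau(self):
        s = sample_at(0.7)
        vals = [lol(s, t) for t in (0.5, 1.0, 2.0, 5.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            elf(sample_at(-1.0), 1.0)
        with pytest.raises(ValueError):
            lol(sample_at(1.0), 0.0)


class TestEnergyDensities:
    def test_weak_contact_point(self):
        g, v, h = energy_densities(0.016, 0.0, -0.011)
        assert g == pytest.approx(0.00108, abs=2e-5)
        assert v == pytest.approx(-0.00490, abs=2e-5)
        assert h == g + v

    def test_uniform_gas_limit(self):
        g, v, h = energy_densities(1.0, 0.0, 0.0)
        assert g == pytest.approx(2.8712, abs=1e-4)
        assert v == pytest.approx(-5.7424, abs=2e-4)
        assert h == pytest.approx(-2.8712, abs=1e-4)

    def test_h_equals_g_plus_v_randomized(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g, v, h = energy_densities(rng.uniform(0.001, 1.0),
                                       rng.uniform(0, 1.0),
                                       rng.uniform(-1.0, 1.0))
            assert h == g + v
        assert total_energy_density(0.092, 0.032) == pytest.approx(0.124)


class TestBCP:
    D_ANG = 1.5
    D_BOHR = D_ANG * BOHR_PER_ANGSTROM

    def dimer_field(self, offset=(0.0, 0.0, 0.0)):
        ox, oy, oz = offset
        geom = Geometry([("H", ox, oy, oz), ("H", ox, oy, oz + self.D_ANG)])
        return promolecular_field(geom, ONE_SHELL)

    def test_symmetric_dimer_bcp_at_midpoint(self):
        field = self.dimer_field()
        bcps = find_bcps(field)
        assert len(bcps) == 1
        rec = bcps[0]
        mid = np.array([0.0, 0.0, self.D_BOHR / 2])
        np.testing.assert_allclose(rec.position, mid, atol=1e-8)
        assert rec.signature == (3, -1)
        # closed form: both atoms at distance d/2
        rho_expected = 2 * C_SHELL * math.exp(-self.D_BOHR / (2 * ZETA))
        assert rec.rho == pytest.approx(rho_expected, rel=1e-10)

    def test_degenerate_perpendicular_curvatures(self):
        field = self.dimer_field()
        s = field.sample([0.0, 0.0, self.D_BOHR / 2])
        lam = s.eigenvalues
        assert lam[0] == pytest.approx(lam[1], abs=1e-10)
        assert lam[1] < 0 < lam[2]

    def test_single_atom_has_no_bcps(self):
        field = promolecular_field(Geometry([("H", 0, 0, 0)]), ONE_SHELL)
        assert find_bcps(field) == []

    def test_translation_invariance(self):
        base = find_bcps(self.dimer_field())[0]
        shift_ang = np.array([1.0, -2.0, 0.5])
        moved = find_bcps(self.dimer_field(tuple(shift_ang)))[0]
        np.testing.assert_allclose(
            moved.position, base.position + shift_ang * BOHR_PER_ANGSTROM,
            atol=1e-8)
        for attr in ("rho", "laplacian", "g", "v", "h"):
            assert getattr(moved, attr) == pytest.approx(
                getattr(base, attr), abs=1e-8)

    def test_heteronuclear_contact_has_bcp(self):
        geom = Geometry([("C", 0, 0, 0), ("N", 0, 0, 2.8)])
        bcps = find_bcps(promolecular_field(geom))
        assert len(bcps) == 1
        assert bcps[0].signature == (3, -1)
        assert 0 < bcps[0].position[2] < 2.8 * BOHR_PER_ANGSTROM


class TestGrid:
    GEOM = Geometry([("C", 0.0, 0.0, 0.0), ("N", 0.0, 0.0, 1.5)])

    def test_rho_positive_and_peaks_near_nucleus(self):
        from fullersense.topology import default_grid
        field = promolecular_field(self.GEOM)
        grid = default_grid(self.GEOM, pad=1.5, step=0.25)
        arrays, grid = evaluate_grid(field, grid, ("rho",))
        rho = arrays["rho"]
        assert np.all(rho > 0)
        ax, ay, az = grid.axes()
        i, j, k = np.unravel_index(np.argmax(rho), rho.shape)
        peak = np.array([ax[i], ay[j], az[k]])
        dists = np.linalg.norm(self.GEOM.coords() - peak, axis=1)
        assert dists.min() <= 0.25 * math.sqrt(3)

    def test_rdg_grid_matches_pointwise(self):
        from fullersense.bundle import GridSpec
        field = promolecular_field(self.GEOM)
        grid = GridSpec((-0.5, -0.5, -0.5), (4, 4, 4), (0.5, 0.5, 0.5))
        arrays, grid = evaluate_grid(field, grid, ("rho", "rdg"))
        ax, ay, az = grid.axes()
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            pt = np.array([ax[idx[0]], ay[idx[1]], az[idx[2]]])
            s = field.sample(pt * BOHR_PER_ANGSTROM)
            assert arrays["rdg"][idx] == pytest.approx(
                rdg(s.rho, s.grad_norm), rel=1e-8)

    def test_localization_fields_bounded(self):
        from fullersense.bundle import GridSpec
        field = promolecular_field(self.GEOM)
        grid = GridSpec((-0.5, -0.5, -0.5), (5, 5, 5), (0.5, 0.5, 0.5))
        arrays, _ = evaluate_grid(field, grid, ("elf", "lol", "rdg"))
        assert np.all((arrays["elf"] >= 0) & (arrays["elf"] <= 1))
        assert np.all((arrays["lol"] >= 0) & (arrays["lol"] <= 1))
        assert np.all(arrays["rdg"] >= 0)

    def test_quantity_validation(self):
        field = promolecular_field(self.GEOM)
        with pytest.raises(ValueError, match="empty"):
            evaluate_grid(field, None, ())
        with pytest.raises(ValueError, match="unknown"):
            evaluate_grid(field, None, ("rho", "mep"))

    def test_grid_is_cube_writable(self, tmp_path):
        from fullersense import read_cube, write_cube
        from fullersense.bundle import GridSpec
        field = promolecular_field(self.GEOM)
        grid = GridSpec((-0.5, -0.5, -0.5), (3, 3, 3), (0.5, 0.5, 0.5))
        arrays, grid = evaluate_grid(field, grid, ("rho",))
        p = tmp_path / "rho.cube"
        write_cube(arrays["rho"], grid, self.GEOM, p)
        vals, _, _ = read_cube(p)
        np.testing.assert_allclose(vals, arrays["rho"], rtol=1e-4)
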