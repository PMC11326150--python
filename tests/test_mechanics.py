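"""Finite-strain kinematics and Mooney-Rivlin constitutive law.

The stress oracle here differentiates an independently written strain
energy numerically — sigma = (1/J)(dW/dF) F^T by central differences — and
is kept separate from the package's closed-form implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainmech import (
    DisplacementField,
    GridGeometry,
    LabelVolume,
    MaterialTable,
    PhantomSpec,
    PipelineConfig,
    TensorField,
    TissueClass,
    cauchy_stress,
    deformation_gradient,
    displacement_gradient,
    green_lagrange_strain,
    make_phantom,
    mooney_rivlin_cauchy_stress,
    mooney_rivlin_energy,
    run_mechanics,
    strain_energy_density,
    strain_rate,
    trim_to_mask,
    von_mises,
)
from brainmech.imageio import ScalarField

from conftest import interior_mask

WM_G, WM_K = 0.624, 5.00e4
GM_G = 1.10


# ---------------------------------------------------------------------------
# independent numerical oracle
# ---------------------------------------------------------------------------


def energy_oracle(F, G, K):
    """Independently coded Mooney-Rivlin energy for a single 3x3 F."""
    J = np.linalg.det(F)
    I1 = np.trace(F.T @ F)
    I1_bar = J ** (-2.0 / 3.0) * I1
    return 0.5 * G * (I1_bar - 3.0) + K * ((J * J - 1.0) / 4.0 - 0.5 * np.log(J))


def stress_oracle(F, G, K, h=1e-6):
    """sigma = (1/J)(dW/dF) F^T by central-difference differentiation."""
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (energy_oracle(Fp, G, K) - energy_oracle(Fm, G, K)) / (2 * h)
    return (P @ F.T) / np.linalg.det(F)


def random_deformation_gradients(n, rng, j_lo=0.9, j_hi=1.1, perturbation=0.1):
    """Random F = I + perturbation, rescaled so det F is uniform in [j_lo, j_hi]."""
    F = np.eye(3) + perturbation * rng.standard_normal((n, 3, 3))
    target_J = rng.uniform(j_lo, j_hi, size=n)
    det = np.linalg.det(F)
    F *= np.cbrt(target_J / det)[:, None, None]
    return F


def uniform_labels(shape, label=3, frames=1):
    geom = GridGeometry.axis_aligned(shape, frames=frames)
    return LabelVolume(np.full(shape, label, np.int32), geom.with_frames(1))


# ---------------------------------------------------------------------------
# material table
# ---------------------------------------------------------------------------


class TestMaterialTable:
    def test_default_brain_tissue_constants(self):
        mat = MaterialTable()
        assert mat.shear_kpa[TissueClass.WM] == 0.624
        assert mat.shear_kpa[TissueClass.GM] == 1.10
        assert mat.shear_kpa[TissueClass.CSF] == 0.50
        assert mat.bulk_kpa[TissueClass.WM] == 5.00e4
        assert mat.bulk_kpa[TissueClass.GM] == 5.00e4
        assert mat.bulk_kpa[TissueClass.CSF] == 2.1e6

    def test_csf_excluded_by_default(self):
        assert TissueClass.CSF not in MaterialTable().included_classes()
        assert TissueClass.CSF in MaterialTable(include_csf=True).included_classes()

    def test_nonpositive_moduli_rejected(self):
        with pytest.raises(ValueError):
            MaterialTable(shear_kpa={TissueClass.WM: 0.0},
                          bulk_kpa={TissueClass.WM: 1.0})

    def test_csv_roundtrip(self, tmp_path):
        mat = MaterialTable()
        p = tmp_path / "mat.csv"
        mat.to_csv(p)
        back = MaterialTable.from_csv(p)
        assert back.shear_kpa == mat.shear_kpa
        assert back.bulk_kpa == mat.bulk_kpa


# ---------------------------------------------------------------------------
# displacement gradient
# ---------------------------------------------------------------------------


class TestDisplacementGradient:
    def test_zero_field_zero_gradient(self):
        geom = GridGeometry.axis_aligned((6, 6, 6))
        field = DisplacementField(np.zeros((6, 6, 6, 1, 3)), geom)
        g = displacement_gradient(field)
        np.testing.assert_array_equal(g.values, 0.0)

    def test_linear_field_exact_everywhere(self):
        """Central and one-sided differences are both exact for affine u."""
        a = 0.07
        geom = GridGeometry.axis_aligned((8, 8, 8), spacing=(1.2, 1.2, 1.2))
        coords = geom.world_coordinates()
        data = np.zeros((8, 8, 8, 1, 3))
        data[..., 0, 0] = a * coords[..., 0]
        g = displacement_gradient(DisplacementField(data, geom))
        np.testing.assert_allclose(g.values[..., 0, 0], a, atol=1e-13)
        np.testing.assert_allclose(g.values[..., 0, 1], 0.0, atol=1e-13)

    def test_sinusoid_converges_second_order(self):
        """Interior error vs k cos(kx) drops ~4x when spacing halves."""
        k = 2 * np.pi / 16.0
        errs = []
        for n, h in ((16, 1.0), (32, 0.5)):
            geom = GridGeometry.axis_aligned((n, 4, 4), spacing=(h, 1.0, 1.0))
            x = geom.world_coordinates()[..., 0]
            data = np.zeros((n, 4, 4, 1, 3))
            data[..., 0, 0] = np.sin(k * x)
            g = displacement_gradient(DisplacementField(data, geom))
            exact = k * np.cos(k * x)
            err = np.abs(g.values[1:-1, :, :, 0, 0, 0] - exact[1:-1])
            errs.append(err.max())
        assert errs[0] / errs[1] > 3.5

    def test_oblique_affine_maps_gradient_to_world(self):
        """A rotated grid still yields the world-frame gradient."""
        theta = 0.4
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        affine = np.eye(4)
        affine[:3, :3] = R * 1.1  # rotation + isotropic scale
        geom = GridGeometry((7, 7, 7), affine)
        coords = geom.world_coordinates()
        A = np.array([[0.03, 0.01, 0.0], [0.0, -0.02, 0.005], [0.0, 0.0, 0.01]])
        data = (coords @ A.T)[:, :, :, None, :]
        g = displacement_gradient(DisplacementField(data, geom))
        np.testing.assert_allclose(
            g.values, np.broadcast_to(A, g.values.shape), atol=1e-12
        )

    def test_single_voxel_mask_rejected(self):
        geom = GridGeometry.axis_aligned((4, 4, 4))
        data = np.full((4, 4, 4, 1, 3), np.nan)
        data[2, 2, 2] = 1.0
        with pytest.raises(ValueError, match="gradient"):
            displacement_gradient(DisplacementField(data, geom))

    def test_isolated_voxel_marked_invalid(self):
        geom = GridGeometry.axis_aligned((6, 6, 6))
        data = np.full((6, 6, 6, 1, 3), np.nan)
        data[1, 1, 1] = 0.5
        data[4, 4, 4] = 0.5
        g = displacement_gradient(DisplacementField(data, geom))
        assert np.isnan(g.values[1, 1, 1]).all()


# ---------------------------------------------------------------------------
# deformation gradient
# ---------------------------------------------------------------------------


class TestDeformationGradient:
    def _tensor(self, gradU):
        geom = GridGeometry.axis_aligned((2, 2, 2))
        vals = np.broadcast_to(gradU, (2, 2, 2, 1, 3, 3)).copy()
        return TensorField(vals, geom, quantity="gradU")

    def test_zero_gradient_gives_identity(self):
        F = deformation_gradient(self._tensor(np.zeros((3, 3))))
        np.testing.assert_allclose(F.values - np.eye(3), 0.0, atol=1e-15)
        np.testing.assert_allclose(F.det().values, 1.0)

    def test_diagonal_closed_form(self):
        F = deformation_gradient(self._tensor(np.diag([0.1, 0.0, 0.0])))
        np.testing.assert_allclose(
            F.values[0, 0, 0, 0], np.diag([1 / 0.9, 1.0, 1.0]), rtol=1e-14
        )
        np.testing.assert_allclose(F.det().values, 1 / 0.9, rtol=1e-14)

    def test_singular_voxel_invalidated_not_raised(self):
        F = deformation_gradient(self._tensor(np.eye(3)))  # I - gradU = 0
        assert np.isnan(F.values).all()

    def test_nan_input_propagates_to_invalid(self):
        g = np.zeros((3, 3))
        tf = self._tensor(g)
        vals = tf.values.copy()
        vals[0, 0, 0] = np.nan
        tf = TensorField(vals, tf.geometry, quantity="gradU")
        F = deformation_gradient(tf)
        assert np.isnan(F.values[0, 0, 0]).all()
        assert np.isfinite(F.values[1, 1, 1]).all()


# ---------------------------------------------------------------------------
# strain
# ---------------------------------------------------------------------------


class TestGreenLagrangeStrain:
    def _F(self, mat):
        geom = GridGeometry.axis_aligned((2, 2, 2))
        vals = np.broadcast_to(mat, (2, 2, 2, 1, 3, 3)).copy()
        return TensorField(vals, geom, quantity="F")

    def test_identity_gives_zero_both_conventions(self):
        F = self._F(np.eye(3))
        for conv in ("standard", "paper"):
            E = green_lagrange_strain(F, conv)
            np.testing.assert_array_equal(E.values, 0.0)

    def test_rotation_gives_zero_both_conventions(self):
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        F = self._F(R)
        for conv in ("standard", "paper"):
            E = green_lagrange_strain(F, conv)
            np.testing.assert_allclose(E.values, 0.0, atol=1e-15)

    def test_uniaxial_closed_forms(self):
        F = self._F(np.diag([1.1, 1.0, 1.0]))
        E_std = green_lagrange_strain(F, "standard")
        assert E_std.values[0, 0, 0, 0, 0, 0] == pytest.approx((1.1**2 - 1) / 2)
        assert E_std.values[0, 0, 0, 0, 0, 0] == pytest.approx(0.105)
        E_paper = green_lagrange_strain(F, "paper")
        assert E_paper.values[0, 0, 0, 0, 0, 0] == pytest.approx(0.21)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            green_lagrange_strain(self._F(np.eye(3)), "weird")


class TestStrainRate:
    def test_constant_strain_zero_rate(self):
        geom = GridGeometry.axis_aligned((2, 2, 2), frames=4)
        vals = np.broadcast_to(np.diag([0.1, 0.2, 0.3]), (2, 2, 2, 4, 3, 3)).copy()
        E = TensorField(vals, geom, quantity="E", symmetric=True)
        rate = strain_rate(E)
        np.testing.assert_array_equal(rate.values, 0.0)
        assert rate.units == "1/s"

    def test_sinusoidal_strain_rate_matches_cosine(self):
        n_t, T, c = 32, 1.0, 0.02
        geom = GridGeometry.axis_aligned((2, 2, 2), frames=n_t,
                                         frame_interval=T / n_t)
        t = np.arange(n_t) * T / n_t
        vals = np.zeros((2, 2, 2, n_t, 3, 3))
        vals[..., 0, 0] = c * np.sin(2 * np.pi * t / T)
        E = TensorField(vals, geom, quantity="E", symmetric=True)
        rate = strain_rate(E)
        exact = (2 * np.pi * c / T) * np.cos(2 * np.pi * t / T)
        # periodic central differences: O(dt^2) accurate
        np.testing.assert_allclose(rate.values[0, 0, 0, :, 0, 0], exact,
                                   atol=np.abs(exact).max() * (2 * np.pi / n_t) ** 2)

    def test_two_frames_rejected(self):
        geom = GridGeometry.axis_aligned((2, 2, 2), frames=2)
        E = TensorField(np.zeros((2, 2, 2, 2, 3, 3)), geom, quantity="E")
        with pytest.raises(ValueError, match="3 frames"):
            strain_rate(E)


# ---------------------------------------------------------------------------
# energy and stress
# ---------------------------------------------------------------------------


class TestStrainEnergy:
    def test_reference_state_zero_energy(self):
        labels = uniform_labels((2, 2, 2))
        geom = labels.geometry
        F = TensorField(np.broadcast_to(np.eye(3), (2, 2, 2, 1, 3, 3)).copy(),
                        geom, quantity="F")
        W = strain_energy_density(F, MaterialTable(), labels)
        np.testing.assert_allclose(W.values, 0.0, atol=1e-12)

    def test_pure_dilation_energy_is_volumetric_only(self):
        J = 1.01
        Fmat = J ** (1 / 3) * np.eye(3)
        labels = uniform_labels((2, 2, 2))
        F = TensorField(np.broadcast_to(Fmat, (2, 2, 2, 1, 3, 3)).copy(),
                        labels.geometry, quantity="F")
        W = strain_energy_density(F, MaterialTable(), labels)
        expected = WM_K * ((J**2 - 1) / 4 - 0.5 * np.log(J))
        np.testing.assert_allclose(W.values, expected, rtol=1e-12)

    def test_simple_shear_energy_is_isochoric_only(self):
        gamma = 0.1
        Fmat = np.eye(3)
        Fmat[0, 1] = gamma
        labels = uniform_labels((2, 2, 2))
        F = TensorField(np.broadcast_to(Fmat, (2, 2, 2, 1, 3, 3)).copy(),
                        labels.geometry, quantity="F")
        W = strain_energy_density(F, MaterialTable(), labels)
        # J = 1, I1_bar = 3 + gamma^2
        np.testing.assert_allclose(W.values, 0.5 * WM_G * gamma**2, rtol=1e-12)

    def test_missing_material_entry_rejected(self):
        labels = uniform_labels((2, 2, 2), label=2)  # GM
        F = TensorField(np.broadcast_to(np.eye(3), (2, 2, 2, 1, 3, 3)).copy(),
                        labels.geometry, quantity="F")
        incomplete = MaterialTable(shear_kpa={TissueClass.WM: 0.624},
                                   bulk_kpa={TissueClass.WM: 5e4})
        with pytest.raises(ValueError, match="GM"):
            strain_energy_density(F, incomplete, labels)


class TestCauchyStress:
    def _stress_for(self, Fmat, label=3):
        labels = uniform_labels((2, 2, 2), label=label)
        F = TensorField(np.broadcast_to(Fmat, (2, 2, 2, 1, 3, 3)).copy(),
                        labels.geometry, quantity="F")
        return cauchy_stress(F, MaterialTable(), labels)

    def test_reference_state_stress_free(self):
        sigma = self._stress_for(np.eye(3))
        np.testing.assert_allclose(sigma.values, 0.0, atol=1e-12)

    def test_pure_dilation_hydrostatic(self):
        J = 1.01
        sigma = self._stress_for(J ** (1 / 3) * np.eye(3))
        p = 0.5 * WM_K * (J - 1 / J)
        np.testing.assert_allclose(sigma.values[0, 0, 0, 0], p * np.eye(3), rtol=1e-10)

    def test_simple_shear_first_order(self):
        gamma = 0.01
        Fmat = np.eye(3)
        Fmat[0, 1] = gamma
        sigma = self._stress_for(Fmat)
        assert sigma.values[0, 0, 0, 0, 0, 1] == pytest.approx(WM_G * gamma, rel=1e-3)

    def test_csf_voxels_invalid_unless_included(self):
        sigma_excl = self._stress_for(np.eye(3), label=1)
        assert np.isnan(sigma_excl.values).all()
        labels = uniform_labels((2, 2, 2), label=1)
        F = TensorField(np.broadcast_to(np.eye(3), (2, 2, 2, 1, 3, 3)).copy(),
                        labels.geometry, quantity="F")
        sigma_incl = cauchy_stress(F, MaterialTable(include_csf=True), labels)
        assert np.isfinite(sigma_incl.values).all()

    def test_matches_numerical_energy_derivative(self, rng):
        """Closed form vs (1/J)(dW/dF)F^T on random deformation gradients."""
        Fs = random_deformation_gradients(200, rng)
        closed = mooney_rivlin_cauchy_stress(Fs, WM_G, WM_K)
        worst = 0.0
        for Fmat, sig in zip(Fs, closed):
            num = stress_oracle(Fmat, WM_G, WM_K)
            worst = max(worst, np.linalg.norm(num - sig) / np.linalg.norm(num))
        assert worst < 1e-5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_energy_nonnegative_for_positive_J(self, seed):
        rng = np.random.default_rng(seed)
        Fs = random_deformation_gradients(40, rng)
        W = mooney_rivlin_energy(Fs, WM_G, WM_K)
        assert (W >= -1e-12).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_stress_objective_under_superposed_rotation(self, seed):
        """sigma(R F) = R sigma(F) R^T for any rotation R."""
        rng = np.random.default_rng(seed)
        F = random_deformation_gradients(1, rng)[0]
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        R = q * np.linalg.det(q)  # proper rotation
        left = mooney_rivlin_cauchy_stress(R @ F, WM_G, WM_K)
        right = R @ mooney_rivlin_cauchy_stress(F, WM_G, WM_K) @ R.T
        np.testing.assert_allclose(left, right, atol=1e-8)

    def test_small_strain_limit_matches_linear_elasticity(self, rng):
        """For ||grad U|| ~ 1e-4, sigma ~ 2G eps + (K - 2G/3) tr(eps) I."""
        for _ in range(20):
            gradU = 1e-4 * rng.standard_normal((3, 3))
            F = np.linalg.inv(np.eye(3) - gradU)
            sigma = mooney_rivlin_cauchy_stress(F, WM_G, WM_K)
            eps = 0.5 * (gradU + gradU.T)
            lam = WM_K - 2 * WM_G / 3
            sigma_lin = 2 * WM_G * eps + lam * np.trace(eps) * np.eye(3)
            err = np.linalg.norm(sigma - sigma_lin) / np.linalg.norm(sigma_lin)
            assert err < 1e-2


class TestVonMises:
    def _tensor(self, mat, quantity="sigma"):
        geom = GridGeometry.axis_aligned((2, 2, 2))
        vals = np.broadcast_to(mat, (2, 2, 2, 1, 3, 3)).copy()
        return TensorField(vals, geom, quantity=quantity, symmetric=True)

    def test_hydrostatic_stress_vanishes(self):
        vm = von_mises(self._tensor(2.5 * np.eye(3)))
        np.testing.assert_allclose(vm.values, 0.0, atol=1e-12)

    def test_uniaxial_stress_equals_magnitude(self):
        vm = von_mises(self._tensor(np.diag([-3.0, 0.0, 0.0])))
        np.testing.assert_allclose(vm.values, 3.0, rtol=1e-12)

    def test_pure_shear_stress_sqrt3_tau(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = 2.0
        vm = von_mises(self._tensor(mat))
        np.testing.assert_allclose(vm.values, np.sqrt(3) * 2.0, rtol=1e-12)

    def test_strain_kind_uses_two_thirds_factor(self):
        mat = np.diag([0.01, -0.005, -0.005])
        vm = von_mises(self._tensor(mat, quantity="E"))
        d = mat - np.trace(mat) / 3 * np.eye(3)
        expected = np.sqrt(2 / 3 * (d * d).sum())
        np.testing.assert_allclose(vm.values, expected, rtol=1e-12)

    def test_nonsymmetric_input_rejected(self):
        geom = GridGeometry.axis_aligned((2, 2, 2))
        tf = TensorField(np.zeros((2, 2, 2, 1, 3, 3)), geom, quantity="F",
                         symmetric=False)
        with pytest.raises(ValueError, match="symmetric"):
            von_mises(tf)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


class TestRunMechanics:
    def test_zero_phantom_all_quantities_zero(self):
        field, labels, _ = make_phantom(PhantomSpec(kind="zero", n_t=4, shape=(10, 10, 10)))
        trimmed = trim_to_mask(field, labels)
        res = run_mechanics(trimmed, labels)
        for key in ("E", "vm_strain", "vm_stress", "E_rate"):
            np.testing.assert_allclose(np.nan_to_num(res[key].values), 0.0, atol=1e-12)

    def test_uniform_stretch_matches_ground_truth(self, trimmed_stretch):
        trimmed, labels, truth = trimmed_stretch
        res = run_mechanics(trimmed, labels)
        inner = interior_mask(labels)
        np.testing.assert_allclose(
            res["E"].values[inner], truth.E[inner], atol=1e-12
        )
        np.testing.assert_allclose(
            res["sigma"].values[inner], truth.sigma[inner], atol=1e-6, equal_nan=True
        )

    def test_single_timepoint_outputs_selected_frame_only(self):
        spec = PhantomSpec(kind="pulsatile_composite", amplitude=0.1, n_t=10,
                           shape=(12, 12, 12))
        field, labels, _ = make_phantom(spec)
        trimmed = trim_to_mask(field, labels)
        cfg = PipelineConfig(temporal_mode="single_timepoint",
                             selection_metric="strain_p90")
        res = run_mechanics(trimmed, labels, config=cfg)
        # modulation sin^2(pi k/10) peaks at k=5
        assert res["E"].frame_indices == (5,)
        assert res["E"].values.shape[3] == 1
        assert res["sigma"].frame_indices == (5,)

    def test_objectivity_rigid_rotation_phantom(self):
        field, labels, _ = make_phantom(
            PhantomSpec(kind="rigid_rotation", amplitude=5.0, n_t=3, shape=(12, 12, 12))
        )
        trimmed = trim_to_mask(field, labels)
        res = run_mechanics(trimmed, labels)
        for conv_values in (res["E"].values, ):
            assert np.nanmax(np.abs(conv_values)) < 1e-8
        assert np.nanmax(res["vm_stress"].values) < 1e-8

    def test_paper_strain_convention_doubles_small_strain(self, trimmed_stretch):
        trimmed, labels, _ = trimmed_stretch
        std = run_mechanics(trimmed, labels)["E"]
        paper = run_mechanics(trimmed, labels,
                              config=PipelineConfig(strain_convention="paper"))["E"]
        np.testing.assert_allclose(paper.values, 2 * std.values,
                                   atol=1e-12, equal_nan=True)

    def test_grid_mismatch_rejected(self, stretch_phantom):
        field, labels, _ = stretch_phantom
        other = uniform_labels((5, 5, 5))
        with pytest.raises(ValueError, match="grid"):
            run_mechanics(field, other)
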