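"""Cavalieri, fractionator, density and volume-tensor estimators vs exact oracles."""

import numpy as np
import pytest

from stereocol import (
    CavalieriCounts,
    EllipsoidCell,
    FractionatorCounts,
    Window3D,
    cavalieri_volume,
    effective_section_spacing,
    exact_volume_tensors,
    fractionator_number,
    number_density,
    rotator_tensor_estimate,
    tensor_summaries,
    voxelize_cells,
)
from stereocol.stereology import ellipsoid_volume_tensors

from conftest import rotation_about_z


class TestCavalieri:
    def test_identity_scaling(self):
        assert cavalieri_volume(CavalieriCounts(1.0, 1.0, np.array([100]))) == 100.0

    def test_zero_counts(self):
        assert cavalieri_volume(CavalieriCounts(20.0, 400.0, np.zeros(5, dtype=int))) == 0.0

    def test_formula(self):
        counts = CavalieriCounts(T=2.5, area_per_point=150.0, counts=np.array([3, 7, 5]))
        assert cavalieri_volume(counts) == pytest.approx(2.5 * 150.0 * 15)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            CavalieriCounts(T=0.0, area_per_point=1.0, counts=np.array([1]))
        with pytest.raises(ValueError):
            CavalieriCounts(T=1.0, area_per_point=1.0, counts=np.array([-1]))


class TestFractionator:
    def test_full_sampling_identity(self):
        c = FractionatorCounts(Q=57, ssf=1, bsf=1, asf=1, hsf=1)
        assert fractionator_number(c) == 57.0

    def test_component_form_leading_factor_two(self):
        # equal component ratios leave only the every-second-slab factor
        c = FractionatorCounts(Q=10, T=40.0, MA=40.0, A=100.0, a=100.0, h=20.0, t_Q=20.0)
        assert fractionator_number(c) == 20.0

    def test_both_forms_must_agree(self):
        good = FractionatorCounts(Q=10, ssf=0.5, bsf=1, asf=1, hsf=1,
                                  T=40.0, MA=40.0, A=100.0, a=100.0, h=20.0, t_Q=20.0)
        assert fractionator_number(good) == 20.0
        bad = FractionatorCounts(Q=10, ssf=0.25, bsf=1, asf=1, hsf=1,
                                 T=40.0, MA=40.0, A=100.0, a=100.0, h=20.0, t_Q=20.0)
        with pytest.raises(ValueError, match="disagree"):
            fractionator_number(bad)

    def test_component_invariants(self):
        with pytest.raises(ValueError, match="disector height"):
            FractionatorCounts(Q=1, T=40.0, MA=40.0, A=100.0, a=100.0, h=30.0, t_Q=20.0)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            FractionatorCounts(Q=1, ssf=0.0, bsf=1, asf=1, hsf=1)


class TestDensityAndSpacing:
    def test_unit_conversion_to_mm3(self):
        assert number_density(100, 50.0) == pytest.approx(2e9)

    def test_zero_count(self):
        assert number_density(0, 10.0) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            number_density(1, 0.0)

    def test_effective_spacing_every_third_section(self):
        assert effective_section_spacing(300.0, 3) == 900.0


class TestExactTensors:
    def test_unit_ball_symmetry(self):
        ball = EllipsoidCell(semi_axes=(1, 1, 1), center=(0, 0, 0))
        t = exact_volume_tensors(ball, reference=(0, 0, 0))
        assert t.rank0 == pytest.approx(4 * np.pi / 3)
        np.testing.assert_allclose(t.rank1, 0.0, atol=1e-12)
        # ∫x_i² dx over the unit ball = 4π/15; rank 2 carries the 1/2! factor
        np.testing.assert_allclose(np.diag(t.rank2), 0.5 * 4 * np.pi / 15, rtol=1e-12)

    def test_offset_ellipsoid_closed_form(self, prolate_cell):
        t = exact_volume_tensors(prolate_cell, reference=(0, 0, 0))
        assert t.rank0 == pytest.approx(4 / 3 * np.pi * 250, rel=1e-12)
        np.testing.assert_allclose(t.rank1 / t.rank0, [2.0, 0.0, 0.0], atol=1e-12)

    def test_matches_midpoint_rule_integration(self, prolate_cell):
        """Voxel-sum integration at fine pitch confirms the closed forms to <0.2%."""
        w = Window3D(40, 40, 40)
        shifted = EllipsoidCell(semi_axes=prolate_cell.semi_axes, center=(22, 20, 20),
                                nucleolus=(20, 20, 20))
        vol = voxelize_cells([shifted], (200.0, 200.0, 200.0), w)
        t_vox = exact_volume_tensors(vol, reference=(20, 20, 20))
        t_exact = exact_volume_tensors(shifted, reference=(20, 20, 20))
        assert t_vox.rank0 == pytest.approx(t_exact.rank0, rel=2e-3)
        np.testing.assert_allclose(t_vox.rank1, t_exact.rank1, rtol=2e-3, atol=1.0)
        np.testing.assert_allclose(t_vox.rank2, t_exact.rank2, rtol=4e-3, atol=20.0)

    def test_rotation_invariant_rank0(self, prolate_cell):
        rot = rotation_about_z(37.0)
        cell = EllipsoidCell(semi_axes=prolate_cell.semi_axes, center=(0, 0, 0), rotation=rot)
        t = exact_volume_tensors(cell, reference=(0, 0, 0))
        assert t.rank0 == pytest.approx(prolate_cell.volume, rel=1e-12)


class TestRotator:
    def test_empty_cell_zero_tensors(self):
        t = rotator_tensor_estimate(None, n_planes=1, seed=0)
        assert t.rank0 == 0.0

    def test_ball_single_plane_exact(self, ball10):
        for seed in range(5):
            t = rotator_tensor_estimate(ball10, n_planes=1, seed=seed)
            assert t.rank0 == pytest.approx(ball10.volume, rel=1e-12)

    def test_reference_outside_rejected(self, ball10):
        with pytest.raises(ValueError, match="reference"):
            rotator_tensor_estimate(ball10, reference=(50, 0, 0), n_planes=1, seed=0)

    def test_unbiased_against_exact_oracle(self, prolate_cell):
        exact = exact_volume_tensors(prolate_cell, reference=(0, 0, 0))
        est = rotator_tensor_estimate(prolate_cell, reference=(0, 0, 0),
                                      n_planes=10_000, seed=1)
        assert est.rank0 == pytest.approx(exact.rank0, rel=0.01)
        scale2 = np.abs(exact.rank2).max()
        np.testing.assert_allclose(est.rank2, exact.rank2, atol=0.02 * scale2)

    def test_monte_carlo_convergence_rate(self, prolate_cell):
        """Relative error roughly halves when the plane count quadruples."""
        exact = exact_volume_tensors(prolate_cell, reference=(0, 0, 0)).rank0
        errs = []
        for n_planes in (100, 400, 1600):
            e = [
                abs(rotator_tensor_estimate(prolate_cell, reference=(0, 0, 0),
                                            n_planes=n_planes, seed=s).rank0 - exact)
                for s in range(40)
            ]
            errs.append(np.mean(e))
        assert errs[2] < errs[1] < errs[0]
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.5)

    def test_tilted_vertical_axis(self, prolate_cell):
        exact = exact_volume_tensors(prolate_cell, reference=(0, 0, 0)).rank0
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        est = rotator_tensor_estimate(prolate_cell, reference=(0, 0, 0),
                                      vertical_axis=axis, n_planes=4000, seed=2)
        assert est.rank0 == pytest.approx(exact, rel=0.02)


class TestTensorSummaries:
    def test_ball_is_isotropic(self, ball10):
        s = tensor_summaries(exact_volume_tensors(ball10, reference=(0, 0, 0)))
        assert s.elongation_index == pytest.approx(1.0, abs=1e-9)
        assert s.displacement == pytest.approx(0.0, abs=1e-9)

    def test_ellipsoid_recovery(self, prolate_cell):
        s = tensor_summaries(exact_volume_tensors(prolate_cell, reference=(0, 0, 0)))
        assert s.elongation_index == pytest.approx(2.0, rel=5e-3)
        np.testing.assert_allclose(s.semi_axes, [10, 5, 5], rtol=5e-3)
        assert s.displacement == pytest.approx(2.0, rel=5e-3)
        assert s.volume == pytest.approx(4 / 3 * np.pi * 250, rel=1e-9)

    def test_fitted_volume_matches_rank0(self, prolate_cell):
        s = tensor_summaries(exact_volume_tensors(prolate_cell, reference=(0, 0, 0)))
        fitted = 4 / 3 * np.pi * np.prod(s.semi_axes)
        assert fitted == pytest.approx(s.volume, rel=1e-9)

    def test_rotated_cell_axes_follow_rotation(self):
        rot = rotation_about_z(30.0)
        cell = EllipsoidCell(semi_axes=(10, 5, 5), center=(0, 0, 0), rotation=rot)
        s = tensor_summaries(ellipsoid_volume_tensors(cell))
        principal = s.axes[0]
        expected = rot @ np.array([1.0, 0.0, 0.0])
        assert abs(principal @ expected) == pytest.approx(1.0, abs=1e-9)

    def test_elongation_never_below_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            semi = np.sort(rng.uniform(3, 12, size=3))[::-1]
            cell = EllipsoidCell(semi_axes=semi, center=(0, 0, 0))
            s = tensor_summaries(ellipsoid_volume_tensors(cell))
            assert s.elongation_index >= 1.0

    def test_zero_volume_rejected(self):
        from stereocol import VolumeTensors

        with pytest.raises(ValueError):
            tensor_summaries(VolumeTensors(0.0, np.zeros(3), np.zeros((3, 3))))

    def test_non_psd_rejected(self):
        from stereocol import VolumeTensors

        bad = VolumeTensors(1.0, np.zeros(3), -np.eye(3))
        with pytest.raises(ValueError, match="positive semidefinite"):
            tensor_summaries(bad)
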