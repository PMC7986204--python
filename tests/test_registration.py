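"""VOI construction, correlation ratio, translation search, cyclic loop."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtvgen.exceptions import (
    EmptyMaskError,
    NoValidRegistrationError,
    UndefinedCostError,
)
from gtvgen.imaging_io import BinaryMask, GridGeometry, ImageVolume
from gtvgen.phantom import PhantomConfig, render_phase_series
from gtvgen.registration import (
    MotionPath,
    RegistrationOutcome,
    SearchSettings,
    Translation,
    VOIMethod,
    _correlation_ratio_1d,
    build_voi,
    correlation_ratio,
    cyclic_phase_order,
    cyclic_register,
    register_translation,
    remove_chest_wall,
    select_registration,
    si_prior_mm,
)
from gtvgen.qa_metrics import surface_dta

from ._oracles import brute_correlation_ratio
from .conftest import sphere_mask


class TestVOIMethods:
    def test_standard_method_table(self):
        assert VOIMethod.standard(1) == VOIMethod(1, 4.0, False, 0.0)
        assert VOIMethod.standard(2) == VOIMethod(2, 4.0, True, 0.0)
        assert VOIMethod.standard(3) == VOIMethod(3, 4.0, False, 20.0)
        assert VOIMethod.standard(4) == VOIMethod(4, 10.0, False, 0.0)

    def test_voi_is_a_4mm_dilation(self, unit_grid):
        igtv = sphere_mask(unit_grid, (0, 0, 0), 8.0)
        image = ImageVolume(unit_grid, np.full(unit_grid.shape, -800.0))
        voi = build_voi(igtv, image, VOIMethod.standard(1))
        assert np.all(~igtv.voxels | voi.voxels)
        mean_d, _ = surface_dta(voi, igtv)
        assert mean_d == pytest.approx(4.0, abs=1.0)

    def test_method4_expands_further_than_method1(self, unit_grid):
        igtv = sphere_mask(unit_grid, (0, 0, 0), 8.0)
        image = ImageVolume(unit_grid, np.full(unit_grid.shape, -800.0))
        v1 = build_voi(igtv, image, VOIMethod.standard(1))
        v4 = build_voi(igtv, image, VOIMethod.standard(4))
        assert np.all(~v1.voxels | v4.voxels)
        mean_d, _ = surface_dta(v4, igtv)
        assert mean_d == pytest.approx(10.0, abs=1.5)

    def test_zero_expansion_is_identity(self, unit_grid):
        igtv = sphere_mask(unit_grid, (0, 0, 0), 8.0)
        image = ImageVolume(unit_grid, np.full(unit_grid.shape, -800.0))
        voi = build_voi(igtv, image, VOIMethod(1, 0.0, False, 0.0))
        assert np.array_equal(voi.voxels, igtv.voxels)

    def test_empty_igtv_rejected(self, unit_grid):
        image = ImageVolume(unit_grid, np.full(unit_grid.shape, -800.0))
        empty = BinaryMask(unit_grid, np.zeros(unit_grid.shape, bool))
        with pytest.raises(EmptyMaskError):
            build_voi(empty, image, VOIMethod.standard(1))


class TestRemoveChestWall:
    def test_bright_slab_removed_from_voi(self, unit_grid):
        vals = np.full(unit_grid.shape, -800.0)
        vals[:, 40:, :] = 300.0  # chest-wall slab above 176 HU
        image = ImageVolume(unit_grid, vals)
        voi = BinaryMask(unit_grid, np.ones(unit_grid.shape, bool))
        out = remove_chest_wall(image, voi)
        assert not out.voxels[:, 40:, :].any()
        assert out.voxels[:, :38, :].all()

    def test_all_lung_image_leaves_voi_unchanged(self, unit_grid):
        image = ImageVolume(unit_grid, np.full(unit_grid.shape, -800.0))
        voi = sphere_mask(unit_grid, (0, 0, 0), 10.0)
        out = remove_chest_wall(image, voi)
        assert np.array_equal(out.voxels, voi.voxels)

    def test_closing_removes_gap_between_plates(self, unit_grid):
        vals = np.full(unit_grid.shape, -800.0)
        vals[:, 38:40, :] = 300.0
        vals[:, 42:44, :] = 300.0  # 2-voxel gap between two bright plates
        image = ImageVolume(unit_grid, vals)
        voi = BinaryMask(unit_grid, np.ones(unit_grid.shape, bool))
        out = remove_chest_wall(image, voi)
        assert not out.voxels[:, 40:42, :].any()  # gap closed and removed


class TestCorrelationRatio:
    def test_identical_images_near_one(self, unit_grid):
        # binned estimator: exact dependence gives 1 up to bin-width variance
        rng = np.random.default_rng(0)
        vals = rng.normal(-500, 300, unit_grid.shape)
        img = ImageVolume(unit_grid, vals)
        mask = sphere_mask(unit_grid, (0, 0, 0), 15.0)
        assert correlation_ratio(img, img, mask) > 0.99

    def test_invariant_under_affine_remap_of_moving(self, unit_grid):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 100, unit_grid.shape)
        fixed = ImageVolume(unit_grid, vals)
        moving = ImageVolume(unit_grid, 2.0 * vals + 5.0)
        mask = sphere_mask(unit_grid, (0, 0, 0), 15.0)
        assert correlation_ratio(fixed, moving, mask) == pytest.approx(
            correlation_ratio(fixed, fixed, mask), abs=1e-12
        )
        assert correlation_ratio(fixed, moving, mask) > 0.99

    def test_independent_noise_gives_near_zero(self):
        rng = np.random.default_rng(2)
        fixed = rng.uniform(0, 1, 10_000)
        moving = rng.uniform(0, 1, 10_000)
        assert _correlation_ratio_1d(fixed, moving, n_bins=32) < 0.05

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(200, 2000)
        fixed = rng.normal(0, 1, n)
        moving = 0.7 * fixed + rng.normal(0, 0.5, n)
        assert _correlation_ratio_1d(fixed, moving) == pytest.approx(
            brute_correlation_ratio(fixed, moving), abs=1e-12
        )

    def test_constant_moving_rejected(self):
        with pytest.raises(UndefinedCostError):
            _correlation_ratio_1d(np.linspace(0, 1, 100), np.zeros(100))


@pytest.fixture(scope="module")
def clean_phantom():
    cfg = PhantomConfig(noise_sd_hu=0.0, seed=1)
    series, truth = render_phase_series(cfg)
    voi = build_voi(truth.igtv_true, series.reference, VOIMethod.standard(1))
    return series, truth, voi


class TestRegisterTranslation:
    def test_identity_registration(self, clean_phantom):
        series, _, voi = clean_phantom
        t, cost = register_translation(
            series.reference, series.reference, voi, Translation()
        )
        assert t == Translation(0.0, 0.0, 0.0)
        assert cost > 0.95  # 1.0 up to bin-quantisation of the estimator

    @pytest.mark.parametrize("label", [0, 20, 70])
    def test_noise_free_recovery_within_half_mm(self, clean_phantom, label):
        series, truth, voi = clean_phantom
        t, cost = register_translation(
            series.reference, series.phases[label], voi, Translation()
        )
        err = np.abs(t.as_array() - truth.path_true.shifts[label].as_array())
        assert np.all(err <= 0.5)
        assert cost > 0.9

    def test_seeding_at_truth_is_not_worsened(self, clean_phantom):
        series, truth, voi = clean_phantom
        true_t = truth.path_true.shifts[0]
        settings = SearchSettings(coarse_halfwidth_mm=4.0)
        t, _ = register_translation(
            series.reference, series.phases[0], voi, true_t, settings
        )
        assert np.all(np.abs(t.as_array() - true_t.as_array()) <= 0.5)


class TestCyclicRegister:
    def test_visiting_order_wraps_from_reference(self):
        assert cyclic_phase_order(50) == [60, 70, 80, 90, 0, 10, 20, 30, 40]

    def test_si_prior_waveform(self):
        assert si_prior_mm(0, 20.0) == pytest.approx(20.0)
        assert si_prior_mm(50, 20.0) == pytest.approx(0.0)
        assert si_prior_mm(20, 20.0) == pytest.approx(10 * (1 + np.cos(0.4 * np.pi)))

    def test_zero_motion_phantom_gives_zero_path(self):
        cfg = PhantomConfig(
            noise_sd_hu=0.0, peak_to_peak_mm=0.0, hysteresis_mm=0.0, seed=2
        )
        series, truth = render_phase_series(cfg)
        voi = build_voi(truth.igtv_true, series.reference, VOIMethod.standard(1))
        out = cyclic_register(series, voi, VOIMethod.standard(1))
        assert np.all(out.path.as_array() == 0)
        assert out.cost_sd == pytest.approx(0.0, abs=1e-9)

    def test_reference_shift_always_zero(self, clean_phantom):
        series, _, voi = clean_phantom
        out = cyclic_register(series, voi, VOIMethod.standard(1))
        assert out.path.shifts[50] == Translation(0.0, 0.0, 0.0)
        assert sorted(out.costs) == [0, 10, 20, 30, 40, 60, 70, 80, 90]


class TestSelectRegistration:
    @staticmethod
    def outcome(method_id, sds):
        path = MotionPath.from_array(np.zeros((10, 3)))
        costs = {k: 0.9 + sds * ((-1) ** i) for i, k in enumerate(sorted(
            set(range(0, 100, 10)) - {50}))}
        return RegistrationOutcome(VOIMethod.standard(method_id), path, costs)

    def test_minimum_sd_selected(self):
        outs = [self.outcome(i + 1, sd) for i, sd in enumerate([0.02, 0.05, 0.04, 0.09])]
        assert select_registration(outs).method.id == 1

    def test_single_outcome_returned(self):
        outs = [self.outcome(3, 0.07)]
        assert select_registration(outs) is outs[0]

    def test_tie_broken_by_lower_method_id(self):
        outs = [self.outcome(3, 0.03), self.outcome(2, 0.03)]
        assert select_registration(outs).method.id == 2

    def test_failed_outcomes_excluded_and_all_failed_raises(self):
        good = self.outcome(4, 0.05)
        bad = dataclasses.replace(self.outcome(1, 0.0), failed=True)
        assert select_registration([bad, good]).method.id == 4
        with pytest.raises(NoValidRegistrationError):
            select_registration([bad])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0.0, 0.2), min_size=1, max_size=4))
    def test_selection_minimises_sd_exhaustively(self, sds):
        outs = [self.outcome((i % 4) + 1, sd) for i, sd in enumerate(sds)]
        chosen = select_registration(outs)
        assert all(chosen.cost_sd <= o.cost_sd + 1e-12 for o in outs)
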