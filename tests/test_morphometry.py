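"""Descriptor oracles, CII arithmetic, thresholds, classification, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomorph import morphometry as M
from cardiomorph import synthetic as syn
from cardiomorph.exceptions import (
    FormatError,
    MeasurementError,
    ProfileError,
    ThresholdError,
    ValidationError,
)
from conftest import ellipse_mask, single_region

CIRCLE_CII = 3.0 - np.pi / 4.0  # aspect 1 − area/box π/4 + roundness 1 + radius ratio 1


def make_cell(cell_id=1, area=300.0, aspect=1.0, area_box=0.785, roundness=1.0, radius_ratio=1.0):
    return M.CellMorphometry.from_descriptors(cell_id, area, aspect, area_box, roundness, radius_ratio)


class TestExtractRegions:
    def test_labels_map_one_to_one(self):
        mask = np.zeros((30, 30), np.int32)
        mask[2:6, 2:6] = 1
        mask[10:16, 10:16] = 2
        mask[20:25, 20:25] = 3
        regions = M.extract_regions(mask)
        assert sorted(r.label for r in regions) == [1, 2, 3]

    def test_empty_mask_gives_empty_list(self):
        assert M.extract_regions(np.zeros((10, 10), np.int32)) == []

    def test_float_mask_rejected(self):
        with pytest.raises(FormatError):
            M.extract_regions(np.zeros((10, 10), float))

    def test_border_region_flagged_and_skipped_by_default(self):
        mask = np.zeros((40, 40), np.int32)
        mask[0:8, 5:13] = 1  # touches row 0
        mask[15:25, 15:25] = 2
        regions = {r.label: r for r in M.extract_regions(mask)}
        assert regions[1].touches_border and not regions[2].touches_border
        cells = M.measure_cells(mask)
        assert [c.cell_id for c in cells] == [2]

    def test_synthetic_field_recovers_all_cells(self):
        spec = syn.PopulationSpec(class_mixture={"N": 1.0}, n_cells=50, seed=4)
        truths = syn.sample_cell_truth(spec)
        _, labels = syn.render_field(truths, syn.RenderConfig(seed=4))
        regions = M.extract_regions(labels)
        assert len(regions) == 50
        assert not any(r.touches_border for r in regions)


class TestMeasureRegion:
    @pytest.mark.parametrize("radius", [30, 40, 60])
    def test_circle_fixed_point(self, circle_region, radius):
        m = M.measure_region(circle_region(radius))
        assert m.aspect == pytest.approx(1.0, rel=0.03)
        assert m.area_box == pytest.approx(np.pi / 4, rel=0.03)
        assert m.roundness == pytest.approx(1.0, rel=0.03)
        assert m.radius_ratio == pytest.approx(1.0, rel=0.03)
        assert m.cii == pytest.approx(CIRCLE_CII, rel=0.03)
        assert m.area == pytest.approx(np.pi * radius**2, rel=0.03)

    def test_two_to_one_ellipse(self):
        m = M.measure_region(single_region(ellipse_mask(60, 30)))
        assert m.aspect == pytest.approx(2.0, rel=0.05)
        assert m.area_box == pytest.approx(np.pi / 4, rel=0.05)
        assert m.radius_ratio == pytest.approx(2.0, rel=0.05)

    def test_pixel_size_scales_area_quadratically(self, circle_region):
        region = circle_region(30)
        m1 = M.measure_region(region, pixel_size=1.0)
        m2 = M.measure_region(region, pixel_size=0.5)
        assert m2.area == pytest.approx(m1.area / 4)
        assert m2.aspect == m1.aspect  # shape descriptors are calibration-free

    def test_tiny_region_rejected(self):
        mask = np.zeros((10, 10), np.int32)
        mask[4:6, 4:6] = 1
        with pytest.raises(MeasurementError, match="floor"):
            M.measure_region(M.extract_regions(mask)[0])

    def test_line_region_rejected(self):
        mask = np.zeros((40, 40), np.int32)
        mask[5, 5:30] = 1
        with pytest.raises(MeasurementError):
            M.measure_region(M.extract_regions(mask)[0])

    def test_segmentation_fallback_on_rgb(self):
        spec = syn.PopulationSpec(class_mixture={"N": 1.0}, n_cells=12, seed=6)
        truths = syn.sample_cell_truth(spec)
        rgb, labels = syn.render_field(truths, syn.RenderConfig(seed=6))
        cells = M.measure_cells(rgb, pixel_size=0.35)
        # watershed may split/miss a cell or two; the bulk must come through
        assert len(cells) >= 9


class TestCII:
    def test_circle_values_give_printed_fixed_point(self):
        assert M.compute_cii_values(1.0, 0.785, 1.0, 1.0) == pytest.approx(2.215)

    def test_plain_arithmetic(self):
        assert M.compute_cii_values(2.0, 0.5, 3.0, 4.0) == 8.5

    def test_compute_cii_matches_stored_field(self):
        m = make_cell(aspect=1.4, area_box=0.7, roundness=1.2, radius_ratio=1.5)
        assert M.compute_cii(m) == pytest.approx(m.cii, abs=1e-12)

    @given(
        aspect=st.floats(1.0, 5.0),
        area_box=st.floats(0.1, 1.0),
        roundness=st.floats(1.0, 4.0),
        radius_ratio=st.floats(1.0, 5.0),
        bump=st.floats(0.01, 1.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_each_descriptor(self, aspect, area_box, roundness, radius_ratio, bump):
        base = M.compute_cii_values(aspect, area_box, roundness, radius_ratio)
        assert M.compute_cii_values(aspect + bump, area_box, roundness, radius_ratio) > base
        assert M.compute_cii_values(aspect, area_box, roundness + bump, radius_ratio) > base
        assert M.compute_cii_values(aspect, area_box, roundness, radius_ratio + bump) > base
        assert M.compute_cii_values(aspect, min(area_box + bump, 1.0), roundness, radius_ratio) <= base

    def test_inconsistent_cii_rejected(self):
        with pytest.raises(ValidationError):
            M.CellMorphometry(1, 300.0, 1.0, 0.785, 1.0, 1.0, cii=5.0)


class TestThresholds:
    def test_degenerate_control_collapses_band(self):
        cells = [make_cell(cell_id=i, area=100.0) for i in range(30)]
        with pytest.warns(UserWarning, match="recommended"):
            t = M.derive_thresholds(cells)
        assert t.area_low == t.area_high == 100.0
        assert t.cii_high == pytest.approx(cells[0].cii)

    def test_gaussian_quantile_oracle(self):
        rng = np.random.default_rng(42)
        cells = [make_cell(cell_id=i, area=a) for i, a in enumerate(rng.normal(300, 40, 1000))]
        t = M.derive_thresholds(cells, M.QuantileConfig(5.0, 95.0, 95.0))
        assert t.area_low == pytest.approx(300 - 1.645 * 40, rel=0.03)
        assert t.area_high == pytest.approx(300 + 1.645 * 40, rel=0.03)

    def test_wider_quantiles_widen_band(self):
        rng = np.random.default_rng(0)
        cells = [make_cell(cell_id=i, area=a) for i, a in enumerate(rng.normal(300, 40, 1000))]
        narrow = M.derive_thresholds(cells, M.QuantileConfig(5.0, 95.0, 95.0))
        wide = M.derive_thresholds(cells, M.QuantileConfig(2.5, 97.5, 97.5))
        assert wide.area_low < narrow.area_low
        assert wide.area_high > narrow.area_high

    def test_too_few_control_cells(self):
        with pytest.raises(ThresholdError):
            M.derive_thresholds([make_cell(cell_id=i) for i in range(10)])


class TestClassification:
    T = M.MorphThresholds(area_low=200.0, area_high=400.0, cii_high=3.0)

    @pytest.mark.parametrize(
        "area,cii_extra,expected",
        [
            (300.0, 0.0, M.MorphClass.N),
            (300.0, 2.0, M.MorphClass.I),
            (500.0, 0.0, M.MorphClass.HR),
            (500.0, 2.0, M.MorphClass.HI),
            (100.0, 0.0, M.MorphClass.AR),
            (100.0, 2.0, M.MorphClass.AI),
        ],
    )
    def test_six_classes(self, area, cii_extra, expected):
        # baseline cell has cii ≈ 2.2 (< 3); cii_extra pushes it over the cutoff
        m = make_cell(area=area, roundness=1.0 + cii_extra)
        assert M.classify_cell(m, self.T) is expected

    def test_boundary_values_take_non_extreme_branch(self):
        at_high = make_cell(area=400.0)
        at_low = make_cell(area=200.0)
        assert M.classify_cell(at_high, self.T) is M.MorphClass.N
        assert M.classify_cell(at_low, self.T) is M.MorphClass.N

    @given(area=st.floats(1e-3, 1e4), rough=st.floats(1.0, 10.0))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_exhaustive_and_exclusive(self, area, rough):
        m = make_cell(area=area, roundness=rough)
        assert M.classify_cell(m, self.T) in M.MorphClass


class TestPopulationProfile:
    T = M.MorphThresholds(area_low=200.0, area_high=400.0, cii_high=3.0)

    def test_pure_normal_population(self):
        cells = [make_cell(cell_id=i) for i in range(50)]
        p = M.population_profile(cells, self.T)
        assert p.percents[M.MorphClass.N] == 100.0
        assert sum(v for c, v in p.percents.items() if c is not M.MorphClass.N) == 0.0

    def test_percentages_close_to_100(self):
        rng = np.random.default_rng(3)
        cells = [make_cell(cell_id=i, area=a, roundness=r)
                 for i, (a, r) in enumerate(zip(rng.uniform(50, 600, 70), rng.uniform(1, 3, 70)))]
        p = M.population_profile(cells, self.T)
        assert abs(sum(p.percents.values()) - 100.0) < 1e-9

    def test_equal_areas_give_zero_variability(self):
        cells = [make_cell(cell_id=i) for i in range(60)]
        p = M.population_profile(cells, self.T)
        assert p.area_variability == 0.0

    def test_few_cells_warns_but_profiles(self):
        cells = [make_cell(cell_id=i) for i in range(10)]
        with pytest.warns(UserWarning, match="10 cells"):
            p = M.population_profile(cells, self.T)
        assert p.n_cells == 10

    def test_empty_population_rejected(self):
        with pytest.raises(ProfileError):
            M.population_profile([], self.T)
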