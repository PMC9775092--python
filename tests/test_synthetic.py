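"""Generator contracts: mixtures, geometry fidelity, seeding, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cardiomorph import synthetic as syn
from cardiomorph.exceptions import PlacementError, ValidationError


class TestSampleCellTruth:
    def test_degenerate_mixture_all_one_class(self):
        spec = syn.PopulationSpec(class_mixture={"N": 1.0}, n_cells=50, seed=1)
        truths = syn.sample_cell_truth(spec)
        assert len(truths) == 50
        assert all(t.class_label == "N" for t in truths)
        assert len({t.cell_id for t in truths}) == 50

    def test_mixture_frequencies_converge(self):
        # binomial 99% interval at n=10^4 is well inside ±1.5 points
        spec = syn.PopulationSpec(
            class_mixture={"N": 0.7, "HR": 0.2, "AR": 0.1}, n_cells=10_000, seed=7
        )
        truths = syn.sample_cell_truth(spec)
        freqs = pd.Series([t.class_label for t in truths]).value_counts(normalize=True)
        for label, p in [("N", 0.7), ("HR", 0.2), ("AR", 0.1)]:
            assert abs(freqs[label] - p) < 0.015

    def test_seed_contract(self):
        kw = dict(class_mixture={"N": 0.7, "HR": 0.3}, n_cells=40)
        t7a = syn.sample_cell_truth(syn.PopulationSpec(seed=7, **kw))
        t7b = syn.sample_cell_truth(syn.PopulationSpec(seed=7, **kw))
        t8 = syn.sample_cell_truth(syn.PopulationSpec(seed=8, **kw))
        assert t7a == t7b
        assert [t.center for t in t7a] != [t.center for t in t8]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(class_mixture={"N": 0.6, "HR": 0.3}, n_cells=10, seed=1),  # sums to 0.9
            dict(class_mixture={"N": 1.0}, n_cells=0, seed=1),
            dict(class_mixture={"N": 1.0}, n_cells=10, seed=1, pixel_size=-1.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            syn.PopulationSpec(**kwargs)

    def test_negative_area_rejected(self):
        with pytest.raises(ValidationError):
            syn.AreaParams(-5.0, 1.0)

    def test_overfull_field_raises_placement_error(self):
        spec = syn.PopulationSpec(
            class_mixture={"N": 1.0}, n_cells=40, seed=3, field_shape=(120, 120)
        )
        with pytest.raises(PlacementError, match="of 40 cells"):
            syn.sample_cell_truth(spec)


class TestRenderField:
    def test_empty_truths_blank_output(self):
        rgb, labels = syn.render_field([])
        assert labels.max() == 0
        assert rgb.shape[:2] == labels.shape

    def test_circle_mask_area_matches_rasterised_circle(self):
        # elongation 1, no boundary noise, radius 30 px at pixel_size 1
        radius = 30.0
        truth = syn.CellTruth(1, "N", (60.0, 60.0), np.pi * radius**2, 1.0, 0.0)
        _, labels = syn.render_field([truth], syn.RenderConfig(pixel_size=1.0, seed=0, shape=(120, 120)))
        area = (labels == 1).sum()
        assert abs(area / (np.pi * radius**2) - 1) < 0.03

    def test_mask_covers_each_cell_within_tolerance(self):
        spec = syn.PopulationSpec(class_mixture={"N": 0.8, "HI": 0.2}, n_cells=30, seed=5)
        truths = syn.sample_cell_truth(spec)
        _, labels = syn.render_field(truths, syn.RenderConfig(pixel_size=spec.pixel_size, seed=5))
        for t in truths:
            px_area = (labels == t.cell_id).sum() * spec.pixel_size**2
            assert abs(px_area / t.nominal_area - 1) < 0.05

    def test_elongation_matches_mask_moments(self):
        from skimage.measure import regionprops

        truths = [syn.CellTruth(1, "I", (80.0, 80.0), 2500.0, 2.0, 0.0)]
        _, labels = syn.render_field(truths, syn.RenderConfig(pixel_size=1.0, seed=2, shape=(160, 160)))
        p = regionprops(labels.astype(int))[0]
        ratio = p.axis_major_length / p.axis_minor_length
        assert abs(ratio / 2.0 - 1) < 0.10

    def test_determinism(self):
        spec = syn.PopulationSpec(class_mixture={"N": 1.0}, n_cells=20, seed=9)
        truths = syn.sample_cell_truth(spec)
        out1 = syn.render_field(truths, syn.RenderConfig(seed=9))
        out2 = syn.render_field(truths, syn.RenderConfig(seed=9))
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])


class TestCollagenField:
    def test_zero_fraction_has_no_stain(self):
        _, truth = syn.simulate_collagen_field(0.0, seed=1)
        assert truth.stain_mask.sum() == 0

    def test_fraction_rendered_exactly(self):
        _, truth = syn.simulate_collagen_field(0.25, seed=3)
        share = truth.stain_mask.mean()
        assert 0.245 <= share <= 0.255

    def test_seed_changes_pattern_not_share(self):
        _, t3 = syn.simulate_collagen_field(0.25, seed=3)
        _, t4 = syn.simulate_collagen_field(0.25, seed=4)
        assert not np.array_equal(t3.stain_mask, t4.stain_mask)
        assert abs(t3.stain_mask.mean() - t4.stain_mask.mean()) < 0.005

    @pytest.mark.parametrize("fraction", [-0.1, 1.2])
    def test_fraction_bounds(self, fraction):
        with pytest.raises(ValidationError):
            syn.simulate_collagen_field(fraction, seed=1)


class TestSerumPanel:
    def test_scale_zero_is_constant(self):
        spec = syn.SerumGroupSpec(
            "g", {"x": syn.AnalyteSpec(5.0, 0.0)}, n_animals=4, seed=1
        )
        df = syn.simulate_serum_panel([spec])
        assert (df["value"] == 5.0).all()

    def test_symmetric_mean_recovers_location(self):
        # anchored at an ICAM-1-like control level of 0.14 ± 0.03
        spec = syn.SerumGroupSpec(
            "g", {"icam1": syn.AnalyteSpec(0.14, 0.03)}, n_animals=100_000, seed=2
        )
        df = syn.simulate_serum_panel([spec])
        assert abs(df["value"].mean() - 0.14) < 0.001

    def test_skewed_family_right_skewed(self):
        spec = syn.SerumGroupSpec(
            "g", {"tg": syn.AnalyteSpec(60.0, 30.0, family="skewed")}, n_animals=10_000, seed=3
        )
        df = syn.simulate_serum_panel([spec])
        assert sps.skew(df["value"]) > 0

    def test_duplicate_groups_rejected(self):
        spec = syn.SerumGroupSpec("g", {"x": syn.AnalyteSpec(1.0, 0.1)}, n_animals=3, seed=1)
        with pytest.raises(ValidationError, match="duplicate"):
            syn.simulate_serum_panel([spec, spec])


class TestCtTable:
    def test_noise_free_folds_are_exact_ct_shifts(self):
        df = syn.simulate_ct_table(
            {"control": 1.0, "half": 0.5}, seed=1, noise_sd=0.0, n_per_group=5
        )
        dct = df.assign(dct=df.ct_target - df.ct_normalizer)
        ref = dct.loc[dct.group == "control", "dct"].mean()
        # fold 0.5 means the target amplifies exactly one cycle later
        assert np.allclose(dct.loc[dct.group == "half", "dct"] - ref, 1.0)
        assert np.allclose(dct.loc[dct.group == "control", "dct"] - ref, 0.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            syn.simulate_ct_table({"a": 2.0}, seed=1, reference_group="control")

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValidationError):
            syn.simulate_ct_table({"control": 1.0, "bad": 0.0}, seed=1)

    def test_monte_carlo_fold_recovery(self):
        from cardiomorph.serum import fold_change_ddct, fold_changes_to_frame

        df = syn.simulate_ct_table(
            {"control": 1.0, "up": 4.0}, seed=11, n_per_group=30, noise_sd=0.2
        )
        folds = fold_changes_to_frame(fold_change_ddct(df, "control"))
        est = folds.loc[folds.group == "up", "fold"].mean()
        assert 3.5 <= est <= 4.5

    def test_seed_required(self):
        with pytest.raises(ValidationError, match="seed"):
            syn.simulate_ct_table({"control": 1.0})
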