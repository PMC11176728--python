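"""Generator ground truth, determinism and end-to-end recovery."""

from __future__ import annotations

import numpy as np
import pytest

from pollensize.errors import InvalidInputError, SceneSizeError
from pollensize.imaging import SegmentConfig, segment_grains
from pollensize.morphometry import mean_width, measure_grain
from pollensize.screening import ScreenConfig, screen
from pollensize.synthetic import (
    GrainShapeSpec,
    MixtureSampleSpec,
    SceneSample,
    make_grain,
    make_scene,
    make_stratigraphic_record,
    make_stratigraphic_scenes,
    radius_for_mean_width,
    sample_sizes,
    silhouette_area_closed_form,
    silhouette_area_supersampled,
    silhouette_mean_width,
)
from pollensize.types import Calibration
from pollensize.unmix import SpeciesComponent

CAL = Calibration(0.25)
NANA = SpeciesComponent("B. nana", 20.54, 0.92)
PUBESCENS = SpeciesComponent("B. pubescens", 25.46, 1.11)


class TestMakeGrain:
    def test_disk_ground_truth_width(self):
        g = make_grain(GrainShapeSpec(base_radius=40.0), CAL)
        assert g.mean_width_um == pytest.approx(2 * 40.0 * 0.25, rel=1e-6)
        assert g.area_um2 == pytest.approx(np.pi * 10.0**2, rel=0.005)

    @pytest.mark.parametrize("amp,rot", [(0.0, 0.0), (3.0, 0.0), (6.0, 40.0), (4.5, 111.0)])
    def test_supersampled_area_matches_closed_form(self, amp, rot):
        spec = GrainShapeSpec(base_radius=35.0, pore_amplitude=amp, rotation=rot)
        assert silhouette_area_supersampled(spec, CAL) == pytest.approx(
            silhouette_area_closed_form(spec, CAL), rel=0.005
        )

    def test_bit_identical_per_seed(self):
        spec = GrainShapeSpec(base_radius=30.0, pore_amplitude=4.0, noise_sd=8.0, seed=77)
        a, b = make_grain(spec, CAL), make_grain(spec, CAL)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask.pixels, b.mask.pixels)

    def test_measured_geometry_matches_ground_truth(self):
        spec = GrainShapeSpec(base_radius=42.0, pore_amplitude=4.0, rotation=25.0)
        g = make_grain(spec, CAL)
        m = measure_grain(g.mask, CAL)
        assert m.mean_width_um == pytest.approx(g.mean_width_um, rel=0.02)
        assert m.area_um2 == pytest.approx(g.area_um2, rel=0.03)

    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidInputError):
            GrainShapeSpec(base_radius=-5.0)


class TestMakeScene:
    def test_empty_scene(self):
        scene = make_scene([], CAL, seed=0, canvas_shape=(200, 200), noise_sd=0.0)
        assert scene.masks == [] and scene.labels == []
        assert scene.image.shape == (200, 200)

    def test_full_overlap_fuses_two_grains(self):
        specs = [GrainShapeSpec(base_radius=30, seed=i) for i in range(2)]
        scene = make_scene(specs, CAL, overlap_fraction=1.0, seed=1,
                           canvas_shape=(400, 400), noise_sd=0.0)
        assert scene.labels == ["fused"]
        assert len(scene.masks) == 1
        assert scene.masks[0].n_components == 1

    def test_canvas_too_small(self):
        specs = [GrainShapeSpec(base_radius=40, seed=i) for i in range(30)]
        with pytest.raises(SceneSizeError):
            make_scene(specs, CAL, seed=0, canvas_shape=(150, 150))

    def test_determinism(self):
        specs = [GrainShapeSpec(base_radius=35, seed=i) for i in range(5)]
        a = make_scene(specs, CAL, detritus_density=5.0, seed=9, canvas_shape=(500, 700))
        b = make_scene(specs, CAL, detritus_density=5.0, seed=9, canvas_shape=(500, 700))
        np.testing.assert_array_equal(a.image, b.image)

    def test_segmenter_recovers_clean_grains_with_high_iou(self):
        specs = [GrainShapeSpec(base_radius=36 + i, pore_amplitude=3.0, seed=i) for i in range(5)]
        scene = make_scene(specs, CAL, seed=4, canvas_shape=(600, 900), noise_sd=4.0)
        found = segment_grains(scene.image, CAL, SegmentConfig(area_gate_um2=(100, 2000)))
        assert len(found) == 5

        def full(mask):
            out = np.zeros(mask.source_shape, bool)
            r0, c0 = mask.origin_offset
            h, w = mask.pixels.shape
            out[r0 : r0 + h, c0 : c0 + w] = mask.pixels
            return out

        truths = [full(m) for m in scene.masks]
        for fm in found:
            f = full(fm)
            iou = max((f & t).sum() / (f | t).sum() for t in truths)
            assert iou >= 0.95


class TestSampleSizes:
    def test_single_component_labels(self):
        v, labels = sample_sizes(MixtureSampleSpec([NANA], np.array([1.0]), 50, seed=0))
        assert set(labels) == {0} and v.shape == (50,)

    def test_zero_proportion_never_drawn(self):
        _, labels = sample_sizes(
            MixtureSampleSpec([NANA, PUBESCENS], np.array([1.0, 0.0]), 500, seed=1)
        )
        assert not np.any(labels == 1)

    def test_label_fractions_match_proportions(self):
        _, labels = sample_sizes(
            MixtureSampleSpec([NANA, PUBESCENS], np.array([0.3, 0.7]), 10_000, seed=2)
        )
        assert np.mean(labels == 0) == pytest.approx(0.3, abs=0.015)

    def test_reproducible(self):
        spec = MixtureSampleSpec([NANA, PUBESCENS], np.array([0.5, 0.5]), 100, seed=3)
        np.testing.assert_array_equal(sample_sizes(spec)[0], sample_sizes(spec)[0])


class TestStratigraphicRecord:
    def test_structure_and_truth_table(self):
        profile = [(float(d), np.array([0.2, 0.8])) for d in range(6)]
        series, truth = make_stratigraphic_record(profile, [NANA, PUBESCENS], 40, seed=5)
        assert len(series) == 6 and len(truth) == 6
        assert all(s.n == 40 for s in series)
        assert truth["p_B. nana"].tolist() == [0.2] * 6

    def test_zero_grains_rejected(self):
        with pytest.raises(InvalidInputError):
            make_stratigraphic_record([(1.0, np.array([1.0]))], [NANA], 0)

    def test_scene_record_widths_encode_mixture(self):
        profile = [(1.0, np.array([0.0, 1.0]))]
        (sample,) = make_stratigraphic_scenes(profile, [NANA, PUBESCENS], 30, CAL, seed=6)
        assert isinstance(sample, SceneSample)
        assert sample.true_widths_um.mean() == pytest.approx(25.46, abs=0.7)
        # scene is measurable: segmented mean widths track the drawn widths
        found = segment_grains(sample.image, CAL, SegmentConfig(area_gate_um2=(100, 2000)))
        assert len(found) == 30
        widths = sorted(mean_width(m, CAL)[0] for m in found)
        np.testing.assert_allclose(widths, sorted(sample.true_widths_um), atol=0.35)


def test_radius_inverts_width_convention():
    r = radius_for_mean_width(20.54, CAL)
    assert (2 * r + 1) * CAL.microns_per_pixel == pytest.approx(20.54)
    with pytest.raises(InvalidInputError):
        radius_for_mean_width(0.1, CAL)
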