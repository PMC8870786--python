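import warnings

import numpy as np
import pytest

from trabkit.core_io import GrayImage, Modality, ROI
from trabkit.phantom import PhantomSpec, generate_phantom
from trabkit.segmentation import (
    Phase,
    PhaseMask,
    binarize_local,
    bubble_report_from_volumes,
    quantify_bubbles,
    segment_three_phase,
)


def dice(a, b):
    return 2 * np.count_nonzero(a & b) / (a.sum() + b.sum())


def shaded_phantom(modality, seed=7):
    """Noisy strut phantom with a +/-30% linear shading gradient."""
    spec = PhantomSpec(width=160, height=160, spacing=0.051, theta_p=67.0,
                       sigma_p=10.0, strut_thickness=0.2, strut_spacing=0.6,
                       noise_sd=15.0, psf_sigma=0.03, modality=modality,
                       seed=seed)
    img, truth = generate_phantom(spec)
    shade = 1.0 + 0.3 * np.linspace(-1.0, 1.0, img.shape[1])[None, :]
    return GrayImage(img.pixels * shade, 0.051, 0.051,
                     modality=modality), truth


class TestBinarizeLocal:
    def test_two_level_image_exact(self, bar_phantom):
        img, truth = bar_phantom  # bone 200 / marrow 50, no noise
        mask = binarize_local(img, window=32, polarity="bone-bright")
        assert np.array_equal(mask.labels, truth.mask.labels)

    def test_shaded_noisy_dice(self):
        img, truth = shaded_phantom(Modality.CT_LIKE)
        mask = binarize_local(img, window=48)
        assert dice(mask.labels == int(Phase.BONE),
                    truth.mask.labels == int(Phase.BONE)) >= 0.95

    def test_polarity_symmetry_mr(self):
        ct_img, truth = shaded_phantom(Modality.CT_LIKE)
        mr_img = GrayImage(400.0 - ct_img.pixels, 0.051, 0.051,
                           modality=Modality.MR_LIKE)
        mask = binarize_local(mr_img, window=48)  # polarity inferred bone-dark
        assert dice(mask.labels == int(Phase.BONE),
                    truth.mask.labels == int(Phase.BONE)) >= 0.95

    def test_affine_intensity_invariance(self):
        img, _ = shaded_phantom(Modality.CT_LIKE)
        ref = binarize_local(img, window=48)
        scaled = GrayImage(3.7 * img.pixels - 250.0, 0.051, 0.051,
                           modality=Modality.CT_LIKE)
        assert np.array_equal(binarize_local(scaled, window=48).labels,
                              ref.labels)

    def test_constant_image_all_marrow_with_warning(self):
        img = GrayImage(np.full((32, 32), 7.0), 1.0, 1.0)
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize_local(img, polarity="bone-bright")
        assert np.all(mask.labels == int(Phase.MARROW))

    def test_invalid_window(self, bar_phantom):
        img, _ = bar_phantom
        with pytest.raises(ValueError, match="window"):
            binarize_local(img, window=4, polarity="bone-bright")

    def test_unknown_modality_needs_polarity(self, bar_phantom):
        img, _ = bar_phantom
        img = GrayImage(img.pixels, 1.0, 1.0, modality=Modality.UNKNOWN)
        with pytest.raises(ValueError, match="polarity"):
            binarize_local(img)

    def test_roi_marks_outside(self, bar_phantom):
        img, _ = bar_phantom
        roi = ROI(np.zeros(img.shape, dtype=bool))
        roi.mask[20:100, 20:100] = True
        mask = binarize_local(img, polarity="bone-bright", roi=roi)
        assert np.all(mask.labels[~roi.mask] == int(Phase.OUTSIDE))
        counts = mask.counts()
        in_roi = counts["BONE"] + counts["MARROW"] + counts["AIR"]
        assert in_roi == roi.mask.sum()  # phases partition the ROI exactly


def three_level_spec(**kw):
    base = dict(width=128, height=128, spacing=0.051, theta_p=0.0,
                strut_thickness=0.2, strut_spacing=0.8, bone_level=220.0,
                marrow_level=100.0, air_level=10.0, seed=3)
    base.update(kw)
    return PhantomSpec(**base)


class TestThreePhase:
    def test_noiseless_exact_recovery(self):
        img, truth = generate_phantom(
            three_level_spec(bubbles=(((72.0, 64.0), 0.25),))
        )
        mask = segment_three_phase(img)
        assert np.array_equal(mask.labels, truth.mask.labels)

    def test_single_bubble_one_air_component(self):
        from skimage.measure import label as cc_label

        img, _ = generate_phantom(
            three_level_spec(noise_sd=8.0, bubbles=(((72.0, 64.0), 0.25),))
        )
        mask = segment_three_phase(img)
        assert cc_label(mask.labels == int(Phase.AIR)).max() == 1

    def test_no_air_gives_empty_air_phase(self):
        img, _ = generate_phantom(three_level_spec())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = segment_three_phase(img)
        assert np.count_nonzero(mask.labels == int(Phase.AIR)) == 0

    def test_two_mode_image_falls_back_with_warning(self):
        pixels = np.where(np.arange(64)[:, None] % 8 < 2, 200.0, 50.0)
        img = GrayImage(np.broadcast_to(pixels, (64, 64)).copy(), 1.0, 1.0,
                        modality=Modality.CT_LIKE)
        with pytest.warns(UserWarning):
            mask = segment_three_phase(img)
        assert np.count_nonzero(mask.labels == int(Phase.AIR)) == 0
        assert np.count_nonzero(mask.labels == int(Phase.BONE)) > 0

    def test_requires_ct_modality(self, bar_phantom):
        img, _ = bar_phantom
        mr = GrayImage(img.pixels, 1.0, 1.0, modality=Modality.MR_LIKE)
        with pytest.raises(ValueError, match="CT_LIKE"):
            segment_three_phase(mr)

    def test_small_air_specks_merged_into_marrow(self):
        img, _ = generate_phantom(three_level_spec())
        pixels = img.pixels.copy()
        pixels[40, 40] = 10.0  # single dark pixel, below min_air_px
        noisy = GrayImage(pixels, 0.051, 0.051, modality=Modality.CT_LIKE)
        mask = segment_three_phase(noisy, min_air_px=4)
        assert mask.labels[40, 40] == int(Phase.MARROW)


class TestQuantifyBubbles:
    def test_table_arithmetic_cycle1(self):
        rep = bubble_report_from_volumes(1540.0, reference_initial=12427.0)
        assert rep.abv_rel_initial == pytest.approx(12.4, abs=0.05)

    def test_table_arithmetic_cycle3(self):
        rep = bubble_report_from_volumes(270.0, reference_initial=12427.0)
        assert rep.abv_rel_initial == pytest.approx(2.2, abs=0.05)

    def test_empty_air_phase_zeroes(self):
        labels = np.full((32, 32), int(Phase.MARROW), dtype=np.uint8)
        mask = PhaseMask(labels, 0.051, 0.051)
        rep = quantify_bubbles(mask, reference_initial=100.0)
        assert rep.abv_abs == 0.0
        assert rep.abv_rel_initial == 0.0
        assert rep.abv_rel_marrow == 0.0

    def test_volume_from_slice_thickness(self):
        labels = np.full((10, 10), int(Phase.MARROW), dtype=np.uint8)
        labels[:2, :5] = int(Phase.AIR)  # 10 air pixels
        mask = PhaseMask(labels, 0.1, 0.1)
        rep = quantify_bubbles(mask, slice_thickness=1.5)
        assert rep.abv_abs == pytest.approx(10 * 0.01 * 1.5)
        assert not rep.is_area
        assert rep.abv_rel_marrow == pytest.approx(10.0)  # 10 of 100 pixels

    def test_area_mode_flagged_without_thickness(self):
        labels = np.full((10, 10), int(Phase.MARROW), dtype=np.uint8)
        labels[0, 0] = int(Phase.AIR)
        rep = quantify_bubbles(PhaseMask(labels, 0.1, 0.1))
        assert rep.is_area
        assert rep.abv_abs == pytest.approx(0.01)

    def test_matches_phantom_truth_within_rasterization(self):
        spec = PhantomSpec(width=128, height=128, spacing=0.051, theta_p=0.0,
                           strut_thickness=0.15, strut_spacing=1.3,
                           bubbles=(((78.0, 64.0), 0.51),),
                           slice_thickness=1.0, seed=1)
        _, truth = generate_phantom(spec)
        rep = quantify_bubbles(truth.mask, slice_thickness=1.0)
        assert rep.abv_abs == pytest.approx(truth.bubble_volume_true, rel=1e-12)
        analytic = np.pi * 0.51**2 * 1.0
        assert rep.abv_abs == pytest.approx(analytic, rel=0.02)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="reference_initial"):
            bubble_report_from_volumes(5.0, reference_initial=0.0)
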