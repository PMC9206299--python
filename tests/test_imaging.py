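"""Background correction, nucleus segmentation, and focus detection."""

import numpy as np
import pandas as pd
import pytest

from synletscreen import simulate
from synletscreen.imaging import (
    FOCI_BOUNDS,
    NUCLEUS_BOUNDS,
    FociImage,
    correct_background,
    detect_foci,
    foci_statistics,
    quantify_field,
    segment_nuclei,
)


@pytest.fixture(scope="module")
def clean_field():
    image, truth = simulate.gen_foci_image(
        seed=8, n_nuclei=5, foci_per_nucleus=3, background_slope=200.0
    )
    return image, truth


def corrected(image):
    return FociImage(
        correct_background(image.nuclear_channel),
        correct_background(image.foci_channel),
        image.pixel_size,
        image.field_id,
        image.condition,
    )


class TestBackground:
    def test_constant_image_goes_to_zero(self):
        out = correct_background(np.full((64, 64), 100.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_planar_gradient_removed_under_discs(self, clean_field):
        image, truth = clean_field
        out = correct_background(image.nuclear_channel)
        # empty-region residual well below the 2000 a.u. disc amplitude
        yy, xx = np.mgrid[0 : out.shape[0], 0 : out.shape[1]]
        empty = np.ones(out.shape, dtype=bool)
        for _, nuc in truth["nuclei"].iterrows():
            empty &= (yy - nuc.cy) ** 2 + (xx - nuc.cx) ** 2 > (nuc.radius_px + 5) ** 2
        assert np.median(out[empty]) < 0.01 * 2000.0

    def test_idempotent_within_tolerance(self, clean_field):
        image, _ = clean_field
        once = correct_background(image.nuclear_channel)
        twice = correct_background(once)
        assert np.abs(twice - once).max() < 0.02 * image.nuclear_channel.max()

    def test_all_zero_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = correct_background(np.zeros((16, 16)))
        assert not out.any()


class TestSegmentation:
    def test_five_discs_all_retained(self, clean_field):
        image, _ = clean_field
        seg = segment_nuclei(corrected(image))
        assert len(seg.nuclei) == 5
        assert seg.qc["retained"] == 5
        for nuc in seg.nuclei:
            assert nuc.area == pytest.approx(400.0, rel=0.05)

    def test_undersized_nucleus_excluded_by_area_filter(self):
        image, truth = simulate.gen_foci_image(seed=9, n_nuclei=3, n_undersized=1)
        seg = segment_nuclei(corrected(image))
        assert len(seg.nuclei) == 3
        assert seg.qc.get("area_um2") == 1
        assert (~truth["nuclei"]["expected_retained"]).sum() == 1

    def test_perfect_disc_shape_ratio_near_one(self, clean_field):
        image, _ = clean_field
        seg = segment_nuclei(corrected(image))
        for nuc in seg.nuclei:
            assert 1.0 <= nuc.shape_ratio <= 1.1
            assert 1.0 <= nuc.lw_ratio <= 1.05

    def test_retained_objects_satisfy_all_windows(self):
        image, _ = simulate.gen_foci_image(seed=10, noise="poisson")
        seg = segment_nuclei(corrected(image))
        for nuc in seg.nuclei:
            assert NUCLEUS_BOUNDS.check(
                nuc.area, nuc.shape_ratio, nuc.lw_ratio, nuc.avg_intensity, nuc.total_intensity
            ) is None


class TestFociDetection:
    @pytest.mark.parametrize("k,area", [(0, 400.0), (1, 400.0), (3, 400.0), (10, 800.0)])
    def test_noiseless_counts_exact(self, k, area):
        image, _ = simulate.gen_foci_image(
            seed=12, n_nuclei=5, foci_per_nucleus=k, nucleus_area_um2=area
        )
        table = quantify_field(image)
        assert sorted(table["n_foci"]) == [k] * 5

    def test_focus_outside_any_nucleus_not_counted(self):
        image, _ = simulate.gen_foci_image(seed=13, n_nuclei=2, foci_per_nucleus=2)
        # plant a bright spot in an empty corner, far from both nuclei
        yy, xx = np.mgrid[0 : image.foci_channel.shape[0], 0 : image.foci_channel.shape[1]]
        stray = 3000.0 * np.exp(-((yy - 8.0) ** 2 + (xx - 8.0) ** 2) / (2 * 1.2**2))
        image.foci_channel = image.foci_channel + stray
        table = quantify_field(image)
        assert table["n_foci"].sum() == 4

    def test_oversized_focus_excluded(self):
        image, truth = simulate.gen_foci_image(seed=14, foci_per_nucleus=3, n_oversized_foci=1)
        table = quantify_field(image)
        assert sorted(table["n_foci"]) == [3] * 5
        assert (~truth["foci"]["expected_retained"]).sum() == 1

    def test_translation_and_rotation_invariance(self):
        image, _ = simulate.gen_foci_image(seed=15, n_nuclei=4, foci_per_nucleus=2)
        base = sorted(quantify_field(image)["n_foci"])
        rolled = FociImage(
            np.roll(image.nuclear_channel, (7, 13), (0, 1)),
            np.roll(image.foci_channel, (7, 13), (0, 1)),
            image.pixel_size,
        )
        rotated = FociImage(
            np.rot90(image.nuclear_channel).copy(),
            np.rot90(image.foci_channel).copy(),
            image.pixel_size,
        )
        assert sorted(quantify_field(rolled)["n_foci"]) == base
        assert sorted(quantify_field(rotated)["n_foci"]) == base

    def test_noisy_detection_f1(self):
        # Poisson counting noise at peak SNR 5
        amp = simulate.poisson_amplitude_for_snr(5.0, 650.0)
        f1s = []
        for seed in range(5):
            image, truth = simulate.gen_foci_image(
                seed=300 + seed, foci_per_nucleus=3, foci_amplitude=amp, noise="poisson"
            )
            ci = corrected(image)
            seg = segment_nuclei(ci)
            records = detect_foci(ci, seg)
            f1, *_ = simulate.detection_f1(records, truth["foci"])
            f1s.append(f1)
        assert np.mean(f1s) >= 0.95

    def test_retained_foci_satisfy_all_windows(self):
        image, _ = simulate.gen_foci_image(seed=16, foci_per_nucleus=5, noise="poisson")
        ci = corrected(image)
        seg = segment_nuclei(ci)
        for rec in detect_foci(ci, seg):
            for area, avg, tot in zip(rec.areas_um2, rec.avg_intensities, rec.total_intensities):
                assert FOCI_BOUNDS.area_um2[0] <= area <= FOCI_BOUNDS.area_um2[1]
                assert FOCI_BOUNDS.avg_intensity[0] <= avg <= FOCI_BOUNDS.avg_intensity[1]
                assert FOCI_BOUNDS.total_intensity[0] <= tot <= FOCI_BOUNDS.total_intensity[1]


class TestStatistics:
    def test_constant_counts(self):
        table = pd.DataFrame(
            {"condition": "c", "field_id": "f", "nucleus_label": [1, 2, 3], "n_foci": [3, 3, 3]}
        )
        stats = foci_statistics(table)
        assert stats["mean_foci_per_cell"].iloc[0] == pytest.approx(3.0)
        assert stats["sem_foci_per_cell"].iloc[0] == pytest.approx(0.0)
        assert stats["cells_per_field"].iloc[0] == pytest.approx(3.0)

    def test_single_nucleus_has_no_sem(self):
        table = pd.DataFrame(
            {"condition": "c", "field_id": "f", "nucleus_label": [1], "n_foci": [4]}
        )
        assert np.isnan(foci_statistics(table)["sem_foci_per_cell"].iloc[0])

    def test_treatment_fold_change_regime(self):
        # conditions with planted means 2 and 6 foci/cell: threefold increase
        tables = []
        for cond, k in (("vehicle", 2), ("combination", 6)):
            image, _ = simulate.gen_foci_image(
                seed=18, foci_per_nucleus=k, nucleus_area_um2=800.0, condition=cond
            )
            tables.append(quantify_field(image))
        stats = foci_statistics(pd.concat(tables)).set_index("condition")
        ratio = (
            stats.loc["combination", "mean_foci_per_cell"]
            / stats.loc["vehicle", "mean_foci_per_cell"]
        )
        assert ratio == pytest.approx(3.0, rel=0.05)
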