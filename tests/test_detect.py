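import numpy as np
import pytest
from skimage import draw as skdraw

from rafh.detect import (
    apply_manual_edits,
    compute_rafh,
    detect_hyperaf,
    local_background,
)
from rafh.geometry import make_rim_band
from rafh.io import BinaryMask, FafImage


@pytest.fixture
def disk_scene():
    """128x128 frame at 10 um/px: dark disk lesion on a flat background of 100."""
    shape = (128, 128)
    ga = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.disk((64, 64), 20)
    ga[rr, cc] = True
    img = np.full(shape, 100, dtype=np.uint8)
    img[ga] = 20
    rim = make_rim_band(ga, 10, 450)
    return FafImage(img, 10), ga, rim


class TestLocalBackground:
    def test_uniform_image_gives_constant_field(self, disk_scene):
        image, ga, rim = disk_scene
        field = local_background(image, ga, rim, window_um=500)
        assert np.all(field[rim.pixels] == 100)
        assert np.all(np.isnan(field[~rim.pixels]))

    def test_median_robust_to_single_outlier(self, disk_scene):
        image, ga, rim = disk_scene
        px = image.pixels.copy()
        px[64, 90] = 255
        field = local_background(FafImage(px, 10), ga, rim, window_um=500)
        assert np.all(field[rim.pixels] == 100)

    def test_global_mode_is_rim_median(self, disk_scene):
        image, ga, rim = disk_scene
        field = local_background(image, ga, rim, mode="global")
        assert np.all(field[rim.pixels] == np.median(image.pixels[rim.pixels]))

    def test_matches_brute_force_windowed_median(self, rng):
        """Exhaustive oracle: per-pixel median over the clipped window, GA excluded."""
        img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        ga = np.zeros((64, 64), dtype=bool)
        rr, cc = skdraw.disk((32, 32), 8)
        ga[rr, cc] = True
        rim = make_rim_band(ga, 10, 200)
        window_um, scale = 150, 10  # 15 px -> half-window 7
        field = local_background(FafImage(img, scale), ga, rim, window_um=window_um)
        half = round(window_um / scale) // 2
        rows, cols = np.nonzero(rim.pixels)
        idx = rng.choice(len(rows), size=20, replace=False)
        for r, c in zip(rows[idx], cols[idx]):
            vals = []
            for i in range(max(r - half, 0), min(r + half + 1, 64)):
                for j in range(max(c - half, 0), min(c + half + 1, 64)):
                    if not ga[i, j]:
                        vals.append(img[i, j])
            assert field[r, c] == np.median(vals)

    def test_window_below_3px_rejected(self, disk_scene):
        image, ga, rim = disk_scene
        with pytest.raises(ValueError, match="window"):
            local_background(image, ga, rim, window_um=20)  # 2 px at 10 um/px

    def test_empty_rim_rejected(self, disk_scene):
        image, ga, _ = disk_scene
        with pytest.raises(ValueError, match="rim"):
            local_background(image, ga, np.zeros(image.shape, dtype=bool))


class TestDetectHyperAF:
    def test_nothing_above_threshold_gives_zero(self, disk_scene):
        image, ga, rim = disk_scene
        result = detect_hyperaf(image, ga, rim)
        assert result.rafh == 0.0
        assert not result.hyper_mask.pixels.any()

    def test_blob_below_offset_not_detected(self, disk_scene):
        image, ga, rim = disk_scene
        px = image.pixels.copy()
        rows, cols = np.nonzero(rim.pixels)
        px[rows[:50], cols[:50]] = 130  # +30 over background, offset is 40
        assert detect_hyperaf(FafImage(px, 10), ga, rim).rafh == 0.0

    def test_compact_blob_fraction_recovered(self, disk_scene):
        image, ga, rim = disk_scene
        px = image.pixels.copy()
        n_rim = rim.count()
        rows, cols = np.nonzero(rim.pixels)
        n_blob = int(round(0.10 * n_rim))
        px[rows[:n_blob], cols[:n_blob]] = 160
        result = detect_hyperaf(FafImage(px, 10), ga, rim)
        assert result.rafh == pytest.approx(0.10, abs=0.02)

    def test_threshold_is_inclusive(self, disk_scene):
        image, ga, rim = disk_scene
        px = image.pixels.copy()
        rows, cols = np.nonzero(rim.pixels)
        px[rows[0], cols[0]] = 140  # exactly background + offset
        result = detect_hyperaf(FafImage(px, 10), ga, rim, background_mode="global")
        assert result.hyper_mask.pixels[rows[0], cols[0]]

    def test_lower_offset_never_decreases_rafh(self, rng, disk_scene):
        image, ga, rim = disk_scene
        px = np.clip(image.pixels.astype(int) + rng.integers(0, 90, size=image.shape), 0, 255)
        img = FafImage(px.astype(np.uint8), 10)
        rafhs = [detect_hyperaf(img, ga, rim, offset=o).rafh for o in (80, 60, 40, 20)]
        assert np.all(np.diff(rafhs) >= 0)

    @pytest.mark.parametrize("offset", [0, 255, -3])
    def test_offset_bounds(self, disk_scene, offset):
        image, ga, rim = disk_scene
        with pytest.raises(ValueError, match="offset"):
            detect_hyperaf(image, ga, rim, offset=offset)


class TestManualEditsAndRafh:
    def test_empty_edits_identity(self, disk_scene):
        image, ga, rim = disk_scene
        auto = detect_hyperaf(image, ga, rim)
        edited = apply_manual_edits(auto, None, None, rim)
        assert np.array_equal(edited.hyper_mask.pixels, auto.hyper_mask.pixels)
        assert edited.rafh == auto.rafh

    def test_remove_everything_gives_zero(self, disk_scene, rng):
        image, ga, rim = disk_scene
        px = image.pixels.copy()
        rows, cols = np.nonzero(rim.pixels)
        pick = rng.choice(len(rows), size=len(rows) // 4, replace=False)
        px[rows[pick], cols[pick]] = 200  # scattered bright speckle, ~25% of rim
        auto = detect_hyperaf(FafImage(px, 10), ga, rim)
        assert auto.rafh > 0.2
        edited = apply_manual_edits(auto, None, BinaryMask(auto.hyper_mask.pixels.copy(), role="edit"), rim)
        assert edited.rafh == 0.0

    def test_add_clipped_to_rim(self, disk_scene):
        image, ga, rim = disk_scene
        auto = detect_hyperaf(image, ga, rim)
        add = np.ones(image.shape, dtype=bool)  # mostly outside the rim
        edited = apply_manual_edits(auto, BinaryMask(add, role="edit"), None, rim)
        assert edited.rafh == 1.0
        assert not (edited.hyper_mask.pixels & ~rim.pixels).any()

    def test_overlapping_edits_rejected(self, disk_scene):
        image, ga, rim = disk_scene
        auto = detect_hyperaf(image, ga, rim)
        overlap = BinaryMask(rim.pixels.copy(), role="edit")
        with pytest.raises(ValueError, match="overlap"):
            apply_manual_edits(auto, overlap, overlap, rim)

    def test_compute_rafh_arithmetic(self):
        rim = np.zeros((40, 40), dtype=bool)
        rim[:25, :40] = True  # 1000 px
        hyper = np.zeros_like(rim)
        hyper[:25, :10] = True  # 250 px
        assert compute_rafh(hyper, rim) == 0.25
        assert compute_rafh(np.zeros_like(rim), rim) == 0.0
        assert compute_rafh(rim, rim) == 1.0

    def test_compute_rafh_contract_violations(self):
        rim = np.zeros((10, 10), dtype=bool)
        rim[:5] = True
        outside = np.zeros_like(rim)
        outside[7, 7] = True
        with pytest.raises(ValueError, match="outside"):
            compute_rafh(outside, rim)
        with pytest.raises(ValueError, match="empty"):
            compute_rafh(outside, np.zeros_like(rim))
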