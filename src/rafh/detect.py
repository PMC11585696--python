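"""Hyperautofluorescence detection within the rim band.

A rim pixel is hyperautofluorescent when its intensity exceeds a local
background reference by at least a fixed offset (+40 on the raw 8-bit scale
by default).  The background reference is the median intensity of non-lesion
pixels inside a square window (500 um side by default) centered on the rim
pixel; the median is robust to the bright speckle being detected.  A global
mode (single median over all rim pixels) is provided for sensitivity
analysis.

RAFH — rim-area focal hyperautofluorescence — is the fraction of rim pixels
flagged hyperautofluorescent; it is a unitless ratio in [0, 1] and is
independent of the pixel scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RimBand
from .io import BinaryMask, FafImage

DEFAULT_OFFSET = 40
DEFAULT_WINDOW_UM = 500.0


@dataclass(frozen=True)
class HyperAFResult:
    """Detected hyperautofluorescence and the resulting RAFH ratio."""

    hyper_mask: BinaryMask
    rafh: float
    threshold_offset: int
    background_mode: str
    window_um: float


def _image_pixels(image: FafImage | np.ndarray) -> np.ndarray:
    return image.pixels if isinstance(image, FafImage) else np.asarray(image)


def _mask_pixels(mask: BinaryMask | np.ndarray) -> np.ndarray:
    return mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)


def _rim_pixels(rim: RimBand | BinaryMask | np.ndarray) -> np.ndarray:
    if isinstance(rim, RimBand):
        return rim.pixels
    return _mask_pixels(rim)


def local_background(
    image: FafImage | np.ndarray,
    ga_mask: BinaryMask | np.ndarray,
    rim: RimBand | BinaryMask | np.ndarray,
    window_um: float = DEFAULT_WINDOW_UM,
    scale_um_per_px: float | None = None,
    mode: str = "local",
) -> np.ndarray:
    """Background reference intensity at each rim pixel.

    Returns a float field shaped like the image, NaN off the rim.  In
    ``local`` mode each rim pixel gets the median of non-GA pixels in the
    square window of side ``window_um`` centered on it (clipped at the image
    edge); in ``global`` mode every rim pixel gets the single median
    intensity of all rim pixels.
    """
    img = _image_pixels(image)
    ga = _mask_pixels(ga_mask)
    rim_px = _rim_pixels(rim)
    if not rim_px.any():
        raise ValueError("rim is empty")
    field = np.full(img.shape, np.nan, dtype=float)
    if mode == "global":
        field[rim_px] = float(np.median(img[rim_px]))
        return field
    if mode != "local":
        raise ValueError(f"unknown background mode {mode!r}")
    if scale_um_per_px is None:
        if not isinstance(image, FafImage):
            raise ValueError("scale_um_per_px required when image is a bare array")
        scale_um_per_px = image.scale_um_per_px
    side_px = round(float(window_um) / float(scale_um_per_px))
    if side_px < 3:
        raise ValueError(f"window of {window_um} um spans {side_px} px (<3) at this scale")
    half = side_px // 2
    non_ga = ~ga
    h, w = img.shape
    rows, cols = np.nonzero(rim_px)
    for r, c in zip(rows.tolist(), cols.tolist()):
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        window = img[r0:r1, c0:c1]
        vals = window[non_ga[r0:r1, c0:c1]]
        # the center rim pixel is itself non-GA, so vals is never empty
        field[r, c] = float(np.median(vals))
    return field


def compute_rafh(
    hyper_mask: BinaryMask | np.ndarray, rim: RimBand | BinaryMask | np.ndarray
) -> float:
    """RAFH = hyperautofluorescent pixel count / rim pixel count (scale-free)."""
    hyper = _mask_pixels(hyper_mask)
    rim_px = _rim_pixels(rim)
    n_rim = int(rim_px.sum())
    if n_rim == 0:
        raise ValueError("rim is empty; RAFH undefined")
    if (hyper & ~rim_px).any():
        raise ValueError("hyperautofluorescence mask extends outside the rim")
    return float(hyper.sum()) / n_rim


def detect_hyperaf(
    image: FafImage | np.ndarray,
    ga_mask: BinaryMask | np.ndarray,
    rim: RimBand | BinaryMask | np.ndarray,
    offset: int = DEFAULT_OFFSET,
    background_mode: str = "local",
    window_um: float = DEFAULT_WINDOW_UM,
    scale_um_per_px: float | None = None,
) -> HyperAFResult:
    """Flag rim pixels with intensity >= background + offset (inclusive).

    The offset operates on raw 8-bit values, no normalization, and must lie
    in [1, 254].
    """
    offset = int(offset)
    if not 1 <= offset <= 254:
        raise ValueError(f"offset must be in [1, 254], got {offset}")
    img = _image_pixels(image).astype(float)
    rim_px = _rim_pixels(rim)
    bg = local_background(
        image, ga_mask, rim, window_um=window_um, scale_um_per_px=scale_um_per_px, mode=background_mode
    )
    hyper = np.zeros(img.shape, dtype=bool)
    hyper[rim_px] = img[rim_px] >= bg[rim_px] + offset
    return HyperAFResult(
        hyper_mask=BinaryMask(hyper, role="hyperaf"),
        rafh=compute_rafh(hyper, rim_px),
        threshold_offset=offset,
        background_mode=background_mode,
        window_um=float(window_um),
    )


def apply_manual_edits(
    auto: HyperAFResult,
    add: BinaryMask | np.ndarray | None,
    remove: BinaryMask | np.ndarray | None,
    rim: RimBand | BinaryMask | np.ndarray,
) -> HyperAFResult:
    """Grader corrections: mask' = ((auto | add) & ~remove) & rim.

    Add and remove masks must be disjoint.  Edits are kept separate from the
    automatic output so the reproducible machine result is never overwritten.
    """
    rim_px = _rim_pixels(rim)
    add_px = _mask_pixels(add) if add is not None else np.zeros(rim_px.shape, dtype=bool)
    rem_px = _mask_pixels(remove) if remove is not None else np.zeros(rim_px.shape, dtype=bool)
    if (add_px & rem_px).any():
        raise ValueError("add and remove edit masks overlap")
    edited = ((auto.hyper_mask.pixels | add_px) & ~rem_px) & rim_px
    return HyperAFResult(
        hyper_mask=BinaryMask(edited, role="hyperaf"),
        rafh=compute_rafh(edited, rim_px),
        threshold_offset=auto.threshold_offset,
        background_mode=auto.background_mode,
        window_um=auto.window_um,
    )
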