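"""Rim-band construction and lesion morphometry.

The junctional zone around a geographic-atrophy (GA) lesion is modelled as
the set of non-lesion pixels whose Euclidean center-to-center distance to the
nearest lesion pixel is at most a fixed width (450 um by default).  Distances
come from the exact Euclidean distance transform, so a multifocal lesion
automatically yields the union of the per-focus bands with overlap counted
once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .io import BinaryMask

#: Rim width used throughout the analysis, in micrometers.
DEFAULT_RIM_WIDTH_UM = 450.0

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class RimBand:
    """The perilesional band within ``width_um`` of the GA border.

    ``touches_border`` flags rims clipped by the image edge; this is a
    warning condition, not an error, because whole-macula frames routinely
    place lesions near the frame boundary.
    """

    mask: BinaryMask
    width_um: float
    touches_border: bool

    @property
    def pixels(self) -> np.ndarray:
        return self.mask.pixels

    def count(self) -> int:
        return self.mask.count()


@dataclass
class LesionMetrics:
    """Per-visit scalar lesion summary."""

    ga_area_mm2: float
    ga_perimeter_mm: float
    focus_count: int
    rim_area_mm2: float
    rafh: float | None = None


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.pixels
    return np.asarray(mask, dtype=bool)


def distance_to_lesion(ga_mask: BinaryMask | np.ndarray, scale_um_per_px: float) -> np.ndarray:
    """Per-pixel Euclidean distance (um) to the nearest GA pixel; 0 on GA.

    Distances are measured between pixel centers via the exact Euclidean
    distance transform of the lesion complement.
    """
    ga = _as_bool(ga_mask)
    if not ga.any():
        raise ValueError("GA mask is empty; distance field undefined")
    d_px = ndimage.distance_transform_edt(~ga)
    return d_px * float(scale_um_per_px)


def make_rim_band(
    ga_mask: BinaryMask | np.ndarray,
    scale_um_per_px: float,
    width_um: float = DEFAULT_RIM_WIDTH_UM,
) -> RimBand:
    """Construct the rim band: pixels with distance in the half-open (0, width].

    Ties at exactly ``width_um`` are included.  Multifocal lesions produce the
    union of the per-focus bands.  Enclosed holes inside the lesion that lie
    within range are rim: they are non-GA pixels within the band by the same
    geometric rule.
    """
    ga = _as_bool(ga_mask)
    if not ga.any():
        raise ValueError("GA mask is empty")
    if ga.all():
        raise ValueError("GA mask fills the grid; no rim exists")
    dist = distance_to_lesion(ga, scale_um_per_px)
    rim = (dist > 0) & (dist <= float(width_um))
    edge = np.zeros_like(rim)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    touches = bool((rim & edge).any())
    return RimBand(BinaryMask(rim, role="rim"), float(width_um), touches)


def mask_area_mm2(mask: BinaryMask | np.ndarray, scale_um_per_px: float) -> float:
    """Pixel-counting area: (true pixels) x (scale/1000)^2 mm^2."""
    px = _as_bool(mask)
    return float(px.sum()) * (float(scale_um_per_px) / 1000.0) ** 2


def mask_perimeter_mm(
    mask: BinaryMask | np.ndarray, scale_um_per_px: float, smooth_sigma_px: float = 1.0
) -> float:
    """Total boundary length in mm via sub-pixel marching-squares contours.

    All foci contribute, and inner (hole) boundaries are included.  The mask
    is padded so contours close around foci touching the frame.  A light
    Gaussian pre-smoothing (sigma 1 px by default) removes the staircase
    bias of contouring raw binary data (~5% overestimation on discs);
    structures too thin to survive the smoothing fall back to unsmoothed
    contours.
    """
    px = _as_bool(mask)
    if not px.any():
        return 0.0

    def contour_length(field: np.ndarray) -> float:
        return sum(
            float(np.sum(np.hypot(*np.diff(c, axis=0).T)))
            for c in measure.find_contours(field, 0.5)
        )

    padded = np.pad(px.astype(float), 4)
    total_px = contour_length(ndimage.gaussian_filter(padded, smooth_sigma_px)) if smooth_sigma_px else 0.0
    if total_px == 0.0:
        total_px = contour_length(padded)
    return total_px * float(scale_um_per_px) / 1000.0


def count_foci(mask: BinaryMask | np.ndarray) -> int:
    """Number of 8-connected components (diagonal contact joins foci)."""
    px = _as_bool(mask)
    _, n = ndimage.label(px, structure=_EIGHT_CONNECTED)
    return int(n)


def lesion_metrics(
    ga_mask: BinaryMask | np.ndarray,
    scale_um_per_px: float,
    width_um: float = DEFAULT_RIM_WIDTH_UM,
) -> tuple[LesionMetrics, RimBand]:
    """Convenience bundle: area, perimeter, focality, and the rim band."""
    rim = make_rim_band(ga_mask, scale_um_per_px, width_um)
    metrics = LesionMetrics(
        ga_area_mm2=mask_area_mm2(ga_mask, scale_um_per_px),
        ga_perimeter_mm=mask_perimeter_mm(ga_mask, scale_um_per_px),
        focus_count=count_foci(ga_mask),
        rim_area_mm2=mask_area_mm2(rim.pixels, scale_um_per_px),
    )
    return metrics, rim
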