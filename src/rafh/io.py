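"""Reading and writing FAF images, binary masks, and longitudinal cohort tables.

All images are 8-bit single-channel grids with an explicit physical scale in
micrometers per pixel; masks are boolean grids co-registered to an image.
Cohort tables are plain CSV with one row per (participant, eye, visit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Exact cohort CSV column order.
COHORT_COLUMNS = [
    "participant_id",
    "eye",
    "arm",
    "time_years",
    "rafh_g1",
    "rafh_g2",
    "ga_area_mm2",
    "ga_perimeter_mm",
    "focus_count",
    "age",
    "sex",
    "bmi",
    "smoking",
    "cvd",
    "faf_pattern_group",
    "foveal_involvement",
    "adherence_pct",
]

MASK_ROLES = ("ga", "rim", "hyperaf", "edit")


class CohortSchemaError(ValueError):
    """Raised when a cohort CSV violates the expected schema."""


@dataclass(frozen=True)
class FafImage:
    """An en-face fundus autofluorescence image.

    Parameters
    ----------
    pixels : ndarray of uint8
        2D intensity grid, values in [0, 255].
    scale_um_per_px : float
        Physical pixel pitch in micrometers per pixel; must be positive
        and finite.  The scale is always supplied by the user — it is never
        inferred from file headers.
    """

    pixels: np.ndarray
    scale_um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("image intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        s = float(self.scale_um_per_px)
        if not np.isfinite(s) or s <= 0:
            raise ValueError(f"scale must be finite and positive, got {s}")
        object.__setattr__(self, "scale_um_per_px", s)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid co-registered to a :class:`FafImage`.

    The ``role`` tag records what the mask delineates: the GA lesion, the
    perilesional rim band, detected hyperautofluorescence, or a manual edit.
    """

    pixels: np.ndarray
    role: str = "ga"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {px.shape}")
        if px.dtype != bool:
            px = px.astype(bool)
        object.__setattr__(self, "pixels", px)
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class EyeSeries:
    """Ordered per-eye visit series from a cohort table.

    ``visits`` is a DataFrame with the cohort schema, sorted by strictly
    increasing ``time_years``.  Eyes with a single visit are retained but
    are not eligible for growth-rate computation.
    """

    participant_id: str
    eye: str
    visits: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.visits["time_years"].to_numpy(dtype=float)
        if len(t) and t.min() < 0:
            raise ValueError("time_years must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"visit times for ({self.participant_id}, {self.eye}) must be strictly increasing"
            )

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def growth_eligible(self) -> bool:
        """At least a baseline and one follow-up visit."""
        return self.n_visits >= 2

    @property
    def times(self) -> np.ndarray:
        return self.visits["time_years"].to_numpy(dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return self.visits["ga_area_mm2"].to_numpy(dtype=float)

    @property
    def perimeters(self) -> np.ndarray:
        return self.visits["ga_perimeter_mm"].to_numpy(dtype=float)


def read_faf_image(
    path: str | Path,
    scale_um_per_px: float,
    *,
    allow_rescale: bool = False,
) -> FafImage:
    """Read a single-channel 8-bit PNG/TIFF as a :class:`FafImage`.

    Multi-channel images are converted to grayscale by the per-pixel channel
    mean (logged).  Images with >8-bit depth raise unless ``allow_rescale``
    is set, in which case the range is linearly mapped onto [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        logger.info("converting %d-channel image %s to grayscale by channel mean", arr.shape[2], path)
        arr = arr.astype(np.float64).mean(axis=2)
    if arr.dtype != np.uint8 and arr.max(initial=0) > 255:
        if not allow_rescale:
            raise ValueError(
                f"{path}: image depth exceeds 8 bits; pass allow_rescale=True to map onto [0, 255]"
            )
        arr = arr.astype(np.float64)
        arr = 255.0 * (arr - arr.min()) / (arr.max() - arr.min())
    return FafImage(np.round(arr).astype(np.uint8), scale_um_per_px)


def read_mask(
    path: str | Path,
    image: FafImage | None = None,
    *,
    role: str = "ga",
    binarize_at: int | None = None,
) -> BinaryMask:
    """Read a 0/255 PNG mask; True wherever the value is 255.

    Any intermediate value (anti-aliasing artifacts, lossy round-trips) is an
    error unless an explicit ``binarize_at`` threshold is supplied, in which
    case pixels strictly above the threshold become True.  When ``image`` is
    given the mask shape must match it exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if binarize_at is None:
        values = np.unique(arr)
        bad = values[(values != 0) & (values != 255)]
        if bad.size:
            raise ValueError(
                f"{path}: mask contains non-binary values {bad[:5].tolist()}; "
                "pass binarize_at to threshold explicitly"
            )
        px = arr == 255
    else:
        px = arr > int(binarize_at)
    if image is not None and px.shape != image.shape:
        raise ValueError(f"mask shape {px.shape} does not match image shape {image.shape}")
    return BinaryMask(px, role=role)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a boolean mask as a 0/255 8-bit PNG."""
    iio.imwrite(Path(path), np.where(mask.pixels, 255, 0).astype(np.uint8))


def _validate_cohort_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort table is missing columns: {missing}")
    for col in ("time_years", "rafh_g1", "rafh_g2", "ga_area_mm2", "ga_perimeter_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().sum() > df[col].isna().sum():
            raise CohortSchemaError(f"column {col!r} contains unparseable numerics")
        df[col] = vals
    dup = df.duplicated(subset=["participant_id", "eye", "time_years"])
    if dup.any():
        rows = df.loc[dup, ["participant_id", "eye", "time_years"]].head()
        raise CohortSchemaError(f"duplicate (participant, eye, time) rows:\n{rows}")
    for col in ("rafh_g1", "rafh_g2"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise CohortSchemaError(f"{col} values must lie in [0, 1]")
    return df


def read_cohort_table(path: str | Path) -> list[EyeSeries]:
    """Read a longitudinal cohort CSV into per-eye visit series.

    Rows are grouped by (participant_id, eye) and sorted by ``time_years``.
    Eyes with a single visit are retained (``growth_eligible`` is False).
    """
    df = pd.read_csv(path)
    df = _validate_cohort_frame(df)
    out: list[EyeSeries] = []
    for (pid, eye), grp in df.groupby(["participant_id", "eye"], sort=True):
        grp = grp.sort_values("time_years").reset_index(drop=True)
        series = EyeSeries(str(pid), str(eye), grp)
        if not series.growth_eligible:
            logger.warning("eye (%s, %s) has a single visit; ineligible for growth", pid, eye)
        out.append(series)
    return out


def cohort_to_frame(series_list: Iterable[EyeSeries]) -> pd.DataFrame:
    """Concatenate eye series back into one flat cohort DataFrame."""
    frames = [s.visits for s in series_list]
    if not frames:
        raise ValueError("no eye series given")
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]


def write_metrics(path: str | Path, records: Sequence[EyeSeries] | pd.DataFrame) -> None:
    """Write per-visit records as a cohort CSV that round-trips losslessly.

    Numeric fields are written with 10 significant digits so that
    ``read_cohort_table(write_metrics(x)) == x`` to float precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = cohort_to_frame(records)
    if df.empty:
        raise ValueError("refusing to write an empty metrics table")
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory {path.parent} does not exist")
    df.to_csv(path, index=False, float_format="%.10g")
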