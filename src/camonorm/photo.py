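"""Calibrated-photograph pathway: grey-standard normalisation, ROI
extraction and RGB greenness.

Used for the heterogeneous-environment experiment, where colour was scored
from photographs rather than spectra.  An image is calibrated by scaling
each channel so the embedded grey standard reads 18% reflectance; greenness
is then G/(R+G+B)*100 averaged over six dorso-lateral regions (left/right
of the 3rd thoracic, 2nd and 6th abdominal segments).  These RGB measures
are device-referred and deliberately not passed through the avian visual
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "GREY_REFLECTANCE",
    "SEGMENT_LABELS",
    "Roi",
    "RoiSet",
    "CalibratedImage",
    "read_image",
    "calibrate_image",
    "extract_roi_means",
    "greenness_rgb",
    "specimen_greenness",
    "linearise_gamma22",
]

GREY_REFLECTANCE = 0.18

#: The six dorso-lateral measurement sites.
SEGMENT_LABELS = (
    "left_t3", "right_t3",
    "left_a2", "right_a2",
    "left_a6", "right_a6",
)


@dataclass(frozen=True)
class Roi:
    """Rectangular region: half-open pixel bounds [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError(f"empty ROI: {self}")

    def slice(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass
class RoiSet:
    """Six labelled specimen regions plus one grey-standard region."""

    specimen: dict[str, Roi]
    grey: Roi

    def __post_init__(self) -> None:
        if len(self.specimen) != 6:
            raise ValueError(
                f"need exactly 6 specimen ROIs, got {len(self.specimen)}")

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape[:2]
        for label, roi in {**self.specimen, "grey": self.grey}.items():
            if roi.row0 < 0 or roi.col0 < 0 or roi.row1 > h or roi.col1 > w:
                raise ValueError(
                    f"ROI '{label}' {roi} outside image bounds {h}x{w}")

    @classmethod
    def from_yaml(cls, path) -> "RoiSet":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        spec = {k: Roi(*v) for k, v in cfg["specimen"].items()}
        return cls(specimen=spec, grey=Roi(*cfg["grey"]))

    def to_yaml(self, path) -> None:
        cfg = {
            "specimen": {k: [r.row0, r.col0, r.row1, r.col1]
                         for k, r in self.specimen.items()},
            "grey": [self.grey.row0, self.grey.col0,
                     self.grey.row1, self.grey.col1],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


@dataclass
class CalibratedImage:
    """Linear-light image scaled so the grey standard reads 0.18."""

    pixels: np.ndarray            # (H, W, 3) float
    factors: np.ndarray           # per-channel scale applied
    source: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) image")


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as float RGB in [0, 1] (integer types rescaled)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def linearise_gamma22(pixels: np.ndarray) -> np.ndarray:
    """Inverse gamma-2.2 transfer: gamma-encoded -> linear light."""
    return np.clip(pixels, 0.0, None) ** 2.2


def calibrate_image(
    raw: np.ndarray,
    rois: RoiSet,
    linearisation=None,
    per_channel: bool = True,
    source: str = "",
) -> CalibratedImage:
    """Normalise an image to the 18% grey standard.

    ``linearisation`` is applied first (callable, or None for images already
    in linear light, e.g. the synthetic fixtures).  Each channel is then
    scaled by 0.18 / mean(channel over grey ROI); with ``per_channel=False``
    a single scalar (mean of the three channel factors' source means) is
    used instead, preserving any colour cast.
    """
    img = np.asarray(raw, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    rois.check_bounds(img.shape[:2])
    if linearisation is not None:
        img = linearisation(img)
    grey = img[rois.grey.slice()]
    means = grey.reshape(-1, 3).mean(axis=0)
    if np.any(means <= 0):
        raise ValueError(f"grey-standard ROI has non-positive mean: {means}")
    if per_channel:
        factors = GREY_REFLECTANCE / means
    else:
        factors = np.full(3, GREY_REFLECTANCE / means.mean())
    return CalibratedImage(img * factors, factors=factors, source=source)


def extract_roi_means(img: CalibratedImage, rois: RoiSet) -> dict[str, np.ndarray]:
    """Arithmetic per-channel mean over each specimen ROI."""
    out = {}
    rois.check_bounds(img.pixels.shape[:2])
    for label, roi in rois.specimen.items():
        patch = img.pixels[roi.slice()]
        if patch.size == 0:
            raise ValueError(f"ROI '{label}' is empty")
        out[label] = patch.reshape(-1, 3).mean(axis=0)
    return out


def greenness_rgb(rgb) -> float:
    """Percentage greenness G/(R+G+B)*100 of one RGB triple."""
    r, g, b = (float(v) for v in np.asarray(rgb, dtype=float))
    total = r + g + b
    if total <= 0:
        raise ValueError("R+G+B must be positive")
    return 100.0 * g / total


def specimen_greenness(roi_means: dict[str, np.ndarray]) -> float:
    """Specimen-level greenness: mean of the per-ROI greenness values."""
    if not roi_means:
        raise ValueError("no ROI means supplied")
    return float(np.mean([greenness_rgb(v) for v in roi_means.values()]))
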