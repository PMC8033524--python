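"""DAB immunohistochemistry quantification.

Reproduces a standard Fiji-style semi-automatic recipe: rolling-ball
background subtraction on the RGB image, H-DAB colour deconvolution
(Ruifrok & Johnston stain vectors), Gaussian blur of the DAB channel, and
a fixed global threshold to measure the stained area fraction inside a
manually drawn region of interest.  The DAB channel follows the
conventional polarity where darker means more stain (255 = unstained), so
positive pixels are those at or below the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: published H-DAB stain vectors (rows: haematoxylin, DAB, residual)
HDAB_STAINS = np.array([
    [0.650, 0.704, 0.286],
    [0.269, 0.568, 0.776],
    [0.0, 0.0, 0.0],  # residual, filled in below
])
HDAB_STAINS[2] = np.cross(HDAB_STAINS[0], HDAB_STAINS[1])
HDAB_STAINS = HDAB_STAINS / np.linalg.norm(HDAB_STAINS, axis=1, keepdims=True)

#: global thresholds used per stain panel (8-bit DAB channel)
PANEL_THRESHOLDS = {"CD31": 222, "NFIB": 170, "ERO1A": 170, "VEGFA": 170}


@dataclass
class RoiImage:
    """An RGB brightfield image with a region-of-interest mask."""

    rgb: np.ndarray  # H x W x 3, uint8
    roi_mask: np.ndarray  # H x W bool
    stain_panel: str = ""
    tissue_mask: Optional[np.ndarray] = None  # e.g. whole-lung area

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        if self.rgb.dtype != np.uint8:
            raise ValueError("rgb must be 8-bit")
        if self.roi_mask.shape != self.rgb.shape[:2]:
            raise ValueError("roi_mask must match image shape")

    @property
    def default_threshold(self) -> int:
        return PANEL_THRESHOLDS.get(self.stain_panel, 170)


@dataclass(frozen=True)
class StainQuantResult:
    """Positive-area measurement for one ROI."""

    positive_area_px: int
    roi_area_px: int
    positive_fraction: float
    threshold_used: int
    metastatic_area_pct: Optional[float] = None


def deconvolve_hdab(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Separate an 8-bit RGB image into (haematoxylin, DAB) 8-bit channels.

    Optical densities are unmixed with the H-DAB stain matrix; each channel
    is re-rendered as ``255 * 10**(-OD)`` so 255 means no stain and darker
    means more stain (the Fiji colour-deconvolution convention).
    """
    from skimage.color import separate_stains

    conv = np.linalg.inv(HDAB_STAINS)
    od = separate_stains(rgb.astype(np.float64) / 255.0, conv)
    od = od * (-np.log10(1e-6))  # undo skimage's log(1e-6) normalisation
    channels = 255.0 * np.power(10.0, -np.clip(od, 0, None))
    h, dab = channels[..., 0], channels[..., 1]
    return h, dab


def subtract_background(rgb: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background subtraction for a light-background image.

    Each channel is inverted, the rolling-ball background estimated and
    subtracted, and the result re-inverted, so unstained background tends
    to white - the standard equivalent of Fiji's Subtract Background with
    the light-background option.
    """
    from skimage.restoration import rolling_ball

    out = np.empty_like(rgb)
    for c in range(3):
        inv = 255.0 - rgb[..., c].astype(np.float64)
        bg = rolling_ball(inv, radius=radius)
        out[..., c] = np.clip(255.0 - (inv - bg), 0, 255).astype(np.uint8)
    return out


def preprocess_dab(roi: RoiImage, rolling_radius: float = 50,
                   blur_sigma: float = 5) -> np.ndarray:
    """Background-subtract, deconvolve and blur; return the DAB channel.

    Returns a float array in [0, 255], darker = more DAB.  A rolling-ball
    radius larger than half the image is clipped with a warning;
    ``rolling_radius=0`` skips background subtraction (the recipe used for
    panels quantified without it).
    """
    if not roi.roi_mask.any():
        raise ValueError("empty ROI")
    rgb = roi.rgb
    if rolling_radius:
        max_r = min(rgb.shape[:2]) // 2
        if rolling_radius > max_r:
            warnings.warn(f"rolling radius {rolling_radius} clipped to {max_r}")
            rolling_radius = max_r
        rgb = subtract_background(rgb, rolling_radius)
    _, dab = deconvolve_hdab(rgb)
    if blur_sigma:
        from skimage.filters import gaussian

        dab = gaussian(dab, sigma=blur_sigma, preserve_range=True)
    return dab


def positive_area(dab_channel: np.ndarray, roi_mask: np.ndarray,
                  threshold: int, positive_below: bool = True,
                  ) -> StainQuantResult:
    """Measure the stained area fraction of an ROI at a fixed threshold.

    With the conventional polarity (``positive_below``), ROI pixels whose
    DAB value is <= threshold count as positive.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    roi_area = int(roi_mask.sum())
    if roi_area == 0:
        raise ValueError("empty ROI")
    vals = dab_channel[roi_mask]
    pos = int((vals <= threshold).sum() if positive_below
              else (vals >= threshold).sum())
    return StainQuantResult(positive_area_px=pos, roi_area_px=roi_area,
                            positive_fraction=pos / roi_area,
                            threshold_used=int(threshold))


def metastatic_burden(lung_mask: np.ndarray,
                      met_roi_masks: Sequence[np.ndarray]) -> float:
    """Percentage of the lung area covered by the union of metastasis ROIs.

    ROI pixels outside the lung mask are clipped with a warning; overlapping
    ROIs are not double-counted.
    """
    lung_area = int(lung_mask.sum())
    if lung_area == 0:
        raise ValueError("zero lung area")
    union = np.zeros_like(lung_mask, dtype=bool)
    for m in met_roi_masks:
        union |= m.astype(bool)
    outside = int((union & ~lung_mask.astype(bool)).sum())
    if outside:
        warnings.warn(f"{outside} ROI pixels outside the lung mask were clipped")
        union &= lung_mask.astype(bool)
    return 100.0 * union.sum() / lung_area


def render_hdab(h_od: np.ndarray, dab_od: np.ndarray) -> np.ndarray:
    """Forward-render an 8-bit RGB image from per-pixel H and DAB optical
    densities (the inverse of :func:`deconvolve_hdab`; used for synthetic
    fixtures and round-trip checks)."""
    od = np.stack([h_od, dab_od, np.zeros_like(h_od)], axis=-1)
    rgb = np.power(10.0, -od @ HDAB_STAINS)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
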