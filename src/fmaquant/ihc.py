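"""Conventional 2D immunostain quantification (proportional stained area).

The comparator to the 3D method: the fraction of pixels positive for an
endothelial immunostain (DAB chromogen) within glomerular profiles or
cortical fields. Positivity is decided by colour deconvolution of the RGB
section into haematoxylin/eosin/DAB absorbance channels with a recorded
threshold on the DAB channel; fixed-threshold behaviour is the default so
results are comparable across sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hed

logger = logging.getLogger(__name__)

#: Default DAB-absorbance threshold (deconvolved units). Stain blobs sit well
#: above this; counterstain and white background sit near zero.
DEFAULT_DAB_THRESHOLD = 0.15


@dataclass
class StainMetrics:
    """Proportional-area result over a set of profiles/fields."""

    per_profile_fractions: list[float]
    mean_fraction: float
    n_profiles: int
    compartment: str  # 'glomerular' | 'tubulointerstitial'
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.per_profile_fractions):
            raise ValueError("stained-area fractions must be in [0, 1]")


def stain_mask(
    image: np.ndarray,
    method: str = "hed",
    threshold: float = DEFAULT_DAB_THRESHOLD,
) -> np.ndarray:
    """Binary mask of stain-positive pixels in an RGB section.

    ``method='hed'`` (default) deconvolves with the published haematoxylin/
    eosin/DAB stain vectors and thresholds the DAB channel; ``method='hue'``
    is a crude hue-gate fallback for non-standard chromogens.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"expected an RGB image (H, W, 3), got shape {img.shape}; "
            "grayscale input cannot be colour-deconvolved"
        )
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    if method == "hed":
        dab = rgb2hed(img)[..., 2]
        mask = dab > threshold
    elif method == "hue":
        import colorsys  # noqa: F401  (documented fallback; vectorised below)
        mx = img.max(axis=2)
        mn = img.min(axis=2)
        brownish = (img[..., 0] > img[..., 2]) & (mx - mn > 0.1) & (mx < 0.9)
        mask = brownish
    else:
        raise ValueError(f"unknown stain_mask method {method!r}")
    logger.info("stain_mask: method=%s threshold=%s positive=%d",
                method, threshold, int(mask.sum()))
    return mask


def proportional_area(mask: np.ndarray, roi: np.ndarray) -> float:
    """Stained pixels within the ROI divided by ROI pixels."""
    mask = np.asarray(mask).astype(bool)
    roi = np.asarray(roi).astype(bool)
    if mask.shape != roi.shape:
        raise ValueError("mask and ROI shapes differ")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    return int((mask & roi).sum()) / n_roi


def evaluate_section(
    image: np.ndarray,
    roi_list: list[np.ndarray],
    compartment: str = "glomerular",
    glomerular_exclusions: list[np.ndarray] | None = None,
    method: str = "hed",
    threshold: float = DEFAULT_DAB_THRESHOLD,
) -> StainMetrics:
    """Proportional stained area over profiles (glomerular mode) or fields.

    In tubulointerstitial mode any supplied glomerular ROIs are removed from
    each field before the fraction is computed, mirroring the 'excluding
    glomeruli' cortical-field readout. Conventional protocol sizes are 30
    glomerular profiles or 10 cortical fields per section; any count >= 1 is
    accepted and logged.
    """
    if compartment not in ("glomerular", "tubulointerstitial"):
        raise ValueError(f"unknown compartment {compartment!r}")
    if not roi_list:
        raise ValueError("need at least one ROI")
    smask = stain_mask(image, method=method, threshold=threshold)
    exclusion = None
    if compartment == "tubulointerstitial" and glomerular_exclusions:
        exclusion = np.zeros(smask.shape, dtype=bool)
        for g in glomerular_exclusions:
            exclusion |= np.asarray(g).astype(bool)
    fractions = []
    for roi in roi_list:
        roi = np.asarray(roi).astype(bool)
        if exclusion is not None:
            roi = roi & ~exclusion
        fractions.append(proportional_area(smask, roi))
    return StainMetrics(
        per_profile_fractions=fractions,
        mean_fraction=float(np.mean(fractions)),
        n_profiles=len(fractions),
        compartment=compartment,
        provenance={"method": method, "threshold": threshold,
                    "excluded_glomeruli": exclusion is not None},
    )


def random_field_rois(
    shape: tuple[int, int],
    n_fields: int,
    field_size: tuple[int, int],
    seed: int = 0,
) -> list[np.ndarray]:
    """Seeded uniform placement of rectangular fields, rejecting out-of-bounds
    positions — a reproducible stand-in for 'randomly selected' fields."""
    h, w = shape
    fh, fw = field_size
    if fh > h or fw > w:
        raise ValueError("field larger than section")
    rng = np.random.default_rng(seed)
    rois = []
    for _ in range(n_fields):
        r0 = int(rng.integers(0, h - fh + 1))
        c0 = int(rng.integers(0, w - fw + 1))
        roi = np.zeros(shape, dtype=bool)
        roi[r0:r0 + fh, c0:c0 + fw] = True
        rois.append(roi)
    return rois
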