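"""Per-section binarisation by a union of automatic thresholds.

Synaptic puncta span a wide intensity range: antibody penetration and
epitope density make some puncta an order of magnitude dimmer than
others, so no single global threshold captures both. Each section is
therefore binarised with several automatic threshold algorithms and the
foregrounds are unioned: a global bimodal method (Otsu) keeps bright
puncta crisp while a tail-sensitive method (Triangle) picks up dim ones.

Thresholds are computed per section, making the result robust to
section-to-section staining variation. Each method's threshold is
floored at a robust background estimate (median + 2.5 × 1.4826·MAD) so
that a method degenerating on a nearly-empty section cannot flood the
mask with camera noise.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import (
    threshold_isodata,
    threshold_li,
    threshold_mean,
    threshold_otsu,
    threshold_triangle,
    threshold_yen,
)

from .stacks import BinaryStack, ChannelStack

__all__ = ["THRESHOLD_METHODS", "DEFAULT_METHODS", "binarize_section",
           "binarize_stack"]

THRESHOLD_METHODS = {
    "otsu": threshold_otsu,
    "triangle": threshold_triangle,
    "li": threshold_li,
    "yen": threshold_yen,
    "mean": threshold_mean,
    "isodata": threshold_isodata,
}

DEFAULT_METHODS = ("otsu", "triangle")

# Background floor in robust SDs above the median; guards against a
# threshold collapsing into the noise on sparse sections.
_FLOOR_K = 2.5
_MAD_TO_SD = 1.4826


def _background_floor(image: np.ndarray) -> float:
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med + _FLOOR_K * _MAD_TO_SD * mad


def binarize_section(
    image: np.ndarray,
    methods: "tuple[str, ...] | list[str]" = DEFAULT_METHODS,
    min_object_px: int = 2,
) -> np.ndarray:
    """Binarise one 2D section as the union of per-method foregrounds.

    2D connected components (8-connectivity) smaller than
    ``min_object_px`` pixels are removed: isolated pixels are
    indistinguishable from shot noise. A constant image yields an empty
    mask, never a full one.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("binarize_section expects a 2D image")
    if not methods:
        raise ValueError("at least one threshold method is required")
    unknown = [m for m in methods if m not in THRESHOLD_METHODS]
    if unknown:
        raise ValueError(
            f"unknown threshold method(s) {unknown}; supported: "
            f"{sorted(THRESHOLD_METHODS)}")
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=bool)
    floor = _background_floor(image)
    mask = np.zeros(image.shape, dtype=bool)
    for m in methods:
        thr = max(float(THRESHOLD_METHODS[m](image)), floor)
        mask |= image > thr
    if min_object_px > 1:
        lab, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        if n:
            sizes = np.bincount(lab.ravel())
            keep = np.flatnonzero(sizes >= min_object_px)
            mask = np.isin(lab, keep[keep > 0])
    return mask


def binarize_stack(
    stack: ChannelStack,
    channel: str,
    methods: "tuple[str, ...] | list[str]" = DEFAULT_METHODS,
    min_object_px: int = 2,
) -> BinaryStack:
    """Binarise one channel of a registered stack, section by section.

    Thresholds are recomputed on every section; there is no
    cross-section leakage, so permuting section order permutes the masks
    identically.
    """
    if channel not in stack.channels:
        raise KeyError(f"channel {channel!r} not in stack")
    vol = stack.channels[channel]
    mask = np.zeros(vol.shape, dtype=bool)
    for k in range(vol.shape[0]):
        mask[k] = binarize_section(vol[k], methods=methods,
                                   min_object_px=min_object_px)
    if stack.valid_mask is not None:
        mask &= stack.valid_mask
    return BinaryStack(mask=mask, channel=channel,
                       pixel_size_xy=stack.pixel_size_xy,
                       section_thickness=stack.section_thickness)
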