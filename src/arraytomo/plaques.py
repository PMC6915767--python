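"""Amyloid plaque detection, proximity and burden metrics.

Fibrillar (dense-core) plaques are detected on the Thioflavin-S channel;
the oligomeric Aβ halo is whatever the pan-Aβ stain adds beyond the
fibrillar core (pan AND NOT core). Every voxel gets a physical distance
to the nearest plaque edge, and synapses/ROIs are classed "near" (< 20
µm) or "far" (otherwise) — the distance band in which plaque-associated
synapse loss is measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import binarize_section
from .stacks import ChannelStack
from .puncta import _STRUCTURE

__all__ = [
    "PlaqueMap", "BurdenResult", "detect_plaques", "classify_near_far",
    "halo_burden", "mask_burden", "estimate_region_volume", "sample_rois", "Roi",
    "NEAR_FAR_CUTOFF_UM",
]

NEAR_FAR_CUTOFF_UM = 20.0


@dataclass
class PlaqueMap:
    """Plaque masks plus the physical edge-distance field.

    ``edge_distance_um[v]`` is the distance (µm, anisotropy respected)
    from voxel ``v`` to the nearest core-plaque voxel: 0 inside and on
    the plaque boundary, ``inf`` everywhere when there is no plaque.
    """

    core_mask: np.ndarray
    edge_distance_um: np.ndarray
    pixel_size_xy: float
    section_thickness: float
    pan_mask: np.ndarray | None = None
    n_plaques: int = 0

    @property
    def halo_mask(self) -> np.ndarray | None:
        if self.pan_mask is None:
            return None
        return self.pan_mask & ~self.core_mask

    @property
    def mean_plaque_area_um2(self) -> float | None:
        """Mean 2D cross-sectional component area, pooled over sections."""
        return _mean_component_area(self.core_mask, self.pixel_size_xy)

    def distance_at(self, x_um: float, y_um: float, z_um: float) -> float:
        """Edge distance at a physical point (nearest-voxel lookup)."""
        r = int(round(y_um / self.pixel_size_xy - 0.5))
        c = int(round(x_um / self.pixel_size_xy - 0.5))
        z = int(round(z_um / self.section_thickness - 0.5))
        nz, nr, nc = self.edge_distance_um.shape
        z = min(max(z, 0), nz - 1)
        r = min(max(r, 0), nr - 1)
        c = min(max(c, 0), nc - 1)
        return float(self.edge_distance_um[z, r, c])


@dataclass
class BurdenResult:
    """Histology burden metrics for one mask within one region.

    ``mean_plaque_area_um2`` is ``None`` (absent) when no component
    exists; counts are per-section means when the input spans sections.
    """

    percent_area: float
    plaque_count: float
    mean_plaque_area_um2: float | None
    total_area_um2: float
    halo_percent_area: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_area <= 100.0:
            raise ValueError("percent area must be within [0, 100]")


def detect_plaques(
    stack: ChannelStack,
    core_channel: str = "thios",
    min_plaque_area_um2: float = 20.0,
    methods: "tuple[str, ...]" = ("otsu", "triangle"),
    pan_channel: str | None = None,
) -> PlaqueMap:
    """Threshold the fibrillar channel and build the edge-distance field.

    Each section is auto-thresholded with the union of ``methods`` (the
    same dim-plus-bright contract as synaptic segmentation, which is what
    lets the faint oligomeric halo survive thresholding), 2D components smaller
    than ``min_plaque_area_um2`` are dropped (guards against
    puncta-scale debris), and surviving footprints are merged across
    sections into 3D plaques using the same ≥1-pixel-overlap rule as
    puncta. The distance transform uses physical voxel sampling, so the
    70 nm z step and ~0.1 µm xy step are respected.
    """
    if core_channel not in stack.channels:
        raise KeyError(f"core channel {core_channel!r} not in stack")
    px = stack.pixel_size_xy
    dz = stack.section_thickness
    min_px = max(1, int(round(min_plaque_area_um2 / px**2)))
    core = _threshold_channel(stack, core_channel, methods, min_px)
    pan = None
    if pan_channel is not None:
        pan = _threshold_channel(stack, pan_channel, methods, min_px)
    _, n_plaques = ndimage.label(core, structure=_STRUCTURE)
    if core.any():
        dist = ndimage.distance_transform_edt(~core, sampling=(dz, px, px))
    else:
        dist = np.full(core.shape, np.inf)
    return PlaqueMap(core_mask=core, edge_distance_um=dist, pixel_size_xy=px,
                     section_thickness=dz, pan_mask=pan, n_plaques=int(n_plaques))


def _threshold_channel(stack, channel, methods, min_px) -> np.ndarray:
    vol = stack.channels[channel]
    mask = np.zeros(vol.shape, dtype=bool)
    for k in range(vol.shape[0]):
        sec = binarize_section(vol[k], methods=methods, min_object_px=1)
        if min_px > 1:
            lab, n = ndimage.label(sec, structure=np.ones((3, 3), bool))
            if n:
                sizes = np.bincount(lab.ravel())
                keep = np.flatnonzero(sizes >= min_px)
                sec = np.isin(lab, keep[keep > 0])
        mask[k] = sec
    return mask


def classify_near_far(distance_um: float, cutoff_um: float = NEAR_FAR_CUTOFF_UM) -> str:
    """"near" iff 0 <= distance < cutoff; the boundary and ∞ are "far"."""
    if distance_um < 0:
        raise ValueError("distance must be non-negative")
    return "near" if distance_um < cutoff_um else "far"


def _mean_component_area(mask: np.ndarray, pixel_size_xy: float) -> float | None:
    """Mean area (µm²) of 2D 8-connected components pooled over sections."""
    mask = np.atleast_3d(mask if mask.ndim == 3 else mask[None])
    areas = []
    for sec in mask:
        lab, n = ndimage.label(sec, structure=np.ones((3, 3), bool))
        if n:
            areas.extend(np.bincount(lab.ravel())[1:] * pixel_size_xy**2)
    return float(np.mean(areas)) if areas else None


def mask_burden(
    mask: np.ndarray,
    pixel_size_xy: float,
    roi: np.ndarray | None = None,
) -> BurdenResult:
    """Percent area, component count and mean component size for a mask.

    ``mask`` may be one section (2D) or a stack (3D, sections pooled);
    ``roi`` restricts the denominator (and the mask) to a region.
    """
    mask = np.asarray(mask, dtype=bool)
    if roi is not None:
        if roi.shape != mask.shape:
            raise ValueError("ROI shape must match mask shape")
        denom = int(roi.sum())
        mask = mask & roi
    else:
        denom = mask.size
    if denom == 0:
        raise ValueError("empty ROI")
    m3 = mask if mask.ndim == 3 else mask[None]
    counts = []
    for sec in m3:
        _, n = ndimage.label(sec, structure=np.ones((3, 3), bool))
        counts.append(n)
    return BurdenResult(
        percent_area=100.0 * mask.sum() / denom,
        plaque_count=float(np.mean(counts)),
        mean_plaque_area_um2=_mean_component_area(mask, pixel_size_xy),
        total_area_um2=float(mask.sum()) * pixel_size_xy**2 / m3.shape[0],
    )


def halo_burden(
    pan_mask: np.ndarray,
    core_mask: np.ndarray,
    pixel_size_xy: float,
    roi: np.ndarray | None = None,
) -> BurdenResult:
    """Burden of the oligomeric halo: pan-Aβ minus the fibrillar core.

    Mirrors subtracting the thresholded fibrillar image from the
    thresholded pan-Aβ image; metrics are computed on the remainder.
    """
    pan_mask = np.asarray(pan_mask, dtype=bool)
    core_mask = np.asarray(core_mask, dtype=bool)
    if pan_mask.shape != core_mask.shape:
        raise ValueError("pan and core masks must have the same shape")
    halo = pan_mask & ~core_mask
    res = mask_burden(halo, pixel_size_xy, roi=roi)
    res.halo_percent_area = res.percent_area
    return res


def estimate_region_volume(
    section_areas_mm2,
    section_spacing_um: float = 1000.0,
    hemisphere_factor: float = 2.0,
) -> float:
    """Region volume (mm³) from sparsely sampled section areas.

    Every measured section stands for a slab ``section_spacing_um``
    thick; summed slab volumes are multiplied by ``hemisphere_factor``
    (2 when only one hemisphere was sectioned).
    """
    areas = np.asarray(list(section_areas_mm2), dtype=float)
    if areas.size and np.any(areas < 0):
        raise ValueError("section areas must be >= 0")
    return float(areas.sum() * (section_spacing_um / 1000.0) * hemisphere_factor)


@dataclass
class Roi:
    """A square xy region of interest spanning the full section depth."""

    id: int
    center_px: tuple[int, int]  # (row, col)
    size_px: int
    label: str
    edge_distance_um: float

    def slices(self) -> tuple[slice, slice]:
        h = self.size_px // 2
        r, c = self.center_px
        return slice(r - h, r - h + self.size_px), slice(c - h, c - h + self.size_px)


def sample_rois(
    stack: ChannelStack,
    plaque_map: PlaqueMap,
    roi_size_um: float,
    n_near: int,
    n_far: int,
    seed: int = 0,
    cutoff_um: float = NEAR_FAR_CUTOFF_UM,
    max_attempts: int = 2000,
) -> list[Roi]:
    """Place non-overlapping square ROIs labelled near/far by their centre.

    Placement is rejection sampling, reproducible under ``seed``. When
    the requested count cannot be placed (e.g. near ROIs in a
    plaque-free field) a partial list is returned with a warning.
    """
    rng = np.random.default_rng(seed)
    _, rows, cols = stack.shape
    size_px = max(1, int(round(roi_size_um / stack.pixel_size_xy)))
    if size_px > min(rows, cols):
        raise ValueError("ROI larger than the field")
    h = size_px // 2
    mid_z = stack.n_sections // 2
    wanted = {"near": n_near, "far": n_far}
    rois: list[Roi] = []
    attempts = 0
    while (wanted["near"] > 0 or wanted["far"] > 0) and attempts < max_attempts:
        attempts += 1
        r = int(rng.integers(h, rows - size_px + h + 1))
        c = int(rng.integers(h, cols - size_px + h + 1))
        d = float(plaque_map.edge_distance_um[mid_z, r, c])
        label = classify_near_far(d, cutoff_um)
        if wanted[label] <= 0:
            continue
        if any(abs(r - r2) < size_px and abs(c - c2) < size_px
               for (r2, c2) in (roi.center_px for roi in rois)):
            continue
        rois.append(Roi(id=len(rois) + 1, center_px=(r, c), size_px=size_px,
                        label=label, edge_distance_um=d))
        wanted[label] -= 1
    if wanted["near"] > 0 or wanted["far"] > 0:
        warnings.warn(
            f"could only place {len(rois)} ROIs; short by "
            f"{wanted['near']} near and {wanted['far']} far", stacklevel=2)
    return rois
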