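"""Core in-memory containers for calibrated serial-section image data.

Array tomography re-stacks ultrathin (~70 nm) physical sections into a 3D
volume, so voxels are strongly anisotropic: xy sampling is set by the camera
and objective (order 0.1 µm/px) while z sampling is the section thickness.
All arrays here use axis order ``(section, row, col)``; anisotropy is carried
as calibration metadata and never resolved by resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChannelStack", "BinaryStack", "StackShapeError"]


class StackShapeError(ValueError):
    """Raised when channels of one stack disagree in shape."""


@dataclass
class ChannelStack:
    """A calibrated multi-channel serial-section intensity volume.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"synaptophysin"``, ``"PSD95"``,
        ``"tau"``, ``"abeta"``, ``"thios"``, ``"dapi"``) to a 3D array
        of shape ``(n_sections, rows, cols)``.
    pixel_size_xy
        Lateral pixel size in µm/px. Must be > 0.
    section_thickness
        Physical section thickness in µm (0.07 for 70 nm ultrathin
        sections). Must be > 0.
    provenance
        Free-text metadata (acquisition notes, generator parameters, ...).
    valid_mask
        Optional per-voxel boolean mask marking voxels that carry real
        data (False where registration shifted data out of the field).
    """

    channels: dict[str, np.ndarray]
    pixel_size_xy: float
    section_thickness: float
    provenance: str = ""
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ChannelStack needs at least one channel")
        if self.pixel_size_xy <= 0 or self.section_thickness <= 0:
            raise ValueError("calibration must be strictly positive")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        ref_name, ref_shape = next(iter(shapes.items()))
        for name, shape in shapes.items():
            if len(shape) != 3:
                raise StackShapeError(f"channel {name!r} is not 3D: shape {shape}")
            if shape != ref_shape:
                raise StackShapeError(
                    f"channel {name!r} has shape {shape}, but {ref_name!r} "
                    f"has {ref_shape}; all channels must match"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_sections(self) -> int:
        return self.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in µm³."""
        return self.pixel_size_xy**2 * self.section_thickness

    @property
    def volume_um3(self) -> float:
        """Physical volume of the whole imaged field in µm³."""
        n, r, c = self.shape
        return n * r * c * self.voxel_volume_um3

    def copy(self) -> "ChannelStack":
        return ChannelStack(
            channels={k: v.copy() for k, v in self.channels.items()},
            pixel_size_xy=self.pixel_size_xy,
            section_thickness=self.section_thickness,
            provenance=self.provenance,
            valid_mask=None if self.valid_mask is None else self.valid_mask.copy(),
        )


@dataclass
class BinaryStack:
    """A thresholded (binarised) single-channel stack.

    Calibration is copied from the source :class:`ChannelStack` so that
    object volumes and distances can be reported in physical units.
    """

    mask: np.ndarray
    channel: str
    pixel_size_xy: float
    section_thickness: float

    def __post_init__(self) -> None:
        if self.mask.ndim != 3:
            raise StackShapeError(f"mask must be 3D, got shape {self.mask.shape}")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        if self.pixel_size_xy <= 0 or self.section_thickness <= 0:
            raise ValueError("calibration must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_xy**2 * self.section_thickness

    @property
    def volume_um3(self) -> float:
        n, r, c = self.shape
        return n * r * c * self.voxel_volume_um3
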