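"""Multi-channel complex transmit-field maps and their linear combination.

A static RF shim is one complex weight per transmit channel; the net
transmit field at voxel r is the superposition B1(r) = sum_c w_c b_c(r)
of the per-channel relative fields b_c.  Flip-angle maps are expressed in
relative units: after power calibration the mean over the calibration
region equals 1 (nominal flip).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid


@dataclass
class ChannelFieldMap:
    """Per-channel complex relative transmit field for one subject.

    Attributes
    ----------
    grid : VoxelGrid
        Sampling lattice shared with the subject's masks.
    values : ndarray, complex, shape (n_channels, nx, ny, nz)
        Relative transmit field of each channel, arbitrary units.
    """

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-D (channel, x, y, z)")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError(
                f"spatial shape {self.values.shape[1:]} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def combine_fields(field_map: ChannelFieldMap, weights: np.ndarray) -> np.ndarray:
    """Superpose channels with complex weights: B1(r) = sum_c w_c b_c(r).

    Returns a complex volume with the grid's spatial shape.
    """
    weights = np.asarray(weights, dtype=complex).ravel()
    if weights.size != field_map.n_channels:
        raise ValueError(
            f"shim has {weights.size} weights but field map has {field_map.n_channels} channels"
        )
    return np.tensordot(weights, field_map.values, axes=(0, 0))


def flip_angle_map(
    field_map: ChannelFieldMap, weights: np.ndarray, roi: np.ndarray
) -> np.ndarray:
    """Relative flip-angle map calibrated so the ROI mean equals 1.

    alpha(r) = s * |B1(r)| with the scale s chosen such that the mean of
    alpha over the ROI is exactly 1 (power calibration against the region
    mean).  Scaling the shim by any nonzero factor leaves alpha unchanged.
    """
    roi = _check_mask(roi, field_map.grid)
    mag = np.abs(combine_fields(field_map, weights))
    mean = float(mag[roi].mean())
    if mean <= 0.0:
        raise ValueError("combined field is identically zero on the ROI; cannot calibrate")
    return mag / mean


def _check_mask(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    return mask
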