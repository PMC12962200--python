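"""Voxel lattice on which all field maps, masks and fraction maps live."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    """A regular, axis-aligned voxel lattice centred on the world origin.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z); each entry must be >= 1.
    voxel_size_mm : tuple of float
        Edge length of a voxel along each axis, in millimetres; all > 0.
    origin_offset_mm : tuple of float
        World-space offset of the grid centre, in millimetres.
    """

    shape: tuple[int, int, int] = (48, 48, 32)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size_mm) != 3:
            raise ValueError("shape and voxel_size_mm must have three entries")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))
        object.__setattr__(self, "origin_offset_mm", tuple(float(s) for s in self.origin_offset_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine; invertible by construction."""
        aff = np.eye(4)
        for ax in range(3):
            aff[ax, ax] = self.voxel_size_mm[ax]
            aff[ax, 3] = (
                self.origin_offset_mm[ax]
                - (self.shape[ax] - 1) / 2.0 * self.voxel_size_mm[ax]
            )
        return aff

    def world_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (*grid.shape, 3)."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * s + o
            for n, s, o in zip(self.shape, self.voxel_size_mm, self.origin_offset_mm)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)


@dataclass(frozen=True)
class CoilGeometry:
    """Transceiver array layout: rings of loop elements on a cylinder.

    The default is a 16-element array arranged as two axial rings of eight
    elements, the second ring rotated by 22.5 degrees relative to the first,
    so the element azimuths interleave.
    """

    n_channels: int = 16
    ring_element_counts: tuple[int, ...] = (8, 8)
    ring_azimuth_offsets_deg: tuple[float, ...] = (0.0, 22.5)
    ring_z_mm: tuple[float, ...] = (20.0, 60.0)
    ring_radius_mm: float = 110.0

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.ring_element_counts)
        object.__setattr__(self, "ring_element_counts", counts)
        object.__setattr__(
            self, "ring_azimuth_offsets_deg", tuple(float(a) for a in self.ring_azimuth_offsets_deg)
        )
        object.__setattr__(self, "ring_z_mm", tuple(float(z) for z in self.ring_z_mm))
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        if sum(counts) != self.n_channels:
            raise ValueError(
                f"ring_element_counts {counts} must sum to n_channels {self.n_channels}"
            )
        n_rings = len(counts)
        if not (len(self.ring_azimuth_offsets_deg) == len(self.ring_z_mm) == n_rings):
            raise ValueError("per-ring parameter lists must have equal length")
        if self.ring_radius_mm <= 0:
            raise ValueError("ring_radius_mm must be positive")

    def element_azimuths_deg(self) -> np.ndarray:
        """Azimuth of each element in degrees, channel order = ring-major."""
        az = []
        for count, offset in zip(self.ring_element_counts, self.ring_azimuth_offsets_deg):
            az.extend(offset + 360.0 / count * np.arange(count))
        return np.asarray(az)

    def element_positions_mm(self) -> np.ndarray:
        """(n_channels, 3) world positions of the element centres."""
        pos = np.empty((self.n_channels, 3))
        i = 0
        for count, offset, z in zip(
            self.ring_element_counts, self.ring_azimuth_offsets_deg, self.ring_z_mm
        ):
            phi = np.deg2rad(offset + 360.0 / count * np.arange(count))
            pos[i : i + count, 0] = self.ring_radius_mm * np.cos(phi)
            pos[i : i + count, 1] = self.ring_radius_mm * np.sin(phi)
            pos[i : i + count, 2] = z
            i += count
        return pos
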