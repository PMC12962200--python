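"""Synthetic head phantoms and multi-channel B1+ field populations.

The generator stands in for in vivo relative B1+ mapping: it produces, for
each synthetic subject, an ellipsoidal head/brain/ROI mask set and one
complex transmit-field volume per coil element.  The field model is
geometric-phenomenological, not electromagnetic: the magnitude of element c
decays with distance from the element (inverse-power law with a smooth
floor) and its phase advances as a travelling wave, -2*pi*d/lambda, plus a
per-channel offset.  At ultra-high field the RF wavelength in tissue is
short compared with the head (default 90 mm), so the channel phases
interfere strongly and an unshimmed combination is markedly inhomogeneous —
the regime that motivates RF shimming in the first place.

The per-channel phase offset is the element azimuth (the transmit field of
a loop element rotates with its azimuthal position, which is what makes a
circularly-polarised mode constructive on the coil axis) plus a small
random per-subject deviation.  Subjects differ by head-pose jitter, a few
percent of head-size variation, and wavelength variation, emulating a
population with consistent but not identical positioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .fields import ChannelFieldMap
from .grid import CoilGeometry, VoxelGrid
from .morphometry import TissueFractionMap

# Default study conditions
DEFAULT_WAVELENGTH_MM = 90.0
DEFAULT_JITTER_MM = 3.0
DEFAULT_JITTER_DEG = 3.0
#: magnitude decay scale and exponent: |b| = 1 / (1 + (d/D0)^P)
_DECAY_D0_MM = 70.0
_DECAY_EXPONENT = 2.0
#: std of the random per-channel phase deviation (radians)
_PHASE_JITTER_SD = 0.15
#: head semi-axes as a fraction of the grid half-extent
_HEAD_FRACTION = 0.75
#: brain semi-axes as a fraction of head semi-axes
_BRAIN_FRACTION = 0.82
#: ROI slab keeps the superior fraction of brain voxels (by z-percentile),
#: leaving out an inferior region emulating cerebellum / temporal lobes
_ROI_SUPERIOR_FRACTION = 0.60


@dataclass(frozen=True)
class RigidPose:
    """Rigid head pose inside the coil: translation (mm) and rotation (deg)."""

    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "translation_mm", tuple(float(t) for t in self.translation_mm))
        object.__setattr__(self, "rotation_deg", tuple(float(r) for r in self.rotation_deg))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform world coordinates (..., 3) by this pose."""
        rot = Rotation.from_euler("xyz", self.rotation_deg, degrees=True)
        return coords @ rot.as_matrix().T + np.asarray(self.translation_mm)


@dataclass
class HeadPhantom:
    """Nested head / brain / ROI masks on a common grid.

    The ROI is a superior slab of the brain mask emulating a
    supraorbital-cerebrum shimming target: it keeps the upper part of the
    cerebrum and excludes the inferior brain (cerebellum, temporal lobes).
    """

    grid: VoxelGrid
    head_mask: np.ndarray
    brain_mask: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("head_mask", "brain_mask", "roi_mask"):
            m = np.asarray(getattr(self, name), dtype=bool)
            if m.shape != self.grid.shape:
                raise ValueError(f"{name} shape {m.shape} does not match grid {self.grid.shape}")
            if not m.any():
                raise ValueError(f"{name} is empty")
            setattr(self, name, m)
        if np.any(self.brain_mask & ~self.head_mask) or np.any(self.roi_mask & ~self.brain_mask):
            raise ValueError("masks must nest: roi ⊆ brain ⊆ head")


@dataclass
class SubjectDataset:
    """One synthetic subject: field map, masks and head pose in the coil."""

    subject_id: str
    field_map: ChannelFieldMap
    phantom: HeadPhantom
    pose: RigidPose = field(default_factory=RigidPose)

    def __post_init__(self) -> None:
        if self.field_map.grid != self.phantom.grid:
            raise ValueError("field map and phantom must share one grid")


@dataclass
class TrainingDatabase:
    """Ordered collection of subject datasets; order is acquisition order.

    The ordering is significant: incremental universal-shim convergence
    studies add datasets in exactly this order.
    """

    datasets: list[SubjectDataset]
    geometry: CoilGeometry | None = None

    def __len__(self) -> int:
        return len(self.datasets)

    def __getitem__(self, i):
        return self.datasets[i]

    def __iter__(self):
        return iter(self.datasets)

    def first(self, k: int) -> "TrainingDatabase":
        """Database restricted to the first k datasets in acquisition order."""
        if not 1 <= k <= len(self.datasets):
            raise ValueError(f"k must be in 1..{len(self.datasets)}, got {k}")
        return TrainingDatabase(self.datasets[:k], geometry=self.geometry)


def make_phantom(grid: VoxelGrid, seed: int) -> HeadPhantom:
    """Build an ellipsoidal head phantom with nested brain and ROI masks.

    Head semi-axes are 75% of the grid half-extent, jittered a few percent
    per seed; the brain is a concentric 82%-scaled ellipsoid; the ROI keeps
    the superior 60% of brain voxels (by z).  Raises ``ValueError`` when the
    grid is too small to contain a nonempty, strictly nested ROI.
    """
    rng = np.random.default_rng(seed)
    half_extent = np.asarray(grid.extent_mm) / 2.0
    head_axes = _HEAD_FRACTION * half_extent * (1.0 + 0.04 * rng.standard_normal(3))
    coords = grid.world_coordinates()
    rho2_head = np.sum((coords / head_axes) ** 2, axis=-1)
    head = rho2_head <= 1.0
    brain = np.sum((coords / (head_axes * _BRAIN_FRACTION)) ** 2, axis=-1) <= 1.0

    if not brain.any() or not head.any():
        raise ValueError(f"grid {grid.shape} too small to contain a head phantom")
    z = coords[..., 2]
    z_cut = np.quantile(z[brain], 1.0 - _ROI_SUPERIOR_FRACTION)
    roi = brain & (z >= z_cut)
    if not roi.any() or roi.sum() == brain.sum() or brain.sum() == head.sum():
        raise ValueError(f"grid {grid.shape} too small for a strictly nested ROI slab")
    return HeadPhantom(grid=grid, head_mask=head, brain_mask=brain, roi_mask=roi)


def simulate_channel_fields(
    phantom: HeadPhantom,
    geometry: CoilGeometry,
    pose: RigidPose | None = None,
    wavelength_mm: float = DEFAULT_WAVELENGTH_MM,
    seed: int = 0,
) -> ChannelFieldMap:
    """Simulate per-channel complex relative B1+ maps for one subject.

    For each channel c and in-head voxel r (after moving the head by
    ``pose``), the magnitude is 1/(1 + (d/D0)^2) with d the distance to the
    element centre, and the phase is -2*pi*d/wavelength + the element
    azimuth + a small random channel offset.  The field is exactly zero
    outside the head mask.
    """
    if wavelength_mm <= 0:
        raise ValueError("wavelength_mm must be positive")
    pose = pose or RigidPose()
    rng = np.random.default_rng(seed)

    coords = pose.apply(phantom.grid.world_coordinates())
    head = phantom.head_mask
    radial = np.hypot(coords[..., 0], coords[..., 1])
    if radial[head].max() >= geometry.ring_radius_mm:
        raise ValueError("pose moves the head outside the coil interior")

    positions = geometry.element_positions_mm()
    azimuth_rad = np.deg2rad(geometry.element_azimuths_deg())
    phase_offsets = azimuth_rad + _PHASE_JITTER_SD * rng.standard_normal(geometry.n_channels)

    in_head = coords[head]  # (M, 3)
    values = np.zeros((geometry.n_channels,) + phantom.grid.shape, dtype=complex)
    for c in range(geometry.n_channels):
        d = np.linalg.norm(in_head - positions[c], axis=1)
        mag = 1.0 / (1.0 + (d / _DECAY_D0_MM) ** _DECAY_EXPONENT)
        phase = -2.0 * np.pi * d / wavelength_mm + phase_offsets[c]
        vol = np.zeros(phantom.grid.shape, dtype=complex)
        vol[head] = mag * np.exp(1j * phase)
        values[c] = vol
    return ChannelFieldMap(grid=phantom.grid, values=values)


def generate_population(
    n_subjects: int,
    geometry: CoilGeometry | None = None,
    grid: VoxelGrid | None = None,
    jitter_scale: tuple[float, float] = (DEFAULT_JITTER_MM, DEFAULT_JITTER_DEG),
    wavelength_mm: float = DEFAULT_WAVELENGTH_MM,
    seed: int = 0,
) -> TrainingDatabase:
    """Generate an ordered population of synthetic subjects.

    Subject i draws its randomness from substreams seeded by fixed
    arithmetic on the base seed (``seed + 1000*i`` for the phantom,
    ``+1`` for the fields, ``+2`` for pose and wavelength jitter), so any
    subject can be regenerated independently.  Pose jitter is Gaussian with
    the given translation (mm) and rotation (deg) scales; the wavelength
    varies by ~3% between subjects.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    geometry = geometry or CoilGeometry()
    grid = grid or VoxelGrid()
    sigma_t, sigma_r = float(jitter_scale[0]), float(jitter_scale[1])

    datasets = []
    for i in range(n_subjects):
        base = int(seed) + 1000 * i
        phantom = make_phantom(grid, seed=base)
        rng = np.random.default_rng(base + 2)
        pose = RigidPose(
            translation_mm=tuple(sigma_t * rng.standard_normal(3)),
            rotation_deg=tuple(sigma_r * rng.standard_normal(3)),
        )
        wl = wavelength_mm * (1.0 + 0.03 * rng.standard_normal())
        fmap = simulate_channel_fields(
            phantom, geometry, pose=pose, wavelength_mm=wl, seed=base + 1
        )
        datasets.append(
            SubjectDataset(subject_id=f"sub-{i + 1:03d}", field_map=fmap, phantom=phantom, pose=pose)
        )
    return TrainingDatabase(datasets, geometry=geometry)


def generate_fraction_pair(
    phantom: HeadPhantom, perturbation: float, seed: int
) -> tuple[TissueFractionMap, TissueFractionMap]:
    """Generate a pair of 3-class (GM, WM, CSF) tissue-fraction maps.

    The first map assigns fuzzy class memberships by normalised ellipsoidal
    radius inside the brain mask (WM core, GM band, thin CSF rim) with mild
    voxel noise.  The second map mixes the first with an independent random
    simplex draw: B = (1-p)*A + p*E, renormalised to sum exactly to 1.
    ``perturbation=0`` returns two identical maps; ``perturbation=1``
    produces voxels whose dominant class differs between the maps.
    """
    if not 0.0 <= perturbation <= 1.0:
        raise ValueError("perturbation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    brain = phantom.brain_mask
    coords = phantom.grid.world_coordinates()[brain]
    half = np.maximum(np.abs(coords).max(axis=0), 1e-9)
    rho = np.sqrt(np.sum((coords / half) ** 2, axis=1))
    rho = rho / max(rho.max(), 1e-9)

    # fuzzy radial bands: GM band mid-radius, WM core, CSF rim
    centers = {"GM": 0.75, "WM": 0.30, "CSF": 0.97}
    widths = {"GM": 0.18, "WM": 0.28, "CSF": 0.07}
    scores = np.stack(
        [
            np.exp(-0.5 * ((rho - centers[k]) / widths[k]) ** 2) + 0.02
            for k in ("GM", "WM", "CSF")
        ]
    )
    scores *= rng.uniform(0.9, 1.1, size=scores.shape)
    frac_a = scores / scores.sum(axis=0)

    simplex = rng.dirichlet(np.full(3, 0.3), size=frac_a.shape[1]).T
    frac_b = (1.0 - perturbation) * frac_a + perturbation * simplex
    # same final renormalisation for both, so perturbation=0 is bit-identical
    frac_a = frac_a / frac_a.sum(axis=0)
    frac_b = frac_b / frac_b.sum(axis=0)

    def _to_map(flat: np.ndarray) -> TissueFractionMap:
        vol = np.zeros((3,) + phantom.grid.shape)
        vol[:, brain] = flat
        return TissueFractionMap(grid=phantom.grid, fractions=vol)

    return _to_map(frac_a), _to_map(frac_b)
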