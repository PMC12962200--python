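"""NIfTI / JSON / CSV interchange for field maps, masks and shim solutions.

Volumetric data travel as NIfTI: multi-channel complex fields as a
magnitude/phase pair of 4-D files (4th axis = channel, phase in radians),
masks as uint8, fraction maps as 4-D float (4th axis = class).  Shim
solutions are JSON with per-channel (magnitude, phase-degrees) entries and
provenance (seed, restart count, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fields import ChannelFieldMap
from .grid import VoxelGrid
from .morphometry import TissueFractionMap
from .shim import ShimVector, _normalize


def _grid_from_image(img) -> VoxelGrid:
    zooms = img.header.get_zooms()[:3]
    aff = img.affine
    shape = img.shape[:3]
    center = aff @ np.array([(n - 1) / 2.0 for n in shape] + [1.0])
    return VoxelGrid(
        shape=tuple(int(n) for n in shape),
        voxel_size_mm=tuple(float(z) for z in zooms),
        origin_offset_mm=tuple(float(c) for c in center[:3]),
    )


def write_channel_maps(field_map: ChannelFieldMap, path_mag, path_phase) -> None:
    """Write a complex channel map as magnitude + phase (radians) NIfTI pair."""
    aff = field_map.grid.affine
    data = np.moveaxis(field_map.values, 0, -1)  # (x, y, z, channel)
    nib.save(nib.Nifti1Image(np.abs(data), aff), str(path_mag))
    nib.save(nib.Nifti1Image(np.angle(data), aff), str(path_phase))


def read_channel_maps(path_mag, path_phase) -> ChannelFieldMap:
    """Assemble a complex channel map from a magnitude/phase NIfTI pair."""
    img_mag = nib.load(str(path_mag))
    img_phase = nib.load(str(path_phase))
    if img_mag.ndim != 4 or img_phase.ndim != 4:
        raise ValueError(
            f"channel maps must be 4-D (channel axis last): "
            f"{path_mag} is {img_mag.ndim}-D, {path_phase} is {img_phase.ndim}-D"
        )
    if img_mag.shape != img_phase.shape or not np.allclose(
        img_mag.affine, img_phase.affine, atol=1e-6
    ):
        raise ValueError(
            f"shape/affine mismatch between {path_mag} and {path_phase}"
        )
    mag = np.asarray(img_mag.dataobj, dtype=float)
    phase = np.asarray(img_phase.dataobj, dtype=float)
    values = np.moveaxis(mag * np.exp(1j * phase), -1, 0)
    return ChannelFieldMap(grid=_grid_from_image(img_mag), values=values)


def write_mask(mask: np.ndarray, grid: VoxelGrid, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), grid.affine), str(path))


def read_mask(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"mask {path} must be 3-D")
    return np.asarray(img.dataobj) > 0, _grid_from_image(img)


def write_fraction_map(frac_map: TissueFractionMap, path) -> None:
    data = np.moveaxis(frac_map.fractions, 0, -1)
    nib.save(nib.Nifti1Image(data, frac_map.grid.affine), str(path))


def read_fraction_map(path) -> TissueFractionMap:
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"fraction map {path} must be 4-D (class axis last)")
    fractions = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    return TissueFractionMap(grid=_grid_from_image(img), fractions=fractions)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


_SHIM_REQUIRED = ("n_channels", "mode", "weights")


def write_shim(
    shim: ShimVector,
    path,
    mode: str = "phase_magnitude",
    cost: float | None = None,
    constraint_report: dict | None = None,
    provenance: dict | None = None,
) -> None:
    payload = {
        "n_channels": shim.n_channels,
        "mode": mode,
        "weights": shim.to_mag_phase(),
        "cost": cost,
        "constraint_report": constraint_report,
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_shim(path) -> tuple[ShimVector, dict]:
    """Read a shim JSON; re-applies the global-phase convention."""
    payload = json.loads(Path(path).read_text())
    missing = [k for k in _SHIM_REQUIRED if k not in payload]
    if missing:
        raise ValueError(f"shim file {path} is missing fields: {missing}")
    shim = ShimVector.from_mag_phase(payload["weights"])
    if shim.n_channels != payload["n_channels"]:
        raise ValueError(
            f"shim file {path}: n_channels={payload['n_channels']} but "
            f"{shim.n_channels} weight entries"
        )
    shim = ShimVector(_normalize(shim.weights))
    meta = {k: v for k, v in payload.items() if k != "weights"}
    return shim, meta


def write_manifest(entries: list[dict], path) -> None:
    Path(path).write_text(json.dumps({"subjects": entries}, indent=2))


def read_manifest(path, check_files: bool = True) -> list[dict]:
    payload = json.loads(Path(path).read_text())
    entries = payload["subjects"]
    if check_files:
        root = Path(path).parent
        for e in entries:
            for key in ("magnitude", "phase", "roi_mask", "brain_mask", "head_mask"):
                if key in e and not (root / e[key]).exists():
                    raise FileNotFoundError(f"manifest references missing file {e[key]}")
    return entries
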