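"""OCT volumes: a stack of depth-by-lateral B-scan frames with physical pitches.

Convention throughout the OCT modules: the probe sits at z = 0 and z grows
with depth, so the corneal apex is the *minimum* z of the anterior surface.
Heights are micrometres internally; curvature radii are reported in mm.

Volumes round-trip as multi-frame grayscale TIFF plus a small YAML metadata
sidecar carrying the pitches, or as per-frame CSV rasters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml


@dataclass(frozen=True)
class OctVolume:
    """frames: (n_frames, n_z, n_x) intensity stack; pitches in µm per sample."""

    frames: np.ndarray
    axial_pitch: float
    lateral_pitch: float
    frame_pitch: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float32)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, n_z, n_x) stack")
        object.__setattr__(self, "frames", frames)
        for name in ("axial_pitch", "lateral_pitch", "frame_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_z(self) -> int:
        return self.frames.shape[1]

    @property
    def n_x(self) -> int:
        return self.frames.shape[2]

    def x_coords(self) -> np.ndarray:
        """Lateral sample positions in µm, centered on the frame."""
        return (np.arange(self.n_x) - (self.n_x - 1) / 2) * self.lateral_pitch

    def y_coords(self) -> np.ndarray:
        """Frame (slow-axis) positions in µm, centered on the stack."""
        return (np.arange(self.n_frames) - (self.n_frames - 1) / 2) * self.frame_pitch


def write_volume(volume: OctVolume, tiff_path: str | Path) -> Path:
    """Write a multi-frame grayscale TIFF and a ``.meta.yaml`` pitch sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(
        tiff_path, volume.frames.astype(np.float32), photometric="minisblack"
    )
    meta = {
        "axial_pitch_um": float(volume.axial_pitch),
        "lateral_pitch_um": float(volume.lateral_pitch),
        "frame_pitch_um": float(volume.frame_pitch),
    }
    sidecar = tiff_path.with_suffix(tiff_path.suffix + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return sidecar


def read_volume(tiff_path: str | Path) -> OctVolume:
    """Read a TIFF volume written by :func:`write_volume` (sidecar required)."""
    tiff_path = Path(tiff_path)
    sidecar = tiff_path.with_suffix(tiff_path.suffix + ".meta.yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    frames = np.asarray(tifffile.imread(tiff_path), dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    return OctVolume(
        frames=frames,
        axial_pitch=float(meta["axial_pitch_um"]),
        lateral_pitch=float(meta["lateral_pitch_um"]),
        frame_pitch=float(meta["frame_pitch_um"]),
    )


def read_frame_csv(csv_path: str | Path) -> np.ndarray:
    """Read one B-scan frame stored as a CSV intensity raster (rows = depth)."""
    return np.loadtxt(csv_path, delimiter=",", dtype=np.float32)


def write_frame_csv(frame: np.ndarray, csv_path: str | Path) -> None:
    np.savetxt(csv_path, np.asarray(frame, dtype=np.float32), delimiter=",", fmt="%.6g")
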