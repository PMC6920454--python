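"""Corneal boundary extraction from OCT B-scans.

Per column (A-scan), surfaces appear as bright axial bands.  The detector:

1. lightly smooths each A-scan axially,
2. estimates the background noise level robustly (median/MAD over the whole
   frame — surfaces occupy few rows, so the statistics are background-
   dominated),
3. takes local axial maxima exceeding ``median + k * sigma`` as candidate
   surface crossings,
4. assigns the first qualifying maximum from the probe side to the anterior
   cornea, the next at least ``min_separation_um`` deeper to the posterior
   cornea, and optionally a third to the anterior lens,
5. refines each to sub-pixel depth by parabolic interpolation,
6. masks columns with no qualifying pair of edges, interpolates their heights
   from neighbours, and smooths each boundary across columns with a
   Savitzky-Golay (local polynomial) filter.

Everything is vectorized across columns; no per-column Python loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import savgol_filter


class SegmentationError(ValueError):
    pass


class NoSurfaceFound(SegmentationError):
    """The frame contains no detectable surface (e.g. pure noise)."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Detector knobs.

    ``noise_k``: peak threshold in robust-noise units above the background
    median.  ``min_separation_um``: minimum axial gap between successive
    surfaces (must be below the corneal thickness scale, ~50 µm in mouse).
    ``boundary_smooth_window``/``poly``: Savitzky-Golay smoothing of each
    boundary across columns (window in columns, forced odd).
    ``min_valid_fraction``: below this fraction of usable columns a frame is
    declared surface-free.
    """

    noise_k: float = 5.0
    min_separation_um: float = 25.0
    axial_smooth_sigma_px: float = 1.0
    boundary_smooth_window: int = 11
    boundary_smooth_poly: int = 2
    min_valid_fraction: float = 0.3
    detect_lens: bool = True


@dataclass
class BscanBoundaries:
    """Per-column boundary heights in µm (NaN where undetected before fill)."""

    anterior_um: np.ndarray
    posterior_um: np.ndarray
    lens_um: np.ndarray | None
    valid: np.ndarray  # columns where both corneal surfaces were detected
    lens_valid: np.ndarray | None


def _first_peak(mask: np.ndarray, not_before: np.ndarray | None = None):
    """Index of the first True per column, optionally at/after ``not_before``."""
    n_z = mask.shape[0]
    if not_before is not None:
        rows = np.arange(n_z)[:, None]
        mask = mask & (rows >= not_before[None, :])
    found = mask.any(axis=0)
    idx = mask.argmax(axis=0)
    return np.where(found, idx, -1), found


def _parabolic_refine(smoothed: np.ndarray, idx: np.ndarray, found: np.ndarray):
    cols = np.arange(smoothed.shape[1])
    i = np.clip(idx, 1, smoothed.shape[0] - 2)
    y0 = smoothed[i - 1, cols]
    y1 = smoothed[i, cols]
    y2 = smoothed[i + 1, cols]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * (y0 - y2) / denom
    shift = np.where(np.isfinite(shift), np.clip(shift, -0.5, 0.5), 0.0)
    out = i + shift
    return np.where(found, out, np.nan)


def _fill_and_smooth(z: np.ndarray, valid: np.ndarray, cfg: SegmentationConfig):
    """Interpolate masked columns from valid neighbours, then smooth."""
    n_x = z.size
    filled = z.copy()
    idx = np.arange(n_x)
    if valid.sum() >= 2:
        filled[~valid] = np.interp(idx[~valid], idx[valid], z[valid])
    elif valid.sum() == 1:
        filled[:] = z[valid][0]
    window = min(cfg.boundary_smooth_window, n_x)
    if window % 2 == 0:
        window -= 1
    if window > cfg.boundary_smooth_poly + 1:
        filled = savgol_filter(filled, window, cfg.boundary_smooth_poly, mode="interp")
    return filled


def segment_bscan(
    frame: np.ndarray,
    axial_pitch: float,
    lateral_pitch: float,
    cfg: SegmentationConfig | None = None,
) -> BscanBoundaries:
    """Extract anterior/posterior corneal (and optionally lens) boundaries.

    Returns boundary heights in µm per lateral column.  Raises
    :class:`SegmentationError` when the frame is axially thinner than the
    required surface separation, and :class:`NoSurfaceFound` when fewer than
    ``min_valid_fraction`` of columns contain a qualifying surface pair.
    """
    cfg = cfg or SegmentationConfig()
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise SegmentationError("frame must be a 2-D depth-by-lateral raster")
    n_z, n_x = frame.shape
    sep_px = max(1, int(round(cfg.min_separation_um / axial_pitch)))
    if n_z <= sep_px:
        raise SegmentationError(
            f"frame depth {n_z} px is not deeper than the minimum surface "
            f"separation ({sep_px} px)"
        )

    smoothed = gaussian_filter1d(frame, cfg.axial_smooth_sigma_px, axis=0)
    med = np.median(smoothed)
    mad = np.median(np.abs(smoothed - med))
    sigma = 1.4826 * mad
    if sigma > 0:
        threshold = med + cfg.noise_k * sigma
    else:
        # Noise-free frame: any clearly-above-background maximum qualifies.
        span = smoothed.max() - med
        if span <= 0:
            raise NoSurfaceFound("frame is constant; no surface present")
        threshold = med + 0.05 * span

    interior = smoothed[1:-1]
    peaks = np.zeros_like(smoothed, dtype=bool)
    peaks[1:-1] = (
        (interior > smoothed[:-2])
        & (interior >= smoothed[2:])
        & (interior > threshold)
    )

    ant_idx, ant_found = _first_peak(peaks)
    post_idx, post_found = _first_peak(peaks, not_before=ant_idx + sep_px)
    valid = ant_found & post_found

    ant = _parabolic_refine(smoothed, ant_idx, valid) * axial_pitch
    post = _parabolic_refine(smoothed, post_idx, valid) * axial_pitch

    lens = lens_valid = None
    if cfg.detect_lens:
        lens_idx, lens_found = _first_peak(peaks, not_before=post_idx + sep_px)
        lens_valid = valid & lens_found
        lens = _parabolic_refine(smoothed, lens_idx, lens_valid) * axial_pitch

    if valid.mean() < cfg.min_valid_fraction:
        raise NoSurfaceFound(
            f"only {int(valid.sum())}/{n_x} columns contain a qualifying "
            "surface pair"
        )

    ant = _fill_and_smooth(ant, valid, cfg)
    post = _fill_and_smooth(post, valid, cfg)
    if lens is not None and lens_valid.sum() >= 2:
        lens = _fill_and_smooth(lens, lens_valid, cfg)
    return BscanBoundaries(
        anterior_um=ant,
        posterior_um=post,
        lens_um=lens,
        valid=valid,
        lens_valid=lens_valid,
    )


class VolumeRejectedError(RuntimeError):
    """Too many frames failed segmentation for the volume to be phenotyped."""


def segment_volume(
    volume,
    cfg: SegmentationConfig | None = None,
    max_failed_frame_fraction: float = 0.5,
):
    """Segment every frame of an :class:`~kerafam.oct.volume.OctVolume`.

    Returns ``(anterior, posterior, lens_or_None)`` as
    :class:`~kerafam.oct.surfaces.SurfaceSheet` objects.  Frames raising
    :class:`NoSurfaceFound` are fully masked; if more than
    ``max_failed_frame_fraction`` of frames fail, the volume is rejected
    with a diagnostic.
    """
    from .surfaces import SurfaceSheet

    cfg = cfg or SegmentationConfig()
    ny, _, nx = volume.frames.shape
    ant = np.full((ny, nx), np.nan)
    post = np.full((ny, nx), np.nan)
    lens = np.full((ny, nx), np.nan)
    ant_mask = np.zeros((ny, nx), dtype=bool)
    lens_mask = np.zeros((ny, nx), dtype=bool)
    n_failed = 0
    failures: list[str] = []
    for i in range(ny):
        try:
            b = segment_bscan(
                volume.frames[i], volume.axial_pitch, volume.lateral_pitch, cfg
            )
        except NoSurfaceFound as exc:
            n_failed += 1
            failures.append(f"frame {i}: {exc}")
            continue
        ant[i] = b.anterior_um
        post[i] = b.posterior_um
        ant_mask[i] = b.valid
        if b.lens_um is not None:
            lens[i] = b.lens_um
            lens_mask[i] = b.lens_valid
    if n_failed > max_failed_frame_fraction * ny:
        detail = "; ".join(failures[:3])
        raise VolumeRejectedError(
            f"{n_failed}/{ny} frames failed segmentation ({detail} ...)"
        )
    mk = dict(lateral_pitch=volume.lateral_pitch, frame_pitch=volume.frame_pitch)
    anterior = SurfaceSheet(z=ant, mask=ant_mask, label="anterior_cornea", **mk)
    posterior = SurfaceSheet(z=post, mask=ant_mask.copy(), label="posterior_cornea", **mk)
    lens_sheet = None
    if lens_mask.any():
        lens_sheet = SurfaceSheet(z=lens, mask=lens_mask, label="anterior_lens", **mk)
    return anterior, posterior, lens_sheet
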