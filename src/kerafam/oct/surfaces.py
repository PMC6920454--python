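"""Surface sheets and the geometric phenotype primitives.

A :class:`SurfaceSheet` is a boundary height field z(x, y) in µm on the
volume's lateral/frame grid (apex-up: smaller z is closer to the probe).
On top of it: pachymetry by direct z-axis subtraction, apex CCT/ACD,
least-squares sphere fitting, and instantaneous (tangential) curvature along
meridians, r_t = (1 + z'^2)^{3/2} / |z''|, with derivatives from local
polynomial fits — the corneal-topography convention for meridional power
maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.optimize import least_squares
from scipy.signal import savgol_filter


class SurfaceError(ValueError):
    pass


class DegenerateGeometryError(SurfaceError):
    """Point set is coplanar/collinear or too small to define a sphere."""


@dataclass
class SurfaceSheet:
    """Height field z(x, y) in µm with a validity mask.

    Grid spacing is inherited from the source volume: columns are spaced by
    ``lateral_pitch`` (x), rows/frames by ``frame_pitch`` (y); both grids are
    centered on zero.
    """

    z: np.ndarray  # (ny, nx) µm
    mask: np.ndarray  # True where the height is measured
    label: str
    lateral_pitch: float
    frame_pitch: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z.shape != self.mask.shape or self.z.ndim != 2:
            raise SurfaceError("z and mask must be matching 2-D arrays")
        if not np.isfinite(self.z[self.mask]).all():
            raise SurfaceError("z must be finite wherever the mask is valid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def x_coords(self) -> np.ndarray:
        nx = self.z.shape[1]
        return (np.arange(nx) - (nx - 1) / 2) * self.lateral_pitch

    def y_coords(self) -> np.ndarray:
        ny = self.z.shape[0]
        return (np.arange(ny) - (ny - 1) / 2) * self.frame_pitch

    def grids_match(self, other: "SurfaceSheet") -> bool:
        return (
            self.z.shape == other.z.shape
            and self.lateral_pitch == other.lateral_pitch
            and self.frame_pitch == other.frame_pitch
        )

    def points(self) -> np.ndarray:
        """Valid samples as an (N, 3) array of (x, y, z) in µm."""
        xx, yy = np.meshgrid(self.x_coords(), self.y_coords())
        return np.column_stack([xx[self.mask], yy[self.mask], self.z[self.mask]])

    def filled_z(self) -> np.ndarray:
        """z with invalid cells filled from their nearest valid neighbour."""
        if self.mask.all():
            return self.z.copy()
        if not self.mask.any():
            raise SurfaceError(f"{self.label}: no valid samples to fill from")
        _, (iy, ix) = distance_transform_edt(
            ~self.mask, return_distances=True, return_indices=True
        )
        return self.z[iy, ix]

    def apex(self, smooth_sigma: float = 1.0) -> tuple[int, int]:
        """Grid index (row, col) of the apex: the minimum of the smoothed
        sheet; ties break toward the grid centroid."""
        zs = gaussian_filter(self.filled_z(), smooth_sigma)
        zs[~self.mask] = np.inf
        zmin = zs.min()
        if not np.isfinite(zmin):
            raise SurfaceError(f"{self.label}: no valid samples")
        cand = np.argwhere(zs <= zmin + 1e-9)
        center = (np.array(self.z.shape) - 1) / 2
        d2 = ((cand - center) ** 2).sum(axis=1)
        iy, ix = cand[int(np.argmin(d2))]
        return int(iy), int(ix)


def pachymetry_map(anterior: SurfaceSheet, posterior: SurfaceSheet) -> np.ma.MaskedArray:
    """Corneal thickness by direct z-axis subtraction (posterior − anterior).

    Thickness is measured along z, not along the surface normal, matching
    how OCT pachymetry maps are assembled from layered boundary heights.
    """
    if not anterior.grids_match(posterior):
        raise SurfaceError("anterior and posterior sheets are on different grids")
    valid = anterior.mask & posterior.mask
    return np.ma.masked_array(posterior.z - anterior.z, mask=~valid)


def cct_and_acd(
    anterior: SurfaceSheet,
    posterior: SurfaceSheet,
    lens: SurfaceSheet | None = None,
) -> tuple[float, float | None]:
    """Central corneal thickness and anterior chamber depth at the apex (µm).

    The apex is the minimum of the smoothed anterior sheet.  ACD is the
    axial lens-to-endothelium distance at the apex column; it is ``None``
    (missing, never zero) when no lens surface is available there.
    """
    iy, ix = anterior.apex()
    thickness = pachymetry_map(anterior, posterior)
    if thickness.mask[iy, ix]:
        raise SurfaceError("apex column has no posterior measurement")
    cct = float(thickness[iy, ix])
    acd = None
    if lens is not None and lens.mask[iy, ix]:
        acd = float(lens.z[iy, ix] - posterior.z[iy, ix])
    return cct, acd


@dataclass(frozen=True)
class SphereFit:
    center_um: tuple[float, float, float]
    radius_um: float
    rms_um: float

    @property
    def radius_mm(self) -> float:
        return self.radius_um / 1000.0

    def z_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Height of the probe-facing (upper) hemisphere at (x, y), µm."""
        cx, cy, cz = self.center_um
        arg = self.radius_um**2 - (np.asarray(x) - cx) ** 2 - (np.asarray(y) - cy) ** 2
        with np.errstate(invalid="ignore"):
            return cz - np.sqrt(arg)


def fit_sphere(surface: SurfaceSheet | np.ndarray) -> SphereFit:
    """Least-squares sphere through a surface sheet or an (N, 3) point cloud.

    Algebraic (Coope) initialization solved by linear least squares, then
    iterative refinement of sum(|p - c| - R)^2.  Raises
    :class:`DegenerateGeometryError` for fewer than 4 points or a
    coplanar/collinear configuration.
    """
    pts = surface.points() if isinstance(surface, SurfaceSheet) else np.asarray(surface, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise SurfaceError("expected an (N, 3) point array")
    if len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 points to fit a sphere")
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    # Coplanarity shows up as rank deficiency of the centered coordinates.
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 3:
        raise DegenerateGeometryError("points are coplanar or collinear")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, cz, t = sol
    radius = float(np.sqrt(max(t + cx**2 + cy**2 + cz**2, 0.0)))

    def residual(params):
        c = params[:3]
        return np.linalg.norm(pts - c, axis=1) - params[3]

    fit = least_squares(residual, x0=[cx, cy, cz, radius], method="lm")
    cx, cy, cz, radius = fit.x
    rms = float(np.sqrt(np.mean(residual(fit.x) ** 2)))
    return SphereFit(center_um=(float(cx), float(cy), float(cz)), radius_um=float(radius), rms_um=rms)


@dataclass
class CurvatureMap:
    """Instantaneous (tangential) radius along meridians through the apex.

    ``radii_mm[j, i]`` is the radius at signed radial offset ``r_um[i]``
    along the meridian at ``angles_rad[j]`` (angles span half a turn; the
    signed offset covers the other half).  NaN marks samples outside the
    valid data.
    """

    radii_mm: np.ndarray
    angles_rad: np.ndarray
    r_um: np.ndarray
    apex_xy_um: tuple[float, float]

    def to_csv(self, path) -> None:
        header = "angle_rad," + ",".join(f"{r:.1f}" for r in self.r_um)
        rows = [header]
        for angle, radii in zip(self.angles_rad, self.radii_mm):
            rows.append(
                f"{angle:.6f}," + ",".join(f"{v:.6g}" for v in radii)
            )
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


def meridional_curvature(
    anterior: SurfaceSheet,
    n_meridians: int = 180,
    zone_radius_um: float | None = None,
    deriv_window: int = 11,
    deriv_poly: int = 4,
) -> CurvatureMap:
    """Tangential curvature map over the nominal optical zone.

    Profiles z(r) are resampled along ``n_meridians`` meridians through the
    apex (signed r, sample step = the lateral pitch); first and second
    derivatives come from local polynomial (Savitzky-Golay) fits; the
    instantaneous radius is (1 + z'^2)^{3/2} / |z''| in mm.  The default
    zone radius is one third of the mapped half-width.
    """
    x = anterior.x_coords()
    y = anterior.y_coords()
    half_width = min(abs(x[0]), abs(x[-1]), abs(y[0]), abs(y[-1]))
    if zone_radius_um is None:
        zone_radius_um = half_width / 3.0
    iy, ix = anterior.apex()
    x0, y0 = x[ix], y[iy]

    dr = anterior.lateral_pitch
    n_r = max(4, int(round(zone_radius_um / dr)))
    r = np.arange(-n_r, n_r + 1) * dr
    angles = np.arange(n_meridians) * np.pi / n_meridians

    px = x0 + r[None, :] * np.cos(angles)[:, None]
    py = y0 + r[None, :] * np.sin(angles)[:, None]
    inside = (px >= x[0]) & (px <= x[-1]) & (py >= y[0]) & (py <= y[-1])
    if not inside.all():
        warnings.warn(
            "optical zone exceeds the mapped area; outside sectors are masked",
            stacklevel=2,
        )

    # Cubic interpolation: a C1 surface keeps second derivatives clean;
    # bilinear kinks would corrupt z'' at the grid scale.  Query points are
    # clamped to the grid; out-of-zone samples are masked via ``inside``.
    interp = RegularGridInterpolator((y, x), anterior.filled_z(), method="cubic")
    valid_interp = RegularGridInterpolator(
        (y, x), anterior.mask.astype(float), method="nearest"
    )
    pts = np.stack(
        [np.clip(py, y[0], y[-1]), np.clip(px, x[0], x[-1])], axis=-1
    )
    z = interp(pts)
    measured = valid_interp(pts) > 0.5
    ok = inside & measured

    window = min(deriv_window, z.shape[1])
    if window % 2 == 0:
        window -= 1
    poly = min(deriv_poly, window - 1)
    dz = savgol_filter(z, window, poly, deriv=1, delta=dr, axis=1, mode="interp")
    d2z = savgol_filter(z, window, poly, deriv=2, delta=dr, axis=1, mode="interp")
    with np.errstate(divide="ignore", invalid="ignore"):
        radii_um = (1.0 + dz**2) ** 1.5 / np.abs(d2z)
    radii_mm = np.where(ok, radii_um / 1000.0, np.nan)
    return CurvatureMap(
        radii_mm=radii_mm, angles_rad=angles, r_um=r, apex_xy_um=(float(x0), float(y0))
    )
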