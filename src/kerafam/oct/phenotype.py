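"""Whole-volume corneal phenotyping: CCT, ACD, pachymetry, curvature,
sphere radius, and the anterior-surface irregularity call.

The irregularity score operationalizes "irregular anterior surface" as the
RMS deviation of the measured anterior sheet from its best-fit sphere over
the optical zone; the flag trips when the score exceeds a threshold set to
``irregularity_k`` times the segmentation noise floor.  This is an explicit
quantitative criterion, not a claim of equivalence to any expert's visual
judgement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import SegmentationConfig, segment_volume
from .surfaces import (
    CurvatureMap,
    SphereFit,
    SurfaceSheet,
    cct_and_acd,
    fit_sphere,
    meridional_curvature,
    pachymetry_map,
)
from .volume import OctVolume


@dataclass
class PhenotypeConfig:
    """Phenotyping knobs.

    Optical-path lengths are reported as-is by default (no refractive-index
    correction); enabling ``refractive_correction`` divides corneal
    thicknesses and ACD by ``group_index``.  The optical zone defaults to
    one third of the mapped half-width.  The irregularity threshold is
    ``irregularity_k`` x ``noise_floor_um`` (default 3 x 1 µm: three times
    the sub-pixel boundary jitter the segmenter leaves after smoothing).
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    zone_radius_um: float | None = None  # None = one third of half-width
    n_meridians: int = 180
    deriv_window: int = 11
    deriv_poly: int = 4
    noise_floor_um: float = 1.0
    irregularity_k: float = 3.0
    refractive_correction: bool = False
    group_index: float = 1.4
    max_failed_frame_fraction: float = 0.5
    compute_curvature: bool = True

    @property
    def irregularity_threshold_um(self) -> float:
        return self.irregularity_k * self.noise_floor_um


@dataclass(frozen=True)
class IrregularityResult:
    score_um: float
    threshold_um: float

    @property
    def irregular(self) -> bool:
        return self.score_um > self.threshold_um


@dataclass
class CornealPhenotype:
    """All phenotype quantities for one volume."""

    cct_um: float
    acd_um: float | None
    r_c_mm: float
    sphere_fit: SphereFit
    pachymetry_um: np.ma.MaskedArray
    curvature_map: CurvatureMap | None
    irregularity_score_um: float
    irregular: bool

    def summary(self) -> str:
        acd = f"{self.acd_um:.1f}" if self.acd_um is not None else "missing"
        flag = "IRREGULAR" if self.irregular else "regular"
        return (
            f"CCT {self.cct_um:.1f} um | ACD {acd} um | "
            f"R_c {self.r_c_mm:.3f} mm | surface {flag} "
            f"(score {self.irregularity_score_um:.2f} um)"
        )


def _zone_mask(sheet: SurfaceSheet, zone_radius_um: float | None) -> np.ndarray:
    x = sheet.x_coords()
    y = sheet.y_coords()
    half_width = min(abs(x[0]), abs(x[-1]), abs(y[0]), abs(y[-1]))
    if zone_radius_um is None:
        zone_radius_um = half_width / 3.0
    iy, ix = sheet.apex()
    xx, yy = np.meshgrid(x - x[ix], y - y[iy])
    return sheet.mask & (xx**2 + yy**2 <= zone_radius_um**2)


def irregularity_call(
    anterior: SurfaceSheet, cfg: PhenotypeConfig | None = None
) -> IrregularityResult:
    """Anterior-surface irregularity: RMS deviation from the best-fit sphere
    over the optical zone, flagged above the configured threshold."""
    cfg = cfg or PhenotypeConfig()
    fit = fit_sphere(anterior)
    zone = _zone_mask(anterior, cfg.zone_radius_um)
    xx, yy = np.meshgrid(anterior.x_coords(), anterior.y_coords())
    model = fit.z_at(xx[zone], yy[zone])
    resid = anterior.z[zone] - model
    resid = resid[np.isfinite(resid)]
    if resid.size == 0:
        raise ValueError("optical zone contains no valid residuals")
    score = float(np.sqrt(np.mean(resid**2)))
    return IrregularityResult(score_um=score, threshold_um=cfg.irregularity_threshold_um)


def detect_irregularity(
    volume: OctVolume, cfg: PhenotypeConfig | None = None
) -> IrregularityResult:
    """Segment a volume and score anterior-surface irregularity only.

    The light path for cohort screening: skips pachymetry/curvature maps.
    """
    cfg = cfg or PhenotypeConfig()
    anterior, _, _ = segment_volume(
        volume, cfg.segmentation, cfg.max_failed_frame_fraction
    )
    return irregularity_call(anterior, cfg)


def phenotype_volume(volume: OctVolume, cfg: PhenotypeConfig | None = None) -> CornealPhenotype:
    """Segment a volume and compute every phenotype quantity.

    Deterministic for fixed input and configuration.  Raises
    :class:`~kerafam.oct.segmentation.VolumeRejectedError` when too many
    frames fail segmentation.
    """
    cfg = cfg or PhenotypeConfig()
    anterior, posterior, lens = segment_volume(
        volume, cfg.segmentation, cfg.max_failed_frame_fraction
    )
    cct, acd = cct_and_acd(anterior, posterior, lens)
    pachy = pachymetry_map(anterior, posterior)
    if cfg.refractive_correction:
        cct /= cfg.group_index
        pachy = pachy / cfg.group_index
        if acd is not None:
            acd /= cfg.group_index
    fit = fit_sphere(anterior)
    irr = irregularity_call(anterior, cfg)
    curvature = None
    if cfg.compute_curvature:
        curvature = meridional_curvature(
            anterior,
            n_meridians=cfg.n_meridians,
            zone_radius_um=cfg.zone_radius_um,
            deriv_window=cfg.deriv_window,
            deriv_poly=cfg.deriv_poly,
        )
    return CornealPhenotype(
        cct_um=float(cct),
        acd_um=None if acd is None else float(acd),
        r_c_mm=fit.radius_mm,
        sphere_fit=fit,
        pachymetry_um=pachy,
        curvature_map=curvature,
        irregularity_score_um=irr.score_um,
        irregular=irr.irregular,
    )
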