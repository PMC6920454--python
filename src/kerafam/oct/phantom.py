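"""Parametric mouse anterior-segment phantoms and OCT volume rendering.

The default geometry echoes the murine scale: anterior corneal sphere of
radius 1.5 mm, concentric posterior sphere of 1.45 mm (50 µm apical
thickness), anterior chamber depth 300 µm to a 1.4 mm lens sphere.  These
are documented fixture choices for testing the phenotyping pipeline, not
measurements of any real animal.

Lesions model the mutant phenotypes qualitatively: ``epithelial_bump``
(localized anterior elevation — the irregular-surface phenotype),
``thinning_cone`` (localized posterior-side thinning, ectasia-like), and
``diffuse_thinning`` (global proportional thinning).  Localized lesions use
a Gaussian footprint with scale ``width_um``.

Rendering places a Gaussian axial point-spread bright band at each surface
crossing, adds Gaussian background noise and optional multiplicative
speckle; it is deterministic for a fixed seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .volume import OctVolume


class PhantomError(ValueError):
    pass


class LesionKind(str, enum.Enum):
    THINNING_CONE = "thinning_cone"
    EPITHELIAL_BUMP = "epithelial_bump"
    DIFFUSE_THINNING = "diffuse_thinning"


@dataclass(frozen=True)
class LesionSpec:
    """One lesion: kind, lateral center, Gaussian width, signed amplitude.

    Amplitude is in µm for the localized kinds (positive bump height /
    negative thinning depth) and a signed *fraction* for
    ``diffuse_thinning`` (-0.2 = 20% thinner everywhere).
    """

    kind: LesionKind
    center_xy_um: tuple[float, float] = (0.0, 0.0)
    width_um: float = 100.0
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", LesionKind(self.kind))
        if self.width_um <= 0:
            raise PhantomError("lesion width must be positive")


@dataclass(frozen=True)
class CorneaPhantomSpec:
    """Ground-truth geometry parameters (µm)."""

    anterior_radius_um: float = 1500.0
    posterior_radius_um: float = 1450.0  # concentric with the anterior sphere
    apex_z_um: float = 100.0
    acd_um: float = 300.0
    lens_radius_um: float = 1400.0
    tilt_deg: tuple[float, float] = (0.0, 0.0)  # rotations about x and y
    lesions: tuple[LesionSpec, ...] = ()
    extent_um: float = 700.0  # half-width over which validity is enforced


class CorneaPhantom:
    """Analytic truth surfaces z_ant(x, y), z_post(x, y), z_lens(x, y).

    Tilt is applied as the lateral apex displacement a small rigid rotation
    about the anterior apex induces on the spherical surfaces.
    """

    def __init__(self, spec: CorneaPhantomSpec):
        self.spec = spec
        tx, ty = np.deg2rad(spec.tilt_deg)
        r_a = spec.anterior_radius_um
        # Rotating a sphere about its apex moves the center off-axis.
        self._cx = r_a * np.sin(ty)
        self._cy = r_a * np.sin(tx)
        self._cz = spec.apex_z_um + r_a * np.cos(tx) * np.cos(ty)

    # -- truth surfaces -----------------------------------------------------
    def _sphere_upper(self, x, y, radius: float) -> np.ndarray:
        arg = radius**2 - (np.asarray(x, float) - self._cx) ** 2 - (
            np.asarray(y, float) - self._cy
        ) ** 2
        if np.any(arg <= 0):
            raise PhantomError("queried point outside the phantom's lateral extent")
        return self._cz - np.sqrt(arg)

    def _lesion_bump(self, x, y) -> np.ndarray:
        """Anterior elevation (µm, toward the probe) from bump lesions."""
        out = np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape)
        for lesion in self.spec.lesions:
            if lesion.kind is not LesionKind.EPITHELIAL_BUMP:
                continue
            d2 = (np.asarray(x) - lesion.center_xy_um[0]) ** 2 + (
                np.asarray(y) - lesion.center_xy_um[1]
            ) ** 2
            out = out + lesion.amplitude * np.exp(-d2 / (2 * lesion.width_um**2))
        return out

    def _thickness_delta(self, x, y, base: np.ndarray) -> np.ndarray:
        """Signed change to corneal thickness from thinning lesions."""
        delta = np.zeros_like(base)
        for lesion in self.spec.lesions:
            if lesion.kind is LesionKind.THINNING_CONE:
                d2 = (np.asarray(x) - lesion.center_xy_um[0]) ** 2 + (
                    np.asarray(y) - lesion.center_xy_um[1]
                ) ** 2
                delta = delta + lesion.amplitude * np.exp(
                    -d2 / (2 * lesion.width_um**2)
                )
            elif lesion.kind is LesionKind.DIFFUSE_THINNING:
                delta = delta + lesion.amplitude * base
        return delta

    def z_anterior(self, x, y) -> np.ndarray:
        return self._sphere_upper(x, y, self.spec.anterior_radius_um) - self._lesion_bump(
            x, y
        )

    def z_posterior(self, x, y) -> np.ndarray:
        base_ant = self._sphere_upper(x, y, self.spec.anterior_radius_um)
        base_post = self._sphere_upper(x, y, self.spec.posterior_radius_um)
        base_thick = base_post - base_ant
        return base_post + self._thickness_delta(x, y, base_thick)

    def thickness(self, x, y) -> np.ndarray:
        """Axial (z-subtraction) corneal thickness truth, µm.

        A bump raises the anterior surface toward the probe, so the axial
        thickness under the bump grows by the bump height.
        """
        return self.z_posterior(x, y) - self.z_anterior(x, y)

    def z_lens(self, x, y) -> np.ndarray:
        apex_post = self.spec.apex_z_um + (
            self.spec.anterior_radius_um - self.spec.posterior_radius_um
        )
        lens_apex = apex_post + self.spec.acd_um
        r_l = self.spec.lens_radius_um
        arg = r_l**2 - (np.asarray(x, float) - self._cx) ** 2 - (
            np.asarray(y, float) - self._cy
        ) ** 2
        out = np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape, np.nan)
        good = arg > 0
        out[good] = lens_apex + r_l - np.sqrt(np.asarray(arg)[good])
        return out


def make_phantom(spec: CorneaPhantomSpec | None = None) -> CorneaPhantom:
    """Build a phantom and verify the thickness stays positive everywhere
    inside the stated lateral extent."""
    spec = spec or CorneaPhantomSpec()
    if spec.anterior_radius_um <= 0 or spec.posterior_radius_um <= 0:
        raise PhantomError("radii must be positive")
    phantom = CorneaPhantom(spec)
    g = np.linspace(-spec.extent_um, spec.extent_um, 41)
    xx, yy = np.meshgrid(g, g)
    thickness = phantom.thickness(xx, yy)
    if np.any(thickness <= 0):
        raise PhantomError(
            f"lesions drive corneal thickness non-positive "
            f"(min {thickness.min():.1f} um)"
        )
    return phantom


@dataclass(frozen=True)
class RenderParams:
    """Rendering geometry and noise (pitches in µm; seed fixes all noise)."""

    axial_pitch: float = 2.0
    lateral_pitch: float = 15.0
    frame_pitch: float = 30.0
    n_z: int = 384
    n_x: int = 96
    n_frames: int = 48
    surface_brightness: float = 1.0
    noise_sigma: float = 0.05
    psf_fwhm_um: float = 8.0
    speckle: bool = False
    seed: int = 0


def render_volume(phantom: CorneaPhantom, rp: RenderParams | None = None) -> OctVolume:
    """Render a noisy OCT volume of a phantom.

    Raises :class:`PhantomError` when a corneal surface leaves the axial
    field of view anywhere in the rendered area; the lens band is clipped
    silently where it exits (as in real anterior-segment scans).
    """
    rp = rp or RenderParams()
    x = (np.arange(rp.n_x) - (rp.n_x - 1) / 2) * rp.lateral_pitch
    y = (np.arange(rp.n_frames) - (rp.n_frames - 1) / 2) * rp.frame_pitch
    z = np.arange(rp.n_z) * rp.axial_pitch
    xx, yy = np.meshgrid(x, y)
    z_ant = phantom.z_anterior(xx, yy)
    z_post = phantom.z_posterior(xx, yy)
    z_lens = phantom.z_lens(xx, yy)
    z_max = z[-1]
    for name, zs in (("anterior", z_ant), ("posterior", z_post)):
        if np.nanmin(zs) < 0 or np.nanmax(zs) > z_max:
            raise PhantomError(f"{name} cornea surface leaves the axial field of view")

    sigma_psf = rp.psf_fwhm_um / 2.3548200450309493  # FWHM -> Gaussian sigma
    rng = np.random.default_rng(rp.seed)
    frames = np.empty((rp.n_frames, rp.n_z, rp.n_x), dtype=np.float32)
    zcol = z[:, None]
    for i in range(rp.n_frames):
        signal = np.zeros((rp.n_z, rp.n_x))
        for zs in (z_ant[i], z_post[i], z_lens[i]):
            good = np.isfinite(zs)
            if not good.any():
                continue
            band = np.zeros((rp.n_z, rp.n_x))
            band[:, good] = np.exp(-((zcol - zs[good][None, :]) ** 2) / (2 * sigma_psf**2))
            signal += rp.surface_brightness * band
        if rp.speckle:
            signal = signal * rng.exponential(1.0, size=signal.shape)
        frame = signal + rng.normal(0.0, rp.noise_sigma, size=signal.shape)
        frames[i] = frame.astype(np.float32)
    return OctVolume(
        frames=frames,
        axial_pitch=rp.axial_pitch,
        lateral_pitch=rp.lateral_pitch,
        frame_pitch=rp.frame_pitch,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortSubject:
    """One simulated animal: its group, true lesion status, and phantom.

    Volumes are rendered lazily via :meth:`render` so large cohorts do not
    hold hundreds of rendered stacks in memory at once.
    """

    subject_id: str
    group: str
    lesioned: bool
    phantom: CorneaPhantom
    render_seed: int

    def render(self, rp: RenderParams | None = None) -> OctVolume:
        rp = rp or RenderParams()
        return render_volume(self.phantom, replace(rp, seed=self.render_seed))


def default_lesion_law(rng: np.random.Generator) -> LesionSpec:
    """Random anterior-surface lesion: a localized epithelial bump with
    amplitude 15-30 µm, width 80-150 µm, centered inside the optical zone."""
    angle = rng.uniform(0, 2 * np.pi)
    radius = rng.uniform(0, 150.0)
    return LesionSpec(
        kind=LesionKind.EPITHELIAL_BUMP,
        center_xy_um=(radius * np.cos(angle), radius * np.sin(angle)),
        width_um=rng.uniform(80.0, 150.0),
        amplitude=rng.uniform(15.0, 30.0),
    )


def simulate_mouse_cohort(
    n_per_group: dict[str, int],
    prevalence_per_group: dict[str, float],
    lesion_law=None,
    seed: int = 0,
    base_spec: CorneaPhantomSpec | None = None,
) -> list[CohortSubject]:
    """Simulate a lesion-prevalence cohort across genotype groups.

    Each subject is independently lesioned with its group's prevalence; the
    truth label is recorded on the subject.  ``lesion_law`` maps an RNG to a
    :class:`LesionSpec` (default: :func:`default_lesion_law`).
    """
    lesion_law = lesion_law or default_lesion_law
    base_spec = base_spec or CorneaPhantomSpec()
    for group, prevalence in prevalence_per_group.items():
        if not 0.0 <= prevalence <= 1.0:
            raise PhantomError(f"prevalence for group {group!r} outside [0, 1]")
    rng = np.random.default_rng([int(seed) % (2**31), 77])
    subjects: list[CohortSubject] = []
    for group, n in n_per_group.items():
        prevalence = prevalence_per_group[group]
        for j in range(n):
            lesioned = bool(rng.random() < prevalence)
            lesions = (lesion_law(rng),) if lesioned else ()
            spec = replace(base_spec, lesions=lesions)
            subjects.append(
                CohortSubject(
                    subject_id=f"{group}_{j:03d}",
                    group=group,
                    lesioned=lesioned,
                    phantom=make_phantom(spec),
                    render_seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return subjects


def cohort_truth_table(subjects: list[CohortSubject]):
    """Truth labels as a DataFrame (subject, group, lesioned)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "lesioned": [s.lesioned for s in subjects],
        }
    )
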