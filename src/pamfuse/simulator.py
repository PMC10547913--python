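"""Synthetic multi-focus OR-PAM focal stacks.

Emulates a virtual optical-resolution photoacoustic microscope on a
120×120×120 grid with (2, 2, 3) µm voxels: absorbing tube phantoms
(tilted fibers or vessel-tree segments) are rendered as antialiased
capsules, each depth plane is blurred laterally with the depth-dependent
Gaussian-beam point-spread function, and calibrated zero-mean Gaussian
noise is added.

The excitation beam is a Gaussian beam of numerical aperture NA and
wavelength λ with waist

    w0 = λ / (π · NA),        zR = π · w0² / λ,
    w(z) = w0 · sqrt(1 + ((z − zf) / zR)²),

where zf is the focal depth.  The lateral PSF at depth z is an isotropic
2D Gaussian of 1/e² radius w(z), i.e. standard deviation w(z)/2.  By
default each plane is additionally scaled by the fluence factor
(w0/w(z))², so amplitude — like in a real OR-PAM stack — decays away from
the focal plane.  An optional fixed axial Gaussian blur stands in for the
finite detection bandwidth; full acoustic propagation is deliberately not
modelled, since the fusion method detects lateral focus/defocus, which is
governed by the optical beam alone.

SNR is peak-referenced: snr_db = 20·log10(max(P) / σ_noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .volume_io import DEFAULT_SPACING, ValidationError, Volume

#: Default grid of the virtual microscope.
DEFAULT_SHAPE = (120, 120, 120)

#: PSF kernels are truncated at this many standard deviations and the
#: discrete taps renormalized, bounding the truncation error.
PSF_TRUNCATE = 4.0


@dataclass(frozen=True)
class BeamModel:
    """Gaussian excitation beam of the virtual microscope."""

    na: float = 0.14
    wavelength_um: float = 0.532
    focal_depth_um: float = 0.0
    amplitude_weighting: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.na < 1.0:
            raise ValidationError(f"numerical aperture must be in (0, 1), got {self.na}")
        if self.wavelength_um <= 0:
            raise ValidationError(f"wavelength must be > 0, got {self.wavelength_um}")

    @property
    def waist_um(self) -> float:
        """Beam waist w0 = λ/(π·NA)."""
        return self.wavelength_um / (math.pi * self.na)

    @property
    def rayleigh_um(self) -> float:
        """Rayleigh range zR = π·w0²/λ."""
        return math.pi * self.waist_um**2 / self.wavelength_um

    def radius_um(self, z_um: float | np.ndarray) -> float | np.ndarray:
        """1/e² beam radius w(z) at depth z (µm from the volume top)."""
        u = (np.asarray(z_um, dtype=np.float64) - self.focal_depth_um) / self.rayleigh_um
        return self.waist_um * np.sqrt(1.0 + u**2)

    def psf_sigma_um(self, z_um: float | np.ndarray) -> float | np.ndarray:
        """Standard deviation of the lateral Gaussian PSF at depth z."""
        return self.radius_um(z_um) / 2.0

    def fluence_weight(self, z_um: float | np.ndarray) -> float | np.ndarray:
        """(w0/w(z))² amplitude factor applied when weighting is enabled."""
        return (self.waist_um / self.radius_um(z_um)) ** 2


@dataclass(frozen=True)
class FiberSpec:
    """A straight absorbing tube (capsule): endpoints in voxel coordinates,
    diameter in µm."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    diameter_um: float = 6.0


@dataclass(frozen=True)
class PhantomSpec:
    """Absorber geometry on a voxel grid.

    ``kind`` is ``"tilted_fiber"`` (straight tubes) or ``"vessel_tree"``
    (a list of branch segments); both are rendered as unions of capsules.
    """

    kind: str = "tilted_fiber"
    segments: tuple[FiberSpec, ...] = ()
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        if self.kind not in ("tilted_fiber", "vessel_tree"):
            raise ValidationError(f"unknown phantom kind {self.kind!r}")
        pitch = min(self.spacing)
        for seg in self.segments:
            for pt in (seg.start, seg.end):
                if not all(0 <= c <= s - 1 for c, s in zip(pt, self.shape)):
                    raise ValidationError(
                        f"segment endpoint {pt} lies outside grid of shape {self.shape}"
                    )
            if seg.diameter_um < pitch:
                raise ValidationError(
                    f"segment diameter {seg.diameter_um} µm below one voxel "
                    f"pitch ({pitch} µm)"
                )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise at a peak-referenced SNR.

    ``snr_db=None`` means no noise.  The noise standard deviation is
    ``max(P) / 10**(snr_db/20)``.
    """

    snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            object.__setattr__(self, "snr_db", None)


def render_phantom(spec: PhantomSpec) -> Volume:
    """Rasterize the phantom: amplitude 1 inside the tubes, antialiased
    edge over about one lateral voxel, 0 outside.

    Distances are computed in physical µm so the anisotropic z pitch is
    honoured; overlapping segments take the voxel-wise maximum.
    """
    data = np.zeros(spec.shape, dtype=np.float64)
    sx, sy, sz = spec.spacing
    edge = min(sx, sy)  # soft-edge width, <= 1 lateral voxel
    scale = np.array(spec.spacing, dtype=np.float64)
    for seg in spec.segments:
        a = np.asarray(seg.start, dtype=np.float64) * scale
        b = np.asarray(seg.end, dtype=np.float64) * scale
        r = seg.diameter_um / 2.0
        reach = r + edge  # µm beyond which the segment contributes nothing
        lo = np.maximum(np.floor((np.minimum(a, b) - reach) / scale), 0).astype(int)
        hi = np.minimum(
            np.ceil((np.maximum(a, b) + reach) / scale) + 1, spec.shape
        ).astype(int)
        grids = np.meshgrid(
            *(np.arange(lo[i], hi[i]) * scale[i] for i in range(3)), indexing="ij"
        )
        pts = np.stack(grids, axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        t = ((pts - a) @ ab) / denom if denom > 0 else np.zeros(pts.shape[:-1])
        t = np.clip(t, 0.0, 1.0)
        nearest = a + t[..., None] * ab
        dist = np.linalg.norm(pts - nearest, axis=-1)
        amp = np.clip((r + edge / 2.0 - dist) / edge, 0.0, 1.0)
        sub = tuple(slice(lo[i], hi[i]) for i in range(3))
        np.maximum(data[sub], amp, out=data[sub])
    return Volume(data=data, spacing=spec.spacing)


def apply_focal_blur(
    truth: Volume, beam: BeamModel, axial_sigma_um: float | None = None
) -> Volume:
    """Blur each z-plane with the depth-dependent lateral Gaussian PSF.

    The kernel per plane is an isotropic (in µm) 2D Gaussian of standard
    deviation w(z)/2, truncated at 4σ and renormalized; with
    ``amplitude_weighting`` the plane is additionally scaled by (w0/w(z))².
    ``axial_sigma_um`` applies an optional fixed Gaussian blur along z
    emulating finite detector bandwidth.
    """
    dx, dy, dz = truth.spacing
    out = np.empty_like(truth.data, dtype=np.float64)
    for k in range(truth.nz):
        sigma_um = float(beam.psf_sigma_um(k * dz))
        plane = gaussian_filter(
            truth.data[:, :, k].astype(np.float64),
            sigma=(sigma_um / dx, sigma_um / dy),
            truncate=PSF_TRUNCATE,
            mode="constant",
        )
        if beam.amplitude_weighting:
            plane *= float(beam.fluence_weight(k * dz))
        out[:, :, k] = plane
    if axial_sigma_um is not None and axial_sigma_um > 0:
        out = gaussian_filter1d(
            out, sigma=axial_sigma_um / dz, axis=2, truncate=PSF_TRUNCATE,
            mode="constant",
        )
    return truth.with_data(out)


def add_noise(v: Volume, noise: NoiseSpec) -> Volume:
    """Add i.i.d. zero-mean Gaussian noise at the requested peak SNR."""
    if noise.snr_db is None:
        return v
    peak = float(np.max(v.data))
    if peak <= 0:
        raise ValidationError("finite SNR requires a volume with positive peak")
    sigma = peak / 10.0 ** (noise.snr_db / 20.0)
    rng = np.random.default_rng(noise.seed)
    return v.with_data(v.data + rng.normal(0.0, sigma, size=v.shape))


def default_fiber_phantom(
    diameter_um: float = 6.0,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> PhantomSpec:
    """Two vertically tilted fibers spanning nearly the full depth range.

    Both fibers tilt in the x–z plane (opposite directions) at constant y,
    so the lateral line perpendicular to each fiber's lateral drift is the
    y axis — the profile direction used for FWHM measurements.
    """
    nx, ny, nz = shape
    x_lo, x_hi = round(0.25 * nx), round(0.75 * nx)
    z_lo, z_hi = round(0.04 * nz), round(0.96 * nz)
    y1, y2 = round(ny / 3), round(2 * ny / 3)
    return PhantomSpec(
        kind="tilted_fiber",
        segments=(
            FiberSpec((x_lo, y1, z_lo), (x_hi, y1, z_hi), diameter_um),
            FiberSpec((x_hi, y2, z_lo), (x_lo, y2, z_hi), diameter_um),
        ),
        shape=shape,
        spacing=spacing,
    )


def fiber_trajectory(spec: PhantomSpec, segment_index: int = 0) -> np.ndarray:
    """Per-z-plane lateral centre ``(x, y)`` of one straight segment.

    Returns an ``(Nz, 2)`` float array; planes outside the segment's depth
    extent are NaN (no structure to measure there).
    """
    seg = spec.segments[segment_index]
    nz = spec.shape[2]
    traj = np.full((nz, 2), np.nan)
    z0, z1 = seg.start[2], seg.end[2]
    if z1 < z0:
        z0, z1 = z1, z0
    dz_span = seg.end[2] - seg.start[2]
    for k in range(nz):
        if z0 - 0.5 <= k <= z1 + 0.5:
            t = 0.0 if dz_span == 0 else (k - seg.start[2]) / dz_span
            t = min(max(t, 0.0), 1.0)
            traj[k, 0] = seg.start[0] + t * (seg.end[0] - seg.start[0])
            traj[k, 1] = seg.start[1] + t * (seg.end[1] - seg.start[1])
    return traj


@dataclass(frozen=True)
class SimulationResult:
    """Multi-focus stack plus ground truth.

    ``volumes`` are the observed (blurred + noisy) stacks, one per focus;
    ``clean`` are the same stacks before noise; ``labels`` assigns each
    voxel the index of the focus whose focal plane is nearest in z (ties
    go to the shallower focus, as recorded in the manifest).
    """

    truth: Volume
    clean: list[Volume]
    volumes: list[Volume]
    labels: np.ndarray
    focal_planes: tuple[int, ...]
    manifest: dict


def simulate_multifocus(
    spec: PhantomSpec,
    focal_planes: tuple[int, ...] = (40, 60),
    beam: BeamModel | None = None,
    noise: NoiseSpec | None = None,
    axial_sigma_voxels: float | None = 2.0,
    master_seed: int = 0,
) -> SimulationResult:
    """Simulate one blurred (+ optionally noisy) volume per focal plane.

    ``beam`` supplies NA, wavelength and the weighting flag; its focal
    depth is replaced per focus.  Noise seeds are derived per volume from
    ``(master_seed, focus_index)`` so stacks are reproducible and
    independent.  ``axial_sigma_voxels`` is the detector-bandwidth blur in
    z-voxels (default 2; ``None`` disables it).
    """
    if len(focal_planes) < 2:
        raise ValidationError(f"need >= 2 focal planes, got {len(focal_planes)}")
    nz = spec.shape[2]
    for fp in focal_planes:
        if not 0 <= fp < nz:
            raise ValidationError(f"focal plane {fp} outside grid depth [0, {nz})")
    beam = beam or BeamModel()
    dz = spec.spacing[2]
    axial_um = None if axial_sigma_voxels is None else axial_sigma_voxels * dz

    truth = render_phantom(spec)
    clean, volumes, seeds = [], [], []
    for i, fp in enumerate(focal_planes):
        focused = replace(beam, focal_depth_um=fp * dz)
        blurred = apply_focal_blur(truth, focused, axial_sigma_um=axial_um)
        clean.append(blurred)
        if noise is not None and noise.snr_db is not None:
            seed = int(np.random.SeedSequence((master_seed, i)).generate_state(1)[0])
            seed %= 2**31
            volumes.append(add_noise(blurred, NoiseSpec(noise.snr_db, seed)))
            seeds.append(seed)
        else:
            volumes.append(blurred)
            seeds.append(None)

    z_idx = np.arange(nz)
    dist = np.abs(z_idx[None, :] - np.asarray(focal_planes)[:, None])
    nearest = np.argmin(dist, axis=0)  # argmin ties -> lower focus index
    labels = np.broadcast_to(nearest, spec.shape).copy()

    manifest = {
        "phantom_kind": spec.kind,
        "shape": list(spec.shape),
        "spacing_um": list(spec.spacing),
        "focal_planes": list(focal_planes),
        "beam": {
            "na": beam.na,
            "wavelength_um": beam.wavelength_um,
            "amplitude_weighting": beam.amplitude_weighting,
            "waist_um": beam.waist_um,
            "rayleigh_um": beam.rayleigh_um,
        },
        "axial_sigma_voxels": axial_sigma_voxels,
        "snr_db": None if noise is None else noise.snr_db,
        "master_seed": master_seed,
        "per_volume_seeds": seeds,
        "label_tie_rule": "equidistant voxels assigned to the shallower focus",
    }
    return SimulationResult(
        truth=truth,
        clean=clean,
        volumes=volumes,
        labels=labels,
        focal_planes=tuple(focal_planes),
        manifest=manifest,
    )
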