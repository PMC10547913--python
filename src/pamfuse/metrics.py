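"""Resolution, depth-of-field, SNR and fusion-quality metrics.

Lateral resolution is measured per depth plane as the full width at half
maximum (FWHM) of the line profile through the structure's centre,
perpendicular to the fiber axis; half-max crossings are located by linear
interpolation and, when noise produces several crossings, the outermost
crossings around the global peak define the width.  The depth of field
(DoF) is the length of the maximal contiguous depth interval containing
the focal plane over which the FWHM stays within twice its focal-plane
value.

Fusion quality on MAP images follows the three standard multi-focus
fusion metrics: cross entropy (CE, bits — lower is better), spatial
frequency (SF — higher is better) and the structural similarity index
summed over both source images (SSIM, in (−2, 2]).  A human-perception
metric (QCV) is intentionally not computed and reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .focus_measure import BlockGrid
from .volume_io import ValidationError, Volume, max_amplitude_projection


@dataclass(frozen=True)
class DepthProfile:
    """One per-plane measurement (FWHM in µm or SNR in dB)."""

    z_index: int
    z_um: float
    value: float
    valid: bool


# ---------------------------------------------------------------------------
# FWHM / DoF / SNR along depth
# ---------------------------------------------------------------------------

def _line_profile(
    v: Volume, trajectory: np.ndarray, k: int, window_halfwidth: int | None
) -> tuple[np.ndarray, int] | None:
    """Lateral profile along y through the trajectory centre at plane k.

    Returns ``(profile, centre_offset)`` or None when the trajectory is
    undefined or out of bounds.
    """
    xc, yc = trajectory[k]
    if not (np.isfinite(xc) and np.isfinite(yc)):
        return None
    xi, yi = int(round(xc)), int(round(yc))
    nx, ny = v.shape[0], v.shape[1]
    if not (0 <= xi < nx and 0 <= yi < ny):
        return None
    line = v.data[xi, :, k]
    if window_halfwidth is None:
        return line, yi
    lo = max(0, yi - window_halfwidth)
    hi = min(ny, yi + window_halfwidth + 1)
    return line[lo:hi], yi - lo


def _fwhm_of_profile(line: np.ndarray, pitch: float) -> tuple[float, int] | None:
    """FWHM (outermost half-max crossings around the global peak) in µm.

    Returns ``(fwhm, peak_index)``, or None when either side never falls
    below half maximum inside the profile.
    """
    peak_idx = int(np.argmax(line))
    peak = float(line[peak_idx])
    if peak <= 0:
        return None
    half = 0.5 * peak
    above = line >= half
    # outermost crossing left of the peak: first rise above half from the left
    left_region = above[: peak_idx + 1]
    if left_region.all():
        return None  # never falls below half on the left
    first_above = int(np.argmax(left_region))  # leftmost True
    if first_above == 0:
        return None
    lo = line[first_above - 1]
    left = (first_above - 1) + (half - lo) / (line[first_above] - lo)
    # outermost crossing right of the peak
    right_region = above[peak_idx:]
    if right_region[-1]:
        return None  # still above half at the profile edge
    last_above = peak_idx + len(right_region) - 1 - int(np.argmax(right_region[::-1]))
    hi = line[last_above + 1]
    right = last_above + (line[last_above] - half) / (line[last_above] - hi)
    return (right - left) * pitch, peak_idx


def fwhm_profile(
    v: Volume,
    trajectory: np.ndarray,
    floor_frac: float = 0.05,
    window_halfwidth: int | None = 12,
    center_tol: int | None = 3,
) -> list[DepthProfile]:
    """Per-plane lateral FWHM of a structure along a known trajectory.

    Parameters
    ----------
    v
        Volume to measure.
    trajectory
        ``(Nz, 2)`` per-plane lateral centre ``(x, y)``; NaN rows mark
        planes without structure.  The profile is taken along y at the
        nearest x column (the direction perpendicular to a fiber tilted in
        the x–z plane).
    floor_frac
        A plane is invalid when its profile peak falls below this fraction
        of the volume maximum (default 5%).
    window_halfwidth
        Restrict the profile to ± this many voxels around the trajectory
        centre (None = whole line); keeps the half-max search local to the
        structure under noise.
    center_tol
        Flag the plane invalid when the detected peak lies more than this
        many voxels from the trajectory centre (None disables the check);
        a far-off peak means the structure, not noise, was not found.
    """
    dy = v.spacing[1]
    vol_max = float(np.max(v.data))
    out: list[DepthProfile] = []
    for k in range(v.nz):
        z_um = k * v.dz
        extracted = _line_profile(v, trajectory, k, window_halfwidth)
        result = None
        if extracted is not None:
            line, centre = extracted
            peak = float(np.max(line))
            if peak >= floor_frac * vol_max:
                measured = _fwhm_of_profile(np.asarray(line, dtype=np.float64), dy)
                if measured is not None:
                    fwhm, peak_idx = measured
                    if center_tol is None or abs(peak_idx - centre) <= center_tol:
                        result = fwhm
        out.append(
            DepthProfile(
                z_index=k,
                z_um=z_um,
                value=result if result is not None else np.nan,
                valid=result is not None,
            )
        )
    return out


def depth_of_field(
    profiles: list[DepthProfile], focal_plane: int, factor: float = 2.0
) -> float:
    """Depth of field (µm) by the FWHM-doubling criterion.

    Length of the maximal contiguous depth interval containing the focal
    plane where ``FWHM(z) <= factor * FWHM(zf)``; the interval boundary is
    sub-plane interpolated when the neighbouring plane has a valid,
    above-threshold FWHM, and stops at the last conforming plane when the
    neighbour is invalid.
    """
    values = np.array([p.value for p in profiles])
    valid = np.array([p.valid for p in profiles])
    z_um = np.array([p.z_um for p in profiles])
    if not (0 <= focal_plane < len(profiles)) or not valid[focal_plane]:
        raise ValidationError(
            f"no valid FWHM measurement at focal plane {focal_plane}"
        )
    threshold = factor * values[focal_plane]
    ok = valid & (values <= threshold)
    lo = hi = focal_plane
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    while hi < len(profiles) - 1 and ok[hi + 1]:
        hi += 1
    length = z_um[hi] - z_um[lo]
    if lo > 0 and valid[lo - 1]:
        frac = (threshold - values[lo]) / (values[lo - 1] - values[lo])
        length += float(np.clip(frac, 0.0, 1.0)) * (z_um[lo] - z_um[lo - 1])
    if hi < len(profiles) - 1 and valid[hi + 1]:
        frac = (threshold - values[hi]) / (values[hi + 1] - values[hi])
        length += float(np.clip(frac, 0.0, 1.0)) * (z_um[hi + 1] - z_um[hi])
    return float(length)


def snr_profile(
    v: Volume,
    trajectory: np.ndarray,
    background_region: tuple[slice, slice],
    window_halfwidth: int | None = 12,
) -> list[DepthProfile]:
    """Per-plane SNR (dB): 20·log10(profile peak / background std).

    ``background_region`` is an (x, y) slice pair free of phantom signal.
    Planes with zero background variation (e.g. noiseless) are flagged
    invalid rather than reported as infinite.
    """
    out: list[DepthProfile] = []
    for k in range(v.nz):
        z_um = k * v.dz
        extracted = _line_profile(v, trajectory, k, window_halfwidth)
        bg = v.data[background_region[0], background_region[1], k]
        sigma = float(np.std(bg))
        value, valid = np.nan, False
        if extracted is not None and sigma > 0:
            peak = float(np.max(extracted[0]))
            if peak > 0:
                value = 20.0 * np.log10(peak / sigma)
                valid = True
        out.append(DepthProfile(z_index=k, z_um=z_um, value=value, valid=valid))
    return out


# ---------------------------------------------------------------------------
# Fusion-quality metrics (on MAP images, per the evaluation protocol)
# ---------------------------------------------------------------------------

def _normalize01(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def cross_entropy(source: np.ndarray, fused: np.ndarray, bins: int = 256) -> float:
    """Cross entropy (bits) between intensity histograms.

    Both images are min–max normalized to [0, 1], histogrammed into equal
    bins with add-one smoothing, and CE = Σ p_src·log2(p_src/p_fused).
    Identical images give exactly 0; Gibbs' inequality makes CE >= 0.
    """
    if source.shape != fused.shape:
        raise ValidationError("images must share one shape")
    if bins < 2:
        raise ValidationError(f"need >= 2 histogram bins, got {bins}")
    hs, _ = np.histogram(_normalize01(source), bins=bins, range=(0.0, 1.0))
    hf, _ = np.histogram(_normalize01(fused), bins=bins, range=(0.0, 1.0))
    ps = (hs + 1) / (hs.sum() + bins)
    pf = (hf + 1) / (hf.sum() + bins)
    return float(np.sum(ps * np.log2(ps / pf)))


def cross_entropy_mean(
    source1: np.ndarray, source2: np.ndarray, fused: np.ndarray, bins: int = 256
) -> float:
    """CE reported against both sources: mean of the two cross entropies."""
    return 0.5 * (
        cross_entropy(source1, fused, bins) + cross_entropy(source2, fused, bins)
    )


def spatial_frequency(img: np.ndarray) -> float:
    """Spatial frequency: sqrt(RF² + CF²) of first-difference energies.

    RF is the root-mean-square of row-wise (along-row) first differences,
    CF likewise column-wise; computed on the native amplitude scale.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValidationError(f"spatial frequency needs a >= 2x2 image, got {img.shape}")
    rf2 = np.mean(np.diff(img, axis=1) ** 2)
    cf2 = np.mean(np.diff(img, axis=0) ** 2)
    return float(np.sqrt(rf2 + cf2))


def ssim_total(
    source1: np.ndarray,
    source2: np.ndarray,
    fused: np.ndarray,
    mode: str = "sum",
) -> float:
    """SSIM of the fused image against both sources.

    Single-scale SSIM with an 11×11 Gaussian window (σ = 1.5), K1 = 0.01,
    K2 = 0.03 and the dynamic range taken as the maximum over the three
    images.  Reported as the SUM over both sources by default (range
    (−2, 2]); ``mode="mean"`` halves it.
    """
    if not (source1.shape == source2.shape == fused.shape):
        raise ValidationError("images must share one shape")
    if mode not in ("sum", "mean"):
        raise ValidationError(f"mode must be 'sum' or 'mean', got {mode!r}")
    data_range = float(max(source1.max(), source2.max(), fused.max()))
    if data_range <= 0:
        data_range = 1.0
    kwargs = dict(
        win_size=11,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        K1=0.01,
        K2=0.03,
        data_range=data_range,
    )
    total = structural_similarity(
        np.asarray(source1, np.float64), np.asarray(fused, np.float64), **kwargs
    ) + structural_similarity(
        np.asarray(source2, np.float64), np.asarray(fused, np.float64), **kwargs
    )
    return float(total) if mode == "sum" else float(total) / 2.0


@dataclass(frozen=True)
class FusionQualityReport:
    """MAP-image fusion metrics; ``qcv`` is explicitly not computed."""

    ce: float
    sf: float
    ssim_total: float
    qcv: str = "not computed"

    def as_dict(self) -> dict:
        return {"ce": self.ce, "sf": self.sf, "ssim_total": self.ssim_total,
                "qcv": self.qcv}


def evaluate_fusion(
    fused: Volume, source1: Volume, source2: Volume, axis: str = "z",
    bins: int = 256,
) -> FusionQualityReport:
    """CE / SF / SSIM of the fused stack's MAP against both sources' MAPs."""
    mf = max_amplitude_projection(fused, axis)
    m1 = max_amplitude_projection(source1, axis)
    m2 = max_amplitude_projection(source2, axis)
    return FusionQualityReport(
        ce=cross_entropy_mean(m1, m2, mf, bins=bins),
        sf=spatial_frequency(mf),
        ssim_total=ssim_total(m1, m2, mf),
    )


# ---------------------------------------------------------------------------
# Focus-classification accuracy against simulator ground truth
# ---------------------------------------------------------------------------

def focus_classification_accuracy(
    fdm: np.ndarray,
    labels: np.ndarray,
    clean_volumes: list[Volume],
    grid: BlockGrid,
    energy_frac: float = 0.01,
    exclude_boundary_blocks: bool = False,
    restrict: str = "blocks",
) -> float:
    """Fraction of voxels where the thresholded FDM picks the in-focus input.

    The FDM is thresholded at 0.5 (> 0.5 selects input 1, < 0.5 input 2;
    exactly 0.5 selects neither and counts as wrong) and compared with the
    nearest-focus ground-truth label, restricted to signal-bearing regions.
    With ``restrict="blocks"`` every voxel of a signal-bearing block counts:
    blocks whose noiseless signal energy (sum of squared amplitude of the
    voxel-wise max over the clean inputs) is at least ``energy_frac`` of
    the maximum block signal energy.  With ``restrict="voxels"`` only
    voxels whose noiseless amplitude is at least ``energy_frac`` of the
    peak amplitude count — the block peripheries, where the decision-map
    smoothing blends toward background, then carry no weight.

    ``exclude_boundary_blocks`` additionally drops the blocks straddling
    the focus-equidistance plane and their face neighbours along z: a
    block-constant decision cannot match the truth boundary inside a block,
    and the decision-map smoothing deliberately blends a few-voxel skin on
    either side of it, so the zone one block edge around the boundary is
    inherently ambiguous.
    """
    if restrict not in ("blocks", "voxels"):
        raise ValidationError(f"restrict must be 'blocks' or 'voxels', got {restrict!r}")
    signal = np.maximum.reduce([v.data for v in clean_volumes])
    energy = signal.astype(np.float64) ** 2
    for axis in range(3):
        energy = np.add.reduceat(energy, grid.starts(axis), axis=axis)
    mask_blocks = energy >= energy_frac * float(energy.max())
    if exclude_boundary_blocks:
        label_sum = labels.astype(np.float64)
        counts = np.ones_like(label_sum)
        for axis in range(3):
            label_sum = np.add.reduceat(label_sum, grid.starts(axis), axis=axis)
            counts = np.add.reduceat(counts, grid.starts(axis), axis=axis)
        mean_label = label_sum / counts
        impure = (mean_label != 0.0) & (mean_label != 1.0)
        near = impure.copy()
        near[:, :, :-1] |= impure[:, :, 1:]
        near[:, :, 1:] |= impure[:, :, :-1]
        mask_blocks &= ~near
    mask = grid.expand(mask_blocks)
    if restrict == "voxels":
        mask &= signal >= energy_frac * float(signal.max())
    if not mask.any():
        raise ValidationError("no signal-bearing blocks above the energy threshold")
    correct = ((fdm > 0.5) & (labels == 0)) | ((fdm < 0.5) & (labels == 1))
    return float(np.mean(correct[mask]))
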