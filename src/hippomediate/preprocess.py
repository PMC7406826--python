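"""Post-realignment cleanup of resting-state BOLD data.

Implements the standard nuisance chain applied after slice-timing and
rigid-body realignment (which are consumed as precomputed inputs):

1. discard the first ``k`` volumes,
2. motion QC and subject exclusion (parameter range and mean FD criteria),
3. a single nuisance regression with Friston-24 motion terms, motion-spike
   ("scrubbing") indicators, CompCor components from a noise-tissue mask,
   a linear trend and an intercept,
4. spatial Gaussian smoothing,
5. temporal band-pass filtering (ideal frequency mask).

The default stage order is regression -> smoothing -> band-pass; the
convenience wrapper :func:`clean` exposes a flag to filter before smoothing
for practitioners who prefer that order.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import ndimage, signal

from .types import MotionParams, NuisanceMatrix, QCReport, Volume4D

__all__ = [
    "discard_initial",
    "compute_fd",
    "exclusion_decision",
    "scrubbing_regressors",
    "friston24",
    "compcor",
    "build_nuisance",
    "regress_out",
    "smooth_gaussian",
    "bandpass",
    "bandpass_series",
    "band_variance_fraction",
    "smoothing_variance_factor",
    "clean",
]

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # approx 2.3548


def discard_initial(
    vol: Volume4D, motion: MotionParams, k: int = 4
) -> tuple[Volume4D, MotionParams]:
    """Drop the first ``k`` volumes from image and motion trace alike.

    The initial volumes are acquired before longitudinal magnetisation
    reaches steady state and are conventionally removed.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if vol.n_volumes != motion.n_volumes:
        raise ValueError(
            f"image has {vol.n_volumes} volumes but motion trace has {motion.n_volumes}"
        )
    if vol.n_volumes <= k:
        raise ValueError(f"cannot discard {k} volumes from a series of length {vol.n_volumes}")
    return vol.replace_data(vol.data[k:]), MotionParams(motion.values[k:])


def compute_fd(motion: MotionParams, head_radius: float = 50.0) -> np.ndarray:
    """Frame-wise displacement (mm) from backward differences.

    ``FD[t] = sum |d translations| + head_radius * sum |d rotations|``, with
    rotations (radians) converted to arc length on a sphere of
    ``head_radius`` mm. ``FD[0] = 0`` by convention.
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    diffs = np.abs(np.diff(motion.values, axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def exclusion_decision(
    motion: MotionParams,
    fd: np.ndarray,
    max_translation: float = 1.5,
    max_rotation_deg: float = 1.5,
    max_mean_fd: float = 0.5,
    subject_id: str = "",
) -> QCReport:
    """Apply the motion exclusion criteria.

    A subject is excluded when any translation exceeds ``max_translation``
    mm, any rotation exceeds ``max_rotation_deg`` degrees, or the mean FD
    exceeds ``max_mean_fd`` mm.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size != motion.n_volumes:
        raise ValueError("FD length does not match motion trace")
    max_trans = float(np.abs(motion.translations).max())
    max_rot_deg = float(np.degrees(np.abs(motion.rotations).max()))
    mean_fd = float(fd.mean())
    reasons = []
    if max_trans > max_translation:
        reasons.append("translation")
    if max_rot_deg > max_rotation_deg:
        reasons.append("rotation")
    if mean_fd > max_mean_fd:
        reasons.append("mean_fd")
    return QCReport(
        subject_id=subject_id,
        max_abs_translation=max_trans,
        max_abs_rotation_deg=max_rot_deg,
        mean_fd=mean_fd,
        excluded=bool(reasons),
        reasons=reasons,
    )


def scrubbing_regressors(
    fd: np.ndarray, thr: float = 0.5, n_before: int = 1, n_after: int = 2
) -> tuple[np.ndarray, list[int]]:
    """Per-volume spike indicators for high-motion timepoints.

    Every volume with ``FD > thr`` flags itself, ``n_before`` volumes
    before and ``n_after`` after (clipped to the series); duplicates are
    merged. Returns the ``(T, n_flagged)`` indicator matrix (one unit
    column per flagged volume, in time order) and the flagged timepoints.
    """
    fd = np.asarray(fd, dtype=float)
    T = fd.size
    flagged: set[int] = set()
    for t in np.flatnonzero(fd > thr):
        for s in range(t - n_before, t + n_after + 1):
            if 0 <= s < T:
                flagged.add(int(s))
    times = sorted(flagged)
    cols = np.zeros((T, len(times)))
    for j, t in enumerate(times):
        cols[t, j] = 1.0
    return cols, times


def friston24(motion: MotionParams) -> np.ndarray:
    """The 24-parameter motion expansion.

    Columns, in order: the 6 parameters, the 6 parameters lagged by one
    volume (zeros at t=0), the 6 squared parameters, and the 6 squared
    lagged parameters.
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least 2 volumes for the lagged expansion")
    p = motion.values
    lag = np.zeros_like(p)
    lag[1:] = p[:-1]
    return np.hstack([p, lag, p**2, lag**2])


def compcor(vol: Volume4D, noise_mask: np.ndarray, k: int = 5) -> np.ndarray:
    """Principal-component time courses from a noise-tissue mask.

    Each noise voxel's series is linearly detrended and scaled to unit
    variance; the returned columns are the top-``k`` temporal singular
    vectors of the resulting time x voxel matrix, unit-norm, ordered by
    singular value, with the sign fixed so each column's first nonzero
    element is positive.
    """
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if noise_mask.shape != vol.grid:
        raise ValueError("noise mask shape does not match image grid")
    if not noise_mask.any():
        raise ValueError("noise mask is empty")
    if k == 0:
        return np.zeros((vol.n_volumes, 0))
    if k >= vol.n_volumes:
        raise ValueError("k must be smaller than the number of volumes")
    ts = vol.data[:, noise_mask]  # (T, Nvox)
    ts = signal.detrend(ts, axis=0, type="linear")
    sd = ts.std(axis=0, ddof=0)
    keep = sd > 0
    ts = ts[:, keep] / sd[keep]
    if ts.shape[1] == 0:
        raise ValueError("all noise-mask voxels have zero variance")
    u, s, _ = np.linalg.svd(ts, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if rank < k:
        warnings.warn(
            f"noise mask supports only {rank} components; returning {min(k, rank)} "
            f"instead of the requested {k}",
            RuntimeWarning,
        )
    k_eff = min(k, rank)
    comps = u[:, :k_eff]
    for j in range(k_eff):
        col = comps[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            comps[:, j] = -col
    return comps


def build_nuisance(
    motion: MotionParams,
    fd: np.ndarray,
    compcor_cols: np.ndarray | None = None,
    scrub_thr: float = 0.5,
    scrub_before: int = 1,
    scrub_after: int = 2,
) -> NuisanceMatrix:
    """Assemble the full nuisance design.

    Column order: Friston-24, spike indicators, CompCor components,
    centred linear trend, intercept.
    """
    T = motion.n_volumes
    fr = friston24(motion)
    spikes, times = scrubbing_regressors(fd, thr=scrub_thr, n_before=scrub_before, n_after=scrub_after)
    if compcor_cols is None:
        compcor_cols = np.zeros((T, 0))
    if compcor_cols.shape[0] != T:
        raise ValueError("compcor columns have wrong length")
    trend = np.arange(T, dtype=float)
    trend -= trend.mean()
    design = np.hstack([fr, spikes, compcor_cols, trend[:, None], np.ones((T, 1))])
    labels = (
        [f"friston{i + 1:02d}" for i in range(24)]
        + [f"spike_{t}" for t in times]
        + [f"compcor{i + 1}" for i in range(compcor_cols.shape[1])]
        + ["trend", "intercept"]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("nuisance design is rank deficient; regression will use a pseudoinverse", RuntimeWarning)
    return NuisanceMatrix(design=design, labels=labels)


def regress_out(vol: Volume4D, nuisance: NuisanceMatrix) -> Volume4D:
    """Replace every voxel series by its least-squares residual on the design."""
    D = nuisance.design
    if D.shape[0] != vol.n_volumes:
        raise ValueError("nuisance design rows do not match number of volumes")
    ts = vol.timeseries_matrix()
    beta = np.linalg.pinv(D) @ ts
    resid = ts - D @ beta
    return vol.replace_data(resid.reshape(vol.data.shape))


def smooth_gaussian(vol: Volume4D, fwhm: float = 4.0) -> Volume4D:
    """Per-volume 3D Gaussian smoothing with an isotropic FWHM in mm.

    The kernel width in voxels is anisotropic whenever voxels are, using
    ``sigma_axis = fwhm / 2.3548 / voxel_size_axis``. Edges are handled by
    nearest-neighbour extension so a constant image is preserved exactly.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return vol.replace_data(vol.data.copy())
    sigma_vox = [fwhm / FWHM_TO_SIGMA / vs for vs in vol.voxel_size]
    out = ndimage.gaussian_filter(vol.data, sigma=[0.0] + sigma_vox, mode="nearest")
    return vol.replace_data(out)


def _band_mask(T: int, tr: float, lo: float, hi: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(T, d=tr)
    return (freqs >= lo) & (freqs <= hi)


def bandpass_series(arr: np.ndarray, tr: float, lo: float = 0.01, hi: float = 0.1) -> np.ndarray:
    """Ideal band-pass along axis 0: keep Fourier bins with ``lo <= f <= hi``.

    The DC component is always removed (``lo > 0`` in practice); the mask
    is hard, so pass/stop behaviour is exact per frequency bin.
    """
    arr = np.asarray(arr, dtype=float)
    nyq = 1.0 / (2.0 * tr)
    if not (0 <= lo < hi):
        raise ValueError(f"need 0 <= lo < hi, got lo={lo}, hi={hi}")
    if hi > nyq + 1e-12:
        raise ValueError(f"hi={hi} Hz exceeds the Nyquist frequency {nyq} Hz")
    T = arr.shape[0]
    spec = np.fft.rfft(arr, axis=0)
    keep = _band_mask(T, tr, lo, hi)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=0)


def bandpass(vol: Volume4D, lo: float = 0.01, hi: float = 0.1) -> Volume4D:
    """Apply :func:`bandpass_series` to every voxel of a 4D image."""
    return vol.replace_data(bandpass_series(vol.data, vol.tr, lo, hi))


def band_variance_fraction(T: int, tr: float, lo: float = 0.01, hi: float = 0.1) -> float:
    """Fraction of white-noise variance retained by the ideal band-pass.

    By Parseval, each interior rFFT bin carries 2/T of a white series'
    variance and the DC/Nyquist bins 1/T; the retained fraction is the
    summed weight of the kept bins. Used by the synthetic generator to
    calibrate planted correlations for the post-filter scale.
    """
    keep = _band_mask(T, tr, lo, hi)
    weights = np.full(keep.size, 2.0 / T)
    weights[0] = 1.0 / T
    if T % 2 == 0:
        weights[-1] = 1.0 / T
    return float(weights[keep].sum())


def smoothing_variance_factor(
    grid: tuple[int, int, int], voxel_size: tuple[float, float, float], fwhm: float
) -> float:
    """Variance multiplier of spatially independent noise under smoothing.

    Equals the sum of squared kernel weights at an interior voxel, computed
    numerically by smoothing a centred impulse with the same settings as
    :func:`smooth_gaussian`.
    """
    if fwhm == 0:
        return 1.0
    impulse = np.zeros(grid)
    impulse[grid[0] // 2, grid[1] // 2, grid[2] // 2] = 1.0
    sigma_vox = [fwhm / FWHM_TO_SIGMA / vs for vs in voxel_size]
    kern = ndimage.gaussian_filter(impulse, sigma=sigma_vox, mode="constant")
    return float((kern**2).sum())


def clean(
    vol: Volume4D,
    motion: MotionParams,
    noise_mask: np.ndarray | None = None,
    n_compcor: int = 5,
    fwhm: float = 4.0,
    band: tuple[float, float] = (0.01, 0.1),
    head_radius: float = 50.0,
    scrub_thr: float = 0.5,
    bandpass_before_smoothing: bool = False,
) -> Volume4D:
    """Full cleanup of an already-truncated image: regression, smoothing, filtering.

    Assumes steady-state volumes were already discarded (see
    :func:`discard_initial`) and QC/exclusion happened upstream.
    """
    fd = compute_fd(motion, head_radius=head_radius)
    cc = None
    if noise_mask is not None and n_compcor > 0:
        cc = compcor(vol, noise_mask, k=n_compcor)
    nuis = build_nuisance(motion, fd, compcor_cols=cc, scrub_thr=scrub_thr)
    out = regress_out(vol, nuis)
    if bandpass_before_smoothing:
        out = bandpass(out, *band)
        out = smooth_gaussian(out, fwhm=fwhm)
    else:
        out = smooth_gaussian(out, fwhm=fwhm)
        out = bandpass(out, *band)
    return out
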