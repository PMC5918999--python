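"""From raw camera frames to a drift-corrected localization table.

Stages: temporal-median background correction, local-maximum candidate
detection, nonlinear least-squares fit of each peak to a symmetric 2D
Gaussian, the precision formula (FWHM of the fitted Gaussian divided by the
square root of the detected photons), and drift correction by redundant
cross-correlation of temporally binned reconstructions.

Pixel convention: pixel (i, j) spans [j*p, (j+1)*p) x [i*p, (i+1)*p) nm with
its centre at ((j+0.5)*p, (i+0.5)*p); stated once, asserted everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy.ndimage import gaussian_filter, maximum_filter, median_filter
from scipy.optimize import least_squares

from .errors import ParameterError
from .simulate import CameraFrameStack
from .table import LocalizationTable, empty_table

logger = logging.getLogger(__name__)

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2.3548 sigma


@dataclass
class PeakFit:
    x_nm: float
    y_nm: float
    sigma_nm: float
    amplitude: float      # photons/pixel above offset
    offset: float         # photons/pixel
    photons: float        # integrated volume above offset
    residual_norm: float
    converged: bool


@dataclass
class DriftTrace:
    """Per-bin displacements vs the first bin; linear interpolation between
    bin centres, constant beyond the ends."""

    bin_frames: int
    bin_centers_frame: np.ndarray
    dx_nm: np.ndarray
    dy_nm: np.ndarray
    interpolated_bins: list = field(default_factory=list)

    def at_frames(self, frames) -> tuple[np.ndarray, np.ndarray]:
        frames = np.asarray(frames, dtype=float)
        dx = np.interp(frames, self.bin_centers_frame, self.dx_nm)
        dy = np.interp(frames, self.bin_centers_frame, self.dy_nm)
        return dx, dy


def estimate_background(stack: CameraFrameStack, window: int = 101) -> CameraFrameStack:
    """Per-pixel temporal median over a sliding window, as a background stack.

    A window larger than the stack falls back to the whole-stack median
    (with a logged warning). Window must be odd and >= 3.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError("window must be odd and >= 3")
    frames = np.asarray(stack.frames, dtype=float)
    if window > len(frames):
        logger.warning(
            "background window %d exceeds stack length %d; using whole-stack median",
            window, len(frames),
        )
        bg = np.broadcast_to(np.median(frames, axis=0), frames.shape).copy()
    else:
        # mirror padding so an event on an edge frame enters its own window once
        bg = median_filter(frames, size=(window, 1, 1), mode="mirror")
    return CameraFrameStack(frames=bg, pixel_nm=stack.pixel_nm)


def correct_background(stack: CameraFrameStack, window: int = 101) -> CameraFrameStack:
    """Raw minus temporal-median background, clipped at zero."""
    bg = estimate_background(stack, window)
    corrected = np.clip(stack.frames - bg.frames, 0.0, None)
    return CameraFrameStack(
        frames=corrected, pixel_nm=stack.pixel_nm,
        psf_sigma_nm=stack.psf_sigma_nm, background_photons=0.0,
    )


def detect_candidates(frame: np.ndarray, threshold: float, min_separation: int = 4):
    """Local maxima strictly above ``threshold``, greedily suppressed.

    Candidates are visited brightest-first (ties broken in row-major order);
    a candidate within Euclidean ``min_separation`` pixels of an accepted
    one is dropped. Returns a list of (row, col) pixel coordinates.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    frame = np.asarray(frame, dtype=float)
    is_max = (frame == maximum_filter(frame, size=3, mode="nearest")) & (frame > threshold)
    rows, cols = np.nonzero(is_max)
    if len(rows) == 0:
        return []
    order = np.lexsort((cols, rows, -frame[rows, cols]))
    accepted: list[tuple[int, int]] = []
    for idx in order:
        r, c = int(rows[idx]), int(cols[idx])
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_separation**2 for ar, ac in accepted):
            accepted.append((r, c))
    return accepted


def robust_noise_scale(frame: np.ndarray) -> float:
    """Noise scale of a background-corrected frame: 1.4826 x MAD about the median."""
    frame = np.asarray(frame, dtype=float)
    med = np.median(frame)
    return float(1.4826 * np.median(np.abs(frame - med)) + 1e-12)


def fit_peak(patch: np.ndarray, pixel_nm: float, init: tuple[float, float] | None = None) -> PeakFit:
    """Least-squares fit of ``offset + A exp(-((u-x)^2+(v-y)^2)/(2 sigma^2))``.

    ``patch`` is a photon-count array of at least 7x7 pixels; ``init`` is an
    (x, y) starting position in nm within the patch (default: its centre).
    Detected photons are the fitted volume above offset,
    ``2 pi A (sigma/p)^2`` in photon units.
    """
    patch = np.asarray(patch, dtype=float)
    ny, nx = patch.shape
    if ny < 7 or nx < 7:
        raise ParameterError("patch must be at least 7x7 pixels")
    p = pixel_nm
    # pixel centres in nm
    uc = (np.arange(nx) + 0.5) * p
    vc = (np.arange(ny) + 0.5) * p
    U, V = np.meshgrid(uc, vc)

    if init is None:
        init = (nx / 2 * p, ny / 2 * p)
    x0, y0 = init
    if not (0 <= x0 <= nx * p and 0 <= y0 <= ny * p):
        raise ParameterError("init position outside patch")
    off0 = float(np.percentile(patch, 20))
    amp0 = max(float(patch.max()) - off0, 1e-3)
    sig0 = 1.3 * p

    def resid(th):
        x, y, s, a, o = th
        model = o + a * np.exp(-((U - x) ** 2 + (V - y) ** 2) / (2 * s**2))
        return (model - patch).ravel()

    lo = [0.0, 0.0, 0.2 * p, 0.0, -np.inf]
    hi = [nx * p, ny * p, 5.0 * max(nx, ny) * p, np.inf, np.inf]
    res = least_squares(
        resid, [x0, y0, sig0, amp0, off0], bounds=(lo, hi),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    x, y, s, a, o = res.x
    photons = 2 * np.pi * a * (s / p) ** 2
    converged = bool(res.success) and a > 0 and 0 < x < nx * p and 0 < y < ny * p
    return PeakFit(
        x_nm=float(x), y_nm=float(y), sigma_nm=float(s), amplitude=float(a),
        offset=float(o), photons=float(photons),
        residual_norm=float(np.sqrt(2 * res.cost)), converged=converged,
    )


def compute_precision(sigma_fit_nm, photons):
    """Localization precision: FWHM of the fitted Gaussian / sqrt(photons)."""
    sigma_fit_nm = np.asarray(sigma_fit_nm, dtype=float)
    photons = np.asarray(photons, dtype=float)
    if np.any(sigma_fit_nm <= 0) or np.any(photons <= 0):
        raise ParameterError("sigma_fit and photons must be positive")
    out = FWHM_FACTOR * sigma_fit_nm / np.sqrt(photons)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# drift correction

def _render_bin(x, y, nx, ny, pixel):
    img = np.zeros((ny, nx))
    ix = np.clip(np.floor(x / pixel).astype(int), 0, nx - 1)
    iy = np.clip(np.floor(y / pixel).astype(int), 0, ny - 1)
    np.add.at(img, (iy, ix), 1.0)
    return img


def _xcorr_shift(img, ref, pixel_nm: float) -> tuple[float, float]:
    """Sub-pixel displacement of ``img`` relative to ``ref`` via FFT
    cross-correlation with a 3x3 centroid refinement of the peak."""
    py = sp_fft.next_fast_len(2 * img.shape[0])
    px = sp_fft.next_fast_len(2 * img.shape[1])
    fa = sp_fft.rfft2(gaussian_filter(img, 1.0), s=(py, px))
    fb = sp_fft.rfft2(gaussian_filter(ref, 1.0), s=(py, px))
    corr = sp_fft.irfft2(fa * np.conj(fb), s=(py, px))
    corr = np.roll(corr, (py // 2, px // 2), axis=(0, 1))
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    # 3x3 neighbourhood centroid; baseline = median of the surrounding 5x5
    # ring, so the broad cross-pair plateau does not tilt the centroid
    nb = corr[max(iy - 1, 0): iy + 2, max(ix - 1, 0): ix + 2]
    ring = corr[max(iy - 2, 0): iy + 3, max(ix - 2, 0): ix + 3]
    baseline = np.median(ring) if ring.size else nb.min()
    nb = np.clip(nb - baseline, 0.0, None)
    total = nb.sum()
    if total > 0 and nb.shape == (3, 3):
        dyc = float((nb * np.array([-1, 0, 1])[:, None]).sum() / total)
        dxc = float((nb * np.array([-1, 0, 1])[None, :]).sum() / total)
    else:
        dyc = dxc = 0.0
    dy = (iy - py // 2) + dyc
    dx = (ix - px // 2) + dxc
    return dx * pixel_nm, dy * pixel_nm


def correct_drift(
    table: LocalizationTable,
    bin_frames: int = 1000,
    render_pixel_nm: float = 20.0,
    min_bin_locs: int = 50,
) -> tuple[LocalizationTable, DriftTrace]:
    """Estimate and subtract stage drift by redundant cross-correlation.

    The acquisition is split into ``bin_frames``-frame bins; each bin is
    rendered as a 2D histogram and its displacement versus the first bin
    estimated by FFT cross-correlation with sub-pixel (3x3 centroid)
    refinement. Per-frame displacements are linearly interpolated between
    bin centres and subtracted. Bins with fewer than ``min_bin_locs``
    localizations are interpolated from their neighbours.
    """
    n_bins = int(np.ceil(table.frames_total / bin_frames))
    if n_bins < 2:
        raise ParameterError("table must span at least 2 drift bins")
    df = table.df
    frames = df["frame"].to_numpy()
    x = df["x_nm"].to_numpy(float)
    y = df["y_nm"].to_numpy(float)
    which = np.minimum(frames // bin_frames, n_bins - 1)

    nx = int(np.ceil(table.field_width_nm / render_pixel_nm))
    ny = int(np.ceil(table.field_height_nm / render_pixel_nm))
    ref = None
    dxs = np.zeros(n_bins)
    dys = np.zeros(n_bins)
    valid = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        sel = which == b
        if b == 0:
            ref = _render_bin(x[sel], y[sel], nx, ny, render_pixel_nm)
            valid[0] = True
            continue
        if sel.sum() < min_bin_locs:
            logger.warning("drift bin %d has %d localizations; interpolating", b, sel.sum())
            continue
        img = _render_bin(x[sel], y[sel], nx, ny, render_pixel_nm)
        dxs[b], dys[b] = _xcorr_shift(img, ref, render_pixel_nm)
        valid[b] = True

    centers = (np.arange(n_bins) + 0.5) * bin_frames
    interpolated = list(np.nonzero(~valid)[0])
    if interpolated:
        dxs[~valid] = np.interp(centers[~valid], centers[valid], dxs[valid])
        dys[~valid] = np.interp(centers[~valid], centers[valid], dys[valid])

    trace = DriftTrace(
        bin_frames=bin_frames, bin_centers_frame=centers,
        dx_nm=dxs, dy_nm=dys, interpolated_bins=interpolated,
    )
    ddx, ddy = trace.at_frames(frames)
    out = table.copy()
    out.df["x_nm"] = x - ddx
    out.df["y_nm"] = y - ddy
    # drift subtraction can nudge events marginally outside the field
    out.df["x_nm"] = out.df["x_nm"].clip(0, table.field_width_nm)
    out.df["y_nm"] = out.df["y_nm"].clip(0, table.field_height_nm)
    logger.info("drift corrected over %d bins; max displacement %.1f nm",
                n_bins, float(np.hypot(dxs, dys).max()))
    return out, trace


# --------------------------------------------------------------------------
# composite

def localize_stack(
    stack: CameraFrameStack,
    threshold_scale: float = 5.0,
    background_window: int = 101,
    min_separation_px: int = 4,
    patch_half_px: int = 4,
    min_photons: float = 30.0,
    sigma_bounds_nm: tuple[float, float] = (50.0, 300.0),
    drift_bin_frames: int | None = 1000,
    drift_render_pixel_nm: float = 20.0,
) -> LocalizationTable:
    """Full localization pipeline: background, detection, fitting, precision,
    drift correction.

    The detection threshold is ``threshold_scale`` times the robust noise
    scale (1.4826 x MAD) of each background-subtracted frame, estimated
    before clipping so the symmetric noise floor is not truncated. Fits are
    rejected (and counted in the log) when the optimizer fails, the photon
    count falls below ``min_photons``, the fitted width leaves
    ``sigma_bounds_nm``, or the position leaves the patch.
    """
    bg = estimate_background(stack, background_window)
    diff = np.asarray(stack.frames, dtype=float) - bg.frames
    p = stack.pixel_nm
    ny, nx = diff.shape[1], diff.shape[2]
    rows = []
    n_candidates = n_rejected = 0
    for f_idx, frame in enumerate(diff):
        thr = threshold_scale * robust_noise_scale(frame)
        if frame.max() <= thr:
            continue
        for (r, c) in detect_candidates(frame, thr, min_separation_px):
            n_candidates += 1
            r0, r1 = r - patch_half_px, r + patch_half_px + 1
            c0, c1 = c - patch_half_px, c + patch_half_px + 1
            if r0 < 0 or c0 < 0 or r1 > ny or c1 > nx:
                n_rejected += 1
                continue
            patch = frame[r0:r1, c0:c1]
            fit = fit_peak(patch, p, init=((c - c0 + 0.5) * p, (r - r0 + 0.5) * p))
            if (not fit.converged or fit.photons < min_photons
                    or not (sigma_bounds_nm[0] <= fit.sigma_nm <= sigma_bounds_nm[1])):
                n_rejected += 1
                continue
            rows.append(
                {
                    "frame": f_idx,
                    "x_nm": fit.x_nm + c0 * p,
                    "y_nm": fit.y_nm + r0 * p,
                    "z_nm": 0.0,
                    "sigma_nm": fit.sigma_nm,
                    "photons": fit.photons,
                    "background": fit.offset,
                    "precision_nm": compute_precision(fit.sigma_nm, fit.photons),
                }
            )
    logger.info(
        "localize_stack: %d candidates, %d accepted, %d rejected "
        "(non-convergence / photons < %.0f / patch clipping)",
        n_candidates, len(rows), n_rejected, min_photons,
    )
    if not rows:
        return empty_table(
            camera_pixel_nm=p, field_width_nm=nx * p, field_height_nm=ny * p,
            frames_total=len(stack.frames),
        )
    table = LocalizationTable(
        pd.DataFrame(rows), camera_pixel_nm=p,
        field_width_nm=nx * p, field_height_nm=ny * p, frames_total=len(stack.frames),
    )
    if drift_bin_frames and table.frames_total > 2 * drift_bin_frames:
        table, _ = correct_drift(table, drift_bin_frames, drift_render_pixel_nm)
    return table
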