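"""Synthetic ground truth for every pipeline stage.

Generates membrane point patterns (homogeneous Poisson or Thomas cluster
process), blinking localization tables with Gaussian localization error,
raw camera frame stacks with Poisson shot noise, and expression time courses
under the production/degradation model. Every generator takes an explicit
seed and is reproducible.

Defaults emulate the acquisition regime the analysis targets: a 25x25 um
illuminated field, 100 nm camera pixels, 30 000 frames, mean localization
precision 20 nm (photoconvertible-protein regime) or 12 nm (organic-dye
regime), and cluster correlation lengths of a few tens of nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import ParameterError
from .table import LocalizationTable, empty_table

logger = logging.getLogger(__name__)

#: Acquisition-regime defaults.
DEFAULT_FIELD_NM = 25_000.0
DEFAULT_FRAMES = 30_000
DEFAULT_PIXEL_NM = 100.0
PALM_PRECISION_NM = 20.0
STORM_PRECISION_NM = 12.0


@dataclass
class GroundTruthField:
    """True molecule positions with cluster assignments and blink counts.

    ``molecules`` has columns ``x_nm, y_nm, z_nm, cluster_id, blink_count``;
    ``cluster_id`` is -1 for molecules of a random (non-clustered) pattern,
    ``blink_count`` is filled in by :func:`simulate_localizations`.
    """

    molecules: pd.DataFrame
    field_width_nm: float
    field_height_nm: float
    mode: str  # "random" | "clustered"
    process_params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def area_um2(self) -> float:
        return self.field_width_nm * self.field_height_nm / 1e6


@dataclass
class CameraFrameStack:
    """Raw (or background/corrected) camera frames in photon counts."""

    frames: np.ndarray  # (n_frames, ny, nx)
    pixel_nm: float = DEFAULT_PIXEL_NM
    psf_sigma_nm: float | None = None
    background_photons: float = 0.0

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class TimecourseSample:
    """Simulated relative membrane densities over time.

    ``data`` is tidy: columns ``time_h, replicate, endogenous, exogenous,
    total`` in fractions of the untransfected steady state. ``expected``
    holds the noise-free curves (one row per time).
    """

    data: pd.DataFrame
    expected: pd.DataFrame
    noise_sd: float
    replicates: int


def thomas_pair_correlation(r, kappa_per_um2: float, s_nm: float):
    """Closed-form pair correlation of a Thomas process.

    g(r) = 1 + exp(-r^2 / (4 s^2)) / (4 pi kappa s^2), with kappa converted
    to clusters/nm^2. This is the exact oracle the cluster generator is
    tested against.
    """
    kappa_nm = kappa_per_um2 / 1e6
    r = np.asarray(r, dtype=float)
    return 1.0 + np.exp(-(r**2) / (4 * s_nm**2)) / (4 * np.pi * kappa_nm * s_nm**2)


def simulate_molecules(
    mode: str,
    field_width_nm: float = DEFAULT_FIELD_NM,
    field_height_nm: float = DEFAULT_FIELD_NM,
    molecule_density_um2: float = 100.0,
    parent_density_um2: float = 50.0,
    displacement_scale_nm: float = 25.0,
    seed: int | np.random.Generator = 0,
) -> GroundTruthField:
    """Draw a ground-truth membrane point pattern.

    ``mode="random"`` is a homogeneous Poisson process at
    ``molecule_density_um2``. ``mode="clustered"`` is a Thomas
    (Neyman-Scott) process: cluster centres are Poisson with intensity
    ``parent_density_um2``, offspring counts per cluster are Poisson with
    mean ``molecule_density_um2 / parent_density_um2``, and offspring are
    displaced from their centre by an isotropic Gaussian of standard
    deviation ``displacement_scale_nm``. Parents are drawn on a field
    extended by 5 displacement scales so edge clusters are not truncated;
    offspring falling outside the field are discarded.
    """
    if field_width_nm <= 0 or field_height_nm <= 0:
        raise ParameterError("field extent must be positive")
    if molecule_density_um2 <= 0:
        raise ParameterError("molecule density must be positive")
    if mode not in ("random", "clustered"):
        raise ParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)

    area_um2 = field_width_nm * field_height_nm / 1e6
    if mode == "random":
        n = rng.poisson(molecule_density_um2 * area_um2)
        x = rng.uniform(0, field_width_nm, n)
        y = rng.uniform(0, field_height_nm, n)
        cluster_id = np.full(n, -1, dtype=int)
    else:
        if parent_density_um2 <= 0 or displacement_scale_nm <= 0:
            raise ParameterError("clustered mode needs positive parent density and scale")
        margin = 5.0 * displacement_scale_nm
        w, h = field_width_nm + 2 * margin, field_height_nm + 2 * margin
        n_parents = rng.poisson(parent_density_um2 * w * h / 1e6)
        px = rng.uniform(-margin, field_width_nm + margin, n_parents)
        py = rng.uniform(-margin, field_height_nm + margin, n_parents)
        mean_offspring = molecule_density_um2 / parent_density_um2
        counts = rng.poisson(mean_offspring, n_parents)
        cluster_id = np.repeat(np.arange(n_parents), counts)
        x = np.repeat(px, counts) + rng.normal(0, displacement_scale_nm, counts.sum())
        y = np.repeat(py, counts) + rng.normal(0, displacement_scale_nm, counts.sum())
        keep = (x >= 0) & (x < field_width_nm) & (y >= 0) & (y < field_height_nm)
        x, y, cluster_id = x[keep], y[keep], cluster_id[keep]

    molecules = pd.DataFrame(
        {
            "x_nm": x,
            "y_nm": y,
            "z_nm": np.zeros(len(x)),
            "cluster_id": cluster_id,
            "blink_count": np.ones(len(x), dtype=int),
        }
    )
    logger.info("simulated %d molecules (%s mode, %.0f/um2 target)",
                len(molecules), mode, molecule_density_um2)
    return GroundTruthField(
        molecules=molecules,
        field_width_nm=field_width_nm,
        field_height_nm=field_height_nm,
        mode=mode,
        process_params={
            "molecule_density_um2": molecule_density_um2,
            "parent_density_um2": parent_density_um2 if mode == "clustered" else None,
            "displacement_scale_nm": displacement_scale_nm if mode == "clustered" else None,
        },
    )


def simulate_localizations(
    truth: GroundTruthField,
    mean_blinks: float = 4.0,
    precision_sigma_nm: float = PALM_PRECISION_NM,
    frames_total: int = DEFAULT_FRAMES,
    drift_velocity_nm_per_frame: tuple[float, float] = (0.0, 0.0),
    photons_mean: float = 250.0,
    camera_pixel_nm: float = DEFAULT_PIXEL_NM,
    seed: int | np.random.Generator = 0,
) -> LocalizationTable:
    """Emit blinking localizations from a ground-truth field.

    Each molecule produces B blinks with B ~ Geometric on {1, 2, ...} of
    mean ``mean_blinks`` (a memoryless-switching null; one parameter). Each
    blink lands at the molecule position plus isotropic Gaussian error of
    standard deviation ``precision_sigma_nm`` per axis, plus the cumulative
    drift of its uniformly assigned frame. The per-row ``precision_nm`` is
    ``precision_sigma_nm`` with per-event jitter, rescaled so the table mean
    equals ``precision_sigma_nm`` exactly; ``photons`` and ``sigma_nm`` are
    drawn self-consistently with the precision formula. ``blink_count`` is
    written back into ``truth.molecules``.
    """
    if mean_blinks < 1:
        raise ParameterError("mean_blinks must be >= 1")
    if precision_sigma_nm <= 0:
        raise ParameterError("precision_sigma_nm must be positive")
    rng = np.random.default_rng(seed)

    n_mol = len(truth)
    if n_mol == 0:
        return empty_table(
            camera_pixel_nm=camera_pixel_nm,
            field_width_nm=truth.field_width_nm,
            field_height_nm=truth.field_height_nm,
            frames_total=frames_total,
        )

    blinks = rng.geometric(1.0 / mean_blinks, n_mol)
    truth.molecules["blink_count"] = blinks
    n = int(blinks.sum())
    mol_idx = np.repeat(np.arange(n_mol), blinks)

    mx = truth.molecules["x_nm"].to_numpy()[mol_idx]
    my = truth.molecules["y_nm"].to_numpy()[mol_idx]
    mz = truth.molecules["z_nm"].to_numpy()[mol_idx]
    frames = rng.integers(0, frames_total, n)
    vx, vy = drift_velocity_nm_per_frame
    x = mx + rng.normal(0, precision_sigma_nm, n) + vx * frames
    y = my + rng.normal(0, precision_sigma_nm, n) + vy * frames

    keep = (x >= 0) & (y >= 0)  # negative drift may push events off-field
    mol_idx, frames, x, y, mz = mol_idx[keep], frames[keep], x[keep], y[keep], mz[keep]
    n = int(keep.sum())

    precision = precision_sigma_nm * np.clip(1 + 0.2 * rng.standard_normal(n), 0.25, None)
    precision *= precision_sigma_nm / precision.mean()  # exact table mean
    photons = np.maximum(rng.poisson(photons_mean, n), 1).astype(float)
    # invert precision = FWHM/sqrt(N) so the formula round-trips per row
    sigma_fit = precision * np.sqrt(photons) / (2 * np.sqrt(2 * np.log(2)))

    df = pd.DataFrame(
        {
            "frame": frames,
            "x_nm": x,
            "y_nm": y,
            "z_nm": mz,
            "sigma_nm": sigma_fit,
            "photons": photons,
            "background": np.zeros(n),
            "precision_nm": precision,
            "molecule_id": mol_idx,
        }
    )
    # drift may push events outside the nominal field: extend metadata extent
    width = max(truth.field_width_nm, float(np.ceil(df["x_nm"].max())) if n else 0)
    height = max(truth.field_height_nm, float(np.ceil(df["y_nm"].max())) if n else 0)
    logger.info("simulated %d localizations from %d molecules", len(df), n_mol)
    return LocalizationTable(
        df,
        camera_pixel_nm=camera_pixel_nm,
        field_width_nm=width,
        field_height_nm=height,
        frames_total=frames_total,
    )


def _integrated_gaussian(x0, y0, sigma_px, cols, rows):
    """Fraction of a unit 2D Gaussian at (x0, y0) px falling in each pixel."""
    s = sigma_px * np.sqrt(2)
    fx = 0.5 * (erf((cols + 1 - x0) / s) - erf((cols - x0) / s))
    fy = 0.5 * (erf((rows + 1 - y0) / s) - erf((rows - y0) / s))
    return fy[:, None] * fx[None, :]


def simulate_frames(
    table: LocalizationTable,
    psf_sigma_nm: float = 130.0,
    photons_per_event: float = 250.0,
    background_photons: float = 5.0,
    frame_dims: tuple[int, int] | None = None,
    poisson_noise: bool = True,
    seed: int | np.random.Generator = 0,
) -> CameraFrameStack:
    """Render a localization table into raw camera frames.

    Each event is an integrated 2D Gaussian PSF of ``photons_per_event``
    total photons centred at its true coordinates on its assigned frame;
    constant background is added and per-pixel Poisson noise applied.
    Events outside the frame bounds are skipped with a warning.
    """
    if psf_sigma_nm <= 0:
        raise ParameterError("psf_sigma_nm must be positive")
    rng = np.random.default_rng(seed)
    p = table.camera_pixel_nm
    if frame_dims is None:
        frame_dims = (
            int(np.ceil(table.field_height_nm / p)),
            int(np.ceil(table.field_width_nm / p)),
        )
    ny, nx = frame_dims
    n_frames = max(int(table.frames_total), 1)
    frames = np.full((n_frames, ny, nx), float(background_photons))

    sigma_px = psf_sigma_nm / p
    half = int(np.ceil(4 * sigma_px)) + 1
    skipped = 0
    for row in table.df.itertuples():
        x_px, y_px = row.x_nm / p, row.y_nm / p
        if not (0 <= x_px < nx and 0 <= y_px < ny):
            skipped += 1
            continue
        cx, cy = int(x_px), int(y_px)
        c0, c1 = max(cx - half, 0), min(cx + half + 1, nx)
        r0, r1 = max(cy - half, 0), min(cy + half + 1, ny)
        patch = _integrated_gaussian(
            x_px, y_px, sigma_px, np.arange(c0, c1), np.arange(r0, r1)
        )
        frames[row.frame, r0:r1, c0:c1] += photons_per_event * patch
    if skipped:
        logger.warning("simulate_frames: skipped %d events outside frame bounds", skipped)
    if poisson_noise:
        frames = rng.poisson(frames).astype(float)
    return CameraFrameStack(
        frames=frames,
        pixel_nm=p,
        psf_sigma_nm=psf_sigma_nm,
        background_photons=background_photons,
    )


def simulate_timecourse(
    P_over_k_endo: float = 0.84,
    P_over_k_exo: float = 1.40,
    t_half_h: float = 40.0,
    times_h=(0.0, 17.0, 41.0),
    noise_sd: float = 0.05,
    replicates: int = 10,
    seed: int | np.random.Generator = 0,
) -> TimecourseSample:
    """Simulate endogenous/exogenous membrane-density time courses.

    The endogenous compartment starts at steady state 1 and relaxes toward
    its (possibly competition-reduced) production/degradation ratio:
    ``endo(t) = (1 - P_e/k) exp(-kt) + P_e/k``. The exogenous compartment
    starts at 0: ``exo(t) = (P_x/k)(1 - exp(-kt))``. Total is their sum
    before noise; multiplicative Gaussian noise is applied per replicate.
    """
    if P_over_k_endo < 0 or P_over_k_exo < 0:
        raise ParameterError("production/degradation ratios must be non-negative")
    if t_half_h <= 0:
        raise ParameterError("t_half_h must be positive")
    times = np.asarray(times_h, dtype=float)
    if np.any(times < 0):
        raise ParameterError("times must be non-negative")
    rng = np.random.default_rng(seed)

    k = np.log(2) / t_half_h
    decay = np.exp(-k * times)
    endo = (1 - P_over_k_endo) * decay + P_over_k_endo
    exo = P_over_k_exo * (1 - decay)
    expected = pd.DataFrame(
        {"time_h": times, "endogenous": endo, "exogenous": exo, "total": endo + exo}
    )

    records = []
    for rep in range(replicates):
        eps = 1 + noise_sd * rng.standard_normal((len(times), 2))
        e = np.maximum(endo * eps[:, 0], 0.0)
        xg = np.maximum(exo * eps[:, 1], 0.0)
        for i, t in enumerate(times):
            records.append(
                {"time_h": t, "replicate": rep, "endogenous": e[i],
                 "exogenous": xg[i], "total": e[i] + xg[i]}
            )
    return TimecourseSample(
        data=pd.DataFrame(records), expected=expected,
        noise_sd=noise_sd, replicates=replicates,
    )
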