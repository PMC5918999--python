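"""Plasma-membrane density quantification and the 3D axial profile.

The per-image statistic is the mean over 5 region-of-interest densities
(mean of means); image means are averaged per experimental group, expressed
as percent of the control group, and compared by one-way ANOVA. Densities
are localized events per square micrometre, not molecules: blinking
multiplicity is unknown for real data, so molecular conversion is out of
scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, ParameterError
from .table import LocalizationTable

logger = logging.getLogger(__name__)

DEFAULT_N_ROIS = 5
DEFAULT_AREA_BOUNDS_UM2 = (0.7, 2.5)
BORDER_MARGIN_NM = 1000.0
AXIAL_BIN_NM = 100.0


@dataclass
class Roi:
    x_nm: float
    y_nm: float
    width_nm: float
    height_nm: float

    @property
    def area_um2(self) -> float:
        return self.width_nm * self.height_nm / 1e6

    @property
    def rect(self) -> tuple[float, float, float, float]:
        return (self.x_nm, self.y_nm, self.x_nm + self.width_nm, self.y_nm + self.height_nm)


@dataclass
class RoiSet:
    rois: list
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rois)


@dataclass
class DensityReport:
    per_group: pd.DataFrame  # label, n_images, mean, sem, percent_of_control
    anova_F: float
    anova_p: float
    anova_df: tuple[int, int]
    control_label: str


@dataclass
class AxialProfile:
    bin_edges_nm: np.ndarray  # 100 nm spacing from the coverslip upward
    values: np.ndarray        # normalized to sum exactly 1


def roi_density(table: LocalizationTable, roi: Roi) -> float:
    """Localized events per um^2 within the half-open roi rectangle."""
    if roi.width_nm <= 0 or roi.height_nm <= 0:
        raise ParameterError("roi must have positive area")
    x = table.df["x_nm"].to_numpy(float)
    y = table.df["y_nm"].to_numpy(float)
    x0, y0, x1, y1 = roi.rect
    n = int(np.sum((x >= x0) & (x < x1) & (y >= y0) & (y < y1)))
    return n / roi.area_um2


def select_rois(
    table: LocalizationTable,
    n: int = DEFAULT_N_ROIS,
    area_bounds_um2: tuple[float, float] = DEFAULT_AREA_BOUNDS_UM2,
    seed: int = 0,
) -> RoiSet:
    """Automatic roi placement avoiding localization voids and cell borders.

    Square candidates with areas drawn in ``area_bounds_um2`` are laid on a
    grid; a candidate is accepted iff its local density is at least 25% of
    the image's median candidate density (void avoidance) and it lies at
    least 1 um inside the bounding box of all localizations (border
    avoidance). Of the accepted candidates, the ``n`` with the most uniform
    internal density (lowest quadrant coefficient of variation) are chosen
    greedily without overlap. Deterministic for a given seed; manual rois
    always remain an alternative that bypasses this heuristic.
    """
    if len(table) == 0:
        raise EstimationError("empty table")
    rng = np.random.default_rng(seed)
    x = table.df["x_nm"].to_numpy(float)
    y = table.df["y_nm"].to_numpy(float)
    bx0, bx1 = x.min() + BORDER_MARGIN_NM, x.max() - BORDER_MARGIN_NM
    by0, by1 = y.min() + BORDER_MARGIN_NM, y.max() - BORDER_MARGIN_NM
    if bx1 <= bx0 or by1 <= by0:
        raise EstimationError("field too small after the 1 um border margin; supply manual rois")

    candidates: list[Roi] = []
    step = np.sqrt(area_bounds_um2[0] * 1e6) / 2  # half the smallest roi side
    for cx in np.arange(bx0, bx1, step):
        for cy in np.arange(by0, by1, step):
            side = np.sqrt(rng.uniform(*area_bounds_um2) * 1e6)
            if cx + side <= bx1 and cy + side <= by1:
                candidates.append(Roi(cx, cy, side, side))
    if not candidates:
        raise EstimationError("no candidate rois fit inside the field; supply manual rois")

    densities = np.array([roi_density(table, r) for r in candidates])
    med = float(np.median(densities))
    accept = densities >= 0.25 * med
    if accept.sum() < n:
        raise EstimationError(
            f"only {int(accept.sum())} acceptable roi candidates (< {n}); supply manual rois"
        )

    def uniformity(roi: Roi) -> float:
        # quadrant coefficient of variation; lower = more uniform
        halves_x = (roi.x_nm, roi.x_nm + roi.width_nm / 2)
        halves_y = (roi.y_nm, roi.y_nm + roi.height_nm / 2)
        counts = []
        for qx in halves_x:
            for qy in halves_y:
                counts.append(
                    np.sum((x >= qx) & (x < qx + roi.width_nm / 2)
                           & (y >= qy) & (y < qy + roi.height_nm / 2))
                )
        counts = np.asarray(counts, dtype=float)
        m = counts.mean()
        return float(counts.std() / m) if m > 0 else np.inf

    accepted = [candidates[i] for i in np.nonzero(accept)[0]]
    scores = np.array([uniformity(r) for r in accepted])
    chosen: list[Roi] = []
    for idx in np.argsort(scores, kind="stable"):
        cand = accepted[idx]
        overlap = any(
            not (cand.x_nm + cand.width_nm <= c.x_nm or c.x_nm + c.width_nm <= cand.x_nm
                 or cand.y_nm + cand.height_nm <= c.y_nm or c.y_nm + c.height_nm <= cand.y_nm)
            for c in chosen
        )
        if not overlap:
            chosen.append(cand)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise EstimationError(
            f"could not place {n} non-overlapping rois; supply manual rois"
        )
    logger.info("selected %d rois; median candidate density %.1f /um2", n, med)
    return RoiSet(rois=chosen, diagnostics={"median_candidate_density_um2": med,
                                            "n_candidates": len(candidates),
                                            "n_accepted": int(accept.sum())})


def image_mean_density(table: LocalizationTable, rois: RoiSet) -> float:
    """Mean of the roi densities: the per-image statistic."""
    return float(np.mean([roi_density(table, r) for r in rois.rois]))


def summarize_groups(per_image_means: dict, control_label: str) -> DensityReport:
    """Group means, SEM, percent of control, and one-way ANOVA across groups.

    ``per_image_means`` maps group label -> list of per-image mean densities
    (one entry per cell). SEM = SD / sqrt(n_images) with ddof = 1.
    """
    if control_label not in per_image_means:
        raise ParameterError(f"control group {control_label!r} missing")
    for label, vals in per_image_means.items():
        if len(vals) < 2:
            raise ParameterError(f"group {label!r} needs >= 2 images")

    control_mean = float(np.mean(per_image_means[control_label]))
    rows = []
    for label, vals in per_image_means.items():
        vals = np.asarray(vals, dtype=float)
        rows.append(
            {
                "label": label,
                "n_images": len(vals),
                "mean_per_um2": float(vals.mean()),
                "sem_per_um2": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                "percent_of_control": float(100.0 * vals.mean() / control_mean),
            }
        )
    groups = [np.asarray(v, dtype=float) for v in per_image_means.values()]
    if all(np.allclose(g, groups[0].mean()) for g in groups):
        F, p = 0.0, 1.0  # identical constants: no variance anywhere
    else:
        F, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return DensityReport(
        per_group=pd.DataFrame(rows), anova_F=float(F), anova_p=float(p),
        anova_df=(df1, df2), control_label=control_label,
    )


def axial_profile(table: LocalizationTable, bin_nm: float = AXIAL_BIN_NM,
                  z_max_nm: float | None = None) -> AxialProfile:
    """Histogram of z in 100 nm steps from the coverslip, normalized to sum 1."""
    if bin_nm <= 0:
        raise ParameterError("bin_nm must be positive")
    z = table.df["z_nm"].to_numpy(float)
    if len(z) == 0:
        raise EstimationError("empty table")
    if np.all(z == 0):
        return AxialProfile(bin_edges_nm=np.array([0.0, bin_nm]), values=np.array([1.0]))
    if z_max_nm is None:
        z_max_nm = float(np.ceil(z.max() / bin_nm) * bin_nm)
    edges = np.arange(0.0, z_max_nm + bin_nm, bin_nm)
    counts, _ = np.histogram(z, bins=edges)
    total = counts.sum()
    if total == 0:
        raise EstimationError("no localizations below z_max")
    return AxialProfile(bin_edges_nm=edges, values=counts / total)
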