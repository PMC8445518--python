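"""NEMA-style region-of-interest analysis of reconstructed images.

Per sphere: a circular ROI of the sphere's inner diameter on the central
slice, 60 equally sized background ROIs, and a half-diameter ROI for
bias analysis across noise realizations.  Figures of merit follow the
NEMA NU-2 image-quality conventions: contrast recovery coefficient
(CRC), background variability (BV), and a contrast-to-noise ratio

    CNR_r = (mu_H,r - mu_B,r) / sqrt(sigma_H,r^2 + sigma_B,r^2)

where sigma_B is the average standard deviation over the background
ROIs.

Layout note: the NEMA standard spreads its 60 background ROIs over five
slices; on a single-slice desk grid all 60 sit on the central slice (12
angular positions times 5 radial rings), so same-size background ROIs
may overlap one another.  They never overlap any sphere (wall included)
and keep 15 mm clearance from the phantom edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PhantomSpec, VoxelGrid

__all__ = [
    "CircularROI",
    "SphereROIs",
    "ROISet",
    "place_rois",
    "roi_mean",
    "crc",
    "crc_cold",
    "background_variability",
    "cnr",
    "bias_analysis",
    "metrics_over_iterations",
]

N_BACKGROUND_ROIS = 60
EDGE_CLEARANCE_MM = 15.0


@dataclass(frozen=True)
class CircularROI:
    """Circular ROI on one transaxial slice; mask by voxel-center test."""

    center_xy_mm: tuple[float, float]
    diameter_mm: float
    slice_index: int

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        x = grid.axis_centers(0)[:, None]
        y = grid.axis_centers(1)[None, :]
        cx, cy = self.center_xy_mm
        return (x - cx) ** 2 + (y - cy) ** 2 <= (self.diameter_mm / 2) ** 2

    def n_voxels(self, grid: VoxelGrid) -> int:
        return int(self.mask(grid).sum())


@dataclass(frozen=True)
class SphereROIs:
    sphere_diameter_mm: float
    is_hot: bool
    sphere_roi: CircularROI
    background_rois: tuple[CircularROI, ...]
    half_diameter_roi: CircularROI


@dataclass(frozen=True)
class ROISet:
    spheres: tuple[SphereROIs, ...]
    slice_index: int


def roi_mean(image: np.ndarray, roi: CircularROI, grid: VoxelGrid) -> float:
    return float(image[:, :, roi.slice_index][roi.mask(grid)].mean())


def _roi_sd(image: np.ndarray, roi: CircularROI, grid: VoxelGrid) -> float:
    values = image[:, :, roi.slice_index][roi.mask(grid)]
    return float(values.std(ddof=1)) if values.size > 1 else 0.0


def place_rois(phantom: PhantomSpec, grid: VoxelGrid) -> ROISet:
    """Deterministic ROI placement from the analytic phantom layout.

    Sphere ROIs take the known sphere centers and inner diameters (no
    estimation from the image).  Background ROI centers are searched on
    concentric rings at 12 angular positions offset from the sphere
    angles; a ring is used only if every position clears all spheres and
    the phantom edge, and five admissible rings give the 60 ROIs.
    """
    if phantom.nema is None:
        raise ValueError("ROI placement requires a NEMA-layout phantom")
    layout = phantom.nema
    slice_index = int(np.argmin(np.abs(grid.axis_centers(2))))

    min_d = min(layout.sphere_inner_diameters_mm)
    n_min = CircularROI((0.0, 0.0), min_d, slice_index).n_voxels(grid)
    if n_min < 5:
        raise ValueError(
            f"grid too coarse: smallest ROI ({min_d} mm) covers {n_min} voxels"
        )

    sphere_outer = [
        d / 2 + layout.wall_thickness_mm for d in layout.sphere_inner_diameters_mm
    ]
    centers2d = [c[:2] for c in layout.sphere_centers_mm]
    half_extent = min(grid.extent_mm[0], grid.extent_mm[1]) / 2

    spheres = []
    for (cx, cy, _cz), d, hot in zip(
        layout.sphere_centers_mm, layout.sphere_inner_diameters_mm, layout.sphere_is_hot
    ):
        roi_r = d / 2
        angles = np.radians(15 + 30 * np.arange(12))
        r_max = min(
            layout.body_radius_mm - EDGE_CLEARANCE_MM - roi_r, half_extent - roi_r
        )
        bg: list[CircularROI] = []
        for ring_r in np.arange(r_max, -0.5, -1.5):
            ok = True
            for a in angles:
                px, py = ring_r * math.cos(a), ring_r * math.sin(a)
                for (sx, sy), s_out in zip(centers2d, sphere_outer):
                    if math.hypot(px - sx, py - sy) < roi_r + s_out:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                for a in angles:
                    bg.append(
                        CircularROI(
                            (ring_r * math.cos(a), ring_r * math.sin(a)), d, slice_index
                        )
                    )
            if len(bg) >= N_BACKGROUND_ROIS:
                break
        if len(bg) < N_BACKGROUND_ROIS:
            raise ValueError(
                f"could not place {N_BACKGROUND_ROIS} background ROIs of "
                f"{d} mm inside the phantom body"
            )
        spheres.append(
            SphereROIs(
                sphere_diameter_mm=d,
                is_hot=hot,
                sphere_roi=CircularROI((cx, cy), d, slice_index),
                background_rois=tuple(bg[:N_BACKGROUND_ROIS]),
                half_diameter_roi=CircularROI((cx, cy), d / 2, slice_index),
            )
        )
    return ROISet(spheres=tuple(spheres), slice_index=slice_index)


def crc(mu_hot: float, mu_bg: float, activity_ratio: float) -> float:
    """Hot-sphere contrast recovery coefficient, percent."""
    if mu_bg <= 0:
        raise ValueError("background mean must be positive")
    if activity_ratio == 1:
        raise ValueError("hot CRC undefined for activity ratio 1")
    return 100.0 * (mu_hot / mu_bg - 1.0) / (activity_ratio - 1.0)


def crc_cold(mu_cold: float, mu_bg: float) -> float:
    """Cold-sphere contrast recovery coefficient, percent."""
    if mu_bg <= 0:
        raise ValueError("background mean must be positive")
    return 100.0 * (1.0 - mu_cold / mu_bg)


def background_variability(bg_roi_means: np.ndarray) -> float:
    """Relative SD (percent) of the background ROI means, N-1 denominator."""
    means = np.asarray(bg_roi_means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 background ROIs")
    m = means.mean()
    if m == 0:
        raise ValueError("background mean is zero")
    return 100.0 * means.std(ddof=1) / m


def cnr(mu_hot: float, mu_bg: float, sigma_hot: float, sigma_bg: float) -> float:
    """Contrast-to-noise ratio; negative for cold contrast."""
    denom = sigma_hot**2 + sigma_bg**2
    if denom <= 0:
        raise ValueError("CNR undefined: both SDs are zero")
    return (mu_hot - mu_bg) / math.sqrt(denom)


def bias_analysis(
    images: list[np.ndarray],
    roi_set: ROISet,
    grid: VoxelGrid,
    expected_kBq_cc: dict[float, float],
) -> pd.DataFrame:
    """Half-diameter ROI bias across noise realizations.

    ``expected_kBq_cc`` maps sphere diameter to the expected activity
    concentration.  Bias is the mean ROI value across realizations
    relative to the expected value (percent, hot spheres); the standard
    error over realizations is reported alongside.  Spheres with zero
    expected activity report the absolute offset instead of a percent.
    """
    if len(images) < 2:
        raise ValueError("bias analysis needs at least 2 noise realizations")
    rows = []
    for sph in roi_set.spheres:
        vals = np.array([roi_mean(img, sph.half_diameter_roi, grid) for img in images])
        expected = expected_kBq_cc[sph.sphere_diameter_mm]
        mean = vals.mean()
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        if expected > 0:
            bias = 100.0 * (mean - expected) / expected
            se_pct = 100.0 * se / expected
        else:
            bias = mean  # absolute offset for cold spheres
            se_pct = se
        rows.append(
            {
                "sphere_diameter_mm": sph.sphere_diameter_mm,
                "is_hot": sph.is_hot,
                "expected_kBq_cc": expected,
                "mean_kBq_cc": mean,
                "bias_percent": bias,
                "se": se_pct,
                "n_realizations": len(vals),
            }
        )
    return pd.DataFrame(rows)


def metrics_over_iterations(
    images_by_model: dict[str, dict[int, np.ndarray]],
    roi_set: ROISet,
    grid: VoxelGrid,
    hot_ratio: float,
) -> pd.DataFrame:
    """CRC / BV / CNR tables: one row per (model, iteration, sphere).

    ``images_by_model`` maps model name to {iteration: image}; all images
    must share ``grid``.
    """
    rows = []
    for model, series in images_by_model.items():
        for iteration in sorted(series):
            image = series[iteration]
            if image.shape != grid.shape:
                raise ValueError(
                    f"image shape {image.shape} does not match grid {grid.shape}"
                )
            for sph in roi_set.spheres:
                mu_h = roi_mean(image, sph.sphere_roi, grid)
                bg_means = np.array(
                    [roi_mean(image, r, grid) for r in sph.background_rois]
                )
                mu_b = float(bg_means.mean())
                sigma_h = _roi_sd(image, sph.sphere_roi, grid)
                sigma_b = float(
                    np.mean([_roi_sd(image, r, grid) for r in sph.background_rois])
                )
                rows.append(
                    {
                        "model": model,
                        "iteration": iteration,
                        "sphere_diameter_mm": sph.sphere_diameter_mm,
                        "is_hot": sph.is_hot,
                        "mu_hot": mu_h,
                        "mu_bg": mu_b,
                        "sigma_hot": sigma_h,
                        "sigma_bg": sigma_b,
                        "crc_percent": (
                            crc(mu_h, mu_b, hot_ratio)
                            if sph.is_hot
                            else crc_cold(mu_h, mu_b)
                        ),
                        "bv_percent": background_variability(bg_means),
                        # zero SD (noiseless image): CNR undefined, not inf
                        "cnr": (
                            cnr(mu_h, mu_b, sigma_h, sigma_b)
                            if sigma_h**2 + sigma_b**2 > 0
                            else float("nan")
                        ),
                    }
                )
    return pd.DataFrame(rows)
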