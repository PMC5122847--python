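"""Post-processing: quality filtering, super-resolution rendering, and
MSD-based diffusion analysis.

The dSTORM filter chain keeps only localizations with a signal-to-background
ratio above a cutoff and a fitted PSF width inside a plausibility window,
and discards localizations belonging to long-lived tracks (non-blinking
fluorophore clusters).  Surviving localizations are rendered into a
super-resolution histogram, optionally splatting each point as a Gaussian of
width equal to its localization precision.

For tracking data, within-track displacements at each lag are pooled per
axis; the maximum-likelihood Gaussian variance per lag grows linearly with
lag time for free diffusion, ``sigma^2(k t_a) = 2 D k t_a + eps``, so an
ordinary least-squares line through the variances yields the diffusion
coefficient ``D`` (half the slope) and an intercept ``eps`` reflecting
localization error and finite exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ResultTable
from .refinement import _delta_erf

__all__ = [
    "DiffusionFit",
    "filter_localizations",
    "discard_cluster_tracks",
    "render_super_resolution",
    "compute_displacements",
    "estimate_diffusion",
]


def _as_df(table) -> pd.DataFrame:
    return table.df if isinstance(table, ResultTable) else table


def filter_localizations(locs, sbr_min: float = 0.8,
                         sigma_center: float = 1.42,
                         sigma_halfwidth: float = 0.4):
    """Keep localizations with ``sbr > sbr_min`` and ``|sigma_x -
    sigma_center| <= sigma_halfwidth``; row order is preserved."""
    if sigma_halfwidth < 0:
        raise ValueError("sigma_halfwidth must be >= 0")
    df = _as_df(locs)
    keep = (df["sbr"] > sbr_min) & (np.abs(df["sigma_x"] - sigma_center) <= sigma_halfwidth)
    out = df[keep]
    return ResultTable(out.reset_index(drop=True), locs.stage_tag) if isinstance(locs, ResultTable) else out


def discard_cluster_tracks(locs, tracks, max_track_length: int = 25):
    """Remove localizations on tracks longer than ``max_track_length`` frames.

    Tracks mark non-blinking emitters (fluorophore clusters); a track of
    exactly ``max_track_length`` points is kept (the rule is strictly
    "longer than").  ``tracks`` must carry a ``loc_index`` column referring
    to row positions in ``locs``; untracked localizations are kept.
    """
    df = _as_df(locs)
    tdf = _as_df(tracks)
    if len(tdf) == 0:
        return locs
    lengths = tdf.groupby("track_id")["frame"].size()
    long_ids = lengths[lengths > max_track_length].index
    bad = tdf.loc[tdf["track_id"].isin(long_ids), "loc_index"].to_numpy().astype(int)
    keep = np.ones(len(df), dtype=bool)
    keep[bad] = False
    out = df[keep].reset_index(drop=True)
    return ResultTable(out, locs.stage_tag) if isinstance(locs, ResultTable) else out


def render_super_resolution(locs, out_pixel_nm: float, mode: str = "counts",
                            pixel_size_nm: float = 1.0,
                            field_nm: float | None = None) -> np.ndarray:
    """Render localizations into a super-resolution image.

    ``counts`` mode builds a plain 2D histogram; ``precision_weighted`` mode
    splats each localization as a unit-integral pixel-integrated Gaussian
    whose per-axis width equals its localization precision (columns
    ``precision_x`` / ``precision_y``, nm).  In both modes the image sums to
    the number of localizations (up to Gaussian truncation at 5 sigma).
    """
    if mode not in ("counts", "precision_weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    df = _as_df(locs)
    x_nm = df["x"].to_numpy(dtype=float) * pixel_size_nm
    y_nm = df["y"].to_numpy(dtype=float) * pixel_size_nm
    if field_nm is None:
        field_nm = float(max(x_nm.max(), y_nm.max()) + 3 * out_pixel_nm) if len(df) else out_pixel_nm
    n = max(int(math.ceil(field_nm / out_pixel_nm)), 1)
    img = np.zeros((n, n))
    if mode == "counts":
        edges = np.arange(n + 1) * out_pixel_nm
        h, _, _ = np.histogram2d(y_nm, x_nm, bins=(edges, edges))
        return h
    for col in ("precision_x", "precision_y"):
        if col not in df.columns:
            raise ValueError(f"precision_weighted mode requires column {col!r}")
    px = df["precision_x"].to_numpy(dtype=float)
    py = df["precision_y"].to_numpy(dtype=float)
    for xi, yi, sx, sy in zip(x_nm / out_pixel_nm, y_nm / out_pixel_nm,
                              px / out_pixel_nm, py / out_pixel_nm):
        sx = max(sx, 1e-3)
        sy = max(sy, 1e-3)
        rx = int(math.ceil(5 * sx)) + 1
        ry = int(math.ceil(5 * sy)) + 1
        cx, cy = int(round(xi)), int(round(yi))
        x0, x1 = max(cx - rx, 0), min(cx + rx + 1, n)
        y0, y1 = max(cy - ry, 0), min(cy + ry + 1, n)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = _delta_erf(np.arange(x0, x1) - xi, sx)
        gy = _delta_erf(np.arange(y0, y1) - yi, sy)
        img[y0:y1, x0:x1] += np.outer(gy, gx)
    return img


def compute_displacements(tracks, max_lag: int = 5) -> dict:
    """Pooled per-axis displacements at each lag.

    For every track and every lag ``k <= max_lag``, collects the
    displacement vectors between points exactly ``k`` frames apart whose
    intermediate frames are all present (intervals spanning a gap-bridged
    stretch are excluded, since their effective time interval is ambiguous).
    The x- and y-components are pooled into a single 1D sample per lag.
    Returns ``{k: 1D ndarray}`` in px.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    tdf = _as_df(tracks)
    out = {k: [] for k in range(1, max_lag + 1)}
    for _, g in tdf.groupby("track_id"):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy().astype(int)
        xs = g["x"].to_numpy(dtype=float)
        ys = g["y"].to_numpy(dtype=float)
        pos = {int(f): i for i, f in enumerate(frames)}
        present = set(pos)
        for k in range(1, max_lag + 1):
            for f in frames:
                f = int(f)
                if f + k not in present:
                    continue
                if any((f + m) not in present for m in range(1, k)):
                    continue
                i, j = pos[f], pos[f + k]
                out[k].append(xs[j] - xs[i])
                out[k].append(ys[j] - ys[i])
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}


@dataclass
class DiffusionFit:
    """Linear MSD fit ``sigma^2 = 2 D dt + eps`` (per-axis convention)."""

    lag_times_s: np.ndarray
    msd_um2: np.ndarray           # per-axis Gaussian variance per lag
    diffusion_um2_s: float
    epsilon_um2: float
    fit_stderr_D: float
    n_per_lag: np.ndarray
    negative_D: bool = False      # flagged, not clipped


def estimate_diffusion(displacements: dict, frame_time_s: float,
                       pixel_size_nm: float, min_count: int = 50,
                       min_lags: int = 3,
                       variance_mode: str = "mle") -> DiffusionFit:
    """Fit a diffusion coefficient from pooled per-axis displacements.

    Per lag, the zero-mean Gaussian variance of the pooled 1D components is
    estimated (closed-form MLE ``mean(d^2)`` by default; ``histogram`` mode
    least-squares-fits a Gaussian to the normalized displacement histogram).
    The variances, converted to um^2, are regressed on lag time by ordinary
    least squares; per axis ``sigma^2 = 2 D dt + eps``.
    """
    if variance_mode not in ("mle", "histogram"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    lags = sorted(k for k, v in displacements.items() if len(v) >= min_count)
    if len(lags) < min_lags:
        raise ValueError(
            f"need >= {min_lags} lags with >= {min_count} displacements, "
            f"got {len(lags)}"
        )
    px_um = pixel_size_nm / 1000.0
    var_um2 = []
    counts = []
    for k in lags:
        d_um = displacements[k] * px_um
        if variance_mode == "mle":
            v = float(np.mean(d_um ** 2))
        else:
            v = _histogram_gaussian_variance(d_um)
        var_um2.append(v)
        counts.append(len(d_um))
    t = np.array(lags, dtype=float) * frame_time_s
    v = np.array(var_um2)
    design = np.column_stack([2.0 * t, np.ones_like(t)])
    coef, res, _, _ = np.linalg.lstsq(design, v, rcond=None)
    d_est, eps = float(coef[0]), float(coef[1])
    dof = len(t) - 2
    if dof > 0:
        resid = v - design @ coef
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
        stderr_d = math.sqrt(max(cov[0, 0], 0.0))
    else:
        stderr_d = math.nan
    return DiffusionFit(t, v, d_est, eps, stderr_d, np.array(counts),
                        negative_D=d_est < 0)


def _histogram_gaussian_variance(d: np.ndarray) -> float:
    """Least-squares Gaussian fit to a normalized displacement histogram."""
    from scipy.optimize import curve_fit
    n_bins = max(int(math.sqrt(len(d))), 11)
    hist, edges = np.histogram(d, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, s):
        return np.exp(-x * x / (2 * s * s)) / (math.sqrt(2 * math.pi) * s)

    s0 = max(float(np.std(d)), 1e-12)
    popt, _ = curve_fit(gauss, centers, hist, p0=[s0])
    return float(popt[0] ** 2)
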