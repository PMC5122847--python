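"""Scoring localization output against ground truth.

Detected localizations are paired per frame with ground-truth emitters by an
optimal one-to-one assignment restricted to a pairing radius; paired points
are true positives, unpaired detections false positives, unpaired truth
false negatives.  Summary statistics are the Jaccard index ``JAC = TP / (TP
+ FN + FP)`` and the root-mean-square error over paired distances.

Structural resolution is measured by Fourier ring correlation (FRC): both
point sets are rendered into super-resolution histograms, and the
correlation between their Fourier transforms is averaged over rings of equal
spatial frequency; the resolution is the inverse of the frequency where the
curve first drops to 1/7th of its maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tracking import assign_frame_pair

__all__ = ["MatchResult", "FRCCurve", "match_localizations", "frc_curve"]


@dataclass
class MatchResult:
    """TP/FP/FN pairing of found localizations against ground truth."""

    pairs: list                    # (truth index, found index, distance px)
    n_tp: int
    n_fp: int
    n_fn: int
    jac: float
    rmse: float
    rmse_unit: str = "px"
    degenerate: bool = False       # both sets empty


def match_localizations(truth, found, radius: float,
                        pixel_size_nm: float | None = None) -> MatchResult:
    """Pair found localizations with ground truth, frame by frame.

    ``truth`` and ``found`` are DataFrames with ``frame, x, y`` columns
    (positions in px).  Within each frame the pairing is the optimal
    assignment among pairs with distance <= ``radius`` (maximum pair count,
    then minimum total distance).  If ``pixel_size_nm`` is given the RMSE is
    reported in nm.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    t = truth.reset_index(drop=True)
    f = found.reset_index(drop=True)
    if len(t) == 0 and len(f) == 0:
        return MatchResult([], 0, 0, 0, 1.0, 0.0, degenerate=True)

    pairs = []
    t_groups = dict(tuple(t.groupby("frame"))) if len(t) else {}
    f_groups = dict(tuple(f.groupby("frame"))) if len(f) else {}
    for frame in sorted(set(t_groups) | set(f_groups)):
        tg = t_groups.get(frame)
        fg = f_groups.get(frame)
        if tg is None or fg is None:
            continue
        a = tg[["x", "y"]].to_numpy(dtype=float)
        b = fg[["x", "y"]].to_numpy(dtype=float)
        for i, j in assign_frame_pair(a, b, radius):
            d = float(np.linalg.norm(a[i] - b[j]))
            pairs.append((int(tg.index[i]), int(fg.index[j]), d))

    n_tp = len(pairs)
    n_fp = len(f) - n_tp
    n_fn = len(t) - n_tp
    jac = n_tp / (n_tp + n_fn + n_fp) if (n_tp + n_fn + n_fp) else 1.0
    if n_tp:
        rmse = math.sqrt(sum(d * d for (_, _, d) in pairs) / n_tp)
    else:
        rmse = 0.0
    unit = "px"
    if pixel_size_nm is not None:
        rmse *= pixel_size_nm
        unit = "nm"
    return MatchResult(pairs, n_tp, n_fp, n_fn, jac, rmse, rmse_unit=unit)


@dataclass
class FRCCurve:
    """Fourier ring correlation versus spatial frequency."""

    spatial_frequency: np.ndarray  # nm^-1 per ring
    correlation: np.ndarray        # raw ring correlation
    smoothed: np.ndarray           # moving-average curve used for the cutoff
    threshold: float               # fraction of the curve maximum (1/7)
    resolution_nm: float           # inverse crossing frequency; nan if none
    no_crossing: bool = False


def _bin_positions(pos_nm: np.ndarray, n: int, super_px: float) -> np.ndarray:
    edges = np.arange(n + 1) * super_px
    h, _, _ = np.histogram2d(pos_nm[:, 1], pos_nm[:, 0], bins=(edges, edges))
    return h


def frc_curve(set_a, set_b, super_px_nm: float, field_nm: float,
              pixel_size_nm: float = 1.0, threshold: float = 1.0 / 7.0,
              smooth_width: int = 3) -> FRCCurve:
    """Fourier ring correlation between two localization sets.

    ``set_a`` / ``set_b`` are DataFrames with ``x, y`` in px (scaled by
    ``pixel_size_nm``); both are binned into 2D histograms of bin size
    ``super_px_nm`` over a square field of ``field_nm``.  The per-ring
    correlation is ``Re<F_A conj(F_B)> / sqrt(<|F_A|^2><|F_B|^2>)``; the
    resolution is the inverse of the lowest frequency where the smoothed
    curve (moving average over ``smooth_width`` rings) first drops below
    ``threshold`` times the curve maximum.
    """
    n = int(math.ceil(field_nm / super_px_nm))
    if n < 64:
        raise ValueError("field must span at least 64 super-pixels")
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both localization sets must be non-empty")

    a_nm = set_a[["x", "y"]].to_numpy(dtype=float) * pixel_size_nm
    b_nm = set_b[["x", "y"]].to_numpy(dtype=float) * pixel_size_nm
    ha = _bin_positions(a_nm, n, super_px_nm)
    hb = _bin_positions(b_nm, n, super_px_nm)

    fa = np.fft.fftshift(np.fft.fft2(ha))
    fb = np.fft.fftshift(np.fft.fft2(hb))
    cy = cx = n // 2
    yy, xx = np.indices((n, n))
    ring = np.round(np.hypot(yy - cy, xx - cx)).astype(int)
    n_rings = n // 2
    num = np.zeros(n_rings)
    den_a = np.zeros(n_rings)
    den_b = np.zeros(n_rings)
    cross = (fa * np.conj(fb)).real
    pa = np.abs(fa) ** 2
    pb = np.abs(fb) ** 2
    mask = ring < n_rings
    np.add.at(num, ring[mask], cross[mask])
    np.add.at(den_a, ring[mask], pa[mask])
    np.add.at(den_b, ring[mask], pb[mask])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(den_a * den_b)
    corr = np.nan_to_num(corr, nan=0.0)

    freq = np.arange(n_rings) / (n * super_px_nm)  # nm^-1

    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        smoothed = np.convolve(corr, kernel, mode="same")
        # edges of 'same' convolution average fewer rings; renormalize
        norm = np.convolve(np.ones_like(corr), kernel, mode="same")
        smoothed = smoothed / norm
    else:
        smoothed = corr.copy()

    cutoff = threshold * float(np.max(smoothed))
    below = np.nonzero(smoothed[1:] < cutoff)[0]
    if len(below) == 0 or len(set_a) < 2 or len(set_b) < 2:
        return FRCCurve(freq, corr, smoothed, threshold, math.nan, no_crossing=True)
    k = int(below[0]) + 1
    if freq[k] <= 0:
        return FRCCurve(freq, corr, smoothed, threshold, math.nan, no_crossing=True)
    return FRCCurve(freq, corr, smoothed, threshold, 1.0 / freq[k], no_crossing=False)
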