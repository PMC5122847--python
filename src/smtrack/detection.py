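"""Stage 2: candidate detection.

Three score-image filters are provided -- a band-pass (difference of
Gaussians), normalized cross-correlation against an in-focus PSF template,
and an a-trous B3-spline wavelet filter -- followed by thresholded
local-maximum extraction with minimum-distance suppression.

All convolutions use mirror boundary handling so that flat image borders do
not produce spurious maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template

from .refinement import integrated_gaussian_kernel

__all__ = [
    "ScoreImage",
    "bandpass_filter",
    "crosscorr_score",
    "wavelet_filter",
    "atrous_decompose",
    "find_candidates",
]


@dataclass
class ScoreImage:
    """A per-pixel detection response map with provenance.

    ``threshold_rule`` records how a data-driven cutoff should be computed
    (free text); filters that suggest one also expose it numerically via
    ``suggested_threshold``.
    """

    values: np.ndarray
    origin: str
    threshold_rule: str = ""
    suggested_threshold: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("score image must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score image contains non-finite values")


def bandpass_filter(frame: np.ndarray, feature_size: float, background_size: float) -> ScoreImage:
    """Difference-of-Gaussians band-pass.

    ``feature_size`` and ``background_size`` are the standard deviations (px)
    of the small- and large-scale smoothings; the response is their
    difference, which is zero-mean on constant input.
    """
    if not 0 < feature_size < background_size:
        raise ValueError(
            f"need 0 < feature_size < background_size, got "
            f"{feature_size}, {background_size}"
        )
    frame = np.asarray(frame, dtype=float)
    small = ndimage.gaussian_filter(frame, feature_size, mode="mirror")
    large = ndimage.gaussian_filter(frame, background_size, mode="mirror")
    return ScoreImage(small - large, origin="bandpass",
                      threshold_rule="absolute response threshold")


def crosscorr_score(frame: np.ndarray, sigma_psf: float, window: int) -> ScoreImage:
    """Normalized cross-correlation against an integrated-Gaussian template.

    Scores lie in [-1, 1]; patches with zero variance (flat regions) score 0.
    ``window`` is the odd template edge length; ``2*ceil(3*sigma)+1`` or more
    is recommended so the template captures the full spot.
    """
    frame = np.asarray(frame, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(frame.shape):
        raise ValueError(f"window {window} larger than frame {frame.shape}")
    half = window // 2
    template = integrated_gaussian_kernel(window, mu_x=half, mu_y=half,
                                          sigma_x=sigma_psf, sigma_y=sigma_psf)
    score = match_template(frame, template, pad_input=True, mode="reflect")
    score = np.nan_to_num(score, nan=0.0, posinf=0.0, neginf=0.0)
    return ScoreImage(np.clip(score, -1.0, 1.0), origin="crosscorr",
                      threshold_rule="correlation coefficient threshold")


_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def atrous_decompose(frame: np.ndarray, levels: int) -> tuple[list, np.ndarray]:
    """Undecimated a-trous B3-spline wavelet decomposition.

    Returns ``(detail_planes, smooth)`` where ``sum(detail_planes) + smooth``
    reconstructs the input exactly.  At level ``j`` the separable B3 kernel
    is dilated by inserting ``2**(j-1) - 1`` zeros between taps.
    """
    frame = np.asarray(frame, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    smooth = frame
    details = []
    for j in range(1, levels + 1):
        spacing = 2 ** (j - 1)
        support = 4 * spacing + 1
        if support > min(frame.shape):
            raise ValueError(
                f"frame {frame.shape} smaller than kernel support {support} "
                f"at level {j}"
            )
        kernel = np.zeros(support)
        kernel[::spacing] = _B3
        nxt = ndimage.convolve1d(smooth, kernel, axis=0, mode="mirror")
        nxt = ndimage.convolve1d(nxt, kernel, axis=1, mode="mirror")
        details.append(smooth - nxt)
        smooth = nxt
    return details, smooth


def wavelet_filter(frame: np.ndarray, levels: int = 2, k_sigma: float = 2.0,
                   detail_plane: int = 2) -> ScoreImage:
    """Spot-scale wavelet response with a robust noise threshold.

    Returns detail plane ``detail_plane`` (1-based; default the 2nd, which
    isolates structure at the scale of a diffraction-limited spot) of the
    a-trous transform.  The suggested threshold is ``k_sigma`` times a robust
    estimate of the noise standard deviation from the 1st (finest) detail
    plane, ``median(|plane1|) / 0.6745``.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if not 1 <= detail_plane <= levels:
        raise ValueError("detail_plane must be in [1, levels]")
    details, _ = atrous_decompose(frame, levels)
    noise_sigma = float(np.median(np.abs(details[0]))) / 0.6745
    return ScoreImage(
        details[detail_plane - 1],
        origin="wavelet",
        threshold_rule=f"{k_sigma} x median(|plane1|)/0.6745",
        suggested_threshold=k_sigma * noise_sigma,
    )


def find_candidates(score: ScoreImage, threshold: float, min_distance: float = 3.0,
                    border: int = 0, frame_index: int = 0) -> pd.DataFrame:
    """Extract integer-pixel local maxima from a score image.

    Keeps strict local maxima with ``score > threshold`` (strict inequality),
    suppresses any maximum within Euclidean ``min_distance`` of a stronger
    one (equal scores: the one with smaller ``(y, x)`` wins), and drops
    maxima within ``border`` px of the image edge so a refinement window can
    always be placed.  Result columns: ``frame, x, y, score``, sorted by
    ``(y, x)``.
    """
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    values = score.values
    # strict local maxima on 8-neighbourhoods; plateaus resolved by (y, x) order
    footprint_max = ndimage.maximum_filter(values, size=3, mode="mirror")
    is_peak = (values >= footprint_max) & (values > threshold)
    ys, xs = np.nonzero(is_peak)
    if border > 0:
        keep = (
            (ys >= border) & (ys < values.shape[0] - border)
            & (xs >= border) & (xs < values.shape[1] - border)
        )
        ys, xs = ys[keep], xs[keep]
    scores = values[ys, xs]
    # rank by descending score, ties by smaller (y, x); greedy suppression
    order = np.lexsort((xs, ys, -scores))
    kept_y, kept_x, kept_s = [], [], []
    min_d2 = float(min_distance) ** 2
    for idx in order:
        y, x = int(ys[idx]), int(xs[idx])
        ok = True
        for ky, kx in zip(kept_y, kept_x):
            if (ky - y) ** 2 + (kx - x) ** 2 < min_d2:
                ok = False
                break
        if ok:
            kept_y.append(y)
            kept_x.append(x)
            kept_s.append(float(scores[idx]))
    df = pd.DataFrame(
        {
            "frame": np.full(len(kept_x), frame_index, dtype=int),
            "x": np.array(kept_x, dtype=float),
            "y": np.array(kept_y, dtype=float),
            "score": np.array(kept_s, dtype=float),
        }
    )
    return df.sort_values(["y", "x"], kind="mergesort").reset_index(drop=True)
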