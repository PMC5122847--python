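"""Stage 1: dark-signal correction and count-to-photon conversion.

Quantitative maximum-likelihood fitting needs pixel values in photons.  For a
camera with linear gain ``g`` (counts/photon) and offset ``o`` (counts), and
an optional dark image ``d`` (mean dark counts per pixel), the conversion is

    photons = max(0, counts - o - d) / g

Negative corrected values (possible through read noise) are clipped to zero
because a Poisson mean cannot be negative; the number of clipped pixels is
logged.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .core_io import MovieStack

__all__ = ["convert_to_photons", "mean_dark_image"]

logger = logging.getLogger(__name__)


def mean_dark_image(dark_movie: MovieStack) -> np.ndarray:
    """Pixelwise mean of a dark-calibration movie."""
    return dark_movie.data.astype(float).mean(axis=0)


def convert_to_photons(
    movie: MovieStack,
    gain: float,
    offset: float = 0.0,
    dark: Optional[np.ndarray] = None,
) -> MovieStack:
    """Convert a counts movie to photons.

    Parameters
    ----------
    movie
        Raw movie in camera counts.
    gain
        Camera gain in counts per photon; must be positive.
    offset
        Constant camera offset in counts.
    dark
        Optional mean dark image (H x W, counts) subtracted pixelwise; pass a
        3D stack through :func:`mean_dark_image` first.
    """
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    data = movie.data.astype(float)
    corrected = data - offset
    if dark is not None:
        dark = np.asarray(dark, dtype=float)
        if dark.ndim == 3:
            dark = dark.mean(axis=0)
        if dark.shape != movie.data.shape[1:]:
            raise ValueError(
                f"dark image shape {dark.shape} does not match frame shape "
                f"{movie.data.shape[1:]}"
            )
        corrected = corrected - dark
    n_clipped = int(np.count_nonzero(corrected < 0))
    if n_clipped:
        logger.info("clipped %d negative pixels to 0 during photon conversion", n_clipped)
    photons = np.clip(corrected, 0.0, None) / gain
    return MovieStack(
        photons,
        pixel_size_nm=movie.pixel_size_nm,
        frame_time_s=movie.frame_time_s,
        unit_flag="photons",
    )
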