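"""Built-in plugin descriptors wiring the algorithm modules into the
plugin system.

Detection: ``bandpass``, ``crosscorr``, ``wavelet`` (each filter + local
maximum extraction).  Refinement: ``gauss_mle`` (Poisson MLE of an
integrated Gaussian, isotropic or astigmatic) and ``radial_symmetry``.
Tracking: ``nearest_neighbor``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import detection, refinement, tracking
from .plugins import ParameterSpec, PluginDescriptor, register_plugin

__all__ = ["BANDPASS", "CROSSCORR", "WAVELET", "GAUSS_MLE", "RADIAL_SYMMETRY",
           "NEAREST_NEIGHBOR"]


def _candidate_rows(score, frame_index, threshold, min_distance, border):
    return detection.find_candidates(score, threshold=threshold,
                                     min_distance=min_distance, border=border,
                                     frame_index=frame_index)


def _bandpass_main(frame, frame_index, params, upstream):
    score = detection.bandpass_filter(frame, params["feature_size"],
                                      params["background_size"])
    return _candidate_rows(score, frame_index, params["threshold"],
                           params["min_distance"], params["border"])


def _crosscorr_main(frame, frame_index, params, upstream):
    score = detection.crosscorr_score(frame, params["sigma_psf"], params["window"])
    return _candidate_rows(score, frame_index, params["threshold"],
                           params["min_distance"], params["border"])


def _wavelet_main(frame, frame_index, params, upstream):
    score = detection.wavelet_filter(frame, params["levels"], params["k_sigma"],
                                     params["detail_plane"])
    return _candidate_rows(score, frame_index, score.suggested_threshold,
                           params["min_distance"], params["border"])


def _gauss_mle_main(frame, frame_index, params, upstream):
    records = []
    half = params["window"] // 2
    model = params["model"]
    for _, row in upstream.iterrows():
        cx, cy = int(round(row["x"])), int(round(row["y"]))
        if not (half <= cx < frame.shape[1] - half and half <= cy < frame.shape[0] - half):
            continue
        loc = refinement.fit_mle(
            frame, (cx, cy), window=params["window"], model=model,
            sigma_init=params["sigma_init"], max_iter=params["max_iter"],
            tol=params["tol"], frame_index=frame_index,
        )
        if not loc.converged:
            continue
        rec = {
            "frame": frame_index,
            "x": loc.x, "y": loc.y,
            "n_photons": loc.params.n_photons,
            "background": loc.params.background,
            "sigma_x": loc.params.sigma_x,
            "sigma_y": loc.params.sigma_y,
            "theta": loc.params.theta,
            "sbr": loc.sbr,
            "converged": True,
            "n_iterations": loc.n_iterations,
        }
        if params["pixel_size_nm"] > 0:
            # inf marks a fit whose Fisher matrix was singular (no finite
            # precision estimate); such rows are removed by quality filters
            prec_x = prec_y = math.inf
            if loc.params.n_photons > 0:
                try:
                    prec_x, prec_y = refinement.localization_precision(
                        loc, params["pixel_size_nm"], model=model)
                except (ValueError, np.linalg.LinAlgError):
                    prec_x = prec_y = math.inf
            if not (math.isfinite(prec_x) and math.isfinite(prec_y)):
                prec_x = prec_y = math.inf
            rec["precision_x"], rec["precision_y"] = prec_x, prec_y
        records.append(rec)
    return pd.DataFrame(records)


def _radial_symmetry_main(frame, frame_index, params, upstream):
    records = []
    w = params["window"]
    half = w // 2
    for _, row in upstream.iterrows():
        cx, cy = int(round(row["x"])), int(round(row["y"]))
        if not (half <= cx < frame.shape[1] - half and half <= cy < frame.shape[0] - half):
            continue
        win = frame[cy - half: cy + half + 1, cx - half: cx + half + 1]
        rc = refinement.radial_symmetry_center(win)
        border = np.concatenate([win[0, :], win[-1, :], win[1:-1, 0], win[1:-1, -1]])
        b0 = float(np.median(border))
        records.append({
            "frame": frame_index,
            "x": cx - half + rc.x, "y": cy - half + rc.y,
            "n_photons": max(float(win.sum() - b0 * win.size), 0.0),
            "background": b0,
            "sigma_x": params["sigma_psf"],
            "degenerate": rc.degenerate,
        })
    return pd.DataFrame(records)


def _nearest_neighbor_main(movie, params, upstream):
    table = tracking.link_nearest_neighbor(
        upstream, max_dist=params["max_dist"], max_gap=params["max_gap"],
        min_length=params["min_length"],
    )
    return table.df


def _px(name, default, tooltip, lo=None, hi=None, kind="float"):
    rng = None if lo is None and hi is None else (lo, hi)
    return ParameterSpec(name, kind, default, tooltip, rng)


_COMMON_DET = (
    _px("threshold", 0.0, "Minimum filter response for a pixel to seed a candidate."),
    _px("min_distance", 3.0, "Minimum distance (px) between two candidates; "
        "the weaker of a closer pair is suppressed.", lo=1.0),
    _px("border", 4, "Candidates closer than this to the frame edge are "
        "dropped so a refinement window always fits.", lo=0, kind="int"),
)

BANDPASS = register_plugin(PluginDescriptor(
    name="bandpass",
    stage="detection",
    description="Difference-of-Gaussians band-pass filter followed by "
                "thresholded local-maximum extraction.",
    params=(
        _px("feature_size", 1.0, "Width (px std) of the small-scale smoothing; "
            "about the PSF sigma.", lo=0.1),
        _px("background_size", 4.0, "Width (px std) of the large-scale "
            "smoothing estimating local background.", lo=0.2),
    ) + _COMMON_DET,
    main=_bandpass_main,
))

CROSSCORR = register_plugin(PluginDescriptor(
    name="crosscorr",
    stage="detection",
    description="Normalized cross-correlation against a theoretical in-focus "
                "integrated-Gaussian PSF template.",
    params=(
        _px("sigma_psf", 1.0, "Gaussian width (px) of the PSF template.", lo=0.2),
        _px("window", 9, "Odd edge length (px) of the template; at least "
            "2*ceil(3 sigma)+1 recommended.", lo=3, kind="int"),
        _px("threshold", 0.2, "Minimum correlation coefficient (in [-1, 1]) "
            "to seed a candidate.", lo=-1.0, hi=1.0),
        _COMMON_DET[1],
        _COMMON_DET[2],
    ),
    main=_crosscorr_main,
))

WAVELET = register_plugin(PluginDescriptor(
    name="wavelet",
    stage="detection",
    description="A-trous B3-spline wavelet filtering; candidates are maxima "
                "of a detail plane above a robust noise threshold.",
    params=(
        _px("levels", 2, "Number of wavelet decomposition levels.", lo=2, kind="int"),
        _px("k_sigma", 2.0, "Threshold in units of the robust noise std "
            "estimated from the finest detail plane.", lo=0.0),
        _px("detail_plane", 2, "Which detail plane (1-based) to use as the "
            "detection score; plane 2 matches spot-sized structure.", lo=1, kind="int"),
    ) + _COMMON_DET[1:],
    main=_wavelet_main,
))

GAUSS_MLE = register_plugin(PluginDescriptor(
    name="gauss_mle",
    stage="refinement",
    description="Poisson maximum-likelihood fit of a pixel-integrated "
                "Gaussian PSF (isotropic or rotated astigmatic); attaches "
                "CRLB localization precision and signal-to-background ratio.",
    params=(
        _px("window", 9, "Odd fit window edge length in px.", lo=5, kind="int"),
        ParameterSpec("model", "list", "isotropic",
                      "PSF model: 'isotropic' (circular) or 'astigmatic' "
                      "(rotated asymmetric, for 3D via astigmatism).",
                      ("isotropic", "astigmatic")),
        _px("sigma_init", 1.0, "Initial Gaussian width (px); use "
            "psf_sigma_from_optics for a physical default.", lo=0.2),
        _px("max_iter", 100, "Maximum optimizer iterations per fit.", lo=1, kind="int"),
        _px("tol", 1e-6, "Relative convergence tolerance of the fit.", lo=0.0),
        _px("pixel_size_nm", 100.0, "Pixel size (nm) used to express the "
            "localization precision; set 0 to skip precision.", lo=0.0),
    ),
    main=_gauss_mle_main,
))

RADIAL_SYMMETRY = register_plugin(PluginDescriptor(
    name="radial_symmetry",
    stage="refinement",
    description="Non-iterative radial-symmetry center refinement: the "
                "least-squares intersection point of image-gradient lines.",
    params=(
        _px("window", 9, "Odd window edge length in px.", lo=3, kind="int"),
        _px("sigma_psf", 1.0, "Nominal PSF width (px) recorded with each "
            "localization (this refiner does not fit a width).", lo=0.1),
    ),
    main=_radial_symmetry_main,
))

NEAREST_NEIGHBOR = register_plugin(PluginDescriptor(
    name="nearest_neighbor",
    stage="tracking",
    description="Frame-to-frame optimal-assignment linker with sqrt-scaled "
                "gap closing and minimum track length filtering.",
    params=(
        _px("max_dist", 5.0, "Maximum link distance (px) per one-frame "
            "interval; scales with sqrt(gap) across gaps.", lo=0.0),
        _px("max_gap", 0, "Frames an emitter may vanish and still be "
            "linked into the same track.", lo=0, kind="int"),
        _px("min_length", 1, "Minimum number of points per kept track.",
            lo=1, kind="int"),
    ),
    main=_nearest_neighbor_main,
    frame_independent=False,
))
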