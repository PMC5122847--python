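"""High-level composition of the four analysis stages.

``localize_movie`` runs detection + refinement on a (photon-unit) movie and
returns a :class:`ResultBundle` with full provenance; ``track_bundle`` adds
trajectories.  These are the programmatic equivalents of the ``locate`` and
``track`` CLI commands.
"""

from __future__ import annotations

from typing import Optional

from . import builtin_plugins  # noqa: F401  (registers built-in plugins)
from .core_io import MovieStack, ResultBundle
from .plugins import registry, run_stage

__all__ = ["localize_movie", "track_bundle"]


def localize_movie(
    movie: MovieStack,
    detector: str = "wavelet",
    refiner: str = "gauss_mle",
    detector_params: Optional[dict] = None,
    refiner_params: Optional[dict] = None,
    frames: Optional[range] = None,
    n_workers: int = 1,
) -> ResultBundle:
    """Detect and refine emitters in every frame of a movie."""
    det = registry.get("detection", detector)
    ref = registry.get("refinement", refiner)
    frame_order = list(frames) if frames is not None else None
    candidates = run_stage(det, movie, detector_params, frame_order=frame_order,
                           n_workers=n_workers)
    localizations = run_stage(ref, movie, refiner_params, upstream=candidates,
                              frame_order=frame_order, n_workers=n_workers)
    return ResultBundle(
        candidates=candidates,
        localizations=localizations,
        provenance={
            "detection": {"plugin": detector,
                          "params": det.resolve_params(detector_params)},
            "refinement": {"plugin": refiner,
                           "params": ref.resolve_params(refiner_params)},
        },
        movie_meta={
            "pixel_size_nm": movie.pixel_size_nm,
            "frame_time_s": movie.frame_time_s,
            "n_frames": movie.n_frames,
            "shape": list(movie.shape),
            "unit_flag": movie.unit_flag,
        },
    )


def track_bundle(
    bundle: ResultBundle,
    tracker: str = "nearest_neighbor",
    tracker_params: Optional[dict] = None,
) -> ResultBundle:
    """Link the bundle's localizations into trajectories (in place)."""
    if bundle.localizations is None:
        raise ValueError("bundle has no localizations to track")
    trk = registry.get("tracking", tracker)
    movie_stub = None  # tracking operates on the localization table only
    bundle.tracks = run_stage(trk, movie_stub, tracker_params,
                              upstream=bundle.localizations)
    bundle.provenance["tracking"] = {
        "plugin": tracker, "params": trk.resolve_params(tracker_params),
    }
    return bundle
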