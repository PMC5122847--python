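"""Synthetic SMLM/SPT movie generation with known ground truth.

Three movie families are provided:

* **Siemens-star dSTORM movies** -- static emitters scattered on the "on"
  sectors of an n-arm Siemens star, switching stochastically between dark
  and fluorescent states with photobleaching (the standard two-state
  telegraph model with geometric bleaching).
* **Emitter-grid speed-test movies** -- a regular 16 x 16 grid of always-on
  emitters duplicated over many frames (noise redrawn per frame).
* **Brownian-motion movies** -- freely diffusing particles for testing
  tracking and MSD analysis.

Rendering uses the same pixel-integrated Gaussian PSF as the refinement
stage, adds a constant background, optionally rescales the photon yield so
the mean peak signal-to-noise ratio ``s / sqrt(s + b)`` hits a target, and
draws each pixel from a Poisson distribution.  Every generator is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_io import MovieStack
from .refinement import PSFParams, _pixel_kernel, psf_sigma_from_optics

__all__ = [
    "OpticsConfig",
    "BlinkKinetics",
    "siemens_star_positions",
    "in_star_sector",
    "sample_blink_trace",
    "simulate_blinking",
    "render_movie",
    "make_siemens_movie",
    "make_grid_movie",
    "simulate_brownian_movie",
]


@dataclass
class OpticsConfig:
    """Imaging parameters of the simulated microscope.

    ``n_photons`` is the photon yield per frame of a fully active emitter
    before any SNR rescaling; ``background`` is in photons per pixel.
    """

    lambda_em: float = 670.0      # nm
    na: float = 1.4
    pixel_size_nm: float = 100.0
    n_photons: float = 50.0
    background: float = 10.0

    def __post_init__(self) -> None:
        for name in ("lambda_em", "na", "pixel_size_nm", "n_photons", "background"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sigma_px(self) -> float:
        return psf_sigma_from_optics(self.lambda_em, self.na, self.pixel_size_nm)


@dataclass
class BlinkKinetics:
    """Two-state blinking kinetics with photobleaching (rates per frame).

    An emitter waits dark for an exponential time with rate ``k_on``, stays
    active for an exponential time with rate ``k_deactivate = k_off +
    k_bleach``, and at the end of each active period bleaches with
    probability ``p_bleach = k_bleach / k_deactivate`` (so the number of
    activations before bleaching is geometric with mean ``1 / p_bleach``).
    The mean cycle time satisfies ``1/k_active = 1/k_deactivate + 1/k_on``.
    """

    k_on: float
    k_off: float = 1.0
    k_bleach: float = 0.15

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.k_bleach) < 0:
            raise ValueError("rates must be non-negative")
        if self.k_deactivate <= 0:
            raise ValueError("k_off + k_bleach must be positive")

    @property
    def k_deactivate(self) -> float:
        return self.k_off + self.k_bleach

    @property
    def p_bleach(self) -> float:
        return self.k_bleach / self.k_deactivate

    @classmethod
    def storm_default(cls, density: float = 7.5) -> "BlinkKinetics":
        """Standard dSTORM rates: k_off = 1, k_bleach = 0.15,
        k_on = k_off / (5 * density)."""
        return cls(k_on=1.0 / (5.0 * density), k_off=1.0, k_bleach=0.15)


def in_star_sector(x: np.ndarray, y: np.ndarray, center: float, n_arms: int) -> np.ndarray:
    """True where (x, y) falls inside an "on" sector of the Siemens star.

    The star alternates "on"/"off" angular sectors of width ``pi / n_arms``.
    """
    phi = np.mod(np.arctan2(y - center, x - center), 2.0 * math.pi)
    return (np.floor(phi / (math.pi / n_arms)).astype(int) % 2) == 0


def siemens_star_positions(
    n_arms: int = 10,
    grid: int = 256,
    density: float = 7.5,
    seed=None,
    n_emitters: int | None = None,
) -> np.ndarray:
    """Scatter emitters uniformly over the filled arms of a Siemens star.

    The star is inscribed in the ``grid x grid`` field; the expected emitter
    count is Poisson with mean ``density`` per px^2 of "on" area (half the
    inscribed disk), unless ``n_emitters`` overrides it.  Positions are
    continuous (sub-pixel), returned as an ``(n, 2)`` array of ``(x, y)``.
    """
    if n_arms < 1:
        raise ValueError("n_arms must be >= 1")
    rng = np.random.default_rng(seed)
    center = (grid - 1) / 2.0
    radius = grid / 2.0
    if n_emitters is None:
        on_area = math.pi * radius * radius / 2.0
        n_emitters = int(rng.poisson(density * on_area))
    out = np.empty((n_emitters, 2))
    filled = 0
    while filled < n_emitters:
        m = max(2 * (n_emitters - filled), 64)
        pts = rng.uniform(0, grid, size=(m, 2))
        r = np.hypot(pts[:, 0] - center, pts[:, 1] - center)
        ok = (r <= radius) & (r > 1e-9) & in_star_sector(pts[:, 0], pts[:, 1], center, n_arms)
        pts = pts[ok]
        take = min(len(pts), n_emitters - filled)
        out[filled: filled + take] = pts[:take]
        filled += take
    return out


def sample_blink_trace(kinetics: BlinkKinetics, rng, horizon: float | None = None) -> list:
    """Sample one emitter's active intervals until bleaching (or ``horizon``).

    Returns a list of ``(t_on, t_off)`` intervals in frame units.  With
    ``horizon=None`` the trace always runs to the bleaching event.
    """
    intervals = []
    if kinetics.k_on <= 0:
        return intervals
    t = 0.0
    while True:
        t += rng.exponential(1.0 / kinetics.k_on)
        if horizon is not None and t >= horizon:
            break
        dur = rng.exponential(1.0 / kinetics.k_deactivate)
        intervals.append((t, t + dur))
        t += dur
        if rng.random() < kinetics.p_bleach:
            break
    return intervals


def simulate_blinking(
    positions: np.ndarray,
    kinetics: BlinkKinetics,
    n_frames: int,
    seed=None,
) -> pd.DataFrame:
    """Generate per-frame ground truth for blinking emitters.

    Returns a DataFrame ``(frame, emitter_id, x, y, A)`` with one row per
    (frame, emitter) where the emitter was active for a fraction ``A in
    (0, 1]`` of that frame's duration.  Emitters are static; no rows appear
    after an emitter's bleaching event.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for eid, (x, y) in enumerate(np.asarray(positions, dtype=float)):
        for (t0, t1) in sample_blink_trace(kinetics, rng, horizon=float(n_frames)):
            f0 = max(int(math.floor(t0)), 0)
            f1 = min(int(math.ceil(t1)), n_frames)
            for f in range(f0, f1):
                a = min(t1, f + 1.0) - max(t0, float(f))
                if a > 0:
                    rows.append((f, eid, x, y, min(a, 1.0)))
    df = pd.DataFrame(rows, columns=["frame", "emitter_id", "x", "y", "A"])
    if len(df):
        # an emitter can straddle a frame with two activations; merge fractions
        df = (df.groupby(["frame", "emitter_id"], as_index=False)
                .agg(x=("x", "first"), y=("y", "first"), A=("A", "sum")))
        df["A"] = df["A"].clip(upper=1.0)
        df = df.sort_values(["frame", "emitter_id"]).reset_index(drop=True)
    return df


def _expected_frame(shape, truth_frame: pd.DataFrame, amplitude: float,
                    sigma: float, background: float) -> np.ndarray:
    """Noiseless expected image ``b + sum_i A_i * amp * kernel_i``."""
    h, w = shape
    img = np.full((h, w), float(background))
    support = int(math.ceil(4 * sigma)) + 1
    for x, y, a in zip(truth_frame["x"], truth_frame["y"], truth_frame["A"]):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - support, 0), min(cx + support + 1, w)
        y0, y1 = max(cy - support, 0), min(cy + support + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        p = PSFParams(x, y, 1.0, 0.0, sigma)
        k = _pixel_kernel(np.arange(x0, x1, dtype=float),
                          np.arange(y0, y1, dtype=float), p)
        img[y0:y1, x0:x1] += a * amplitude * k
    return img


def _peak_kernel_value(x: float, y: float, sigma: float) -> float:
    """Integrated-Gaussian weight of the pixel under the emitter."""
    p = PSFParams(x, y, 1.0, 0.0, sigma)
    return float(_pixel_kernel(np.array([round(x)], dtype=float),
                               np.array([round(y)], dtype=float), p)[0, 0])


def snr_scale_factor(truth: pd.DataFrame, optics: OpticsConfig, target_snr: float) -> float:
    """Photon-yield rescaling so mean peak SNR equals ``target_snr``.

    SNR of one active emitter is ``s / sqrt(s + b)`` with ``s`` the expected
    peak-pixel signal; the mean over all truth rows is matched by scaling
    ``N`` with the returned factor.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    sigma = optics.sigma_px
    b = optics.background
    peaks = np.array([
        a * optics.n_photons * _peak_kernel_value(x, y, sigma)
        for x, y, a in zip(truth["x"], truth["y"], truth["A"])
    ])
    if len(peaks) == 0:
        return 1.0

    def mean_snr(c):
        s = c * peaks
        return float(np.mean(s / np.sqrt(s + b))) - target_snr

    lo, hi = 1e-9, 1e9
    if mean_snr(lo) > 0 or mean_snr(hi) < 0:
        raise ValueError("target_snr out of attainable range")
    return float(brentq(mean_snr, lo, hi, xtol=1e-10, rtol=1e-12))


def render_movie(
    truth: pd.DataFrame,
    optics: OpticsConfig,
    shape: tuple,
    n_frames: int,
    target_snr: float | None = None,
    seed=None,
    frame_time_s: float | None = None,
) -> tuple:
    """Render ground truth into a Poisson-noisy movie.

    Returns ``(MovieStack, reference)`` where ``reference`` is the noiseless
    expected movie (float T x H x W).  If ``target_snr`` is given the photon
    yield is globally rescaled first (see :func:`snr_scale_factor`).
    """
    rng = np.random.default_rng(seed)
    sigma = optics.sigma_px
    scale = 1.0 if target_snr is None else snr_scale_factor(truth, optics, target_snr)
    amplitude = scale * optics.n_photons
    reference = np.empty((n_frames,) + tuple(shape))
    grouped = dict(tuple(truth.groupby("frame"))) if len(truth) else {}
    empty = pd.DataFrame({"x": [], "y": [], "A": []})
    for f in range(n_frames):
        reference[f] = _expected_frame(shape, grouped.get(f, empty),
                                       amplitude, sigma, optics.background)
    movie = MovieStack(
        rng.poisson(reference).astype(np.float64),
        pixel_size_nm=optics.pixel_size_nm,
        frame_time_s=frame_time_s,
        unit_flag="photons",
    )
    return movie, reference


def make_siemens_movie(
    n_arms: int = 10,
    grid: int = 256,
    density: float = 7.5,
    n_frames: int = 1500,
    target_snr: float | None = None,
    optics: OpticsConfig | None = None,
    kinetics: BlinkKinetics | None = None,
    n_emitters: int | None = None,
    seed=None,
) -> tuple:
    """Siemens-star dSTORM movie with the standard preset.

    Defaults: 10 arms on a 256 x 256 px grid at 100 nm pixels, density 7.5,
    N = 50 photons, b = 10 photons/px, lambda = 670 nm, NA = 1.4, rates
    k_off = 1, k_bleach = 0.15, k_on = k_off/(5 * density), 1500 frames.
    Returns ``(movie, truth, reference)``.
    """
    optics = optics or OpticsConfig()
    kinetics = kinetics or BlinkKinetics.storm_default(density)
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pos, s_blink, s_render = seq.spawn(3)
    positions = siemens_star_positions(n_arms, grid, density, seed=s_pos,
                                       n_emitters=n_emitters)
    truth = simulate_blinking(positions, kinetics, n_frames, seed=s_blink)
    movie, reference = render_movie(truth, optics, (grid, grid), n_frames,
                                    target_snr=target_snr, seed=s_render)
    return movie, truth, reference


def make_grid_movie(
    frame_px: int = 512,
    n_side: int = 16,
    n_frames: int = 3500,
    snr: float = 10.0,
    optics: OpticsConfig | None = None,
    seed=None,
    render: bool = True,
) -> tuple:
    """Speed-test movie: a regular emitter grid duplicated over many frames.

    One expected frame is rendered and duplicated; Poisson noise is redrawn
    independently for every frame.  Ground truth contains ``n_side**2`` rows
    per frame, all with ``A = 1`` (no blinking).  With ``render=False`` only
    the ground truth is built and the movie is ``None``.  Returns
    ``(movie_or_None, truth)``.
    """
    optics = optics or OpticsConfig()
    spacing = frame_px / n_side
    if spacing < 8 * optics.sigma_px:
        raise ValueError("emitter spacing must be >= 8 sigma")
    coords = spacing / 2.0 - 0.5 + spacing * np.arange(n_side)
    gx, gy = np.meshgrid(coords, coords)
    xs, ys = gx.ravel(), gy.ravel()
    n_emitters = n_side * n_side
    frames = np.repeat(np.arange(n_frames), n_emitters)
    truth = pd.DataFrame({
        "frame": frames,
        "emitter_id": np.tile(np.arange(n_emitters), n_frames),
        "x": np.tile(xs, n_frames),
        "y": np.tile(ys, n_frames),
        "A": np.ones(n_emitters * n_frames),
    })
    if not render:
        return None, truth
    rng = np.random.default_rng(seed)
    one = truth[truth["frame"] == 0]
    scale = snr_scale_factor(one, optics, snr)
    expected = _expected_frame((frame_px, frame_px), one,
                               scale * optics.n_photons, optics.sigma_px,
                               optics.background)
    data = np.empty((n_frames, frame_px, frame_px), dtype=np.float64)
    for f in range(n_frames):
        data[f] = rng.poisson(expected)
    movie = MovieStack(data, pixel_size_nm=optics.pixel_size_nm, unit_flag="photons")
    return movie, truth


def simulate_brownian_movie(
    diffusion_um2_s: float,
    frame_time_s: float,
    n_particles: int = 200,
    n_frames: int = 200,
    grid: int = 256,
    optics: OpticsConfig | None = None,
    snr: float | None = 10.0,
    seed=None,
    render: bool = True,
) -> tuple:
    """Brownian-motion movie with ground-truth tracks.

    Per-frame steps are independent Gaussians of per-axis variance
    ``2 * D * t_a`` (converted to px); particles reflect at the field
    borders.  Returns ``(movie, true_tracks)`` where ``true_tracks`` is a
    DataFrame ``(track_id, frame, x, y)``; with ``render=False`` the movie
    is ``None`` (tracks only).
    """
    if diffusion_um2_s < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed)
    px_um = optics.pixel_size_nm / 1000.0
    step_px = math.sqrt(2.0 * diffusion_um2_s * frame_time_s) / px_um
    pos = rng.uniform(0, grid - 1, size=(n_particles, 2))
    traj = np.empty((n_frames, n_particles, 2))
    traj[0] = pos
    span = grid - 1.0
    for f in range(1, n_frames):
        pos = pos + rng.normal(0.0, step_px, size=pos.shape)
        # reflect at [0, grid-1]; in-range coordinates pass through exactly
        outside = (pos < 0) | (pos > span)
        if outside.any():
            pos = np.where(outside,
                           span - np.abs(np.mod(pos, 2 * span) - span), pos)
        traj[f] = pos
    tracks = pd.DataFrame({
        "track_id": np.tile(np.arange(n_particles), n_frames),
        "frame": np.repeat(np.arange(n_frames), n_particles),
        "x": traj[:, :, 0].ravel(),
        "y": traj[:, :, 1].ravel(),
    }).sort_values(["track_id", "frame"]).reset_index(drop=True)
    if not render:
        return None, tracks
    truth = pd.DataFrame({
        "frame": tracks["frame"],
        "emitter_id": tracks["track_id"],
        "x": tracks["x"],
        "y": tracks["y"],
        "A": np.ones(len(tracks)),
    })
    movie, _ = render_movie(truth, optics, (grid, grid), n_frames,
                            target_snr=snr, seed=rng.integers(2 ** 31),
                            frame_time_s=frame_time_s)
    return movie, tracks
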