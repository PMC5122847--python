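"""Stage 3: sub-pixel position refinement.

Candidates are refined by maximum-likelihood fitting of a pixel-integrated
Gaussian PSF under a Poisson noise model, or by the non-iterative
radial-symmetry center finder.  The expected photon count in pixel ``k`` for
an emitter at ``(mu_x, mu_y)`` with ``N`` signal photons, background ``b``
photons/px and widths ``(sigma_x, sigma_y)`` (optionally rotated by
``theta``) is

    mu_k = N * dEx(u_k) * dEy(v_k) + b

where ``dE(t) = [erf((t + 1/2)/(sqrt(2) sigma)) - erf((t - 1/2)/(sqrt(2)
sigma))] / 2`` integrates the Gaussian over the pixel along each (possibly
rotated) axis.  Over an unbounded grid the signal term sums to ``N``.

The theoretical localization precision attached to each fit is the
Cramer-Rao lower bound of the same model, obtained by numerically building
the Fisher information matrix at the fitted parameters -- so precision and
model are always consistent, whatever widths or rotation were fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy import optimize
from scipy.special import erf

__all__ = [
    "PSFParams",
    "Localization",
    "integrated_gaussian_model",
    "integrated_gaussian_kernel",
    "psf_sigma_from_optics",
    "fit_mle",
    "radial_symmetry_center",
    "localization_precision",
    "fisher_information",
    "crlb_position",
    "RadialCenter",
]

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class PSFParams:
    """Parameters of a (possibly rotated, asymmetric) integrated-Gaussian PSF.

    Positions are in pixel units of the enclosing frame; ``n_photons`` is the
    total signal above background; ``background`` is per pixel.  Isotropic
    spots have ``sigma_y == sigma_x`` and ``theta == 0``.
    """

    mu_x: float
    mu_y: float
    n_photons: float
    background: float
    sigma_x: float
    sigma_y: Optional[float] = None
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_y is None:
            self.sigma_y = self.sigma_x
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma must be positive")
        if self.n_photons < 0 or self.background < 0:
            raise ValueError("n_photons and background must be non-negative")


def _delta_erf(t: np.ndarray, sigma: float) -> np.ndarray:
    """Integral of a unit Gaussian over a 1-px bin centered at offset ``t``."""
    s = _SQRT2 * sigma
    return 0.5 * (erf((t + 0.5) / s) - erf((t - 0.5) / s))


def _pixel_kernel(xs: np.ndarray, ys: np.ndarray, p: PSFParams) -> np.ndarray:
    """Per-pixel integrated-Gaussian weights on the grid ``ys x xs``."""
    X, Y = np.meshgrid(xs - p.mu_x, ys - p.mu_y)
    if p.theta != 0.0:
        c, s = math.cos(p.theta), math.sin(p.theta)
        U = c * X + s * Y
        V = -s * X + c * Y
    else:
        U, V = X, Y
    return _delta_erf(U, p.sigma_x) * _delta_erf(V, p.sigma_y)


def integrated_gaussian_model(xs: np.ndarray, ys: np.ndarray, p: PSFParams) -> np.ndarray:
    """Expected photon image ``N * dEx * dEy + b`` on pixel centers ``ys x xs``."""
    return p.n_photons * _pixel_kernel(np.asarray(xs, float), np.asarray(ys, float), p) + p.background


def integrated_gaussian_kernel(window: int, mu_x: float, mu_y: float,
                               sigma_x: float, sigma_y: Optional[float] = None,
                               theta: float = 0.0) -> np.ndarray:
    """Unit-photon integrated-Gaussian template on a ``window x window`` grid."""
    p = PSFParams(mu_x, mu_y, 1.0, 0.0, sigma_x, sigma_y, theta)
    grid = np.arange(window, dtype=float)
    return _pixel_kernel(grid, grid, p)


def psf_sigma_from_optics(lambda_em: float, na: float, pixel_size_nm: float = 1.0) -> float:
    """Gaussian width of an in-focus PSF from emission wavelength and NA.

    Uses the Gaussian approximation of the Airy pattern, ``sigma_nm = 0.21 *
    lambda / NA``, returned in pixel units (nm if ``pixel_size_nm`` is 1).
    """
    if lambda_em <= 0 or na <= 0 or pixel_size_nm <= 0:
        raise ValueError("lambda_em, na, pixel_size_nm must be positive")
    return 0.21 * lambda_em / na / pixel_size_nm


@dataclass
class Localization:
    """A refined localization with fit diagnostics.

    Positions/widths are in pixels of the source frame; ``sbr`` is the
    expected peak signal density (photons in the pixel under the emitter)
    divided by the background.
    """

    frame: int
    params: PSFParams
    sbr: float
    converged: bool
    n_iterations: int
    window: int
    center: tuple  # (cx, cy) integer window center in the frame
    precision_x: float = math.nan  # nm
    precision_y: float = math.nan  # nm

    @property
    def x(self) -> float:
        return self.params.mu_x

    @property
    def y(self) -> float:
        return self.params.mu_y


def _window_grid(center_x: int, center_y: int, window: int):
    half = window // 2
    xs = np.arange(center_x - half, center_x + half + 1, dtype=float)
    ys = np.arange(center_y - half, center_y + half + 1, dtype=float)
    return xs, ys


def _sbr(p: PSFParams) -> float:
    """Peak-pixel signal density over background."""
    if p.background <= 0:
        return math.inf
    px, py = round(p.mu_x), round(p.mu_y)
    peak = p.n_photons * _pixel_kernel(
        np.array([float(px)]), np.array([float(py)]), p
    )[0, 0]
    return float(peak / p.background)


def _nll_and_grad_iso(theta_vec, xs, ys, data):
    """Poisson NLL and analytic gradient, isotropic model.

    Parameter vector: (mu_x, mu_y, ln N, ln b, ln sigma).
    """
    mu_x, mu_y, ln_n, ln_b, ln_s = theta_vec
    n = math.exp(ln_n)
    b = math.exp(ln_b)
    sig = math.exp(ln_s)
    s2 = _SQRT2 * sig

    u = xs - mu_x
    v = ys - mu_y
    au, bu = (u + 0.5) / s2, (u - 0.5) / s2
    av, bv = (v + 0.5) / s2, (v - 0.5) / s2
    ex = 0.5 * (erf(au) - erf(bu))          # (W,)
    ey = 0.5 * (erf(av) - erf(bv))          # (H,)
    gau, gbu = np.exp(-au * au), np.exp(-bu * bu)
    gav, gbv = np.exp(-av * av), np.exp(-bv * bv)

    K = np.outer(ey, ex)
    model = n * K + b
    nll = float(np.sum(model - data * np.log(model)))

    resid = 1.0 - data / model               # dNLL/dmodel
    # d ex / d mu_x and d ex / d sigma (1D pieces)
    dex_dmu = -(gau - gbu) / (_SQRT2PI * sig)
    dey_dmu = -(gav - gbv) / (_SQRT2PI * sig)
    dex_ds = -((u + 0.5) * gau - (u - 0.5) * gbu) / (_SQRT2PI * sig * sig)
    dey_ds = -((v + 0.5) * gav - (v - 0.5) * gbv) / (_SQRT2PI * sig * sig)

    g_mux = float(np.sum(resid * (n * np.outer(ey, dex_dmu))))
    g_muy = float(np.sum(resid * (n * np.outer(dey_dmu, ex))))
    g_lnn = float(np.sum(resid * (n * K)))
    g_lnb = float(np.sum(resid) * b)
    g_lns = float(np.sum(resid * (n * (np.outer(ey, dex_ds) + np.outer(dey_ds, ex)))) * sig)
    return nll, np.array([g_mux, g_muy, g_lnn, g_lnb, g_lns])


def _nll_astig(theta_vec, xs, ys, data):
    mu_x, mu_y, ln_n, ln_b, ln_sx, ln_sy, th = theta_vec
    p = PSFParams(mu_x, mu_y, math.exp(ln_n), math.exp(ln_b),
                  math.exp(ln_sx), math.exp(ln_sy), th)
    model = integrated_gaussian_model(xs, ys, p)
    return float(np.sum(model - data * np.log(model)))


def fit_mle(
    frame: np.ndarray,
    candidate: tuple,
    window: int = 9,
    model: str = "isotropic",
    sigma_init: float = 1.3,
    init: Optional[dict] = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    frame_index: int = 0,
) -> Localization:
    """Poisson maximum-likelihood fit of an integrated-Gaussian PSF.

    Minimizes ``sum(model - data * log(model))`` over an odd ``window``
    centered on the candidate pixel.  Positivity of N, b and the widths is
    enforced by optimizing their logarithms; the position is bounded to the
    window.  An all-zero window yields a non-converged localization rather
    than an exception.

    Parameters in ``init`` (keys among ``mu_x, mu_y, n_photons, background,
    sigma_x, sigma_y, theta``) override the default initialization (position
    from the candidate, background from the window-border median, N from the
    background-subtracted window sum, width from ``sigma_init``).
    """
    if model not in ("isotropic", "astigmatic"):
        raise ValueError(f"unknown model {model!r}")
    frame = np.asarray(frame, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    half = window // 2
    cx, cy = int(round(candidate[0])), int(round(candidate[1]))
    if not (half <= cx < frame.shape[1] - half and half <= cy < frame.shape[0] - half):
        raise ValueError(
            f"window {window} around candidate ({cx}, {cy}) does not fit in "
            f"frame of shape {frame.shape}"
        )
    xs, ys = _window_grid(cx, cy, window)
    data = frame[cy - half: cy + half + 1, cx - half: cx + half + 1]

    init = dict(init or {})
    border = np.concatenate([data[0, :], data[-1, :], data[1:-1, 0], data[1:-1, -1]])
    b0 = max(float(np.median(border)), 1e-3)
    n0 = max(float(data.sum() - b0 * data.size), 1.0)
    p0 = {
        "mu_x": float(cx), "mu_y": float(cy),
        "n_photons": n0, "background": b0,
        "sigma_x": sigma_init, "sigma_y": sigma_init, "theta": 0.0,
    }
    p0.update(init)

    def _fail(n_it=0):
        params = PSFParams(p0["mu_x"], p0["mu_y"], 0.0, p0["background"],
                           p0["sigma_x"], p0["sigma_y"], 0.0)
        return Localization(frame_index, params, 0.0, False, n_it, window, (cx, cy))

    if not np.any(data > 0):
        return _fail()

    bounds_mu = [(cx - half, cx + half), (cy - half, cy + half)]
    # log-parameter bounds keep the Poisson model valid and well-scaled
    ln_amp = (math.log(1e-6), math.log(1e9))
    ln_sig = (math.log(0.2), math.log(2.0 * window))
    opts = {"maxiter": max_iter, "ftol": tol * 1e-6, "gtol": 1e-10}
    if model == "isotropic":
        x0 = np.array([p0["mu_x"], p0["mu_y"], math.log(p0["n_photons"]),
                       math.log(p0["background"]), math.log(p0["sigma_x"])])
        res = optimize.minimize(
            _nll_and_grad_iso, x0, args=(xs, ys, data), jac=True,
            method="L-BFGS-B",
            bounds=bounds_mu + [ln_amp, ln_amp, ln_sig],
            options=opts,
        )
        mu_x, mu_y, ln_n, ln_b, ln_s = res.x
        params = PSFParams(mu_x, mu_y, math.exp(ln_n), math.exp(ln_b),
                           math.exp(ln_s), None, 0.0)
    else:
        x0 = np.array([p0["mu_x"], p0["mu_y"], math.log(p0["n_photons"]),
                       math.log(p0["background"]), math.log(p0["sigma_x"]),
                       math.log(p0["sigma_y"]), p0["theta"]])
        res = optimize.minimize(
            _nll_astig, x0, args=(xs, ys, data),
            method="L-BFGS-B",
            bounds=bounds_mu + [ln_amp, ln_amp, ln_sig, ln_sig,
                                (-math.pi / 2, math.pi / 2)],
            options=opts,
        )
        mu_x, mu_y, ln_n, ln_b, ln_sx, ln_sy, th = res.x
        params = PSFParams(mu_x, mu_y, math.exp(ln_n), math.exp(ln_b),
                           math.exp(ln_sx), math.exp(ln_sy), th)

    converged = bool(res.success) and np.all(np.isfinite(res.x))
    return Localization(
        frame_index, params, _sbr(params), converged, int(res.nit), window, (cx, cy)
    )


class RadialCenter(NamedTuple):
    x: float
    y: float
    degenerate: bool


def radial_symmetry_center(window: np.ndarray) -> RadialCenter:
    """Closed-form radial-symmetry center of a spot image.

    Every image-gradient vector of a radially symmetric spot points at (or
    away from) its center; the center is recovered as the weighted
    least-squares point of closest approach of the gradient lines, computed
    on the half-pixel dual lattice with 45-degree rotated finite differences.
    Non-iterative and independent of intensity units.  A window with no
    gradient returns its geometric center, flagged degenerate.
    """
    I = np.asarray(window, dtype=float)
    ny, nx = I.shape
    if ny < 3 or nx < 3:
        raise ValueError("window must be at least 3x3")
    fallback = RadialCenter((nx - 1) / 2.0, (ny - 1) / 2.0, True)

    # gradients along the two diagonals, defined on the dual lattice of
    # pixel-corner midpoints (coordinates offset by +1/2)
    dIdu = I[:-1, 1:] - I[1:, :-1]
    dIdv = I[:-1, :-1] - I[1:, 1:]
    k = np.ones((3, 3)) / 9.0
    from scipy import ndimage
    fdu = ndimage.convolve(dIdu, k, mode="constant")
    fdv = ndimage.convolve(dIdv, k, mode="constant")
    grad2 = fdu * fdu + fdv * fdv
    total = grad2.sum()
    if total <= 0:
        return fallback

    xm, ym = np.meshgrid(np.arange(nx - 1) + 0.5, np.arange(ny - 1) + 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = -(fdv + fdu) / (fdu - fdv)  # slope of gradient line in (x, y)
    vertical = ~np.isfinite(m)
    m = np.where(vertical, 1e9, m)  # near-vertical lines
    m = np.where(vertical & (grad2 == 0), 0.0, m)

    x_centroid = (grad2 * xm).sum() / total
    y_centroid = (grad2 * ym).sum() / total
    dist = np.sqrt((xm - x_centroid) ** 2 + (ym - y_centroid) ** 2)
    w = np.where(dist > 0, grad2 / np.maximum(dist, 1e-12), 0.0)

    b = ym - m * xm
    wm2p1 = w / (m * m + 1.0)
    sw = wm2p1.sum()
    smmw = (m * m * wm2p1).sum()
    smw = (m * wm2p1).sum()
    smbw = (m * b * wm2p1).sum()
    sbw = (b * wm2p1).sum()
    det = smw * smw - smmw * sw
    if abs(det) < 1e-300 or sw == 0:
        return fallback
    xc = (smbw * sw - smw * sbw) / det
    yc = (smbw * smw - smmw * sbw) / det
    if not (np.isfinite(xc) and np.isfinite(yc)):
        return fallback
    return RadialCenter(float(xc), float(yc), False)


_FISHER_ORDER_ISO = ("mu_x", "mu_y", "n_photons", "background", "sigma_x")
_FISHER_ORDER_ASTIG = ("mu_x", "mu_y", "n_photons", "background",
                       "sigma_x", "sigma_y", "theta")


def fisher_information(p: PSFParams, window: int, center: tuple,
                       model: str = "isotropic") -> np.ndarray:
    """Fisher information matrix of the Poisson integrated-Gaussian model.

    Entries ``I_ij = sum_k (d mu_k/d theta_i)(d mu_k/d theta_j) / mu_k`` over
    the fit window, with derivatives taken numerically (central differences)
    in the natural parameters.  Parameter order: (mu_x, mu_y, N, b, sigma_x
    [, sigma_y, theta]).
    """
    names = _FISHER_ORDER_ISO if model == "isotropic" else _FISHER_ORDER_ASTIG
    xs, ys = _window_grid(center[0], center[1], window)

    def render(values: dict) -> np.ndarray:
        q = PSFParams(values["mu_x"], values["mu_y"], values["n_photons"],
                      values["background"], values["sigma_x"],
                      values["sigma_x"] if model == "isotropic" else values["sigma_y"],
                      0.0 if model == "isotropic" else values["theta"])
        return integrated_gaussian_model(xs, ys, q)

    base = {n: getattr(p, n) for n in _FISHER_ORDER_ASTIG}
    mu = render(base)
    derivs = []
    for name in names:
        v = base[name]
        if name in ("mu_x", "mu_y", "theta"):
            h = 1e-4
        else:
            # positivity-constrained parameter: keep the lower sample valid
            h = 1e-4 * max(abs(v), 1.0)
            if v - h <= 0:
                h = 0.5 * v if v > 0 else 1e-8
        hi, lo = dict(base), dict(base)
        hi[name] = v + h
        lo[name] = max(v - h, 0.0)
        derivs.append((render(hi) - render(lo)) / (hi[name] - lo[name]))
    n = len(names)
    info = np.empty((n, n))
    inv_mu = 1.0 / np.maximum(mu, 1e-12)
    for i in range(n):
        for j in range(i, n):
            info[i, j] = info[j, i] = float(np.sum(derivs[i] * derivs[j] * inv_mu))
    return info


def crlb_position(p: PSFParams, window: int, center: tuple,
                  model: str = "isotropic") -> tuple:
    """CRLB standard deviation of (mu_x, mu_y) in px for the given model."""
    info = fisher_information(p, window, center, model)
    cov = np.linalg.inv(info)
    return float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))


def localization_precision(loc: Localization, pixel_size_nm: float,
                           model: str = "isotropic") -> tuple:
    """Theoretical per-axis standard error of a fit, in nm.

    Computed as the position CRLB of the fitted model at the fitted
    parameters; requires a converged fit with positive photon count.
    """
    if not loc.converged:
        raise ValueError("precision undefined for a non-converged localization")
    if loc.params.n_photons <= 0:
        raise ValueError("precision undefined for N <= 0")
    sx, sy = crlb_position(loc.params, loc.window, loc.center, model)
    return sx * pixel_size_nm, sy * pixel_size_nm
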