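# smtrack

Single-molecule localization microscopy (SMLM) and single-particle tracking
(SPT) in Python: a plugin-driven pipeline that takes a raw camera movie
through dark/gain correction, candidate detection, sub-pixel PSF refinement
and trajectory linking, together with a synthetic-movie generator with
ground truth, evaluation statistics, and diffusion analysis.

## Who this is for

dSTORM/PALM movies consist of thousands of frames of sparse, blinking
fluorophores.  Reconstructing a super-resolved image (or trajectories of
diffusing probes) requires detecting each emitter, fitting its position to
a fraction of a pixel, and linking positions over time.  `smtrack` is aimed
at people who develop or benchmark such algorithms: every stage is an
interchangeable plugin, and the built-in simulator generates movies with
exact ground truth so each stage can be validated end to end.

## The model at the core

A point emitter at sub-pixel position (μx, μy) emitting N photons over a
background of b photons/pixel produces the expected camera image

    E[n_k] = N · ΔEx(u_k) · ΔEy(v_k) + b,
    ΔE(t)  = ½ [ erf((t + ½)/(√2 σ)) − erf((t − ½)/(√2 σ)) ],

the 2D Gaussian PSF of width σ integrated over each pixel (optionally with
unequal σx, σy and a rotation θ for astigmatic 3D imaging).  Pixel values
are Poisson distributed, so positions are refined by minimizing the Poisson
negative log-likelihood Σ(model − data·log model) over a window around each
candidate.  The per-localization precision is the Cramér–Rao lower bound of
the same model, computed from the numerical Fisher information at the
fitted parameters.  σ defaults to the Gaussian–Airy approximation
σ = 0.21·λ/NA.

Detection offers three filters (difference-of-Gaussians band-pass,
normalized cross-correlation with the PSF template, à-trous B3-spline
wavelet planes); tracking is per-frame-pair optimal (Hungarian) assignment
with √gap-scaled gap closing; evaluation provides Jaccard index, RMSE over
optimally paired localizations, and Fourier ring correlation with the 1/7
criterion; diffusion is estimated from the per-axis displacement variance
per lag, σ²(k·t_a) = 2·D·k·t_a + ε.

## Worked example

```python
from smtrack import (make_siemens_movie, localize_movie, track_bundle,
                     match_localizations)

# 50-frame dSTORM movie of emitters on a Siemens star, mean peak SNR 5
movie, truth, _ = make_siemens_movie(grid=128, n_frames=50, n_emitters=800,
                                     target_snr=5, seed=1)
bundle = localize_movie(movie, detector="wavelet", refiner="gauss_mle")
bundle = track_bundle(bundle, tracker_params={"max_dist": 2.0})

m = match_localizations(truth, bundle.localizations.df, radius=2.0,
                        pixel_size_nm=movie.pixel_size_nm)
print(f"JAC={m.jac:.3f}  RMSE={m.rmse:.1f} nm  "
      f"TP={m.n_tp} FP={m.n_fp} FN={m.n_fn}")
```

Output:

    JAC=0.637  RMSE=34.1 nm  TP=1125 FP=9 FN=631

The Jaccard index counts how many true emitter appearances were recovered
(misses are dominated by emitters active for only a small fraction of a
frame); the RMSE is the localization error over the paired detections,
about a third of a pixel at this photon budget.

The same pipeline is available from the shell:

    smtrack simulate siemens -o movie.tif --truth truth.csv --seed 1 \
        --grid-size 128 --n-frames 50 --n-emitters 800 --snr 5
    smtrack locate movie.tif -o bundle.h5 --detector wavelet
    smtrack track bundle.h5 -o tracked.h5 --nearest-neighbor-max-dist 2
    smtrack evaluate tracked.h5 --truth truth.csv

`smtrack list-plugins` prints every plugin with its parameters, defaults,
ranges and tooltips (all auto-generated from the plugin descriptors).

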