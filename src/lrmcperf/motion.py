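"""Respiratory motion estimation and the warp operators M / M^H.

The reconstruction needs, for every heartbeat, a nonrigid displacement field
taking the reference respiratory state to that beat's state (the forward
warp in the acquisition model) plus its Hermitian adjoint.  Because
registration across a contrast bolus is ill-posed, motion is estimated
against ICA-synthesized references: an independent-component decomposition
of the beat-to-beat series isolates the quasi-periodic respiratory
component, which is zeroed before resynthesis, yielding a motion-suppressed
series with matching contrast for every frame.

The warp is bilinear interpolation assembled as a sparse matrix, so its
transpose (used for M^H) is exact — a requirement for the conjugate-gradient
inversion, where an approximate inverse warp would break symmetry of the
normal equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.signal import detrend
from sklearn.decomposition import FastICA
import SimpleITK as sitk

__all__ = [
    "ICAModel",
    "MotionFieldSeries",
    "identity_motion",
    "warp",
    "warp_transpose",
    "warp_matrix",
    "ica_references",
    "register_ffd",
    "estimate_motion",
    "scale_motion",
]


# ---------------------------------------------------------------------------
# Warp operator
# ---------------------------------------------------------------------------

def warp_matrix(field: np.ndarray) -> sp.csr_matrix:
    """Sparse bilinear-interpolation matrix for one displacement field.

    ``field`` has shape ``(2, N, N)`` holding (row, col) displacements in
    pixels: output pixel ``(r, c)`` samples the input at
    ``(r + field[0, r, c], c + field[1, r, c])``.  Samples falling outside
    the FOV contribute zero.
    """
    if not np.all(np.isfinite(field)):
        raise ValueError("displacement field contains non-finite values")
    _, nr, nc = field.shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    sr = (rr + field[0]).ravel()
    sc = (cc + field[1]).ravel()
    r0 = np.floor(sr).astype(int)
    c0 = np.floor(sc).astype(int)
    fr = sr - r0
    fc = sc - c0
    rows, cols, vals = [], [], []
    out_idx = np.arange(nr * nc)
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        r = r0 + dr
        c = c0 + dc
        ok = (r >= 0) & (r < nr) & (c >= 0) & (c < nc) & (w > 0)
        rows.append(out_idx[ok])
        cols.append((r * nc + c)[ok])
        vals.append(w[ok])
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nr * nc, nr * nc))
    return mat.tocsr()


def warp(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Resample ``image`` at displaced coordinates (out-of-FOV -> 0)."""
    mat = warp_matrix(np.asarray(field, dtype=float))
    return (mat @ image.ravel()).reshape(image.shape)


def warp_transpose(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Exact matrix transpose of :func:`warp` (not the inverse warp)."""
    mat = warp_matrix(np.asarray(field, dtype=float))
    return (mat.T @ image.ravel()).reshape(image.shape)


@dataclass
class MotionFieldSeries:
    """Per-heartbeat forward/backward displacement fields in pixels.

    ``forward[t]`` maps the reference state to frame ``t`` (the M operator);
    ``backward[t]`` approximately inverts it and is used for visualization
    and for aligning series by resampling rather than by transposition.
    """

    forward: np.ndarray   # (n_frames, 2, N, N)
    backward: np.ndarray  # (n_frames, 2, N, N)
    reference_frame: int | None = None
    _fwd_mats: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.forward.shape != self.backward.shape:
            raise ValueError("forward/backward field shapes differ")
        if self.forward.ndim != 4 or self.forward.shape[1] != 2:
            raise ValueError("fields must have shape (n_frames, 2, N, N)")

    @property
    def n_frames(self) -> int:
        return self.forward.shape[0]

    @property
    def shape(self) -> tuple:
        return self.forward.shape[2:]

    def _mat(self, t: int) -> sp.csr_matrix:
        if t not in self._fwd_mats:
            self._fwd_mats[t] = warp_matrix(self.forward[t])
        return self._fwd_mats[t]

    def warp_forward(self, t: int, image: np.ndarray) -> np.ndarray:
        """Apply M_t (reference state -> frame t appearance)."""
        return (self._mat(t) @ image.ravel()).reshape(image.shape)

    def warp_forward_transpose(self, t: int, image: np.ndarray) -> np.ndarray:
        """Apply M_t^H, the exact transpose of the forward warp."""
        return (self._mat(t).T @ image.ravel()).reshape(image.shape)

    def warp_backward(self, t: int, image: np.ndarray) -> np.ndarray:
        """Resample frame t back to the reference state (approximate
        inverse of the forward warp; for alignment and display)."""
        return warp(image, self.backward[t])

    def inversion_error(self) -> np.ndarray:
        """Median endpoint error of composing forward then backward fields,
        one value per frame (diagnostic for the invertibility contract)."""
        errs = np.empty(self.n_frames)
        nr, nc = self.shape
        rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        for t in range(self.n_frames):
            # x -> x + b(x) -> (x + b(x)) + f(x + b(x)); sample f at displaced pts
            br, bc = self.backward[t]
            fr = warp(self.forward[t, 0], self.backward[t])
            fc = warp(self.forward[t, 1], self.backward[t])
            errs[t] = np.median(np.hypot(br + fr, bc + fc))
        return errs


def identity_motion(n_frames: int, matrix_size: int) -> MotionFieldSeries:
    z = np.zeros((n_frames, 2, matrix_size, matrix_size))
    return MotionFieldSeries(z, z.copy())


def scale_motion(fields: MotionFieldSeries, factor: float) -> MotionFieldSeries:
    """Scale every displacement vector (0 -> identity, 2 -> doubled motion)."""
    if factor < 0:
        raise ValueError("motion scale factor must be non-negative")
    return MotionFieldSeries(fields.forward * factor, fields.backward * factor,
                             fields.reference_frame)


# ---------------------------------------------------------------------------
# ICA motion references
# ---------------------------------------------------------------------------

@dataclass
class ICAModel:
    """Fitted temporal ICA with the respiratory component identified."""

    sources: np.ndarray        # (n_frames, n_components) temporal courses
    mixing: np.ndarray         # (n_pixels, n_components) spatial maps
    mean: np.ndarray           # (n_pixels,) temporal mean removed by the fit
    resp_index: int | None
    n_components: int
    frame_rate_hz: float
    peak_freqs_hz: np.ndarray  # per-component spectral peak (DC excluded)
    peak_mags: np.ndarray


def _spectral_peaks(sources: np.ndarray, frame_rate_hz: float):
    """Per-component (peak frequency, peak magnitude), DC bin excluded,
    temporal courses detrended first so bolus dynamics do not mask the
    respiratory line."""
    n = sources.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate_hz)
    spec = np.abs(np.fft.rfft(detrend(sources, axis=0), axis=0))
    spec[0] = 0.0  # exclude DC
    # ties broken toward lower frequency by argmax on the first maximum
    idx = spec.argmax(axis=0)
    return freqs[idx], spec[idx, np.arange(sources.shape[1])]


def ica_references(X: np.ndarray, n_components: int = 5,
                   resp_band_hz: tuple = (0.2, 0.5),
                   frame_rate_hz: float = 1.0, seed: int = 0):
    """Synthesize a motion-suppressed reference series by removing the
    respiratory independent component.

    ``X`` is the magnitude image series ``(n_frames, N, N)``.  The series is
    decomposed into ``n_components`` temporal independent components (after
    PCA whitening); the component whose detrended spectrum peaks inside
    ``resp_band_hz`` with the largest magnitude is zeroed before
    resynthesis.  If no component peaks in band, the series is resynthesized
    from all components and ``resp_index`` is ``None``.

    Returns ``(X_ref, ICAModel)`` with ``X_ref`` the same shape as ``X``.
    """
    n_frames = X.shape[0]
    if n_components >= n_frames:
        raise ValueError("n_components must be smaller than the frame count")
    lo, hi = resp_band_hz
    if hi >= frame_rate_hz / 2 + 1e-12:
        warnings.warn("respiratory band extends beyond the frame-rate Nyquist "
                      "limit; in-band peaks above Nyquist are unobservable")
    casorati = X.reshape(n_frames, -1)  # frames x pixels
    # whitening breaks down past the numerical rank of the centered series
    # (exactly low-rank synthetic input); cap the component count there
    sv = np.linalg.svd(casorati - casorati.mean(axis=0), compute_uv=False)
    eff_rank = int(np.sum(sv > 1e-9 * sv[0]))
    n_components = max(2, min(n_components, eff_rank))
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=1000, tol=1e-10)
    sources = ica.fit_transform(casorati)        # (n_frames, n_comp)
    mixing = ica.mixing_                         # (n_pixels, n_comp)
    mean = ica.mean_
    peak_freqs, peak_mags = _spectral_peaks(sources, frame_rate_hz)
    in_band = (peak_freqs > lo) & (peak_freqs < hi)
    if np.any(in_band):
        cand = np.where(in_band)[0]
        resp_index = int(cand[np.argmax(peak_mags[cand])])
        keep = sources.copy()
        keep[:, resp_index] = 0.0
    else:
        warnings.warn("no ICA component peaks inside the respiratory band; "
                      "returning the full-rank resynthesis")
        resp_index = None
        keep = sources
    X_ref = (keep @ mixing.T + mean).reshape(X.shape)
    model = ICAModel(sources=sources, mixing=mixing, mean=mean,
                     resp_index=resp_index, n_components=n_components,
                     frame_rate_hz=frame_rate_hz,
                     peak_freqs_hz=peak_freqs, peak_mags=peak_mags)
    return X_ref, model


# ---------------------------------------------------------------------------
# B-spline free-form-deformation registration
# ---------------------------------------------------------------------------

def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.abs(np.asarray(img, dtype=float))
    p = np.percentile(img, 99)
    if p <= 0:
        return img
    return np.clip(img / p, 0, 1.5)


def _ffd_single(moving: np.ndarray, fixed: np.ndarray, grid_spacing_px: float,
                levels: int) -> np.ndarray:
    """One B-spline FFD solve at a fixed control-grid spacing."""
    fixed_im = sitk.GetImageFromArray(fixed)
    moving_im = sitk.GetImageFromArray(moving)
    mesh = [max(2, int(round(s / grid_spacing_px))) for s in fixed.shape[::-1]]
    tx0 = sitk.BSplineTransformInitializer(fixed_im, mesh, order=3)

    reg = sitk.ImageRegistrationMethod()
    # correlation is insensitive to the residual intensity-scale differences
    # between a frame and its ICA-resynthesized reference
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(tx0, inPlace=True)
    reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-7,
                             numberOfIterations=100,
                             maximumNumberOfCorrections=5)
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    sigmas = [float(max(s // 2, 0)) for s in shrink]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense sampling: deterministic
    tx = reg.Execute(fixed_im, moving_im)

    f2d = sitk.TransformToDisplacementFieldFilter()
    f2d.SetReferenceImage(fixed_im)
    disp = sitk.GetArrayFromImage(f2d.Execute(tx))  # (N, N, 2) as (x, y)
    return np.stack([disp[..., 1], disp[..., 0]])   # -> (row, col)


def register_ffd(moving: np.ndarray, fixed: np.ndarray,
                 grid_spacing_px: float = 12.0, levels: int = 3,
                 bending_weight: float = 1e-2) -> np.ndarray:
    """Multi-resolution B-spline free-form-deformation registration.

    Estimates the dense displacement field (2, N, N), in pixels, such that
    sampling ``moving`` at ``x + field(x)`` approximates ``fixed`` — i.e.
    ``warp(moving, field) ~ fixed``.  Correlation metric on
    99th-percentile-normalized magnitude images, LBFGS-B optimization with
    dense sampling, so the result is deterministic.
    """
    moving = _normalize(moving)
    fixed = _normalize(fixed)
    if moving.shape != fixed.shape:
        raise ValueError("moving/fixed shape mismatch")
    if np.ptp(moving) == 0 or np.ptp(fixed) == 0:
        warnings.warn("constant image in registration; returning zero field")
        return np.zeros((2,) + fixed.shape)

    field = _ffd_single(moving, fixed, grid_spacing_px, levels)

    if bending_weight > 0:
        # light quadratic smoothing of the dense field stands in for the
        # bending-energy prior (LBFGSB in SimpleITK has no built-in penalty)
        from scipy.ndimage import gaussian_filter
        sigma = float(np.sqrt(bending_weight) * grid_spacing_px / 4)
        if sigma > 0.05:
            field = np.stack([gaussian_filter(f, sigma) for f in field])
    return field


def _register_series(X, X_ref, grid_spacing_px, levels, bending_weight):
    n_frames = X.shape[0]
    fwd = np.empty((n_frames, 2) + X.shape[1:])
    bwd = np.empty_like(fwd)
    for t in range(n_frames):
        # forward: warping the reference-state image must reproduce frame t
        fwd[t] = register_ffd(X_ref[t], X[t], grid_spacing_px, levels,
                              bending_weight)
        bwd[t] = register_ffd(X[t], X_ref[t], grid_spacing_px, levels,
                              bending_weight)
    return MotionFieldSeries(fwd, bwd)


def estimate_motion(X: np.ndarray, X_ref: np.ndarray,
                    grid_spacing_px: float = 12.0, levels: int = 3,
                    bending_weight: float = 1e-2, refine_passes: int = 0,
                    refine_window: int = 5) -> MotionFieldSeries:
    """Register every frame against its contrast-matched motion-suppressed
    reference, returning forward (reference -> frame) and backward fields.

    ``refine_passes > 0`` adds reference-refinement iterations: the series
    is aligned with the current motion estimate, temporally median-filtered
    (suppressing residual aliasing and any motion the first references
    retained), warped back to each frame's state as improved references,
    and re-registered.  Two passes are usually enough when the initial
    references still carry part of the respiratory excursion.
    """
    if X.shape != X_ref.shape:
        raise ValueError("series shape mismatch")
    motion = _register_series(X, X_ref, grid_spacing_px, levels, bending_weight)
    from scipy.ndimage import median_filter
    for _ in range(refine_passes):
        aligned = np.stack([warp(X[t], motion.backward[t])
                            for t in range(X.shape[0])])
        smooth = median_filter(aligned, size=(refine_window, 1, 1),
                               mode="nearest")
        refs = np.stack([warp(smooth[t], motion.forward[t])
                         for t in range(X.shape[0])])
        motion = _register_series(X, refs, grid_spacing_px, levels,
                                  bending_weight)
    return motion
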