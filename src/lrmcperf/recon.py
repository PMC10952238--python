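"""Reconstruction algorithms: zero-filled gridding, iterative SENSE,
low-rank plus sparse, and the motion-corrected low-rank (LRMC) inversion.

LRMC solves

    argmin_y  1/2 || A F C M U_r y - k ||^2  +  lambda * sum_b ||T_b||_*

by ADMM: a conjugate-gradient data-consistency step on the normal
equations, a patch-tensor denoising step (block matching + higher-order
SVD soft-thresholding) on the singular images, and a scaled dual update.
With ``lambda = 0`` the method reduces to plain CG on the
subspace-and-motion-constrained least-squares problem, which is the variant
used in the simulation studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .encoding import CoilMaps, EncodingOperator, RadialKSpace, ramp_dcf
from .motion import MotionFieldSeries, scale_motion
from .subspace import TemporalSubspace

logger = logging.getLogger(__name__)

__all__ = [
    "PatchTensorConfig",
    "ADMMConfig",
    "SingularImageStack",
    "conjugate_gradient",
    "zero_filled",
    "itsense",
    "lps",
    "hd_prost_denoise",
    "lrmc",
    "motion_error_sweep",
]


class SolverError(RuntimeError):
    """Raised when an iterative solver produces non-finite iterates."""


@dataclass
class SingularImageStack:
    """The ``r`` compressed (singular) images being reconstructed."""

    images: np.ndarray  # complex (r, N, N)

    def __post_init__(self):
        if self.images.ndim != 3 or self.images.shape[0] < 1:
            raise ValueError("singular image stack must be (r, N, N) with r >= 1")
        if not np.all(np.isfinite(self.images.view(float))):
            raise ValueError("non-finite singular images")

    @property
    def rank(self) -> int:
        return self.images.shape[0]


@dataclass
class PatchTensorConfig:
    """Patch-tensor regularizer settings (patch pixels x similar patches x
    singular images).  Paper-level parameter is the weight ``lambda`` in
    :class:`ADMMConfig`; these internals follow common practice for the
    regularizer."""

    patch_size_px: int = 5
    search_window_px: int = 21
    n_similar: int = 10
    stride_px: int = 2
    matching_reference: str = "rss"  # root-sum-of-squares of singular images
    threshold_rule: str = "soft"

    def __post_init__(self):
        if self.patch_size_px % 2 == 0:
            raise ValueError("patch size must be odd")
        if self.n_similar < 2:
            raise ValueError("need at least 2 similar patches")
        if self.search_window_px < self.patch_size_px:
            raise ValueError("search window must cover at least one patch")


@dataclass
class ADMMConfig:
    """ADMM solver settings; defaults follow the reference configuration
    (10 outer iterations, 3 inner CG iterations, lambda = 1e-3)."""

    outer_iters: int = 10
    inner_cg_iters: int = 3
    lambda_reg: float = 1e-3
    penalty_mu: float | None = None  # default: 0.1 * mean|E^H k|
    cg_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.outer_iters < 1 or self.inner_cg_iters < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")
        if self.penalty_mu is not None and self.penalty_mu <= 0:
            raise ValueError("penalty_mu must be positive")


# ---------------------------------------------------------------------------
# Conjugate gradient
# ---------------------------------------------------------------------------

def conjugate_gradient(normal_op, rhs: np.ndarray, x0: np.ndarray | None = None,
                       n_iters: int = 6, tol: float = 1e-6):
    """CG on the (Hermitian positive semidefinite) normal equations
    ``normal_op(x) = rhs``.  Returns ``(x, residual_norms)``.
    """
    x = np.zeros_like(rhs) if x0 is None else x0.copy()
    r = rhs - normal_op(x) if x0 is not None else rhs.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    b_norm = float(np.linalg.norm(rhs.ravel()))
    resids = [np.sqrt(rs)]
    for _ in range(n_iters):
        if np.sqrt(rs) <= tol * max(b_norm, 1e-30):
            break
        ap = normal_op(p)
        denom = float(np.vdot(p, ap).real)
        if denom <= 0:
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = float(np.vdot(r, r).real)
        if not np.isfinite(rs_new):
            raise SolverError("conjugate gradient diverged (non-finite residual)")
        p = r + (rs_new / rs) * p
        rs = rs_new
        resids.append(np.sqrt(rs))
    return x, np.array(resids)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def zero_filled(k: RadialKSpace, coils: CoilMaps) -> np.ndarray:
    """Density-compensated gridded reconstruction with coil combination."""
    op = EncodingOperator(k.traj, coils)
    dcf = ramp_dcf(k.traj)
    weighted = k.data * dcf[None, None]
    return op.adjoint(weighted)


def itsense(k: RadialKSpace, coils: CoilMaps, n_iters: int = 6,
            tol: float = 0.0) -> np.ndarray:
    """Frame-by-frame unregularized iterative SENSE.

    Solves ``(AFC)^H (AFC) x = (AFC)^H k`` per frame by CG from a zero
    start (six iterations by default).  Returns the frame series.
    """
    op = EncodingOperator(k.traj, coils)
    n_frames = k.traj.n_frames
    out = np.empty((n_frames, coils.maps.shape[1], coils.maps.shape[2]),
                   dtype=complex)
    for t in range(n_frames):
        nufft = op._nuffts[t]

        def normal(x, t=t, nufft=nufft):
            img = x.reshape(out.shape[1:])
            acc = np.zeros_like(img)
            for c in range(coils.n_coils):
                s = nufft.forward(coils.maps[c] * img)
                acc += np.conj(coils.maps[c]) * nufft.adjoint(s)
            return acc.ravel()

        rhs = np.zeros(out.shape[1:], dtype=complex)
        for c in range(coils.n_coils):
            rhs += np.conj(coils.maps[c]) * nufft.adjoint(k.data[t, c].ravel())
        x, _ = conjugate_gradient(normal, rhs.ravel(), n_iters=n_iters, tol=tol)
        out[t] = x.reshape(out.shape[1:])
    return out


def _power_iteration(op, shape, n_iters=12, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    x /= np.linalg.norm(x.ravel())
    lam = 1.0
    for _ in range(n_iters):
        y = op(x)
        lam = float(np.linalg.norm(y.ravel()))
        if lam == 0:
            return 1.0
        x = y / lam
    return lam


def lps(k: RadialKSpace, coils: CoilMaps, lambda_L: float = 0.1,
        lambda_S: float = 0.1, n_iters: int = 6):
    """Low-rank plus sparse decomposition of the dynamic series.

    Iterative shrinkage: gradient step through the per-frame SENSE
    operator, singular-value soft-thresholding of the Casorati matrix of L
    (threshold ``lambda_L * sigma_1``), and soft-thresholding of the
    temporal FFT of S (threshold ``lambda_S * max|FFT|``).  Returns
    ``(L, S)``; ``L + S`` is the reconstruction.
    """
    if lambda_L < 0 or lambda_S < 0:
        raise ValueError("regularization weights must be non-negative")
    op = EncodingOperator(k.traj, coils)
    n_frames = k.traj.n_frames
    n = coils.maps.shape[1]

    # sqrt-DCF weighting on both model and data: the normal operator stays
    # Hermitian PSD but is near-identity for radial sampling, so a handful
    # of shrinkage iterations suffices (the usual preconditioning of the
    # cited scheme)
    w = np.sqrt(ramp_dcf(k.traj))[None, None]

    def forward_w(x):
        return op.forward(x) * w

    def adjoint_w(data):
        return op.adjoint(data * w)

    def normal_w(x):
        return adjoint_w(forward_w(x))

    # spectral normalization: after dividing by sqrt(lam) the weighted
    # operator has unit norm, so the shrinkage step size is one and the
    # adjoint image is on the solution scale
    lam = max(_power_iteration(normal_w, (n_frames, n, n), n_iters=20), 1e-30)
    root = np.sqrt(lam)

    M0 = adjoint_w(k.data * w) / lam
    scale = float(np.abs(M0).max())  # thresholds become scale-free
    if scale == 0:
        return np.zeros_like(M0), np.zeros_like(M0)
    kdat_w = k.data * w / root / scale
    M = M0 / scale
    L = M.copy()
    S = np.zeros_like(M)
    for it in range(n_iters):
        # L: SVT of the Casorati matrix of M - S at lambda_L * sigma_1
        cas = (M - S).reshape(n_frames, -1)
        u, s, vh = np.linalg.svd(cas, full_matrices=False)
        s = np.maximum(s - lambda_L * s[0], 0.0)
        L = ((u * s) @ vh).reshape(n_frames, n, n)
        # S: soft-threshold the temporal FFT of M - L; the threshold is
        # anchored to the first-pass transform peak, not re-scaled each
        # iteration (a shrinking anchor over-regularizes)
        tf = np.fft.fft(M - L, axis=0, norm="ortho")
        if it == 0:
            thr_s = lambda_S * np.abs(tf).max()
        mag = np.abs(tf)
        tf = tf * np.maximum(mag - thr_s, 0.0) / np.maximum(mag, 1e-30)
        S = np.fft.ifft(tf, axis=0, norm="ortho")
        # data consistency on M = L + S (unit step on the normalized model)
        resid = forward_w(L + S) / root - kdat_w
        M = (L + S) - adjoint_w(resid) / root
        if not np.all(np.isfinite(M.view(float))):
            raise SolverError("L+S iteration diverged")
    return L * scale, S * scale


# ---------------------------------------------------------------------------
# HD-PROST patch-tensor denoising
# ---------------------------------------------------------------------------

def _soft_threshold_modes(tensor: np.ndarray, tau: float) -> np.ndarray:
    """Average of the three mode-unfolding SVD soft-thresholdings — a
    surrogate proximal step for the multilinear nuclear-norm penalty."""
    out = np.zeros_like(tensor)
    shape = tensor.shape
    for mode in range(3):
        unfolded = np.moveaxis(tensor, mode, 0).reshape(shape[mode], -1)
        u, s, vh = np.linalg.svd(unfolded, full_matrices=False)
        s = np.maximum(s - tau, 0.0)
        rec = (u * s) @ vh
        rec = rec.reshape([shape[mode]] + [shape[m] for m in range(3) if m != mode])
        out += np.moveaxis(rec, 0, mode)
    return out / 3.0


def hd_prost_denoise(y: np.ndarray, cfg: PatchTensorConfig,
                     threshold: float) -> np.ndarray:
    """Patch-based high-order low-rank denoising of singular images.

    For each strided voxel: block matching (L2 patch distance on the
    root-sum-of-squares of the singular images, ties by scan order) selects
    the K most similar patches in the search window; the 3-mode tensor
    (patch pixels x K patches x r singular images) has each mode unfolding
    soft-thresholded at ``threshold``; overlapping estimates are averaged
    uniformly.
    """
    r, nr, nc = y.shape
    p = cfg.patch_size_px
    half = p // 2
    win = cfg.search_window_px // 2
    if nr < cfg.search_window_px or nc < cfg.search_window_px:
        raise ValueError("image smaller than the search window")

    ref = np.sqrt((np.abs(y) ** 2).sum(axis=0)) if cfg.matching_reference == "rss" \
        else np.abs(y[0])

    # patch views indexed by top-left corner
    from numpy.lib.stride_tricks import sliding_window_view
    ref_patches = sliding_window_view(ref, (p, p))           # (nr-p+1, nc-p+1, p, p)
    y_patches = sliding_window_view(y, (p, p), axis=(1, 2))  # (r, nr-p+1, nc-p+1, p, p)

    accum = np.zeros_like(y)
    weight = np.zeros((nr, nc))
    centers_r = list(range(half, nr - half, cfg.stride_px))
    centers_c = list(range(half, nc - half, cfg.stride_px))
    if centers_r[-1] != nr - half - 1:
        centers_r.append(nr - half - 1)
    if centers_c[-1] != nc - half - 1:
        centers_c.append(nc - half - 1)

    for cr in centers_r:
        # candidate patch centers inside the search window, as top-left corners
        r_lo = max(half, cr - win) - half
        r_hi = min(nr - half - 1, cr + win) - half
        for cc in centers_c:
            c_lo = max(half, cc - win) - half
            c_hi = min(nc - half - 1, cc + win) - half
            cand = ref_patches[r_lo:r_hi + 1, c_lo:c_hi + 1]
            target = ref_patches[cr - half, cc - half]
            d = ((cand - target) ** 2).sum(axis=(-2, -1)).ravel()
            k = min(cfg.n_similar, d.size)
            # stable selection: ties resolved by scan order
            order = np.argsort(d, kind="stable")[:k]
            rows = r_lo + order // (c_hi - c_lo + 1)
            cols = c_lo + order % (c_hi - c_lo + 1)
            group = y_patches[:, rows, cols]            # (r, k, p, p)
            tensor = np.transpose(group.reshape(r, k, p * p), (2, 1, 0))  # (p^2, k, r)
            den = _soft_threshold_modes(tensor, threshold)
            den = np.transpose(den, (2, 1, 0)).reshape(r, k, p, p)
            for j in range(k):
                rr, cj = rows[j], cols[j]
                accum[:, rr:rr + p, cj:cj + p] += den[:, j]
                weight[rr:rr + p, cj:cj + p] += 1.0
    missing = weight == 0
    accum[:, missing] = y[:, missing]
    weight[missing] = 1.0
    return accum / weight[None]


# ---------------------------------------------------------------------------
# LRMC
# ---------------------------------------------------------------------------

def lrmc(k: RadialKSpace, coils: CoilMaps, motion: MotionFieldSeries,
         subspace: TemporalSubspace, admm: ADMMConfig | None = None,
         patch: PatchTensorConfig | None = None, callback=None):
    """Motion-corrected low-rank reconstruction.

    Returns ``(SingularImageStack, series)`` with ``series`` the expanded,
    motion-corrected frame series (every frame in the reference state).
    With ``lambda_reg == 0`` the ADMM splitting is bypassed and the
    subspace-constrained least-squares problem is solved with plain CG for
    ``outer_iters * inner_cg_iters`` iterations.
    """
    admm = admm or ADMMConfig()
    patch = patch or PatchTensorConfig()
    op = EncodingOperator(k.traj, coils, motion=motion, subspace=subspace)
    rhs = op.adjoint(k.data)

    if admm.lambda_reg == 0:
        total = admm.outer_iters * admm.inner_cg_iters
        y, resids = conjugate_gradient(op.normal, rhs, n_iters=total,
                                       tol=admm.cg_tolerance)
        logger.info("unregularized LRMC: %d CG iters, final residual %.3e",
                    len(resids) - 1, resids[-1])
        stack = SingularImageStack(y)
        return stack, subspace.expand(y)

    mu = admm.penalty_mu if admm.penalty_mu is not None \
        else 0.1 * float(np.abs(rhs).mean())
    tau = admm.lambda_reg / mu

    y = np.zeros_like(rhs)
    T = np.zeros_like(rhs)
    u = np.zeros_like(rhs)
    for it in range(admm.outer_iters):
        def penalized(x):
            return op.normal(x) + mu * x

        y, _ = conjugate_gradient(penalized, rhs + mu * (T - u), x0=y,
                                  n_iters=admm.inner_cg_iters,
                                  tol=admm.cg_tolerance)
        T = hd_prost_denoise(y + u, patch, tau * np.abs(y + u).max())
        u = u + y - T
        primal = float(np.linalg.norm((y - T).ravel()))
        logger.info("ADMM iter %d: primal residual %.3e", it + 1, primal)
        if callback is not None:
            callback(it, y, T, primal)
        if not np.all(np.isfinite(y.view(float))):
            raise SolverError("LRMC ADMM diverged")
    stack = SingularImageStack(y)
    return stack, subspace.expand(y)


def motion_error_sweep(k: RadialKSpace, coils: CoilMaps,
                       motion_true: MotionFieldSeries,
                       subspace: TemporalSubspace,
                       scales=(0.0, 0.5, 1.0, 1.5, 2.0),
                       admm: ADMMConfig | None = None,
                       evaluate=None) -> list[dict]:
    """Unregularized LRMC under scaled motion-model errors.

    ``scales`` multiply the true displacement fields (1.0 = correct motion,
    0.0 = motion ignored, 2.0 = doubled).  ``evaluate(series)`` maps each
    reconstruction to a dict of metrics (e.g. myocardial CoV and MAE);
    returns one row per scale.
    """
    scales = list(scales)
    if 1.0 not in scales:
        raise ValueError("scales must include 1.0 (the true motion)")
    admm = admm or ADMMConfig(lambda_reg=0.0)
    if admm.lambda_reg != 0:
        admm = ADMMConfig(outer_iters=admm.outer_iters,
                          inner_cg_iters=admm.inner_cg_iters, lambda_reg=0.0,
                          cg_tolerance=admm.cg_tolerance, seed=admm.seed)
    rows = []
    for s in scales:
        _, series = lrmc(k, coils, scale_motion(motion_true, s), subspace,
                         admm=admm)
        row = {"scale": float(s)}
        if evaluate is not None:
            row.update(evaluate(series))
        rows.append(row)
    return rows
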