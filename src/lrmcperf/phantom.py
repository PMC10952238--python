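"""Numerical first-pass myocardial perfusion phantom.

Generates a beat-to-beat short-axis perfusion series with known ground
truth: elliptical right-ventricle / left-ventricle / myocardium / liver
geometry, gamma-variate bolus enhancement per tissue (RV enhances first,
then LV, then myocardium), smooth nonrigid respiratory deformation sampled
once per heartbeat, smooth complex coil sensitivities, and golden-angle
radial k-space with complex Gaussian noise.  Everything downstream —
operator oracles, registration ground truth, metric references — derives
from this module.

The moving series is produced by applying the *same* bilinear warp operator
used in the reconstruction model to the reference-state frames, so the
generative model is exactly representable by the encoding operator; this is
deliberate, as it lets the model-consistency tests separate solver error
from model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .encoding import CoilMaps, RadialKSpace, TrajectorySpec, EncodingOperator, radial_trajectory
from .motion import MotionFieldSeries, warp

__all__ = [
    "TissueCurve",
    "PhantomSpec",
    "PerfusionPhantom",
    "gamma_variate",
    "make_phantom",
    "simulate_coils",
    "sample_kspace",
]

LABELS = {"background": 0, "rv_blood": 1, "lv_blood": 2, "myocardium": 3,
          "liver": 4}


def gamma_variate(t, t0, alpha, beta, amplitude, baseline=0.0):
    """Gamma-variate bolus curve, peak-normalized so the maximum enhancement
    equals ``amplitude`` (reached at ``t = t0 + alpha*beta``).

    ``baseline`` for ``t <= t0``; continuous at the onset.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("gamma-variate shape and scale must be positive")
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, float(baseline))
    late = t > t0
    tau = (t[late] - t0) / beta
    out[late] = baseline + amplitude * (tau / alpha) ** alpha * np.exp(alpha - tau)
    return out if out.ndim else float(out)


@dataclass
class TissueCurve:
    """Gamma-variate parameters for one tissue (times in seconds)."""
    t0: float
    alpha: float
    beta: float
    amplitude: float
    baseline: float

    def __call__(self, t):
        return gamma_variate(t, self.t0, self.alpha, self.beta,
                             self.amplitude, self.baseline)

    @property
    def peak_time(self) -> float:
        return self.t0 + self.alpha * self.beta


def _default_tissues() -> dict:
    # Onsets ordered RV -> LV -> myocardium (first-pass transit); liver late.
    return {
        "rv_blood": TissueCurve(t0=3.0, alpha=3.0, beta=1.5, amplitude=1.0, baseline=0.10),
        "lv_blood": TissueCurve(t0=8.0, alpha=3.0, beta=2.0, amplitude=0.90, baseline=0.10),
        "myocardium": TissueCurve(t0=12.0, alpha=2.5, beta=4.0, amplitude=0.35, baseline=0.15),
        "liver": TissueCurve(t0=18.0, alpha=2.5, beta=6.0, amplitude=0.25, baseline=0.15),
    }


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic acquisition.

    Defaults mirror the target acquisition: 128 matrix, 60 heartbeats at
    1 s, 8 coils, 53 spokes/frame, 2% k-space noise, 0.3 Hz respiration
    with ~10 px peak displacement.  ``desk()`` gives a reduced instance for
    fast end-to-end runs (64 matrix, 30 frames, 4 coils, 27 spokes — the
    same ~4x undersampling factor — and motion scaled with the matrix).
    """

    matrix_size: int = 128
    n_frames: int = 60
    heartbeat_interval_s: float = 1.0
    n_coils: int = 8
    spokes_per_frame: int = 53
    samples_per_spoke: int | None = None  # default 2x matrix (readout oversampling)
    tissue_params: dict = dc_field(default_factory=_default_tissues)
    motion_amplitude_px: float = 10.0
    resp_freq_hz: float = 0.3
    resp_drift_px: float = 1.0
    noise_fraction: float = 0.02
    texture_strength: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if self.matrix_size < 32:
            raise ValueError("matrix_size must be at least 32")
        if self.n_frames < 8:
            raise ValueError("n_frames must be at least 8")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be non-negative")
        nyq = 0.5 / self.heartbeat_interval_s
        if not (0 < self.resp_freq_hz < nyq):
            raise ValueError(f"resp_freq_hz must lie in (0, {nyq}) so the "
                             "respiratory trace is representable beat-to-beat")
        order = [self.tissue_params[k].t0
                 for k in ("rv_blood", "lv_blood", "myocardium")]
        if not (order[0] < order[1] < order[2]):
            raise ValueError("tissue onsets must satisfy RV < LV < myocardium")
        if self.samples_per_spoke is None:
            self.samples_per_spoke = 2 * self.matrix_size

    @classmethod
    def desk(cls, **overrides) -> "PhantomSpec":
        params = dict(matrix_size=64, n_frames=30, n_coils=4,
                      spokes_per_frame=27, motion_amplitude_px=5.0,
                      resp_drift_px=0.5)
        params.update(overrides)
        return cls(**params)

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.heartbeat_interval_s

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / self.heartbeat_interval_s

    def trajectory(self) -> TrajectorySpec:
        return radial_trajectory(self.n_frames, self.spokes_per_frame,
                                 self.samples_per_spoke)


@dataclass
class PerfusionPhantom:
    """Ground-truth bundle: moving series, motion, coils, masks, geometry."""

    truth_series: np.ndarray       # complex (n_frames, N, N), moving
    reference_series: np.ndarray   # complex (n_frames, N, N), motionless
    motion_fields: MotionFieldSeries
    coil_maps: CoilMaps
    masks: np.ndarray              # int label map, reference state
    heart_roi: tuple               # (row0, row1, col0, col1) bounding box
    spec: PhantomSpec

    def __post_init__(self):
        if self.truth_series.shape[0] != self.spec.n_frames:
            raise ValueError("frame count mismatch")
        for name, lab in LABELS.items():
            if name != "background" and not np.any(self.masks == lab):
                raise ValueError(f"tissue '{name}' is empty")
        if not np.all(np.isfinite(np.abs(self.truth_series))):
            raise ValueError("non-finite truth values")

    def mask(self, tissue: str) -> np.ndarray:
        return self.masks == LABELS[tissue]

    def mean_curve(self, tissue: str, series: np.ndarray | None = None) -> np.ndarray:
        """Per-frame mean magnitude over a tissue mask (reference state)."""
        s = self.reference_series if series is None else series
        m = self.mask(tissue)
        return np.abs(s[:, m]).mean(axis=1)

    def key_frames(self) -> dict:
        """Peak-enhancement frame per tissue (argmax of mask-mean signal)."""
        return {t: int(np.argmax(self.mean_curve(t)))
                for t in ("rv_blood", "lv_blood", "myocardium")}


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _ellipse(shape, center, semi, oversample=1):
    n = shape * oversample
    r = (np.arange(n) + 0.5) / oversample - 0.5
    rr, cc = np.meshgrid(r, r, indexing="ij")
    return (((rr - center[0]) / semi[0]) ** 2 +
            ((cc - center[1]) / semi[1]) ** 2) <= 1.0


def _geometry(n: int, oversample: int = 4):
    """Anti-aliased tissue fraction maps plus crisp label masks.

    Proportions follow a mid-ventricular short-axis view: LV blood pool
    ringed by myocardium, crescent-shaped RV to its left, liver inferior,
    all inside a torso ellipse.
    """
    s = n  # reference scale
    torso = _ellipse(n, (0.52 * s, 0.50 * s), (0.42 * s, 0.46 * s), oversample)
    lv_c = (0.42 * s, 0.58 * s)
    epi = _ellipse(n, lv_c, (0.165 * s, 0.165 * s), oversample)
    endo = _ellipse(n, lv_c, (0.095 * s, 0.095 * s), oversample)
    rv_out = _ellipse(n, (0.42 * s, 0.40 * s), (0.16 * s, 0.19 * s), oversample)
    rv = rv_out & ~epi
    liver = _ellipse(n, (0.78 * s, 0.42 * s), (0.12 * s, 0.28 * s), oversample)
    myo = epi & ~endo
    lv = endo
    body = torso & ~(myo | lv | rv | liver)

    def down(m):
        hi = m.astype(float).reshape(n, oversample, n, oversample)
        return hi.mean(axis=(1, 3))

    fractions = {"body": down(body), "rv_blood": down(rv), "lv_blood": down(lv),
                 "myocardium": down(myo), "liver": down(liver)}
    labels = np.zeros((n, n), dtype=np.int8)
    for name in ("rv_blood", "lv_blood", "myocardium", "liver"):
        labels[fractions[name] > 0.5] = LABELS[name]
    # heart bounding box with a margin, clipped to the FOV
    hr = np.where((labels == LABELS["rv_blood"]) | (labels == LABELS["lv_blood"])
                  | (labels == LABELS["myocardium"]))
    pad = max(2, n // 16)
    roi = (max(int(hr[0].min()) - pad, 0), min(int(hr[0].max()) + pad, n),
           max(int(hr[1].min()) - pad, 0), min(int(hr[1].max()) + pad, n))
    return fractions, labels, roi


# ---------------------------------------------------------------------------
# Motion, coils, assembly
# ---------------------------------------------------------------------------

def _smooth_basis(n: int, rng, control: int = 6):
    """Fixed smooth deformation basis, unit peak magnitude: a dominant
    head-foot translation component plus a random B-spline-like nonrigid
    residual (cubic upsampling of coarse control-point offsets)."""
    coarse = rng.normal(size=(2, control, control))
    nonrigid = np.stack([zoom(c, n / control, order=3, mode="nearest")
                         for c in coarse])
    nonrigid = np.stack([gaussian_filter(f, n / 16) for f in nonrigid])
    nonrigid /= np.abs(nonrigid).max()
    basis = np.zeros((2, n, n))
    basis[0] = 1.0            # head-foot translation (rows)
    basis += 0.35 * nonrigid  # nonrigid residual
    return basis / np.hypot(basis[0], basis[1]).max()


def _invert_field(fwd: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """Fixed-point inversion b(x) = -f(x + b(x)) of a displacement field."""
    bwd = -fwd.copy()
    for _ in range(n_iter):
        br = warp(fwd[0], bwd)
        bc = warp(fwd[1], bwd)
        bwd = -np.stack([br, bc])
    return bwd


def simulate_coils(n_coils: int, matrix_size: int, seed: int = 0) -> CoilMaps:
    """Smooth complex coil maps: Gaussian magnitude lobes centered on a ring
    around the FOV with low-order polynomial phase.  Root-sum-of-squares is
    strictly positive everywhere.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be at least 1")
    n = matrix_size
    if n_coils == 1:
        return CoilMaps(np.ones((1, n, n), dtype=complex))
    rng = np.random.default_rng(seed)
    r = np.linspace(-1, 1, n)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    maps = np.empty((n_coils, n, n), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.15, 0.15)
        cy, cx = 1.15 * np.sin(ang), 1.15 * np.cos(ang)
        mag = np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * 0.75 ** 2))
        phase = (rng.uniform(-np.pi, np.pi)
                 + 0.8 * rng.normal() * rr + 0.8 * rng.normal() * cc
                 + 0.4 * rng.normal() * rr * cc)
        maps[c] = (0.08 + mag) * np.exp(1j * phase)
    return CoilMaps(maps)


def make_phantom(spec: PhantomSpec) -> PerfusionPhantom:
    """Assemble the full ground-truth phantom for one random seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.matrix_size
    fractions, labels, roi = _geometry(n)

    # smooth multiplicative texture (tissue heterogeneity; also gives the
    # registration metric gradients inside uniform regions)
    texture = gaussian_filter(rng.normal(size=(n, n)), n / 24)
    texture = 1.0 + spec.texture_strength * texture / np.abs(texture).max()

    times = spec.frame_times_s
    curves = {name: spec.tissue_params[name](times)
              for name in spec.tissue_params}
    curves["body"] = np.full(spec.n_frames, 0.20)

    reference = np.zeros((spec.n_frames, n, n))
    for name, frac in fractions.items():
        reference += frac[None] * curves[name][:, None, None]
    reference *= texture[None]
    reference = reference.astype(complex)

    # beat-to-beat respiratory displacement: sinusoid plus slow drift,
    # sampled at heartbeat times, scaling one fixed smooth deformation basis
    basis = _smooth_basis(n, rng)
    phase = rng.uniform(0, 2 * np.pi)
    trace = np.sin(2 * np.pi * spec.resp_freq_hz * times + phase)
    if spec.resp_drift_px > 0 and spec.motion_amplitude_px > 0:
        trace = trace + (spec.resp_drift_px / max(spec.motion_amplitude_px, 1e-9)) \
            * (times / times[-1] - 0.5)
    fwd = spec.motion_amplitude_px * trace[:, None, None, None] * basis[None]
    if spec.motion_amplitude_px == 0:
        bwd = np.zeros_like(fwd)
    else:
        bwd = np.stack([_invert_field(fwd[t]) for t in range(spec.n_frames)])
    motion = MotionFieldSeries(fwd, bwd)

    truth = np.stack([motion.warp_forward(t, reference[t])
                      for t in range(spec.n_frames)])

    coils = simulate_coils(spec.n_coils, n, seed=spec.seed + 1)
    return PerfusionPhantom(truth_series=truth, reference_series=reference,
                            motion_fields=motion, coil_maps=coils,
                            masks=labels, heart_roi=roi, spec=spec)


def sample_kspace(phantom: PerfusionPhantom, traj: TrajectorySpec | None = None,
                  noise_fraction: float | None = None,
                  seed: int | None = None) -> RadialKSpace:
    """Acquire noisy multi-coil radial k-space from the moving truth series.

    Complex Gaussian noise with per-component standard deviation
    ``noise_fraction * max|k| / sqrt(2)``, so the RMS magnitude of the noise
    equals the requested fraction of the k-space peak.
    """
    spec = phantom.spec
    traj = spec.trajectory() if traj is None else traj
    if traj.n_frames != spec.n_frames:
        raise ValueError("trajectory/phantom frame count mismatch")
    noise_fraction = spec.noise_fraction if noise_fraction is None else noise_fraction
    seed = spec.seed + 2 if seed is None else seed

    op = EncodingOperator(traj, phantom.coil_maps)
    data = op.forward(phantom.truth_series)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_fraction * np.abs(data).max() / np.sqrt(2)
        data = data + sigma * (rng.standard_normal(data.shape)
                               + 1j * rng.standard_normal(data.shape))
    return RadialKSpace(data, traj)
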