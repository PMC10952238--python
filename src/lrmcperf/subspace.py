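"""Patient-specific temporal subspace of the contrast dynamics.

After motion alignment, the perfusion series is highly redundant across
heartbeats: its Casorati matrix (pixels x frames) is approximately low
rank, with the temporal right-singular vectors spanning the bolus dynamics.
The reconstruction solves for ``r`` singular images instead of ``n_frames``
frames, with the orthonormal temporal basis ``U_r`` mapping between them.

Alignment into the reference state before the SVD matters: without it, the
leading modes absorb respiratory motion, which the reconstruction corrects
through the warp operator instead — the basis should carry contrast only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motion import MotionFieldSeries

__all__ = ["TemporalSubspace", "align_series", "estimate_subspace"]


@dataclass
class TemporalSubspace:
    """Orthonormal temporal basis ``Ur`` (n_frames x r) plus the spectrum
    it was truncated from."""

    Ur: np.ndarray
    singular_values: np.ndarray
    energy_threshold: float
    roi: tuple | None = None

    def __post_init__(self):
        gram = self.Ur.conj().T @ self.Ur
        if not np.allclose(gram, np.eye(self.rank), atol=1e-10):
            raise ValueError("temporal basis is not orthonormal")

    @property
    def rank(self) -> int:
        return self.Ur.shape[1]

    @property
    def n_frames(self) -> int:
        return self.Ur.shape[0]

    def project(self, series: np.ndarray) -> np.ndarray:
        """``Ur^H`` along the frame axis: frame series -> singular images."""
        if series.shape[0] != self.n_frames:
            raise ValueError("frame count mismatch")
        return np.tensordot(self.Ur.conj().T, series, axes=1)

    def expand(self, singular: np.ndarray) -> np.ndarray:
        """``Ur`` along the compressed axis: singular images -> frames."""
        if singular.shape[0] != self.rank:
            raise ValueError("rank mismatch")
        return np.tensordot(self.Ur, singular, axes=1)

    @classmethod
    def identity(cls, n_frames: int) -> "TemporalSubspace":
        return cls(np.eye(n_frames), np.ones(n_frames), 1.0)


def align_series(X: np.ndarray, motion: MotionFieldSeries,
                 mode: str = "transpose") -> np.ndarray:
    """Bring every frame into the reference motion state.

    ``mode='transpose'`` applies ``M_t^H`` (operator-consistent with the
    reconstruction's adjoint); ``mode='inverse'`` resamples with the
    backward field (visually cleaner, not the operator adjoint).
    """
    if X.shape[0] != motion.n_frames:
        raise ValueError("series/motion frame count mismatch")
    if mode == "transpose":
        return np.stack([motion.warp_forward_transpose(t, X[t])
                         for t in range(motion.n_frames)])
    if mode == "inverse":
        return np.stack([motion.warp_backward(t, X[t])
                         for t in range(motion.n_frames)])
    raise ValueError(f"unknown alignment mode '{mode}'")


def rank_from_energy(singular_values: np.ndarray, energy_threshold: float) -> int:
    """Smallest rank whose cumulative squared singular values reach the
    requested fraction of total energy."""
    s2 = np.asarray(singular_values, dtype=float) ** 2
    cum = np.cumsum(s2) / s2.sum()
    return int(np.searchsorted(cum, energy_threshold - 1e-12) + 1)


def estimate_subspace(X_aligned: np.ndarray, energy_threshold: float = 0.96,
                      roi: tuple | None = None,
                      fixed_rank: int | None = None) -> TemporalSubspace:
    """SVD the (optionally ROI-restricted) Casorati matrix of the aligned
    series; truncate the temporal basis at the energy threshold.

    ``roi`` is ``(row0, row1, col0, col1)``; the SVD sees only those pixels
    (a large box around the heart keeps background/liver dynamics from
    diluting the basis) but the returned basis is applied globally.
    ``fixed_rank`` overrides the threshold rule.
    """
    if not (0 < energy_threshold <= 1):
        raise ValueError("energy_threshold must lie in (0, 1]")
    n_frames = X_aligned.shape[0]
    if roi is not None:
        r0, r1, c0, c1 = roi
        if not (0 <= r0 < r1 <= X_aligned.shape[1]
                and 0 <= c0 < c1 <= X_aligned.shape[2]):
            raise ValueError("roi outside image")
        block = X_aligned[:, r0:r1, c0:c1]
        if block[0].size == 0:
            raise ValueError("empty roi")
    else:
        block = X_aligned
    casorati = block.reshape(n_frames, -1).T  # pixels x frames
    _, s, vh = np.linalg.svd(casorati, full_matrices=False)
    r = fixed_rank if fixed_rank is not None else rank_from_energy(s, energy_threshold)
    r = int(min(max(r, 1), n_frames))
    Ur = vh[:r].conj().T  # (n_frames, r)
    return TemporalSubspace(Ur=Ur, singular_values=s,
                            energy_threshold=energy_threshold, roi=roi)
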