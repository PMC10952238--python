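"""File formats and run configuration.

Canonical on-disk layouts (all self-describing):

* **Radial k-space** (HDF5): ``/data_real``, ``/data_imag``
  ``[frame, coil, spoke, sample]``; ``/coords`` ``[frame, spoke, sample, 2]``
  in cycles/FOV; optional ``/dcf``; JSON trajectory metadata in the root
  attribute ``meta``.
* **Complex image series** (HDF5): ``/series_real``, ``/series_imag``.
* **Temporal subspace** (HDF5): ``/Ur_real``, ``/Ur_imag``,
  ``/singular_values``; attrs ``threshold``, ``rank``, ``roi``.
* **Displacement fields** (HDF5): ``/forward``, ``/backward``
  ``[frame, 2, row, col]`` in pixels.
* **Magnitude series / fields for external viewers**: NIfTI via nibabel.
* **Run configuration**: YAML mirroring every solver/phantom parameter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .encoding import RadialKSpace, TrajectorySpec, CoilMaps
from .motion import MotionFieldSeries
from .subspace import TemporalSubspace

__all__ = [
    "FormatError",
    "RunConfig",
    "write_kspace", "read_kspace",
    "write_series", "read_series",
    "write_subspace", "read_subspace",
    "write_motion", "read_motion",
    "write_coils", "read_coils",
    "write_nifti_series", "read_nifti_series",
    "write_report",
]


class FormatError(ValueError):
    """Malformed file layout; the message names the missing dataset."""


def _require(h5, name):
    if name not in h5:
        raise FormatError(f"missing dataset '{name}'")
    return h5[name]


# ---------------------------------------------------------------------------
# HDF5 layouts
# ---------------------------------------------------------------------------

def write_kspace(path, k: RadialKSpace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data_real", data=k.data.real)
        f.create_dataset("data_imag", data=k.data.imag)
        f.create_dataset("coords", data=k.traj.coordinates)
        if k.dcf is not None:
            f.create_dataset("dcf", data=k.dcf)
        f.attrs["meta"] = json.dumps({
            "n_frames": k.traj.n_frames,
            "spokes_per_frame": k.traj.spokes_per_frame,
            "samples_per_spoke": k.traj.samples_per_spoke,
            "golden_angle_deg": k.traj.golden_angle_deg,
            "continuous_across_frames": k.traj.continuous_across_frames,
            "units": "cycles/FOV",
        })


def read_kspace(path) -> RadialKSpace:
    with h5py.File(path, "r") as f:
        data = _require(f, "data_real")[:] + 1j * _require(f, "data_imag")[:]
        coords = _require(f, "coords")[:]
        meta = json.loads(f.attrs["meta"])
        dcf = f["dcf"][:] if "dcf" in f else None
    traj = TrajectorySpec(meta["n_frames"], meta["spokes_per_frame"],
                          meta["samples_per_spoke"], meta["golden_angle_deg"],
                          meta["continuous_across_frames"], coordinates=coords)
    return RadialKSpace(data, traj, dcf)


def write_series(path, series: np.ndarray) -> None:
    series = np.asarray(series)
    with h5py.File(path, "w") as f:
        f.create_dataset("series_real", data=series.real)
        f.create_dataset("series_imag", data=series.imag)


def read_series(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return _require(f, "series_real")[:] + 1j * _require(f, "series_imag")[:]


def write_subspace(path, sub: TemporalSubspace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Ur_real", data=sub.Ur.real)
        f.create_dataset("Ur_imag", data=sub.Ur.imag)
        f.create_dataset("singular_values", data=sub.singular_values)
        f.attrs["threshold"] = sub.energy_threshold
        f.attrs["rank"] = sub.rank
        if sub.roi is not None:
            f.attrs["roi"] = list(sub.roi)


def read_subspace(path) -> TemporalSubspace:
    with h5py.File(path, "r") as f:
        Ur = _require(f, "Ur_real")[:] + 1j * _require(f, "Ur_imag")[:]
        sv = _require(f, "singular_values")[:]
        thr = float(f.attrs["threshold"])
        roi = tuple(int(v) for v in f.attrs["roi"]) if "roi" in f.attrs else None
    return TemporalSubspace(Ur, sv, thr, roi)


def write_motion(path, motion: MotionFieldSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("forward", data=motion.forward)
        f.create_dataset("backward", data=motion.backward)
        if motion.reference_frame is not None:
            f.attrs["reference_frame"] = motion.reference_frame


def read_motion(path) -> MotionFieldSeries:
    with h5py.File(path, "r") as f:
        fwd = _require(f, "forward")[:]
        bwd = _require(f, "backward")[:]
        ref = int(f.attrs["reference_frame"]) if "reference_frame" in f.attrs else None
    return MotionFieldSeries(fwd, bwd, ref)


def write_coils(path, coils: CoilMaps) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("maps_real", data=coils.maps.real)
        f.create_dataset("maps_imag", data=coils.maps.imag)


def read_coils(path) -> CoilMaps:
    with h5py.File(path, "r") as f:
        return CoilMaps(_require(f, "maps_real")[:] + 1j * _require(f, "maps_imag")[:])


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_nifti_series(path, series: np.ndarray) -> None:
    """Magnitude series as one 3D NIfTI volume, frames along the last axis."""
    mag = np.abs(np.asarray(series)).astype(np.float32)
    vol = np.moveaxis(mag, 0, -1)  # (row, col, frame)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def read_nifti_series(path) -> np.ndarray:
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    return np.moveaxis(vol, -1, 0)


def write_report(path, report) -> None:
    payload = report.as_dict() if hasattr(report, "as_dict") else report
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run needs, round-trippable through YAML."""

    phantom: dict = dc_field(default_factory=dict)      # PhantomSpec overrides
    methods: list = dc_field(default_factory=lambda: ["zerofill", "itsense", "lps", "lrmc"])
    itsense_iters: int = 6
    lps_lambda_L: float = 0.1
    lps_lambda_S: float = 0.1
    lps_iters: int = 6
    ica_components: int = 5
    resp_band_hz: tuple = (0.2, 0.5)
    registration_grid_px: float = 12.0
    registration_levels: int = 3
    motion_smooth_sigma_px: float = 1.0
    motion_refine_passes: int = 2
    energy_threshold: float = 0.96
    fixed_rank: int | None = 8  # the rank used for every in vivo case
    admm: dict = dc_field(default_factory=dict)         # ADMMConfig overrides
    patch: dict = dc_field(default_factory=dict)        # PatchTensorConfig overrides
    use_truth_motion: bool = False
    cov_window: int = 7
    n_profiles: int = 10
    out_dir: str = "run"
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["resp_band_hz"] = list(self.resp_band_hz)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "resp_band_hz" in d:
            d["resp_band_hz"] = tuple(d["resp_band_hz"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
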