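# lrmcperf

Motion-corrected low-rank reconstruction for free-breathing, first-pass
myocardial perfusion MRI — with the full estimation chain, baselines, a
numerical perfusion phantom, and quantitative evaluation.

First-pass perfusion captures a gadolinium bolus transiting RV → LV →
myocardium, one image per heartbeat per slice, under free breathing: every
frame is heavily undersampled (golden-angle radial, ~4×) *and* sits in a
different respiratory state. This package reconstructs the series by
solving

    min_y  1/2 Σ_t ‖A_t F C M_t (U_r y)_t − k_t‖²  +  λ Σ_b ‖T_b‖_*

where `y` are r compressed *singular images*, `U_r` an orthonormal
temporal basis of the contrast dynamics, `M_t` the nonrigid warp to beat
t's respiratory state, `C` coil sensitivities, `A_t F` the NUFFT on beat
t's spokes, and the penalty is a patch-based high-order low-rank prior
(pixels × similar patches × singular images tensors). The problem is
solved with ADMM (CG data-consistency step + patch-tensor denoising).
Motion fields and subspace are estimated from the data itself: auxiliary
iterative-SENSE reconstruction → ICA synthesis of motion-suppressed,
contrast-matched registration references → B-spline free-form-deformation
registration per heartbeat → SVD of the motion-aligned series. Iterative
SENSE and low-rank-plus-sparse (L+S) reconstructions are included as
baselines, and a numerical phantom (gamma-variate enhancement, beat-to-beat
nonrigid respiratory deformation, smooth coil maps, noisy radial k-space)
makes everything testable without scanner data.

Audience: MR reconstruction researchers and students who want a complete,
NumPy/SciPy-level reference implementation of motion-corrected subspace
reconstruction with exactly-adjoint operators and a reproducible synthetic
testbed.

## Worked example

Reconstruct a synthetic acquisition three ways and compare:

```python
import numpy as np
from lrmcperf import (PhantomSpec, make_phantom, sample_kspace,
                      itsense, lps, lrmc, zero_filled,
                      estimate_subspace, align_series,
                      evaluate_reconstructions)
from lrmcperf.recon import ADMMConfig, PatchTensorConfig

spec = PhantomSpec.desk(seed=1)        # 64x64, 30 heartbeats, 4 coils,
ph = make_phantom(spec)                # 27 spokes/beat, 5 px breathing,
k = sample_kspace(ph)                  # 2% k-space noise

sub = estimate_subspace(align_series(ph.truth_series, ph.motion_fields),
                        roi=ph.heart_roi, fixed_rank=8)

recons = {"itsense": itsense(k, ph.coil_maps),
          "zerofill": zero_filled(k, ph.coil_maps)}
L, S = lps(k, ph.coil_maps)
recons["lps"] = L + S
_, recons["lrmc"] = lrmc(k, ph.coil_maps, ph.motion_fields, sub,
                         admm=ADMMConfig(), patch=PatchTensorConfig())

report = evaluate_reconstructions(recons, ph, co_registered={"lrmc": True})
for m in ("itsense", "lps", "lrmc"):
    print(f"{m:8s} CoV {report.mean_cov_pct[m]:5.1f}%  "
          f"sharpness {np.mean(list(report.sharpness_pct[m].values())):5.1f}%  "
          f"MAE {report.mae[m]:.4f}")
```

prints

```
itsense  CoV  24.6%  sharpness  55.7%  MAE 0.0304
lps      CoV  18.6%  sharpness  61.0%  MAE 0.0392
lrmc     CoV   1.9%  sharpness  76.9%  MAE 0.0340
```

The myocardial temporal coefficient of variation (flicker of the
per-segment signal around its median-filtered course — residual aliasing
and motion) drops an order of magnitude with motion-corrected low-rank
reconstruction, while boundary sharpness at the enhancement key frames
rises by ~20 points; MAE is computed against the ground truth each method
estimates (motion-corrected vs moving).

The same pipeline is scriptable from the shell:

```bash
lrmcperf pipeline --out run1 --seed 1       # simulate → estimate → reconstruct → evaluate
lrmcperf sweep --scales 0,0.5,1.0,1.5,2.0 --out sweep1 --seed 1
```

`run1/` contains every stage (HDF5 + NIfTI) with a manifest; `sweep1/`
holds the motion-error study (unregularized reconstruction with the true
motion scaled by each factor — CoV and MAE are minimized at scale 1.0).

## Layout

```
src/lrmcperf/
  phantom.py    numerical perfusion phantom (geometry, bolus curves, motion, coils, k-space)
  encoding.py   trajectory, gridding NUFFT, coils, full encoding operator E and E^H
  motion.py     sparse bilinear warp M/M^H, ICA references, FFD registration
  subspace.py   motion-aligned SVD, temporal basis, project/expand
  recon.py      CG, zero-filled, itSENSE, L+S, patch-tensor denoising, LRMC ADMM, motion sweep
  metrics.py    sharpness, temporal CoV, MAE, AHA segments, method comparison report
  io.py         HDF5/NIfTI/YAML layouts, run configuration
  pipeline.py   five-stage orchestration with manifest
  cli.py        `lrmcperf simulate|recon|sweep|evaluate|pipeline`
docs/methods.md   model, parameters, numerical choices, limitations
```
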