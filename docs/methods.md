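# Methods

`lrmcperf` reconstructs free-breathing, beat-to-beat first-pass myocardial
perfusion series from undersampled golden-angle radial k-space by solving a
motion-corrected low-rank inverse problem, and ships the auxiliary
estimation chain (ICA motion references, nonrigid registration, temporal
subspace), two baseline reconstructions (iterative SENSE, low-rank plus
sparse), a numerical perfusion phantom, and the evaluation metrics used to
compare them. This note records the model, the parameter choices, the
numerical decisions, and what the synthetic experiments do and do not show.

## The reconstruction model

One saturation-prepared image is acquired per heartbeat per slice, so each
frame `t` sits in its own respiratory state. The acquisition of frame `t`
is modeled as

    k_t = A_t F C M_t U_r y + n_t

where `y` are `r` complex *singular images* (the unknowns), `U_r` is an
orthonormal temporal basis mapping them to `N` contrast frames, `M_t` warps
the reference respiratory state to beat `t`'s state, `C` applies coil
sensitivities, and `A_t F` evaluates the nonuniform Fourier transform on
the spokes acquired during beat `t`. Because motion sits inside the
encoding operator, every acquired spoke contributes to every reconstructed
frame; because the temporal basis is global, the problem has `r·N_pix`
unknowns instead of `N·N_pix`.

The regularized problem is

    min_y  1/2 Σ_t ||A_t F C M_t (U_r y)_t − k_t||²  +  λ Σ_b ||T_b||_*

with a patch-based high-order low-rank penalty: for each (strided) voxel
`b`, block matching collects the K most similar patches in a search window
and stacks them into a 3-mode tensor (patch pixels × K patches × r singular
images) whose multilinear rank is penalized. ADMM alternates a
conjugate-gradient data-consistency step on `(E^H E + μI) y = E^H k +
μ(T − u)`, a tensor-denoising step `T = prox(y + u)`, and the scaled dual
update. With `λ = 0` the ADMM machinery is bypassed and the problem is
solved by plain CG — this unregularized variant is what the simulation
studies use.

Defaults (all overridable in `ADMMConfig` / `PatchTensorConfig`):
10 outer iterations, 3 inner CG iterations, `λ = 1e-3`;
patch 5×5 px, search window 21×21 px, K = 10 similar patches, stride 2,
block matching on the root-sum-of-squares of the singular images;
the ADMM penalty `μ` defaults to `0.1·mean|E^H k|` so behavior is invariant
to global data scaling; the denoise threshold is `(λ/μ)·max|y + u|`. The
tensor proximal step soft-thresholds the singular values of each of the
three mode unfoldings and averages the refolded estimates — a standard
surrogate for the multilinear nuclear norm that avoids an inner iteration.

## Encoding operators

* **NUFFT.** Kaiser-Bessel gridding on a 2× oversampled grid, kernel width
  12 (Fessler-Sutton β). The nonuniform interpolation is a precomputed
  sparse matrix, so the adjoint is its exact conjugate transpose composed
  with an orthonormal inverse FFT: adjoint dot-product tests pass at
  machine precision *by construction*, while accuracy against a
  brute-force DFT is ~1e-10 on unit-scale images. Conventions: k-space in
  cycles/FOV within [−0.5, 0.5), image origin at `floor(N/2)`, unscaled-DFT
  normalization (a centered unit impulse gives unit-magnitude samples).
* **Golden-angle trajectory.** Spoke angle `m·111.24611797…°` with the
  spoke index continuous across the whole scan, so every frame's spokes
  interleave; radii span [−0.5, 0.5) with 2× readout oversampling
  (`samples_per_spoke = 2·matrix`).
* **Warp.** Bilinear interpolation assembled as a sparse matrix;
  out-of-FOV samples contribute zero. `M^H` is the exact matrix transpose
  (not the inverse warp): this is what makes `E^H E` Hermitian and CG
  convergent. An approximate inverse warp (fixed-point inversion of the
  forward field) is kept for alignment and display.
* **Density compensation.** Ramp `|k|` capped at DC, used only for
  zero-filled/gridded images and for the √DCF preconditioning inside L+S —
  never inside CG normal equations, which would destroy exact adjointness.

## Auxiliary estimation chain

1. **Iterative SENSE** (6 CG iterations per frame, no regularization)
   provides the auxiliary series.
2. **ICA references.** The magnitude series (frames × pixels Casorati
   matrix) is decomposed by FastICA into 5 temporal components after PCA
   whitening (the component count is capped at the numerical rank of the
   centered matrix — whitening is singular past it on exactly-low-rank
   synthetic input). Each component's temporal course is detrended and the
   component whose spectral peak (DC excluded, ties toward lower frequency)
   lies inside the respiratory band (0.2, 0.5) Hz with the largest peak
   magnitude is zeroed before resynthesis. If no component peaks in band,
   the full-rank resynthesis is returned with a warning. The result is a
   contrast-matched, motion-suppressed reference for every frame.
3. **Registration.** B-spline free-form deformation per frame pair
   (frame ↔ its reference), SimpleITK implementation: correlation metric
   (insensitive to the intensity-scale bias of ICA resynthesis) on
   99th-percentile-normalized magnitudes, control-grid spacing 12 px,
   3-level multiresolution, LBFGS-B with dense sampling (fully
   deterministic), and a light Gaussian smoothing of the dense field in
   lieu of a bending-energy term. Both directions are registered: the
   forward field (reference → frame) enters the encoding operator, the
   backward field aligns and visualizes.
   Because a single ICA pass cannot remove the harmonics that a nonlinear
   warp generates (the displacement trace and its square are statistically
   *dependent* sources, so no rotation of independent components isolates
   them), `estimate_motion` optionally refines: align with the current
   estimate, median-filter along time (window 5) to suppress residual
   aliasing and motion, warp back to each frame's state as improved
   references, and re-register (2 passes in the pipeline default).
4. **Subspace.** The aligned series (via `M^H`, the operator-consistent
   choice) is SVD'd on a rectangular ROI around the heart; the temporal
   right-singular vectors are truncated at 96% cumulative squared singular
   value energy, or at a fixed rank. The pipeline default is the fixed
   rank 8 used for every in vivo case; the energy rule remains the
   function-level default. The basis is estimated on the ROI but applied
   globally — consequently tissues absent from the ROI (liver, background)
   are represented only approximately, which is visible in whole-image
   summaries but not in cardiac ones.

## Baselines

* **Zero-filled**: density-compensated gridding adjoint with conjugate
  coil combination.
* **itSENSE**: frame-by-frame CG on the SENSE normal equations, 6
  iterations, zero start. Early stopping is the only regularization — on
  undersampled radial data the normal operator is effectively
  rank-deficient, and long CG runs drift in its null space while the data
  residual stays flat. "The" unregularized solution is therefore defined
  by the iteration budget, as in standard CG-SENSE practice.
* **L+S**: iterative shrinkage splitting the series into a low-rank
  background `L` (singular-value soft-threshold of the Casorati matrix at
  `λ_L·σ₁`) and a temporally-sparse component `S` (soft-threshold of the
  temporal FFT, threshold anchored at the first-pass transform peak —
  re-anchoring each iteration over-regularizes). Defaults `λ_L = λ_S =
  0.1`, 6 iterations. The operator is √DCF-weighted on both sides and
  spectrally normalized by a power-iteration estimate so the shrinkage
  step size is exactly one; without that normalization the data term is on
  the wrong scale and the iterates collapse.

## Numerical phantom

The phantom emulates a mid-ventricular short-axis slice: torso, liver,
crescent RV blood pool, circular LV blood pool, myocardial annulus, each
rendered at 4× supersampling and averaged down (soft, realistic edges).
Each tissue follows a gamma-variate bolus curve, peak-normalized so the
maximum enhancement equals its amplitude at `t0 + α·β`:

| tissue      | t0 (s) | α   | β (s) | amplitude | baseline | peak (s) |
|-------------|-------:|----:|------:|----------:|---------:|---------:|
| RV blood    | 3      | 3.0 | 1.5   | 1.00      | 0.10     | 7.5      |
| LV blood    | 8      | 3.0 | 2.0   | 0.90      | 0.10     | 14       |
| myocardium  | 12     | 2.5 | 4.0   | 0.35      | 0.15     | 22       |
| liver       | 18     | 2.5 | 6.0   | 0.25      | 0.15     | 33       |

The RV → LV → myocardium onset ordering is enforced. A smooth seeded
multiplicative texture (±12%) models tissue heterogeneity and gives the
registration metric gradients inside otherwise-flat regions. Respiratory
motion is one fixed smooth deformation basis (dominant head-foot
translation plus a 35% nonrigid residual from cubic-upsampled random
control points) scaled by a sinusoidal trace (0.3 Hz inside the (0.2, 0.5)
Hz band) plus a slow linear drift, sampled once per heartbeat — one motion
state per beat, no intra-shot motion. The moving series is produced by the
*same* bilinear warp operator the reconstruction uses, so the generative
model is exactly representable and model-consistency tests separate solver
error from model mismatch. Coil maps are smooth offset-Gaussian magnitudes
with low-order polynomial phase on a ring around the FOV (strictly
positive root-sum-of-squares); k-space noise is i.i.d. complex Gaussian
with per-component σ = 2% of the k-space peak divided by √2, so the RMS
noise magnitude equals the stated fraction.

Default acquisition mirrors the target protocol: matrix 128, 60 heartbeats
at 1 s, 8 coils, 53 spokes/frame, 10 px peak displacement (the in vivo
range [11.6, 26.4] mm at 2 mm/px, scaled down). `PhantomSpec.desk()` is
the reduced instance used throughout the tests and the acceptance script:
matrix 64, 30 heartbeats, 4 coils, 27 spokes (the same ≈4× undersampling
relative to the ≈100-spoke fully-sampled requirement), 5 px motion. These
sizes keep the complete study — three reconstructions plus a five-point
motion-error sweep — around four minutes on one CPU.

What the phantom does **not** model: saturation-recovery signal physics
(curves are prescribed directly, not via Bloch simulation), through-plane
motion, arrhythmia or mistriggering, dark-rim/intra-shot cardiac motion,
and coil-array noise correlation. Passing tests therefore demonstrate the
correctness and behavior of the operators and solvers under a known,
representable generative model — not clinical image quality.

## Evaluation metrics

* **Sharpness** of a line profile: min-max normalize, locate the first
  upward crossings of 0.2 and 0.8 by linear interpolation; sharpness is
  `1/|p80 − p20|` (1/px) clipped at 1 and reported in percent. A one-pixel
  step yields a 0.6 px rise, hence the clip. A 3-sample running median is
  applied first: it is the identity on monotone edges (both defining
  anchors — the step edge and the erf edge with 20–80% width `1.683σ` —
  are unchanged) but keeps single-sample noise spikes from defining the
  normalization levels. Profiles are drawn programmatically: rays from the
  mask centroid through the boundary of a phantom-defined structure, 10
  per boundary, 8 px long at 0.25 px sampling — replacing the manual
  line-drawing protocol. For series that are *not* co-registered, the
  sample coordinates are displaced by the true motion at the evaluated
  frame (the manual protocol likewise re-draws lines per method).
* **Temporal CoV**: RMS deviation of a signal from its running-median
  (window 7, reflected edges), divided by the filtered mean, in percent.
  The median passes the bolus upslope but rejects frame-to-frame flicker
  from residual aliasing and motion. Note an odd-window median *tracks* a
  period-2 alternation, so sparse spikes — not alternating signals — are
  the right closed-form test case.
* **MAE**: mean absolute difference after independent [0, 1] min-max
  normalization of each magnitude series. Motion-corrected reconstructions
  are scored against the motionless reference series, uncorrected ones
  against the moving truth — each method against the object it estimates.
* **AHA segments**: angular sectors (6 basal/mid, 4 apical) about the LV
  center, counted counterclockwise from the RV insertion point; CoV is
  computed per segment mean curve and averaged.

## Study protocols and their rationale

The *simulation protocol* supplies the reconstruction with the phantom's
true motion fields and a subspace estimated from the truth-aligned series —
exactly the setting of the motion-error sweep, where scaling the true
fields by 0, 0.5, 1, 1.5, 2 probes under- and over-estimated motion. On
the desk instance both the myocardial segmental CoV and the MAE are
minimized at scale 1.0, doubled motion is worse than ignoring motion in
MAE, and every sweep point beats zero-filling in CoV — blurring for
under-corrected motion, noise amplification for over-corrected.

The method comparison (itSENSE vs L+S vs regularized LRMC) uses the same
protocol. The full self-contained pipeline — ICA references, registration,
refinement — is exercised end-to-end separately; at desk scale its median
field error is ≈2.6 px of a 5 px excursion. Thirty to sixty frames give
the ICA decomposition too few temporal samples, and the warp's harmonics
are statistically dependent on the fundamental, which caps what
single-component removal can suppress; motion estimation quality is the
known limiting factor of this framework class, and desk scale sharpens it.

## Known limitations

* Unregularized reconstructions depend on the CG iteration budget (see
  itSENSE note above); reported unregularized results state their budget.
* The ICA reference synthesis degrades gracefully but noticeably as the
  displacement leaves the linear intensity-response regime (≳2 px at
  matrix 64); the refinement loop recovers part, not all, of the gap to
  ground-truth motion.
* `warp_transpose` is adjoint-exact but not mass-preserving; alignment for
  *display* should use the backward (inverse) field.
* The ROI-restricted subspace does not span dynamics of tissues outside
  the ROI; whole-image error measures partially reflect this choice rather
  than cardiac reconstruction quality.
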