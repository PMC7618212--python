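# Methods

## Forward model

A multi-shot 3D EPI volume is acquired over `n_shots` excitations on a
seg-CAIPI trajectory: the (ky, kz) plane is decimated by `R_y × R_z` on a
Δkz-blipped CAIPI lattice, and the sampled kz platters are distributed over
the shots so that each *interleave* (the future shot group) covers k-space
with stride `n_groups` while running sequentially through its own platters.
Shots are binned into `n` shot groups of consecutive shots; each group is
reconstructed as its own complex image `x_i` (one phase state per group).
Within a group, consecutive shots form *temporal subdivisions*, each with
its own rigid-motion state.

The signal model for subdivision `(i, j)` is `y_ij = A_ij F S T_intra,ij
T_inter,i x_i`: rigid motion (image side), coil sensitivity encoding,
centered unitary Fourier transform, sampling mask. The group images are
assumed mutually aligned; `T_inter,1` is pinned to the identity (global
pose is unidentifiable from k-space data, only relative motion matters —
the evaluation removes the reference offset for the same reason).

## Rigid transforms

Translation is a k-space phase ramp; rotation is the classical three-pass
shear decomposition `Shear_a(-tan θ/2) · Shear_b(sin θ) · Shear_a(-tan
θ/2)`, each shear a per-line linear phase in the conjugate domain. Every
pass is exactly unitary: energy is preserved to machine precision and the
operator adjoint is the reversed pass sequence with negated parameters,
which is what the encoding adjoint uses (dot-product tests pass at 1e-12).
Conventions: rotation center and phase origin at the center voxel `N//2`;
translations in mm, divided by the voxel size before phase construction;
angles act in index space; wrap-around from the shears is accepted (the
object is assumed inside the FOV with a margin). Angles beyond 45° take an
exact quarter-turn index permutation first (square planes only). Parameter
derivatives are analytic — each pass differentiated in its conjugate
domain and chained with the product rule — and are validated against
central finite differences (1e-4 relative).

## Subproblem 1: structured low-rank ADMM

With the motion fixed, the group images solve

    min_X ||A F S T X − Y||² + λ Σ_l ||H_2D F X_l||_* .

In 2D there is a single slice; the 6×6 block-Hankel lifting of the stacked
group k-spaces has shape `(N1−5)(N2−5) × 36·n`. ADMM splits with `Z = F X`:
the X-update is CG on the motion-inclusive normal equations `(EᴴE + ρ)X =
EᴴY + ρFᴴ(Z−U)`, the Z-update is lift → singular-value soft threshold →
overlap-count-normalized adjoint, with a standard scaled dual ascent.

Two solver parameterizations differ deliberately from a naive reading of
the objective:

* **Relative threshold.** The data are normalized so the initial adjoint
  reconstruction has unit peak SOS magnitude, but the SVT threshold is
  `λ/ρ` *relative to the largest singular value of the initial lifted
  matrix* (then frozen, so all iterations minimize one fixed convex
  objective). Absolute singular values of the lifting vary by orders of
  magnitude with image content and grid size, while the inter-channel
  inconsistency the penalty targets lives in the *normalized* spectrum
  tail; a fixed absolute threshold of 0.1 on this data scale would be
  ~2·10⁻⁴ of σ_max and threshold nothing. With λ = 0.1 and ρ = 5 the
  effective cut is 2% of σ_max.
* **Initialization.** The group-image stack starts as the combined-group
  SENSE image replicated per group. At the per-group undersampling
  (R_eff = 16, regular, mostly along z) independent per-group CG-SENSE is
  unusable for any realistic coil count, and the Hankel coupling refines a
  consistent stack far better than it can fuse four mutually inconsistent
  aliased ones. Using the same initialization with and without motion
  freezing also makes the degenerate motion-free case collapse exactly
  onto the motion-naive solve.

Divergence (objective above 10× its initial value) raises an error with
diagnostics. With λ = 0 the solve reduces to CG-SENSE.

## Subproblems 2 and 3: motion estimation

Inter-group motion is estimated by intensity-based rigid registration of
the group magnitude images to the first group: a 3-level Gaussian pyramid,
bounded Powell search, correlation-ratio cost with 64 bins. Accepted
residuals update `T_inter` and re-align the image stack, leaving the data
consistency of `T_inter,i x_i` unchanged. Intra-group motion solves the
per-subdivision data-consistency residual by damped Levenberg–Marquardt:
complex residuals enter the normal equations through their real/imaginary
parts, damping is multiplicative (×10 on reject, ×0.1 on accept), steps
are capped at 1°/1 mm per iteration, and accepted steps never increase
the residual. The LM reference is a *data-consistency polished* copy of
each group image (`min_x ||A_i F S T x − y_i||² + μ||x − X_i||²`, CG,
μ = 0.02): the SLR solve trades a little data consistency for cross-group
structure, and that systematic mismatch otherwise masquerades as motion.

Three stability guards act at the solvers' own resolution and were
calibrated on the separation between spurious and genuine updates
(measured ~0.15% vs ~97% cost improvement): updates below 0.01°/0.01 mm
are discarded; a registration residual must improve the correlation ratio
by ≥2%; an LM result must improve the residual by ≥1%. These make the
motion-free degenerate case exactly stationary.

`T_intra` is initialized by mcSENSE on a single combined shot group
(ignoring phase variations), which alternates a CG-SENSE image update with
per-subdivision LM until the relative image change drops below 10⁻³. The
same solver in per-group mode with frozen motion provides image
initializations. The outer mcSLR loop alternates subproblems 1→2→3 and
stops when the relative change of the SOS-combined image falls below 10⁻³
or the iteration budget is exhausted. The registration step optimizes an
image-similarity cost, not the global objective, so the recorded objective
may tick up there; it is reported in the diagnostics, not hidden.

## Synthetic data

The simulator emulates a 2D ky–kz slice of a 7T 3D EPI fMRI acquisition at
1.5 mm isotropic resolution (140×96 matrix, TE/TR = 20/40 ms): a
piecewise-smooth brain-like complex phantom (elliptical compartments,
smooth texture, smooth phase, ≥8-voxel support margin); smooth complex
coil maps (Gaussian lobes around the FOV, SOS-normalized; 8 coils by
default — the count is a free choice, and measurements showed the study
conclusions are insensitive to 8 vs 32); per-volume inter-group phase
states (low-order polynomial + Gaussian-filtered random field, first state
zero, π peak-to-peak by default, drawn fresh each volume since respiratory
phase states drift over a time series); per-shot rigid motion linearly
interpolated from 8 knots i.i.d. uniform in ±1.5° (in-plane rotation) and
±1.5 mm (1D translation along y); complex Gaussian noise at 30 dB
image-domain SNR. Everything is reproducible from `(spec, seed)`.

What the generator does *not* emulate: EPI readout physics (T2* decay,
distortion, ghosting), through-plane motion, pose-dependent B0 changes,
real coil-array structure, and the rich texture/phase statistics of in
vivo brain. Passing tests therefore demonstrate the correctness and
internal consistency of the algorithms on controlled conditions, not
in vivo performance.

## Problem sizes and budgets

The study reproduction runs the full 140×96 / 48-shot / R=2×2 geometry
with 8 volumes and reduced iteration budgets (outer ≤ 4, 2 ADMM iterations
per outer, CG 8, mcSENSE ≤ 6 alternations with the 10⁻³ stop); corruption
amplitudes are never reduced. Library defaults keep the larger budgets
(outer 100, ADMM 5) matching the simulation protocol; an `in_vivo_preset`
carries the 1-ADMM-iteration / 30-outer setting.

## Known limitations

* **Data-driven motion initialization fails on this trajectory with
  synthetic inputs.** Each 1-shot subdivision samples a single kz platter,
  and the per-group sampling is coherent (regular stride-8 platters). Any
  least-squares reference image reconstructed at identity pose is then a
  k-space *mosaic* — each group's platters hold that group's own posed
  data — so the data-consistency cost of every shot and group has a deep
  minimum at zero motion, and alternating estimation cannot escape it
  (verified over many initialization variants, coil counts and phantom
  types; a time-series-mean reference recovers part of the group-level
  translations but not rotations). The LM and registration components
  themselves are accurate once given a clean reference; what is missing is
  an initialization oracle. Consequently the motion-estimate RMSE measured
  by the acceptance script remains near the corruption scale rather than
  the sub-0.15 mm / 0.14° regime, and mcSLR's tSNR gain over the
  motion-naive solve is correspondingly small on these conditions.
* The nuclear-norm fusion is weak under coherent undersampling: it
  meaningfully improves a consistent warm start (group-image error 0.32 vs
  0.47 for per-group SENSE) but cannot de-alias from scratch without coil
  information.
* tz (through-platter translation) is weakly identifiable from single-kz
  subdivisions: its per-platter signature is a single constant phase.
* 3D mode of the rigid transforms exists but the reconstruction engine is
  2D (the pseudo-3D slice decoupling of the full method).
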