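"""Data-driven rigid-motion estimation.

Three estimators cooperate in the joint image-motion reconstruction:

* :func:`register_rigid` -- multiresolution intensity-based rigid
  registration (correlation-ratio cost, derivative-free Powell search) used
  to estimate inter-shot-group motion from the reconstructed group images;
* :func:`lm_intra_motion` -- a damped Levenberg-Marquardt solve of the
  data-consistency residual for the intra-shot-group motion of one temporal
  subdivision, using analytic rigid-transform Jacobians;
* :func:`mcsense_solve` -- joint SENSE image + per-subdivision motion
  estimation (no phase-variation handling), serving both as a baseline
  method and as the initializer of the intra-group motion.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize

from .config import LMConfig, ReconConfig
from .encoding import CoilSensitivities, sense_adjoint, sense_forward
from .fourier import fft2c
from .rigid_motion import (
    MotionTrace,
    RigidMotionParams,
    apply_rigid,
    compose,
    identity_params,
    invert,
    rigid_jacobian,
)
from .hankel_slr import cg_solve
from .sampling import SamplingScheme

__all__ = [
    "correlation_ratio",
    "register_rigid",
    "estimate_inter_group",
    "lm_intra_motion",
    "mcsense_solve",
]


# ---------------------------------------------------------------------------
# inter-shot-group registration

def correlation_ratio(reference: np.ndarray, moving: np.ndarray, bins: int = 64) -> float:
    """Correlation-ratio cost between two magnitude images (lower = better).

    The reference intensities are binned; the cost is the within-bin
    variance of the moving image normalized by its total variance,
    ``sum_k n_k var_k / (N var)``, i.e. ``1 - eta^2``.
    """
    ref = reference.ravel()
    mov = moving.ravel()
    total_var = mov.var()
    if total_var == 0:
        return 0.0
    lo, hi = ref.min(), ref.max()
    if hi <= lo:
        return 1.0
    idx = np.clip(((ref - lo) / (hi - lo) * bins).astype(np.int64), 0, bins - 1)
    n_k = np.bincount(idx, minlength=bins)
    s_k = np.bincount(idx, weights=mov, minlength=bins)
    s2_k = np.bincount(idx, weights=mov**2, minlength=bins)
    nz = n_k > 0
    within = (s2_k[nz] - s_k[nz] ** 2 / n_k[nz]).sum()
    return float(within / (mov.size * total_var))


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=0.5 * factor)
    return sm[::factor, ::factor]


def register_rigid(
    moving: np.ndarray,
    reference: np.ndarray,
    voxel_size=(1.0, 1.0),
    bins: int = 64,
    levels: int = 3,
    init: RigidMotionParams | None = None,
    bound_deg: float = 15.0,
    bound_mm: float = 10.0,
) -> RigidMotionParams:
    """Estimate the rigid transform mapping ``moving`` onto ``reference``.

    2D magnitude images; 3-level Gaussian pyramid, bounded Powell search on
    the correlation-ratio cost at each level, warm-started from the coarser
    level.  Returns ``p`` such that ``apply_rigid(moving, p) ~ reference``.

    The search is bounded (``bound_deg`` / ``bound_mm``) because with
    undersampled inputs the similarity cost has spurious minima at aliasing
    replicas far from the true pose; if no bounded minimum improves on the
    initial cost the initial parameters are returned unchanged.
    """
    moving = np.abs(np.asarray(moving, dtype=float))
    reference = np.abs(np.asarray(reference, dtype=float))
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must share a shape")
    if moving.std() == 0 or reference.std() == 0:
        raise ValueError("cannot register a constant image")
    p = identity_params("2d", voxel_size) if init is None else init
    bounds = [(-bound_deg, bound_deg), (-bound_mm, bound_mm), (-bound_mm, bound_mm)]
    vec = np.clip(p.as_vector(), [b[0] for b in bounds], [b[1] for b in bounds])
    init_vec = vec.copy()
    for lvl in reversed(range(levels)):
        factor = 2**lvl
        if min(moving.shape) // factor < 16:
            continue
        mov_l = _downsample(moving, factor)
        ref_l = _downsample(reference, factor)
        vs_l = tuple(v * factor for v in voxel_size)
        p_l = RigidMotionParams((vec[0],), (vec[1], vec[2]), "2d", vs_l)

        def cost(v):
            q = p_l.with_vector(v)
            warped = np.abs(apply_rigid(mov_l, q))
            return correlation_ratio(ref_l, warped, bins)

        res = optimize.minimize(
            cost,
            vec,
            method="Powell",
            bounds=bounds,
            options={"xtol": 1e-3, "ftol": 1e-7, "maxfev": 400},
        )
        vec = res.x
    # safety: never accept a result worse than the starting point
    p_full = RigidMotionParams((vec[0],), (vec[1], vec[2]), "2d", tuple(voxel_size))
    p_init = RigidMotionParams(
        (init_vec[0],), (init_vec[1], init_vec[2]), "2d", tuple(voxel_size)
    )

    def full_cost(q):
        return correlation_ratio(reference, np.abs(apply_rigid(moving, q)), bins)

    if full_cost(p_full) > full_cost(p_init):
        return p_init
    return p_full


def estimate_inter_group(
    X: np.ndarray,
    current_t_inter: list[RigidMotionParams],
    voxel_size=(1.0, 1.0),
    bins: int = 64,
    levels: int = 3,
    realign: bool = False,
    deadzone: float = 0.01,
):
    """Update inter-shot-group motion by registering group images to group 1.

    Each group image (2..n) is registered to the first group's magnitude
    image to obtain the residual motion ``dT``; the inter-group estimate is
    composed with ``dT^-1`` and, with ``realign=True``, the group image is
    re-aligned by ``dT`` so the stack stays mutually aligned while the data
    consistency of ``T_inter,i x_i`` is unchanged.  Group 1 stays identity.
    """
    n = X.shape[0]
    if n < 2:
        raise ValueError("inter-group registration needs at least 2 groups")
    t_inter = list(current_t_inter)
    X_out = X.copy() if realign else X
    ref = np.abs(X[0])
    for i in range(1, n):
        dT = register_rigid(
            np.abs(X[i]), ref, voxel_size=voxel_size, bins=bins, levels=levels
        )
        # dead-zone at the search's own resolution: residuals smaller than
        # 0.01 deg / 0.01 mm are registration noise, not motion
        if np.abs(dT.as_vector()).max() < deadzone:
            continue
        t_inter[i] = compose(t_inter[i], invert(dT))
        if realign:
            X_out[i] = apply_rigid(X[i], dT)
    if realign:
        return t_inter, X_out
    return t_inter


# ---------------------------------------------------------------------------
# intra-shot-group LM

def _encode_sampled(img, sens, mask_idx):
    """Encode an image and gather the sampled points of each shot.

    ``mask_idx``: list of flat (ky, kz) index arrays, one per shot.
    Returns a 1-D complex vector stacking (shot, coil, sample).
    """
    k = fft2c(sens.maps * img[None]).reshape(sens.n_coils, -1)
    return np.concatenate([k[:, idx].ravel() for idx in mask_idx])


def lm_intra_motion(
    y_ij: np.ndarray,
    masks_ij: np.ndarray,
    sens: CoilSensitivities,
    x_i: np.ndarray,
    t_inter_i: RigidMotionParams,
    init: RigidMotionParams,
    config: LMConfig | None = None,
    min_rel_improvement: float = 0.0,
) -> RigidMotionParams:
    """LM solve of the data-consistency motion problem for one subdivision.

        min_p || A_ij F S T(p) T_inter,i x_i - y_ij ||^2

    ``y_ij``: the subdivision's shots, ``(n_shots_ij, n_coils, N1, N2)``;
    ``masks_ij``: matching boolean shot masks.  Complex residuals enter the
    normal equations through their real/imaginary parts, keeping the damped
    system real and SPD; accepted steps never increase the residual.
    """
    if config is None:
        config = LMConfig()
    if not np.any(masks_ij):
        raise ValueError("empty subdivision mask: motion is unidentifiable")
    mask_idx = [np.flatnonzero(m) for m in masks_ij]
    y_vec = np.concatenate(
        [y_ij[s].reshape(sens.n_coils, -1)[:, idx].ravel()
         for s, idx in enumerate(mask_idx)]
    )
    x_ref = apply_rigid(x_i, t_inter_i) if not t_inter_i.is_identity() else x_i
    p = init
    n_rot = len(p.rotations)
    caps = np.array(
        [config.max_step_deg] * n_rot + [config.max_step_mm] * len(p.translations)
    )

    def residual(q):
        return _encode_sampled(apply_rigid(x_ref, q), sens, mask_idx) - y_vec

    r = residual(p)
    cost = float(np.vdot(r, r).real)
    cost_init = cost
    mu = config.damping_init
    for _ in range(config.max_iters):
        jac_imgs = rigid_jacobian(x_ref, p)
        # columns: encode each derivative image through A F S
        J = np.stack(
            [_encode_sampled(jac_imgs[k], sens, mask_idx)
             for k in range(jac_imgs.shape[0])],
            axis=1,
        )
        g = np.real(J.conj().T @ r)
        if np.linalg.norm(g) < config.gradient_tol:
            break
        H = np.real(J.conj().T @ J)
        accepted = False
        for _try in range(8):
            damped = H + mu * np.diag(np.maximum(np.diag(H), 1e-30))
            try:
                step = np.linalg.solve(damped, -g)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    "rank-deficient LM normal equations for subdivision"
                )
            over = np.max(np.abs(step) / caps)
            if over > 1.0:
                step = step / over
            p_new = p.with_vector(p.as_vector() + step)
            r_new = residual(p_new)
            cost_new = float(np.vdot(r_new, r_new).real)
            if cost_new <= cost:
                p, r, cost = p_new, r_new, cost_new
                mu = max(mu * config.damping_down, 1e-12)
                accepted = True
                break
            mu *= config.damping_up
        if not accepted:
            break
    # optional guard: treat sub-threshold residual improvements as noise
    # (the reference image's own reconstruction error, not motion)
    if min_rel_improvement > 0.0 and cost > (1.0 - min_rel_improvement) * cost_init:
        return init
    return p


# ---------------------------------------------------------------------------
# mcSENSE

def _states_of_scheme(scheme: SamplingScheme):
    """All (group, subdivision) states in temporal order."""
    return [
        (i, j)
        for i in range(scheme.n_groups)
        for j in range(scheme.n_subdivisions_per_group)
    ]


def mcsense_solve(
    Y: np.ndarray,
    sens: CoilSensitivities,
    scheme: SamplingScheme,
    config: ReconConfig,
    voxel_size=(1.0, 1.0),
    combined: bool = True,
    init_trace: MotionTrace | None = None,
    update_motion: bool = True,
    max_iters: int | None = None,
):
    """Joint SENSE image + per-subdivision rigid motion estimation.

    In combined mode a single image is reconstructed from all shots
    (phase variations are ignored), alternating a CG-SENSE image update
    with an LM motion update per temporal subdivision until the relative
    image change drops below ``config.rel_change_tol`` or ``max_iters``
    (default ``config.mcsense_iters_max``) is reached.  The first
    subdivision's motion is pinned to identity (global pose gauge).

    With ``combined=False`` the per-group images are reconstructed by
    CG-SENSE under the frozen ``init_trace`` (no motion updates), which is
    how the shot-group image stack is initialized.

    Returns ``(X, trace, diagnostics)`` where ``X`` is ``(1, N1, N2)`` in
    combined mode and ``(n_groups, N1, N2)`` otherwise.
    """
    scheme._require_binned()
    if combined:
        work = _combined_scheme(scheme)
    else:
        work = scheme
    trace = (
        init_trace.copy()
        if init_trace is not None
        else MotionTrace.identity(
            work.n_groups, work.n_subdivisions_per_group, "2d", voxel_size
        )
    )
    if max_iters is None:
        max_iters = config.mcsense_iters_max

    def image_update(x0):
        def op(v):
            return sense_adjoint(sense_forward(v, sens, work, trace), sens, work, trace)

        rhs = sense_adjoint(Y, sens, work, trace)
        return cg_solve(op, rhs, x0=x0, iters=config.cg_iters, tol=config.cg_tol)

    X = image_update(None)
    rel_changes: list[float] = []
    if not update_motion or not combined:
        # frozen-motion CG-SENSE (per-group initialization path)
        return X, trace, {"rel_change": rel_changes}
    for it in range(max_iters):
        # motion update per subdivision (first state is the gauge reference)
        for idx, (i, j) in enumerate(_states_of_scheme(work)):
            if idx == 0:
                continue
            shots = work.shots_of_subdivision(i, j)
            p_new = lm_intra_motion(
                Y[shots],
                work.shot_masks[shots],
                sens,
                X[i],
                trace.t_inter[i],
                trace.t_intra[i][j],
                config.lm,
                min_rel_improvement=0.01,
            )
            step = p_new.as_vector() - trace.t_intra[i][j].as_vector()
            # updates below the solver's resolution are noise, not motion
            if np.abs(step).max() >= 0.01:
                trace.t_intra[i][j] = p_new
        X_new = image_update(X)
        num = float(np.linalg.norm(X_new - X))
        den = float(np.linalg.norm(X)) or 1.0
        rel_changes.append(num / den)
        X = X_new
        if rel_changes[-1] < config.rel_change_tol:
            break
    return X, trace, {"rel_change": rel_changes}


def _combined_scheme(scheme: SamplingScheme) -> SamplingScheme:
    """View of the scheme with a single shot group (subdivisions kept)."""
    import copy

    comb = copy.copy(scheme)
    n_shots = scheme.n_shots
    sub_size = scheme.shots_per_subdivision
    shots = np.arange(n_shots)
    comb.group_of_shot = np.zeros(n_shots, dtype=int)
    comb.subdivision_of_shot = np.stack(
        [np.zeros(n_shots, dtype=int), shots // sub_size], axis=1
    )
    comb.n_groups = 1
    comb.n_subdivisions_per_group = n_shots // sub_size
    return comb
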