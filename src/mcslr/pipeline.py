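"""mcSLR outer loop and the four-way method dispatcher.

``mcslr_reconstruct`` alternates three subproblems per outer iteration:

1. shot-group images ``X`` by the ADMM structured low-rank solve with the
   current motion estimates held fixed;
2. inter-shot-group motion by rigid registration of the group images to
   the first group (which also re-aligns the warm-started images);
3. intra-shot-group motion per temporal subdivision by Levenberg-Marquardt
   on the data-consistency residual.

The intra-group motion is initialized by an mcSENSE solve of a single
combined shot group; the image stack is initialized by frozen-motion
per-group CG-SENSE.  The loop stops when the relative change of the
sum-of-squares combined image falls below tolerance or the iteration
budget is exhausted.  Subproblem 2 optimizes an image-similarity cost
rather than the global objective, so the objective may tick up at that
step; it is recorded in the diagnostics rather than hidden.
"""

from __future__ import annotations

import numpy as np

from .config import ReconConfig
from .encoding import CoilSensitivities
from .hankel_slr import cg_solve, slr_admm_solve, slr_objective, _data_scale
from .motion_estimation import lm_intra_motion, mcsense_solve
from .rigid_motion import MotionTrace
from .sampling import SamplingScheme

__all__ = ["sos_combine", "mcslr_reconstruct", "reconstruct", "METHODS"]

METHODS = ("sense", "mcsense", "slr", "mcslr")


def sos_combine(X: np.ndarray) -> np.ndarray:
    """Sum-of-squares magnitude combination across shot-group images."""
    X = np.asarray(X)
    if X.ndim < 3 or X.shape[0] < 1:
        raise ValueError("expected a (n_groups, ...) image stack")
    return np.sqrt((np.abs(X) ** 2).sum(axis=0))


def _combined_state_index(scheme: SamplingScheme, i: int, j: int) -> int:
    return i * scheme.n_subdivisions_per_group + j


_MOTION_DEADZONE = 0.01  # deg / mm: below the motion solvers' resolution


def _group_view(scheme: SamplingScheme, i: int) -> SamplingScheme:
    """Single-group view of the scheme (shots renumbered, subdivisions kept)."""
    import copy

    shots = scheme.shots_of_group(i)
    view = copy.copy(scheme)
    view.shot_masks = scheme.shot_masks[shots]
    n = len(shots)
    view.group_of_shot = np.zeros(n, dtype=int)
    view.subdivision_of_shot = np.stack(
        [np.zeros(n, dtype=int), scheme.subdivision_of_shot[shots, 1]], axis=1
    )
    view.n_groups = 1
    return view


def _polish_groups(X, Y, sens, scheme, trace, config, mu=0.02, iters=8):
    """Data-consistency refinement of each group image.

    Solves ``min_x ||A_i F S T x - y_i||^2 + mu ||x - X_i||^2`` per group by
    CG, warm-started at ``X_i``.  The structured low-rank solve trades a
    little data consistency for cross-group structure; the motion
    subproblems, however, must compare predictions against each group's own
    measurements, and a systematic data mismatch there masquerades as
    rigid motion.  The polished stack is used only inside the motion
    updates; ``X`` itself is not modified.
    """
    from .hankel_slr import cg_solve
    from .encoding import sense_adjoint as adj, sense_forward as fwd

    X_hat = X.copy()
    for i in range(scheme.n_groups):
        view = _group_view(scheme, i)
        vtrace = MotionTrace(
            t_inter=[trace.t_inter[i]], t_intra=[list(trace.t_intra[i])]
        )
        shots = scheme.shots_of_group(i)
        rhs = adj(Y[shots], sens, view, vtrace)[0] + mu * X[i]

        def op(v):
            return adj(fwd(v[None], sens, view, vtrace), sens, view, vtrace)[0] + mu * v

        X_hat[i] = cg_solve(op, rhs, x0=X[i].copy(), iters=iters, tol=config.cg_tol)
    return X_hat


def _init_motion(Y, sens, scheme, config, voxel_size, diagnostics):
    """T_intra init (and combined image): mcSENSE on one combined group."""
    X_comb, comb_trace, diag = mcsense_solve(
        Y, sens, scheme, config, voxel_size=voxel_size, combined=True
    )
    diagnostics["mcsense_init_rel_change"] = diag["rel_change"]
    trace = MotionTrace.identity(
        scheme.n_groups, scheme.n_subdivisions_per_group, "2d", voxel_size
    )
    for i in range(scheme.n_groups):
        for j in range(scheme.n_subdivisions_per_group):
            k = _combined_state_index(scheme, i, j)
            trace.t_intra[i][j] = comb_trace.t_intra[0][k]
    return trace, X_comb[0]


def mcslr_reconstruct(
    Y: np.ndarray,
    sens: CoilSensitivities,
    scheme: SamplingScheme,
    config: ReconConfig | None = None,
    voxel_size=(1.0, 1.0),
    freeze_motion: bool = False,
    init_trace: MotionTrace | None = None,
):
    """Joint image + rigid-motion structured low-rank reconstruction.

    Returns ``(X, trace, sos_image, diagnostics)``.  With
    ``freeze_motion=True`` the motion stays at identity and the solve
    reduces to the plain (motion-naive) SLR reconstruction.
    """
    if config is None:
        config = ReconConfig()
    scheme._require_binned()
    diagnostics: dict = {"objective": [], "rel_change": [], "motion": []}

    if freeze_motion:
        trace = MotionTrace.identity(
            scheme.n_groups, scheme.n_subdivisions_per_group, "2d", voxel_size
        )
    elif init_trace is not None:
        trace = init_trace.copy()
    else:
        trace, _ = _init_motion(Y, sens, scheme, config, voxel_size, diagnostics)

    scale = _data_scale(Y, sens, scheme, trace)
    # X init: the combined-group SENSE image replicated per group.  Per-group
    # CG-SENSE is hopeless at the per-group undersampling (the aliasing is
    # regular, mostly along z), and the Hankel coupling can refine a
    # consistent starting stack far better than it can fuse four mutually
    # inconsistent aliased ones.  The same init is used with and without
    # motion freezing, so on degenerate (motion-free) input the joint loop
    # collapses exactly onto the motion-naive solve.
    X_comb = _sense_reconstruct(Y, sens, scheme, config)[0]
    X = np.stack([X_comb] * scheme.n_groups)
    sos = sos_combine(X)
    admm_state: dict = {}
    for it in range(config.outer_iters_max):
        # subproblem 1: SLR ADMM with fixed motion (splitting state persists)
        X = slr_admm_solve(
            Y, sens, scheme, trace, config, x0=X, scale=scale, state=admm_state
        )
        if not np.all(np.isfinite(X)):
            raise RuntimeError(f"non-finite image at outer iteration {it}")
        if not freeze_motion:
            X_hat = _polish_groups(X, Y, sens, scheme, trace, config)
            # subproblem 2: inter-group registration of the group images;
            # accepted residuals re-align both the stack and its polished
            # counterpart
            if scheme.n_groups >= 2:
                from .motion_estimation import register_rigid
                from .rigid_motion import apply_rigid, compose, invert

                from .motion_estimation import correlation_ratio

                for i in range(1, scheme.n_groups):
                    dT = register_rigid(
                        np.abs(X[i]),
                        np.abs(X[0]),
                        voxel_size=voxel_size,
                        bins=config.registration_bins,
                        levels=config.registration_levels,
                    )
                    if np.abs(dT.as_vector()).max() < _MOTION_DEADZONE:
                        continue
                    # accept only residuals that improve the similarity
                    # meaningfully: reconstructed group images carry
                    # undersampling texture on which the cost has shallow
                    # spurious minima, and realigning on those feeds an
                    # unstable register/re-solve loop
                    ref = np.abs(X[0])
                    c0 = correlation_ratio(ref, np.abs(X[i]), config.registration_bins)
                    c1 = correlation_ratio(
                        ref, np.abs(apply_rigid(X[i], dT)), config.registration_bins
                    )
                    if c1 > 0.98 * c0:
                        continue
                    trace.t_inter[i] = compose(trace.t_inter[i], invert(dT))
                    X[i] = apply_rigid(X[i], dT)
                    X_hat[i] = apply_rigid(X_hat[i], dT)
            # subproblem 3: intra-group LM per subdivision
            for i in range(scheme.n_groups):
                for j in range(scheme.n_subdivisions_per_group):
                    shots = scheme.shots_of_subdivision(i, j)
                    p_new = lm_intra_motion(
                        Y[shots],
                        scheme.shot_masks[shots],
                        sens,
                        X_hat[i],
                        trace.t_inter[i],
                        trace.t_intra[i][j],
                        config.lm,
                        min_rel_improvement=0.01,
                    )
                    step = p_new.as_vector() - trace.t_intra[i][j].as_vector()
                    if np.abs(step).max() >= _MOTION_DEADZONE:
                        trace.t_intra[i][j] = p_new
        sos_new = sos_combine(X)
        num = float(np.linalg.norm(sos_new - sos))
        den = float(np.linalg.norm(sos)) or 1.0
        rel = num / den
        diagnostics["rel_change"].append(rel)
        diagnostics["objective"].append(
            slr_objective(
                X / scale, Y / scale, sens, scheme, trace, config,
                lam_abs=config.admm_rho * admm_state.get("tau_abs", 0.0),
            )
        )
        diagnostics["motion"].append(
            [
                [trace.total(i, j).as_vector().tolist()
                 for j in range(scheme.n_subdivisions_per_group)]
                for i in range(scheme.n_groups)
            ]
        )
        sos = sos_new
        if rel < config.rel_change_tol:
            break
    return X, trace, sos, diagnostics


def _sense_reconstruct(Y, sens, scheme, config):
    """Plain CG-SENSE: single image from all shots, no motion, lam = 0."""
    union = scheme.union_mask()
    ksum = (Y * scheme.shot_masks[:, None]).sum(axis=0)

    from .fourier import fft2c, ifft2c

    def op(v):
        k = fft2c(sens.maps * v[0][None]) * union[None]
        return (np.conj(sens.maps) * ifft2c(k)).sum(axis=0)[None]

    rhs = (np.conj(sens.maps) * ifft2c(ksum)).sum(axis=0)[None]
    X = cg_solve(op, rhs, iters=config.cg_iters * config.admm_iters, tol=config.cg_tol)
    return X


def reconstruct(
    method: str,
    Y: np.ndarray,
    sens: CoilSensitivities,
    scheme: SamplingScheme,
    config: ReconConfig | None = None,
    voxel_size=(1.0, 1.0),
):
    """Dispatch to one of SENSE / mcSENSE / SLR / mcSLR.

    Returns ``(X, trace, sos_image, diagnostics)``; SENSE and mcSENSE
    return a single-image stack.  SLR is mcSLR with motion frozen at
    identity; SENSE is a single combined group with ``lam = 0`` and no
    motion model.
    """
    if config is None:
        config = ReconConfig()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "sense":
        X = _sense_reconstruct(Y, sens, scheme, config)
        trace = MotionTrace.identity(1, 1, "2d", voxel_size)
        return X, trace, sos_combine(X), {}
    if method == "mcsense":
        X, trace, diag = mcsense_solve(
            Y, sens, scheme, config, voxel_size=voxel_size, combined=True
        )
        return X, trace, sos_combine(X), diag
    freeze = method == "slr"
    return mcslr_reconstruct(
        Y, sens, scheme, config, voxel_size=voxel_size, freeze_motion=freeze
    )
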