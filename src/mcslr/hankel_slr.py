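"""Block-Hankel lifting, singular value thresholding, and the ADMM solver.

Shot-group images that share a magnitude and differ only by smooth phase
have k-spaces related by short convolution kernels; a matrix stacking the
sliding k-space patches of all groups (the block-Hankel lifting) is then
low rank.  The reconstruction exploits this through a nuclear-norm penalty
solved by ADMM: an auxiliary variable ``Z = F X`` carries the structured
low-rank constraint (lift -> SVT -> count-normalized adjoint), while the
``X`` update is a CG solve of the motion-inclusive SENSE normal equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .config import ReconConfig
from .encoding import CoilSensitivities, sense_adjoint, sense_forward
from .fourier import fft2c, ifft2c
from .rigid_motion import MotionTrace
from .sampling import SamplingScheme

__all__ = [
    "HankelOperatorSpec",
    "hankel_lift",
    "hankel_adjoint",
    "overlap_counts",
    "svt",
    "singular_spectrum",
    "slr_admm_solve",
    "cg_solve",
]


@dataclass(frozen=True)
class HankelOperatorSpec:
    """Sliding-kernel lifting geometry for one multi-channel k-space plane."""

    kernel: tuple[int, int]
    plane_shape: tuple[int, int]
    n_channels: int

    def __post_init__(self):
        k1, k2 = self.kernel
        n1, n2 = self.plane_shape
        if not (1 < k1 <= n1 and 1 < k2 <= n2):
            raise ValueError(
                f"kernel {self.kernel} invalid for plane {self.plane_shape}"
            )

    @property
    def matrix_shape(self) -> tuple[int, int]:
        k1, k2 = self.kernel
        n1, n2 = self.plane_shape
        return ((n1 - k1 + 1) * (n2 - k2 + 1), k1 * k2 * self.n_channels)


def hankel_lift(z: np.ndarray, spec: HankelOperatorSpec) -> np.ndarray:
    """Lift multi-channel k-space ``(C, N1, N2)`` to the block-Hankel matrix.

    Row ``r`` concatenates, channel-major, the vectorized ``k1 x k2`` patch
    at sliding position ``r`` (row-major positions).
    """
    z = np.asarray(z)
    if z.shape != (spec.n_channels, *spec.plane_shape):
        raise ValueError(f"expected shape {(spec.n_channels, *spec.plane_shape)}")
    k1, k2 = spec.kernel
    win = np.lib.stride_tricks.sliding_window_view(z, (k1, k2), axis=(1, 2))
    # win: (C, P1, P2, k1, k2) -> (P1*P2, C*k1*k2)
    mat = np.moveaxis(win, 0, 2).reshape(spec.matrix_shape)
    return np.ascontiguousarray(mat)


@lru_cache(maxsize=8)
def _adjoint_indices(spec: HankelOperatorSpec) -> np.ndarray:
    k1, k2 = spec.kernel
    n1, n2 = spec.plane_shape
    p1, p2 = n1 - k1 + 1, n2 - k2 + 1
    pos1 = np.arange(p1)[:, None, None, None, None]
    pos2 = np.arange(p2)[None, :, None, None, None]
    ch = np.arange(spec.n_channels)[None, None, :, None, None]
    d1 = np.arange(k1)[None, None, None, :, None]
    d2 = np.arange(k2)[None, None, None, None, :]
    flat = ch * (n1 * n2) + (pos1 + d1) * n2 + (pos2 + d2)
    return flat.reshape(spec.matrix_shape)


def hankel_adjoint(mat: np.ndarray, spec: HankelOperatorSpec) -> np.ndarray:
    """Exact adjoint of :func:`hankel_lift` (overlap-add scatter)."""
    if mat.shape != spec.matrix_shape:
        raise ValueError(f"expected matrix shape {spec.matrix_shape}")
    out = np.zeros(spec.n_channels * np.prod(spec.plane_shape), dtype=mat.dtype)
    np.add.at(out, _adjoint_indices(spec), mat)
    return out.reshape(spec.n_channels, *spec.plane_shape)


@lru_cache(maxsize=8)
def overlap_counts(spec: HankelOperatorSpec) -> np.ndarray:
    """Per-location patch-overlap counts ``c`` with ``HH H z = c * z``."""
    ones = np.ones((spec.n_channels, *spec.plane_shape))
    return hankel_adjoint(hankel_lift(ones, spec), spec).real


def svt(mat: np.ndarray, tau: float) -> np.ndarray:
    """Singular value soft thresholding: shrink each sigma by ``tau``."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    u, s, vh = np.linalg.svd(mat, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (u[:, keep] * s[keep]) @ vh[keep]


def singular_spectrum(z: np.ndarray, spec: HankelOperatorSpec) -> np.ndarray:
    """Normalized (by the largest) singular values of the lifted matrix."""
    s = np.linalg.svd(hankel_lift(z, spec), compute_uv=False)
    if s[0] > 0:
        s = s / s[0]
    return s


def nuclear_norm(mat: np.ndarray) -> float:
    return float(np.linalg.svd(mat, compute_uv=False).sum())


def cg_solve(op, rhs, x0=None, iters: int = 10, tol: float = 1e-6):
    """Conjugate gradients on ``op(x) = rhs`` for Hermitian PSD ``op``."""
    x = np.zeros_like(rhs) if x0 is None else x0.copy()
    r = rhs - op(x)
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    rhs_norm = float(np.vdot(rhs, rhs).real) or 1.0
    for _ in range(iters):
        if rs / rhs_norm < tol**2:
            break
        ap = op(p)
        alpha = rs / float(np.vdot(p, ap).real)
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = float(np.vdot(r, r).real)
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


def _data_scale(Y, sens, scheme, trace):
    """Peak SOS magnitude of the adjoint reconstruction (normalization)."""
    x0 = sense_adjoint(Y, sens, scheme, trace)
    sos = np.sqrt((np.abs(x0) ** 2).sum(axis=0))
    return float(sos.max()) or 1.0


def slr_objective(
    X, Y, sens, scheme, trace, config: ReconConfig, lam_abs: float | None = None
) -> float:
    """Data-consistency + nuclear-norm objective at ``X``.

    ``lam_abs`` is the absolute nuclear-norm weight actually in force
    (defaults to ``config.lam``, which is on the relative scale).
    """
    resid = sense_forward(X, sens, scheme, trace) - Y
    val = float(np.vdot(resid, resid).real)
    lam = config.lam if lam_abs is None else lam_abs
    if lam > 0:
        spec = HankelOperatorSpec(config.kernel, X.shape[1:], X.shape[0])
        val += lam * nuclear_norm(hankel_lift(fft2c(X), spec))
    return val


def slr_admm_solve(
    Y: np.ndarray,
    sens: CoilSensitivities,
    scheme: SamplingScheme,
    trace: MotionTrace | None,
    config: ReconConfig,
    x0: np.ndarray | None = None,
    scale: float | None = None,
    n_iters: int | None = None,
    state: dict | None = None,
) -> np.ndarray:
    """ADMM solve of the motion-inclusive structured low-rank problem.

        min_X ||A F S T X - Y||^2 + lam * sum_l ||H2D F X_l||_*

    The motion trace is held fixed.  ``scale`` normalizes the data so the
    initial adjoint reconstruction has unit peak SOS magnitude (computed if
    not given); ``x0`` warm-starts X (given on the data scale of ``Y``).
    In 2D there is one slice, so the pseudo-3D sum has a single term.

    ``state`` (a dict) carries the ADMM auxiliary/dual variables across
    calls, so an outer loop can interleave motion updates without
    restarting the splitting; pass the same dict on every call.

    With ``lam == 0`` this reduces to CG-SENSE on the group images.
    """
    scheme._require_binned()
    n_groups = scheme.n_groups
    if Y.ndim != 4:
        raise ValueError("Y must be (n_shots, n_coils, N_ky, N_kz)")
    if scale is None:
        scale = _data_scale(Y, sens, scheme, trace)
    Yn = Y / scale
    rhs_data = sense_adjoint(Yn, sens, scheme, trace)
    X = rhs_data.copy() if x0 is None else (x0 / scale).astype(rhs_data.dtype)
    iters = config.admm_iters if n_iters is None else n_iters

    if config.lam == 0.0:
        def op(v):
            return sense_adjoint(sense_forward(v, sens, scheme, trace), sens, scheme, trace)

        X = cg_solve(op, rhs_data, x0=X, iters=config.cg_iters * iters, tol=config.cg_tol)
        return X * scale

    spec = HankelOperatorSpec(config.kernel, X.shape[1:], n_groups)
    counts = overlap_counts(spec)
    rho = config.admm_rho
    tau_rel = config.lam / rho
    if state is not None and "Z" in state:
        Z, U = state["Z"], state["U"]
        tau_abs = state["tau_abs"]
    else:
        Z = fft2c(X)
        U = np.zeros_like(Z)
        # freeze the threshold on the first lift: lam/rho relative to the
        # largest singular value of the initial lifted matrix.  The
        # relative scaling keeps the printed regularization weights
        # meaningful across data scales (inter-channel inconsistency lives
        # in the normalized spectrum tail); freezing it makes every later
        # iteration minimize one fixed convex objective.
        s0 = np.linalg.svd(hankel_lift(Z, spec), compute_uv=False)
        tau_abs = tau_rel * (s0[0] if s0.size else 0.0)
        if state is not None:
            state["tau_abs"] = tau_abs

    obj0 = None
    for _ in range(iters):
        # X update: (EH E + rho I) X = EH Y + rho FH (Z - U)
        rhs = rhs_data + rho * ifft2c(Z - U)

        def op(v):
            return (
                sense_adjoint(sense_forward(v, sens, scheme, trace), sens, scheme, trace)
                + rho * v
            )

        X = cg_solve(op, rhs, x0=X, iters=config.cg_iters, tol=config.cg_tol)
        # Z update: count-normalized approximate prox of the nuclear norm
        # of the lifted matrix (lift -> SVT at the frozen threshold ->
        # overlap-normalized adjoint)
        V = fft2c(X) + U
        M = svt(hankel_lift(V, spec), tau_abs)
        Z = hankel_adjoint(M, spec) / counts
        U = U + fft2c(X) - Z
        obj = slr_objective(X, Yn, sens, scheme, trace, config, lam_abs=rho * tau_abs)
        if obj0 is None:
            obj0 = obj
        elif obj > 10.0 * obj0:
            raise RuntimeError(
                f"ADMM diverged: objective {obj:.3e} exceeds 10x initial {obj0:.3e}"
            )
    if state is not None:
        state["Z"], state["U"] = Z, U
    return X * scale
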