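"""Multi-coil SENSE encoding chain ``A F S T`` and its adjoint.

The forward model for shot group ``i``, temporal subdivision ``j`` is

    y_ij = A_ij F S T_intra,ij T_inter,i x_i

with ``T`` the rigid-motion operator (applied image-side), ``S`` the coil
sensitivity encoding, ``F`` the centered unitary Fourier transform and
``A_ij`` the subdivision's sampling mask.  The adjoint applies the exact
adjoint of every factor in reverse, so the pair passes dot-product tests at
machine precision for any sampling scheme and motion trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import fft2c, ifft2c
from .rigid_motion import MotionTrace, apply_rigid, apply_rigid_adjoint
from .sampling import SamplingScheme

__all__ = [
    "CoilSensitivities",
    "AcquiredKspace",
    "sense_forward",
    "sense_adjoint",
    "coil_compress",
]


@dataclass
class CoilSensitivities:
    """Complex sensitivity map per coil, shape ``(n_coils, *image_shape)``."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def image_shape(self) -> tuple[int, ...]:
        return self.maps.shape[1:]


@dataclass
class AcquiredKspace:
    """Measured multi-coil k-space, shape ``(n_shots, n_coils, N_ky, N_kz)``.

    Values are zero off the shot masks; ``data[s]`` holds shot ``s`` on the
    full grid for convenience.
    """

    data: np.ndarray
    scheme: SamplingScheme
    noise_sigma: float | None = None

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]


def _check_trace(scheme: SamplingScheme, trace: MotionTrace) -> None:
    scheme._require_binned()
    if trace.n_groups != scheme.n_groups:
        raise ValueError(
            f"trace has {trace.n_groups} groups, scheme has {scheme.n_groups}"
        )
    for i in range(scheme.n_groups):
        if len(trace.t_intra[i]) != scheme.n_subdivisions_per_group:
            raise ValueError(f"missing intra-group motion entries for group {i}")


def sense_forward(
    X: np.ndarray,
    sens: CoilSensitivities,
    scheme: SamplingScheme,
    trace: MotionTrace | None = None,
) -> np.ndarray:
    """Apply ``A F S T`` per (group, subdivision); returns masked k-space.

    ``X`` has shape ``(n_groups, N_ky, N_kz)``; output shape is
    ``(n_shots, n_coils, N_ky, N_kz)`` with data only on the shot masks.
    Linear in ``X`` for a fixed trace.
    """
    scheme._require_binned()
    if trace is not None:
        _check_trace(scheme, trace)
    n_shots = scheme.n_shots
    cdt = np.result_type(X.dtype, sens.maps.dtype, np.complex64)
    Y = np.zeros((n_shots, sens.n_coils, *scheme.grid_shape), dtype=cdt)
    for i in range(scheme.n_groups):
        for j in range(scheme.n_subdivisions_per_group):
            img = X[i]
            if trace is not None:
                p = trace.total(i, j)
                if not p.is_identity():
                    img = apply_rigid(img, p)
            k = fft2c(sens.maps * img[None])
            for s in scheme.shots_of_subdivision(i, j):
                Y[s] = np.where(scheme.shot_masks[s][None], k, 0)
    return Y


def sense_adjoint(
    Y: np.ndarray,
    sens: CoilSensitivities,
    scheme: SamplingScheme,
    trace: MotionTrace | None = None,
) -> np.ndarray:
    """Exact adjoint of :func:`sense_forward`."""
    scheme._require_binned()
    if trace is not None:
        _check_trace(scheme, trace)
    cdt = np.result_type(Y.dtype, sens.maps.dtype, np.complex64)
    X = np.zeros((scheme.n_groups, *scheme.grid_shape), dtype=cdt)
    conj_maps = np.conj(sens.maps)
    for i in range(scheme.n_groups):
        for j in range(scheme.n_subdivisions_per_group):
            shots = scheme.shots_of_subdivision(i, j)
            ksum = (Y[shots] * scheme.shot_masks[shots][:, None]).sum(axis=0)
            img = (conj_maps * ifft2c(ksum)).sum(axis=0)
            if trace is not None:
                p = trace.total(i, j)
                if not p.is_identity():
                    img = apply_rigid_adjoint(img, p)
            X[i] += img
    return X


def normal_operator(sens, scheme, trace=None):
    """Return ``x -> EH E x`` for the group-image stack (used by CG)."""

    def op(X):
        return sense_adjoint(sense_forward(X, sens, scheme, trace), sens, scheme, trace)

    return op


def coil_compress(
    Y: AcquiredKspace, sens: CoilSensitivities, n_virtual: int
) -> tuple[AcquiredKspace, CoilSensitivities, float]:
    """SVD coil compression to ``n_virtual`` virtual coils.

    The compression matrix comes from the SVD of the sampled data stacked
    as ``(n_coils, samples)``; the same linear combination is applied to the
    sensitivity maps.  Returns ``(Y', S', energy_retained)`` where the energy
    fraction is the sum of the kept squared singular values over the total.
    """
    n_coils = Y.n_coils
    if n_virtual <= 0:
        raise ValueError("n_virtual must be positive")
    if n_virtual > n_coils:
        raise ValueError(f"n_virtual={n_virtual} exceeds n_coils={n_coils}")
    mat = np.moveaxis(Y.data, 1, 0)[:, Y.scheme.shot_masks].reshape(n_coils, -1)
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    energy = float((s[:n_virtual] ** 2).sum() / max((s**2).sum(), np.finfo(float).tiny))
    comp = u[:, :n_virtual].conj().T  # (n_virtual, n_coils)
    data = np.einsum("vc,scyz->svyz", comp, Y.data)
    maps = np.einsum("vc,cyz->vyz", comp, sens.maps)
    return (
        AcquiredKspace(data=data, scheme=Y.scheme, noise_sigma=Y.noise_sigma),
        CoilSensitivities(maps=maps),
        energy,
    )
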