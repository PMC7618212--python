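"""Rigid-body transforms by Fourier phase ramps and shears.

Rotation is implemented with the classical three-pass shear decomposition

    R(theta) = Shear_a(-tan(theta/2)) . Shear_b(sin theta) . Shear_a(-tan(theta/2))

where each shear is a per-line linear phase in the conjugate domain, and
translation is a k-space phase ramp.  Every pass is an exactly unitary
operator, so rotation needs no regridding, preserves image energy exactly,
and the operator's adjoint is the reversed pass sequence with negated
parameters (:func:`apply_rigid_adjoint`).

Conventions (declared once, used everywhere):

* rotation center and phase-ramp origin are the center voxel ``N // 2``;
* rotation angles act in index (voxel) space; translations are given in mm
  and divided by ``voxel_size`` before phase-ramp construction;
* images are assumed zero near the edges (object within FOV); wrap-around
  from the Fourier shears is accepted;
* 2D mode: image axes ``(0, 1) = (y, z)``, parameters
  ``(rotation_yz_deg, ty_mm, tz_mm)``; 3D mode: six parameters, rotations
  applied in the order Rz, then Ry, then Rx (content map ``Rx Ry Rz``).

Angles with ``|theta| > 45 deg`` are handled by an exact quarter-turn index
permutation (square planes only) followed by a residual shear rotation,
because the shear decomposition degenerates near 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as spfft

__all__ = [
    "RigidMotionParams",
    "MotionTrace",
    "apply_rigid",
    "apply_rigid_adjoint",
    "rigid_jacobian",
    "compose",
    "invert",
    "identity_params",
    "read_trace_tsv",
    "write_trace_tsv",
]


@dataclass(frozen=True)
class RigidMotionParams:
    """Rigid transform parameters.

    2D mode: ``rotations = (r_yz_deg,)``, ``translations = (ty_mm, tz_mm)``.
    3D mode: ``rotations = (rx, ry, rz)`` deg, ``translations = (tx, ty, tz)`` mm.
    """

    rotations: tuple[float, ...]
    translations: tuple[float, ...]
    mode: str = "2d"
    voxel_size: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self):
        n_rot = {"2d": 1, "3d": 3}.get(self.mode)
        if n_rot is None:
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.rotations) != n_rot:
            raise ValueError(f"{self.mode} mode needs {n_rot} rotation(s)")
        n_t = 2 if self.mode == "2d" else 3
        if len(self.translations) != n_t:
            raise ValueError(f"{self.mode} mode needs {n_t} translations")
        if len(self.voxel_size) != n_t:
            raise ValueError("voxel_size length must match translations")
        # store angles wrapped into (-180, 180]
        wrapped = tuple(-((-a + 180.0) % 360.0 - 180.0) for a in self.rotations)
        object.__setattr__(self, "rotations", wrapped)
        object.__setattr__(self, "translations", tuple(float(t) for t in self.translations))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def n_params(self) -> int:
        return len(self.rotations) + len(self.translations)

    def as_vector(self) -> np.ndarray:
        """Parameter vector ``[rotations_deg..., translations_mm...]``."""
        return np.array(list(self.rotations) + list(self.translations), dtype=float)

    def with_vector(self, vec: np.ndarray) -> "RigidMotionParams":
        n_r = len(self.rotations)
        return replace(
            self,
            rotations=tuple(float(v) for v in vec[:n_r]),
            translations=tuple(float(v) for v in vec[n_r:]),
        )

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.as_vector()) <= tol))


def identity_params(mode: str = "2d", voxel_size=None) -> RigidMotionParams:
    if mode == "2d":
        vs = (1.0, 1.0) if voxel_size is None else tuple(voxel_size)
        return RigidMotionParams((0.0,), (0.0, 0.0), "2d", vs)
    vs = (1.0, 1.0, 1.0) if voxel_size is None else tuple(voxel_size)
    return RigidMotionParams((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), "3d", vs)


# ---------------------------------------------------------------------------
# elemental unitary passes

def _freq(n: int) -> np.ndarray:
    return spfft.fftfreq(n)


def _coord(n: int) -> np.ndarray:
    return np.arange(n) - n // 2


def _reshape_along(v: np.ndarray, axis: int, ndim: int) -> np.ndarray:
    shape = [1] * ndim
    shape[axis] = v.size
    return v.reshape(shape)


def _shift(img: np.ndarray, axis: int, s: float, deriv: bool = False):
    """Shift content by ``s`` samples along ``axis`` (circular, subvoxel).

    With ``deriv=True`` also return the derivative of the output w.r.t. ``s``.
    """
    n = img.shape[axis]
    f = _reshape_along(_freq(n), axis, img.ndim)
    k = spfft.fft(img, axis=axis)
    phase = np.exp(-2j * np.pi * f * s)
    out = spfft.ifft(k * phase, axis=axis)
    if not deriv:
        return out
    d = spfft.ifft(k * phase * (-2j * np.pi * f), axis=axis)
    return out, d


def _shear(img, shift_axis: int, coord_axis: int, alpha: float, deriv: bool = False):
    """Shift along ``shift_axis`` by ``alpha * centered coord`` of ``coord_axis``.

    Content map: ``x_shift += alpha * (x_coord - c_coord)``.  With
    ``deriv=True`` also return d(out)/d(alpha).
    """
    n_s = img.shape[shift_axis]
    n_c = img.shape[coord_axis]
    f = _reshape_along(_freq(n_s), shift_axis, img.ndim)
    y = _reshape_along(_coord(n_c), coord_axis, img.ndim)
    k = spfft.fft(img, axis=shift_axis)
    w = -2j * np.pi * f * y
    phase = np.exp(w * alpha)
    out = spfft.ifft(k * phase, axis=shift_axis)
    if not deriv:
        return out
    d = spfft.ifft(k * phase * w, axis=shift_axis)
    return out, d


def _quarter_turns(img: np.ndarray, plane: tuple[int, int], k: int) -> np.ndarray:
    """Exact rotation by ``k * 90 deg`` in ``plane`` about the center voxel.

    Index permutation with wrap-around; requires the two plane axes to have
    equal length (quarter turns do not preserve rectangular grids).
    """
    a, b = plane
    n = img.shape[a]
    if img.shape[b] != n:
        raise ValueError(
            "rotations beyond 45 deg need a square plane for the exact "
            f"quarter-turn step; got {img.shape[a]}x{img.shape[b]}"
        )
    k = k % 4
    out = img
    c = n // 2
    idx = np.arange(n)
    qa_grid, qb_grid = np.meshgrid(idx, idx, indexing="ij")
    # content map (x_a, x_b) -> (-x_b, x_a) about c:
    # out[q_a, q_b] = in[c + (q_b - c), c - (q_a - c)]  (mod n)
    src_row = (c + (qb_grid - c)) % n
    src_col = (c - (qa_grid - c)) % n
    for _ in range(k):
        A = np.moveaxis(out, (a, b), (0, 1))
        A = A[src_row, src_col]
        out = np.moveaxis(A, (0, 1), (a, b))
    return out


def _rotate(img, plane: tuple[int, int], theta_deg: float, deriv: bool = False):
    """Rotate content by ``theta_deg`` in ``plane = (a, b)`` about the center.

    Content map on centered coords: ``x_a' = c x_a - s x_b``,
    ``x_b' = s x_a + c x_b``.  With ``deriv=True`` also return
    d(out)/d(theta_deg) (product rule over the three shears; not supported
    on the quarter-turn branch for ``|theta| > 45``).
    """
    a_ax, b_ax = plane
    theta = float(theta_deg)
    n_quarter = 0
    if abs(theta) > 45.0:
        n_quarter = int(np.round(theta / 90.0))
        img = _quarter_turns(img, plane, n_quarter)
        theta = theta - 90.0 * n_quarter
        if deriv:
            raise NotImplementedError("jacobian not available for |theta| > 45 deg")
    th = np.deg2rad(theta)
    alpha = -np.tan(th / 2.0)
    beta = np.sin(th)
    if not deriv:
        out = _shear(img, a_ax, b_ax, alpha)
        out = _shear(out, b_ax, a_ax, beta)
        out = _shear(out, a_ax, b_ax, alpha)
        return out
    dalpha = -0.5 / np.cos(th / 2.0) ** 2  # d alpha / d theta(rad)
    dbeta = np.cos(th)
    s1, d1 = _shear(img, a_ax, b_ax, alpha, deriv=True)
    s2, d2s = _shear(s1, b_ax, a_ax, beta, deriv=True)
    d2 = _shear(d1, b_ax, a_ax, beta)
    out, d3s = _shear(s2, a_ax, b_ax, alpha, deriv=True)
    # chain: d(out)/dtheta = S3'(S2 S1) + S3(S2' S1) + S3 S2 S1'
    term1 = d3s * dalpha
    term2 = _shear(d2s, a_ax, b_ax, alpha) * dbeta
    term3 = _shear(d2, a_ax, b_ax, alpha) * dalpha
    dout = (term1 + term2 + term3) * (np.pi / 180.0)  # per degree
    return out, dout


# ---------------------------------------------------------------------------
# public transform API

def _check_mode(image: np.ndarray, params: RigidMotionParams) -> None:
    need = 2 if params.mode == "2d" else 3
    if image.ndim != need:
        raise ValueError(
            f"{params.mode} params require a {need}-D image, got {image.ndim}-D"
        )


def _rot_planes(mode: str):
    # applied in listed order; 3D content map is Rx . Ry . Rz
    if mode == "2d":
        return [((0, 1), 0)]
    return [((0, 1), 2), ((0, 2), 1), ((1, 2), 0)]  # (plane, rotation index)


def apply_rigid(image: np.ndarray, params: RigidMotionParams) -> np.ndarray:
    """Apply the rigid transform (rotate about center, then translate)."""
    _check_mode(image, params)
    out = np.asarray(image, dtype=np.result_type(image.dtype, np.complex64))
    for plane, ridx in _rot_planes(params.mode):
        th = params.rotations[ridx]
        if th != 0.0:
            out = _rotate(out, plane, th)
    for ax, (t, vs) in enumerate(zip(params.translations, params.voxel_size)):
        if t != 0.0:
            out = _shift(out, ax, t / vs)
    return out


def apply_rigid_adjoint(image: np.ndarray, params: RigidMotionParams) -> np.ndarray:
    """Exact adjoint (= inverse) of :func:`apply_rigid` for the same params.

    Applies the reversed pass sequence with negated raw parameters; since
    every pass is unitary this is the exact operator adjoint, passing
    dot-product tests at machine precision.
    """
    _check_mode(image, params)
    out = np.asarray(image, dtype=np.result_type(image.dtype, np.complex64))
    for ax in reversed(range(len(params.translations))):
        t = params.translations[ax]
        if t != 0.0:
            out = _shift(out, ax, -t / params.voxel_size[ax])
    for plane, ridx in reversed(_rot_planes(params.mode)):
        th = params.rotations[ridx]
        if th != 0.0:
            out = _rotate(out, plane, -th)
    return out


def rigid_jacobian(image: np.ndarray, params: RigidMotionParams) -> np.ndarray:
    """Derivatives of ``apply_rigid(image, p)`` w.r.t. each parameter.

    Returns an array ``(n_params, *image.shape)`` ordered like
    :meth:`RigidMotionParams.as_vector` (rotations in deg, translations in
    mm).  Analytic: each pass is differentiated in its conjugate domain and
    chained by the product rule.
    """
    _check_mode(image, params)
    cdt = np.result_type(image.dtype, np.complex64)
    base = np.asarray(image, dtype=cdt)
    planes = _rot_planes(params.mode)
    n_rot = len(params.rotations)
    rot_derivs: dict[int, np.ndarray] = {}
    out = base
    # forward through rotations, tracking the derivative of each
    for k, (plane, ridx) in enumerate(planes):
        th = params.rotations[ridx]
        out_new, d = _rotate(out, plane, th, deriv=True)
        # push previously computed derivatives through this rotation
        for key in rot_derivs:
            rot_derivs[key] = _rotate(rot_derivs[key], plane, th)
        rot_derivs[ridx] = d
        out = out_new
    # translations: derivative of the shift pass, and push everything through
    trans_derivs: dict[int, np.ndarray] = {}
    for ax, (t, vs) in enumerate(zip(params.translations, params.voxel_size)):
        s = t / vs
        out_new, ds = _shift(out, ax, s, deriv=True)
        for key in rot_derivs:
            rot_derivs[key] = _shift(rot_derivs[key], ax, s)
        for key in trans_derivs:
            trans_derivs[key] = _shift(trans_derivs[key], ax, s)
        trans_derivs[ax] = ds / vs  # per mm
        out = out_new
    jac = np.empty((params.n_params, *base.shape), dtype=cdt)
    for ridx in range(n_rot):
        jac[ridx] = rot_derivs[ridx]
    for ax in range(len(params.translations)):
        jac[n_rot + ax] = trans_derivs[ax]
    return jac


# ---------------------------------------------------------------------------
# parameter algebra

def _rot_matrix(params: RigidMotionParams) -> np.ndarray:
    if params.mode == "2d":
        th = np.deg2rad(params.rotations[0])
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])
    rx, ry, rz = (np.deg2rad(a) for a in params.rotations)
    cz, sz = np.cos(rz), np.sin(rz)
    cy, sy = np.cos(ry), np.sin(ry)
    cx, sx = np.cos(rx), np.sin(rx)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Ry = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rx @ Ry @ Rz


def _angles_from_matrix(m: np.ndarray, mode: str) -> tuple[float, ...]:
    if mode == "2d":
        return (float(np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))),)
    beta = np.arcsin(np.clip(-m[0, 2], -1.0, 1.0))
    gamma = np.arctan2(-m[0, 1], m[0, 0])
    alpha = np.arctan2(-m[1, 2], m[2, 2])
    return tuple(float(np.rad2deg(a)) for a in (alpha, beta, gamma))


def compose(a: RigidMotionParams, b: RigidMotionParams) -> RigidMotionParams:
    """Parameters of ``T_a after T_b`` (``b`` applied first).

    Rotation matrices multiply; translations compose in voxel coordinates
    (the space the shears rotate in) and are reported back in mm.
    """
    if a.mode != b.mode:
        raise ValueError("cannot compose transforms of different modes")
    ra, rb = _rot_matrix(a), _rot_matrix(b)
    vs = np.asarray(a.voxel_size)
    ta = np.asarray(a.translations) / vs
    tb = np.asarray(b.translations) / vs
    t = ra @ tb + ta
    return replace(
        a,
        rotations=_angles_from_matrix(ra @ rb, a.mode),
        translations=tuple((t * vs).tolist()),
    )


def invert(p: RigidMotionParams) -> RigidMotionParams:
    """Parameters of the inverse transform."""
    r = _rot_matrix(p)
    vs = np.asarray(p.voxel_size)
    t = np.asarray(p.translations) / vs
    ti = -(r.T @ t)
    return replace(
        p,
        rotations=_angles_from_matrix(r.T, p.mode),
        translations=tuple((ti * vs).tolist()),
    )


# ---------------------------------------------------------------------------
# motion traces

@dataclass
class MotionTrace:
    """Hierarchical rigid motion: per-group T_inter, per-subdivision T_intra.

    ``t_inter[0]`` is the identity (the first shot group is the alignment
    reference); the total transform of subdivision ``(i, j)`` is
    ``T_intra[i][j] . T_inter[i]``.
    """

    t_inter: list[RigidMotionParams]
    t_intra: list[list[RigidMotionParams]]

    @property
    def n_groups(self) -> int:
        return len(self.t_inter)

    @property
    def n_subdivisions_per_group(self) -> int:
        return len(self.t_intra[0])

    def total(self, i: int, j: int) -> RigidMotionParams:
        return compose(self.t_intra[i][j], self.t_inter[i])

    @classmethod
    def identity(
        cls, n_groups: int, n_sub: int, mode: str = "2d", voxel_size=None
    ) -> "MotionTrace":
        return cls(
            t_inter=[identity_params(mode, voxel_size) for _ in range(n_groups)],
            t_intra=[
                [identity_params(mode, voxel_size) for _ in range(n_sub)]
                for _ in range(n_groups)
            ],
        )

    def copy(self) -> "MotionTrace":
        return MotionTrace(list(self.t_inter), [list(row) for row in self.t_intra])


_TSV_HEADER = "volume\tgroup\tsubdivision\ttx_mm\tty_mm\ttz_mm\trx_deg\try_deg\trz_deg"


def _params_to_row(p: RigidMotionParams) -> tuple[float, ...]:
    if p.mode == "2d":
        # 2D axes (y, z); in-plane rotation sits in the y-z plane (about x)
        ty, tz = p.translations
        return (0.0, ty, tz, p.rotations[0], 0.0, 0.0)
    tx, ty, tz = p.translations
    rx, ry, rz = p.rotations
    return (tx, ty, tz, rx, ry, rz)


def write_trace_tsv(path, traces, mode: str = "2d") -> None:
    """Write per-(volume, group, subdivision) total transforms as TSV.

    ``traces`` is a list of :class:`MotionTrace`, one per volume.
    """
    lines = [_TSV_HEADER]
    for v, trace in enumerate(traces):
        for i in range(trace.n_groups):
            for j in range(len(trace.t_intra[i])):
                row = _params_to_row(trace.total(i, j))
                lines.append(
                    "\t".join([str(v), str(i), str(j)] + [f"{x:.6f}" for x in row])
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trace_tsv(path, mode: str = "2d", voxel_size=None):
    """Read a TSV trace back as nested totals: ``[volume][group][subdivision]``."""
    rows = np.loadtxt(path, skiprows=1, ndmin=2)
    out: dict[int, dict[int, dict[int, RigidMotionParams]]] = {}
    for row in rows:
        v, i, j = (int(row[0]), int(row[1]), int(row[2]))
        tx, ty, tz, rx, ry, rz = row[3:9]
        if mode == "2d":
            p = RigidMotionParams(
                (rx,), (ty, tz), "2d",
                (1.0, 1.0) if voxel_size is None else tuple(voxel_size),
            )
        else:
            p = RigidMotionParams(
                (rx, ry, rz), (tx, ty, tz), "3d",
                (1.0, 1.0, 1.0) if voxel_size is None else tuple(voxel_size),
            )
        out.setdefault(v, {}).setdefault(i, {})[j] = p
    return [
        [[out[v][i][j] for j in sorted(out[v][i])] for i in sorted(out[v])]
        for v in sorted(out)
    ]
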