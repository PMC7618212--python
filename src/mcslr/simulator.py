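"""Synthetic multi-shot EPI acquisition simulator.

Generates everything the reconstruction needs without any data download: a
piecewise-smooth complex brain-like phantom, smooth complex coil maps,
smooth inter-shot-group phase-variation states (fresh per volume, as
respiration-driven phase states drift over a time series), per-shot rigid
motion traces linearly interpolated from uniform random knots, and
seg-CAIPI-sampled multi-coil k-space with complex Gaussian noise.

Every stochastic element is reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import SimulationSpec
from .encoding import CoilSensitivities
from .fourier import fft2c
from .rigid_motion import MotionTrace, RigidMotionParams, apply_rigid
from .sampling import SamplingScheme, bin_shots, generate_seg_caipi

__all__ = [
    "make_phantom",
    "make_coil_maps",
    "make_phase_states",
    "make_motion_trace",
    "smooth_random_field",
    "simulate_acquisition",
    "simulate",
    "SimulatedRun",
    "sigma_for_snr_db",
]


def _ellipse(shape, center, semi, angle_deg=0.0):
    n1, n2 = shape
    y, z = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    th = np.deg2rad(angle_deg)
    dy, dz = y - center[0], z - center[1]
    u = np.cos(th) * dy + np.sin(th) * dz
    v = -np.sin(th) * dy + np.cos(th) * dz
    return (u / semi[0]) ** 2 + (v / semi[1]) ** 2 <= 1.0


def smooth_random_field(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length set by
    ``sigma`` (Gaussian filter width in voxels; the autocorrelation is
    Gaussian with std ``sigma * sqrt(2)``, half width ~ ``1.665 sigma``)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_phantom(shape, seed: int, margin: int = 8) -> np.ndarray:
    """Piecewise-smooth brain-like complex phantom.

    Elliptical compartments (head, cortical ring, ventricles, focal blobs)
    plus smooth random texture; magnitude in [0, 1]; smooth nonzero phase;
    support at least ``margin`` voxels from every edge.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = shape
    c = (n1 / 2.0, n2 / 2.0)
    a1 = n1 / 2.0 - margin - 2
    a2 = n2 / 2.0 - margin - 2
    head = _ellipse(shape, c, (a1, a2))
    brain = _ellipse(shape, c, (0.82 * a1, 0.82 * a2))
    mag = np.zeros(shape)
    mag[head] = 0.35  # scalp/skull band
    mag[brain] = 0.75
    # ventricles: two small dark ellipses near center
    for sgn in (-1, 1):
        vent = _ellipse(
            shape, (c[0] - 0.05 * a1, c[1] + sgn * 0.18 * a2),
            (0.22 * a1, 0.08 * a2), angle_deg=sgn * 20.0,
        )
        mag[vent] = 0.25
    # focal structures
    for _ in range(6):
        ctr = (
            c[0] + rng.uniform(-0.5, 0.5) * a1,
            c[1] + rng.uniform(-0.5, 0.5) * a2,
        )
        semi = (rng.uniform(0.04, 0.1) * a1, rng.uniform(0.04, 0.1) * a2)
        blob = _ellipse(shape, ctr, semi, angle_deg=rng.uniform(0, 180))
        mag[blob & brain] = rng.uniform(0.45, 1.0)
    texture = smooth_random_field(shape, 2.5, rng) * 0.08
    mag = np.clip(mag + texture * brain, 0.0, 1.0) * head
    mag = ndimage.gaussian_filter(mag, 0.8)
    mag = np.clip(mag, 0.0, 1.0)
    mag[~head] = 0.0
    phase = 0.4 * smooth_random_field(shape, 8.0, rng)
    return (mag * np.exp(1j * phase)).astype(np.complex128)


def support_mask(phantom: np.ndarray, thresh: float = 0.05) -> np.ndarray:
    return np.abs(phantom) > thresh


def make_coil_maps(shape, n_coils: int, seed: int) -> CoilSensitivities:
    """Smooth complex coil maps: Gaussian lobes around the FOV, normalized
    to unit sum-of-squares magnitude everywhere (hence inside any support)."""
    rng = np.random.default_rng(seed)
    n1, n2 = shape
    if n_coils == 1:
        return CoilSensitivities(maps=np.ones((1, n1, n2), dtype=np.complex128))
    y, z = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    maps = np.empty((n_coils, n1, n2), dtype=np.complex128)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.15, 0.15)
        cy = n1 / 2 + 0.62 * n1 / 2 * np.cos(ang)
        cz = n2 / 2 + 0.62 * n2 / 2 * np.sin(ang)
        w1, w2 = 0.55 * n1, 0.55 * n2
        lobe = np.exp(-(((y - cy) / w1) ** 2 + ((z - cz) / w2) ** 2))
        ph = (
            rng.uniform(0, 2 * np.pi)
            + 2 * np.pi * rng.uniform(-0.3, 0.3) * (y - n1 / 2) / n1
            + 2 * np.pi * rng.uniform(-0.3, 0.3) * (z - n2 / 2) / n2
        )
        maps[c] = lobe * np.exp(1j * ph)
    sos = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= np.maximum(sos, 1e-12)[None]
    return CoilSensitivities(maps=maps)


def make_phase_states(
    shape, n_states: int, amplitude: float, smoothness: float, seed: int
) -> np.ndarray:
    """Smooth inter-shot-group phase maps, first state identically zero.

    Each nonzero state is a low-order polynomial plus a smooth random
    field, rescaled so its peak-to-peak amplitude equals ``amplitude``.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = shape
    y = (np.arange(n1) - n1 // 2)[:, None] / n1
    z = (np.arange(n2) - n2 // 2)[None, :] / n2
    states = np.zeros((n_states, n1, n2))
    for k in range(1, n_states):
        poly = rng.uniform(-1, 1) + rng.uniform(-1, 1) * y + rng.uniform(-1, 1) * z
        field = poly + 0.7 * smooth_random_field(shape, smoothness, rng)
        if amplitude > 0:
            field = field - field.mean()
            p2p = field.max() - field.min()
            states[k] = field * (amplitude / p2p) if p2p > 0 else 0.0
    return states


def make_motion_trace(
    n_shots: int,
    n_knots: int,
    rot_range: float,
    trans_range: float,
    seed: int,
) -> list[RigidMotionParams]:
    """Per-shot rigid motion by linear interpolation from uniform knots.

    Knot values are i.i.d. uniform in ``+/-rot_range`` deg (in-plane
    rotation) and ``+/-trans_range`` mm (1D translation along y); per-shot
    values interpolate linearly between knots placed evenly over the shots.
    """
    rng = np.random.default_rng(seed)
    knot_rot = rng.uniform(-rot_range, rot_range, size=n_knots)
    knot_ty = rng.uniform(-trans_range, trans_range, size=n_knots)
    t_knots = np.linspace(0, n_shots - 1, n_knots)
    t = np.arange(n_shots)
    rot = np.interp(t, t_knots, knot_rot)
    ty = np.interp(t, t_knots, knot_ty)
    return [
        RigidMotionParams((float(rot[s]),), (float(ty[s]), 0.0), "2d")
        for s in range(n_shots)
    ]


def sigma_for_snr_db(phantom: np.ndarray, snr_db: float) -> float:
    """Noise std per real/imag channel for a target image-domain SNR.

    SNR (dB) is mean support magnitude over the noise standard deviation;
    with a unitary FFT the same sigma applies in k-space.
    """
    mask = support_mask(phantom)
    mu = float(np.abs(phantom)[mask].mean())
    return mu / 10.0 ** (snr_db / 20.0)


@dataclass
class SimulatedRun:
    """Everything one simulated time series produced, truth included."""

    spec: SimulationSpec
    scheme: SamplingScheme
    sens: CoilSensitivities
    kspace: np.ndarray  # (n_volumes, n_shots, n_coils, N1, N2)
    phantom: np.ndarray
    truth_images: np.ndarray  # (n_volumes, n_groups, N1, N2), aligned
    phase_states: np.ndarray  # (n_volumes, n_groups, N1, N2)
    shot_traces: list[list[RigidMotionParams]]  # [volume][shot]
    noise_sigma: float

    @property
    def voxel_size(self) -> tuple[float, float]:
        return (self.spec.voxel_size_mm, self.spec.voxel_size_mm)

    def support(self) -> np.ndarray:
        return support_mask(self.phantom)

    def truth_trace(self, volume: int) -> MotionTrace:
        """Ground-truth per-subdivision motion (per-shot params averaged
        over each subdivision's shots; exact for 1-shot subdivisions)."""
        sch = self.scheme
        trace = MotionTrace.identity(
            sch.n_groups, sch.n_subdivisions_per_group, "2d", self.voxel_size
        )
        shots = self.shot_traces[volume]
        for i in range(sch.n_groups):
            for j in range(sch.n_subdivisions_per_group):
                idx = sch.shots_of_subdivision(i, j)
                vecs = np.stack([shots[s].as_vector() for s in idx])
                mean = vecs.mean(axis=0)
                trace.t_intra[i][j] = RigidMotionParams(
                    (float(mean[0]),),
                    (float(mean[1]), float(mean[2])),
                    "2d",
                    self.voxel_size,
                )
        return trace


def simulate_acquisition(
    phantom: np.ndarray,
    sens: CoilSensitivities,
    phase_states: np.ndarray,
    shot_trace: list[RigidMotionParams],
    scheme: SamplingScheme,
    noise_sigma: float,
    seed: int,
) -> np.ndarray:
    """Forward-simulate one volume: per shot, move the group's
    phase-modulated image, coil-encode, Fourier transform, sample the shot
    mask, and add complex Gaussian noise on the sampled points."""
    scheme._require_binned()
    if len(shot_trace) != scheme.n_shots:
        raise ValueError(
            f"trace has {len(shot_trace)} shots, scheme has {scheme.n_shots}"
        )
    rng = np.random.default_rng(seed)
    n_shots, n_coils = scheme.n_shots, sens.n_coils
    Y = np.zeros((n_shots, n_coils, *scheme.grid_shape), dtype=np.complex128)
    for s in range(n_shots):
        g = scheme.group_of_shot[s]
        img = phantom * np.exp(1j * phase_states[g])
        p = shot_trace[s]
        if not p.is_identity():
            img = apply_rigid(img, p)
        k = fft2c(sens.maps * img[None])
        Y[s] = np.where(scheme.shot_masks[s][None], k, 0)
    if noise_sigma > 0:
        noise = noise_sigma * (
            rng.standard_normal(Y.shape) + 1j * rng.standard_normal(Y.shape)
        )
        Y += noise * scheme.shot_masks[:, None]
    return Y


def simulate(spec: SimulationSpec) -> SimulatedRun:
    """Simulate the full time series defined by ``spec``."""
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + 3 * spec.n_volumes)]
    scheme = generate_seg_caipi(
        spec.image_shape,
        spec.accel,
        spec.n_shots,
        caipi_shift=spec.caipi_shift,
        n_interleaves=spec.n_groups,
    )
    scheme = bin_shots(scheme, spec.n_groups, spec.shots_per_subdivision)
    phantom = make_phantom(spec.image_shape, seeds[0])
    sens = make_coil_maps(spec.image_shape, spec.n_coils, seeds[1])
    if spec.noise_sigma is not None:
        sigma = spec.noise_sigma
    elif spec.snr_db is not None:
        sigma = sigma_for_snr_db(phantom, spec.snr_db)
    else:
        sigma = 0.0
    vs = (spec.voxel_size_mm, spec.voxel_size_mm)
    n_vol = spec.n_volumes
    kspace = np.empty(
        (n_vol, spec.n_shots, spec.n_coils, *spec.image_shape), dtype=np.complex64
    )
    truth = np.empty((n_vol, spec.n_groups, *spec.image_shape), dtype=np.complex64)
    phases = np.empty((n_vol, spec.n_groups, *spec.image_shape), dtype=np.float32)
    traces: list[list[RigidMotionParams]] = []
    for v in range(n_vol):
        s_phase, s_motion, s_noise = seeds[4 + 3 * v : 7 + 3 * v]
        ph = make_phase_states(
            spec.image_shape,
            spec.n_groups,
            spec.phase_amplitude_rad,
            spec.phase_smoothness,
            s_phase,
        )
        raw = make_motion_trace(
            spec.n_shots,
            spec.n_motion_knots,
            spec.rot_range_deg,
            spec.trans_range_mm,
            s_motion,
        )
        trace = [
            RigidMotionParams(p.rotations, p.translations, "2d", vs) for p in raw
        ]
        Y = simulate_acquisition(phantom, sens, ph, trace, scheme, sigma, s_noise)
        kspace[v] = Y
        phases[v] = ph
        truth[v] = phantom[None] * np.exp(1j * ph)
        traces.append(trace)
    return SimulatedRun(
        spec=spec,
        scheme=scheme,
        sens=sens,
        kspace=kspace,
        phantom=phantom,
        truth_images=truth,
        phase_states=phases,
        shot_traces=traces,
        noise_sigma=float(sigma),
    )
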