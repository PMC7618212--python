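"""Configuration dataclasses for reconstruction, motion solving, simulation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

__all__ = ["ReconConfig", "LMConfig", "SimulationSpec"]


@dataclass
class LMConfig:
    """Levenberg-Marquardt settings for intra-shot-group motion estimation.

    Damped Gauss-Newton on the real/imaginary-stacked data-consistency
    residual: multiplicative damping (``damping_up`` on reject,
    ``damping_down`` on accept) with per-iteration step caps so a single bad
    linearization cannot throw the motion state far off.
    """

    max_iters: int = 5
    damping_init: float = 1e-2
    damping_up: float = 10.0
    damping_down: float = 0.1
    max_step_deg: float = 1.0
    max_step_mm: float = 1.0
    gradient_tol: float = 1e-9

    def __post_init__(self):
        if self.damping_up <= 1.0:
            raise ValueError("damping_up must be > 1")
        if not 0.0 < self.damping_down < 1.0:
            raise ValueError("damping_down must be in (0, 1)")
        if self.max_step_deg <= 0 or self.max_step_mm <= 0:
            raise ValueError("step bounds must be positive")


@dataclass
class ReconConfig:
    """Solver settings shared by the four reconstruction methods.

    ``lam`` balances data consistency against the structured low-rank
    penalty (0.1 is the simulation default); the block-Hankel kernel is
    6x6; ``admm_rho`` is the ADMM penalty after normalizing the data so the
    initial adjoint reconstruction has unit peak magnitude, which lets one
    ``lam`` transfer across datasets.
    """

    lam: float = 0.1
    kernel: tuple[int, int] = (6, 6)
    admm_iters: int = 5
    admm_rho: float = 5.0
    cg_iters: int = 10
    cg_tol: float = 1e-6
    outer_iters_max: int = 100
    rel_change_tol: float = 1e-3
    lm: LMConfig = field(default_factory=LMConfig)
    mcsense_iters_max: int = 100
    registration_bins: int = 64
    registration_levels: int = 3

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if not 0.0 < self.rel_change_tol < 1.0:
            raise ValueError("rel_change_tol must be in (0, 1)")
        for name in ("admm_iters", "admm_rho", "cg_iters", "outer_iters_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def in_vivo_preset(cls) -> "ReconConfig":
        """One ADMM iteration per outer loop, 30 outer iterations."""
        return cls(lam=0.06, admm_iters=1, outer_iters_max=30)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel"] = list(self.kernel)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReconConfig":
        d = dict(d)
        if "kernel" in d:
            d["kernel"] = tuple(d["kernel"])
        if "lm" in d and isinstance(d["lm"], dict):
            d["lm"] = LMConfig(**d["lm"])
        return cls(**d)


@dataclass
class SimulationSpec:
    """Study conditions of the 2D multi-shot EPI motion/phase simulation.

    Defaults mirror the simulated acquisition: a 140x96 ky-kz plane at
    1.5 mm isotropic resolution, 48 shots at R = 2x2 seg-CAIPI binned into
    4 shot groups with 1-shot temporal subdivisions, 16 volumes, per-shot
    rigid motion linearly interpolated from 8 knots drawn uniformly in
    +/-1.5 deg (in-plane rotation) and +/-1.5 mm (1D translation along y),
    smooth inter-shot-group phase variation of pi peak-to-peak, and complex
    Gaussian noise at 30 dB SNR.
    """

    image_shape: tuple[int, int] = (140, 96)
    voxel_size_mm: float = 1.5
    n_coils: int = 8
    n_shots: int = 48
    n_groups: int = 4
    shots_per_subdivision: int = 1
    n_volumes: int = 16
    accel: tuple[int, int] = (2, 2)
    caipi_shift: int = 1
    rot_range_deg: float = 1.5
    trans_range_mm: float = 1.5
    n_motion_knots: int = 8
    phase_amplitude_rad: float = float(np.pi)
    phase_smoothness: float = 12.0
    snr_db: float | None = 30.0
    noise_sigma: float | None = None
    te_tr_ms: tuple[float, float] = (20.0, 40.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_motion_knots < 2:
            raise ValueError("n_motion_knots must be >= 2")
        for name in ("rot_range_deg", "trans_range_mm", "phase_amplitude_rad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["accel"] = list(self.accel)
        d["te_tr_ms"] = list(self.te_tr_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        for key in ("image_shape", "accel", "te_tr_ms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
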