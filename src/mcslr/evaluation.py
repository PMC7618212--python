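"""Evaluation: temporal SNR, motion-estimate RMSE, image NRMSE.

tSNR is voxelwise temporal mean over temporal standard deviation after an
optional rigid registration of every volume to the first, which removes
residual inter-volume misregistration from the temporal variance.  Motion
RMSE compares per-subdivision total transforms (T_intra composed with
T_inter) after removing the global reference offset: absolute pose is
unidentifiable from k-space data alone, only relative motion matters.
"""

from __future__ import annotations

import numpy as np

from .motion_estimation import register_rigid
from .rigid_motion import MotionTrace, apply_rigid

__all__ = ["tsnr_map", "motion_rmse", "nrmse", "TSNR_CAP"]

TSNR_CAP = 1e6  # assigned to voxels with zero temporal variance


def tsnr_map(
    series: np.ndarray,
    mask: np.ndarray | None = None,
    do_register: bool = True,
    voxel_size=(1.0, 1.0),
):
    """tSNR of a magnitude time series ``(n_volumes, N1, N2)``.

    Returns ``(map, mean_in_mask, diagnostics)``; zero-variance voxels
    inside the mask are capped at :data:`TSNR_CAP` and counted.
    """
    series = np.abs(np.asarray(series, dtype=float))
    if series.ndim != 3 or series.shape[0] < 3:
        raise ValueError("need a (n_volumes >= 3, N1, N2) series")
    if mask is None:
        mask = np.ones(series.shape[1:], dtype=bool)
    if do_register:
        reg = [series[0]]
        for v in range(1, series.shape[0]):
            p = register_rigid(series[v], series[0], voxel_size=voxel_size)
            reg.append(np.abs(apply_rigid(series[v], p)))
        series = np.stack(reg)
    mean = series.mean(axis=0)
    sd = series.std(axis=0, ddof=1)
    tsnr = np.full(mean.shape, TSNR_CAP)
    nz = sd > 0
    tsnr[nz] = mean[nz] / sd[nz]
    tsnr = np.minimum(tsnr, TSNR_CAP)
    n_capped = int(np.count_nonzero((~nz) & mask))
    diagnostics = {
        "n_capped_in_mask": n_capped,
        "frac_capped_in_mask": n_capped / max(int(mask.sum()), 1),
    }
    return tsnr, float(tsnr[mask].mean()), diagnostics


def _trace_matrix(traces: list[MotionTrace]) -> np.ndarray:
    """Stack per-subdivision total-transform parameter vectors.

    Shape ``(n_volumes, n_subdivisions_total, n_params)`` in temporal
    order (groups, then subdivisions within group).
    """
    rows = []
    for trace in traces:
        vol = [
            trace.total(i, j).as_vector()
            for i in range(trace.n_groups)
            for j in range(len(trace.t_intra[i]))
        ]
        rows.append(np.stack(vol))
    return np.stack(rows)


def motion_rmse(
    estimated: list[MotionTrace] | MotionTrace,
    truth: list[MotionTrace] | MotionTrace,
) -> dict:
    """Gauge-removed per-parameter RMSE between motion traces (deg, mm).

    For each volume the difference of total transforms is taken per
    subdivision and the first subdivision's difference is subtracted (the
    reference-offset gauge), then parameterwise root-mean-squares are
    pooled across subdivisions and volumes.  Returns a dict with
    ``rotation_deg`` (all rotation parameters pooled), ``translation_mm``
    (all translation parameters pooled) and the per-parameter detail.
    """
    if isinstance(estimated, MotionTrace):
        estimated = [estimated]
    if isinstance(truth, MotionTrace):
        truth = [truth]
    if len(estimated) != len(truth):
        raise ValueError("trace lists differ in length")
    est = _trace_matrix(estimated)
    tru = _trace_matrix(truth)
    if est.shape != tru.shape:
        raise ValueError(f"trace bookkeeping mismatch: {est.shape} vs {tru.shape}")
    diff = est - tru
    diff = diff - diff[:, :1, :]  # remove per-volume reference offset
    n_rot = len(estimated[0].t_inter[0].rotations)
    per_param = np.sqrt((diff**2).mean(axis=(0, 1)))
    return {
        "rotation_deg": float(np.sqrt((diff[..., :n_rot] ** 2).mean())),
        "translation_mm": float(np.sqrt((diff[..., n_rot:] ** 2).mean())),
        "per_param": per_param.tolist(),
    }


def nrmse(image: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Scale-fitted normalized RMSE of magnitudes over ``mask``.

    The global scale minimizing ``||a |image| - |truth|||`` is fitted
    first, so the measure is invariant to overall intensity scaling.
    """
    img = np.abs(np.asarray(image)).astype(float)
    tru = np.abs(np.asarray(truth)).astype(float)
    if mask is not None:
        img, tru = img[mask], tru[mask]
    denom = float((img * img).sum())
    a = float((img * tru).sum()) / denom if denom > 0 else 0.0
    t_norm = float(np.linalg.norm(tru))
    if t_norm == 0:
        return float(np.linalg.norm(a * img - tru))
    return float(np.linalg.norm(a * img - tru) / t_norm)
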