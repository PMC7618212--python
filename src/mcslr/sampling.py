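"""seg-CAIPI sampling schemes and shot / shot-group / subdivision bookkeeping.

A multi-shot 3D EPI acquisition covers the (ky, kz) phase-encode plane over
many shots.  The seg-CAIPI trajectory decimates the plane by ``R_y x R_z``
on a Delta-kz-blipped CAIPI lattice and orders the sampled kz platters so
that the shots of every interleave (the future shot group) cover k-space
roughly uniformly while each interleave itself runs sequentially through
its platters.

Conventions: the k-space grid uses matrix indexing with DC at ``N // 2``;
non-divisible grids are rejected rather than padded, since silent padding
would change the acceleration factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SamplingScheme", "generate_seg_caipi", "bin_shots"]


@dataclass
class SamplingScheme:
    """Per-shot k-space masks plus shot->group and shot->subdivision maps.

    ``shot_masks`` are pairwise disjoint boolean masks over the (ky, kz)
    grid whose union is the R_y x R_z-decimated CAIPI lattice.  Group and
    subdivision bookkeeping is filled by :func:`bin_shots`.
    """

    grid_shape: tuple[int, int]
    shot_masks: np.ndarray  # bool, (n_shots, N_ky, N_kz)
    accel: tuple[int, int]
    caipi_shift: int
    interleave_order: str
    n_interleaves: int
    group_of_shot: np.ndarray | None = None  # (n_shots,) int
    subdivision_of_shot: np.ndarray | None = None  # (n_shots, 2) int (group, sub)
    n_groups: int = 0
    n_subdivisions_per_group: int = 0
    shots_per_subdivision: int = 0

    @property
    def n_shots(self) -> int:
        return self.shot_masks.shape[0]

    def union_mask(self) -> np.ndarray:
        return self.shot_masks.any(axis=0)

    def group_mask(self, i: int) -> np.ndarray:
        self._require_binned()
        return self.shot_masks[self.group_of_shot == i].any(axis=0)

    def shots_of_group(self, i: int) -> np.ndarray:
        self._require_binned()
        return np.flatnonzero(self.group_of_shot == i)

    def shots_of_subdivision(self, i: int, j: int) -> np.ndarray:
        self._require_binned()
        sel = (self.subdivision_of_shot[:, 0] == i) & (
            self.subdivision_of_shot[:, 1] == j
        )
        return np.flatnonzero(sel)

    def subdivision_mask(self, i: int, j: int) -> np.ndarray:
        return self.shot_masks[self.shots_of_subdivision(i, j)].any(axis=0)

    def _require_binned(self) -> None:
        if self.group_of_shot is None:
            raise ValueError("scheme has no group bookkeeping; call bin_shots first")


def generate_seg_caipi(
    grid_shape: tuple[int, int],
    accel: tuple[int, int],
    n_shots: int,
    caipi_shift: int = 1,
    interleave_order: str = "interleaved",
    n_interleaves: int | None = None,
) -> SamplingScheme:
    """Generate a seg-CAIPI sampling scheme.

    Parameters
    ----------
    grid_shape : (N_ky, N_kz)
    accel : (R_y, R_z) undersampling factors.
    n_shots : number of shots covering the sampled platters.
    caipi_shift : ky-offset increment (in units of the R_y-decimated grid)
        between successive sampled kz platters.
    interleave_order : "interleaved" or "sequential".  Interleaved assigns
        platter ``g + k * n_interleaves`` to the ``k``-th shot of interleave
        ``g``, so any interleave's platters form an arithmetic progression
        with stride ``n_interleaves``; sequential assigns platters in
        acquisition order.
    n_interleaves : number of interleaves (defaults to 4, the intended
        number of shot groups); ignored for sequential ordering.
    """
    n_ky, n_kz = grid_shape
    r_y, r_z = accel
    if n_ky % r_y != 0:
        raise ValueError(f"N_ky={n_ky} not divisible by R_y={r_y}")
    if n_kz % r_z != 0:
        raise ValueError(f"N_kz={n_kz} not divisible by R_z={r_z}")
    n_platters = n_kz // r_z
    if n_platters % n_shots != 0:
        raise ValueError(
            f"number of sampled kz platters ({n_platters}) not divisible by "
            f"n_shots={n_shots}"
        )
    platters_per_shot = n_platters // n_shots
    if interleave_order not in ("interleaved", "sequential"):
        raise ValueError(f"unknown interleave_order {interleave_order!r}")
    if interleave_order == "sequential":
        n_il = 1
    else:
        n_il = 4 if n_interleaves is None else int(n_interleaves)
    if n_shots % n_il != 0:
        raise ValueError(f"n_shots={n_shots} not divisible by n_interleaves={n_il}")

    # platter p lives at kz = p * r_z (DC platter kz = N//2 is sampled when
    # N_kz//2 is a multiple of r_z -- true for even platter counts)
    shots_per_il = n_shots // n_il
    masks = np.zeros((n_shots, n_ky, n_kz), dtype=bool)
    for s in range(n_shots):
        g = s // shots_per_il
        k = s % shots_per_il
        for u in range(platters_per_shot):
            p = g + (k * platters_per_shot + u) * n_il
            kz = p * r_z
            ky_offset = (p * caipi_shift) % r_y
            masks[s, ky_offset::r_y, kz] = True
    return SamplingScheme(
        grid_shape=(n_ky, n_kz),
        shot_masks=masks,
        accel=(r_y, r_z),
        caipi_shift=caipi_shift,
        interleave_order=interleave_order,
        n_interleaves=n_il,
    )


def bin_shots(
    scheme: SamplingScheme, n_groups: int, shots_per_subdivision: int
) -> SamplingScheme:
    """Fill group / temporal-subdivision bookkeeping (consecutive binning).

    Consecutive shots go to consecutive groups; each group's shots are split
    into consecutive temporal subdivisions of ``shots_per_subdivision``.
    """
    n_shots = scheme.n_shots
    if n_shots % n_groups != 0:
        raise ValueError(f"n_shots={n_shots} not divisible by n_groups={n_groups}")
    group_size = n_shots // n_groups
    if group_size % shots_per_subdivision != 0:
        raise ValueError(
            f"group size {group_size} not divisible by "
            f"shots_per_subdivision={shots_per_subdivision}"
        )
    shots = np.arange(n_shots)
    group = shots // group_size
    sub = (shots % group_size) // shots_per_subdivision
    scheme.group_of_shot = group
    scheme.subdivision_of_shot = np.stack([group, sub], axis=1)
    scheme.n_groups = n_groups
    scheme.n_subdivisions_per_group = group_size // shots_per_subdivision
    scheme.shots_per_subdivision = shots_per_subdivision
    return scheme
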