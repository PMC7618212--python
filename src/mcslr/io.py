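"""HDF5 run container and NIfTI / TSV / JSON outputs.

Layout of the run container:

* ``/kspace/data``       complex64, volume x coil x shot x ky x kz
* ``/sens/maps``         complex64, coil x y x z
* ``/sampling/shot_masks``, ``/sampling/group_of_shot``,
  ``/sampling/subdivision_of_shot`` plus scheme attributes
* ``/truth/images``, ``/truth/motion`` (per shot), ``/truth/phase``
* ``/meta/voxel_size_mm``, ``/meta/te_tr_ms``, ``/meta/spec_yaml``
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml

from .config import SimulationSpec
from .encoding import CoilSensitivities
from .rigid_motion import RigidMotionParams
from .sampling import SamplingScheme
from .simulator import SimulatedRun

__all__ = ["save_run", "load_run", "save_nifti"]


def save_run(path, run: SimulatedRun) -> None:
    """Write a simulated run (k-space, sensitivities, sampling, truth)."""
    sch = run.scheme
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "/kspace/data",
            data=np.moveaxis(run.kspace, 2, 1).astype(np.complex64),
        )  # volume x coil x shot x ky x kz
        f.create_dataset("/sens/maps", data=run.sens.maps.astype(np.complex64))
        g = f.create_group("/sampling")
        g.create_dataset("shot_masks", data=sch.shot_masks)
        g.create_dataset("group_of_shot", data=sch.group_of_shot)
        g.create_dataset("subdivision_of_shot", data=sch.subdivision_of_shot)
        g.attrs["grid_shape"] = sch.grid_shape
        g.attrs["accel"] = sch.accel
        g.attrs["caipi_shift"] = sch.caipi_shift
        g.attrs["interleave_order"] = sch.interleave_order
        g.attrs["n_interleaves"] = sch.n_interleaves
        g.attrs["n_groups"] = sch.n_groups
        g.attrs["shots_per_subdivision"] = sch.shots_per_subdivision
        t = f.create_group("/truth")
        t.create_dataset("images", data=run.truth_images.astype(np.complex64))
        t.create_dataset("phase", data=run.phase_states.astype(np.float32))
        t.create_dataset("phantom", data=run.phantom.astype(np.complex64))
        motion = np.array(
            [[p.as_vector() for p in vol] for vol in run.shot_traces], dtype=np.float64
        )  # volume x shot x (rot_deg, ty_mm, tz_mm)
        t.create_dataset("motion", data=motion)
        m = f.create_group("/meta")
        m.create_dataset("voxel_size_mm", data=float(run.spec.voxel_size_mm))
        m.create_dataset("te_tr_ms", data=np.asarray(run.spec.te_tr_ms))
        m.create_dataset("noise_sigma", data=float(run.noise_sigma))
        m.create_dataset(
            "spec_yaml", data=yaml.safe_dump(run.spec.to_dict()).encode()
        )


def load_run(path) -> SimulatedRun:
    """Read a run container back into a :class:`SimulatedRun`."""
    with h5py.File(path, "r") as f:
        spec = SimulationSpec.from_dict(
            yaml.safe_load(f["/meta/spec_yaml"][()].decode())
        )
        kspace = np.moveaxis(f["/kspace/data"][()], 1, 2)
        sens = CoilSensitivities(maps=f["/sens/maps"][()])
        g = f["/sampling"]
        scheme = SamplingScheme(
            grid_shape=tuple(int(v) for v in g.attrs["grid_shape"]),
            shot_masks=g["shot_masks"][()].astype(bool),
            accel=tuple(int(v) for v in g.attrs["accel"]),
            caipi_shift=int(g.attrs["caipi_shift"]),
            interleave_order=str(g.attrs["interleave_order"]),
            n_interleaves=int(g.attrs["n_interleaves"]),
            group_of_shot=g["group_of_shot"][()],
            subdivision_of_shot=g["subdivision_of_shot"][()],
            n_groups=int(g.attrs["n_groups"]),
            shots_per_subdivision=int(g.attrs["shots_per_subdivision"]),
        )
        scheme.n_subdivisions_per_group = (
            scheme.n_shots // scheme.n_groups // scheme.shots_per_subdivision
        )
        motion = f["/truth/motion"][()]
        vs = (spec.voxel_size_mm, spec.voxel_size_mm)
        traces = [
            [
                RigidMotionParams((row[0],), (row[1], row[2]), "2d", vs)
                for row in vol
            ]
            for vol in motion
        ]
        return SimulatedRun(
            spec=spec,
            scheme=scheme,
            sens=sens,
            kspace=kspace,
            phantom=f["/truth/phantom"][()],
            truth_images=f["/truth/images"][()],
            phase_states=f["/truth/phase"][()],
            shot_traces=traces,
            noise_sigma=float(f["/meta/noise_sigma"][()]),
        )


def save_nifti(path, image: np.ndarray, voxel_size_mm: float = 1.0) -> None:
    """Save a 2D (or stacked) magnitude image as NIfTI."""
    import nibabel as nib

    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[..., None]
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.abs(arr).astype(np.float32), affine), str(path))


def save_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
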