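"""NIfTI input/output, sidecars and complex-series persistence.

Quantitative maps travel as NIfTI volumes with a JSON sidecar recording
units, seed and software version.  Complex series are stored as paired
real/imaginary 4-D NIfTI files plus a TSV schedule sidecar (columns slice,
acquisition, ti_ms); slices live on the third spatial axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .forward import ComplexSeries
from .protocol import AcquisitionProtocol, TISchedule

__all__ = [
    "read_nifti",
    "write_nifti",
    "write_map",
    "save_series",
    "load_series",
]


def _affine(voxel_size_mm):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_nifti(volume, path, voxel_size_mm=(1.0, 1.0, 1.0), affine=None) -> None:
    if affine is None:
        affine = _affine(voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(volume), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_nifti(path):
    """Load a NIfTI volume; returns ``(data, affine)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def _check_affines(path_a, aff_a, path_b, aff_b):
    if not np.allclose(aff_a, aff_b, atol=1e-6):
        raise ValueError(
            f"affine mismatch between {path_a} and {path_b}; "
            "the volumes are not co-registered"
        )


def write_map(volume, path, voxel_size_mm=(1.0, 1.0, 1.0), units="", seed=None,
              extra=None) -> None:
    """Write a quantitative map plus its JSON sidecar."""
    path = Path(path)
    write_nifti(volume, path, voxel_size_mm)
    sidecar = {
        "units": units,
        "seed": seed,
        "software": f"msirepi {__version__}",
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def save_series(series: ComplexSeries, stem, seed=None) -> dict:
    """Persist a complex series as ``<stem>_real.nii`` / ``<stem>_imag.nii``
    plus ``<stem>_schedule.tsv`` and a JSON sidecar; returns the paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "real": stem.parent / f"{stem.name}_real.nii",
        "imag": stem.parent / f"{stem.name}_imag.nii",
        "schedule": stem.parent / f"{stem.name}_schedule.tsv",
        "sidecar": stem.parent / f"{stem.name}.json",
    }
    write_nifti(series.data.real, paths["real"], series.voxel_size_mm)
    write_nifti(series.data.imag, paths["imag"], series.voxel_size_mm)
    series.schedule.to_tsv(paths["schedule"])
    sidecar = {
        "protocol": series.protocol.to_dict(),
        "voxel_size_mm": list(series.voxel_size_mm),
        "seed": seed,
        "software": f"msirepi {__version__}",
    }
    paths["sidecar"].write_text(json.dumps(sidecar, default=str, indent=2))
    return paths


def load_series(stem) -> ComplexSeries:
    """Load a complex series written by :func:`save_series`."""
    stem = Path(stem)
    real_p = stem.parent / f"{stem.name}_real.nii"
    imag_p = stem.parent / f"{stem.name}_imag.nii"
    sched_p = stem.parent / f"{stem.name}_schedule.tsv"
    side_p = stem.parent / f"{stem.name}.json"
    for p in (real_p, imag_p, sched_p, side_p):
        if not p.exists():
            raise FileNotFoundError(f"missing series component: {p}")
    real, aff_r = read_nifti(real_p)
    imag, aff_i = read_nifti(imag_p)
    _check_affines(real_p, aff_r, imag_p, aff_i)
    if real.shape != imag.shape:
        raise ValueError(
            f"shape mismatch between {real_p} ({real.shape}) and "
            f"{imag_p} ({imag.shape})"
        )
    sidecar = json.loads(side_p.read_text())
    proto_dict = dict(sidecar["protocol"])
    proto_dict["slice_offsets"] = tuple(proto_dict["slice_offsets"])
    protocol = AcquisitionProtocol(**proto_dict)
    schedule = TISchedule.from_tsv(sched_p, tr_ms=protocol.tr_ms,
                                   min_ti_ms=protocol.min_ti_ms)
    return ComplexSeries(
        data=real + 1j * imag,
        schedule=schedule,
        protocol=protocol,
        voxel_size_mm=tuple(sidecar["voxel_size_mm"]),
    )
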