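"""Synthetic digital phantoms with known ground truth.

Two families are provided: a calibrated-sphere slab mimicking the
ISMRM/NIST system phantom plates (known T1 and paramagnetic-ion
concentration per sphere, no magnetization transfer) and a schematic
two-tissue "brain" (WM core, GM shell) with a smooth transmit-field map and
a uniform MT ratio.  Both carry every map the forward model consumes:
intrinsic T1, S0, b/a, B1 scale, background phase and integer region labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomVolume",
    "RegionSpec",
    "make_sphere_phantom",
    "make_brain_phantom",
    "nist_t1_plate",
    "nist_t2_plate",
    "save_phantom",
    "load_phantom",
]

# Printed anchor values for the first ten spheres of each NIST plate at 3 T:
# T1 plate (NiCl2) spans 1998 ms (sphere 1) to 89 ms (sphere 10); the
# T2 plate (MnCl2) spans 3025 ms to 293 ms.  Intermediate spheres and the
# concentrations are SYNTHETIC stand-ins: T1 interpolates geometrically
# between the anchors and concentrations are back-computed from a linear
# relaxivity model R1 = r*C + R1_water using the plate relaxivities
# 0.63 (NiCl2) and 0.81 (MnCl2) s^-1 mM^-1 with R1_water = 0.3 s^-1.
# Users with the true NIST table should pass their own RegionSpec list.
_T1_PLATE_ANCHORS_MS = (1998.0, 89.0)
_T2_PLATE_ANCHORS_MS = (3025.0, 293.0)
_RELAXIVITY_T1_PLATE = 0.63  # s^-1 mM^-1 (NiCl2)
_RELAXIVITY_T2_PLATE = 0.81  # s^-1 mM^-1 (MnCl2)
_R1_WATER = 0.3  # s^-1


@dataclass(frozen=True)
class RegionSpec:
    """One labelled region: name, geometry and reference values."""

    name: str
    center_vox: tuple
    radius_vox: float
    t1_ms: float
    concentration_mM: float = float("nan")
    s0: float = 1.0
    ba_per_deg: float = 0.0


@dataclass
class PhantomVolume:
    """Ground-truth volumes of a digital phantom (all same shape)."""

    t1_ms: np.ndarray
    s0: np.ndarray
    ba_per_deg: np.ndarray
    b1_scale: np.ndarray
    phase_rad: np.ndarray
    labels: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    region_table: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {
            a.shape
            for a in (
                self.t1_ms,
                self.s0,
                self.ba_per_deg,
                self.b1_scale,
                self.phase_rad,
                self.labels,
            )
        }
        if len(shapes) != 1:
            raise ValueError(f"phantom volumes have inconsistent shapes: {shapes}")
        support = self.labels > 0
        if support.any() and np.any(self.t1_ms[support] <= 0):
            raise ValueError("t1_ms must be positive inside the phantom support")
        if np.any(self.s0[~support] != 0):
            raise ValueError("background (label 0) must have s0 = 0")

    @property
    def shape(self) -> tuple:
        return self.t1_ms.shape

    @property
    def support(self) -> np.ndarray:
        return self.labels > 0

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _concentration_for_t1(t1_ms: float, relaxivity: float) -> float:
    return max((1000.0 / t1_ms - _R1_WATER) / relaxivity, 0.0)


def _plate_specs(prefix, anchors, relaxivity, centers, radius):
    t_hi, t_lo = anchors
    t1s = np.geomspace(t_hi, t_lo, 10)
    # keep the printed endpoints exact despite float rounding
    t1s[0], t1s[-1] = t_hi, t_lo
    return [
        RegionSpec(
            name=f"{prefix}_{i + 1}",
            center_vox=tuple(centers[i]),
            radius_vox=radius,
            t1_ms=float(t1s[i]),
            concentration_mM=_concentration_for_t1(float(t1s[i]), relaxivity),
        )
        for i in range(10)
    ]


def _ring_centers(grid_shape, n=10, margin=0.32):
    """Sphere centres on a ring in the central slice plane."""
    nx, ny, nz = grid_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    r = margin * min(nx, ny)
    ang = 2 * np.pi * np.arange(n) / n
    return [(cx + r * np.cos(a), cy + r * np.sin(a), cz) for a in ang]


def nist_t1_plate(grid_shape=(64, 64, 8), radius_vox=4.0):
    """Default T1-plate layout (NiCl2 spheres T1_1 ... T1_10)."""
    return _plate_specs(
        "T1", _T1_PLATE_ANCHORS_MS, _RELAXIVITY_T1_PLATE,
        _ring_centers(grid_shape), radius_vox,
    )


def nist_t2_plate(grid_shape=(64, 64, 8), radius_vox=4.0):
    """Default T2-plate layout (MnCl2 spheres T2_1 ... T2_10; their T1s)."""
    return _plate_specs(
        "T2", _T2_PLATE_ANCHORS_MS, _RELAXIVITY_T2_PLATE,
        _ring_centers(grid_shape), radius_vox,
    )


def make_sphere_phantom(
    spec=None,
    grid_shape=(64, 64, 8),
    voxel_size_mm=(2.0, 2.0, 2.0),
) -> PhantomVolume:
    """Embed labelled calibrated spheres in an empty background.

    ``spec`` is a list of :class:`RegionSpec`; by default the ten-sphere
    T1 plate (:func:`nist_t1_plate`).  Aqueous spheres carry no MT (b/a = 0).
    Overlapping spheres raise an error; a zero radius yields an empty label.
    """
    if spec is None:
        spec = nist_t1_plate(grid_shape)
    shape = tuple(grid_shape)
    t1 = np.zeros(shape)
    s0 = np.zeros(shape)
    ba = np.zeros(shape)
    b1 = np.ones(shape)
    phase = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)

    idx = np.indices(shape).astype(float)
    table = {}
    for lab, region in enumerate(spec, start=1):
        cx, cy, cz = region.center_vox
        d2 = (idx[0] - cx) ** 2 + (idx[1] - cy) ** 2 + (idx[2] - cz) ** 2
        if region.radius_vox <= 0:
            mask = np.zeros(shape, dtype=bool)
        else:
            mask = d2 <= region.radius_vox**2
        if np.any(labels[mask] != 0):
            raise ValueError(f"sphere '{region.name}' overlaps an earlier sphere")
        if mask.any():
            if any(not (0 <= c < n) for c, n in zip(region.center_vox, shape)):
                raise ValueError(f"sphere '{region.name}' centre outside the grid")
            labels[mask] = lab
            t1[mask] = region.t1_ms
            s0[mask] = region.s0
            ba[mask] = region.ba_per_deg
        table[lab] = {
            "name": region.name,
            "reference_t1_ms": region.t1_ms,
            "concentration_mM": region.concentration_mM,
        }
    return PhantomVolume(
        t1_ms=t1, s0=s0, ba_per_deg=ba, b1_scale=b1, phase_rad=phase,
        labels=labels, voxel_size_mm=tuple(voxel_size_mm), region_table=table,
    )


# Reference tissue values: GM 1699 ms / WM 1135 ms intrinsic T1 (no fat
# suppression) and a uniform MT ratio b/a = 0.0045 per degree.
GM_T1_MS = 1699.0
WM_T1_MS = 1135.0
BRAIN_BA_PER_DEG = 0.0045


def make_brain_phantom(
    grid_shape=(32, 32, 8),
    voxel_size_mm=(2.0, 2.0, 2.0),
    seed=0,
    b1_range=(0.7, 1.3),
    t1_gm_ms=GM_T1_MS,
    t1_wm_ms=WM_T1_MS,
    ba_per_deg=BRAIN_BA_PER_DEG,
) -> PhantomVolume:
    """Schematic two-tissue brain: WM ellipsoid core inside a GM shell.

    The transmit field X(r) falls off radially from 1.0 at the grid centre
    to the lower bound of ``b1_range`` at the corner; a smooth random phase
    map (seeded) provides a non-trivial background phase.  The geometry is
    deliberately schematic — nested smooth shapes, not anatomy.
    """
    if any(n < s for n, s in zip(grid_shape, (16, 16, 8))):
        raise ValueError("grid_shape must be at least (16, 16, 8)")
    shape = tuple(grid_shape)
    nx, ny, nz = shape
    idx = np.indices(shape).astype(float)
    c = [(n - 1) / 2.0 for n in shape]
    # normalised ellipsoidal radius (1 at the head boundary)
    rho = np.sqrt(
        ((idx[0] - c[0]) / (0.45 * nx)) ** 2
        + ((idx[1] - c[1]) / (0.45 * ny)) ** 2
        + ((idx[2] - c[2]) / (0.48 * nz)) ** 2
    )
    gm = rho <= 1.0
    wm = rho <= 0.62
    labels = np.zeros(shape, dtype=np.int32)
    labels[gm] = 1
    labels[wm] = 2

    t1 = np.zeros(shape)
    t1[labels == 1] = t1_gm_ms
    t1[labels == 2] = t1_wm_ms
    s0 = np.zeros(shape)
    s0[labels == 1] = 1.0
    s0[labels == 2] = 0.95
    ba = np.zeros(shape)
    ba[labels > 0] = ba_per_deg

    # smooth radial B1 falloff, exactly 1 at the grid centre
    corner_rho = float(
        np.sqrt(
            (c[0] / (0.45 * nx)) ** 2
            + (c[1] / (0.45 * ny)) ** 2
            + (c[2] / (0.48 * nz)) ** 2
        )
    )
    lo, hi = b1_range
    b1 = hi - (hi - lo) * (rho / corner_rho) ** 2
    b1 = b1 * (1.0 / b1[int(c[0]), int(c[1]), int(c[2])])
    b1 = np.clip(b1, lo, hi)

    rng = np.random.default_rng(seed)
    # slowly varying phase: low-order random polynomial of the coordinates
    coeff = rng.normal(0, 0.2, size=4)
    xn, yn, zn = (idx[i] / shape[i] - 0.5 for i in range(3))
    phase = coeff[0] + coeff[1] * xn + coeff[2] * yn + coeff[3] * zn

    table = {
        1: {"name": "GM", "reference_t1_ms": t1_gm_ms, "concentration_mM": float("nan")},
        2: {"name": "WM", "reference_t1_ms": t1_wm_ms, "concentration_mM": float("nan")},
    }
    return PhantomVolume(
        t1_ms=t1, s0=s0, ba_per_deg=ba, b1_scale=b1, phase_rad=phase,
        labels=labels, voxel_size_mm=tuple(voxel_size_mm), region_table=table,
    )


_VOLUME_KEYS = ("t1_ms", "s0", "ba_per_deg", "b1_scale", "phase_rad", "labels")


def save_phantom(phantom: PhantomVolume, directory) -> None:
    """Persist a phantom as a directory of NIfTI volumes + JSON region table."""
    from .io import write_nifti

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for key in _VOLUME_KEYS:
        write_nifti(getattr(phantom, key), directory / f"{key}.nii", phantom.voxel_size_mm)
    meta = {
        "voxel_size_mm": list(phantom.voxel_size_mm),
        "region_table": {str(k): v for k, v in phantom.region_table.items()},
    }
    (directory / "regions.json").write_text(json.dumps(meta, indent=2))


def load_phantom(directory) -> PhantomVolume:
    from .io import read_nifti

    directory = Path(directory)
    meta = json.loads((directory / "regions.json").read_text())
    vols = {}
    for key in _VOLUME_KEYS:
        vols[key], _ = read_nifti(directory / f"{key}.nii")
    vols["labels"] = vols["labels"].astype(np.int32)
    return PhantomVolume(
        **vols,
        voxel_size_mm=tuple(meta["voxel_size_mm"]),
        region_table={int(k): v for k, v in meta["region_table"].items()},
    )
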