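"""Acquisition protocols and slice-offset inversion-time scheduling.

In multi-slice multi-shot inversion-recovery EPI (MS-IR-EPI) a non-selective
inversion pulse is followed by one slice-selective 90deg excitation per
"excitation slot"; the TR period is densely packed with
``n_slices / sms_factor`` such slots.  Each slice therefore experiences a
single inversion time (TI) per acquired volume, set by the slot it occupies.
Repeating the volume acquisition with the slice order shifted by a constant
slot offset gives every slice a set of equally spaced, distinct TIs from
which a T1 recovery curve can be fitted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionProtocol",
    "TISchedule",
    "build_ti_schedule",
    "fs_pulse_rate",
    "load_protocol",
    "save_protocol",
]


class ProtocolError(ValueError):
    """Raised when an acquisition protocol violates its invariants."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and geometry of one MS-IR-EPI run.

    Parameters
    ----------
    tr_ms:
        Repetition time between successive inversion pulses (ms).
    n_slices:
        Number of imaged slices.
    sms_factor:
        Simultaneous multi-slice factor (>= 1).  Slices in an SMS group are
        excited together and share a TI.
    slice_offsets:
        Ordered slot offsets, one per repeated acquisition.  May be
        fractional (used to re-space reduced-TI schedules); integer offsets
        reproduce the scanner behaviour.
    min_ti_ms:
        Inversion time of the first excitation slot (ms).
    fs_flip_angle_deg:
        Nominal flip angle of the spectrally selective fat-suppression
        (SPIR) pulse; 0 disables fat suppression.
    fs_duty:
        Fraction of excitations preceded by an FS pulse (1.0 default; 0.5
        for the alternate-pulse scheme that exactly halves MT effects).
    inversion_efficiency:
        Fraction of full inversion achieved by the adiabatic pulse, in (0, 1].
    slice_gap_mm:
        Gap between slices (bookkeeping only).
    acq_minutes:
        Total acquisition duration in minutes (used for SNR per unit time).
    """

    tr_ms: float
    n_slices: int
    sms_factor: int = 1
    slice_offsets: tuple = (0,)
    min_ti_ms: float = 44.5
    fs_flip_angle_deg: float = 0.0
    fs_duty: float = 1.0
    inversion_efficiency: float = 1.0
    slice_gap_mm: float = 0.0
    acq_minutes: float = float("nan")

    def __post_init__(self):
        object.__setattr__(self, "slice_offsets", tuple(float(o) for o in self.slice_offsets))
        if self.tr_ms <= 0:
            raise ProtocolError(f"tr_ms must be positive, got {self.tr_ms}")
        if self.n_slices < 1:
            raise ProtocolError(f"n_slices must be >= 1, got {self.n_slices}")
        if self.sms_factor < 1:
            raise ProtocolError(f"sms_factor must be >= 1, got {self.sms_factor}")
        if self.n_slices % self.sms_factor != 0:
            raise ProtocolError(
                f"n_slices ({self.n_slices}) is not divisible by "
                f"sms_factor ({self.sms_factor})"
            )
        if not 0 < self.min_ti_ms < self.tr_ms:
            raise ProtocolError(
                f"min_ti_ms ({self.min_ti_ms}) must lie in (0, tr_ms={self.tr_ms})"
            )
        if not self.slice_offsets:
            raise ProtocolError("slice_offsets must contain at least one offset")
        n_slots = self.n_slots
        for o in self.slice_offsets:
            if not 0 <= o < n_slots:
                raise ProtocolError(
                    f"slice offset {o} out of range [0, {n_slots})"
                )
        if len(set(self.slice_offsets)) != len(self.slice_offsets):
            raise ProtocolError("slice offsets must be distinct")
        if not 0.0 <= self.fs_duty <= 1.0:
            raise ProtocolError(f"fs_duty must lie in [0, 1], got {self.fs_duty}")
        if not 0.0 < self.inversion_efficiency <= 1.0:
            raise ProtocolError(
                f"inversion_efficiency must lie in (0, 1], got {self.inversion_efficiency}"
            )
        if self.fs_flip_angle_deg < 0:
            raise ProtocolError("fs_flip_angle_deg must be non-negative")

    @property
    def n_slots(self) -> int:
        """Number of excitation slots per TR."""
        return self.n_slices // self.sms_factor

    @property
    def n_acquisitions(self) -> int:
        return len(self.slice_offsets)

    @property
    def slot_duration_ms(self) -> float:
        return self.tr_ms / self.n_slots

    def excitation_group(self, slice_index) -> np.ndarray:
        """Excitation-slot group index g(s) of each slice.

        SMS groups are formed by slices {s, s + n_slots, s + 2*n_slots, ...},
        i.e. the simultaneously excited slices are evenly distributed across
        the volume, and the base (offset 0) order is ascending in g.
        """
        s = np.asarray(slice_index)
        if np.any((s < 0) | (s >= self.n_slices)):
            raise ProtocolError("slice index out of range")
        return s % self.n_slots

    def to_dict(self) -> dict:
        d = asdict(self)
        d["slice_offsets"] = list(self.slice_offsets)
        return d


@dataclass(frozen=True)
class TISchedule:
    """Per-slice inversion times across repeated acquisitions.

    ``ti_ms[s, k]`` is the inversion time of slice ``s`` in acquisition
    ``k``; ``slot_duration_ms`` is the spacing of the base slot grid.
    """

    ti_ms: np.ndarray
    slot_duration_ms: float
    min_ti_ms: float
    tr_ms: float

    @property
    def n_slices(self) -> int:
        return self.ti_ms.shape[0]

    @property
    def n_acquisitions(self) -> int:
        return self.ti_ms.shape[1]

    def slice_tis(self, slice_index: int, sort: bool = True) -> np.ndarray:
        tis = self.ti_ms[slice_index]
        return np.sort(tis) if sort else tis.copy()

    def spacing(self, slice_index: int = 0) -> float:
        """Common difference of a slice's sorted TIs.

        Raises ``ValueError`` when the spacing is not uniform.
        """
        tis = self.slice_tis(slice_index)
        if len(tis) < 2:
            raise ValueError("spacing needs at least two inversion times")
        diffs = np.diff(tis)
        if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-9):
            raise ValueError(f"non-uniform TI spacing: {diffs}")
        return float(diffs[0])

    def to_frame(self):
        """Long-format table with columns slice, acquisition, ti_ms."""
        import pandas as pd

        s, k = np.indices(self.ti_ms.shape)
        return pd.DataFrame(
            {
                "slice": s.ravel(),
                "acquisition": k.ravel(),
                "ti_ms": self.ti_ms.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr_ms: float, min_ti_ms: float | None = None) -> "TISchedule":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        required = {"slice", "acquisition", "ti_ms"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"schedule file {path} must contain columns {sorted(required)}"
            )
        n_s = int(df["slice"].max()) + 1
        n_k = int(df["acquisition"].max()) + 1
        ti = np.full((n_s, n_k), np.nan)
        ti[df["slice"].to_numpy(), df["acquisition"].to_numpy()] = df["ti_ms"].to_numpy()
        if np.isnan(ti).any():
            raise ValueError(f"schedule file {path} has missing (slice, acquisition) cells")
        if min_ti_ms is None:
            min_ti_ms = float(ti.min())
        # slot grid spacing recovered from the distinct TIs of one acquisition
        base = np.sort(np.unique(ti[:, 0]))
        slot = float(np.min(np.diff(base))) if len(base) > 1 else tr_ms
        return cls(ti_ms=ti, slot_duration_ms=slot, min_ti_ms=min_ti_ms, tr_ms=tr_ms)


def build_ti_schedule(protocol: AcquisitionProtocol) -> TISchedule:
    """Generate the slice-specific TI schedule implied by slice-offset cycling.

    Slice ``s`` in acquisition ``k`` occupies excitation slot
    ``(g(s) + offsets[k]) mod n_slots`` where ``g(s)`` is the slice's
    excitation-group index, so its inversion time is::

        ti[s, k] = min_ti + ((g(s) + offsets[k]) mod n_slots) * slot_duration

    All slices of an SMS group share identical TIs.  A warning is logged
    (not raised) when per-slice TI spacing is non-uniform.
    """
    n_slots = protocol.n_slots
    slot = protocol.slot_duration_ms
    g = protocol.excitation_group(np.arange(protocol.n_slices))
    offsets = np.asarray(protocol.slice_offsets, dtype=float)
    slots = np.mod(g[:, None] + offsets[None, :], n_slots)
    ti = protocol.min_ti_ms + slots * slot
    sched = TISchedule(
        ti_ms=ti,
        slot_duration_ms=slot,
        min_ti_ms=protocol.min_ti_ms,
        tr_ms=protocol.tr_ms,
    )
    if sched.n_acquisitions > 1:
        diffs = np.diff(np.sort(ti, axis=1), axis=1)
        if not np.allclose(diffs, diffs[:, :1], rtol=1e-9, atol=1e-6):
            logger.warning(
                "per-slice TI spacing is non-uniform for offsets %s", protocol.slice_offsets
            )
    return sched


def fs_pulse_rate(protocol: AcquisitionProtocol) -> float:
    """Fat-suppression pulses per second.

    One SPIR pulse precedes each excitation slot (scaled by the duty cycle),
    so the rate is ``fs_duty * n_slots / (tr_ms / 1000)``; zero when fat
    suppression is disabled.
    """
    if protocol.fs_flip_angle_deg == 0:
        return 0.0
    return protocol.fs_duty * protocol.n_slots / (protocol.tr_ms / 1000.0)


def save_protocol(protocol: AcquisitionProtocol, path) -> None:
    """Write a protocol as JSON or YAML depending on the file suffix."""
    path = Path(path)
    d = protocol.to_dict()
    # NaN is not valid JSON; omit unset optional duration
    if isinstance(d.get("acq_minutes"), float) and math.isnan(d["acq_minutes"]):
        del d["acq_minutes"]
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_protocol(path) -> AcquisitionProtocol:
    """Read a protocol from a JSON or YAML file with fields matching
    :class:`AcquisitionProtocol`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"protocol file not found: {path}")
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return AcquisitionProtocol(**d)
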