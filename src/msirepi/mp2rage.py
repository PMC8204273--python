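"""MP2RAGE forward model, combination image and lookup-table T1 estimation.

MP2RAGE acquires two GRE blocks per adiabatic inversion, at inversion times
TI1 and TI2, with small flip angles.  The bias-free combination

    S = Re( S_TI1 * conj(S_TI2) ) / (|S_TI1|^2 + |S_TI2|^2)   in [-0.5, 0.5]

encodes T1 monotonically over the physiological range and is inverted
through a precomputed lookup table.  Because the GRE trains repeatedly tip
the longitudinal magnetization, the effective flip angle (hence the lookup)
depends on the local transmit field; a B1 map selects the appropriate table
per voxel.

The steady state is solved in closed form: every sequence element (inversion,
free recovery, GRE train) acts on Mz as an affine map ``Mz -> A*Mz + B``, so
the periodic steady state is the fixed point of the composed map.  Blocks
are assumed centric-ordered: the stated TI marks the central k-space line,
acquired by the first excitation of the block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MP2RAGEParams",
    "LookupTable",
    "MP1_PARAMS",
    "mp2rage_combine",
    "mp2rage_forward",
    "build_lookup",
    "estimate_t1_mp2rage",
]

PHYSIO_T1_RANGE_MS = (500.0, 3000.0)


@dataclass(frozen=True)
class MP2RAGEParams:
    """Timing and flip angles of an MP2RAGE protocol.

    ``ordering`` states which excitation of a block acquires the central
    k-space line that defines the block's TI: ``"linear"`` (the standard
    published signal model; the TI marks the middle of the train) or
    ``"centric"`` (central line first, block starts at the TI).
    """

    tr_shot_s: float
    ti1_ms: float
    ti2_ms: float
    fa1_deg: float
    fa2_deg: float
    n_readouts: int
    echo_spacing_ms: float
    inversion_efficiency: float = 1.0
    ordering: str = "linear"

    def __post_init__(self):
        tr = self.tr_shot_s * 1000.0
        if self.ordering not in {"linear", "centric"}:
            raise ValueError("ordering must be 'linear' or 'centric'")
        if not 0 < self.ti1_ms < self.ti2_ms < tr:
            raise ValueError("require 0 < ti1 < ti2 < tr_shot")
        if self.n_readouts < 0 or self.echo_spacing_ms < 0:
            raise ValueError("n_readouts and echo_spacing_ms must be non-negative")
        if not 0 < self.inversion_efficiency <= 1:
            raise ValueError("inversion_efficiency must lie in (0, 1]")
        h = self.pre_center_pulses
        block = self.n_readouts * self.echo_spacing_ms
        start1 = self.ti1_ms - h * self.echo_spacing_ms
        start2 = self.ti2_ms - h * self.echo_spacing_ms
        if start1 < 0:
            raise ValueError("GRE block 1 starts before the inversion")
        if start1 + block > start2:
            raise ValueError("GRE block 1 overlaps block 2")
        if start2 + block > tr:
            raise ValueError("GRE block 2 overruns the shot")

    @property
    def pre_center_pulses(self) -> int:
        """Excitations played before the central k-space line of a block."""
        return self.n_readouts // 2 if self.ordering == "linear" else 0

    @property
    def tr_shot_ms(self) -> float:
        return self.tr_shot_s * 1000.0


# 0.7 mm whole-head protocol used for the 7 T comparison
MP1_PARAMS = MP2RAGEParams(
    tr_shot_s=5.0,
    ti1_ms=900.0,
    ti2_ms=2757.0,
    fa1_deg=5.0,
    fa2_deg=3.0,
    n_readouts=224,
    echo_spacing_ms=5.5,
)


@dataclass
class LookupTable:
    """Tabulated combination values with the invertible monotonic branch."""

    t1_grid_ms: np.ndarray
    s_mp2rage_values: np.ndarray
    b1_scale: float
    monotonic_range: tuple

    @property
    def branch(self):
        i, j = self.monotonic_range
        return self.t1_grid_ms[i:j], self.s_mp2rage_values[i:j]


def mp2rage_combine(s_ti1, s_ti2):
    """Bias-free combination of the two complex GRE images.

    ``Re(S1 * conj(S2)) / (|S1|^2 + |S2|^2)``, bounded in [-0.5, 0.5] and
    defined as 0 where both inputs vanish.
    """
    s1 = np.asarray(s_ti1, dtype=complex)
    s2 = np.asarray(s_ti2, dtype=complex)
    num = np.real(s1 * np.conj(s2))
    den = np.abs(s1) ** 2 + np.abs(s2) ** 2
    out = np.zeros(np.broadcast(s1, s2).shape)
    np.divide(num, den, out=out, where=den > 0)
    if out.ndim == 0:
        return float(out)
    return out


def _gre_block(a, b, cos_fa, e_esp, n):
    """Affine Mz map of an n-pulse GRE train with echo spacing relaxation.

    One repetition is pulse (Mz *= cos) then relaxation over the echo
    spacing; the closed form uses the geometric sum of the per-repetition
    gain ``g = cos_fa * e_esp``.
    """
    if n == 0:
        return a, b
    g = np.asarray(cos_fa * e_esp)
    gn = g**n
    one_minus_g = 1.0 - g
    series = np.where(
        np.abs(one_minus_g) < 1e-15,
        float(n),
        (1.0 - gn) / np.where(np.abs(one_minus_g) < 1e-15, 1.0, one_minus_g),
    )
    return a * gn, b * gn + (1.0 - e_esp) * series


def mp2rage_forward(t1_ms, params: MP2RAGEParams, b1_scale=1.0):
    """Steady-state GRE signals and combination value for a given T1.

    Returns ``(gre1, gre2, combination)``; scalar inputs give scalars,
    array T1 gives arrays.  Flip angles are scaled by ``b1_scale``; the
    adiabatic inversion is not (its efficiency is a separate parameter).
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    fa1 = np.deg2rad(params.fa1_deg * b1_scale)
    fa2 = np.deg2rad(params.fa2_deg * b1_scale)
    e = params.inversion_efficiency
    esp = params.echo_spacing_ms
    n = params.n_readouts
    h = params.pre_center_pulses  # pulses before the central line
    block_ms = n * esp
    start1 = params.ti1_ms - h * esp
    start2 = params.ti2_ms - h * esp
    gaps = (
        start1,  # inversion -> block 1 first excitation
        start2 - (start1 + block_ms),
        params.tr_shot_ms - (start2 + block_ms),
    )

    def relax(a, b, t):
        et = np.exp(-t / t1)
        return a * et, b * et + (1.0 - et)

    e_esp = np.exp(-esp / t1)
    # compose the affine cycle starting just after the inversion
    a, b = np.full_like(t1, -e), np.zeros_like(t1)
    a, b = relax(a, b, gaps[0])
    a, b = _gre_block(a, b, np.cos(fa1), e_esp, h)
    a1, b1 = a, b  # Mz at the central line of block 1
    a, b = _gre_block(a, b, np.cos(fa1), e_esp, n - h)
    a, b = relax(a, b, gaps[1])
    a, b = _gre_block(a, b, np.cos(fa2), e_esp, h)
    a2, b2 = a, b  # Mz at the central line of block 2
    a, b = _gre_block(a, b, np.cos(fa2), e_esp, n - h)
    a, b = relax(a, b, gaps[2])

    # fixed point of Mz -> a*Mz + b over one shot (Mz measured pre-inversion)
    mz_pre = b / (1.0 - a)
    mz1 = a1 * mz_pre + b1
    mz2 = a2 * mz_pre + b2
    gre1 = np.sin(fa1) * mz1
    gre2 = np.sin(fa2) * mz2
    comb = mp2rage_combine(gre1 + 0j, gre2 + 0j)
    if np.isscalar(t1_ms) or np.ndim(t1_ms) == 0:
        return float(gre1), float(gre2), float(comb)
    return gre1, gre2, np.asarray(comb)


def build_lookup(params: MP2RAGEParams, b1_scale=1.0, t1_grid_ms=None) -> LookupTable:
    """Tabulate the forward combination over a T1 grid.

    The invertible branch is the longest contiguous strictly monotonic run
    of the tabulated values that intersects the physiological T1 range
    (500-3000 ms).
    """
    if t1_grid_ms is None:
        t1_grid_ms = np.arange(100.0, 6000.1, 5.0)
    grid = np.asarray(t1_grid_ms, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("t1_grid_ms must be strictly ascending")
    _, _, vals = mp2rage_forward(grid, params, b1_scale)
    vals = np.atleast_1d(vals)
    if len(grid) == 1:
        return LookupTable(grid, vals, b1_scale, (0, 1))
    d = np.sign(np.diff(vals))
    runs = []
    start = 0
    for i in range(1, len(d)):
        if d[i] != d[start] or d[i] == 0:
            runs.append((start, i + 1))
            start = i
    runs.append((start, len(d) + 1))
    lo, hi = PHYSIO_T1_RANGE_MS
    best, best_overlap = None, -1.0
    for i, j in runs:
        if np.any(d[i:j - 1] == 0):
            continue
        overlap = min(grid[j - 1], hi) - max(grid[i], lo)
        if overlap <= 0:
            continue
        # prefer the branch covering most of the physiological range,
        # breaking ties by total length
        if overlap > best_overlap or (
            overlap == best_overlap and best is not None and (j - i) > (best[1] - best[0])
        ):
            best, best_overlap = (i, j), overlap
    if best is None:
        raise ValueError("no strictly monotonic branch intersects 500-3000 ms")
    return LookupTable(grid, vals, b1_scale, best)


def _invert_table(table: LookupTable, values):
    t1b, sb = table.branch
    if sb[0] > sb[-1]:  # np.interp needs ascending x
        sb, t1b = sb[::-1], t1b[::-1]
    v = np.asarray(values, dtype=float)
    out = np.interp(v, sb, t1b, left=np.nan, right=np.nan)
    return out


def estimate_t1_mp2rage(
    combination,
    params: MP2RAGEParams,
    b1_map=None,
    t1_grid_ms=None,
    b1_levels=21,
    b1_range=(0.5, 1.5),
):
    """Lookup-table T1 estimation with per-voxel B1 correction.

    A small bank of tables at evenly spaced B1 levels is built; each voxel
    is inverted through the table nearest to its X value (X = 1 with a
    warning when no B1 map is given).  Combination values outside the
    invertible branch map to NaN.  Returns ``(t1_map, valid_mask)``.
    """
    comb = np.asarray(combination, dtype=float)
    if np.any(np.abs(comb[np.isfinite(comb)]) > 0.5 + 1e-9):
        raise ValueError("combination values must lie in [-0.5, 0.5]")
    if b1_map is None:
        logger.warning("no B1 map provided; assuming X(r) = 1 everywhere")
        levels = np.array([1.0])
        assign = np.zeros(comb.shape, dtype=int)
    else:
        x = np.asarray(b1_map, dtype=float)
        if x.shape != comb.shape:
            raise ValueError("B1 map shape does not match the combination map")
        levels = np.linspace(b1_range[0], b1_range[1], b1_levels)
        assign = np.argmin(np.abs(x[..., None] - levels[None, :]), axis=-1)
    t1 = np.full(comb.shape, np.nan)
    for i, lev in enumerate(levels):
        sel = assign == i
        if not np.any(sel):
            continue
        table = build_lookup(params, b1_scale=lev, t1_grid_ms=t1_grid_ms)
        t1[sel] = _invert_table(table, comb[sel])
    valid = np.isfinite(t1)
    return t1, valid
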