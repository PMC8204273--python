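"""Polarity restoration and voxel-wise mono-exponential T1 fitting.

The acquired data are complex; the recovery curve changes sign at the null
point, so the magnitude alone is not fittable by the signed model.  The
phase of the longest-TI acquisition (far from any null for tissue T1s)
serves as the per-voxel reference: samples whose phase lies within pi/2 of
the reference are positive, the rest negative.  The signed data are then fit
voxel-wise to

    S(TI) = S0 * [1 - 2 exp(-TI/T1) + exp(-TR/T1)]

by damped Gauss-Newton (Levenberg-Marquardt) least squares, vectorised
across voxels.  A dictionary (lookup-table) fit over a T1 grid is provided
as a fast alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ComplexSeries
from .protocol import TISchedule

__all__ = [
    "FitResult",
    "restore_polarity",
    "fit_t1_map",
    "fit_t1_curves",
    "lut_fit_t1",
    "fit_t1_volume",
]

T1_BOUNDS_MS = (1.0, 20000.0)


@dataclass
class FitResult:
    """Voxel-wise fit outputs; invalid voxels carry NaN."""

    t1_ms: np.ndarray
    s0: np.ndarray
    rss: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray


def restore_polarity(series, schedule: TISchedule | None = None):
    """Restore the sign of magnitude data from complex phase.

    Parameters
    ----------
    series:
        :class:`~msirepi.forward.ComplexSeries` or a complex ndarray whose
        last axis is the acquisition axis (then ``schedule`` is required).

    Returns
    -------
    signed : ndarray
        Signed magnitudes, same shape as the input data.
    zero_mask : ndarray (bool)
        True where the reference sample was zero (sign defaulted to +1).
    """
    if isinstance(series, ComplexSeries):
        data = series.data
        schedule = series.schedule
    else:
        data = np.asarray(series)
        if schedule is None:
            raise ValueError("schedule is required when passing a bare array")
    if data.shape[-1] < 2:
        raise ValueError("polarity restoration needs at least 2 acquisitions")

    # reference acquisition per slice: the one with the largest TI
    ref_idx = np.argmax(schedule.ti_ms, axis=1)  # (n_slices,)
    signed = np.empty(data.shape, dtype=float)
    zero_mask = np.zeros(data.shape[:-1], dtype=bool)
    # slice axis is -2 by convention (x, y, slice, acq); handle (N, acq) too
    if data.ndim >= 2 and data.shape[-2] == schedule.n_slices:
        slices = range(schedule.n_slices)
        for s in slices:
            d = data[..., s, :]
            ref = d[..., ref_idx[s]]
            signed[..., s, :], zero_mask[..., s] = _sign_from_phase(d, ref)
    else:
        raise ValueError(
            f"data shape {data.shape} does not carry {schedule.n_slices} slices "
            "on the second-to-last axis"
        )
    return signed, zero_mask


def restore_polarity_curves(data: np.ndarray, ref_index: int):
    """Polarity restoration for a batch of single-slice curves (N, n_ti)."""
    ref = data[..., ref_index]
    return _sign_from_phase(data, ref)


def _sign_from_phase(d, ref):
    zero = ref == 0
    phi_ref = np.angle(np.where(zero, 1.0, ref))
    dphi = np.angle(d) - phi_ref[..., None]
    # principal value in (-pi, pi]
    dphi = np.mod(dphi + np.pi, 2 * np.pi) - np.pi
    sign = np.where(np.abs(dphi) < np.pi / 2, 1.0, -1.0)
    return sign * np.abs(d), zero


def _model_and_jac(tis, tr_ms, s0, t1):
    e_ti = np.exp(-tis[None, :] / t1[:, None])
    e_tr = np.exp(-tr_ms / t1)[:, None]
    base = 1.0 - 2.0 * e_ti + e_tr
    f = s0[:, None] * base
    df_ds0 = base
    df_dt1 = s0[:, None] * (
        -2.0 * e_ti * tis[None, :] / t1[:, None] ** 2
        + e_tr * tr_ms / t1[:, None] ** 2
    )
    return f, df_ds0, df_dt1


def _lm_fit(y, tis, tr_ms, s0_init, t1_init, rtol=1e-8, max_iter=200):
    """Batch Levenberg-Marquardt for the 2-parameter IR model.

    ``y`` has shape (N, n_ti).  Bounds on T1 are enforced by projection.
    Returns (s0, t1, rss, converged).
    """
    lo, hi = T1_BOUNDS_MS
    s0 = np.asarray(s0_init, dtype=float).copy()
    t1 = np.clip(np.asarray(t1_init, dtype=float), lo, hi).copy()
    n = y.shape[0]
    lam = np.full(n, 1e-3)
    f, j0, j1 = _model_and_jac(tis, tr_ms, s0, t1)
    r = f - y
    rss = np.einsum("ij,ij->i", r, r)
    active = np.ones(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        ya, ra = y[active], r[active]
        j0a, j1a = j0[active], j1[active]
        a00 = np.einsum("ij,ij->i", j0a, j0a)
        a01 = np.einsum("ij,ij->i", j0a, j1a)
        a11 = np.einsum("ij,ij->i", j1a, j1a)
        g0 = np.einsum("ij,ij->i", j0a, ra)
        g1 = np.einsum("ij,ij->i", j1a, ra)
        la = lam[active]
        d00 = a00 * (1 + la)
        d11 = a11 * (1 + la)
        det = d00 * d11 - a01 * a01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step0 = -(d11 * g0 - a01 * g1) / det
        step1 = -(-a01 * g0 + d00 * g1) / det
        s0_new = s0[active] + step0
        t1_new = np.clip(t1[active] + step1, lo, hi)
        f_new, j0_new, j1_new = _model_and_jac(tis, tr_ms, s0_new, t1_new)
        r_new = f_new - ya
        rss_new = np.einsum("ij,ij->i", r_new, r_new)
        improved = rss_new < rss[active]

        idx = np.flatnonzero(active)
        imp_idx = idx[improved]
        rej_idx = idx[~improved]
        # accepted steps
        if imp_idx.size:
            rel = np.maximum(
                np.abs(step0[improved]) / np.maximum(np.abs(s0_new[improved]), 1e-12),
                np.abs(step1[improved]) / np.maximum(np.abs(t1_new[improved]), 1e-12),
            )
            s0[imp_idx] = s0_new[improved]
            t1[imp_idx] = t1_new[improved]
            r[imp_idx] = r_new[improved]
            j0[imp_idx] = j0_new[improved]
            j1[imp_idx] = j1_new[improved]
            rss[imp_idx] = rss_new[improved]
            lam[imp_idx] = np.maximum(lam[imp_idx] * 0.3, 1e-12)
            done = rel < rtol
            converged[imp_idx[done]] = True
            active[imp_idx[done]] = False
        # rejected steps: increase damping
        if rej_idx.size:
            lam[rej_idx] = lam[rej_idx] * 10.0
            stuck = lam[rej_idx] > 1e12
            # damping exhausted: local minimum reached
            converged[rej_idx[stuck]] = True
            active[rej_idx[stuck]] = False
    return s0, t1, rss, converged


def _initial_guess(y, tis):
    """T1 from the null-point long-TR approximation, S0 from the plateau."""
    i_null = np.argmin(np.abs(y), axis=1)
    t1_init = np.clip(tis[i_null] / np.log(2.0), *T1_BOUNDS_MS)
    s0_init = np.max(np.abs(y), axis=1)
    return s0_init, t1_init


def fit_t1_curves(
    y: np.ndarray,
    tis: np.ndarray,
    tr_ms: float,
    refit_null: bool = True,
    noise_floor: float | None = None,
    rtol: float = 1e-8,
):
    """Fit a batch of signed recovery curves sharing one TI vector.

    ``y`` has shape (N, n_ti).  When ``refit_null`` is set, voxels whose
    minimum-|S| sample lies within the noise floor (all voxels if
    ``noise_floor`` is None) are fitted a second time with that sample's
    sign flipped and the lower-RSS solution kept — the sample nearest the
    null is the one whose restored sign is least reliable.

    Returns (s0, t1, rss, valid).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    tis = np.asarray(tis, dtype=float)
    if y.shape[1] != tis.shape[0]:
        raise ValueError(f"{y.shape[1]} samples but {tis.shape[0]} inversion times")
    if y.shape[1] < 3:
        raise ValueError("at least 3 samples are required for a 2-parameter fit")
    nonzero = np.any(y != 0, axis=1)
    s0_init, t1_init = _initial_guess(y, tis)
    s0, t1, rss, conv = _lm_fit(y, tis, tr_ms, s0_init, t1_init, rtol=rtol)

    if refit_null:
        i_null = np.argmin(np.abs(y), axis=1)
        if noise_floor is None:
            candidates = nonzero.copy()
        else:
            candidates = nonzero & (
                np.abs(y[np.arange(len(y)), i_null]) < 2.0 * noise_floor
            )
        if candidates.any():
            y2 = y[candidates].copy()
            rows = np.arange(y2.shape[0])
            y2[rows, i_null[candidates]] *= -1.0
            s0b_init, t1b_init = _initial_guess(y2, tis)
            s0b, t1b, rssb, convb = _lm_fit(y2, tis, tr_ms, s0b_init, t1b_init, rtol=rtol)
            better = rssb < rss[candidates]
            idx = np.flatnonzero(candidates)[better]
            s0[idx] = s0b[better]
            t1[idx] = t1b[better]
            rss[idx] = rssb[better]
            conv[idx] = convb[better]

    lo, hi = T1_BOUNDS_MS
    valid = conv & nonzero & (t1 > lo) & (t1 < hi)
    s0 = np.where(valid, s0, np.nan)
    t1 = np.where(valid, t1, np.nan)
    rss = np.where(valid, rss, np.nan)
    return s0, t1, rss, valid


def fit_t1_map(
    signed_series: np.ndarray,
    schedule: TISchedule,
    tr_ms: float,
    mask: np.ndarray | None = None,
    refit_null: bool = True,
    noise_floor: float | None = None,
) -> FitResult:
    """Voxel-wise two-parameter IR fit with slice-specific inversion times.

    ``signed_series`` is (x, y, slice, acquisition) polarity-restored data.
    Voxels outside ``mask`` (or all-zero voxels) are invalid, with NaN maps.
    R^2 is computed against the mean-signal baseline of the signed data.
    """
    data = np.asarray(signed_series, dtype=float)
    if data.ndim != 4:
        raise ValueError("signed_series must be 4-D (x, y, slice, acquisition)")
    if data.shape[2] != schedule.n_slices or data.shape[3] != schedule.n_acquisitions:
        raise ValueError(
            f"series shape {data.shape} inconsistent with schedule "
            f"({schedule.n_slices} x {schedule.n_acquisitions})"
        )
    vol_shape = data.shape[:3]
    t1_map = np.full(vol_shape, np.nan)
    s0_map = np.full(vol_shape, np.nan)
    rss_map = np.full(vol_shape, np.nan)
    r2_map = np.full(vol_shape, np.nan)
    valid_map = np.zeros(vol_shape, dtype=bool)

    for s in range(schedule.n_slices):
        sel = np.ones(vol_shape[:2], dtype=bool) if mask is None else mask[:, :, s]
        sel = sel & np.any(data[:, :, s, :] != 0, axis=-1)
        if not sel.any():
            continue
        y = data[:, :, s, :][sel]
        tis = schedule.ti_ms[s]
        order = np.argsort(tis)
        s0, t1, rss, valid = fit_t1_curves(
            y[:, order], tis[order], tr_ms,
            refit_null=refit_null, noise_floor=noise_floor,
        )
        tss = np.einsum("ij,ij->i", y - y.mean(axis=1, keepdims=True),
                        y - y.mean(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = 1.0 - rss / tss
        t1_map[:, :, s][sel] = t1
        s0_map[:, :, s][sel] = s0
        rss_map[:, :, s][sel] = rss
        r2_map[:, :, s][sel] = r2
        valid_map[:, :, s][sel] = valid
    return FitResult(t1_ms=t1_map, s0=s0_map, rss=rss_map, r_squared=r2_map, valid=valid_map)


def lut_fit_t1(
    y: np.ndarray,
    tis: np.ndarray,
    tr_ms: float,
    t1_grid_ms: np.ndarray | None = None,
):
    """Dictionary (lookup-table) T1 estimation: nearest match over a T1 grid.

    For each grid T1 the amplitude S0 is profiled out analytically, so the
    match minimises the exact least-squares objective restricted to the
    grid.  Returns (s0, t1, rss).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    tis = np.asarray(tis, dtype=float)
    if t1_grid_ms is None:
        t1_grid_ms = np.geomspace(50.0, 10000.0, 2048)
    grid = np.asarray(t1_grid_ms, dtype=float)
    # dictionary of unit-amplitude signals, (G, n_ti)
    d = (
        1.0
        - 2.0 * np.exp(-tis[None, :] / grid[:, None])
        + np.exp(-tr_ms / grid)[:, None]
    )
    dd = np.einsum("gj,gj->g", d, d)  # (G,)
    yd = y @ d.T  # (N, G)
    yy = np.einsum("ij,ij->i", y, y)  # (N,)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = yy[:, None] - yd**2 / dd[None, :]
    best = np.argmin(rss, axis=1)
    rows = np.arange(y.shape[0])
    s0 = yd[rows, best] / dd[best]
    return s0, grid[best], rss[rows, best]


def fit_t1_volume(
    series: ComplexSeries,
    mask: np.ndarray | None = None,
    refit_null: bool = True,
    noise_floor: float | None = None,
) -> FitResult:
    """Polarity restoration followed by the voxel-wise T1 fit."""
    signed, _ = restore_polarity(series)
    return fit_t1_map(
        signed,
        series.schedule,
        series.protocol.tr_ms,
        mask=mask,
        refit_null=refit_null,
        noise_floor=noise_floor,
    )
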