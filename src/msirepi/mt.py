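"""Magnetization-transfer correction of fat-suppression effects on R1.

Spectrally selective fat-suppression (SPIR) pulses accelerate the apparent
longitudinal relaxation through magnetization transfer.  The measured rate
is modelled as linear in the pulse flip angle,

    R1(r) = alpha(r) + beta(r) * FA * X(r),        alpha = a*m(r), beta = b*m(r)

so a least-squares regression of R1 against FA*X(r) per voxel yields the
intercept alpha, slope beta and their ratio b/a.  The corrected (intrinsic)
rate removes the MT contribution by division:

    R1_corr(r) = R1(r) / (1 + (b/a) * FA * X(r)).

The global variant replaces the voxel-wise b/a map by a single scalar taken
from the dominant mode of a two-Gaussian mixture fitted to the brain-wide
b/a distribution.  A paired acquisition with the fat-suppression pulse on
every alternate excitation (duty 0.5) halves the MT increment exactly and
gives a closed-form two-point solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "MTModelFit",
    "fit_ba_map",
    "smooth_ba_map",
    "global_ba",
    "correct_r1_map",
    "ba_from_half_rate",
]

DEFAULT_GLOBAL_BA_PER_DEG = 0.0045
"""Across-subject mean b/a (deg^-1); may vary by cohort, sequence and
scanner — always overridable with calibration data."""


@dataclass
class MTModelFit:
    """Voxel-wise linear MT model fit and the derived global scalar."""

    alpha_per_s: np.ndarray
    beta_per_s_deg: np.ndarray
    ba_per_deg: np.ndarray
    fit_r2: np.ndarray
    valid: np.ndarray
    global_ba_per_deg: float | None = None
    mixture: dict | None = None


def fit_ba_map(r1_maps, fa_list_deg, b1_map=None) -> MTModelFit:
    """Voxel-wise OLS of R1 against FA*X(r) over the acquired flip angles.

    ``r1_maps`` is a sequence of co-registered R1 volumes (s^-1), one per
    nominal SPIR flip angle in ``fa_list_deg``.  Voxels with non-positive
    intercept are flagged invalid.  At least two distinct flip angles are
    required.
    """
    maps = [np.asarray(m, dtype=float) for m in r1_maps]
    fas = np.asarray(fa_list_deg, dtype=float)
    if len(maps) != len(fas):
        raise ValueError("one R1 map per flip angle is required")
    if len(set(fas.tolist())) < 2:
        raise ValueError(
            "at least two acquisitions with distinct flip angles are required"
        )
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("R1 maps are not co-registered (shape mismatch)")
    if b1_map is None:
        logger.warning("no B1 map provided; assuming X(r) = 1 everywhere")
        x = np.ones(shape)
    else:
        x = np.asarray(b1_map, dtype=float)
        if x.shape != shape:
            raise ValueError("B1 map shape does not match the R1 maps")

    y = np.stack(maps, axis=-1)  # (..., n_fa)
    reg = fas[None, :] * x.reshape(-1, 1)  # per-voxel regressor FA*X
    yy = y.reshape(-1, len(fas))
    n = len(fas)
    sx = reg.sum(axis=1)
    sxx = np.einsum("ij,ij->i", reg, reg)
    sy = yy.sum(axis=1)
    sxy = np.einsum("ij,ij->i", reg, yy)
    denom = n * sxx - sx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (n * sxy - sx * sy) / denom
        alpha = (sy - beta * sx) / n
        resid = yy - (alpha[:, None] + beta[:, None] * reg)
        rss = np.einsum("ij,ij->i", resid, resid)
        tss = np.einsum("ij,ij->i", yy - (sy / n)[:, None], yy - (sy / n)[:, None])
        r2 = 1.0 - rss / tss
        ba = beta / alpha
    valid = np.isfinite(alpha) & (alpha > 0) & np.isfinite(beta)
    alpha = np.where(valid, alpha, np.nan).reshape(shape)
    beta = np.where(valid, beta, np.nan).reshape(shape)
    ba = np.where(valid, ba, np.nan).reshape(shape)
    r2 = np.where(valid, r2, np.nan).reshape(shape)
    return MTModelFit(
        alpha_per_s=alpha,
        beta_per_s_deg=beta,
        ba_per_deg=ba,
        fit_r2=r2,
        valid=valid.reshape(shape),
    )


def smooth_ba_map(ba_map, fwhm_mm, voxel_size_mm, mask=None) -> np.ndarray:
    """Mask-normalised Gaussian smoothing of a b/a map.

    ``sigma = FWHM / (2 sqrt(2 ln 2))`` per axis, converted to voxels.
    Smoothing weights are renormalised over valid (finite, in-mask) voxels
    so edges are not pulled toward zero; ``fwhm_mm = 0`` is the identity.
    """
    ba = np.asarray(ba_map, dtype=float)
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return ba.copy()
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (ba.ndim,))
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vox
    w = np.isfinite(ba)
    if mask is not None:
        w = w & np.asarray(mask, dtype=bool)
    filled = np.where(w, ba, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(w.astype(float), sigma=sigma_vox, mode="constant")
    out = np.full_like(ba, np.nan)
    inside = den > 1e-12
    out[inside] = num[inside] / den[inside]
    out[~w & np.isfinite(ba)] = ba[~w & np.isfinite(ba)]  # outside mask: passthrough
    out[~np.isfinite(ba)] = np.nan
    return out


def global_ba(ba_map, tissue_mask=None, n_components=2, seed=0):
    """Global b/a scalar from a two-Gaussian mixture of the masked values.

    The mixture is fit by EM and the returned scalar is the mode of the
    fitted mixture density (its argmax over the data range).  For well
    separated components this is the mode of the highest-amplitude
    Gaussian — the component with the greater peak density
    ``weight / (sigma*sqrt(2*pi))``, not the heaviest component — while for
    overlapping components it estimates the distribution peak without
    splitting artefacts.  Degenerate fits fall back to the histogram mode
    with a warning.  Returns ``(scalar, mixture_dict)``; the dict reports
    the component parameters and which component carries the highest peak.
    """
    ba = np.asarray(ba_map, dtype=float)
    if tissue_mask is not None:
        ba = ba[np.asarray(tissue_mask, dtype=bool)]
    vals = ba[np.isfinite(ba)]
    if vals.size == 0:
        raise ValueError("empty mask: no valid b/a values")
    if vals.size < 100:
        raise ValueError(f"at least 100 valid voxels required, got {vals.size}")

    if np.ptp(vals) == 0:
        mix = {
            "weights": [1.0],
            "means": [float(vals[0])],
            "stds": [0.0],
            "fallback": "identical-values",
        }
        return float(vals[0]), mix

    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=n_components, covariance_type="full", random_state=seed,
        n_init=3, reg_covar=1e-12,
    )
    gm.fit(vals.reshape(-1, 1))
    weights = gm.weights_.ravel()
    means = gm.means_.ravel()
    stds = np.sqrt(gm.covariances_.ravel())
    mix = {
        "weights": weights.tolist(),
        "means": means.tolist(),
        "stds": stds.tolist(),
    }
    if np.any(stds < 1e-12 * max(np.std(vals), 1e-30)) or not np.all(np.isfinite(stds)):
        logger.warning("degenerate mixture fit; falling back to histogram mode")
        hist, edges = np.histogram(vals, bins="auto")
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        mix["fallback"] = "histogram-mode"
        return float(mode), mix
    peak_density = weights / (stds * np.sqrt(2.0 * np.pi))
    mix["dominant_component"] = int(np.argmax(peak_density))
    # mode of the mixture density on a fine grid over the data range
    grid = np.linspace(vals.min(), vals.max(), 4096)
    pdf = np.zeros_like(grid)
    for w, mu, sd in zip(weights, means, stds):
        pdf += w / (sd * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((grid - mu) / sd) ** 2)
    return float(grid[np.argmax(pdf)]), mix


def correct_r1_map(r1_map, ba, fa_deg, b1_map=None, fs_duty=1.0):
    """Remove the fat-suppression MT contribution from a measured R1 map.

    ``R1_corr = R1 / (1 + ba * duty * FA * X(r))``; ``ba`` may be a scalar
    (global correction) or a map (voxel-wise correction).  Voxels whose
    denominator is non-positive are set to NaN.  Returns
    ``(r1_corrected, valid_mask)``.
    """
    r1 = np.asarray(r1_map, dtype=float)
    if fa_deg < 0:
        raise ValueError("fa_deg must be non-negative")
    if b1_map is None:
        if fa_deg > 0:
            logger.warning("no B1 map provided; assuming X(r) = 1 everywhere")
        x = 1.0
    else:
        x = np.asarray(b1_map, dtype=float)
    denom = 1.0 + np.asarray(ba) * fs_duty * fa_deg * x
    denom = np.broadcast_to(denom, r1.shape)
    valid = denom > 0
    out = np.full(r1.shape, np.nan)
    np.divide(r1, denom, out=out, where=valid)
    return out, valid & np.isfinite(out)


def ba_from_half_rate(r1_full, r1_half, fa_deg, b1_map=None):
    """Closed-form (b/a, intrinsic R1) from a duty-1 / duty-0.5 map pair.

    With q = ba*FA*X the two measurements are R1_full = R1_0 (1 + q) and
    R1_half = R1_0 (1 + q/2), giving exactly

        R1_0 = 2*R1_half - R1_full,      q = 2 (R1_full - R1_half) / R1_0.

    Voxels with ``r1_half > r1_full`` (violating monotonicity) or
    ``R1_0 <= 0`` are invalid.  Returns ``(ba_map, r1_intrinsic, valid)``.
    """
    rf = np.asarray(r1_full, dtype=float)
    rh = np.asarray(r1_half, dtype=float)
    if rf.shape != rh.shape:
        raise ValueError("R1 map pair is not co-registered (shape mismatch)")
    if fa_deg <= 0:
        raise ValueError("fa_deg must be positive for the half-rate scheme")
    x = np.ones_like(rf) if b1_map is None else np.asarray(b1_map, dtype=float)
    r1_0 = 2.0 * rh - rf
    valid = (rh <= rf) & (r1_0 > 0) & (x > 0)
    q = np.full(rf.shape, np.nan)
    np.divide(2.0 * (rf - rh), r1_0, out=q, where=valid)
    ba = np.full(rf.shape, np.nan)
    np.divide(q, fa_deg * x, out=ba, where=valid)
    r1_0 = np.where(valid, r1_0, np.nan)
    return ba, r1_0, valid
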