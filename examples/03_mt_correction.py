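"""Magnetization-transfer correction of fat-suppression effects.

Fat-suppression (SPIR) pulses shorten the apparent T1 through MT.  This
script simulates the full flip-angle sweep (0-70 deg) on the brain phantom,
fits the linear model R1 = alpha + beta * FA * X(r) per voxel, extracts the
global b/a ratio from a two-Gaussian mixture, and corrects the FA = 70 deg
map back to the intrinsic T1.
"""

import numpy as np

import msirepi as m

phantom = m.make_brain_phantom(grid_shape=(24, 24, 8), seed=1)
fas = [0.0, 30.0, 40.0, 50.0, 60.0, 70.0]

r1_maps, valid = [], phantom.support
for fa in fas:
    proto = m.AcquisitionProtocol(
        tr_ms=5000.0, n_slices=8, slice_offsets=tuple(range(8)),
        min_ti_ms=44.5, fs_flip_angle_deg=fa,
    )
    fit = m.fit_t1_volume(m.simulate_series(phantom, proto, snr=None))
    r1_maps.append(np.where(fit.valid, 1000.0 / fit.t1_ms, np.nan))
    valid = valid & fit.valid

gm = (phantom.labels == 1) & valid
print("apparent GM T1 vs SPIR flip angle (MT shortens T1):")
for fa, r1 in zip(fas, r1_maps):
    print(f"  FA {fa:4.0f} deg: median T1 {np.median(1000.0 / r1[gm]):7.1f} ms")

ba_fit = m.fit_ba_map(r1_maps, fas, phantom.b1_scale)
gba, mixture = m.global_ba(ba_fit.ba_per_deg, ba_fit.valid & valid)
print(f"\nglobal b/a from the mixture mode: {gba:.5f} per degree "
      f"(phantom truth 0.00450)")

corrected, _ = m.correct_r1_map(r1_maps[-1], gba, 70.0, phantom.b1_scale)
t1_corr = 1000.0 / corrected
err = np.abs(t1_corr[gm] - phantom.t1_ms[gm]) / phantom.t1_ms[gm]
print(f"corrected FA=70 GM T1: median {np.median(t1_corr[gm]):.1f} ms "
      f"(intrinsic 1699); worst-voxel error {100 * np.nanmax(err):.3f}%")

# the paired half-duty scheme solves the same problem from two acquisitions
sup = phantom.support
r1_int = 1000.0 / phantom.t1_ms[sup]
x = phantom.b1_scale[sup]
full = m.apparent_r1(r1_int, 0.0045, 90.0, x, fs_duty=1.0)
half = m.apparent_r1(r1_int, 0.0045, 90.0, x, fs_duty=0.5)
ba_hr, r1_0, ok = m.ba_from_half_rate(full, half, 90.0, x)
print(f"\nhalf-rate closed form: b/a = {np.median(ba_hr):.5f} per degree, "
      f"intrinsic R1 recovered exactly ({np.allclose(r1_0, r1_int)})")
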