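"""Forward simulation and voxel-wise T1 fitting on a digital brain phantom.

Simulates a complex multi-slice IR-EPI series (8 TIs, TR 5 s) from a
two-tissue phantom with known T1, restores signal polarity from the phase,
fits the two-parameter recovery model per voxel, and compares the fitted
maps with the ground truth — first noiseless, then at SNR 25.
"""

import numpy as np

import msirepi as m

phantom = m.make_brain_phantom(grid_shape=(24, 24, 8), seed=1)
proto = m.AcquisitionProtocol(
    tr_ms=5000.0, n_slices=8, slice_offsets=tuple(range(8)), min_ti_ms=44.5,
)

for snr in (None, 25.0):
    series = m.simulate_series(phantom, proto, snr=snr, seed=7)
    fit = m.fit_t1_volume(series, noise_floor=None if snr is None else 1.0 / snr)
    label = "noiseless" if snr is None else f"SNR {snr:.0f}"
    print(f"--- {label} ---")
    for lab, name, truth in ((1, "GM", 1699.0), (2, "WM", 1135.0)):
        mask = (phantom.labels == lab) & fit.valid
        med = np.median(fit.t1_ms[mask])
        spread = np.percentile(fit.t1_ms[mask], [25, 75])
        print(f"  {name}: median fitted T1 {med:7.1f} ms (truth {truth:.0f}), "
              f"IQR [{spread[0]:.0f}, {spread[1]:.0f}] ms, "
              f"{int(mask.sum())} voxels")

print("\nnoiseless medians match truth to machine precision; at SNR 25 the "
      "median stays within a fraction of a percent while the IQR shows the "
      "per-voxel noise the Monte-Carlo module quantifies.")
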