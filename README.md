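# msirepi

Quantitative T1 mapping with multi-slice multi-shot inversion-recovery EPI
(MS-IR-EPI), for MR physicists and neuroimagers who need accurate,
high-resolution longitudinal-relaxation maps and a way to validate their
processing chain on digital phantoms.

In MS-IR-EPI a non-selective adiabatic inversion is followed by a train of
slice-selective 90° excitations that fills the whole TR, so each slice is
read out at one inversion time TI per volume.  Repeating the volume with the
slice order shifted by a constant slot offset gives every slice a set of
equally spaced TIs, and the signed steady-state recovery

S(TI) = S₀ [1 − 2 e^(−TI/T1) + e^(−TR/T1)]

is fitted voxel-wise for (S₀, T1) after the signal polarity has been
restored from the complex phase (S₀ carries the proton density weighted by
T2\*).  The toolkit implements this chain end to end, plus the analyses
around it:

- **protocol** — acquisition protocols, slice-offset TI scheduling, SPIR
  fat-suppression pulse rates;
- **forward** — the steady-state IR signal (with inversion efficiency
  e ≤ 1: S = S₀[1 − (1+e)e^(−TI/T1) + e·e^(−TR/T1)]) and complex-noise
  simulation of full series;
- **phantoms** — NIST-style calibrated sphere plates and a schematic
  two-tissue brain with ground-truth T1, S₀, B1 and MT maps;
- **fitting** — phase-based polarity restoration and a vectorised
  Levenberg–Marquardt fit of the two-parameter model, with a lookup-table
  fast path;
- **mt** — magnetization-transfer correction of fat-suppression effects:
  the linear model R1(r) = a·m(r) + b·FA·X(r)·m(r) is regressed across SPIR
  flip angles FA (X(r) is the relative transmit field) and inverted per
  voxel, R1,corr = R1 / (1 + (b/a)·FA·X), either with the voxel-wise b/a
  map or with a global b/a taken from the mode of a two-Gaussian mixture;
  a paired full/half-duty scheme gives a closed-form alternative;
- **mp2rage** — the MP2RAGE steady-state signal, the bounded combination
  S = Re(S_TI1·S_TI2\*)/(|S_TI1|² + |S_TI2|²) ∈ [−0.5, 0.5], and
  B1-corrected lookup-table inversion, as the comparator sequence;
- **evaluation** — Monte-Carlo precision/banding studies, inversion-
  efficiency bias, SNR per unit time, CoV, histogram peak/FWHM and
  relaxivity regressions.

## Worked example

`examples/` contains one short script per capability.  Simulating the brain
phantom at 8 TIs (TR 5 s) and fitting it (`examples/02_simulate_and_fit.py`)
prints:

```
--- noiseless ---
  GM: median fitted T1  1699.0 ms (truth 1699), IQR [1699, 1699] ms, 1448 voxels
  WM: median fitted T1  1135.0 ms (truth 1135), IQR [1135, 1135] ms, 456 voxels
--- SNR 25 ---
  GM: median fitted T1  1695.5 ms (truth 1699), IQR [1647, 1744] ms, 1448 voxels
  WM: median fitted T1  1139.3 ms (truth 1135), IQR [1110, 1169] ms, 456 voxels
```

Noiseless recovery is exact (the fit inverts its own forward model); at
SNR 25 the median stays within a fraction of a percent and the
interquartile range shows the per-voxel noise.  The MT-correction example
(`examples/03_mt_correction.py`) shows the apparent GM T1 shrinking from
1699 ms to 1326 ms as the SPIR flip angle rises to 70°, recovers the global
b/a = 0.00450 per degree from the mixture mode, and corrects the 70° map
back to 1699 ms with sub-0.001% worst-voxel error.

A thin CLI mirrors the library:

```bash
msirepi phantom --kind brain --out ph/
msirepi simulate --phantom ph/ --protocol ms1.json --snr 25 --seed 7 --out run
msirepi fit --series run --out maps
```

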