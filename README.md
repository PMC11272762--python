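# spectqc

NEMA NU 1-2018 performance analysis for 3D-ring pixelated CZT SPECT
systems — energy resolution, flood-field uniformity, count-rate
performance, planar and SPECT spatial resolution, planar/volume
sensitivity with detector–detector variation, and IEC body-phantom
tomographic contrast — together with a synthetic phantom/detector
simulator so that every metric can be validated by parameter recovery
without a physical scanner.

It is written for medical physicists running acceptance and periodic QC
on ring-geometry CZT cameras (stacked 16×16-pixel modules, 2.46 mm pixel
pitch, twelve detector columns) and for anyone who needs a tested,
scriptable implementation of the NU 1-2018 analysis chain.

## The metrics

* **Energy resolution** — the photopeak maximum is located with a
  3-point parabolic fit; the FWHM is the distance between the
  half-height crossings linearly interpolated on each side. Resolution
  is 100·FWHM/E_peak per detector column, with the fleet average and
  range.
* **Flood-field uniformity** — raw pixels are summed into 2×4
  super-pixels (4.92 × 9.84 mm²), smoothed with the unit-sum 9-point
  kernel (1,2,1; 2,4,2; 1,2,1)/16, then
  IU = 100·(max−min)/(max+min) over the UFOV/CFOV and
  DU = the same statistic maximized over 5-super-pixel sliding windows.
  Defective pixels (counts/median outside [0.7, 1.3]) and their
  8-connected clusters are reported separately.
* **Count-rate performance** (decay-source method) — for each timed
  measurement *i*:
  C_i = K_i − R_bkg·Δt_i,
  OCR_i = C_i / (τ·(1 − e^(−Δt_i/τ))),
  ICR_i = OCR_n · e^((t_n−t_i)/τ),
  with τ the mean lifetime and *n* a late loss-free reference. The curve
  readouts are the maximum OCR and the ICR where OCR/ICR crosses 0.8.
* **Spatial resolution** — FWHM/FWTM of the line-spread function per
  detector, extrapolated between collimator distances with
  R_target = (target + l_eff)/(measured + l_eff) · R_measured
  (l_eff = 17.72 mm for Tc-99m); SPECT point/line sources are reduced to
  orthogonal summed views and reported as central transaxial/axial and
  peripheral radial/tangential/axial resolutions.
* **Sensitivity** — planar: R = (C/τ)·e^(ΔT/τ)/(1 − e^(−T_acq/τ)),
  S = R/A_cal; volume: SVS = A/B_c, VSAC = SVS/Length,
  DDS = 100·(c_max − c_min)/c_max over the per-detector totals.
* **Tomographic contrast** (IEC body phantom, 8:1 sphere-to-background
  ratio) — Q_H = (c_H/c_B − 1)/(a_H/a_B − 1)·100 %,
  Q_C = (1 − c_C/c_B)·100 %, background variability
  N_j = SD_j/c_B,j·100 % over K = 60 background ROIs per sphere size,
  and the residual lung error ΔC_lung = 100·C_lung/C_B,37mm.

## Worked example

Simulate twelve Tc-99m spectra (4.5 M counts each, 0.5 keV channels, 2 %
flat background) at a true fractional FWHM of 5.27 % and recover the
fleet energy resolution:

```python
from spectqc import phantom_sim as sim, spectrometry as sp

spectra = [sim.gen_spectrum(140.5, 0.0527, 4.5e6, 0.5, 0.02, seed=s,
                            isotope="Tc99m", detector_id=f"D{s:02d}")[0]
           for s in range(1, 13)]
res = sp.energy_resolution(spectra, nominal_peak_keV=140.5)
print(f"peak energy : {res.peak_energy_keV:.2f} keV")
print(f"FWHM        : {res.fwhm_keV:.3f} keV")
lo, hi = res.resolution_range_percent
print(f"resolution  : {res.resolution_percent:.2f} % ({lo:.2f}-{hi:.2f} %)")
```

prints

```
peak energy : 140.48 keV
FWHM        : 7.415 keV
resolution  : 5.28 % (5.27-5.29 %)
```

i.e. the NEMA estimator recovers the simulated 5.27 % resolution to
within a hundredth of a percentage point at these counting statistics;
the (min–max) range shows the Poisson spread across the twelve columns.

The same analyses are available from the shell, e.g.

```sh
qc simulate spectrum --config spec.yaml --seed 1 --out spec.h5
qc energy-res --in spec.h5 --peak-kev 140.5 --report energy.json
qc report --in results/ --tolerances limits.yaml --out qc.json
```

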