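# actinospec

Action and response spectroscopy of ultraviolet-radiation (UVR) effects on
retinal pigment epithelium (RPE) monolayers.

Cultured RPE (e.g. the ARPE-19 line) can be exposed to narrow 10-nm bands of
UVR from 290 to 405 nm at several irradiances, and its injury read out three
ways: an endpoint viability assay (resazurin-type fluorescence), continuous
electric cell–substrate impedance sensing (ECIS) of the monolayer during
exposure, and high-content-imaging (HCI) feature tables covering nuclear,
mitochondrial, oxidative-stress and membrane-integrity probes. `actinospec`
turns those raw plate readouts into wavelength spectra of damage efficiency
and asks whether the wavelength responses fall into discrete bands.

## What it computes

- **Control scaling** — viability is expressed as percent of the
  lysed-control (0) to dark-control (100) range,
  `((χ − MIN)/(MAX − MIN))·100`; ECIS traces are scaled per time point
  between the no-cell (0) and dark (1) control traces, then divided by their
  time-zero value.
- **Viability response spectrum** — per wavelength, ordinary least squares of
  scaled viability on irradiance across the three intensity conditions
  (full, ND 0.2, ND 0.4 neutral-density filters; transmittance `10^(−OD)`).
  The slope *b(λ)* measures damage efficiency; spectra plot *b²(λ)*
  normalised to a visible reference band (405 nm).
- **ECIS action spectrum** — a fixed "common action" (a 60% fall of
  impedance, resistance or capacitance from its time-zero value) defines a
  per-well time-to-action; with the band irradiance *E(λ)* this gives a dose
  *D(λ) = E·t·3600* and an efficiency *1/D(λ)*, normalised to 400 nm.
  Wells that never reach the action are censored, not averaged.
- **HCI response spectra** — per-condition feature means, normalised to the
  dark control, regressed on irradiance feature-by-feature; group spectra
  (all features, per probe compartment, or the punctate SER-'spot' texture
  kernel) average the squared slopes.
- **Monte-Carlo consensus clustering** — the wavelength × feature slope
  matrix is subsample-clustered (k-means) per candidate K; the proportion of
  ambiguous clustering (PAC) of each consensus matrix is compared against
  simulated K = 1 Gaussian references that preserve the data's
  principal-component structure, giving a p-value and relative
  cluster-stability index (RCSI) per K and a selected K.
- **Synthetic data** — forward models for all three assays with documented,
  planted effect profiles (`paper-profile`, `null`, `two-band`), so every
  stage is testable by parameter recovery without any external data.

## Worked example

```python
from actinospec import build_action_spectrum
from actinospec.synthetic_data import gen_ecis_traces, preset

profile = preset("paper-profile")
traces, plate_map, irradiance = gen_ecis_traces(profile, seed=42)
spectrum = build_action_spectrum(traces, plate_map, irradiance)
print(spectrum[["mean_time_to_action_h", "normalised_efficiency", "n_wells"]].round(3))
```

```
               mean_time_to_action_h  normalised_efficiency  n_wells
wavelength_nm
290.0                          1.199               9613.856        4
300.0                          1.208               9551.235        4
310.0                          1.210               9540.045        4
320.0                          5.980                 96.371        4
330.0                          6.025                 95.618        4
340.0                          6.108                 94.459        4
350.0                          6.034                 95.482        4
360.0                         28.972                  9.967        4
370.0                         59.079                  0.976        4
380.0                         59.903                  0.962        4
390.0                         59.577                  0.967        4
400.0                         57.622                  1.000        4
```

Reading the output: UV-B bands (290–310 nm) reach the common action in about
1.2 h — roughly 10⁴-fold the dose efficiency of the 400-nm reference — the
short-wave UV-A bands 320–350 nm form a plateau near 100-fold, and long-wave
UV-A is comparable to visible light. These recover the efficiencies planted
by the `paper-profile` preset within a few percent.

The same pipeline runs from the shell:

```sh
actinospec simulate --preset paper-profile --out sim/ --seed 42
actinospec run-all --out run/ --seed 42        # all stages + cluster report
```

`run-all` writes the three spectra as CSV, the wavelength × feature
coefficient matrix, and a JSON cluster report (per-K PAC / p / RCSI,
selected K, wavelength-band mapping).

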