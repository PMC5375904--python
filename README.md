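# sorsmix

Spectral unmixing and depth profiling for spatially offset Raman
spectroscopy (SORS) scans of layered samples.

## The problem

Conventional backscattering Raman spectroscopy probes only the surface of
a turbid sample: a chemical powder sealed inside one or more gelatin
capsule layers is invisible at the usual zero-offset geometry once the
wall is thick enough. SORS collects the Raman signal at a series of
lateral offsets from the laser spot; with growing offset the collected
photons have sampled deeper material, so the subsurface powder's
contribution progressively outweighs the surface capsule's. Each offset
scan therefore yields a *mixed* spectral matrix `D` (offsets ×
wavenumber channels) whose rows blend two pure spectra with
offset-dependent weights.

`sorsmix` provides, as a library and a CLI:

* a seeded synthetic-data generator emulating point-scan SORS
  acquisitions of urea, ibuprofen, and acetaminophen under 1–8 capsule
  layers (101 spectra per sample over 0–10 mm offsets, 24 samples per
  study, fluorescence background, detector noise);
* preprocessing: 500–2000 cm⁻¹ analysis window and iterative polynomial
  baseline correction, giving the 101×975 analysis matrix;
* self-modeling mixture analysis (SMA): SIMPLISMA-style pure-variable
  selection (purity spectra with determinant-based weights) followed by
  non-negative alternating least squares, resolving `D ≈ C·S` into pure
  component spectra `S` and contributions `C`;
* identification of each resolved spectrum by spectral information
  divergence, `SID = D(p‖q) + D(q‖p)`, against a reference library;
* depth-profiling diagnostics: spatial profiles, powder/capsule
  peak-intensity ratio versus offset, and SNR-based detectability.

It is aimed at chemometrics practitioners who want a reproducible,
tested reference pipeline for SORS-style unmixing experiments.

## Worked example

```python
import numpy as np
import sorsmix as sx

library = sx.default_library()
sample = sx.SampleConfig("urea", n_layers=3)
scan = sx.ScanConfig(seed=42)            # 0-10 mm, 0.1 mm steps -> 101 spectra
dataset = sx.simulate_scan(sample, scan, library)
pre = sx.preprocess(dataset)             # 500-2000 cm^-1 window + baseline

result = sx.unmix_dataset(pre, k=2)
report = sx.identify_components(result, library)
for entry in report.entries:
    print(f"component {entry['component_index']}: {entry['best_label']} "
          f"(SID {entry['best_sid']:.3f}, margin {entry['margin']:.3f})")

quiet = sx.simulate_scan(sample, scan, library, sx.MixingParams().noiseless())
profile = sx.ratio_profile(sx.preprocess(quiet), chem_center=1009.0)
for d in (0.0, 1.0, 2.0, 3.0):
    r = float(profile.loc[np.isclose(profile.offset_mm, d), "ratio"].iloc[0])
    print(f"noise-free 1009/644 ratio at {d:.0f} mm: {r:5.2f}")
```

prints

```
component 0: urea (SID 2.594, margin 29.418)
component 1: capsule (SID 6.765, margin 18.515)
noise-free 1009/644 ratio at 0 mm:  2.00
noise-free 1009/644 ratio at 1 mm:  3.92
noise-free 1009/644 ratio at 2 mm:  7.67
noise-free 1009/644 ratio at 3 mm: 15.01
```

The two pure variables land on the urea key peak (1009 cm⁻¹) and the
capsule key peak (644 cm⁻¹); both resolved spectra are identified
correctly, with large margins to the second-best match. The ratio
profile shows the subsurface/surface trend that makes SORS work: for
the three-layer sample the urea/capsule peak ratio grows from about 2
with no offset to 15 at a 3 mm offset.

The same chain is available from the shell:

```sh
sorsmix generate --seed 7 --out data/          # 24 CSV+JSON pairs
sorsmix preprocess --in data/urea_L3.csv --out pre.csv
sorsmix unmix --in pre.csv --out sma/          # S.csv (2x975), C.csv (101x2)
sorsmix identify --in pre.csv --sma sma/ --out report.json
sorsmix profile --in pre.csv --wavenumbers 644,1009 --out profile.csv
sorsmix run-all --seed 7 --out study/          # full study + summary + manifest
```

See `docs/methods.md` for the model, its calibration, the numerical
choices, and known limitations.

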