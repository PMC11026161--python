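# neurelec

Analysis toolkit for flexible neural microelectrode arrays: the
electrochemical workup of capacitive microelectrodes, the standard
in-vivo recording metrics, intrafascicular stimulation selectivity, and
a morphology-based microglia activation readout — together with seeded
synthetic-data generators so every stage is verifiable without any
experimental download.

## Who this is for

Groups characterizing porous thin-film microelectrodes (graphene-based
or otherwise) and validating them in vivo face the same chain of
analyses over and over: impedance spectra to fit, voltammograms and
pulse transients to integrate, recordings to score, recruitment curves
to threshold, histology to quantify. `neurelec` implements that chain
as one tested library with a thin CLI, with the exact conventions
stated on every output.

## What it computes

**Electrochemistry** (`neurelec.electrochem`)

- EIS fitting to a series resistance + constant phase element,
  `Z(ω) = R_s + 1/(Q(jω)^n)`, by weighted least squares on modulus and
  phase jointly; the CPE is converted to an equivalent capacitance
  (`C = (Q·R_s^(1−n))^(1/n)` by default) and normalized by geometric
  area.
- Charge storage capacity from cyclic voltammetry:
  `cCSC = (1/(νA))∫|i⁻|dV` over the cathodic current (aCSC analogous).
- Pulse-transient analysis: the ohmic drop `I·R_access` is the
  instantaneous voltage step at the current edge; the cathodic/anodic
  excursions are the extreme interfacial polarizations after removing
  it; charge density per phase is `I·t_phase/A`.
- Charge injection capacity: the smallest charge density whose
  ohmic-corrected excursion reaches the water window (−0.9 / +0.8 V vs
  Ag/AgCl by default), interpolated between tested amplitudes; plus a
  pulse-width × charge-density excursion map.

**Recording metrics** (`neurelec.recording`)

- Zero-phase band filters (LFP ≥ 10 Hz, MUA ≥ 200 Hz, SUA 450–6000 Hz,
  50 Hz notch + harmonics, detrend), 20 ms sliding rms, Welch PSD.
- In-vivo / post-mortem SNR: per frequency `20·ln√(PSD_IV/PSD_PM)`
  (natural-log dB convention, with decadic as an option — the
  convention is stamped on every output), interpolated onto 20
  log-spaced points between 10 Hz and 1 kHz.
- Evoked potentials: trial average, N1 as the most negative deflection
  in a configurable post-stimulus window, AEP SNR = |N1| / sd of the
  20 ms pre-stimulus baseline; PSTH + raster from sorted spike times.

**Stimulation selectivity** (`neurelec.stim`)

- CMAP amplitudes (baseline to maximum negative peak), recruitment
  curves normalized per muscle by the experiment-wide maximum,
  interpolated 5/30/95% threshold currents, and the selectivity index
  `SI_i = nCMAP_i / Σ_j nCMAP_j` evaluated either at the minimal
  functionally relevant current (any muscle ≥ 5%) or at a benchmark
  activation level of a target muscle (default 30%).

**Microglia activation** (`neurelec.microglia`)

- Tubeness enhancement → adaptive two-class Otsu segmentation (50 px
  window) → size/border filtering (3–40 px equivalent diameter) →
  *Extent* (area / bounding-box area) → activated vs non-activated
  classification with a built-in threshold sensitivity sweep.

**Synthetic data** (`neurelec.synth`) — seeded generators for all of the
above: R+CPE spectra, capacitive CVs, biphasic transients, cortical
recordings (1/f background, evoked templates, Poisson-modulated spikes,
2.5 µV noise floor), two-fascicle recruitment datasets, and micrographs
of ameboid vs ramified cells, each returning ground truth.

## Worked example

```python
import numpy as np
from neurelec import (GeneratorConfig, gen_eis_spectrum, fit_eis,
                      gen_pulse_trace, analyze_transient)

area = np.pi * (12.5e-4) ** 2          # 25-um disc, cm^2
cfg = GeneratorConfig(seed=0, noise_level=0.0)

spec = gen_eis_spectrum(20e3, 6.82e-8, 1.0, np.logspace(0, 5, 41),
                        cfg, geometric_area=area)
fit = fit_eis(spec)
print(f"C = {fit.capacitance*1e9:.1f} nF -> "
      f"{fit.areal_capacitance*1e3:.1f} mF/cm^2")

trace = gen_pulse_trace(20e3, 68e-9, 1.0, 15e-6, 1e-3, 1e6, area, cfg)
m = analyze_transient(trace)
print(f"ohmic drop {m.ohmic_drop:.3f} V, "
      f"cathodic excursion {m.cathodic_excursion:.4f} V, "
      f"charge density {m.charge_density:.2f} mC/cm^2")
```

prints

```
C = 68.2 nF -> 13.9 mF/cm^2
ohmic drop 0.300 V, cathodic excursion -0.2204 V, charge density 3.06 mC/cm^2
```

i.e. a 68.2 nF interface on a 25 µm disc is 13.9 mF cm⁻² of areal
capacitance, and a 15 µA / 1 ms biphasic pulse through 20 kΩ access
resistance steps by I·R = 0.30 V, polarizes the interface by
I·t/C ≈ 0.22 V, and delivers ≈ 3 mC cm⁻² per phase.

The same operations are available from the shell:

```
neurelec synth eis --seed 1 --out run/
neurelec eis-fit run/eis.csv --out run/
```

Every command writes its results as JSON/CSV next to a `manifest.json`
recording the tool version, resolved configuration and input digests.

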