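# Methods

This note records the models behind each module, the defaults that
matter, what the synthetic generators do and do not emulate, and the
design choices made where several conventions were defensible.

## Electrochemistry

**Equivalent circuit.** A capacitive microelectrode in saline is
modelled as an access resistance `R_s` in series with a constant phase
element, `Z(ω) = R_s + 1/(Q(jω)^n)`, `n ∈ (0, 1]`. The CPE captures the
distributed capacitance of a porous coating; `n = 1` is an ideal
capacitor. Fitting is by bounded least squares on the joint residual
`[(|Z_m|−|Z|)/|Z|, φ_m−φ]`; the 1/|Z| modulus weighting keeps every
frequency decade comparable so the low-frequency capacitive branch does
not dominate the high-frequency resistive plateau. Spectra with phase
≈ 0 everywhere carry no information about `Q` and raise a degenerate-fit
error rather than returning a clipped value; the same policy applies to
any non-physical parameter estimate.

**CPE → capacitance.** The default conversion is the
single-time-constant relation `C = (Q·R_s^(1−n))^(1/n)`, which reduces
to `C = Q` as `n → 1` (and is applied as `C = Q` for `n > 0.999` to
avoid the `R_s^0` ambiguity); `direct` (`C = Q`) is available. The rule
in effect is recorded on every fit result, since the two differ
measurably for `n < 0.9`.

**CSC.** `cCSC = (1/(νA))∫|i⁻|dV` via trapezoidal integration over the
measured sweep, cathodic and anodic currents separated by sign; an
"incomplete cycle" error is raised unless the potential traverses at
least 95% of the window in both directions. For an ideal capacitor this
reduces to `C_A·ΔV` — 17 mC cm⁻² for 10 mF cm⁻² over a 1.7 V window —
at any scan rate, which the tests verify to 1%.

**Transients and CIC.** The pulse onset is detected as the first
voltage-difference sample exceeding 25% of the largest step in the
trace; the ohmic drop is the discontinuity straddling that edge (first
sample after minus last sample before). An optional back-extrapolation
(line fit over the first k post-onset samples, default k = 3 when
enabled) is provided for band-limited recordings where the edge is
smeared. The interfacial potential is the trace minus baseline minus
`i(t)·R_access` with the current waveform reconstructed from the
trace's metadata. The cathodic excursion is reported as the **signed
minimum within the cathodic phase** (end-of-phase sampling is an
option; for a passive R–CPE electrode the two coincide), the anodic
excursion as the signed maximum, and window comparisons are on signed
values against (−0.9, +0.8) V vs Ag/AgCl. CIC interpolates linearly in
charge density between the bracketing tested amplitudes (the minimal
monotone assumption); `last_safe` returns the largest tested density
still inside the window instead. A first-amplitude violation is flagged
`below_grid`; a window never reached returns the largest tested density
flagged `out_of_grid` as a lower bound.

## Recording metrics

All filters are Butterworth (default order 4) applied forward–backward,
so evoked-peak latencies are preserved; the notch is a cascade of IIR
notches at 50 Hz and harmonics below Nyquist (Q = 35). The sliding rms
uses a centred 20 ms window that shrinks at the edges (no padding). The
PSD is Welch's method — 2 s Hann segments, 50% overlap — over the first
60 s of the recording; the duration is enforced, the segment parameters
are configurable defaults.

The in-vivo / post-mortem SNR is the per-frequency amplitude ratio
`√(PSD_IV/PSD_PM)` mapped to dB. The default mapping is `20·ln(·)` —
the "natural" convention, kept because it is the form this statistic
is conventionally printed with for these devices — with `20·log10(·)`
("decadic") one flag away; the two differ by a factor ln(10) ≈ 2.30, so
the convention is stamped on every SNR output and neither is silently
assumed. The dB curve is interpolated linearly in log-frequency onto 20
log-spaced points between 10 Hz and 1 kHz.

Evoked averaging drops events without a full peri-event window. The
baseline sd is taken over the 20 ms pre-stimulus of the *averaged*
waveform, N1 is the most negative deflection within a 10–100 ms
post-stimulus search window (bracketing the ~40 ms peak typical of
auditory responses), and the AEP SNR is |N1|/sd, reported both as a
ratio and in dB under the chosen convention. A zero baseline sd is a
degenerate input and raises. PSTH bins are left-closed, so a spike
exactly at the stimulus lands in the bin whose left edge is 0. Spike
*sorting* is out of scope — spike times are inputs; the k·MAD threshold
detector (k = 5) exists only to exercise synthetic recordings.

## Stimulation selectivity

Recruitment curves are normalized per muscle by the experiment-wide
maximum CMAP over all sites and currents; thresholds at 5/30/95% are
first crossings with linear interpolation between grid points (ties
break toward the lower current), and a level never reached is `None`,
never extrapolated. The selectivity index is evaluated **at the exact
grid current** — the minimum current at which any muscle reaches the 5%
minimal-relevant level, or the first current at which a target muscle
reaches the 30% benchmark — because the defining current comes from the
tested pulse train, not from an interpolated continuum. Unresponsive
muscles contribute 0 to the SI denominator; a site silent at its
evaluation current yields no SI rather than 0/0. Best-site ties break
by lower evaluation current, then site order.

## Microglia pipeline

Enhancement is a tubeness operator: per scale σ (default 2 px, the
conventional choice for ~3 px processes), `σ²·max(0, −λ_min)` of the
Gaussian-smoothed Hessian (reflect boundary), maximum over scales.
This measure responds to ridges *and* to compact somata; vesselness
variants with a blobness penalty suppress exactly the ameboid cells the
classifier must keep, so they are not used. Segmentation thresholds the
enhanced image (a flag switches to raw intensities) with tile-wise Otsu
on a 50 px grid, thresholds bilinearly interpolated between tile
centres and clamped at the edges; tiles with under 10% of the global
intensity range fall back to the global Otsu threshold, and all tile
thresholds are clamped to 0.7–1.5× the global threshold — the usual
adaptive-Otsu convention — so featureless regions never threshold their
own noise. Holes inside binary objects are filled (ridge enhancement
hollows out large somata, which are still one cell), components use
8-connectivity, and objects outside 3–40 px equivalent diameter or
touching the image border are discarded. There is no declumping:
touching cells count as one object, a documented limitation.

Classification uses *Extent* = area / bounding-box area: compact
ameboid (activated) cells fill most of their box (a disk is π/4 ≈
0.785), ramified cells with thin radiating processes do not (a cross of
two 3×11 bars is 57/121 ≈ 0.471). The direction of the rule is
physiology; the cut-off is not a measured constant, so the default 0.5
is always reported and every summary carries a sensitivity sweep over
0.3–0.7.

## Synthetic generators

Every generator is a pure function of its parameters and a seeded
config: identical configs are bit-identical, and `noise_level = 0`
returns the forward model exactly — this is what makes the closed-form
tests possible. Noise scales are defined per generator relative to the
local signal scale (modulus fraction and phase radians for EIS, of
`C·A·ν` for CV, of the peak voltage for transients, of the curve
maximum — truncated at zero — for recruitment, of the cell/background
contrast for micrographs).

The recording generator sums a 1/f-shaped background (spectrally shaped
white noise, exponent 1 by default — the field's generic LFP model, not
a measured spectrum), Gaussian evoked components, Poisson spike trains
(5 Hz baseline, a 100 ms post-stimulus multiplicative burst) convolved
with biphasic 1 ms waveforms, and a white noise floor whose default rms
of 2.5 µV emulates a low-noise electrode at the instrumentation limit.
The recruitment generator places sites in a peroneal/tibial two-fascicle
geometry (five sites peroneal, one boundary, three tibial, emulating a
transverse intrafascicular array), with logistic curves whose
cross-fascicle responses are 10× attenuated and threshold-shifted, on a
0–150 µA grid in 3 µA steps. The micrograph generator packs disks
(9–15 px) and soma-bearing crosses by rejection sampling with separated
bounding boxes.

What the generators do **not** emulate: electrode drift and faradaic
leakage; correlated multi-channel noise, movement and line artefacts;
spike waveform variability and overlap; EMG stimulus artefacts;
uneven illumination, staining variability and touching cells in
micrographs. Passing tests therefore demonstrate correctness of the
computations under the stated models, not robustness to every artefact
of real data.

## Problem sizes and numerical choices

The test and acceptance runs use sizes chosen to make statistical
contracts tight while keeping the whole suite interactive: 41-point
log-spaced spectra over 5 decades, 4000-sample CV cycles, 1 MHz-sampled
1 ms pulses (200 kHz within CIC sweeps of 16 amplitudes), 60 s of
2 kHz recording for noise/PSD contracts, 100 trials for evoked
recovery, 51-current recruitment grids, and 50 seeded 256² micrographs.
Floating-point JSON output is serialized at 9 significant digits so
golden files are platform-stable. Known limitations: the CPE→C
conversion is convention-dependent for strongly non-ideal interfaces;
the SNR dB magnitude depends on the logarithm convention (always
reported); no declumping in segmentation; the onset detector assumes a
resolvable current edge (≥ 20 samples per phase is enforced).
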