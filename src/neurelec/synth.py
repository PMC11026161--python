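"""Seeded synthetic-data generators.

Every generator is a pure function of its parameters and a
:class:`GeneratorConfig` — identical configs give bit-identical outputs,
and ``noise_level = 0`` returns the deterministic forward model exactly.
The generators emulate the input types the analysis modules consume:

* R + CPE electrode impedance spectra,
* ideal-capacitor cyclic voltammograms,
* biphasic-pulse voltage transients (ohmic step + CPE polarization),
* multichannel cortical recordings (1/f LFP background, event-locked
  evoked templates, Poisson-modulated spike trains, white noise floor —
  defaults emulate a 2.5 uV rms electrode noise floor),
* sigmoidal two-fascicle CMAP recruitment datasets,
* micrographs of ameboid (compact) vs ramified (cross-shaped) cells.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

from .electrochem import (
    CyclicVoltammogram,
    ImpedanceSpectrum,
    PulseTrace,
    cpe_impedance,
)
from .errors import InvalidParameterError, PackingError
from .recording import RecordingSegment
from .stim import RecruitmentDataset


@dataclass
class GeneratorConfig:
    """Shared generator configuration.

    ``noise_level`` is a dimensionless fraction of the relevant signal
    scale (documented per generator); 0 disables noise entirely.
    """

    seed: int = 0
    noise_level: float = 0.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_level < 0:
            raise InvalidParameterError("noise_level must be >= 0")

    def rng(self, stream: str = "") -> np.random.Generator:
        """Independent, reproducible stream per generator."""
        tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence([self.seed, tag])
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Electrochemistry
# ---------------------------------------------------------------------------

def gen_eis_spectrum(R_s: float, Q: float, n_exp: float, freq_grid,
                     cfg: GeneratorConfig, geometric_area: float = 1.0,
                     electrode_id: str = "synthetic") -> ImpedanceSpectrum:
    """Impedance spectrum of a series R + CPE electrode.

    Forward model ``Z(w) = R_s + 1/(Q (jw)^n)``.  Noise: multiplicative
    Gaussian on the modulus (sd = noise_level) and additive Gaussian on
    the phase (sd = noise_level radians).
    """
    freq = np.asarray(freq_grid, dtype=float)
    if np.any(freq <= 0):
        raise InvalidParameterError("frequencies must be > 0")
    if Q <= 0:
        raise InvalidParameterError("Q must be > 0")
    if R_s < 0:
        raise InvalidParameterError("R_s must be >= 0")
    if not 0 < n_exp <= 1:
        raise InvalidParameterError("n_exp must be in (0, 1]")

    z = cpe_impedance(freq, R_s, Q, n_exp)
    if cfg.noise_level > 0:
        rng = cfg.rng("eis")
        mod = np.abs(z) * (1.0 + cfg.noise_level * rng.standard_normal(freq.size))
        ph = np.angle(z) + cfg.noise_level * rng.standard_normal(freq.size)
        z = mod * np.exp(1j * ph)
    return ImpedanceSpectrum(frequencies=freq, impedance=z,
                             electrode_id=electrode_id, geometric_area=geometric_area)


def gen_cv(areal_capacitance: float, window: tuple[float, float], scan_rate: float,
           area: float, cfg: GeneratorConfig,
           samples_per_cycle: int = 2000) -> CyclicVoltammogram:
    """Ideal-capacitor cyclic voltammogram, ``i = +/- C A v``.

    One full triangular cycle V_min -> V_max -> V_min.  Noise: additive
    Gaussian on the current with sd = noise_level * C A v.
    """
    v_min, v_max = window
    if not v_min < v_max:
        raise InvalidParameterError("window must satisfy V_min < V_max")
    if scan_rate <= 0 or area <= 0 or areal_capacitance <= 0:
        raise InvalidParameterError("scan_rate, area and capacitance must be > 0")
    half = samples_per_cycle // 2
    up = np.linspace(v_min, v_max, half, endpoint=False)
    down = np.linspace(v_max, v_min, samples_per_cycle - half)
    potential = np.concatenate([up, down])
    i0 = areal_capacitance * area * scan_rate
    current = np.where(np.concatenate([np.ones(half), -np.ones(samples_per_cycle - half)]) > 0,
                       i0, -i0)
    if cfg.noise_level > 0:
        current = current + cfg.noise_level * i0 * cfg.rng("cv").standard_normal(current.size)
    return CyclicVoltammogram(potential=potential, current=current, scan_rate=scan_rate,
                              geometric_area=area, window=(v_min, v_max))


def gen_pulse_trace(R_access: float, Q: float, n_exp: float, amplitude: float,
                    phase_width: float, fs: float, area: float, cfg: GeneratorConfig,
                    cathodic_first: bool = True, pre_time: float | None = None,
                    post_time: float | None = None) -> PulseTrace:
    """Voltage transient of a charge-balanced biphasic current pulse.

    Current through R_access in series with a CPE; the CPE step response
    is ``v(t) = I t^n / (Q Gamma(1+n))`` (a linear ramp ``I t / C`` for
    n = 1), superposed over the pulse's current transitions, plus the
    instantaneous ohmic term ``i(t) R_access``.  Noise: additive
    Gaussian with sd = noise_level * max |v|.
    """
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be >= 0")
    if fs * phase_width < 20:
        raise InvalidParameterError(
            f"pulse undersampled: need fs >= {20.0 / phase_width:.3g} Hz "
            f"for phase_width {phase_width:g} s"
        )
    if Q <= 0 or not 0 < n_exp <= 1:
        raise InvalidParameterError("Q must be > 0 and n_exp in (0, 1]")

    pre = 0.25 * phase_width if pre_time is None else pre_time
    post = 2.0 * phase_width if post_time is None else post_time
    n_pre = max(int(round(pre * fs)), 2)
    n_ph = int(round(phase_width * fs))
    n_post = max(int(round(post * fs)), 1)
    n_tot = n_pre + 2 * n_ph + n_post
    t = np.arange(n_tot) / fs

    sign1 = -1.0 if cathodic_first else 1.0
    current = np.zeros(n_tot)
    current[n_pre:n_pre + n_ph] = sign1 * amplitude
    current[n_pre + n_ph:n_pre + 2 * n_ph] = -sign1 * amplitude

    # superpose CPE step responses at each current transition
    v_cpe = np.zeros(n_tot)
    steps = [
        (t[n_pre], sign1 * amplitude),
        (t[n_pre + n_ph], -2.0 * sign1 * amplitude),
        (t[n_pre + 2 * n_ph], sign1 * amplitude),
    ]
    g = gamma_fn(1.0 + n_exp)
    for t0, di in steps:
        tau = t - t0
        mask = tau >= 0
        v_cpe[mask] += di * tau[mask] ** n_exp / (Q * g)
    voltage = current * R_access + v_cpe

    if cfg.noise_level > 0 and amplitude > 0:
        scale = float(np.max(np.abs(voltage)))
        voltage = voltage + cfg.noise_level * scale * cfg.rng("pulse").standard_normal(n_tot)
    return PulseTrace(time=t, voltage=voltage, amplitude=amplitude,
                      phase_width=phase_width, cathodic_first=cathodic_first,
                      geometric_area=area, sampling_rate=fs)


# ---------------------------------------------------------------------------
# Neural recordings
# ---------------------------------------------------------------------------

def _biphasic_waveform(fs: float, amplitude_uv: float, width_s: float = 0.001) -> np.ndarray:
    """Biphasic extracellular spike template: sharp negative lobe followed
    by a shallower positive rebound, total length ~``width_s``."""
    n = max(int(round(width_s * fs)), 4)
    t = np.arange(n) / fs
    s1 = width_s / 8.0
    s2 = width_s / 4.0
    w = -np.exp(-0.5 * ((t - 0.25 * width_s) / s1) ** 2) \
        + 0.45 * np.exp(-0.5 * ((t - 0.62 * width_s) / s2) ** 2)
    return amplitude_uv * w / np.max(np.abs(w))


def _evoked_template(fs: float, components) -> tuple[np.ndarray, float]:
    """Sum of Gaussian deflections; returns (waveform, length_s).

    Each component is a dict with ``amplitude_uv`` (signed),
    ``latency_s`` and ``width_s`` (Gaussian sd).
    """
    if not components:
        return np.zeros(1), 0.0
    t_end = max(c["latency_s"] + 5.0 * c["width_s"] for c in components)
    n = int(round(t_end * fs)) + 1
    t = np.arange(n) / fs
    w = np.zeros(n)
    for c in components:
        w += c["amplitude_uv"] * np.exp(-0.5 * ((t - c["latency_s"]) / c["width_s"]) ** 2)
    return w, t_end


def gen_neural_recording(
    n_channels: int,
    fs: float,
    duration: float,
    cfg: GeneratorConfig,
    evoked_spec=None,
    spike_spec=None,
    noise_rms: float = 2.5,
    event_times=None,
    lfp_rms: float = 0.0,
    lfp_exponent: float = 1.0,
    max_samples: int = 200_000_000,
) -> tuple[RecordingSegment, dict]:
    """Synthetic multichannel cortical recording with ground truth.

    The trace is the sum of a 1/f-shaped LFP background (rms ``lfp_rms``
    uV, power ~ f^-lfp_exponent), event-locked evoked templates
    (``evoked_spec``: list of Gaussian components, see
    :func:`_evoked_template`), spike trains convolved with biphasic unit
    waveforms (``spike_spec``: list of unit dicts with ``rate_hz``,
    ``burst_gain``, ``burst_window_s``, ``amplitude_uv``, ``width_s``,
    ``channel``), and white noise of rms ``noise_rms`` uV (default
    2.5 uV, the electrode noise floor the generator emulates).

    Returns ``(segment, ground_truth)`` where the ground truth carries
    the evoked template, per-unit spike times and all amplitudes.
    """
    n_samples = int(round(duration * fs))
    if n_channels * n_samples > max_samples:
        raise InvalidParameterError("requested recording exceeds the sample budget")
    events = np.asarray([] if event_times is None else event_times, dtype=float)
    evoked_spec = evoked_spec or []
    spike_spec = spike_spec or []

    template, t_len = _evoked_template(fs, evoked_spec)
    if events.size > 1:
        min_isi = float(np.min(np.diff(np.sort(events))))
        if t_len > min_isi:
            raise InvalidParameterError(
                f"evoked template ({t_len:g} s) longer than the shortest "
                f"inter-event interval ({min_isi:g} s)"
            )

    rng = cfg.rng("recording")
    data = np.zeros((n_channels, n_samples))

    if lfp_rms > 0:
        white = rng.standard_normal((n_channels, n_samples))
        spec = np.fft.rfft(white, axis=1)
        f = np.fft.rfftfreq(n_samples, 1.0 / fs)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-lfp_exponent / 2.0)
        shaped = np.fft.irfft(spec * shape, n=n_samples, axis=1)
        rms = np.sqrt(np.mean(shaped ** 2, axis=1, keepdims=True))
        data += lfp_rms * shaped / np.where(rms > 0, rms, 1.0)

    if template.size > 1 and np.any(template):
        for t0 in events:
            i0 = int(round(t0 * fs))
            j1 = min(i0 + template.size, n_samples)
            if i0 < n_samples:
                data[:, i0:j1] += template[: j1 - i0]

    gt_spikes: dict[str, np.ndarray] = {}
    for u, unit in enumerate(spike_spec):
        rate = unit.get("rate_hz", 5.0)
        gain = unit.get("burst_gain", 5.0)
        b_lo, b_hi = unit.get("burst_window_s", (0.0, 0.1))
        ch = unit.get("channel", 0)
        base = np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
        extra = []
        if gain > 1 and events.size:
            lam = rate * (gain - 1.0) * (b_hi - b_lo)
            for t0 in events:
                k = rng.poisson(lam)
                extra.append(t0 + rng.uniform(b_lo, b_hi, k))
        times = np.sort(np.concatenate([base] + extra)) if extra else base
        times = times[times < duration]
        gt_spikes[unit.get("unit_id", f"u{u}")] = times
        wave = _biphasic_waveform(fs, unit.get("amplitude_uv", -60.0),
                                  unit.get("width_s", 0.001))
        train = np.zeros(n_samples)
        idx = np.round(times * fs).astype(int)
        np.add.at(train, idx[idx < n_samples], 1.0)
        data[ch] += np.convolve(train, wave)[:n_samples]

    if noise_rms > 0 and cfg.noise_level >= 0:
        data += noise_rms * rng.standard_normal((n_channels, n_samples))

    segment = RecordingSegment(
        sampling_rate=fs, data=data,
        event_times=events,
        metadata={"synthetic": True, "seed": cfg.seed, "noise_rms_uv": noise_rms,
                  "lfp_rms_uv": lfp_rms, "lfp_exponent": lfp_exponent},
    )
    ground_truth = {
        "evoked_template": template,
        "evoked_spec": evoked_spec,
        "spike_times": gt_spikes,
        "noise_rms_uv": noise_rms,
    }
    return segment, ground_truth


# ---------------------------------------------------------------------------
# Recruitment
# ---------------------------------------------------------------------------

#: Which fascicle innervates which muscle in the sciatic-nerve preparation.
MUSCLE_FASCICLE = {"TA": "peroneal", "GM": "tibial", "PL": "tibial"}

#: Electrode-site placement emulating a transverse intrafascicular array
#: crossing both fascicles (first five sites peroneal, last three tibial).
DEFAULT_SITE_FASCICLE = {
    **{f"A{i}": "peroneal" for i in range(1, 6)},
    "A6": "boundary",
    **{f"A{i}": "tibial" for i in range(7, 10)},
}


def default_sigmoid_params(
    sites, muscles, site_fascicle_map, rng,
    muscle_fascicle=None, attenuation: float = 10.0,
    threshold_range=(40.0, 60.0), distant_threshold_shift: float = 50.0,
    slope: float = 0.2, max_mv_range=(1.0, 3.0),
) -> dict:
    """Logistic parameters per site x muscle for a two-fascicle nerve.

    A site drives muscles of its own fascicle with full amplitude and a
    low threshold; muscles of the distant fascicle respond with a
    ``attenuation``-fold smaller maximum and a higher threshold.  Sites
    on the fascicle boundary drive both with intermediate strength.
    """
    muscle_fascicle = muscle_fascicle or MUSCLE_FASCICLE
    params = {}
    for site in sites:
        fasc = site_fascicle_map[site]
        for m in muscles:
            thr = rng.uniform(*threshold_range)
            vmax = rng.uniform(*max_mv_range)
            if fasc == "boundary":
                vmax /= math.sqrt(attenuation)
                thr += distant_threshold_shift / 2.0
            elif muscle_fascicle[m] != fasc:
                vmax /= attenuation
                thr += distant_threshold_shift
            params[(site, m)] = {"threshold_ua": thr, "slope": slope, "max_mv": vmax}
    return params


def gen_recruitment_dataset(
    cfg: GeneratorConfig,
    sites=None,
    muscles=("TA", "GM", "PL"),
    site_fascicle_map=None,
    sigmoid_params=None,
    current_grid=None,
    attenuation: float = 10.0,
) -> RecruitmentDataset:
    """Sigmoidal CMAP recruitment table over a current grid.

    Noise-free amplitudes follow ``max / (1 + exp(-slope (I - thr)))``;
    noise is additive Gaussian on the amplitude (sd = noise_level * max
    of that curve), truncated at zero.  Defaults emulate a nine-site
    intrafascicular array across the peroneal/tibial fascicles with
    currents 0-150 uA in 3 uA steps.
    """
    sites = list(sites) if sites is not None else [f"A{i}" for i in range(1, 10)]
    muscles = list(muscles)
    site_fascicle_map = site_fascicle_map or {
        s: DEFAULT_SITE_FASCICLE.get(s, "peroneal") for s in sites
    }
    grid = (np.arange(0.0, 150.0 + 1e-9, 3.0) if current_grid is None
            else np.asarray(current_grid, dtype=float))
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("current grid must be strictly increasing")

    rng = cfg.rng("recruitment")
    if sigmoid_params is None:
        sigmoid_params = default_sigmoid_params(sites, muscles, site_fascicle_map,
                                                rng, attenuation=attenuation)
    rows = []
    for site in sites:
        for m in muscles:
            p = sigmoid_params[(site, m)]
            if p["max_mv"] < 0:
                raise InvalidParameterError("maximum CMAP amplitude must be >= 0")
            amp = p["max_mv"] / (1.0 + np.exp(-p["slope"] * (grid - p["threshold_ua"])))
            if cfg.noise_level > 0:
                amp = amp + cfg.noise_level * p["max_mv"] * rng.standard_normal(grid.size)
                amp = np.clip(amp, 0.0, None)
            for c, a in zip(grid, amp):
                rows.append({"site": site, "muscle": m, "current_ua": c, "cmap_mv": a})
    table = pd.DataFrame(rows)
    return RecruitmentDataset(table=table, ground_truth={
        "sigmoid_params": sigmoid_params,
        "site_fascicle_map": site_fascicle_map,
        "muscle_fascicle_map": {m: MUSCLE_FASCICLE.get(m) for m in muscles},
    })


# ---------------------------------------------------------------------------
# Micrographs
# ---------------------------------------------------------------------------

def _draw_disk(canvas, centre, radius, value):
    from skimage.draw import disk as sk_disk
    rr, cc = sk_disk(centre, radius, shape=canvas.shape)
    canvas[rr, cc] = value
    return np.stack([rr, cc], axis=1)


def _draw_cross(canvas, centre, bar_length, bar_width, soma_diameter, value):
    """Ramified-cell phantom: two perpendicular bars plus an optional
    small central soma disk (ramified microglia have a compact soma with
    radiating processes; the soma also keeps the phantom connected under
    ridge enhancement)."""
    from skimage.draw import disk as sk_disk
    r, c = centre
    hw = bar_width // 2
    hl = bar_length // 2
    mask = np.zeros_like(canvas, dtype=bool)
    mask[r - hw:r + hw + 1, c - hl:c + hl + 1] = True
    mask[r - hl:r + hl + 1, c - hw:c + hw + 1] = True
    if soma_diameter > 0:
        rr, cc = sk_disk((r, c), soma_diameter / 2.0, shape=canvas.shape)
        mask[rr, cc] = True
    canvas[mask] = value
    return np.argwhere(mask)


def gen_microglia_image(
    cfg: GeneratorConfig,
    shape: tuple[int, int] = (256, 256),
    n_ameboid: int = 5,
    n_ramified: int = 5,
    body_diameter_range: tuple[int, int] = (9, 15),
    process_spec: dict | None = None,
    background: float = 0.05,
    cell_intensity: float = 0.8,
    margin: int = 6,
    min_separation: int = 10,
    max_tries: int = 2000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthetic micrograph of ameboid and ramified cells + ground truth.

    Ameboid (activated-like) cells are filled disks with diameters drawn
    from ``body_diameter_range``; ramified (surveillant-like) cells are
    crosses of two perpendicular bars with a small central soma
    (``process_spec``: ``bar_length``, ``bar_width``, ``soma_diameter``;
    default 15 x 3 px bars, 5 px soma).  Cells are placed by rejection
    sampling with non-overlapping, separated bounding boxes away from
    the border.  Noise: additive Gaussian with
    sd = noise_level * (cell_intensity - background).

    Returns ``(image, ground_truth)``; the ground-truth table has one
    row per cell with kind, centroid, area, bounding box and Extent.
    """
    process_spec = process_spec or {"bar_length": 15, "bar_width": 3,
                                    "soma_diameter": 5}
    bar_len = int(process_spec["bar_length"])
    bar_w = int(process_spec["bar_width"])
    soma_d = int(process_spec.get("soma_diameter", 0))
    if bar_len % 2 == 0 or bar_w % 2 == 0:
        raise InvalidParameterError("bar_length and bar_width must be odd")
    h, w = shape
    rng = cfg.rng("microglia")
    img = np.full(shape, background, dtype=float)

    placed: list[tuple[int, int, int, int]] = []  # bounding boxes (r0, c0, r1, c1)

    def fits(r0, c0, r1, c1):
        if r0 < margin or c0 < margin or r1 > h - margin or c1 > w - margin:
            return False
        s = min_separation
        return all(r1 + s <= pr0 or pr1 + s <= r0 or c1 + s <= pc0 or pc1 + s <= c0
                   for pr0, pc0, pr1, pc1 in placed)

    rows = []
    kinds = ["ameboid"] * n_ameboid + ["ramified"] * n_ramified
    for kind in kinds:
        for attempt in range(max_tries):
            if kind == "ameboid":
                d = int(rng.integers(body_diameter_range[0], body_diameter_range[1] + 1))
                half = d // 2 + 1
            else:
                half = bar_len // 2 + 1
            r = int(rng.integers(half, h - half))
            c = int(rng.integers(half, w - half))
            r0, c0, r1, c1 = r - half, c - half, r + half + 1, c + half + 1
            if not fits(r0, c0, r1, c1):
                continue
            if kind == "ameboid":
                coords = _draw_disk(img, (r, c), d / 2.0, cell_intensity)
            else:
                coords = _draw_cross(img, (r, c), bar_len, bar_w, soma_d,
                                     cell_intensity)
            placed.append((r0, c0, r1, c1))
            bmin = coords.min(axis=0)
            bmax = coords.max(axis=0)
            bh, bw_ = int(bmax[0] - bmin[0] + 1), int(bmax[1] - bmin[1] + 1)
            rows.append({
                "kind": kind, "centroid_row": r, "centroid_col": c,
                "area_px": len(coords),
                "bbox_min_row": int(bmin[0]), "bbox_min_col": int(bmin[1]),
                "bbox_h": bh, "bbox_w": bw_,
                "extent": len(coords) / (bh * bw_),
            })
            break
        else:
            raise PackingError(
                f"could not place {kind} cell after {max_tries} tries "
                f"(requested {n_ameboid} + {n_ramified} cells in {shape})"
            )

    if cfg.noise_level > 0:
        img = img + cfg.noise_level * (cell_intensity - background) \
            * rng.standard_normal(shape)
    return img, pd.DataFrame(rows)
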