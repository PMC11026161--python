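"""Electrochemical characterization of microelectrodes.

Implements the standard in vitro workup of a capacitive microelectrode:

* **EIS fitting** — the impedance spectrum is fitted to a series
  resistance plus constant phase element (CPE),
  ``Z(w) = R_s + 1/(Q (jw)^n)``, the minimal equivalent circuit for a
  porous capacitive coating.  The CPE is converted to an equivalent
  capacitance and normalized by geometric area.
* **CSC** — cathodic/anodic charge storage capacity by integrating a
  cyclic voltammogram and normalizing by scan rate and area.
* **Pulse transients** — ohmic-drop removal and interfacial polarization
  excursions from the voltage response to biphasic current pulses.
* **CIC** — charge injection capacity: the charge density per phase at
  which the ohmic-corrected polarization reaches the water window
  (default -0.9 V cathodic / +0.8 V anodic vs Ag/AgCl).
* **CIL map** — grid of cathodic excursions over pulse width x charge
  density, plus a maximum-safe-density query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateFitError, FitError, InvalidParameterError

#: Default electrochemical water window, V vs Ag/AgCl (cathodic, anodic limit).
WATER_WINDOW = (-0.9, 0.8)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImpedanceSpectrum:
    """Frequency-indexed complex impedance of one electrode.

    Parameters
    ----------
    frequencies : array of float
        Hz, strictly positive, sorted ascending.
    impedance : array of complex
        Complex impedance in ohm at each frequency.
    electrode_id : str
        Free-form label.
    geometric_area : float
        Geometric (not electrochemical) electrode area in cm^2.
    """

    frequencies: np.ndarray
    impedance: np.ndarray
    electrode_id: str = ""
    geometric_area: float = 1.0

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=complex)
        if self.frequencies.size != self.impedance.size:
            raise InvalidParameterError("frequencies and impedance must have equal length")
        if self.frequencies.size and np.any(self.frequencies <= 0):
            raise InvalidParameterError("frequencies must be strictly positive")
        if self.frequencies.size and np.any(np.diff(self.frequencies) <= 0):
            order = np.argsort(self.frequencies)
            self.frequencies = self.frequencies[order]
            self.impedance = self.impedance[order]
        if not (np.all(np.isfinite(self.frequencies)) and np.all(np.isfinite(self.impedance))):
            raise InvalidParameterError("impedance spectrum contains non-finite values")
        if self.geometric_area <= 0:
            raise InvalidParameterError("geometric_area must be > 0")

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.impedance)

    @property
    def phase_rad(self) -> np.ndarray:
        return np.angle(self.impedance)


@dataclass
class CpeFit:
    """Result of a series R + CPE fit to an impedance spectrum."""

    R_series: float              # ohm
    Q_cpe: float                 # S * s^n
    n_exponent: float            # dimensionless, (0, 1]
    capacitance: float           # F, equivalent capacitance of the CPE
    areal_capacitance: float     # F / cm^2
    rms_residual: float          # dimensionless (weighted)
    conversion: str = "brug"     # CPE -> C rule in effect


@dataclass
class CyclicVoltammogram:
    """One (or more) triangular potential sweep(s) with the current trace."""

    potential: np.ndarray        # V vs Ag/AgCl
    current: np.ndarray          # A
    scan_rate: float             # V/s
    geometric_area: float        # cm^2
    window: tuple[float, float]  # (V_min, V_max)

    def __post_init__(self):
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.potential.size != self.current.size:
            raise InvalidParameterError("potential and current must have equal length")
        if self.scan_rate <= 0:
            raise InvalidParameterError("scan_rate must be > 0")
        if self.geometric_area <= 0:
            raise InvalidParameterError("geometric_area must be > 0")
        v_min, v_max = self.window
        if not v_min < v_max:
            raise InvalidParameterError("window must satisfy V_min < V_max")


@dataclass
class CscResult:
    """Cathodic and anodic charge storage capacity, mC/cm^2."""

    cCSC: float
    aCSC: float
    scan_rate: float


@dataclass
class PulseTrace:
    """Electrode voltage response to a current-controlled biphasic pulse."""

    time: np.ndarray             # s
    voltage: np.ndarray          # V vs Ag/AgCl
    amplitude: float             # A, per-phase current magnitude
    phase_width: float           # s
    cathodic_first: bool = True
    geometric_area: float = 1.0  # cm^2
    sampling_rate: float = 0.0   # Hz

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.size != self.voltage.size:
            raise InvalidParameterError("time and voltage must have equal length")
        if self.sampling_rate <= 0 and self.time.size > 1:
            self.sampling_rate = 1.0 / float(np.median(np.diff(self.time)))
        if self.sampling_rate * self.phase_width < 20:
            raise InvalidParameterError(
                "pulse undersampled: need sampling_rate >= "
                f"{20.0 / self.phase_width:.3g} Hz for phase_width {self.phase_width:g} s"
            )
        if self.geometric_area <= 0:
            raise InvalidParameterError("geometric_area must be > 0")


@dataclass
class TransientMetrics:
    """Ohmic-corrected polarization metrics of one pulse transient.

    ``cathodic_excursion`` is the signed minimum of the interfacial
    potential (relative to baseline) during the cathodic phase;
    ``anodic_excursion`` the signed maximum during the anodic phase.
    """

    ohmic_drop: float            # V, magnitude of the instantaneous step
    access_resistance: float     # ohm
    cathodic_excursion: float    # V, signed
    anodic_excursion: float      # V, signed
    charge_density: float        # mC/cm^2 per phase


@dataclass
class CilMap:
    """Cathodic excursion magnitude over a pulse-width x charge-density grid."""

    pulse_widths: np.ndarray       # s
    charge_densities: np.ndarray   # mC/cm^2
    excursion_matrix: np.ndarray   # V (magnitude), shape (n_widths, n_densities)

    def __post_init__(self):
        self.pulse_widths = np.asarray(self.pulse_widths, dtype=float)
        self.charge_densities = np.asarray(self.charge_densities, dtype=float)
        self.excursion_matrix = np.asarray(self.excursion_matrix, dtype=float)
        if self.excursion_matrix.shape != (self.pulse_widths.size, self.charge_densities.size):
            raise InvalidParameterError("excursion_matrix shape must be (n_widths, n_densities)")

    def max_safe_density(self, window: tuple[float, float] = WATER_WINDOW) -> np.ndarray:
        """Per pulse width, the largest tested density whose cathodic
        excursion magnitude stays inside the window; NaN if none does."""
        limit = abs(window[0])
        out = np.full(self.pulse_widths.size, np.nan)
        for i in range(self.pulse_widths.size):
            safe = self.charge_densities[self.excursion_matrix[i] <= limit]
            if safe.size:
                out[i] = safe.max()
        return out


@dataclass
class CicResult:
    """Charge injection capacity of one electrode at one pulse width."""

    cic: float                   # mC/cm^2; lower bound if out_of_grid
    limiting_side: str           # "cathodic" | "anodic" | "none"
    pulse_width: float           # s
    window: tuple[float, float] = WATER_WINDOW
    out_of_grid: bool = False    # window never reached; cic is a lower bound
    below_grid: bool = False     # first tested amplitude already exceeded window
    method: str = "interpolate"


# ---------------------------------------------------------------------------
# Forward model helpers
# ---------------------------------------------------------------------------

def cpe_impedance(freq: np.ndarray, R_s: float, Q: float, n: float) -> np.ndarray:
    """Series R + CPE impedance ``R_s + 1/(Q (j 2 pi f)^n)``."""
    w = 2.0 * np.pi * np.asarray(freq, dtype=float)
    return R_s + 1.0 / (Q * (1j * w) ** n)


def cpe_to_capacitance(R_s: float, Q: float, n: float, rule: str = "brug") -> float:
    """Convert CPE parameters to an equivalent capacitance.

    ``brug`` uses the single-time-constant relation
    ``C = (Q * R_s^(1-n))^(1/n)`` (for n close to 1 this reduces to Q);
    ``direct`` takes C = Q, treating the CPE magnitude as a capacitance.
    """
    if rule == "direct":
        return float(Q)
    if rule != "brug":
        raise InvalidParameterError(f"unknown CPE->C conversion rule {rule!r}")
    if n >= 0.999 or R_s == 0.0:
        # R_s^(1-n) -> 1 as n -> 1; avoids 0^0 ambiguity at R_s = 0
        return float(Q)
    if R_s < 0:
        raise InvalidParameterError("R_series must be >= 0 for the brug conversion")
    return float((Q * R_s ** (1.0 - n)) ** (1.0 / n))


# ---------------------------------------------------------------------------
# EIS
# ---------------------------------------------------------------------------

def fit_eis(spectrum: ImpedanceSpectrum, cpe_to_c: str = "brug") -> CpeFit:
    """Fit a series R + CPE model to an impedance spectrum.

    Least squares on modulus and phase jointly, with the modulus residual
    weighted by 1/|Z| so every frequency decade contributes comparably.

    Raises
    ------
    DegenerateFitError
        If the spectrum has no capacitive signature (phase ~ 0 everywhere).
    FitError
        If the optimizer fails or returns non-physical parameters.
    """
    f = spectrum.frequencies
    if f.size < 8:
        raise InvalidParameterError("fit_eis needs at least 8 frequencies")
    if np.log10(f[-1] / f[0]) < 2.0:
        raise InvalidParameterError("fit_eis needs frequencies spanning >= 2 decades")

    z = spectrum.impedance
    mod = np.abs(z)
    ph = np.angle(z)
    if np.max(np.abs(ph)) < 0.02:  # < ~1.1 deg everywhere: pure resistor
        raise DegenerateFitError(
            "no capacitive signature: phase is ~0 at all frequencies, Q is unidentifiable",
            diagnostics={"max_abs_phase_rad": float(np.max(np.abs(ph)))},
        )

    # initial guesses: R from the high-frequency real part, n from the phase
    # plateau, Q from the low-frequency CPE branch
    r0 = max(float(z.real[-1]), 0.0)
    n0 = min(max(float(np.median(-ph / (np.pi / 2))), 0.3), 1.0)
    w0 = 2.0 * np.pi * f[0]
    zc0 = max(mod[0] - r0, mod[0] * 1e-3)
    q0 = 1.0 / (zc0 * w0 ** n0)

    def residuals(theta):
        r, logq, n = theta
        zm = cpe_impedance(f, r, 10.0 ** logq, n)
        return np.concatenate([
            (np.abs(zm) - mod) / mod,
            np.angle(zm) - ph,
        ])

    try:
        sol = least_squares(
            residuals,
            x0=[r0, math.log10(q0), n0],
            bounds=([0.0, -18.0, 0.05], [np.inf, 3.0, 1.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise FitError(f"EIS least-squares failed: {exc}") from exc
    if not sol.success:
        raise FitError("EIS least-squares did not converge",
                       diagnostics={"status": sol.status, "message": sol.message})

    r_hat, logq_hat, n_hat = sol.x
    q_hat = 10.0 ** logq_hat
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    if q_hat <= 0 or n_hat <= 0:
        raise FitError("non-physical CPE parameters", diagnostics={"Q": q_hat, "n": n_hat})

    cap = cpe_to_capacitance(r_hat, q_hat, n_hat, rule=cpe_to_c)
    if cap <= 0:
        raise FitError("derived capacitance is non-positive",
                       diagnostics={"R": r_hat, "Q": q_hat, "n": n_hat})
    return CpeFit(
        R_series=float(r_hat),
        Q_cpe=float(q_hat),
        n_exponent=float(n_hat),
        capacitance=cap,
        areal_capacitance=cap / spectrum.geometric_area,
        rms_residual=rms,
        conversion=cpe_to_c,
    )


def impedance_at(spectrum: ImpedanceSpectrum, f: float) -> float:
    """|Z| at frequency ``f`` by linear interpolation in log-frequency."""
    fr = spectrum.frequencies
    if not (fr[0] <= f <= fr[-1]):
        raise InvalidParameterError(
            f"frequency {f:g} Hz outside spectrum range [{fr[0]:g}, {fr[-1]:g}] Hz"
        )
    return float(np.interp(np.log10(f), np.log10(fr), spectrum.modulus))


# ---------------------------------------------------------------------------
# CV / CSC
# ---------------------------------------------------------------------------

def csc_from_cv(cv: CyclicVoltammogram) -> CscResult:
    """Charge storage capacity from one complete CV cycle.

    cCSC = integral of |i| over potential for cathodic (negative) current,
    divided by scan rate and geometric area; aCSC analogous for anodic
    current.  Reported in mC/cm^2.
    """
    p, i = cv.potential, cv.current
    if p.size < 4:
        raise InvalidParameterError("CV trace too short")
    dv = np.diff(p)
    up = float(np.sum(dv[dv > 0]))
    down = float(-np.sum(dv[dv < 0]))
    span = cv.window[1] - cv.window[0]
    if up < 0.95 * span or down < 0.95 * span:
        raise InvalidParameterError(
            "incomplete CV cycle: sweep must traverse the window in both directions"
        )

    i_neg = np.abs(np.minimum(i, 0.0))
    i_pos = np.maximum(i, 0.0)
    adv = np.abs(dv)
    q_c = float(np.sum(0.5 * (i_neg[:-1] + i_neg[1:]) * adv))  # A*V
    q_a = float(np.sum(0.5 * (i_pos[:-1] + i_pos[1:]) * adv))
    scale = 1e3 / (cv.scan_rate * cv.geometric_area)            # -> mC/cm^2
    return CscResult(cCSC=q_c * scale, aCSC=q_a * scale, scan_rate=cv.scan_rate)


# ---------------------------------------------------------------------------
# Pulse transients / CIC
# ---------------------------------------------------------------------------

def _detect_onset(voltage: np.ndarray) -> int:
    """Index of the first sample after the pulse-onset discontinuity."""
    dv = np.abs(np.diff(voltage))
    peak = dv.max()
    if peak == 0:
        raise FitError("no detectable current-step instant",
                       diagnostics={"max_abs_dv": 0.0})
    cand = np.nonzero(dv > 0.25 * peak)[0]
    return int(cand[0]) + 1


def analyze_transient(
    trace: PulseTrace,
    window: tuple[float, float] = WATER_WINDOW,
    extremum: str = "within_phase",
    backextrap_samples: int = 0,
) -> TransientMetrics:
    """Ohmic drop and interfacial excursions of one biphasic pulse transient.

    The ohmic drop is the voltage discontinuity straddling the current
    onset (first sample after minus last sample before); with
    ``backextrap_samples = k > 0`` a line is fitted to the first k
    post-onset samples and extrapolated back to the onset instant, which
    removes the polarization ramp contribution in band-limited traces.
    The interfacial potential is the trace minus baseline minus
    ``i(t) * R_access``, with i(t) reconstructed from the trace metadata.
    """
    v = trace.voltage
    if trace.amplitude == 0 or np.allclose(v, v[0]):
        cd = trace.amplitude * trace.phase_width / trace.geometric_area * 1e3
        return TransientMetrics(0.0, 0.0, 0.0, 0.0, cd)
    if trace.amplitude < 0:
        raise InvalidParameterError("amplitude must be > 0 (polarity via cathodic_first)")

    i_on = _detect_onset(v)
    if i_on < 2:
        raise FitError("no pre-pulse baseline before detected onset",
                       diagnostics={"onset_index": i_on})
    baseline = float(np.mean(v[:i_on]))

    npw = int(round(trace.phase_width * trace.sampling_rate))
    sign1 = -1.0 if trace.cathodic_first else 1.0
    current = np.zeros_like(v)
    current[i_on:i_on + npw] = sign1 * trace.amplitude
    current[i_on + npw:i_on + 2 * npw] = -sign1 * trace.amplitude

    if backextrap_samples > 1:
        k = min(backextrap_samples, npw)
        t_seg = trace.time[i_on:i_on + k]
        coef = np.polyfit(t_seg, v[i_on:i_on + k], 1)
        v_at_onset = float(np.polyval(coef, trace.time[i_on]))
    else:
        v_at_onset = float(v[i_on])
    ohmic_drop = abs(v_at_onset - v[i_on - 1])
    r_access = ohmic_drop / trace.amplitude

    pol = v - baseline - current * r_access
    ph1 = slice(i_on, i_on + npw)
    ph2 = slice(i_on + npw, i_on + 2 * npw)
    cat_slice, an_slice = (ph1, ph2) if trace.cathodic_first else (ph2, ph1)
    if extremum == "within_phase":
        cat = float(np.min(pol[cat_slice]))
        ano = float(np.max(pol[an_slice]))
    elif extremum == "end_of_phase":
        cat = float(pol[cat_slice][-1])
        ano = float(pol[an_slice][-1])
    else:
        raise InvalidParameterError(f"unknown extremum policy {extremum!r}")

    cd = trace.amplitude * trace.phase_width / trace.geometric_area * 1e3
    return TransientMetrics(
        ohmic_drop=ohmic_drop,
        access_resistance=r_access,
        cathodic_excursion=cat,
        anodic_excursion=ano,
        charge_density=cd,
    )


def _crossing_density(densities, excursions, limit, side) -> tuple[float | None, bool]:
    """First charge density at which the signed excursion reaches ``limit``.

    Returns (density, below_grid).  Linear interpolation between the
    bracketing tested densities; None if the limit is never reached.
    """
    reached = excursions <= limit if side == "cathodic" else excursions >= limit
    idx = np.nonzero(reached)[0]
    if idx.size == 0:
        return None, False
    j = int(idx[0])
    if j == 0:
        return float(densities[0]), True
    e0, e1 = excursions[j - 1], excursions[j]
    d0, d1 = densities[j - 1], densities[j]
    frac = (limit - e0) / (e1 - e0)
    return float(d0 + frac * (d1 - d0)), False


def cic_from_excursions(
    charge_densities,
    cathodic_excursions=None,
    anodic_excursions=None,
    window: tuple[float, float] = WATER_WINDOW,
    pulse_width: float = float("nan"),
    method: str = "interpolate",
) -> CicResult:
    """Charge injection capacity from tested densities and signed excursions.

    The CIC is the smallest charge density at which either excursion
    reaches its window edge, linearly interpolated between the bracketing
    tested densities (``method="interpolate"``, default) or the largest
    tested density still inside the window (``method="last_safe"``).
    """
    d = np.asarray(charge_densities, dtype=float)
    if d.size < 2:
        raise InvalidParameterError("need >= 2 tested amplitudes")
    if np.any(np.diff(d) <= 0):
        raise InvalidParameterError("charge densities must be strictly increasing")
    if method not in ("interpolate", "last_safe"):
        raise InvalidParameterError(f"unknown CIC method {method!r}")

    candidates: list[tuple[float, str, bool]] = []
    for exc, side, limit in (
        (cathodic_excursions, "cathodic", window[0]),
        (anodic_excursions, "anodic", window[1]),
    ):
        if exc is None:
            continue
        exc = np.asarray(exc, dtype=float)
        if exc.size != d.size:
            raise InvalidParameterError("excursions must match charge_densities length")
        dens, below = _crossing_density(d, exc, limit, side)
        if dens is not None:
            candidates.append((dens, side, below))
    if not candidates:
        return CicResult(cic=float(d[-1]), limiting_side="none", pulse_width=pulse_width,
                         window=window, out_of_grid=True, method=method)
    dens, side, below = min(candidates)
    if method == "last_safe" and not below:
        dens = float(d[d < dens][-1])
    return CicResult(cic=dens, limiting_side=side, pulse_width=pulse_width,
                     window=window, below_grid=below, method=method)


def compute_cic(
    traces: list[PulseTrace],
    window: tuple[float, float] = WATER_WINDOW,
    method: str = "interpolate",
    extremum: str = "within_phase",
) -> CicResult:
    """CIC from pulse transients measured at increasing current amplitude."""
    if len(traces) < 2:
        raise InvalidParameterError("need >= 2 pulse traces at different amplitudes")
    pw = traces[0].phase_width
    area = traces[0].geometric_area
    for t in traces[1:]:
        if not math.isclose(t.phase_width, pw, rel_tol=1e-9):
            raise InvalidParameterError("all traces must share one pulse width")
        if not math.isclose(t.geometric_area, area, rel_tol=1e-9):
            raise InvalidParameterError("all traces must share one geometric area")
    metrics = [analyze_transient(t, window=window, extremum=extremum) for t in traces]
    order = np.argsort([m.charge_density for m in metrics])
    dens = np.array([metrics[k].charge_density for k in order])
    cat = np.array([metrics[k].cathodic_excursion for k in order])
    ano = np.array([metrics[k].anodic_excursion for k in order])
    return cic_from_excursions(dens, cat, ano, window=window,
                               pulse_width=pw, method=method)


def build_cil_map(
    model: dict,
    pulse_widths,
    charge_densities,
    window: tuple[float, float] = WATER_WINDOW,
    samples_per_phase: int = 200,
) -> CilMap:
    """Cathodic-excursion map over a pulse-width x charge-density grid.

    ``model`` describes a passive electrode: keys ``R`` (ohm), ``Q``
    (S s^n), ``n``, ``area`` (cm^2).  For each grid point a noise-free
    transient is synthesized and analyzed; the matrix holds the cathodic
    excursion magnitude in volts.
    """
    from .synth import GeneratorConfig, gen_pulse_trace

    pws = np.asarray(pulse_widths, dtype=float)
    cds = np.asarray(charge_densities, dtype=float)
    if pws.size == 0 or cds.size == 0:
        raise InvalidParameterError("pulse-width and charge-density grids must be non-empty")
    if np.any(np.diff(pws) <= 0) or np.any(np.diff(cds) <= 0):
        raise InvalidParameterError("grids must be strictly increasing")

    cfg = GeneratorConfig(seed=0, noise_level=0.0)
    mat = np.zeros((pws.size, cds.size))
    for i, pw in enumerate(pws):
        fs = samples_per_phase / pw
        for j, cd in enumerate(cds):
            amp = cd * 1e-3 * model["area"] / pw  # mC/cm^2 -> A
            tr = gen_pulse_trace(model["R"], model["Q"], model["n"], amp, pw,
                                 fs, model["area"], cfg)
            m = analyze_transient(tr, window=window)
            mat[i, j] = abs(m.cathodic_excursion)
    return CilMap(pulse_widths=pws, charge_densities=cds, excursion_matrix=mat)


def build_cil_map_from_traces(traces: list[PulseTrace],
                              window: tuple[float, float] = WATER_WINDOW) -> CilMap:
    """Assemble a CIL map from measured transients on a complete grid."""
    if not traces:
        raise InvalidParameterError("no traces provided")
    area = traces[0].geometric_area
    for t in traces:
        if not math.isclose(t.geometric_area, area, rel_tol=1e-9):
            raise InvalidParameterError("inconsistent geometric areas across traces")
    rows: dict[float, dict[float, float]] = {}
    for t in traces:
        m = analyze_transient(t, window=window)
        rows.setdefault(t.phase_width, {})[round(m.charge_density, 12)] = abs(m.cathodic_excursion)
    pws = sorted(rows)
    cds = sorted({cd for r in rows.values() for cd in r})
    mat = np.full((len(pws), len(cds)), np.nan)
    for i, pw in enumerate(pws):
        for j, cd in enumerate(cds):
            if cd in rows[pw]:
                mat[i, j] = rows[pw][cd]
    if np.any(np.isnan(mat)):
        raise InvalidParameterError("traces do not cover a complete width x density grid")
    return CilMap(np.array(pws), np.array(cds), mat)


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityTrend:
    """Relative impedance drift over a continuous-pulsing protocol."""

    pulse_counts: np.ndarray
    impedance: np.ndarray            # ohm, |Z| at the monitored frequency
    relative_drift: np.ndarray       # fraction vs baseline, per point
    max_abs_drift: float             # fraction
    extras: dict = field(default_factory=dict)


def stability_series(measurements) -> StabilityTrend:
    """Per-point relative |Z| change vs baseline over pulsing milestones.

    ``measurements`` is a sequence of (pulse_count, impedance_ohm) pairs
    with non-decreasing counts.
    """
    meas = list(measurements)
    if len(meas) < 2:
        raise InvalidParameterError("need at least 2 measurements")
    counts = np.array([m[0] for m in meas], dtype=float)
    z = np.array([m[1] for m in meas], dtype=float)
    if np.any(np.diff(counts) < 0):
        raise InvalidParameterError("pulse counts must be non-decreasing")
    if z[0] == 0:
        raise InvalidParameterError("baseline impedance must be nonzero")
    drift = (z - z[0]) / z[0]
    return StabilityTrend(counts, z, drift, float(np.max(np.abs(drift))))
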