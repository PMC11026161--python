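"""Typed readers/writers for the toolkit's file dialects, plus run manifests.

CSV dialects (exact column names):

* EIS spectra        ``frequency_hz,z_real_ohm,z_imag_ohm``
* CV sweeps          ``potential_v,current_a``
* pulse transients   ``time_s,voltage_v``
* events             ``event_time_s``
* spike times        ``unit_id,spike_time_s``
* recruitment        ``site,muscle,current_ua,cmap_mv``

Scalar metadata (scan rate, area, sampling rate, ...) travels in ``# key:
value`` comment lines at the top of the CSV, or in a JSON sidecar for raw
binary recordings.  All JSON output serializes floats with 9 significant
digits so golden files are stable across platforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .electrochem import CyclicVoltammogram, ImpedanceSpectrum, PulseTrace
from .errors import EmptyInputError, InputFormatError
from .recording import RecordingSegment
from .stim import RecruitmentDataset

_UNIT_HINTS = {
    "frequency_hz": ("frequency",),
    "z_real_ohm": ("z_real",),
    "z_imag_ohm": ("z_imag",),
    "potential_v": ("potential",),
    "current_a": ("current",),
    "time_s": ("time",),
    "voltage_v": ("voltage",),
    "event_time_s": ("event_time",),
    "current_ua": ("current",),
    "cmap_mv": ("cmap",),
    "spike_time_s": ("spike_time",),
}


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def _read_csv(path, required: list[str]) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line.lstrip("#").strip()
        if ":" in stripped:
            k, v = stripped.split(":", 1)
            try:
                meta[k.strip()] = json.loads(v.strip())
            except json.JSONDecodeError:
                meta[k.strip()] = v.strip()
    body = [ln for ln in lines[body_start:] if ln.strip()]
    if not body or len(body) < 2:
        raise EmptyInputError(f"{path}: no records")
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(body)))
    for col in required:
        if col in df.columns:
            continue
        stem = col.rsplit("_", 1)[0]
        wrong = [c for c in df.columns
                 if c.rsplit("_", 1)[0] == stem or c.startswith(_UNIT_HINTS.get(col, (col,))[0])]
        if wrong:
            raise InputFormatError(
                f"{path}: column {wrong[0]!r} does not match required {col!r} "
                "(unit suffix mismatch?)"
            )
        raise InputFormatError(f"{path}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        meta.setdefault("unknown_columns", extra)
    return df, meta


def _write_csv(path, df: pd.DataFrame, meta: dict | None = None):
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {json.dumps(v)}\n")
        df.to_csv(fh, index=False, lineterminator="\n",
                  float_format=lambda x: format(x, ".9g"))


# ---------------------------------------------------------------------------
# Electrochemistry formats
# ---------------------------------------------------------------------------

def read_eis_csv(path, geometric_area: float | None = None) -> ImpedanceSpectrum:
    df, meta = _read_csv(path, ["frequency_hz", "z_real_ohm", "z_imag_ohm"])
    area = geometric_area or meta.get("geometric_area_cm2", 1.0)
    return ImpedanceSpectrum(
        frequencies=df["frequency_hz"].to_numpy(),
        impedance=df["z_real_ohm"].to_numpy() + 1j * df["z_imag_ohm"].to_numpy(),
        electrode_id=str(meta.get("electrode_id", "")),
        geometric_area=float(area),
    )


def write_eis_csv(path, spectrum: ImpedanceSpectrum, meta: dict | None = None):
    df = pd.DataFrame({
        "frequency_hz": spectrum.frequencies,
        "z_real_ohm": spectrum.impedance.real,
        "z_imag_ohm": spectrum.impedance.imag,
    })
    _write_csv(path, df, {
        "geometric_area_cm2": spectrum.geometric_area,
        "electrode_id": spectrum.electrode_id,
        **(meta or {}),
    })


def read_cv_csv(path, scan_rate: float | None = None,
                geometric_area: float | None = None) -> CyclicVoltammogram:
    df, meta = _read_csv(path, ["potential_v", "current_a"])
    sr = scan_rate or meta.get("scan_rate_v_s")
    area = geometric_area or meta.get("geometric_area_cm2")
    if sr is None or area is None:
        raise InputFormatError(f"{path}: scan_rate_v_s and geometric_area_cm2 required "
                               "(header metadata or arguments)")
    pot = df["potential_v"].to_numpy()
    window = meta.get("window_v", [float(pot.min()), float(pot.max())])
    return CyclicVoltammogram(potential=pot, current=df["current_a"].to_numpy(),
                              scan_rate=float(sr), geometric_area=float(area),
                              window=tuple(window))


def write_cv_csv(path, cv: CyclicVoltammogram, meta: dict | None = None):
    df = pd.DataFrame({"potential_v": cv.potential, "current_a": cv.current})
    _write_csv(path, df, {
        "scan_rate_v_s": cv.scan_rate,
        "geometric_area_cm2": cv.geometric_area,
        "window_v": list(cv.window),
        **(meta or {}),
    })


def read_transient_csv(path, **overrides) -> PulseTrace:
    df, meta = _read_csv(path, ["time_s", "voltage_v"])
    kwargs = {
        "amplitude": meta.get("amplitude_a"),
        "phase_width": meta.get("phase_width_s"),
        "cathodic_first": meta.get("cathodic_first", True),
        "geometric_area": meta.get("geometric_area_cm2", 1.0),
        "sampling_rate": meta.get("sampling_rate_hz", 0.0),
    }
    kwargs.update(overrides)
    if kwargs["amplitude"] is None or kwargs["phase_width"] is None:
        raise InputFormatError(f"{path}: amplitude_a and phase_width_s required")
    return PulseTrace(time=df["time_s"].to_numpy(), voltage=df["voltage_v"].to_numpy(),
                      **{k: v for k, v in kwargs.items()})


def write_transient_csv(path, trace: PulseTrace, meta: dict | None = None):
    df = pd.DataFrame({"time_s": trace.time, "voltage_v": trace.voltage})
    _write_csv(path, df, {
        "amplitude_a": trace.amplitude,
        "phase_width_s": trace.phase_width,
        "cathodic_first": trace.cathodic_first,
        "geometric_area_cm2": trace.geometric_area,
        "sampling_rate_hz": trace.sampling_rate,
        **(meta or {}),
    })


# ---------------------------------------------------------------------------
# Recordings: raw little-endian binary + JSON sidecar, or wide CSV
# ---------------------------------------------------------------------------

def write_recording_binary(path, segment: RecordingSegment):
    """float32 little-endian, channel-major, with a ``<path>.json`` sidecar."""
    path = Path(path)
    segment.data.astype("<f4").tofile(path)
    sidecar = {
        "sampling_rate_hz": segment.sampling_rate,
        "n_channels": segment.n_channels,
        "n_samples": segment.n_samples,
        "dtype": "<f4",
        "units": "uV",
        "channel_labels": segment.channel_labels,
        "event_times_s": segment.event_times.tolist(),
        "metadata": _jsonable(segment.metadata),
    }
    path.with_suffix(path.suffix + ".json").write_text(dumps_compact(sidecar))


def read_recording_binary(path) -> RecordingSegment:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise InputFormatError(f"missing JSON sidecar {sidecar_path}")
    side = json.loads(sidecar_path.read_text())
    data = np.fromfile(path, dtype=side["dtype"]).astype(float)
    n_ch, n_s = side["n_channels"], side["n_samples"]
    if data.size != n_ch * n_s:
        raise InputFormatError(
            f"{path}: expected {n_ch * n_s} samples, found {data.size}"
        )
    return RecordingSegment(
        sampling_rate=side["sampling_rate_hz"],
        data=data.reshape(n_ch, n_s),
        channel_labels=side.get("channel_labels", []),
        event_times=np.asarray(side.get("event_times_s", [])),
        metadata=side.get("metadata", {}),
    )


def write_recording_csv(path, segment: RecordingSegment):
    t = np.arange(segment.n_samples) / segment.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for lbl, row in zip(segment.channel_labels, segment.data):
        df[f"{lbl}_uv"] = row
    _write_csv(path, df, {
        "sampling_rate_hz": segment.sampling_rate,
        "event_times_s": segment.event_times.tolist(),
    })


def read_events_csv(path) -> np.ndarray:
    df, _ = _read_csv(path, ["event_time_s"])
    return df["event_time_s"].to_numpy(dtype=float)


def read_spikes_csv(path) -> dict[str, np.ndarray]:
    df, _ = _read_csv(path, ["unit_id", "spike_time_s"])
    return {str(u): g["spike_time_s"].to_numpy(dtype=float)
            for u, g in df.groupby("unit_id", sort=False)}


def read_recruitment_csv(path) -> RecruitmentDataset:
    df, _ = _read_csv(path, ["site", "muscle", "current_ua", "cmap_mv"])
    return RecruitmentDataset(table=df)


def write_recruitment_csv(path, dataset: RecruitmentDataset, meta: dict | None = None):
    _write_csv(path, dataset.table, meta or {})


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """8/16-bit grayscale TIFF or PNG -> float array in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    return arr.astype(float)


def write_image(path, image: np.ndarray):
    """Write a float image in [0, 1] as 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    u16 = np.round(arr * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, u16)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, u16)


# ---------------------------------------------------------------------------
# JSON reports & manifests
# ---------------------------------------------------------------------------

def _round_sig(x: float, sig: int = 9) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(format(x, f".{sig}g"))


def _jsonable(obj, sig: int = 9):
    """Recursively convert to JSON-serializable values with 9-sig-digit floats."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj), sig)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v, sig) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v, sig) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def dumps_compact(obj) -> str:
    return json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n"


def write_report(path, payload: dict):
    Path(path).write_text(dumps_compact(payload))


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    tool_version: str
    subcommand: str
    config: dict
    input_digests: dict = field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path):
        write_report(path, asdict(self))
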