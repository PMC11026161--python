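"""Intrafascicular stimulation selectivity.

Recruitment curves are built from compound muscle action potential
(CMAP) amplitudes recorded while biphasic current pulses of increasing
amplitude are delivered through each electrode site.  Amplitudes are
normalized per muscle by the experiment-wide maximum (nCMAP), threshold
currents are read off at 5/30/95% of maximal activation, and a
selectivity index

    SI_i = nCMAP_i / sum_j nCMAP_j

is evaluated per site, either at the minimal functionally relevant
current (first current at which any muscle reaches 5% activation) or at
the current where a target muscle first reaches a benchmark activation
level (default 30%, the level conventionally taken as sufficient to
overcome gravity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .recording import RecordingSegment

THRESHOLD_LEVELS = (0.05, 0.30, 0.95)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RecruitmentDataset:
    """Per-site, per-muscle CMAP amplitude versus stimulation current.

    ``table`` columns: ``site, muscle, current_ua, cmap_mv``.
    """

    table: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"site", "muscle", "current_ua", "cmap_mv"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidParameterError(f"recruitment table missing columns: {sorted(missing)}")
        if (self.table["cmap_mv"] < 0).any():
            raise InvalidParameterError("CMAP amplitudes must be >= 0")
        for (site, muscle), grp in self.table.groupby(["site", "muscle"], sort=False):
            cur = grp["current_ua"].to_numpy()
            if np.any(np.diff(cur) <= 0):
                raise InvalidParameterError(
                    f"currents must be strictly increasing (site {site}, muscle {muscle})"
                )

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.table["site"]))

    @property
    def muscles(self) -> list[str]:
        return list(dict.fromkeys(self.table["muscle"]))

    def currents(self, site: str, muscle: str) -> np.ndarray:
        grp = self.table[(self.table["site"] == site) & (self.table["muscle"] == muscle)]
        return grp["current_ua"].to_numpy(dtype=float)

    def amplitudes(self, site: str, muscle: str) -> np.ndarray:
        grp = self.table[(self.table["site"] == site) & (self.table["muscle"] == muscle)]
        return grp["cmap_mv"].to_numpy(dtype=float)


@dataclass
class RecruitmentCurve:
    """Normalized recruitment curve of one site x muscle pair."""

    site: str
    muscle: str
    currents: np.ndarray          # uA
    ncmap: np.ndarray             # in [0, 1], normalized per muscle
    max_raw_amplitude: float      # mV, experiment-wide per-muscle maximum
    thresholds: dict              # level -> uA (interpolated) or None
    unresponsive: bool = False


@dataclass
class SelectivityResult:
    """Selectivity indices per site and best site per muscle.

    ``per_site`` maps site -> {"current_ua": float, "si": {muscle: float}}
    (sites with no qualifying current are absent); ``per_muscle`` maps
    muscle -> {"site": str, "si": float, "current_ua": float}.
    """

    criterion: str
    level: float
    per_site: dict
    per_muscle: dict
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def extract_cmaps(emg: RecordingSegment, stim_times, response_window: float = 0.010,
                  baseline_window: float = 0.002, channel: int = 0) -> np.ndarray:
    """CMAP amplitude per stimulus: baseline minus the post-stimulus minimum.

    The amplitude is measured from the pre-stimulus baseline (mean over
    ``baseline_window``) to the maximum negative peak within
    ``response_window`` after the stimulus, reported >= 0 in the units of
    the trace.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    fs = emg.sampling_rate
    x = emg.data[channel]
    n_resp = int(round(response_window * fs))
    n_base = max(int(round(baseline_window * fs)), 1)
    idx = np.round(stim_times * fs).astype(int)
    if stim_times.size > 1:
        gaps = np.diff(idx)
        if np.any(gaps < n_resp):
            raise InvalidParameterError("response windows overlap between stimuli")
    amps = np.empty(stim_times.size)
    for k, i0 in enumerate(idx):
        if i0 - n_base < 0 or i0 + n_resp > x.size:
            raise InvalidParameterError(f"response window for stimulus {k} outside the trace")
        baseline = float(np.mean(x[i0 - n_base:i0]))
        peak = float(np.min(x[i0:i0 + n_resp]))
        amps[k] = max(baseline - peak, 0.0)
    return amps


def _first_crossing(currents: np.ndarray, values: np.ndarray, level: float) -> float | None:
    """Current of the first crossing of ``level``, linearly interpolated.

    Ties at equal currents break toward the lower current (the first
    grid point at or above the level is used as the bracketing sample).
    """
    above = values >= level
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    j = int(idx[0])
    if j == 0 or values[j] == values[j - 1]:
        return float(currents[j])
    frac = (level - values[j - 1]) / (values[j] - values[j - 1])
    return float(currents[j - 1] + frac * (currents[j] - currents[j - 1]))


def build_recruitment(dataset: RecruitmentDataset,
                      levels=THRESHOLD_LEVELS) -> dict[tuple[str, str], RecruitmentCurve]:
    """Normalized recruitment curves with interpolated threshold currents.

    Normalization is by the per-muscle maximum over all sites and
    currents in the experiment.  Thresholds are the first crossing of
    each level, linearly interpolated between bracketing grid points;
    levels never reached give ``None`` (flagged, not extrapolated).
    """
    max_per_muscle = {
        m: float(dataset.table.loc[dataset.table["muscle"] == m, "cmap_mv"].max())
        for m in dataset.muscles
    }
    curves: dict[tuple[str, str], RecruitmentCurve] = {}
    for site in dataset.sites:
        for muscle in dataset.muscles:
            cur = dataset.currents(site, muscle)
            amp = dataset.amplitudes(site, muscle)
            if cur.size == 0:
                continue
            vmax = max_per_muscle[muscle]
            if vmax == 0:
                curves[(site, muscle)] = RecruitmentCurve(
                    site, muscle, cur, np.zeros_like(amp), 0.0,
                    {lv: None for lv in levels}, unresponsive=True)
                continue
            ncmap = amp / vmax
            thr = {lv: _first_crossing(cur, ncmap, lv) for lv in levels}
            curves[(site, muscle)] = RecruitmentCurve(site, muscle, cur, ncmap, vmax, thr)
    return curves


def _si_at_current(curves, site, muscles, current) -> dict | None:
    """SI vector at an exact grid current; None if the site is silent there."""
    vals = {}
    for m in muscles:
        c = curves[(site, m)]
        j = np.nonzero(np.isclose(c.currents, current))[0]
        vals[m] = float(c.ncmap[j[0]]) if j.size else 0.0
    total = sum(vals.values())
    if total == 0:
        return None
    return {m: v / total for m, v in vals.items()}


def _best_sites(per_site, muscles) -> dict:
    """Best site per muscle; ties break by lower evaluation current, then
    site order (insertion order of per_site)."""
    out = {}
    for m in muscles:
        best = None
        for site, entry in per_site.items():
            cand = (-entry["si"][m], entry["current_ua"])
            if best is None or cand < best[0]:
                best = (cand, site, entry)
        if best is not None and -best[0][0] > 0:
            out[m] = {"site": best[1], "si": -best[0][0], "current_ua": best[2]["current_ua"]}
    return out


def selectivity_at_minimal_relevant(dataset: RecruitmentDataset,
                                    relevance_level: float = 0.05) -> SelectivityResult:
    """SI per site at the minimal functionally relevant current.

    Per site, the evaluation current is the minimum grid current at
    which any muscle's nCMAP reaches ``relevance_level`` (default 5% of
    that muscle's experiment-wide maximum); SI is computed there for all
    muscles, on the exact grid current (no interpolation).
    """
    curves = build_recruitment(dataset)
    muscles = dataset.muscles
    per_site = {}
    for site in dataset.sites:
        cur = None
        for m in muscles:
            c = curves[(site, m)]
            idx = np.nonzero(c.ncmap >= relevance_level)[0]
            if idx.size:
                cand = float(c.currents[idx[0]])
                cur = cand if cur is None else min(cur, cand)
        if cur is None:
            continue
        si = _si_at_current(curves, site, muscles, cur)
        if si is not None:
            per_site[site] = {"current_ua": cur, "si": si}
    diagnostics = {}
    if not per_site:
        diagnostics["reason"] = (
            f"no site reached nCMAP >= {relevance_level:g} for any muscle"
        )
    return SelectivityResult(
        criterion="minimal_relevant", level=relevance_level,
        per_site=per_site, per_muscle=_best_sites(per_site, muscles),
        diagnostics=diagnostics,
    )


def selectivity_at_activation_level(dataset: RecruitmentDataset, target_muscle: str,
                                    level: float = 0.30) -> SelectivityResult:
    """SI per site at the current where ``target_muscle`` reaches ``level``.

    Per site, the evaluation current is the first grid current at which
    the target muscle's nCMAP reaches the benchmark activation level
    (default 30%); sites where the target never reaches the level are
    flagged in the diagnostics.
    """
    if target_muscle not in dataset.muscles:
        raise InvalidParameterError(f"unknown muscle {target_muscle!r}")
    curves = build_recruitment(dataset)
    muscles = dataset.muscles
    per_site = {}
    unreached = []
    for site in dataset.sites:
        c = curves[(site, target_muscle)]
        idx = np.nonzero(c.ncmap >= level)[0]
        if idx.size == 0:
            unreached.append(site)
            continue
        cur = float(c.currents[idx[0]])
        si = _si_at_current(curves, site, muscles, cur)
        if si is not None:
            per_site[site] = {"current_ua": cur, "si": si}
    diagnostics = {"target_level_unreached_sites": unreached}
    if not per_site:
        diagnostics["reason"] = (
            f"{target_muscle} never reached nCMAP >= {level:g} at any site"
        )
    return SelectivityResult(
        criterion="activation_level", level=level,
        per_site=per_site, per_muscle=_best_sites(per_site, muscles),
        diagnostics=diagnostics,
    )
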