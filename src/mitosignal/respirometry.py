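"""High-resolution respirometry trace analysis.

Implements the analysis chain for a closed-chamber oxygraph record following a
substrate-uncoupler-inhibitor titration (SUIT) protocol:

calibration -> oxygen flux -> phase segmentation at titration events ->
steady-state plateau extraction -> respiratory profile (OXPHOS, LEAK, RCR).

Units: time in seconds, O2 concentration in uM, tissue concentration in
mg ml^-1, flux in pmol O2 s^-1 mg^-1. Consumption is positive flux. With
``sample_conc`` mg/ml, a flux J corresponds to an O2 slope of
-J * sample_conc / 1000 uM/s.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter

STATE_OXPHOS = "OXPHOS_CI+CII"
STATE_LEAK = "LEAK_CI+CII"

#: MiR05 oxygen solubility relative to pure water.
DEFAULT_SOLUBILITY_FACTOR = 0.92


@dataclass(frozen=True)
class OxygraphTrace:
    """A time-stamped O2 concentration series with titration event marks."""

    time: np.ndarray
    o2: np.ndarray
    events: tuple[tuple[float, str], ...]
    sample_conc: float
    temperature: float = 37.0
    solubility_factor: float = DEFAULT_SOLUBILITY_FACTOR

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        o2 = np.asarray(self.o2, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "o2", o2)
        if time.size < 2 or o2.size != time.size:
            raise ValueError("trace needs >= 2 samples with matching time/o2 lengths")
        if np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.sample_conc <= 0:
            raise ValueError("sample_conc must be > 0")
        if not 0 < self.solubility_factor <= 2:
            raise ValueError("solubility_factor must lie in (0, 2]")
        ev = tuple(sorted(((float(t), str(lab)) for t, lab in self.events), key=lambda e: e[0]))
        object.__setattr__(self, "events", ev)
        for t, lab in ev:
            if not time[0] <= t <= time[-1]:
                raise ValueError(f"event {lab!r} at t={t} outside trace time range")


@dataclass(frozen=True)
class Phase:
    """One segment of the SUIT protocol, opened by the titration that labels it."""

    label: str
    t_start: float
    t_end: float

    @property
    def empty(self) -> bool:
        return self.t_start >= self.t_end


@dataclass(frozen=True)
class PhaseFlux:
    state: str
    flux: float
    window: tuple[float, float]
    stability: float


@dataclass(frozen=True)
class RespiratoryProfile:
    """OXPHOS/LEAK fluxes and the respiratory control ratio OXPHOS / LEAK."""

    oxphos_ci_cii: float
    leak_ci_cii: float
    rcr: float | None
    rcr_defined: bool = True
    extras: Mapping[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def calibrate_o2(
    raw_signal,
    saturation_reference: float,
    solubility_factor: float = DEFAULT_SOLUBILITY_FACTOR,
    raw_air: float | None = None,
    raw_zero: float = 0.0,
) -> np.ndarray:
    """Two-point linear O2 calibration.

    ``saturation_reference`` is the air-saturation concentration of pure water
    (uM) at the run's temperature and pressure; the medium's saturation is that
    value scaled by ``solubility_factor``. ``raw_air``/``raw_zero`` are the raw
    sensor readings at air saturation and at zero oxygen; by default the raw
    signal is assumed already expressed on the pure-water concentration scale
    (``raw_air = saturation_reference``).
    """
    raw = np.asarray(raw_signal, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw signal contains non-finite values")
    if saturation_reference <= 0:
        raise ValueError("saturation_reference must be > 0")
    if raw_air is None:
        raw_air = saturation_reference
    if raw_air == raw_zero:
        raise ValueError("air and zero calibration points coincide")
    return (raw - raw_zero) / (raw_air - raw_zero) * saturation_reference * solubility_factor


def _uniform_dt(time: np.ndarray) -> float:
    steps = np.diff(time)
    dt = float(np.median(steps))
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("savgol flux requires uniformly sampled time")
    return dt


def oxygen_flux(trace: OxygraphTrace, smooth_window_s: float = 21.0, method: str = "savgol") -> np.ndarray:
    """Pointwise oxygen flux in pmol O2 s^-1 mg^-1 (consumption positive).

    ``savgol`` differentiates with a local quadratic (Savitzky-Golay) fit over
    ``smooth_window_s``; ``gradient`` is a plain finite-difference fallback used
    by oracle checks. Negative values (reoxygenation) are reported, not clipped.
    """
    if method == "gradient":
        dodt = np.gradient(trace.o2, trace.time)
    elif method == "savgol":
        dt = _uniform_dt(trace.time)
        win = int(round(smooth_window_s / dt))
        win = max(win, 5)
        if win % 2 == 0:
            win += 1
        if win > trace.time.size:
            raise ValueError("smoothing window longer than trace")
        dodt = savgol_filter(trace.o2, window_length=win, polyorder=2, deriv=1, delta=dt)
    else:
        raise ValueError(f"unknown method {method!r}")
    return -dodt * 1000.0 / trace.sample_conc


def segment_phases(trace: OxygraphTrace, equilibration_s: float = 60.0) -> list[Phase]:
    """Split the record into titration-labeled phases, excluding equilibration.

    Phase i spans ``[event_i + equilibration_s, event_{i+1})``; the final phase
    runs to the end of the trace. Samples before the first event form a leading
    ``baseline`` phase. A phase fully consumed by equilibration is reported
    empty with a warning rather than dropped.
    """
    if equilibration_s < 0:
        raise ValueError("equilibration_s must be >= 0")
    t0, t_end = float(trace.time[0]), float(trace.time[-1])
    phases: list[Phase] = []
    if not trace.events:
        return [Phase("baseline", t0, t_end)]
    if trace.events[0][0] > t0:
        phases.append(Phase("baseline", t0, trace.events[0][0]))
    for i, (te, label) in enumerate(trace.events):
        nxt = trace.events[i + 1][0] if i + 1 < len(trace.events) else t_end
        start = te + equilibration_s
        if start >= nxt:
            warnings.warn(
                f"phase {label!r} fully consumed by the {equilibration_s}s equilibration window",
                stacklevel=2,
            )
            start = nxt
        phases.append(Phase(label, start, nxt))
    return phases


def steady_state_flux(
    trace: OxygraphTrace,
    flux: np.ndarray,
    phase: Phase,
    window_s: float = 300.0,
) -> PhaseFlux:
    """Most-stable-plateau flux of one phase.

    The window of length ``window_s`` minimising the rolling SD of the flux
    series is selected; the reported flux is the least-squares O2 slope over
    that window (identical to the mean flux on noise-free data, markedly less
    noisy otherwise). The winning window's flux SD is reported as stability.
    """
    sel = (trace.time >= phase.t_start) & (trace.time < phase.t_end)
    idx = np.flatnonzero(sel)
    if idx.size < 2:
        raise ValueError(f"phase {phase.label!r} contains too few samples")
    dt = float(np.median(np.diff(trace.time[idx])))
    w = int(round(window_s / dt)) + 1
    if w > idx.size:
        raise ValueError(f"phase {phase.label!r} shorter than the {window_s}s plateau window")
    w = max(w, 3)
    fwin = np.lib.stride_tricks.sliding_window_view(flux[idx], w)
    sds = fwin.std(axis=1)
    b = int(np.argmin(sds))
    chosen = idx[b : b + w]
    t_sel = trace.time[chosen]
    slope = np.polyfit(t_sel - t_sel[0], trace.o2[chosen], 1)[0]
    return PhaseFlux(
        state=phase.label,
        flux=float(-slope * 1000.0 / trace.sample_conc),
        window=(float(t_sel[0]), float(t_sel[-1])),
        stability=float(sds[b]),
    )


def respiratory_profile(phase_fluxes: Mapping[str, float] | Sequence[PhaseFlux]) -> RespiratoryProfile:
    """Assemble OXPHOS_CI+CII / LEAK_CI+CII / RCR from per-state fluxes.

    Non-positive LEAK leaves the RCR undefined (``rcr=None, rcr_defined=False``)
    rather than producing a misleading ratio.
    """
    if not isinstance(phase_fluxes, Mapping):
        phase_fluxes = {pf.state: pf.flux for pf in phase_fluxes}
    missing = [s for s in (STATE_OXPHOS, STATE_LEAK) if s not in phase_fluxes]
    if missing:
        raise ValueError(f"missing required respiratory states: {missing}")
    oxphos = float(phase_fluxes[STATE_OXPHOS])
    leak = float(phase_fluxes[STATE_LEAK])
    extras = {k: float(v) for k, v in phase_fluxes.items() if k not in (STATE_OXPHOS, STATE_LEAK)}
    if leak > 0:
        return RespiratoryProfile(oxphos, leak, oxphos / leak, True, extras)
    return RespiratoryProfile(oxphos, leak, None, False, extras)


def analyze_trace(
    trace: OxygraphTrace,
    equilibration_s: float = 60.0,
    smooth_window_s: float = 21.0,
    window_s: float = 300.0,
) -> tuple[list[PhaseFlux], RespiratoryProfile | None]:
    """Full per-trace analysis: flux series, phase plateaus, respiratory profile.

    Phases too short for the plateau window are skipped with a warning; the
    profile is None when either required state is absent.
    """
    flux = oxygen_flux(trace, smooth_window_s=smooth_window_s)
    results: list[PhaseFlux] = []
    for phase in segment_phases(trace, equilibration_s=equilibration_s):
        if phase.empty:
            continue
        try:
            results.append(steady_state_flux(trace, flux, phase, window_s=window_s))
        except ValueError as exc:
            warnings.warn(str(exc), stacklevel=2)
    by_state = {pf.state: pf.flux for pf in results}
    profile = None
    if STATE_OXPHOS in by_state and STATE_LEAK in by_state:
        profile = respiratory_profile(by_state)
    return results, profile
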