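"""Measurement procedures on oscillator trajectories.

Everything the package reports about a simulation comes through here:
peak detection with sub-grid refinement, peak-spacing period estimation,
circular phase-shift estimation between two rhythms, arrhythmicity
detection, constant-light (Aschoff) intensity scans, phase-response
curves and entrainment-range scans.

Period protocol
---------------
Periods are estimated from the spacing of successive peaks of a chosen
variable (the *per* mRNA ``M`` in all standard experiments) inside an
observation window, 80–120 h by default.  Because a damped or long-period
rhythm may place only one peak strictly inside the window, the estimate
uses every peak-to-peak cycle that *overlaps* the window, including the
nearest bounding peaks just outside it; the trajectory therefore has to
extend somewhat past the window.  Peak positions are refined by a local
quadratic fit through the three samples around each grid maximum.

Phase convention
----------------
``estimate_phase_shift(A, B)`` is positive when B peaks later than A.
The shift is a circular mean of nearest-peak offsets, reported either
centered in ``(-T/2, T/2]`` (``wrap="centered"``) or as a forward lag in
``[0, T)`` (``wrap="forward"``, the natural scale for a peripheral clock
lagging a central one by more than half a period).

Arrhythmicity
-------------
A window of signal is called arrhythmic when its modulation depth —
peak-to-trough amplitude divided by the window mean — falls below a
floor (default 1%).  Normalising by the signal's own mean rather than by
an absolute amount makes the classification comparable across variants
whose stimulus ports shift the mean mRNA level very differently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .core_model import CoreParameters, OscillatorState, VariantSpec
from .coupling import NetworkSpec, assemble_network, single_oscillator
from .simulate import SolverSettings, Trajectory, integrate
from .stimuli import StimulusSpec, discontinuity_times

__all__ = [
    "ArrhythmicSignalError",
    "NonEntrainedError",
    "PeriodEstimate",
    "PhaseShiftEstimate",
    "ScanResult",
    "find_peaks",
    "estimate_period",
    "estimate_phase_shift",
    "detect_arrhythmia",
    "scan_constant_light",
    "phase_response_curve",
    "entrainment_range",
    "resynchronization_time",
    "run_network",
    "run_single",
    "sinusoid_trajectory",
    "constant_trajectory",
    "DEFAULT_PERIOD_WINDOW",
    "DEFAULT_TRANSIENT_CUT",
]

DEFAULT_PERIOD_WINDOW = (80.0, 120.0)
DEFAULT_TRANSIENT_CUT = 72.0  # two days of transient plus margin
ARRHYTHMIA_FLOOR = 0.01  # modulation-depth detection limit


class ArrhythmicSignalError(RuntimeError):
    """Fewer than two usable peaks: no period can be assigned."""


class NonEntrainedError(RuntimeError):
    """The two rhythms have different periods; a fixed phase shift is undefined."""


@dataclass(frozen=True)
class PeriodEstimate:
    """Mean successive-peak spacing and the peaks that produced it."""

    period: float
    peak_times: tuple[float, ...]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period!r}")
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")


@dataclass(frozen=True)
class PhaseShiftEstimate:
    """Circular peak-time offset between two rhythms of common period."""

    shift: float
    reference_period: float
    transient_cut: float
    wrap: str = "centered"

    def __post_init__(self) -> None:
        T = self.reference_period
        lo, hi = (-T / 2, T / 2) if self.wrap == "centered" else (0.0, T)
        if not (lo - 1e-9 <= self.shift <= hi + 1e-9):
            raise ValueError(f"shift {self.shift!r} outside the {self.wrap} range for T={T!r}")


@dataclass
class ScanResult:
    """Rows of a parameter scan plus a turning-point summary."""

    table: pd.DataFrame
    scan_column: str
    turning_point: float | None = None
    locked_interval: tuple[float, float] | None = None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# peak detection and period estimation
# ---------------------------------------------------------------------------


def _refine_peak(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through the three samples around grid maximum i."""
    if i == 0 or i == len(t) - 1:
        return float(t[i]), float(y[i])
    t0 = t[i]
    coeff = np.polyfit(t[i - 1 : i + 2] - t0, y[i - 1 : i + 2], 2)
    a, b, c = coeff
    if a >= 0:  # degenerate (flat) neighbourhood: keep the grid point
        return float(t0), float(y[i])
    dt = -b / (2 * a)
    # Ties and pathological fits resolve toward the earlier grid time.
    dt = float(np.clip(dt, t[i - 1] - t0, t[i + 1] - t0))
    return float(t0 + dt), float(c - b * b / (4 * a))


def find_peaks(
    traj: Trajectory,
    variable: str,
    window: tuple[float, float] | None = None,
    min_prominence: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Refined local maxima of ``variable``, optionally restricted to ``window``.

    Returns ``(times, heights)``; an empty pair when the series has no
    interior maxima (e.g. a constant series).  ``min_prominence`` drops
    ripples below a given peak prominence (µM).
    """
    y = traj[variable]
    idx, _ = _scipy_find_peaks(y, prominence=min_prominence or None)
    times = np.empty(idx.size)
    heights = np.empty(idx.size)
    for k, i in enumerate(idx):
        times[k], heights[k] = _refine_peak(traj.t, y, i)
    if window is not None:
        lo, hi = window
        mask = (times >= lo) & (times <= hi)
        times, heights = times[mask], heights[mask]
    return times, heights


def estimate_period(
    traj: Trajectory,
    variable: str,
    window: tuple[float, float] = DEFAULT_PERIOD_WINDOW,
    min_prominence: float = 0.0,
) -> PeriodEstimate:
    """Mean spacing of the successive-peak cycles overlapping ``window``.

    Raises :class:`ArrhythmicSignalError` when no complete peak-to-peak
    cycle touches the window.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window {window!r}")
    times, _ = find_peaks(traj, variable, window=None, min_prominence=min_prominence)
    if times.size < 2:
        raise ArrhythmicSignalError(
            f"{times.size} peak(s) of {variable!r}: cannot estimate a period"
        )
    spacings = []
    used: list[float] = []
    for a, b in zip(times[:-1], times[1:]):
        # keep a peak-to-peak cycle when at least half of it lies inside the
        # window; this admits the bounding peaks of a cycle straddling a
        # window edge but rejects cycles that belong to a different regime
        # (e.g. one spanning the moment a stimulus is switched off)
        overlap = min(b, hi) - max(a, lo)
        if overlap >= 0.5 * (b - a):
            spacings.append(b - a)
            if not used or used[-1] != a:
                used.append(a)
            used.append(b)
    if not spacings:
        raise ArrhythmicSignalError(f"no peak-to-peak cycle of {variable!r} overlaps {window!r}")
    return PeriodEstimate(float(np.mean(spacings)), tuple(used), window)


# ---------------------------------------------------------------------------
# phase shifts
# ---------------------------------------------------------------------------


def _circular_mean_offset(deltas: np.ndarray, T: float) -> float:
    angles = 2.0 * np.pi * deltas / T
    mean_angle = math.atan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))
    return mean_angle * T / (2.0 * np.pi)


def _wrap(shift: float, T: float, wrap: str) -> float:
    if wrap == "forward":
        return shift % T
    centered = (shift + T / 2) % T - T / 2
    return T / 2 if centered == -T / 2 else centered


def estimate_phase_shift(
    traj_a: Trajectory,
    traj_b: Trajectory,
    variable: str,
    transient_cut: float = DEFAULT_TRANSIENT_CUT,
    variable_b: str | None = None,
    wrap: Literal["centered", "forward"] = "centered",
    period_tol: float = 0.5,
    window: tuple[float, float] | None = None,
) -> PhaseShiftEstimate:
    """Circular peak-time offset of rhythm B relative to rhythm A.

    Positive means B peaks later.  Both rhythms must be rhythmic after
    ``transient_cut`` with periods equal within ``period_tol`` hours
    (entrained or free-running at a common rate); otherwise
    :class:`NonEntrainedError` is raised.  ``traj_b``/``variable_b`` may
    name a second column of the same trajectory (coupled-network runs).
    """
    variable_b = variable_b or variable
    lo = transient_cut
    hi_a, hi_b = traj_a.t[-1], traj_b.t[-1]
    if window is not None:
        lo, hi = window
        hi_a = hi_b = hi
    pa = estimate_period(traj_a, variable, window=(lo, hi_a))
    pb = estimate_period(traj_b, variable_b, window=(lo, hi_b))
    if abs(pa.period - pb.period) > period_tol:
        raise NonEntrainedError(
            f"periods differ by {abs(pa.period - pb.period):.2f} h "
            f"({pa.period:.2f} vs {pb.period:.2f}): rhythms are not locked"
        )
    T = 0.5 * (pa.period + pb.period)
    peaks_a = np.asarray(pa.peak_times)
    peaks_b = np.asarray(pb.peak_times)
    deltas = np.array([b - peaks_a[np.argmin(np.abs(peaks_a - b))] for b in peaks_b])
    shift = _wrap(_circular_mean_offset(deltas, T), T, wrap)
    return PhaseShiftEstimate(shift, T, transient_cut, wrap)


def detect_arrhythmia(
    traj: Trajectory,
    variable: str,
    window: tuple[float, float] = DEFAULT_PERIOD_WINDOW,
    floor_fraction: float = ARRHYTHMIA_FLOOR,
) -> tuple[bool, float]:
    """Classify ``variable`` in ``window`` as arrhythmic; return the amplitude.

    Arrhythmic means the modulation depth (peak-to-trough amplitude over
    the window mean) is below ``floor_fraction``: the oscillation has
    faded beyond detection even if tiny ripples remain.  Returns
    ``(is_arrhythmic, peak_to_trough_amplitude)``.
    """
    seg = traj.window(*window)[variable]
    if seg.size == 0:
        raise ValueError(f"window {window!r} contains no samples")
    amplitude = float(seg.max() - seg.min())
    mean = float(seg.mean())
    if mean <= 0:
        return True, amplitude
    return amplitude / mean < floor_fraction, amplitude


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------


def run_network(
    spec: NetworkSpec,
    settings: SolverSettings | None = None,
    extra_series: dict | None = None,
) -> Trajectory:
    """Assemble and integrate a network with its stimulus breakpoints."""
    settings = settings or SolverSettings()
    rhs = assemble_network(spec)
    extras = dict(extra_series or {})
    for osc in spec.oscillators:
        if not osc.stimulus.is_state_valued and osc.stimulus.kind != "zero":
            extras.setdefault(f"{osc.id}.u", osc.stimulus)
    return integrate(
        rhs,
        spec.initial_vector(),
        settings,
        breakpoints=spec.breakpoints(settings.t_end),
        names=spec.variable_names(),
        extra_series=extras,
    )


def run_single(
    variant: VariantSpec | None = None,
    stimulus: StimulusSpec | None = None,
    params: CoreParameters | None = None,
    initial: OscillatorState | None = None,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """One oscillator; columns are ``osc.M``, ``osc.P0``, ... and ``osc.u``."""
    spec = single_oscillator(variant=variant, stimulus=stimulus, params=params, initial=initial)
    return run_network(spec, settings)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def scan_constant_light(
    variant_kind: Literal["fly", "mammal", "mrna_decay"] = "fly",
    c_grid: Sequence[float] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 10)),
    alpha: float = 1.0,
    gamma: float = 2.0,
    rho: float = 1.0,
    window: tuple[float, float] = DEFAULT_PERIOD_WINDOW,
    settings: SolverSettings | None = None,
    params: CoreParameters | None = None,
) -> ScanResult:
    """Period of the stimulated clock versus constant stimulus intensity.

    For each intensity ``c`` the variant model is integrated and the
    period of ``M`` measured in ``window``; entries whose oscillation has
    faded below the detection floor are marked arrhythmic.  The turning
    point (grid argmin of the period over rhythmic rows) summarises
    whether weak constant light shortens and strong light lengthens the
    period — the model's account of Aschoff's rule.
    """
    c_grid = [float(c) for c in c_grid]
    if any(c < 0 for c in c_grid) or np.any(np.diff(c_grid) <= 0) and len(c_grid) > 1:
        raise ValueError("c_grid must be non-negative and strictly increasing")
    if settings is None:
        settings = SolverSettings(t_end=window[1] + 30.0)
    rows = []
    for c in c_grid:
        variant = {
            "fly": lambda: VariantSpec.fly(alpha),
            "mrna_decay": lambda: VariantSpec.mrna_decay(alpha),
            "mammal": lambda: VariantSpec.mammal(gamma, rho),
        }[variant_kind]()
        traj = run_single(
            variant=variant, stimulus=StimulusSpec.constant(c), params=params, settings=settings
        )
        arrhythmic, amplitude = detect_arrhythmia(traj, "osc.M", window=window)
        try:
            period = estimate_period(traj, "osc.M", window=window).period
        except ArrhythmicSignalError:
            period, arrhythmic = np.nan, True
        rows.append(
            {
                "c": c,
                "period": np.nan if arrhythmic else period,
                "amplitude": amplitude,
                "status": "arrhythmic" if arrhythmic else "rhythmic",
            }
        )
    table = pd.DataFrame(rows)
    rhythmic = table.dropna(subset=["period"])
    turning = float(rhythmic.loc[rhythmic["period"].idxmin(), "c"]) if len(rhythmic) else None
    return ScanResult(table, scan_column="c", turning_point=turning)


def phase_response_curve(
    variant: VariantSpec | None = None,
    pulse_duration: float = 1.0,
    pulse_magnitude: float = 1.0,
    ct_grid: Sequence[float] = (0, 3, 6, 9, 12, 15, 18, 21),
    t_end: float = 240.0,
    settings: SolverSettings | None = None,
) -> ScanResult:
    """Steady-state phase shift versus the circadian time of a single pulse.

    Circadian time 0 is anchored at a reference peak of ``M`` on the
    free-running limit cycle (the first peak after 48 h); CT ``x`` maps to
    ``x/24`` of the free-running period after that peak.  For each CT one
    rectangular pulse is applied through the variant's port and the
    post-transient peaks are compared against the unpulsed control; the
    shift is circular in ``(-T/2, T/2]``, positive when the pulsed clock
    peaks later (phase delay).
    """
    variant = variant or VariantSpec.fly(1.0)
    if pulse_magnitude < 0:
        raise ValueError("pulse magnitude must be >= 0")
    settings = settings or SolverSettings(t_end=t_end)
    control = run_single(variant=variant, stimulus=StimulusSpec.zero(), settings=settings)
    free = estimate_period(control, "osc.M", window=(48.0, settings.t_end))
    T = free.period
    anchor = free.peak_times[0]
    rows = []
    for ct in ct_grid:
        t_pulse = anchor + (float(ct) / 24.0) * T
        stim = StimulusSpec.pulse(t_start=t_pulse, duration=pulse_duration, magnitude=pulse_magnitude)
        traj = run_single(variant=variant, stimulus=stim, settings=settings)
        cut = t_pulse + pulse_duration + DEFAULT_TRANSIENT_CUT
        arrhythmic, _ = detect_arrhythmia(traj, "osc.M", window=(cut, settings.t_end))
        if arrhythmic:
            rows.append({"ct": float(ct), "shift": np.nan, "status": "arrhythmic"})
            continue
        est = estimate_phase_shift(
            control, traj, "osc.M", transient_cut=cut, wrap="centered", period_tol=0.5
        )
        rows.append({"ct": float(ct), "shift": est.shift, "status": "rhythmic"})
    return ScanResult(pd.DataFrame(rows), scan_column="ct")


def entrainment_range(
    variant: VariantSpec | None = None,
    amplitude: float = 1.0,
    T_grid: Sequence[float] = tuple(np.round(np.arange(20.0, 28.5, 0.5), 10)),
    t_end: float = 480.0,
    period_tol: float = 0.1,
    drift_tol: float = 0.5,
    settings: SolverSettings | None = None,
) -> ScanResult:
    """Which Zeitgeber periods the clock locks to, at a given stimulus strength.

    For each Zeitgeber period ``T`` the model is driven by the
    raised-cosine cycle scaled by ``amplitude``; it counts as entrained
    when the observed post-transient period matches ``T`` within
    ``period_tol`` hours and the peak-phase drift over the last five
    cycles stays below ``drift_tol`` hours.  ``locked_interval`` is the
    contiguous locked stretch of the grid containing 24 h.
    """
    variant = variant or VariantSpec.fly(1.0)
    if any(T <= 0 for T in T_grid):
        raise ValueError("Zeitgeber periods must be positive")
    settings = settings or SolverSettings(t_end=t_end)
    rows = []
    for T in T_grid:
        T = float(T)
        if amplitude == 0.0:
            stim = StimulusSpec.zero()
        else:
            stim = StimulusSpec.periodic(phi=0.0, period=T, amplitude=amplitude)
        traj = run_single(variant=variant, stimulus=stim, settings=settings)
        # the approach to lock is a slowly damped phase oscillation, so the
        # classification window starts at half the horizon, well past the
        # standard two-day transient
        window = (max(DEFAULT_TRANSIENT_CUT, settings.t_end / 2), settings.t_end)
        try:
            est = estimate_period(traj, "osc.M", window=window)
        except ArrhythmicSignalError:
            rows.append({"T_zeit": T, "period": np.nan, "status": "arrhythmic"})
            continue
        locked = abs(est.period - T) <= period_tol
        if locked and len(est.peak_times) >= 6:
            last = np.asarray(est.peak_times[-6:])
            residuals = last - np.arange(last.size) * T
            locked = residuals.max() - residuals.min() < drift_tol
        status = "locked" if locked else "unlocked"
        rows.append({"T_zeit": T, "period": est.period, "status": status})
    table = pd.DataFrame(rows)
    locked_interval = None
    locked_mask = (table["status"] == "locked").to_numpy()
    t_arr = table["T_zeit"].to_numpy()
    if locked_mask.any():
        # contiguous locked block containing (or nearest to) 24 h
        blocks = []
        start = None
        for i, flag in enumerate(locked_mask):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                blocks.append((start, i - 1))
                start = None
        if start is not None:
            blocks.append((start, len(locked_mask) - 1))
        for lo_i, hi_i in blocks:
            if t_arr[lo_i] - 1e-9 <= 24.0 <= t_arr[hi_i] + 1e-9:
                locked_interval = (float(t_arr[lo_i]), float(t_arr[hi_i]))
                break
    return ScanResult(table, scan_column="T_zeit", locked_interval=locked_interval)


def resynchronization_time(
    traj: Trajectory,
    variable_a: str,
    variable_b: str,
    t_switch: float,
    threshold: float = 1.0,
    period_hint: float = 24.0,
) -> float:
    """Hours after ``t_switch`` until B's peaks realign with A's.

    Walks B's peaks after the switch and returns the elapsed time to the
    first peak whose circular offset from the nearest A peak drops below
    ``threshold`` hours.  Raises if realignment never happens within the
    trajectory.
    """
    peaks_a, _ = find_peaks(traj, variable_a, window=(t_switch, traj.t[-1]))
    peaks_b, _ = find_peaks(traj, variable_b, window=(t_switch, traj.t[-1]))
    if peaks_a.size == 0 or peaks_b.size == 0:
        raise ArrhythmicSignalError("no peaks after the switch")
    for b in peaks_b:
        delta = b - peaks_a[np.argmin(np.abs(peaks_a - b))]
        offset = abs(_wrap(delta, period_hint, "centered"))
        if offset < threshold:
            return float(b - t_switch)
    raise NonEntrainedError(
        f"peak offset never fell below {threshold} h within the trajectory"
    )


# ---------------------------------------------------------------------------
# synthetic fixtures (analytic waveforms with known period/amplitude)
# ---------------------------------------------------------------------------


def sinusoid_trajectory(
    period: float,
    amplitude: float = 1.0,
    phase: float = 0.0,
    offset: float = 2.0,
    damping: float = 0.0,
    t_end: float = 200.0,
    dt: float = 0.05,
    name: str = "y",
) -> Trajectory:
    """``offset + amplitude*exp(-damping*t)*cos(2*pi*t/period + phase)``.

    Analytic waveform with known period, amplitude and peak positions,
    used to exercise the measurement operations without ODE runs.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    y = offset + amplitude * np.exp(-damping * t) * np.cos(2 * np.pi * t / period + phase)
    return Trajectory(t, {name: y}, {"period": period, "amplitude": amplitude})


def constant_trajectory(value: float = 1.0, t_end: float = 200.0, dt: float = 0.05, name: str = "y") -> Trajectory:
    t = np.arange(0.0, t_end + dt / 2, dt)
    return Trajectory(t, {name: np.full_like(t, value)})
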