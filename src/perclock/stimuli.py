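"""Time-dependent stimulus intensities u(t) — the input side of the
oscillator interface.

A stimulus is a named non-negative function of time.  The same objects
serve as external Zeitgebers (light, feeding) and as the currency through
which coupled oscillators exchange signals: a ``signal_tap`` stimulus
reads a state variable of another oscillator instead of the clock time
(resolved by the network assembler, see :mod:`perclock.coupling`).

Conventions
-----------
* Intensities are dimensionless and >= 0; the coupling constants of the
  variant terms absorb units so every added rate is in µM/h.
* A phase ``phi`` (radians) corresponds to a Zeitgeber advance of
  ``phi*period/(2*pi)`` hours: the peak of ``cos(2*pi*t/period + phi)+1``
  sits at ``t = -phi*period/(2*pi) (mod period)``.
* Pulse intervals are half-open ``[start, start+duration)`` so abutting
  pulses never double-count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "StimulusSpec",
    "eval_periodic",
    "eval_scaled_periodic",
    "eval_food_switch",
    "eval_constant",
    "eval_pulse",
    "eval_log",
    "discontinuity_times",
]

StimulusKind = Literal[
    "zero",
    "periodic",
    "scaled_periodic",
    "constant",
    "food_switch",
    "pulse",
    "log_transformed",
    "signal_tap",
]


def eval_periodic(t: float, phi: float = 0.0, period: float = 24.0) -> float:
    """Raised-cosine Zeitgeber ``cos(2*pi*t/period + phi) + 1``, range [0, 2]."""
    if period <= 0:
        raise ValueError(f"period must be positive, got {period!r}")
    return math.cos(2.0 * math.pi * t / period + phi) + 1.0


def eval_scaled_periodic(t: float, phi: float = 0.0, period: float = 24.0) -> float:
    """Quarter-amplitude raised cosine, range [0, 0.5] (feeding-strength cue)."""
    return 0.25 * eval_periodic(t, phi, period)


def eval_food_switch(
    t: float,
    phi_tilde: float,
    phi: float,
    t_switch: float,
    period: float = 24.0,
) -> float:
    """Feeding cue whose phase jumps from ``phi_tilde`` to ``phi`` at ``t_switch``.

    Models a feeding schedule moved back to its normal time of day: until
    ``t_switch`` food arrives with phase ``phi_tilde`` (e.g. ``pi`` for
    night feeding), afterwards with phase ``phi``.
    """
    if t_switch <= 0:
        raise ValueError(f"t_switch must be positive, got {t_switch!r}")
    if t <= t_switch:
        return eval_scaled_periodic(t, phi_tilde, period)
    return eval_scaled_periodic(t, phi, period)


def eval_constant(t: float, c: float) -> float:
    """Constant stimulus of intensity ``c`` (constant-light protocols)."""
    if c < 0:
        raise ValueError(f"constant intensity must be >= 0, got {c!r}")
    return c


def eval_pulse(t: float, t_start: float, duration: float, magnitude: float) -> float:
    """Rectangular pulse: ``magnitude`` on ``[t_start, t_start+duration)``, else 0."""
    if magnitude < 0:
        raise ValueError(f"pulse magnitude must be >= 0, got {magnitude!r}")
    if duration <= 0:
        raise ValueError(f"pulse duration must be positive, got {duration!r}")
    return magnitude if t_start <= t < t_start + duration else 0.0


def eval_log(t: float, inner: "StimulusSpec") -> float:
    """Illuminance compression ``ln(1 + u(t))`` of a nested stimulus."""
    return math.log1p(inner(t))


@dataclass(frozen=True)
class StimulusSpec:
    """Declarative description of one stimulus; callable as ``spec(t)``.

    Use the classmethod constructors (:meth:`periodic`, :meth:`constant`,
    ...) rather than filling fields by hand.  ``signal_tap`` specs cannot
    be evaluated from time alone — the network assembler substitutes the
    tapped oscillator variable at integration time.
    """

    kind: StimulusKind = "zero"
    phi: float = 0.0
    phi_tilde: float = 0.0
    period: float = 24.0
    c: float = 0.0
    t_switch: float = 0.0
    t_start: float = 0.0
    duration: float = 1.0
    magnitude: float = 1.0
    amplitude: float = 1.0
    inner: "StimulusSpec | None" = None
    tap: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period!r}")
        if self.kind == "constant" and self.c < 0:
            raise ValueError(f"constant intensity must be >= 0, got {self.c!r}")
        if self.kind == "pulse":
            if self.magnitude < 0:
                raise ValueError(f"pulse magnitude must be >= 0, got {self.magnitude!r}")
            if self.duration <= 0:
                raise ValueError(f"pulse duration must be positive, got {self.duration!r}")
        if self.kind == "food_switch" and self.t_switch <= 0:
            raise ValueError(f"t_switch must be positive, got {self.t_switch!r}")
        if self.kind == "log_transformed" and self.inner is None:
            raise ValueError("log_transformed stimulus requires an inner stimulus")
        if self.kind == "signal_tap" and self.tap is None:
            raise ValueError("signal_tap stimulus requires a (oscillator id, variable) tap")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude!r}")

    # -- constructors -------------------------------------------------

    @classmethod
    def zero(cls) -> "StimulusSpec":
        return cls(kind="zero")

    @classmethod
    def periodic(
        cls, phi: float = 0.0, period: float = 24.0, amplitude: float = 1.0
    ) -> "StimulusSpec":
        """Raised-cosine light cycle; ``amplitude`` scales the whole waveform."""
        return cls(kind="periodic", phi=phi, period=period, amplitude=amplitude)

    @classmethod
    def scaled_periodic(cls, phi: float = 0.0, period: float = 24.0) -> "StimulusSpec":
        return cls(kind="scaled_periodic", phi=phi, period=period)

    @classmethod
    def constant(cls, c: float) -> "StimulusSpec":
        return cls(kind="constant", c=c)

    @classmethod
    def food_switch(
        cls,
        phi_tilde: float,
        phi: float,
        t_switch: float,
        period: float = 24.0,
    ) -> "StimulusSpec":
        return cls(
            kind="food_switch", phi_tilde=phi_tilde, phi=phi, t_switch=t_switch, period=period
        )

    @classmethod
    def pulse(cls, t_start: float, duration: float = 1.0, magnitude: float = 1.0) -> "StimulusSpec":
        return cls(kind="pulse", t_start=t_start, duration=duration, magnitude=magnitude)

    @classmethod
    def log_transformed(cls, inner: "StimulusSpec") -> "StimulusSpec":
        return cls(kind="log_transformed", inner=inner)

    @classmethod
    def signal_tap(cls, oscillator_id: str, variable: str) -> "StimulusSpec":
        return cls(kind="signal_tap", tap=(oscillator_id, variable))

    # -- evaluation ----------------------------------------------------

    def __call__(self, t: float) -> float:
        if self.kind == "zero":
            return 0.0
        if self.kind == "periodic":
            return self.amplitude * eval_periodic(t, self.phi, self.period)
        if self.kind == "scaled_periodic":
            return eval_scaled_periodic(t, self.phi, self.period)
        if self.kind == "constant":
            return self.c
        if self.kind == "food_switch":
            return eval_food_switch(t, self.phi_tilde, self.phi, self.t_switch, self.period)
        if self.kind == "pulse":
            return eval_pulse(t, self.t_start, self.duration, self.magnitude)
        if self.kind == "log_transformed":
            return eval_log(t, self.inner)
        raise ValueError(
            f"stimulus kind {self.kind!r} is state-valued and cannot be evaluated from time alone"
        )

    @property
    def is_state_valued(self) -> bool:
        return self.kind == "signal_tap"


def discontinuity_times(spec: StimulusSpec, t_end: float) -> list[float]:
    """Breakpoints of ``spec`` inside ``(0, t_end)``, for the integrator.

    Piecewise stimuli (feeding-schedule switches, pulses) have jump
    discontinuities; restarting the integration there avoids step-size
    pathologies.  Smooth stimuli return an empty list.
    """
    times: list[float] = []
    if spec.kind == "food_switch":
        times.append(spec.t_switch)
    elif spec.kind == "pulse":
        times.extend([spec.t_start, spec.t_start + spec.duration])
    elif spec.kind == "log_transformed":
        times.extend(discontinuity_times(spec.inner, t_end))
    return sorted(t for t in set(times) if 0.0 < t < t_end)
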