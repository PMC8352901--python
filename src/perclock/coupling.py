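"""Coupling oscillators through the stimulus interface.

A network is a list of oscillators, each with its own parameters, stimulus
and stimulus port, plus coupling terms through which one oscillator's
state variable acts on another — the input–output interface.  Three
coupling forms are provided, all injected into the target's ``P0``
equation by default (the protein port):

* ``product_decay`` — ``-alpha_t * P0_target * source``: extra digestion
  of the target's PER when the source agent is high; locks the pair in
  antiphase.
* ``gated_decay``   — ``-alpha_t * P0_target * exp(-beta * source)``: a
  high source *suppresses* the digestion; locks the pair in phase.
* ``dual_input``    — the gated term plus a bilinear feeding term
  ``-delta * u_food(t) * P0_target``: the peripheral clock integrates
  the central signal and a food Zeitgeber at once.

Driving the product decay with the source's ``P2`` instead of ``P0``
shifts the locked phase away from plain antiphase, showing how peripheral
clocks can adopt intermediate phase relationships.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .core_model import (
    STATE_NAMES,
    AuxState,
    CoreParameters,
    MachineryParams,
    OscillatorState,
    VariantSpec,
    machinery_rhs,
    variant_rhs,
)
from .stimuli import StimulusSpec, discontinuity_times

__all__ = [
    "CouplingTerm",
    "Oscillator",
    "NetworkSpec",
    "NetworkError",
    "antiphase_coupling_term",
    "inphase_coupling_term",
    "p2_coupling_term",
    "dual_input_term",
    "assemble_network",
    "single_oscillator",
    "build_ensemble",
    "ensemble_readout",
]

CouplingForm = Literal["product_decay", "gated_decay", "dual_input"]


class NetworkError(ValueError):
    """Configuration error in a network specification (dangling ids etc.)."""


def antiphase_coupling_term(P0_tilde: float, source: float, alpha_t: float) -> float:
    """Product-decay contribution ``-alpha_t * P0_tilde * source`` (µM/h).

    Added to the target's dP0/dt: simultaneous high levels of the source
    agent and the target's PER cause extra digestion, which settles the
    pair roughly half a period apart.
    """
    return -alpha_t * P0_tilde * source


def inphase_coupling_term(P0_tilde: float, source: float, alpha_t: float, beta: float) -> float:
    """Gated-decay contribution ``-alpha_t * P0_tilde * exp(-beta * source)``.

    A higher source level means *less* digestion of the target's PER, so
    the target tracks the source in phase.  ``beta = 0`` degenerates to a
    constant first-order decay.
    """
    return -alpha_t * P0_tilde * math.exp(-beta * source)


def p2_coupling_term(P0p_tilde: float, P2_source: float, alpha_p: float) -> float:
    """Product decay driven by the source's biphosphorylated PER (``P2``).

    Because ``P2`` peaks at a different phase than ``P0``, this coupling
    locks the target at an intermediate offset rather than plain antiphase.
    """
    return -alpha_p * P0p_tilde * P2_source


def dual_input_term(
    P0_tilde: float,
    source: float,
    alpha_t: float,
    beta: float,
    u_food: float,
    delta: float,
) -> float:
    """Gated central coupling plus bilinear feeding input.

    ``-alpha_t*P0_tilde*exp(-beta*source) - delta*u_food*P0_tilde``:
    the peripheral oscillator integrates the central clock signal and the
    food Zeitgeber simultaneously.
    """
    return inphase_coupling_term(P0_tilde, source, alpha_t, beta) - delta * u_food * P0_tilde


@dataclass(frozen=True)
class CouplingTerm:
    """One directed coupling edge.

    ``target`` / ``source`` are ``(oscillator id, variable name)`` pairs;
    the contribution is added to the target variable's derivative (``P0``
    in all the standard configurations).  ``food`` supplies the second
    input of the ``dual_input`` form.
    """

    target: tuple[str, str]
    form: CouplingForm
    source: tuple[str, str]
    alpha_t: float
    beta: float | None = None
    delta: float | None = None
    food: StimulusSpec | None = None

    def __post_init__(self) -> None:
        if self.alpha_t <= 0:
            raise NetworkError(f"coupling constant alpha_t must be positive, got {self.alpha_t!r}")
        if self.form in ("gated_decay", "dual_input"):
            if self.beta is None or self.beta < 0:
                raise NetworkError(f"form {self.form!r} requires beta >= 0, got {self.beta!r}")
        elif self.beta is not None:
            raise NetworkError("beta is only used by gated_decay/dual_input couplings")
        if self.form == "dual_input":
            if self.delta is None or self.delta <= 0:
                raise NetworkError(f"dual_input requires delta > 0, got {self.delta!r}")
            if self.food is None:
                raise NetworkError("dual_input requires a food stimulus")
        elif self.delta is not None or self.food is not None:
            raise NetworkError("delta/food are only used by dual_input couplings")

    def contribution(self, target_value: float, source_value: float, t: float) -> float:
        if self.form == "product_decay":
            return antiphase_coupling_term(target_value, source_value, self.alpha_t)
        if self.form == "gated_decay":
            return inphase_coupling_term(target_value, source_value, self.alpha_t, self.beta)
        return dual_input_term(
            target_value, source_value, self.alpha_t, self.beta, self.food(t), self.delta
        )


@dataclass(frozen=True)
class Oscillator:
    """One unit of a network: parameters, initial state, stimulus port."""

    id: str
    params: CoreParameters = field(default_factory=CoreParameters.default)
    initial: OscillatorState = field(default_factory=OscillatorState.default)
    variant: VariantSpec = field(default_factory=VariantSpec.none)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec.zero)
    initial_aux: AuxState | None = None

    def __post_init__(self) -> None:
        if self.variant.kind == "mammal_machinery" and self.initial_aux is None:
            mach = self.variant.machinery
            object.__setattr__(self, "initial_aux", AuxState(T=mach.T0, Tstar=0.0))


@dataclass(frozen=True)
class NetworkSpec:
    """Oscillators plus coupling edges; ids must be unique and resolvable."""

    oscillators: tuple[Oscillator, ...]
    couplings: tuple[CouplingTerm, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "oscillators", tuple(self.oscillators))
        object.__setattr__(self, "couplings", tuple(self.couplings))
        ids = [osc.id for osc in self.oscillators]
        if len(set(ids)) != len(ids):
            raise NetworkError(f"duplicate oscillator ids in {ids!r}")
        known = set(ids)
        for term in self.couplings:
            for role, (osc_id, var) in (("target", term.target), ("source", term.source)):
                if osc_id not in known:
                    raise NetworkError(f"coupling {role} references unknown oscillator {osc_id!r}")
                if var not in STATE_NAMES:
                    raise NetworkError(f"coupling {role} references unknown variable {var!r}")
        for osc in self.oscillators:
            if osc.stimulus.is_state_valued:
                tap_id, tap_var = osc.stimulus.tap
                if tap_id not in known:
                    raise NetworkError(f"signal tap references unknown oscillator {tap_id!r}")
                if tap_var not in STATE_NAMES:
                    raise NetworkError(f"signal tap references unknown variable {tap_var!r}")

    def variable_names(self) -> list[str]:
        names = []
        for osc in self.oscillators:
            names.extend(f"{osc.id}.{v}" for v in STATE_NAMES)
            if osc.variant.kind == "mammal_machinery":
                names.extend([f"{osc.id}.T", f"{osc.id}.Tstar"])
        return names

    def initial_vector(self) -> np.ndarray:
        parts = []
        for osc in self.oscillators:
            parts.append(osc.initial.to_array())
            if osc.variant.kind == "mammal_machinery":
                parts.append(np.array([osc.initial_aux.T, osc.initial_aux.Tstar]))
        return np.concatenate(parts)

    def breakpoints(self, t_end: float) -> list[float]:
        times: set[float] = set()
        for osc in self.oscillators:
            if not osc.stimulus.is_state_valued:
                times.update(discontinuity_times(osc.stimulus, t_end))
        for term in self.couplings:
            if term.food is not None:
                times.update(discontinuity_times(term.food, t_end))
        return sorted(times)


def _layout(spec: NetworkSpec) -> dict[str, tuple[int, int]]:
    """Map oscillator id -> (state offset, block width) in the flat vector."""
    offsets = {}
    pos = 0
    for osc in spec.oscillators:
        width = 5 + (2 if osc.variant.kind == "mammal_machinery" else 0)
        offsets[osc.id] = (pos, width)
        pos += width
    return offsets


def assemble_network(spec: NetworkSpec) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the combined right-hand side over the concatenated state.

    The returned function is a pure function of ``(t, y)``: coupling terms
    and signal taps read source values from the current global state, so
    declaration order never affects the result.  Dangling references are
    rejected when the :class:`NetworkSpec` is constructed.
    """
    offsets = _layout(spec)
    var_index = {name: i for i, name in enumerate(STATE_NAMES)}

    osc_info = []
    for osc in spec.oscillators:
        off, width = offsets[osc.id]
        tap = None
        if osc.stimulus.is_state_valued:
            tap_id, tap_var = osc.stimulus.tap
            tap = offsets[tap_id][0] + var_index[tap_var]
        osc_info.append((osc, off, width, tap))

    coupling_info = []
    for term in spec.couplings:
        t_id, t_var = term.target
        s_id, s_var = term.source
        t_idx = offsets[t_id][0] + var_index[t_var]
        s_idx = offsets[s_id][0] + var_index[s_var]
        coupling_info.append((term, t_idx, s_idx))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty_like(y)
        for osc, off, width, tap in osc_info:
            block = y[off : off + 5]
            u = y[tap] if tap is not None else osc.stimulus(t)
            u = max(u, 0.0)
            if osc.variant.kind == "mammal_machinery":
                Tstar = y[off + 6]
                core = variant_rhs(block, osc.params, VariantSpec.none(), 0.0)
                core[0] += osc.variant.gamma * Tstar
                dy[off : off + 5] = core
                mach = osc.variant.machinery
                dT, dTs = machinery_rhs((y[off + 5], Tstar), u, mach.rho_m, mach.xi)
                dy[off + 5] = dT
                dy[off + 6] = dTs
            else:
                dy[off : off + width] = variant_rhs(block, osc.params, osc.variant, u)
        for term, t_idx, s_idx in coupling_info:
            dy[t_idx] += term.contribution(y[t_idx], y[s_idx], t)
        return dy

    return rhs


def single_oscillator(
    variant: VariantSpec | None = None,
    stimulus: StimulusSpec | None = None,
    params: CoreParameters | None = None,
    initial: OscillatorState | None = None,
    osc_id: str = "osc",
) -> NetworkSpec:
    """Convenience wrapper: a one-unit network for the standard experiments."""
    return NetworkSpec(
        oscillators=(
            Oscillator(
                id=osc_id,
                params=params or CoreParameters.default(),
                initial=initial or OscillatorState.default(),
                variant=variant or VariantSpec.none(),
                stimulus=stimulus or StimulusSpec.zero(),
            ),
        )
    )


def build_ensemble(
    n: int,
    alpha: float = 1.0,
    spread: float = 0.0,
    stimulus: StimulusSpec | None = None,
    variant_kind: str = "fly",
    rng: np.random.Generator | None = None,
) -> NetworkSpec:
    """``n`` uncoupled units driven by the same stimulus, with inhomogeneous
    stimulus coupling constants.

    The per-unit constants are spread deterministically and linearly over
    ``[alpha*(1-spread), alpha*(1+spread)]`` (units differ e.g. because
    tissue shields them from light differently); pass ``rng`` for a random
    spread instead.  The macroscopic readout is the sum of the units' mRNA
    series (:func:`ensemble_readout`): inhomogeneous coupling lets a single
    well-timed pulse desynchronize the units and collapse the macroscopic
    amplitude — the singularity mechanism.
    """
    if n < 1:
        raise ValueError(f"ensemble size must be >= 1, got {n!r}")
    if spread < 0 or spread >= 1:
        raise ValueError(f"spread must lie in [0, 1), got {spread!r}")
    if rng is not None and spread > 0:
        alphas = rng.uniform(alpha * (1 - spread), alpha * (1 + spread), size=n)
    elif n == 1:
        alphas = np.array([alpha])
    else:
        alphas = np.linspace(alpha * (1 - spread), alpha * (1 + spread), n)
    stimulus = stimulus or StimulusSpec.zero()
    factory = {"fly": VariantSpec.fly, "mrna_decay": VariantSpec.mrna_decay}[variant_kind]
    oscillators = tuple(
        Oscillator(id=f"unit{i}", variant=factory(alpha=float(a)), stimulus=stimulus)
        for i, a in enumerate(alphas)
    )
    return NetworkSpec(oscillators=oscillators)


def ensemble_readout(traj, spec: NetworkSpec, variable: str = "M") -> np.ndarray:
    """Macroscopic oscillation: sum of ``variable`` over all units."""
    return np.sum([traj[f"{osc.id}.{variable}"] for osc in spec.oscillators], axis=0)
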