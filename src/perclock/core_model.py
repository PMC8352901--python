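"""Five-variable PER limit-cycle oscillator and its stimulus-extended variants.

The core model describes the negative feedback loop of the *Drosophila*
period gene: *per* mRNA (``M``) is translated into unphosphorylated PER
protein (``P0``), which is reversibly phosphorylated twice (``P1``, ``P2``);
the fully phosphorylated form is degraded and shuttled into the nucleus
(``PN``), where it represses its own transcription through a Hill-type
term.  With the default parameters the system settles on a limit cycle
with a free-running period of about 23.7 h.

External stimuli (light, feeding signals, drugs) enter through bilinear
control terms added to a single equation — the "port" of the oscillator:

* ``mrna_decay`` — the stimulus accelerates mRNA decay (``-alpha*u*M``);
* ``fly``        — the stimulus degrades unphosphorylated PER
  (``-alpha*u*P0``), the effective picture of light-driven TIM/PER
  degradation in flies;
* ``mammal``     — the stimulus induces transcription with saturation
  (``+gamma*u*exp(-rho*M)``), the effective picture of light-induced
  *per* transcription in mammals;
* ``mammal_machinery`` — the saturating exponential is unfolded into an
  explicit two-species transcription-machinery pool (``T``/``Tstar``)
  and the induction term becomes ``+gamma*Tstar``.

A two-species linear subsystem (:func:`cooperativity_rhs`) expresses
quadratic stimulus effects (``u**2``) as a product of two agents, keeping
every stimulus term bilinear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Literal

import numpy as np

__all__ = [
    "CoreParameters",
    "OscillatorState",
    "MachineryParams",
    "VariantSpec",
    "AuxState",
    "InvalidStateError",
    "core_rhs",
    "variant_rhs",
    "machinery_rhs",
    "cooperativity_rhs",
]

HillForm = Literal["KI", "K1", "mixed"]

STATE_NAMES = ("M", "P0", "P1", "P2", "PN")


class InvalidStateError(ValueError):
    """Raised when a state passed to a derivative function is not finite."""


@dataclass(frozen=True)
class CoreParameters:
    """Rate and Michaelis constants of the five-variable PER oscillator.

    Units: rates ``vs``, ``vm``, ``vd``, ``V1``–``V4`` in µM/h; first-order
    constants ``ks``, ``k1``, ``k2`` in 1/h; Michaelis/threshold constants
    ``Km``, ``KI``, ``Kd``, ``K1``–``K4`` in µM; ``n`` is the dimensionless
    Hill cooperativity degree.

    ``hill_form`` selects the numerator/denominator constants of the
    transcription-inhibition Hill term:

    * ``"KI"`` (default): ``vs*KI^n/(KI^n + PN^n)`` — the original
      Goldbeter form, which yields the 23.7 h free-running period;
    * ``"K1"``: ``vs*K1^n/(K1^n + PN^n)``;
    * ``"mixed"``: ``vs*K1^n/(KI^n + PN^n)``.

    The alternatives are retained for auditability; all derived results in
    this package use the default.
    """

    vs: float = 0.76
    vm: float = 0.65
    Km: float = 0.5
    ks: float = 0.38
    vd: float = 0.95
    k1: float = 1.9
    k2: float = 1.3
    KI: float = 1.0
    Kd: float = 0.2
    n: int = 4
    K1: float = 2.0
    K2: float = 2.0
    K3: float = 2.0
    K4: float = 2.0
    V1: float = 3.2
    V2: float = 1.58
    V3: float = 5.0
    V4: float = 2.5
    hill_form: HillForm = "KI"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "hill_form":
                continue
            value = getattr(self, f.name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {value!r}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"Hill degree n must be an integer >= 1, got {self.n!r}")
        if self.hill_form not in ("KI", "K1", "mixed"):
            raise ValueError(f"unknown hill_form {self.hill_form!r}")

    @classmethod
    def default(cls) -> "CoreParameters":
        """The published parameter set (23.7 h free-running period)."""
        return cls()

    def hill_constants(self) -> tuple[float, float]:
        """(numerator constant, denominator constant) of the Hill term."""
        if self.hill_form == "KI":
            return self.KI, self.KI
        if self.hill_form == "K1":
            return self.K1, self.K1
        return self.K1, self.KI


@dataclass(frozen=True)
class OscillatorState:
    """Amounts (µM) of the five model species.

    ``M``: cytosolic *per* mRNA; ``P0``/``P1``/``P2``: un-, mono- and
    biphosphorylated PER protein; ``PN``: nuclear biphosphorylated PER.
    """

    M: float = 0.5
    P0: float = 0.5
    P1: float = 0.5
    P2: float = 0.6
    PN: float = 1.5

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidStateError(f"non-finite oscillator state {arr!r}")
        if np.any(arr < -1e-9):
            raise InvalidStateError(f"negative oscillator state {arr!r}")

    @classmethod
    def default(cls) -> "OscillatorState":
        return cls()

    def to_array(self) -> np.ndarray:
        return np.array([self.M, self.P0, self.P1, self.P2, self.PN], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "OscillatorState":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class MachineryParams:
    """Transcription-machinery pool: stimulation rate ``rho_m`` (1/h per
    intensity unit), relaxation rate ``xi`` (1/h), total pool ``T0`` (µM)."""

    rho_m: float = 1.0
    xi: float = 0.5
    T0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rho_m", "xi", "T0"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"machinery constant {name} must be strictly positive, got {value!r}")


VariantKind = Literal["none", "mrna_decay", "fly", "mammal", "mammal_machinery"]


@dataclass(frozen=True)
class VariantSpec:
    """Which stimulus port is open and with which coupling constants.

    ``alpha`` weights the bilinear decay ports (``mrna_decay``, ``fly``);
    ``gamma`` is the transcription-induction gain and ``rho`` the
    saturation constant of the mammalian port.  Constants that the active
    kind does not use must be left unset.
    """

    kind: VariantKind = "none"
    alpha: float | None = None
    gamma: float | None = None
    rho: float | None = None
    machinery: MachineryParams | None = None

    def __post_init__(self) -> None:
        needed: dict[str, tuple[str, ...]] = {
            "none": (),
            "mrna_decay": ("alpha",),
            "fly": ("alpha",),
            "mammal": ("gamma", "rho"),
            "mammal_machinery": ("gamma", "machinery"),
        }
        if self.kind not in needed:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        for name in needed[self.kind]:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"variant {self.kind!r} requires constant {name!r}")
            if name != "machinery" and (not np.isfinite(value) or value <= 0):
                raise ValueError(f"variant constant {name} must be strictly positive, got {value!r}")
        for name in ("alpha", "gamma", "rho", "machinery"):
            if name not in needed[self.kind] and getattr(self, name) is not None:
                raise ValueError(f"variant {self.kind!r} does not use constant {name!r}")

    @classmethod
    def none(cls) -> "VariantSpec":
        return cls(kind="none")

    @classmethod
    def mrna_decay(cls, alpha: float = 1.0) -> "VariantSpec":
        return cls(kind="mrna_decay", alpha=alpha)

    @classmethod
    def fly(cls, alpha: float = 1.0) -> "VariantSpec":
        return cls(kind="fly", alpha=alpha)

    @classmethod
    def mammal(cls, gamma: float = 2.0, rho: float = 1.0) -> "VariantSpec":
        return cls(kind="mammal", gamma=gamma, rho=rho)

    @classmethod
    def mammal_machinery(
        cls, gamma: float = 2.0, machinery: MachineryParams | None = None
    ) -> "VariantSpec":
        return cls(kind="mammal_machinery", gamma=gamma, machinery=machinery or MachineryParams())


@dataclass(frozen=True)
class AuxState:
    """Transcription-machinery and cooperativity species (µM).

    ``T + Tstar`` is conserved along any trajectory (the pool is closed);
    ``M1*M2`` stands in for a quadratic stimulus effect ``u**2``.
    """

    T: float = 1.0
    Tstar: float = 0.0
    M1: float = 0.0
    M2: float = 0.0


def _check_finite(arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise InvalidStateError(f"non-finite state passed to derivative: {arr!r}")


def core_rhs(state: OscillatorState | np.ndarray, params: CoreParameters) -> np.ndarray:
    """Time derivatives (µM/h) of ``(M, P0, P1, P2, PN)`` for the core model.

    The transcription term is ``vs*Knum^n/(Kden^n + PN^n)`` with the
    numerator/denominator constants set by ``params.hill_form``; mRNA decays
    by Michaelis–Menten kinetics, PER is translated at rate ``ks*M``,
    reversibly phosphorylated twice, degraded from ``P2`` and exchanged
    with the nucleus at first-order rates ``k1``/``k2``.
    """
    y = state.to_array() if isinstance(state, OscillatorState) else np.asarray(state, dtype=float)
    _check_finite(y)
    M, P0, P1, P2, PN = y
    knum, kden = params.hill_constants()
    transcription = params.vs * knum**params.n / (kden**params.n + PN**params.n)
    v12 = params.V1 * P0 / (params.K1 + P0) - params.V2 * P1 / (params.K2 + P1)
    v34 = params.V3 * P1 / (params.K3 + P1) - params.V4 * P2 / (params.K4 + P2)
    dM = transcription - params.vm * M / (params.Km + M)
    dP0 = params.ks * M - v12
    dP1 = v12 - v34
    dP2 = v34 - params.k1 * P2 + params.k2 * PN - params.vd * P2 / (params.Kd + P2)
    dPN = params.k1 * P2 - params.k2 * PN
    return np.array([dM, dP0, dP1, dP2, dPN])


def variant_rhs(
    state: OscillatorState | np.ndarray,
    params: CoreParameters,
    variant: VariantSpec,
    u: float,
) -> np.ndarray:
    """Core derivatives plus the single bilinear stimulus term of ``variant``.

    ``u`` is the (dimensionless, non-negative) stimulus intensity.  With
    ``u == 0`` every variant is identical to the core model.  The
    ``mammal_machinery`` kind is excluded here because its induction term
    reads the auxiliary ``Tstar`` species, not ``u`` directly; use
    :func:`machinery_rhs` alongside the core equations for that variant.
    """
    if u < 0 or not math.isfinite(u):
        raise ValueError(f"stimulus intensity must be finite and >= 0, got {u!r}")
    if variant.kind == "none" and u != 0.0:
        raise ValueError("stimulus supplied but the variant has no input port (kind='none')")
    deriv = core_rhs(state, params)
    if variant.kind == "none":
        return deriv
    y = state.to_array() if isinstance(state, OscillatorState) else np.asarray(state, dtype=float)
    M, P0 = y[0], y[1]
    if variant.kind == "mrna_decay":
        deriv[0] -= variant.alpha * u * M
    elif variant.kind == "fly":
        deriv[1] -= variant.alpha * u * P0
    elif variant.kind == "mammal":
        deriv[0] += variant.gamma * u * math.exp(-variant.rho * M)
    else:
        raise ValueError(
            f"variant kind {variant.kind!r} cannot be evaluated from a scalar intensity"
        )
    return deriv


def machinery_rhs(
    aux: AuxState | tuple[float, float],
    u: float,
    rho_m: float,
    xi: float,
) -> tuple[float, float]:
    """Derivatives (dT/dt, dTstar/dt) of the transcription-machinery pool.

    The stimulus converts unstimulated machinery ``T`` into the stimulated
    form ``Tstar`` at rate ``rho_m*u*T``; ``Tstar`` relaxes back at rate
    ``xi*Tstar``.  The two derivatives sum to zero, so ``T + Tstar`` is a
    conserved pool fixed by the initial condition.
    """
    if rho_m <= 0 or xi <= 0:
        raise ValueError(f"machinery rate constants must be positive, got rho_m={rho_m}, xi={xi}")
    if u < 0 or not math.isfinite(u):
        raise ValueError(f"stimulus intensity must be finite and >= 0, got {u!r}")
    T, Tstar = (aux.T, aux.Tstar) if isinstance(aux, AuxState) else aux
    dT = -rho_m * u * T + xi * Tstar
    return dT, -dT


def cooperativity_rhs(
    M1: float, M2: float, u: float, gamma_h: float
) -> tuple[float, float]:
    """Derivatives of the two-species stand-in for a quadratic stimulus.

    Each species grows linearly with the stimulus and decays at ``gamma_h``:
    ``dMi/dt = (u - gamma_h)*Mi``.  The product ``M1*M2`` then plays the
    role of ``u**2`` in any downstream bilinear term.
    """
    if not (math.isfinite(M1) and math.isfinite(M2) and math.isfinite(u)):
        raise InvalidStateError("non-finite input to cooperativity subsystem")
    return (u - gamma_h) * M1, (u - gamma_h) * M2
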