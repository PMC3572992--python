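"""Chemical synapses with pulsed-transmitter first-order kinetics, and gap junctions.

A chemical synapse injects ``I = g_max * r * (V_post - E_syn)`` (subtracted
from the postsynaptic membrane equation, so the current pulls V_post toward
E_syn).  The open-channel fraction r follows first-order transmitter binding

    dr/dt = alpha * [T] * (1 - r) - beta * r,

where the transmitter concentration [T] is a rectangular pulse: each upward
crossing of the presynaptic spike threshold starts (or restarts) a pulse of
fixed duration (default 1 s) during which [T] = T_max, and [T] = 0
otherwise.  Gap junctions are ohmic: ``I = g * (V_pre - V_post)`` into the
postsynaptic cell.

Kinetic rates keep the native millisecond units of the kinetic scheme they
descend from, while the transmitter pulse lasts 1 s (the cell model's
second-based clock): each presynaptic spike opens a 1 s release window
within which r relaxes quickly to alpha*T/(alpha*T+beta), and after the
last spike's window closes r decays within milliseconds.  The open
fraction therefore tracks the presynaptic activity envelope with ~1 s
memory.  Connection-class defaults (alpha per mM per ms, beta per ms):

=================  ======  ======
class              alpha   beta
=================  ======  ======
H -> SRC           2.0     0.75
SRC -> SRC         1.0     0.1
SRC -> CG          1.0     0.1
CG -> CG           2.0     0.2
CG -> CPG          1.5     0.5
CPG fast           2.5     1.0
CPG slow           2.5     0.25
=================  ======  ======
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapseSpec",
    "SynapseState",
    "KINETICS_BY_CLASS",
    "E_SYN_DEFAULTS",
    "transmitter",
    "register_spike",
    "r_derivative",
    "chemical_current",
    "gap_current",
]

#: (alpha, beta) per connection class, in per-mM-per-ms / per-ms
KINETICS_BY_CLASS = {
    "H->SRC": (2.0, 0.75),
    "SRC->SRC": (1.0, 0.1),
    "SRC->CG": (1.0, 0.1),
    "CG->CG": (2.0, 0.2),
    "CG->CPG": (1.5, 0.5),
    "CPG-fast": (2.5, 1.0),
    "CPG-slow": (2.5, 0.25),
}

#: shared reversal potentials (mV) of chemical synapses
E_SYN_DEFAULTS = {"inhibitory": -80.0, "excitatory": 0.0}

#: presynaptic spike-detection threshold for transmitter release (mV)
SPIKE_THRESHOLD = 0.0

DEFAULT_PULSE_S = 1.0
DEFAULT_T_MAX = 1.0  # mM


@dataclass(frozen=True)
class SynapseSpec:
    """One directed connection.

    ``kind`` is ``inhibitory``/``excitatory`` (chemical) or ``gap``.  Gap
    junctions carry only ``g_max``; chemical synapses additionally carry a
    reversal potential and first-order kinetics.
    """

    pre: str
    post: str
    kind: str
    g_max: float
    E_syn: float | None = None
    alpha: float | None = None      # per mM per ms
    beta: float | None = None       # per ms
    pulse_duration: float = DEFAULT_PULSE_S   # s
    T_max: float = DEFAULT_T_MAX              # mM

    def __post_init__(self) -> None:
        if self.kind not in ("inhibitory", "excitatory", "gap"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if not np.isfinite(self.g_max) or self.g_max < 0:
            raise ValueError(f"g_max must be >= 0, got {self.g_max!r}")
        if self.kind == "gap":
            if self.E_syn is not None or self.alpha is not None or self.beta is not None:
                raise ValueError("gap junctions carry no E_syn or kinetics")
        else:
            E = E_SYN_DEFAULTS[self.kind] if self.E_syn is None else self.E_syn
            object.__setattr__(self, "E_syn", float(E))
            if self.alpha is None or self.beta is None:
                raise ValueError(f"chemical synapse {self.pre}->{self.post} needs alpha and beta")
            if self.alpha <= 0 or self.beta <= 0:
                raise ValueError("alpha and beta must be positive")
            if self.pulse_duration <= 0 or self.T_max <= 0:
                raise ValueError("pulse_duration and T_max must be positive")

    @property
    def is_chemical(self) -> bool:
        return self.kind != "gap"

    @classmethod
    def chemical(cls, pre, post, kind, g_max, conn_class, **kwargs) -> "SynapseSpec":
        """Build a chemical synapse with class-keyed kinetic defaults."""
        alpha, beta = KINETICS_BY_CLASS[conn_class]
        kwargs.setdefault("alpha", alpha)
        kwargs.setdefault("beta", beta)
        return cls(pre=pre, post=post, kind=kind, g_max=g_max, **kwargs)


@dataclass
class SynapseState:
    """Kinetic state of one chemical synapse.

    Times carry whatever unit the caller uses consistently for ``t`` and
    ``pulse_duration`` (the engine works in ms and converts the
    second-valued pulse duration accordingly).
    """

    r: float = 0.0                  # open-channel fraction
    pulse_end: float = -np.inf      # absolute time the current pulse ends
    last_trigger: float = -np.inf   # absolute time of last presynaptic spike

    def validate(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"open fraction r={self.r} outside [0, 1]")


def register_spike(state: SynapseState, spec: SynapseSpec, t: float) -> None:
    """Record a presynaptic threshold crossing at time t.

    Starts a transmitter pulse; a crossing during an active pulse restarts
    the pulse clock, extending the release window.
    """
    if not spec.is_chemical:
        raise ValueError("gap junctions release no transmitter")
    state.last_trigger = t
    state.pulse_end = t + spec.pulse_duration


def transmitter(V_pre: float, state: SynapseState, spec: SynapseSpec, t: float) -> float:
    """Transmitter concentration [T] (mM) seen by the synapse at time t.

    Detects an upward crossing implicitly via :func:`register_spike`; this
    function only reads the pulse clock (``V_pre`` is accepted for interface
    symmetry with the smooth-release variant used by the variational
    analysis).
    """
    if not spec.is_chemical:
        raise ValueError("gap junctions release no transmitter")
    return spec.T_max if t < state.pulse_end else 0.0


def r_derivative(r: float, T: float, alpha: float, beta: float) -> float:
    """dr/dt of the open-channel fraction (per ms)."""
    return alpha * T * (1.0 - r) - beta * r


def chemical_current(r: float, V_post: float, spec: SynapseSpec) -> float:
    """Synaptic current ``g_max * r * (V_post - E_syn)`` (nA).

    The engine subtracts this from the capacitive balance, so a positive
    value (V_post above E_syn) hyperpolarizes the postsynaptic cell.
    """
    if not spec.is_chemical:
        raise ValueError("use gap_current for gap junctions")
    return spec.g_max * r * (V_post - spec.E_syn)


def gap_current(V_post: float, V_pre: float, g: float) -> float:
    """Ohmic gap-junction current ``g * (V_pre - V_post)`` (nA) into post."""
    if g < 0:
        raise ValueError("gap conductance must be >= 0")
    return g * (V_pre - V_post)
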