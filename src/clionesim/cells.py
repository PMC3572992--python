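"""Single-neuron model: an eight-current molluscan (Komendantov-Kononenko) cell.

The membrane carries eight currents

* two ohmic leaks, ``I_K = g_K (V - V_K)`` and ``I_Na = g_Na (V - V_Na)``;
* a slow voltage-dependent sodium current ``I_NaV`` with an instantaneous
  sigmoidal activation;
* the slow chemosensitive B-current ``I_B`` with activation ``mB`` and
  inactivation ``hB`` (the interplay of I_NaV, I_B and the calcium subsystem
  produces the slow bursting wave);
* fast spike currents ``I_NaTTX`` (m^3 h kinetics) and ``I_KTEA`` (n^4);
* a voltage-gated calcium current ``I_Ca`` (mCa^2) feeding an intracellular
  calcium pool, and a calcium-activated calcium current ``I_CaCa`` gated by
  both depolarization and the pool concentration.

The intracellular calcium pool [Ca] fills from I_Ca (scaled by the cell
volume and a buffering factor rho) and is cleared at rate k_s.  All four cell
classes used by the network model (hunting interneuron, statocyst receptor,
cerebral interneuron, wing-CPG cell) share every kinetic constant and differ
only in the eight maximal conductances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from . import constants as k

__all__ = [
    "NeuronParams",
    "NeuronState",
    "CELL_CLASSES",
    "cell_class_params",
    "kk_derivatives",
    "steady_gating",
    "resting_init",
]

CELL_CLASSES = ("hunting", "SRC", "cerebral", "CPG")


def _load_param_table() -> dict:
    text = resources.files("clionesim.data").joinpath("cell_params.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class NeuronParams:
    """Maximal conductances (uS) plus the shared constants of one cell."""

    g_K: float
    g_Na: float
    g_NaV: float
    g_B: float
    g_NaTTX: float
    g_KTEA: float
    g_Ca: float
    g_CaCa: float
    cell_class: str = "SRC"
    C_m: float = k.C_M            # nF
    E_Na: float = k.V_NA          # mV
    E_K: float = k.V_K
    E_B: float = k.V_B
    E_Ca: float = k.V_CA

    def __post_init__(self) -> None:
        for name in self.conductance_names():
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"non-finite conductance {name}={value!r}")
            if value < 0:
                raise ValueError(f"negative conductance {name}={value!r}")
        if not np.isfinite(self.C_m) or self.C_m <= 0:
            raise ValueError(f"capacitance C_m must be positive, got {self.C_m!r}")
        for name in ("E_Na", "E_K", "E_B", "E_Ca"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite potential {name}")

    @staticmethod
    def conductance_names() -> tuple[str, ...]:
        return k.CONDUCTANCE_NAMES

    @property
    def g_max(self) -> np.ndarray:
        """The eight maximal conductances in canonical order (uS)."""
        return np.array([getattr(self, n) for n in self.conductance_names()])

    def with_overrides(self, **kwargs) -> "NeuronParams":
        return replace(self, **kwargs)


@dataclass
class NeuronState:
    """Dynamical state of one cell.

    Gating variables live in [0, 1]; the calcium concentration is >= 0.
    """

    V: float                       # membrane potential, mV
    mB: float                      # B-current activation
    hB: float                      # B-current inactivation
    m: float                       # fast Na activation
    h: float                       # fast Na inactivation
    n: float                       # delayed-rectifier activation
    mCa: float                     # Ca-current activation
    Ca: float                      # intracellular calcium, mM

    FIELDS = ("V", "mB", "hB", "m", "h", "n", "mCa", "Ca")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NeuronState":
        return cls(*(float(v) for v in np.asarray(y)))

    def validate(self) -> None:
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            bad = [f for f, v in zip(self.FIELDS, y) if not np.isfinite(v)]
            raise ValueError(f"non-finite state field(s): {', '.join(bad)}")
        for f in ("mB", "hB", "m", "h", "n", "mCa"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"gating variable {f}={v} outside [0, 1]")
        if self.Ca < 0:
            raise ValueError(f"negative calcium concentration Ca={self.Ca}")


_PARAM_TABLE: dict | None = None


def cell_class_params(cell_class: str, overrides: dict | None = None) -> NeuronParams:
    """Parameters for one of the four shipped cell classes.

    The maximal-conductance table is read from the packaged
    ``data/cell_params.yaml`` file; ``overrides`` replaces individual fields.
    """
    global _PARAM_TABLE
    if _PARAM_TABLE is None:
        _PARAM_TABLE = _load_param_table()
    try:
        row = dict(_PARAM_TABLE["cell_classes"][cell_class])
    except KeyError:
        raise ValueError(
            f"unknown cell class {cell_class!r}; expected one of {CELL_CLASSES}"
        ) from None
    if overrides:
        row.update(overrides)
    return NeuronParams(cell_class=cell_class, **row)


# ---------------------------------------------------------------------------
# gating steady states (shared with the compiled engine kernels)
# ---------------------------------------------------------------------------

def steady_gating(V: float) -> dict:
    """Voltage-dependent steady-state values of all six gating variables."""
    return {
        "mB": 1.0 / (1.0 + np.exp(0.4 * (V + 34.0))),
        "hB": 1.0 / (1.0 + np.exp(-0.55 * (V + 43.0))),
        "m": 1.0 / (1.0 + np.exp(-0.4 * (V + 31.0))),
        "h": 1.0 / (1.0 + np.exp(0.25 * (V + 45.0))),
        "n": 1.0 / (1.0 + np.exp(-0.18 * (V + 25.0))),
        "mCa": 1.0 / (1.0 + np.exp(-0.2 * V)),
    }


def membrane_currents(state: NeuronState, params: NeuronParams) -> dict:
    """The eight membrane currents (nA) at the given state."""
    V, Ca = state.V, state.Ca
    phi_NaV = 1.0 / (1.0 + np.exp(-0.2 * (V + 45.0)))
    # pacemaker-type Ca-dependent current: favored at hyperpolarized V,
    # shut off as intracellular Ca accumulates (burst terminator)
    phi_CaCa = 1.0 / (1.0 + np.exp(0.06 * (V + 45.0)))
    chi_Ca = 1.0 / (1.0 + np.exp(k.K_BETA * (Ca - k.BETA_CA)))
    return {
        "I_K": params.g_K * (V - params.E_K),
        "I_Na": params.g_Na * (V - params.E_Na),
        "I_NaV": params.g_NaV * phi_NaV * (V - params.E_Na),
        "I_B": params.g_B * state.mB * state.hB * (V - params.E_B),
        "I_NaTTX": params.g_NaTTX * state.m**3 * state.h * (V - params.E_Na),
        "I_KTEA": params.g_KTEA * state.n**4 * (V - params.E_K),
        "I_Ca": params.g_Ca * state.mCa**2 * (V - params.E_Ca),
        "I_CaCa": params.g_CaCa * phi_CaCa * chi_Ca * (V - params.E_Ca),
    }


def kk_derivatives(
    state: NeuronState, params: NeuronParams, I_ext: float = 0.0
) -> NeuronState:
    """Time derivative of the full cell state.

    ``I_ext`` (nA) is the sum of all externally supplied currents (stimulus,
    synaptic, gap-junction), with depolarizing currents positive.  Returns a
    :class:`NeuronState` whose fields hold d/dt values (mV/ms, 1/ms, mM/ms).
    """
    state.validate()
    if not np.isfinite(I_ext):
        raise ValueError("non-finite external current I_ext")
    I = membrane_currents(state, params)
    dV = (I_ext - sum(I.values())) / params.C_m
    ss = steady_gating(state.V)
    dmB = (ss["mB"] - state.mB) / k.TAU_MB
    dhB = (ss["hB"] - state.hB) / k.TAU_HB
    dm = (ss["m"] - state.m) / k.TAU_M
    dh = (ss["h"] - state.h) / k.TAU_H
    dn = (ss["n"] - state.n) / k.TAU_N
    dmCa = (ss["mCa"] - state.mCa) / k.TAU_MCA
    dCa = k.RHO * (-k.K_CA_FLUX * I["I_Ca"] - k.K_S * state.Ca)
    return NeuronState(dV, dmB, dhB, dm, dh, dn, dmCa, dCa)


def resting_init(
    params: NeuronParams,
    seed: int,
    v_band: tuple[float, float] = (-65.0, -50.0),
) -> NeuronState:
    """Deterministic near-rest initial state, distinct for distinct seeds.

    Draws V uniformly in ``v_band``, sets every gating variable to its
    steady-state value at that V, and seeds a small positive calcium level.
    Used to desynchronize otherwise identical cells at network start.
    """
    rng = np.random.default_rng(seed)
    V = float(rng.uniform(*v_band))
    ss = steady_gating(V)
    # calcium starts loaded (as after recent activity): the Ca-gated
    # pacemaker current is initially inactivated and recovers over tens of
    # seconds, so cells do not all burst simultaneously at startup
    Ca = float(rng.uniform(1.0e-3, 1.4e-3))
    return NeuronState(V, ss["mB"], ss["hB"], ss["m"], ss["h"], ss["n"], ss["mCa"], Ca)
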