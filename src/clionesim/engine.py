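"""Network assembly and integration: pack a :class:`NetworkSpec` into flat
arrays, run the adaptive embedded Runge-Kutta integrator, detect spikes and
collect a :class:`SimulationResult`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, constants as k
from .cells import resting_init
from .circuits import NetworkSpec, StimulusProtocol

__all__ = [
    "PackedNetwork",
    "SimulationResult",
    "pack_network",
    "initial_state",
    "integrate",
    "spike_detect",
    "dopri_integrate",
]

_TAU = np.array([k.TAU_MB, k.TAU_HB, k.TAU_M, k.TAU_H, k.TAU_N, k.TAU_MCA])


class IntegrationError(RuntimeError):
    pass


@dataclass
class PackedNetwork:
    """Flat-array view of a network, ready for the compiled kernels."""

    spec: NetworkSpec
    cell_ids: tuple[str, ...]
    g8: np.ndarray            # (N, 8) maximal conductances
    cm: np.ndarray            # (N,) capacitance, nF
    e_na: np.ndarray
    e_k: np.ndarray
    e_b: np.ndarray
    e_ca: np.ndarray
    c_pre: np.ndarray         # chemical synapse arrays
    c_post: np.ndarray
    c_g: np.ndarray
    c_e: np.ndarray
    c_alpha: np.ndarray
    c_beta: np.ndarray
    c_tmax: np.ndarray
    c_pulse: np.ndarray       # per-cell transmitter pulse duration (ms)
    gp_a: np.ndarray          # gap junction arrays (undirected pairs)
    gp_b: np.ndarray
    gp_g: np.ndarray
    chem_edges: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_chem(self) -> int:
        return len(self.c_pre)

    @property
    def dim(self) -> int:
        return _kernels.NV * self.n_cells + self.n_chem

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.g8, self.cm, self.c_pre, self.c_post, self.c_g, self.c_e,
                    self.c_alpha, self.c_beta, self.c_tmax, self.c_pulse,
                    self.gp_a, self.gp_b, self.gp_g):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(",".join(self.cell_ids).encode())
        return h.hexdigest()[:16]


def pack_network(net: NetworkSpec) -> PackedNetwork:
    net.validate(strict=True)
    ids = net.cell_ids
    n = len(ids)
    idx = {cid: i for i, cid in enumerate(ids)}
    g8 = np.zeros((n, 8))
    cm = np.zeros(n)
    e_na = np.zeros(n)
    e_k = np.zeros(n)
    e_b = np.zeros(n)
    e_ca = np.zeros(n)
    for i, (_, _, p) in enumerate(net.cells):
        g8[i] = p.g_max
        cm[i] = p.C_m
        e_na[i] = p.E_Na
        e_k[i] = p.E_K
        e_b[i] = p.E_B
        e_ca[i] = p.E_Ca
    chem = [e for e in net.edges if e.is_chemical]
    gaps = [e for e in net.edges if not e.is_chemical]
    # transmitter pulse clocks are per presynaptic cell; seconds -> ms
    c_pulse = np.full(n, 1000.0)
    for e in chem:
        c_pulse[idx[e.pre]] = e.pulse_duration * 1000.0
    return PackedNetwork(
        spec=net,
        cell_ids=tuple(ids),
        g8=g8, cm=cm, e_na=e_na, e_k=e_k, e_b=e_b, e_ca=e_ca,
        c_pre=np.array([idx[e.pre] for e in chem], dtype=np.int64),
        c_post=np.array([idx[e.post] for e in chem], dtype=np.int64),
        c_g=np.array([e.g_max for e in chem], dtype=float),
        c_e=np.array([e.E_syn for e in chem], dtype=float),
        c_alpha=np.array([e.alpha for e in chem], dtype=float),   # per mM per ms
        c_beta=np.array([e.beta for e in chem], dtype=float),     # per ms
        c_tmax=np.array([e.T_max for e in chem], dtype=float),
        c_pulse=c_pulse,
        gp_a=np.array([idx[e.pre] for e in gaps], dtype=np.int64),
        gp_b=np.array([idx[e.post] for e in gaps], dtype=np.int64),
        gp_g=np.array([e.g_max for e in gaps], dtype=float),
        chem_edges=chem,
    )


def initial_state(packed: PackedNetwork, seed: int = 0) -> np.ndarray:
    """Desynchronized near-rest initial state for every cell; synapses closed."""
    y0 = np.zeros(packed.dim)
    for i, (cid, _, p) in enumerate(packed.spec.cells):
        child = (int(seed) * 10007 + 31 * i + 7) % (2**31)
        st = resting_init(p, child)
        y0[_kernels.NV * i:_kernels.NV * (i + 1)] = st.as_array()
    return y0


@dataclass
class SimulationResult:
    """Uniformly resampled voltage traces plus per-cell spike times."""

    t_grid: np.ndarray                  # ms
    V: np.ndarray                       # (n_cells, n_t), mV
    spikes: dict[str, np.ndarray]       # cell id -> spike times (ms)
    cell_ids: tuple[str, ...]
    events: list
    meta: dict
    y_final: np.ndarray | None = None
    ranges: np.ndarray | None = None

    def trace(self, cell_id: str) -> np.ndarray:
        return self.V[self.cell_ids.index(cell_id)]

    @property
    def dt(self) -> float:
        return float(self.t_grid[1] - self.t_grid[0])

    def window(self, t0: float, t1: float) -> "SimulationResult":
        """Restrict traces and spikes to [t0, t1] (ms)."""
        m = (self.t_grid >= t0) & (self.t_grid <= t1)
        spikes = {c: s[(s >= t0) & (s <= t1)] for c, s in self.spikes.items()}
        return SimulationResult(
            t_grid=self.t_grid[m], V=self.V[:, m], spikes=spikes,
            cell_ids=self.cell_ids, events=self.events, meta=dict(self.meta),
        )

    def save_traces(self, path) -> None:
        """Delimited text: time column plus one voltage column per cell."""
        header = "t_ms," + ",".join(self.cell_ids)
        np.savetxt(path, np.column_stack([self.t_grid, self.V.T]),
                   delimiter=",", header=header, comments="")

    def save_spikes(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({c: list(map(float, s)) for c, s in self.spikes.items()}, fh)


def integrate(
    net: NetworkSpec,
    protocol: StimulusProtocol,
    tol: float = 1e-6,
    dt_out: float = 0.5,
    seed: int | None = None,
    y0: np.ndarray | None = None,
    smooth_transmitter: bool = False,
    spike_threshold: float = 0.0,
    refractory: float = 2.0,
) -> SimulationResult:
    """Integrate a network under a stimulation protocol.

    ``tol`` is used for both the relative and absolute per-step error
    control of the embedded Runge-Kutta pair.  Output voltages are sampled
    on a uniform ``dt_out`` grid; spike times are the sub-step interpolated
    upward crossings of ``spike_threshold`` and feed the transmitter pulses.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    packed = pack_network(net)
    if seed is None:
        seed = protocol.seed
    if y0 is None:
        y0 = initial_state(packed, seed)
    y0 = np.asarray(y0, dtype=float)
    # smooth mode appends one transmitter-release state per cell
    full_dim = packed.dim + (packed.n_cells if smooth_transmitter else 0)
    if smooth_transmitter and y0.shape == (packed.dim,):
        y0 = np.concatenate([y0, np.zeros(packed.n_cells)])
    if y0.shape != (full_dim,):
        raise ValueError(f"y0 must have shape ({packed.dim},) or ({full_dim},)")
    ev_times, ev_i = protocol.schedule(net)
    h_max = min(0.5, dt_out)
    (status, t_end, y_end, v_out, spk_t, spk_c, n_spk, ranges) = \
        _kernels.integrate_network(
            y0, float(protocol.duration), tol, tol, h_max,
            packed.n_cells, packed.g8, packed.cm,
            packed.e_na, packed.e_k, packed.e_b, packed.e_ca,
            _TAU, k.RHO, k.K_CA_FLUX, k.K_S, k.K_BETA, k.BETA_CA,
            packed.c_pre, packed.c_post, packed.c_g, packed.c_e,
            packed.c_alpha, packed.c_beta, packed.c_tmax, packed.c_pulse,
            packed.gp_a, packed.gp_b, packed.gp_g,
            ev_times, ev_i,
            dt_out, spike_threshold, refractory, 1 if smooth_transmitter else 0,
        )
    if status == _kernels.STATUS_NONFINITE:
        raise IntegrationError(f"non-finite state at t = {t_end:.3f} ms")
    if status == _kernels.STATUS_STEP_UNDERFLOW:
        raise IntegrationError(f"step-size underflow at t = {t_end:.3f} ms")
    n_t = v_out.shape[1]
    t_grid = np.arange(n_t) * dt_out
    spikes = {cid: spk_t[spk_c == i] for i, cid in enumerate(packed.cell_ids)}
    events = [
        {"t": float(t), "pressed": src}
        for t, src in [(0.0, protocol.pressed_src)] + list(protocol.switch_events)
    ]
    meta = {
        "config_hash": packed.content_hash(),
        "seed": int(seed),
        "tol": float(tol),
        "dt_out": float(dt_out),
        "duration": float(protocol.duration),
        "hunting_on": bool(protocol.hunting_on),
        "smooth_transmitter": bool(smooth_transmitter),
    }
    return SimulationResult(
        t_grid=t_grid, V=v_out, spikes=spikes, cell_ids=packed.cell_ids,
        events=events, meta=meta, y_final=y_end, ranges=ranges,
    )


def spike_detect(
    trace: np.ndarray,
    threshold: float = 0.0,
    dt: float = 0.5,
    refractory: float = 2.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Upward threshold-crossing times from a uniformly sampled trace.

    Crossing times are linearly interpolated between samples; crossings
    closer than ``refractory`` ms to the previous accepted one are ignored.
    """
    v = np.asarray(trace, dtype=float)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    times = t0 + (idx + frac) * dt
    out = [times[0]]
    for t in times[1:]:
        if t - out[-1] >= refractory:
            out.append(t)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# generic integrator (same embedded pair) for small test systems
# ---------------------------------------------------------------------------

def dopri_integrate(f, y0, t_span, rtol=1e-6, atol=1e-6, dt_out=None, h_max=np.inf):
    """Adaptive Dormand-Prince 5(4) for an arbitrary smooth system.

    Pure-numpy counterpart of the compiled network stepper, sharing the same
    tableau and error control; used for closed-form validation systems and
    as the flow engine of the generic Lyapunov routine.  Returns (t, Y) with
    Y of shape (n_t, dim): the accepted steps, or samples on a ``dt_out``
    grid when given.
    """
    t0, t1 = map(float, t_span)
    y = np.asarray(y0, dtype=float).copy()
    A, B5, B4, C = _kernels._A, _kernels._B5, _kernels._B4, _kernels._C
    t = t0
    h = min(1e-2 * (t1 - t0), h_max)
    ts, ys = [t], [y.copy()]
    k_st = np.empty((7, y.size))
    k_st[0] = f(t, y)
    grid = None
    if dt_out is not None:
        grid = np.arange(t0, t1 + 1e-9 * max(1.0, abs(t1)), dt_out)
        out = np.empty((grid.size, y.size))
        out[0] = y
        gi = 1
    while t < t1 - 1e-12:
        h = min(h, h_max, t1 - t)
        if h < 1e-13 * max(1.0, abs(t)):
            raise IntegrationError(f"step-size underflow at t = {t}")
        for s in range(1, 7):
            k_st[s] = f(t + C[s] * h, y + h * (A[s, :s] @ k_st[:s]))
        y5 = y + h * (B5 @ k_st)
        err_v = h * ((B5 - B4) @ k_st)
        sc = atol + rtol * np.maximum(np.abs(y), np.abs(y5))
        err = float(np.sqrt(np.mean((err_v / sc) ** 2)))
        if err <= 1.0:
            t_new = t + h
            if grid is not None:
                f0, f1 = k_st[0], k_st[6]
                while gi < grid.size and grid[gi] <= t_new + 1e-12:
                    # cubic Hermite dense output from the FSAL derivatives
                    w = (grid[gi] - t) / h
                    h00 = (1 + 2 * w) * (1 - w) ** 2
                    h10 = w * (1 - w) ** 2
                    h01 = w * w * (3 - 2 * w)
                    h11 = w * w * (w - 1)
                    out[gi] = h00 * y + h10 * h * f0 + h01 * y5 + h11 * h * f1
                    gi += 1
            y = y5
            t = t_new
            ts.append(t)
            ys.append(y.copy())
            k_st[0] = k_st[6]
            h *= min(5.0, 0.9 * err ** -0.2 if err > 1e-10 else 5.0)
        else:
            h *= max(0.2, 0.9 * err ** -0.2)
    if grid is not None:
        return grid, out
    return np.asarray(ts), np.asarray(ys)
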