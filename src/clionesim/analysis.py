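"""Quantitative characterization of simulated dynamics.

Contents
--------
* Lyapunov spectra from the model vector field (tangent-space propagation
  with QR renormalization), for the network models and for arbitrary small
  test systems;
* activation intervals (threshold crossings of voltage traces);
* wing-rhythm frequency and cycle-period variability from motoneuron bursts;
* hunting-episode detection/typing and PCA of episode-windowed firing-rate
  signals;
* peristimulus time histograms (PSTH) aligned to arbitrary event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from . import _kernels, constants as k
from .circuits import NetworkSpec, StimulusProtocol
from .engine import PackedNetwork, SimulationResult, initial_state, pack_network, _TAU

__all__ = [
    "LyapunovResult",
    "lyapunov_spectrum",
    "lyapunov_spectrum_generic",
    "activation_intervals",
    "burst_intervals",
    "rhythm_frequency",
    "smooth_rates",
    "detect_episodes",
    "classify_episodes",
    "episode_pca",
    "psth",
]


# ---------------------------------------------------------------------------
# Lyapunov spectra
# ---------------------------------------------------------------------------

@dataclass
class LyapunovResult:
    """Lyapunov exponents (per ms) with their convergence history.

    ``exponents`` are sorted descending.  ``n_positive`` counts exponents
    whose converged estimate exceeds ``positive_tol`` (three standard errors
    of the tail of the running estimate by default).  ``convergence_t`` /
    ``convergence`` hold the running estimates at each renormalization.
    """

    exponents: np.ndarray
    convergence_t: np.ndarray
    convergence: np.ndarray
    positive_tol: np.ndarray
    converged: bool = True

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.exponents > self.positive_tol))

    @property
    def per_second(self) -> np.ndarray:
        return self.exponents * 1000.0

    def summary(self) -> dict:
        return {
            "exponents_per_s": [float(x) for x in self.per_second],
            "n_positive": self.n_positive,
            "converged": bool(self.converged),
        }


def _finalize_spectrum(conv_t, conv, converged) -> LyapunovResult:
    order = np.argsort(conv[-1])[::-1]
    conv = conv[:, order]
    exps = conv[-1]
    # standard error of the tail of the running estimate
    tail = conv[max(len(conv) // 2, len(conv) - 50):]
    se = tail.std(axis=0) / np.sqrt(max(len(tail), 1))
    tol = 3.0 * se + 1e-12
    return LyapunovResult(
        exponents=exps,
        convergence_t=conv_t,
        convergence=conv,
        positive_tol=tol,
        converged=converged,
    )


def lyapunov_spectrum(
    net: NetworkSpec,
    protocol: StimulusProtocol,
    n_exp: int = 4,
    t_total: float = 60000.0,
    renorm_dt: float = 250.0,
    seed: int = 0,
    t_transient: float = 20000.0,
    tol: float = 1e-8,
    y0: np.ndarray | None = None,
) -> LyapunovResult:
    """Lyapunov spectrum of a network under a (switch-free) protocol.

    The flow plus ``n_exp`` tangent vectors are integrated together; the
    tangent (variational) dynamics use analytic Jacobian-vector products
    evaluated at every Runge-Kutta stage, with QR renormalization every
    ``renorm_dt`` ms.  Transmitter release uses the smooth first-order
    variant of the pulse law so the vector field is continuously
    differentiable (the synaptic open fractions r and release states s are
    part of the state).  A transient of ``t_transient`` ms is integrated
    (and discarded) first so the tangent dynamics sample the attractor.

    Convergence is judged from the relative spread of the running estimate
    of the leading exponent over the final quarter of the run; a
    non-convergent result is returned flagged, never silently.
    """
    packed = pack_network(net)
    if protocol.switch_events:
        raise ValueError("Lyapunov analysis requires an autonomous (switch-free) protocol")
    if n_exp > packed.dim:
        raise ValueError(f"n_exp={n_exp} exceeds state dimension {packed.dim}")
    ev_times, ev_i = protocol.schedule(net)
    i_ext = ev_i[0]
    if y0 is None:
        y0 = initial_state(packed, seed)
    # the smooth-release variant appends one transmitter state per cell
    if y0.shape == (packed.dim,):
        y0 = np.concatenate([y0, np.zeros(packed.n_cells)])
    aug_dim = packed.dim + packed.n_cells

    # transient: run the smooth flow onto the attractor
    if t_transient > 0:
        (status, _, y0, *_rest) = _kernels.integrate_network(
            y0, t_transient, tol, tol, 0.5,
            packed.n_cells, packed.g8, packed.cm,
            packed.e_na, packed.e_k, packed.e_b, packed.e_ca,
            _TAU, k.RHO, k.K_CA_FLUX, k.K_S, k.K_BETA, k.BETA_CA,
            packed.c_pre, packed.c_post, packed.c_g, packed.c_e,
            packed.c_alpha, packed.c_beta, packed.c_tmax, packed.c_pulse,
            packed.gp_a, packed.gp_b, packed.gp_g,
            ev_times, ev_i, 1000.0, 0.0, 2.0, 1,
        )
        if status != _kernels.STATUS_OK:
            raise RuntimeError("transient integration failed")

    rng = np.random.default_rng(seed)
    w0 = rng.standard_normal((aug_dim, n_exp))
    w0, _ = np.linalg.qr(w0)

    status, _log_sum, conv_t, conv = _kernels.integrate_tangent(
        y0, np.ascontiguousarray(w0), t_total, renorm_dt, tol, tol, 0.5,
        packed.n_cells, packed.g8, packed.cm,
        packed.e_na, packed.e_k, packed.e_b, packed.e_ca,
        _TAU, k.RHO, k.K_CA_FLUX, k.K_S, k.K_BETA, k.BETA_CA,
        packed.c_pre, packed.c_post, packed.c_g, packed.c_e,
        packed.c_alpha, packed.c_beta, packed.c_tmax, packed.c_pulse,
        packed.gp_a, packed.gp_b, packed.gp_g,
        np.ascontiguousarray(i_ext),
    )
    if status != _kernels.STATUS_OK or len(conv) < 8:
        raise RuntimeError(f"tangent integration failed (status {status})")
    tail = conv[-max(len(conv) // 4, 4):]
    lead_scale = max(abs(conv[-1]).max(), 1e-9)
    converged = bool(tail[:, 0].std() < 0.2 * lead_scale + 1e-9)
    return _finalize_spectrum(conv_t, conv, converged)


def lyapunov_spectrum_generic(
    f,
    y0: np.ndarray,
    n_exp: int,
    t_total: float,
    renorm_dt: float = 0.5,
    dt: float = 1e-3,
    seed: int = 0,
    jac=None,
) -> LyapunovResult:
    """Lyapunov spectrum of an arbitrary smooth system ``dy/dt = f(t, y)``.

    Fixed-step RK4 on the augmented (flow + tangent) system; tangents use
    the analytic ``jac`` when given, else forward-difference Jacobian-vector
    products.  Intended for small validation systems (linear flows, Lorenz).
    """
    y0 = np.asarray(y0, dtype=float)
    dim = y0.size
    if n_exp > dim:
        raise ValueError("n_exp exceeds dimension")
    rng = np.random.default_rng(seed)
    w, _ = np.linalg.qr(rng.standard_normal((dim, n_exp)))
    y = y0.copy()

    def jvp(t, y, w_mat):
        if jac is not None:
            return jac(t, y) @ w_mat
        f0 = f(t, y)
        out = np.empty_like(w_mat)
        for j in range(w_mat.shape[1]):
            wn = np.linalg.norm(w_mat[:, j])
            eps = 1e-7 * (1.0 + np.linalg.norm(y)) / max(wn, 1e-300)
            out[:, j] = (f(t, y + eps * w_mat[:, j]) - f0) / eps
        return out

    def aug_rhs(t, y, w_mat):
        return f(t, y), jvp(t, y, w_mat)

    n_renorm = int(round(t_total / renorm_dt))
    steps = max(int(round(renorm_dt / dt)), 1)
    h = renorm_dt / steps
    log_sum = np.zeros(n_exp)
    conv_t = np.empty(n_renorm)
    conv = np.empty((n_renorm, n_exp))
    t = 0.0
    for chk in range(n_renorm):
        for _ in range(steps):
            k1y, k1w = aug_rhs(t, y, w)
            k2y, k2w = aug_rhs(t + h / 2, y + h / 2 * k1y, w + h / 2 * k1w)
            k3y, k3w = aug_rhs(t + h / 2, y + h / 2 * k2y, w + h / 2 * k2w)
            k4y, k4w = aug_rhs(t + h, y + h * k3y, w + h * k3w)
            y = y + h / 6 * (k1y + 2 * k2y + 2 * k3y + k4y)
            w = w + h / 6 * (k1w + 2 * k2w + 2 * k3w + k4w)
            t += h
        q, r = np.linalg.qr(w)
        d = np.abs(np.diag(r))
        q *= np.sign(np.diag(r))
        log_sum += np.log(np.maximum(d, 1e-300))
        w = q
        conv_t[chk] = t
        conv[chk] = log_sum / t
    tail = conv[-max(n_renorm // 4, 4):]
    lead_scale = max(abs(conv[-1]).max(), 1e-9)
    converged = bool(tail[:, 0].std() < 0.2 * lead_scale + 1e-9)
    return _finalize_spectrum(conv_t, conv, converged)


# ---------------------------------------------------------------------------
# activation intervals and rhythm measurement
# ---------------------------------------------------------------------------

@dataclass
class ActivationIntervals:
    """Per-cell (start, end) intervals (ms) where the signal is 'active'."""

    intervals: dict[str, np.ndarray]   # cell id -> (n, 2) array

    def __getitem__(self, cell_id: str) -> np.ndarray:
        return self.intervals[cell_id]

    def cells(self):
        return list(self.intervals)


def activation_intervals(
    result: SimulationResult,
    threshold: float = 0.0,
    min_duration: float = 0.0,
    cells: list[str] | None = None,
    envelope_ms: float = 0.0,
) -> ActivationIntervals:
    """Maximal runs of V > threshold per cell; short runs are discarded.

    ``envelope_ms`` > 0 applies a morphological closing over that window
    first, so burst-level activations are read as single intervals.
    """
    if envelope_ms > 0:
        from scipy.ndimage import grey_closing

        size = max(int(round(envelope_ms / result.dt)), 1)
    out = {}
    for cid in cells or result.cell_ids:
        v = result.trace(cid)
        if envelope_ms > 0:
            v = grey_closing(v, size=size)
        above = v > threshold
        d = np.diff(above.astype(np.int8))
        starts = np.nonzero(d == 1)[0] + 1
        ends = np.nonzero(d == -1)[0] + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, above.size]
        iv = np.column_stack([result.t_grid[starts], result.t_grid[ends - 1]])
        dur = iv[:, 1] - iv[:, 0]
        out[cid] = iv[dur >= min_duration]
    return ActivationIntervals(out)


def burst_intervals(
    spikes: np.ndarray, max_isi: float = 1500.0, pad: float = 20.0
) -> np.ndarray:
    """Group a spike train into burst (start, end) intervals (ms).

    Successive spikes closer than ``max_isi`` belong to the same burst;
    ``pad`` extends each burst by a nominal spike width.
    """
    s = np.asarray(spikes, dtype=float)
    if s.size == 0:
        return np.empty((0, 2))
    breaks = np.nonzero(np.diff(s) > max_isi)[0]
    starts = np.r_[s[0], s[breaks + 1]]
    ends = np.r_[s[breaks], s[-1]] + pad
    return np.column_stack([starts, ends])


def rhythm_frequency(
    spikes_1A: np.ndarray,
    spikes_2A: np.ndarray,
    window: tuple[float, float] | None = None,
    max_isi: float = 1500.0,
) -> dict:
    """Wing-rhythm frequency from the alternating motoneuron bursts.

    Burst onsets are grouped by an inter-burst gap criterion; the cycle
    period is the interval between successive onsets of the same cell.
    Returns dorsal (1A) and ventral (2A) frequencies in Hz and the pooled
    coefficient of variation of the cycle period.  With fewer than three
    bursts on either side the result carries ``ok=False``.
    """
    out = {"ok": True, "flags": []}
    periods_all = []
    for name, spk in (("dorsal", spikes_1A), ("ventral", spikes_2A)):
        s = np.asarray(spk, dtype=float)
        if window is not None:
            s = s[(s >= window[0]) & (s <= window[1])]
        iv = burst_intervals(s, max_isi=max_isi)
        if len(iv) < 3:
            out["ok"] = False
            out["flags"].append(f"fewer than 3 {name} bursts")
            out[f"{name}_hz"] = np.nan
            continue
        periods = np.diff(iv[:, 0])
        out[f"{name}_hz"] = 1000.0 / periods.mean()
        periods_all.append(periods)
    if periods_all:
        p = np.concatenate(periods_all)
        out["cycle_cv"] = float(p.std() / p.mean())
    else:
        out["cycle_cv"] = np.nan
    return out


# ---------------------------------------------------------------------------
# episodes and PCA
# ---------------------------------------------------------------------------

def smooth_rates(
    spikes: dict[str, np.ndarray],
    t_grid: np.ndarray,
    kernel_ms: float = 100.0,
    cells: list[str] | None = None,
) -> np.ndarray:
    """Gaussian-smoothed firing-rate traces (Hz), cells x time."""
    cells = cells or list(spikes)
    dt = float(t_grid[1] - t_grid[0])
    sigma_bins = kernel_ms / dt
    half = int(np.ceil(4 * sigma_bins))
    x = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (x / sigma_bins) ** 2)
    kern /= kern.sum() * dt / 1000.0     # unit area in seconds
    rates = np.zeros((len(cells), t_grid.size))
    t0 = t_grid[0]
    for i, c in enumerate(cells):
        idx = np.round((np.asarray(spikes[c]) - t0) / dt).astype(int)
        idx = idx[(idx >= 0) & (idx < t_grid.size)]
        counts = np.bincount(idx, minlength=t_grid.size).astype(float)
        rates[i] = np.convolve(counts, kern, mode="same")
    return rates


@dataclass
class Episode:
    """One hunting episode: a window with a recurring activation sequence."""

    start: float
    end: float
    n_repeats: int
    motif: tuple = ()
    ep_type: str = ""

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_episodes(
    word_seq,
    min_repeats: int = 3,
    min_len: int = 3,
    min_active: int = 2,
    max_gap_words: int = 10,
    max_len: int = 8,
    max_span: float = 30000.0,
) -> list[Episode]:
    """Hunting episodes: windows where a similar activation sequence recurs
    consecutively at least ``min_repeats`` times.

    Works on a compressed activity-word sequence (see :mod:`.phaselock`).
    Occurrences of a word motif (length ``min_len``..``max_len``, at least
    ``min_active`` distinct cells) count as consecutive when at most
    ``max_gap_words`` symbols separate one occurrence's end from the next
    occurrence's start; a chain of ``min_repeats`` or more consecutive
    occurrences spans one episode.  Chains are split so no episode exceeds
    ``max_span`` ms, and overlapping candidates of different motifs are
    resolved by keeping the one with the most repeats, so the returned
    episodes are disjoint windows each characterized by one motif.
    """
    from .phaselock import n_active_in_motif

    words = [int(w) for w in word_seq.words]
    times = np.asarray(word_seq.times)
    n = len(words)
    occ_by_motif: dict[tuple, list[int]] = {}
    for L in range(min_len, min(max_len, n) + 1):
        for i in range(n - L + 1):
            motif = tuple(words[i:i + L])
            occ_by_motif.setdefault(motif, []).append(i)

    raw: list[Episode] = []
    for motif, starts in occ_by_motif.items():
        if len(starts) < min_repeats:
            continue
        if n_active_in_motif(motif) < min_active:
            continue
        L = len(motif)
        # non-overlapping occurrences, then chain by gap
        occ = []
        last_end = -1
        for s in starts:
            if s > last_end:
                occ.append(s)
                last_end = s + L - 1
        def flush(chain):
            if len(chain) < min_repeats:
                return
            # split so each episode stays within max_span
            block = [chain[0]]
            for s in chain[1:]:
                t_end = times[min(s + L - 1, n - 1)]
                if t_end - times[block[0]] > max_span:
                    if len(block) >= min_repeats:
                        raw.append(Episode(
                            start=float(times[block[0]]),
                            end=float(times[min(block[-1] + L - 1, n - 1)]),
                            n_repeats=len(block), motif=motif))
                    block = [s]
                else:
                    block.append(s)
            if len(block) >= min_repeats:
                raw.append(Episode(
                    start=float(times[block[0]]),
                    end=float(times[min(block[-1] + L - 1, n - 1)]),
                    n_repeats=len(block), motif=motif))

        chain = [occ[0]]
        for s in occ[1:]:
            if s - (chain[-1] + L) <= max_gap_words:
                chain.append(s)
            else:
                flush(chain)
                chain = [s]
        flush(chain)

    # greedy selection of disjoint episodes, strongest (most repeats) first
    raw.sort(key=lambda e: (-e.n_repeats * len(e.motif), e.start))
    chosen: list[Episode] = []
    for ep in raw:
        if all(ep.end < c.start or ep.start > c.end for c in chosen):
            chosen.append(ep)
    chosen.sort(key=lambda e: e.start)
    return chosen


def classify_episodes(
    episodes: list[Episode],
    intervals: ActivationIntervals,
    src_ids: list[str],
    long_threshold: float = 1000.0,
) -> list[Episode]:
    """Type each episode by which cells have long mean activations.

    A cell is 'long' inside an episode when its mean activation duration
    exceeds ``long_threshold`` ms.  The episode type string is the sorted
    tuple of long cells ('all-short' / 'all-long' for the uniform cases),
    mirroring the long-vs-short activation typing of hunting episodes.
    """
    for ep in episodes:
        longs = []
        for cid in src_ids:
            iv = intervals[cid]
            m = (iv[:, 0] < ep.end) & (iv[:, 1] > ep.start)
            if not m.any():
                continue
            if (iv[m, 1] - iv[m, 0]).mean() >= long_threshold:
                longs.append(cid)
        if not longs:
            ep.ep_type = "all-short"
        elif len(longs) == len(src_ids):
            ep.ep_type = "all-long"
        else:
            ep.ep_type = "long:" + "+".join(sorted(longs))
    return episodes


@dataclass
class EpisodePCA:
    components: np.ndarray            # (n_pc, n_channels)
    explained_variance_ratio: np.ndarray
    trajectories: list[np.ndarray]    # per-episode (n_t, 3) projections
    episode_types: list[str]

    @property
    def cum3(self) -> float:
        """Cumulative variance fraction of the first three components."""
        return float(self.explained_variance_ratio[:3].sum())


def episode_pca(
    rates: np.ndarray,
    t_grid: np.ndarray,
    episodes: list[Episode],
    n_components: int = 3,
) -> EpisodePCA:
    """PCA of episode-windowed multichannel rate signals.

    The signals of all episodes are concatenated (channels = variables,
    time samples = observations), components are extracted once, and each
    episode's trajectory is projected on the first three components.
    """
    if len(episodes) < 2:
        raise ValueError("need at least 2 episodes for the episode PCA")
    segs = []
    for ep in episodes:
        m = (t_grid >= ep.start) & (t_grid <= ep.end)
        segs.append(rates[:, m].T)
    data = np.concatenate(segs, axis=0)
    if np.allclose(data.std(axis=0), 0):
        raise ValueError("degenerate (zero-variance) episode signals")
    # keep every component so the variance fractions sum to 1
    n_pc = min(rates.shape[0], data.shape[0])
    pca = _SKPCA(n_components=n_pc)
    pca.fit(data)
    ratio = np.asarray(pca.explained_variance_ratio_)
    trajs = [pca.transform(s)[:, :3] for s in segs]
    return EpisodePCA(
        components=pca.components_,
        explained_variance_ratio=ratio,
        trajectories=trajs,
        episode_types=[ep.ep_type for ep in episodes],
    )


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

@dataclass
class PSTH:
    bin_edges: np.ndarray              # ms, relative to alignment
    counts: dict[str, np.ndarray]      # cell id -> per-bin spike counts
    n_alignments: int

    def rate(self, cell_id: str) -> np.ndarray:
        """Mean spike rate per bin (Hz) across alignments."""
        width_s = np.diff(self.bin_edges) / 1000.0
        return self.counts[cell_id] / (self.n_alignments * width_s)


def classify_motor_response(
    spikes_1A: np.ndarray,
    spikes_2A: np.ndarray,
    onset: float,
    window: tuple[float, float] = (0.0, 4000.0),
    order_margin: float = 50.0,
) -> str:
    """Class of the wing motor response following one alignment event.

    Classes are defined by the presence and order of 1A and 2A firing in
    the window after the event: ``none``, ``1A``, ``2A``, ``1A->2A`` or
    ``2A->1A`` (order from the first spike of each cell; simultaneous
    onsets within ``order_margin`` ms count as ``1A->2A``).
    """
    a = np.asarray(spikes_1A, dtype=float)
    b = np.asarray(spikes_2A, dtype=float)
    lo, hi = onset + window[0], onset + window[1]
    a = a[(a >= lo) & (a <= hi)]
    b = b[(b >= lo) & (b <= hi)]
    if a.size == 0 and b.size == 0:
        return "none"
    if b.size == 0:
        return "1A"
    if a.size == 0:
        return "2A"
    return "1A->2A" if a[0] <= b[0] + order_margin else "2A->1A"


def response_reliability(
    onsets: np.ndarray,
    spikes_1A: np.ndarray,
    spikes_2A: np.ndarray,
    window: tuple[float, float] = (0.0, 4000.0),
) -> dict:
    """Fraction of occurrences whose motor response matches the modal class.

    Returns the modal class, the match fraction, and the per-occurrence
    class labels, for one phase-lock pattern's occurrence onsets.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one onset")
    labels = [classify_motor_response(spikes_1A, spikes_2A, t, window) for t in onsets]
    values, counts = np.unique(labels, return_counts=True)
    modal = values[np.argmax(counts)]
    return {
        "modal_class": str(modal),
        "fraction": float(counts.max() / len(labels)),
        "labels": labels,
        "n": len(labels),
    }


def psth(
    spikes: dict[str, np.ndarray],
    alignment_times: np.ndarray,
    window: tuple[float, float] = (0.0, 4000.0),
    bin_width: float = 100.0,
) -> PSTH:
    """Histogram of spike times relative to repeated alignment events."""
    align = np.asarray(alignment_times, dtype=float)
    if align.size == 0:
        raise ValueError("need at least one alignment time")
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    counts = {}
    for cid, s in spikes.items():
        s = np.asarray(s, dtype=float)
        rel = (s[None, :] - align[:, None]).ravel()
        rel = rel[(rel >= edges[0]) & (rel <= edges[-1])]
        counts[cid], _ = np.histogram(rel, bins=edges)
    return PSTH(bin_edges=edges, counts=counts, n_alignments=align.size)
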