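"""Deterministic surrogate-data generators for the analysis layer.

These emulate only the statistical/temporal structure the analyses assume
(threshold crossings, spike latencies, planted word motifs) — not the
biophysics — so every analysis operation is testable in milliseconds.
Everything is bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phaselock import ActivityWordSequence, N_BITS_DEFAULT

__all__ = ["FixtureSpec", "make_traces", "make_spikes", "make_wordstream"]


@dataclass
class FixtureSpec:
    """Recipe for surrogate traces / spike trains / word streams.

    ``schedule`` maps channel name -> list of (start, end) activation
    intervals in ms.  ``motifs`` is a list of (word-tuple, occurrence-onset
    positions) planted into the word stream.  ``latency_rules`` maps channel
    name -> (event_times, latency_ms): the channel emits one spike at each
    event time + latency (+ jitter when ``latency_jitter`` > 0).
    """

    duration: float = 10000.0           # ms
    dt: float = 0.5                     # ms
    n_channels: int = 6
    schedule: dict = field(default_factory=dict)
    motifs: list = field(default_factory=list)
    filler_words: int = 0               # random filler words between motifs
    latency_rules: dict = field(default_factory=dict)
    latency_jitter: float = 0.0         # ms (std of Gaussian jitter)
    noise_amplitude: float = 0.0        # mV additive Gaussian on traces
    baseline: float = -60.0             # mV
    active_level: float = 20.0          # mV
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        for ch, ivs in self.schedule.items():
            prev_end = -np.inf
            for a, b in sorted(ivs):
                if a >= b:
                    raise ValueError(f"empty interval ({a}, {b}) on {ch}")
                if b > self.duration:
                    raise ValueError(f"interval ({a}, {b}) exceeds duration")
                if a < prev_end:
                    raise ValueError(f"overlapping intervals on {ch}")
                prev_end = b


def make_traces(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Voltage-like traces crossing 0 mV exactly on the scheduled intervals.

    Returns (t_grid, V[channels, time], ground_truth) where ground_truth
    maps channel -> (n, 2) interval array as realized on the grid.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    names = [f"ch{i+1}" for i in range(spec.n_channels)]
    V = np.full((spec.n_channels, t.size), spec.baseline)
    truth = {}
    for i, name in enumerate(names):
        ivs = spec.schedule.get(name, [])
        realized = []
        for a, b in ivs:
            m = (t >= a) & (t <= b)
            V[i, m] = spec.active_level
            if m.any():
                realized.append([t[m][0], t[m][-1]])
        truth[name] = np.asarray(realized).reshape(-1, 2)
    if spec.noise_amplitude > 0:
        V = V + rng.normal(0.0, spec.noise_amplitude, V.shape)
    return t, V, truth


def make_spikes(spec: FixtureSpec) -> tuple[dict, dict]:
    """Spike trains realizing the latency rules.

    Returns (spikes, ground_truth) where spikes maps channel -> sorted spike
    times and ground_truth records the noiseless event + latency times.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    spikes, truth = {}, {}
    for ch, (events, latency) in spec.latency_rules.items():
        base = np.asarray(events, dtype=float) + float(latency)
        jit = rng.normal(0.0, spec.latency_jitter, base.size) if spec.latency_jitter else 0.0
        s = np.sort(base + jit)
        spikes[ch] = s[(s >= 0) & (s <= spec.duration)]
        truth[ch] = base
    return spikes, truth


def make_wordstream(spec: FixtureSpec) -> tuple[ActivityWordSequence, dict]:
    """Compressed word stream containing exactly the planted motifs.

    Motif occurrences are placed at the requested symbol positions with
    seeded random filler words in between; filler never recreates a planted
    motif and never duplicates its neighbor (so the stream stays
    compressed).  Returns the sequence and a ground-truth dict with the
    planted positions and onset times.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_bits = spec.n_channels
    placements = []
    for motif, positions in spec.motifs:
        motif = tuple(int(w) for w in motif)
        if any(not 0 <= w < 2 ** n_bits for w in motif):
            raise ValueError("motif word out of range for channel count")
        for p in positions:
            placements.append((int(p), motif))
    placements.sort()
    for (p1, m1), (p2, _m2) in zip(placements, placements[1:]):
        if p2 < p1 + len(m1):
            raise ValueError(f"overlapping motif placements at {p1} and {p2}")

    total = (max(p + len(m) for p, m in placements) if placements else 0) + spec.filler_words
    words = np.full(total, -1, dtype=np.int64)
    for p, m in placements:
        words[p:p + len(m)] = m

    forbidden = {tuple(m) for _, m in placements}
    all_words = np.arange(2 ** n_bits)
    for i in range(total):
        if words[i] >= 0:
            continue
        while True:
            w = int(rng.integers(0, 2 ** n_bits))
            if i > 0 and w == words[i - 1]:
                continue
            if i + 1 < total and w == words[i + 1]:
                continue
            words[i] = w
            # reject fillers that complete a forbidden motif around i
            bad = False
            for motif in forbidden:
                L = len(motif)
                for s in range(max(0, i - L + 1), min(i + 1, total - L + 1)):
                    window = words[s:s + L]
                    if np.all(window >= 0) and tuple(window) == motif:
                        if not any(s == p for p, m in placements if len(m) == L):
                            bad = True
                            break
                if bad:
                    break
            if bad:
                words[i] = -1
                continue
            break

    dt_word = spec.duration / max(total, 1)
    times = np.arange(total) * dt_word
    seq = ActivityWordSequence(times, words, n_bits=n_bits, compressed=True)
    truth = {
        "placements": placements,
        "onset_times": {
            tuple(m): np.asarray([times[p] for p, m2 in placements if m2 == tuple(m)])
            for _, m in placements
        },
        "word_dt": dt_word,
    }
    return seq, truth
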