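"""Activation phase locks: symbolic analysis of the sensory dynamics.

The six SRC voltage traces are discretized into 6-bit *activity words*
(bit i set iff SRC(i+1) is above threshold at that sample; SRC1 is the
most-significant bit).  Consecutive identical words are collapsed
(*compression*), which removes the effect of activation-duration
differences.  An *activation phase lock* is a motif of consecutive
compressed words that recurs many times and involves at least four
distinct SRCs — a preserved switching order inside the otherwise chaotic
hunting dynamics.  Motif occurrences align the motoneuron PSTHs that test
whether a given sensory sequence evokes a stereotyped motor response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivityWordSequence",
    "PhaseLockPattern",
    "discretize",
    "compress",
    "find_phase_locks",
    "find_phase_locks_pooled",
    "lock_onsets",
    "n_active_in_motif",
    "word_to_str",
]

N_BITS_DEFAULT = 6


def word_to_str(word: int, n_bits: int = N_BITS_DEFAULT) -> str:
    return format(word, f"0{n_bits}b")


def n_active_in_motif(motif, n_bits: int = N_BITS_DEFAULT) -> int:
    """Number of distinct channels active anywhere in a word motif."""
    acc = 0
    for w in motif:
        acc |= int(w)
    return bin(acc).count("1")


@dataclass
class ActivityWordSequence:
    """A timed sequence of activity words.

    ``times[j]`` is the time (ms) at which ``words[j]`` first held; in a
    compressed sequence no two consecutive words are equal.
    """

    times: np.ndarray
    words: np.ndarray
    n_bits: int = N_BITS_DEFAULT
    compressed: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.words = np.asarray(self.words, dtype=np.int64)
        if self.times.shape != self.words.shape:
            raise ValueError("times and words must have equal length")
        if self.compressed and len(self.words) > 1:
            if np.any(self.words[1:] == self.words[:-1]):
                raise ValueError("sequence flagged compressed has equal consecutive words")

    def __len__(self) -> int:
        return len(self.words)

    def to_text(self) -> str:
        """One `<time_ms> <binary word>` pair per line."""
        return "\n".join(
            f"{t:.3f} {word_to_str(w, self.n_bits)}"
            for t, w in zip(self.times, self.words)
        )

    @classmethod
    def from_text(cls, text: str, compressed: bool = False) -> "ActivityWordSequence":
        times, words, n_bits = [], [], N_BITS_DEFAULT
        for line in text.strip().splitlines():
            t, w = line.split()
            times.append(float(t))
            words.append(int(w, 2))
            n_bits = len(w)
        return cls(np.asarray(times), np.asarray(words), n_bits=n_bits,
                   compressed=compressed)


@dataclass
class PhaseLockPattern:
    """A recurring motif of compressed activity words."""

    motif: tuple
    occurrences: np.ndarray          # (n, 2): start ms, end ms
    n_bits: int = N_BITS_DEFAULT

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrences)

    @property
    def n_distinct_active(self) -> int:
        return n_active_in_motif(self.motif, self.n_bits)

    def to_dict(self) -> dict:
        return {
            "motif": [word_to_str(w, self.n_bits) for w in self.motif],
            "occurrences": [[float(a), float(b)] for a, b in self.occurrences],
            "n_occurrences": self.n_occurrences,
            "n_distinct_active": self.n_distinct_active,
        }


def discretize(
    V: np.ndarray,
    t_grid: np.ndarray,
    threshold: float = 0.0,
    n_bits: int | None = None,
    envelope_ms: float = 0.0,
) -> ActivityWordSequence:
    """Binary activity words from multichannel voltage traces.

    ``V`` is channels x time; channel 0 (SRC1) maps to the most-significant
    bit.  The statocyst entry points pass exactly six channels; other widths
    are accepted with ``n_bits`` set explicitly.

    With ``envelope_ms`` > 0 each trace is morphologically closed over that
    window before thresholding, so a burst whose inter-spike dips fall below
    the threshold still reads as one continuous activation (the burst
    envelope).  Closing fills gaps shorter than the window but does not
    extend an activation beyond its outermost crossings.
    """
    V = np.atleast_2d(np.asarray(V))
    if envelope_ms > 0:
        from scipy.ndimage import grey_closing

        size = max(int(round(envelope_ms / float(t_grid[1] - t_grid[0]))), 1)
        V = np.stack([grey_closing(v, size=size) for v in V])
    n_ch = V.shape[0]
    if n_bits is None:
        if n_ch != N_BITS_DEFAULT:
            raise ValueError(
                f"expected 6 channels (got {n_ch}); pass n_bits to generalize"
            )
        n_bits = n_ch
    elif n_bits != n_ch:
        raise ValueError("n_bits must equal the channel count")
    bits = (V > threshold)
    weights = 2 ** np.arange(n_bits - 1, -1, -1, dtype=np.int64)
    words = bits.T @ weights
    return ActivityWordSequence(np.asarray(t_grid, dtype=float), words, n_bits=n_bits)


def compress(seq: ActivityWordSequence) -> ActivityWordSequence:
    """Collapse consecutive identical words, keeping first-occurrence times."""
    if len(seq) == 0:
        return ActivityWordSequence(seq.times, seq.words, seq.n_bits, compressed=True)
    keep = np.r_[True, seq.words[1:] != seq.words[:-1]]
    return ActivityWordSequence(
        seq.times[keep], seq.words[keep], n_bits=seq.n_bits, compressed=True
    )


def find_phase_locks(
    seq: ActivityWordSequence,
    min_len: int = 3,
    min_active: int = 4,
    min_occurrences: int = 30,
    max_len: int = 12,
) -> list[PhaseLockPattern]:
    """All maximal recurring word motifs meeting the phase-lock criteria.

    A motif is a run of ``min_len``..``max_len`` consecutive words of the
    compressed sequence.  Occurrences are counted left-to-right without
    overlap.  A motif is *maximal* when no extension of it (one word longer,
    at either end) has the same occurrence count — shorter sub-motifs of an
    accepted motif are reported only if they occur strictly more often.
    Patterns are ordered by occurrence count, then motif length, then
    lexicographically.
    """
    if not seq.compressed:
        raise ValueError("find_phase_locks requires a compressed sequence")
    words = seq.words
    times = seq.times
    n = len(words)
    counts: dict[tuple, list[int]] = {}
    for L in range(min_len, min(max_len, n) + 1):
        for i in range(n - L + 1):
            motif = tuple(int(w) for w in words[i:i + L])
            counts.setdefault(motif, []).append(i)

    def nonoverlap(starts: list[int], L: int) -> list[int]:
        picked, last_end = [], -1
        for s in starts:
            if s > last_end:
                picked.append(s)
                last_end = s + L - 1
        return picked

    candidates = {}
    for motif, starts in counts.items():
        if n_active_in_motif(motif, seq.n_bits) < min_active:
            continue
        occ = nonoverlap(starts, len(motif))
        if len(occ) >= min_occurrences:
            candidates[motif] = occ

    # maximality: drop motifs strictly contained in an equally frequent longer one
    accepted = []
    for motif, occ in candidates.items():
        contained = False
        for other, occ2 in candidates.items():
            if other == motif or len(other) <= len(motif):
                continue
            if len(occ2) >= len(occ):
                L, M = len(motif), len(other)
                if any(other[k:k + L] == motif for k in range(M - L + 1)):
                    contained = True
                    break
        if not contained:
            accepted.append((motif, occ))

    accepted.sort(key=lambda mo: (-len(mo[1]), -len(mo[0]), mo[0]))
    patterns = []
    for motif, occ in accepted:
        L = len(motif)
        spans = np.array([
            [times[s], times[min(s + L - 1, n - 1)]] for s in occ
        ])
        patterns.append(PhaseLockPattern(motif=motif, occurrences=spans,
                                         n_bits=seq.n_bits))
    return patterns


def find_phase_locks_pooled(
    seqs: list[ActivityWordSequence],
    min_len: int = 3,
    min_active: int = 4,
    min_occurrences: int = 30,
    max_len: int = 12,
) -> list[PhaseLockPattern]:
    """Phase locks whose occurrences are pooled over several recordings.

    The occurrence criterion applies to the total count across all supplied
    (compressed) sequences — sequences of separate simulations or trials of
    equal length.  Occurrence spans are reported per sequence order with
    times as recorded; a motif must appear in at least two sequences, so
    patterns idiosyncratic to a single recording are excluded.
    """
    per_seq = [
        find_phase_locks(s, min_len=min_len, min_active=min_active,
                         min_occurrences=2, max_len=max_len)
        for s in seqs
    ]
    totals: dict[tuple, list] = {}
    for si, pats in enumerate(per_seq):
        for p in pats:
            entry = totals.setdefault(p.motif, [0, 0, []])
            entry[0] += p.n_occurrences
            entry[1] += 1
            entry[2].append(p.occurrences)
    out = []
    for motif, (count, n_series, spans) in totals.items():
        if count >= min_occurrences and n_series >= min(2, len(seqs)):
            out.append(PhaseLockPattern(
                motif=motif,
                occurrences=np.concatenate(spans),
                n_bits=seqs[0].n_bits,
            ))
    out.sort(key=lambda p: (-p.n_occurrences, -len(p.motif), p.motif))
    return out


def lock_onsets(pattern: PhaseLockPattern, seq: ActivityWordSequence) -> np.ndarray:
    """Occurrence onset times (ms) of a pattern's motif in a sequence.

    Recomputed against ``seq`` (not read from the pattern), so a pattern
    mined in one recording can be located in another.  Non-overlapping
    left-to-right matching; strictly increasing times; empty if absent.
    """
    if not seq.compressed:
        raise ValueError("lock_onsets requires a compressed sequence")
    motif = np.asarray(pattern.motif, dtype=np.int64)
    L = len(motif)
    words = seq.words
    onsets = []
    i = 0
    while i <= len(words) - L:
        if np.array_equal(words[i:i + L], motif):
            onsets.append(seq.times[i])
            i += L
        else:
            i += 1
    return np.asarray(onsets)
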