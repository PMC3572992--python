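"""Symbolic activity-word algorithm: discretization, compression, motif
mining against a brute-force oracle, and duration invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clionesim import phaselock as pl
from clionesim.fixtures import FixtureSpec, make_traces, make_wordstream


def _seq(words, compressed=True):
    words = np.asarray(words, dtype=np.int64)
    return pl.ActivityWordSequence(np.arange(len(words), dtype=float) * 100.0,
                                   words, compressed=compressed)


class TestDiscretize:
    def test_named_example_word(self):
        """SRC3 and SRC6 above threshold -> word 001001."""
        V = np.full((6, 10), -60.0)
        V[2], V[5] = 20.0, 20.0
        t = np.arange(10) * 0.5
        seq = pl.discretize(V, t)
        assert pl.word_to_str(seq.words[0]) == "001001"

    def test_all_below_gives_zero_word(self):
        V = np.full((6, 5), -60.0)
        seq = pl.discretize(V, np.arange(5.0))
        assert np.all(seq.words == 0)

    def test_word_string_round_trip(self):
        for w in range(64):
            assert int(pl.word_to_str(w), 2) == w

    def test_channel_count_enforced_unless_explicit(self):
        V = np.zeros((4, 5))
        with pytest.raises(ValueError, match="6 channels"):
            pl.discretize(V, np.arange(5.0))
        seq = pl.discretize(V, np.arange(5.0), n_bits=4)
        assert seq.n_bits == 4

    def test_envelope_closes_intra_burst_dips(self):
        t = np.arange(0, 3000.0, 0.5)
        V = np.full((6, t.size), -60.0)
        # three spike peaks with sub-threshold dips in between
        for start in (1000.0, 1150.0, 1300.0):
            i = int(start / 0.5)
            V[0, i:i + 40] = 20.0
        plain = pl.compress(pl.discretize(V, t))
        env = pl.compress(pl.discretize(V, t, envelope_ms=400.0))
        assert np.sum(plain.words == 0b100000) == 3
        assert np.sum(env.words == 0b100000) == 1


class TestCompress:
    def test_collapses_duplicates(self):
        seq = _seq([5, 5, 5, 9, 9, 3], compressed=False)
        out = pl.compress(seq)
        assert list(out.words) == [5, 9, 3]
        assert list(out.times) == [0.0, 300.0, 500.0]

    def test_idempotent(self):
        seq = _seq([5, 5, 9, 9, 3, 3, 3], compressed=False)
        once = pl.compress(seq)
        twice = pl.compress(once)
        assert np.array_equal(once.words, twice.words)
        assert np.array_equal(once.times, twice.times)

    def test_empty(self):
        out = pl.compress(_seq([], compressed=False))
        assert len(out) == 0 and out.compressed

    @given(st.lists(st.integers(0, 63), max_size=200))
    @settings(deadline=None, max_examples=100)
    def test_no_adjacent_duplicates_after_compression(self, words):
        out = pl.compress(_seq(words, compressed=False))
        assert not np.any(out.words[1:] == out.words[:-1])


def brute_force_phase_locks(words, min_len, min_active, min_occ, max_len):
    """Independent enumeration: every window as a candidate motif, counted by
    naive left-to-right non-overlapping rescan; same maximality rule."""
    n = len(words)
    cands = {}
    for L in range(min_len, min(max_len, n) + 1):
        for i in range(n - L + 1):
            motif = tuple(words[i:i + L])
            if motif in cands:
                continue
            acc = 0
            for w in motif:
                acc |= w
            if bin(acc).count("1") < min_active:
                continue
            count, j, starts = 0, 0, []
            while j <= n - L:
                if tuple(words[j:j + L]) == motif:
                    count += 1
                    starts.append(j)
                    j += L
                else:
                    j += 1
            if count >= min_occ:
                cands[motif] = starts
    final = {}
    for motif, starts in cands.items():
        keep = True
        for other, starts2 in cands.items():
            if len(other) > len(motif) and len(starts2) >= len(starts):
                if any(other[k:k + len(motif)] == motif
                       for k in range(len(other) - len(motif) + 1)):
                    keep = False
                    break
        if keep:
            final[motif] = starts
    return final


class TestFindPhaseLocks:
    def test_planted_motif_recovered(self):
        motif = (0b100100, 0b110100, 0b010110, 0b010011, 0b000011)
        spec = FixtureSpec(duration=60000.0, seed=5, filler_words=300,
                           motifs=[(motif, list(range(0, 2400, 8)))])
        seq, truth = make_wordstream(spec)
        pats = pl.find_phase_locks(seq, min_len=3, min_active=4,
                                   min_occurrences=30, max_len=5)
        assert any(p.motif == motif and p.n_occurrences == 300 for p in pats)

    def test_three_cell_motif_excluded(self):
        motif = (0b100100, 0b000100, 0b000101)   # only SRCs 1, 4, 6
        spec = FixtureSpec(duration=60000.0, seed=6, filler_words=100,
                           motifs=[(motif, list(range(0, 500, 5)))])
        seq, _ = make_wordstream(spec)
        pats = pl.find_phase_locks(seq, min_len=3, min_active=4,
                                   min_occurrences=10, max_len=3)
        assert not any(p.motif == motif for p in pats)

    def test_uncompressed_rejected(self):
        with pytest.raises(ValueError, match="compressed"):
            pl.find_phase_locks(_seq([1, 2, 3], compressed=False))

    @given(st.integers(0, 2**32 - 1), st.integers(50, 500))
    @settings(deadline=None, max_examples=25)
    def test_matches_brute_force_enumeration(self, seed, n):
        """Property sweep: on random compressed word streams the miner agrees
        exactly with independent exhaustive enumeration."""
        rng = np.random.default_rng(seed)
        words = [int(rng.integers(0, 64))]
        while len(words) < n:
            w = int(rng.integers(0, 64))
            if w != words[-1]:
                words.append(w)
        seq = _seq(words)
        got = pl.find_phase_locks(seq, min_len=3, min_active=4,
                                  min_occurrences=3, max_len=6)
        want = brute_force_phase_locks(words, 3, 4, 3, 6)
        assert {p.motif for p in got} == set(want)
        for p in got:
            assert p.n_occurrences == len(want[p.motif])

    def test_ordering_deterministic(self):
        words = [1, 2, 60, 1, 2, 60, 5, 1, 2, 60, 9, 1, 2, 60]
        seq = _seq(words)
        a = pl.find_phase_locks(seq, min_len=3, min_active=4, min_occurrences=2)
        b = pl.find_phase_locks(seq, min_len=3, min_active=4, min_occurrences=2)
        assert [p.motif for p in a] == [p.motif for p in b]


class TestDurationInvariance:
    def test_stretching_activations_preserves_motifs(self):
        """The algorithm's purpose: activation durations do not matter, only
        the switching order."""
        base = {"ch1": [(500.0, 1000.0)], "ch2": [(900.0, 1500.0)],
                "ch3": [(1400.0, 2000.0)], "ch4": [(1900.0, 2600.0)]}
        stretched = {c: [(2.0 * a, 2.0 * b) for a, b in ivs]
                     for c, ivs in base.items()}
        words = []
        for sched, dur in ((base, 8000.0), (stretched, 16000.0)):
            spec = FixtureSpec(duration=dur, schedule=sched)
            t, V, _ = make_traces(spec)
            seq = pl.compress(pl.discretize(V, t))
            words.append(list(seq.words))
        assert words[0] == words[1]


class TestLockOnsets:
    def test_planted_onsets_recovered(self):
        motif = (0b110000, 0b010100, 0b001100, 0b001001)
        positions = [0, 40, 90, 200, 321]
        spec = FixtureSpec(duration=40000.0, seed=9, filler_words=150,
                           motifs=[(motif, positions)])
        seq, truth = make_wordstream(spec)
        pattern = pl.PhaseLockPattern(motif=motif, occurrences=np.empty((0, 2)))
        onsets = pl.lock_onsets(pattern, seq)
        assert onsets == pytest.approx(truth["onset_times"][motif])
        assert np.all(np.diff(onsets) > 0)

    def test_absent_pattern_empty(self):
        seq = _seq([1, 2, 3, 4])
        pattern = pl.PhaseLockPattern(motif=(9, 10, 11),
                                      occurrences=np.empty((0, 2)))
        assert pl.lock_onsets(pattern, seq).size == 0

    def test_single_occurrence(self):
        seq = _seq([7, 1, 2, 3, 9])
        pattern = pl.PhaseLockPattern(motif=(1, 2, 3),
                                      occurrences=np.empty((0, 2)))
        onsets = pl.lock_onsets(pattern, seq)
        assert onsets == pytest.approx([100.0])
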