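"""Asymmetry index, Shannon diversity and the sequential windowing."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from playface.indices import (WindowPair, before_after_indices,
                              extract_windows, pai, shannon)
from playface.pipeline import detect_all_rfm, sequential_table
from playface.simulate import effects_params, generate

from conftest import make_expression, make_pattern, make_session

PATTERN_NAMES = ["play bite", "play slap", "play flee", "play shelter",
                 "pirouetting", "somersault", "play chase", "tickle"]
CATEGORY = {"play bite": "offensive", "play slap": "offensive",
            "play chase": "offensive", "play flee": "defensive",
            "play shelter": "defensive", "pirouetting": "neutral",
            "somersault": "neutral", "tickle": "neutral"}


def random_window(rng, n=None):
    n = n or rng.integers(1, 9)
    events = []
    for i in range(n):
        pat = PATTERN_NAMES[rng.integers(len(PATTERN_NAMES))]
        actor = "A" if rng.random() < 0.5 else "B"
        solitary = CATEGORY[pat] == "neutral" and rng.random() < 0.3
        events.append(make_pattern(float(i), actor=actor,
                                   target=None if solitary else
                                   ("B" if actor == "A" else "A"),
                                   pattern=pat, category=CATEGORY[pat]))
    return events


class TestPAI:
    def test_hand_worked_window(self):
        w = [make_pattern(1, "A", "B", "play bite", "offensive"),
             make_pattern(2, "A", "B", "play slap", "offensive"),
             make_pattern(3, "B", "A", "play flee", "defensive"),
             make_pattern(4, "A", None, "pirouetting", "neutral")]
        assert pai(w, "A", "B") == pytest.approx(0.75)

    def test_all_neutral_window_is_symmetric(self):
        w = [make_pattern(i, "A", "B", "tickle", "neutral") for i in range(3)]
        assert pai(w, "A", "B") == 0.0

    def test_empty_window_not_available(self):
        assert math.isnan(pai([], "A", "B"))

    def test_antisymmetry_and_bounds_on_random_windows(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            w = random_window(rng)
            v = pai(w, "A", "B")
            assert -1.0 <= v <= 1.0
            assert pai(w, "B", "A") == pytest.approx(-v)

    def test_extreme_value_iff_fully_one_sided(self):
        w = [make_pattern(i, "A", "B", "play bite", "offensive")
             for i in range(5)]
        assert pai(w, "A", "B") == 1.0
        w[0] = make_pattern(0, "A", None, "somersault", "neutral")
        assert pai(w, "A", "B") < 1.0

    def test_matches_count_based_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            w = random_window(rng)
            off_a = sum(1 for e in w if e.category == "offensive"
                        and e.actor == "A" and e.target == "B")
            off_b = sum(1 for e in w if e.category == "offensive"
                        and e.actor == "B" and e.target == "A")
            def_a = sum(1 for e in w if e.category == "defensive"
                        and e.actor == "A" and e.target == "B")
            def_b = sum(1 for e in w if e.category == "defensive"
                        and e.actor == "B" and e.target == "A")
            expected = ((off_a + def_b) - (off_b + def_a)) / len(w)
            assert pai(w, "A", "B") == pytest.approx(expected)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.sampled_from(PATTERN_NAMES), st.booleans(),
                          st.booleans()),
                min_size=1, max_size=10))
def test_index_invariants_hold_for_arbitrary_windows(spec):
    """PAI antisymmetry/bounds and Shannon bounds for any pattern window."""
    w = []
    for i, (pat, actor_is_a, solitary) in enumerate(spec):
        actor = "A" if actor_is_a else "B"
        target = (None if solitary and CATEGORY[pat] == "neutral"
                  else ("B" if actor == "A" else "A"))
        w.append(make_pattern(float(i), actor=actor, target=target,
                              pattern=pat, category=CATEGORY[pat]))
    v = pai(w, "A", "B")
    assert -1.0 <= v <= 1.0
    assert pai(w, "B", "A") == pytest.approx(-v)
    h = shannon(w)
    assert 0.0 <= h <= math.log(len({e.pattern for e in w})) + 1e-12


class TestShannon:
    def test_worked_session_example(self):
        # play slapping x3, play sheltering x1, pirouetting x1
        w = ([make_pattern(i, pattern="play slap", category="offensive")
              for i in range(3)]
             + [make_pattern(3, "B", "A", "play shelter", "defensive"),
                make_pattern(4, "A", None, "pirouetting", "neutral")])
        assert shannon(w) == pytest.approx(0.9503, abs=1e-4)

    def test_identical_patterns_zero(self):
        w = [make_pattern(i, pattern="play bite") for i in range(6)]
        assert shannon(w) == 0.0

    def test_uniform_maximum(self):
        w = [make_pattern(i, pattern=p, category=CATEGORY[p])
             for i, p in enumerate(PATTERN_NAMES[:5])]
        assert shannon(w) == pytest.approx(math.log(5))

    def test_bounds_and_player_invariance_on_random_windows(self):
        rng = np.random.default_rng(29)
        for _ in range(1000):
            w = random_window(rng)
            h = shannon(w)
            k = len({e.pattern for e in w})
            assert 0.0 <= h <= math.log(k) + 1e-12
            relabeled = [make_pattern(e.time,
                                      "B" if e.actor == "A" else "A",
                                      None if e.target is None else
                                      ("B" if e.target == "A" else "A"),
                                      e.pattern, e.category) for e in w]
            assert shannon(relabeled) == pytest.approx(h)


class TestExtractWindows:
    def _session(self, n_patterns, focal_times):
        patterns = [make_pattern(float(i) + 0.5) for i in range(n_patterns)]
        focals = [make_expression(t) for t in focal_times]
        return make_session(patterns, focals), focals

    def test_full_windows_both_sides(self):
        s, focals = self._session(10, [5.0])
        (w,) = extract_windows(s, focals)
        assert len(w.before) == 4 and len(w.after) == 4
        assert all(p.time < 5.0 for p in w.before)
        assert all(p.time > 5.0 for p in w.after)

    def test_too_close_consecutive_focals_thinned(self):
        # 5 patterns between the focal onsets < 12 required
        s, focals = self._session(30, [5.0, 10.2])
        windows = extract_windows(s, focals)
        assert len(windows) == 1 and windows[0].focal is focals[0]

    def test_sufficiently_spaced_focals_both_retained(self):
        s, focals = self._session(30, [5.0, 18.0])  # 12 patterns between
        assert len(extract_windows(s, focals)) == 2

    def test_focal_at_session_start_dropped(self):
        s, focals = self._session(10, [0.2])
        assert extract_windows(s, focals) == []

    def test_short_side_retained_when_nonempty(self):
        s, focals = self._session(10, [2.0])
        (w,) = extract_windows(s, focals)
        assert len(w.before) == 2 and len(w.after) == 4

    def test_spacing_measured_from_last_retained(self):
        # middle focal excluded; third focal spaced >= 12 from the first
        s, focals = self._session(40, [5.0, 9.0, 18.0])
        windows = extract_windows(s, focals)
        assert [w.focal for w in windows] == [focals[0], focals[2]]


class TestBeforeAfterIndices:
    def test_symmetric_windows_give_equal_indices(self):
        w = [make_pattern(i, "A", "B", "play bite", "offensive")
             for i in range(4)]
        wp = WindowPair(focal=None, before=tuple(w), after=tuple(w), k=4)
        idx = before_after_indices(wp, ("A", "B"))
        assert idx.pai_before == idx.pai_after
        assert idx.h_before == idx.h_after

    def test_generator_effects_recovered_in_index_shifts(self):
        # offense shifts toward the emitter after unreplicated FPF;
        # diversity rises after unreplicated PF
        sessions, _ = generate(effects_params(seed=31, n_dyads=50,
                                              sessions_per_dyad=42))
        table = sequential_table(sessions, detect_all_rfm(sessions))
        fpf = table[table["focal_kind"] == "FPF-not-mim"]
        pf = table[table["focal_kind"] == "PF-not-mim"]
        assert len(fpf) >= 200 and len(pf) >= 200
        assert (fpf["pai_after"] - fpf["pai_before"]).mean() > 0
        assert (pf["h_after"] - pf["h_before"]).mean() > 0
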