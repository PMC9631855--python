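"""Independent 1-ms discretized brute-force reference implementation.

Everything here works sample-by-sample on boolean per-millisecond coverage
arrays and stays deliberately independent of the interval-algebra code under
test.
"""
from __future__ import annotations

import numpy as np

WHITE, GRAY, BLACK = 0, 1, 2
OUT_NO_FOG, OUT_FOG, OUT_DISCUSSION = 0, 1, 2


def cover_array(track) -> np.ndarray:
    arr = np.zeros(track.trial_duration_ms, dtype=bool)
    for ep in track.episodes:
        arr[ep.begin_ms : ep.end_ms] = True
    return arr


def runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (begin, end, value)."""
    out = []
    n = len(values)
    i = 0
    while i < n:
        j = i
        while j < n and values[j] == values[i]:
            j += 1
        out.append((i, j, int(values[i])))
        i = j
    return out


def color_array(a, b) -> np.ndarray:
    ca, cb = cover_array(a), cover_array(b)
    colors = np.zeros(len(ca), dtype=np.int8)
    colors[ca ^ cb] = GRAY
    colors[ca & cb] = BLACK
    return colors


def oracle_segments(a, b) -> list[dict]:
    """Maximal color segments with per-rater coverage and gray class."""
    ca, cb = cover_array(a), cover_array(b)
    colors = color_array(a, b)
    segs = []
    rr = runs(colors)
    for idx, (begin, end, color) in enumerate(rr):
        gray_class = "not-applicable"
        if color == GRAY:
            before_black = idx > 0 and rr[idx - 1][2] == BLACK
            after_black = idx + 1 < len(rr) and rr[idx + 1][2] == BLACK
            if before_black and after_black:
                gray_class = "enclosed"
            elif after_black:
                gray_class = "preceding"
            elif before_black:
                gray_class = "following"
            else:
                gray_class = "isolated"
        segs.append(
            {
                "begin": begin,
                "end": end,
                "color": {WHITE: "white", GRAY: "gray", BLACK: "black"}[color],
                "gray_class": gray_class,
                "a_cover": int(ca[begin:end].sum()),
                "b_cover": int(cb[begin:end].sum()),
            }
        )
    return segs


def oracle_resolve(a, b, tolerance_ms, correction) -> np.ndarray:
    """Per-millisecond outcome array (0 no_FOG, 1 FOG, 2 discussion)."""
    out = np.zeros(a.trial_duration_ms, dtype=np.int8)
    for seg in oracle_segments(a, b):
        begin, end = seg["begin"], seg["end"]
        if seg["color"] == "black":
            out[begin:end] = OUT_FOG
        elif seg["color"] == "white":
            out[begin:end] = OUT_NO_FOG
        elif seg["gray_class"] == "isolated":
            out[begin:end] = OUT_DISCUSSION
        elif (end - begin) > tolerance_ms:
            out[begin:end] = OUT_DISCUSSION
        elif correction == "include":
            out[begin:end] = OUT_FOG
        else:
            out[begin:end] = OUT_NO_FOG
    return out


def oracle_episodes(outcomes: np.ndarray) -> list[tuple[int, int]]:
    return [(b, e) for b, e, v in runs(outcomes) if v == OUT_FOG]


def oracle_table(a, b) -> tuple[int, int, int, int]:
    """(a, b, c, d) durations from per-ms coverage."""
    ca, cb = cover_array(a), cover_array(b)
    return (
        int((ca & cb).sum()),
        int((ca & ~cb).sum()),
        int((~ca & cb).sum()),
        int((~ca & ~cb).sum()),
    )


def resolved_to_array(resolved, duration) -> np.ndarray:
    """Expand resolved segments from the code under test to a per-ms array."""
    mapping = {"no_FOG": OUT_NO_FOG, "FOG": OUT_FOG, "discussion": OUT_DISCUSSION}
    out = np.full(duration, -1, dtype=np.int8)
    for seg in resolved:
        out[seg.begin_ms : seg.end_ms] = mapping[seg.outcome.value]
    assert (out >= 0).all(), "resolved segments do not cover the trial"
    return out


def random_tracks(rng, trial_id="t", max_duration=4000, max_episodes=4):
    """A random normalized two-rater fixture for oracle comparisons."""
    from fogcombine import AnnotatedEpisode, RaterTrack
    from fogcombine.elan import normalize_track

    duration = int(rng.integers(500, max_duration))

    def one(rater):
        n = int(rng.integers(0, max_episodes + 1))
        eps = []
        for _ in range(n):
            begin = int(rng.integers(0, duration - 1))
            end = int(rng.integers(begin + 1, min(duration, begin + duration // 2) + 1))
            end = min(end, duration)
            if end > begin:
                eps.append(AnnotatedEpisode(begin, end, rater_id=rater))
        return normalize_track(RaterTrack(rater, trial_id, tuple(eps), duration))

    return one("rater1"), one("rater2")
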