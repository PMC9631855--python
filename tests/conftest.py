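from __future__ import annotations

import numpy as np
import pytest

from fogcombine import AnnotatedEpisode, Phenotype, RaterTrack


def make_track(
    intervals,
    rater_id="rater1",
    trial_id="trial",
    trial_duration_ms=None,
    phenotype=Phenotype.UNSPECIFIED,
    trigger=None,
):
    """Build a RaterTrack from (begin, end) pairs or (begin, end, phenotype[, trigger])."""
    episodes = []
    for iv in intervals:
        begin, end = iv[0], iv[1]
        ph = iv[2] if len(iv) > 2 else phenotype
        tr = iv[3] if len(iv) > 3 else trigger
        episodes.append(
            AnnotatedEpisode(begin, end, phenotype=Phenotype(ph), trigger=tr, rater_id=rater_id)
        )
    if trial_duration_ms is None:
        trial_duration_ms = max((e.end_ms for e in episodes), default=0) + 1000
    return RaterTrack(rater_id, trial_id, tuple(episodes), trial_duration_ms)


@pytest.fixture
def mk_track():
    return make_track


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)
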