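"""Synthetic ground-truth episode streams and imperfect simulated raters.

A SimulationSpec describes a ground-truth FOG stream (log-normal episode
durations and inter-episode gaps) and per-rater imperfections: truncated
normal boundary jitter, missed episodes, episodes split in two, and label
confusion. Everything is deterministic under ``rng_seed``.
"""
from __future__ import annotations

from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .elan import normalize_track
from .model import PHENOTYPES, TRIGGERS, AnnotatedEpisode, Phenotype, RaterTrack

PerRater = Union[float, tuple[float, float]]


class SimulationSpec(BaseModel):
    """Parameters of one simulated two-rater trial.

    Per-rater parameters accept a scalar (both raters) or a (rater1, rater2)
    pair.
    """

    trial_id: str = "trial"
    trial_duration_ms: int = Field(default=60_000, gt=0)
    n_episodes: int = Field(default=5, ge=0)
    episode_duration_mean_ms: float = Field(default=3000.0, gt=0)
    episode_duration_sigma: float = Field(default=0.5, ge=0)  # log-space sd
    gap_mean_ms: float = Field(default=5000.0, gt=0)
    gap_sigma: float = Field(default=0.5, ge=0)
    min_episode_ms: int = Field(default=200, gt=0)
    min_gap_ms: int = Field(default=200, gt=0)
    boundary_jitter_sd_ms: PerRater = 0.0
    jitter_truncation_sds: float = Field(default=3.0, gt=0)
    p_miss: PerRater = 0.0
    p_split: PerRater = 0.0
    label_confusion_rate: PerRater = 0.0
    rng_seed: int = 0

    @field_validator("p_miss", "p_split", "label_confusion_rate")
    @classmethod
    def _probability(cls, v: PerRater) -> PerRater:
        for x in v if isinstance(v, tuple) else (v,):
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {x}")
        return v

    @field_validator("boundary_jitter_sd_ms")
    @classmethod
    def _nonnegative(cls, v: PerRater) -> PerRater:
        for x in v if isinstance(v, tuple) else (v,):
            if x < 0:
                raise ValueError(f"jitter sd must be >= 0: {x}")
        return v

    def per_rater(self, name: str, rater_index: int) -> float:
        value = getattr(self, name)
        if isinstance(value, tuple):
            return value[rater_index]
        return value


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    """Log-normal samples with the requested arithmetic mean."""
    if sigma == 0:
        return np.full(size, mean)
    mu = np.log(mean) - sigma * sigma / 2.0
    return rng.lognormal(mu, sigma, size)


def generate_truth(spec: SimulationSpec, max_attempts: int = 200) -> RaterTrack:
    """Generate a disjoint ground-truth episode stream.

    Episodes and the gaps before them are sampled independently and laid out
    left to right; a layout exceeding the trial duration is resampled.
    Raises ValueError when the spec cannot fit after ``max_attempts`` tries.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_episodes
    if n == 0:
        return RaterTrack("truth", spec.trial_id, (), spec.trial_duration_ms)

    for _ in range(max_attempts):
        durations = np.maximum(
            np.rint(_lognormal(rng, spec.episode_duration_mean_ms,
                               spec.episode_duration_sigma, n)).astype(int),
            spec.min_episode_ms,
        )
        gaps = np.maximum(
            np.rint(_lognormal(rng, spec.gap_mean_ms, spec.gap_sigma, n)).astype(int),
            spec.min_gap_ms,
        )
        if int(durations.sum() + gaps.sum()) > spec.trial_duration_ms:
            continue
        episodes = []
        cursor = 0
        for dur, gap in zip(durations, gaps):
            begin = cursor + int(gap)
            end = begin + int(dur)
            episodes.append(
                AnnotatedEpisode(
                    begin_ms=begin,
                    end_ms=end,
                    phenotype=PHENOTYPES[rng.integers(len(PHENOTYPES))],
                    trigger=TRIGGERS[rng.integers(len(TRIGGERS))],
                    rater_id="truth",
                    source_tier="FOG",
                )
            )
            cursor = end
        return RaterTrack("truth", spec.trial_id, tuple(episodes), spec.trial_duration_ms)

    raise ValueError(
        f"could not fit {n} episodes into a {spec.trial_duration_ms} ms trial "
        f"after {max_attempts} attempts"
    )


def _truncated_normal(rng: np.random.Generator, sd: float, trunc_sds: float) -> float:
    """One N(0, sd) draw truncated (by resampling) to +/- trunc_sds * sd."""
    if sd == 0:
        return 0.0
    bound = trunc_sds * sd
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= bound:
            return x


def _confuse(rng: np.random.Generator, value, pool) -> object:
    alternatives = [v for v in pool if v != value]
    return alternatives[rng.integers(len(alternatives))]


def simulate_rater(
    truth: RaterTrack,
    spec: SimulationSpec,
    rater_id: str,
    rater_index: int = 0,
) -> RaterTrack:
    """Derive one imperfect rater annotation track from the ground truth.

    Surviving episode boundaries get truncated-normal jitter (clipped to keep
    end > begin and to trial bounds); episodes are dropped with p_miss, split
    in two with p_split, and labels confused at label_confusion_rate. The
    result is normalized.
    """
    rng = np.random.default_rng([spec.rng_seed, 7919, rater_index])
    jitter_sd = spec.per_rater("boundary_jitter_sd_ms", rater_index)
    p_miss = spec.per_rater("p_miss", rater_index)
    p_split = spec.per_rater("p_split", rater_index)
    confusion = spec.per_rater("label_confusion_rate", rater_index)

    episodes: list[AnnotatedEpisode] = []
    for ep in truth.episodes:
        if rng.random() < p_miss:
            continue
        begin = ep.begin_ms + _truncated_normal(rng, jitter_sd, spec.jitter_truncation_sds)
        end = ep.end_ms + _truncated_normal(rng, jitter_sd, spec.jitter_truncation_sds)
        begin = int(round(max(0.0, begin)))
        end = int(round(min(float(truth.trial_duration_ms), end)))
        if end <= begin:  # keep the episode alive at minimal length
            end = min(begin + 1, truth.trial_duration_ms)
            begin = end - 1

        phenotype = ep.phenotype
        if phenotype is not Phenotype.UNSPECIFIED and rng.random() < confusion:
            phenotype = _confuse(rng, phenotype, PHENOTYPES)
        trigger = ep.trigger
        if trigger is not None and rng.random() < confusion:
            trigger = _confuse(rng, trigger, TRIGGERS)

        spans: list[tuple[int, int]]
        if rng.random() < p_split:
            # carve a central gap of ~20% of the episode duration
            dur = end - begin
            g0 = begin + int(round(0.4 * dur))
            g1 = begin + int(round(0.6 * dur))
            if g0 > begin and end > g1 and g1 > g0:
                spans = [(begin, g0), (g1, end)]
            else:
                spans = [(begin, end)]
        else:
            spans = [(begin, end)]

        for s_begin, s_end in spans:
            episodes.append(
                AnnotatedEpisode(
                    begin_ms=s_begin,
                    end_ms=s_end,
                    phenotype=phenotype,
                    trigger=trigger,
                    rater_id=rater_id,
                    source_tier="FOG",
                )
            )

    track = RaterTrack(rater_id, truth.trial_id, tuple(episodes), truth.trial_duration_ms)
    return normalize_track(track)


def simulate_pair(
    spec: SimulationSpec,
) -> tuple[RaterTrack, RaterTrack, RaterTrack]:
    """Ground truth plus two simulated raters ("rater1", "rater2")."""
    truth = generate_truth(spec)
    r1 = simulate_rater(truth, spec, "rater1", rater_index=0)
    r2 = simulate_rater(truth, spec, "rater2", rater_index=1)
    return truth, r1, r2
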