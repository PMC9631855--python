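"""Core data model: annotated episodes and per-rater annotation tracks.

All times are integer milliseconds from trial start; intervals are half-open
``[begin_ms, end_ms)`` so that abutting episodes do not overlap and durations
are additive.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class Phenotype(str, enum.Enum):
    """FOG episode phenotype label."""

    TREMBLING = "trembling"
    SHUFFLING = "shuffling"
    AKINESIA = "akinesia"
    UNSPECIFIED = "unspecified"

    @classmethod
    def parse(cls, text: Optional[str]) -> "Phenotype":
        """Parse a free-text annotation value into a phenotype.

        Matching is case-insensitive on the known labels; the annotation value
        may carry extra ``;``/``,``-separated tokens (flags, triggers) which
        are ignored. Anything unrecognized maps to UNSPECIFIED.
        """
        if not text:
            return cls.UNSPECIFIED
        import re

        for token in re.split(r"[;,]", text):
            token = token.strip().lower()
            if token in (cls.TREMBLING.value, cls.SHUFFLING.value, cls.AKINESIA.value):
                return cls(token)
        return cls.UNSPECIFIED


#: The concrete (non-UNSPECIFIED) phenotype labels.
PHENOTYPES = (Phenotype.TREMBLING, Phenotype.SHUFFLING, Phenotype.AKINESIA)

#: Conventional trigger labels used by the annotation template.
TRIGGERS = ("FOG_Target", "FOG_180_R", "FOG_Doorway")


@dataclass(frozen=True, order=True)
class AnnotatedEpisode:
    """One rater's FOG interval with phenotype and trigger labels."""

    begin_ms: int
    end_ms: int
    phenotype: Phenotype = Phenotype.UNSPECIFIED
    trigger: Optional[str] = None
    rater_id: str = ""
    source_tier: str = ""

    def __post_init__(self) -> None:
        if self.begin_ms < 0:
            raise ValueError(f"episode begin must be >= 0, got {self.begin_ms}")
        if self.end_ms <= self.begin_ms:
            raise ValueError(
                f"episode must have positive duration: [{self.begin_ms}, {self.end_ms})"
            )

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.begin_ms

    def overlaps(self, begin_ms: int, end_ms: int) -> bool:
        """True if this episode overlaps the half-open interval [begin, end)."""
        return self.begin_ms < end_ms and begin_ms < self.end_ms


@dataclass(frozen=True)
class RaterTrack:
    """One rater's set of episodes for a trial.

    Episodes are stored sorted by begin time. A freshly parsed track may
    contain overlapping or abutting episodes; :func:`fogcombine.elan.normalize_track`
    merges those. Comparison operations require normalized tracks.
    """

    rater_id: str
    trial_id: str
    episodes: tuple[AnnotatedEpisode, ...]
    trial_duration_ms: int

    def __post_init__(self) -> None:
        eps = tuple(sorted(self.episodes, key=lambda e: (e.begin_ms, e.end_ms)))
        object.__setattr__(self, "episodes", eps)
        if self.trial_duration_ms < 0:
            raise ValueError("trial_duration_ms must be >= 0")
        for ep in eps:
            if ep.end_ms > self.trial_duration_ms:
                raise ValueError(
                    f"episode [{ep.begin_ms}, {ep.end_ms}) exceeds trial duration "
                    f"{self.trial_duration_ms}"
                )

    @property
    def is_normalized(self) -> bool:
        """True when no two episodes overlap or abut."""
        return all(
            nxt.begin_ms > cur.end_ms
            for cur, nxt in zip(self.episodes, self.episodes[1:])
        )

    @property
    def total_fog_ms(self) -> int:
        return sum(e.duration_ms for e in self.episodes)

    def percent_time_frozen(self) -> float:
        """Fraction of observed time annotated as FOG, as a percentage."""
        if self.trial_duration_ms == 0:
            raise ValueError("trial duration is zero")
        return 100.0 * self.total_fog_ms / self.trial_duration_ms

    def with_duration(self, trial_duration_ms: int) -> "RaterTrack":
        return replace(self, trial_duration_ms=trial_duration_ms)
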