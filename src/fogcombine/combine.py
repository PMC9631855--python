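"""Timeline partition and gray-area resolution.

The trial timeline is partitioned into maximal *black* (both raters annotate
FOG), *white* (neither does) and *gray* (exactly one does) segments. Gray
segments are classified by their adjacency to black segments and then
resolved into agreed-FOG, agreed-no-FOG, or to-be-discussed segments using
two parameters:

* ``tolerance_ms`` — a non-isolated gray segment no longer than the tolerance
  is treated as annotation imprecision and resolved automatically; a longer
  one goes to discussion. The tie (duration == tolerance) resolves
  automatically.
* ``correction`` — whether a resolvable gray segment is counted as FOG
  (``include``) or not (``exclude``).

Isolated gray segments (no adjacent black segment) always go to discussion,
regardless of length or correction.
"""
from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .model import AnnotatedEpisode, Phenotype, RaterTrack

logger = logging.getLogger(__name__)


class Color(str, enum.Enum):
    BLACK = "black"
    WHITE = "white"
    GRAY = "gray"


class GrayClass(str, enum.Enum):
    ISOLATED = "isolated"
    PRECEDING = "preceding"
    FOLLOWING = "following"
    ENCLOSED = "enclosed"
    NOT_APPLICABLE = "not-applicable"


class Correction(str, enum.Enum):
    INCLUDE = "include"
    EXCLUDE = "exclude"


class Outcome(str, enum.Enum):
    FOG = "FOG"
    NO_FOG = "no_FOG"
    DISCUSSION = "discussion"


class Provenance(str, enum.Enum):
    BLACK = "black"
    WHITE = "white"
    GRAY_INCLUDED = "gray-included"
    GRAY_EXCLUDED = "gray-excluded->no_FOG"
    GRAY_ISOLATED = "gray-isolated->discussion"
    GRAY_LONG = "gray-long->discussion"


DISCUSSION_PROVENANCES = frozenset({Provenance.GRAY_ISOLATED, Provenance.GRAY_LONG})

CHECK_TYPE = "check_type"
CHECK_TRIGGER = "check_trigger"


@dataclass(frozen=True)
class CombineConfig:
    """Tolerance and correction parameters.

    ``tolerance_ms`` may be ``math.inf`` (every non-isolated gray resolves).
    """

    tolerance_ms: float = 2000
    correction: Correction = Correction.EXCLUDE

    def __post_init__(self) -> None:
        if self.tolerance_ms < 0:
            raise ValueError("tolerance_ms must be >= 0")
        object.__setattr__(self, "correction", Correction(self.correction))


@dataclass(frozen=True)
class Segment:
    """A maximal constant-color stretch of the timeline.

    ``a_cover_ms``/``b_cover_ms`` record how much of the segment each rater
    annotated (a gray segment may mix single-rater coverage when one rater's
    episode abuts the other's).
    """

    begin_ms: int
    end_ms: int
    color: Color
    gray_class: GrayClass = GrayClass.NOT_APPLICABLE
    a_cover_ms: int = 0
    b_cover_ms: int = 0

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.begin_ms


@dataclass(frozen=True)
class TimelinePartition:
    """Ordered, gap-free black/white/gray classification of a trial."""

    trial_id: str
    trial_duration_ms: int
    segments: tuple[Segment, ...]
    rater_a: RaterTrack
    rater_b: RaterTrack


@dataclass(frozen=True)
class ResolvedSegment:
    """A post-resolution segment with provenance and disagreement flags."""

    begin_ms: int
    end_ms: int
    outcome: Outcome
    provenance: Provenance
    flags: frozenset[str] = frozenset()
    phenotype: Phenotype = Phenotype.UNSPECIFIED
    trigger: Optional[str] = None

    def __post_init__(self) -> None:
        is_discussion = self.outcome is Outcome.DISCUSSION
        if is_discussion != (self.provenance in DISCUSSION_PROVENANCES):
            raise ValueError(
                f"outcome {self.outcome} inconsistent with provenance {self.provenance}"
            )

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.begin_ms


@dataclass(frozen=True)
class CombinedEpisode:
    """A maximal run of resolved FOG segments."""

    begin_ms: int
    end_ms: int
    phenotype: Phenotype = Phenotype.UNSPECIFIED
    trigger: Optional[str] = None
    flags: frozenset[str] = frozenset()

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.begin_ms


def partition_timeline(a: RaterTrack, b: RaterTrack) -> TimelinePartition:
    """Partition the trial into maximal black/white/gray segments.

    Both tracks must be normalized and share trial_id and duration. Gray
    classes are assigned (see :func:`classify_gray`).
    """
    if a.trial_id != b.trial_id:
        raise ValueError(f"trial_id mismatch: {a.trial_id!r} vs {b.trial_id!r}")
    if a.trial_duration_ms != b.trial_duration_ms:
        raise ValueError(
            f"trial_duration_ms mismatch: {a.trial_duration_ms} vs {b.trial_duration_ms}"
        )
    for track in (a, b):
        if not track.is_normalized:
            raise ValueError(
                f"track {track.rater_id!r} has overlapping/abutting episodes; "
                "apply normalize_track first"
            )
    duration = a.trial_duration_ms

    cuts = {0, duration}
    for track in (a, b):
        for ep in track.episodes:
            cuts.add(ep.begin_ms)
            cuts.add(ep.end_ms)
    points = sorted(p for p in cuts if 0 <= p <= duration)

    def covered(track: RaterTrack, t: int) -> bool:
        # episodes are disjoint and cut points align with boundaries, so
        # membership at the left edge decides the whole elementary interval
        return any(ep.begin_ms <= t < ep.end_ms for ep in track.episodes)

    raw: list[Segment] = []
    for p, q in zip(points, points[1:]):
        in_a = covered(a, p)
        in_b = covered(b, p)
        if in_a and in_b:
            color = Color.BLACK
        elif in_a or in_b:
            color = Color.GRAY
        else:
            color = Color.WHITE
        raw.append(
            Segment(
                p,
                q,
                color,
                a_cover_ms=(q - p) if in_a else 0,
                b_cover_ms=(q - p) if in_b else 0,
            )
        )

    # merge adjacent equal-color elementary segments into maximal ones
    merged: list[Segment] = []
    for seg in raw:
        if merged and merged[-1].color is seg.color:
            prev = merged[-1]
            merged[-1] = replace(
                prev,
                end_ms=seg.end_ms,
                a_cover_ms=prev.a_cover_ms + seg.a_cover_ms,
                b_cover_ms=prev.b_cover_ms + seg.b_cover_ms,
            )
        else:
            merged.append(seg)

    partition = TimelinePartition(
        trial_id=a.trial_id,
        trial_duration_ms=duration,
        segments=tuple(merged),
        rater_a=a,
        rater_b=b,
    )
    return classify_gray(partition)


def classify_gray(partition: TimelinePartition) -> TimelinePartition:
    """Label each gray segment isolated / preceding / following / enclosed.

    Adjacency means zero-gap abutment with a *black* segment (to-be-discussed
    gray neighbors do not count as definite FOG).
    """
    segs = list(partition.segments)
    out: list[Segment] = []
    for i, seg in enumerate(segs):
        if seg.color is not Color.GRAY:
            out.append(replace(seg, gray_class=GrayClass.NOT_APPLICABLE))
            continue
        black_before = i > 0 and segs[i - 1].color is Color.BLACK
        black_after = i + 1 < len(segs) and segs[i + 1].color is Color.BLACK
        if black_before and black_after:
            cls = GrayClass.ENCLOSED
        elif black_after:
            cls = GrayClass.PRECEDING  # gray precedes a definite episode
        elif black_before:
            cls = GrayClass.FOLLOWING
        else:
            cls = GrayClass.ISOLATED
        out.append(replace(seg, gray_class=cls))
    return replace(partition, segments=tuple(out))


def _covering_episodes(track: RaterTrack, seg: Segment) -> list[AnnotatedEpisode]:
    return [ep for ep in track.episodes if ep.overlaps(seg.begin_ms, seg.end_ms)]


def _segment_labels(
    partition: TimelinePartition, seg: Segment
) -> tuple[Phenotype, Optional[str]]:
    """Phenotype/trigger of a segment from the raters' covering episodes.

    Black: the label both raters agree on, else unspecified. Gray: the
    covering rater's label(s); conflicting labels collapse to unspecified.
    """
    eps = _covering_episodes(partition.rater_a, seg) + _covering_episodes(
        partition.rater_b, seg
    )
    phenos = {e.phenotype for e in eps}
    trigs = {e.trigger for e in eps}
    pheno = phenos.pop() if len(phenos) == 1 else Phenotype.UNSPECIFIED
    trig = trigs.pop() if len(trigs) == 1 else None
    return pheno, trig


def resolve(partition: TimelinePartition, cfg: CombineConfig) -> list[ResolvedSegment]:
    """Resolve every segment of a classified partition.

    Returns one ResolvedSegment per partition segment, in timeline order:
    black -> FOG, white -> no_FOG, gray isolated -> discussion (always),
    gray non-isolated longer than the tolerance -> discussion, otherwise
    FOG/no_FOG per the correction. Gray segments resolved to FOG inherit
    phenotype/trigger from the bordering black segment (enclosed: from the
    earlier one).
    """
    segs = partition.segments
    labels = [_segment_labels(partition, s) for s in segs]
    resolved: list[ResolvedSegment] = []
    for i, seg in enumerate(segs):
        pheno, trig = labels[i]
        if seg.color is Color.BLACK:
            resolved.append(
                ResolvedSegment(
                    seg.begin_ms, seg.end_ms, Outcome.FOG, Provenance.BLACK,
                    phenotype=pheno, trigger=trig,
                )
            )
        elif seg.color is Color.WHITE:
            resolved.append(
                ResolvedSegment(seg.begin_ms, seg.end_ms, Outcome.NO_FOG, Provenance.WHITE)
            )
        elif seg.gray_class is GrayClass.ISOLATED:
            resolved.append(
                ResolvedSegment(
                    seg.begin_ms, seg.end_ms, Outcome.DISCUSSION,
                    Provenance.GRAY_ISOLATED, phenotype=pheno, trigger=trig,
                )
            )
        elif seg.duration_ms > cfg.tolerance_ms:
            resolved.append(
                ResolvedSegment(
                    seg.begin_ms, seg.end_ms, Outcome.DISCUSSION,
                    Provenance.GRAY_LONG, phenotype=pheno, trigger=trig,
                )
            )
        elif cfg.correction is Correction.INCLUDE:
            # inherit labels from the bordering black segment; an enclosed
            # gray inherits from the earlier (preceding) black neighbor
            if seg.gray_class is GrayClass.PRECEDING:
                pheno, trig = labels[i + 1]
            else:  # FOLLOWING or ENCLOSED: earlier black
                pheno, trig = labels[i - 1]
            resolved.append(
                ResolvedSegment(
                    seg.begin_ms, seg.end_ms, Outcome.FOG,
                    Provenance.GRAY_INCLUDED, phenotype=pheno, trigger=trig,
                )
            )
        else:
            resolved.append(
                ResolvedSegment(
                    seg.begin_ms, seg.end_ms, Outcome.NO_FOG,
                    Provenance.GRAY_EXCLUDED, phenotype=pheno, trigger=trig,
                )
            )
        logger.debug(
            "resolved [%d, %d) %s/%s -> %s (%s)",
            seg.begin_ms, seg.end_ms, seg.color.value, seg.gray_class.value,
            resolved[-1].outcome.value, resolved[-1].provenance.value,
        )
    return resolved


def merge_episodes(segments: Sequence[ResolvedSegment]) -> list[CombinedEpisode]:
    """Merge maximal runs of FOG segments into combined episodes.

    Conflicting phenotype/trigger labels inside one run collapse to
    unspecified and raise the corresponding check flag; flags propagate by
    union.
    """
    episodes: list[CombinedEpisode] = []
    run: list[ResolvedSegment] = []

    def flush() -> None:
        if not run:
            return
        phenos = {s.phenotype for s in run if s.phenotype is not Phenotype.UNSPECIFIED}
        trigs = {s.trigger for s in run if s.trigger is not None}
        flags: set[str] = set().union(*(s.flags for s in run))
        if len(phenos) > 1:
            flags.add(CHECK_TYPE)
        if len(trigs) > 1:
            flags.add(CHECK_TRIGGER)
        episodes.append(
            CombinedEpisode(
                begin_ms=run[0].begin_ms,
                end_ms=run[-1].end_ms,
                phenotype=phenos.pop() if len(phenos) == 1 else Phenotype.UNSPECIFIED,
                trigger=trigs.pop() if len(trigs) == 1 else None,
                flags=frozenset(flags),
            )
        )
        run.clear()

    for seg in segments:
        if seg.outcome is Outcome.FOG:
            if run and run[-1].end_ms != seg.begin_ms:
                flush()
            run.append(seg)
        else:
            flush()
    flush()
    return episodes


def flag_label_disagreements(
    a: RaterTrack, b: RaterTrack, episodes: Iterable[CombinedEpisode]
) -> list[CombinedEpisode]:
    """Flag combined episodes whose raters disagree on phenotype or trigger.

    For each combined episode the phenotype (trigger) label sets of the two
    raters' overlapping episodes are compared; differing sets raise
    ``check_type`` (``check_trigger``). When both raters agree on a single
    label the episode carries it.
    """
    out: list[CombinedEpisode] = []
    for ep in episodes:
        a_eps = [e for e in a.episodes if e.overlaps(ep.begin_ms, ep.end_ms)]
        b_eps = [e for e in b.episodes if e.overlaps(ep.begin_ms, ep.end_ms)]
        if not a_eps and not b_eps:
            out.append(ep)
            continue
        flags = set(ep.flags)
        pheno, trig = ep.phenotype, ep.trigger

        pa = {e.phenotype for e in a_eps}
        pb = {e.phenotype for e in b_eps}
        if pa != pb:
            flags.add(CHECK_TYPE)
        elif len(pa) == 1:
            pheno = next(iter(pa))

        ta = {e.trigger for e in a_eps}
        tb = {e.trigger for e in b_eps}
        if ta != tb:
            flags.add(CHECK_TRIGGER)
        elif len(ta) == 1:
            trig = next(iter(ta))

        out.append(replace(ep, phenotype=pheno, trigger=trig, flags=frozenset(flags)))
    return out


def discussion_items(
    resolved: Sequence[ResolvedSegment], trial_id: str
) -> list[dict]:
    """The to-be-discussed list for the third-rater session."""
    return [
        {
            "trial": trial_id,
            "begin_ms": s.begin_ms,
            "end_ms": s.end_ms,
            "reason": s.provenance.value,
        }
        for s in resolved
        if s.outcome is Outcome.DISCUSSION
    ]
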