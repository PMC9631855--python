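"""Reading and writing ELAN tab-delimited annotation exports.

Supported column layout (header row optional):

    Tier <TAB> Begin Time <TAB> End Time [<TAB> Duration] <TAB> Annotation

Three time dialects are handled: ``ms`` (integer milliseconds), ``s.ms``
(seconds with decimal fraction) and ``hh:mm:ss.ms``. ``auto`` sniffs per
field: a value containing ":" is hh:mm:ss.ms, else containing "." is s.ms,
else ms.
"""
from __future__ import annotations

import logging
import re
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .combine import CombinedEpisode, Outcome, ResolvedSegment
from .model import AnnotatedEpisode, Phenotype, RaterTrack

logger = logging.getLogger(__name__)

DIALECTS = ("ms", "s.ms", "hh:mm:ss.ms", "auto")

#: tier_map roles
ROLE_FOG = "fog"
ROLE_TRIGGER = "trigger"
ROLE_IGNORE = "ignore"


class ElanFormatError(ValueError):
    """Raised for unparseable rows/fields, naming the offending row."""


class TierError(ValueError):
    """Raised in strict mode for tiers absent from the tier map."""


_HMS_RE = re.compile(r"^(\d+):([0-5]?\d):([0-5]?\d)(?:\.(\d{1,3}))?$")


def sniff_dialect(text: str) -> str:
    """Guess the time dialect of one field (":" > "." > plain ms)."""
    if ":" in text:
        return "hh:mm:ss.ms"
    if "." in text:
        return "s.ms"
    return "ms"


def parse_time(text: str, dialect: str = "auto") -> int:
    """Parse a time field to integer milliseconds."""
    text = text.strip()
    if dialect == "auto":
        dialect = sniff_dialect(text)
    if dialect == "ms":
        if not re.fullmatch(r"\d+", text):
            raise ElanFormatError(f"not an integer millisecond value: {text!r}")
        return int(text)
    if dialect == "s.ms":
        m = re.fullmatch(r"(\d+)(?:\.(\d+))?", text)
        if not m:
            raise ElanFormatError(f"not a seconds value: {text!r}")
        sec = int(m.group(1))
        frac = (m.group(2) or "")[:3].ljust(3, "0")
        return sec * 1000 + int(frac)
    if dialect == "hh:mm:ss.ms":
        m = _HMS_RE.fullmatch(text)
        if not m:
            raise ElanFormatError(f"not an hh:mm:ss.ms value: {text!r}")
        h, mnt, s = int(m.group(1)), int(m.group(2)), int(m.group(3))
        frac = (m.group(4) or "").ljust(3, "0")
        return ((h * 60 + mnt) * 60 + s) * 1000 + int(frac)
    raise ValueError(f"unknown dialect {dialect!r}")


def format_time(ms: int, dialect: str) -> str:
    """Format integer milliseconds in the given dialect (exactly invertible)."""
    if ms < 0:
        raise ValueError("negative time")
    if dialect == "ms":
        return str(ms)
    if dialect == "s.ms":
        return f"{ms // 1000}.{ms % 1000:03d}"
    if dialect == "hh:mm:ss.ms":
        s, frac = divmod(ms, 1000)
        m, s = divmod(s, 60)
        h, m = divmod(m, 60)
        return f"{h:02d}:{m:02d}:{s:02d}.{frac:03d}"
    raise ValueError(f"unknown dialect {dialect!r}")


def _split_rows(path: Union[str, Path]) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def _looks_like_header(fields: list[str]) -> bool:
    if len(fields) < 4:
        return True
    try:
        parse_time(fields[1], "auto")
        parse_time(fields[2], "auto")
        return False
    except ElanFormatError:
        return True


def _tier_role(tier: str, tier_map: Optional[Mapping[str, str]], strict: bool) -> str:
    if tier_map is None:
        # heuristic default: tiers mentioning "trigger" carry triggers,
        # everything else carries FOG episodes
        return ROLE_TRIGGER if "trigger" in tier.lower() else ROLE_FOG
    if tier in tier_map:
        return tier_map[tier]
    if strict:
        raise TierError(f"tier {tier!r} not present in tier map")
    logger.warning("ignoring annotations on unmapped tier %r", tier)
    return ROLE_IGNORE


def read_elan_export(
    path: Union[str, Path],
    dialect: str = "auto",
    tier_map: Optional[Mapping[str, str]] = None,
    rater_id: str = "",
    trial_id: str = "",
    trial_duration_ms: Optional[int] = None,
    strict: bool = False,
) -> RaterTrack:
    """Read one rater's ELAN tab-delimited export into a RaterTrack.

    ``tier_map`` maps tier names to roles ("fog", "trigger", "ignore"); when
    omitted, tier names containing "trigger" feed triggers and all other
    tiers feed FOG episodes. A trigger annotation is attached to the FOG
    episode it overlaps by more than half of the episode's duration.

    The trial duration defaults to the maximum end time seen in the file.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = _split_rows(path)
    if rows and _looks_like_header(rows[0][1]):
        rows = rows[1:]

    fog_rows: list[tuple[int, str, int, int, str]] = []
    trigger_rows: list[tuple[int, int, str]] = []
    for lineno, fields in rows:
        if len(fields) < 4:
            raise ElanFormatError(f"{path}:{lineno}: expected >= 4 tab-separated columns")
        tier = fields[0].strip()
        role = _tier_role(tier, tier_map, strict)
        if role == ROLE_IGNORE:
            continue
        try:
            begin = parse_time(fields[1], dialect)
            end = parse_time(fields[2], dialect)
        except ElanFormatError as exc:
            raise ElanFormatError(f"{path}:{lineno}: {exc}") from exc
        # column 4 is Duration when 5+ columns are present
        value = (fields[4] if len(fields) >= 5 else fields[3]).strip()
        if begin >= end:
            raise ElanFormatError(
                f"{path}:{lineno}: begin time {begin} ms >= end time {end} ms"
            )
        if role == ROLE_FOG:
            fog_rows.append((lineno, tier, begin, end, value))
        elif role == ROLE_TRIGGER:
            trigger_rows.append((begin, end, value))
        else:
            raise ValueError(f"unknown tier role {role!r} for tier {tier!r}")

    episodes = []
    for lineno, tier, begin, end, value in fog_rows:
        trigger = _attach_trigger(begin, end, trigger_rows)
        episodes.append(
            AnnotatedEpisode(
                begin_ms=begin,
                end_ms=end,
                phenotype=Phenotype.parse(value),
                trigger=trigger,
                rater_id=rater_id,
                source_tier=tier,
            )
        )

    if trial_duration_ms is None:
        trial_duration_ms = max((e.end_ms for e in episodes), default=0)
    return RaterTrack(
        rater_id=rater_id,
        trial_id=trial_id,
        episodes=tuple(episodes),
        trial_duration_ms=trial_duration_ms,
    )


def _attach_trigger(
    begin: int, end: int, trigger_rows: Sequence[tuple[int, int, str]]
) -> Optional[str]:
    """Best trigger overlapping (begin, end) by more than half its duration."""
    duration = end - begin
    best: Optional[str] = None
    best_overlap = 0
    for t_begin, t_end, value in trigger_rows:
        overlap = min(end, t_end) - max(begin, t_begin)
        if overlap * 2 > duration and overlap > best_overlap:
            best, best_overlap = value, overlap
    return best


def normalize_track(track: RaterTrack) -> RaterTrack:
    """Merge same-rater episodes that overlap or abut.

    Merged phenotype/trigger keep the common value when identical, otherwise
    collapse to unspecified with a logged warning.
    """
    merged: list[AnnotatedEpisode] = []
    for ep in track.episodes:  # already sorted by RaterTrack
        if merged and ep.begin_ms <= merged[-1].end_ms:
            prev = merged[-1]
            pheno = prev.phenotype
            trig = prev.trigger
            if ep.phenotype != prev.phenotype:
                logger.warning(
                    "rater %r: merging episodes with conflicting phenotypes "
                    "%s vs %s at [%d, %d); label set to unspecified",
                    track.rater_id, prev.phenotype.value, ep.phenotype.value,
                    prev.begin_ms, ep.end_ms,
                )
                pheno = Phenotype.UNSPECIFIED
            if ep.trigger != prev.trigger:
                logger.warning(
                    "rater %r: merging episodes with conflicting triggers "
                    "%r vs %r at [%d, %d); trigger cleared",
                    track.rater_id, prev.trigger, ep.trigger,
                    prev.begin_ms, ep.end_ms,
                )
                trig = None
            merged[-1] = replace(
                prev, end_ms=max(prev.end_ms, ep.end_ms), phenotype=pheno, trigger=trig
            )
        else:
            merged.append(ep)
    return replace(track, episodes=tuple(merged))


_HEADER = ("Tier", "Begin Time", "End Time", "Duration", "Annotation")

#: tier names used in resolved-output tables
TIER_FOG_AGREED = "FOG_agreed"
TIER_DISCUSSION = "FOG_discussion"
TIER_COMBINED = "FOG_combined"


def _annotation_value(
    phenotype: Phenotype, trigger: Optional[str], flags: Sequence[str], extra: str = ""
) -> str:
    parts = []
    if phenotype is not Phenotype.UNSPECIFIED:
        parts.append(phenotype.value)
    if trigger:
        parts.append(trigger)
    parts.extend(sorted(flags))
    if extra:
        parts.append(extra)
    return "; ".join(parts) if parts else "FOG"


def _write_rows(path: Union[str, Path], rows: list[tuple[str, int, int, str]], dialect: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for tier, begin, end, value in rows:
            fh.write(
                "\t".join(
                    (
                        tier,
                        format_time(begin, dialect),
                        format_time(end, dialect),
                        format_time(end - begin, dialect),
                        value,
                    )
                )
                + "\n"
            )


def write_resolved_table(
    segments: Sequence[ResolvedSegment],
    path: Union[str, Path],
    dialect: str = "hh:mm:ss.ms",
) -> None:
    """Write resolved segments as an ELAN-reimportable tab-delimited table.

    Agreed-FOG segments go on the ``FOG_agreed`` tier and to-be-discussed
    segments on ``FOG_discussion`` (annotation value names the reason);
    agreed no-FOG segments are not exported. Reading the file back with
    :func:`read_elan_export` reproduces segment boundaries exactly.
    """
    if dialect == "auto":
        dialect = "hh:mm:ss.ms"
    rows = []
    for seg in segments:
        if seg.outcome is Outcome.FOG:
            rows.append(
                (
                    TIER_FOG_AGREED,
                    seg.begin_ms,
                    seg.end_ms,
                    _annotation_value(seg.phenotype, seg.trigger, sorted(seg.flags)),
                )
            )
        elif seg.outcome is Outcome.DISCUSSION:
            rows.append(
                (
                    TIER_DISCUSSION,
                    seg.begin_ms,
                    seg.end_ms,
                    _annotation_value(
                        seg.phenotype, seg.trigger, sorted(seg.flags),
                        extra=seg.provenance.value,
                    ),
                )
            )
    _write_rows(path, rows, dialect)


def write_combined_table(
    episodes: Sequence[CombinedEpisode],
    path: Union[str, Path],
    dialect: str = "hh:mm:ss.ms",
) -> None:
    """Write combined FOG episodes on a single ``FOG_combined`` tier."""
    if dialect == "auto":
        dialect = "hh:mm:ss.ms"
    rows = [
        (
            TIER_COMBINED,
            ep.begin_ms,
            ep.end_ms,
            _annotation_value(ep.phenotype, ep.trigger, sorted(ep.flags)),
        )
        for ep in episodes
    ]
    _write_rows(path, rows, dialect)


def write_rater_track(
    track: RaterTrack,
    path: Union[str, Path],
    dialect: str = "hh:mm:ss.ms",
    fog_tier: str = "FOG",
    trigger_tier: str = "FOG_triggers",
) -> None:
    """Write a RaterTrack as an ELAN tab-delimited export.

    Episodes go on ``fog_tier`` with the phenotype as annotation value;
    triggers, when present, are mirrored on ``trigger_tier`` over the same
    span so the file round-trips through :func:`read_elan_export`.
    """
    if dialect == "auto":
        dialect = "hh:mm:ss.ms"
    rows: list[tuple[str, int, int, str]] = []
    for ep in track.episodes:
        rows.append((fog_tier, ep.begin_ms, ep.end_ms, ep.phenotype.value))
        if ep.trigger:
            rows.append((trigger_tier, ep.begin_ms, ep.end_ms, ep.trigger))
    rows.sort(key=lambda r: (r[1], r[2], r[0]))
    _write_rows(path, rows, dialect)


def write_discussion_list(
    items: Sequence[dict], path: Union[str, Path], dialect: str = "hh:mm:ss.ms"
) -> None:
    """Write the to-be-discussed list as a TSV (trial, begin, end, reason)."""
    if dialect == "auto":
        dialect = "hh:mm:ss.ms"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Trial\tBegin Time\tEnd Time\tReason\n")
        for item in items:
            fh.write(
                "\t".join(
                    (
                        str(item["trial"]),
                        format_time(item["begin_ms"], dialect),
                        format_time(item["end_ms"], dialect),
                        str(item["reason"]),
                    )
                )
                + "\n"
            )
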