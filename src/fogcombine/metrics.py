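"""Duration-weighted interrater agreement statistics.

All metrics are computed from a 2x2 contingency table whose cells are
durations (milliseconds) rather than counts of sampled epochs:

    a = both raters annotate FOG        b = rater 1 only
    c = rater 2 only                    d = neither

The recommended trio is positive agreement, negative agreement and the
prevalence index; Cohen's kappa and ICC(2,1) are provided for comparison.
Undefined values are explicit ``None``, never silent zeros.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .combine import (
    Color,
    Outcome,
    ResolvedSegment,
    TimelinePartition,
)
from .model import RaterTrack

#: The single ICC variant this package computes; always reported by name.
ICC_VARIANT = "ICC(2,1): two-way random effects, absolute agreement, single rater"


@dataclass(frozen=True)
class AgreementTable:
    """Duration-weighted 2x2 contingency table."""

    a_ms: int
    b_ms: int
    c_ms: int
    d_ms: int

    def __post_init__(self) -> None:
        for name in ("a_ms", "b_ms", "c_ms", "d_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_ms(self) -> int:
        return self.a_ms + self.b_ms + self.c_ms + self.d_ms

    def swapped(self) -> "AgreementTable":
        """The table with raters exchanged (b and c swapped)."""
        return AgreementTable(self.a_ms, self.c_ms, self.b_ms, self.d_ms)


@dataclass(frozen=True)
class AgreementReport:
    """Per-trial or pooled metric values with explicit defined/undefined state."""

    positive_agreement: Optional[float]
    negative_agreement: Optional[float]
    prevalence_index: Optional[float]
    cohens_kappa: Optional[float]
    icc: Optional[float] = None
    icc_variant: Optional[str] = None
    scope: str = "per-trial"

    def as_dict(self) -> dict:
        return {
            "scope": self.scope,
            "positive_agreement": self.positive_agreement,
            "negative_agreement": self.negative_agreement,
            "prevalence_index": self.prevalence_index,
            "cohens_kappa": self.cohens_kappa,
            "icc": self.icc,
            "icc_variant": self.icc_variant,
        }


def tabulate(partition: TimelinePartition) -> AgreementTable:
    """Contingency table from a pre-resolution partition.

    a = total black, d = total white, b/c = gray durations covered by
    rater 1 / rater 2 respectively.
    """
    a = b = c = d = 0
    for seg in partition.segments:
        if seg.color is Color.BLACK:
            a += seg.duration_ms
        elif seg.color is Color.WHITE:
            d += seg.duration_ms
        else:
            b += seg.a_cover_ms
            c += seg.b_cover_ms
    return AgreementTable(a, b, c, d)


def tabulate_post(
    partition: TimelinePartition, resolved: Sequence[ResolvedSegment]
) -> AgreementTable:
    """Contingency table after tolerance/correction resolution.

    Gray segments resolved to FOG count toward a, those resolved to no-FOG
    toward d; only the remaining discussion segments stay as single-rater
    disagreement (split into b/c by covering rater). Intended for sensitivity
    reporting next to the pre-resolution table.
    """
    if len(partition.segments) != len(resolved):
        raise ValueError("partition and resolved segments do not align")
    a = b = c = d = 0
    for seg, res in zip(partition.segments, resolved):
        if res.outcome is Outcome.FOG:
            a += seg.duration_ms
        elif res.outcome is Outcome.NO_FOG:
            d += seg.duration_ms
        else:
            b += seg.a_cover_ms
            c += seg.b_cover_ms
    return AgreementTable(a, b, c, d)


def tabulate_epochs(a: RaterTrack, b: RaterTrack, epoch_ms: int) -> AgreementTable:
    """Fixed-epoch sampled table for comparability with epoch-based studies.

    The trial is cut into consecutive epochs of ``epoch_ms``; a rater marks
    an epoch positive when FOG covers at least half of it (majority rule; the
    trailing partial epoch uses half of its actual length). Cell values are
    epoch counts scaled by ``epoch_ms`` so units stay milliseconds.
    """
    if epoch_ms <= 0:
        raise ValueError("epoch_ms must be > 0")
    if a.trial_duration_ms != b.trial_duration_ms:
        raise ValueError("trial durations differ")
    duration = a.trial_duration_ms

    def positive(track: RaterTrack, lo: int, hi: int) -> bool:
        covered = sum(
            max(0, min(hi, ep.end_ms) - max(lo, ep.begin_ms)) for ep in track.episodes
        )
        return 2 * covered >= (hi - lo)

    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    for lo in range(0, duration, epoch_ms):
        hi = min(lo + epoch_ms, duration)
        pa, pb = positive(a, lo, hi), positive(b, lo, hi)
        key = "a" if pa and pb else "b" if pa else "c" if pb else "d"
        cells[key] += 1
    return AgreementTable(
        cells["a"] * epoch_ms, cells["b"] * epoch_ms,
        cells["c"] * epoch_ms, cells["d"] * epoch_ms,
    )


def positive_agreement(t: AgreementTable) -> Optional[float]:
    """Specific agreement for the FOG category: 2a / (2a + b + c).

    Undefined (None) when neither rater annotates any FOG.
    """
    denom = 2 * t.a_ms + t.b_ms + t.c_ms
    if denom == 0:
        return None
    return 2 * t.a_ms / denom


def negative_agreement(t: AgreementTable) -> Optional[float]:
    """Specific agreement for the no-FOG category: 2d / (2d + b + c).

    Undefined (None) when both raters annotate FOG continuously.
    """
    denom = 2 * t.d_ms + t.b_ms + t.c_ms
    if denom == 0:
        return None
    return 2 * t.d_ms / denom


def prevalence_index(t: AgreementTable) -> Optional[float]:
    """(a - d) / N in [-1, 1]: -1 = no FOG at all, +1 = continuously FOG."""
    n = t.total_ms
    if n == 0:
        return None
    return (t.a_ms - t.d_ms) / n


def cohens_kappa(t: AgreementTable) -> Optional[float]:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    Undefined (None) when the expected agreement p_e equals 1, e.g. when both
    raters annotate no FOG for the whole trial.
    """
    n = t.total_ms
    if n == 0:
        return None
    # integer arithmetic keeps the p_e == 1 test exact
    pe_num = (t.a_ms + t.b_ms) * (t.a_ms + t.c_ms) + (t.c_ms + t.d_ms) * (t.b_ms + t.d_ms)
    if pe_num == n * n:
        return None
    p_o = (t.a_ms + t.d_ms) / n
    p_e = pe_num / (n * n)
    return (p_o - p_e) / (1 - p_e)


def icc_2_1(
    scores_rater1: Sequence[float], scores_rater2: Sequence[float]
) -> Optional[float]:
    """ICC(2,1) between two raters' per-trial summary scores.

    Two-way random effects, absolute agreement, single rater, via the
    standard mean-squares decomposition. Requires >= 2 trials. Returns None
    when the denominator is zero (all scores identical and constant).
    """
    x = np.column_stack([
        np.asarray(scores_rater1, dtype=float),
        np.asarray(scores_rater2, dtype=float),
    ])
    n, k = x.shape
    if n < 2:
        raise ValueError("ICC requires at least 2 trials")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return None
    return float((msr - mse) / denom)


def pool_tables(tables: Iterable[AgreementTable]) -> AgreementTable:
    """Cellwise sum of per-trial tables (duration-weighted pooling)."""
    tables = list(tables)
    if not tables:
        raise ValueError("cannot pool an empty list of tables")
    return AgreementTable(
        sum(t.a_ms for t in tables),
        sum(t.b_ms for t in tables),
        sum(t.c_ms for t in tables),
        sum(t.d_ms for t in tables),
    )


def compute_report(
    table: AgreementTable,
    scope: str = "per-trial",
    icc: Optional[float] = None,
) -> AgreementReport:
    """All table-based metrics for one table, plus an optional ICC value."""
    return AgreementReport(
        positive_agreement=positive_agreement(table),
        negative_agreement=negative_agreement(table),
        prevalence_index=prevalence_index(table),
        cohens_kappa=cohens_kappa(table),
        icc=icc,
        icc_variant=ICC_VARIANT if icc is not None else None,
        scope=scope,
    )
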