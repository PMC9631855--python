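# fogcombine

Combine two independent raters' video annotations of freezing-of-gait (FOG)
episodes into agreed-FOG / agreed-no-FOG / to-be-discussed segments, and
report duration-weighted interrater agreement.

Videos are annotated per rater in [ELAN](https://archive.mpi.nl/tla/elan) and
exported as tab-delimited files. `fogcombine` compares the two tracks on a
millisecond timeline:

- **black** segments (both raters annotate FOG) become agreed FOG,
- **white** segments (neither does) become agreed no-FOG,
- **gray** segments (exactly one does) are resolved by two parameters:
  - **tolerance** (default 2 s): a gray segment bordering an agreed-FOG
    segment and no longer than the tolerance is treated as annotation
    imprecision; a longer one goes on the discussion list. A gray segment
    with no adjacent agreed-FOG segment (an *isolated* possible episode)
    always goes to discussion.
  - **correction** (`include` | `exclude`, default `exclude`): whether a
    short bordering gray segment counts as FOG or not.

Episodes annotated by both raters but with different phenotype
(trembling / shuffling / akinesia) or trigger labels are flagged
`check_type` / `check_trigger` for review.

Agreement is reported on the *pre-resolution* overlap as a duration-weighted
2×2 table: positive agreement, negative agreement and prevalence index
(the recommended trio), plus Cohen's kappa (explicitly `undefined` when both
raters annotate no FOG) and ICC(2,1) over per-trial %time-frozen scores.

## CLI

```sh
# combine one trial's two rater files
fogcombine combine --rater1 r1.txt --rater2 r2.txt \
    --tolerance 2.0 --correction exclude --dialect auto --out outdir/

# agreement metrics only (JSON to stdout)
fogcombine metrics --rater1 r1.txt --rater2 r2.txt [--epoch-s 1]

# deterministic synthetic two-rater fixtures
fogcombine simulate --spec spec.json --seed 7 --out fixtures/
```

`combine` writes into `--out`:

- `resolved_segments.txt` — ELAN-reimportable table (tiers `FOG_agreed`,
  `FOG_discussion`);
- `combined_episodes.txt` — merged agreed-FOG episodes (`FOG_combined` tier);
- `discussion_list.tsv` — segments for the third-rater session, with reasons;
- `metrics.json` — agreement metrics plus the tolerance/correction used;
- `timeline.png` — per-trial bar figure (raters, overlap, combined outcome);
- `run.log` — every resolution decision with provenance.

Input files are tab-delimited `Tier, Begin Time, End Time, [Duration],
Annotation` rows; time dialects `ms`, `s.ms`, `hh:mm:ss.ms`, or `auto`.
Use `--fog-tier` / `--trigger-tier` to map tier names when the defaults
(any tier = FOG; tiers containing "trigger" = triggers) do not fit.

## Library

```python
from fogcombine import (
    read_elan_export, normalize_track, partition_timeline,
    CombineConfig, resolve, merge_episodes, tabulate, compute_report,
)

a = normalize_track(read_elan_export("r1.txt", rater_id="rater1", trial_duration_ms=60_000))
b = normalize_track(read_elan_export("r2.txt", rater_id="rater2", trial_duration_ms=60_000))
partition = partition_timeline(a, b)
episodes = merge_episodes(resolve(partition, CombineConfig(tolerance_ms=2000, correction="include")))
report = compute_report(tabulate(partition))
```

All times are integer milliseconds; intervals are half-open `[begin, end)`.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes a 1-ms discretized brute-force oracle
(`tests/oracle.py`) against which the interval algebra is checked on
thousands of randomized fixtures, plus property tests (hypothesis) for the
metric bounds, rater symmetry, scale invariance and the correction/tolerance
monotonicity guarantees. `tests/test_acceptance.py` holds the acceptance
criteria.

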