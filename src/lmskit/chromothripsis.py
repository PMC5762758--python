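"""Chromothripsis calling from segmented copy-number profiles.

Chromothripsis — catastrophic localized chromosome shattering — leaves a
characteristic footprint of copy-number states oscillating between two
levels. The caller operationalizes this as a switch-density criterion: a
chromosome is positive when it carries at least ``min_switches``
alternating copy-number state switches whose density (switches per Mb of
affected region) reaches ``min_ratio``. With the defaults (6 switches,
ratio 0.2) this corresponds to at least ten alternating switches within
50 Mb, or six within 30 Mb. Relating the switch count to the span of the
affected region keeps large chromosomes from reaching the count by chance.

"Alternating" is interpreted, by default, as oscillation between exactly
two states (A,B,A,B,...); monotone staircases of distinct states do not
count. The ``switch_policy`` argument switches to counting every adjacent
state change for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log2
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    """A copy-number segment with 1-based inclusive coordinates."""

    start: int
    end: int
    log2: float | None = None
    state: int | None = None

    def __post_init__(self):
        if self.end < self.start:
            raise ProfileError(f"segment end {self.end} < start {self.start}")


@dataclass(frozen=True)
class SegmentProfile:
    """Ordered, non-overlapping segments of one chromosome of one sample."""

    sample: str
    chrom: str
    segments: tuple[Segment, ...]

    def __post_init__(self):
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ProfileError(
                    f"{self.sample} {self.chrom}: segments overlap or are unsorted "
                    f"({a.start}-{a.end} then {b.start}-{b.end})"
                )

    def states(self) -> list[int]:
        states = [s.state for s in self.segments]
        if any(s is None for s in states):
            raise ProfileError(f"{self.sample} {self.chrom}: missing copy-number states")
        return states  # type: ignore[return-value]


@dataclass(frozen=True)
class ChromothripsisCall:
    """Per-chromosome switch-density verdict."""

    sample: str
    chrom: str
    n_switches: int
    affected_span_mb: float
    ratio: float
    positive: bool


def correct_log2(
    profile: SegmentProfile,
    tumor_chrom_read_fraction: float,
    normal_chrom_read_fraction: float,
) -> SegmentProfile:
    """Shift all segment log2 ratios by log2(tumor fraction / normal fraction).

    Used to account for whole-chromosome gains and losses given the
    proportion of total reads mapping to the chromosome in tumor and
    matched normal. Segment boundaries are unchanged; applying the inverse
    fractions restores the input.
    """
    if tumor_chrom_read_fraction <= 0 or normal_chrom_read_fraction <= 0:
        raise ProfileError("chromosome read fractions must be positive")
    shift = log2(tumor_chrom_read_fraction / normal_chrom_read_fraction)
    segs = []
    for s in profile.segments:
        if s.log2 is None:
            raise ProfileError(f"{profile.sample} {profile.chrom}: segment missing log2")
        segs.append(replace(s, log2=s.log2 + shift))
    return SegmentProfile(profile.sample, profile.chrom, tuple(segs))


def discretize_states(profile: SegmentProfile, ploidy_baseline: float = 2.0) -> SegmentProfile:
    """Assign integer copy-number states from log2 ratios.

    state = round(baseline * 2^log2), floored at 0. Segments that already
    carry a state pass through untouched.
    """
    segs = []
    for s in profile.segments:
        if s.state is not None:
            segs.append(s)
            continue
        if s.log2 is None:
            raise ProfileError(f"{profile.sample} {profile.chrom}: segment has neither log2 nor state")
        state = int(max(round(ploidy_baseline * 2.0**s.log2), 0))
        segs.append(replace(s, state=state))
    return SegmentProfile(profile.sample, profile.chrom, tuple(segs))


def _breakpoints(segments: Sequence[Segment]) -> list[float]:
    """Breakpoint positions: midpoint between adjacent segment end/start."""
    return [
        (a.end + b.start) / 2.0 for a, b in zip(segments, segments[1:])
    ]


def _two_state_runs(states: Sequence[int]) -> list[tuple[int, int]]:
    """Maximal runs of oscillation between exactly two states.

    Returns (first, last) segment-index pairs of every maximal run
    containing at least one switch. Within a run every adjacent pair
    differs and only two distinct states occur, i.e. s[i] == s[i-2].
    Runs may share a boundary segment (e.g. 1,2,1,3,1,3 yields runs
    [0..2] and [2..5]).
    """
    n = len(states)
    runs: list[tuple[int, int]] = []
    i0 = 0
    for i in range(1, n):
        if states[i] == states[i - 1]:
            if i - 1 > i0:
                runs.append((i0, i - 1))
            i0 = i
        elif i - i0 >= 2 and states[i] != states[i - 2]:
            # a third state breaks the oscillation; it may seed a new run
            # together with the previous segment
            runs.append((i0, i - 1))
            i0 = i - 1
    if n - 1 > i0:
        runs.append((i0, n - 1))
    return runs


def count_switches(
    profile: SegmentProfile,
    *,
    switch_policy: str = "two-state",
    run_mode: str = "max",
) -> tuple[int, float]:
    """Count alternating copy-number state switches and their span in Mb.

    Under the default ``two-state`` policy only switches participating in
    an oscillation between exactly two states count; ``run_mode='max'``
    scores the single best oscillating run (ties broken toward the denser
    one), ``run_mode='union'`` pools switches across all oscillating runs
    and spans from the first to the last pooled switch. The
    ``any-change`` policy counts every adjacent state change.

    The span is the distance between the first and last counted breakpoint
    (segment-boundary midpoints) in Mb; it is 0 when fewer than two
    switches exist.
    """
    if switch_policy not in ("two-state", "any-change"):
        raise ProfileError(f"unknown switch policy {switch_policy!r}")
    if run_mode not in ("max", "union"):
        raise ProfileError(f"unknown run mode {run_mode!r}")
    states = profile.states()
    if len(states) < 2:
        return 0, 0.0
    bps = _breakpoints(profile.segments)

    if switch_policy == "any-change":
        idx = [i for i in range(1, len(states)) if states[i] != states[i - 1]]
        if not idx:
            return 0, 0.0
        span = (bps[idx[-1] - 1] - bps[idx[0] - 1]) / 1e6
        return len(idx), span

    runs = _two_state_runs(states)
    if not runs:
        return 0, 0.0
    if run_mode == "union":
        n = sum(b - a for a, b in runs)
        first = runs[0][0]
        last = runs[-1][1]
        span = (bps[last - 1] - bps[first]) / 1e6
        return n, span
    best = None
    for a, b in runs:
        n = b - a
        span = (bps[b - 1] - bps[a]) / 1e6 if n >= 2 else 0.0
        key = (n, -span)
        if best is None or key > best[0]:
            best = (key, n, span)
    assert best is not None
    return best[1], best[2]


def call_chromothripsis(
    profile: SegmentProfile,
    *,
    min_switches: int = 6,
    min_ratio: float = 0.2,
    switch_policy: str = "two-state",
    run_mode: str = "max",
) -> ChromothripsisCall:
    """Call chromothripsis on one chromosome by switch density.

    Positive iff the chromosome carries at least ``min_switches``
    alternating switches AND the ratio of switch count to affected span in
    Mb is at least ``min_ratio`` (inclusive: ten switches over exactly
    50 Mb, ratio 0.2, is positive). The ratio is defined as 0 when fewer
    than two switches exist (no span).
    """
    n, span = count_switches(profile, switch_policy=switch_policy, run_mode=run_mode)
    ratio = 0.0 if n < 2 else (n / span if span > 0 else float("inf"))
    positive = n >= min_switches and ratio >= min_ratio
    return ChromothripsisCall(profile.sample, profile.chrom, n, span, ratio, positive)


def call_profiles(
    profiles: Iterable[SegmentProfile], **kwargs
) -> pd.DataFrame:
    """Call every chromosome and return a tidy per-chromosome table."""
    rows = []
    for p in profiles:
        c = call_chromothripsis(p, **kwargs)
        rows.append(
            (c.sample, c.chrom, c.n_switches, c.affected_span_mb, c.ratio, c.positive)
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "n_switches", "affected_span_mb", "ratio", "positive"],
    )


def summarize_samples(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample count of chromothripsis-positive chromosomes."""
    return (
        calls.groupby("sample")["positive"]
        .agg(n_affected_chromosomes="sum", any_positive="any")
        .reset_index()
    )


def profiles_from_seg(df: pd.DataFrame) -> list[SegmentProfile]:
    """Build profiles from a SEG-like table (sample, chrom, start, end, log2[, state])."""
    profiles = []
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("start")
        segs = tuple(
            Segment(
                int(r.start),
                int(r.end),
                None if "log2" not in grp.columns or pd.isna(r.log2) else float(r.log2),
                None
                if "state" not in grp.columns or pd.isna(getattr(r, "state", np.nan))
                else int(r.state),
            )
            for r in grp.itertuples()
        )
        profiles.append(SegmentProfile(str(sample), str(chrom), segs))
    return profiles


def profiles_to_seg(profiles: Iterable[SegmentProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for s in p.segments:
            rows.append((p.sample, p.chrom, s.start, s.end, s.log2, s.state))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "log2", "state"])
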