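"""Heuristic filtering of candidate somatic SNV and indel calls.

Tumor/normal SNV candidates from a pileup-based caller pass through a
fixed chain of heuristic rules: minimum variant-read support, minimum
variant allele frequency (VAF), a strand-artifact rule (single-strand
support combined with a platform-specific error-profile sequence
context), control coverage and control contamination thresholds, and
region-based exclusions (low-mappability/blacklist tracks; simultaneous
overlap with two or more repeat classes).

Indel candidates from a diploid caller (Platypus-style) are kept when
somatic (control genotype 0/0) and either flagged PASS or not carrying a
bias flag (badReads, alleleBias, strandBias) at VAF below 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .catalog import read_bed

#: Region classes whose mere presence excludes a variant.
EXCLUDED_REGION_CLASSES = frozenset({"low-mappability", "blacklist"})
#: Repeat classes; overlapping any two at once excludes a variant.
REPEAT_REGION_CLASSES = frozenset(
    {"tandem-repeat", "simple-repeat", "low-complexity", "satellite", "segmental-duplication"}
)

#: Fixed rule order of the SNV filter chain.
SNV_RULES = (
    "min_variant_reads",      # >= 5 variant reads
    "min_vaf",                # VAF >= 5%
    "strand_artifact",        # single-strand support in an error-profile context
    "control_coverage",       # control coverage >= 10
    "control_contamination",  # < 1/30 of control bases support the variant
    "excluded_region",        # low-mappability / blacklist overlap
    "repeat_overlap",         # any two repeat classes at once
)

INDEL_BIAS_FLAGS = frozenset({"badReads", "alleleBias", "strandBias"})
_KNOWN_INDEL_FLAGS = INDEL_BIAS_FLAGS | {"PASS", "."}


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateSnv:
    """A candidate somatic SNV with the evidence the filter chain consumes.

    ``control_coverage`` / ``control_var_reads`` may be None (e.g.
    tumor-only calling); the verdict is then not determined.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_var_reads: int
    tumor_total_reads: int
    var_reads_forward: int = 0
    var_reads_reverse: int = 0
    control_coverage: int | None = None
    control_var_reads: int | None = None
    region_annotations: frozenset[str] = frozenset()
    error_profile_context: bool = False

    def __post_init__(self):
        if self.tumor_var_reads < 0 or self.tumor_total_reads < 0:
            raise FilterError(f"{self.chrom}:{self.pos} negative read counts")
        if self.tumor_var_reads > self.tumor_total_reads:
            raise FilterError(
                f"{self.chrom}:{self.pos} variant reads exceed total reads"
            )
        object.__setattr__(self, "region_annotations", frozenset(self.region_annotations))

    @property
    def vaf(self) -> float:
        if self.tumor_total_reads == 0:
            return 0.0
        return self.tumor_var_reads / self.tumor_total_reads


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failed_rules: tuple[str, ...]
    determined: bool = True

    def __post_init__(self):
        if self.determined and self.passed != (len(self.failed_rules) == 0):
            raise FilterError("verdict inconsistency: pass flag vs failed rules")


def filter_snv(
    c: CandidateSnv,
    *,
    min_var_reads: int = 5,
    min_vaf: float = 0.05,
    min_control_coverage: int = 10,
    max_control_fraction: float = 1.0 / 30.0,
) -> FilterVerdict:
    """Apply the SNV heuristic filter chain in fixed rule order.

    The verdict lists every failed rule. Missing control evidence yields a
    not-determined verdict (no rules evaluated).
    """
    if c.control_coverage is None or c.control_var_reads is None:
        return FilterVerdict(False, (), determined=False)
    failed: list[str] = []
    if c.tumor_var_reads < min_var_reads:
        failed.append("min_variant_reads")
    if c.vaf < min_vaf:
        failed.append("min_vaf")
    single_strand = (c.var_reads_forward == 0) != (c.var_reads_reverse == 0)
    if single_strand and c.error_profile_context:
        failed.append("strand_artifact")
    if c.control_coverage < min_control_coverage:
        failed.append("control_coverage")
    control_fraction = (
        c.control_var_reads / c.control_coverage if c.control_coverage > 0 else 1.0
    )
    if not control_fraction < max_control_fraction:
        failed.append("control_contamination")
    if c.region_annotations & EXCLUDED_REGION_CLASSES:
        failed.append("excluded_region")
    if len(c.region_annotations & REPEAT_REGION_CLASSES) >= 2:
        failed.append("repeat_overlap")
    return FilterVerdict(not failed, tuple(failed))


def filter_snvs(candidates: Iterable[CandidateSnv], **kwargs) -> list[FilterVerdict]:
    return [filter_snv(c, **kwargs) for c in candidates]


@dataclass(frozen=True)
class CandidateIndel:
    """A Platypus-style indel candidate."""

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_flags: frozenset[str]
    control_genotype: str  # e.g. "0/0"
    vaf: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "filter_flags", frozenset(self.filter_flags))


def filter_indel(c: CandidateIndel, *, rescue_max_vaf: float = 0.10) -> FilterVerdict:
    """Filter an indel candidate by caller flags and somatic status.

    Non-somatic candidates (control genotype other than 0/0) fail. PASS
    candidates pass. Candidates carrying badReads, alleleBias or
    strandBias fail when their VAF is below ``rescue_max_vaf``; other
    (unrecognized) flags are retained with a warning.
    """
    failed: list[str] = []
    if c.control_genotype != "0/0":
        failed.append("not_somatic")
    flags = c.filter_flags - {"."}
    if "PASS" not in flags:
        bias = flags & INDEL_BIAS_FLAGS
        if bias and (c.vaf is None or c.vaf < rescue_max_vaf):
            failed.append("bias_flag_low_vaf")
        unknown = flags - _KNOWN_INDEL_FLAGS
        if unknown:
            warnings.warn(
                f"{c.chrom}:{c.pos} unrecognized filter flag(s) {sorted(unknown)}; retained",
                stacklevel=2,
            )
    return FilterVerdict(not failed, tuple(failed))


class RegionIndex:
    """Named region sets over 0-based half-open intervals, point-queryable."""

    def __init__(self, region_sets: Mapping[str, Iterable[tuple[str, int, int]]]):
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        for name, intervals in region_sets.items():
            per_chrom: dict[str, IntervalTree] = {}
            for chrom, start, end in intervals:
                per_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
            self._trees[name] = per_chrom

    @classmethod
    def from_bed_files(cls, bed_paths: Mapping[str, str]) -> "RegionIndex":
        return cls({name: read_bed(path) for name, path in bed_paths.items()})

    def classes_at(self, chrom: str, pos: int) -> frozenset[str]:
        """Region classes overlapping a 1-based position (queried at pos-1)."""
        hits = set()
        for name, per_chrom in self._trees.items():
            tree = per_chrom.get(chrom)
            if tree is not None and tree.overlaps_point(pos - 1):
                hits.add(name)
        return frozenset(hits)


def annotate_regions(
    variants: Sequence[CandidateSnv], regions: RegionIndex
) -> list[CandidateSnv]:
    """Return copies of the variants with region annotations filled in."""
    return [
        replace(v, region_annotations=regions.classes_at(v.chrom, v.pos))
        for v in variants
    ]
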