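"""Gene genotype integration: allele-specific copy number, lesions, WGD.

Integrates per-gene genetic lesions (SNVs, indels, fusions/rearrangements,
microalterations, germline variants, deletions) with allele-specific copy
number into a genotype class, flags biallelic inactivation, checks
variant-allele-frequency congruence with tumor purity, and calls
whole-genome duplication (WGD) from genome-wide allele-specific profiles.

Copy-number classes follow the standard allele-specific taxonomy: a gene
with minor copy number 0 has lost one parental allele — LOH (1+0),
copy-number-neutral LOH (2+0), or higher-ploidy LOH (>=3+0) — while
retention of both parental alleles (minor >= 1) places it in the
normal/biallelic-alteration group, where biallelic inactivation requires
damaging lesions on both alleles. Homozygous deletion (0+0) is itself
biallelic inactivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

LESION_TYPES = frozenset(
    {"SNV", "indel", "fusion/rearrangement", "microalteration", "germline variant", "deletion"}
)


class GenotypeError(ValueError):
    pass


class CnClass(str, Enum):
    NORMAL_BIALLELIC = "normal/biallelic"
    LOH = "LOH"
    CNN_LOH = "CNN-LOH"
    HIGHER_PLOIDY_LOH = "higher-ploidy LOH"
    HOMOZYGOUS_DELETION = "homozygous deletion"


@dataclass(frozen=True)
class GeneLesion:
    sample: str
    gene: str
    lesion_type: str
    damaging: bool
    allele: str = "unknown"  # "A" (retained/major), "B", or "unknown"
    vaf: float | None = None

    def __post_init__(self):
        if self.lesion_type not in LESION_TYPES:
            raise GenotypeError(
                f"unknown lesion type {self.lesion_type!r}; expected one of {sorted(LESION_TYPES)}"
            )
        if self.allele not in ("A", "B", "unknown"):
            raise GenotypeError(f"allele must be A, B or unknown, got {self.allele!r}")


@dataclass(frozen=True)
class AlleleCN:
    """Allele-specific copy number for a gene or segment."""

    sample: str
    gene: str
    major_cn: int
    minor_cn: int
    ploidy: float | None = None
    purity: float | None = None

    def __post_init__(self):
        if self.major_cn < 0 or self.minor_cn < 0:
            raise GenotypeError(f"{self.sample}/{self.gene}: negative copy number")
        if self.major_cn < self.minor_cn:
            raise GenotypeError(
                f"{self.sample}/{self.gene}: major CN {self.major_cn} < minor CN {self.minor_cn}"
            )
        if self.purity is not None and not (0 < self.purity <= 1):
            raise GenotypeError(f"{self.sample}/{self.gene}: purity must lie in (0, 1]")


@dataclass(frozen=True)
class GeneGenotype:
    sample: str
    gene: str
    cn_class: CnClass
    biallelic_inactivation: bool
    evidence: tuple[str, ...] = ()


def classify_cn(acn: AlleleCN) -> CnClass:
    """Copy-number class of a gene from its (major, minor) configuration."""
    major, minor = acn.major_cn, acn.minor_cn
    if major == 0 and minor == 0:
        return CnClass.HOMOZYGOUS_DELETION
    if minor >= 1:
        return CnClass.NORMAL_BIALLELIC
    if major == 1:
        return CnClass.LOH
    if major == 2:
        return CnClass.CNN_LOH
    return CnClass.HIGHER_PLOIDY_LOH


def vaf_purity_congruence(
    vaf: float,
    purity: float,
    major_cn: int,
    minor_cn: int,
    *,
    mutated_copies: int | None = None,
    tolerance: float = 0.1,
) -> tuple[float, bool]:
    """Expected VAF under the retained-allele model and a congruence flag.

    expected VAF = purity * m / (purity * totalCN + 2 * (1 - purity)) with
    m mutated copies (default: the major copy number, i.e. the mutation
    sits on every copy of the retained allele). A truncal mutation on the
    retained allele of an LOH gene is congruent with purity under this
    model.
    """
    if not (0 < purity <= 1):
        raise GenotypeError("purity must lie in (0, 1]")
    total = major_cn + minor_cn
    if total == 0:
        raise GenotypeError("expected VAF undefined at total copy number 0")
    m = major_cn if mutated_copies is None else mutated_copies
    expected = purity * m / (purity * total + 2.0 * (1.0 - purity))
    return expected, abs(vaf - expected) <= tolerance


def flag_biallelic(
    acn: AlleleCN,
    lesions: Sequence[GeneLesion],
    *,
    hemizygous: bool = False,
    vaf_tolerance: float = 0.1,
) -> GeneGenotype:
    """Integrate copy number and lesions into a biallelic-inactivation call.

    True iff (a) homozygous deletion; (b) minor CN 0 with at least one
    damaging lesion attributable to the retained allele; (c) minor CN >= 1
    with damaging lesions assigned to both alleles; or (d) a hemizygous
    locus (e.g. chromosome X in a male sample) with any damaging lesion.
    Lesions annotated on the lost allele of an LOH gene are inconsistent
    with the copy-number state: a warning is emitted and the lesion is
    ignored for the flag. An unknown-allele lesion in an LOH gene counts
    for the retained allele, unless its VAF together with the sample
    purity is incongruent with the retained-allele expectation.
    """
    cls = classify_cn(acn)
    damaging = [l for l in lesions if l.damaging]
    evidence: list[str] = []

    if cls is CnClass.HOMOZYGOUS_DELETION:
        evidence.append("homozygous deletion")
        evidence += [f"{l.lesion_type} ({l.allele})" for l in damaging]
        return GeneGenotype(acn.sample, acn.gene, cls, True, tuple(evidence))

    if hemizygous:
        if damaging:
            evidence += [f"{l.lesion_type} on hemizygous locus" for l in damaging]
            return GeneGenotype(acn.sample, acn.gene, cls, True, tuple(evidence))
        return GeneGenotype(acn.sample, acn.gene, cls, False, ())

    if acn.minor_cn == 0:
        retained_hits = []
        for l in damaging:
            if l.allele == "B":
                warnings.warn(
                    f"{acn.sample}/{acn.gene}: damaging {l.lesion_type} annotated on the "
                    "lost allele of an LOH gene; ignored for the biallelic flag",
                    stacklevel=2,
                )
                continue
            if l.allele == "unknown" and l.vaf is not None and acn.purity is not None:
                _, congruent = vaf_purity_congruence(
                    l.vaf, acn.purity, acn.major_cn, acn.minor_cn, tolerance=vaf_tolerance
                )
                if not congruent:
                    continue
            retained_hits.append(l)
        if retained_hits:
            evidence.append(f"{cls.value} (single parental allele retained)")
            evidence += [f"{l.lesion_type} on retained allele" for l in retained_hits]
            return GeneGenotype(acn.sample, acn.gene, cls, True, tuple(evidence))
        return GeneGenotype(acn.sample, acn.gene, cls, False, ())

    alleles_hit = {l.allele for l in damaging if l.allele in ("A", "B")}
    if alleles_hit == {"A", "B"}:
        evidence += [f"{l.lesion_type} on allele {l.allele}" for l in damaging if l.allele in ("A", "B")]
        return GeneGenotype(acn.sample, acn.gene, cls, True, tuple(evidence))
    return GeneGenotype(acn.sample, acn.gene, cls, False, ())


@dataclass(frozen=True)
class WgdCall:
    status: str  # "positive", "negative", "not_determined"
    ploidy: float
    fraction_major_ge2: float

    @property
    def is_wgd(self) -> bool | None:
        if self.status == "not_determined":
            return None
        return self.status == "positive"


def call_wgd(
    major_cn: Sequence[int] | np.ndarray,
    segment_lengths: Sequence[float] | np.ndarray,
    ploidy: float,
    *,
    min_ploidy: float = 2.9,
    min_major_fraction: float = 0.5,
    genome_size: float | None = None,
    min_coverage: float = 0.5,
) -> WgdCall:
    """Call whole-genome duplication from allele-specific segments.

    Positive iff estimated ploidy >= ``min_ploidy`` and the length-weighted
    fraction of the assessed genome with major copy number >= 2 exceeds
    ``min_major_fraction``. When ``genome_size`` is given and the segments
    cover less than ``min_coverage`` of it, the call is not determined.
    """
    major = np.asarray(major_cn, dtype=float)
    lengths = np.asarray(segment_lengths, dtype=float)
    if major.shape != lengths.shape:
        raise GenotypeError("major_cn and segment_lengths must align")
    if (lengths <= 0).any():
        raise GenotypeError("segment lengths must be positive")
    covered = float(lengths.sum())
    frac = float(lengths[major >= 2].sum() / covered) if covered > 0 else 0.0
    if genome_size is not None and covered < min_coverage * genome_size:
        return WgdCall("not_determined", float(ploidy), frac)
    positive = ploidy >= min_ploidy and frac > min_major_fraction
    return WgdCall("positive" if positive else "negative", float(ploidy), frac)


def cohort_summary(genotypes: Iterable[GeneGenotype]) -> dict[str, float]:
    """Percent of samples with biallelic inactivation, per gene."""
    per_gene: dict[str, list[bool]] = {}
    for g in genotypes:
        per_gene.setdefault(g.gene, []).append(g.biallelic_inactivation)
    return {gene: 100.0 * sum(flags) / len(flags) for gene, flags in per_gene.items()}
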