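"""ALT classification from C-circle assays and telomere content by qPCR.

C-circles — partially single-stranded extrachromosomal circles of
telomeric repeats — are a specific biomarker of alternative lengthening
of telomeres (ALT). In the dot-blot assay, genomic DNA is amplified with
(+pol) and without (−pol) Φ29 polymerase; a sample is ALT-positive when
the +pol chemiluminescent signal is at least twofold the −pol control and
at least threefold the membrane background.

Telomere content is quantified by qPCR as the T/S ratio (telomere repeat
signal normalized to the single-copy gene 36B4); tumor-vs-control log2
T/S ratios express relative telomere gain or loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from scipy import stats


class TelomereError(ValueError):
    pass


class AltStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_DETERMINED = "not_determined"


@dataclass(frozen=True)
class CCircleMeasurement:
    """Dot-blot intensities for one sample; missing values mean not determined."""

    sample: str
    intensity_pol: float | None
    intensity_nopol: float | None
    background: float | None


@dataclass(frozen=True)
class TelomereQpcr:
    """Telomere (T) and single-copy-gene (S) qPCR quantities, tumor and control."""

    sample: str
    tumor_t: float
    tumor_s: float
    control_t: float
    control_s: float


@dataclass(frozen=True)
class TsRatioResult:
    sample: str
    tumor_ts: float
    control_ts: float
    log2_ratio: float


def classify_alt(
    m: CCircleMeasurement,
    *,
    pol_vs_nopol: float = 2.0,
    pol_vs_background: float = 3.0,
) -> AltStatus:
    """Classify ALT status from C-circle intensities.

    Positive iff intensity_pol >= pol_vs_nopol * intensity_nopol AND
    intensity_pol >= pol_vs_background * background (both thresholds
    inclusive, "at least twofold/threefold"). Any missing intensity yields
    NOT_DETERMINED; negative intensities are invalid.
    """
    values = (m.intensity_pol, m.intensity_nopol, m.background)
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
        return AltStatus.NOT_DETERMINED
    if any(v < 0 for v in values):  # type: ignore[operator]
        raise TelomereError(f"sample {m.sample!r}: negative intensity")
    pol, nopol, bg = values  # type: ignore[misc]
    if pol >= pol_vs_nopol * nopol and pol >= pol_vs_background * bg:
        return AltStatus.POSITIVE
    return AltStatus.NEGATIVE


def ts_ratio(q: TelomereQpcr) -> TsRatioResult:
    """T/S ratios for tumor and control and their log2 tumor-vs-control ratio."""
    if q.tumor_s <= 0 or q.control_s <= 0:
        raise TelomereError(f"sample {q.sample!r}: single-copy-gene signal must be > 0")
    if q.tumor_t <= 0 or q.control_t <= 0:
        raise TelomereError(f"sample {q.sample!r}: telomere signal must be > 0")
    tumor = q.tumor_t / q.tumor_s
    control = q.control_t / q.control_s
    return TsRatioResult(q.sample, tumor, control, math.log2(tumor / control))


def alt_association(
    alt_status: Mapping[str, AltStatus | str | bool],
    feature: Mapping[str, bool],
) -> tuple[float, list[list[int]]]:
    """Two-sided Fisher exact association of ALT positivity with a binary feature.

    Samples with NOT_DETERMINED status or absent from either mapping are
    excluded. Returns (p-value, 2x2 table [[ALT+ & feat, ALT+ & no-feat],
    [ALT- & feat, ALT- & no-feat]]).
    """
    table = [[0, 0], [0, 0]]
    n = 0
    for sample, status in alt_status.items():
        if sample not in feature:
            continue
        if isinstance(status, bool):
            alt = status
        else:
            status = AltStatus(status)
            if status is AltStatus.NOT_DETERMINED:
                continue
            alt = status is AltStatus.POSITIVE
        table[0 if alt else 1][0 if feature[sample] else 1] += 1
        n += 1
    if n == 0:
        raise TelomereError("no classifiable samples shared between status and feature")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), table
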