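"""Mutational catalogs over the 96 trinucleotide substitution classes.

Builds per-sample catalogs from somatic SNVs and corrects them for the
different occurrence of triplet motifs between an exome capture target and
the whole genome, so that exposures fitted against genome-derived
signature references are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contexts import (
    BASES,
    CONTEXTS_96,
    PYRIMIDINE_TRIPLETS,
    PYRIMIDINES,
    context_label,
    fold_triplet,
    triplet_of_context,
)

logger = logging.getLogger(__name__)


class CatalogError(ValueError):
    """Raised for invalid SNV records or undefined motif corrections."""

    def __init__(self, message: str, record_errors: Sequence[str] = ()):
        super().__init__(message)
        self.record_errors = list(record_errors)


@dataclass(frozen=True)
class SnvRecord:
    """A somatic single-nucleotide variant with its reference-strand 3-mer.

    ``pos`` is 1-based (VCF convention); ``context`` is the reference 3-mer
    at positions pos-1..pos+1 with ``ref`` as middle base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    context: str
    sample: str

    def validate(self) -> str | None:
        """Return an error description, or None if the record is valid."""
        ref, alt, ctx = self.ref.upper(), self.alt.upper(), self.context.upper()
        if len(ref) != 1 or len(alt) != 1 or len(ctx) != 3:
            return f"{self.chrom}:{self.pos} malformed ref/alt/context"
        if ref == alt:
            return f"{self.chrom}:{self.pos} ref equals alt ({ref})"
        if any(b not in BASES for b in (ref, alt)):
            return f"{self.chrom}:{self.pos} non-ACGT allele {ref}>{alt}"
        if ctx[1] != ref:
            return f"{self.chrom}:{self.pos} context {ctx} does not center on ref {ref}"
        return None


@dataclass(frozen=True)
class MutationalCatalog:
    """Per-sample SNV counts over the 96 substitution classes.

    ``counts`` is a 96 x n_samples frame indexed by the context labels in
    the conventional order. Counts may be non-integer after motif
    normalization.
    """

    counts: pd.DataFrame

    def __post_init__(self):
        if list(self.counts.index) != list(CONTEXTS_96):
            raise CatalogError("catalog must have exactly the 96 context rows in order")
        if (self.counts.to_numpy() < 0).any():
            raise CatalogError("catalog counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, sample: str) -> np.ndarray:
        return self.counts[sample].to_numpy(dtype=float)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("context").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "MutationalCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.reindex(CONTEXTS_96))

    @classmethod
    def zeros(cls, samples: Sequence[str]) -> "MutationalCatalog":
        return cls(pd.DataFrame(0.0, index=list(CONTEXTS_96), columns=list(samples)))


@dataclass(frozen=True)
class TripletFrequencies:
    """Occurrence counts of the 32 pyrimidine-centered 3-mers in a region set."""

    counts: pd.Series

    def __post_init__(self):
        object.__setattr__(
            self, "counts", self.counts.reindex(PYRIMIDINE_TRIPLETS).astype(float)
        )
        if self.counts.isna().any():
            raise CatalogError("triplet frequencies must cover all 32 pyrimidine 3-mers")

    @property
    def relative(self) -> pd.Series:
        total = float(self.counts.sum())
        if total <= 0:
            raise CatalogError("triplet frequencies sum to zero")
        return self.counts / total


def build_catalog(
    snvs: Iterable[SnvRecord], samples: Sequence[str] | None = None
) -> MutationalCatalog:
    """Count SNVs into a 96 x samples catalog.

    Each valid record increments exactly one cell; purine-reference records
    are folded to the pyrimidine strand. Records with N-containing contexts
    are skipped with a logged tally; records violating the SnvRecord
    invariants raise a CatalogError listing every offending record.
    """
    errors: list[str] = []
    skipped_n = 0
    cells: dict[tuple[str, str], float] = {}
    seen_samples: list[str] = list(samples) if samples is not None else []
    for rec in snvs:
        if rec.sample not in seen_samples:
            if samples is not None:
                errors.append(f"{rec.chrom}:{rec.pos} unknown sample {rec.sample!r}")
                continue
            seen_samples.append(rec.sample)
        ctx = rec.context.upper()
        if "N" in ctx or "N" in rec.ref.upper() or "N" in rec.alt.upper():
            skipped_n += 1
            continue
        err = rec.validate()
        if err is not None:
            errors.append(err)
            continue
        label = context_label(rec.ref, rec.alt, ctx)
        key = (label, rec.sample)
        cells[key] = cells.get(key, 0.0) + 1.0
    if errors:
        raise CatalogError(
            f"{len(errors)} invalid SNV record(s); see .record_errors", errors
        )
    if skipped_n:
        logger.info("build_catalog: skipped %d SNV(s) with N-containing context", skipped_n)
    cat = pd.DataFrame(0.0, index=list(CONTEXTS_96), columns=seen_samples)
    for (label, sample), n in cells.items():
        cat.loc[label, sample] = n
    return MutationalCatalog(cat)


def attach_contexts(
    variants: Iterable[tuple[str, int, str, str, str]], fasta
) -> list[SnvRecord]:
    """Build SnvRecords by extracting the 3-mer context from a reference.

    ``variants`` yields (chrom, pos, ref, alt, sample) with 1-based pos;
    ``fasta`` is a pyfaidx.Fasta or any mapping of chrom -> sequence string.
    """
    out = []
    for chrom, pos, ref, alt, sample in variants:
        seq = fasta[chrom]
        ctx = str(seq[pos - 2 : pos + 1])
        out.append(SnvRecord(chrom, pos, ref, alt, ctx, sample))
    return out


def read_snvs_vcf(path, sample: str, fasta=None) -> list[SnvRecord]:
    """Read biallelic SNVs from a VCF into SnvRecords.

    Multi-allelic or non-SNV records raise; ``fasta`` (pyfaidx.Fasta or
    mapping) supplies contexts. Without a reference the VCF must carry an
    INFO field ``CTX`` holding the 3-mer.
    """
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        if len(v.ALT) != 1:
            raise CatalogError(f"{v.CHROM}:{v.POS} multi-allelic record; split upstream")
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            raise CatalogError(f"{v.CHROM}:{v.POS} not an SNV ({ref}>{alt})")
        if fasta is not None:
            ctx = str(fasta[v.CHROM][v.POS - 2 : v.POS + 1])
        else:
            ctx = v.INFO.get("CTX")
            if ctx is None:
                raise CatalogError(
                    f"{v.CHROM}:{v.POS} no reference supplied and no CTX INFO field"
                )
        records.append(SnvRecord(v.CHROM, v.POS, ref, alt, str(ctx), sample))
    return records


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent 0-based half-open intervals (BED semantics)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise CatalogError(f"empty or inverted interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def count_triplets(
    regions: Iterable[tuple[str, int, int]], reference
) -> TripletFrequencies:
    """Count pyrimidine-folded 3-mers whose center lies inside a region set.

    ``regions`` are 0-based half-open; overlapping intervals are merged
    first so no center is counted twice. ``reference`` is a pyfaidx.Fasta
    or mapping of chrom -> sequence. A center needs both flanking bases, so
    centers at the very ends of a contig are skipped; N-containing 3-mers
    are excluded with a logged tally.
    """
    counts = dict.fromkeys(PYRIMIDINE_TRIPLETS, 0.0)
    skipped_n = 0
    for chrom, start, end in merge_intervals(regions):
        seq = reference[chrom]
        length = len(seq)
        if end > length:
            raise CatalogError(
                f"interval {chrom}:{start}-{end} extends beyond contig end ({length})"
            )
        lo = max(start, 1)
        hi = min(end, length - 1)
        if hi <= lo:
            continue
        window = str(seq[lo - 1 : hi + 1]).upper()
        for i in range(hi - lo):
            tri = window[i : i + 3]
            if "N" in tri:
                skipped_n += 1
                continue
            counts[tri if tri[1] in PYRIMIDINES else fold_triplet(tri)] += 1.0
    if skipped_n:
        logger.info("count_triplets: skipped %d N-containing 3-mer(s)", skipped_n)
    return TripletFrequencies(pd.Series(counts))


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED file into 0-based half-open intervals, flagging bad lines."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CatalogError(f"{path}:{lineno}: malformed BED line {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise CatalogError(
                    f"{path}:{lineno}: non-integer coordinates in {line!r}"
                ) from None
            out.append((fields[0], start, end))
    return out


def normalize_motifs(
    catalog: MutationalCatalog,
    target: TripletFrequencies,
    genome: TripletFrequencies,
) -> MutationalCatalog:
    """Correct a target-capture catalog toward whole-genome motif frequencies.

    Each context row is scaled by the ratio of the genome-wide relative
    frequency of its underlying 3-mer to the target relative frequency, so
    mutations in motifs under-represented on the capture target are
    up-weighted. Counts may become non-integer.
    """
    t_rel = target.relative
    g_rel = genome.relative
    if (t_rel <= 0).any():
        missing = list(t_rel.index[t_rel <= 0])
        raise CatalogError(f"zero target frequency for 3-mer(s) {missing}; correction undefined")
    ratios = pd.Series(
        [g_rel[triplet_of_context(c)] / t_rel[triplet_of_context(c)] for c in CONTEXTS_96],
        index=list(CONTEXTS_96),
    )
    return MutationalCatalog(catalog.counts.mul(ratios, axis=0))


def motif_correction_factors(
    target: TripletFrequencies, genome: TripletFrequencies
) -> pd.Series:
    """The per-context scaling factors applied by :func:`normalize_motifs`."""
    t_rel, g_rel = target.relative, genome.relative
    return pd.Series(
        [g_rel[triplet_of_context(c)] / t_rel[triplet_of_context(c)] for c in CONTEXTS_96],
        index=list(CONTEXTS_96),
    )
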