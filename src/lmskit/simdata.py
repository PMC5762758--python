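"""Synthetic cohorts with the statistical structure of the real inputs.

The generators emulate, at desk scale, the four input families of the
analysis: (a) mutational catalogs drawn from known signature mixtures
with count noise, (b) per-chromosome copy-number profiles with and
without oscillating two-state patterns, (c) C-circle dot-blot intensity
triplets (+pol, −pol, background) with matched telomere-qPCR tables, and
(d) per-gene lesion/allele-specific copy-number configurations with and
without whole-genome duplication. Every generator writes a truth table
alongside the data; labels are constructed, never inferred.

Defaults mirror the study cohort: 49 samples, 223 mutations per sample
(the cohort median), 35% of samples with a chromothriptic chromosome,
55% with WGD, 78% ALT-positive. Coordinates live on a single synthetic
250-Mb pseudo-chromosome per record so no reference genome is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chromothripsis import Segment, SegmentProfile, profiles_to_seg
from .contexts import CONTEXTS_96
from .catalog import MutationalCatalog
from .sigfit import SignatureSet

PSEUDO_CHROM_LENGTH = 250_000_000
NOISE_MODELS = ("multinomial", "poisson")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic cohort.

    ``signature_mix`` maps signature ids to true relative exposures
    (non-negative, summing to at most 1; any remainder is spread uniformly
    over the 96 contexts as unattributed noise). The same seed yields
    bit-identical outputs.
    """

    seed: int = 0
    n_samples: int = 49
    signature_mix: Mapping[str, float] = field(
        default_factory=lambda: {"S1": 0.5, "S2": 0.3, "S3": 0.2}
    )
    mutations_per_sample: int = 223
    chromothripsis_fraction: float = 0.35
    wgd_fraction: float = 0.55
    noise_model: str = "multinomial"

    def __post_init__(self):
        if self.n_samples <= 0:
            raise SimulationError("n_samples must be positive")
        if self.mutations_per_sample <= 0:
            raise SimulationError("mutations_per_sample must be positive")
        for frac_name in ("chromothripsis_fraction", "wgd_fraction"):
            frac = getattr(self, frac_name)
            if not (0.0 <= frac <= 1.0):
                raise SimulationError(f"{frac_name} must lie in [0, 1]")
        mix = dict(self.signature_mix)
        if any(w < 0 for w in mix.values()):
            raise SimulationError("signature mix weights must be non-negative")
        if sum(mix.values()) > 1.0 + 1e-9:
            raise SimulationError("signature mix weights must sum to at most 1")
        if self.noise_model not in NOISE_MODELS:
            raise SimulationError(f"noise_model must be one of {NOISE_MODELS}")
        object.__setattr__(self, "signature_mix", mix)

    def sample_names(self) -> list[str]:
        width = max(2, len(str(self.n_samples)))
        return [f"SIM{i + 1:0{width}d}" for i in range(self.n_samples)]


def synthetic_signature_set(
    n_signatures: int = 3,
    seed: int = 0,
    cutoffs: Mapping[str, float] | None = None,
    concentration: float = 1.0,
) -> SignatureSet:
    """A small synthetic signature reference.

    Each signature is a Dirichlet draw over the 96 contexts. The default
    concentration of 1 yields profiles whose mass is spread over all
    contexts with moderate variation, like real signature references
    (which range from a few dominant peaks over a broad base to nearly
    flat); lower concentrations give unrealistically spiky profiles. Ids
    are "S1".."Sk"; cutoffs default to 0 (retain anything with positive
    exposure).
    """
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1}" for i in range(n_signatures)]
    mat = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    df = pd.DataFrame(mat, index=list(CONTEXTS_96), columns=ids)
    df = df / df.sum(axis=0)
    cut = pd.Series(0.0, index=ids) if cutoffs is None else pd.Series(dict(cutoffs))
    return SignatureSet(df, cut)


def simulate_catalogs(
    config: SimConfig, signatures: SignatureSet
) -> tuple[MutationalCatalog, pd.DataFrame]:
    """Draw per-sample catalogs from the configured signature mixture.

    Each sample's 96-vector has expectation mutations_per_sample x
    (W . mix + uniform remainder). Under multinomial noise the column sum
    equals mutations_per_sample exactly; under Poisson it does so in
    expectation. The truth table records the true absolute and relative
    exposures per sample and signature.
    """
    mix = dict(config.signature_mix)
    unknown = [s for s in mix if s not in signatures.ids]
    if unknown:
        raise SimulationError(f"signature mix references unknown signature(s) {unknown}")
    rng = np.random.default_rng(config.seed)
    W = signatures.matrix.to_numpy(dtype=float)
    weights = np.array([mix.get(s, 0.0) for s in signatures.ids])
    p = W @ weights
    remainder = 1.0 - weights.sum()
    if remainder > 1e-12:
        p = p + remainder / 96.0
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    n = config.mutations_per_sample
    samples = config.sample_names()
    cols = {}
    for sample in samples:
        if config.noise_model == "multinomial":
            cols[sample] = rng.multinomial(n, p).astype(float)
        else:
            cols[sample] = rng.poisson(n * p).astype(float)
    catalog = MutationalCatalog(pd.DataFrame(cols, index=list(CONTEXTS_96)))
    truth = pd.DataFrame(
        [
            (sample, sig, n * mix.get(sig, 0.0), mix.get(sig, 0.0))
            for sample in samples
            for sig in signatures.ids
        ],
        columns=["sample", "signature", "true_exposure", "true_rel_exposure"],
    )
    return catalog, truth


def make_oscillating_profile(
    sample: str,
    n_switches: int,
    span_mb: float,
    *,
    chrom: str = "chr1",
    offset: int = 50_000_000,
    states: tuple[int, int] = (2, 1),
    chrom_length: int = PSEUDO_CHROM_LENGTH,
) -> SegmentProfile:
    """A single-chromosome profile with exactly ``n_switches`` alternating
    switches whose first and last breakpoints are ``span_mb`` Mb apart.

    Breakpoints are evenly spaced; flanking segments extend to the
    chromosome ends at the first oscillation state. With a single switch
    the span is 0 by construction.
    """
    if n_switches < 1:
        seg = Segment(1, chrom_length, log2=0.0, state=states[0])
        return SegmentProfile(sample, chrom, (seg,))
    span = int(round(span_mb * 1e6))
    if offset + span >= chrom_length:
        raise SimulationError("oscillation exceeds chromosome length")
    if n_switches == 1:
        bps = [offset]
    else:
        bps = [offset + round(i * span / (n_switches - 1)) for i in range(n_switches)]
    bounds = [1] + [b + 1 for b in bps] + [chrom_length + 1]
    segs = []
    a, b = states
    for i in range(len(bounds) - 1):
        state = a if i % 2 == 0 else b
        log2 = float(np.log2(max(state, 0.5) / 2.0))
        segs.append(Segment(bounds[i], bounds[i + 1] - 1, log2=log2, state=state))
    return SegmentProfile(sample, chrom, tuple(segs))


def simulate_profiles(
    config: SimConfig,
    *,
    positive_switches: int = 10,
    positive_span_mb: float = 50.0,
) -> tuple[list[SegmentProfile], pd.DataFrame]:
    """Per-sample single-chromosome profiles with truth labels.

    Positive samples carry an oscillating two-state run engineered to pass
    the switch-density caller (defaults: 10 switches over 50 Mb, ratio
    0.2). Negative samples are flat, carry fewer than 6 switches, or carry
    many switches at sub-threshold density.
    """
    rng = np.random.default_rng(config.seed + 1)
    profiles: list[SegmentProfile] = []
    labels = []
    for sample in config.sample_names():
        positive = bool(rng.random() < config.chromothripsis_fraction)
        offset = int(rng.integers(20_000_000, 120_000_000))
        if positive:
            prof = make_oscillating_profile(
                sample, positive_switches, positive_span_mb, offset=offset
            )
        else:
            kind = rng.integers(0, 3)
            if kind == 0:  # flat chromosome
                prof = make_oscillating_profile(sample, 0, 0.0, offset=offset)
            elif kind == 1:  # too few switches
                prof = make_oscillating_profile(sample, 3, 20.0, offset=offset)
            else:  # enough switches but sub-threshold density
                prof = make_oscillating_profile(sample, 8, 100.0, offset=offset)
        profiles.append(prof)
        labels.append((sample, positive))
    truth = pd.DataFrame(labels, columns=["sample", "chromothripsis"])
    return profiles, truth


def simulate_telomere_tables(
    config: SimConfig, *, alt_fraction: float = 38 / 49
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """C-circle intensity triplets, qPCR T/S tables, and ALT truth labels.

    ALT-positive rows satisfy both intensity thresholds (+pol at least
    twice −pol and three times background) with margin; negative rows
    violate at least one. Telomere content (T/S) is drawn independently of
    ALT status, reflecting the absence of correlation between the two in
    tumors.
    """
    rng = np.random.default_rng(config.seed + 2)
    cc_rows, qpcr_rows, truth_rows = [], [], []
    for sample in config.sample_names():
        alt = bool(rng.random() < alt_fraction)
        bg = float(rng.lognormal(mean=0.0, sigma=0.25))
        nopol = float(bg * rng.uniform(0.8, 1.6))
        threshold = max(2.0 * nopol, 3.0 * bg)
        if alt:
            pol = float(threshold * rng.uniform(1.2, 5.0))
        else:
            pol = float(threshold * rng.uniform(0.2, 0.95))
        cc_rows.append((sample, pol, nopol, bg))
        tumor_s = float(rng.lognormal(0.0, 0.2))
        control_s = float(rng.lognormal(0.0, 0.2))
        tumor_t = float(tumor_s * rng.lognormal(0.3, 0.8))
        control_t = float(control_s * rng.lognormal(0.0, 0.3))
        qpcr_rows.append((sample, tumor_t, tumor_s, control_t, control_s))
        truth_rows.append((sample, alt))
    ccircle = pd.DataFrame(
        cc_rows, columns=["sample", "intensity_pol", "intensity_nopol", "background"]
    )
    qpcr = pd.DataFrame(
        qpcr_rows, columns=["sample", "tumor_t", "tumor_s", "control_t", "control_s"]
    )
    truth = pd.DataFrame(truth_rows, columns=["sample", "alt_positive"])
    return ccircle, qpcr, truth


#: (cn_class, major, minor, lesion plan, biallelic truth) templates cycled
#: across (sample, gene) pairs so every genotype class is represented.
_GENOTYPE_TEMPLATES = (
    ("LOH", 1, 0, [("SNV", "A", True)], True),
    ("CNN-LOH", 2, 0, [("indel", "A", True)], True),
    ("higher-ploidy LOH", 3, 0, [("SNV", "unknown", True)], True),
    ("normal/biallelic", 2, 1, [("SNV", "A", True), ("fusion/rearrangement", "B", True)], True),
    ("normal/biallelic", 2, 1, [], False),
    ("normal/biallelic", 2, 1, [("SNV", "A", True)], False),
    ("homozygous deletion", 0, 0, [("deletion", "unknown", True)], True),
)

_GENOTYPE_GENES = ("TP53", "RB1", "ATRX")


def simulate_genotypes(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Lesion and allele-specific CN tables plus genotype and WGD truth.

    Returns (lesions, allele_cn, wgd_segments, truth). Per (sample, gene)
    a genotype template is assigned covering all five copy-number classes
    across the cohort; WGD samples get ploidy near 4 with almost all of a
    20-segment pseudo-genome at major copy >= 2, non-WGD samples ploidy
    near 2 with mostly 1+1 segments. Lesion VAFs are drawn congruent with
    purity under the retained-allele model.
    """
    rng = np.random.default_rng(config.seed + 3)
    lesion_rows, acn_rows, seg_rows, truth_rows = [], [], [], []
    template_idx = 0
    for sample in config.sample_names():
        purity = float(rng.uniform(0.4, 0.95))
        wgd = bool(rng.random() < config.wgd_fraction)
        if wgd:
            ploidy = float(rng.normal(3.9, 0.15))
            majors = rng.choice([2, 2, 2, 3], size=20)
            minors = np.minimum(rng.choice([1, 2, 2], size=20), majors)
        else:
            ploidy = float(rng.normal(2.0, 0.1))
            majors = rng.choice([1, 1, 1, 2], size=20)
            minors = np.minimum(rng.choice([0, 1, 1], size=20), majors)
        seg_len = PSEUDO_CHROM_LENGTH // 20
        for i, (ma, mi) in enumerate(zip(majors, minors)):
            seg_rows.append(
                (sample, i * seg_len + 1, (i + 1) * seg_len, int(ma), int(mi))
            )
        for gene in _GENOTYPE_GENES:
            cls, major, minor, lesion_plan, biallelic = _GENOTYPE_TEMPLATES[
                template_idx % len(_GENOTYPE_TEMPLATES)
            ]
            template_idx += 1
            acn_rows.append((sample, gene, major, minor, ploidy, purity))
            for lesion_type, allele, damaging in lesion_plan:
                total = major + minor
                if total > 0 and lesion_type in ("SNV", "indel"):
                    expected = purity * major / (purity * total + 2 * (1 - purity))
                    vaf = float(np.clip(expected + rng.normal(0.0, 0.02), 0.0, 1.0))
                else:
                    vaf = np.nan
                lesion_rows.append((sample, gene, lesion_type, allele, damaging, vaf))
            truth_rows.append((sample, gene, cls, biallelic, wgd, ploidy, purity))
    lesions = pd.DataFrame(
        lesion_rows, columns=["sample", "gene", "lesion_type", "allele", "damaging", "vaf"]
    )
    allele_cn = pd.DataFrame(
        acn_rows, columns=["sample", "gene", "major_cn", "minor_cn", "ploidy", "purity"]
    )
    wgd_segments = pd.DataFrame(
        seg_rows, columns=["sample", "start", "end", "major_cn", "minor_cn"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "gene", "cn_class", "biallelic", "wgd", "ploidy", "purity"],
    )
    return lesions, allele_cn, wgd_segments, truth


def simulate_cohort(
    config: SimConfig, outdir, signatures: SignatureSet | None = None
) -> dict[str, Path]:
    """Generate every synthetic table and write them (with truths) as TSV.

    Returns a name -> path mapping of everything written. Output is
    byte-identical for identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if signatures is None:
        signatures = synthetic_signature_set(seed=config.seed)
    paths: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame, index: bool = False):
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        paths[name] = path

    catalog, catalog_truth = simulate_catalogs(config, signatures)
    write("catalog", catalog.counts.rename_axis("context"), index=True)
    write("catalog_truth", catalog_truth)
    sig_df = signatures.matrix.rename_axis("context")
    write("signatures", sig_df, index=True)

    profiles, profile_truth = simulate_profiles(config)
    write("profiles", profiles_to_seg(profiles))
    write("profiles_truth", profile_truth)

    ccircle, qpcr, alt_truth = simulate_telomere_tables(config)
    write("ccircle", ccircle)
    write("qpcr", qpcr)
    write("alt_truth", alt_truth)

    lesions, allele_cn, wgd_segments, genotype_truth = simulate_genotypes(config)
    write("lesions", lesions)
    write("allele_cn", allele_cn)
    write("wgd_segments", wgd_segments)
    write("genotype_truth", genotype_truth)
    return paths
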