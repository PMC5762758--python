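# Methods

## Mutational catalogs and motif correction

Somatic SNVs are classified into the 96 trinucleotide substitution
classes (six pyrimidine-strand substitution types × 16 flank
combinations); purine-reference variants are reverse-complemented before
classification, so a catalog is invariant under reverse-complementing the
whole variant set. N-containing contexts are excluded with a logged
tally; records whose context does not center on the reference base are
rejected with a per-record error list.

Exome catalogs are corrected for capture-target composition: each context
row is scaled by the ratio of the *relative* genome-wide frequency of its
pyrimidine-folded 3-mer to its relative frequency on the target.
Relative (not absolute) frequencies are used because target and genome
totals are not comparable; this is the only scale-invariant choice, and
it makes the correction exactly invertible (round-trip to 1e-12 is
tested). Overlapping capture intervals are merged before counting
(standard BED semantics) so no 3-mer center is counted twice, and only
the catalog — never the signature matrix — is corrected.

## Supervised signature decomposition

Exposures solve `argmin_{h≥0} ‖v − W h‖₂` (scipy's NNLS). The two-pass
scheme drops, after a first full fit, every signature whose relative
exposure is not *strictly greater* than its cutoff, then refits the
reduced set. Cutoffs are interpreted on the relative-exposure scale
(fraction of the sample's total mutations); with a cutoff of 0 any
signature with positive exposure is retained, so zero-cutoff fits
coincide with single-pass NNLS. The published per-signature cutoffs for
the 30 Alexandrov-COSMIC reference signatures are bundled as printed
constants (`COSMIC_AC_CUTOFFS`); their ROC derivation against a
7042-sample pan-cancer corpus is out of scope. If every signature is
dropped the sample is flagged degenerate with all-zero exposures and
residual ‖v‖.

### Profile-likelihood confidence intervals

Residuals of the fit are modelled as i.i.d. Gaussian with variance
`σ² = RSS₀/96` (maximum-likelihood estimate from the unperturbed model,
floored at 1e-9 so exact fits yield point-like intervals rather than a
degenerate likelihood). For a retained signature `j`, the exposure is
fixed at a perturbed value `e`, the remaining exposures refit by NNLS
(one degree of freedom less), and the likelihood-ratio statistic
`ΛR(e) = (RSS(e) − RSS₀)/σ²` referred to χ²₁. The 95% limits are the two
perturbations where the per-tail p-value reaches 0.05/2 = 0.025; the
lower limit is clipped at 0, and an upper limit that cannot be bracketed
within the geometric-expansion budget is reported as +inf (flagged
unbounded). Roots are found by a damped Gauss–Newton iteration on the
p-gap with a numeric derivative, falling back to bisection whenever the
Newton step leaves the maintained bracket; tolerance 1e-6 on the p-scale,
at most 100 iterations. Intervals are parameterized on the absolute
exposure (mutation-count) scale and recorded as such in the result
metadata; relative-scale intervals follow by dividing by the sample
total.

Calibration note: the Gaussian i.i.d. residual model is an approximation
to the true multinomial count noise, whose per-context variance is
`n·p_c(1−p_c)`. The approximation is good when the mixture probability
vector is spread out — as it is for real signature references, whose
profiles range from a few dominant peaks over a broad base to nearly flat
— and Monte-Carlo coverage at 5,000 mutations per sample is then at the
nominal 95%. For artificially spiky profiles (most mass in a handful of
contexts) the pooled variance underestimates the noise along the
perturbed direction and the intervals undercover; this is an inherited
limitation of the residual-likelihood construction, not of the root
finder.

### Enrichment

Signature "presence" in a sample means retained after pass 2 with
exposure > 0 (a stricter CI-excludes-zero notion is available via
`exposure_excludes_zero`). Cohort-vs-background presence is compared per
signature with two-sided Fisher exact tests and Benjamini–Hochberg
correction across all tested signatures; tests cross-check the p-values
against exact rational hypergeometric enumeration and the q-values
against a direct sort-based BH implementation.

## Chromothripsis calling

Input is an ordered per-chromosome segment profile with integer
copy-number states, supplied directly or derived as
`state = round(baseline · 2^log2)` (floored at 0) after an optional
whole-chromosome correction that shifts every log2 ratio by
`log2(tumor read fraction / normal read fraction)`.

"Alternating switches" are formalized as oscillation between exactly two
states: a maximal run is a contiguous stretch of segments in which every
adjacent pair differs and only two distinct states occur. The chromosome
score is the switch count of the best run (ties broken toward the denser
run), its span the distance in Mb between the run's first and last
breakpoints, where a breakpoint is the midpoint between adjacent segment
end/start. A call is positive iff `n_switches ≥ 6` and
`n_switches/span ≥ 0.2` (inclusive, since the defining worked examples —
10/50 Mb and 6/30 Mb — sit exactly at 0.2); with fewer than two switches
the ratio is defined as 0. Monotone staircases of distinct states do not
count as oscillation; the `switch_policy="any-change"` and
`run_mode="union"` options expose the alternative formalizations
(count every adjacent change; pool switches across runs) for sensitivity
analyses. The implementation is verified against an exhaustive oracle
enumerating all two-state alternating windows on profiles of up to 20
segments. The original study's two-reviewer visual assessment is replaced
by this deterministic caller; no manual override hook is provided.

## Telomeres

ALT classification uses inclusive thresholds — +pol ≥ 2×(−pol) and
+pol ≥ 3×background — and is scale-invariant in the three intensities.
How the membrane background is localized per blot is a wet-lab concern;
it enters as a provided scalar per sample, and any missing intensity
yields "not determined". Cq-to-quantity conversion (PCR efficiency
modelling) is out of scope: inputs are already-quantified T and S
signals, from which T/S ratios and the tumor-vs-control log2 ratio are
computed. Association of ALT status with a binary feature uses the
two-sided Fisher exact test after excluding not-determined samples.

## Genotype integration and WGD

The copy-number classification is a total function over
`major ≥ minor ≥ 0` (exhaustively tested up to 6): minor ≥ 1 →
normal/biallelic group; (1,0) → LOH; (2,0) → CNN-LOH; (≥3,0) →
higher-ploidy LOH; (0,0) → homozygous deletion, which is itself
biallelic inactivation. Biallelic inactivation is additionally flagged
when a gene with minor CN 0 carries a damaging lesion attributable to
the retained allele, or when both alleles of a balanced gene carry
damaging lesions. Unknown-allele lesions in LOH genes are resolved
optimistically: they count for the retained allele unless their VAF,
together with the sample purity, is incongruent (|observed − expected| >
0.1) with the retained-allele expectation
`πm/(π·CN_total + 2(1−π))`. Lesions annotated on the lost allele are
inconsistent with the copy-number state: they trigger a warning and are
ignored, which keeps the flag monotone in added lesions. Hemizygous loci
(chromosome X genes in male samples) are complete after a single hit;
hemizygosity is a caller-supplied flag since sex is sample metadata.
Expression-based surrogate inactivation calls are accepted only as
external annotations, never computed here.

WGD is positive at ploidy ≥ 2.9 with the length-weighted fraction of
major CN ≥ 2 exceeding 0.5. The source criterion is qualitative
("elevated ploidy, two or more copies of most parental-specific
chromosomes"); the numeric thresholds follow the common pan-cancer
convention and are configurable. With a supplied genome size, segment
coverage below 50% yields "not determined". Reconciliation of competing
allele-specific solutions (e.g. between two callers) is left to input
preparation.

## Variant filtering

The SNV chain applies, in fixed order: variant reads ≥ 5; VAF ≥ 5%
(inclusive, as worded); single-strand support combined with an
error-profile context; control coverage ≥ 10; control variant fraction
< 1/30 (strict); excluded-region overlap (low-mappability/blacklist);
and simultaneous overlap with ≥ 2 repeat classes. Verdicts list every
failed rule, making the filter idempotent and auditable; missing control
fields yield a not-determined verdict. The platform error-profile motifs
are not enumerated in the source description, so the context flag is
caller-supplied (an annotation step with user patterns and a ±10-base
window can populate it; with no patterns the rule never fires — the
documented default). For indels only the explicitly specified rules are
implemented: control genotype 0/0 required; PASS passes; bias flags
(badReads/alleleBias/strandBias) fail below 10% VAF (strict, as worded);
unrecognized flags are retained with a warning. The unspecified rescue
"scoring scheme" for other non-PASS flag combinations is deliberately
not invented. Region annotation is point-in-interval at `pos − 1` in
0-based half-open BED space, via interval trees.

## Synthetic cohorts

The generator produces, per seed, byte-identical TSVs plus truth tables
for all four input families. Defaults mirror the study cohort it
emulates: 49 samples, 223 mutations per sample (the cohort median;
multinomial noise keeps the total exact per sample, Poisson noise —
offered because real burdens range roughly 79–1101 — keeps it exact only
in expectation), 35% chromothripsis-positive samples (10 switches/50 Mb
when positive; flat, 3-switch, or 8-switch/100 Mb profiles when
negative), 55% WGD (ploidy ~3.9 with ~100% of a 20-segment pseudo-genome
at major ≥ 2, vs ploidy ~2.0 and ~25%), and 78% ALT-positive (38/49).
Signature profiles are Dirichlet(1) draws over the 96 contexts —
spread-out profiles comparable in flatness to real references (see the
calibration note above). Genotype templates cycle through all five
copy-number classes with lesion plans whose VAFs are drawn congruent
with purity. Coordinates live on a single 250-Mb pseudo-chromosome so no
reference genome is required, and positions are randomized per sample.

What the simulations do *not* emulate: sequencing-level artifacts (no
reads are simulated), inter-sample burden variation under the default
multinomial model, segmentation noise in copy-number profiles (segments
are exact), correlated lesion co-occurrence across genes, and dot-blot
measurement error structure beyond independent lognormal intensities.
Passing closed-loop tests therefore demonstrates internal consistency of
the decision rules and estimators at realistic signal levels, not
robustness to upstream calling errors.

## Problem sizes in the test suite

The suite runs in well under a minute on one core: CI coverage uses 200
samples at 5,000 mutations (600 intervals), two-pass behaviour 100
random mixtures, the Fisher cross-check enumerates all 2×2 tables with
row margins ≤ 12, the chromothripsis oracle checks 200 random profiles
of ≤ 20 segments, and the filter fixture plants violations in 50
records. These sizes give stable verdicts for every stochastic check at
the stated tolerances.
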