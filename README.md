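# lmskit

A Python toolkit for the bespoke computational stages of integrative
somatic tumor-genome studies of genomically unstable sarcomas
(leiomyosarcoma-style cohorts): supervised mutational-signature
decomposition with confidence intervals, chromothripsis calling from
segmented copy number, ALT classification from C-circle assays, telomere
content from qPCR, multi-evidence biallelic-inactivation and
whole-genome-duplication genotyping, and heuristic somatic-variant
filtering. A synthetic-data module generates cohorts with known truth for
every stage, so the whole pipeline runs and is testable without access to
controlled patient data.

Intended users are cancer-genomics analysts who already have upstream
calls — somatic SNVs/indels, segmented copy-number profiles,
allele-specific copy numbers, C-circle and qPCR measurements — and need
the downstream statistical integration.

## What it computes

**Signature decomposition** (`lmskit.sigfit`). A sample's mutational
catalog `v` (counts over the 96 trinucleotide substitution classes,
optionally motif-corrected for exome capture via `lmskit.catalog`) is
modelled as `v ≈ W h` with a fixed column-stochastic signature matrix `W`
and non-negative exposures `h` fitted by NNLS. The fit runs twice:
signatures whose relative exposure `h_s / Σv` does not exceed a
per-signature cutoff (the published Alexandrov-COSMIC cutoffs ship as
`COSMIC_AC_CUTOFFS`) are dropped, and the reduced set is refitted. 95%
confidence intervals come from profile likelihoods: one exposure is
perturbed and fixed, the rest refit, residuals scored under an i.i.d.
Gaussian likelihood, and a 1-df likelihood-ratio test located at p =
0.05/2 per tail. Cohort-vs-background presence of each signature is
tested by two-sided Fisher exact tests with Benjamini–Hochberg
correction.

**Chromothripsis** (`lmskit.chromothripsis`). Per chromosome, the caller
counts copy-number state switches oscillating between exactly two states
and is positive when `n_switches ≥ 6` and `n_switches / span(Mb) ≥ 0.2`
— equivalently at least ten alternating switches within 50 Mb, or six
within 30 Mb. Whole-chromosome log2-ratio shifts are corrected from
per-chromosome read fractions.

**Telomeres** (`lmskit.telomere`). A sample is ALT-positive when its
C-circle +pol signal is at least twice the −pol control and at least
three times background (inclusive). Telomere content is the qPCR T/S
ratio; tumor-vs-control log2 T/S ratios quantify gain or loss.

**Genotype integration** (`lmskit.genotype`). Allele-specific copy
numbers map to LOH (1+0), CNN-LOH (2+0), higher-ploidy LOH (≥3+0),
normal/biallelic (minor ≥ 1) or homozygous deletion (0+0). Biallelic
inactivation requires a damaging lesion on the retained allele under LOH
(unknown-allele lesions resolved by VAF-vs-purity congruence,
`expected VAF = πm / (π·CN_total + 2(1−π))`), lesions on both alleles
otherwise, or homozygous deletion. WGD is called at ploidy ≥ 2.9 with
major copy ≥ 2 over more than half of the assessed genome.

**Variant filtering** (`lmskit.varfilter`). SNV candidates must show ≥ 5
variant reads, VAF ≥ 5%, no single-strand support in an error-profile
context, control coverage ≥ 10 with < 1/30 of control bases supporting
the variant, and no overlap with excluded regions or with two repeat
classes at once. Indels need control genotype 0/0 and either a PASS flag
or no bias flag (badReads/alleleBias/strandBias) at VAF < 10%.

## Worked example

```sh
python examples/signature_fitting.py
```

```
true mixture: S1=0.50  S2=0.30  S3=0.20  (223 mutations/sample)

sample   sig   exposure    rel             95% CI  excl. 0
SIM01    S1       107.3   0.48  [   81.9,  132.8]  yes
SIM01    S2        68.3   0.31  [   43.1,   93.4]  yes
SIM01    S3        47.8   0.21  [   22.6,   72.9]  yes

SIM02    S1       128.6   0.58  [   97.7,  159.5]  yes
SIM02    S2        70.1   0.31  [   39.6,  100.5]  yes
SIM02    S3        22.9   0.10  [    0.0,   53.3]  no
...
cohort mean relative exposures: [0.485 0.34  0.175]
```

Each `exposure` is the number of a sample's 223 mutations attributed to a
signature; `rel` divides by the sample total. The interval for SIM02/S3
touches zero — at 223 mutations a 20% process is not always securely
detectable in a single exome, which is why the cohort-level view matters.
The other examples (`chromothripsis_calling.py`, `telomere_alt.py`,
`genotype_wgd.py`, `variant_filtering.py`, `catalog_normalization.py`)
exercise the remaining modules the same way, one capability per script.

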