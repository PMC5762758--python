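"""Trinucleotide-context conventions for somatic SNV catalogs.

Somatic single-base substitutions are classified into 96 classes: six
pyrimidine-strand substitution types (C>A, C>G, C>T, T>A, T>C, T>G) times
the 4 x 4 combinations of the immediate 5' and 3' flanking bases.
Substitutions whose reference base is a purine are reverse-complemented
onto the pyrimidine strand before classification, so e.g. G>A in context
TGT is the same class as C>T in context ACA.

The row order used throughout the package is the conventional one of
public signature references: grouped by substitution type, flanks in
alphabetical order within each group.
"""

from __future__ import annotations

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"

#: The 96 substitution classes, labelled "A[C>A]A" style.
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

#: The 32 pyrimidine-centered 3-mers (16 C-centered + 16 T-centered).
PYRIMIDINE_TRIPLETS: tuple[str, ...] = tuple(
    f"{five}{mid}{three}" for mid in PYRIMIDINES for five in BASES for three in BASES
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fold_triplet(triplet: str) -> str:
    """Fold a 3-mer onto the pyrimidine strand.

    Purine-centered 3-mers are reverse-complemented; pyrimidine-centered
    ones pass through. Raises ValueError for non-ACGT bases (callers decide
    whether to skip N-containing 3-mers).
    """
    if len(triplet) != 3:
        raise ValueError(f"not a 3-mer: {triplet!r}")
    t = triplet.upper()
    if any(b not in BASES for b in t):
        raise ValueError(f"non-ACGT base in 3-mer: {triplet!r}")
    return t if t[1] in PYRIMIDINES else reverse_complement(t)


def context_label(ref: str, alt: str, context: str) -> str:
    """96-class label for a substitution given its reference-strand 3-mer.

    ``context`` is the reference 3-mer centered on the variant position and
    must have ``ref`` as its middle base. Purine-reference substitutions are
    folded to the pyrimidine strand.
    """
    ref, alt = ref.upper(), alt.upper()
    ctx = context.upper()
    if len(ctx) != 3 or ctx[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt: {ref!r}")
    for b in (ref, alt, *ctx):
        if b not in BASES:
            raise ValueError(f"non-ACGT base in {ref}>{alt} {context!r}")
    if ref in PURINES:
        ctx = reverse_complement(ctx)
        ref = ctx[1]
        alt = reverse_complement(alt)
    sub = f"{ref}>{alt}"
    if sub not in SUBSTITUTIONS:
        raise ValueError(f"invalid substitution {sub}")
    return f"{ctx[0]}[{sub}]{ctx[2]}"


def triplet_of_context(label: str) -> str:
    """The pyrimidine 3-mer underlying a 96-class label, e.g. A[C>T]A -> ACA."""
    return label[0] + label[2] + label[6]
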