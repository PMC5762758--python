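"""Run the heuristic somatic SNV filter chain on illustrative candidates.

Builds a handful of candidate SNVs — one clean, the rest each violating a
single rule — annotates them against toy region tracks, and prints the
verdicts with the rules they failed.
"""

from lmskit.varfilter import (
    CandidateIndel,
    CandidateSnv,
    RegionIndex,
    annotate_regions,
    filter_indel,
    filter_snvs,
)

candidates = [
    CandidateSnv("chr1", 1000, "C", "T", 20, 100, 12, 8, 60, 0),     # clean
    CandidateSnv("chr1", 2000, "C", "A", 4, 40, 2, 2, 60, 0),        # 4 variant reads
    CandidateSnv("chr1", 3000, "G", "A", 10, 250, 5, 5, 60, 0),      # VAF 4%
    CandidateSnv("chr1", 4000, "C", "T", 20, 100, 20, 0, 60, 0,
                 error_profile_context=True),                         # one strand + error context
    CandidateSnv("chr1", 5000, "C", "T", 20, 100, 12, 8, 9, 0),      # control coverage 9
    CandidateSnv("chr1", 6000, "C", "T", 20, 100, 12, 8, 60, 2),     # 2/60 control support
    CandidateSnv("chr1", 7000, "C", "T", 20, 100, 12, 8, 60, 0),     # lands in two repeat tracks
]

regions = RegionIndex({
    "simple-repeat": [("chr1", 6900, 7100)],
    "low-complexity": [("chr1", 6950, 7050)],
})
candidates = annotate_regions(candidates, regions)

print(f"{'position':<12} {'reads':>7} {'VAF':>6}  verdict")
for c, verdict in zip(candidates, filter_snvs(candidates)):
    out = "PASS" if verdict.passed else "fail: " + ", ".join(verdict.failed_rules)
    print(f"{c.chrom}:{c.pos:<7} {c.tumor_var_reads:>3}/{c.tumor_total_reads:<3} "
          f"{c.vaf:>6.2f}  {out}")

indel = CandidateIndel("chr2", 500, "A", "AT", {"alleleBias"}, "0/0", vaf=0.08)
print(f"\nindel chr2:500 alleleBias at VAF 0.08 -> "
      f"{'PASS' if filter_indel(indel).passed else 'fail (bias flag below 10% VAF)'}")
print("A candidate must clear every rule: >=5 variant reads, VAF >= 5%, no "
      "single-strand artifact context, control coverage >= 10 with < 1/30 "
      "variant support, and no excluded-region or double-repeat overlap.")
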