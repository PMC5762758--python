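"""Fit mutational signatures to a synthetic cohort, with confidence intervals.

Simulates 12 exomes carrying a known three-signature mixture (50/30/20%,
223 mutations each, multinomial noise), decomposes each catalog by
two-pass NNLS, and prints the fitted relative exposures with 95%
profile-likelihood confidence intervals for the first few samples.
"""

import numpy as np

from lmskit.sigfit import exposure_excludes_zero, supervised_decompose
from lmskit.simdata import SimConfig, simulate_catalogs, synthetic_signature_set

signatures = synthetic_signature_set(3, seed=0)
config = SimConfig(seed=42, n_samples=12, signature_mix={"S1": 0.5, "S2": 0.3, "S3": 0.2})
catalog, truth = simulate_catalogs(config, signatures)

results = supervised_decompose(catalog, signatures, compute_ci=True)

print("true mixture: S1=0.50  S2=0.30  S3=0.20  (223 mutations/sample)\n")
print(f"{'sample':<8} {'sig':<4} {'exposure':>9} {'rel':>6}  {'95% CI':>17}  excl. 0")
for res in results[:4]:
    for sig in res.retained:
        lo, hi = res.cis[sig]
        flag = "yes" if exposure_excludes_zero(res, sig) else "no"
        print(
            f"{res.sample:<8} {sig:<4} {res.exposure(sig):>9.1f} "
            f"{res.relative_exposure(sig):>6.2f}  [{lo:>7.1f},{hi:>7.1f}]  {flag}"
        )
    print()

rel = np.array([r.relative_exposures for r in results])
print("cohort mean relative exposures:", np.round(rel.mean(axis=0), 3))
print(
    "Each row attributes a sample's mutations to a signature; an interval\n"
    "excluding zero means the signature's contribution is statistically secure."
)
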