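"""Supervised mutational-signature decomposition.

A sample's 96-context mutational catalog v is modelled as a non-negative
linear combination of fixed reference signatures W (column-stochastic,
96 x S): v ~ W h with exposures h >= 0 fitted by non-negative least
squares (NNLS). To increase specificity the fit is run twice: after the
first pass only signatures whose relative exposure (exposure divided by
the sample's total mutation count) exceeds a per-signature cutoff are
kept, and the NNLS is re-run on the reduced signature set.

95% confidence intervals for the retained exposures use profile
likelihoods: the exposure of one signature is perturbed and held fixed,
the remaining exposures are refit by NNLS (a model with one degree of
freedom less), residuals are scored under an i.i.d. Gaussian likelihood,
and a 1-df likelihood-ratio test locates the perturbations where the
per-tail p-value reaches alpha/2.

Cohort-level enrichment of signature presence against a background corpus
is tested per signature with two-sided Fisher exact tests and
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .catalog import MutationalCatalog
from .contexts import CONTEXTS_96

#: Relative-exposure retention cutoffs for the 30 reference signatures
#: (AC = Alexandrov-COSMIC), derived externally by ROC analysis against a
#: 7042-sample pan-cancer corpus and taken here as fixed constants.
COSMIC_AC_CUTOFFS: dict[str, float] = {
    "AC1": 0.0,
    "AC2": 0.03404847,
    "AC3": 0.139839,
    "AC4": 0.02281439,
    "AC5": 0.0,
    "AC6": 0.003660315,
    "AC7": 0.02841319,
    "AC8": 0.1870989,
    "AC9": 0.0953648,
    "AC10": 0.0164065,
    "AC11": 0.08238725,
    "AC12": 0.1920715,
    "AC13": 0.03769936,
    "AC14": 0.03080224,
    "AC15": 0.03182855,
    "AC16": 0.3553548,
    "AC17": 0.004075963,
    "AC18": 0.2692715,
    "AC19": 0.04038686,
    "AC20": 0.05066134,
    "AC21": 0.04219805,
    "AC22": 0.03908793,
    "AC23": 0.03900049,
    "AC24": 0.04254174,
    "AC25": 0.02448377,
    "AC26": 0.02830282,
    "AC27": 0.02223076,
    "AC28": 0.0315642,
    "AC29": 0.07392201,
    "AC30": 0.06332517,
}

_VARIANCE_FLOOR = 1e-9


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class SignatureSet:
    """A fixed reference signature matrix with per-signature cutoffs.

    ``matrix`` is 96 x S, indexed by the 96 context labels, each column a
    probability profile summing to 1; ``cutoffs`` maps every signature to
    its relative-exposure retention threshold in [0, 1).
    """

    matrix: pd.DataFrame
    cutoffs: pd.Series

    def __post_init__(self):
        if list(self.matrix.index) != list(CONTEXTS_96):
            raise SignatureError("signature matrix must have the 96 context rows in order")
        w = self.matrix.to_numpy(dtype=float)
        if (w < 0).any():
            raise SignatureError("signature columns must be non-negative")
        sums = w.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = list(self.matrix.columns[np.abs(sums - 1.0) > 1e-6])
            raise SignatureError(f"signature columns must sum to 1: {bad}")
        object.__setattr__(self, "cutoffs", self.cutoffs.astype(float))
        missing = [s for s in self.matrix.columns if s not in self.cutoffs.index]
        if missing:
            raise SignatureError(f"no cutoff defined for signature(s) {missing}")
        cut = self.cutoffs.loc[list(self.matrix.columns)]
        if ((cut < 0) | (cut >= 1)).any():
            raise SignatureError("cutoffs must lie in [0, 1)")

    @property
    def ids(self) -> list[str]:
        return list(self.matrix.columns)

    def subset(self, ids: Sequence[str]) -> "SignatureSet":
        return SignatureSet(self.matrix[list(ids)], self.cutoffs.loc[list(ids)])

    @classmethod
    def read_tsv(cls, matrix_path, cutoffs=None) -> "SignatureSet":
        """Load a signature matrix TSV (first column context labels).

        ``cutoffs`` may be a path to a two-column TSV (signature, cutoff),
        a mapping, or None for all-zero cutoffs (plain NNLS behaviour).
        """
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0).reindex(CONTEXTS_96)
        if cutoffs is None:
            cut = pd.Series(0.0, index=mat.columns)
        elif isinstance(cutoffs, (str,)) or hasattr(cutoffs, "__fspath__"):
            df = pd.read_csv(cutoffs, sep="\t", index_col=0)
            cut = df.iloc[:, 0]
        else:
            cut = pd.Series(dict(cutoffs))
        return cls(mat, cut)


@dataclass
class ExposureResult:
    """Per-sample decomposition result.

    ``exposures`` is aligned with ``signatures`` (the full candidate set);
    dropped signatures carry exposure exactly 0. Confidence intervals, when
    computed, are stored per retained signature as (lower, upper) on the
    absolute exposure scale (mutation counts); an unbounded side is +inf.
    """

    sample: str
    signatures: tuple[str, ...]
    exposures: np.ndarray
    retained: tuple[str, ...]
    total_mutations: float
    residual: np.ndarray
    degenerate: bool = False
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_parameterization: str = "absolute exposure (mutation counts)"

    @property
    def relative_exposures(self) -> np.ndarray:
        if self.total_mutations <= 0:
            return np.zeros_like(self.exposures)
        return self.exposures / self.total_mutations

    def exposure(self, signature: str) -> float:
        return float(self.exposures[self.signatures.index(signature)])

    def relative_exposure(self, signature: str) -> float:
        return float(self.relative_exposures[self.signatures.index(signature)])

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.residual))


def nnls_fit(v: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, float]:
    """argmin_{h>=0} ||v - W h||_2 together with the residual norm."""
    v = np.asarray(v, dtype=float)
    W = np.asarray(W, dtype=float)
    if v.ndim != 1 or W.ndim != 2 or W.shape[0] != v.shape[0]:
        raise SignatureError(
            f"dimension mismatch: v has shape {v.shape}, W has shape {W.shape}"
        )
    if W.shape[1] == 0:
        return np.zeros(0), float(np.linalg.norm(v))
    h, rnorm = optimize.nnls(W, v)
    return h, float(rnorm)


def supervised_decompose(
    catalog: MutationalCatalog | pd.DataFrame,
    signatures: SignatureSet,
    *,
    compute_ci: bool = False,
    alpha: float = 0.05,
) -> list[ExposureResult]:
    """Two-pass NNLS decomposition of every sample in a catalog.

    Pass 1 fits all signatures; signatures whose relative exposure is not
    strictly greater than their cutoff are removed (a cutoff of 0 therefore
    retains any signature with positive exposure); pass 2 refits the
    retained set. Samples where every signature is removed are flagged
    degenerate with all-zero exposures.
    """
    counts = catalog.counts if isinstance(catalog, MutationalCatalog) else catalog
    W = signatures.matrix.to_numpy(dtype=float)
    ids = signatures.ids
    cutoffs = signatures.cutoffs.loc[ids].to_numpy(dtype=float)
    results = []
    for sample in counts.columns:
        v = counts[sample].to_numpy(dtype=float)
        total = float(v.sum())
        if total <= 0:
            raise SignatureError(f"sample {sample!r} has non-positive total mutation count")
        h1, _ = nnls_fit(v, W)
        keep = (h1 / total) > cutoffs
        if not keep.any():
            res = ExposureResult(
                sample=sample,
                signatures=tuple(ids),
                exposures=np.zeros(len(ids)),
                retained=(),
                total_mutations=total,
                residual=v.copy(),
                degenerate=True,
            )
            results.append(res)
            continue
        Wk = W[:, keep]
        h2, _ = nnls_fit(v, Wk)
        exposures = np.zeros(len(ids))
        exposures[keep] = h2
        retained = tuple(s for s, k in zip(ids, keep) if k)
        res = ExposureResult(
            sample=sample,
            signatures=tuple(ids),
            exposures=exposures,
            retained=retained,
            total_mutations=total,
            residual=v - Wk @ h2,
        )
        if compute_ci:
            ci = exposure_ci(v, Wk, h2, alpha=alpha)
            res.cis = {sig: (float(lo), float(hi)) for sig, (lo, hi) in zip(retained, ci)}
        results.append(res)
    return results


def _profile_rss(v: np.ndarray, W: np.ndarray, j: int, e: float) -> float:
    """Residual sum of squares with exposure j fixed at e, others refit."""
    r = v - e * W[:, j]
    Wrest = np.delete(W, j, axis=1)
    if Wrest.shape[1] == 0:
        return float(r @ r)
    _, rnorm = optimize.nnls(Wrest, r)
    return float(rnorm**2)


def profile_likelihood_p(
    v: np.ndarray, W: np.ndarray, h: np.ndarray, j: int, e: float
) -> float:
    """p-value of the 1-df likelihood-ratio test for perturbing exposure j to e.

    The Gaussian residual variance is the maximum-likelihood estimate from
    the unperturbed (initial) model, floored to avoid degeneracy on exact
    fits. At e = h[j] the statistic is 0 and p = 1.
    """
    v = np.asarray(v, dtype=float)
    W = np.asarray(W, dtype=float)
    r0 = v - W @ np.asarray(h, dtype=float)
    rss0 = float(r0 @ r0)
    sigma2 = max(rss0 / v.shape[0], _VARIANCE_FLOOR)
    lr = max(_profile_rss(v, W, j, e) - rss0, 0.0) / sigma2
    return float(stats.chi2.sf(lr, df=1))


def _root_on_p(pfun, lo: float, hi: float, target: float, tol: float, max_iter: int):
    """Find e in [lo, hi] with pfun(e) = target by damped Gauss-Newton.

    pfun is monotone between the bracket ends; a bisection step is taken
    whenever the Newton update leaves the bracket or the derivative
    vanishes. Returns the root (within ``tol`` on the p-scale when
    converged; the final bracket midpoint otherwise).
    """
    flo = pfun(lo) - target
    fhi = pfun(hi) - target
    if flo * fhi > 0:
        return hi
    x = 0.5 * (lo + hi)
    for _ in range(max_iter):
        fx = pfun(x) - target
        if abs(fx) < tol:
            return x
        if flo * fx <= 0:
            hi, fhi = x, fx
        else:
            lo, flo = x, fx
        step = max(abs(hi - lo) * 1e-3, 1e-12)
        d = (pfun(x + step) - pfun(x - step)) / (2 * step)
        if d != 0.0:
            xn = x - fx / d
            if not (min(lo, hi) < xn < max(lo, hi)):
                xn = 0.5 * (lo + hi)
        else:
            xn = 0.5 * (lo + hi)
        x = xn
    return 0.5 * (lo + hi)


def exposure_ci(
    v: np.ndarray,
    W: np.ndarray | pd.DataFrame,
    h: np.ndarray,
    *,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Profile-likelihood confidence intervals for retained exposures.

    For each column j of the retained matrix W the exposure is perturbed
    away from its point estimate h[j], the other exposures are refit, and
    the limits are the perturbations where the 1-df likelihood-ratio
    p-value reaches alpha/2 per tail. The lower limit is bounded below at
    0; an upper limit that cannot be bracketed within the expansion budget
    is reported as +inf (unbounded).

    Returns an array of shape (k, 2) with (lower, upper) rows aligned with
    the columns of W, on the absolute-exposure (mutation count) scale.
    """
    v = np.asarray(v, dtype=float)
    W = np.asarray(W, dtype=float)
    h = np.asarray(h, dtype=float)
    n, k = W.shape
    r0 = v - W @ h
    rss0 = float(r0 @ r0)
    sigma2 = max(rss0 / n, _VARIANCE_FLOOR)
    p_target = alpha / 2.0
    out = np.empty((k, 2))
    scale = max(float(v.sum()), 1.0)
    for j in range(k):

        def pfun(e, j=j):
            lr = max(_profile_rss(v, W, j, float(e)) - rss0, 0.0) / sigma2
            return float(stats.chi2.sf(lr, df=1))

        hj = float(h[j])
        # lower limit: clipped at 0 when even e = 0 is not rejected
        if pfun(0.0) > p_target:
            lo = 0.0
        else:
            lo = float(_root_on_p(pfun, 0.0, hj, p_target, tol, max_iter))
        # upper limit: expand a bracket geometrically, then root-find
        step = max(0.05 * scale, 1.0)
        hi_edge = hj + step
        expansions = 0
        while pfun(hi_edge) > p_target and expansions < 60:
            step *= 2.0
            hi_edge = hj + step
            expansions += 1
        if pfun(hi_edge) > p_target:
            hi = math.inf
        else:
            hi = float(_root_on_p(pfun, hj, hi_edge, p_target, tol, max_iter))
        out[j] = (max(lo, 0.0), hi)
    return out


def exposure_excludes_zero(result: ExposureResult, signature: str) -> bool:
    """True iff the signature was retained and its CI lower bound is > 0."""
    if signature not in result.retained:
        return False
    ci = result.cis.get(signature)
    if ci is None:
        raise SignatureError(
            f"no confidence interval computed for {signature!r} in sample {result.sample!r}"
        )
    return ci[0] > 0.0


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-signature cohort-vs-background presence comparison."""

    table: pd.DataFrame  # columns: cohort_present, cohort_absent, background_present, background_absent, odds_ratio, p_value, q_value


def cohort_enrichment(
    cohort_presence: Mapping[str, int],
    background_presence: Mapping[str, int],
    cohort_n: int,
    background_n: int,
) -> EnrichmentResult:
    """Fisher exact enrichment of signature presence vs a background corpus.

    ``cohort_presence``/``background_presence`` give, per signature, the
    number of samples in which the signature is present (by default:
    retained with exposure > 0). Two-sided p-values are BH-adjusted across
    all tested signatures.
    """
    if cohort_n <= 0:
        raise SignatureError("cohort size must be positive")
    if background_n <= 0:
        raise SignatureError("background size must be positive")
    sigs = sorted(set(cohort_presence) | set(background_presence))
    rows = []
    for sig in sigs:
        a = int(cohort_presence.get(sig, 0))
        c = int(background_presence.get(sig, 0))
        if a > cohort_n or c > background_n:
            raise SignatureError(f"presence count exceeds cohort size for {sig}")
        b, d = cohort_n - a, background_n - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((sig, a, b, c, d, odds, p))
    df = pd.DataFrame(
        rows,
        columns=[
            "signature",
            "cohort_present",
            "cohort_absent",
            "background_present",
            "background_absent",
            "odds_ratio",
            "p_value",
        ],
    ).set_index("signature")
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return EnrichmentResult(df)


def signature_presence(results: Sequence[ExposureResult]) -> dict[str, int]:
    """Count, per signature, the samples where it is retained with exposure > 0."""
    counts: dict[str, int] = {}
    for res in results:
        for sig in res.retained:
            if res.exposure(sig) > 0:
                counts[sig] = counts.get(sig, 0) + 1
    return counts


def exposures_to_frame(results: Sequence[ExposureResult]) -> pd.DataFrame:
    """Long-format table of exposures, relative exposures and CI limits."""
    rows = []
    for res in results:
        for sig in res.signatures:
            exp = res.exposure(sig)
            lo, hi = res.cis.get(sig, (np.nan, np.nan))
            rows.append(
                (res.sample, sig, exp, exp / res.total_mutations, lo, hi, sig in res.retained)
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "signature", "exposure", "rel_exposure", "ci_lo", "ci_hi", "retained"],
    )
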