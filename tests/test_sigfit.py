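"""Supervised NNLS decomposition, profile-likelihood CIs, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import bh_adjust, fisher_two_sided_exact, restricted_nnls

from lmskit.sigfit import (
    SignatureError,
    SignatureSet,
    cohort_enrichment,
    exposure_ci,
    exposure_excludes_zero,
    nnls_fit,
    profile_likelihood_p,
    supervised_decompose,
)
from lmskit.catalog import MutationalCatalog
from lmskit.contexts import CONTEXTS_96
from lmskit.simdata import SimConfig, simulate_catalogs, synthetic_signature_set


def catalog_from_vector(v, sample="T1"):
    return MutationalCatalog(
        pd.DataFrame({sample: np.asarray(v, dtype=float)}, index=list(CONTEXTS_96))
    )


class TestNnlsFit:
    def test_exact_single_signature(self, sigset3):
        W = sigset3.matrix.to_numpy()
        h, rnorm = nnls_fit(100.0 * W[:, 0], W)
        np.testing.assert_allclose(h, [100.0, 0.0, 0.0], atol=1e-8)
        assert rnorm < 1e-8

    def test_zero_vector_gives_zero_exposures(self, sigset3):
        h, rnorm = nnls_fit(np.zeros(96), sigset3.matrix.to_numpy())
        np.testing.assert_allclose(h, 0.0)
        assert rnorm == 0.0

    def test_exact_two_component_mixture(self, sigset3):
        W = sigset3.matrix.to_numpy()
        v = 60.0 * W[:, 0] + 40.0 * W[:, 1]
        h, rnorm = nnls_fit(v, W)
        np.testing.assert_allclose(h, [60.0, 40.0, 0.0], atol=1e-8)
        assert rnorm < 1e-8

    def test_dimension_mismatch_raises(self, sigset3):
        with pytest.raises(SignatureError, match="dimension"):
            nnls_fit(np.zeros(95), sigset3.matrix.to_numpy())

    def test_residual_never_increases_with_more_signatures(self, sigset5, rng):
        W = sigset5.matrix.to_numpy()
        v = rng.uniform(0, 10, size=96)
        for k in range(1, 6):
            _, r_small = nnls_fit(v, W[:, : k - 1]) if k > 1 else (None, np.linalg.norm(v))
            _, r_big = nnls_fit(v, W[:, :k])
            assert r_big <= r_small + 1e-10

    def test_exposures_scale_linearly_with_input(self, sigset3, rng):
        W = sigset3.matrix.to_numpy()
        v = rng.uniform(0, 10, size=96)
        h1, _ = nnls_fit(v, W)
        h2, _ = nnls_fit(3.5 * v, W)
        np.testing.assert_allclose(h2, 3.5 * h1, rtol=1e-8, atol=1e-10)


class TestSupervisedDecompose:
    def test_zero_cutoffs_match_single_pass(self, sigset3):
        W = sigset3.matrix.to_numpy()
        v = 150.0 * W[:, 0] + 70.0 * W[:, 2]
        res = supervised_decompose(catalog_from_vector(v), sigset3)[0]
        h_direct, _ = nnls_fit(v, W)
        np.testing.assert_allclose(res.exposures, h_direct, atol=1e-8)
        # with cutoff 0, anything with positive (even epsilon) exposure is kept
        assert {"S1", "S3"} <= set(res.retained)
        assert res.exposure("S1") == pytest.approx(150.0, abs=1e-6)
        assert res.exposure("S3") == pytest.approx(70.0, abs=1e-6)

    def test_subthreshold_signature_dropped_at_printed_cutoff(self, sigset3):
        """A 5% relative exposure falls below the HRR-signature cutoff 0.139839."""
        cutoffs = {"S1": 0.0, "S2": 0.139839, "S3": 0.0}
        sigs = SignatureSet(sigset3.matrix, pd.Series(cutoffs))
        W = sigs.matrix.to_numpy()
        v = 1000.0 * (0.95 * W[:, 0] + 0.05 * W[:, 1])
        res = supervised_decompose(catalog_from_vector(v), sigs)[0]
        assert "S2" not in res.retained
        assert res.exposure("S2") == 0.0
        # the same mixture with zero cutoff retains the minor signature
        res0 = supervised_decompose(catalog_from_vector(v), sigset3)[0]
        assert "S2" in res0.retained

    def test_pass2_matches_restricted_oracle_on_random_mixtures(self, sigset5, rng):
        """Two-pass exposures equal an NNLS restricted to the retained set."""
        W = sigset5.matrix.to_numpy()
        ids = sigset5.ids
        cutoffs = pd.Series(rng.uniform(0.0, 0.15, size=5), index=ids)
        sigs = SignatureSet(sigset5.matrix, cutoffs)
        for _ in range(100):
            weights = rng.dirichlet(np.ones(5)) * rng.uniform(0.5, 1.0)
            v = rng.poisson(2000.0 * (W @ weights)).astype(float)
            if v.sum() == 0:
                continue
            res = supervised_decompose(catalog_from_vector(v), sigs)[0]
            h1, _ = nnls_fit(v, W)
            keep = (h1 / v.sum()) > cutoffs.to_numpy()
            oracle = restricted_nnls(v, W, keep)
            np.testing.assert_allclose(res.exposures, oracle, atol=1e-8)

    def test_noise_free_support_recovery(self, sigset3):
        W = sigset3.matrix.to_numpy()
        v = 2000.0 * (0.7 * W[:, 0] + 0.3 * W[:, 1])
        res = supervised_decompose(catalog_from_vector(v), sigset3)[0]
        oracle = restricted_nnls(v, W, [True, True, False])
        np.testing.assert_allclose(res.exposures, oracle, atol=1e-8)

    def test_pass2_residual_at_least_pass1(self, sigset5, rng):
        W = sigset5.matrix.to_numpy()
        cutoffs = pd.Series(0.1, index=sigset5.ids)
        sigs = SignatureSet(sigset5.matrix, cutoffs)
        v = rng.poisson(500.0 * (W @ rng.dirichlet(np.ones(5)))).astype(float)
        res = supervised_decompose(catalog_from_vector(v), sigs)[0]
        _, r1 = nnls_fit(v, W)
        assert res.residual_norm >= r1 - 1e-10

    def test_all_dropped_is_flagged_degenerate(self, sigset3):
        cutoffs = pd.Series(0.99, index=sigset3.ids)
        sigs = SignatureSet(sigset3.matrix, cutoffs)
        W = sigs.matrix.to_numpy()
        v = 90.0 * W[:, 0] + 60.0 * W[:, 1] + 50.0 * W[:, 2]
        res = supervised_decompose(catalog_from_vector(v), sigs)[0]
        assert res.degenerate
        assert res.retained == ()
        np.testing.assert_allclose(res.exposures, 0.0)
        assert res.residual_norm == pytest.approx(np.linalg.norm(v))

    def test_parameter_recovery_mae(self, sigset3):
        """Mean absolute error of relative exposures < 0.03 on a synthetic cohort."""
        cfg = SimConfig(
            seed=11,
            n_samples=50,
            mutations_per_sample=2000,
            signature_mix={"S1": 0.5, "S2": 0.3, "S3": 0.2},
        )
        cat, truth = simulate_catalogs(cfg, sigset3)
        res = supervised_decompose(cat, sigset3)
        tm = truth.set_index(["sample", "signature"])["true_rel_exposure"]
        errs = [
            abs(r.relative_exposure(s) - tm[(r.sample, s)])
            for r in res
            for s in r.signatures
        ]
        assert np.mean(errs) < 0.03


class TestExposureCi:
    def test_unperturbed_model_has_p_one(self, sigset3):
        W = sigset3.matrix.to_numpy()
        v = np.round(500.0 * (0.6 * W[:, 0] + 0.4 * W[:, 1]))
        h, _ = nnls_fit(v, W)
        assert profile_likelihood_p(v, W, h, 0, float(h[0])) == pytest.approx(1.0)

    def test_ci_contains_point_estimate(self, sigset3, rng):
        W = sigset3.matrix.to_numpy()
        v = rng.poisson(1000.0 * (W @ np.array([0.5, 0.3, 0.2]))).astype(float)
        h, _ = nnls_fit(v, W)
        ci = exposure_ci(v, W, h)
        for j, (lo, hi) in enumerate(ci):
            assert lo <= h[j] <= hi
            assert lo >= 0.0

    def test_exact_fit_yields_tight_interval(self, sigset3):
        """With the variance floored on an exact fit, the CI collapses to the point."""
        W = sigset3.matrix.to_numpy()
        v = 300.0 * W[:, 0]
        h, _ = nnls_fit(v, W[:, :1])
        ci = exposure_ci(v, W[:, :1], h)
        lo, hi = ci[0]
        assert hi - lo < 1.0

    def test_excludes_zero_flag(self, sigset3):
        cfg = SimConfig(seed=3, n_samples=1, mutations_per_sample=5000)
        cat, _ = simulate_catalogs(cfg, sigset3)
        res = supervised_decompose(cat, sigset3, compute_ci=True)[0]
        for sig in res.retained:
            lo, _ = res.cis[sig]
            assert exposure_excludes_zero(res, sig) == (lo > 0)
        dropped = [s for s in res.signatures if s not in res.retained]
        for sig in dropped:
            assert not exposure_excludes_zero(res, sig)


class TestEnrichment:
    def test_identical_proportions_give_p_one(self):
        res = cohort_enrichment({"S1": 10}, {"S1": 10}, 20, 20)
        assert res.table.loc["S1", "p_value"] == pytest.approx(1.0)

    def test_matches_exhaustive_hypergeometric(self):
        res = cohort_enrichment({"S1": 8}, {"S1": 2}, 10, 10)
        expected = fisher_two_sided_exact([[8, 2], [2, 8]])
        assert res.table.loc["S1", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_bh_is_monotone_in_p_rank(self, rng):
        cohort = {f"S{i}": int(rng.integers(0, 21)) for i in range(8)}
        background = {f"S{i}": int(rng.integers(0, 101)) for i in range(8)}
        res = cohort_enrichment(cohort, background, 20, 100)
        df = res.table.sort_values("p_value")
        assert (np.diff(df["q_value"].to_numpy()) >= -1e-12).all()
        assert (df["q_value"] >= df["p_value"] - 1e-12).all()

    def test_bh_matches_sort_based_oracle(self, rng):
        cohort = {f"S{i}": int(rng.integers(0, 16)) for i in range(10)}
        background = {f"S{i}": int(rng.integers(0, 200)) for i in range(10)}
        res = cohort_enrichment(cohort, background, 15, 200)
        np.testing.assert_allclose(
            res.table["q_value"].to_numpy(),
            bh_adjust(res.table["p_value"].to_numpy()),
            rtol=1e-12,
        )

    def test_zero_cohort_is_an_error(self):
        with pytest.raises(SignatureError):
            cohort_enrichment({"S1": 0}, {"S1": 5}, 0, 10)

    def test_margins_preserved(self):
        res = cohort_enrichment({"S1": 7, "S2": 3}, {"S1": 40, "S2": 60}, 12, 100)
        t = res.table
        assert ((t["cohort_present"] + t["cohort_absent"]) == 12).all()
        assert ((t["background_present"] + t["background_absent"]) == 100).all()
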