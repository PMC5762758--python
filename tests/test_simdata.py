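"""Synthetic-cohort generators: determinism, truth recovery, noise structure."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from lmskit.chromothripsis import call_chromothripsis
from lmskit.genotype import (
    AlleleCN,
    GeneLesion,
    call_wgd,
    classify_cn,
    flag_biallelic,
)
from lmskit.sigfit import nnls_fit, supervised_decompose
from lmskit.simdata import (
    SimConfig,
    SimulationError,
    make_oscillating_profile,
    simulate_catalogs,
    simulate_cohort,
    simulate_genotypes,
    simulate_profiles,
    simulate_telomere_tables,
    synthetic_signature_set,
)
from lmskit.telomere import AltStatus, CCircleMeasurement, classify_alt


class TestSimConfig:
    def test_zero_mutations_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(mutations_per_sample=0)

    def test_mix_exceeding_one_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(signature_mix={"S1": 0.8, "S2": 0.4})

    def test_negative_weight_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(signature_mix={"S1": -0.1})

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(chromothripsis_fraction=1.5)

    def test_unknown_noise_model_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(noise_model="gamma")


class TestSimulateCatalogs:
    def test_unknown_signature_id_rejected(self, sigset3):
        cfg = SimConfig(signature_mix={"S9": 1.0})
        with pytest.raises(SimulationError, match="S9"):
            simulate_catalogs(cfg, sigset3)

    def test_multinomial_column_sums_exact(self, sigset3):
        cfg = SimConfig(seed=2, n_samples=8, mutations_per_sample=137)
        cat, _ = simulate_catalogs(cfg, sigset3)
        assert (cat.totals() == 137).all()

    def test_poisson_column_sums_in_expectation(self, sigset3):
        cfg = SimConfig(
            seed=2, n_samples=300, mutations_per_sample=200, noise_model="poisson"
        )
        cat, _ = simulate_catalogs(cfg, sigset3)
        mean_total = cat.totals().mean()
        # mean of 300 Poisson(200) totals: SE = sqrt(200/300) ~ 0.8
        assert abs(mean_total - 200) < 4 * np.sqrt(200 / 300)

    def test_single_component_mixture_tracks_signature(self, sigset3):
        cfg = SimConfig(
            seed=4, n_samples=1, mutations_per_sample=20000, signature_mix={"S1": 1.0}
        )
        cat, _ = simulate_catalogs(cfg, sigset3)
        p = cat.column(cat.samples[0]) / 20000
        w = sigset3.matrix["S1"].to_numpy()
        # multinomial error: compare within 5 binomial SDs cellwise
        sd = np.sqrt(w * (1 - w) / 20000)
        assert (np.abs(p - w) <= 5 * sd + 1e-12).all()

    def test_mean_fitted_exposures_recover_truth(self, sigset3):
        """Cohort-mean NNLS exposures match the generating mixture within 3 SE."""
        cfg = SimConfig(
            seed=6,
            n_samples=200,
            mutations_per_sample=10000,
            signature_mix={"S1": 0.6, "S2": 0.4, "S3": 0.0},
        )
        cat, _ = simulate_catalogs(cfg, sigset3)
        res = supervised_decompose(cat, sigset3)
        rel = np.array([r.relative_exposures for r in res])
        for j, true_val in enumerate([0.6, 0.4]):
            mean = rel[:, j].mean()
            se = rel[:, j].std(ddof=1) / np.sqrt(len(res))
            assert abs(mean - true_val) <= 3 * se + 1e-3
        # the absent signature picks up only the small non-negativity bias
        assert rel[:, 2].mean() < 0.01

    def test_truth_table_structure(self, sigset3):
        cfg = SimConfig(seed=1, n_samples=3)
        _, truth = simulate_catalogs(cfg, sigset3)
        assert set(truth.columns) == {
            "sample", "signature", "true_exposure", "true_rel_exposure",
        }
        assert len(truth) == 3 * 3


class TestSimulateProfiles:
    def test_fraction_zero_all_negative(self):
        profiles, truth = simulate_profiles(SimConfig(seed=3, chromothripsis_fraction=0.0))
        assert not truth["chromothripsis"].any()
        assert not any(call_chromothripsis(p).positive for p in profiles)

    def test_fraction_one_all_positive(self):
        profiles, truth = simulate_profiles(
            SimConfig(seed=3, n_samples=20, chromothripsis_fraction=1.0)
        )
        assert truth["chromothripsis"].all()
        for p in profiles:
            call = call_chromothripsis(p)
            assert call.positive
            assert call.n_switches == 10
            assert call.affected_span_mb == pytest.approx(50.0, abs=1e-6)

    def test_labels_reproduce_under_fixed_seed(self):
        cfg = SimConfig(seed=9, n_samples=30)
        _, t1 = simulate_profiles(cfg)
        _, t2 = simulate_profiles(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_closed_loop_label_recovery(self):
        """The caller recovers every truth label on noise-free profiles."""
        profiles, truth = simulate_profiles(SimConfig(seed=13, n_samples=60))
        calls = [call_chromothripsis(p).positive for p in profiles]
        assert calls == truth["chromothripsis"].tolist()


class TestSimulateTelomere:
    def test_closed_loop_alt_recovery(self):
        cc, _, truth = simulate_telomere_tables(SimConfig(seed=21, n_samples=60))
        for row, alt in zip(cc.itertuples(), truth["alt_positive"]):
            status = classify_alt(
                CCircleMeasurement(
                    row.sample, row.intensity_pol, row.intensity_nopol, row.background
                )
            )
            assert (status is AltStatus.POSITIVE) == alt

    def test_boundary_row_is_positive_inclusively(self):
        status = classify_alt(CCircleMeasurement("B", 6.0, 3.0, 2.0))
        assert status is AltStatus.POSITIVE


class TestSimulateGenotypes:
    def test_all_five_classes_emitted(self):
        _, acn, _, truth = simulate_genotypes(SimConfig(seed=5, n_samples=10))
        assert set(truth["cn_class"]) == {
            "LOH", "CNN-LOH", "higher-ploidy LOH", "normal/biallelic",
            "homozygous deletion",
        }

    def test_loh_rows_have_expected_cn(self):
        _, acn, _, truth = simulate_genotypes(SimConfig(seed=5, n_samples=10))
        merged = acn.merge(truth, on=["sample", "gene"])
        loh = merged[merged["cn_class"] == "LOH"]
        assert (loh["major_cn"] == 1).all()
        assert (loh["minor_cn"] == 0).all()
        normal = merged[merged["cn_class"] == "normal/biallelic"]
        assert (normal["minor_cn"] >= 1).all()

    def test_closed_loop_class_and_flag_recovery(self):
        """Downstream classifiers recover every truth row without noise."""
        lesions, acn, _, truth = simulate_genotypes(SimConfig(seed=8, n_samples=20))
        lesion_map = {
            key: grp for key, grp in lesions.groupby(["sample", "gene"])
        }
        for row in truth.itertuples():
            a = acn[(acn["sample"] == row.sample) & (acn["gene"] == row.gene)].iloc[0]
            cn = AlleleCN(
                row.sample, row.gene, int(a.major_cn), int(a.minor_cn),
                ploidy=float(a.ploidy), purity=float(a.purity),
            )
            assert classify_cn(cn).value == row.cn_class
            grp = lesion_map.get((row.sample, row.gene))
            gene_lesions = []
            if grp is not None:
                for l in grp.itertuples():
                    gene_lesions.append(
                        GeneLesion(
                            l.sample, l.gene, l.lesion_type, bool(l.damaging),
                            allele=l.allele,
                            vaf=None if pd.isna(l.vaf) else float(l.vaf),
                        )
                    )
            got = flag_biallelic(cn, gene_lesions)
            assert got.biallelic_inactivation == row.biallelic

    def test_closed_loop_wgd_recovery(self):
        _, _, segments, truth = simulate_genotypes(SimConfig(seed=8, n_samples=30))
        wgd_truth = truth.drop_duplicates("sample").set_index("sample")
        for sample, grp in segments.groupby("sample"):
            lengths = (grp["end"] - grp["start"] + 1).to_numpy(dtype=float)
            call = call_wgd(
                grp["major_cn"].to_numpy(), lengths, float(wgd_truth.loc[sample, "ploidy"])
            )
            assert call.is_wgd == bool(wgd_truth.loc[sample, "wgd"])

    def test_wgd_samples_have_high_ploidy_and_major_ge2(self):
        _, _, segments, truth = simulate_genotypes(SimConfig(seed=8, n_samples=30))
        per_sample = truth.drop_duplicates("sample")
        for row in per_sample[per_sample["wgd"]].itertuples():
            assert row.ploidy > 3.0
            grp = segments[segments["sample"] == row.sample]
            assert (grp["major_cn"] >= 2).mean() > 0.5


class TestCohortWriter:
    def test_outputs_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = SimConfig(seed=17, n_samples=6)
        d1 = simulate_cohort(cfg, tmp_path / "run1")
        d2 = simulate_cohort(cfg, tmp_path / "run2")
        assert d1.keys() == d2.keys()
        for name in d1:
            assert filecmp.cmp(d1[name], d2[name], shallow=False), name

    def test_different_seed_changes_output(self, tmp_path):
        d1 = simulate_cohort(SimConfig(seed=17, n_samples=6), tmp_path / "a")
        d2 = simulate_cohort(SimConfig(seed=18, n_samples=6), tmp_path / "b")
        assert not filecmp.cmp(d1["catalog"], d2["catalog"], shallow=False)

    def test_truths_written_alongside_data(self, tmp_path):
        paths = simulate_cohort(SimConfig(seed=17, n_samples=4), tmp_path / "c")
        for name in ("catalog_truth", "profiles_truth", "alt_truth", "genotype_truth"):
            assert paths[name].exists()


def test_oscillating_profile_geometry():
    p = make_oscillating_profile("T1", 10, 50.0, offset=60_000_000)
    # 10 breakpoints -> 11 segments; first/last breakpoints 50 Mb apart
    assert len(p.segments) == 11
    starts = [s.start for s in p.segments]
    assert starts[1] == 60_000_001
    assert p.segments[-1].start - p.segments[1].start == 50_000_000
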