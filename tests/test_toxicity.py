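"""Toxicity estimation: enrichment scores, error model, merging, tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prdscan import synthetic_data as sd
from prdscan import toxicity as tx
from prdscan.design import tdp43_library

from conftest import make_count_records


class TestEnrichmentScore:
    def test_equal_frequencies_give_zero(self):
        assert tx.enrichment_score(0.01, 0.01) == pytest.approx(0.0)

    def test_halved_frequency(self):
        assert tx.enrichment_score(0.02, 0.01) == pytest.approx(-0.6931, abs=1e-4)

    def test_antisymmetric_under_ratio_inversion(self):
        assert tx.enrichment_score(0.01, 0.02) == pytest.approx(
            -tx.enrichment_score(0.02, 0.01)
        )

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            tx.enrichment_score(0.0, 0.01)


class TestRelativeToxicity:
    def test_wt_reference_is_zero(self):
        assert tx.relative_toxicity(1.3, 1.3) == 0.0

    def test_direct_subtraction(self):
        assert tx.relative_toxicity(0.3, 1.0) == pytest.approx(0.7)

    def test_enriched_variant_is_negative(self):
        # variant growing faster than WT: ES_x > ES_WT
        assert tx.relative_toxicity(2.0, 1.0) < 0


class TestToxicityError:
    def test_worked_example(self):
        err = tx.toxicity_error(100, 100, 1000, 1000, eps_r=0.0)
        assert err == pytest.approx(math.sqrt(0.022), abs=1e-6)
        assert err == pytest.approx(0.1483, abs=1e-3)

    def test_replicate_error_floor(self):
        big = 1e12
        err = tx.toxicity_error(big, big, big, big, eps_r=0.05)
        assert err == pytest.approx(0.05, rel=1e-5)

    @given(
        counts=st.tuples(*[st.integers(1, 10**6)] * 4),
        eps=st.floats(0, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_formula(self, counts, eps):
        """Spreadsheet-style oracle: term-by-term evaluation."""
        expected = math.sqrt(sum(1.0 / c for c in counts) + eps * eps)
        assert tx.toxicity_error(*counts, eps_r=eps) == pytest.approx(
            expected, rel=1e-12
        )

    def test_monotone_decreasing_in_each_count(self):
        base = tx.toxicity_error(100, 100, 100, 100)
        for i in range(4):
            counts = [100] * 4
            counts[i] = 200
            assert tx.toxicity_error(*counts) < base

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            tx.toxicity_error(0, 10, 10, 10)


class TestNormalizePerGeneration:
    def test_unit_doublings_unchanged(self, tiny_design):
        df = pd.DataFrame(
            {"tox_rep1": [1.2], "err_rep1": [0.3]}
        )
        out = tx.normalize_per_generation(df, [1.0])
        pd.testing.assert_frame_equal(out, df)

    def test_division(self):
        df = pd.DataFrame({"tox_rep1": [1.2], "err_rep1": [0.6]})
        out = tx.normalize_per_generation(df, [6.0])
        assert out.loc[0, "tox_rep1"] == pytest.approx(0.2)
        assert out.loc[0, "err_rep1"] == pytest.approx(0.1)

    def test_ordering_preserved(self):
        df = pd.DataFrame(
            {"tox_rep1": [0.1, 0.5, -0.2], "err_rep1": [0.1, 0.1, 0.1]}
        )
        out = tx.normalize_per_generation(df, [5.5])
        assert list(out["tox_rep1"].rank()) == list(df["tox_rep1"].rank())


class TestReplicateError:
    def test_recovers_injected_noise(self, tiny_design):
        """Known replicate noise SD is recovered from excess variance."""
        sigma = 0.05
        design = tiny_design
        records = make_count_records(
            design,
            toxicities=np.zeros(10_000),
            lam_in=np.full(10_000, 5000.0),
            seed=0,
            replicate_noise_sd=sigma,
        )
        est, _ = tx.per_replicate_estimates(records, design)
        est = tx.normalize_per_generation(est, design.generations)
        model = tx.estimate_replicate_error(est)
        assert model.eps_r == pytest.approx(sigma, rel=0.10)

    def test_identical_replicates_give_near_zero(self, tiny_design):
        records = make_count_records(
            tiny_design,
            toxicities=np.zeros(2000),
            lam_in=np.full(2000, 50_000.0),
            seed=1,
            replicate_noise_sd=0.0,
        )
        est, _ = tx.per_replicate_estimates(records, tiny_design)
        est = tx.normalize_per_generation(est, tiny_design.generations)
        model = tx.estimate_replicate_error(est)
        assert model.eps_r < 0.003

    def test_single_replicate_rejected(self):
        df = pd.DataFrame(
            {"tox_rep1": [0.0], "err_rep1": [0.1],
             "n_in_rep1": [100], "n_out_rep1": [100]}
        )
        with pytest.raises(ValueError, match="two replicates"):
            tx.estimate_replicate_error(df)


class TestBayesianCorrection:
    def test_shrinkage_vanishes_for_deeply_covered_doubles(self, tiny_design):
        """With deep coverage the posterior sits on the raw estimate."""
        rng = np.random.default_rng(6)
        n_singles = 60
        records = make_count_records(
            tiny_design,
            toxicities=rng.normal(0.05, 0.1, n_singles),
            lam_in=np.full(n_singles, 5e4),
            seed=7,
            n_doubles=300,
            lam_double=3e4,
        )
        est, _ = tx.estimate_toxicity(records, tiny_design, prior_min_input=50)
        raw, _ = tx.estimate_toxicity(records, tiny_design, bayesian=False)
        dd = est["n_aa_mut"] == 2
        assert est.loc[dd, "bayes_corrected"].all()
        for r in range(1, 4):
            a = est.loc[dd, f"tox_rep{r}"].to_numpy(float)
            b = raw.loc[dd.to_numpy(), f"tox_rep{r}"].to_numpy(float)
            e = est.loc[dd, f"err_rep{r}"].to_numpy(float)
            ok = np.isfinite(a) & np.isfinite(b)
            assert np.median(np.abs(a[ok] - b[ok]) / e[ok]) < 0.05

    def test_zero_output_doubles_get_finite_estimates(self, toxicity_run):
        est = toxicity_run["estimates"]
        dd = est[(est["n_aa_mut"] == 2) & est["bayes_corrected"]]
        zero_out = dd[
            (dd["n_out_rep1"] == 0) & (dd["n_in_rep1"] > 0)
        ]
        assert len(zero_out) > 0
        assert np.isfinite(zero_out["tox_rep1"]).all()

    def test_rmse_improves_for_sparse_doubles(self, calibration_result):
        assert (
            calibration_result["rmse_corrected"] < calibration_result["rmse_raw"]
        )


class TestMergeAndNormalize:
    def test_equal_error_merge_is_arithmetic_mean(self):
        df = pd.DataFrame(
            {"tox_rep1": [1.0], "tox_rep2": [1.0],
             "err_rep1": [0.1], "err_rep2": [0.1]}
        )
        merged, err = tx._merge_rows(
            df[["tox_rep1", "tox_rep2"]].to_numpy(),
            df[["err_rep1", "err_rep2"]].to_numpy(),
        )
        assert merged[0] == pytest.approx(1.0)
        assert err[0] == pytest.approx(0.1 / math.sqrt(2), abs=1e-4)
        assert err[0] == pytest.approx(0.0707, abs=1e-4)

    def test_silent_weighted_mean_is_exactly_zero(self, toxicity_run):
        merged = toxicity_run["merged"]
        sil = merged[
            merged["is_silent"] & (merged["n_codon_mut"] == 1)
        ]
        w = 1.0 / sil["sigma"] ** 2
        mean = (w * sil["toxicity"]).sum() / w.sum()
        assert abs(mean) < 1e-10

    def test_stop_means_coincide_across_libraries(self, library_design):
        rng = np.random.default_rng(0)
        designs = [tdp43_library("290-331"), tdp43_library("332-373")]
        ests = []
        for i, design in enumerate(designs):
            lan = sd.make_landscape(design, seed=20 + i)
            counts = sd.simulate_experiment(
                design, lan, n_molecules=40_000, depth=500_000, seed=30 + i,
                misreads=False,
            )
            from prdscan import variant_table as vt

            rec, _ = vt.filter_variants(
                vt.translate_and_aggregate(counts, design)
            )
            est, _ = tx.estimate_toxicity(rec, design)
            ests.append(est)
        merged = tx.merge_and_normalize(ests)
        means = []
        for lib in merged["library"].unique():
            stop = merged[
                (merged["library"] == lib)
                & merged["is_stop"]
                & (merged["n_aa_mut"] == 1)
            ]
            w = 1.0 / stop["sigma"] ** 2
            means.append(float((w * stop["toxicity"]).sum() / w.sum()))
        assert abs(means[0] - means[1]) < 1e-12

    def test_empty_silent_class_rejected(self, tiny_design):
        records = make_count_records(
            tiny_design, np.zeros(50), np.full(50, 1000.0), seed=3, n_silent=0
        )
        est, _ = tx.estimate_toxicity(records, tiny_design)
        with pytest.raises(ValueError, match="silent"):
            tx.merge_and_normalize([est.drop(index=est.index[est.is_silent])])


class TestClassifyVsWt:
    def test_wt_like_variant_is_indistinguishable(self):
        df = pd.DataFrame(
            {"toxicity": [0.0], "tox_rep1": [0.0], "tox_rep2": [0.0],
             "tox_rep3": [0.0]}
        )
        labels = tx.classify_vs_wt(df)
        assert labels.iloc[0] == "indistinguishable"

    def test_null_simulation_controls_fdr(self):
        rng = np.random.default_rng(1)
        n = 4000
        reps = rng.normal(0, 0.05, size=(n, 3))
        df = pd.DataFrame(
            {
                "toxicity": reps.mean(axis=1),
                "tox_rep1": reps[:, 0],
                "tox_rep2": reps[:, 1],
                "tox_rep3": reps[:, 2],
            }
        )
        labels = tx.classify_vs_wt(df, fdr=0.05)
        assert (labels != "indistinguishable").mean() <= 0.05

    def test_strong_effects_flagged_with_correct_sign(self):
        rng = np.random.default_rng(2)
        strong = 1.0 + rng.normal(0, 0.01, size=(200, 3))
        weak = rng.normal(0, 0.01, size=(200, 3))
        reps = np.vstack([strong, -strong, weak])
        df = pd.DataFrame(
            {
                "toxicity": reps.mean(axis=1),
                "tox_rep1": reps[:, 0],
                "tox_rep2": reps[:, 1],
                "tox_rep3": reps[:, 2],
            }
        )
        labels = tx.classify_vs_wt(df, fdr=0.05)
        assert (labels.iloc[:200] == "more_toxic").all()
        assert (labels.iloc[200:400] == "less_toxic").all()

    def test_too_few_replicates_flagged_indistinguishable(self):
        df = pd.DataFrame(
            {"toxicity": [2.0], "tox_rep1": [2.0], "tox_rep2": [np.nan],
             "tox_rep3": [np.nan]}
        )
        assert tx.classify_vs_wt(df).iloc[0] == "indistinguishable"


class TestEndToEndRecovery:
    def test_slope_and_correlation_against_truth(self, calibration_result):
        assert 0.95 <= calibration_result["slope"] <= 1.05
        assert calibration_result["pearson_r"] > 0.95

    def test_interval_coverage(self, calibration_result):
        assert calibration_result["coverage_pct"] == pytest.approx(95.0, abs=3.0)
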