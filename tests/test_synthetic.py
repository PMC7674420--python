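import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wlpred.labels import label_cohort
from wlpred.postprandial import featurize_postprandial, fluc1, marker_bounds, normalize_minmax
from wlpred.rf import CVConfig, mean_metrics, run_cv
from wlpred.synthetic import (
    SynthConfig,
    draw_delta_w_pct,
    inject_missingness,
    simulate_all,
    simulate_cohort,
    simulate_genotypes,
    simulate_omics_blocks,
    simulate_postprandial,
)


@pytest.fixture(scope="module")
def small_cfg():
    return SynthConfig(n_participants=40, n_otus=12, n_metabolites=8, n_snps=30,
                       ld_block_size=6, seed=11)


@pytest.fixture(scope="module")
def small_sim(small_cfg):
    cohort, truth = simulate_cohort(small_cfg)
    blocks = simulate_omics_blocks(small_cfg, cohort, truth)
    return cohort, truth, blocks


class TestConfigValidation:
    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            SynthConfig(n_participants=1)

    def test_bad_sd(self):
        with pytest.raises(ValueError):
            SynthConfig(responder_sd_pct=0)

    def test_bad_missingness(self):
        with pytest.raises(ValueError):
            SynthConfig(missingness={"Diet": 1.5})

    def test_empty_arms(self):
        with pytest.raises(ValueError):
            SynthConfig(arms=())


class TestCohortStructure:
    def test_two_periods_distinct_arms(self, small_sim):
        cohort, _, _ = small_sim
        for pid, sub in cohort.groupby("participant_id"):
            assert len(sub) <= 2
            assert sub["diet_arm"].nunique() == len(sub)
            assert "refined" in set(sub["diet_arm"])  # one control arm per trial

    def test_positive_weights(self, small_sim):
        cohort, _, _ = small_sim
        assert (cohort["w_before"] > 0).all()
        assert (cohort["w_after"].dropna() > 0).all()

    def test_one_missing_weight_by_default(self, small_sim):
        cohort, _, _ = small_sim
        assert cohort["w_after"].isna().sum() == 1

    def test_labels_match_ground_truth(self, small_sim):
        cohort, truth, _ = small_sim
        labels = label_cohort(cohort).set_index("sample_id")
        merged = truth.set_index("sample_id").join(labels)
        usable = merged[merged["label"] >= 0]
        assert (usable["label"] == usable["responder"]).all()


class TestSeedDeterminism:
    def test_cohort_byte_identical(self):
        cfg = SynthConfig(n_participants=20, n_otus=8, n_metabolites=5, n_snps=12, seed=3)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a[0].to_csv() == b[0].to_csv()
        assert a[1].to_csv() == b[1].to_csv()

    def test_blocks_byte_identical(self):
        cfg = SynthConfig(n_participants=16, n_otus=6, n_metabolites=5, n_snps=12, seed=4)
        c1, t1 = simulate_cohort(cfg)
        c2, t2 = simulate_cohort(cfg)
        b1 = simulate_omics_blocks(cfg, c1, t1)
        b2 = simulate_omics_blocks(cfg, c2, t2)
        assert set(b1) == set(b2)
        for label in b1:
            assert b1[label].data.to_csv() == b2[label].data.to_csv()

    def test_postprandial_byte_identical(self):
        cfg = SynthConfig(n_participants=10, seed=5)
        c, t = simulate_cohort(cfg)
        assert simulate_postprandial(cfg, c, t).to_csv() == simulate_postprandial(cfg, c, t).to_csv()


class TestDeltaWCalibration:
    def test_responder_mean_matches_configured(self):
        cfg = SynthConfig(seed=0)
        draws = draw_delta_w_pct(cfg, True, 10_000, np.random.default_rng(0))
        assert (draws < 0).all()
        assert abs((-draws).mean() - 1.67) < 0.1

    def test_nonresponder_mean_matches_configured(self):
        cfg = SynthConfig(seed=0)
        draws = draw_delta_w_pct(cfg, False, 10_000, np.random.default_rng(0))
        assert (draws >= 0).all()
        assert abs(draws.mean() - 1.39) < 0.1

    def test_sd_converges_within_three_se(self):
        cfg = SynthConfig(seed=0)
        draws = draw_delta_w_pct(cfg, True, 10_000, np.random.default_rng(1))
        se = cfg.responder_sd_pct / np.sqrt(2 * (len(draws) - 1))
        assert abs(draws.std(ddof=1) - 1.42) < 3 * se + 0.02


class TestBlocks:
    def test_diet_one_hot(self, small_sim):
        _, _, blocks = small_sim
        diet = blocks["Diet"].data
        assert diet.shape[1] == 3
        np.testing.assert_array_equal(diet.sum(axis=1), 1)
        assert set(np.unique(diet.to_numpy())) <= {0, 1}

    def test_16s_rows_sum_to_one(self, small_sim):
        _, _, blocks = small_sim
        rel = blocks["16S_B"].data
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-9)

    def test_unique_feature_names(self, small_sim):
        _, _, blocks = small_sim
        for b in blocks.values():
            assert len(set(b.feature_names)) == len(b.feature_names)

    def test_no_nan(self, small_sim):
        _, _, blocks = small_sim
        for b in blocks.values():
            assert not b.data.isna().any().any()

    def test_genotype_constant_within_participant(self, small_sim):
        cohort, _, blocks = small_sim
        geno = blocks["Genotype"].data.copy()
        geno["pid"] = cohort.set_index("sample_id").loc[geno.index, "participant_id"]
        assert (geno.groupby("pid").nunique() <= 1).all().all()

    def test_planted_unknown_block_raises(self):
        cfg = SynthConfig(n_participants=10, planted_features=(("NoSuch", "x", 1.0),), seed=1)
        c, t = simulate_cohort(cfg)
        with pytest.raises(ValueError, match="unknown blocks"):
            simulate_omics_blocks(cfg, c, t)

    def test_planted_unknown_feature_raises(self):
        cfg = SynthConfig(n_participants=10, n_clinical=3,
                          planted_features=(("ClinicalA", "clin_99", 1.0),), seed=1)
        c, t = simulate_cohort(cfg)
        with pytest.raises(KeyError):
            simulate_omics_blocks(cfg, c, t)

    def test_planted_effect_shifts_responder_mean(self):
        cfg = SynthConfig(n_participants=300, n_otus=8, n_metabolites=5, n_snps=12,
                          planted_features=(("ClinicalA", "clin_00", 1.5),), seed=6)
        c, t = simulate_cohort(cfg)
        blocks = simulate_omics_blocks(cfg, c, t)
        vals = blocks["ClinicalA"].data["clin_00"]
        resp = t.set_index("sample_id")["responder"].astype(bool)
        gap = vals[resp.to_numpy()].mean() - vals[~resp.to_numpy()].mean()
        assert gap > 0.8  # ~1.5 SD planted, allow sampling noise

    def test_zero_effect_means_equal(self):
        cfg = SynthConfig(n_participants=400, n_otus=8, n_metabolites=5, n_snps=12, seed=7)
        c, t = simulate_cohort(cfg)
        blocks = simulate_omics_blocks(cfg, c, t)
        vals = blocks["ClinicalA"].data["clin_00"]
        resp = t.set_index("sample_id")["responder"].astype(bool).to_numpy()
        gap = vals[resp].mean() - vals[~resp].mean()
        assert abs(gap) < 0.2


class TestGenotypes:
    def test_hardy_weinberg_at_maf_03(self):
        cfg = SynthConfig(n_participants=2000, n_snps=20, ld_rho=0.0, seed=8)
        ids = [f"P{i}" for i in range(2000)]
        geno, _ = simulate_genotypes(cfg, ids, np.random.default_rng(8), mafs=0.3)
        freqs = np.array([(geno.to_numpy() == k).mean() for k in (0, 1, 2)])
        np.testing.assert_allclose(freqs, [0.49, 0.42, 0.09], atol=0.02)

    def test_perfect_ld_duplicates_columns(self):
        cfg = SynthConfig(n_participants=50, n_snps=6, ld_block_size=3, ld_rho=1.0, seed=9)
        ids = [f"P{i}" for i in range(50)]
        geno, _ = simulate_genotypes(cfg, ids, np.random.default_rng(9), mafs=0.4)
        block = geno[["snp_0000", "snp_0001", "snp_0002"]]
        assert (block.nunique(axis=1) == 1).all()

    def test_positions_attached(self, small_sim):
        _, _, blocks = small_sim
        positions = blocks["Genotype"].data.attrs["positions"]
        assert len(positions) == blocks["Genotype"].data.shape[1]


@pytest.fixture(scope="module")
def series():
    cfg = SynthConfig(n_participants=30, seed=10, postprandial_missing_one_frac=0.1,
                      postprandial_missing_many_frac=0.05)
    c, t = simulate_cohort(cfg)
    return cfg, c, t, simulate_postprandial(cfg, c, t)


class TestPostprandial:
    def test_blood_series_length_five(self, series):
        _, _, _, long_df = series
        counts = long_df[long_df["marker"] == "glucose"].groupby("sample_id").size()
        assert (counts == 5).all()

    def test_breath_series_length_eight(self, series):
        _, _, _, long_df = series
        counts = long_df[long_df["marker"] == "breath_h2"].groupby("sample_id").size()
        assert (counts == 8).all()

    def test_missingness_injected(self, series):
        _, _, _, long_df = series
        assert long_df["value"].isna().sum() > 0

    def test_zero_volatility_effect_equal_fluc1(self):
        cfg = SynthConfig(n_participants=150, postprandial_volatility_effect=0.0,
                          postprandial_missing_one_frac=0.0,
                          postprandial_missing_many_frac=0.0, seed=12)
        c, t = simulate_cohort(cfg)
        long_df = simulate_postprandial(cfg, c, t)
        glu = long_df[long_df["marker"] == "glucose"]
        bounds = marker_bounds(glu)["glucose"]
        resp = t.set_index("sample_id")["responder"]
        f1 = {}
        for sid, sub in glu.groupby("sample_id"):
            v = sub.sort_values("time_min")["value"].to_numpy()
            f1[sid] = fluc1(normalize_minmax(v, bounds))
        f1 = pd.Series(f1)
        a = f1[resp[f1.index] == 1]
        b = f1[resp[f1.index] == 0]
        assert stats.mannwhitneyu(a, b).pvalue > 0.01

    def test_nonzero_volatility_raises_responder_fluc1(self):
        cfg = SynthConfig(n_participants=150, postprandial_volatility_effect=1.5,
                          postprandial_missing_one_frac=0.0,
                          postprandial_missing_many_frac=0.0, seed=13)
        c, t = simulate_cohort(cfg)
        long_df = simulate_postprandial(cfg, c, t)
        feats = featurize_postprandial(long_df, grid_sizes=(10,))
        f1 = feats["PostPranFluc1"]["glucose_fluc1"]
        resp = t.set_index("sample_id")["responder"]
        assert f1[resp[f1.index] == 1].mean() > f1[resp[f1.index] == 0].mean()


class TestMissingness:
    def test_zero_fractions_keep_all(self, small_cfg, small_sim):
        _, _, blocks = small_sim
        out, complete = inject_missingness(blocks, small_cfg)
        assert len(complete) == len(blocks["Diet"].data)

    def test_thirty_percent_drop(self):
        cfg = SynthConfig(n_participants=100, n_otus=8, n_metabolites=5, n_snps=12,
                          missingness={"16S_B": 0.3}, seed=14)
        c, t = simulate_cohort(cfg)
        blocks = simulate_omics_blocks(cfg, c, t)
        out, complete = inject_missingness(blocks, cfg)
        assert len(out["16S_B"].data) == 140  # 200 observations - 30%
        assert set(complete) == set(out["16S_B"].data.index)

    def test_complete_cases_subset_of_every_block(self):
        cfg = SynthConfig(n_participants=60, n_otus=8, n_metabolites=5, n_snps=12,
                          missingness={"16S_B": 0.2, "LC-MS": 0.1}, seed=15)
        c, t = simulate_cohort(cfg)
        blocks = simulate_omics_blocks(cfg, c, t)
        out, complete = inject_missingness(blocks, cfg)
        for b in out.values():
            assert set(complete) <= set(b.data.index)

    def test_full_drop_rejected(self, small_cfg, small_sim):
        _, _, blocks = small_sim
        cfg = SynthConfig(n_participants=40, seed=11)
        object.__setattr__(cfg, "missingness", {"Diet": 1.0})
        with pytest.raises(ValueError):
            inject_missingness(blocks, cfg)


class TestDownstreamSignal:
    def test_auc_monotone_in_planted_effect(self):
        effects = [0.0, 1.0, 2.0]
        reps = 8
        mean_aucs = []
        for effect in effects:
            aucs = []
            for rep in range(reps):
                cfg = SynthConfig(
                    n_participants=40, n_otus=6, n_metabolites=5, n_snps=12,
                    diet_effect={}, participant_intercept_sd=0.0,
                    planted_features=(("ClinicalA", "clin_00", effect),) if effect else (),
                    seed=500 + rep,
                )
                c, t = simulate_cohort(cfg)
                blocks = simulate_omics_blocks(cfg, c, t)
                y = t.set_index("sample_id")["responder"]
                X = blocks["ClinicalA"].data[["clin_00"]]
                cv = CVConfig(n_shuffles=2, n_folds=3, n_trees=10, seed=rep)
                aucs.append(mean_metrics(run_cv(X, y.loc[X.index], cv))["roc_auc"])
            mean_aucs.append(np.mean(aucs))
        assert mean_aucs[0] <= mean_aucs[1] + 0.05
        assert mean_aucs[1] <= mean_aucs[2] + 0.05
        assert mean_aucs[2] > 0.7


class TestSimulateAll:
    def test_returns_consistent_bundle(self):
        cfg = SynthConfig(n_participants=14, n_otus=6, n_metabolites=4, n_snps=10,
                          missingness={"LC-MS": 0.2}, seed=16)
        cohort, truth, blocks, postprandial, complete = simulate_all(cfg)
        assert len(cohort) == 28
        assert set(complete) <= set(cohort["sample_id"])
        assert set(postprandial["sample_id"]) == set(cohort["sample_id"])
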