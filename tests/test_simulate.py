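import math

import numpy as np
import pandas as pd
import pytest

import cllmir as cm
from cllmir.simulate import ConfigError
from conftest import null_cohort_config

PANEL = ["miR-155", "miR-181a", "miR-181b", "miR-29c", "miR-223", "miR-x1", "miR-x2"]


def small_config(seed=0, **kw):
    defaults = dict(
        n_cll=10,
        n_control=6,
        n_activated=4,
        feature_names=PANEL,
        planted_up={"miR-155": math.log2(50.0)},
        planted_down={"miR-181a": -math.log2(100.0), "miR-181b": -math.log2(100.0)},
        high_background_features=frozenset(),
        seed=seed,
    )
    defaults.update(kw)
    return cm.CohortConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw,field",
        [
            (dict(n_cll=1), "n_cll"),
            (dict(n_control=1), "n_control"),
            (dict(noise_sd_log2=0.0), "noise_sd_log2"),
            (dict(censor_rate=1.5), "censor_rate"),
            (dict(frac_zap70_pos=-0.1), "frac_zap70_pos"),
            (dict(planted_up={"not-on-panel": 1.0}), "planted_up"),
            (dict(prognostic_correlation=1.0), "prognostic_correlation"),
        ],
    )
    def test_invalid_field_named_in_error(self, kw, field):
        with pytest.raises(ConfigError, match=field):
            small_config(**kw)

    def test_planted_sets_must_not_overlap(self):
        with pytest.raises(ConfigError, match="overlap"):
            small_config(
                planted_up={"miR-155": 1.0}, planted_down={"miR-155": -1.0}
            )

    def test_effect_sign_must_match_direction(self):
        with pytest.raises(ConfigError, match="sign"):
            small_config(planted_up={"miR-155": -1.0})


class TestGenerateCohort:
    def test_shapes_and_determinism(self):
        cfg = small_config(seed=5)
        m1, t1, _ = cm.generate_cohort(cfg)
        m2, t2, _ = cm.generate_cohort(small_config(seed=5))
        assert m1.shape == (len(PANEL), 20)
        assert list(t1["group"]) == ["CLL"] * 10 + ["control_B"] * 6 + ["activated_B"] * 4
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1, t2)
        m3, _, _ = cm.generate_cohort(small_config(seed=6))
        assert not m1.equals(m3)

    def test_planted_fold_changes_realized(self):
        """miR-155 ~50x up and miR-181a/b ~100x down in CLL vs control,
        averaged over replicate cohorts."""
        ratios = {"miR-155": [], "miR-181a": []}
        for seed in range(30):
            cfg = small_config(seed=seed, n_cll=20, n_control=12)
            mat, table, _ = cm.generate_cohort(cfg)
            log2 = np.log2(mat)
            cll = table.index[table["group"] == "CLL"]
            ctl = table.index[table["group"] == "control_B"]
            for f in ratios:
                ratios[f].append(
                    log2.loc[f, cll].mean() - log2.loc[f, ctl].mean()
                )
        assert np.mean(ratios["miR-155"]) == pytest.approx(math.log2(50), abs=0.2)
        assert np.mean(ratios["miR-181a"]) == pytest.approx(-math.log2(100), abs=0.2)

    def test_null_and_planted_effect_calibration(self):
        """Mean realized group difference over 50 cohorts is within
        3*SE of the configured effect (planted and null features)."""
        diffs = {"miR-155": [], "miR-x1": []}
        for seed in range(50):
            cfg = small_config(seed=seed, planted_up={"miR-155": 2.0})
            mat, table, _ = cm.generate_cohort(cfg)
            log2 = np.log2(mat)
            cll = table.index[table["group"] == "CLL"]
            ctl = table.index[table["group"] == "control_B"]
            for f in diffs:
                diffs[f].append(log2.loc[f, cll].mean() - log2.loc[f, ctl].mean())
        for f, target in (("miR-155", 2.0), ("miR-x1", 0.0)):
            arr = np.asarray(diffs[f])
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr.mean() - target) < 3 * se + 1e-12

    def test_activated_group_carries_the_same_planted_effects(self):
        cfg = small_config(seed=3, n_activated=12, n_control=12)
        mat, table, truth = cm.generate_cohort(cfg)
        gm = truth.group_means_log2
        assert gm.loc["miR-155", "activated_B"] - gm.loc["miR-155", "control_B"] == (
            pytest.approx(math.log2(50))
        )
        assert gm.loc["miR-x1", "activated_B"] == gm.loc["miR-x1", "control_B"]

    def test_high_background_offset_is_additive_on_raw_scale(self):
        cfg = small_config(high_background_features=frozenset({"miR-x1"}))
        mat, _, truth = cm.generate_cohort(cfg)
        base = small_config(high_background_features=frozenset())
        mat0, _, _ = cm.generate_cohort(base)
        offset = 10.0 * 2.0**cfg.baseline_log2_mean
        np.testing.assert_allclose(mat.loc["miR-x1"], mat0.loc["miR-x1"] + offset)
        assert truth.high_background_features == ["miR-x1"]

    def test_clinical_fractions(self):
        cfg = cm.CohortConfig(seed=2)
        _, table, _ = cm.generate_cohort(cfg)
        cll = table[table["group"] == "CLL"]
        assert (cll["zap70"] == "pos").sum() == 14
        assert (cll["igvh"] == "unmutated").sum() == 14
        assert (table.loc[table["group"] != "CLL", "zap70"] == "NA").all()

    def test_prognostic_pair_is_correlated(self):
        cfg = small_config(seed=9, n_cll=200)
        mat, table, _ = cm.generate_cohort(cfg)
        cll = table.index[table["group"] == "CLL"]
        log2 = np.log2(mat)
        r = np.corrcoef(log2.loc["miR-29c", cll], log2.loc["miR-223", cll])[0, 1]
        assert r == pytest.approx(cfg.prognostic_correlation, abs=0.15)


class TestGenerateSurvival:
    def test_null_hazard_gives_nominal_logrank_rate(self):
        """With zero hazard coefficients and no censoring, the log-rank
        test between median-split groups rejects at ~5%."""
        rej = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = small_config(
                seed=seed, n_cll=30, censor_rate=0.0,
                prognostic_features={"miR-29c": 0.0, "miR-223": 0.0},
            )
            mat, table, truth = cm.generate_cohort(cfg)
            table = cm.generate_survival(cfg, truth, table, mat)
            cll = table[table["group"] == "CLL"]
            expr = np.log2(mat.loc["miR-29c", cll.index])
            low = expr <= expr.median()
            _, p = cm.logrank_test(
                cll.loc[low.values, "ttft_days"], cll.loc[low.values, "event"],
                cll.loc[~low.values, "ttft_days"], cll.loc[~low.values, "event"],
            )
            rej += p < 0.05
        ci = 1.96 * math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) < ci + 0.01

    def test_negative_coefficient_low_expression_shorter_time(self):
        """coef -1 on one miRNA, n_cll=200: the low-expression half has
        the smaller Kaplan-Meier median in >=95% of 50 seeds."""
        wins = 0
        for seed in range(50):
            cfg = small_config(
                seed=seed, n_cll=200, censor_rate=0.0,
                prognostic_features={"miR-29c": -1.0},
            )
            mat, table, truth = cm.generate_cohort(cfg)
            table = cm.generate_survival(cfg, truth, table, mat)
            cll = table[table["group"] == "CLL"]
            expr = np.log2(mat.loc["miR-29c", cll.index])
            low = (expr <= expr.median()).values
            km_low = cm.km_estimate(cll.loc[low, "ttft_days"], cll.loc[low, "event"])
            km_high = cm.km_estimate(cll.loc[~low, "ttft_days"], cll.loc[~low, "event"])

            def median_time(km):
                below = km.survival <= 0.5
                return km.times[below][0] if below.any() else np.inf

            wins += median_time(km_low) < median_time(km_high)
        assert wins >= 48  # 95% of 50, with one seed of slack

    def test_all_censored_edge(self):
        cfg = small_config(censor_rate=1.0)
        mat, table, truth = cm.generate_cohort(cfg)
        table = cm.generate_survival(cfg, truth, table, mat)
        cll = table[table["group"] == "CLL"]
        assert (cll["event"] == 0).all()
        screen = cm.survival_screen(np.log2(mat), table, min_leaf_floor=2)
        assert not screen["significant"].any()
        assert screen["cutpoint"].isna().all()

    def test_censor_rate_approximately_honored(self):
        rates = []
        for seed in range(30):
            cfg = small_config(seed=seed, n_cll=60, censor_rate=0.3)
            mat, table, truth = cm.generate_cohort(cfg)
            table = cm.generate_survival(cfg, truth, table, mat)
            cll = table[table["group"] == "CLL"]
            rates.append(1.0 - cll["event"].mean())
        assert np.mean(rates) == pytest.approx(0.3, abs=0.08)

    def test_missing_prognostic_feature_raises(self):
        cfg = small_config()
        mat, table, truth = cm.generate_cohort(cfg)
        with pytest.raises(KeyError, match="miR-29c"):
            cm.generate_survival(cfg, truth, table, mat.drop(index="miR-29c"))

    def test_non_cll_samples_have_missing_survival(self):
        cfg = small_config()
        mat, table, truth = cm.generate_cohort(cfg)
        table = cm.generate_survival(cfg, truth, table, mat)
        other = table[table["group"] != "CLL"]
        assert other["ttft_days"].isna().all()


class TestGenerateCtTable:
    def test_planted_fold_moves_delta_ct(self):
        """An 8-fold planted increase shifts CLL delta-Ct by -3 cycles
        relative to control (by construction of the Ct model)."""
        cfg = small_config(planted_up={"miR-155": 3.0}, planted_down={})
        _, table, truth = cm.generate_cohort(cfg)
        ct = cm.generate_ct_table(cfg, truth, replicate_sd=0.0)
        dct = cm.delta_ct(ct)
        dct = dct[dct["target"] == "miR-155"].set_index("sample_id")
        cll = [s for s in dct.index if s.startswith("L")]
        ctl = [s for s in dct.index if not s.startswith("L")]
        shift = dct.loc[cll, "delta_ct"].mean() - dct.loc[ctl, "delta_ct"].mean()
        assert shift == pytest.approx(-3.0, abs=1e-9)

    def test_zero_effect_gives_unit_fold(self):
        cfg = null_cohort_config(0, n_features=6, n_cll=4, n_control=3)
        _, table, truth = cm.generate_cohort(cfg)
        ct = cm.generate_ct_table(
            cfg, truth, targets=["miR-null-0"], replicate_sd=0.0
        )
        ctl = [s for s in ct["sample_id"].unique() if s.startswith("CB")]
        rel = cm.delta_delta_ct(ct, calibrator=ctl)
        np.testing.assert_allclose(rel["fold"], 1.0, atol=1e-9)

    def test_reference_designation_required(self):
        cfg = small_config()
        _, _, truth = cm.generate_cohort(cfg)
        with pytest.raises(ValueError, match="reference"):
            cm.generate_ct_table(cfg, truth, reference="")

    def test_every_sample_has_reference_rows(self):
        cfg = small_config()
        _, _, truth = cm.generate_cohort(cfg)
        ct = cm.generate_ct_table(cfg, truth)
        refs = ct[ct["target"] == "RNU44"]
        assert set(refs["sample_id"]) == set(ct["sample_id"])


def test_ground_truth_round_trips_through_json(tmp_path):
    cfg = small_config(seed=4)
    mat, table, truth = cm.generate_cohort(cfg)
    table = cm.generate_survival(cfg, truth, table, mat)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = cm.GroundTruth.from_json(path)
    assert back.true_up == truth.true_up
    assert back.true_down == truth.true_down
    assert back.true_cutpoints == truth.true_cutpoints
    pd.testing.assert_frame_equal(
        back.group_means_log2[truth.group_means_log2.columns],
        truth.group_means_log2,
    )
    pd.testing.assert_frame_equal(
        back.latent_log2[truth.latent_log2.columns], truth.latent_log2
    )
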