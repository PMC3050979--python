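import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import cllmir as cm
from conftest import null_cohort_config

floats = st.floats(-50.0, 50.0, allow_nan=False)
classes = st.lists(floats, min_size=2, max_size=10)


class TestSnrScore:
    def test_identical_groups_score_zero(self):
        assert cm.snr_score([3, 4, 5], [3, 4, 5]) == 0.0

    def test_hand_computed_value(self):
        # mu=(2,5), s=(1,1): (2-5)/sqrt(2)
        assert cm.snr_score([1, 2, 3], [4, 5, 6]) == pytest.approx(
            -3 / math.sqrt(2)
        )

    def test_higher_in_class1_is_positive(self):
        assert cm.snr_score([10, 11, 12], [1, 2, 3]) > 0

    def test_degenerate_zero_variance(self):
        assert cm.snr_score([2, 2, 2], [2, 2]) == 0.0
        with pytest.warns(UserWarning, match="zero within-class variance"):
            assert cm.snr_score([3, 3], [1, 1]) == math.inf

    def test_class_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            cm.snr_score([1.0], [2.0, 3.0])

    @given(classes, classes)
    def test_antisymmetry(self, a, b):
        assert cm.snr_score(a, b) == -cm.snr_score(b, a)

    @given(classes, classes, st.floats(-10, 10), st.floats(0.1, 10))
    def test_shift_and_scale_invariance(self, a, b, shift, scale):
        a, b = np.asarray(a), np.asarray(b)
        base = cm.snr_score(a, b)
        assert cm.snr_score(a + shift, b + shift) == pytest.approx(
            base, rel=1e-9, abs=1e-9
        )
        assert cm.snr_score(a * scale, b * scale) == pytest.approx(
            base, rel=1e-9, abs=1e-9
        )


def bh_brute_force(p):
    """O(m^2) step-up: q_i = min over ranks j >= rank(i) of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, i in enumerate(order):
        q[i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(pos, m)), 1.0
        )
    return q


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert cm.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            cm.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(cm.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cm.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_and_is_monotone(self, p):
        q = cm.bh_adjust(p)
        np.testing.assert_allclose(q, bh_brute_force(p), atol=1e-12)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(p) - 1e-12).all()


class TestMarkerSelection:
    def test_permuting_samples_leaves_scores_identical(self, normalized_cohort):
        _, norm, table, _, _ = normalized_cohort
        labels = {s: g for s, g in table["group"].items() if g != "activated_B"}
        base = cm.marker_selection(norm, labels, class1="CLL")
        perm_cols = list(norm.columns)[::-1]
        perm = cm.marker_selection(norm[perm_cols], labels, class1="CLL")
        pd.testing.assert_frame_equal(base, perm)

    def test_planted_up_set_tops_ranking(self):
        """Top-5 scores (CLL as class 1) recover the planted up set in
        >=90% of 20 seeds."""
        hits = 0
        for seed in range(20):
            cfg = cm.CohortConfig(seed=seed)
            mat, table, truth = cm.generate_cohort(cfg)
            norm, _ = cm.normalize_matrix(mat)
            labels = {
                s: g for s, g in table["group"].items() if g != "activated_B"
            }
            mk = cm.marker_selection(norm, labels, class1="CLL")
            hits += set(mk.head(len(truth.true_up))["feature"]) == set(
                truth.true_up
            )
        assert hits >= 18

    def test_small_class_rejected(self):
        X = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        with pytest.raises(ValueError, match="2 samples"):
            cm.SNRMarkerRanker().fit(X, ["A", "B", "B", "B"])

    def test_class1_designation_flips_sign(self, normalized_cohort):
        _, norm, table, _, _ = normalized_cohort
        labels = {s: g for s, g in table["group"].items() if g != "activated_B"}
        a = cm.marker_selection(norm, labels, class1="CLL").set_index("feature")
        b = cm.marker_selection(norm, labels, class1="control_B").set_index("feature")
        np.testing.assert_allclose(a["score"], -b.loc[a.index, "score"])


class TestActivationSignature:
    def test_alpha_one_assigns_every_feature_by_sign(self, normalized_cohort):
        _, norm, table, _, _ = normalized_cohort
        sig = cm.derive_activation_signature(norm, table["group"], alpha=1.0)
        assert len(sig.up) + len(sig.down) == norm.shape[0]

    def test_null_cohort_gives_empty_signature(self):
        import warnings

        empties = 0
        for seed in range(20):
            cfg = null_cohort_config(seed, n_features=30)
            mat, table, _ = cm.generate_cohort(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                sig = cm.derive_activation_signature(np.log2(mat), table["group"])
            empties += sig.is_empty
        assert empties >= 18

    def test_groups_required(self, normalized_cohort):
        _, norm, table, _, _ = normalized_cohort
        labels = table["group"].replace("activated_B", "control_B")
        with pytest.raises(ValueError, match="activated"):
            cm.derive_activation_signature(norm, labels)


def fisher_brute_force(table):
    """Two-sided Fisher p by exhaustive enumeration of 2x2 tables with
    the observed margins, summing probabilities <= the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = stats.hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


class TestClinicalAssociation:
    def make_cohort(self, seed=0):
        cfg = cm.CohortConfig(seed=seed)
        mat, table, truth = cm.generate_cohort(cfg)
        norm, _ = cm.normalize_matrix(mat)
        return norm, table

    def test_identical_expression_gives_p_one(self):
        norm, table = self.make_cohort()
        cll = [s for s in norm.columns if table.loc[s, "group"] == "CLL"]
        flat = norm[cll].copy()
        flat.loc["miR-29c"] = 5.0  # identical across all patients -> all ties
        res = cm.clinical_association(
            flat, table[table["group"] == "CLL"], "zap70", features=["miR-29c"]
        )
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        tab = [[8, 1], [2, 9]]
        _, p = stats.fisher_exact(tab)
        assert p == pytest.approx(fisher_brute_force(tab), abs=1e-12)

    def test_planted_zap70_association_recovered(self):
        """ZAP70+ is assigned from the latent prognostic score, so the
        prognostic miRNAs associate with ZAP70 at q <= 0.10."""
        hits = 0
        for seed in range(20):
            norm, table = self.make_cohort(seed)
            res = cm.clinical_association(
                norm, table[table["group"] == "CLL"], "zap70"
            ).set_index("feature")
            hits += (res.loc[["miR-29c", "miR-223"], "q"] <= 0.10).all()
        assert hits >= 18

    def test_kruskal_used_for_three_categories(self):
        norm, table = self.make_cohort()
        table = table.copy()
        cll = table[table["group"] == "CLL"].index
        cats = ["low", "mid", "high"] * (len(cll) // 3 + 1)
        table.loc[cll, "stage"] = cats[: len(cll)]
        res = cm.clinical_association(
            norm, table.loc[cll], "stage", features=["miR-155"]
        )
        assert res["test"].iloc[0] == "kruskal"

    def test_constant_covariate_rejected(self):
        norm, table = self.make_cohort()
        table = table.copy()
        table.loc[table["group"] == "CLL", "zap70"] = "pos"
        with pytest.raises(ValueError, match="constant"):
            cm.clinical_association(norm, table[table["group"] == "CLL"], "zap70")


def test_welch_p_uniform_under_null():
    """Welch p-values across 1000 null features pass a KS uniformity
    check."""
    cfg = null_cohort_config(7, n_features=1000)
    mat, table, _ = cm.generate_cohort(cfg)
    labels = {s: g for s, g in table["group"].items() if g != "activated_B"}
    mk = cm.marker_selection(np.log2(mat), labels)
    assert stats.kstest(mk["p"], "uniform").pvalue > 0.01
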