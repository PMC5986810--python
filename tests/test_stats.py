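"""Mixed ANOVA, FDR, permutation machinery and the full pipeline."""

import json

import numpy as np
import pandas as pd
import pytest

from sadnet import (
    GROUPS,
    PARADIGMS,
    compare_group_correlations,
    edge_condition_tests,
    fdr_adjust,
    interaction_anova,
    permutation_group_diff,
    permutation_interaction_test,
    run_pipeline,
)


def _worked_dataset():
    """2 groups x 2 subjects x 2 paradigms with hand-checkable sums of squares."""
    data = {("g1", "s1"): (1, 3), ("g1", "s2"): (2, 6), ("g2", "s3"): (4, 4), ("g2", "s4"): (5, 5)}
    rows = []
    for (g, s), (p1, p2) in data.items():
        rows.append({"subject": s, "group": g, "paradigm": "P1", "y": p1})
        rows.append({"subject": s, "group": g, "paradigm": "P2", "y": p2})
    return pd.DataFrame(rows)


class TestInteractionAnova:
    def test_worked_dataset_sums_of_squares(self):
        # grand mean 3.75; SS_group = SS_paradigm = SS_interaction = 4.5;
        # F_group = 1.8 against between-subject error, F_paradigm =
        # F_interaction = 9 against the within-subject residual
        df = _worked_dataset()
        table = interaction_anova(df["y"], df["subject"], df["paradigm"], df["group"])
        for effect in ("group", "paradigm", "interaction"):
            assert table.loc[effect, "ss"] == pytest.approx(4.5, abs=1e-10)
        assert table.loc["group", "F"] == pytest.approx(1.8, abs=1e-10)
        assert table.loc["paradigm", "F"] == pytest.approx(9.0, abs=1e-10)
        assert table.loc["interaction", "F"] == pytest.approx(9.0, abs=1e-10)

    def test_matches_reference_mixed_anova_on_unbalanced_groups(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        rows = []
        for i in range(22):
            g = "A" if i < 12 else "B"
            base = rng.normal()
            for p in ("P1", "P2"):
                bump = 0.6 if (g == "A" and p == "P2") else 0.0
                rows.append(
                    {"subject": f"s{i}", "group": g, "paradigm": p, "y": base + bump + rng.normal()}
                )
        df = pd.DataFrame(rows)
        mine = interaction_anova(df["y"], df["subject"], df["paradigm"], df["group"])
        ref = pg.mixed_anova(data=df, dv="y", within="paradigm", between="group", subject="subject")
        ref_f = dict(zip(ref["Source"], ref["F"]))
        assert mine.loc["group", "F"] == pytest.approx(ref_f["group"], abs=1e-8)
        assert mine.loc["paradigm", "F"] == pytest.approx(ref_f["paradigm"], abs=1e-8)
        assert mine.loc["interaction", "F"] == pytest.approx(ref_f["Interaction"], abs=1e-8)

    def test_additive_shift_in_both_groups_is_not_an_interaction(self):
        rng = np.random.default_rng(2)
        pvals = []
        for rep in range(40):
            rows = []
            for i in range(20):
                g = "A" if i < 10 else "B"
                base = rng.normal()
                for p, bump in (("P1", 0.0), ("P2", 1.0)):  # same shift in both groups
                    rows.append(
                        {"subject": f"s{i}", "group": g, "paradigm": p,
                         "y": base + bump + 0.5 * rng.normal()}
                    )
            df = pd.DataFrame(rows)
            table = interaction_anova(df["y"], df["subject"], df["paradigm"], df["group"])
            pvals.append(table.loc["interaction", "p"])
        assert np.mean(np.asarray(pvals) < 0.05) < 0.2

    def test_group_specific_shift_detected_at_n22(self):
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(20):
            rows = []
            for i in range(22):
                g = "A" if i < 12 else "B"
                base = rng.normal()
                for p in ("P1", "P2"):
                    bump = 2.0 if (g == "A" and p == "P2") else 0.0
                    rows.append(
                        {"subject": f"s{i}", "group": g, "paradigm": p,
                         "y": base + bump + 0.5 * rng.normal()}
                    )
            df = pd.DataFrame(rows)
            table = interaction_anova(df["y"], df["subject"], df["paradigm"], df["group"])
            hits += table.loc["interaction", "p"] < 0.01
        assert hits >= 18  # >= 90% power at a large planted effect

    def test_unbalanced_subject_fails_with_name(self):
        df = _worked_dataset().iloc[:-1]
        with pytest.raises(ValueError, match="s4"):
            interaction_anova(df["y"], df["subject"], df["paradigm"], df["group"])

    def test_permutation_variant_agrees_in_direction(self):
        df = _worked_dataset()
        res = permutation_interaction_test(
            df["y"], df["subject"], df["paradigm"], df["group"], n_perm=500, seed=0
        )
        assert res.p <= 1.0 and res.observed == pytest.approx(3.0)  # |(3-1+6-2)/2 - 0|


class TestFdr:
    def _brute_force(self, pvals, alpha):
        """Step-up rule straight from its definition."""
        p = np.asarray(pvals, dtype=float)
        m = len(p)
        order = np.argsort(p)
        ranked = p[order]
        k_max = 0
        for k in range(1, m + 1):
            if ranked[k - 1] <= k * alpha / m:
                k_max = k
        reject = np.zeros(m, dtype=bool)
        reject[order[:k_max]] = True
        adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
        adjusted = np.empty(m)
        adjusted[order] = np.minimum(adj, 1.0)
        return adjusted, reject

    def test_hand_example_three_rejections(self):
        adjusted, reject = fdr_adjust([0.001, 0.02, 0.03, 0.5], alpha=0.05)
        assert reject.sum() == 3
        assert not reject[3]
        assert np.all(adjusted >= [0.001, 0.02, 0.03, 0.5])

    def test_all_ones_no_rejections(self):
        _, reject = fdr_adjust(np.ones(10))
        assert not reject.any()

    def test_single_p_unchanged(self):
        adjusted, _ = fdr_adjust([0.03])
        assert adjusted[0] == pytest.approx(0.03)

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(500):
            m = int(rng.integers(1, 25))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            adjusted, reject = fdr_adjust(p, alpha=0.05)
            exp_adj, exp_rej = self._brute_force(p, 0.05)
            np.testing.assert_allclose(adjusted, exp_adj, atol=1e-12)
            np.testing.assert_array_equal(reject, exp_rej)


class TestPermutationGroupDiff:
    @staticmethod
    def _mean_diff(data, labels):
        names = list(dict.fromkeys(labels))
        return data[np.asarray(labels) == names[0]].mean() - data[np.asarray(labels) == names[1]].mean()

    def test_extreme_statistic_gets_near_minimal_p(self):
        # the observed split is the unique maximizer, but a random
        # relabeling can redraw it (probability 1/252 per resample), so p
        # sits at the add-one floor plus the handful of such ties
        data = np.array([10.0] * 5 + [0.0] * 5)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        res = permutation_group_diff(self._mean_diff, data, labels, n_perm=250, tail="one", seed=0)
        assert 1 / 251 <= res.p <= 6 / 251

    def test_same_seed_identical(self, rng):
        data = rng.standard_normal(12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        a = permutation_group_diff(self._mean_diff, data, labels, n_perm=200, seed=5)
        b = permutation_group_diff(self._mean_diff, data, labels, n_perm=200, seed=5)
        assert (a.observed, a.p) == (b.observed, b.p)

    def test_constant_statistic_warns_with_p_one(self):
        data = np.ones(8)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.warns(UserWarning, match="constant"):
            res = permutation_group_diff(self._mean_diff, data, labels, n_perm=100, seed=0)
        assert res.p == 1.0


class TestEdgeConditionTests:
    def test_nineteen_tests_per_hub_and_planted_edge_found(self, small_cohort, small_cohort_matrices):
        _, by_subject = small_cohort_matrices
        groups = {s.subject_id: s.group for s in small_cohort.subjects}
        table = edge_condition_tests(by_subject, "dlPFCl", groups)
        assert len(table) == 19
        assert (table["p_fdr"] >= table["p_interaction"] - 1e-12).all()
        # follow-up paired t-tests filled only for significant edges
        sig = table["significant"]
        for g in set(groups.values()):
            col = table[f"paired_t_p[{g}]"]
            assert col[~sig].isna().all()

    def test_unknown_hub_rejected(self, small_cohort, small_cohort_matrices):
        _, by_subject = small_cohort_matrices
        groups = {s.subject_id: s.group for s in small_cohort.subjects}
        with pytest.raises(ValueError, match="not among"):
            edge_condition_tests(by_subject, "nope", groups)


class TestCompareGroupCorrelations:
    def test_planted_difference_detected(self):
        rng = np.random.default_rng(4)
        hits = 0
        for rep in range(20):
            x = rng.standard_normal(22)
            y = np.empty(22)
            y[:11] = -x[:11]  # first group exactly on a line (r = -1)
            y[11:] = rng.standard_normal(11)  # second group independent
            labels = np.array(["a"] * 11 + ["b"] * 11)
            out = compare_group_correlations(x, y, labels, n_perm=200, seed=rep, alternative="less")
            assert out["r"]["a"] == pytest.approx(-1.0)
            hits += out["p"] <= 0.05
        assert hits >= 19

    def test_deterministic(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        a = compare_group_correlations(x, y, labels, n_perm=150, seed=3)
        b = compare_group_correlations(x, y, labels, n_perm=150, seed=3)
        assert a == b

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_group_correlations(
                np.arange(5.0), np.arange(5.0), np.array(["a", "a", "b", "b", "b"])
            )


class TestPipeline:
    CONFIG = {
        "simulate": {"n_subjects_high": 3, "n_subjects_low": 3, "n_volumes": 160, "tr": 2.0},
        "graph": {"n_restarts": 10, "n_perm": 200, "gamma_neg_grid": [0.35, 0.45]},
    }

    def test_smoke_report_sections(self, tmp_path):
        report = run_pipeline(self.CONFIG, out_dir=tmp_path / "out", seed=11)
        for key in (
            "communities",
            "hubs",
            "edge_tests",
            "behavior",
            "selected_threshold_pct",
            "gamma_scan",
            "q_contrast",
        ):
            assert key in report
        assert report["n_subjects"] == 6
        for p in PARADIGMS:
            assert len(report["communities"][p]["partition"]) == 20
        assert set(report["edge_tests"]) == {"dlPFCl", "mFPl"}
        assert len(report["edge_tests"]["dlPFCl"]) == 19
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "behavioral_summary.tsv").exists()

    def test_same_seed_byte_identical_report(self, tmp_path):
        run_pipeline(self.CONFIG, out_dir=tmp_path / "a", seed=5)
        run_pipeline(self.CONFIG, out_dir=tmp_path / "b", seed=5)
        a = (tmp_path / "a" / "report.json").read_bytes()
        b = (tmp_path / "b" / "report.json").read_bytes()
        assert a == b

    def test_reads_cohort_directory(self, tmp_path, small_cohort):
        from sadnet import write_cohort

        write_cohort(small_cohort, tmp_path / "cohort")
        cfg = dict(self.CONFIG)
        cfg["input_dir"] = str(tmp_path / "cohort")
        report = run_pipeline(cfg, seed=2)
        assert report["n_subjects"] == 6
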