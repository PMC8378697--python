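"""Outlier screening, paired tests, Holm correction, and mixed models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazekit.report import (
    build_report,
    fit_task_effector_model,
    fit_task_eccentricity_model,
    holm_bonferroni,
    paired_comparison,
    screen_outliers,
)


class TestScreenOutliers:
    def test_equal_values_no_flags(self):
        df = pd.DataFrame(
            {"task": ["w"] * 5, "measure": ["m"] * 5, "value": [2.0] * 5}
        )
        assert not screen_outliers(df)["outlier"].any()

    def test_far_value_flagged(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 8.0]
        df = pd.DataFrame(
            {"task": ["w"] * 7, "measure": ["m"] * 7, "value": vals}
        )
        out = screen_outliers(df)
        assert out["outlier"].tolist() == [False] * 6 + [True]

    def test_flagging_is_per_condition(self):
        df = pd.DataFrame(
            {
                "task": ["w"] * 6 + ["s"] * 6,
                "measure": ["m"] * 12,
                "value": [1, 1.1, 0.9, 1, 1.05, 6.0] + [6, 6.1, 5.9, 6, 6.05, 1.0],
            }
        )
        out = screen_outliers(df)
        assert out.loc[out["task"] == "w", "outlier"].sum() == 1
        assert out.loc[out["task"] == "s", "outlier"].sum() == 1


class TestPairedComparison:
    def test_matches_formula_oracle(self):
        """t and d agree with hand-rolled formulas to 1e-10."""
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 50)
        b = a - rng.normal(0.5, 1.0, 50)
        res = paired_comparison(a, b)
        diff = a - b
        t_hand = diff.mean() / (diff.std(ddof=1) / np.sqrt(50))
        d_hand = diff.mean() / diff.std(ddof=1)
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.cohens_d == pytest.approx(d_hand, abs=1e-10)
        assert res.df == 49

    def test_d_equals_t_over_sqrt_n(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 28), rng.normal(0.3, 1, 28)
        res = paired_comparison(a, b)
        assert res.cohens_d == pytest.approx(res.t_statistic / np.sqrt(28), abs=1e-6)

    def test_identical_vectors_rejected(self):
        v = np.arange(10.0)
        with pytest.raises(ValueError, match="zero variance"):
            paired_comparison(v, v)

    def test_constant_shift_rejected(self):
        v = np.arange(10.0)
        with pytest.raises(ValueError, match="zero variance"):
            paired_comparison(v + 1.0, v)


class TestHolm:
    def test_both_rejected_stepwise(self):
        reject, adj = holm_bonferroni(np.array([0.01, 0.04]))
        assert reject.tolist() == [True, True]
        assert adj == pytest.approx([0.02, 0.04])

    def test_step_down_stops_at_first_failure(self):
        reject, adj = holm_bonferroni(np.array([0.03, 0.04]))
        assert reject.tolist() == [False, False]

    def test_single_large_p(self):
        reject, _ = holm_bonferroni(np.array([0.5]))
        assert not reject[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni(np.array([0.5, 1.2]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(0, 0.2, 9)
        reject, adj = holm_bonferroni(p)
        sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05, method="holm")
        assert np.array_equal(reject, sm_rej)
        assert np.allclose(adj, sm_adj)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_fewer_rejections_than_bonferroni(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 12))
        holm_rej, adj = holm_bonferroni(p)
        bonf_rej = p <= 0.05 / p.size
        assert (holm_rej | ~bonf_rej).all()
        # adjusted p-values are monotone in raw-p order
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


def _spread_cohort(rng, n=28, task_effect=4.0, effector_effect=0.0, interaction=0.0):
    rows = []
    for p in range(n):
        u = rng.normal(0, 1)
        for task, toff in [("walking", 0.0), ("searching", task_effect)]:
            for eff, eoff in [("eye", 0.0), ("head", effector_effect)]:
                inter = interaction if (task == "searching" and eff == "head") else 0
                rows.append(
                    {
                        "participant": f"p{p}",
                        "task": task,
                        "effector": eff,
                        "value": 10 + u + toff + eoff + inter + rng.normal(0, 1.5),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedModels:
    def test_detects_task_effect_and_null_effector(self):
        """Strong task effect is detected; null effector term stays at the
        nominal false-positive level across replicates."""
        rng = np.random.default_rng(0)
        task_p, eff_p = [], []
        for _ in range(40):
            ms = fit_task_effector_model(_spread_cohort(rng))
            task_p.append(ms.terms["C(task)"]["p"])
            eff_p.append(ms.terms["C(effector)"]["p"])
        assert np.mean(np.array(task_p) < 0.05) == 1.0
        assert np.mean(np.array(eff_p) < 0.05) <= 0.15

    def test_duplication_invariance_of_estimates(self):
        rng = np.random.default_rng(1)
        df = _spread_cohort(rng, interaction=3.0)
        ms1 = fit_task_effector_model(df)
        ms2 = fit_task_effector_model(pd.concat([df, df], ignore_index=True))
        f1 = {k: v["F"] for k, v in ms1.terms.items()}
        # balanced duplication leaves the point estimates (hence F ordering)
        # qualitatively intact; interaction stays the dominant term
        assert ms2.terms["C(task):C(effector)"]["p"] < 0.01
        assert set(ms2.terms) == set(f1)

    def test_interaction_detected_when_head_gains_more(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(10):
            df = _spread_cohort(rng, task_effect=2.0, interaction=5.0)
            ms = fit_task_effector_model(df)
            hits += ms.terms["C(task):C(effector)"]["p"] < 0.05
        assert hits >= 9

    def test_eccentricity_model_null_and_alternative(self):
        rng = np.random.default_rng(3)
        null_rej, alt_rej, task_rej = 0, 0, 0
        reps = 10
        for _ in range(reps):
            rows = []
            for p in range(28):
                u = rng.normal(0, 3)
                for task, toff in [("walking", 0.0), ("searching", 10.0)]:
                    for b in (10, 20, 30, 40, 50, 60, 70, 80):
                        if rng.uniform() < 0.15:
                            continue  # absent bins allowed
                        rows.append(
                            {
                                "participant": f"p{p}",
                                "task": task,
                                "bin": b,
                                "value_null": 50 + u + toff + rng.normal(0, 4),
                                "value_alt": 40
                                + u
                                + toff
                                + 2.5 * (b - 10) / 10
                                + rng.normal(0, 4),
                            }
                        )
            df = pd.DataFrame(rows)
            ms_null = fit_task_eccentricity_model(
                df.rename(columns={"value_null": "value"})
            )
            ms_alt = fit_task_eccentricity_model(
                df.rename(columns={"value_alt": "value"})
            )
            null_rej += ms_null.terms["C(bin)"]["p"] < 0.05
            alt_rej += ms_alt.terms["C(bin)"]["p"] < 0.05
            task_rej += ms_alt.terms["C(task)"]["p"] < 0.05
        assert null_rej <= 1
        assert alt_rej >= 9
        assert task_rej == reps


def test_build_report_structure(tmp_path):
    rng = np.random.default_rng(4)
    table = pd.DataFrame(
        {
            "participant": ["p0", "p0", "p1", "p1"],
            "task": ["walking", "searching"] * 2,
            "effector": [None] * 4,
            "measure": ["mean_speed_ms"] * 4,
            "value": rng.uniform(0.5, 1.2, 4),
        }
    )
    report = build_report(table, out_dir=tmp_path)
    assert {r["task"] for r in report["locomotion"]} == {"walking", "searching"}
    assert (tmp_path / "report.json").exists()
    assert (tmp_path / "locomotion_table.csv").exists()


def test_report_without_head_marks_contribution_absent():
    table = pd.DataFrame(
        {
            "participant": ["p0", "p1", "p2"],
            "task": ["walking"] * 3,
            "effector": ["eye"] * 3,
            "measure": ["spread"] * 3,
            "value": [11.0, 12.0, 11.5],
        }
    )
    report = build_report(table, contribution_table=None)
    assert report["head_contribution"] is None
    assert report["spread"][0]["n"] == 3
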