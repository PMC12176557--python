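"""Nonparametric comparison layer: rank-test oracles, exclusion
handling, and the assembled suite."""

import numpy as np
import pandas as pd
import pytest

import metresponse as mr
from metresponse import stats as st


def signed_rank_oracle(x, y):
    """Brute-force two-sided Wilcoxon signed-rank statistic:
    min(T+, T-) over average ranks of nonzero |differences|."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(len(d))
    sorted_abs = absd[order]
    i = 0
    while i < len(d):
        j = i
        while j < len(d) and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average of ranks i+1..j
        i = j
    t_plus = ranks[d > 0].sum()
    t_minus = ranks[d < 0].sum()
    return min(t_plus, t_minus)


def kruskal_oracle(groups):
    """Brute-force Kruskal-Wallis H with tie correction."""
    allv = np.concatenate(groups)
    n = len(allv)
    order = np.argsort(allv, kind="stable")
    ranks = np.empty(n)
    sv = allv[order]
    i = 0
    tie_term = 0.0
    while i < n:
        j = i
        while j < n and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        t = j - i
        tie_term += t**3 - t
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    correction = 1.0 - tie_term / (n**3 - n)
    return h / correction if correction > 0 else 0.0


class TestPairedTest:
    def test_identical_pairs_degenerate(self):
        idx = list("abcde")
        a = pd.Series([1.0, 2, 3, 4, 5], index=idx)
        res = st.paired_longitudinal_test(a, a)
        assert res.degenerate and res.p_value == 1.0

    def test_statistic_matches_bruteforce(self):
        idx = list("abcdef")
        a = pd.Series([1.0, 2, 3, 4, 5, 6], index=idx)
        b = pd.Series([2.0, 3, 4, 5, 6, 7], index=idx)
        res = st.paired_longitudinal_test(a, b)
        assert res.statistic == pytest.approx(signed_rank_oracle(a, b))

    def test_random_pairs_match_bruteforce(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            n = int(rng.integers(3, 20))
            idx = [f"p{i}" for i in range(n)]
            a = pd.Series(rng.normal(size=n), index=idx)
            b = pd.Series(a.to_numpy() + rng.normal(size=n), index=idx)
            res = st.paired_longitudinal_test(a, b)
            assert res.statistic == pytest.approx(signed_rank_oracle(a, b))

    def test_missing_value_excluded_and_listed(self):
        idx = list("abcd")
        a = pd.Series([1.0, 2, 3, 4], index=idx)
        b = pd.Series([2.0, 4, np.nan, 1], index=idx)
        res = st.paired_longitudinal_test(a, b)
        assert res.n_used == 3
        assert res.excluded_patients == ["c"]

    def test_too_few_pairs_errors(self):
        a = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            st.paired_longitudinal_test(a, a)


class TestGroupTest:
    def test_identical_multisets_h_zero(self):
        idx = [f"p{i}" for i in range(6)]
        v = pd.Series([1.0, 2, 3, 1, 2, 3], index=idx)
        lab = pd.Series([True] * 3 + [False] * 3, index=idx)
        res = st.group_test(v, lab)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_match_bruteforce(self):
        idx = [f"p{i}" for i in range(6)]
        v = pd.Series([1.0, 2, 3, 10, 11, 12], index=idx)
        lab = pd.Series([True] * 3 + [False] * 3, index=idx)
        res = st.group_test(v, lab)
        assert res.statistic == pytest.approx(kruskal_oracle([[10, 11, 12], [1, 2, 3]]))

    def test_random_groups_match_bruteforce(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            idx = [f"p{i}" for i in range(n)]
            v = pd.Series(rng.integers(0, 5, n).astype(float), index=idx)
            lab = pd.Series(rng.random(n) < 0.5, index=idx)
            if lab.all() or (~lab).all() or v.nunique() == 1:
                continue
            res = st.group_test(v, lab)
            groups = [v[lab == lev].to_numpy() for lev in sorted(lab.unique(), key=str)]
            assert res.statistic == pytest.approx(kruskal_oracle(groups))

    def test_single_class_errors(self):
        idx = list("abc")
        v = pd.Series([1.0, 2, 3], index=idx)
        lab = pd.Series([True, True, True], index=idx)
        with pytest.raises(ValueError, match="2 groups"):
            st.group_test(v, lab)


class TestCorrelate:
    def test_perfect_positive(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        res = st.correlate(x, 2 * x)
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        res = st.correlate(x, -x)
        assert res.statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(3, 40))
            idx = [f"p{i}" for i in range(n)]
            x = pd.Series(rng.normal(size=n), index=idx)
            y = pd.Series(rng.normal(size=n), index=idx)
            if x.nunique() < 2 or y.nunique() < 2:
                continue
            res = st.correlate(x, y)
            xv, yv = x.to_numpy(), y.to_numpy()
            r = np.sum((xv - xv.mean()) * (yv - yv.mean())) / np.sqrt(
                np.sum((xv - xv.mean()) ** 2) * np.sum((yv - yv.mean()) ** 2)
            )
            assert res.statistic == pytest.approx(r)

    def test_zero_variance_degenerate(self):
        x = pd.Series([1.0, 1, 1], index=list("abc"))
        y = pd.Series([1.0, 2, 3], index=list("abc"))
        res = st.correlate(x, y)
        assert res.degenerate and np.isnan(res.statistic)


class TestSuite:
    def _metrics_and_labels(self, lesions, clinical):
        summ = mr.volumetric_summary(lesions)
        labels = mr.classify_cohort(clinical, summ)
        metrics = st.metrics_long_table(
            mr.dissemination_table(lesions),
            edge_counts=mr.edge_count_table(lesions),
            volumetrics=summ,
        )
        return metrics, labels[["patient_id", "er_4wk", "bor_responder", "lte", "lr"]]

    def test_row_cardinality(self, small_cohort):
        _, lesions, clinical, _ = small_cohort
        metrics, labels = self._metrics_and_labels(lesions, clinical)
        res = st.run_comparison_suite(metrics, labels)
        n_metrics = metrics["metric"].nunique()
        assert len(res) == n_metrics * 4 * 3 + n_metrics * 3

    def test_patient_reordering_invariance(self, small_cohort):
        _, lesions, clinical, _ = small_cohort
        metrics, labels = self._metrics_and_labels(lesions, clinical)
        res1 = st.run_comparison_suite(metrics, labels)
        res2 = st.run_comparison_suite(
            metrics.sample(frac=1.0, random_state=1),
            labels.sample(frac=1.0, random_state=2),
        )
        np.testing.assert_allclose(
            res1["p_value"].to_numpy(), res2["p_value"].to_numpy(), equal_nan=True
        )

    def test_identical_patients_no_significance(self):
        rows = []
        for i in range(8):
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "timepoint": "t0",
                    "metric": "total_volume",
                    "value": 100.0,
                }
            )
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "timepoint": "t1",
                    "metric": "total_volume",
                    "value": 100.0,
                }
            )
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "timepoint": "t2",
                    "metric": "total_volume",
                    "value": 100.0,
                }
            )
        metrics = pd.DataFrame(rows)
        labels = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(8)], "grp": [True] * 4 + [False] * 4}
        )
        res = st.run_comparison_suite(metrics, labels)
        ok = res[res.p_value.notna()]
        assert not ok["significant"].any()

    def test_injected_volume_effect_detected(self):
        """A strong responder volume effect makes volume-change group
        rows significant while permuted labels stay null on average."""
        cfg = mr.CohortConfig(
            n_patients=40,
            seed=21,
            responder_fraction=0.5,
            arm1_change={"responder": (0.4, 0.05), "non_responder": (1.0, 0.05)},
        )
        lesions, clinical, truth = mr.generate_cohort(cfg)
        summ = mr.volumetric_summary(lesions).set_index("patient_id")
        gt = truth.set_index("patient_id")["responder"]
        res = st.group_test(summ["change_pct_t0_t1"], gt)
        assert res.p_value < 1e-4
        rng = np.random.default_rng(0)
        perm_ps = []
        for _ in range(20):
            perm = pd.Series(rng.permutation(gt.to_numpy()), index=gt.index)
            perm_ps.append(st.group_test(summ["change_pct_t0_t1"], perm).p_value)
        assert np.median(perm_ps) > 0.05
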