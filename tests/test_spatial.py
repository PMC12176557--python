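"""Anatomical networks, co-occurrence, dissemination metrics, presence grid."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import metresponse as mr
from metresponse.spatial import patient_site_sets

from conftest import lesion_frame, make_lesion_row


class TestPatientNetwork:
    @pytest.mark.parametrize("k,edges", [(0, 0), (1, 0), (2, 2), (4, 12), (10, 90)])
    def test_ordered_edge_count_law(self, k, edges):
        sites = list(mr.DEFAULT_TAXONOMY.codes)[:k]
        g = mr.build_patient_network(sites)
        assert g.number_of_edges() == edges == k * (k - 1)

    def test_unordered_convention(self):
        g = mr.build_patient_network([2, 3, 5, 13], convention="unordered")
        assert g.number_of_edges() == 6

    def test_unknown_site_rejected(self):
        with pytest.raises(KeyError):
            mr.build_patient_network([2, 4])


class TestCombineNetworks:
    def test_single_patient_identity(self):
        g = mr.build_patient_network([2, 3, 5])
        c = mr.combine_networks([g])
        assert set(c.nodes) == {2, 3, 5}
        assert all(c.nodes[n]["weight"] == 1 for n in c.nodes)
        assert all(c[u][v]["weight"] == 1 for u, v in c.edges)
        assert c.number_of_edges() == g.number_of_edges()

    def test_three_patients_same_pair(self):
        nets = [mr.build_patient_network([2, 3]) for _ in range(3)]
        c = mr.combine_networks(nets)
        assert c[2][3]["weight"] == 3
        assert c[3][2]["weight"] == 3
        assert c.nodes[2]["weight"] == 3

    def test_disjoint_patients(self):
        c = mr.combine_networks(
            [mr.build_patient_network([2]), mr.build_patient_network([3])]
        )
        assert c.number_of_edges() == 0
        assert c.nodes[2]["weight"] == 1 and c.nodes[3]["weight"] == 1

    def test_cohort_scope_rejected_as_input(self):
        c = mr.combine_networks([mr.build_patient_network([2, 3])])
        with pytest.raises(ValueError, match="patient-scope"):
            mr.combine_networks([c])

    def test_edge_weight_bounded_by_node_weights(self, small_cohort):
        _, lesions, _, _ = small_cohort
        nets = [
            mr.build_patient_network(s)
            for s in patient_site_sets(lesions, "t0").values()
        ]
        c = mr.combine_networks(nets)
        for u, v in c.edges:
            assert c[u][v]["weight"] <= min(c.nodes[u]["weight"], c.nodes[v]["weight"])


class TestCooccurrence:
    def test_one_patient_two_sites(self):
        df = lesion_frame(
            [
                make_lesion_row("A", "t0", 5, 1),
                make_lesion_row("A", "t0", 13, 1),
            ]
        )
        m = mr.cooccurrence_matrix(df, "t0")
        assert m.loc[5, 13] == m.loc[13, 5] == 1
        assert m.loc[5, 5] == m.loc[13, 13] == 1
        assert m.to_numpy().sum() == 4

    def test_empty_cohort_zero_matrix(self):
        df = pd.DataFrame(columns=mr.cohort.LESION_COLUMNS)
        df = df.astype({"site_code": int, "lesion_index": int})
        m = mr.cooccurrence_matrix(mr.validate_lesion_table(df), "t0")
        assert (m.to_numpy() == 0).all()

    def test_random_cohort_vs_exhaustive_counting(self, small_cohort):
        _, lesions, _, _ = small_cohort
        for tp in mr.TIMEPOINTS:
            m = mr.cooccurrence_matrix(lesions, tp)
            sets = patient_site_sets(lesions, tp)
            for a in mr.DEFAULT_TAXONOMY.codes:
                assert m.loc[a, a] == sum(a in s for s in sets.values())
                for b in mr.DEFAULT_TAXONOMY.codes:
                    if a != b:
                        expect = sum(a in s and b in s for s in sets.values())
                        assert m.loc[a, b] == expect

    def test_cohort_edge_weights_equal_cooccurrence(self, small_cohort):
        _, lesions, _, _ = small_cohort
        m = mr.cooccurrence_matrix(lesions, "t0")
        nets = [
            mr.build_patient_network(s)
            for s in patient_site_sets(lesions, "t0").values()
        ]
        c = mr.combine_networks(nets)
        for a, b in itertools.permutations(mr.DEFAULT_TAXONOMY.codes, 2):
            got = c[a][b]["weight"] if c.has_edge(a, b) else 0
            assert got == m.loc[a, b]


class TestLnCooccurrence:
    def test_all_single_ln_zero_pct(self):
        df = lesion_frame(
            [make_lesion_row(p, "t0", 13, 1) for p in ("A", "B", "C")]
        )
        assert mr.ln_cooccurrence_fraction(df, "t0") == 0.0

    def test_two_of_three_multi_ln(self):
        rows = [
            make_lesion_row("A", "t0", 13, 1),
            make_lesion_row("A", "t0", 14, 1),
            make_lesion_row("B", "t0", 15, 1),
            make_lesion_row("B", "t0", 16, 1),
            make_lesion_row("C", "t0", 17, 1),
        ]
        frac = mr.ln_cooccurrence_fraction(lesion_frame(rows), "t0")
        assert frac == pytest.approx(200.0 / 3.0)

    def test_no_ln_patients_undefined(self):
        df = lesion_frame([make_lesion_row("A", "t0", 5, 1)])
        assert mr.ln_cooccurrence_fraction(df, "t0") is None


class TestDissemination:
    def _obs(self, coms, n_lesions=None):
        n = len(coms)
        return pd.DataFrame(
            {
                "patient_id": ["A"] * n,
                "timepoint": ["t0"] * n,
                "site_code": list(mr.DEFAULT_TAXONOMY.codes)[:n],
                "total_volume_mm3": [10.0] * n,
                "n_lesions": n_lesions or [1] * n,
                "com_x_mm": [c[0] for c in coms],
                "com_y_mm": [c[1] for c in coms],
                "com_z_mm": [c[2] for c in coms],
            }
        )

    def test_three_four_five_triangle(self):
        m = mr.dissemination_metrics(self._obs([(0, 0, 0), (3, 4, 0)]))
        assert m["total_intersite_distance_mm"] == 5.0
        assert m["max_intersite_distance_mm"] == 5.0

    def test_single_site_zero_distances(self):
        m = mr.dissemination_metrics(self._obs([(1, 2, 3)]))
        assert m["total_intersite_distance_mm"] == 0.0
        assert m["max_intersite_distance_mm"] == 0.0

    def test_collinear_three_sites(self):
        m = mr.dissemination_metrics(self._obs([(0, 0, 0), (1, 0, 0), (2, 0, 0)]))
        assert m["total_intersite_distance_mm"] == pytest.approx(4.0)
        assert m["max_intersite_distance_mm"] == pytest.approx(2.0)

    def test_bruteforce_double_loop_and_translation_invariance(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(0, 11))
            coms = rng.normal(0, 100, (n, 3))
            m = mr.dissemination_metrics(self._obs([tuple(c) for c in coms]))
            total = 0.0
            dmax = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    d = float(np.linalg.norm(coms[i] - coms[j]))
                    total += d
                    dmax = max(dmax, d)
            assert m["total_intersite_distance_mm"] == pytest.approx(total)
            assert m["max_intersite_distance_mm"] == pytest.approx(dmax)
            assert m["max_intersite_distance_mm"] <= m["total_intersite_distance_mm"] + 1e-12
            shift = rng.normal(0, 500, 3)
            m2 = mr.dissemination_metrics(self._obs([tuple(c + shift) for c in coms]))
            assert m2["total_intersite_distance_mm"] == pytest.approx(total)

    def test_ratio_undefined_without_sites(self):
        m = mr.dissemination_metrics(self._obs([]))
        assert m["lesion_site_ratio"] is None
        assert m["n_sites"] == 0

    def test_table_n_sites_le_n_lesions(self, small_cohort):
        _, lesions, _, _ = small_cohort
        t = mr.dissemination_table(lesions)
        assert (t["n_sites"] <= t["n_lesions"]).all()

    def test_sites_lesions_correlation_in_range(self, small_cohort):
        _, lesions, _, _ = small_cohort
        t = mr.dissemination_table(lesions)
        t = t[t.timepoint == "t0"].set_index("patient_id")
        res = mr.correlate(t["n_sites"], t["n_lesions"])
        assert -1.0 <= res.statistic <= 1.0


class TestPresenceChecker:
    def test_single_record_single_true(self):
        grid = mr.presence_checker(lesion_frame([make_lesion_row("A", "t0", 5, 1)]))
        assert grid["present"].sum() == 1
        row = grid[grid.present].iloc[0]
        assert (row["patient_id"], row["site_code"], row["timepoint"]) == ("A", 5, "t0")

    def test_disappearing_site(self):
        rows = [make_lesion_row("A", "t0", 5, 1)]
        grid = mr.presence_checker(lesion_frame(rows))
        g = grid.set_index(["patient_id", "site_code", "timepoint"])["present"]
        assert g.loc[("A", 5, "t0")] and not g.loc[("A", 5, "t1")]

    def test_marginals_match_cooccurrence_diagonal(self, small_cohort):
        _, lesions, _, _ = small_cohort
        grid = mr.presence_checker(lesions)
        for tp in mr.TIMEPOINTS:
            m = mr.cooccurrence_matrix(lesions, tp)
            sub = grid[grid.timepoint == tp]
            marg = sub.groupby("site_code")["present"].sum()
            for code in mr.DEFAULT_TAXONOMY.codes:
                assert marg.loc[code] == m.loc[code, code]
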