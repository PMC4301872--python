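"""Container, I/O, collapsing, alignment and merge semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import sigscore as sg
from sigscore.core import FEATURE_COLUMNS

from conftest import make_compendium, make_sample_table


class TestExpressionIO:
    def test_round_trip(self, tiny_compendium, tmp_path):
        path = tmp_path / "expr.tsv"
        sg.write_expression(tiny_compendium, path)
        back = sg.read_expression(path)
        pd.testing.assert_frame_equal(back.values, tiny_compendium.values, atol=1e-9)
        pd.testing.assert_frame_equal(back.features, tiny_compendium.features)

    def test_missing_cells_round_trip(self, tmp_path):
        c = make_compendium([[1.0, np.nan], [np.nan, 2.0], [0.5, -0.5]])
        path = tmp_path / "expr.tsv"
        sg.write_expression(c, path)
        back = sg.read_expression(path, min_present_fraction=0.0)
        assert back.values.shape == (3, 2)
        assert np.isnan(back.values.iloc[0, 1]) and np.isnan(back.values.iloc[1, 0])

    def test_duplicate_probe_is_hard_error(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "probe_id\tgene_symbol\tentrez_id\ta1\n"
            "pX\tS\t1\t0.1\n"
            "pX\tS\t1\t0.2\n"
        )
        with pytest.raises(sg.SigscoreError, match="pX"):
            sg.read_expression(path)

    def test_non_numeric_cell_names_coordinates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "probe_id\tgene_symbol\tentrez_id\ta1\ta2\n"
            "p0\tS\t1\t0.1\t0.2\n"
            "p1\tS\t2\toops\t0.3\n"
        )
        with pytest.raises(sg.SigscoreError, match=r"p1.*a1|a1.*p1"):
            sg.read_expression(path)

    def test_low_coverage_features_dropped(self, tmp_path):
        c = make_compendium(
            [[1, np.nan, np.nan, np.nan], [1, 2, 3, 4]],
        )
        path = tmp_path / "expr.tsv"
        sg.write_expression(c, path)
        back = sg.read_expression(path, min_present_fraction=0.7)
        assert list(back.values.index) == ["p1"]


class TestCollapseProbes:
    def test_mean_of_two_probes(self):
        c = make_compendium([[1.0], [3.0]], entrez=["g", "g"])
        gm = sg.collapse_probes(c)
        assert gm.id_space == "entrez"
        assert gm.values.loc["g", "a0"] == pytest.approx(2.0)

    def test_missing_value_uses_remaining_probes(self):
        c = make_compendium([[1.0, np.nan], [3.0, 5.0]], entrez=["g", "g"])
        gm = sg.collapse_probes(c)
        assert gm.values.loc["g", "a1"] == pytest.approx(5.0)

    def test_unannotated_probes_dropped_and_empty_errors(self):
        c = make_compendium([[1.0], [2.0]], entrez=["", "7"])
        assert list(sg.collapse_probes(c).ids) == ["7"]
        all_blank = make_compendium([[1.0]], entrez=[""])
        with pytest.raises(sg.SigscoreError):
            sg.collapse_probes(all_blank)

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(10, 3))
        entrez = [str(g) for g in rng.integers(1, 5, size=10)]
        c = make_compendium(values, entrez=entrez)
        gm = sg.collapse_probes(c)
        # brute-force per-gene per-array mean
        for gene in set(entrez):
            rows = [i for i, e in enumerate(entrez) if e == gene]
            expected = values[rows].mean(axis=0)
            np.testing.assert_allclose(gm.values.loc[gene].to_numpy(), expected)


class TestAlignment:
    def test_printed_overlap_arithmetic(self):
        ids = [f"id{i}" for i in range(848)]
        sig = sg.import_signature([(i, "up") for i in ids], id_space="probe", name="s1p")
        c = make_compendium(np.zeros((825, 2)), probe_ids=ids[:825])
        _, _, report = sg.align_to_signature(c, sig)
        assert report.n_matched == 825
        assert report.percent_overlap == 97.3

    def test_full_containment_preserves_order(self):
        rng = np.random.default_rng(1)
        c = make_compendium(rng.normal(size=(6, 2)))
        sig = sg.import_signature(
            [("p4", "up"), ("p1", "down"), ("p3", "up")], id_space="probe"
        )
        gm, aligned, report = sg.align_to_signature(c, sig)
        assert report.percent_overlap == 100.0
        assert list(gm.ids) == ["p4", "p1", "p3"] == list(aligned.member_ids)

    def test_matched_set_equals_intersection_oracle(self):
        rng = np.random.default_rng(2)
        sig_ids = [f"x{i}" for i in rng.choice(100, size=50, replace=False)]
        mat_ids = [f"x{i}" for i in rng.choice(100, size=30, replace=False)]
        sig = sg.import_signature([(i, "up") for i in sig_ids], id_space="probe")
        c = make_compendium(rng.normal(size=(30, 2)), probe_ids=mat_ids)
        gm, _, report = sg.align_to_signature(c, sig)
        assert set(gm.ids) == set(sig_ids) & set(mat_ids)
        assert report.n_matched == len(set(sig_ids) & set(mat_ids))

    def test_zero_overlap_is_hard_error(self):
        c = make_compendium(np.zeros((2, 2)))
        sig = sg.import_signature([("absent", "up")], id_space="probe")
        with pytest.raises(sg.SigscoreError):
            sg.align_to_signature(c, sig)

    def test_collapse_then_align_commutes(self):
        rng = np.random.default_rng(3)
        entrez = ["1", "1", "2", "3", "3", "4"]
        c = make_compendium(rng.normal(size=(6, 4)), entrez=entrez)
        sig = sg.import_signature([("1", "up"), ("3", "down")], id_space="entrez")
        via_compendium, _, _ = sg.align_to_signature(c, sig)
        via_collapsed, _, _ = sg.align_to_signature(sg.collapse_probes(c), sig)
        pd.testing.assert_frame_equal(via_compendium.values, via_collapsed.values)


class TestMerge:
    def test_intersection_feature_count(self):
        rng = np.random.default_rng(4)
        a = make_compendium(rng.normal(size=(120, 3)), cohort="A")
        b = make_compendium(
            rng.normal(size=(110, 2)),
            probe_ids=[f"p{i}" for i in range(20, 130)],
            array_ids=["b0", "b1"],
            cohort="B",
        )
        merged = sg.merge_compendia([a, b])
        assert merged.n_features == 100
        assert merged.n_arrays == 5

    def test_three_singletons_keep_batch_labels(self):
        cs = [
            make_compendium([[float(i)], [float(i)]], array_ids=[f"arr{i}"], cohort=f"c{i}")
            for i in range(3)
        ]
        merged = sg.merge_compendia(cs)
        assert merged.n_arrays == 3
        assert merged.batches.nunique() == 3

    def test_overlapping_array_ids_error(self):
        a = make_compendium(np.zeros((3, 1)), array_ids=["same"])
        b = make_compendium(np.zeros((3, 1)), array_ids=["same"])
        with pytest.raises(sg.SigscoreError):
            sg.merge_compendia([a, b])

    @given(st.integers(0, 2**31 - 1))
    def test_feature_sets_match_intersection_oracle_and_associativity(self, seed):
        rng = np.random.default_rng(seed)
        id_sets = [rng.choice(40, size=rng.integers(10, 30), replace=False) for _ in range(3)]
        cs = [
            make_compendium(
                rng.normal(size=(len(ids), 1)),
                probe_ids=[f"p{i}" for i in sorted(ids)],
                array_ids=[f"arr{k}"],
                cohort=f"c{k}",
            )
            for k, ids in enumerate(id_sets)
        ]
        merged = sg.merge_compendia(cs)
        expected = set.intersection(*(set(f"p{i}" for i in ids) for ids in id_sets))
        assert set(merged.values.index) == expected
        reordered = sg.merge_compendia([cs[2], cs[0], cs[1]])
        assert set(reordered.values.index) == expected


class TestCohortSummary:
    def test_printed_patient_arithmetic(self):
        sizes = {"dSSc": 70, "lSSc": 10, "control": 26, "morphea": 4, "eos_fasciitis": 1}
        rows = []
        i = 0
        for dx, n in sizes.items():
            for _ in range(n):
                rows.append((f"a{i}", f"pt{i}", dx))
                i += 1
        s = make_sample_table(
            [r[0] for r in rows],
            [r[1] for r in rows],
            diagnosis=[r[2] for r in rows],
        )
        summary = sg.summarize_cohort(s)
        assert summary.n_patients == 111
        assert summary.patients_per_diagnosis == sizes
        assert sum(summary.patients_per_diagnosis.values()) == summary.n_patients

    def test_empty_table(self):
        assert sg.summarize_cohort(pd.DataFrame()).n_arrays == 0

    def test_conflicting_diagnosis_flagged_counted_once_as_latest(self):
        s = make_sample_table(
            ["a0", "a1"], ["pt0", "pt0"], diagnosis=["lSSc", "dSSc"]
        )
        summary = sg.summarize_cohort(s)
        assert summary.conflicting_diagnosis_patients == ("pt0",)
        assert summary.patients_per_diagnosis == {"dSSc": 1}

    def test_counts_match_set_oracle(self):
        rng = np.random.default_rng(5)
        n = 40
        pts = [f"pt{i}" for i in rng.integers(0, 15, size=n)]
        sites = rng.choice(["forearm_lesional", "back_nonlesional"], size=n)
        tps = rng.choice(["t0", "t6"], size=n)
        s = make_sample_table(
            [f"a{i}" for i in range(n)], pts, biopsy_site=list(sites), timepoint_label=list(tps)
        )
        summary = sg.summarize_cohort(s)
        assert summary.n_patients == len(set(pts))
        assert summary.n_unique_biopsies == len(set(zip(pts, sites, tps)))
        assert summary.n_arrays == n
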