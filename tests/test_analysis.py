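import itertools

import numpy as np
import pandas as pd
import pytest

from rtkrecruit.analytical import AnalyticalResult
from rtkrecruit.analysis import (
    RANK_METRICS,
    cluster_cell_lines,
    compare_numerical_vs_analytical,
    cross_cell_summary,
    rank_deviation,
    rank_partners,
    recruitment_matrix,
)
from rtkrecruit.cell_model import CellProfile, InteractionMap, RecruitmentResult


def fake_result(bound, cell="fake", igf1r=1e4):
    return RecruitmentResult(
        cell=cell, dose_nM=1.0, partners=sorted(bound), bound_copies=dict(bound),
        phospho_occupancy={}, crosslinked_fraction=0.5, igf1r_copies=igf1r,
    )


def fake_analytical(bound):
    order = sorted(bound, key=lambda p: (-bound[p], p))
    return AnalyticalResult(r_free=1e-9, names=tuple(sorted(bound)),
                            bound=dict(bound), ranking=order)


class TestRankings:
    def test_copy_number_ranks_shc1_above_irs1(self, hela_fixture):
        prof, imap = hela_fixture
        r = rank_partners("copy_number", profile=prof, imap=imap)
        assert r.rank_of("SHC1") < r.rank_of("IRS1")

    def test_kd_metric_equals_sorted_min_kd(self, hela_fixture):
        prof, imap = hela_fixture
        r = rank_partners("kd", imap=imap, profile=prof)
        resorted = sorted(r.order, key=lambda p: (imap.min_kd(p), p))
        assert list(r.order) == resorted

    def test_all_metrics_agree_on_a_single_partner(self, hela_fixture):
        _, imap = hela_fixture
        prof = CellProfile(name="solo", copies={"IGF1R": 1e4, "SHC1": 1e5})
        res = fake_result({"SHC1": 10.0})
        ana = fake_analytical({"SHC1": 1e-9})
        for metric in RANK_METRICS:
            r = rank_partners(metric, result=res, analytical=ana,
                              profile=prof, imap=imap, partners=["SHC1"])
            assert r.order == ("SHC1",)

    def test_unexpressed_partners_are_excluded_not_ranked_last(self, hela_fixture):
        prof, imap = hela_fixture
        r = rank_partners("copy_number", profile=prof, imap=imap,
                          partners=prof.expressed_partners(imap) + ["ITK"])
        assert "ITK" in r.unexpressed
        assert "ITK" not in r.order

    def test_ranks_are_a_permutation(self, hela_steady):
        r = rank_partners("simulation", result=hela_steady)
        assert sorted(r.ranks.values()) == list(range(1, len(r.order) + 1))

    def test_invariant_under_uniform_rescaling(self, hela_fixture):
        prof, imap = hela_fixture
        scaled = CellProfile(name="x3", copies={p: 3 * c for p, c in prof.copies.items()})
        a = rank_partners("copy_number", profile=prof, imap=imap)
        b = rank_partners("copy_number", profile=scaled, imap=imap)
        assert a.order == b.order
        big = InteractionMap.from_edges(
            tuple((p, s, 7 * kd) for p, s, kd in imap.edges))
        c = rank_partners("kd", imap=imap, profile=prof)
        d = rank_partners("kd", imap=big, profile=prof)
        assert c.order == d.order


class TestRankDeviation:
    def test_identical_rankings_give_zeros(self, hela_steady):
        r = rank_partners("simulation", result=hela_steady)
        dev = rank_deviation(r, r)
        assert all(d == 0 for d in dev.deviations.values())
        assert dev.n_discrepant == 0

    def test_swapped_neighbors(self):
        a = fake_result({"A": 2.0, "B": 1.0})
        b = fake_result({"A": 1.0, "B": 2.0})
        ra = rank_partners("simulation", result=a)
        rb = rank_partners("simulation", result=b)
        dev = rank_deviation(ra, rb)
        assert dev.deviations == {"A": -1, "B": 1}

    def test_antisymmetric_and_zero_sum(self, rng):
        names = [f"P{i}" for i in range(8)]
        for _ in range(5):
            va = dict(zip(names, rng.permutation(8) + 1.0))
            vb = dict(zip(names, rng.permutation(8) + 1.0))
            ra = rank_partners("simulation", result=fake_result(va))
            rb = rank_partners("simulation", result=fake_result(vb))
            fwd = rank_deviation(ra, rb).deviations
            bwd = rank_deviation(rb, ra).deviations
            assert sum(fwd.values()) == 0
            assert all(fwd[p] == -bwd[p] for p in names)

    def test_partner_set_mismatch_rejected(self):
        ra = rank_partners("simulation", result=fake_result({"A": 1.0}))
        rb = rank_partners("simulation", result=fake_result({"B": 1.0}))
        with pytest.raises(ValueError):
            rank_deviation(ra, rb)


class TestCrossCellSummary:
    def test_single_line_summary_is_that_ranking(self, hela_steady):
        r = rank_partners("simulation", result=hela_steady)
        summ = cross_cell_summary({"only": r})
        for p in r.order:
            assert summ.loc[p, "mean_rank"] == r.rank_of(p)
            assert summ.loc[p, "sd_rank"] == 0.0
        top = r.order[0]
        assert summ.loc[top, "share_rank1"] == 1.0

    def test_unexpressed_conventions(self):
        ra = rank_partners("simulation", result=fake_result({"A": 2.0, "B": 1.0}))
        prof = CellProfile(name="x", copies={"A": 1.0, "B": 0.0})
        rb = rank_partners("simulation", result=fake_result({"A": 2.0, "B": 1.0}),
                           profile=prof)
        summ_ex = cross_cell_summary({"l1": ra, "l2": rb}, unexpressed="exclude")
        summ_last = cross_cell_summary({"l1": ra, "l2": rb}, unexpressed="last")
        assert summ_ex.loc["B", "mean_rank"] == 2.0        # only where expressed
        assert summ_last.loc["B", "mean_rank"] == 2.0      # rank m+1 = 2 in l2 too
        assert summ_ex.loc["B", "n_expressed"] == 1


class TestNumericalVsAnalytical:
    def test_identical_predictions_give_r_one(self):
        bound = {"A": 5.0, "B": 3.0, "C": 1.0}
        res = fake_result(bound)
        conv = 1.0 / (6.02214076e23 * 2e-12)
        ana = fake_analytical({p: v * conv for p, v in bound.items()})
        r, p, tab = compare_numerical_vs_analytical(res, ana, 2e-12)
        assert r == pytest.approx(1.0)

    def test_antiordered_predictions_give_r_minus_one(self):
        res = fake_result({"A": 1.0, "B": 2.0, "C": 3.0})
        conv = 1.0 / (6.02214076e23 * 2e-12)
        ana = fake_analytical({"A": 3 * conv, "B": 2 * conv, "C": 1 * conv})
        r, _, _ = compare_numerical_vs_analytical(res, ana, 2e-12)
        assert r == pytest.approx(-1.0)

    def test_too_few_partners_rejected(self):
        res = fake_result({"A": 1.0, "B": 2.0})
        ana = fake_analytical({"A": 1.0, "B": 2.0})
        with pytest.raises(ValueError):
            compare_numerical_vs_analytical(res, ana, 2e-12)


class TestClustering:
    def test_identical_rows_merge_first_at_height_zero(self):
        mat = pd.DataFrame(
            [[1.0, 0.5, 0.1], [1.0, 0.5, 0.1], [4.0, 3.0, 2.0]],
            index=["dup1", "dup2", "far"], columns=["A", "B", "C"])
        res = cluster_cell_lines(mat)
        first = res.row_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_outlier_joins_last(self):
        """Ward distances by hand: the distant row merges at the top."""
        mat = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0]],
            index=["a", "b", "outlier"], columns=["A", "B"])
        res = cluster_cell_lines(mat)
        last = res.row_linkage[-1]
        # the final merge joins the (a,b) cluster (id 3) with the outlier (2)
        assert {int(last[0]), int(last[1])} == {2, 3}

    def test_duplicate_profiles_cocluster(self, hela_model, hela_steady):
        """The same cell line 'measured twice' lands in one tight cluster."""
        import dataclasses
        res2 = dataclasses.replace(hela_steady, cell="HELA_S3_LIKE_bis")
        other = []
        for k, scale in enumerate((0.3, 3.0, 0.05)):
            bc = {p: v * scale for p, v in hela_steady.bound_copies.items()}
            other.append(dataclasses.replace(
                hela_steady, cell=f"other{k}", bound_copies=bc))
        mat = recruitment_matrix([hela_steady, *other, res2])
        cl = cluster_cell_lines(mat)
        pos = {name: i for i, name in enumerate(cl.row_order)}
        assert abs(pos["HELA_S3_LIKE"] - pos["HELA_S3_LIKE_bis"]) == 1

    def test_invariant_under_row_permutation(self, rng):
        mat = pd.DataFrame(rng.uniform(size=(6, 4)),
                           index=[f"L{i}" for i in range(6)],
                           columns=list("ABCD"))
        perm = rng.permutation(6)
        res1 = cluster_cell_lines(mat)
        res2 = cluster_cell_lines(mat.iloc[perm])
        def merge_sets(m, link):
            out = []
            clusters = {i: {m.index[i]} for i in range(len(m))}
            nxt = len(m)
            for a, b, _h, _n in link:
                clusters[nxt] = clusters[int(a)] | clusters[int(b)]
                out.append(frozenset(clusters[nxt]))
                nxt += 1
            return out
        assert merge_sets(mat, res1.row_linkage) == merge_sets(mat.iloc[perm],
                                                               res2.row_linkage)

    def test_nans_rejected(self):
        mat = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], columns=["A", "B"])
        with pytest.raises(ValueError):
            cluster_cell_lines(mat)
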