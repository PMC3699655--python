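import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from eosid import (
    GeneList,
    SelectionThresholds,
    compute_fold_change,
    gate_sputum_subjects,
    intersect_branches,
    run_selection,
    select_bal_upregulated,
    select_mepolizumab_decreased,
    select_sputum_associated,
)
from eosid.datamodel import ExpressionMatrix, MARKER_GENES
from eosid.selection import VENN_REGIONS, mepolizumab_criteria

from conftest import make_matrix, make_metadata, random_study_matrices


# ---------------------------------------------------------------------------
# independent brute-force oracles (set comprehensions over raw values)
# ---------------------------------------------------------------------------

def brute_all_above(fc: pd.DataFrame, threshold: float) -> set[str]:
    return {g for g in fc.index
            if all(fc.loc[g, s] > threshold for s in fc.columns)}


def brute_mepo(matrix, meta, candidates, threshold: float) -> set[str]:
    out = set()
    vals = matrix.to_linear().values
    for g in candidates:
        ok = True
        for subj in meta.subjects("BAL"):
            v = {v: vals.loc[g, meta.sample_for(subj, "BAL", v)]
                 for v in ("V1", "V2", "V3", "V4")}
            direct = v["V2"] / v["V4"]
            ratio = (v["V2"] / v["V1"]) / (v["V4"] / v["V3"])
            if not (direct > threshold and ratio > threshold):
                ok = False
        if ok:
            out.add(g)
    return out


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

class TestComputeFoldChange:
    def test_linear_ratio(self):
        meta = make_metadata(n_bal=1, n_sputum=0)
        m = make_matrix({"B1_BAL_V1": [100.0], "B1_BAL_V2": [250.0],
                         "B1_BAL_V3": [1.0], "B1_BAL_V4": [1.0]}, ["G"])
        fc = compute_fold_change(m, meta, ("V2", "V1"), "BAL")
        assert fc.loc["G", "B1"] == pytest.approx(2.5)

    def test_log2_input_exponentiated(self):
        meta = make_metadata(n_bal=1, n_sputum=0)
        m = make_matrix({"B1_BAL_V1": [6.0], "B1_BAL_V2": [8.0],
                         "B1_BAL_V3": [0.0], "B1_BAL_V4": [0.0]}, ["G"],
                        scale="log2")
        fc = compute_fold_change(m, meta, ("V2", "V1"), "BAL")
        assert fc.loc["G", "B1"] == pytest.approx(4.0)

    def test_self_contrast_is_one(self):
        meta = make_metadata(n_bal=1, n_sputum=0)
        m = make_matrix({f"B1_BAL_{v}": [37.0] for v in
                         ("V1", "V2", "V3", "V4")}, ["G"])
        fc = compute_fold_change(m, meta, ("V2", "V2"), "BAL")
        assert fc.loc["G", "B1"] == 1.0

    def test_missing_visit_names_subject(self, toy_metadata):
        m = make_matrix({"B1_BAL_V1": [1.0]}, ["G"])
        with pytest.raises(ValueError, match="B1"):
            compute_fold_change(m, toy_metadata, ("V2", "V1"), "BAL")

    def test_unknown_contrast_visit(self, toy_metadata):
        m = make_matrix({"B1_BAL_V1": [1.0]}, ["G"])
        with pytest.raises(ValueError, match="V9"):
            compute_fold_change(m, toy_metadata, ("V9", "V1"), "BAL")

    def test_zero_denominator_floored_not_infinite(self):
        meta = make_metadata(n_bal=1, n_sputum=0)
        m = make_matrix({"B1_BAL_V1": [0.0, 10.0], "B1_BAL_V2": [5.0, 10.0],
                         "B1_BAL_V3": [1.0, 1.0], "B1_BAL_V4": [1.0, 1.0]},
                        ["G1", "G2"])
        fc = compute_fold_change(m, meta, ("V2", "V1"), "BAL")
        assert np.isfinite(fc.loc["G1", "B1"])
        assert fc.loc["G1", "B1"] > 1e5  # floored, still huge

    def test_chain_property(self):
        """FC(V2/V1) * FC(V3/V2) = FC(V3/V1) exactly (noiseless data)."""
        rng = np.random.default_rng(7)
        bal, _, meta = random_study_matrices(rng, n_genes=30)
        f21 = compute_fold_change(bal, meta, ("V2", "V1"), "BAL")
        f32 = compute_fold_change(bal, meta, ("V3", "V2"), "BAL")
        f31 = compute_fold_change(bal, meta, ("V3", "V1"), "BAL")
        np.testing.assert_allclose((f21 * f32).to_numpy(), f31.to_numpy(),
                                   rtol=1e-9)


# ---------------------------------------------------------------------------
# branches vs brute force
# ---------------------------------------------------------------------------

class TestBalBranch:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        fc = pd.DataFrame(rng.lognormal(0.5, 0.8, (40, 3)),
                          index=[f"G{i}" for i in range(40)],
                          columns=["s1", "s2", "s3"])
        selected = select_bal_upregulated(fc).to_set()
        assert selected == brute_all_above(fc, 2.0)

    def test_boundary_exactly_at_threshold_excluded(self):
        fc = pd.DataFrame({"s1": [2.0, 2.01], "s2": [3.0, 3.0]},
                          index=["AT", "ABOVE"])
        assert select_bal_upregulated(fc).symbols == ("ABOVE",)

    def test_non_strict_mode_includes_boundary(self):
        fc = pd.DataFrame({"s1": [2.0]}, index=["AT"])
        th = SelectionThresholds(strict=False)
        assert select_bal_upregulated(fc, th).symbols == ("AT",)

    def test_empty_records_error(self):
        with pytest.raises(ValueError, match="no subjects"):
            select_bal_upregulated(pd.DataFrame(index=["G"]))


class TestMepolizumabBranch:
    def _study(self, values_by_visit):
        meta = make_metadata(n_bal=1, n_sputum=0)
        genes = [f"G{i}" for i in range(len(next(iter(values_by_visit.values()))))]
        m = make_matrix({f"B1_BAL_{v}": vals for v, vals in
                         values_by_visit.items()}, genes)
        return m, meta

    def test_toy_gene_passing_both_criteria(self):
        # direct 100/40 = 2.5 > 1.5 and (100/10)/(40/10) = 2.5 > 1.5
        m, meta = self._study({"V1": [10.0], "V2": [100.0],
                               "V3": [10.0], "V4": [40.0]})
        got = select_mepolizumab_decreased(m, meta, GeneList("c", ["G0"]))
        assert got.symbols == ("G0",)

    def test_and_rule_excludes_single_criterion_pass(self):
        # direct 2.0 > 1.5 but fold-change ratio (2/1)/(1/0.6)=1.2 < 1.5
        m, meta = self._study({"V1": [50.0], "V2": [100.0],
                               "V3": [30.0], "V4": [50.0]})
        direct, ratio = mepolizumab_criteria(m, meta)
        assert direct.iloc[0, 0] == pytest.approx(2.0)
        assert ratio.iloc[0, 0] == pytest.approx(1.2)
        got = select_mepolizumab_decreased(m, meta, GeneList("c", ["G0"]))
        assert len(got) == 0
        or_mode = SelectionThresholds(mepo_rule="or")
        got_or = select_mepolizumab_decreased(m, meta, GeneList("c", ["G0"]),
                                              or_mode)
        assert got_or.symbols == ("G0",)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        bal, _, meta = random_study_matrices(rng, n_genes=30, n_bal=3)
        cands = GeneList("c", bal.gene_ids)
        got = select_mepolizumab_decreased(bal, meta, cands).to_set()
        assert got == brute_mepo(bal, meta, bal.gene_ids, 1.5)

    def test_absent_candidate_raises_with_symbols(self, toy_metadata):
        rng = np.random.default_rng(3)
        bal, _, meta = random_study_matrices(rng, n_genes=10)
        with pytest.raises(KeyError, match="NOTAGENE"):
            select_mepolizumab_decreased(bal, meta, GeneList("c", ["NOTAGENE"]))

    def test_returns_subset_of_candidates(self):
        rng = np.random.default_rng(5)
        bal, _, meta = random_study_matrices(rng, n_genes=25)
        cands = GeneList("c", bal.gene_ids[:10])
        got = select_mepolizumab_decreased(bal, meta, cands)
        assert got.to_set() <= cands.to_set()


class TestSputumGatingAndBranch:
    def test_all_four_markers_required(self):
        fc = pd.DataFrame({"s1": [3.0, 3.0, 3.0, 1.9], "s2": [3.0] * 4},
                          index=list(MARKER_GENES))
        assert gate_sputum_subjects(fc) == ["s2"]

    def test_exactly_two_fold_not_gated(self):
        fc = pd.DataFrame({"s1": [2.0, 2.0, 2.0, 2.0]},
                          index=list(MARKER_GENES))
        assert gate_sputum_subjects(fc) == []

    def test_missing_marker_is_error(self):
        fc = pd.DataFrame({"s1": [3.0]}, index=["IL5RA"])
        with pytest.raises(KeyError, match="RNASE2"):
            gate_sputum_subjects(fc)

    def test_gating_matches_brute_force(self):
        rng = np.random.default_rng(17)
        fc = pd.DataFrame(rng.lognormal(0.6, 0.6, (10, 6)),
                          index=list(MARKER_GENES) +
                          [f"G{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(6)])
        expected = [s for s in fc.columns
                    if all(fc.loc[m, s] > 2.0 for m in MARKER_GENES)]
        assert gate_sputum_subjects(fc) == expected

    def test_selection_restricted_to_gated_subjects(self):
        rng = np.random.default_rng(29)
        fc = pd.DataFrame(rng.lognormal(0.4, 0.7, (20, 4)),
                          index=[f"G{i}" for i in range(20)],
                          columns=list("abcd"))
        got = select_sputum_associated(fc, ["b", "d"]).to_set()
        assert got == brute_all_above(fc[["b", "d"]], 1.5)

    def test_empty_gate_is_error(self):
        fc = pd.DataFrame({"s1": [1.0]}, index=["G"])
        with pytest.raises(ValueError, match="no subjects passed"):
            select_sputum_associated(fc, [])

    def test_no_gene_above_threshold_is_valid_empty_result(self):
        fc = pd.DataFrame({"s1": [1.0, 1.2]}, index=["G1", "G2"])
        assert len(select_sputum_associated(fc, ["s1"])) == 0


# ---------------------------------------------------------------------------
# intersection / Venn
# ---------------------------------------------------------------------------

symbols = st.sets(st.sampled_from([f"G{i}" for i in range(12)]), max_size=12)


class TestIntersectBranches:
    @given(symbols, symbols, symbols)
    def test_regions_partition_the_union(self, b, m, s):
        res = intersect_branches(GeneList("bal_up", sorted(b)),
                                 GeneList("mepo_down", sorted(m)),
                                 GeneList("sputum_assoc", sorted(s)))
        regions = [res.regions[k] for k in VENN_REGIONS]
        assert frozenset().union(*regions) == b | m | s
        assert sum(len(r) for r in regions) == len(b | m | s)
        assert res.intersection.to_set() == b & m & s

    def test_disjoint_sets_have_empty_overlap_regions(self):
        res = intersect_branches(GeneList("b", ["A"]), GeneList("m", ["B"]),
                                 GeneList("s", ["C"]))
        counts = res.region_counts()
        assert counts["all_three"] == 0
        assert counts["bal_sputum"] == counts["bal_mepo"] == \
            counts["sputum_mepo"] == 0

    def test_nested_sets_intersect_to_innermost(self):
        a, b, c = ["X"], ["X", "Y"], ["X", "Y", "Z"]
        res = intersect_branches(GeneList("b", a), GeneList("m", b),
                                 GeneList("s", c))
        assert res.intersection.symbols == ("X",)

    def test_published_cardinalities_reproduced_from_fixture_counts(self):
        """The printed Venn: 299 BAL, 99 mepolizumab, 365 sputum genes give
        regions 111 (BAL∩sputum only), 57 (all three), 168 total shared."""
        bal = [f"B{i}" for i in range(299)]
        # the 99 mepolizumab genes are a subset of the 299
        mepo = bal[:99]
        # 57 sputum genes inside the mepolizumab set, 111 only in BAL,
        # remainder sputum-only = 365 - 168
        sputum = mepo[:57] + bal[99:99 + 111] + [f"S{i}" for i in range(197)]
        res = intersect_branches(GeneList("b", bal), GeneList("m", mepo),
                                 GeneList("s", sputum))
        counts = res.region_counts()
        assert counts["all_three"] == 57
        assert counts["bal_sputum"] == 111
        assert counts["all_three"] + counts["bal_sputum"] == 168


# ---------------------------------------------------------------------------
# whole-pipeline properties
# ---------------------------------------------------------------------------

class TestPipelineProperties:
    def test_threshold_monotonicity_selection_never_grows(self):
        rng = np.random.default_rng(41)
        fc = pd.DataFrame(rng.lognormal(0.7, 0.7, (50, 4)),
                          index=[f"G{i}" for i in range(50)],
                          columns=list("abcd"))
        sizes = [len(select_bal_upregulated(
            fc, SelectionThresholds(bal_up_fc=t)))
            for t in (1.5, 2.0, 3.0, 5.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_order_invariance(self):
        rng = np.random.default_rng(43)
        bal, spu, meta = random_study_matrices(rng, n_genes=25,
                                               boost_markers=True)
        res = run_selection(bal, spu, meta)
        perm = rng.permutation(bal.shape[0])
        bal2 = ExpressionMatrix(bal.values.iloc[perm])
        spu2 = ExpressionMatrix(spu.values.iloc[rng.permutation(spu.shape[0])])
        res2 = run_selection(bal2, spu2, meta)
        assert res.intersection.to_set() == res2.intersection.to_set()
        assert res.region_counts() == res2.region_counts()
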