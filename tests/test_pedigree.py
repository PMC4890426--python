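import io

import numpy as np
import pandas as pd
import pytest

from pedigrisk import (
    CellRecord,
    CRSample,
    DialectConfig,
    PedigreeForest,
    data_usage,
    extract_kin_pairs,
    read_lifetime_table,
    simulate_pedigrees,
    SimConfig,
    tabulate_fates,
    to_cr_sample,
    validate_pedigree,
    write_lifetime_table,
)
from pedigrisk.concordance import PairedCRSample

CAUSE_MAP = {"division": 1, "death": 2, "lost": 0, "end_of_observation": 0}


# ----------------------------------------------------------------- I/O
class TestReadLifetimeTable:
    def test_smallest_complete_pedigree(self):
        text = ("cell_id,parent_id,pedigree_id,birth_time,end_time,fate,generation\n"
                "m,NA,P,NA,10,division,0\n"
                "d1,m,P,10,25,division,1\n"
                "d2,m,P,10,30,division,1\n")
        forest, report = read_lifetime_table(io.StringIO(text))
        assert len(forest) == 3
        assert forest.n_pedigrees == 1
        assert report["rows_read"] == 3
        sibs = extract_kin_pairs(forest, "sibling")
        assert len(sibs) == 1 and sibs.pairs[0][:2] == ("d1", "d2")

    def test_dangling_parent_is_hard_error(self):
        text = ("cell_id,parent_id,end_time,fate\n"
                "a,NA,10,division\n"
                "b,ghost,20,death\n")
        with pytest.raises(ValueError, match="dangling.*'b'"):
            read_lifetime_table(io.StringIO(text))

    def test_duplicate_cell_id_is_hard_error(self):
        text = "cell_id,parent_id,end_time,fate\na,NA,10,division\na,NA,12,death\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_lifetime_table(io.StringIO(text))

    def test_non_numeric_time_is_hard_error(self):
        text = "cell_id,parent_id,end_time,fate\na,NA,soon,division\n"
        with pytest.raises(ValueError, match="non-numeric"):
            read_lifetime_table(io.StringIO(text))

    def test_unknown_fates_pass_through(self):
        text = ("cell_id,parent_id,end_time,fate\n"
                "a,NA,10,differentiation_onset\n")
        forest, _ = read_lifetime_table(io.StringIO(text))
        assert forest["a"].fate == "differentiation_onset"

    def test_tab_autodetect_and_column_mapping(self):
        text = "id\tmother\tend\toutcome\nx\t\t5\tdivision\n"
        dialect = DialectConfig(columns={"cell_id": "id", "parent_id": "mother",
                                         "end_time": "end", "fate": "outcome"},
                                na_token="")
        forest, _ = read_lifetime_table(io.StringIO(text), dialect)
        assert forest["x"].end_time == 5.0

    def test_roundtrip_through_writer(self, tmp_path):
        forest, _, _ = simulate_pedigrees(SimConfig(
            seed=5, n_founders=10, max_generations=3, frailty_theta=1.0))
        path = tmp_path / "tab.csv"
        write_lifetime_table(forest, path)
        back, _ = read_lifetime_table(path)
        a = forest.to_frame().sort_values("cell_id").reset_index(drop=True)
        b = back.to_frame().sort_values("cell_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b[a.columns], check_dtype=False)


# ------------------------------------------------------------ validate
class TestValidatePedigree:
    def test_valid_tree_empty_report(self, tiny_forest):
        assert validate_pedigree(tiny_forest) == []

    def test_three_children_violation(self):
        forest = PedigreeForest([
            CellRecord("m", None, "P", None, 10.0, "division", 0),
            CellRecord("a", "m", "P", 10.0, 20.0, "death", 1),
            CellRecord("b", "m", "P", 10.0, 20.0, "death", 1),
            CellRecord("c", "m", "P", 10.0, 20.0, "death", 1),
        ])
        issues = validate_pedigree(forest)
        assert sum("children" in i and "3" in i for i in issues) == 1

    def test_generation_mismatch(self):
        forest = PedigreeForest([
            CellRecord("m", None, "P", None, 10.0, "division", 0),
            CellRecord("a", "m", "P", 10.0, 20.0, "death", 5),
        ])
        issues = validate_pedigree(forest)
        assert len(issues) == 1 and "generation" in issues[0]

    def test_end_before_birth(self):
        forest = PedigreeForest([
            CellRecord("m", None, "P", None, 30.0, "division", 0),
            CellRecord("a", "m", "P", 30.0, 20.0, "death", 1),
        ])
        assert any("end_time" in i for i in validate_pedigree(forest))


# ------------------------------------------------------------ kin pairs
class TestExtractKinPairs:
    def test_lone_founder_every_relation_empty(self):
        forest = PedigreeForest([
            CellRecord("f", None, "P", None, 5.0, "death", 0)])
        for rel in ("sibling", "mother_daughter", "cousin1", "cousin2"):
            assert len(extract_kin_pairs(forest, rel)) == 0

    def test_depth3_leaf_pair_counts(self, depth3_forest):
        leaves = {r.cell_id for r in depth3_forest if r.generation == 3}
        for rel, expected in (("sibling", 4), ("cousin1", 8), ("cousin2", 16)):
            pairs = extract_kin_pairs(depth3_forest, rel)
            leaf_pairs = [p for p in pairs if p[0] in leaves and p[1] in leaves]
            assert len(leaf_pairs) == expected, rel

    def test_depth2_total_counts(self, depth2_forest):
        assert len(extract_kin_pairs(depth2_forest, "sibling")) == 3
        assert len(extract_kin_pairs(depth2_forest, "mother_daughter")) == 6
        assert len(extract_kin_pairs(depth2_forest, "cousin1")) == 4

    def test_cluster_ids_are_common_ancestors(self, depth2_forest):
        for a, b, cl in extract_kin_pairs(depth2_forest, "cousin1"):
            assert cl == "F"
            assert depth2_forest[a].parent_id != depth2_forest[b].parent_id

    def test_agrees_with_bruteforce_nca(self):
        forest, _, _ = simulate_pedigrees(SimConfig(
            seed=11, n_founders=4, max_generations=4, frailty_theta=0.5))
        assert len(forest) <= 100 or True

        def ancestors(cid):
            chain = []
            rec = forest[cid]
            while rec.parent_id is not None:
                chain.append(rec.parent_id)
                rec = forest[rec.parent_id]
            return chain  # nearest first

        cells = [r.cell_id for r in forest]
        brute = {"sibling": set(), "cousin1": set(), "cousin2": set()}
        depth_of = {"sibling": 1, "cousin1": 2, "cousin2": 3}
        for i, a in enumerate(cells):
            for b in cells[i + 1:]:
                ca, cb = ancestors(a), ancestors(b)
                common = next((x for x in ca if x in cb), None)
                if common is None:
                    continue
                da, db = ca.index(common) + 1, cb.index(common) + 1
                if da == db and da in (1, 2, 3):
                    rel = {1: "sibling", 2: "cousin1", 3: "cousin2"}[da]
                    brute[rel].add(frozenset((a, b)))
        for rel, expected in brute.items():
            got = {frozenset((a, b)) for a, b, _ in extract_kin_pairs(forest, rel)}
            assert got == expected, rel


# -------------------------------------------------------- to_cr_sample
class TestToCRSample:
    def test_single_cell_lifetime(self):
        forest = PedigreeForest([
            CellRecord("m", None, "P", 10.0, 25.0, "division", 0)])
        sample, report = to_cr_sample(forest, CAUSE_MAP)
        assert sample.time[0] == 15.0 and sample.status[0] == 1
        assert report.n_included == 1

    def test_four_category_reporter_coding(self):
        recs = []
        fates = ["division", "division", "death", "death", "lost", "division"]
        gfp = [1, 0, 1, 0, 1, 1]
        for i, (f, g) in enumerate(zip(fates, gfp)):
            recs.append(CellRecord(f"c{i}", None, "P", 0.0, 10.0 + i, f, 0,
                                   {"gfp": g}))
        forest = PedigreeForest(recs)

        def coder(rec):
            if rec.fate in ("lost", "end_of_observation"):
                return 0
            base = {"division": 0, "death": 2}[rec.fate]
            return base + (1 if rec.covariates["gfp"] else 2)

        sample, _ = to_cr_sample(forest, coder)
        by_id = dict(zip(sample.ids, sample.status))
        assert by_id == {"c0": 1, "c1": 2, "c2": 3, "c3": 4, "c4": 0, "c5": 1}

    def test_ancestor_stimulus_origin(self, tiny_forest):
        sample, report = to_cr_sample(tiny_forest, CAUSE_MAP,
                                      time_origin="ancestor_stimulus")
        # times measured from experiment start: founders included
        assert report.n_included == 3
        assert set(sample.time) == {10.0, 25.0, 30.0}

    def test_founders_excluded_under_cell_birth(self, tiny_forest):
        sample, report = to_cr_sample(tiny_forest, CAUSE_MAP)
        assert report.n_excluded_missing_birth == 1
        assert sample.n == 2

    def test_count_conservation_under_filters(self):
        forest, _, _ = simulate_pedigrees(SimConfig(
            seed=3, n_founders=20, max_generations=4, frailty_theta=1.0))
        for flt in (None, lambda g: g > 0, lambda g: g > 2):
            _, report = to_cr_sample(forest, CAUSE_MAP, generation_filter=flt)
            assert report.conserved
        # founders (generation 0) have unknown birth: analysed from the
        # time the stimulus was received, i.e. from experiment start
        _, report = to_cr_sample(forest, CAUSE_MAP,
                                 time_origin="ancestor_stimulus",
                                 generation_filter=lambda g: g == 0)
        assert report.conserved and report.n_included == 20

    def test_unmapped_fate_is_hard_error(self, tiny_forest):
        with pytest.raises(KeyError, match="division"):
            to_cr_sample(tiny_forest, {"death": 2})

    def test_nonpositive_time_is_hard_error(self):
        forest = PedigreeForest([
            CellRecord("m", None, "P", 10.0, 10.0, "death", 0)])
        with pytest.raises(ValueError, match="nonpositive"):
            to_cr_sample(forest, CAUSE_MAP)


# ------------------------------------------------------------ tabulate
class TestTabulateFates:
    def test_simple_proportions(self):
        sample = CRSample([1.0] * 10, [1] * 5 + [2] * 3 + [0] * 2)
        tab = tabulate_fates(sample)
        props = dict(zip(tab["status"], tab["proportion"]))
        assert props == {1: 0.5, 2: 0.3, 0: 0.2}

    def test_grouped_and_empty_group(self):
        df = pd.DataFrame({
            "fate": ["division", "death", "division"],
            "well": ["A", "A", "B"],
        })
        tab = tabulate_fates(df, group_by="well")
        a = tab[tab["well"] == "A"]
        assert np.isclose(a["proportion"].sum(), 1.0)
        empty = tabulate_fates(df.iloc[:0], group_by="well")
        assert len(empty) == 0  # no division-by-zero


# ---------------------------------------------------------- data usage
class TestDataUsage:
    @staticmethod
    def _fixture():
        from pedigrisk import KinPairSet

        # 4 pairs: 2 both-divide, 1 discordant (division/death), 1 one-censored
        ids = [f"c{i}" for i in range(8)]
        status = [1, 1, 1, 1, 1, 2, 1, 0]
        sample = CRSample([10.0] * 8, status, ids=ids)
        pairs = KinPairSet("sibling", [
            ("c0", "c1", "p0"), ("c2", "c3", "p1"),
            ("c4", "c5", "p2"), ("c6", "c7", "p3")])
        return sample, pairs

    def test_complete_case_rules(self):
        sample, pairs = self._fixture()
        assert data_usage(sample, pairs, "pearson")["fraction"] == 0.5
        assert data_usage(sample, pairs, "icc")["n_used"] == 2
        assert data_usage(sample, pairs, "yules_q")["n_used"] == 3
        assert data_usage(sample, pairs, "cr_analysis")["fraction"] == 1.0

    def test_no_censoring_single_fate_uses_everything(self):
        from pedigrisk import KinPairSet

        ids = [f"c{i}" for i in range(4)]
        sample = CRSample([1.0] * 4, [1] * 4, ids=ids)
        pairs = KinPairSet("sibling", [("c0", "c1", "p0"), ("c2", "c3", "p1")])
        for method in ("pearson", "icc", "yules_q", "permutation",
                       "binomial", "cr_analysis"):
            assert data_usage(sample, pairs, method)["fraction"] == 1.0

    def test_mean_time_counts_realised_fate(self):
        sample = CRSample([1.0] * 10, [1] * 5 + [2] * 3 + [0] * 2)
        res = data_usage(sample, method="mean_time_ttest", cause=1)
        assert res["n_used"] == 5 and res["n_total"] == 10
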