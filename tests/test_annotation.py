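"""Annotation overlay and structural cross-referencing."""

import numpy as np
import pandas as pd
import pytest

from gmscreen.annotation import (annotation_coverage, crossref_structural,
                                 overlay_matrix, top_pathways_by_genes)


def records_table(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "metabolite_id", "pcc", "pqc",
                                     "category"])
    return df


def ann_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "compound_id", "reaction_id",
                                       "pathway_name"])


class TestOverlay:
    def test_minimal_one_pathway_matrix(self):
        # two genes and two compounds in one pathway, one specific reaction:
        # 2 x 2 matrix with exactly one masked cell
        rec = records_table([("g1", "c1", 0.2, 0.8, ""),
                             ("g1", "c2", 0.1, 0.1, ""),
                             ("g2", "c1", 0.0, 0.3, ""),
                             ("g2", "c2", 0.0, 0.2, "")])
        ann = ann_table([("g1", "c1", "R1", "glycolysis"),
                         ("g2", "c2", "", "glycolysis")])
        matrix, mask, meta = overlay_matrix(rec, ann, top_pathways=9)
        assert matrix.shape == (2, 2)
        assert int(mask.to_numpy().sum()) == 1
        assert mask.at[("glycolysis", "g1"), ("glycolysis", "c1")]
        assert matrix.loc[("glycolysis", "g1"), ("glycolysis", "c1")] == \
            pytest.approx(0.8)

    def test_pathway_ordering_by_gene_count(self):
        ann = ann_table([(f"g{i}", "c1", "R", "A") for i in range(5)]
                        + [(f"h{i}", "c2", "R", "B") for i in range(3)])
        assert top_pathways_by_genes(ann, 2) == ["A", "B"]
        rec = records_table([(g, c, 0.0, 0.0, "") for g in
                             [f"g{i}" for i in range(5)] + [f"h{i}" for i in range(3)]
                             for c in ("c1", "c2")])
        matrix, mask, meta = overlay_matrix(rec, ann)
        assert meta["pathways"] == ["A", "B"]
        assert [p for p, _ in meta["rows"][:5]] == ["A"] * 5

    def test_mask_cardinality_matches_surviving_entries(self, small_panel):
        from gmscreen.correlation import screen_pairs
        _, panel, _ = small_panel
        rec = screen_pairs(panel.genes, panel.metabolites)
        matrix, mask, _ = overlay_matrix(rec, panel.annotation, top_pathways=12)
        genes = set(rec["gene_id"])
        mets = set(rec["metabolite_id"])
        surviving = {(g, c) for g, c in zip(panel.annotation.gene_id,
                                            panel.annotation.compound_id)
                     if g in genes and c in mets}
        assert int(mask.to_numpy().sum()) >= len(surviving)
        linked_cells = {(r[1], c[1]) for r in mask.index for c in mask.columns
                        if mask.at[r, c]}
        assert linked_cells == surviving

    def test_multi_pathway_compound_duplicated(self):
        rec = records_table([("g1", "c1", 0.1, 0.5, ""), ("g2", "c1", 0.1, 0.4, "")])
        ann = ann_table([("g1", "c1", "R1", "A"), ("g2", "c1", "R2", "B")])
        matrix, mask, meta = overlay_matrix(rec, ann, top_pathways=9)
        assert [c for c in matrix.columns] == [("A", "c1"), ("B", "c1")]
        assert mask.at[("A", "g1"), ("A", "c1")]
        assert mask.at[("B", "g2"), ("B", "c1")]
        # linkage is gene-compound wide, independent of block
        assert mask.at[("A", "g1"), ("B", "c1")]

    def test_disjoint_vocabulary_warns_and_empty(self):
        rec = records_table([("g1", "c1", 0.0, 0.0, "")])
        ann = ann_table([("other", "nothere", "R", "A")])
        with pytest.warns(UserWarning):
            matrix, mask, meta = overlay_matrix(rec, ann)
        assert matrix.empty and mask.empty


class TestCrossref:
    def _flags(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "metabolite_id",
                                           "sample_id", "flagged"])

    def test_exact_match_on_gene_and_flagged_line(self):
        rec = records_table([("g1", "m1", 0.9, 0.1, "outlier_driven"),
                             ("g2", "m2", 0.8, 0.1, "outlier_driven"),
                             ("g3", "m3", 0.7, 0.1, "outlier_driven")])
        flags = self._flags([("g1", "m1", "s1", 1), ("g1", "m1", "s2", 0),
                             ("g2", "m2", "s5", 1), ("g3", "m3", "s9", 1)])
        mutations = pd.DataFrame({"gene_id": ["g1", "g2", "gX"],
                                  "cell_line": ["s1", "s6", "s9"]})
        cnv = pd.DataFrame(columns=["gene_id", "cell_line", "copy_number"])
        out = crossref_structural(rec, flags, mutations, cnv)
        # g1/s1 matches; g2's mutation is on an unflagged line; gX is elsewhere
        assert len(out) == 1
        assert out.iloc[0]["gene_id"] == "g1"
        assert out.iloc[0]["source"] == "mutation"

    def test_ordered_by_pcc_descending(self):
        rec = records_table([("g1", "m1", 0.7, 0.1, "outlier_driven"),
                             ("g2", "m2", 0.95, 0.1, "outlier_driven")])
        flags = self._flags([("g1", "m1", "s1", 1), ("g2", "m2", "s2", 1)])
        mutations = pd.DataFrame({"gene_id": ["g1", "g2"],
                                  "cell_line": ["s1", "s2"]})
        cnv = pd.DataFrame(columns=["gene_id", "cell_line", "copy_number"])
        out = crossref_structural(rec, flags, mutations, cnv)
        assert list(out["gene_id"]) == ["g2", "g1"]

    def test_cnv_match_carries_copy_number(self):
        rec = records_table([("g1", "m1", 0.90, 0.008, "outlier_driven")])
        flags = self._flags([("g1", "m1", "MCF7", 1)])
        mutations = pd.DataFrame(columns=["gene_id", "cell_line"])
        cnv = pd.DataFrame({"gene_id": ["g1"], "cell_line": ["MCF7"],
                            "copy_number": [14.22]})
        out = crossref_structural(rec, flags, mutations, cnv)
        assert out.iloc[0]["source"] == "cnv"
        assert out.iloc[0]["copy_number"] == pytest.approx(14.22)

    def test_empty_knowledge_tables(self):
        rec = records_table([("g1", "m1", 0.9, 0.0, "outlier_driven")])
        flags = self._flags([("g1", "m1", "s1", 1)])
        out = crossref_structural(
            rec, flags, pd.DataFrame(columns=["gene_id", "cell_line"]),
            pd.DataFrame(columns=["gene_id", "cell_line", "copy_number"]))
        assert out.empty

    def test_permuted_cell_lines_break_matches(self):
        # matches require joint gene AND line identity, so permuting the
        # cell-line column of the mutation table destroys them
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        lines = [f"s{i}" for i in range(30)]
        rec = records_table([(g, f"m{i}", 0.9, 0.0, "outlier_driven")
                             for i, g in enumerate(genes)])
        flags = self._flags([(g, f"m{i}", lines[i], 1)
                             for i, g in enumerate(genes)])
        mutations = pd.DataFrame({"gene_id": genes, "cell_line": lines})
        exact = crossref_structural(rec, flags, mutations,
                                    pd.DataFrame(columns=["gene_id", "cell_line",
                                                          "copy_number"]))
        permuted = mutations.assign(cell_line=rng.permutation(lines))
        broken = crossref_structural(rec, flags, permuted,
                                     pd.DataFrame(columns=["gene_id", "cell_line",
                                                           "copy_number"]))
        assert len(exact) == 30
        assert len(broken) <= 4  # chance-level collisions only


class TestCoverage:
    def test_counts_on_planted_truth(self):
        rec = records_table([("g1", "c1", 0.4, 0.8, ""),
                             ("g2", "c2", 0.1, 0.1, ""),
                             ("g3", "c3", 0.2, np.nan, ""),
                             ("g4", "c4", 0.9, 0.9, "")])
        ann = ann_table([("g1", "c1", "R", "A"), ("g2", "c2", "R", "A"),
                         ("g3", "c3", "R", "B"), ("gX", "cX", "R", "B")])
        cov = annotation_coverage(rec, ann, pqc_high=0.5)
        assert cov["n_direct_annotated"] == 3
        assert cov["n_direct_defined"] == 2
        assert cov["n_direct_high_pqc"] == 1
        assert cov["n_high_pqc_total"] == 2
        assert cov["n_high_pqc_unannotated"] == 1

    def test_unreachable_threshold(self):
        rec = records_table([("g1", "c1", 0.4, 0.8, "")])
        ann = ann_table([("g1", "c1", "R", "A")])
        cov = annotation_coverage(rec, ann, pqc_high=1.01)
        assert cov["n_direct_high_pqc"] == 0
        assert cov["n_high_pqc_total"] == 0

    def test_disjoint_vocabularies_all_zero(self):
        rec = records_table([("g1", "c1", 0.4, 0.8, "")])
        ann = ann_table([("gZ", "cZ", "R", "A")])
        cov = annotation_coverage(rec, ann, pqc_high=0.5)
        assert cov["n_direct_annotated"] == 0
        assert cov["n_direct_high_pqc"] == 0
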