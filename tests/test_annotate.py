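"""Gene assignment, frequency tables, gene selection and family tests."""

import pandas as pd
import pytest

from hemimeth.annotate import (
    annotate_sites,
    compare_family_proportions,
    default_family_tags,
    frequency_tables,
    gene_summary,
    load_family_tags,
    select_genes,
)
from hemimeth.io import GeneModel


def _model(name, chrom, start, end, strand="+", p_start=None, p_end=None):
    tss = start if strand == "+" else end
    if p_start is None:
        p_start, p_end = (max(1, tss - 2000), tss - 1) if strand == "+" else (tss + 1, tss + 2000)
    return GeneModel(name, chrom, strand, start, end, tss, p_start, p_end)


def _calls(positions, chrom="chr1", label="MU"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": list(positions), "label": label, "p_value": 0.01, "mean_diff": 0.8}
    )


GENES = [
    _model("GENE1", "chr1", 3000, 5000),
    _model("GENE2", "chr1", 10000, 12000, strand="-"),  # promoter 12001..14000
    _model("GENE3", "chr1", 4000, 6000),  # overlaps GENE1 body
]


class TestAssignment:
    def test_body_and_promoter_assignment(self):
        assign = annotate_sites(_calls([3500, 12500, 20_000]), GENES)
        got = set(assign[["pos", "gene", "region"]].itertuples(index=False, name=None))
        assert (3500, "GENE1", "body") in got
        assert (12500, "GENE2", "promoter") in got
        assert not any(pos == 20_000 for pos, _, _ in got)

    def test_site_in_overlapping_genes_assigned_to_each(self):
        assign = annotate_sites(_calls([4500]), GENES)
        assert set(assign["gene"]) == {"GENE1", "GENE3"}

    def test_promoter_of_plus_gene_upstream_of_body(self):
        assign = annotate_sites(_calls([2500]), GENES)
        assert ("GENE1", "promoter") in set(assign[["gene", "region"]].itertuples(index=False, name=None))

    def test_only_hemi_labels_are_annotated(self):
        calls = _calls([3500, 3600])
        calls.loc[1, "label"] = "NS"
        assign = annotate_sites(calls, GENES)
        assert set(assign["pos"]) == {3500}

    def test_removing_promoters_leaves_body_assignments(self):
        no_promoter = [
            GeneModel(g.gene_name, g.chrom, g.strand, g.start, g.end, g.tss, 1, 0) for g in GENES
        ]
        with_p = annotate_sites(_calls([3500, 2500]), GENES)
        without_p = annotate_sites(_calls([3500, 2500]), no_promoter)
        assert (without_p["region"] == "body").all()
        pd.testing.assert_frame_equal(
            with_p[with_p["region"] == "body"].reset_index(drop=True), without_p
        )


class TestFrequencyTables:
    def _assign(self, gene_counts, region="body"):
        rows = []
        pos = 1000
        for gene, k in gene_counts.items():
            for _ in range(k):
                rows.append(("chr1", pos, "MU", gene, region))
                pos += 10
        return pd.DataFrame(rows, columns=["chrom", "pos", "label", "gene", "region"])

    def test_body_bins_one_to_nine_and_overflow(self):
        body, _ = frequency_tables(self._assign({"A": 1, "B": 1, "C": 3, "D": 12}), self._assign({}))
        assert body.loc["1", "tumor"] == 2
        assert body.loc["3", "tumor"] == 1
        assert body.loc[">=10", "tumor"] == 1
        assert body["tumor"].sum() == 4

    def test_promoter_bins_are_exact_counts(self):
        _, promoter = frequency_tables(
            self._assign({"A": 2, "B": 8}, region="promoter"), self._assign({}, region="promoter")
        )
        assert promoter.loc["2", "tumor"] == 1
        assert promoter.loc["8", "tumor"] == 1

    def test_no_assignments_all_zero(self):
        body, promoter = frequency_tables(self._assign({}), self._assign({}))
        assert body.to_numpy().sum() == 0


class TestSelection:
    def _assign(self, gene_positions):
        rows = [
            ("chr1", pos, "MU", gene, "body")
            for gene, positions in gene_positions.items()
            for pos in positions
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "label", "gene", "region"])

    def test_threshold_inclusive_at_five(self):
        tumor = self._assign({"A": range(100, 150, 10), "B": range(200, 240, 10)})
        selected = select_genes(tumor, self._assign({}), min_sites=5, mode="tumor")
        assert selected["gene"].tolist() == ["A"]
        assert selected["count"].tolist() == [5]

    def test_shared_counts_identical_positions(self):
        tumor = self._assign({"A": [100, 110, 120, 130, 140, 150]})
        normal = self._assign({"A": [100, 110, 120, 130, 140]})
        shared = select_genes(tumor, normal, min_sites=5, mode="shared")
        assert shared["count"].tolist() == [5]

    def test_shared_is_symmetric_in_cohort_order(self):
        tumor = self._assign({"A": [100, 110, 120], "B": [500, 510]})
        normal = self._assign({"A": [110, 120, 900], "B": [500]})
        fwd = select_genes(tumor, normal, min_sites=1, mode="shared")
        rev = select_genes(normal, tumor, min_sites=1, mode="shared")
        pd.testing.assert_frame_equal(fwd, rev)

    def test_shared_counts_orientation_mismatch_unless_strict(self):
        tumor = self._assign({"A": [100]})
        normal = self._assign({"A": [100]})
        normal["label"] = "UM"
        assert select_genes(tumor, normal, 1, "shared")["count"].tolist() == [1]
        assert select_genes(tumor, normal, 1, "shared", strict_orientation=True).empty

    def test_min_sites_one_returns_every_gene_and_selection_is_monotone(self):
        tumor = self._assign({"A": range(100, 160, 10), "B": [300], "C": range(400, 440, 10)})
        sizes = [len(select_genes(tumor, self._assign({}), k, "tumor")) for k in range(1, 8)]
        assert sizes[0] == 3
        assert sizes == sorted(sizes, reverse=True)

    def test_ties_broken_by_gene_name(self):
        tumor = self._assign({"B": [100, 110], "A": [200, 210]})
        assert select_genes(tumor, self._assign({}), 1, "tumor")["gene"].tolist() == ["A", "B"]


class TestFamilies:
    def test_published_family_comparisons(self):
        # TF membership 8/41 vs 7/35 and OG membership 3/41 vs 4/35
        tags = {**{f"T{i}": {"TF"} for i in range(8)}, **{f"N{i}": {"TF"} for i in range(7)},
                **{f"OT{i}": {"OG"} for i in range(3)}, **{f"ON{i}": {"OG"} for i in range(4)}}
        list_a = [f"T{i}" for i in range(8)] + [f"OT{i}" for i in range(3)] + [f"XA{i}" for i in range(30)]
        list_b = [f"N{i}" for i in range(7)] + [f"ON{i}" for i in range(4)] + [f"XB{i}" for i in range(24)]
        assert len(list_a) == 41 and len(list_b) == 35
        assert round(compare_family_proportions(list_a, list_b, "TF", tags).p_two_sided, 2) == 0.96
        assert round(compare_family_proportions(list_a, list_b, "OG", tags).p_two_sided, 2) == 0.54

    def test_identical_composition_gives_unit_p(self):
        tags = {"A": {"TF"}}
        res = compare_family_proportions(["A", "B"], ["A", "B"], "TF", tags)
        assert res.p_two_sided == 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            compare_family_proportions([], ["A"], "TF", {})

    def test_bundled_tags_load(self):
        tags = default_family_tags()
        assert tags["WT1"] == {"TF", "TS"}
        assert tags["PRDM16"] == {"OG", "TF", "TCG"}
        assert all(t in {"TF", "TS", "OG", "HP", "TCG", "PK", "CGF"} for ts in tags.values() for t in ts)

    def test_mapping_file_round_trip(self, tmp_path):
        path = tmp_path / "tags.tsv"
        path.write_text("# comment\nG1\tTF,OG\nG2\tPK\n")
        assert load_family_tags(path) == {"G1": {"TF", "OG"}, "G2": {"PK"}}


def test_gene_summary_counts_and_shared_bound():
    tumor = pd.DataFrame(
        [("chr1", 100, "MU", "A", "body"), ("chr1", 110, "MU", "A", "body"), ("chr1", 2500, "MU", "A", "promoter")],
        columns=["chrom", "pos", "label", "gene", "region"],
    )
    normal = pd.DataFrame(
        [("chr1", 100, "UM", "A", "body")], columns=["chrom", "pos", "label", "gene", "region"]
    )
    summary = gene_summary(tumor, normal, {"A": {"TF"}}).set_index("gene")
    row = summary.loc["A"]
    assert (row.body_count_tumor, row.body_count_normal) == (2, 1)
    assert row.promoter_count_tumor == 1
    assert row.shared_count == 1
    assert row.shared_count <= min(row.body_count_tumor, row.body_count_normal)
    assert row.family_tags == "TF"
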