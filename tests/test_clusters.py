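"""Cluster detection, pattern encoding, taxonomy and summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import CLUSTER_PATTERN_COUNTS, clusters_from_pattern_counts
from hemimeth.clusters import (
    Cluster,
    categorize_cluster,
    cluster_length,
    clusters_from_tsv,
    clusters_to_tsv,
    compare_cluster_lengths,
    detect_clusters,
    pattern_string,
    summarize_clusters,
)


def _calls(rows):
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "label"])
    return frame


class TestDetection:
    def test_ns_breaks_a_run(self):
        clusters, singles = detect_clusters(
            _calls([("chr1", 100, "MU"), ("chr1", 110, "MU"), ("chr1", 125, "NS"), ("chr1", 140, "UM")])
        )
        assert [(c.start, c.end) for c in clusters] == [(100, 110)]
        assert [(s.pos, s.orientation) for s in singles] == [(140, "UM")]

    def test_na_does_not_break_by_default_but_can(self):
        rows = [("chr1", 100, "MU"), ("chr1", 110, "NA"), ("chr1", 120, "MU")]
        clusters, singles = detect_clusters(_calls(rows))
        assert [(c.start, c.end) for c in clusters] == [(100, 120)]
        clusters, singles = detect_clusters(_calls(rows), na_breaks_runs=True)
        assert clusters == []
        assert len(singles) == 2

    def test_chromosome_change_breaks_runs(self):
        clusters, _ = detect_clusters(
            _calls([("chr1", 100, "MU"), ("chr1", 110, "MU"), ("chr2", 100, "UM"), ("chr2", 110, "UM")])
        )
        assert [(c.chrom, c.pattern) for c in clusters] == [("chr1", "MM-UU"), ("chr2", "UU-MM")]

    def test_max_gap_breaks_distant_neighbours(self):
        rows = [("chr1", 100, "MU"), ("chr1", 110, "MU"), ("chr1", 500, "MU"), ("chr1", 510, "MU")]
        clusters, _ = detect_clusters(_calls(rows))
        assert len(clusters) == 1
        clusters, _ = detect_clusters(_calls(rows), max_gap=100)
        assert [(c.start, c.end) for c in clusters] == [(100, 110), (500, 510)]

    def test_three_site_mixed_cluster_pattern(self):
        clusters, _ = detect_clusters(
            _calls([("chr1", 100, "MU"), ("chr1", 110, "MU"), ("chr1", 120, "UM")])
        )
        assert clusters[0].pattern == "MMU-UUM"
        assert clusters[0].category == "bigger"

    def test_no_hemi_sites_no_output(self):
        clusters, singles = detect_clusters(_calls([("chr1", 100, "NS"), ("chr1", 110, "NA")]))
        assert clusters == [] and singles == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            detect_clusters(_calls([("chr1", 200, "MU"), ("chr1", 100, "MU")]))

    def test_partition_every_hemi_site_in_one_cluster_or_singleton(self, rng, calls_frame):
        labels = rng.choice(["MU", "UM", "NS", "NA"], size=300, p=[0.2, 0.2, 0.3, 0.3])
        calls = pd.DataFrame(
            {
                "chrom": np.repeat(["chr1", "chr2", "chr3"], 100),
                "pos": np.tile(np.arange(100, 100 + 100 * 7, 7), 3),
                "label": labels,
            }
        )
        clusters, singles = detect_clusters(calls)
        covered = [(c.chrom, p) for c in clusters for p in c.site_positions]
        covered += [(s.chrom, s.pos) for s in singles]
        hemi = list(
            calls.loc[calls["label"].isin(["MU", "UM"]), ["chrom", "pos"]].itertuples(index=False, name=None)
        )
        assert sorted(covered) == sorted(hemi)
        assert len(covered) == len(set(covered))


class TestPatternsAndTaxonomy:
    @pytest.mark.parametrize(
        "orientations, pattern",
        [
            (("MU", "MU", "MU"), "MMM-UUU"),
            (("MU", "UM"), "MU-UM"),
            (("UM",), "U-M"),
        ],
    )
    def test_pattern_rendering(self, orientations, pattern):
        assert pattern_string(orientations) == pattern

    @pytest.mark.parametrize(
        "orientations, category",
        [
            (("MU", "MU"), "regular_pair_MU"),
            (("UM", "UM"), "regular_pair_UM"),
            (("MU", "UM"), "polarity_MU_UM"),
            (("UM", "MU"), "polarity_UM_MU"),
            (("MU", "MU", "UM"), "bigger"),
            (("UM",) * 5, "bigger"),
        ],
    )
    def test_taxonomy(self, orientations, category):
        positions = tuple(100 + 2 * i for i in range(len(orientations)))
        assert categorize_cluster(Cluster("chr1", positions, orientations)) == category

    def test_pattern_halves_are_complements(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 9))
            orientations = tuple(rng.choice(["MU", "UM"], size=n))
            fwd, rev = pattern_string(orientations).split("-")
            assert len(fwd) == len(rev) == n
            assert all({a, b} == {"M", "U"} for a, b in zip(fwd, rev))

    def test_strand_swap_maps_categories(self, rng):
        swap = {"MU": "UM", "UM": "MU"}
        mapping = {
            "regular_pair_MU": "regular_pair_UM",
            "regular_pair_UM": "regular_pair_MU",
            "polarity_MU_UM": "polarity_UM_MU",
            "polarity_UM_MU": "polarity_MU_UM",
            "bigger": "bigger",
        }
        for _ in range(30):
            n = int(rng.integers(2, 7))
            orientations = tuple(rng.choice(["MU", "UM"], size=n))
            positions = tuple(100 + 2 * i for i in range(n))
            original = Cluster("chr1", positions, orientations)
            flipped = Cluster("chr1", positions, tuple(swap[o] for o in orientations))
            assert flipped.category == mapping[original.category]
            assert flipped.length_bp == original.length_bp

    @pytest.mark.parametrize("positions, length", [((150, 170), 20), ((100, 102), 2), ((100, 110, 160), 60)])
    def test_length_is_end_minus_start(self, positions, length):
        orientations = ("MU",) * len(positions)
        assert cluster_length(Cluster("chr1", positions, orientations)) == length


class TestSummaries:
    def test_published_pattern_inventory_reconciles(self):
        # the full normal-column pattern inventory: 185 bigger clusters and
        # a regular total of 548 against 35 polarity pairs
        clusters = clusters_from_pattern_counts(0)
        summary = summarize_clusters(clusters, [])
        regular = summary.regular_table.set_index("category")
        polarity = summary.polarity_table.set_index("category")
        assert regular.loc["bigger", "count"] == 185
        assert int(regular["count"].sum()) == 548
        assert regular.loc["MM-UU", "percent"] == 30.66
        assert regular.loc["UU-MM", "percent"] == 35.58
        assert int(polarity["count"].sum()) == 35
        assert polarity.loc["MU-UM", "percent"] == 80.0
        assert len(clusters) == 583

    def test_tumor_inventory_polarity_percentages(self):
        summary = summarize_clusters(clusters_from_pattern_counts(1), [])
        polarity = summary.polarity_table.set_index("category")
        assert polarity.loc["MU-UM", "count"] == 32
        assert polarity.loc["MU-UM", "percent"] == 88.89
        regular = summary.regular_table.set_index("category")
        assert regular.loc["bigger", "count"] == 152
        assert int(regular["count"].sum()) == 477

    def test_pattern_table_counts_match_input(self):
        clusters = clusters_from_pattern_counts(0)
        table = summarize_clusters(clusters, []).pattern_table.set_index("pattern")
        for fwd, n_normal, _ in CLUSTER_PATTERN_COUNTS:
            if n_normal:
                rev = "".join("U" if c == "M" else "M" for c in fwd)
                assert table.loc[f"{fwd}-{rev}", "count"] == n_normal
        assert int(table["count"].sum()) == 583

    def test_empty_input_gives_empty_tables(self):
        summary = summarize_clusters([], [])
        assert summary.pattern_table.empty
        assert (summary.regular_table["count"] == 0).all()
        assert summary.n_singletons == 0

    def test_category_groups_partition_all_clusters(self, rng):
        clusters = clusters_from_pattern_counts(1)
        summary = summarize_clusters(clusters, [])
        total = int(summary.regular_table["count"].sum() + summary.polarity_table["count"].sum())
        assert total == len(clusters)
        assert len(summary.lengths["regular"]) + len(summary.lengths["polarity"]) == total


def test_compare_cluster_lengths_examples():
    assert compare_cluster_lengths([2, 4, 6], [20, 40, 60]).p_two_sided == pytest.approx(0.1)
    identical = compare_cluster_lengths([5, 9, 9], [9, 5, 9])
    assert identical.p_two_sided == 1.0
    with pytest.raises(ValueError):
        compare_cluster_lengths([], [1])


def test_cluster_tsv_round_trip():
    clusters = clusters_from_pattern_counts(1)[:50]
    back = clusters_from_tsv(clusters_to_tsv(clusters))
    assert back == clusters
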