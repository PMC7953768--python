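"""Hemimethylation cluster detection, pattern encoding and taxonomy.

A cluster is a maximal run of >= 2 consecutive hemimethylated (MU/UM) CpG
sites, scanning testable sites in genomic order: an intervening NS site or
a chromosome change breaks a run, an untestable NA site does not (it
carries no evidence either way; a strict mode is available).  Runs of
length one are singletons.

Patterns are written forward-strand-first: "MMM-UUU" is three consecutive
sites methylated on the forward strand only, "MU-UM" a polarity pair.  The
taxonomy used for reporting:

* regular pairs: two sites with the same orientation (MM-UU or UU-MM),
* polarity pairs: two sites with opposite orientations (MU-UM or UM-MU),
* bigger: every cluster of >= 3 sites, counted with the regular clusters
  in regular/polarity summary tables regardless of its internal mix.

Cluster length is the base-pair distance between the first and last CpG.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .stats import RankSumResult, rank_sum_test

__all__ = [
    "Cluster",
    "ClusterSummary",
    "detect_clusters",
    "pattern_string",
    "categorize_cluster",
    "cluster_length",
    "summarize_clusters",
    "compare_cluster_lengths",
    "clusters_to_tsv",
    "clusters_from_tsv",
    "clusters_to_bed",
]

REGULAR_CATEGORIES = ("regular_pair_MU", "regular_pair_UM", "bigger")
POLARITY_CATEGORIES = ("polarity_MU_UM", "polarity_UM_MU")


@dataclass(frozen=True)
class Cluster:
    chrom: str
    site_positions: tuple[int, ...]
    orientations: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.site_positions) < 2:
            raise ValueError("a cluster needs at least 2 sites")
        if list(self.site_positions) != sorted(set(self.site_positions)):
            raise ValueError("site positions must be strictly increasing")
        if len(self.orientations) != len(self.site_positions):
            raise ValueError("one orientation per site required")
        if any(o not in {"MU", "UM"} for o in self.orientations):
            raise ValueError("orientations must be MU or UM")

    @property
    def start(self) -> int:
        return self.site_positions[0]

    @property
    def end(self) -> int:
        return self.site_positions[-1]

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def pattern(self) -> str:
        return pattern_string(self.orientations)

    @property
    def category(self) -> str:
        return categorize_cluster(self)


@dataclass(frozen=True)
class Singleton:
    """A hemimethylated site with no adjacent hemimethylated neighbour."""

    chrom: str
    pos: int
    orientation: str


def pattern_string(orientations) -> str:
    """Encode orientations as "F-R": forward-strand M/U and its complement.

    MU contributes M to the forward half; UM contributes U.  The reverse
    half is the sitewise complement, so (MU, MU, MU) -> "MMM-UUU" and
    (MU, UM) -> "MU-UM".
    """
    orientations = list(orientations)
    if not orientations:
        raise ValueError("orientations must be nonempty")
    fwd = "".join("M" if o == "MU" else "U" for o in orientations)
    rev = "".join("U" if c == "M" else "M" for c in fwd)
    return f"{fwd}-{rev}"


def categorize_cluster(cluster: Cluster) -> str:
    """Taxonomy category: regular pair, polarity pair, or bigger (>= 3 sites)."""
    o = cluster.orientations
    if len(o) >= 3:
        return "bigger"
    a, b = o
    if a == b:
        return "regular_pair_MU" if a == "MU" else "regular_pair_UM"
    return "polarity_MU_UM" if a == "MU" else "polarity_UM_MU"


def cluster_length(cluster: Cluster) -> int:
    """Base pairs between the first and the last CpG site of the cluster."""
    return cluster.length_bp


def detect_clusters(
    calls: pd.DataFrame,
    max_gap: int | None = None,
    na_breaks_runs: bool = False,
) -> tuple[list[Cluster], list[Singleton]]:
    """Group consecutive MU/UM sites into clusters and singletons.

    ``calls`` must be sorted by (chrom, pos).  A run breaks on an NS site,
    a chromosome change, optionally an NA site (``na_breaks_runs``), or a
    gap above ``max_gap`` bp between successive hemi sites.
    """
    chroms = calls["chrom"].to_numpy()
    pos = calls["pos"].to_numpy()
    order = pd.DataFrame({"chrom": chroms, "pos": pos})
    if not order.equals(order.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)):
        raise ValueError("calls must be sorted by (chrom, pos)")

    clusters: list[Cluster] = []
    singletons: list[Singleton] = []
    run_pos: list[int] = []
    run_orient: list[str] = []
    run_chrom: str | None = None

    def flush() -> None:
        nonlocal run_pos, run_orient
        if len(run_pos) >= 2:
            clusters.append(Cluster(run_chrom, tuple(run_pos), tuple(run_orient)))
        elif len(run_pos) == 1:
            singletons.append(Singleton(run_chrom, run_pos[0], run_orient[0]))
        run_pos, run_orient = [], []

    for chrom, p, label in zip(chroms, pos, calls["label"].to_numpy()):
        if label == "NA" and not na_breaks_runs:
            continue
        breaks = (
            chrom != run_chrom
            or label in ("NS", "NA")
            or (max_gap is not None and run_pos and p - run_pos[-1] > max_gap)
        )
        if breaks:
            flush()
            run_chrom = chrom
        if label in ("MU", "UM"):
            run_pos.append(p)
            run_orient.append(label)
    flush()
    return clusters, singletons


def _pattern_sort_key(pattern: str):
    # Table-style ordering: M before U on the dash-stripped string,
    # longer pattern first on prefix ties.
    stripped = pattern.replace("-", "")
    return (stripped, -len(stripped))


@dataclass
class ClusterSummary:
    """Tabulated cluster statistics for one cohort.

    ``pattern_table``: per-pattern counts; ``regular_table`` /
    ``polarity_table``: category counts with percentages of their group
    total; ``lengths``: bp length vectors keyed by {regular, polarity},
    ready for histogramming.
    """

    pattern_table: pd.DataFrame
    regular_table: pd.DataFrame
    polarity_table: pd.DataFrame
    n_singletons: int
    lengths: dict[str, list[int]]


def summarize_clusters(clusters: list[Cluster], singletons: list[Singleton]) -> ClusterSummary:
    pattern_counts = Counter(c.pattern for c in clusters)
    pattern_table = pd.DataFrame(
        {"pattern": sorted(pattern_counts, key=_pattern_sort_key), "count": 0}
    )
    pattern_table["count"] = pattern_table["pattern"].map(pattern_counts)

    category_counts = Counter(c.category for c in clusters)

    def _group_table(categories, names):
        total = sum(category_counts[c] for c in categories)
        rows = []
        for cat, name in zip(categories, names):
            count = category_counts[cat]
            pct = round(100.0 * count / total, 2) if total else None
            rows.append({"category": name, "count": count, "percent": pct})
        return pd.DataFrame(rows), total

    regular_table, _ = _group_table(REGULAR_CATEGORIES, ["MM-UU", "UU-MM", "bigger"])
    polarity_table, _ = _group_table(POLARITY_CATEGORIES, ["MU-UM", "UM-MU"])

    lengths = {
        "regular": [c.length_bp for c in clusters if c.category in REGULAR_CATEGORIES],
        "polarity": [c.length_bp for c in clusters if c.category in POLARITY_CATEGORIES],
    }
    return ClusterSummary(pattern_table, regular_table, polarity_table, len(singletons), lengths)


def compare_cluster_lengths(lengths_a, lengths_b) -> RankSumResult:
    """Rank-sum comparison of two cohorts' cluster-length distributions."""
    if len(lengths_a) == 0 or len(lengths_b) == 0:
        raise ValueError("both length vectors must be nonempty")
    return rank_sum_test(lengths_a, lengths_b)


def clusters_to_tsv(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "n_sites": c.n_sites,
                "pattern": c.pattern,
                "category": c.category,
                "length_bp": c.length_bp,
                "positions": ",".join(str(p) for p in c.site_positions),
            }
            for c in clusters
        ],
        columns=["chrom", "start", "end", "n_sites", "pattern", "category", "length_bp", "positions"],
    )


def clusters_from_tsv(frame: pd.DataFrame) -> list[Cluster]:
    """Rebuild :class:`Cluster` objects from a detail table written by
    :func:`clusters_to_tsv`."""
    out = []
    for row in frame.itertuples(index=False):
        positions = tuple(int(p) for p in str(row.positions).split(","))
        fwd = row.pattern.split("-")[0]
        orientations = tuple("MU" if ch == "M" else "UM" for ch in fwd)
        out.append(Cluster(row.chrom, positions, orientations))
    return out


def clusters_to_bed(clusters: list[Cluster]) -> pd.DataFrame:
    """Clusters as BED rows: 0-based half-open span, name=pattern, score=size."""
    return pd.DataFrame(
        [
            {"chrom": c.chrom, "start": c.start - 1, "end": c.end + 1, "name": c.pattern, "score": c.n_sites}
            for c in clusters
        ],
        columns=["chrom", "start", "end", "name", "score"],
    )
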