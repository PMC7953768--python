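"""Gene-level annotation of hemimethylated sites.

Sites labelled MU/UM are assigned to every gene body and, independently,
every promoter window that contains them; a gene's hemimethylation burden
is the number of distinct hemimethylated positions assigned to it.  The
module also builds per-gene frequency tables, selects highly
hemimethylated genes (>= ``min_sites`` per cohort, or shared at identical
coordinates in both cohorts) and compares gene-family proportions between
cohorts with the pooled two-proportion z-test.

Family tags (TF transcription factor, TS tumor suppressor, OG oncogene,
HP homeodomain protein, TCG translocated cancer gene, PK protein kinase,
CGF cytokine/growth factor) come from a user-supplied two-column mapping
file; a static tag set for commonly reported cancer genes ships with the
package.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel
from .stats import TwoProportionResult, two_proportion_test

__all__ = [
    "annotate_sites",
    "frequency_tables",
    "select_genes",
    "compare_family_proportions",
    "load_family_tags",
    "default_family_tags",
    "gene_summary",
]

FAMILY_TAGS = ("TF", "TS", "OG", "HP", "TCG", "PK", "CGF")

_ASSIGN_COLUMNS = ["chrom", "pos", "label", "gene", "region"]


def _build_trees(gene_models: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        tree = trees.setdefault(g.chrom, IntervalTree())
        tree.addi(g.start, g.end + 1, (g.gene_name, "body"))
        if g.has_promoter:
            tree.addi(g.promoter_start, g.promoter_end + 1, (g.gene_name, "promoter"))
    return trees


def annotate_sites(calls: pd.DataFrame, gene_models: list[GeneModel]) -> pd.DataFrame:
    """Assign each MU/UM site to overlapping gene bodies and promoters.

    Returns one row per (site, gene, region) with columns chrom, pos,
    label, gene, region; intergenic sites produce no rows.  A site inside
    several overlapping genes is assigned to each of them.
    """
    trees = _build_trees(gene_models)
    hemi = calls[calls["label"].isin(["MU", "UM"])]
    rows = []
    for row in hemi.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in sorted(tree[row.pos], key=lambda iv: iv.data):
            gene, region = hit.data
            rows.append((row.chrom, row.pos, row.label, gene, region))
    return pd.DataFrame(rows, columns=_ASSIGN_COLUMNS)


def _gene_counts(assignments: pd.DataFrame, region: str | None = None) -> pd.Series:
    frame = assignments if region is None else assignments[assignments["region"] == region]
    # a site in both the body and promoter of one gene still counts once
    return frame.drop_duplicates(["chrom", "pos", "gene"]).groupby("gene").size()


def frequency_tables(
    assignments_tumor: pd.DataFrame, assignments_normal: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-count frequency tables for bodies and promoters.

    The body table bins per-gene hemi-site counts into 1..9 and ">=10";
    the promoter table uses exact counts.  Columns are the two cohorts.
    """

    def _binned(assign, region, body_bins):
        counts = _gene_counts(assign, region)
        if body_bins:
            binned = counts.clip(upper=10)
            labels = [str(i) for i in range(1, 10)] + [">=10"]
            freq = binned.value_counts().reindex(range(1, 11), fill_value=0)
            freq.index = labels
        else:
            freq = counts.value_counts().sort_index()
            freq.index = freq.index.astype(str)
        return freq

    body = pd.DataFrame(
        {
            "tumor": _binned(assignments_tumor, "body", True),
            "normal": _binned(assignments_normal, "body", True),
        }
    ).fillna(0).astype(int)
    body.index.name = "sites_per_gene_body"

    promoter = pd.DataFrame(
        {
            "tumor": _binned(assignments_tumor, "promoter", False),
            "normal": _binned(assignments_normal, "promoter", False),
        }
    ).fillna(0).astype(int)
    promoter = promoter.reindex(sorted(promoter.index, key=int))
    promoter.index.name = "sites_per_promoter"
    return body, promoter


def select_genes(
    assignments_tumor: pd.DataFrame,
    assignments_normal: pd.DataFrame,
    min_sites: int = 5,
    mode: str = "tumor",
    strict_orientation: bool = False,
) -> pd.DataFrame:
    """Rank genes by hemimethylation burden.

    ``mode="tumor"``/``"normal"`` ranks genes by that cohort's distinct
    hemi-site count where it reaches ``min_sites``.  ``mode="shared"``
    ranks by the number of positions hemimethylated in BOTH cohorts at
    identical coordinates within the gene; by default the orientation may
    differ between cohorts (``strict_orientation=True`` requires the same
    MU/UM label).  Ties are broken by gene name.
    """
    if mode in {"tumor", "normal"}:
        assign = assignments_tumor if mode == "tumor" else assignments_normal
        counts = _gene_counts(assign)
    elif mode == "shared":
        keys = ["chrom", "pos", "gene"] + (["label"] if strict_orientation else [])
        t = assignments_tumor.drop_duplicates(keys)[keys]
        n = assignments_normal.drop_duplicates(keys)[keys]
        shared = t.merge(n, on=keys)
        counts = shared.drop_duplicates(["chrom", "pos", "gene"]).groupby("gene").size()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    counts = counts[counts >= min_sites]
    out = counts.rename("count").reset_index()
    return out.sort_values(["count", "gene"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


def compare_family_proportions(
    genes_a, genes_b, family: str, tags: dict[str, set[str]]
) -> TwoProportionResult:
    """Pooled z-test of one family's share of two gene lists."""
    genes_a, genes_b = list(genes_a), list(genes_b)
    if not genes_a or not genes_b:
        raise ValueError("both gene lists must be nonempty")
    k_a = sum(1 for g in genes_a if family in tags.get(g, set()))
    k_b = sum(1 for g in genes_b if family in tags.get(g, set()))
    return two_proportion_test(k_a, len(genes_a), k_b, len(genes_b))


def load_family_tags(path) -> dict[str, set[str]]:
    """Read a two-column gene -> comma-separated-tags mapping file."""
    tags: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        gene, tag_field = parts
        tags[gene] = {t.strip() for t in tag_field.split(",") if t.strip()}
    return tags


def default_family_tags() -> dict[str, set[str]]:
    """The tag set shipped with the package (cancer-related gene families)."""
    with resources.as_file(resources.files("hemimeth").joinpath("data/gene_family_tags.tsv")) as p:
        return load_family_tags(p)


def gene_summary(
    assignments_tumor: pd.DataFrame,
    assignments_normal: pd.DataFrame,
    tags: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-gene summary: body/promoter counts per cohort, shared count, tags."""
    tags = tags or {}
    parts = {
        "body_count_tumor": _gene_counts(assignments_tumor, "body"),
        "body_count_normal": _gene_counts(assignments_normal, "body"),
        "promoter_count_tumor": _gene_counts(assignments_tumor, "promoter"),
        "promoter_count_normal": _gene_counts(assignments_normal, "promoter"),
    }
    shared = select_genes(assignments_tumor, assignments_normal, min_sites=1, mode="shared")
    parts["shared_count"] = shared.set_index("gene")["count"]
    table = pd.DataFrame(parts).fillna(0).astype(int)
    table.index.name = "gene"
    table["family_tags"] = [",".join(sorted(tags.get(g, set()))) for g in table.index]
    return table.reset_index()
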