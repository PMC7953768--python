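"""Tumor-vs-normal cluster overlap classification.

Each cluster span (first to last CpG, closed interval; single-bp touching
counts as overlap) is classified against the opposite cohort's clusters:

* ``only`` — no overlapping partner,
* ``exact`` — a partner with the identical span,
* ``contained_in_other`` — some partner covers it with at least one
  endpoint strictly inside,
* ``contains_other`` — it covers some partner likewise,
* ``other_overlap`` — any remaining partial overlap.

The categories are mutually exclusive with precedence exact >
contained_in_other > contains_other > other_overlap.  Counting is per
cluster and per cohort, so one long cluster containing two short partners
contributes 1 to its own cohort's ``contains_other`` while each partner
contributes 1 to ``contained_in_other`` — the counts of the two cohorts'
containment columns are therefore allowed to differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .clusters import Cluster

__all__ = ["OverlapRecord", "classify_overlaps", "per_chromosome_breakdown", "overlap_report"]

RELATIONS = ("only", "exact", "contained_in_other", "contains_other", "other_overlap")


@dataclass(frozen=True)
class OverlapRecord:
    cohort: str
    cluster: Cluster
    relation: str
    partners: tuple[Cluster, ...]


def _classify_one(cluster: Cluster, others: list[Cluster]) -> tuple[str, tuple[Cluster, ...]]:
    span = (cluster.start, cluster.end)
    partners = tuple(
        o for o in others if o.chrom == cluster.chrom and o.start <= span[1] and span[0] <= o.end
    )
    if not partners:
        return "only", partners
    if any((o.start, o.end) == span for o in partners):
        return "exact", partners
    if any(o.start <= span[0] and span[1] <= o.end for o in partners):
        return "contained_in_other", partners
    if any(span[0] <= o.start and o.end <= span[1] for o in partners):
        return "contains_other", partners
    return "other_overlap", partners


def classify_overlaps(
    clusters_a: list[Cluster],
    clusters_b: list[Cluster],
    label_a: str = "tumor",
    label_b: str = "normal",
) -> tuple[list[OverlapRecord], list[OverlapRecord], pd.DataFrame]:
    """Classify every cluster of each cohort against the other cohort.

    Returns the per-cluster records for both cohorts and a summary count
    table (rows = cohorts, columns = total + the five relations).
    """
    records_a = [OverlapRecord(label_a, c, *_classify_one(c, clusters_b)) for c in clusters_a]
    records_b = [OverlapRecord(label_b, c, *_classify_one(c, clusters_a)) for c in clusters_b]

    def _counts(records, label):
        row = {"cohort": label, "total": len(records)}
        for rel in RELATIONS:
            row[rel] = sum(1 for r in records if r.relation == rel)
        return row

    summary = pd.DataFrame([_counts(records_a, label_a), _counts(records_b, label_b)]).set_index("cohort")
    return records_a, records_b, summary


def per_chromosome_breakdown(records: list[OverlapRecord]) -> pd.DataFrame:
    """Relation counts by (cohort, chromosome); rows sum to cohort totals."""
    if not records:
        return pd.DataFrame(columns=["cohort", "chrom", *RELATIONS, "total"])
    rows = pd.DataFrame(
        [{"cohort": r.cohort, "chrom": r.cluster.chrom, "relation": r.relation} for r in records]
    )
    table = (
        rows.pivot_table(index=["cohort", "chrom"], columns="relation", aggfunc="size", fill_value=0)
        .reindex(columns=list(RELATIONS), fill_value=0)
        .reset_index()
    )
    table.columns.name = None
    table["total"] = table[list(RELATIONS)].sum(axis=1)
    return table


def overlap_report(records: list[OverlapRecord]) -> pd.DataFrame:
    """Detail TSV rows: one line per cluster with its relation and partners."""
    return pd.DataFrame(
        [
            {
                "cohort": r.cohort,
                "chrom": r.cluster.chrom,
                "start": r.cluster.start,
                "end": r.cluster.end,
                "pattern": r.cluster.pattern,
                "relation": r.relation,
                "partner_count": len(r.partners),
                "partner_spans": ";".join(f"{p.start}-{p.end}" for p in r.partners),
            }
            for r in records
        ],
        columns=["cohort", "chrom", "start", "end", "pattern", "relation", "partner_count", "partner_spans"],
    )
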