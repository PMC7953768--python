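"""End-to-end orchestration: calls → clusters → cross-tab → overlap → genes.

`run_analysis` operates on in-memory cohorts and returns every report as a
plain object; `run` adds file I/O around it (manifests in, TSV/BED bundle
plus run.log out).  All summary reports are projections of the detail
tables, so every printed count can be recomputed from the TSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (
    annotate_sites,
    compare_family_proportions,
    default_family_tags,
    frequency_tables,
    gene_summary,
    load_family_tags,
    select_genes,
)
from .calling import CallingConfig, call_sites, calls_to_bed, cross_tabulate, summarize_calls
from .clusters import (
    clusters_to_bed,
    clusters_to_tsv,
    compare_cluster_lengths,
    detect_clusters,
    summarize_clusters,
)
from .io import Cohort, read_gene_models, read_stranded_table
from .overlap import classify_overlaps, overlap_report, per_chromosome_breakdown
from .stats import two_proportion_test

logger = logging.getLogger("hemimeth")

__all__ = ["RunConfig", "run", "run_analysis", "compare_cutoffs", "load_cohort"]


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Manifests list one canonical TSV per sample; the two lists must be
    paired in the same order.  ``cutoffs`` drives the multi-cutoff summary
    table; all downstream stages use ``calling.cutoff`` (default 0.4).
    """

    tumor_files: list[Path]
    normal_files: list[Path]
    out_dir: Path
    calling: CallingConfig = field(default_factory=CallingConfig)
    cutoffs: tuple[float, ...] = (0.4, 0.6, 0.8)
    max_gap: int | None = None
    na_breaks_runs: bool = False
    gene_models: Path | None = None
    gene_model_format: str | None = None
    promoter_upstream: int = 2000
    promoter_downstream: int = 0
    family_tags: Path | None = None
    min_gene_sites: int = 5

    def __post_init__(self) -> None:
        if not self.tumor_files or not self.normal_files:
            raise ValueError("both cohort manifests must be nonempty")


def load_cohort(label: str, files: list[Path]) -> Cohort:
    tables = {}
    for path in files:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"manifest entry does not exist: {path}")
        sid = path.stem
        tables[sid] = read_stranded_table(path, sid)
    return Cohort.from_sample_tables(label, tables)


@dataclass
class AnalysisResult:
    calls: dict[str, pd.DataFrame]
    clusters: dict[str, list]
    singletons: dict[str, list]
    call_summary: pd.DataFrame
    cutoff_table: pd.DataFrame
    crosstab: pd.DataFrame
    cluster_summaries: dict[str, object]
    length_comparison: object | None
    overlap_records: dict[str, list]
    overlap_summary: pd.DataFrame
    overlap_by_chrom: pd.DataFrame
    gene_tables: dict[str, pd.DataFrame] | None


def run_analysis(
    tumor: Cohort,
    normal: Cohort,
    config: RunConfig | None = None,
    gene_models=None,
    family_tags: dict[str, set[str]] | None = None,
) -> AnalysisResult:
    """Run every analysis stage on in-memory cohorts."""
    if config is None:
        config = RunConfig([Path("-")], [Path("-")], Path("."))
    cohorts = {"tumor": tumor, "normal": normal}

    calls = {lab: call_sites(c, config.calling) for lab, c in cohorts.items()}
    clusters, singletons = {}, {}
    for lab in cohorts:
        clusters[lab], singletons[lab] = detect_clusters(
            calls[lab], max_gap=config.max_gap, na_breaks_runs=config.na_breaks_runs
        )
        logger.info(
            "%s: %d hemi sites, %d clusters, %d singletons",
            lab,
            int(calls[lab]["label"].isin(["MU", "UM"]).sum()),
            len(clusters[lab]),
            len(singletons[lab]),
        )

    call_summary = pd.DataFrame(
        {lab: summarize_calls(calls[lab], clusters[lab]) for lab in cohorts}
    ).T.rename_axis("cohort")
    cutoff_table = compare_cutoffs(tumor, normal, config.cutoffs, config)
    crosstab = cross_tabulate(calls["tumor"], calls["normal"])
    cluster_summaries = {lab: summarize_clusters(clusters[lab], singletons[lab]) for lab in cohorts}

    lengths = {lab: [c.length_bp for c in clusters[lab]] for lab in cohorts}
    length_comparison = (
        compare_cluster_lengths(lengths["normal"], lengths["tumor"])
        if lengths["tumor"] and lengths["normal"]
        else None
    )

    rec_t, rec_n, overlap_summary = classify_overlaps(clusters["tumor"], clusters["normal"])
    overlap_records = {"tumor": rec_t, "normal": rec_n}
    overlap_by_chrom = per_chromosome_breakdown(rec_t + rec_n)

    gene_tables = None
    if gene_models:
        assign = {lab: annotate_sites(calls[lab], gene_models) for lab in cohorts}
        body, promoter = frequency_tables(assign["tumor"], assign["normal"])
        tags = family_tags if family_tags is not None else default_family_tags()
        selections = {
            mode: select_genes(assign["tumor"], assign["normal"], config.min_gene_sites, mode)
            for mode in ("tumor", "normal", "shared")
        }
        family_rows = []
        for fam in ("TF", "OG"):
            if len(selections["tumor"]) and len(selections["normal"]):
                res = compare_family_proportions(
                    selections["tumor"]["gene"], selections["normal"]["gene"], fam, tags
                )
                family_rows.append(
                    {"family": fam, "z": res.z_statistic, "p_two_sided": res.p_two_sided}
                )
        gene_tables = {
            "assignments_tumor": assign["tumor"],
            "assignments_normal": assign["normal"],
            "body_frequency": body,
            "promoter_frequency": promoter,
            "selected_tumor": selections["tumor"],
            "selected_normal": selections["normal"],
            "selected_shared": selections["shared"],
            "family_tests": pd.DataFrame(family_rows, columns=["family", "z", "p_two_sided"]),
            "gene_summary": gene_summary(assign["tumor"], assign["normal"], tags),
        }

    return AnalysisResult(
        calls,
        clusters,
        singletons,
        call_summary,
        cutoff_table,
        crosstab,
        cluster_summaries,
        length_comparison,
        overlap_records,
        overlap_summary,
        overlap_by_chrom,
        gene_tables,
    )


def compare_cutoffs(
    tumor: Cohort, normal: Cohort, cutoffs=(0.4, 0.6, 0.8), config: RunConfig | None = None
) -> pd.DataFrame:
    """Multi-cutoff summary: totals, in-cluster counts, percentages and the
    between-cohort pooled two-proportion p-value per mean-difference cutoff."""
    base = config.calling if config is not None else CallingConfig()
    max_gap = config.max_gap if config is not None else None
    na_breaks = config.na_breaks_runs if config is not None else False
    rows = []
    for cutoff in cutoffs:
        calling = replace(base, cutoff=cutoff)
        row: dict = {"cutoff": cutoff}
        counts = {}
        for lab, cohort in (("normal", normal), ("tumor", tumor)):
            calls = call_sites(cohort, calling)
            cl, sg = detect_clusters(calls, max_gap=max_gap, na_breaks_runs=na_breaks)
            summary = summarize_calls(calls, cl)
            counts[lab] = (summary["sites_in_clusters"], summary["total_hemi_sites"])
            row[f"total_{lab}"] = summary["total_hemi_sites"]
            row[f"in_clusters_{lab}"] = summary["sites_in_clusters"]
            row[f"percentage_{lab}"] = summary["percentage"]
        (k1, n1), (k2, n2) = counts["normal"], counts["tumor"]
        if n1 > 0 and n2 > 0:
            row["p_two_sided"] = two_proportion_test(k1, n1, k2, n2).p_two_sided
        else:
            row["p_two_sided"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def run(config: RunConfig) -> AnalysisResult:
    """Execute the full pipeline from files and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("hemimeth %s", __version__)
        logger.info("config: %r", config)
        tumor = load_cohort("tumor", config.tumor_files)
        normal = load_cohort("normal", config.normal_files)
        logger.info("loaded %d tumor / %d normal sites", tumor.n_sites, normal.n_sites)

        gene_models = None
        if config.gene_models is not None:
            gene_models = read_gene_models(
                config.gene_models,
                format=config.gene_model_format,
                promoter_upstream=config.promoter_upstream,
                promoter_downstream=config.promoter_downstream,
            )
        tags = load_family_tags(config.family_tags) if config.family_tags else None

        result = run_analysis(tumor, normal, config, gene_models, tags)

        for lab in ("tumor", "normal"):
            _write_tsv(result.calls[lab], out / f"calls_{lab}.tsv")
            calls_to_bed(result.calls[lab]).to_csv(
                out / f"hemi_sites_{lab}.bed", sep="\t", index=False, header=False
            )
            _write_tsv(clusters_to_tsv(result.clusters[lab]), out / f"clusters_{lab}.tsv")
            clusters_to_bed(result.clusters[lab]).to_csv(
                out / f"clusters_{lab}.bed", sep="\t", index=False, header=False
            )
            summary = result.cluster_summaries[lab]
            _write_tsv(summary.pattern_table, out / f"cluster_patterns_{lab}.tsv")
            _write_tsv(summary.regular_table, out / f"regular_clusters_{lab}.tsv")
            _write_tsv(summary.polarity_table, out / f"polarity_clusters_{lab}.tsv")
            pd.DataFrame(
                [(cat, l) for cat, ls in summary.lengths.items() for l in ls],
                columns=["category_group", "length_bp"],
            ).to_csv(out / f"cluster_lengths_{lab}.tsv", sep="\t", index=False)
        _write_tsv(result.call_summary, out / "call_summary.tsv", index=True)
        _write_tsv(result.cutoff_table, out / "cutoff_comparison.tsv")
        _write_tsv(result.crosstab, out / "call_crosstab.tsv", index=True)
        _write_tsv(
            overlap_report(result.overlap_records["tumor"] + result.overlap_records["normal"]),
            out / "overlap_detail.tsv",
        )
        _write_tsv(result.overlap_summary, out / "overlap_summary.tsv", index=True)
        _write_tsv(result.overlap_by_chrom, out / "overlap_by_chromosome.tsv")
        if result.length_comparison is not None:
            pd.DataFrame(
                [
                    {
                        "statistic_u": result.length_comparison.statistic_u,
                        "p_two_sided": result.length_comparison.p_two_sided,
                        "method": result.length_comparison.method,
                    }
                ]
            ).to_csv(out / "length_comparison.tsv", sep="\t", index=False)
        if result.gene_tables is not None:
            for name, frame in result.gene_tables.items():
                _write_tsv(frame, out / f"{name}.tsv", index=name.endswith("_frequency"))
        logger.info("report bundle written to %s", out)
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
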