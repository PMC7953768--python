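"""Per-CpG hemimethylation calling.

At every CpG with enough informative samples the forward-minus-reverse
methylation-level differences across samples are fed to a paired Wilcoxon
signed-rank test, and the site is labelled:

* ``MU`` — significantly methylated-forward / unmethylated-reverse
  (p < alpha and mean difference >= +cutoff),
* ``UM`` — the converse (mean difference <= -cutoff),
* ``NS`` — testable but not significant under both filters,
* ``NA`` — untestable (fewer than ``min_samples`` informative pairs).

Significance alone is never sufficient: the mean-difference filter must
also pass, so a site with p = 0.01 but a mean difference of 0.2 at cutoff
0.4 remains NS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort, coverage_filter
from .stats import bh_adjust, signed_rank_test

__all__ = ["CallingConfig", "call_sites", "cross_tabulate", "summarize_calls", "calls_to_bed", "LABELS"]

LABELS = ("MU", "UM", "NS", "NA")


@dataclass
class CallingConfig:
    """Thresholds controlling site calling.

    alpha : significance level for the signed-rank p-value (default 0.05).
    cutoff : minimum absolute mean strand difference (default 0.4; the
        study grid also used 0.6 and 0.8).
    min_samples : minimum informative pairs for a site to be testable.  The
        default 6 is the smallest n at which the exact two-sided signed-rank
        test can reach p < 0.05 (min p = 2**(1-n)), so smaller n is
        untestable by construction.
    min_reads : per-strand read-depth floor for a sample to count as
        informative at a site.
    exact_threshold : switch from the exact signed-rank null to the normal
        approximation above this many informative pairs.
    bh_correct : apply Benjamini-Hochberg adjustment to the per-site
        p-values before labelling (off by default; raw p-values with the
        mean-difference filter are the primary procedure).
    """

    alpha: float = 0.05
    cutoff: float = 0.4
    min_samples: int = 6
    min_reads: int = 4
    exact_threshold: int = 25
    pooled_coverage: bool = False
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must be in (0, 1]")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def call_sites(cohort: Cohort, config: CallingConfig | None = None) -> pd.DataFrame:
    """Label every site in a cohort as MU, UM, NS or NA.

    Returns a DataFrame with columns chrom, pos, label, p_value, mean_diff,
    n_informative, sorted by (chrom, pos).  ``mean_diff`` is the mean over
    informative samples of (forward level - reverse level); positive means
    forward-strand methylation, matching the MU orientation.  Untestable
    sites carry NaN p-value and mean_diff.
    """
    config = config or CallingConfig()
    mask = coverage_filter(cohort, config.min_reads, pooled=config.pooled_coverage)

    with np.errstate(invalid="ignore", divide="ignore"):
        fwd_level = cohort.fwd_meth / cohort.fwd_total
        rev_level = cohort.rev_meth / cohort.rev_total
    diffs = fwd_level - rev_level

    n_sites = cohort.n_sites
    p_values = np.full(n_sites, np.nan)
    mean_diffs = np.full(n_sites, np.nan)
    n_informative = mask.sum(axis=1)

    testable = n_informative >= config.min_samples
    for i in np.nonzero(testable)[0]:
        d = diffs[i, mask[i]]
        res = signed_rank_test(d, exact_threshold=config.exact_threshold)
        p_values[i] = res.p_two_sided
        mean_diffs[i] = d.mean()

    if config.bh_correct and testable.any():
        p_values[testable] = bh_adjust(p_values[testable])

    labels = np.full(n_sites, "NA", dtype=object)
    sig = testable & (p_values < config.alpha)
    labels[testable] = "NS"
    labels[sig & (mean_diffs >= config.cutoff)] = "MU"
    labels[sig & (mean_diffs <= -config.cutoff)] = "UM"

    out = cohort.sites.copy()
    out["label"] = labels
    out["p_value"] = p_values
    out["mean_diff"] = mean_diffs
    out["n_informative"] = n_informative
    return out


def cross_tabulate(tumor_calls: pd.DataFrame, normal_calls: pd.DataFrame) -> pd.DataFrame:
    """4x4 tumor-label x normal-label count table over the union of sites.

    A site absent from one cohort's call set entirely counts as NA for that
    cohort; each union site increments exactly one cell.
    """
    t = tumor_calls.set_index(["chrom", "pos"])["label"]
    n = normal_calls.set_index(["chrom", "pos"])["label"]
    union = t.index.union(n.index)
    t = t.reindex(union, fill_value="NA")
    n = n.reindex(union, fill_value="NA")
    table = pd.crosstab(t, n).reindex(index=LABELS, columns=LABELS, fill_value=0)
    table.index.name = "tumor"
    table.columns.name = "normal"
    return table


def summarize_calls(calls: pd.DataFrame, clusters) -> dict:
    """One summary row: total hemi sites, sites in clusters, percentage.

    The percentage is ``100 * in_clusters / total`` rounded to two
    decimals; with zero hemi sites it is undefined and reported as None.
    """
    total = int(calls["label"].isin(["MU", "UM"]).sum())
    in_clusters = int(sum(len(c.site_positions) for c in clusters))
    pct = round(100.0 * in_clusters / total, 2) if total > 0 else None
    return {"total_hemi_sites": total, "sites_in_clusters": in_clusters, "percentage": pct}


def calls_to_bed(calls: pd.DataFrame) -> pd.DataFrame:
    """MU/UM sites as BED rows (0-based half-open, name=label, score=|mean_diff|*1000)."""
    hemi = calls[calls["label"].isin(["MU", "UM"])]
    return pd.DataFrame(
        {
            "chrom": hemi["chrom"],
            "start": hemi["pos"] - 1,
            "end": hemi["pos"] + 1,
            "name": hemi["label"],
            "score": (1000 * hemi["mean_diff"].abs()).round().astype(int),
            "strand": np.where(hemi["label"] == "MU", "+", "-"),
        }
    ).reset_index(drop=True)
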