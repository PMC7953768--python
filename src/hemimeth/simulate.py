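"""Synthetic paired tumor/normal strand-resolved methylation cohorts.

The generator emulates an RRBS-like design: CpG positions grouped into
dense islands, negative-binomial read depth per (site, sample, strand)
with occasional dropout, strand-symmetric background methylation levels
drawn from a concentrated beta (real bisulfite signals cluster near 0 and
1), and planted hemimethylation events — singletons, regular clusters and
polarity pairs of either orientation — whose strand-specific levels come
from separate "high" and "low" beta distributions.  Tumor and normal share
each unplanted site's background level, so cohort cross-tabulation and
overlap logic see realistic concordance.  All output is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Cohort, read_stranded_table, write_stranded_table

__all__ = [
    "ChromLayout",
    "PlantedEvent",
    "SimulationConfig",
    "default_config",
    "generate",
    "write_fixture",
]


@dataclass(frozen=True)
class ChromLayout:
    """One chromosome's CpG island layout.

    ``island_cpg_count`` CpGs spaced ``intra_island_spacing`` bp apart,
    ``n_islands`` islands separated by ``inter_island_spacing`` bp.
    """

    chrom: str
    n_islands: int
    island_cpg_count: int
    intra_island_spacing: int = 20
    inter_island_spacing: int = 5000

    def positions(self) -> list[int]:
        if self.intra_island_spacing < 2:
            raise ValueError("CpG sites are at least 2 bp apart")
        out = []
        pos = 1000
        for _ in range(self.n_islands):
            for _ in range(self.island_cpg_count):
                out.append(pos)
                pos += self.intra_island_spacing
            pos += self.inter_island_spacing
        return out


@dataclass(frozen=True)
class PlantedEvent:
    """A hemimethylation signal planted at consecutive CpG sites.

    ``site_indices`` index the flat (chrom, pos) list produced by the
    layout.  ``kind`` is singleton / regular_cluster / polarity_cluster;
    orientations must match the kind (all equal for regular, exactly two
    opposite for polarity).  ``effect`` holds the (high, low) beta shape
    pairs for the methylated and unmethylated strand levels.
    """

    cohort: str  # tumor | normal | both
    kind: str
    orientations: tuple[str, ...]
    site_indices: tuple[int, ...]
    effect: tuple[tuple[float, float], tuple[float, float]] = ((18.0, 2.0), (1.0, 19.0))

    def __post_init__(self) -> None:
        if self.cohort not in {"tumor", "normal", "both"}:
            raise ValueError("cohort must be tumor, normal or both")
        if len(self.orientations) != len(self.site_indices):
            raise ValueError("one orientation per planted site")
        if any(o not in {"MU", "UM"} for o in self.orientations):
            raise ValueError("orientations must be MU or UM")
        if self.kind == "singleton" and len(self.site_indices) != 1:
            raise ValueError("singleton events plant exactly one site")
        if self.kind == "regular_cluster" and len(set(self.orientations)) != 1:
            raise ValueError("regular clusters share one orientation")
        if self.kind == "polarity_cluster" and (
            len(self.site_indices) != 2 or self.orientations[0] == self.orientations[1]
        ):
            raise ValueError("polarity clusters are two opposite-orientation sites")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the emulated design: 18 paired samples, island-dense
    CpG positions, mean read depth 30 per strand with moderate
    overdispersion, a sparse symmetric-beta background, and a 5% dropout
    rate per (site, sample, strand).
    """

    n_samples: int = 18
    chrom_layout: tuple[ChromLayout, ...] = (
        ChromLayout("chr1", 8, 10),
        ChromLayout("chr2", 6, 8),
    )
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    background_beta: tuple[float, float] = (0.3, 0.3)
    planted_events: tuple[PlantedEvent, ...] = ()
    dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("counts and coverage parameters must be positive")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be a probability")


def default_config(seed: int = 0) -> SimulationConfig:
    """Default scenario: both cohorts share a background; events cover every
    taxonomy branch (singletons, regular clusters of both orientations,
    polarity pairs of both orders; tumor-only, normal-only and shared)."""
    events = (
        # shared in both cohorts: one regular cluster and one polarity pair
        PlantedEvent("both", "regular_cluster", ("MU",) * 3, (0, 1, 2)),
        PlantedEvent("both", "polarity_cluster", ("UM", "MU"), (20, 21)),
        # tumor-only signals
        PlantedEvent("tumor", "regular_cluster", ("UM",) * 2, (40, 41)),
        PlantedEvent("tumor", "polarity_cluster", ("MU", "UM"), (60, 61)),
        PlantedEvent("tumor", "singleton", ("MU",), (75,)),
        # normal-only signals
        PlantedEvent("normal", "regular_cluster", ("MU",) * 4, (90, 91, 92, 93)),
        PlantedEvent("normal", "singleton", ("UM",), (110,)),
    )
    return SimulationConfig(planted_events=events, seed=seed)


def _layout_sites(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for layout in config.chrom_layout:
        for pos in layout.positions():
            rows.append((layout.chrom, pos))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def _nb_counts(rng: np.random.Generator, shape, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=shape)


def generate(config: SimulationConfig) -> tuple[Cohort, Cohort, dict]:
    """Simulate (tumor, normal) cohorts plus the planted ground truth.

    The truth dict carries ``sites`` (DataFrame: chrom, pos, cohort, label
    for every planted site) and ``clusters`` (DataFrame: cohort, chrom,
    start, end, pattern, category, n_sites for every planted multi-site
    event).
    """
    sites = _layout_sites(config)
    n_sites, n_samples = len(sites), config.n_samples
    if sites.empty and config.planted_events:
        raise ValueError("planted events but empty layout")
    for ev in config.planted_events:
        if any(i < 0 or i >= n_sites for i in ev.site_indices):
            raise ValueError(f"planted event indices {ev.site_indices} outside layout of {n_sites} sites")

    rng = np.random.default_rng(config.seed)
    base_level = rng.beta(*config.background_beta, size=n_sites)

    # planted orientation per (site, cohort); None = background
    planted: dict[str, dict[int, PlantedEvent]] = {"tumor": {}, "normal": {}}
    orientation: dict[str, dict[int, str]] = {"tumor": {}, "normal": {}}
    for ev in config.planted_events:
        cohorts = ("tumor", "normal") if ev.cohort == "both" else (ev.cohort,)
        for c in cohorts:
            for idx, orient in zip(ev.site_indices, ev.orientations):
                if idx in planted[c]:
                    raise ValueError(f"site index {idx} planted twice in {c}")
                planted[c][idx] = ev
                orientation[c][idx] = orient

    sample_ids = [f"S{j + 1:02d}" for j in range(n_samples)]
    cohorts: dict[str, Cohort] = {}
    for label in ("tumor", "normal"):
        fwd_total = _nb_counts(rng, (n_sites, n_samples), config.coverage_mean, config.coverage_dispersion)
        rev_total = _nb_counts(rng, (n_sites, n_samples), config.coverage_mean, config.coverage_dispersion)
        if config.dropout_rate > 0:
            fwd_total[rng.random((n_sites, n_samples)) < config.dropout_rate] = 0
            rev_total[rng.random((n_sites, n_samples)) < config.dropout_rate] = 0

        fwd_level = np.repeat(base_level[:, None], n_samples, axis=1)
        rev_level = fwd_level.copy()
        for idx, ev in planted[label].items():
            high, low = ev.effect
            hi = rng.beta(*high, size=n_samples)
            lo = rng.beta(*low, size=n_samples)
            if orientation[label][idx] == "MU":
                fwd_level[idx], rev_level[idx] = hi, lo
            else:
                fwd_level[idx], rev_level[idx] = lo, hi

        fwd_meth = rng.binomial(fwd_total, fwd_level)
        rev_meth = rng.binomial(rev_total, rev_level)
        cohorts[label] = Cohort(label, list(sample_ids), sites.copy(), fwd_meth, fwd_total, rev_meth, rev_total)

    truth_sites = pd.DataFrame(
        [
            {
                "chrom": sites.iloc[idx]["chrom"],
                "pos": int(sites.iloc[idx]["pos"]),
                "cohort": c,
                "label": orientation[c][idx],
            }
            for c in ("tumor", "normal")
            for idx in sorted(orientation[c])
        ],
        columns=["chrom", "pos", "cohort", "label"],
    )
    cluster_rows = []
    from .clusters import Cluster

    for ev in config.planted_events:
        if len(ev.site_indices) < 2:
            continue
        positions = tuple(int(sites.iloc[i]["pos"]) for i in ev.site_indices)
        cl = Cluster(str(sites.iloc[ev.site_indices[0]]["chrom"]), positions, ev.orientations)
        for c in ("tumor", "normal") if ev.cohort == "both" else (ev.cohort,):
            cluster_rows.append(
                {
                    "cohort": c,
                    "chrom": cl.chrom,
                    "start": cl.start,
                    "end": cl.end,
                    "pattern": cl.pattern,
                    "category": cl.category,
                    "n_sites": cl.n_sites,
                }
            )
    truth_clusters = pd.DataFrame(
        cluster_rows, columns=["cohort", "chrom", "start", "end", "pattern", "category", "n_sites"]
    )
    return cohorts["tumor"], cohorts["normal"], {"sites": truth_sites, "clusters": truth_clusters}


def write_fixture(tumor: Cohort, normal: Cohort, truth: dict, directory) -> dict[str, list[Path]]:
    """Write per-sample canonical TSVs plus the truth tables.

    Files round-trip through :func:`hemimeth.io.read_stranded_table`.
    Returns the written sample paths per cohort label.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[Path]] = {}
    for cohort in (tumor, normal):
        paths = []
        for j, sid in enumerate(cohort.sample_ids):
            table = cohort.sites.copy()
            table["fwd_meth"] = cohort.fwd_meth[:, j]
            table["fwd_total"] = cohort.fwd_total[:, j]
            table["rev_meth"] = cohort.rev_meth[:, j]
            table["rev_total"] = cohort.rev_total[:, j]
            path = directory / f"{cohort.label}_{sid}.tsv"
            write_stranded_table(table, path)
            paths.append(path)
        written[cohort.label] = paths
    truth["sites"].to_csv(directory / "truth_sites.tsv", sep="\t", index=False)
    truth["clusters"].to_csv(directory / "truth_clusters.tsv", sep="\t", index=False)
    return written


def read_fixture(directory, label: str) -> Cohort:
    """Re-assemble one cohort from a written fixture directory."""
    directory = Path(directory)
    tables = {}
    for path in sorted(directory.glob(f"{label}_*.tsv")):
        sid = path.stem.split("_", 1)[1]
        tables[sid] = read_stranded_table(path, sid)
    return Cohort.from_sample_tables(label, tables)
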