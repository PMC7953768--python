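import itertools

import numpy as np
import pandas as pd
import pytest

from hemimeth.clusters import Cluster
from hemimeth.io import Cohort

# Forward-strand halves and (normal, tumor) counts of the published cluster
# pattern inventory used to cross-check the taxonomy bookkeeping.
CLUSTER_PATTERN_COUNTS = [
    ("M" * 12, 1, 1),
    ("M" * 10, 1, 1),
    ("M" * 8, 2, 2),
    ("M" * 7, 2, 2),
    ("M" * 6, 5, 3),
    ("M" * 5, 6, 7),
    ("M" * 4, 18, 13),
    ("MMM", 55, 32),
    ("MM", 168, 153),
    ("MMU", 0, 1),
    ("MU", 28, 32),
    ("UMM", 1, 0),
    ("UM", 7, 4),
    ("UUM", 1, 0),
    ("UU", 195, 172),
    ("UUU", 52, 44),
    ("UUUU", 22, 22),
    ("U" * 5, 9, 14),
    ("U" * 6, 3, 4),
    ("U" * 6 + "M", 0, 1),
    ("U" * 7, 4, 3),
    ("U" * 7 + "M", 1, 0),
    ("U" * 8, 2, 2),
]


def clusters_from_pattern_counts(column: int) -> list[Cluster]:
    """Materialize one cohort's pattern inventory as Cluster objects.

    ``column`` 0 selects the normal counts, 1 the tumor counts.  Positions
    are synthetic (2 bp spacing on disjoint stretches); only orientations
    matter for taxonomy checks.
    """
    out = []
    base = 1000
    for fwd, n_normal, n_tumor in CLUSTER_PATTERN_COUNTS:
        count = (n_normal, n_tumor)[column]
        orientations = tuple("MU" if ch == "M" else "UM" for ch in fwd)
        for _ in range(count):
            positions = tuple(base + 2 * i for i in range(len(fwd)))
            out.append(Cluster("chr1", positions, orientations))
            base += 2 * len(fwd) + 10
    return out


def brute_force_signed_rank_p(differences) -> float:
    """Independent oracle: exact two-sided signed-rank p by direct
    enumeration of every sign assignment of the observed rank vector."""
    from scipy.stats import rankdata

    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def cohort_from_levels(fwd_levels, rev_levels, total: int = 10, label: str = "tumor") -> Cohort:
    """Build a single- or multi-site cohort from per-site per-sample
    methylation levels; counts are level*total rounded, depth constant."""
    fwd = np.asarray(fwd_levels, dtype=float)
    rev = np.asarray(rev_levels, dtype=float)
    if fwd.ndim == 1:
        fwd, rev = fwd[None, :], rev[None, :]
    n_sites, n_samples = fwd.shape
    sites = pd.DataFrame({"chrom": ["chr1"] * n_sites, "pos": [100 + 10 * i for i in range(n_sites)]})
    totals = np.full((n_sites, n_samples), total, dtype=np.int64)
    return Cohort(
        label,
        [f"S{j}" for j in range(n_samples)],
        sites,
        np.rint(fwd * total).astype(np.int64),
        totals.copy(),
        np.rint(rev * total).astype(np.int64),
        totals.copy(),
    )


def swap_strands(cohort: Cohort) -> Cohort:
    return Cohort(
        cohort.label,
        list(cohort.sample_ids),
        cohort.sites.copy(),
        cohort.rev_meth.copy(),
        cohort.rev_total.copy(),
        cohort.fwd_meth.copy(),
        cohort.fwd_total.copy(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calls_frame():
    """A small sorted call table exercising every label."""
    rows = [
        ("chr1", 100, "MU"),
        ("chr1", 110, "MU"),
        ("chr1", 120, "NA"),
        ("chr1", 130, "UM"),
        ("chr1", 145, "NS"),
        ("chr1", 160, "UM"),
        ("chr2", 100, "MU"),
        ("chr2", 102, "UM"),
        ("chr2", 130, "NS"),
        ("chr2", 150, "MU"),
    ]
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "label"])
    frame["p_value"] = np.where(frame["label"].isin(["MU", "UM"]), 0.01, 0.5)
    frame["mean_diff"] = np.select(
        [frame["label"] == "MU", frame["label"] == "UM"], [0.8, -0.8], 0.0
    )
    frame["n_informative"] = 18
    return frame
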