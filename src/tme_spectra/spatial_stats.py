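"""Spatial statistics: minimum inter-type distances and neighborhood enrichment.

Distances are computed within each ROI (cells in different tissue cores have
no meaningful mutual distance) and pooled across ROIs per group. Two-group
distance comparisons use the two-sided Wilcoxon rank-sum test with the effect
size r = Z / sqrt(N), N being the total number of minimum-distance
measurements across both groups; positive r means group-1 distances are
stochastically larger. Neighborhood enrichment standardises observed
co-neighbour edge counts on a fixed spatial graph against a label-permutation
null (z-score per cell-type pair), with an exhaustive-enumeration mode for
small instances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from sympy.utilities.iterables import multiset_permutations

from .core_data import CellTable

__all__ = [
    "DistanceComparison",
    "SpatialGraph",
    "NeighborhoodEnrichment",
    "min_distance_distributions",
    "compare_distances",
    "build_spatial_graph",
    "neighborhood_enrichment",
]


@dataclass
class DistanceComparison:
    """Two groups' minimum-distance samples and their rank-sum comparison."""

    source_type: str
    target_type: str
    distances1: np.ndarray  # um
    distances2: np.ndarray  # um
    u_stat: float
    z: float
    p: float
    n: int  # n1 + n2 minimum-distance measurements
    r: float  # Z / sqrt(N)
    group1: str = "group1"
    group2: str = "group2"


def min_distance_distributions(
    cells: CellTable,
    source_type: str,
    target_type: str,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Per source cell, distance (um) to the nearest target cell in its ROI.

    When source and target types coincide the cell itself is excluded. ROIs
    lacking targets (or, for same-type queries, with a single cell) are
    skipped with a warning. Returns columns: roi_id, case_id, cell_id,
    distance_um.
    """
    df = cells.df
    known = set(df["population"].unique())
    for t in (source_type, target_type):
        if t not in known:
            raise ValueError(f"unknown cell type {t!r}; present: {sorted(known)}")

    same = source_type == target_type
    out = []
    for roi, sub in df.groupby("roi_id", sort=True):
        src = sub[sub["population"] == source_type]
        tgt = sub[sub["population"] == target_type]
        if len(src) == 0:
            continue
        if len(tgt) == 0 or (same and len(tgt) < 2):
            warnings.warn(f"ROI {roi!r}: no valid {target_type!r} targets; skipped", stacklevel=2)
            continue
        tree = cKDTree(tgt[["x_px", "y_px"]].to_numpy(dtype=float))
        q = src[["x_px", "y_px"]].to_numpy(dtype=float)
        if same:
            d, _ = tree.query(q, k=2)
            d = d[:, 1]
        else:
            d, _ = tree.query(q, k=1)
        out.append(
            pd.DataFrame(
                {
                    "roi_id": roi,
                    "case_id": src["case_id"].to_numpy(),
                    "cell_id": src["cell_id"].to_numpy(),
                    "distance_um": d * pixel_size_um,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["roi_id", "case_id", "cell_id", "distance_um"])
    return pd.concat(out, ignore_index=True)


def compare_distances(
    distances1: Sequence[float],
    distances2: Sequence[float],
    source_type: str = "",
    target_type: str = "",
    group1: str = "group1",
    group2: str = "group2",
) -> DistanceComparison:
    """Two-sided Wilcoxon rank-sum comparison with effect size r = Z / sqrt(N).

    Z is the tie-corrected standardized U statistic of sample 1 (positive
    when group-1 distances are stochastically larger). The p-value is exact
    for small tie-free samples and normal-approximated otherwise (scipy's
    default policy).
    """
    d1 = np.asarray(distances1, dtype=float)
    d2 = np.asarray(distances2, dtype=float)
    if len(d1) == 0 or len(d2) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(d1), len(d2)
    n = n1 + n2

    u1, p = stats.mannwhitneyu(d1, d2, alternative="two-sided")

    # tie-corrected normal standardization of U1
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([d1, d2])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = 0.0 if var == 0 else (u1 - mu) / math.sqrt(var)
    r = z / math.sqrt(n)

    return DistanceComparison(
        source_type=source_type,
        target_type=target_type,
        distances1=d1,
        distances2=d2,
        u_stat=float(u1),
        z=float(z),
        p=float(p),
        n=n,
        r=float(r),
        group1=group1,
        group2=group2,
    )


# ---------------------------------------------------------------------------
# spatial graph + neighborhood enrichment
# ---------------------------------------------------------------------------


@dataclass
class SpatialGraph:
    """Undirected spatial neighbours graph over the cells of one ROI."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) int array, i < j, no self-edges
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if len(e) and (e[:, 0] == e[:, 1]).any():
            raise ValueError("self-edges are not allowed")
        e = np.sort(e, axis=1)
        order = np.lexsort((e[:, 1], e[:, 0]))
        self.edges = e[order]
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)[order]


def build_spatial_graph(
    xy: np.ndarray,
    method: str = "knn",
    k: int = 6,
    radius_um: float | None = None,
    pixel_size_um: float = 1.0,
) -> SpatialGraph:
    """kNN (symmetrized) or fixed-radius spatial neighbours graph.

    ``xy`` is an (n, 2) array of pixel coordinates. kNN: edge i-j iff j is
    among i's k nearest; radius: edge iff the physical distance <= radius_um.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    if n < 2:
        raise ValueError("need at least 2 cells")
    tree = cKDTree(xy)
    if method == "knn":
        if k >= n:
            raise ValueError(f"k={k} must be < n={n}")
        _, idx = tree.query(xy, k=k + 1)
        pairs = set()
        for i in range(n):
            for j in idx[i, 1:]:
                pairs.add((min(i, int(j)), max(i, int(j))))
        edges = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    elif method == "radius":
        if radius_um is None or radius_um <= 0:
            raise ValueError("radius method needs positive radius_um")
        pairs_list = tree.query_pairs(radius_um / pixel_size_um, output_type="ndarray")
        edges = np.asarray(pairs_list, dtype=np.int64).reshape(-1, 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpatialGraph(n_nodes=n, edges=edges)


@dataclass
class NeighborhoodEnrichment:
    """Per cell-type pair z-scores of co-neighbour counts vs a permutation null."""

    types: list[str]
    zscores: pd.DataFrame  # types x types, symmetric
    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    n_permutations: int
    seed: int | None
    exhaustive: bool = False


def _pair_counts(edges_a: np.ndarray, edges_b: np.ndarray, codes: np.ndarray, t: int) -> np.ndarray:
    """t x t symmetric matrix of edge counts by endpoint-type pair."""
    ca, cb = codes[edges_a], codes[edges_b]
    lo = np.minimum(ca, cb)
    hi = np.maximum(ca, cb)
    flat = np.bincount(lo * t + hi, minlength=t * t)
    m = flat.reshape(t, t).astype(float)
    return m + np.triu(m, 1).T


def neighborhood_enrichment(
    graph: SpatialGraph,
    labels: Sequence[str],
    n_permutations: int = 1000,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> NeighborhoodEnrichment:
    """Neighborhood-enrichment z-scores on a fixed graph.

    The observed statistic per (type a, type b) is the number of graph edges
    joining an a-cell to a b-cell. The null permutes labels over nodes with
    the graph fixed; z = (obs - null mean) / null sd, with z = 0 wherever the
    null sd is 0. ``exhaustive=True`` enumerates every distinct labeling
    (multiset permutations) instead of sampling; refuse when there are more
    than 1e6 of them.
    """
    labels = np.asarray(labels)
    if len(labels) != graph.n_nodes:
        raise ValueError("labels length must equal the number of nodes")
    types, codes = np.unique(labels, return_inverse=True)
    t = len(types)
    if t < 2:
        warnings.warn("single label class; all z-scores are 0", stacklevel=2)
    ea, eb = graph.edges[:, 0], graph.edges[:, 1]
    obs = _pair_counts(ea, eb, codes, t)

    if exhaustive:
        counts = np.bincount(codes, minlength=t)
        n_distinct = math.factorial(len(codes))
        for c in counts:
            n_distinct //= math.factorial(int(c))
        if n_distinct > 1_000_000:
            raise ValueError(f"{n_distinct} distinct labelings exceed the exhaustive limit")
        samples = np.empty((n_distinct, t, t))
        for i, perm in enumerate(multiset_permutations(codes.tolist())):
            samples[i] = _pair_counts(ea, eb, np.asarray(perm), t)
        n_used = n_distinct
    else:
        rng = np.random.default_rng(seed)
        samples = np.empty((n_permutations, t, t))
        perm = codes.copy()
        for i in range(n_permutations):
            rng.shuffle(perm)
            samples[i] = _pair_counts(ea, eb, perm, t)
        n_used = n_permutations

    mean = samples.mean(axis=0)
    sd = samples.std(axis=0)
    z = np.zeros_like(obs)
    nz = sd > 0
    z[nz] = (obs[nz] - mean[nz]) / sd[nz]

    idx = pd.Index(types, name="cell_type")
    as_df = lambda m: pd.DataFrame(m, index=idx, columns=idx)
    return NeighborhoodEnrichment(
        types=list(types),
        zscores=as_df(z),
        observed=as_df(obs),
        null_mean=as_df(mean),
        null_sd=as_df(sd),
        n_permutations=n_used,
        seed=seed,
        exhaustive=exhaustive,
    )
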