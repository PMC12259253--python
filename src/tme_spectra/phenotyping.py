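"""Gating, phenotype clustering, and per-group statistics.

Cells are first gated into lineage populations by ordered marker
positivity/negativity rules (e.g. CD4 T = CK- CD68- CD20- CD3+ CD4+ CD8-).
Within a population, multimarker phenotypes are clustered PhenoGraph-style:
exact k-nearest-neighbour graph on transformed intensities (arcsinh cofactor
5, then per-marker z-score), Jaccard shared-neighbour edge weights, and
modularity-maximising Louvain community detection. Per-cluster group
statistics follow the two-group design: proportions, fold changes, Fisher's
exact test with Holm adjustment. Single-marker group comparisons report both
a pooled rank-sum test and a linear mixed-effects model with a random
intercept per case (the hierarchical, per-patient-variability-aware test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .core_data import CellTable, CohortManifest, PanelConfig

__all__ = [
    "GatingScheme",
    "ClusterModel",
    "ClusterStats",
    "MarkerComparison",
    "DEFAULT_GATING",
    "gate_populations",
    "cluster_cells",
    "cluster_group_stats",
    "marker_group_comparison",
    "marker_panel_comparison",
    "cluster_marker_heatmap",
    "T_CELL_FUNCTIONAL_MARKERS",
    "TAM_FUNCTIONAL_MARKERS",
]

#: functional panels used for population-level comparisons and clustering
T_CELL_FUNCTIONAL_MARKERS = (
    "TBET", "CD45RO", "CD25", "PD1", "GRZB", "KI67", "LAG3", "TIM3", "FOXP3",
)
TAM_FUNCTIONAL_MARKERS = (
    "PDL1", "PDL2", "B7H3", "B7H4", "VISTA", "IDO1", "KI67", "B2M",
)


@dataclass
class GatingScheme:
    """Ordered positivity/negativity rules; first match wins.

    Each rule maps a population label to requirements ``{marker: True/False}``
    (True = intensity > threshold). Cells matching no rule are 'unassigned'.
    """

    rules: list[tuple[str, dict[str, bool]]]
    thresholds: dict[str, float]

    def required_markers(self) -> set[str]:
        out: set[str] = set()
        for _, req in self.rules:
            out |= set(req)
        return out


#: the four-population scheme of the emulated study plus a B-cell rule
DEFAULT_GATING_RULES: list[tuple[str, dict[str, bool]]] = [
    ("CD4T", {"CK": False, "CD68": False, "CD20": False, "CD3": True, "CD4": True, "CD8": False}),
    ("CD8T", {"CK": False, "CD68": False, "CD20": False, "CD3": True, "CD4": False, "CD8": True}),
    ("TAM", {"CK": False, "CD68": True, "CD20": False, "CD3": False}),
    ("tumor", {"CK": True, "CD68": False, "CD20": False, "CD3": False}),
    ("B", {"CK": False, "CD68": False, "CD20": True, "CD3": False}),
]


def default_gating(panel: PanelConfig) -> GatingScheme:
    return GatingScheme(rules=list(DEFAULT_GATING_RULES), thresholds=dict(panel.gate_thresholds))


DEFAULT_GATING = default_gating


def gate_populations(cells: CellTable, scheme: GatingScheme) -> CellTable:
    """Assign each cell the first matching rule's population label."""
    for m in scheme.required_markers():
        if m not in cells.markers:
            raise ValueError(f"gating rule references unknown marker {m!r}")
        if m not in scheme.thresholds:
            raise ValueError(f"no gate threshold for marker {m!r}")
    df = cells.df
    n = len(df)
    labels = np.full(n, "unassigned", dtype=object)
    unmatched = np.ones(n, dtype=bool)
    for pop, req in scheme.rules:
        ok = unmatched.copy()
        for marker, positive in req.items():
            pos = df[marker].to_numpy(dtype=float) > scheme.thresholds[marker]
            ok &= pos if positive else ~pos
        labels[ok] = pop
        unmatched &= ~ok
    return cells.with_columns(population=labels)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """PhenoGraph-style clustering parameters.

    Transform: arcsinh with the given cofactor then per-marker z-score
    (constant markers are left at zero). Graph: exact Euclidean kNN,
    Jaccard shared-neighbour weights, Louvain at the given resolution.
    """

    k_neighbors: int = 15
    resolution: float = 1.0
    arcsinh_cofactor: float = 5.0
    seed: int = 0


def transform_intensities(x: np.ndarray, cofactor: float = 5.0) -> np.ndarray:
    """arcsinh(x / cofactor) then per-column z-score (constant columns -> 0)."""
    t = np.arcsinh(np.asarray(x, dtype=float) / cofactor)
    mu = t.mean(axis=0)
    sd = t.std(axis=0)
    # treat numerically-constant columns as constant (z-score -> 0)
    const = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    sd = np.where(const, 1.0, sd)
    out = (t - mu) / sd
    out[:, const] = 0.0
    return out


def knn_indices(x: np.ndarray, k: int) -> np.ndarray:
    """Indices of each row's k nearest neighbours (Euclidean, self excluded)."""
    n = len(x)
    if k >= n:
        raise ValueError(f"k_neighbors={k} must be < n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(x)
    _, idx = nn.kneighbors(x)
    return idx[:, 1:]


def shared_neighbor_graph(idx: np.ndarray) -> nx.Graph:
    """Jaccard shared-neighbour weighted graph from a kNN index array."""
    n, k = idx.shape
    sets = [set(row) for row in idx]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if g.has_edge(i, j):
                continue
            shared = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            w = shared / union if union else 0.0
            if w > 0:
                g.add_edge(i, j, weight=w)
    return g


def cluster_cells(
    cells: CellTable,
    markers: Sequence[str],
    model: ClusterModel | None = None,
) -> np.ndarray:
    """Cluster one population's cells; returns 1-based labels (size-ordered)."""
    model = model or ClusterModel()
    x = cells.intensity_matrix(markers)
    if len(x) < model.k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1={model.k_neighbors + 1} cells, got {len(x)}"
        )
    t = transform_intensities(x, model.arcsinh_cofactor)
    idx = knn_indices(t, model.k_neighbors)
    g = shared_neighbor_graph(idx)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=model.resolution, seed=model.seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.zeros(len(x), dtype=np.int64)
    for lab, members in enumerate(comms, start=1):
        for i in members:
            labels[i] = lab
    return labels


# ---------------------------------------------------------------------------
# per-group cluster statistics
# ---------------------------------------------------------------------------


@dataclass
class ClusterStats:
    """Per-cluster two-group composition statistics.

    ``table`` columns: cluster, n_<group1>, n_<group2>, prop_<group1>,
    prop_<group2>, fold_change (group1 / group2), fisher_p, fisher_p_adj.
    """

    table: pd.DataFrame
    group1: str
    group2: str


def cluster_group_stats(
    cells: CellTable,
    manifest: CohortManifest,
    group1: str | None = None,
    cluster_col: str = "cluster",
) -> ClusterStats:
    """Proportions, fold changes, and Fisher exact tests per cluster.

    ``group1`` names the fold-change numerator (default: first manifest
    group); the 2x2 table per cluster is (in cluster / not in cluster) by
    group, tested two-sided with Holm adjustment across clusters.
    """
    ga, gb = manifest.require_two_groups()
    if group1 is None:
        group1 = ga
    group2 = gb if group1 == ga else ga
    if group1 not in (ga, gb):
        raise ValueError(f"group1={group1!r} not in manifest groups {(ga, gb)}")

    df = cells.df
    group_of = manifest.group_of()
    unknown = set(df["case_id"]) - set(group_of)
    if unknown:
        raise ValueError(f"cells reference cases missing from manifest: {sorted(unknown)[:5]}")
    groups = df["case_id"].map(group_of)
    clusters = df[cluster_col]
    if clusters.isna().any():
        raise ValueError("all cells must carry a cluster label")

    n1_total = int((groups == group1).sum())
    n2_total = int((groups == group2).sum())
    if n1_total == 0 or n2_total == 0:
        raise ValueError("each group needs at least one cell in the population")

    rows = []
    for c in sorted(pd.unique(clusters)):
        in_c = clusters == c
        n1 = int((in_c & (groups == group1)).sum())
        n2 = int((in_c & (groups == group2)).sum())
        p1, p2 = n1 / n1_total, n2 / n2_total
        fc = p1 / p2 if p2 > 0 else np.inf
        _, p = stats.fisher_exact(
            [[n1, n1_total - n1], [n2, n2_total - n2]], alternative="two-sided"
        )
        rows.append(
            {
                "cluster": c,
                f"n_{group1}": n1,
                f"n_{group2}": n2,
                f"prop_{group1}": p1,
                f"prop_{group2}": p2,
                "fold_change": fc,
                "fisher_p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    table["fisher_p_adj"] = multipletests(table["fisher_p"], method="holm")[1]
    return ClusterStats(table=table, group1=group1, group2=group2)


# ---------------------------------------------------------------------------
# single-marker group comparisons
# ---------------------------------------------------------------------------


@dataclass
class MarkerComparison:
    marker: str
    group1: str
    group2: str
    mean1: float
    mean2: float
    rank_stat: float
    rank_p: float
    mixed_estimate: float  # group1 - group2 fixed effect
    mixed_group1: float
    mixed_group2: float
    mixed_se: float
    mixed_p: float
    singular_fit: bool
    rank_p_adj: float | None = None
    mixed_p_adj: float | None = None


def marker_group_comparison(
    cells: CellTable,
    marker: str,
    manifest: CohortManifest,
    group1: str | None = None,
) -> MarkerComparison:
    """Two-group comparison of one marker's per-cell intensities.

    Reports (a) a pooled two-sided Wilcoxon rank-sum test and (b) the group
    fixed effect from a linear mixed model with a random intercept per case
    (between-individual variability). A variance estimate pinned at the zero
    boundary is flagged as a singular fit, not dropped.
    """
    if marker not in cells.df.columns:
        raise ValueError(f"marker {marker!r} absent from cell table")
    ga, gb = manifest.require_two_groups()
    if group1 is None:
        group1 = ga
    group2 = gb if group1 == ga else ga

    df = cells.df
    group_of = manifest.group_of()
    groups = df["case_id"].map(group_of)
    y = df[marker].to_numpy(dtype=float)
    y1 = y[(groups == group1).to_numpy()]
    y2 = y[(groups == group2).to_numpy()]
    for g, n_cases in (
        (group1, df.loc[(groups == group1).to_numpy(), "case_id"].nunique()),
        (group2, df.loc[(groups == group2).to_numpy(), "case_id"].nunique()),
    ):
        if n_cases < 2:
            raise ValueError(f"group {g!r} needs >= 2 cases with cells")

    stat, rank_p = stats.mannwhitneyu(y1, y2, alternative="two-sided")

    sub = pd.DataFrame(
        {
            "y": y,
            "g": (groups == group1).astype(float).to_numpy(),
            "case": df["case_id"].to_numpy(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        md = MixedLM.from_formula("y ~ g", groups="case", data=sub)
        fit = md.fit(reml=True)
        if not np.isfinite(float(fit.bse["g"])):
            fit = md.fit(reml=True, method="cg")
    est = float(fit.params["g"])
    se = float(fit.bse["g"])
    p = float(fit.pvalues["g"])
    if not np.isfinite(p):
        # variance pinned at the zero boundary: the GLS fit degenerates to
        # OLS; use its Wald test so the comparison still reports a p-value
        import statsmodels.api as sm

        x = sm.add_constant(sub["g"].to_numpy())
        ols = sm.OLS(sub["y"].to_numpy(), x).fit()
        est, se, p = float(ols.params[1]), float(ols.bse[1]), float(ols.pvalues[1])
    intercept = float(fit.params["Intercept"])
    singular = bool(np.isclose(float(fit.cov_re.iloc[0, 0]), 0.0, atol=1e-10))

    return MarkerComparison(
        marker=marker,
        group1=group1,
        group2=group2,
        mean1=float(np.mean(y1)),
        mean2=float(np.mean(y2)),
        rank_stat=float(stat),
        rank_p=float(rank_p),
        mixed_estimate=est,
        mixed_group1=intercept + est,
        mixed_group2=intercept,
        mixed_se=se,
        mixed_p=p,
        singular_fit=singular,
    )


def marker_panel_comparison(
    cells: CellTable,
    markers: Sequence[str],
    manifest: CohortManifest,
    group1: str | None = None,
) -> list[MarkerComparison]:
    """Per-marker comparisons with Holm adjustment across the panel."""
    out = [marker_group_comparison(cells, m, manifest, group1=group1) for m in markers]
    rank_adj = multipletests([c.rank_p for c in out], method="holm")[1]
    mixed_adj = multipletests([c.mixed_p for c in out], method="holm")[1]
    for c, ra, ma in zip(out, rank_adj, mixed_adj):
        c.rank_p_adj = float(ra)
        c.mixed_p_adj = float(ma)
    return out


def cluster_marker_heatmap(
    cells: CellTable,
    labels: np.ndarray | Sequence[int],
    markers: Sequence[str],
) -> pd.DataFrame:
    """Cluster x marker matrix of mean intensities min-max scaled to [0, 1]
    per marker across clusters; markers constant across clusters map to 0."""
    labels = np.asarray(labels)
    if len(labels) != len(cells):
        raise ValueError("labels length must match cell count")
    uniq = np.unique(labels)
    x = cells.intensity_matrix(markers)
    means = np.array([x[labels == c].mean(axis=0) for c in uniq])
    lo = means.min(axis=0)
    hi = means.max(axis=0)
    span = hi - lo
    scaled = np.zeros_like(means)
    nz = span > 0
    scaled[:, nz] = (means[:, nz] - lo[nz]) / span[nz]
    return pd.DataFrame(scaled, index=pd.Index(uniq, name="cluster"), columns=list(markers))
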