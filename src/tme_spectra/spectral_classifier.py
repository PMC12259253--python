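"""Segmentation-free spectral-graph classification of tissue images.

The pipeline turns each case's multichannel image into a small set of
micro-patches centred on the strongest tumor-marker (CK) signal, builds a
weighted similarity graph over those patches, and summarises each antibody as
the steady-state distribution (SSD) of a personalized PageRank random walk on
that graph, with the antibody's per-patch expression as the restart
(teleport) distribution. Stacking the SSDs of all markers over all cases
gives a markers x patches representation matrix whose columns (patches) are
embedded with diffusion maps and classified with an RBF SVM under
leave-one-case-out cross-validation (held-out patches enter the embedding via
Nystrom extension only). Markers are ranked by the L1 distance between their
group-averaged, rank-aligned SSDs.

The default SSD construction (per-case patch graph, per-marker teleport) is
the primary strategy; an alternative that walks over a marker graph within
each patch is available via ``strategy="marker_graph"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.svm import SVC

from .core_data import CohortManifest, MultichannelImage

__all__ = [
    "PatchParams",
    "Patch",
    "PageRankParams",
    "RepresentationMatrix",
    "DiffusionMap",
    "ClassificationResult",
    "MarkerRanking",
    "select_patches",
    "case_patch_graph",
    "personalized_pagerank_ssd",
    "build_representation_matrix",
    "loocv_classify",
    "rank_markers",
]


@dataclass
class PatchParams:
    """Patch selection: how many patches per case and their physical size."""

    n_patches_per_case: int = 14
    patch_side_um: float = 35.0
    selection_marker: str = "CK"
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_patches_per_case < 2:
            raise ValueError("n_patches_per_case must be >= 2")
        if self.patch_side_um <= 0:
            raise ValueError("patch_side_um must be > 0")

    def side_px(self, pixel_size_um: float) -> int:
        return max(1, int(round(self.patch_side_um / pixel_size_um)))


@dataclass
class Patch:
    """One square micro-patch and its per-marker mean expression."""

    case_id: str
    roi_id: str
    center_yx: tuple[int, int]
    side_px: int
    expression: np.ndarray  # length = n markers, panel order

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if not np.all(np.isfinite(self.expression)) or (self.expression < 0).any():
            raise ValueError("patch expression must be finite and >= 0")


@dataclass
class PageRankParams:
    """Personalized-PageRank parameters (damping, tolerance, iteration cap).

    The default damping 0.5 balances the walk and restart terms: on a small,
    nearly complete patch graph a single damped step mixes almost completely,
    so the classical web-graph value 0.85 leaves the steady state dominated
    by the (marker-independent) graph stationary distribution and nearly
    erases the per-marker teleport signal.
    """

    alpha: float = 0.5
    tol: float = 1e-12
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def select_patches(image: MultichannelImage, params: PatchParams) -> list[Patch]:
    """Greedily select the n highest-mean windows of the selection marker.

    The selection channel is filtered with a patch-sized box filter; patch
    centres are taken at successive maxima of the filtered map and, when
    overlap is disallowed, positions whose patch would overlap an accepted
    one are excluded. Raises if the image is smaller than one patch or if
    fewer than ``n_patches_per_case`` feasible positions exist.
    """
    side = params.side_px(image.pixel_size_um)
    h, w = image.shape_yx
    if h < side or w < side:
        raise ValueError(f"image {h}x{w} smaller than one {side}px patch")
    ch = image.channel(params.selection_marker)

    # box-filter via integral image: window mean at each valid top-left corner
    ii = np.cumsum(np.cumsum(ch, axis=0), axis=1)
    ii = np.pad(ii, ((1, 0), (1, 0)))
    sums = (
        ii[side:, side:] - ii[:-side, side:] - ii[side:, :-side] + ii[:-side, :-side]
    )
    scores = sums / (side * side)  # shape (h-side+1, w-side+1), index = top-left

    n = params.n_patches_per_case
    patches: list[Patch] = []
    scores = scores.copy()
    for _ in range(n):
        if np.all(np.isneginf(scores)):
            raise ValueError(
                f"only {len(patches)} of {n} non-overlapping patches fit the image"
            )
        flat = int(np.argmax(scores))
        ty, tx = np.unravel_index(flat, scores.shape)
        cy, cx = int(ty) + side // 2, int(tx) + side // 2
        block = image.data[:, ty : ty + side, tx : tx + side]
        patches.append(
            Patch(
                case_id=image.case_id,
                roi_id=image.roi_id,
                center_yx=(cy, cx),
                side_px=side,
                expression=block.mean(axis=(1, 2)),
            )
        )
        if params.allow_overlap:
            scores[ty, tx] = -np.inf
        else:
            y0, y1 = max(0, ty - side + 1), min(scores.shape[0], ty + side)
            x0, x1 = max(0, tx - side + 1), min(scores.shape[1], tx + side)
            scores[y0:y1, x0:x1] = -np.inf
    return patches


def case_patch_graph(
    expression: np.ndarray, params: PageRankParams | None = None
) -> np.ndarray:
    """Gaussian-kernel affinity matrix over one case's patches.

    ``expression`` is (n_patches, n_markers); vectors are standardized per
    marker across the case's patches, and w_ij = exp(-||e_i - e_j||^2 / eps)
    with eps the median squared pairwise distance (fallback 1 when all
    patches are identical). The diagonal is zero.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need a 2-D array with >= 2 patches")
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (x - mu) / sd
    d2 = squareform(pdist(xs, metric="sqeuclidean"))
    off = d2[~np.eye(len(x), dtype=bool)]
    eps = float(np.median(off))
    if eps == 0:
        eps = 1.0
    w = np.exp(-d2 / eps)
    np.fill_diagonal(w, 0.0)
    return w


def _row_normalize(w: np.ndarray) -> np.ndarray:
    rs = w.sum(axis=1, keepdims=True)
    out = np.where(rs > 0, w / np.where(rs == 0, 1.0, rs), 1.0 / w.shape[1])
    return out


def personalized_pagerank_ssd(
    w: np.ndarray,
    teleport: np.ndarray,
    params: PageRankParams | None = None,
) -> np.ndarray:
    """Stationary distribution of the damped walk with restart distribution t.

    Solves s = alpha * M^T s + (1 - alpha) * t by power iteration, with M the
    row-normalized walk matrix of ``w`` and t the teleport vector normalized
    to sum 1. The result is a probability vector over patches.
    """
    params = params or PageRankParams()
    t = np.asarray(teleport, dtype=float)
    if t.ndim != 1 or len(t) != w.shape[0]:
        raise ValueError("teleport length must match the number of nodes")
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("teleport needs at least one positive entry and none negative")
    t = t / t.sum()
    m_t = _row_normalize(w).T
    s = t.copy()
    for _ in range(params.max_iter):
        s_new = params.alpha * (m_t @ s) + (1.0 - params.alpha) * t
        resid = np.abs(s_new - s).sum()
        s = s_new
        if resid < params.tol:
            s = s / s.sum()
            return s
    raise RuntimeError(f"PageRank did not converge: residual {resid:.3e} after {params.max_iter} iterations")


@dataclass
class RepresentationMatrix:
    """Markers x patches SSD feature matrix with per-column metadata.

    ``meta`` columns: case_id, roi_id, patch_index (within case), group
    (filled by :func:`attach_groups` / the classifier).
    """

    values: np.ndarray  # (n_markers, n_patches)
    markers: list[str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.markers):
            raise ValueError("row count must equal number of markers")
        if self.values.shape[1] != len(self.meta):
            raise ValueError("column count must equal metadata rows")

    @property
    def cases(self) -> list[str]:
        return list(pd.unique(self.meta["case_id"]))

    def columns_of(self, case_id: str) -> np.ndarray:
        return np.flatnonzero((self.meta["case_id"] == case_id).to_numpy())

    def attach_groups(self, manifest: CohortManifest) -> None:
        self.meta = self.meta.assign(group=self.meta["case_id"].map(manifest.group_of()))


def build_representation_matrix(
    case_patches: Mapping[str, Sequence[Patch]],
    markers: Sequence[str],
    params: PageRankParams | None = None,
    strategy: str = "patch_graph",
) -> RepresentationMatrix:
    """Assemble per-case SSD features into a markers x patches matrix.

    ``strategy="patch_graph"`` (default): one affinity graph per case over
    its patches; row m of that case's block is the personalized-PageRank SSD
    with marker m's per-patch expression as teleport, so each (case, marker)
    block sums to 1 over the case's patches. A marker expressed nowhere in a
    case falls back to a uniform teleport.

    ``strategy="marker_graph"``: the walk runs over markers within each patch
    (nodes = markers, affinities from their scalar expressions); each column
    is then a probability vector over markers.
    """
    params = params or PageRankParams()
    markers = list(markers)
    cols: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for case_id, patches in case_patches.items():
        if len(patches) < 2:
            raise ValueError(f"case {case_id!r} has {len(patches)} patches; need >= 2")
        expr = np.stack([p.expression for p in patches])  # (P, M)
        if expr.shape[1] != len(markers):
            raise ValueError("patch expression length must match marker list")
        if strategy == "patch_graph":
            w = case_patch_graph(expr, params)
            block = np.empty((len(markers), len(patches)))
            for mi in range(len(markers)):
                tel = expr[:, mi]
                if tel.sum() <= 0:
                    tel = np.ones(len(patches))
                block[mi] = personalized_pagerank_ssd(w, tel, params)
            cols.append(block)
        elif strategy == "marker_graph":
            block = np.empty((len(markers), len(patches)))
            for pi in range(len(patches)):
                x = expr[pi][:, None]
                d2 = squareform(pdist(x, metric="sqeuclidean"))
                off = d2[~np.eye(len(markers), dtype=bool)]
                eps = float(np.median(off)) or 1.0
                wm = np.exp(-d2 / eps)
                np.fill_diagonal(wm, 0.0)
                tel = expr[pi]
                if tel.sum() <= 0:
                    tel = np.ones(len(markers))
                block[:, pi] = personalized_pagerank_ssd(wm, tel, params)
            cols.append(block)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        for pi, p in enumerate(patches):
            meta_rows.append(
                {"case_id": case_id, "roi_id": p.roi_id, "patch_index": pi}
            )
    values = np.concatenate(cols, axis=1)
    return RepresentationMatrix(values=values, markers=markers, meta=pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# diffusion maps with Nystrom out-of-sample extension
# ---------------------------------------------------------------------------


class DiffusionMap:
    """Diffusion-map embedding of feature vectors with Nystrom extension.

    Fit: Gaussian kernel K on the training points (bandwidth = median squared
    pairwise distance unless given), optional density normalization
    K <- K / (q qT) with q the kernel degrees (removes sampling-density
    effects; heterogeneous point densities otherwise localize the leading
    eigenvectors on tight clusters), Markov matrix P = D^-1 K, eigenpairs via
    the symmetric conjugation D^-1/2 K D^-1/2. The leading eigenvalue is 1
    with a constant eigenvector and is excluded; coordinates are the next
    ``n_components`` right eigenvectors scaled by their eigenvalues. A new
    point x is embedded as p(x, .) @ psi_i per retained component, which
    reproduces a training point's fitted coordinates exactly.
    """

    def __init__(
        self,
        n_components: int = 3,
        eps: float | None = None,
        density_normalize: bool = True,
    ):
        self.n_components = n_components
        self.eps = eps
        self.density_normalize = density_normalize

    def fit(self, x: np.ndarray) -> "DiffusionMap":
        x = np.asarray(x, dtype=float)
        n = len(x)
        if n < self.n_components + 1:
            raise ValueError("need at least n_components + 1 training points")
        d2 = squareform(pdist(x, metric="sqeuclidean"))
        eps = self.eps
        if eps is None:
            off = d2[~np.eye(n, dtype=bool)]
            eps = float(np.median(off))
            if eps == 0:
                eps = 1.0
        k = np.exp(-d2 / eps)
        q = k.sum(axis=1)  # raw kernel degrees, kept for the extension
        if self.density_normalize:
            k = k / np.outer(q, q)
        deg = k.sum(axis=1)
        d_inv_sqrt = 1.0 / np.sqrt(deg)
        a = k * np.outer(d_inv_sqrt, d_inv_sqrt)
        evals, evecs = eigh(a)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # right eigenvectors of P = D^-1 K
        psi = evecs * d_inv_sqrt[:, None]
        # deterministic sign: largest-|.| entry positive
        for j in range(psi.shape[1]):
            i = int(np.argmax(np.abs(psi[:, j])))
            if psi[i, j] < 0:
                psi[:, j] = -psi[:, j]
        if n - 1 < self.n_components:
            raise ValueError("n_components exceeds the nontrivial spectrum")
        self.eps_ = float(eps)
        self.train_x_ = x
        self.raw_degrees_ = q
        self.eigenvalues_ = evals  # evals[0] == 1 (trivial)
        self.psi_ = psi
        sel = slice(1, 1 + self.n_components)
        self.coords_ = psi[:, sel] * evals[sel]
        return self

    def transform(self, y: np.ndarray) -> np.ndarray:
        """Nystrom extension of new points into the fitted embedding."""
        y = np.asarray(y, dtype=float).reshape(-1, self.train_x_.shape[1])
        k = np.exp(-cdist(y, self.train_x_, metric="sqeuclidean") / self.eps_)
        if self.density_normalize:
            qy = k.sum(axis=1, keepdims=True)
            k = k / (qy * self.raw_degrees_[None, :])
        p = k / k.sum(axis=1, keepdims=True)
        sel = slice(1, 1 + self.n_components)
        return p @ self.psi_[:, sel]

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).coords_


# ---------------------------------------------------------------------------
# leave-one-case-out classification and marker ranking
# ---------------------------------------------------------------------------


@dataclass
class ClassificationResult:
    patch_predictions: pd.DataFrame  # case_id, group, predicted
    case_predictions: pd.DataFrame  # case_id, group, predicted
    confusion: pd.DataFrame  # true group x predicted
    case_accuracy: float
    patch_accuracy: float


def patch_feature_matrix(rep: RepresentationMatrix) -> np.ndarray:
    """Per-patch feature vectors for embedding and classification.

    Each column of the representation matrix is centred over markers before
    being used as a point: the across-marker mean of a patch's SSD entries is
    a marker-independent random-walk quantity (it reflects only the patch's
    connectivity in its case graph), so removing it leaves each marker's
    relative steady-state deviation — the component that carries phenotype.
    Returns an (n_patches, n_markers) array.
    """
    r = rep.values
    return (r - r.mean(axis=0, keepdims=True)).T


@dataclass
class _Fold:
    case_id: str
    test_mask: np.ndarray
    train_coords: np.ndarray
    test_coords: np.ndarray


def compute_loocv_embeddings(
    rep: RepresentationMatrix, n_components: int = 10
) -> list[_Fold]:
    """Per-fold diffusion embeddings (labels never enter this stage).

    For each case: standardize features on the training columns, fit the
    diffusion map on them, Nystrom-extend the held-out columns, and
    standardize the embedding coordinates (fitted on training coordinates)
    so all retained diffusion directions enter the SVM on a common scale.
    """
    x_all = patch_feature_matrix(rep)
    case_ids = rep.meta["case_id"].to_numpy()
    folds = []
    for case in pd.unique(case_ids):
        test = case_ids == case
        xtr, xte = x_all[~test], x_all[test]
        mu, sd = xtr.mean(axis=0), xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        dm = DiffusionMap(n_components=n_components).fit((xtr - mu) / sd)
        ctr = dm.coords_
        cte = dm.transform((xte - mu) / sd)
        cmu, csd = ctr.mean(axis=0), ctr.std(axis=0)
        csd = np.where(csd == 0, 1.0, csd)
        folds.append(
            _Fold(
                case_id=str(case),
                test_mask=test,
                train_coords=(ctr - cmu) / csd,
                test_coords=(cte - cmu) / csd,
            )
        )
    return folds


def loocv_classify(
    rep: RepresentationMatrix,
    manifest: CohortManifest,
    n_components: int = 10,
    svm_c: float = 1.0,
    svm_gamma: str | float = "scale",
    folds: list[_Fold] | None = None,
) -> ClassificationResult:
    """Leave-one-case-out RBF-SVM classification of patch columns.

    Each fold fits the diffusion embedding and the SVM on the other cases'
    columns only; the held-out case's patches are Nystrom-extended into that
    embedding and predicted individually, and the case label is the majority
    vote over its patches (an exact vote tie is broken by the sign of the
    summed SVM decision values, keeping the vote deterministic and the
    permutation null at chance level). The SVM uses
    balanced class weights so removing a case's patches from the training
    fold does not bias ambiguous predictions toward the other group.
    ``folds`` accepts precomputed embeddings (label-independent), e.g. to
    rerun the classification under permuted group labels cheaply.
    """
    g1, g2 = manifest.require_two_groups()
    rep.attach_groups(manifest)
    meta = rep.meta
    if meta["group"].isna().any():
        missing = meta.loc[meta["group"].isna(), "case_id"].unique()
        raise ValueError(f"cases missing from manifest: {list(missing)[:5]}")
    cases = list(pd.unique(meta["case_id"]))
    for g in (g1, g2):
        if len([c for c in cases if manifest.group_of()[c] == g]) < 2:
            raise ValueError(f"group {g!r} needs >= 2 cases")

    if folds is None:
        folds = compute_loocv_embeddings(rep, n_components=n_components)
    groups_all = meta["group"].to_numpy()
    patch_rows = []
    case_rows = []
    for fold in folds:
        test = fold.test_mask
        y_train = groups_all[~test]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold for case {fold.case_id!r} has a single training class")
        svm = SVC(C=svm_c, kernel="rbf", gamma=svm_gamma, class_weight="balanced")
        svm.fit(fold.train_coords, y_train)
        pred = svm.predict(fold.test_coords)
        true_group = groups_all[test][0]
        for p in pred:
            patch_rows.append({"case_id": fold.case_id, "group": true_group, "predicted": p})
        votes = pd.Series(pred).value_counts()
        if len(votes) > 1 and votes.iloc[0] == votes.iloc[1]:
            # exact vote tie: decide by the summed SVM decision value
            # (deterministic; sign > 0 means the second class in the SVM's
            # sorted class order)
            total = float(svm.decision_function(fold.test_coords).sum())
            case_pred = svm.classes_[1] if total > 0 else svm.classes_[0]
        else:
            case_pred = votes.index[0]
        case_rows.append(
            {"case_id": fold.case_id, "group": true_group, "predicted": case_pred}
        )

    patch_df = pd.DataFrame(patch_rows)
    case_df = pd.DataFrame(case_rows)
    confusion = pd.crosstab(case_df["group"], case_df["predicted"])
    case_acc = float((case_df["group"] == case_df["predicted"]).mean())
    patch_acc = float((patch_df["group"] == patch_df["predicted"]).mean())
    return ClassificationResult(
        patch_predictions=patch_df,
        case_predictions=case_df,
        confusion=confusion,
        case_accuracy=case_acc,
        patch_accuracy=patch_acc,
    )


@dataclass
class MarkerRanking:
    """Markers ordered by the L1 distance between group-average sorted SSDs."""

    table: pd.DataFrame  # marker, l1_distance, rank (1 = most discriminating)

    @property
    def ranked_markers(self) -> list[str]:
        return self.table.sort_values("rank")["marker"].tolist()


def rank_markers(rep: RepresentationMatrix, manifest: CohortManifest) -> MarkerRanking:
    """Rank markers by between-group L1 distance of their SSD profiles.

    Patch identities are not comparable across cases, so each case's SSD for
    a marker is sorted descending before averaging within group; the marker
    score is the L1 distance between the two group-average sorted vectors.
    Cases with unequal patch counts are aligned on the common minimum count
    (with a warning).
    """
    g1, g2 = manifest.require_two_groups()
    rep.attach_groups(manifest)
    meta = rep.meta
    counts = meta.groupby("case_id").size()
    p_min = int(counts.min())
    if counts.nunique() > 1:
        warnings.warn(
            f"unequal patches per case; aligning on the minimum ({p_min})", stacklevel=2
        )
    group_of = manifest.group_of()
    sorted_by_case: dict[str, np.ndarray] = {}
    for case in pd.unique(meta["case_id"]):
        cols = rep.columns_of(case)
        block = rep.values[:, cols]
        s = -np.sort(-block, axis=1)[:, :p_min]  # descending, aligned
        sorted_by_case[case] = s
    rows = []
    for mi, marker in enumerate(rep.markers):
        means = {}
        for g in (g1, g2):
            mats = [s[mi] for c, s in sorted_by_case.items() if group_of[c] == g]
            if not mats:
                raise ValueError(f"group {g!r} has no cases")
            means[g] = np.mean(mats, axis=0)
        rows.append({"marker": marker, "l1_distance": float(np.abs(means[g1] - means[g2]).sum())})
    table = pd.DataFrame(rows)
    table["rank"] = (
        table["l1_distance"].rank(ascending=False, method="first").astype(int)
    )
    return MarkerRanking(table=table.sort_values("rank").reset_index(drop=True))
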