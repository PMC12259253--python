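"""Synthetic two-group IMC cohort generator.

Emulates the structure of a matched NSCLC tissue-microarray cohort imaged by
mass cytometry: per-case regions of interest containing compact CK+ tumor
nests surrounded by stroma with CD4/CD8 T cells, CD68+ macrophages (TAMs) and
CD20+ B cells. Two group-dependent signals can be planted:

* functional-marker shifts (lognormal per-cell intensities whose log-mean
  differs by group, with a per-case random intercept), including an
  "exhausted" T-cell subpopulation (high PD-1 / LAG3 / KI67, low GRZB) whose
  prevalence differs by group; and
* spatial exclusion (immune cells placed at larger distances from the tumor
  nest in one group).

Every draw is recorded in a ground-truth cell table so each downstream stage
(segmentation, gating, clustering, group statistics, spatial statistics, the
spectral patch classifier) can be tested for recovery of the planted signal.

Intensity model: cell i of population P gets, for marker m,
``value = exp(mu[P, m, group] + delta_case[m] + noise_sd * z)`` with
``delta_case ~ N(0, case_effect_sd)`` shared by all cells of a case and
``z ~ N(0, 1)`` per cell. Cells are rendered as a nuclear disk (DNA and H3
channels) plus a larger cytoplasm/membrane disk carrying the population's
lineage markers and all functional markers; the background is low-rate
Poisson noise. Placement is hard-core (a minimum centre separation) so the
images are segmentable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_data import (
    DEFAULT_PANEL,
    CellTable,
    CohortManifest,
    MultichannelImage,
    PanelConfig,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_case_image",
    "generate_cohort",
    "truth_summary",
    "TruthSummary",
    "classifier_validation_config",
    "ranking_validation_config",
    "POPULATIONS",
    "LINEAGE_OF",
]

#: population -> lineage markers painted positive on that population's cells
LINEAGE_OF: dict[str, tuple[str, ...]] = {
    "tumor": ("CK",),
    "CD4T": ("CD3", "CD4"),
    "CD8T": ("CD3", "CD8"),
    "TAM": ("CD68",),
    "B": ("CD20",),
}

POPULATIONS = tuple(LINEAGE_OF)

_LN = math.log

# Group-wise log-mean intensities for the differential functional markers,
# (HIV-like group, control group). Values for KI67/GRZB/PD-1 on T cells and
# PD-L1/PD-L2/KI67 on TAMs follow the magnitudes of the random-effects group
# estimates the pipeline is meant to recover; the remaining checkpoint and
# activation markers get qualitatively matching moderate shifts.
_DEFAULT_MARKER_EFFECTS: dict[tuple[str, str], tuple[float, float]] = {
    ("CD8T", "KI67"): (_LN(1.62), _LN(0.53)),
    ("CD8T", "GRZB"): (_LN(0.55), _LN(0.42)),
    ("CD8T", "PD1"): (_LN(0.27), _LN(0.18)),
    ("CD8T", "LAG3"): (_LN(0.25), _LN(0.15)),
    ("CD8T", "TIM3"): (_LN(0.22), _LN(0.15)),
    ("CD8T", "CD25"): (_LN(0.30), _LN(0.20)),
    ("CD8T", "CD45RO"): (_LN(0.80), _LN(0.55)),
    ("CD8T", "TBET"): (_LN(0.35), _LN(0.25)),
    ("CD4T", "PD1"): (_LN(0.34), _LN(0.19)),
    ("CD4T", "KI67"): (_LN(1.60), _LN(0.56)),
    ("CD4T", "CD25"): (_LN(0.35), _LN(0.22)),
    ("CD4T", "LAG3"): (_LN(0.28), _LN(0.17)),
    ("CD4T", "TBET"): (_LN(0.30), _LN(0.22)),
    ("TAM", "PDL1"): (_LN(0.16), _LN(0.11)),
    ("TAM", "PDL2"): (_LN(0.30), _LN(0.20)),
    ("TAM", "KI67"): (_LN(1.43), _LN(0.36)),
    ("TAM", "B7H3"): (_LN(0.30), _LN(0.20)),
    ("TAM", "B7H4"): (_LN(0.25), _LN(0.17)),
    ("TAM", "VISTA"): (_LN(0.35), _LN(0.23)),
    ("TAM", "IDO1"): (_LN(0.22), _LN(0.15)),
    ("TAM", "B2M"): (_LN(0.90), _LN(0.65)),
    ("tumor", "B2M"): (_LN(0.80), _LN(0.55)),
}

#: log-mean overrides for "exhausted" (effector-burned-out-like) T cells
_EXHAUSTED_OVERRIDES: dict[str, float] = {
    "PD1": _LN(0.90),
    "LAG3": _LN(0.80),
    "KI67": _LN(2.50),
    "GRZB": _LN(0.12),
    "CD25": _LN(0.70),
}


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator (defaults = the emulated study)."""

    n_cases_per_group: int = 18
    rois_per_case: int = 1
    roi_size_px: tuple[int, int] = (200, 200)
    pixel_size_um: float = 1.0
    cell_counts: dict[str, int] = field(
        default_factory=lambda: {"tumor": 50, "CD4T": 40, "CD8T": 40, "TAM": 30, "B": 20}
    )
    marker_effects: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MARKER_EFFECTS)
    )
    baseline_log_mean: float = _LN(0.15)
    lineage_log_mean: float = _LN(5.0)
    nuclear_log_mean: float = _LN(8.0)
    exhausted_fraction: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CD8T": (0.199, 0.047), "CD4T": (0.352, 0.098)}
    )
    exclusion_shift_um: tuple[float, float] = (15.0, 0.0)
    base_distance_um: float = 20.0
    noise_sd: float = 0.4
    case_effect_sd: float = 0.25
    nucleus_radius_px: int = 3
    cell_radius_px: int = 6
    min_separation_px: float = 9.0
    background_rate: float = 0.05
    n_nest_disks: int = 2
    nest_radius_frac: float = 0.25
    group_labels: tuple[str, str] = ("PWH", "PWOH")
    panel: PanelConfig = field(default_factory=lambda: DEFAULT_PANEL)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases_per_group < 1:
            raise ValueError("n_cases_per_group must be >= 1")
        if any(v < 0 for v in self.cell_counts.values()):
            raise ValueError("cell counts must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.case_effect_sd < 0:
            raise ValueError("case_effect_sd must be >= 0")
        unknown = set(self.cell_counts) - set(LINEAGE_OF)
        if unknown:
            raise ValueError(f"unknown populations in cell_counts: {sorted(unknown)}")
        h, w = self.roi_size_px
        # crude packing bound: hard-core disks of radius min_separation/2
        n_total = sum(self.cell_counts.values())
        if n_total * math.pi * (self.min_separation_px / 2.0) ** 2 > 0.7 * h * w:
            raise ValueError("infeasible packing: too many cells for the ROI")

    def null(self) -> "SimulationConfig":
        """A copy with every group-dependent effect removed (calibration runs)."""
        eff = {k: (v[1], v[1]) for k, v in self.marker_effects.items()}
        exh = {k: (v[1], v[1]) for k, v in self.exhausted_fraction.items()}
        return replace(
            self, marker_effects=eff, exhausted_fraction=exh, exclusion_shift_um=(0.0, 0.0)
        )


@dataclass
class SyntheticCohort:
    manifest: CohortManifest
    images: list[MultichannelImage]
    truth: CellTable
    config: SimulationConfig


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(math.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= radius**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _nest_mask(
    shape: tuple[int, int],
    rng: np.random.Generator,
    n_disks: int,
    radius_frac: float = 0.25,
) -> np.ndarray:
    """Tumor nest as a union of overlapping disks near the ROI centre."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    base_r = radius_frac * min(h, w)
    for _ in range(n_disks):
        cy = h / 2 + rng.uniform(-0.08, 0.08) * h
        cx = w / 2 + rng.uniform(-0.08, 0.08) * w
        r = base_r * rng.uniform(1.0, 1.2)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def _hardcore_ok(y: float, x: float, placed: list[tuple[float, float]], min_sep: float) -> bool:
    for py, px in placed:
        if (y - py) ** 2 + (x - px) ** 2 < min_sep**2:
            return False
    return True


def _place_in_nest(
    n: int,
    nest: np.ndarray,
    margin: int,
    min_sep: float,
    placed: list[tuple[float, float]],
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    h, w = nest.shape
    ys, xs = np.nonzero(nest)
    inside = (ys >= margin) & (ys < h - margin) & (xs >= margin) & (xs < w - margin)
    ys, xs = ys[inside], xs[inside]
    order = rng.permutation(len(ys))
    out: list[tuple[float, float]] = []
    for idx in order:
        if len(out) == n:
            break
        y, x = float(ys[idx]), float(xs[idx])
        if _hardcore_ok(y, x, placed, min_sep):
            out.append((y, x))
            placed.append((y, x))
    if len(out) < n:
        raise ValueError(f"infeasible packing: placed {len(out)}/{n} tumor cells")
    return out


def _place_in_stroma(
    n: int,
    dist_to_nest_px: np.ndarray,
    target_mean_px: float,
    shift_px: float,
    margin: int,
    min_sep: float,
    placed: list[tuple[float, float]],
    rng: np.random.Generator,
) -> tuple[list[tuple[float, float]], list[float]]:
    """Place immune cells at exponential(+shift) distances from the nest edge."""
    h, w = dist_to_nest_px.shape
    ys, xs = np.nonzero(dist_to_nest_px > 0)
    inside = (ys >= margin) & (ys < h - margin) & (xs >= margin) & (xs < w - margin)
    ys, xs = ys[inside], xs[inside]
    dists = dist_to_nest_px[ys, xs]
    order = np.argsort(dists)
    ys, xs, dists = ys[order], xs[order], dists[order]
    out: list[tuple[float, float]] = []
    realized: list[float] = []
    max_redraws = 200 * max(n, 1)
    redraws = 0
    while len(out) < n:
        redraws += 1
        if redraws > max_redraws:
            raise ValueError(f"infeasible packing: placed {len(out)}/{n} stromal cells")
        d = rng.exponential(target_mean_px) + shift_px
        lo = np.searchsorted(dists, d - 0.75)
        hi = np.searchsorted(dists, d + 0.75)
        if hi <= lo:
            continue  # drawn distance outside the ROI's stromal range: redraw
        # several placement attempts at the SAME drawn distance, so hard-core
        # rejection does not bias the realized distance distribution
        placed_ok = False
        for idx in rng.integers(lo, hi, size=min(30, 3 * (hi - lo))):
            y, x = float(ys[idx]), float(xs[idx])
            if _hardcore_ok(y, x, placed, min_sep):
                out.append((y, x))
                realized.append(float(dist_to_nest_px[int(y), int(x)]))
                placed.append((y, x))
                placed_ok = True
                break
        del placed_ok
    return out, realized


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _log_mean(config: SimulationConfig, pop: str, marker: str, role: str, g: int, exhausted: bool) -> float:
    if role == "nuclear":
        return config.nuclear_log_mean
    if marker in LINEAGE_OF[pop]:
        return config.lineage_log_mean
    if role == "lineage":
        return -np.inf  # other populations' lineage markers: background only
    if exhausted and marker in _EXHAUSTED_OVERRIDES:
        return _EXHAUSTED_OVERRIDES[marker]
    eff = config.marker_effects.get((pop, marker))
    if eff is not None:
        return eff[g]
    return config.baseline_log_mean


def generate_case_image(
    config: SimulationConfig,
    group: str,
    case_id: str,
    roi_id: str,
    seed: np.random.SeedSequence | int,
    render: bool = True,
) -> tuple[MultichannelImage | None, CellTable]:
    """Generate one ROI: an image stack (optional) and its ground-truth table.

    ``render=False`` skips painting the pixel data (the truth table alone is
    enough for distance and statistics calibration runs).
    """
    rng = np.random.default_rng(seed)
    panel = config.panel
    g = config.group_labels.index(group)
    h, w = config.roi_size_px
    px = config.pixel_size_um

    nest = _nest_mask((h, w), rng, config.n_nest_disks, config.nest_radius_frac)
    dist_to_nest = ndimage.distance_transform_edt(~nest)

    margin = config.cell_radius_px + 1
    placed: list[tuple[float, float]] = []
    positions: dict[str, list[tuple[float, float]]] = {}
    nest_dist: dict[str, list[float]] = {}

    n_tumor = config.cell_counts.get("tumor", 0)
    positions["tumor"] = (
        _place_in_nest(n_tumor, nest, margin, config.min_separation_px, placed, rng)
        if n_tumor
        else []
    )
    nest_dist["tumor"] = [0.0] * n_tumor

    shift_px = config.exclusion_shift_um[g] / px
    base_px = config.base_distance_um / px
    for pop in ("CD4T", "CD8T", "TAM", "B"):
        n = config.cell_counts.get(pop, 0)
        if n == 0:
            positions[pop] = []
            nest_dist[pop] = []
            continue
        pos, realized = _place_in_stroma(
            n, dist_to_nest, base_px, shift_px, margin, config.min_separation_px, placed, rng
        )
        positions[pop] = pos
        nest_dist[pop] = realized

    # per-case random intercept, one per marker, shared by all cells
    delta_case = {
        m.name: rng.normal(0.0, config.case_effect_sd) for m in panel.markers
    }

    nuc_area = len(_disk_offsets(config.nucleus_radius_px))
    records: list[dict] = []
    cell_id = 0
    for pop in POPULATIONS:
        if pop not in positions:
            continue
        f_exh = config.exhausted_fraction.get(pop, (0.0, 0.0))[g]
        for (y, x), d_nest in zip(positions[pop], nest_dist[pop]):
            cell_id += 1
            exhausted = bool(rng.random() < f_exh)
            rec: dict = {
                "cell_id": cell_id,
                "case_id": case_id,
                "roi_id": roi_id,
                "x_px": x,
                "y_px": y,
                "area_px": nuc_area,
                "population": pop,
                "cluster": pd.NA,
                "subpopulation": "exhausted" if exhausted else "typical",
                "dist_to_nest_um": d_nest * px,
            }
            for m in panel.markers:
                mu = _log_mean(config, pop, m.name, m.role, g, exhausted)
                if np.isneginf(mu):
                    rec[m.name] = 0.0
                else:
                    rec[m.name] = float(
                        np.exp(mu + delta_case[m.name] + config.noise_sd * rng.normal())
                    )
            records.append(rec)

    truth = CellTable.from_records(records, panel.marker_names) if records else CellTable.empty(
        panel.marker_names
    )
    if not records:
        truth.df["subpopulation"] = pd.Series(dtype=object)
        truth.df["dist_to_nest_um"] = pd.Series(dtype=float)
        truth.df["case_id"] = truth.df["case_id"].astype(object)

    image = None
    if render:
        data = rng.poisson(config.background_rate, size=(panel.n_channels, h, w)).astype(
            np.float64
        )
        nuc_off = _disk_offsets(config.nucleus_radius_px)
        cell_off = _disk_offsets(config.cell_radius_px)
        ch_index = {m.name: i for i, m in enumerate(panel.markers)}
        nuclear = [m.name for m in panel.markers if m.role == "nuclear"]
        for rec in records:
            cy, cx = int(round(rec["y_px"])), int(round(rec["x_px"]))
            nys = np.clip(nuc_off[:, 0] + cy, 0, h - 1)
            nxs = np.clip(nuc_off[:, 1] + cx, 0, w - 1)
            cys = np.clip(cell_off[:, 0] + cy, 0, h - 1)
            cxs = np.clip(cell_off[:, 1] + cx, 0, w - 1)
            for m in panel.markers:
                v = rec[m.name]
                if v <= 0:
                    continue
                c = ch_index[m.name]
                if m.name in nuclear:
                    np.maximum.at(data[c], (nys, nxs), v)
                else:
                    np.maximum.at(data[c], (cys, cxs), v)
        image = MultichannelImage(
            case_id=case_id,
            roi_id=roi_id,
            data=data,
            channel_names=panel.marker_names,
            pixel_size_um=px,
        )
    return image, truth


def generate_cohort(config: SimulationConfig, render: bool = True) -> SyntheticCohort:
    """Generate the full two-group cohort with deterministic per-case seeds."""
    ss = np.random.SeedSequence(config.seed)
    n_cases = 2 * config.n_cases_per_group
    children = ss.spawn(n_cases * config.rois_per_case)
    rows = []
    images: list[MultichannelImage] = []
    truths: list[pd.DataFrame] = []
    markers = config.panel.marker_names
    k = 0
    for gi, group in enumerate(config.group_labels):
        for ci in range(config.n_cases_per_group):
            case_id = f"{group}_{ci + 1:02d}"
            rows.append({"case_id": case_id, "group": group})
            for ri in range(config.rois_per_case):
                roi_id = f"{case_id}_roi{ri + 1}"
                img, truth = generate_case_image(
                    config, group, case_id, roi_id, children[k], render=render
                )
                k += 1
                if img is not None:
                    images.append(img)
                truths.append(truth.df)
    manifest = CohortManifest(pd.DataFrame(rows))
    all_truth = pd.concat(truths, ignore_index=True)
    truth_table = (
        CellTable(all_truth, markers) if len(all_truth) else CellTable.empty(markers)
    )
    return SyntheticCohort(manifest=manifest, images=images, truth=truth_table, config=config)


# ---------------------------------------------------------------------------
# validation presets
# ---------------------------------------------------------------------------


def classifier_validation_config(n_cases_per_group: int = 20, seed: int = 0) -> SimulationConfig:
    """Cohort with a large planted three-marker group effect and no other
    group differences: the recovery benchmark for the spectral patch
    classifier. The effect (log-mean shift 2.0, i.e. ~7.4x) sits on PD-L2
    (TAMs) and CD25 (CD4/CD8 T cells), echoing the checkpoint/activation
    markers that discriminate the two groups."""
    base = SimulationConfig()
    eff = {k: (v[1], v[1]) for k, v in base.marker_effects.items()}
    for key in (("TAM", "PDL2"), ("CD8T", "CD25"), ("CD4T", "CD25")):
        eff[key] = (base.baseline_log_mean + 2.0, base.baseline_log_mean)
    return SimulationConfig(
        n_cases_per_group=n_cases_per_group,
        marker_effects=eff,
        exhausted_fraction={},
        exclusion_shift_um=(0.0, 0.0),
        seed=seed,
    )


def ranking_validation_config(n_cases_per_group: int = 8, seed: int = 0) -> SimulationConfig:
    """Cohort in which exactly one marker (PD-L2, expressed on TAMs and
    focally on tumor cells) carries a group shift (log-mean +2.5): the
    recovery benchmark for SSD-based marker ranking."""
    base = SimulationConfig()
    eff = {k: (v[1], v[1]) for k, v in base.marker_effects.items()}
    for key in (("TAM", "PDL2"), ("tumor", "PDL2")):
        eff[key] = (base.baseline_log_mean + 2.5, base.baseline_log_mean)
    return SimulationConfig(
        n_cases_per_group=n_cases_per_group,
        marker_effects=eff,
        exhausted_fraction={},
        exclusion_shift_um=(0.0, 0.0),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# truth summaries
# ---------------------------------------------------------------------------


@dataclass
class TruthSummary:
    """Ground-truth recovery targets: per-(population, marker, group) mean
    log-intensity and per-group mean immune-to-nest distance."""

    marker_means: pd.DataFrame  # population, marker, group, n, mean_log_intensity
    distance_means: pd.DataFrame  # group, n, mean_dist_um


def truth_summary(
    cohort: SyntheticCohort, markers: Sequence[str] | None = None
) -> TruthSummary:
    df = cohort.truth.df
    if len(df) == 0:
        raise ValueError("empty cohort")
    group_of = cohort.manifest.group_of()
    df = df.assign(group=df["case_id"].map(group_of))
    markers = list(markers or cohort.truth.markers)

    rows = []
    pops = [p for p in POPULATIONS if p in cohort.config.cell_counts]
    for pop in pops:
        sub = df[df["population"] == pop]
        for group in cohort.config.group_labels:
            gsub = sub[sub["group"] == group]
            for m in markers:
                vals = gsub[m].to_numpy(dtype=float)
                vals = vals[vals > 0]
                rows.append(
                    {
                        "population": pop,
                        "marker": m,
                        "group": group,
                        "n": len(vals),
                        "mean_log_intensity": float(np.log(vals).mean())
                        if len(vals)
                        else np.nan,
                    }
                )
    marker_means = pd.DataFrame(rows)

    imm = df[df["population"] != "tumor"]
    drows = []
    for group in cohort.config.group_labels:
        gsub = imm[imm["group"] == group]
        drows.append(
            {
                "group": group,
                "n": len(gsub),
                "mean_dist_um": float(gsub["dist_to_nest_um"].mean()) if len(gsub) else np.nan,
            }
        )
    return TruthSummary(marker_means=marker_means, distance_means=pd.DataFrame(drows))
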