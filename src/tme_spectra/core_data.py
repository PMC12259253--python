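"""Shared domain types and I/O for the IMC analysis pipeline.

Defines the antibody panel configuration, the multichannel image container,
the per-cell measurement table, and the cohort manifest, together with the
TIFF / CSV / YAML readers and writers every downstream stage uses.

Conventions
-----------
* Pixel coordinates are 0-based (row = y, column = x); a cell centroid is the
  arithmetic mean of its member-pixel coordinates.
* Physical distances are ``pixel distance * pixel_size_um``.
* CSV is the canonical on-disk format for cell tables and manifests.
* Intensities are stored raw; transformations (arcsinh, scaling) are applied
  downstream and never persisted into a cell table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Marker",
    "PanelConfig",
    "MultichannelImage",
    "CellTable",
    "CohortManifest",
    "DEFAULT_PANEL",
    "read_image_stack",
    "write_image_stack",
    "read_cell_table",
    "write_cell_table",
    "read_manifest",
    "write_manifest",
]

MARKER_ROLES = ("lineage", "functional", "structural", "nuclear")

#: Core (non-marker) columns of a cell table, in canonical order.
CELL_TABLE_CORE_COLUMNS = (
    "cell_id",
    "case_id",
    "roi_id",
    "x_px",
    "y_px",
    "area_px",
    "population",
    "cluster",
)


@dataclass(frozen=True)
class Marker:
    """One antibody channel: name, position in the image stack, and role."""

    name: str
    channel_index: int
    role: str = "functional"

    def __post_init__(self) -> None:
        if self.role not in MARKER_ROLES:
            raise ValueError(
                f"marker {self.name!r}: role {self.role!r} not in {MARKER_ROLES}"
            )
        if self.channel_index < 0:
            raise ValueError(f"marker {self.name!r}: negative channel index")


@dataclass
class PanelConfig:
    """Antibody panel: ordered markers, gate thresholds, pixel size.

    The marker order here is order-defining: every downstream matrix (cell
    table intensity columns, representation-matrix rows) follows it.
    """

    markers: list[Marker]
    gate_thresholds: dict[str, float] = field(default_factory=dict)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        idx = [m.channel_index for m in self.markers]
        if len(set(idx)) != len(idx):
            raise ValueError("channel indices must be unique")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name, thr in self.gate_thresholds.items():
            if name not in names:
                raise ValueError(f"gate threshold for unknown marker {name!r}")
            if thr < 0:
                raise ValueError(f"gate threshold for {name!r} must be >= 0")

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def n_channels(self) -> int:
        return len(self.markers)

    def markers_with_role(self, role: str) -> list[str]:
        return [m.name for m in self.markers if m.role == role]

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "markers": [
                {"name": m.name, "channel_index": m.channel_index, "role": m.role}
                for m in self.markers
            ],
            "gate_thresholds": dict(self.gate_thresholds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelConfig":
        markers = [
            Marker(m["name"], int(m["channel_index"]), m.get("role", "functional"))
            for m in d["markers"]
        ]
        return cls(
            markers=markers,
            gate_thresholds={k: float(v) for k, v in d.get("gate_thresholds", {}).items()},
            pixel_size_um=float(d.get("pixel_size_um", 1.0)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PanelConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _default_panel() -> PanelConfig:
    """The 27-channel NSCLC TME panel used throughout: DNA intercalator and
    histone H3 for nuclei, six lineage markers (CK, CD3, CD4, CD8, CD68,
    CD20), structural vimentin/GAPDH, and the functional/checkpoint set."""
    spec: list[tuple[str, str]] = [
        ("DNA", "nuclear"),
        ("VIMENTIN", "structural"),
        ("TBET", "functional"),
        ("CD47", "functional"),
        ("CK", "lineage"),
        ("CD45RO", "functional"),
        ("PDL1", "functional"),
        ("GAPDH", "structural"),
        ("B7H3", "functional"),
        ("LAG3", "functional"),
        ("TIM3", "functional"),
        ("FOXP3", "functional"),
        ("CD4", "lineage"),
        ("B7H4", "functional"),
        ("CD68", "lineage"),
        ("PD1", "functional"),
        ("CD20", "lineage"),
        ("CD8", "lineage"),
        ("CD25", "functional"),
        ("VISTA", "functional"),
        ("KI67", "functional"),
        ("B2M", "functional"),
        ("CD3", "lineage"),
        ("IDO1", "functional"),
        ("PDL2", "functional"),
        ("GRZB", "functional"),
        ("H3", "nuclear"),
    ]
    markers = [Marker(name, i, role) for i, (name, role) in enumerate(spec)]
    thresholds = {name: 1.0 for name, role in spec if role == "lineage"}
    return PanelConfig(markers=markers, gate_thresholds=thresholds, pixel_size_um=1.0)


DEFAULT_PANEL: PanelConfig = _default_panel()


@dataclass
class MultichannelImage:
    """A C x H x W intensity stack for one region of interest (ROI)."""

    case_id: str
    roi_id: str
    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected C x H x W array, got shape {self.data.shape}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} channels but {len(self.channel_names)} names"
            )
        self._validate_pixels()

    def _validate_pixels(self) -> None:
        bad = ~np.isfinite(self.data)
        if bad.any():
            c, y, x = (int(v[0]) for v in np.nonzero(bad))
            raise ValueError(
                f"non-finite pixel in channel {self.channel_names[c]!r} "
                f"at (y={y}, x={x})"
            )
        neg = self.data < 0
        if neg.any():
            c, y, x = (int(v[0]) for v in np.nonzero(neg))
            raise ValueError(
                f"negative pixel in channel {self.channel_names[c]!r} "
                f"at (y={y}, x={x})"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in image") from None
        return self.data[i]


class CellTable:
    """Per-cell records: identity, centroid, area, raw mean intensities.

    Thin wrapper over a pandas DataFrame with a fixed core schema plus one
    column per panel marker (in panel order). Extra columns (e.g. ground-truth
    annotations from the simulator) are carried through I/O untouched.
    """

    def __init__(self, df: pd.DataFrame, markers: Sequence[str]):
        self.markers = list(markers)
        missing = [c for c in CELL_TABLE_CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cell table missing core columns: {missing}")
        missing_m = [m for m in self.markers if m not in df.columns]
        if missing_m:
            raise ValueError(f"cell table missing marker columns: {missing_m}")
        self.df = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        dup = df.duplicated(subset=["roi_id", "cell_id"])
        if dup.any():
            ids = df.loc[dup, ["roi_id", "cell_id"]].to_records(index=False).tolist()
            raise ValueError(f"duplicate cell_id within ROI: {ids[:5]}")
        if len(df) and (df["area_px"] < 1).any():
            raise ValueError("area_px must be >= 1")
        vals = df[self.markers].to_numpy(dtype=float) if len(df) else np.empty((0, 0))
        if vals.size and ((vals < 0) | ~np.isfinite(vals)).any():
            raise ValueError("marker intensities must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellTable):
            return NotImplemented
        return self.markers == other.markers and self.df.equals(other.df)

    @property
    def columns(self) -> list[str]:
        extra = [
            c
            for c in self.df.columns
            if c not in CELL_TABLE_CORE_COLUMNS and c not in self.markers
        ]
        return list(CELL_TABLE_CORE_COLUMNS) + self.markers + extra

    def intensity_matrix(self, markers: Sequence[str] | None = None) -> np.ndarray:
        """n_cells x n_markers raw intensities, columns in panel order."""
        return self.df[list(markers or self.markers)].to_numpy(dtype=float)

    def subset(self, mask) -> "CellTable":
        return CellTable(self.df.loc[mask].reset_index(drop=True), self.markers)

    def with_columns(self, **cols) -> "CellTable":
        df = self.df.copy()
        for k, v in cols.items():
            df[k] = v
        return CellTable(df, self.markers)

    @classmethod
    def empty(cls, markers: Sequence[str]) -> "CellTable":
        cols = list(CELL_TABLE_CORE_COLUMNS) + list(markers)
        df = pd.DataFrame({c: pd.Series(dtype=_COLUMN_DTYPES.get(c, float)) for c in cols})
        return cls(df, markers)

    @classmethod
    def from_records(
        cls, records: Iterable[dict], markers: Sequence[str]
    ) -> "CellTable":
        df = pd.DataFrame(list(records))
        if "population" not in df.columns:
            df["population"] = "unassigned"
        if "cluster" not in df.columns:
            df["cluster"] = pd.array([pd.NA] * len(df), dtype="Int64")
        return cls(df, markers)


_COLUMN_DTYPES = {
    "cell_id": "int64",
    "case_id": "object",
    "roi_id": "object",
    "x_px": "float64",
    "y_px": "float64",
    "area_px": "int64",
    "population": "object",
    "cluster": "Int64",
}


@dataclass
class CohortManifest:
    """Case-level metadata: one row per case with its group label."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "case_id" not in self.df.columns or "group" not in self.df.columns:
            raise ValueError("manifest needs 'case_id' and 'group' columns")
        if self.df["case_id"].duplicated().any():
            raise ValueError("duplicate case_id in manifest")
        self.df = self.df.reset_index(drop=True)

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group"].unique())

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.df["case_id"], self.df["group"]))

    def cases_in(self, group: str) -> list[str]:
        return self.df.loc[self.df["group"] == group, "case_id"].tolist()

    def require_two_groups(self) -> tuple[str, str]:
        g = self.groups
        if len(g) != 2:
            raise ValueError(f"expected exactly two groups, found {g}")
        return g[0], g[1]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_image_stack(path: str | Path, panel: PanelConfig) -> MultichannelImage:
    """Read a multipage TIFF / OME-TIFF as a panel-ordered image stack.

    Pages are reordered to panel channel order. Raises on a channel-count
    mismatch or non-finite / negative pixels (the error names the offending
    channel and coordinates).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a C x H x W stack, got shape {arr.shape}")
    if arr.shape[0] != panel.n_channels:
        raise ValueError(
            f"{path}: {arr.shape[0]} channels but panel defines {panel.n_channels}"
        )
    data = arr.astype(np.float64)[[m.channel_index for m in panel.markers]]
    return MultichannelImage(
        case_id=path.stem,
        roi_id=path.stem,
        data=data,
        channel_names=panel.marker_names,
        pixel_size_um=panel.pixel_size_um,
    )


def write_image_stack(image: MultichannelImage, path: str | Path) -> None:
    tifffile.imwrite(str(path), image.data.astype(np.float32), photometric="minisblack")


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table to CSV with the canonical column order."""
    table.df[table.columns].to_csv(path, index=False)


def read_cell_table(path: str | Path, markers: Sequence[str]) -> CellTable:
    """Read a cell table CSV; validates schema and invariants."""
    df = pd.read_csv(path, dtype={"case_id": str, "roi_id": str})
    if "cluster" in df.columns:
        df["cluster"] = df["cluster"].astype("Int64")
    if len(df) == 0:
        out = CellTable.empty(markers)
        extra = [c for c in df.columns if c not in out.df.columns]
        for c in extra:
            out.df[c] = pd.Series(dtype=float)
        return out
    return CellTable(df, markers)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> CohortManifest:
    return CohortManifest(pd.read_csv(path, dtype={"case_id": str, "group": str}))
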