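"""Core data containers shared by all pipeline stages.

The lingua franca between stages is the :class:`ParcelVector` (one scalar per
parcel).  Volumes are plain 3-D arrays with an isotropic-or-not voxel size;
the x axis (axis 0) carries the left/right distinction, with "left" meaning
voxel index ``x < nx // 2`` and homotopic reflection ``x -> nx - 1 - x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

MASK = "mask"
FREQUENCY = "frequency_percent"

#: canonical resting-state network names used for community affiliation
NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)
PRIMARY_NETWORKS = frozenset({"visual", "somatomotor"})
ASSOCIATION_NETWORKS = frozenset(
    {"dorsal_attention", "ventral_attention", "frontoparietal", "default"}
)


class GeometryError(ValueError):
    """Raised when volumes/parcellations disagree on grid geometry."""


def reflect_x(values: np.ndarray) -> np.ndarray:
    """Homotopic reflection across the sagittal midline (axis 0)."""
    return values[::-1, ...]


@dataclass
class VolumeMap:
    """A 3-D scalar field on a voxel grid.

    ``kind`` is either a binary lesion ``mask`` or a ``frequency_percent``
    map whose voxel values are the percentage of the cohort's tumours
    overlapping that voxel.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    kind: str = FREQUENCY

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError("VolumeMap requires a 3-D array")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError("voxel_size_mm must be three positive lengths")
        if self.kind == MASK:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be in {0, 1}")
        elif self.kind == FREQUENCY:
            if self.values.size and (
                np.nanmin(self.values) < -1e-9 or np.nanmax(self.values) > 100 + 1e-9
            ):
                raise ValueError("frequency values must lie in [0, 100]")
        else:
            raise ValueError(f"unknown VolumeMap kind: {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other: "VolumeMap | Parcellation") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk, dtype=float) * np.asarray(self.voxel_size_mm)

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        vox = np.asarray(xyz, dtype=float) / np.asarray(self.voxel_size_mm)
        return np.round(vox).astype(int)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), self.affine)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(self.to_nifti(), str(path))
        return path

    @classmethod
    def from_nifti(cls, source: str | Path | nib.Nifti1Image, kind: str = FREQUENCY) -> "VolumeMap":
        img = source if isinstance(source, nib.Nifti1Image) else nib.load(str(source))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asarray(img.dataobj, dtype=float), tuple(zooms), kind=kind)


# required columns of the parcel metadata table
PARCEL_COLUMNS = (
    "hemisphere",
    "homotopic_id",
    "network",
    "is_cortical",
    "structure",
    "cx",
    "cy",
    "cz",
)


@dataclass
class Parcellation:
    """Labelled voxel volume plus per-parcel metadata.

    ``labels`` uses 0 for background.  ``table`` is indexed by parcel id and
    carries hemisphere ('L'/'R'), the homotopic partner id, one of the seven
    canonical network affiliations, a cortical/subcortical flag, an optional
    anatomical ``structure`` tag (used to bind NSC niches such as the
    hippocampus and caudate), and a unit-sphere centroid (cx, cy, cz) for
    cortical parcels (NaN for subcortical ones).
    """

    labels: np.ndarray
    table: pd.DataFrame
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError("parcellation labels must be a 3-D array")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        missing = [c for c in PARCEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"parcel table lacks columns: {missing}")
        present = np.unique(self.labels)
        present = present[present > 0]
        if not np.array_equal(np.sort(self.table.index.to_numpy()), present):
            raise ValueError("parcel table index does not match label volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def parcel_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    def ids(self, scope: str = "bilateral", cortical_only: bool = False) -> np.ndarray:
        """Parcel ids for an analysis scope ('left', 'right' or 'bilateral')."""
        tab = self.table
        if scope == "left":
            tab = tab[tab["hemisphere"] == "L"]
        elif scope == "right":
            tab = tab[tab["hemisphere"] == "R"]
        elif scope != "bilateral":
            raise ValueError(f"unknown scope {scope!r}")
        if cortical_only:
            tab = tab[tab["is_cortical"]]
        return tab.index.to_numpy()

    def voxel_indices(self, parcel_id: int) -> np.ndarray:
        return np.argwhere(self.labels == parcel_id)

    def voxel_centroids_mm(self, ids: Sequence[int] | None = None) -> np.ndarray:
        """Volumetric centre of mass of each parcel, in mm."""
        ids = self.parcel_ids if ids is None else np.asarray(ids)
        out = np.empty((len(ids), 3))
        for k, pid in enumerate(ids):
            vox = np.argwhere(self.labels == pid)
            out[k] = vox.mean(axis=0) * np.asarray(self.voxel_size_mm)
        return out

    def sphere_centroids(self, ids: Sequence[int]) -> np.ndarray:
        pts = self.table.loc[list(ids), ["cx", "cy", "cz"]].to_numpy(dtype=float)
        if np.isnan(pts).any():
            raise GeometryError("requested parcels lack spherical centroids")
        return pts

    def save(self, labels_path: str | Path, table_path: str | Path) -> None:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), aff), str(labels_path))
        self.table.to_csv(table_path, sep="\t", index_label="parcel_id")

    @classmethod
    def load(cls, labels_path: str | Path, table_path: str | Path) -> "Parcellation":
        img = nib.load(str(labels_path))
        table = pd.read_csv(table_path, sep="\t", index_col="parcel_id")
        table["is_cortical"] = table["is_cortical"].astype(bool)
        table["structure"] = table["structure"].fillna("")
        return cls(
            np.asarray(img.dataobj, dtype=np.int32),
            table,
            tuple(img.header.get_zooms()[:3]),
        )


@dataclass
class ParcelVector:
    """One scalar per parcel; NaN marks an explicitly missing value."""

    ids: np.ndarray
    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.ids.shape != self.values.shape or self.ids.ndim != 1:
            raise ValueError("ids and values must be matching 1-D arrays")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("duplicate parcel ids")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.ids, name=self.name or None)

    def align_to(self, ids: Sequence[int]) -> "ParcelVector":
        """Reindex onto ``ids``; parcels absent from self become NaN."""
        s = self.to_series().reindex(np.asarray(ids))
        return ParcelVector(np.asarray(ids), s.to_numpy(), units=self.units, name=self.name)

    def value_of(self, parcel_id: int) -> float:
        idx = np.flatnonzero(self.ids == parcel_id)
        if len(idx) == 0:
            raise KeyError(f"parcel {parcel_id} not in vector")
        return float(self.values[idx[0]])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame({"parcel_id": self.ids, "value": self.values})
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
        return path

    @classmethod
    def load(cls, path: str | Path, units: str = "", name: str = "") -> "ParcelVector":
        df = pd.read_csv(path, sep="\t")
        return cls(df["parcel_id"].to_numpy(), df["value"].to_numpy(), units=units, name=name)


@dataclass
class Connectome:
    """Symmetric non-negative weighted adjacency over parcels."""

    weights: np.ndarray
    parcel_ids: np.ndarray
    community: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.parcel_ids = np.asarray(self.parcel_ids)
        self.community = np.asarray(self.community)
        n = len(self.parcel_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix does not match parcel ids")
        if len(self.community) != n:
            raise ValueError("community labels do not match parcel ids")
        if np.abs(self.weights - self.weights.T).max(initial=0.0) > 1e-12:
            raise ValueError("weights must be symmetric (tol 1e-12)")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if self.weights.size and self.weights.min() < 0:
            raise ValueError("weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.parcel_ids)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.weights, index=self.parcel_ids, columns=self.parcel_ids)
        df.to_csv(path, sep="\t", float_format="%.12g", index_label="parcel_id")
        return path


@dataclass
class ExpressionAtlas:
    """Samples x genes expression values with per-sample spatial coordinates."""

    expression: pd.DataFrame
    coords: pd.DataFrame  # columns x, y, z (mm), indexed like expression

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.coords.index):
            raise ValueError("expression and coordinate tables must share sample ids")
        for c in ("x", "y", "z"):
            if c not in self.coords.columns:
                raise ValueError("coords table needs x, y, z columns")

    @property
    def n_samples(self) -> int:
        return len(self.expression)

    @property
    def genes(self) -> np.ndarray:
        return self.expression.columns.to_numpy()

    def save(self, expr_path: str | Path, coords_path: str | Path) -> None:
        self.expression.to_csv(expr_path, sep="\t", index_label="sample_id",
                               float_format="%.8g")
        self.coords.to_csv(coords_path, sep="\t", index_label="sample_id",
                           float_format="%.8g")

    @classmethod
    def load(cls, expr_path: str | Path, coords_path: str | Path) -> "ExpressionAtlas":
        expr = pd.read_csv(expr_path, sep="\t", index_col="sample_id")
        coords = pd.read_csv(coords_path, sep="\t", index_col="sample_id")
        return cls(expr, coords)


@dataclass
class GeneSet:
    """A named list of gene identifiers with a provenance note."""

    name: str
    genes: list[str]
    note: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def resolve(self, atlas: ExpressionAtlas) -> tuple["GeneSet", list[str]]:
        """Drop ids absent from the atlas; return (resolved set, dropped ids)."""
        known = set(map(str, atlas.expression.columns))
        kept = [g for g in self.genes if g in known]
        dropped = [g for g in self.genes if g not in known]
        return GeneSet(self.name, kept, note=self.note), dropped

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text("\n".join(self.genes) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        path = Path(path)
        genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        return cls(name or path.stem, genes)
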