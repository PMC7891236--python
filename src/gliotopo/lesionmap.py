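"""Tumour frequency mapping from binary lesion masks.

Pipeline order is fixed: build the voxel-wise frequency map, smooth with a
Gaussian kernel, mirror to one hemisphere, then aggregate to parcels (with
an optional white-matter extension of the parcel labels).  The unsmoothed,
unmirrored map is always kept alongside, because the transcriptomic
alignment consumes it separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .containers import (
    ASSOCIATION_NETWORKS,
    FREQUENCY,
    MASK,
    GeometryError,
    Parcellation,
    ParcelVector,
    PRIMARY_NETWORKS,
    VolumeMap,
    reflect_x,
)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class EmptyCohortError(ValueError):
    pass


def build_frequency_map(masks: list[VolumeMap]) -> VolumeMap:
    """Voxel-wise percentage of masks overlapping each voxel."""
    if not masks:
        raise EmptyCohortError("need at least one mask")
    first = masks[0]
    total = np.zeros(first.shape, dtype=np.float64)
    for m in masks:
        if m.kind != MASK:
            raise ValueError("build_frequency_map expects binary masks")
        if not m.same_grid(first):
            raise GeometryError("all masks must share grid shape and voxel size")
        total += m.values
    return VolumeMap(100.0 * total / len(masks), first.voxel_size_mm, kind=FREQUENCY)


def smooth_map(vol: VolumeMap, fwhm_mm: float) -> VolumeMap:
    """Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return VolumeMap(vol.values.copy(), vol.voxel_size_mm, kind=vol.kind)
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in vol.voxel_size_mm]
    sm = ndimage.gaussian_filter(np.asarray(vol.values, dtype=float), sigma_vox)
    return VolumeMap(np.clip(sm, 0.0, 100.0), vol.voxel_size_mm, kind=vol.kind)


def mirror_map(vol: VolumeMap, to: str = "left") -> VolumeMap:
    """Average each target-hemisphere voxel with its homotopic reflection.

    The source hemisphere is retained unchanged for reference.  Averaging
    (rather than summing) preserves the percentage interpretation.
    """
    nx = vol.shape[0]
    if nx % 2 != 0:
        raise GeometryError("mirroring needs an even first axis (defined midline)")
    if to not in ("left", "right"):
        raise ValueError("to must be 'left' or 'right'")
    vals = np.asarray(vol.values, dtype=float)
    averaged = 0.5 * (vals + reflect_x(vals))
    out = vals.copy()
    half = nx // 2
    if to == "left":
        out[:half] = averaged[:half]
    else:
        out[half:] = averaged[half:]
    return VolumeMap(out, vol.voxel_size_mm, kind=vol.kind)


def extend_labels(parc: Parcellation, wm_extension_mm: float) -> np.ndarray:
    """Dilate parcel labels into unlabelled voxels up to ``wm_extension_mm``.

    Competing parcels are resolved by the nearest parcel boundary; exact
    distance ties go to the lower parcel id.
    """
    labels = parc.labels.copy()
    if wm_extension_mm <= 0:
        return labels
    bg = np.argwhere(labels == 0)
    if len(bg) == 0:
        return labels
    fg = np.argwhere(labels > 0)
    vox = np.asarray(parc.voxel_size_mm)
    tree = cKDTree(fg * vox)
    k2 = min(2, len(fg))
    d, nearest = tree.query(bg * vox, k=k2)
    d = np.atleast_2d(d.T).T
    nearest = np.atleast_2d(nearest.T).T
    within = d[:, 0] <= wm_extension_mm + 1e-9
    bg_in, d_in = bg[within], d[within, 0]
    assigned = labels[tuple(fg[nearest[within, 0]].T)]
    # resolve exact ties deterministically: lowest id among co-minimal parcels
    if k2 == 2:
        tied = np.flatnonzero(d[within, 1] <= d_in + 1e-9)
        for row in tied:
            hits = tree.query_ball_point(bg_in[row] * vox, d_in[row] + 1e-9)
            cands = labels[tuple(fg[hits].T)]
            dists = np.linalg.norm((fg[hits] - bg_in[row]) * vox, axis=1)
            assigned[row] = cands[dists <= dists.min() + 1e-9].min()
    labels[tuple(bg_in.T)] = assigned
    return labels


def parcel_aggregate(
    vol: VolumeMap,
    parc: Parcellation,
    scope: str = "left",
    wm_extension_mm: float = 4.0,
    extended_labels: np.ndarray | None = None,
) -> ParcelVector:
    """Mean map value per parcel after white-matter extension of the labels.

    Parcels with no voxels after masking are flagged missing (NaN), never
    silently zero.  ``extended_labels`` lets callers reuse a cached
    :func:`extend_labels` result.
    """
    if not vol.same_grid(parc):
        raise GeometryError("map and parcellation must share the voxel grid")
    labels = extended_labels if extended_labels is not None \
        else extend_labels(parc, wm_extension_mm)
    ids = parc.ids(scope)
    vals = np.asarray(vol.values, dtype=float)
    lab_flat = labels.ravel()
    n_max = int(lab_flat.max()) + 1
    sums = np.bincount(lab_flat, weights=vals.ravel(), minlength=n_max)
    counts = np.bincount(lab_flat, minlength=n_max)
    out = np.full(len(ids), np.nan)
    for k, pid in enumerate(ids):
        if pid < n_max and counts[pid] > 0:
            out[k] = sums[pid] / counts[pid]
    return ParcelVector(ids, out, units=vol.kind, name="tumour_frequency")


def frequency_pipeline(
    masks: list[VolumeMap],
    parc: Parcellation,
    fwhm_mm: float = 2.0,
    mirror_to: str = "left",
    wm_extension_mm: float = 4.0,
    scope: str = "left",
    extended_labels: np.ndarray | None = None,
) -> tuple[VolumeMap, VolumeMap, ParcelVector]:
    """Full map pipeline; returns (raw map, processed map, parcel vector)."""
    raw = build_frequency_map(masks)
    processed = mirror_map(smooth_map(raw, fwhm_mm), to=mirror_to)
    vec = parcel_aggregate(processed, parc, scope=scope,
                           wm_extension_mm=wm_extension_mm,
                           extended_labels=extended_labels)
    return raw, processed, vec


@dataclass
class SplitHalfResult:
    r_point: float
    ci: tuple[float, float]
    rs: np.ndarray
    lgg_fractions: tuple[float, float]


def _stratified_split(
    grades: np.ndarray, multiplier: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint halves with Group 1's LGG share ~ multiplier x the cohort's."""
    n = len(grades)
    lgg_idx = np.flatnonzero(grades == "LGG")
    hgg_idx = np.flatnonzero(grades != "LGG")
    if len(lgg_idx) < 2 or len(hgg_idx) < 2:
        raise ValueError("need at least two patients of each grade to split")
    frac = len(lgg_idx) / n
    n1 = int(np.ceil(n / 2))
    lgg1 = int(np.clip(round(multiplier * frac * n1), 0, min(n1, len(lgg_idx))))
    lgg_perm = rng.permutation(lgg_idx)
    hgg_perm = rng.permutation(hgg_idx)
    g1 = np.concatenate([lgg_perm[:lgg1], hgg_perm[: n1 - lgg1]])
    g2 = np.setdiff1d(np.arange(n), g1)
    return np.sort(g1), g2


def split_half_replicability(
    cohort: list[tuple[VolumeMap, str]],
    parc: Parcellation,
    n_repeats: int = 100,
    lgg_ratio_multiplier: float = 1.5,
    fwhm_mm: float = 2.0,
    wm_extension_mm: float = 4.0,
    seed: int = 0,
) -> SplitHalfResult:
    """Inter-parcel correlation between frequency maps of disjoint half-cohorts.

    Each repeat reassigns patients to two halves with LGG proportions of
    ~``multiplier`` and ~``2 - multiplier`` times the cohort fraction, runs
    the full map pipeline on both halves, and records the Pearson
    correlation across parcels.  Returns the first repeat's r plus the
    [2.5, 97.5] percentile interval over repeats.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    grades = np.array([g for _, g in cohort])
    masks = [m for m, _ in cohort]
    rng = np.random.default_rng(seed)
    ext = extend_labels(parc, wm_extension_mm)
    rs = np.empty(n_repeats)
    fracs = (np.nan, np.nan)
    for rep in range(n_repeats):
        g1, g2 = _stratified_split(grades, lgg_ratio_multiplier, rng)
        vecs = []
        for grp in (g1, g2):
            _, _, vec = frequency_pipeline(
                [masks[i] for i in grp], parc,
                fwhm_mm=fwhm_mm, wm_extension_mm=wm_extension_mm,
                extended_labels=ext,
            )
            vecs.append(vec.values)
        ok = ~np.isnan(vecs[0]) & ~np.isnan(vecs[1])
        rs[rep] = np.corrcoef(vecs[0][ok], vecs[1][ok])[0, 1]
        if rep == 0:
            fracs = (float(np.mean(grades[g1] == "LGG")),
                     float(np.mean(grades[g2] == "LGG")))
    ci = (float(np.percentile(rs, 2.5)), float(np.percentile(rs, 97.5)))
    return SplitHalfResult(float(rs[0]), ci, rs, fracs)


def network_summaries(
    vol: VolumeMap, parc: Parcellation
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-network (and primary/association) voxel-frequency summaries.

    Returns a table of mean voxel frequency per group and, for raincloud
    plotting downstream, the distribution of non-zero voxel values.
    """
    known = set(parc.table["network"].unique())
    unknown = known - (PRIMARY_NETWORKS | ASSOCIATION_NETWORKS | {"limbic"})
    if unknown:
        raise ValueError(f"unknown network labels: {sorted(unknown)}")
    vals = np.asarray(vol.values, dtype=float)
    rows, dists = [], {}
    groups: dict[str, np.ndarray] = {}
    for net in sorted(known):
        ids = parc.table.index[parc.table["network"] == net].to_numpy()
        groups[net] = np.isin(parc.labels, ids)
    groups["primary"] = np.logical_or.reduce(
        [groups[n] for n in sorted(known & PRIMARY_NETWORKS)] or [np.zeros_like(vals, bool)]
    )
    groups["association"] = np.logical_or.reduce(
        [groups[n] for n in sorted(known & ASSOCIATION_NETWORKS)] or [np.zeros_like(vals, bool)]
    )
    for name, mask in groups.items():
        v = vals[mask]
        rows.append({
            "group": name,
            "n_voxels": int(mask.sum()),
            "mean_frequency": float(v.mean()) if v.size else np.nan,
        })
        dists[name] = v[v > 0]
    return pd.DataFrame(rows).set_index("group"), dists
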