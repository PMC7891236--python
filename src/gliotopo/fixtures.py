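"""Synthetic inputs with the statistical structure the analysis assumes.

The real study ingredients -- a lesion cohort co-registered to a template, a
group-averaged functional connectome, and a spatially sampled expression
atlas -- are emulated here at desk scale: spatially autocorrelated
ground-truth fields, a mirror-symmetric Voronoi parcellation with
unit-sphere centroids (so spin nulls are well defined by construction), a
modular loading matrix whose correlation graph has seven communities, and a
smooth expression atlas with planted marker / driver gene sets.  Planted
effect sizes are named correlations; every maker draws from a seeded
generator so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .containers import (
    MASK,
    NETWORKS,
    ExpressionAtlas,
    GeneSet,
    GeometryError,
    Parcellation,
    ParcelVector,
    VolumeMap,
)

# per-maker rng stream ids (appended to the config seed)
_STREAM_PARC = 1
_STREAM_FIELDS = 2
_STREAM_LESIONS = 3
_STREAM_CONNECTOME = 4
_STREAM_EXPRESSION = 5

#: mixing weight of the shared spatial profile within a planted gene set
_SET_COHERENCE = 0.5
#: smooth/noise mix for background genes
_GENE_SMOOTHNESS = 0.5


class SizingError(ValueError):
    """Grid or count parameters are mutually infeasible."""


class DegenerateFieldError(ValueError):
    """A ground-truth field carries no usable signal (e.g. all zero)."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions at desk scale: a 335-patient
    cohort with ~23% low-grade tumours, a 334-parcel mirror-symmetric
    parcellation (167 per hemisphere, 8 of them subcortical), and an
    AHBA-shaped expression atlas scaled to 2000 genes x 600 left-hemisphere
    samples.  ``effect_sizes`` are the planted map-map correlations.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    n_parcels_per_hemisphere: int = 167
    n_subcortical: int = 8
    n_patients: int = 335
    lgg_fraction: float = 0.23
    smoothness_mm: float = 12.0
    n_genes: int = 2000
    n_samples: int = 600
    n_components: int = 256
    n_marker_genes: int = 25
    marker_decoys: int = 0
    n_driver_genes: int = 17
    driver_decoys: int = 3
    lesion_radius_median_mm: float = 20.0
    lesion_radius_sigma: float = 0.4
    effect_sizes: dict = field(
        default_factory=lambda: {"hub": 0.5, "opc": 0.5, "driver": 0.5}
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.lgg_fraction <= 1.0):
            raise ValueError("lgg_fraction must lie in [0, 1]")
        for name in ("n_parcels_per_hemisphere", "n_genes", "n_samples",
                     "n_components", "n_marker_genes", "n_driver_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not (0 <= self.n_subcortical < self.n_parcels_per_hemisphere):
            raise ValueError("n_subcortical must be in [0, n_parcels_per_hemisphere)")
        if self.smoothness_mm < 0:
            raise ValueError("smoothness_mm must be >= 0")
        for key, val in self.effect_sizes.items():
            if not (-1.0 <= val <= 1.0):
                raise ValueError(f"effect size {key!r} must lie in [-1, 1]")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise SizingError("grid_shape must be three axes of >= 4 voxels")
        if self.grid_shape[0] % 2 != 0:
            raise GeometryError("first axis must be even so a midline exists")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


# ---------------------------------------------------------------------------
# parcellation


def _ellipsoid_mask(shape: tuple[int, int, int], voxel: float) -> np.ndarray:
    centre = (np.asarray(shape) - 1) / 2.0
    semi = 0.46 * np.asarray(shape)
    idx = np.indices(shape).reshape(3, -1).T
    r2 = (((idx - centre) / semi) ** 2).sum(axis=1)
    return (r2 <= 1.0).reshape(shape)


def _best_candidate(rng: np.random.Generator, existing: list[np.ndarray],
                    propose, n_cand: int = 8) -> np.ndarray:
    """Mitchell best-candidate sampling: spreads seeds apart deterministically."""
    cands = [propose(rng) for _ in range(n_cand)]
    if not existing:
        return cands[0]
    ex = np.asarray(existing)
    dists = [np.min(np.linalg.norm(ex - c, axis=1)) for c in cands]
    return cands[int(np.argmax(dists))]


def make_parcellation(cfg: SyntheticConfig) -> Parcellation:
    """Mirror-symmetric Voronoi parcellation inside a half-ellipsoid 'brain'.

    Cortical seeds sit on an outer shell (their unit directions from the
    hemisphere origin become the spherical centroids the spin test needs);
    subcortical seeds sit in a deep central zone.  Right-hemisphere labels
    are the sagittal reflection of the left, offset by the per-hemisphere
    parcel count, so every parcel has an exact homotopic partner.
    """
    nx, ny, nz = cfg.grid_shape
    vox = float(cfg.voxel_size_mm)
    n_half = cfg.n_parcels_per_hemisphere
    n_sub = cfg.n_subcortical
    n_cort = n_half - n_sub

    brain = _ellipsoid_mask(cfg.grid_shape, vox)
    left = np.zeros_like(brain)
    left[: nx // 2] = True
    left &= brain
    left_vox = np.argwhere(left)
    if len(left_vox) < 8 * n_half:
        raise SizingError(
            f"grid hosts {len(left_vox)} left voxels for {n_half} parcels; "
            "need at least 8 voxels per parcel"
        )
    left_mm = left_vox * vox
    origin = left_mm.mean(axis=0)
    centre_mm = (np.asarray(cfg.grid_shape) - 1) / 2.0 * vox
    semi_mm = 0.46 * np.asarray(cfg.grid_shape) * vox

    rng = cfg.rng(_STREAM_PARC)

    def _ray_extent(direction: np.ndarray) -> float:
        # largest s with origin + s*d inside the ellipsoid and the left half
        rel = (origin - centre_mm) / semi_mm
        dd = direction / semi_mm
        a = np.dot(dd, dd)
        b = 2 * np.dot(rel, dd)
        c = np.dot(rel, rel) - 1.0
        disc = b * b - 4 * a * c
        if disc <= 0:
            return 0.0
        s_ell = (-b + np.sqrt(disc)) / (2 * a)
        if direction[0] > 1e-9:
            s_mid = (centre_mm[0] - vox - origin[0]) / direction[0]
            s_ell = min(s_ell, s_mid)
        return max(s_ell, 0.0)

    def _propose_cortical(r: np.random.Generator) -> np.ndarray:
        while True:
            d = r.normal(size=3)
            d /= np.linalg.norm(d)
            ext = _ray_extent(d)
            if ext >= 4 * vox:
                return origin + d * ext * r.uniform(0.72, 0.95)

    def _propose_subcortical(r: np.random.Generator) -> np.ndarray:
        while True:
            p = origin + r.normal(scale=0.18 * semi_mm.min(), size=3)
            rel = (p - centre_mm) / semi_mm
            if (rel ** 2).sum() < 0.2 and p[0] < centre_mm[0] - vox:
                return p

    seeds: list[np.ndarray] = []
    for _ in range(n_cort):
        seeds.append(_best_candidate(rng, seeds, _propose_cortical))
    for _ in range(n_sub):
        seeds.append(_best_candidate(rng, seeds, _propose_subcortical))
    seeds_arr = np.asarray(seeds)

    tree = cKDTree(seeds_arr)
    _, assign = tree.query(left_mm)
    labels = np.zeros(cfg.grid_shape, dtype=np.int32)
    labels[tuple(left_vox.T)] = assign + 1

    _enforce_contiguity(labels, seeds_arr, left_vox, vox)

    # mirror: right-hemisphere partner of left parcel L is L + n_half
    right_labels = labels[::-1, :, :]
    labels = np.where(right_labels > 0, right_labels + n_half, labels)

    directions = (seeds_arr - origin)
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    networks = _assign_networks(cfg, directions, n_cort, n_sub)

    rows = []
    structures = {n_cort + 1: "hippocampus", n_cort + 2: "caudate"} if n_sub >= 2 else {}
    for lid in range(1, n_half + 1):
        cortical = lid <= n_cort
        d = directions[lid - 1]
        for hemi, pid, partner in (("L", lid, lid + n_half), ("R", lid + n_half, lid)):
            cx, cy, cz = ((d if hemi == "L" else d * np.array([-1.0, 1.0, 1.0]))
                          if cortical else (np.nan, np.nan, np.nan))
            rows.append(
                dict(parcel_id=pid, hemisphere=hemi, homotopic_id=partner,
                     network=networks[lid - 1], is_cortical=cortical,
                     structure=structures.get(lid, ""), cx=cx, cy=cy, cz=cz)
            )
    table = pd.DataFrame(rows).set_index("parcel_id").sort_index()
    return Parcellation(labels, table, (vox, vox, vox))


def _enforce_contiguity(labels: np.ndarray, seeds_mm: np.ndarray,
                        left_vox: np.ndarray, vox: float) -> None:
    """Reattach stray voxels so every label is one 6-connected component."""
    structure = ndimage.generate_binary_structure(3, 1)
    stray = np.zeros(labels.shape, dtype=bool)
    for lid in range(1, len(seeds_mm) + 1):
        mask = labels == lid
        comp, n_comp = ndimage.label(mask, structure=structure)
        if n_comp <= 1:
            continue
        seed_vox = np.round(seeds_mm[lid - 1] / vox).astype(int)
        seed_vox = np.clip(seed_vox, 0, np.asarray(labels.shape) - 1)
        keep = comp[tuple(seed_vox)]
        if keep == 0:
            sizes = ndimage.sum_labels(mask, comp, index=range(1, n_comp + 1))
            keep = int(np.argmax(sizes)) + 1
        stray |= mask & (comp != keep)
    labels[stray] = 0
    # grow neighbouring labels into the stray voxels (deterministic sweep)
    while stray.any():
        grew = False
        coords = np.argwhere(stray)
        for i, j, k in coords:
            best = 0
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                               (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                ii, jj, kk = i + di, j + dj, k + dk
                if 0 <= ii < labels.shape[0] and 0 <= jj < labels.shape[1] \
                        and 0 <= kk < labels.shape[2]:
                    lab = labels[ii, jj, kk]
                    if lab > 0 and (best == 0 or lab < best):
                        best = lab
            if best:
                labels[i, j, k] = best
                stray[i, j, k] = False
                grew = True
        if not grew:  # isolated pocket: give it to the nearest seed
            for i, j, k in coords:
                d = np.linalg.norm(seeds_mm - np.array([i, j, k]) * vox, axis=1)
                labels[i, j, k] = int(np.argmin(d)) + 1
                stray[i, j, k] = False


def _assign_networks(cfg: SyntheticConfig, directions: np.ndarray,
                     n_cort: int, n_sub: int) -> list[str]:
    """Seven spatially coherent communities from clustered seed directions."""
    from sklearn.cluster import KMeans

    n_clusters = min(7, n_cort)
    km = KMeans(n_clusters=n_clusters, n_init=4,
                random_state=int(cfg.seed) % (2 ** 31))
    lab = km.fit_predict(directions[:n_cort])
    order = sorted(range(n_clusters), key=lambda cl: tuple(km.cluster_centers_[cl]))
    name_of = {int(cl): NETWORKS[rank % 7] for rank, cl in enumerate(order)}
    nets = [name_of[int(l)] for l in lab]
    for s in range(n_sub):  # subcortical parcels inherit the nearest cortical community
        d = directions[n_cort + s]
        nearest = int(np.argmax(directions[:n_cort] @ d))
        nets.append(nets[nearest])
    return nets


# ---------------------------------------------------------------------------
# ground-truth fields


def _parcel_centroids_mm(parc: Parcellation, ids: np.ndarray) -> np.ndarray:
    lab = parc.labels.ravel()
    n_max = int(lab.max()) + 1
    counts = np.bincount(lab, minlength=n_max).astype(float)
    coords = np.indices(parc.shape).reshape(3, -1)
    cent = np.empty((n_max, 3))
    for ax in range(3):
        cent[:, ax] = np.bincount(lab, weights=coords[ax], minlength=n_max)
    with np.errstate(invalid="ignore"):
        cent /= counts[:, None]
    return cent[np.asarray(ids)] * np.asarray(parc.voxel_size_mm)


def _smooth_kernel(points_mm: np.ndarray, smoothness_mm: float) -> np.ndarray:
    n = len(points_mm)
    if smoothness_mm <= 0:
        return np.eye(n)
    d2 = ((points_mm[:, None, :] - points_mm[None, :, :]) ** 2).sum(axis=2)
    kern = np.exp(-d2 / (2.0 * smoothness_mm ** 2))
    # normalise so white noise keeps unit variance after smoothing
    return kern / np.sqrt((kern ** 2).sum(axis=1, keepdims=True))


def _zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def make_ground_truth_fields(cfg: SyntheticConfig, parc: Parcellation) -> dict[str, ParcelVector]:
    """Spatially autocorrelated left-hemisphere fields with planted correlations.

    Returns 'frequency' (non-negative placement intensity), 'hub', 'opc' and
    'driver' fields; the latter three correlate with the frequency field at
    ``effect_sizes['hub'|'opc'|'driver']`` (in expectation).
    """
    rng = cfg.rng(_STREAM_FIELDS)
    left_ids = parc.ids("left")
    pts = _parcel_centroids_mm(parc, left_ids)
    kern = _smooth_kernel(pts, cfg.smoothness_mm)

    def smooth_noise() -> np.ndarray:
        f = kern @ rng.normal(size=len(left_ids))
        return (f - f.mean()) / f.std(ddof=1)

    base = smooth_noise()
    fields: dict[str, np.ndarray] = {}
    for name in ("hub", "opc", "driver"):
        rho = float(cfg.effect_sizes.get(name, 0.0))
        fields[name] = rho * base + np.sqrt(max(0.0, 1 - rho ** 2)) * smooth_noise()

    span = base.max() - base.min()
    freq = (base - base.min()) + 0.15 * (span if span > 0 else 1.0)
    out = {"frequency": ParcelVector(left_ids, freq, units="a.u.", name="frequency")}
    for name, vals in fields.items():
        out[name] = ParcelVector(left_ids, vals, units="z", name=name)
    return out


# ---------------------------------------------------------------------------
# lesion cohort


def make_lesion_cohort(
    cfg: SyntheticConfig, parc: Parcellation, truth: ParcelVector
) -> list[tuple[VolumeMap, str]]:
    """Binary spherical lesion masks placed with probability ~ ``truth``.

    ``truth`` is defined on left-hemisphere parcels and mirrored to both
    hemispheres; each patient gets one contiguous spherical blob whose
    centre voxel is drawn from the planted placement law, and a grade label
    drawn with P(LGG) = ``lgg_fraction``.
    """
    vals = truth.values
    if np.any(vals < 0) or np.any(np.isnan(vals)):
        raise ValueError("truth field must be non-negative and complete")
    if vals.sum() <= 0:
        raise DegenerateFieldError("placement truth is all zero")
    rng = cfg.rng(_STREAM_LESIONS)

    truth_by_id = dict(zip(truth.ids, vals))
    all_ids = parc.parcel_ids
    left_of = {
        pid: (pid if parc.table.loc[pid, "hemisphere"] == "L"
              else int(parc.table.loc[pid, "homotopic_id"]))
        for pid in all_ids
    }
    weights = np.array([truth_by_id[left_of[pid]] for pid in all_ids], dtype=float)
    weights /= weights.sum()

    voxel_lists = {pid: np.argwhere(parc.labels == pid) for pid in all_ids}
    vox = np.asarray(parc.voxel_size_mm)
    shape = np.asarray(parc.shape)

    cohort: list[tuple[VolumeMap, str]] = []
    for _ in range(cfg.n_patients):
        pid = all_ids[rng.choice(len(all_ids), p=weights)]
        vlist = voxel_lists[pid]
        centre = vlist[rng.integers(len(vlist))]
        radius = float(np.clip(
            rng.lognormal(np.log(cfg.lesion_radius_median_mm), cfg.lesion_radius_sigma),
            1.5 * vox.min(), 0.3 * (shape * vox).min(),
        ))
        mask = _sphere_mask(shape, vox, centre, radius)
        grade = "LGG" if rng.random() < cfg.lgg_fraction else "HGG"
        cohort.append((VolumeMap(mask, tuple(vox), kind=MASK), grade))
    return cohort


def _sphere_mask(shape: np.ndarray, vox: np.ndarray, centre_vox: np.ndarray,
                 radius_mm: float) -> np.ndarray:
    lo = np.maximum(0, np.floor(centre_vox - radius_mm / vox).astype(int))
    hi = np.minimum(shape, np.ceil(centre_vox + radius_mm / vox).astype(int) + 1)
    mask = np.zeros(tuple(shape), dtype=np.uint8)
    grid = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
    d2 = (((grid - centre_vox) * vox) ** 2).sum(axis=1)
    inside = grid[d2 <= radius_mm ** 2]
    mask[tuple(inside.T)] = 1
    return mask


# ---------------------------------------------------------------------------
# connectome source


def make_connectome_source(
    cfg: SyntheticConfig, parc: Parcellation, hub_truth: ParcelVector
) -> pd.DataFrame:
    """Per-parcel component-loading vectors emulating a group-PCA connectome.

    Pairwise Pearson correlation of the returned rows yields a modular graph
    (communities = the parcel table's network affiliations) whose realized
    nodal strength rank-correlates with ``hub_truth`` at a level controlled
    by ``effect_sizes['hub']``.
    """
    if cfg.n_components < 2:
        raise ValueError("need at least 2 components")
    rng = cfg.rng(_STREAM_CONNECTOME)
    ids = parc.parcel_ids
    n = len(ids)

    truth_by_id = dict(zip(hub_truth.ids, hub_truth.values))
    hub = np.array([
        truth_by_id[pid if parc.table.loc[pid, "hemisphere"] == "L"
                    else int(parc.table.loc[pid, "homotopic_id"])]
        for pid in ids
    ])
    z = stats.norm.ppf((stats.rankdata(hub) - 0.5) / n)

    rho = float(cfg.effect_sizes.get("hub", 0.0))
    latent = rho * z + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(size=n)
    b = 0.2 + 0.6 * (stats.rankdata(latent) - 1) / max(n - 1, 1)
    a = 0.5
    e = np.sqrt(np.clip(1.0 - a ** 2 - b ** 2, 1e-9, None))

    nets = parc.table.loc[ids, "network"].to_numpy()
    shared = {net: rng.normal(size=cfg.n_components) for net in dict.fromkeys(nets)}
    hub_axis = rng.normal(size=cfg.n_components)
    loadings = np.empty((n, cfg.n_components))
    for i in range(n):
        loadings[i] = (a * shared[nets[i]] + b[i] * hub_axis
                       + e[i] * rng.normal(size=cfg.n_components))
    return pd.DataFrame(loadings, index=pd.Index(ids, name="parcel_id"))


# ---------------------------------------------------------------------------
# expression atlas


def make_expression_atlas(
    cfg: SyntheticConfig, parc: Parcellation, target: ParcelVector
) -> tuple[ExpressionAtlas, dict[str, GeneSet], dict]:
    """Spatially smooth expression atlas with planted marker and driver sets.

    Samples are placed at random in-parcel coordinates in the left
    hemisphere (subcortical parcels oversampled, as in post-mortem atlases).
    Most genes are smooth spatial noise; the marker set shares a common
    profile correlated with ``target`` at ``effect_sizes['opc']`` and the
    driver set loads on a profile correlated at ``effect_sizes['driver']``.
    Each set may include planted anti-correlated decoy genes.

    Returns (atlas, gene sets, planted-truth metadata for calibration).
    """
    n_special = cfg.n_marker_genes + cfg.n_driver_genes
    if cfg.n_genes < n_special:
        raise SizingError("n_genes smaller than the requested gene-set sizes")
    if cfg.marker_decoys >= cfg.n_marker_genes or cfg.driver_decoys >= cfg.n_driver_genes:
        raise SizingError("decoy count must be smaller than its gene set")
    left_ids = parc.ids("left")
    if cfg.n_samples < len(left_ids):
        warnings.warn(
            "fewer samples than parcels: some parcels will have no expression data",
            stacklevel=2,
        )
    rng = cfg.rng(_STREAM_EXPRESSION)

    tab = parc.table.loc[left_ids]
    sizes = np.array([np.count_nonzero(parc.labels == pid) for pid in left_ids], float)
    w = sizes * np.where(tab["is_cortical"].to_numpy(), 1.0, 5.0)
    w /= w.sum()
    sample_parcel = left_ids[rng.choice(len(left_ids), size=cfg.n_samples, p=w)]

    vox = np.asarray(parc.voxel_size_mm)
    voxel_lists = {pid: np.argwhere(parc.labels == pid) for pid in left_ids}
    coords = np.empty((cfg.n_samples, 3))
    for s, pid in enumerate(sample_parcel):
        vlist = voxel_lists[pid]
        coords[s] = (vlist[rng.integers(len(vlist))] + rng.uniform(-0.5, 0.5, 3)) * vox

    target_by_id = dict(zip(target.ids, target.values))
    t = _zscore(np.array([target_by_id[pid] for pid in sample_parcel]))

    kern = _smooth_kernel(coords, cfg.smoothness_mm)

    def smooth_profile() -> np.ndarray:
        return _zscore(kern @ rng.normal(size=cfg.n_samples))

    def planted_profile(rho: float) -> np.ndarray:
        return rho * t + np.sqrt(max(0.0, 1 - rho ** 2)) * smooth_profile()

    marker_profile = planted_profile(float(cfg.effect_sizes.get("opc", 0.0)))
    driver_profile = planted_profile(float(cfg.effect_sizes.get("driver", 0.0)))

    c = np.sqrt(_SET_COHERENCE)
    nse = np.sqrt(1 - _SET_COHERENCE)
    h = np.sqrt(_GENE_SMOOTHNESS)

    n_bg = cfg.n_genes - n_special
    bg = h * _zscore(kern @ rng.normal(size=(cfg.n_samples, n_bg))) \
        + np.sqrt(1 - _GENE_SMOOTHNESS) * rng.normal(size=(cfg.n_samples, n_bg))

    def set_block(profile: np.ndarray, n_members: int, n_decoys: int) -> np.ndarray:
        noise = rng.normal(size=(cfg.n_samples, n_members + n_decoys))
        signs = np.ones(n_members + n_decoys)
        if n_decoys:
            signs[n_members:] = -1.0
        return signs * c * profile[:, None] + nse * noise

    marker_block = set_block(marker_profile, cfg.n_marker_genes - cfg.marker_decoys,
                             cfg.marker_decoys)
    driver_block = set_block(driver_profile, cfg.n_driver_genes - cfg.driver_decoys,
                             cfg.driver_decoys)

    expr = np.concatenate([marker_block, driver_block, bg], axis=1)
    gene_names = np.array([f"G{g + 1:05d}" for g in range(cfg.n_genes)])
    order = rng.permutation(cfg.n_genes)
    expr = expr[:, order]
    columns = gene_names  # names are positional after shuffling the columns
    inv = np.empty(cfg.n_genes, dtype=int)
    inv[order] = np.arange(cfg.n_genes)

    marker_names = [columns[inv[g]] for g in range(cfg.n_marker_genes)]
    driver_names = [columns[inv[cfg.n_marker_genes + g]] for g in range(cfg.n_driver_genes)]
    marker_decoys = marker_names[cfg.n_marker_genes - cfg.marker_decoys:]
    driver_decoys = driver_names[cfg.n_driver_genes - cfg.driver_decoys:]

    sample_ids = [f"S{s + 1:04d}" for s in range(cfg.n_samples)]
    atlas = ExpressionAtlas(
        pd.DataFrame(expr, index=pd.Index(sample_ids, name="sample_id"), columns=columns),
        pd.DataFrame(coords, index=pd.Index(sample_ids, name="sample_id"),
                     columns=["x", "y", "z"]),
    )
    sets = {
        "opc_markers": GeneSet("opc_markers", marker_names,
                               note="synthetic OPC marker panel"),
        "glioma_drivers": GeneSet("glioma_drivers", driver_names,
                                  note="synthetic proto-oncogene panel"),
    }
    planted = {
        "marker_profile": marker_profile,
        "driver_profile": driver_profile,
        "marker_decoys": marker_decoys,
        "driver_decoys": driver_decoys,
        "sample_parcel": sample_parcel,
        "sample_target": t,
    }
    return atlas, sets, planted
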