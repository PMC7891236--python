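"""Imaging-transcriptomics: PLS regression of expression against frequency.

Expression samples are aligned to the (smoothed, left-mirrored) tumour
frequency map; the response is the square root of the frequency at each
sample location (reducing skew) and the predictors are the z-scored gene
columns.  A deflation-based PLS with a single response extracts successive
gene-weight directions maximizing covariance with the response; model
significance comes from shuffling the sample labels, per-gene Z-statistics
from bootstrap resampling with sign alignment, and gene-set enrichment
from median ranks against random same-size sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionAtlas, GeneSet, Parcellation, ParcelVector, VolumeMap
from .cellorigin import assign_samples_to_parcels
from .lesionmap import mirror_map, smooth_map

logger = logging.getLogger(__name__)


@dataclass
class AlignedDataset:
    """Z-scored expression matrix with a matched per-sample response."""

    X: np.ndarray  # samples x genes, each column mean 0 / sd 1
    y: np.ndarray  # sqrt tumour frequency per sample, >= 0
    genes: np.ndarray
    sample_ids: np.ndarray
    sample_coords: np.ndarray  # mm, after mirroring
    sample_parcel: np.ndarray

    def __post_init__(self) -> None:
        if len(self.y) != self.X.shape[0]:
            raise ValueError("response length must equal the sample count")
        if np.any(self.y < 0):
            raise ValueError("response must be non-negative")


def align_samples_to_frequency(
    atlas: ExpressionAtlas,
    raw_map: VolumeMap,
    parc: Parcellation,
    fwhm_mm: float = 2.0,
) -> AlignedDataset:
    """Match expression samples to the processed tumour frequency map.

    The raw (non-smoothed, non-mirrored) map is smoothed and mirrored to
    the left here; right-hemisphere samples are reflected to their
    homotopic coordinates.  Samples falling outside the grid are dropped
    with a log message.
    """
    processed = mirror_map(smooth_map(raw_map, fwhm_mm), to="left")
    vox = np.asarray(processed.voxel_size_mm)
    shape = np.asarray(processed.shape)
    mid_mm = (shape[0] - 1) * vox[0] / 2.0

    coords = atlas.coords[["x", "y", "z"]].to_numpy(dtype=float).copy()
    right = coords[:, 0] > mid_mm
    coords[right, 0] = 2 * mid_mm - coords[right, 0]  # homotopic reflection

    ijk = np.round(coords / vox).astype(int)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    if not inside.all():
        logger.info("dropping %d samples outside the brain grid", int((~inside).sum()))
    ijk, coords = ijk[inside], coords[inside]

    y = np.sqrt(processed.values[tuple(ijk.T)])
    expr = atlas.expression.loc[inside].to_numpy(dtype=float)
    if expr.shape[0] > 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.nan_to_num(expr.std(axis=0, ddof=1))
    else:
        sd = np.zeros(expr.shape[1])
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d zero-variance genes", int((~keep).sum()))
    X = (expr[:, keep] - expr[:, keep].mean(axis=0)) / sd[keep]

    sub_atlas = ExpressionAtlas(
        atlas.expression.loc[inside],
        pd.DataFrame(coords, index=atlas.coords.index[inside], columns=["x", "y", "z"]),
    )
    assigned = assign_samples_to_parcels(sub_atlas, parc)
    return AlignedDataset(
        X=X,
        y=np.asarray(y, dtype=float),
        genes=atlas.expression.columns.to_numpy()[keep],
        sample_ids=atlas.expression.index.to_numpy()[inside],
        sample_coords=coords,
        sample_parcel=assigned,
    )


@dataclass
class PLSFit:
    """Deflation-based PLS with a single response.

    ``weights[:, k]`` is the unit-norm gene-weight vector of component k
    (computed on the k-times-deflated X); ``scores[:, k]`` the sample
    scores; ``variance_explained_y[k]`` the increment of response variance
    explained by component k (orthogonal scores make increments additive).
    """

    weights: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    variance_explained_y: np.ndarray
    n_components: int
    algorithm: str = "NIPALS, single response, X-deflation"


class DegenerateDataError(ValueError):
    pass


def _pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """Core NIPALS loop; X and y are centred copies and get deflated."""
    n, p = X.shape
    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    Q = np.empty(n_components)
    ss_y = float(y @ y)
    if ss_y == 0:
        raise DegenerateDataError("response has zero variance")
    var = np.empty(n_components)
    for k in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            raise DegenerateDataError("X carries no covariance with the response")
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            raise DegenerateDataError("degenerate component (zero score variance)")
        p_load = X.T @ t / tt
        q = float(y @ t) / tt
        X = X - np.outer(t, p_load)
        y = y - q * t
        W[:, k], T[:, k], Q[k] = w, t, q
        var[k] = q * q * tt / ss_y
    return W, T, Q, var


def fit_pls(d: AlignedDataset, n_components: int = 2,
            scree_components: int | None = None) -> PLSFit:
    """Successive covariance-maximizing components of X against y.

    ``scree_components`` (default: n_components + 6, capped by rank) adds
    further components to the variance-explained report so the stopping
    rationale -- later components explaining near-indistinguishable shares
    -- can be checked.
    """
    n = d.X.shape[0]
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")
    if not np.any(d.X):
        raise DegenerateDataError("all-zero predictor matrix")
    k_all = min((scree_components or n_components + 6), n - 1, d.X.shape[1])
    k_all = max(k_all, n_components)
    Xc = d.X - d.X.mean(axis=0)
    yc = d.y - d.y.mean()
    W, T, Q, var = _pls1(Xc.copy(), yc.copy(), k_all)
    return PLSFit(W, T, Q, var, n_components)


def permute_pls_significance(
    d: AlignedDataset,
    fit: PLSFit,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the variance explained by the leading components.

    The statistic is the total response variance explained by the first
    ``fit.n_components`` components; the null shuffles the sample labels
    mapping X to y.
    """
    k = fit.n_components
    observed = float(fit.variance_explained_y[:k].sum())
    Xc = d.X - d.X.mean(axis=0)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(d.y)
        yc = yp - yp.mean()
        _, _, _, var = _pls1(Xc.copy(), yc, k)
        null[i] = var.sum()
    return (1 + int(np.sum(null >= observed))) / (1 + n_perm)


@dataclass
class GeneRanking:
    """Bootstrap Z-statistics and descending-|Z| signed ranks per component.

    Ranks are 1..n_genes, descending by Z (most positively weighted gene
    first); ties break deterministically by gene id.
    """

    genes: np.ndarray
    z: np.ndarray  # genes x components
    ranks: np.ndarray  # genes x components, permutation of 1..n_genes
    n_boot: int
    redrawn: int = 0

    def table(self) -> pd.DataFrame:
        cols = {}
        for k in range(self.z.shape[1]):
            cols[f"z_pls{k + 1}"] = self.z[:, k]
            cols[f"rank{k + 1}"] = self.ranks[:, k]
        return pd.DataFrame(cols, index=pd.Index(self.genes, name="gene_id"))


def bootstrap_gene_z(
    d: AlignedDataset,
    n_boot: int = 1000,
    n_components: int = 2,
    seed: int = 0,
) -> GeneRanking:
    """Z = original weight / bootstrap SD of the weight, per gene and component.

    Each bootstrap draw resamples samples with replacement and refits;
    every bootstrap component is sign-aligned to the original by the sign
    of its weight-vector dot product.  Draws where a component collapses
    are redrawn (counted).
    """
    fit = fit_pls(d, n_components=n_components)
    W0 = fit.weights[:, :n_components]
    rng = np.random.default_rng(seed)
    n = d.X.shape[0]
    acc = np.zeros_like(W0)
    acc2 = np.zeros_like(W0)
    redrawn = 0
    done = 0
    while done < n_boot:
        idx = rng.integers(n, size=n)
        Xb = d.X[idx]
        yb = d.y[idx]
        try:
            Wb, _, _, _ = _pls1(Xb - Xb.mean(axis=0), yb - yb.mean(), n_components)
        except DegenerateDataError:
            redrawn += 1
            if redrawn > 100 + n_boot:
                raise
            continue
        signs = np.sign(np.einsum("pk,pk->k", Wb, W0))
        signs[signs == 0] = 1.0
        Wb = Wb * signs
        acc += Wb
        acc2 += Wb ** 2
        done += 1
    if redrawn:
        logger.info("redrew %d collapsed bootstrap draws", redrawn)
    sd = np.sqrt(np.maximum(acc2 / n_boot - (acc / n_boot) ** 2, 0.0))
    sd = np.where(sd == 0, np.inf, sd)
    z = W0 / sd

    ranks = np.empty_like(z, dtype=int)
    for k in range(z.shape[1]):
        # descending z; ties broken by gene id via a stable secondary sort
        idx = np.lexsort((d.genes, -z[:, k]))
        ranks[idx, k] = np.arange(1, len(d.genes) + 1)
    return GeneRanking(d.genes.copy(), z, ranks, n_boot, redrawn)


def rank_enrichment_test(
    ranking: GeneRanking,
    set_: GeneSet,
    component: int = 1,
    n_null: int = 10000,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Median rank of the gene set vs random same-size sets (small = enriched).

    Returns (observed median rank, p).  ``exhaustive=True`` enumerates all
    same-size gene subsets for an exact p (feasible only for toy sizes).
    """
    ranks_all = ranking.ranks[:, component - 1]
    pos = {g: r for g, r in zip(ranking.genes, ranks_all)}
    present = [g for g in set_.genes if g in pos]
    absent = [g for g in set_.genes if g not in pos]
    if absent:
        logger.info("set genes absent from ranking dropped: %s", absent)
    if not present:
        raise ValueError("no set genes present in the ranking")
    observed = float(np.median([pos[g] for g in present]))
    k = len(present)
    if exhaustive:
        null = [float(np.median(c))
                for c in itertools.combinations(sorted(ranks_all), k)]
        p = float(np.sum(np.asarray(null) <= observed)) / len(null)
    else:
        rng = np.random.default_rng(seed)
        null = np.median(
            ranks_all[np.argsort(rng.random((n_null, len(ranks_all))), axis=1)[:, :k]],
            axis=1,
        )
        p = (1 + int(np.sum(null <= observed))) / (1 + n_null)
    return observed, float(p)


def map_loadings_to_parcels(
    fit: PLSFit,
    d: AlignedDataset,
    parc: Parcellation,
) -> tuple[dict[str, ParcelVector], pd.DataFrame]:
    """Median per-parcel sample score ("loading") for each component.

    Parcels assigned zero samples receive the mean loading of the whole
    sample group.  Also returns a per-parcel sample-count summary split by
    cortical/subcortical.
    """
    left_ids = parc.ids("left")
    counts = pd.Series(0, index=left_ids, dtype=int)
    vc = pd.Series(d.sample_parcel).value_counts()
    counts.loc[counts.index.intersection(vc.index)] = vc
    out: dict[str, ParcelVector] = {}
    for k in range(fit.n_components):
        scores = fit.scores[:, k]
        vals = np.empty(len(left_ids))
        for i, pid in enumerate(left_ids):
            sel = d.sample_parcel == pid
            vals[i] = float(np.median(scores[sel])) if sel.any() else float(scores.mean())
        out[f"pls{k + 1}"] = ParcelVector(left_ids, vals, name=f"pls{k + 1}_loading")
    is_cort = parc.table.loc[left_ids, "is_cortical"].to_numpy()
    summary = pd.DataFrame(
        {
            "group": ["cortical", "subcortical"],
            "n_parcels": [int(is_cort.sum()), int((~is_cort).sum())],
            "mean_samples": [counts[is_cort].mean(), counts[~is_cort].mean()],
            "sd_samples": [counts[is_cort].std(), counts[~is_cort].std()],
            "empty_parcels": [int((counts[is_cort] == 0).sum()),
                              int((counts[~is_cort] == 0).sum())],
        }
    ).set_index("group")
    return out, summary
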