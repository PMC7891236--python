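"""Cellular correlates: NSC niche localization and OPC marker enrichment.

Neural stem cells in the adult brain are confined to the subventricular
zone (adjacent to the caudate) and the hippocampal dentate gyrus, so the
niche test asks whether tumour frequency in the two niche parcels exceeds
the average over random parcel pairs.  The OPC distribution is estimated
from the co-expression of a marker gene panel in a spatial expression
atlas: the panel's spatial specificity is checked against random same-size
gene sets, discordant members are filtered out, and the median regional
enrichment becomes a per-parcel score map.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import ExpressionAtlas, GeneSet, Parcellation, ParcelVector

logger = logging.getLogger(__name__)


def nsc_niche_test(
    freq: ParcelVector,
    niche_parcels: tuple[int, int] | None = None,
    parc: Parcellation | None = None,
    n_null: int = 10000,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Mean tumour frequency over the NSC niche parcels vs random pairs.

    ``niche_parcels`` defaults to the parcels tagged 'hippocampus' and
    'caudate' in the parcel table.  The null draws ``n_null`` random
    distinct parcel pairs (pairs may repeat across draws and may include
    the niche parcels).  With ``exhaustive=True`` the null enumerates every
    unordered pair instead, giving an exact p-value.
    """
    if niche_parcels is None:
        if parc is None:
            raise ValueError("need niche_parcels or a parcellation with structure tags")
        tagged = {
            s: pid for pid, s in parc.table["structure"].items()
            if s in ("hippocampus", "caudate") and pid in set(freq.ids)
        }
        if set(tagged) != {"hippocampus", "caudate"}:
            raise KeyError("parcel table does not tag hippocampus and caudate in scope")
        niche_parcels = (tagged["hippocampus"], tagged["caudate"])
    try:
        observed = float(np.mean([freq.value_of(p) for p in niche_parcels]))
    except KeyError as exc:
        raise KeyError(f"unknown niche parcel: {exc}") from exc

    vals = freq.values[~freq.missing]
    n = len(vals)
    if exhaustive:
        null = np.array([
            0.5 * (vals[i] + vals[j]) for i, j in itertools.combinations(range(n), 2)
        ])
        p = float(np.sum(null >= observed)) / len(null)
    else:
        rng = np.random.default_rng(seed)
        idx = np.array([rng.choice(n, size=2, replace=False) for _ in range(n_null)])
        null = vals[idx].mean(axis=1)
        p = (1 + int(np.sum(null >= observed))) / (1 + n_null)
    return observed, float(p)


def _set_expression(set_: GeneSet, atlas: ExpressionAtlas) -> np.ndarray:
    expr = atlas.expression[list(set_.genes)].to_numpy(dtype=float)
    keep = expr.std(axis=0) > 0
    if not keep.all():
        dropped = [g for g, k in zip(set_.genes, keep) if not k]
        logger.info("excluding zero-variance genes: %s", dropped)
        expr = expr[:, keep]
    return expr


def _mean_pairwise_correlation(expr: np.ndarray) -> float:
    c = np.corrcoef(expr.T)
    iu = np.triu_indices(c.shape[0], 1)
    return float(c[iu].mean())


def coexpression_specificity(
    set_: GeneSet,
    atlas: ExpressionAtlas,
    n_null: int = 1000,
    seed: int = 0,
) -> float:
    """Is the set's mean pairwise spatial correlation higher than chance?

    The null statistic is the same mean pairwise Pearson correlation for
    ``n_null`` random same-size gene sets drawn from the atlas.
    """
    if len(set_) < 2:
        raise ValueError("need a gene set of size >= 2")
    resolved, dropped = set_.resolve(atlas)
    if dropped:
        logger.info("unresolvable gene ids dropped: %s", dropped)
    expr = _set_expression(resolved, atlas)
    observed = _mean_pairwise_correlation(expr)
    rng = np.random.default_rng(seed)
    all_genes = atlas.expression.columns.to_numpy()
    k = expr.shape[1]
    null = np.empty(n_null)
    data = atlas.expression.to_numpy(dtype=float)
    for i in range(n_null):
        cols = rng.choice(len(all_genes), size=k, replace=False)
        null[i] = _mean_pairwise_correlation(data[:, cols])
    return (1 + int(np.sum(null >= observed))) / (1 + n_null)


def filter_gene_set(set_: GeneSet, atlas: ExpressionAtlas) -> GeneSet:
    """Single-pass removal of genes discordant with the rest of the set.

    A gene is removed when its mean correlation with the other members is
    <= 0.  The pass is not iterated to convergence.
    """
    if len(set_) < 2:
        raise ValueError("need a gene set of size >= 2")
    resolved, dropped = set_.resolve(atlas)
    if dropped:
        logger.info("unresolvable gene ids dropped: %s", dropped)
    expr = atlas.expression[list(resolved.genes)].to_numpy(dtype=float)
    c = np.corrcoef(expr.T)
    np.fill_diagonal(c, np.nan)
    mean_with_others = np.nanmean(c, axis=1)
    kept = [g for g, m in zip(resolved.genes, mean_with_others) if m > 0]
    removed = [g for g in resolved.genes if g not in kept]
    if removed:
        logger.info("filtered discordant genes: %s", removed)
    if not kept:
        raise ValueError("all genes removed by co-expression filter")
    return GeneSet(set_.name, kept,
                   note=(set_.note + f" | filtered out: {','.join(removed) or 'none'}").strip())


def assign_samples_to_parcels(atlas: ExpressionAtlas, parc: Parcellation) -> np.ndarray:
    """Nearest-neighbour sample -> parcel assignment.

    Each sample maps to the parcel of the nearest labelled voxel (Euclidean
    distance in mm; exact ties go to the lower parcel id).
    """
    fg = np.argwhere(parc.labels > 0)
    vox = np.asarray(parc.voxel_size_mm)
    tree = cKDTree(fg * vox)
    pts = atlas.coords[["x", "y", "z"]].to_numpy(dtype=float)
    k2 = min(2, len(fg))
    d, idx = tree.query(pts, k=k2)
    d = np.atleast_2d(d.T).T
    idx = np.atleast_2d(idx.T).T
    assigned = parc.labels[tuple(fg[idx[:, 0]].T)].astype(int)
    if k2 == 2:  # deterministic tie-break: lower parcel id
        for s in np.flatnonzero(d[:, 1] <= d[:, 0] + 1e-9):
            hits = tree.query_ball_point(pts[s], d[s, 0] + 1e-9)
            dd = np.linalg.norm(fg[hits] * vox - pts[s], axis=1)
            cands = parc.labels[tuple(np.asarray(fg[hits])[dd <= dd.min() + 1e-9].T)]
            assigned[s] = cands.min()
    return assigned


@dataclass
class EnrichmentResult:
    score_map: ParcelVector
    coexpression_p: float
    removed_genes: list[str]
    n_null: int
    sample_scores: np.ndarray = field(repr=False, default=None)


def marker_score_map(
    set_: GeneSet,
    atlas: ExpressionAtlas,
    parc: Parcellation,
    n_null: int = 1000,
    seed: int = 0,
    prefiltered: bool = False,
) -> EnrichmentResult:
    """Median regional enrichment of a marker gene set on cortical parcels.

    Per-sample score = median of the set's z-scored expression; per-parcel
    score = median over the parcel's nearest-neighbour-assigned cortical
    samples.  Parcels with no samples are flagged missing and excluded from
    downstream correlations.
    """
    p_coexpr = coexpression_specificity(set_, atlas, n_null=n_null, seed=seed)
    filtered = set_ if prefiltered else filter_gene_set(set_, atlas)
    removed = sorted(set(set_.genes) - set(filtered.genes))

    expr = _set_expression(filtered, atlas)
    z = (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=1)
    sample_scores = np.median(z, axis=1)

    assigned = assign_samples_to_parcels(atlas, parc)
    cortical = parc.table.loc[assigned, "is_cortical"].to_numpy()
    ids = parc.ids("left", cortical_only=True)
    scores = np.full(len(ids), np.nan)
    for k, pid in enumerate(ids):
        sel = (assigned == pid) & cortical
        if sel.any():
            scores[k] = float(np.median(sample_scores[sel]))
    score_map = ParcelVector(ids, scores, units="z", name=f"{set_.name}_score")
    return EnrichmentResult(score_map, p_coexpr, removed, n_null, sample_scores)
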