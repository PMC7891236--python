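"""Weighted functional connectome construction and hub metrics.

Edge weights are Pearson correlations between parcel-mean component
loadings (a memory-efficient stand-in for correlating mean time series);
negative correlations and the diagonal are zeroed and no further density
threshold is applied.  Hub metrics follow the standard weighted
definitions: shortest-path metrics use edge lengths 1/weight, betweenness
is normalised by (n-1)(n-2) over ordered pairs, participation and
within-module degree z-score use the parcel table's canonical-network
communities, clustering is the geometric-mean (Onnela) variant, and
"local efficiency" here is nodal efficiency -- the mean inverse
shortest-path length from a node to every other node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .containers import Connectome, Parcellation, ParcelVector
from .spatialnull import SpinEnsemble, SpinTestResult, spin_correlation_test

HUB_METRICS = (
    "strength",
    "betweenness",
    "participation",
    "within_module_z",
    "clustering",
    "local_efficiency",
    "eigenvector",
)


def build_parcel_connectome(
    loadings: pd.DataFrame, parc: Parcellation, voxel_parcels: np.ndarray | None = None
) -> Connectome:
    """Correlation connectome from per-parcel (or per-voxel) loading vectors.

    If ``loadings`` rows are voxels, ``voxel_parcels`` gives each row's
    parcel id and rows are averaged within parcels first (analogous to a
    mean time series).  Communities come from the parcel table's network
    affiliations.
    """
    if voxel_parcels is not None:
        loadings = loadings.groupby(np.asarray(voxel_parcels)).mean()
        loadings = loadings.loc[loadings.index > 0]
    if loadings.shape[1] < 2:
        raise ValueError("need at least 2 components per parcel")
    ids = parc.parcel_ids
    missing = np.setdiff1d(ids, loadings.index.to_numpy())
    if len(missing):
        raise ValueError(f"parcels without loading vectors: {missing.tolist()}")
    mat = loadings.loc[ids].to_numpy(dtype=float)
    w = np.corrcoef(mat)
    w = np.where(w > 0, w, 0.0)
    np.fill_diagonal(w, 0.0)
    w = 0.5 * (w + w.T)
    community = parc.table.loc[ids, "network"].to_numpy()
    return Connectome(w, ids, community)


@dataclass
class HubTable:
    """Per-parcel hub metrics with a record of screened-out columns."""

    values: pd.DataFrame  # index parcel_id, columns = metrics
    community: np.ndarray
    screened_out: list[str] = field(default_factory=list)
    screening_report: pd.DataFrame | None = None

    def metric(self, name: str) -> ParcelVector:
        return ParcelVector(self.values.index.to_numpy(),
                            self.values[name].to_numpy(), name=name)

    @property
    def metrics(self) -> list[str]:
        return list(self.values.columns)


def _distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths on edge lengths 1/weight."""
    n = len(weights)
    src, dst = np.nonzero(np.triu(weights, 1))
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    lengths = (1.0 / weights[src, dst]).tolist()
    return np.asarray(g.distances(weights=lengths))


def hub_metrics(c: Connectome) -> HubTable:
    """All seven weighted hub metrics for every node of the connectome."""
    w = c.weights
    n = c.n_nodes
    strength = w.sum(axis=1)

    src, dst = np.nonzero(np.triu(w, 1))
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    lengths = (1.0 / w[src, dst]).tolist()
    bc = np.asarray(g.betweenness(weights=lengths))
    denom = (n - 1) * (n - 2) if n > 2 else 1
    betweenness = 2.0 * bc / denom  # igraph counts unordered pairs

    comms = pd.unique(c.community)
    kappa = np.stack([w[:, c.community == m].sum(axis=1) for m in comms], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = kappa / strength[:, None]
    participation = np.where(strength > 0, 1.0 - np.nansum(frac ** 2, axis=1), 0.0)

    within = np.zeros(n)
    for m in comms:
        members = c.community == m
        k_in = w[np.ix_(members, members)].sum(axis=1)
        sd = k_in.std()  # population SD, toolbox convention
        within[members] = (k_in - k_in.mean()) / sd if sd > 0 else 0.0

    wmax = w.max() if w.max() > 0 else 1.0
    a3 = np.linalg.matrix_power(np.cbrt(w / wmax), 3)
    deg = (w > 0).sum(axis=1)
    denom_c = deg * (deg - 1)
    clustering = np.where(denom_c > 0, np.diagonal(a3) / np.where(denom_c > 0, denom_c, 1), 0.0)

    dist = _distances(w)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    local_efficiency = inv.sum(axis=1) / max(n - 1, 1)

    if w.any():
        evals, evecs = np.linalg.eigh(w)
        vec = np.abs(evecs[:, np.argmax(evals)])
    else:
        vec = np.zeros(n)
    eigenvector = vec

    values = pd.DataFrame(
        {
            "strength": strength,
            "betweenness": betweenness,
            "participation": participation,
            "within_module_z": within,
            "clustering": clustering,
            "local_efficiency": local_efficiency,
            "eigenvector": eigenvector,
        },
        index=pd.Index(c.parcel_ids, name="parcel_id"),
    )
    return HubTable(values, c.community.copy())


def homotopic_average(h: HubTable, parc: Parcellation) -> HubTable:
    """Average each metric over homotopic pairs, indexed by left parcels."""
    left_ids = parc.ids("left")
    partners = parc.table.loc[left_ids, "homotopic_id"].to_numpy()
    missing = np.setdiff1d(np.concatenate([left_ids, partners]),
                           h.values.index.to_numpy())
    if len(missing):
        raise ValueError(f"unpaired parcels: {missing.tolist()}")
    vals = 0.5 * (h.values.loc[left_ids].to_numpy()
                  + h.values.loc[partners].to_numpy())
    out = pd.DataFrame(vals, index=pd.Index(left_ids, name="parcel_id"),
                       columns=h.values.columns)
    community = parc.table.loc[left_ids, "network"].to_numpy()
    return HubTable(out, community, screened_out=list(h.screened_out),
                    screening_report=h.screening_report)


def screen_redundant_metrics(
    h: HubTable,
    threshold: float = 0.95,
    stability_range: tuple[float, float] = (0.65, 0.99),
    stability_steps: int = 18,
) -> HubTable:
    """Drop metrics whose |Spearman| with nodal strength exceeds ``threshold``.

    Nodal strength itself is always retained.  A stability report records
    which metrics would be screened at thresholds across
    ``stability_range`` (the screened set is monotone in the threshold).
    """
    strength = h.values["strength"].to_numpy()
    rhos = {}
    for m in h.values.columns:
        if m == "strength":
            continue
        rhos[m] = abs(float(stats.spearmanr(strength, h.values[m].to_numpy()).statistic))
    removed = sorted(m for m, r in rhos.items() if r > threshold)
    kept = [m for m in h.values.columns if m not in removed]

    grid = np.linspace(*stability_range, stability_steps)
    report = pd.DataFrame(
        {f"{thr:.2f}": {m: rhos[m] > thr for m in rhos} for thr in grid}
    ).T
    report.index.name = "threshold"

    return HubTable(h.values[kept].copy(), h.community,
                    screened_out=list(h.screened_out) + removed,
                    screening_report=report)


def hub_frequency_association(
    h: HubTable,
    freq: ParcelVector,
    ens: SpinEnsemble,
    sidedness: str = "one",
) -> dict[str, SpinTestResult]:
    """Spin test of every surviving hub metric against tumour frequency.

    The hub metric (not the frequency map) is the spun map.
    """
    out = {}
    for m in h.metrics:
        out[m] = spin_correlation_test(h.metric(m), freq, ens, sidedness=sidedness,
                                       spin_target="x")
    return out
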