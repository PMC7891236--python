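"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (nested loops, exhaustive
enumeration, Floyd-Warshall with explicit path counting) and shares no
code with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def count_frequency_loop(masks: list[np.ndarray]) -> np.ndarray:
    """Per-voxel percentage overlap by an explicit voxel-by-voxel loop."""
    shape = masks[0].shape
    out = np.zeros(shape, dtype=float)
    for idx in np.ndindex(shape):
        c = 0
        for m in masks:
            if m[idx]:
                c += 1
        out[idx] = 100.0 * c / len(masks)
    return out


def shortest_path_counts(w: np.ndarray, tol: float = 1e-9):
    """Floyd-Warshall distances plus minimal-path counts on lengths 1/w."""
    n = len(w)
    with np.errstate(divide="ignore"):
        L = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(L, 0.0)
    dist = L.copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    # sigma[s, t]: number of minimal paths, by DP over nodes sorted by dist from s
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(dist[s])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            total = 0.0
            for p in range(n):
                if p != t and np.isfinite(L[p, t]) and np.isfinite(dist[s, p]) \
                        and abs(dist[s, p] + L[p, t] - dist[s, t]) <= tol * max(1.0, dist[s, t]):
                    total += sigma[s, p]
            sigma[s, t] = total
    return dist, sigma


def betweenness_brute(w: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Normalised betweenness by exhaustive fractional path accounting."""
    n = len(w)
    dist, sigma = shortest_path_counts(w, tol)
    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) < 3 or not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                    continue
                if abs(dist[s, v] + dist[v, t] - dist[s, t]) <= tol * max(1.0, dist[s, t]):
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if n > 2:
        bc /= (n - 1) * (n - 2)
    return bc


def strength_brute(w: np.ndarray) -> np.ndarray:
    n = len(w)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            out[i] += w[i, j]
    return out


def participation_brute(w: np.ndarray, community: np.ndarray) -> np.ndarray:
    n = len(w)
    out = np.zeros(n)
    for i in range(n):
        k_i = w[i].sum()
        if k_i == 0:
            out[i] = 0.0
            continue
        acc = 0.0
        for m in set(community.tolist()):
            kappa = sum(w[i, j] for j in range(n) if community[j] == m)
            acc += (kappa / k_i) ** 2
        out[i] = 1.0 - acc
    return out


def within_module_z_brute(w: np.ndarray, community: np.ndarray) -> np.ndarray:
    n = len(w)
    out = np.zeros(n)
    for m in set(community.tolist()):
        members = [i for i in range(n) if community[i] == m]
        k_in = [sum(w[i, j] for j in members) for i in members]
        mu = float(np.mean(k_in))
        sd = float(np.std(k_in))  # population SD
        for i, ki in zip(members, k_in):
            out[i] = (ki - mu) / sd if sd > 0 else 0.0
    return out


def nodal_efficiency_brute(w: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    n = len(w)
    dist, _ = shortest_path_counts(w, tol)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                acc += 1.0 / dist[i, j]
        out[i] = acc / (n - 1) if n > 1 else 0.0
    return out


def clustering_brute(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering: geometric-mean triangle intensity."""
    n = len(w)
    wmax = w.max() if w.max() > 0 else 1.0
    wn = w / wmax
    out = np.zeros(n)
    for i in range(n):
        deg = sum(1 for j in range(n) if w[i, j] > 0)
        if deg < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    acc += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        out[i] = acc / (deg * (deg - 1))
    return out


def eigenvector_power_iteration(w: np.ndarray, iters: int = 20000) -> np.ndarray:
    v = np.ones(len(w))
    for _ in range(iters):
        nv = w @ v
        nrm = np.linalg.norm(nv)
        if nrm == 0:
            return np.zeros(len(w))
        nv /= nrm
        if np.allclose(nv, v, atol=1e-14):
            v = nv
            break
        v = nv
    return np.abs(v)


def median_rank_enumeration(ranks: np.ndarray, k: int, observed: float) -> float:
    """Exact p: share of all k-subsets with median rank <= observed."""
    import statistics

    total = 0
    hits = 0
    for combo in itertools.combinations(list(ranks), k):
        total += 1
        if statistics.median(combo) <= observed:
            hits += 1
    return hits / total


def pair_mean_enumeration(values: np.ndarray, observed: float) -> float:
    """Exact p: share of all unordered parcel pairs with mean >= observed."""
    total = 0
    hits = 0
    for a, b in itertools.combinations(list(values), 2):
        total += 1
        if (a + b) / 2.0 >= observed:
            hits += 1
    return hits / total


def morans_i_loop(values: np.ndarray, weights: np.ndarray) -> float:
    n = len(values)
    z = values - values.mean()
    num = 0.0
    wsum = 0.0
    for i in range(n):
        for j in range(n):
            num += weights[i, j] * z[i] * z[j]
            wsum += weights[i, j]
    return n / wsum * num / (z @ z)


def smooth_fields_pair(centroids: np.ndarray, rho: float, rng: np.random.Generator,
                       smoothness_mm: float = 12.0) -> tuple[np.ndarray, np.ndarray]:
    """Two spatially smooth fields with population correlation ``rho``."""
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    kern = np.exp(-d2 / (2.0 * smoothness_mm ** 2)) if smoothness_mm > 0 \
        else np.eye(len(centroids))
    kern = kern / np.sqrt((kern ** 2).sum(axis=1, keepdims=True))

    def draw():
        f = kern @ rng.normal(size=len(centroids))
        return (f - f.mean()) / f.std(ddof=1)

    a = draw()
    b = rho * a + np.sqrt(max(0.0, 1 - rho ** 2)) * draw()
    return a, b
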