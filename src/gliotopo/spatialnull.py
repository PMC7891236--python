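"""Spatial-permutation ("spin") inference and Moran's I diagnostics.

Parcel-level brain maps are spatially autocorrelated, so naive permutation
nulls overstate significance.  The spin test rotates the spherical
embedding of the cortical parcels by a uniform random 3-D rotation and
reassigns each rotated centroid to the nearest original centroid, producing
contiguity-preserving null maps.  Subcortical parcels, which have no
spherical embedding, are permuted uniformly among themselves (or excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .containers import GeometryError, Parcellation, ParcelVector


@dataclass
class SpinEnsemble:
    """n_spins x n_parcels table of source indices.

    Row ``s`` reorders a ParcelVector on ``ids``: the spun value at
    position ``i`` is ``x[permutations[s, i]]``.
    """

    permutations: np.ndarray
    ids: np.ndarray
    n_spins: int
    scope_mask: np.ndarray  # True where the parcel was rotated (cortical)
    bijective: bool = False
    seed: int | None = None

    def apply(self, x: np.ndarray) -> np.ndarray:
        """All spun versions of ``x`` (n_spins x n_parcels)."""
        return np.asarray(x)[self.permutations]


@dataclass
class SpinTestResult:
    rho_observed: float
    null_rhos: np.ndarray
    p_spin: float
    sidedness: str
    n_spins: int

    def to_dict(self) -> dict:
        return {
            "rho": self.rho_observed,
            "p_spin": self.p_spin,
            "sidedness": self.sidedness,
            "n_spins": self.n_spins,
        }


def build_spin_ensemble(
    parc: Parcellation,
    n_spins: int = 10000,
    seed: int = 0,
    scope: str = "left",
    include_subcortex: bool = True,
    bijective: bool = False,
    rotations: np.ndarray | None = None,
) -> SpinEnsemble:
    """Spin ensemble over the parcels of one analysis scope.

    Per spin, one uniform random rotation is applied jointly to all
    cortical unit-sphere centroids (the mirrored rotation to the right
    hemisphere when scope is bilateral) and each rotated centroid is
    reassigned to the nearest original centroid by great-circle distance.
    With ``bijective=True`` the reassignment is the optimal one-to-one
    matching instead (exactly conserving the multiset of values).
    ``rotations`` is a test hook for injecting fixed rotation matrices.
    """
    ids = parc.ids(scope, cortical_only=not include_subcortex)
    tab = parc.table.loc[ids]
    cort = tab["is_cortical"].to_numpy()
    if not cort.any():
        raise GeometryError("scope contains no cortical parcels to rotate")
    rng = np.random.default_rng(seed)
    if rotations is None:
        rotations = Rotation.random(n_spins, rng=rng).as_matrix()
    else:
        rotations = np.asarray(rotations, dtype=float)
        if rotations.shape != (n_spins, 3, 3):
            raise ValueError("rotations must have shape (n_spins, 3, 3)")

    perms = np.tile(np.arange(len(ids)), (n_spins, 1))
    flip = np.diag([-1.0, 1.0, 1.0])
    for hemi in ("L", "R"):
        sel = np.flatnonzero(cort & (tab["hemisphere"] == hemi).to_numpy())
        if len(sel) == 0:
            continue
        pts = parc.sphere_centroids(ids[sel])
        rots = rotations if hemi == "L" else flip @ rotations @ flip
        # chunk the (n_spins, n, n) similarity tensor to bound memory
        chunk = max(1, int(2e7 // (len(sel) ** 2 + 1)))
        for start in range(0, n_spins, chunk):
            rot = np.einsum("sab,nb->sna", rots[start:start + chunk], pts)
            sim = np.einsum("sna,ma->snm", rot, pts)  # cos of great-circle dist
            if bijective:
                for s in range(sim.shape[0]):
                    rows, cols = linear_sum_assignment(-sim[s])
                    perms[start + s, sel[rows]] = sel[cols]
            else:
                perms[start:start + chunk, sel] = sel[np.argmax(sim, axis=2)]
    sub = np.flatnonzero(~cort)
    for s in range(n_spins):
        if len(sub):
            perms[s, sub] = sub[rng.permutation(len(sub))]
    return SpinEnsemble(perms, ids, n_spins, scope_mask=cort,
                        bijective=bijective, seed=seed)


def _aligned(x: ParcelVector, y: ParcelVector, ens: SpinEnsemble) -> tuple[np.ndarray, np.ndarray]:
    return x.align_to(ens.ids).values, y.align_to(ens.ids).values


def spin_correlation_test(
    x: ParcelVector,
    y: ParcelVector,
    ens: SpinEnsemble,
    sidedness: str = "one",
    spin_target: str = "x",
) -> SpinTestResult:
    """Spearman correlation of two parcel maps against the spin null.

    ``spin_target`` names the map that is spatially permuted.  The default
    p-value is one-sided in the direction of the observed sign, with the
    standard +1 correction; ``sidedness='two'`` doubles the smaller tail.
    Parcels with a missing value in either map are excluded pairwise.
    """
    xv, yv = _aligned(x, y, ens)
    ok = ~np.isnan(xv) & ~np.isnan(yv)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete parcel pairs")
    for v, nm in ((xv[ok], "x"), (yv[ok], "y")):
        if np.ptp(v) == 0:
            raise ValueError(f"constant input vector {nm!r}: correlation undefined")
    rho = float(stats.spearmanr(xv[ok], yv[ok]).statistic)

    spun, fixed = (xv, yv) if spin_target == "x" else (yv, xv)
    spun_all = ens.apply(spun)
    if ok.all() and not np.isnan(spun_all).any():
        rank_fixed = stats.rankdata(fixed)
        ranks = np.apply_along_axis(stats.rankdata, 1, spun_all)
        rf = (rank_fixed - rank_fixed.mean()) / rank_fixed.std()
        rz = (ranks - ranks.mean(axis=1, keepdims=True)) / ranks.std(axis=1, keepdims=True)
        null = rz @ rf / len(rf)
    else:  # pairwise-complete fallback when either map has missing parcels
        null = np.empty(ens.n_spins)
        for s in range(ens.n_spins):
            sv = spun_all[s]
            m = ~np.isnan(sv) & ~np.isnan(fixed)
            null[s] = stats.spearmanr(sv[m], fixed[m]).statistic

    n = ens.n_spins
    p_up = (1 + int(np.sum(null >= rho))) / (1 + n)
    p_dn = (1 + int(np.sum(null <= rho))) / (1 + n)
    if sidedness == "one":
        p = p_up if rho >= 0 else p_dn
    elif sidedness == "two":
        p = min(1.0, 2.0 * min(p_up, p_dn))
    else:
        raise ValueError("sidedness must be 'one' or 'two'")
    return SpinTestResult(rho, null, float(p), sidedness, n)


def morans_i(
    x: ParcelVector,
    parc: Parcellation,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Moran's I with inverse-distance weights on the spherical centroids.

    Weights are w_ij = 1/d_ij (chord distance between unit-sphere
    centroids), row-normalised, w_ii = 0.  The p-value comes from uniform
    permutation of the parcel values (the permutation-null mean of I is
    -1/(n-1)).  Only parcels with a spherical embedding participate.
    """
    ids = np.asarray(x.ids)
    cortical = parc.table.loc[ids, "is_cortical"].to_numpy()
    ids = ids[cortical]
    vals = x.align_to(ids).values
    if np.isnan(vals).any():
        raise ValueError("morans_i requires complete values")
    if np.ptp(vals) == 0:
        raise ValueError("constant vector: variance degenerate")
    pts = parc.sphere_centroids(ids)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)

    def moran(v: np.ndarray) -> float:
        z = v - v.mean()
        return float(len(z) / w.sum() * (z @ w @ z) / (z @ z))

    i_obs = moran(vals)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = moran(rng.permutation(vals))
    if alternative == "greater":
        p = (1 + int(np.sum(null >= i_obs))) / (1 + n_perm)
    elif alternative == "two-sided":
        mu = null.mean()
        p = (1 + int(np.sum(np.abs(null - mu) >= abs(i_obs - mu)))) / (1 + n_perm)
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return i_obs, float(p)


def morans_i_statistic(vals: np.ndarray, weights: np.ndarray) -> float:
    """Bare Moran's I for a given (already zero-diagonal) weight matrix."""
    vals = np.asarray(vals, dtype=float)
    z = vals - vals.mean()
    return float(len(z) / weights.sum() * (z @ weights @ z) / (z @ z))
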