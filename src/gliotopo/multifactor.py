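"""Integrative regression of parcel-wise tumour frequency.

Connectomic (nodal strength), cellular (OPC score) and transcriptomic
(PLS1/PLS2 loading) predictors are z-scored on the left-hemisphere parcel
index and regressed against the z-scored square root of tumour frequency.
An interaction model with the five two-way cross-scale products gates a
main-effects model; unique contributions are squared partial correlations,
and predictor significance comes from spinning the response map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import ParcelVector
from .spatialnull import SpinEnsemble

PREDICTORS = ("strength", "opc", "pls1", "pls2")
INTERACTIONS = (
    ("strength", "opc"),
    ("strength", "pls1"),
    ("strength", "pls2"),
    ("opc", "pls1"),
    ("opc", "pls2"),
)


@dataclass
class DesignTable:
    """Z-scored response and predictors with explicit missingness flags.

    Columns are z-scored over their non-missing parcels first; missing
    cells are then zero-filled (i.e. set to the column mean) and recorded
    in ``missing``.
    """

    data: pd.DataFrame  # index parcel_id; columns sqrt_frequency + PREDICTORS
    missing: pd.DataFrame  # same shape, True where a cell was zero-filled

    @property
    def response(self) -> np.ndarray:
        return self.data["sqrt_frequency"].to_numpy()

    def predictors(self) -> np.ndarray:
        return self.data[list(PREDICTORS)].to_numpy()


def _zscore_with_nan(v: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(v)
    if ok.sum() < 2 or np.nanstd(v) == 0:
        raise ValueError("degenerate column: constant or nearly all missing")
    out = np.full_like(v, np.nan, dtype=float)
    out[ok] = (v[ok] - v[ok].mean()) / v[ok].std(ddof=1)
    return out


def assemble_design(
    freq: ParcelVector,
    strength: ParcelVector,
    opc: ParcelVector,
    pls1: ParcelVector,
    pls2: ParcelVector,
) -> DesignTable:
    """Align all vectors on the frequency map's parcel index and z-score.

    The response is the z-scored square root of tumour frequency.  Parcels
    where a predictor could not be computed (e.g. subcortical parcels for
    the OPC score) are zero-filled after z-scoring and flagged.
    """
    ids = np.asarray(freq.ids)
    cols = {
        "sqrt_frequency": np.sqrt(np.maximum(freq.values, 0.0)),
        "strength": strength.align_to(ids).values,
        "opc": opc.align_to(ids).values,
        "pls1": pls1.align_to(ids).values,
        "pls2": pls2.align_to(ids).values,
    }
    data, missing = {}, {}
    for name, v in cols.items():
        z = _zscore_with_nan(np.asarray(v, dtype=float))
        miss = np.isnan(z)
        data[name] = np.where(miss, 0.0, z)
        missing[name] = miss
    idx = pd.Index(ids, name="parcel_id")
    return DesignTable(pd.DataFrame(data, index=idx), pd.DataFrame(missing, index=idx))


@dataclass
class ModelFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    interactions: bool
    partial_r2: pd.Series | None = None
    spin_p: pd.Series | None = None
    spin_correction: str = ""

    def table(self) -> pd.DataFrame:
        """Regression-table export (predictor, beta, SE, t, % variance, p_spin)."""
        rows = []
        for term in self.params.index:
            rows.append({
                "predictor": term,
                "beta": self.params[term],
                "se": self.bse[term],
                "t": self.tvalues[term],
                "pct_explained_variance": (
                    100 * self.partial_r2[term]
                    if self.partial_r2 is not None and term in self.partial_r2.index
                    else np.nan
                ),
                "p_spin_corrected": (
                    self.spin_p[term]
                    if self.spin_p is not None and term in self.spin_p.index
                    else np.nan
                ),
            })
        return pd.DataFrame(rows).set_index("predictor")


class CollinearityError(ValueError):
    pass


def _design_matrix(d: DesignTable, interactions: bool) -> pd.DataFrame:
    X = d.data[list(PREDICTORS)].copy()
    if interactions:
        for a, b in INTERACTIONS:
            X[f"{a}:{b}"] = d.data[a] * d.data[b]
    return sm.add_constant(X, prepend=True)


def fit_glioma_model(d: DesignTable, interactions: bool = False) -> ModelFit:
    """Ordinary least squares of sqrt tumour frequency on the predictors.

    With ``interactions=True`` the five two-way cross-scale products are
    added.  Raises :class:`CollinearityError` naming the offending columns
    when the design is rank deficient.
    """
    X = _design_matrix(d, interactions)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = [
            c for c in X.columns if c != "const"
            and np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise CollinearityError(f"rank-deficient design; offending columns: {bad}")
    res = sm.OLS(d.response, X).fit()
    fit = ModelFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_statistic=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        interactions=interactions,
    )
    if not interactions:
        fit.partial_r2 = pd.Series(partial_variance(d, fit)) / 100.0
    return fit


def significant_interactions(fit: ModelFit, alpha: float = 0.05) -> list[str]:
    """Interaction terms with p < alpha (uncorrected), the model-selection gate."""
    if not fit.interactions:
        return []
    terms = [f"{a}:{b}" for a, b in INTERACTIONS]
    return [t for t in terms if fit.pvalues[t] < alpha]


def _partial_r2_single(y: np.ndarray, x: np.ndarray, others: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(y)), others])
    proj = A @ np.linalg.lstsq(A, np.column_stack([y, x]), rcond=None)[0]
    ry = y - proj[:, 0]
    rx = x - proj[:, 1]
    return float(np.corrcoef(ry, rx)[0, 1] ** 2)


def partial_variance(d: DesignTable, fit: ModelFit | None = None) -> dict[str, float]:
    """Squared partial correlation of each predictor with the response, x100."""
    y = d.response
    X = d.predictors()
    out = {}
    for i, name in enumerate(PREDICTORS):
        others = np.delete(X, i, axis=1)
        out[name] = 100.0 * _partial_r2_single(y, X[:, i], others)
    return out


def predictor_spin_pvalues(
    d: DesignTable,
    ens: SpinEnsemble,
    correction: str = "bonferroni",
) -> pd.Series:
    """Spin significance of each predictor's partial explained variance.

    The null spins the response map (spatially contiguous null models of
    tumour frequency) and recomputes every predictor's partial R^2; p-values
    are Bonferroni-corrected across the four predictors by default
    (``correction='none'`` disables it).
    """
    ids = d.data.index.to_numpy()
    if not np.array_equal(np.sort(ids), np.sort(ens.ids)):
        raise ValueError("spin ensemble and design table cover different parcels")
    order = pd.Index(ens.ids).get_indexer(ids)
    y = d.response
    X = d.predictors()
    n = len(y)

    observed = {name: v / 100.0 for name, v in partial_variance(d).items()}

    # residualize each predictor (and the spun responses) on the other three
    y_spun_all = y[order][ens.permutations]  # n_spins x n, in ens order
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    y_spun_all = y_spun_all[:, inv]  # back to design order

    counts = {}
    for i, name in enumerate(PREDICTORS):
        others = np.delete(X, i, axis=1)
        A = np.column_stack([np.ones(n), others])
        Q, _ = np.linalg.qr(A)
        resid = lambda M: M - Q @ (Q.T @ M)
        rx = resid(X[:, i])
        rx = rx / np.linalg.norm(rx)
        rys = resid(y_spun_all.T)  # n x n_spins
        norms = np.linalg.norm(rys, axis=0)
        r2 = (rx @ rys / np.where(norms == 0, np.inf, norms)) ** 2
        counts[name] = int(np.sum(r2 >= observed[name]))

    k = len(PREDICTORS)
    ps = {}
    for name in PREDICTORS:
        p = (1 + counts[name]) / (1 + ens.n_spins)
        if correction == "bonferroni":
            p = min(1.0, k * p)
        elif correction != "none":
            raise ValueError("correction must be 'bonferroni' or 'none'")
        ps[name] = p
    return pd.Series(ps, name=f"p_spin_{correction}")
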