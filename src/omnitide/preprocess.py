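"""Normalization, filtering, imputation and time-course differential selection.

The differential-selection strategy is a two-step polynomial regression over
the timepoint index grid: step 1 fits a global polynomial model per feature
and screens by the F-test of the full model against an intercept-only model
(BH-adjusted within the layer); step 2 applies backward elimination of
polynomial terms and reports the coefficient of determination of the
retained model. A feature is called differential when

    adj_p <= alpha  AND  r_squared >= r2_min  AND  max|log2FC| >= lfc_min

with log2 fold changes taken per timepoint relative to the control (t0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .omics import OmicsMatrix

logger = logging.getLogger(__name__)

_EPS_TSS = 1e-12


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """NaN-aware quantile normalization across sample columns."""
    grid = np.linspace(0.0, 1.0, min(1001, max(df.shape[0], 2)))
    col_quant = np.array([np.nanquantile(df[c].to_numpy(), grid) for c in df.columns])
    ref = col_quant.mean(axis=0)
    ranks = df.rank(method="average")
    counts = df.notna().sum(axis=0)
    out = df.copy()
    for c in df.columns:
        q = (ranks[c].to_numpy() - 0.5) / counts[c]
        vals = np.interp(q, grid, ref)
        vals[np.isnan(q)] = np.nan
        out[c] = vals
    return out


def _impute_half_minimum(df: pd.DataFrame) -> pd.DataFrame:
    """Half-minimum on the linear scale: log2(x/2) = log2(x) - 1."""
    fill = df.min(axis=1) - 1.0
    return df.apply(lambda row: row.fillna(fill[row.name]), axis=1)


def _impute_lls(df: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Local least squares: regress each incomplete feature on its k most
    correlated complete features and predict the missing entries."""
    complete = df.dropna(axis=0)
    incomplete_idx = df.index[df.isna().any(axis=1)]
    if len(complete) < max(k, 2):
        logger.warning(
            "LLS imputation: only %d complete features (< k=%d); "
            "falling back to half-minimum",
            len(complete),
            k,
        )
        return _impute_half_minimum(df)
    out = df.copy()
    comp_arr = complete.to_numpy()
    for fid in incomplete_idx:
        row = df.loc[fid].to_numpy(dtype=float)
        obs = ~np.isnan(row)
        if obs.sum() < 3:
            out.loc[fid] = pd.Series(row, index=df.columns).fillna(
                np.nanmin(row) - 1.0
            )
            continue
        y = row[obs]
        with np.errstate(invalid="ignore", divide="ignore"):
            sub = comp_arr[:, obs]
            sub_c = sub - sub.mean(axis=1, keepdims=True)
            y_c = y - y.mean()
            denom = np.sqrt((sub_c**2).sum(axis=1) * (y_c**2).sum())
            corr = np.where(denom > 0, (sub_c * y_c).sum(axis=1) / denom, 0.0)
        top = np.argsort(-np.abs(corr))[:k]
        X_obs = np.column_stack([np.ones(obs.sum()), comp_arr[top][:, obs].T])
        beta, *_ = np.linalg.lstsq(X_obs, y, rcond=None)
        X_mis = np.column_stack(
            [np.ones((~obs).sum()), comp_arr[top][:, ~obs].T]
        )
        row[~obs] = X_mis @ beta
        out.loc[fid] = row
    return out


def _mask_replicate_outliers(matrix: OmicsMatrix) -> pd.DataFrame:
    """Mask entries deviating >= 1 SD from their replicate mean (per
    feature and timepoint); the metabolomics outlier rule."""
    df = matrix.values.copy()
    for t in matrix.timepoints:
        cols = matrix.columns_at(int(t))
        block = df[cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        dev = block.sub(mu, axis=0).abs()
        mask = dev.ge(sd, axis=0) & (sd > 0).to_numpy()[:, None]
        df[cols] = block.mask(mask)
    return df


def preprocess(
    matrix: OmicsMatrix,
    min_valid_fraction: float = 0.70,
    impute_method: str = "lls",
    quantile_normalize: bool = False,
    zero_center: bool = False,
    metab_sd_outlier: bool = False,
    lls_k: int = 10,
) -> OmicsMatrix:
    """Filter, impute and normalize one layer.

    Features with fewer than ``min_valid_fraction`` valid values are removed;
    remaining missing entries are imputed (``"lls"`` or ``"half_minimum"``).
    ``zero_center`` subtracts the per-feature mean within each replicate
    block (batch removal for a balanced plex-per-replicate design).
    """
    if impute_method not in ("lls", "half_minimum"):
        raise ValueError(f"unknown impute_method {impute_method!r}")
    df = matrix.values
    n = df.shape[1]
    valid = df.notna().sum(axis=1) / n
    df = df.loc[valid >= min_valid_fraction]
    df = df.loc[df.notna().any(axis=1)]  # all-missing is dropped, never imputed
    m = OmicsMatrix(matrix.layer, df.copy(), matrix.sample_meta.copy())

    if quantile_normalize:
        m.values = _quantile_normalize(m.values)
    if metab_sd_outlier:
        m.values = _mask_replicate_outliers(m)
        m.values = m.values.loc[m.values.notna().any(axis=1)]
    if m.values.isna().any().any():
        if impute_method == "lls":
            m.values = _impute_lls(m.values, k=lls_k)
        else:
            m.values = _impute_half_minimum(m.values)
    if zero_center:
        for _, cols in m.replicate_blocks().items():
            block = m.values[cols]
            m.values[cols] = block.sub(block.mean(axis=1), axis=0)
    return OmicsMatrix(m.layer, m.values, m.sample_meta)


# ---------------------------------------------------------------------------
# log2 fold-change profiles
# ---------------------------------------------------------------------------


def log2fc_profile(matrix: OmicsMatrix, reference_timepoint: int = 0) -> pd.DataFrame:
    """Feature x (T-1) table of log2FC vs the reference timepoint.

    Entry (v, t) is the replicate-mean log2 intensity at timepoint t minus
    the replicate mean at the reference — i.e. the log2 ratio of geometric
    means on the linear scale.
    """
    means = matrix.timepoint_means()
    if reference_timepoint not in means.columns:
        raise ValueError(f"reference timepoint {reference_timepoint} absent")
    lfc = means.sub(means[reference_timepoint], axis=0)
    lfc = lfc.drop(columns=[reference_timepoint])
    lfc.columns = [f"t{int(c)}" for c in lfc.columns]
    return lfc


# ---------------------------------------------------------------------------
# two-step differential selection
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    """Per-feature time-course differential statistics for one layer."""

    layer: str
    table: pd.DataFrame  # F_statistic, p_value, adj_p, r_squared, max_abs_log2fc, selected
    lfc: pd.DataFrame  # feature x t1..t{T-1} log2FC profile

    @property
    def selected_features(self) -> pd.Index:
        return self.table.index[self.table["selected"]]

    def to_tsv(self, path) -> None:
        self.table.join(self.lfc).to_csv(path, sep="\t", index_label="feature")


def _poly_design(time_idx: np.ndarray, terms: tuple[int, ...]) -> np.ndarray:
    cols = [np.ones_like(time_idx, dtype=float)]
    cols += [time_idx.astype(float) ** d for d in terms]
    return np.column_stack(cols)


def _fit_group(Y: np.ndarray, X: np.ndarray):
    """OLS of every row of Y on X. Returns (beta, rss, se) with shapes
    (n_feat, p), (n_feat,), (n_feat, p)."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T
    resid = Y - beta @ X.T
    rss = (resid**2).sum(axis=1)
    dof = n - p
    xtx_inv_diag = np.diag(pinv @ pinv.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = np.where(dof > 0, rss / max(dof, 1), np.inf)
    se = np.sqrt(np.outer(sigma2, xtx_inv_diag))
    return beta, rss, se, dof


def select_differential(
    matrix: OmicsMatrix,
    degree: int = 3,
    alpha: float = 0.05,
    r2_min: float = 0.6,
    lfc_min: float = 1.0,
    term_alpha: float | None = None,
    reference_timepoint: int = 0,
) -> DEResult:
    """Two-step time-course regression with BH control within the layer.

    Step 1 screens by the F-test of the degree-``degree`` polynomial model
    (time on the index grid) against the intercept-only model. Step 2
    performs backward elimination of polynomial terms at per-term
    ``term_alpha`` and reports the retained model's R². Features are
    ``selected`` per the triple-threshold rule.
    """
    tps = matrix.timepoints
    if len(tps) < degree + 2:
        raise ValueError(
            f"need >= degree+2 distinct timepoints ({degree + 2}), got {len(tps)}"
        )
    if term_alpha is None:
        term_alpha = alpha
    Y = matrix.values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("matrix has missing values; run preprocess first")
    time_idx = matrix.sample_meta["timepoint"].to_numpy(dtype=float)
    n_feat, n = Y.shape

    # step 1: global F-screen, full polynomial vs intercept
    full_terms = tuple(range(1, degree + 1))
    X_full = _poly_design(time_idx, full_terms)
    _, rss_full, _, dof_full = _fit_group(Y, X_full)
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    flat = tss <= _EPS_TSS
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((tss - rss_full) / degree) / (rss_full / dof_full)
    pvals = np.where(
        flat,
        1.0,
        np.where(rss_full <= _EPS_TSS, 0.0, stats.f.sf(F, degree, dof_full)),
    )
    pvals = np.clip(pvals, 0.0, 1.0)
    F = np.where(flat, 0.0, F)
    adj_p = multipletests(pvals, method="fdr_bh")[1]

    # step 2: backward elimination, grouped by identical active term sets
    r2 = np.zeros(n_feat)
    active: dict[tuple[int, ...], np.ndarray] = {
        full_terms: np.flatnonzero(~flat)
    }
    final_groups: list[tuple[tuple[int, ...], np.ndarray]] = []
    while active:
        terms, idx = active.popitem()
        if len(idx) == 0:
            continue
        if not terms:
            final_groups.append((terms, idx))
            continue
        X = _poly_design(time_idx, terms)
        _, rss, se, dof = _fit_group(Y[idx], X)
        beta = Y[idx] @ np.linalg.pinv(X).T
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = np.abs(beta[:, 1:]) / se[:, 1:]
        # exact fits: se == 0 -> term infinitely significant
        tstat = np.where(np.isnan(tstat), np.inf, tstat)
        pt = 2.0 * stats.t.sf(tstat, max(dof, 1))
        worst = np.argmax(pt, axis=1)
        worst_p = pt[np.arange(len(idx)), worst]
        done = worst_p <= term_alpha
        final_groups.append((terms, idx[done]))
        for j in np.flatnonzero(~done):
            new_terms = tuple(t for i, t in enumerate(terms) if i != worst[j])
            key = new_terms
            active.setdefault(key, np.empty(0, dtype=int))
            active[key] = np.append(active[key], idx[j])
    for terms, idx in final_groups:
        if len(idx) == 0:
            continue
        if not terms:
            r2[idx] = 0.0
            continue
        X = _poly_design(time_idx, terms)
        _, rss, _, _ = _fit_group(Y[idx], X)
        r2[idx] = 1.0 - rss / tss[idx]
    r2 = np.clip(r2, 0.0, 1.0)
    r2[flat] = 0.0

    lfc = log2fc_profile(matrix, reference_timepoint)
    max_abs_lfc = lfc.abs().max(axis=1).to_numpy()
    selected = (adj_p <= alpha) & (r2 >= r2_min) & (max_abs_lfc >= lfc_min)

    table = pd.DataFrame(
        {
            "F_statistic": F,
            "p_value": pvals,
            "adj_p": adj_p,
            "r_squared": r2,
            "max_abs_log2fc": max_abs_lfc,
            "selected": selected,
        },
        index=matrix.feature_ids,
    )
    return DEResult(matrix.layer, table, lfc)
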