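"""Cross-layer coupling: configuration matrices, RV and partial-RV
coefficients, a PC-style skeleton over layers, and per-gene / per-timepoint
fold-change agreement statistics.

Each layer's sample-space geometry is summarized by the configuration matrix
S = X Xᵀ (samples x samples, features mean-centered), and the similarity of
two layers by the RV coefficient

    RV(S_i, S_j) = vec(S_i)ᵀ vec(S_j) / sqrt(vec(S_i)ᵀvec(S_i) · vec(S_j)ᵀvec(S_j)),

which lies in [0, 1] for positive semidefinite inputs. Partial RV applies the
recursive partial-correlation formula to the matrix of RV coefficients.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ConfigurationMatrix:
    layer: str
    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("configuration matrix must be square")
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("configuration matrix must be symmetric")
        self.S = S


def configuration_matrix(
    X, layer: str = "", center: bool = True
) -> ConfigurationMatrix:
    """S = X Xᵀ with samples as rows; columns (features) mean-centered.

    Centering is on by default: the uncentered product is dominated by mean
    intensities. Pass ``center=False`` for the exact-formula variant.
    """
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 sample rows")
    if np.isnan(A).any():
        raise ValueError("matrix has missing values; preprocess first")
    if center:
        A = A - A.mean(axis=0, keepdims=True)
    return ConfigurationMatrix(layer, A @ A.T)


def rv_coefficient(S_i, S_j) -> float:
    """RV matrix correlation of two equally sized configuration matrices."""
    A = S_i.S if isinstance(S_i, ConfigurationMatrix) else np.asarray(S_i, float)
    B = S_j.S if isinstance(S_j, ConfigurationMatrix) else np.asarray(S_j, float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    na, nb = np.sqrt((A * A).sum()), np.sqrt((B * B).sum())
    if na == 0.0 or nb == 0.0:
        raise ValueError("RV undefined for a zero configuration matrix")
    return float((A * B).sum() / (na * nb))


def rv_matrix(configs: dict[str, ConfigurationMatrix]) -> pd.DataFrame:
    """Symmetric layer x layer RV coefficient table with unit diagonal."""
    names = sorted(configs)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        v = rv_coefficient(configs[a], configs[b])
        out.loc[a, b] = out.loc[b, a] = v
    return out


def _as_corr_frame(m) -> pd.DataFrame:
    df = pd.DataFrame(m) if not isinstance(m, pd.DataFrame) else m
    if df.shape[0] != df.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.diag(df.to_numpy(dtype=float)), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    return df


def partial_rv(rv_mat, i, j, conditioning_set=()) -> float:
    """Partial matrix correlation of layers i and j given a conditioning set.

    Applies the first-order recursion
        r_ij.k = (r_ij - r_ik r_jk) / sqrt((1 - r_ik^2)(1 - r_jk^2))
    recursing over the conditioning set in sorted order; the empty set
    returns the marginal RV unchanged.
    """
    df = _as_corr_frame(rv_mat)
    cond = sorted(set(conditioning_set) - {i, j})

    def rec(a, b, rest: tuple) -> float:
        if not rest:
            return float(df.loc[a, b])
        k = rest[-1]
        head = rest[:-1]
        r_ab = rec(a, b, head)
        r_ak = rec(a, k, head)
        r_bk = rec(b, k, head)
        denom_sq = (1.0 - r_ak**2) * (1.0 - r_bk**2)
        if denom_sq <= 1e-15:
            raise ValueError(
                f"degenerate conditioning: |r| = 1 involving {k!r}"
            )
        return (r_ab - r_ak * r_bk) / np.sqrt(denom_sq)

    return float(rec(i, j, tuple(cond)))


def topology_skeleton(rv_mat, epsilon: float, max_cond: int = 2) -> nx.Graph:
    """PC-algorithm skeleton phase over the layer RV matrix.

    Starting from the complete graph, for conditioning-set sizes 0, 1, ...,
    ``max_cond``, edge (i, j) is removed whenever some conditioning set drawn
    from the current neighbors of i or j gives |partial RV| < epsilon.
    Deterministic given sorted node order; no edge orientation is attempted.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    df = _as_corr_frame(rv_mat)
    nodes = sorted(df.index)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(itertools.combinations(nodes, 2))
    for order in range(0, max_cond + 1):
        for i, j in sorted(g.edges()):
            neighbors = sorted((set(g[i]) | set(g[j])) - {i, j})
            if len(neighbors) < order:
                continue
            for S in itertools.combinations(neighbors, order):
                try:
                    pr = partial_rv(df, i, j, S)
                except ValueError:
                    continue
                if abs(pr) < epsilon:
                    g.remove_edge(i, j)
                    break
    return g


def per_timepoint_r2(lfc_A: pd.DataFrame, lfc_B: pd.DataFrame) -> pd.Series:
    """Adjusted R² of the per-timepoint regression of layer-B log2FC on
    layer-A log2FC over shared genes: 1 - (1 - R²)(n - 1)/(n - 2)."""
    shared = lfc_A.index.intersection(lfc_B.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, have {len(shared)}")
    cols = [c for c in lfc_A.columns if c in set(lfc_B.columns)]
    out = {}
    for c in cols:
        x = lfc_A.loc[shared, c].to_numpy(dtype=float)
        y = lfc_B.loc[shared, c].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        n = len(x)
        if n < 3:
            out[c] = np.nan
            continue
        if np.var(x) == 0.0:
            raise ValueError(f"zero variance in predictor at {c}")
        r = np.corrcoef(x, y)[0, 1]
        r2 = r * r
        out[c] = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return pd.Series(out)


def pairwise_gene_pcc(lfc_A: pd.DataFrame, lfc_B: pd.DataFrame) -> pd.Series:
    """Per-gene Pearson correlation of the two layers' log2FC profiles.

    Genes with a zero-variance profile in either layer are returned as NaN
    (flagged, with a logged count) and must be excluded downstream.
    """
    shared = lfc_A.index.intersection(lfc_B.index)
    cols = [c for c in lfc_A.columns if c in set(lfc_B.columns)]
    if len(cols) < 3:
        raise ValueError("need >= 3 common timepoints")
    a = lfc_A.loc[shared, cols].to_numpy(dtype=float)
    b = lfc_B.loc[shared, cols].to_numpy(dtype=float)
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    va = (a_c**2).sum(axis=1)
    vb = (b_c**2).sum(axis=1)
    denom = np.sqrt(va * vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a_c * b_c).sum(axis=1) / denom, np.nan)
    n_na = int(np.isnan(r).sum())
    if n_na:
        logger.info("pairwise_gene_pcc: %d zero-variance profiles flagged NA", n_na)
    return pd.Series(np.clip(r, -1.0, 1.0), index=shared)
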