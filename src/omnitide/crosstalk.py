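"""Ligand-receptor crosstalk from secretome and surfaceome layers.

Regulated pairs: a curated L-R database is intersected with ligands measured
in the secretome (SEC) and receptors in the membrane (MEM) or N-glyco
surfaceome (GLYCO) layer; both partners must be confidently measured
(p < p_max), and the combined per-timepoint fold change

    C = L_log2FC + R_log2FC

must reach |C| >= c_min at one or more timepoints (sign giving direction).
Cluster-level communication scores a pair between sender cluster x and
receiver cluster y as mean ligand expression in x times mean receptor
expression in y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class LRPairRecord:
    ligand: str
    receptor: str
    receptor_layer: str
    ligand_lfc: pd.Series
    receptor_lfc: pd.Series
    combined: pd.Series
    ligand_p: float
    receptor_p: float
    direction: pd.Series  # 'up' / 'down' / 'none' per timepoint
    regulated: bool


def de_stats(de_result) -> pd.DataFrame:
    """Flatten a DEResult into the stats table this module consumes:
    per-feature ``p_value`` plus per-timepoint log2FC columns."""
    return de_result.lfc.join(de_result.table[["p_value"]])


def _direction(combined: pd.Series, c_min: float) -> pd.Series:
    return pd.Series(
        np.where(combined >= c_min, "up", np.where(combined <= -c_min, "down", "none")),
        index=combined.index,
    )


def find_regulated_lr(
    sec_stats: pd.DataFrame,
    mem_stats: pd.DataFrame,
    lr_db,
    glyco_stats: pd.DataFrame | None = None,
    p_max: float = 0.01,
    c_min: float = 1.0,
    codirectional: bool = False,
) -> list[LRPairRecord]:
    """Regulated L-R pairs from the SEC (ligand) and MEM/GLYCO (receptor)
    stats tables.

    A receptor present in both MEM and GLYCO is taken from the layer with the
    smaller p-value (ties broken by layer name). With ``codirectional`` set,
    a timepoint only counts when sign(L) == sign(R) there.
    """
    lfc_cols = [c for c in sec_stats.columns if c.startswith("t")]
    db = list(dict.fromkeys((str(l), str(r)) for l, r in lr_db))  # dedupe, keep order
    rec_layers = {"MEM": mem_stats}
    if glyco_stats is not None:
        rec_layers["GLYCO"] = glyco_stats
    out: list[LRPairRecord] = []
    n_skipped = 0
    for lig, rec in sorted(db):
        if lig not in sec_stats.index:
            n_skipped += 1
            continue
        candidates = [
            (float(tbl.loc[rec, "p_value"]), name)
            for name, tbl in sorted(rec_layers.items())
            if rec in tbl.index
        ]
        if not candidates:
            n_skipped += 1
            continue
        rec_p, rec_layer = min(candidates)
        lig_p = float(sec_stats.loc[lig, "p_value"])
        if lig_p >= p_max or rec_p >= p_max:
            continue
        l_lfc = sec_stats.loc[lig, lfc_cols].astype(float)
        r_lfc = rec_layers[rec_layer].loc[rec, lfc_cols].astype(float)
        combined = l_lfc + r_lfc
        direction = _direction(combined, c_min)
        if codirectional:
            same_sign = np.sign(l_lfc) == np.sign(r_lfc)
            direction = direction.where(same_sign, "none")
        regulated = bool((direction != "none").any())
        rec_obj = LRPairRecord(
            lig, rec, rec_layer, l_lfc, r_lfc, combined, lig_p, rec_p, direction, regulated
        )
        if regulated:
            out.append(rec_obj)
    if n_skipped:
        logger.info("find_regulated_lr: %d db pairs not measured in the "
                    "expected layers", n_skipped)
    return out


def score_cluster_crosstalk(
    pairs: list[LRPairRecord] | list[tuple[str, str]],
    clusters: pd.DataFrame,
) -> pd.DataFrame:
    """Communication score for every (pair, sender, receiver) combination.

    ``clusters`` is a cluster x gene table of mean expression. The score is
    bilinear: meanL(sender) * meanR(receiver), over all ordered cluster pairs
    including sender == receiver. Returns a ranked DataFrame.
    """
    if clusters.empty:
        raise ValueError("empty cluster expression table")
    rows = []
    genes = set(clusters.columns)
    n_skipped = 0
    for p in pairs:
        lig, rec = (p.ligand, p.receptor) if isinstance(p, LRPairRecord) else p
        if lig not in genes or rec not in genes:
            n_skipped += 1
            continue
        for sender in clusters.index:
            for receiver in clusters.index:
                score = float(clusters.loc[sender, lig] * clusters.loc[receiver, rec])
                rows.append(
                    {
                        "ligand": lig,
                        "receptor": rec,
                        "sender": sender,
                        "receiver": receiver,
                        "score": score,
                    }
                )
    if n_skipped:
        logger.info("score_cluster_crosstalk: %d pairs absent from the "
                    "cluster table", n_skipped)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["score", "ligand", "receptor", "sender", "receiver"],
            ascending=[False, True, True, True, True],
        ).reset_index(drop=True)
    return df


def lr_cooccurrence_pcc(
    expression: pd.DataFrame, pairs
) -> pd.DataFrame:
    """Pearson correlation of ligand and receptor expression across samples
    (rows = samples, columns = genes); a generic cohort-style validation."""
    if expression.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    rows = []
    for p in pairs:
        lig, rec = (p.ligand, p.receptor) if isinstance(p, LRPairRecord) else p
        if lig not in expression.columns or rec not in expression.columns:
            continue
        x = expression[lig].to_numpy(dtype=float)
        y = expression[rec].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            raise ValueError(f"zero variance for pair ({lig}, {rec})")
        rows.append({"ligand": lig, "receptor": rec,
                     "pcc": float(np.corrcoef(x, y)[0, 1])})
    return pd.DataFrame(rows)
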