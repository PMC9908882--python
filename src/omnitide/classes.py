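"""Regulatory gene classes, cross-layer concordance, and kinase activity.

Genes quantified in at least two proteomic layers are assigned to one of
three regulatory classes from the Pearson correlations (PCC) of their
cross-layer log2FC profiles:

* Class I     — consistently correlated: every layer pair has r >= 0.4,
                regulation at or before translation;
* Class II-B  — anticorrelated: some layer pair has r <= -0.4, active
                post-translational control;
* Class II-A  — neither: uncorrelated profiles.

The anticorrelation test takes precedence, so one strong negative pair is
never masked by several positive ones.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import pairwise_gene_pcc

logger = logging.getLogger(__name__)

CLASS_I = "I"
CLASS_IIA = "II-A"
CLASS_IIB = "II-B"


@dataclass
class GeneClassRecord:
    gene: str
    pcc_by_pair: dict[tuple[str, str], float]
    label: str

    @property
    def n_layer_pairs(self) -> int:
        return len(self.pcc_by_pair)


def assign_class(pcc_by_pair, r_high: float = 0.4, r_low: float = -0.4) -> str:
    """Class label from a collection of layer-pair PCCs.

    NaN PCCs (zero-variance profiles) are excluded; if nothing finite
    remains the gene is unclassifiable and a ValueError is raised.
    """
    vals = (
        list(pcc_by_pair.values()) if isinstance(pcc_by_pair, dict) else list(pcc_by_pair)
    )
    finite = [v for v in vals if v is not None and not math.isnan(v)]
    if not finite:
        raise ValueError("all PCCs are NA; gene unclassifiable")
    if any(v <= r_low for v in finite):
        return CLASS_IIB
    if all(v >= r_high for v in finite):
        return CLASS_I
    return CLASS_IIA


def classify_genes(
    lfc_by_layer: dict[str, pd.DataFrame],
    proteomic_layers=None,
    min_layers: int = 2,
    r_high: float = 0.4,
    r_low: float = -0.4,
) -> pd.DataFrame:
    """Assign a class to every gene present in >= ``min_layers`` proteomic
    layers. Returns a frame indexed by gene with columns ``class`` and
    ``n_layer_pairs``."""
    layers = sorted(proteomic_layers) if proteomic_layers else sorted(lfc_by_layer)
    pcc_store: dict[str, dict[tuple[str, str], float]] = {}
    for a, b in itertools.combinations(layers, 2):
        if a not in lfc_by_layer or b not in lfc_by_layer:
            continue
        shared = lfc_by_layer[a].index.intersection(lfc_by_layer[b].index)
        if len(shared) == 0:
            continue
        pcc = pairwise_gene_pcc(lfc_by_layer[a], lfc_by_layer[b])
        for g, r in pcc.items():
            pcc_store.setdefault(g, {})[(a, b)] = r
    rows = {}
    n_unclassified = 0
    for g, pairs in pcc_store.items():
        finite = {k: v for k, v in pairs.items() if not math.isnan(v)}
        # membership in >= min_layers layers, judged from the pairs seen
        layers_of_g = set(itertools.chain.from_iterable(pairs))
        if len(layers_of_g) < min_layers or not finite:
            n_unclassified += 1
            continue
        rows[g] = {
            "class": assign_class(finite, r_high, r_low),
            "n_layer_pairs": len(finite),
        }
    if n_unclassified:
        logger.info("classify_genes: %d genes left unclassified", n_unclassified)
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def class_persistence(classes_A: pd.Series, classes_B: pd.Series) -> dict:
    """Fraction of shared genes keeping the same class label in two datasets,
    overall and per class of A."""
    shared = classes_A.index.intersection(classes_B.index)
    if len(shared) == 0:
        raise ValueError("no shared classified genes")
    a = classes_A.loc[shared]
    b = classes_B.loc[shared]
    same = a == b
    per_class = {
        cls: float(same[a == cls].mean()) for cls in sorted(a.unique())
    }
    return {
        "overall": float(same.mean()),
        "per_class": per_class,
        "n_shared": int(len(shared)),
    }


def concordance_fraction(
    de_genes, pcc_vs_reference: pd.Series, r_cut: float = 0.1, count_na: bool = False
) -> float:
    """Fraction of differential genes whose PCC against the reference layer
    is <= ``r_cut`` (i.e. no corresponding alteration in the reference).

    NaN PCCs are excluded from the denominator unless ``count_na`` is set,
    in which case they count as discordant (no measurable agreement).
    """
    genes = [g for g in de_genes if g in pcc_vs_reference.index]
    if not genes:
        raise ValueError("empty differential gene set (or none overlap reference)")
    vals = pcc_vs_reference.loc[genes]
    if count_na:
        return float(((vals <= r_cut) | vals.isna()).mean())
    vals = vals.dropna()
    if len(vals) == 0:
        raise ValueError("all PCCs NA")
    return float((vals <= r_cut).mean())


def protein_phospho_concordance(
    psite_lfc: pd.DataFrame,
    protein_lfc: pd.DataFrame,
    site_to_protein: dict[str, str] | None = None,
    poor_cut: float = 0.4,
    opposite_cut: float = -0.1,
) -> dict:
    """Per-phosphosite PCC against the parent protein's log2FC profile.

    Sites whose parent protein is absent from the protein layer are excluded
    with a logged count. Returns the per-site PCC series plus the fractions
    below the two cutoffs (poor correlation r < poor_cut; opposite direction
    r <= opposite_cut).
    """
    if site_to_protein is None:
        site_to_protein = {s: str(s).rsplit("_S", 1)[0] for s in psite_lfc.index}
    cols = [c for c in psite_lfc.columns if c in set(protein_lfc.columns)]
    prot_set = set(protein_lfc.index)
    records = {}
    n_unmapped = 0
    for site in psite_lfc.index:
        parent = site_to_protein.get(site)
        if parent is None or parent not in prot_set:
            n_unmapped += 1
            continue
        x = psite_lfc.loc[site, cols].to_numpy(dtype=float)
        y = protein_lfc.loc[parent, cols].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            records[site] = np.nan
            continue
        records[site] = float(np.corrcoef(x, y)[0, 1])
    if n_unmapped:
        logger.info(
            "protein_phospho_concordance: %d unmapped sites excluded", n_unmapped
        )
    pcc = pd.Series(records, dtype=float)
    finite = pcc.dropna()
    return {
        "pcc": pcc,
        "fraction_poor": float((finite < poor_cut).mean()) if len(finite) else np.nan,
        "fraction_opposite": float((finite <= opposite_cut).mean())
        if len(finite)
        else np.nan,
        "n_sites": int(len(finite)),
        "n_unmapped": n_unmapped,
    }


@dataclass
class KinaseActivity:
    kinase: str
    z_by_timepoint: pd.Series
    n_substrates: int
    stage_sums: dict[str, float] = field(default_factory=dict)


def kinase_activity(
    psite_lfc: pd.DataFrame,
    kinase_substrate_map: dict[str, list[str]],
    m_min: int = 3,
    stage_bins: dict[str, tuple[int, ...]] | None = None,
) -> list[KinaseActivity]:
    """KSEA-style mean-enrichment z-scores per kinase and timepoint.

        z = (mean(substrate lfc) - mean(all lfc)) * sqrt(m) / sd(all lfc)

    computed against the background of all regulated-site fold changes at
    that timepoint; kinases with fewer than ``m_min`` mapped substrates are
    skipped. Stage activity is the sum of |z| over each stage's timepoint
    bin (default: E = {t1, t2}, E/M = {t3, t4, t5}, M = {t6..t9}).
    """
    if stage_bins is None:
        from .synthetic import STAGE_BINS

        stage_bins = STAGE_BINS
    bg = psite_lfc.to_numpy(dtype=float)
    col_mean = np.nanmean(bg, axis=0)
    col_sd = np.nanstd(bg, axis=0, ddof=1)
    if np.any(col_sd == 0.0):
        raise ValueError("background sd is zero at some timepoint")
    site_index = set(psite_lfc.index)
    out: list[KinaseActivity] = []
    for kinase in sorted(kinase_substrate_map):
        subs = [s for s in kinase_substrate_map[kinase] if s in site_index]
        m = len(subs)
        if m < m_min:
            continue
        sub_mean = psite_lfc.loc[subs].mean(axis=0).to_numpy(dtype=float)
        z = (sub_mean - col_mean) * np.sqrt(m) / col_sd
        z_ser = pd.Series(z, index=psite_lfc.columns)
        sums = {}
        for stage, tps in stage_bins.items():
            cols = [f"t{t}" for t in tps if f"t{t}" in z_ser.index]
            sums[stage] = float(z_ser[cols].abs().sum()) if cols else 0.0
        out.append(KinaseActivity(kinase, z_ser, m, sums))
    return out
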