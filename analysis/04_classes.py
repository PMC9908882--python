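#!/usr/bin/env python
"""Assign regulatory classes from cross-layer fold-change correlations,
compare them against the planted labels, summarize protein-phosphosite
concordance, and compute kinase activity scores per EMT stage.

Reads results/data/ and results/de/, writes results/classes/.
"""

import json
from pathlib import Path

import pandas as pd

from omnitide.classes import (
    classify_genes,
    kinase_activity,
    protein_phospho_concordance,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "classes"
PROTEOMIC = ["WCP", "NUC", "MEM", "SEC", "GLYCO", "EXOS"]


def lfc_table(layer: str) -> pd.DataFrame:
    df = pd.read_csv(ROOT / "de" / f"{layer.lower()}_de.tsv", sep="\t", index_col=0)
    return df[[c for c in df.columns if c.startswith("t") and c[1:].isdigit()]]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((ROOT / "data" / "ground_truth.json").read_text())

    lfc = {layer: lfc_table(layer) for layer in PROTEOMIC}
    table = classify_genes(lfc)
    table.to_csv(OUT / "classes.tsv", sep="\t", index_label="gene")
    counts = table["class"].value_counts().to_dict()
    planted = truth["class_label"]
    covered = [g for g in planted if g in table.index]
    agree = sum(table.loc[g, "class"] == planted[g] for g in covered)
    print(f"classified {len(table)} genes: {counts}")
    print(f"planted-label agreement: {agree}/{len(covered)} "
          f"({agree / max(len(covered), 1):.1%}) at the study noise level")

    phos = lfc_table("PHOS")
    conc = protein_phospho_concordance(phos, lfc["WCP"])
    print(f"protein-phosphosite concordance over {conc['n_sites']} sites: "
          f"{conc['fraction_poor']:.1%} with r < 0.4, "
          f"{conc['fraction_opposite']:.1%} with r <= -0.1")

    # synthetic kinase-substrate map: consecutive blocks of 8 sites per kinase
    sites = list(phos.index)
    km = {f"KIN{i + 1:02d}": sites[i * 8:(i + 1) * 8] for i in range(len(sites) // 8)}
    acts = kinase_activity(phos, km, m_min=3)
    rows = [{"kinase": a.kinase, "m": a.n_substrates, **a.stage_sums} for a in acts]
    pd.DataFrame(rows).to_csv(OUT / "kinase_activity.tsv", sep="\t", index=False)
    top = max(rows, key=lambda r: r["E/M"] ) if rows else None
    if top:
        print(f"most E/M-active kinase: {top['kinase']} "
              f"(sum |z| = {top['E/M']:.2f} over t3-t5)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
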