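#!/usr/bin/env python
"""Identify regulated ligand-receptor pairs (ligand in SEC, receptor in
MEM/GLYCO, both p < 0.01, combined |log2FC| >= 1) and score sender->receiver
communication between cell clusters.

Reads results/data/ and results/de/, writes results/crosstalk/.
"""

import json
from pathlib import Path

import pandas as pd

from omnitide import crosstalk

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "crosstalk"


def stats(layer: str) -> pd.DataFrame:
    df = pd.read_csv(ROOT / "de" / f"{layer}_de.tsv", sep="\t", index_col=0)
    cols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    return df[cols + ["p_value"]]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((ROOT / "data" / "ground_truth.json").read_text())
    db = [tuple(p) for p in truth["lr_db"]]
    pairs = crosstalk.find_regulated_lr(
        stats("sec"), stats("mem"), db, glyco_stats=stats("glyco")
    )
    rows = [
        {
            "ligand": p.ligand,
            "receptor": p.receptor,
            "receptor_layer": p.receptor_layer,
            "max_abs_C": float(p.combined.abs().max()),
            "first_regulated_t": (p.direction != "none").idxmax(),
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(OUT / "regulated_pairs.tsv", sep="\t", index=False)
    planted = {tuple(p) for p in truth["lr_regulated"]}
    found = {(p.ligand, p.receptor) for p in pairs}
    print(f"regulated pairs: {len(found)} found, {len(planted)} planted, "
          f"{len(found & planted)} overlap")

    clusters = pd.read_csv(ROOT / "data" / "clusters.tsv", sep="\t", index_col=0)
    cl_truth = json.loads((ROOT / "data" / "cluster_truth.json").read_text())
    scores = crosstalk.score_cluster_crosstalk(
        [tuple(p) for p in cl_truth["lr_regulated"]], clusters
    )
    scores.to_csv(OUT / "cluster_scores.tsv", sep="\t", index=False)
    top = scores.iloc[0]
    print(f"top communication edge: {top.ligand}->{top.receptor} "
          f"from {top.sender} to {top.receiver} (score {top.score:.2f})")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
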