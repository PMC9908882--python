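#!/usr/bin/env python
"""Preprocess every simulated layer and select temporally differential
features with the two-step polynomial regression (adj. p <= 0.05, r^2 >=
0.6, max |log2FC| >= 1, BH within each layer).

Reads results/data/, writes results/de/ (one stats table per layer) and
prints per-layer regulated counts next to the planted counts.
"""

import json
from pathlib import Path

from omnitide.omics import OmicsMatrix
from omnitide.preprocess import preprocess, select_differential

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "de"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((ROOT / "data" / "ground_truth.json").read_text())
    for path in sorted((ROOT / "data").glob("*.tsv")):
        name = path.stem.upper()
        if name in ("INTERACTOME", "CLUSTERS"):
            continue
        m = preprocess(OmicsMatrix.from_tsv(path, name))
        res = select_differential(m)
        res.to_tsv(OUT / f"{name.lower()}_de.tsv")
        n_sel = int(res.table["selected"].sum())
        n_planted = len(truth["differential_features"].get(name, []))
        print(f"{name}: {n_sel}/{len(res.table)} selected "
              f"(planted differential: {n_planted})")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
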