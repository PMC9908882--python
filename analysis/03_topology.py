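#!/usr/bin/env python
"""Quantify how much sample-space structure the layers share: RV matrix
correlations between configuration matrices, partial RVs, and the
PC-skeleton summarizing which layers stay coupled after conditioning.

Reads results/data/, writes results/topology/ (RV matrix TSV, skeleton
GraphML) and prints the strongest couplings.
"""

import itertools
from pathlib import Path

import networkx as nx

from omnitide import topology
from omnitide.omics import OmicsMatrix
from omnitide.preprocess import preprocess

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "topology"
EPSILON = 0.1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    configs = {}
    for path in sorted((ROOT / "data").glob("*.tsv")):
        name = path.stem.upper()
        if name in ("INTERACTOME", "CLUSTERS"):
            continue
        m = preprocess(OmicsMatrix.from_tsv(path, name))
        configs[name] = topology.configuration_matrix(m.values.T.to_numpy(), name)
    rv = topology.rv_matrix(configs)
    rv.to_csv(OUT / "rv_matrix.tsv", sep="\t")
    skel = topology.topology_skeleton(rv, EPSILON)
    nx.write_graphml(skel, OUT / "skeleton.graphml")

    pairs = sorted(
        ((rv.loc[a, b], a, b) for a, b in itertools.combinations(rv.index, 2)),
        reverse=True,
    )
    print("strongest layer couplings (RV):")
    for val, a, b in pairs[:5]:
        others = [k for k in rv.index if k not in (a, b)][:2]
        pr = topology.partial_rv(rv, a, b, tuple(others))
        print(f"  {a} ~ {b}: RV = {val:.3f}, partial RV | {','.join(others)} = {pr:.3f}")
    print(f"skeleton at eps={EPSILON}: {skel.number_of_edges()} edges "
          f"among {skel.number_of_nodes()} layers")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
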