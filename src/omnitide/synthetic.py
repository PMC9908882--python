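"""Synthetic multi-omics time courses with fully known planted ground truth.

The generator emulates the study design downstream stages expect: ten
timepoints (index 0 = untreated control) in three biological replicates,
several omics layers drawing features from a shared gene universe, latent
temporal programs with switch-like transitions (an early switch out of the
epithelial state and a later switch into the mesenchymal state), planted
differential features, planted cross-layer correlation classes
(I / II-A / II-B), planted regulated ligand-receptor pairs, and a directed
scaffold network containing a prized signaling cascade rooted at designated
receptor nodes.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .omics import OmicsMatrix, sample_name

EDGE_TYPES = (
    "kinase->target",
    "TF->target",
    "TF->miRNA",
    "signaling",
    "miRNA->gene",
    "gene->metabolite",
    "phosphatase->target",
)

#: timepoint labels for the default 10-point design: control, 4 h, then days.
TIMEPOINT_LABELS = ("t0", "4h", "d1", "d2", "d3", "d4", "d5", "d6", "d8", "d12")

#: stage bins on the timepoint index grid (E -> E/M at t3, E/M -> M at t6)
STAGE_BINS = {"E": (1, 2), "E/M": (3, 4, 5), "M": (6, 7, 8, 9)}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class LayerSpec:
    name: str
    n_features: int
    overlap_fraction: float = 0.8
    proteomic: bool = True


@dataclass
class LatentProgram:
    """Switch-like temporal program: flat, then a step of ``amplitude`` log2
    units at ``switch_time`` (logistic with finite ``sharpness``, hard step
    when sharpness is None)."""

    switch_time: int
    amplitude: float = 2.0
    sharpness: float | None = None

    def profile(self, n_timepoints: int) -> np.ndarray:
        t = np.arange(n_timepoints, dtype=float)
        if self.sharpness is None:
            prof = self.amplitude * (t >= self.switch_time).astype(float)
        else:
            z = self.sharpness * (t - (self.switch_time - 0.5))
            prof = self.amplitude / (1.0 + np.exp(-z))
            prof -= prof[0]
        prof[0] = 0.0
        return prof


@dataclass
class LRConfig:
    n_pairs: int = 20
    n_planted_regulated: int = 6
    n_clusters: int = 6


@dataclass
class NetworkConfig:
    n_nodes: int = 40
    n_edges: int = 80
    cascade_length: int = 4
    root_names: tuple[str, ...] = ("TGFBR1", "TGFBR2")
    activation_timepoint: int = 3


@dataclass
class SimulationConfig:
    n_timepoints: int = 10
    n_replicates: int = 3
    n_genes: int = 500
    layers: list[LayerSpec] = field(
        default_factory=lambda: [
            LayerSpec("WCP", 400),
            LayerSpec("NUC", 300),
            LayerSpec("MEM", 250),
            LayerSpec("SEC", 200),
            LayerSpec("GLYCO", 150),
            LayerSpec("EXOS", 150),
            LayerSpec("MRNA", 450, proteomic=False),
        ]
    )
    latent_programs: list[LatentProgram] = field(
        default_factory=lambda: [LatentProgram(3, 2.0), LatentProgram(6, 2.0)]
    )
    noise_sd: float = 0.25
    class_fractions: tuple[float, float, float] = (0.26, 0.52, 0.22)
    frac_differential: float = 0.3
    lr_config: LRConfig = field(default_factory=LRConfig)
    network_config: NetworkConfig = field(default_factory=NetworkConfig)
    batch_sd: float = 0.0
    missing_fraction: float = 0.0
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    n_phos_sites: int = 150
    phos_coupled_fraction: float = 0.5

    def validate(self) -> None:
        fracs = [self.frac_differential, self.missing_fraction, *self.class_fractions]
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")
        if sum(self.class_fractions) > 1.0 + 1e-9:
            raise ValueError("class fractions sum above 1")
        for p in self.latent_programs:
            if not 1 <= p.switch_time <= self.n_timepoints - 1:
                raise ValueError(
                    f"switch_time {p.switch_time} outside [1, {self.n_timepoints - 1}]"
                )
        nc = self.network_config
        if nc.n_edges < nc.cascade_length:
            raise ValueError("n_edges must be >= cascade_length")
        if self.lr_config.n_planted_regulated > self.lr_config.n_pairs:
            raise ValueError("n_planted_regulated exceeds n_pairs")


@dataclass
class GroundTruth:
    """Planted answers for every downstream stage."""

    differential_features: dict[str, list[str]] = field(default_factory=dict)
    class_label: dict[str, str] = field(default_factory=dict)
    coupled_layers: list[tuple[str, str]] = field(default_factory=list)
    lr_db: list[tuple[str, str]] = field(default_factory=list)
    lr_regulated: list[tuple[str, str]] = field(default_factory=list)
    lr_cluster_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    cascade_nodes: list[str] = field(default_factory=list)
    cascade_edges: list[tuple[str, str]] = field(default_factory=list)
    prize_activation: dict[str, int] = field(default_factory=dict)
    roots: list[str] = field(default_factory=list)
    phos_coupled_sites: list[str] = field(default_factory=list)
    planted_profiles: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def _random_profile(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """A random switch or pulse profile on the non-control timepoints."""
    T = cfg.n_timepoints
    amp = float(rng.choice([p.amplitude for p in cfg.latent_programs]))
    sign = float(rng.choice([-1.0, 1.0]))
    kind = rng.integers(0, 2)
    t = np.arange(T, dtype=float)
    if kind == 0:
        sw = int(rng.integers(1, T - 1))
        prof = (t >= sw).astype(float)
    else:
        a = int(rng.integers(1, T - 3))
        b = int(rng.integers(a + 2, T))
        prof = ((t >= a) & (t < b)).astype(float)
    prof[0] = 0.0
    return sign * amp * prof


def _orthogonal_profiles(
    rng: np.random.Generator, cfg: SimulationConfig, k: int
) -> list[np.ndarray]:
    """k profiles whose pairwise Pearson correlation over t1..T-1 is exactly 0
    (Gram-Schmidt on the centered non-control part); used for Class II-A."""
    T = cfg.n_timepoints
    amp = cfg.latent_programs[0].amplitude
    out: list[np.ndarray] = []
    basis: list[np.ndarray] = []
    attempts = 0
    while len(out) < k and attempts < 50 * k:
        attempts += 1
        raw = _random_profile(rng, cfg)[1:]
        v = _center(raw.astype(float))
        for b in basis:
            v = v - (v @ b) * b
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            continue
        basis.append(v / norm)
        prof_tail = v / np.abs(v).max() * amp
        prof = np.concatenate([[0.0], prof_tail])
        out.append(prof)
    if len(out) < k:
        raise RuntimeError("could not construct enough orthogonal profiles")
    return out


# ---------------------------------------------------------------------------
# multi-omics generator
# ---------------------------------------------------------------------------


def simulate_multiomics(
    config: SimulationConfig, seed: int
) -> tuple[dict[str, OmicsMatrix], GroundTruth]:
    """Generate one omics matrix per configured layer plus ground truth.

    Class I genes carry the same latent profile (plus independent noise) in
    every layer where they occur; Class II-B genes carry a sign-flipped
    profile in one designated layer; Class II-A genes carry mutually
    orthogonal (uncorrelated) profiles; non-differential features are flat
    plus noise.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    T, R = config.n_timepoints, config.n_replicates
    universe = _gene_ids(config.n_genes)

    # feature sets per layer: shared genes + private features
    layer_genes: dict[str, list[str]] = {}
    for spec in config.layers:
        n_shared = int(round(spec.overlap_fraction * spec.n_features))
        n_shared = min(n_shared, config.n_genes)
        shared = sorted(
            rng.choice(universe, size=n_shared, replace=False).tolist()
        )
        private = [f"{spec.name}_P{i + 1:05d}" for i in range(spec.n_features - n_shared)]
        layer_genes[spec.name] = shared + private

    proteomic = [s.name for s in config.layers if s.proteomic]
    # genes present in >= 2 proteomic layers are eligible for class labels
    presence: dict[str, list[str]] = {}
    for lname in proteomic:
        for g in layer_genes[lname]:
            if not g.startswith(tuple(f"{s.name}_P" for s in config.layers)):
                presence.setdefault(g, []).append(lname)
    eligible = sorted(g for g, ls in presence.items() if len(ls) >= 2)
    for i, a in enumerate(proteomic):
        for b in proteomic[i + 1 :]:
            shared_ab = [g for g in eligible if a in presence[g] and b in presence[g]]
            if len(shared_ab) < 2:
                raise ValueError(
                    f"layers {a}/{b} share {len(shared_ab)} classified genes (<2); "
                    "raise overlap_fraction or layer sizes"
                )

    truth = GroundTruth(roots=list(config.network_config.root_names))
    truth.coupled_layers = [
        (a, b) for i, a in enumerate(proteomic) for b in proteomic[i + 1 :]
    ]

    # plant class structure on differential eligible genes
    n_diff_eligible = int(round(config.frac_differential * len(eligible)))
    diff_genes = sorted(
        rng.choice(eligible, size=n_diff_eligible, replace=False).tolist()
    )
    f1, f2, _ = config.class_fractions
    denom = sum(config.class_fractions)
    n1 = int(round(f1 / denom * len(diff_genes))) if denom > 0 else 0
    n2 = int(round(f2 / denom * len(diff_genes))) if denom > 0 else 0
    class_of: dict[str, str] = {}
    for g in diff_genes[:n1]:
        class_of[g] = "I"
    for g in diff_genes[n1 : n1 + n2]:
        class_of[g] = "II-A"
    for g in diff_genes[n1 + n2 :]:
        class_of[g] = "II-B"
    truth.class_label = dict(class_of)

    # per-(gene, layer) planted profile
    profile_of: dict[tuple[str, str], np.ndarray] = {}
    for g in diff_genes:
        layers_g = presence[g]
        cls = class_of[g]
        if cls == "I":
            prog = config.latent_programs[
                int(rng.integers(0, len(config.latent_programs)))
            ]
            sgn = float(rng.choice([-1.0, 1.0]))
            prof = sgn * prog.profile(T)
            for ln in layers_g:
                profile_of[(g, ln)] = prof
        elif cls == "II-B":
            prog = config.latent_programs[
                int(rng.integers(0, len(config.latent_programs)))
            ]
            prof = prog.profile(T)
            flip = sorted(layers_g)[0]
            for ln in layers_g:
                profile_of[(g, ln)] = -prof if ln == flip else prof
        else:  # II-A: exactly uncorrelated profiles across layers
            profs = _orthogonal_profiles(rng, config, len(layers_g))
            for ln, prof in zip(sorted(layers_g), profs):
                profile_of[(g, ln)] = prof

    # ligand-receptor plant: ligands live in SEC, receptors in MEM (or GLYCO)
    lig_layer = "SEC" if "SEC" in layer_genes else None
    rec_layer = "MEM" if "MEM" in layer_genes else ("GLYCO" if "GLYCO" in layer_genes else None)
    if lig_layer and rec_layer:
        nlr = config.lr_config.n_pairs
        ligands = [f"LIG{i + 1:04d}" for i in range(nlr)]
        receptors = [f"REC{i + 1:04d}" for i in range(nlr)]
        layer_genes[lig_layer] = layer_genes[lig_layer] + ligands
        layer_genes[rec_layer] = layer_genes[rec_layer] + receptors
        truth.lr_db = list(zip(ligands, receptors))
        planted = list(
            rng.choice(nlr, size=config.lr_config.n_planted_regulated, replace=False)
        )
        for idx in sorted(planted):
            L, Rc = ligands[idx], receptors[idx]
            prog = config.latent_programs[int(rng.integers(0, len(config.latent_programs)))]
            sgn = float(rng.choice([-1.0, 1.0]))
            profile_of[(L, lig_layer)] = sgn * prog.profile(T)
            profile_of[(Rc, rec_layer)] = sgn * prog.profile(T)
            truth.lr_regulated.append((L, Rc))

    # other differential (non-class) features: private/unshared, random profile.
    # L-R database genes are excluded: non-planted pairs stay non-regulated.
    lr_gene_ids = {g for pair in truth.lr_db for g in pair}
    for spec in config.layers:
        pool = [
            f
            for f in layer_genes[spec.name]
            if (f, spec.name) not in profile_of
            and f not in class_of
            and f not in lr_gene_ids
        ]
        n_extra = int(round(config.frac_differential * len(pool)))
        chosen = rng.choice(pool, size=n_extra, replace=False) if n_extra else []
        for f in chosen:
            prof = _random_profile(rng, config)
            if np.abs(prof).max() < 1e-9:
                continue
            profile_of[(f, spec.name)] = prof

    # PHOS layer: site-level features mapping to parent genes
    if config.n_phos_sites > 0:
        site_ids, site_profiles = [], {}
        parent_pool = [g for g in universe[: config.n_genes]]
        parents = rng.choice(parent_pool, size=config.n_phos_sites, replace=True)
        ref_layer = proteomic[0] if proteomic else None
        n_coupled = int(round(config.phos_coupled_fraction * config.n_phos_sites))
        for i, parent in enumerate(parents):
            sid = f"{parent}_S{i + 1}"
            site_ids.append(sid)
            coupled = i < n_coupled
            if coupled and ref_layer and (parent, ref_layer) in profile_of:
                site_profiles[sid] = profile_of[(parent, ref_layer)]
                truth.phos_coupled_sites.append(sid)
            elif coupled:
                site_profiles[sid] = np.zeros(T)
                truth.phos_coupled_sites.append(sid)
            else:
                site_profiles[sid] = _random_profile(rng, config)
        layer_genes["PHOS"] = site_ids
        for sid in site_ids:
            if np.abs(site_profiles[sid]).max() > 1e-9:
                profile_of[(sid, "PHOS")] = site_profiles[sid]

    # materialize matrices
    cols = [sample_name(t, r) for t in range(T) for r in range(R)]
    t_of_col = np.repeat(np.arange(T), R)
    layers_out: dict[str, OmicsMatrix] = {}
    all_layer_names = [s.name for s in config.layers] + (
        ["PHOS"] if config.n_phos_sites > 0 else []
    )
    for lname in all_layer_names:
        feats = layer_genes[lname]
        n_feat = len(feats)
        baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_feat)
        prof_mat = np.zeros((n_feat, T))
        diffs = []
        for i, f in enumerate(feats):
            prof = profile_of.get((f, lname))
            if prof is not None:
                prof_mat[i] = prof
                diffs.append(f)
        batch = (
            rng.normal(0.0, config.batch_sd, size=(n_feat, R))
            if config.batch_sd > 0
            else np.zeros((n_feat, R))
        )
        noise = (
            rng.normal(0.0, config.noise_sd, size=(n_feat, T * R))
            if config.noise_sd > 0
            else np.zeros((n_feat, T * R))
        )
        vals = (
            baseline[:, None]
            + prof_mat[:, t_of_col]
            + np.tile(batch, (1, T))
            + noise
        )
        if config.missing_fraction > 0:
            mask = rng.random(vals.shape) < config.missing_fraction
            vals = np.where(mask, np.nan, vals)
        df = pd.DataFrame(vals, index=feats, columns=cols)
        layers_out[lname] = OmicsMatrix(lname, df)
        truth.differential_features[lname] = sorted(diffs)
        truth.planted_profiles[lname] = {
            f: profile_of[(f, lname)].tolist()
            for f in diffs
        }

    return layers_out, truth


# ---------------------------------------------------------------------------
# interactome generator
# ---------------------------------------------------------------------------


def simulate_interactome(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Directed typed edge list embedding a planted prized cascade.

    The cascade ``root -> c1 -> ... -> c_L`` is the only path from the root
    into its terminal, whose prize activates at
    ``network_config.activation_timepoint``; background edges connect only
    background nodes, so an exact prize-collecting solver recovers exactly
    the cascade once the prize is active (for large beta and small costs).
    """
    config.validate()
    nc = config.network_config
    if nc.cascade_length > nc.n_nodes - 1:
        raise ValueError("cascade_length exceeds n_nodes - 1")
    rng = np.random.default_rng(seed)
    roots = list(nc.root_names)
    if not roots:
        raise ValueError("root_names must be non-empty")
    root = roots[0]
    cascade = [root] + [f"CASC{i + 1:03d}" for i in range(nc.cascade_length)]
    n_bg = nc.n_nodes - len(cascade) - (len(roots) - 1)
    bg_nodes = [f"BG{i + 1:04d}" for i in range(max(n_bg, 0))]

    edges: list[tuple[str, str]] = list(zip(cascade[:-1], cascade[1:]))
    n_background_edges = nc.n_edges - len(edges)
    seen = set(edges)
    attempts = 0
    while len(edges) < nc.n_edges and attempts < 100 * nc.n_edges and len(bg_nodes) >= 2:
        attempts += 1
        u, v = rng.choice(bg_nodes, size=2, replace=False)
        if (u, v) in seen or u == v:
            continue
        seen.add((u, v))
        edges.append((u, v))
    types = [EDGE_TYPES[i % len(EDGE_TYPES)] for i in range(len(edges))]
    signs = rng.choice(["+", "-"], size=len(edges))
    df = pd.DataFrame(
        {
            "source": [e[0] for e in edges],
            "target": [e[1] for e in edges],
            "type": types,
            "sign": signs,
        }
    )
    truth = GroundTruth(roots=roots)
    truth.cascade_nodes = cascade
    truth.cascade_edges = list(zip(cascade[:-1], cascade[1:]))
    truth.prize_activation = {cascade[-1]: nc.activation_timepoint}
    return df, truth


def prize_schedule_from_truth(
    truth: GroundTruth, nodes, n_timepoints: int = 10
) -> pd.DataFrame:
    """Materialize the planted cumulative 0/1 prize schedule (node x t1..T-1)."""
    cols = [f"t{t}" for t in range(1, n_timepoints)]
    df = pd.DataFrame(0, index=sorted(nodes), columns=cols, dtype=int)
    for node, t_act in truth.prize_activation.items():
        for t in range(t_act, n_timepoints):
            df.loc[node, f"t{t}"] = 1
    return df


# ---------------------------------------------------------------------------
# cluster expression generator
# ---------------------------------------------------------------------------


def simulate_cluster_expression(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cluster-mean expression table with planted sender/receiver clusters.

    For each planted regulated L-R pair, one sender cluster expresses the
    ligand and one receiver cluster expresses the receptor; all other means
    are zero plus (optional) noise, so the planted (pair, sender, receiver)
    triple tops the product score ranking.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    lrc = config.lr_config
    ligands = [f"LIG{i + 1:04d}" for i in range(lrc.n_pairs)]
    receptors = [f"REC{i + 1:04d}" for i in range(lrc.n_pairs)]
    clusters = [f"C{i + 1}" for i in range(lrc.n_clusters)]
    genes = ligands + receptors
    base = np.zeros((lrc.n_clusters, len(genes)))
    if config.noise_sd > 0:
        base += np.abs(rng.normal(0.0, 0.05 * config.noise_sd, size=base.shape))
    df = pd.DataFrame(base, index=clusters, columns=genes)
    truth = GroundTruth()
    planted_idx = sorted(
        rng.choice(lrc.n_pairs, size=lrc.n_planted_regulated, replace=False).tolist()
    )
    for idx in planted_idx:
        L, Rc = ligands[idx], receptors[idx]
        sender, receiver = rng.choice(lrc.n_clusters, size=2, replace=False)
        df.loc[clusters[sender], L] = 4.0
        df.loc[clusters[receiver], Rc] = 3.0
        truth.lr_regulated.append((L, Rc))
        truth.lr_cluster_pairs[f"{L}|{Rc}"] = (clusters[sender], clusters[receiver])
    truth.lr_db = list(zip(ligands, receptors))
    return df, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_simulation(outdir, layers: dict[str, OmicsMatrix], truth: GroundTruth) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, m in layers.items():
        m.to_tsv(out / f"{name.lower()}.tsv")
    truth.to_json(out / "ground_truth.json")
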