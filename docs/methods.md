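# Methods

This note documents the models, statistics and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Study design emulated

All stages assume a longitudinal bulk design: one untreated control (t0)
plus nine treatment timepoints, three biological replicates per timepoint
(30 samples per layer), log2-scale intensities. Timepoint labels follow an
early-dense grid (t0, 4 h, then days 1–6, 8, 12) but **time is coded on the
uniform index grid 0..9** for all regression and stage logic: downstream
stage bins are defined on indices (E = t1–t2, E/M = t3–t5, M = t6–t9), the
true sampling is non-uniform, and the index coding keeps the polynomial
design well conditioned. The coding is configurable per call.

## Preprocessing

- **Valid-value filter** — features observed in < 70% of samples are
  removed (default `min_valid_fraction = 0.70`).
- **Imputation** — local least squares (LLS): each incomplete feature is
  regressed on its k = 10 most-correlated complete features over the
  observed columns and missing entries are predicted; with fewer complete
  features than k the method falls back to half-minimum with a logged
  warning. Half-minimum acts on the linear scale — half of the observed
  minimum, i.e. the feature's log2 minimum − 1 — matching its
  below-detection-limit semantics.
- **Quantile normalization** (optional) — NaN-aware: per-column ranks are
  mapped through the mean quantile curve of all columns.
- **Zero-centering** (optional) — subtract each feature's mean within every
  replicate block. Because one replicate corresponds to one multiplexed
  batch in the emulated design, this removes batch offsets exactly; the
  generator's `batch_sd` plants exactly this structure.
- **Replicate-outlier rule** (optional, metabolite-style layers) — entries
  deviating ≥ 1 SD from their feature × timepoint replicate mean are
  masked. The rule is aggressive with three replicates and is off by
  default.

## Differential selection

Per feature, step 1 fits ordinary least squares of intensity on polynomial
time terms (default degree 3 — flexible enough for one or two switch-like
transitions over ten points without overfitting) and screens with the
F-test of the full model against intercept-only; p-values are BH-adjusted
within each layer (layers are reported separately, so the multiplicity
family is the layer). Step 2 performs backward elimination of polynomial
terms at per-term α and reports the retained model's coefficient of
determination r². A feature is selected when adj. p ≤ α (default 0.05), r²
≥ 0.6, and max |log2FC| ≥ 1, where the log2FC profile is the difference of
replicate-mean log2 intensities vs t0.

Degenerate cases: an exactly flat feature has zero model and residual
variance; its p-value is defined as 1 and it is never selected. Exact fits
(zero residuals at zero noise) give p = 0 and infinitely significant terms.

The implementation vectorizes both steps across features, grouping features
that share the same retained-term set, so the 200 × 1000-feature
calibration suite runs in seconds.

Calibration behavior: under a global null the realized fraction of
adj.-p-significant features is far below the nominal 0.05 (BH controls the
FDR, and under the complete null rejections require extreme order
statistics); the acceptance check asserts only the upper bound.

## Layer topology

Configuration matrices are S = XXᵀ with samples as rows and **features
mean-centered first**; the uncentered product is dominated by mean
intensities and the RV between uncentered matrices of any two expressed
layers is ≈ 1 regardless of structure. `center=False` reproduces the bare
formula, and the orthogonal-invariance identity is tested in that mode.
Replicates are kept as distinct samples; layers are compared on the full
30-sample grid.

Partial RV applies the recursive first-order partial-correlation formula,
recursing over the conditioning set in sorted order; conditioning sets are
capped at size 2 in the skeleton (sufficient below ~10 layers). The PC
step implements the skeleton phase only — collider orientation is
deliberately out of scope since the quantity of interest here is which
couplings survive conditioning, not edge direction. The skeleton is
deterministic given sorted node order. Edge removal is monotone in ε at
conditioning order 0 and tested there; monotonicity is not guaranteed at
higher orders because removals change the available conditioning sets.

## Regulatory classes

Genes present in ≥ 2 proteomic layers are classified from pairwise Pearson
correlations of their (T−1)-point log2FC profiles. The anticorrelation
test (any pair ≤ −0.4 → Class II-B) takes precedence over Class I (all
pairs ≥ 0.4): one strong anticorrelated pair is direct evidence of
post-translational control and must not be masked by other correlated
pairs. Zero-variance profiles yield NA correlations, which are excluded;
genes with only NA pairs are unclassified (with a logged count).

Kinase activity uses the standard mean-enrichment z,
z = (mean(substrate lfc) − mean(all lfc))·√m / sd(all lfc), per timepoint,
with stage activity the sum of |z| over each stage's timepoint bin and a
minimum substrate count m ≥ 3. The formula choice is a package decision
(the most common published form consistent with "enrichment z-scores");
it is location-invariant by construction and its analytic value under a
shifted-substrate model (√m · shift / sd) anchors the acceptance check.

## Ligand–receptor crosstalk

The search space is constrained by compartment: ligands must be measured in
the secretome, receptors in the membrane or surfaceome layer; both partners
need p < 0.01. A receptor measured in both layers is taken from the layer
with the smaller p-value (deterministic tie-break by layer name). The
combined per-timepoint change C = L + R gates regulation at |C| ≥ 1 with
sign giving direction; an optional `codirectional` flag additionally
requires sign(L) = sign(R), off by default since the combined-change
criterion alone is the primary rule. Cluster communication is bilinear:
meanL(sender) × meanR(receiver) over all ordered cluster pairs.

## Network reconstruction

Edge weights are w(e) = 1/kout(source) on the deduplicated simple digraph
(parallel typed edges collapse onto one edge carrying all types), costs
c(e) = 1 − w(e) ∈ [0, 1). Prizes are binary and cumulative: a node is
prized at t if the max |log2FC| over all its measurements (all layers;
phosphosites collapse to their parent protein) strictly exceeds 1 at any
timepoint ≤ t. Uniform prizes avoid biasing the forest toward
high-fold-change nodes; cumulativity makes successive forests build on
their predecessors.

The objective is the canonical prize-collecting Steiner forest form
f(F) = Σ_{v∉V_F}(β·p(v) − μ·k(v)) + Σ_{e∈E_F} c(e) + ω·κ with defaults
β = 10, ω = 5, μ = 0, D = 5. Interpretations fixed here: D is the maximum
hop depth from each tree's root (the dummy-adjacent node is depth 0);
trees must be reachable from the designated roots along *directed* edges;
μ·k(v) uses total scaffold degree (inert at μ = 0 but implemented and
tested at μ > 0). Rooting is realized by the standard dummy-node
construction; internally each opened tree is simply charged ω, which is
equivalent.

**Exact solver** — branch-and-bound over per-node parent assignments
(absent / tree root / one incoming edge), nodes ordered roots-first by
BFS; a suffix lower bound from each node's best option prunes the search;
final validation resolves depths and rejects cycles. Refuses instances
over 24 candidate edges; intended as the oracle on small instances.

**Heuristic** — deterministic cheapest-path accretion: repeatedly attach
the prized node whose depth-feasible min-cost directed path from the
current forest (or an unopened root, charged ω) has the most negative
margin, where path costs credit the prize gain of every new node
collected. The path search is one Bellman–Ford sweep per depth layer over
(node, depth) states with parent-chain checks keeping paths simple. Three
refinements close most of the gap to the optimum: (1) exact re-routing of
the selected node set (a small branch-and-bound for the min-cost
depth-bounded arborescence forest on the induced subgraph); (2) local
improvement that dissolves the subtree under each node — singly and in
pairs — and re-accretes, with a tabu on re-opening a dissolved root; (3)
deterministic multi-start over subsets of designated roots pre-opened,
since greedy margins cannot see that opening an extra tree near the
prizes saves depth budget. No randomness anywhere; ties break
lexicographically. On the random small-instance suite the heuristic
matches the exact optimum on ≥ 99% of instances.

Prized nodes unreachable within depth D are left unconnected and their
penalty paid — never an error.

## Controllability

The directed network maps to a bipartite graph (out-copies vs in-copies,
one edge per link); Hopcroft–Karp gives the maximum matching, and
N_D = max(N − |M|, 1) — the floor of one encodes that a perfectly matched
network still needs at least one input. Self-loops are removed before
mapping (self-dynamics is conventionally treated separately). Single-node
removal recomputes N′_D and classifies indispensable / neutral /
dispensable. Only N_D and the classes are contract-stable; the driver
witness set is one of possibly many maximum-matching witnesses, made
deterministic by lexicographic tie-breaks. The pipeline runs the analysis
on the union of all per-timepoint forests by default (which timepoint's
network to analyze is a convention; the CLI accepts any graph).

## Synthetic data: what it emulates and what it does not

The generator plants: switch-like latent programs (hard steps by default,
logistic with finite sharpness optionally) at an early (t3) and late (t6)
transition; per-layer feature sets sampled from a shared gene universe;
Class I genes with identical profiles in every layer, Class II-B genes
sign-flipped in one designated layer, Class II-A genes with *exactly
orthogonal* profiles across layers (Gram–Schmidt on random step/pulse
shapes), so zero-noise recovery is exact by construction; regulated L-R
pairs with co-directional ligand/receptor programs, with all other
database genes held flat so the planted set is exactly recoverable;
additive Gaussian noise on the log2 scale; per-replicate batch offsets;
uniform missingness with optional left-censoring semantics via the
half-minimum path; and a scaffold whose background edges avoid the planted
cascade, making the cascade the unique optimal forest once its terminal
prize activates.

Defaults are the study conditions: 10 × 3 design; noise σ = 0.25 log2
units (per-feature noise magnitudes are not published for such designs;
0.25 is a realistic TMT-style replicate spread and is documented, not
calibrated); class fractions 0.26/0.52/0.22 matching the reported class
proportions; 30% of eligible features differential; program amplitude 2.

Not emulated: raw spectra or reads, single-cell count matrices and their
cell-cycle structure, non-Gaussian heavy-tailed noise,
intensity-dependent missingness, correlated noise between layers, and
realistic interactome topology (background edges are uniform random).
Passing the planted-truth checks therefore demonstrates correctness of
the algorithms under the stated generative model, not performance on real
mass-spectrometry data.

## Problem sizes used in verification

The acceptance script and test suite use: 100 random PCSF instances with
≤ 12 nodes / ≤ 20 edges (the exact solver's comfortable regime); 500
random digraphs with ≤ 8 nodes for matching enumeration; 200 × 1000
features for null calibration and 200 runs for power; one default-size
simulation (≈ 2000 features across 8 layers) for planted-truth recovery;
1000 replicates for the kinase-score analytic check. These sizes give
Monte-Carlo standard errors well below the asserted tolerances.

## Known limitations

- The heuristic PCSF solver is not an approximation algorithm with a
  proven ratio; its quality is certified empirically against the exact
  solver on small instances only.
- The PC step orients no edges; "influence" direction between layers is
  not inferred.
- BH within layers controls the FDR per layer, not across the union of
  layers.
- LLS imputation assumes linear relations between features; with few
  complete features it degrades to half-minimum.
- The two-step regression reports r² of the retained polynomial model; a
  hard step is approximated, not fit exactly, by a cubic, so r² for true
  switches saturates around 0.8–0.9 rather than 1 at moderate noise.
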