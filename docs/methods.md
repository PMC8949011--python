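# Methods

This document records the model underlying `structphy`, every parameter
convention and default, and the known limitations of the synthetic data
generator. Quantities are in Ångströms unless stated otherwise. All problem
sizes used in tests and defaults (chain lengths, family sizes, permutation
counts) are the package's own choices, sized for a single CPU core.

## 1. Structures and IO (`structphy.structio`)

A `Structure` is an ordered CA trace: residue numbers (strictly increasing
integers), coordinates (float64, shape `(L, 3)`), a one-letter sequence, and
optional per-residue confidences in `[0, 100]`. PDB files are read and
written via gemmi using only `ATOM`/CA records; predicted-model confidences
(pLDDT) travel in the B-factor column, the standard convention for predicted
structures. B-factors above 100 cannot be confidences, so reading such a
file keeps coordinates but drops the confidence channel with a warning.
FASTA round-trips through Biopython; Newick through scikit-bio with branch
lengths written to 6 significant digits; square matrices as labelled TSV.

## 2. Superposition and TM-score (`structphy.superpose`)

**Kabsch.** Optimal rigid superposition by SVD of the cross-covariance of
centred coordinates, with the usual determinant correction so the result is
a proper rotation (no reflection). Requires ≥ 3 points; near-collinear point
sets make the rotation about the common axis ill-determined, so those emit a
warning (the RMSD itself is still the global minimum). The test suite checks
Kabsch against a brute-force minimiser (40 random-quaternion starts plus
Nelder–Mead refinement over rotation vectors) to 1e-3 Å on random small
systems.

**TM-score.** For a correspondence of `|c|` residue pairs against a reference
of length `L`:

    TM = (1/L) * Σ_pairs 1 / (1 + (d_i / d0(L))^2),
    d0(L) = max(0.5, 1.24 * (L - 15)^(1/3) - 1.8)

Two modes: `fixed-frame` scores the coordinates as given (used by the exact
hand-checkable contract: all pairs at distance exactly `d0` give
`(|c|/L) * 0.5`), and `full-search` (the default) maximises TM over
superpositions using fragment seeds of length `L`, `L/2`, `L/4` (minimum 4)
followed by iterated superposition on inlier pairs within
`max(4.5, d0)` Å, the standard TM-score search heuristic. Normalisation is
by the reference (first) structure's length in benchmarking; homologue
search normalises by the shorter chain so fragments are not penalised twice.

**Sequence-independent alignment.** `structural_align` alternates a 3-state
Needleman–Wunsch (gap-open 0.6, gap-extend 0, numba-compiled) over the
TM-style per-pair score matrix with re-superposition on the current
correspondence, until the correspondence is stable. Initial frames come from
threading-offset seeds (the best 3 diagonal offsets by quick TM); fragment
seeds are added only when the best seed scores TM < 0.6. The correspondence
is constrained to be sequential (strictly increasing in both chains).

## 3. Elastic distance-matrix score and Z (`structphy.daliscore`)

The elastic score compares intramolecular CA–CA distance matrices over an
ordered correspondence `{(i_k, j_k)}`:

    S = Σ_{k,l} φ(k, l)
    φ(k, l) = θ                                              if k = l
            = (θ − |d^A_{i_k i_l} − d^B_{j_k j_l}| / d*) e^{−(d*/α)^2}  else
    d* = (d^A + d^B) / 2,  θ = 0.20,  α = 20 Å

summed over ordered pairs (so off-diagonal terms count twice). This is the
Dali functional form; unlike RMSD it is superposition-free and tolerant of
hinge motions, which is exactly why it anchors the phylogenetic distance.

**Z-score.** Two calibrations are available and must be stated with any
result:

- `polynomial` (default): `Z = (S − m(n)) / (0.5 · m(n))` with
  `m(n) = 7.9494 + 0.70852 n + 2.5895e-4 n² − 1.9156e-6 n³`,
  `n = √(L_A · L_B)` capped at 400 — the published background fit for this
  score family.
- `simulated`: `SimulatedBackground` draws 200 random pairs of synthetic
  compact chains per 10-wide bin of `n`, scores them with the same aligner,
  and uses the empirical mean/SD. Slower but self-consistent with this
  package's generator; results are cached per bin and fully seeded.

The two calibrations differ systematically (the polynomial was fit to real
protein backgrounds), so annotation experiments that care about false-positive
rates on *synthetic* decoys use the simulated background.

**Derived quantities.**

- Relative Z-error of a prediction (Eq. 1 convention):
  `z_error = (Z_gt − Z_pd) / Z_gt`, where `Z_gt` is the experimental
  structure's self-Z and `Z_pd` the predicted-vs-experimental Z. It is 0 for
  a perfect model and 1 when the model retains no detectable similarity.
  Values slightly outside `[0, 1]` are possible in principle (a model can in
  rare cases score below a random chain); within the accuracy range the
  package targets (pairs at ≤ 2.5 Å RMSD) it stays in `[0, 1]`.
- Pseudo-distance between structures Q and T (Eq. 2 convention):
  `D_QT = Z_QQ + Z_TT − 2 Z_QT`, clamped at 0 (tiny negative values from
  alignment asymmetry trigger a warning and are clamped). `D_QQ = 0` exactly.
  The all-vs-all Z matrix is symmetrised (`(Z + Zᵀ)/2`) before conversion.

## 4. Trees (`structphy.treebuild`)

**Structural tree.** UPGMA (plus complete/single linkage variants) is
implemented directly rather than via scipy so tie-breaking is fully
deterministic: among equal-distance merges the lexicographically smallest
pair of cluster names wins. Node heights are `d/2`, so an exactly
ultrametric input is recovered exactly. A cross-check test confirms merge
heights agree with scipy's average linkage.

**Sequence tree.** Pairwise Needleman–Wunsch identity → distance
`1 − identity` → scikit-bio neighbour joining, with negative branch lengths
clamped to 0. NJ output is unrooted; topology comparisons against rooted
references therefore use unrooted bipartition sets, not rooted
Robinson–Foulds.

## 5. Congruence (`structphy.congruence`)

Cophenetic matrices are unfolded to their upper triangles, ranked with
mid-ranks, and Kendall's W is computed with the tie correction:

    W = (12 Σ_i R_i² − 3 p² m (m+1)²) / (p² m (m² − 1) − p Σ_j T_j)

For `p = 2` matrices, `W = (r_S + 1) / 2` with `r_S` the Spearman
correlation, and exactly reversed ranks give `W = 0`. Significance uses the
CADM permutation test: all matrices except the first are row/column
permuted together, and `p = (1 + #{W_perm ≥ W_obs}) / (1 + n_perm)`, so the
smallest attainable p at 999 permutations is 0.001. Type-I error is verified
empirically (independent random matrices reject at ≈ 5%).

## 6. Annotation (`structphy.annotate`)

A query is searched against an annotated library with `structural_align` +
`elastic_score` (Z normalised by the shorter chain's self-alignment
convention), hits sorted by Z. Classification uses the top hit's Z with the
conventional boundaries, both strict:

    Z > 4            significant
    2 ≤ Z ≤ 4        weak
    Z < 2            no_homologue

Function counts aggregate the categories of significant hits only; weak hits
are reported but never counted as annotations.

## 7. Benchmarking (`structphy.benchmark`)

`evaluate_pair` matches predicted and experimental chains by residue number
(zero overlap is an error), then reports TM-score (normalised by the
experimental length), RMSD over the matched set, relative Z-error, and mean
pLDDT of the prediction (error if the model carries no confidences; models
with mean pLDDT < 70 are flagged low-confidence, the usual reliability
cutoff). Set summaries give median/mean/SD per metric with Tukey outliers
(beyond 1.5 IQR), and a boxplot-ready JSON payload. Values are sorted before
aggregation so every statistic is invariant to record order.

## 8. Synthetic data (`structphy.simdata`)

The generator exists so that every claim in this package can be tested
against a planted ground truth. Its pieces, and their realism limits:

**Backbones.** Self-avoiding random CA walks with bond lengths in
`[3.75, 3.85]` Å and a minimum non-bonded separation of 4.0 Å, confined to a
sphere of radius `3.0 · L^0.38` about the running centroid with inward
steering beyond 80% of that radius. Backtracking (discard the last 5
residues after 100 consecutive placement failures) keeps generation robust;
more than 20000 retries raises rather than looping. The confinement
reproduces the empirical globular-protein scaling `Rg ≈ 2.2 · L^0.38`.
Limits: no secondary structure, no side chains, no hydrophobic core — these
chains are "protein-shaped", not proteins.

**Family evolution.** A root backbone evolves down a given Newick tree.
Along a branch of length `b`, coordinates receive a Gaussian displacement
field normalised so the per-component RMS is exactly
`coordinate_noise_rate · √b` (Brownian scaling in expectation *and* per
realization; this removes realization-variance noise from calibration
experiments — the expected pairwise coordinate RMSD between two leaves still
scales as `rate · √(path length)`). Sequences mutate as a Poisson process at
`substitution_rate` per site per unit branch length. With probability
`hinge_probability` per branch (default 0.1), one hinge move is applied: the
C-terminal tail beyond a random interior pivot is rotated by a uniform
5–20° Rodrigues rotation (rotating either arm differs only by a global rigid
motion, so the arm choice is immaterial).

Hinge moves are realistic for multi-lobed proteins but deliberately violate
the molecular-clock assumption behind UPGMA: a single hinge changes the
distance matrix by an amount unrelated to branch length. Tree-recovery
calibration experiments therefore run with `hinge_probability = 0`; with
hinges on, recovery degrades (≈ 50–60% exact-topology recovery at otherwise
identical settings) for reasons inherent to clock-based clustering, not to
the implementation.

**Planted trees.** `random_ultrametric_tree` draws `n − 1` merge heights as
a normalised cumulative sum of `U(0.8, 1.2)` gaps scaled to a total `depth`
(default 1.0), then coalesces uniformly random pairs. The bounded gaps
guarantee no two merge heights are nearly degenerate, so "exact topology
recovery" is a well-posed target.

**Predictions.** `make_prediction_pair` perturbs an experimental structure
to a requested target RMSD (achieved within 10%) and assigns pLDDT-like
confidences that decrease with local displacement.

**Libraries.** Annotated homologue libraries are built as several
independently evolved families plus unrelated decoy chains, with one
held-out member per family serving as the query with a known correct answer.

## 9. Determinism and the CLI

Every stochastic routine takes an explicit seed (`< 2^31`) and uses
`numpy.random.default_rng`; nothing reads global RNG state. The CLI
(`structphy pipeline` and the individual stages) writes a `manifest.json`
per run containing the scenario, library versions, and SHA-256 checksums of
all inputs and outputs — and no timestamps — so two runs of the same
scenario produce byte-identical output trees. Scenario files are YAML;
command-line flags override file values.
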