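# Methods

## Scope and model

`decoyclust` scores and clusters ensembles of protein conformations
("decoys") represented by their Cα traces. Every measure is
alignment-free: atom *i* of one model is paired with atom *i* of the
other, so all models in a comparison must have the same atom count. The
Cα-only default is the community convention for these scores; the atom
name is configurable for users who want, e.g., Cβ traces, but no
all-atom or sequence-aligned mode is attempted.

## Closed-form cRMSD

cRMSD is the minimum per-atom RMSD over proper rigid motions. Instead of
building the optimal rotation, we use the covariance identity: center
both sets, form M = (1/N) Σ (aᵢ−ā)(bᵢ−b̄)ᵀ, take the singular values
λ₁ ≥ λ₂ ≥ λ₃ of M and S = sign(det M); then
cRMSD² = R_A² + R_B² − 2(λ₁+λ₂+Sλ₃) with R the radius of gyration about
the centroid. The 1/N placement is chosen on both M and R² so the
identity holds per atom exactly — the equality tests against an
independent SVD/Wahba oracle pin this normalization down.

The λ are obtained from the characteristic cubic of MᵀM by the
trigonometric (Viète) solution for symmetric 3×3 matrices, which is
cheaper than a general SVD. Numerical guards:

* eigenvalues are clamped at 0 before the square root (round-off can
  produce −1e−16);
* the final radicand is clamped at 0 (identical sets would otherwise take
  the square root of a tiny negative number);
* near-degenerate discriminants fall back to a direct SVD of M: when the
  deviatoric norm p² < 1e−12·‖K‖² (near-triple root) or 1−|r| < 1e−9 in
  the arccos argument (near-double root). The double-root case matters in
  practice — an elongated helix compared with itself has two nearly equal
  small covariance eigenvalues, and the arccos path loses ~5 digits
  there while the SVD of M keeps the identity at the 1e−7 Å level.

Because the closed form subtracts quantities of order R², it resolves
"identical" only to about √(ε·R²) ≈ 1e−7–1e−6 Å; tests that assert
self-identity use 1e−6 Å, and the oracle-agreement tolerance of 1e−5 Å
over 10⁴ random pairs (N ∈ 4–200, reflected pairs included) is met with
four orders of margin.

The explicit rotation solver (needed by the GDT search) is the standard
SVD construction with the determinant sign fix: the column of the
smallest singular value is flipped when the unconstrained optimum is a
reflection, which also resolves degenerate (collinear) fragments
deterministically through the SVD's sign convention.

## Search scores (GDT_TS, TM-score, MaxSub)

Exact GDT optimization is NP-hard; the package uses one shared heuristic
for all three scores. Seed fragments are all stride-1 contiguous windows
of lengths {4, ⌊N/4⌋, ⌊N/2⌋, N} (duplicates removed, lengths < 4
dropped); the extended (`gdtExt`) variant adds powers of two 8, 16, 32, …
< N — "many more fragments" is left quantitative in the original
description, and powers of two give geometric coverage at modest cost.
Each seed's Kabsch transform is applied to the whole chain and refined:
atom pairs closer than 3.5 Å are re-superimposed until the selected count
is unchanged for 4 consecutive iterations, with a hard cap of 100
iterations (oscillation between two selections is possible and the
original procedure states no cap) and termination when fewer than 3 atoms
qualify.

The measure is evaluated at **every** visited superposition — seed and
each refinement step — and the maximum kept; whether the original
evaluates intermediates or only converged superpositions is not
documented, and evaluating everywhere is a superset that can only raise
the reported maximum. GDT_TS maximizes each cutoff's count independently
and reports (100/4)·Σ_c max C_c / N, so identical structures score 100;
the raw-count form of the total score is normalized to the community
[0, 100] convention. TM-score uses d₀ = 1.24(N−15)^⅓ − 1.8 Å floored at
0.5 Å (the formula is non-positive for N ≤ 17); MaxSub fixes d₀ = 3.5 Å.

The search is deterministic (no randomness, fixed seed order), and its
value is invariant under rigid motions of either input to ~1e−6 (the
refinement selection can flip at cutoff boundaries under coordinate
round-off, which bounds the attainable drift).

## Contact-map overlap

Contacts are unordered Cα pairs strictly closer than the cutoff (default
8 Å) with sequence separation ≥ `min_separation` (default 0, i.e. only
the trivial i=j exclusion); the original tool's defaults are not
documented anywhere, so both are explicit parameters. The score is the
Sørensen index 100·2|A∩B|/(|A|+|B|). Two empty maps score 100
(identically empty structures), one empty against non-empty scores 0;
both are conventions for the 0/0 ratio.

## Matrices, filtering, distances

All-vs-all computes each unordered pair exactly once — N(N−1)/2
evaluations — and mirrors it, making the matrix symmetric by construction
even where the search heuristic would be slightly asymmetric in argument
order. The pair list is mapped in lexicographic order, serially or over
joblib workers, and assembled in order, so results are bit-identical for
any worker count. No triangle-inequality pruning is attempted (that
belongs to a different algorithm family); threshold selection is a plain
post-hoc scan with strict inequality at the threshold. Similarity
measures convert to dissimilarities affinely (1−TM, 100−GDT/CMO) for
clustering; RMSD-type measures pass through.

## Clustering and representative selection

Hierarchical agglomerative clustering (single, maximum = complete,
average linkage) uses scipy's linkage on the condensed distance matrix,
cut to exactly k clusters; scipy's deterministic tie-handling stands in
for a bespoke lexicographic merge rule, a difference that can only
surface on exactly tied merge distances (measure-zero for noisy
ensembles, and the single-linkage partition is independently verified
against a minimum-spanning-tree-cut oracle). k is always user-supplied;
no automatic cluster-number detection.

K-means is a hand-rolled Lloyd iteration over the rows of the distance
matrix — each model's feature vector is its distance profile to all
models, which keeps the method applicable to every measure without
touching coordinates (which features the original clustering code
consumed is not documented; this choice is recorded as a deviation risk).
Defaults: 10 restarts, 300 iterations cap, seeded initial centers drawn
without replacement; empty clusters are re-seeded with the worst-fit
point; best restart by within-cluster sum of squares, earlier restart on
ties. The per-run objective history is exposed and tested non-increasing.

The ensemble representative minimizes ⟨R⟩/f over clusters — ⟨R⟩ the mean
over unordered within-cluster pairs (0 for singletons), f the cluster's
fraction of the ensemble — then returns the winning cluster's medoid
(minimal mean distance to co-members, lowest index on ties). The
selection rule picks only the cluster; the medoid step is this package's
choice of which member to return.

The CLI method codes 0–3 map to {K-means, single, maximum, average}; only
code 0 is externally pinned by the original tool's documented usage, so
1/2/3 follow the order the methods are conventionally listed in.

## Synthetic decoy generator

The generator emulates multi-trajectory decoy sets at the villin scale
(36 residues, defaults 3 clusters × 20 members): a base trace (ideal
α-helix: 2.3 Å radius, 1.5 Å rise, 100°/residue, giving ~3.8 Å Cα–Cα
steps; or an extended strand / fixed-step random walk), one seed per
cluster produced by rotating the chain about an internal hinge, and
members as seed + isotropic Gaussian noise. A hinge rotation — not a
translation, which superposition removes — is the simplest smooth
deformation that survives optimal superposition; the angle is calibrated
by bisection on the actual cRMSD so `between_offset` is an honest
cRMSD-scale separation (clamped at the half-turn maximum for short
chains). Per-coordinate noise of sd σ puts within-cluster cRMSD near
σ√6 ≈ 0.73 Å at σ = 0.3.

What it does *not* emulate: physical energetics, chain self-avoidance,
realistic Ramachandran statistics, heterogeneous cluster shapes, or the
long tails of real decoy distributions. Passing the clustering tests
therefore shows the pipeline recovers planted metric structure at ≥ 5×
separation-to-spread ratio — not that any method resolves the harder,
overlapping clusters of real decoy sets.

## Problem sizes

The default test-suite and acceptance-script runs use 10⁴ random pairs
for the cRMSD oracle comparison, ensembles of 60 models × 36 residues for
matrix/clustering stages and 10 × 20 for CLI round-trips — sizes at which
every stage completes in seconds while still exercising all code paths;
the library itself has no size-dependent switches, so behaviour at
thousands of decoys differs only in runtime (O(N²) pair evaluations).
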