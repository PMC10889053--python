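# Methods

## Model and assumptions

The package treats a protein–ligand complex as a labelled heavy-atom point
cloud. Hydrogens are removed at load time and never reach the topological
layers; waters are dropped, only the first alternate location is kept, and
non-standard residues are retained (their atoms simply match or miss the
element scheme). The interaction region is defined atom-wise: every ligand
heavy atom plus every protein heavy atom whose minimum Euclidean distance
to *any* ligand atom is ≤ cutoff, with a closed threshold. The alternative
reading — distance to the ligand centroid — would shrink the region
asymmetrically for elongated ligands; the any-atom convention is the
standard one for binding-pocket extraction and is what we implement.

### Hyperdigraphs and chain algebra

A k-directed hyperedge is an ordered (k+1)-tuple of distinct vertices. The
ambient chain group C_k(V) is freely generated by *all* such tuples;
distinct tuples are distinct orthonormal generators (reversal is not a sign
flip). The boundary is the alternating sum over vertex omissions,

∂(x_0,…,x_k) = Σ_i (−1)^i (x_0,…,x̂_i,…,x_k),

which satisfies ∂∘∂ = 0 — the property every spectral and homological claim
downstream rests on. The admissible chain space
Ω_k = {x ∈ span(F_k) : ∂x ∈ span(F_{k−1})} is computed as the null space of
the boundary components landing on face tuples outside F_{k−1}; for
face-closed inputs (all Vietoris–Rips output) there are no such components
and Ω_k = span(F_k) exactly, so the general machinery only pays its cost on
hand-built hyperdigraphs with missing faces.

The VR hyperdigraph at scale η keeps every vertex subset whose weight is
≤ η (closed threshold). The weight is the subset diameter by default; a
radius convention (diameter/2) is available as a config switch since both
appear in common usage. Orientation: vertices sorted by descending Pauling
electronegativity, ties broken by atom index. This makes directions encode
element differences while remaining a total, deterministic order. The
orientation never affects the L_0 spectrum (it is the graph Laplacian for
any orientation — a tested invariant), so the embedding below is
orientation-insensitive; orientation matters only for the higher-k algebra
exposed in the API.

### Laplacians

L_k = B_{k+1}B_{k+1}ᵀ + B_kᵀB_k with boundary matrices expressed in
orthonormal Ω bases; L_0 = B_1B_1ᵀ. The persistent Laplacian for nested
hyperdigraphs a ⊆ b restricts the boundary of b to
Ω_{k+1}^{a,b} = {x ∈ Ω_{k+1}^b : ∂x ∈ Ω_k^a}, found as a null space after
projecting the boundary image onto the orthogonal complement of Ω_k^a. Its
kernel dimension equals the persistent Betti number, which the test suite
verifies against an independent rank–nullity oracle on random nested pairs.

One caution on printed spectral folklore: the bound λ_k^max ≤ 2·d_k (d_k
the maximum cofacet count) holds for the graph Laplacian L_0 but fails for
k ≥ 1 — the filled triangle has L_1 spectrum {3, 3, 3} with a single
cofacet per edge. We assert the bound at k = 0 only.

## The element-specific embedding

11 protein element sets × 13 ligand element sets = 143 combinations, in
protein-major order, recorded in `scheme_version` so feature files are
self-describing. For each combination the cross-distance matrix is +∞
within each molecule and on one-sided combinations (a combination with
atoms on only one side carries no interaction and contributes zero rows),
so the threshold graph at every scale is bipartite protein–ligand.

Only L_0 statistics enter the embedding: zero multiplicity, then mean,
population standard deviation, minimum, maximum and sum of the strictly
positive eigenvalues. When no positive eigenvalue exists all five positive
statistics are 0 (including the minimum), which keeps the 6-vector finite
for the sparse combinations that dominate early filtration steps. The
population (not sample) standard deviation is used; the choice is arbitrary
but fixed and documented for reproducibility. Per-snapshot Laplacians feed
the sequence — the multiscale character comes from the grid itself — while
persistent pairs remain available through the API.

Since the embedding is dimension ≤ 1, L_0 is evaluated directly as D − A of
the thresholded cross-distance matrix; a test cross-checks this
specialization against the full hyperdigraph code path.

### Filtration grids

Grid values are start + i·step for i = 1..N (half-open at the start). This
yields exactly 100 steps for 0→10/0.1 and 50 for 2→12/0.2 and avoids the
degenerate all-disconnected d = 0 snapshot. Presets: `large` = 20 Å cutoff
with the 0→10 grid; `small` = 12 Å cutoff with the 2→12 grid. Zero
eigenvalues are detected with a relative threshold 1e−8·max(1, λ_max)
(eigensolver noise scales with the spectral radius); rank and null-space
decisions use tolerance 1e−8, and the chain-complex identity is verified to
1e−10.

## The sequence model

The transformer is implemented on a small reverse-mode autodiff engine over
numpy (`pthl.model.autodiff`): float64 throughout, deterministic given the
seed. Each step's 143×6 matrix is flattened by a channel-mixing projection
(linear → ReLU → linear, the 1×1-conv equivalent), a trainable per-position
multiscale embedding is added, and post-norm encoder layers with
multi-head scaled dot-product attention follow. Pretraining masks a random
half of the positions (ratio configurable) with a learned token and
reconstructs the full sequence through a decoder stack no deeper than the
encoder, under an MSE loss; MAE is available as a config switch. Fine-tuning
regresses the first-position encoder output to a scalar with MSE.

Defaults: d_model 512, 8 heads, 6 encoder / 2 decoder layers in the
full-scale preset; the `tiny` preset (d_model 32, 2 heads, 2+1 layers,
d_ff 64) is what the tests and the acceptance script train, with Adam at
1e−3–3e−3 and batches of 8. The exact full-scale depth, head count, mask
ratio and optimizer schedule are deliberately exposed as configuration
rather than asserted as canonical — they are tunables, and the package's
claims are about mechanisms (loss decreases, attention convexity, exact
gradients), not about benchmark scores.

Attribution: the attention score of a sequence is the mean attention weight
onto each key position across all layers, heads and queries — a convex
length-T vector whose argmax names the dominant filtration scale. The
saliency map is the absolute input gradient of the scalar prediction,
exact to machine precision by construction (verified against an analytic
linear surrogate).

## Evaluation metrics

Scoring: Pearson correlation and RMSE, with kcal/mol obtained by
multiplying −log-unit values by 1.3633. Ranking: high-level success
requires the predicted order within a cluster to match the experimental
order exactly (experimental ties count as failures by default;
configurable), low-level success only the top complex; high ≤ low by
construction. Docking: a ligand counts as a success when its top-scored
pose has RMSD strictly below 2 Å to the native pose (RMSD without
superposition — poses share the receptor frame); score ties break by the
lowest pose id. Screening: candidates rank by S = S1·S2; the top-α set has
ceil(α·n) members so at least one compound is always selected; success at α
asks whether the best true binder (highest experimental affinity when
affinities are given, else any binder) is selected, and
EF_α = (binders in top α)/(total binders·α) averaged over targets.
Consensus: repetitions average a random without-replacement subset of
model prediction vectors and record PCC/RMSE.

## Synthetic data

The generators define the conditions every test runs under.
`benchmark_tables` mirrors the benchmark shapes — 65 clusters of 3 (or any
size), 195 ligands × 100 poses with at least one sub-2 Å pose each, 65
targets × 3 true binders — with predictions equal to ground truth plus
Gaussian noise of configurable scale, so noise 0 makes every metric's
expected value exact. `synthetic_complex` places uniformly random heavy
atoms: the ligand in a central box one quarter of the protein box (default
16 Å, ~60 protein / ~15 ligand atoms, element pools C/N/O/S and the 9
ligand elements) to emulate a pocket's geometry at a size where full
eigendecompositions stay instant. What these fixtures do **not** emulate:
covalent geometry, chemically plausible element frequencies, correlated
noise between models, or the difficulty of real affinity prediction — so
passing tests demonstrate the correctness of the machinery (topology,
spectra, bookkeeping, optimization, metric arithmetic), not predictive
performance on real complexes.

Problem sizes used by the test suite and the acceptance script — point
clouds of ≤ 12 points, regions of a few dozen atoms, tiny-config training
for ≤ 400 steps — are chosen so the full pipeline verifies in minutes on a
single CPU; they are desk-scale stand-ins for the production presets, which
the same code runs unchanged.

## Known limitations

* Alpha (Delaunay-restricted) hyperdigraph construction is not implemented;
  the VR route is the only filtration (noted as an extension point).
* Dense eigensolvers throughout: fine for element-specific L_0 blocks
  (bounded by region size), not intended for whole-protein complexes at
  high dimension.
* The transformer is a correct, deterministic reference implementation, not
  a high-throughput trainer; production-scale pretraining would need a GPU
  framework behind the same interfaces.
* Multi-model NMR inputs use the first model only; no protonation, bond
  perception or charge assignment is attempted.
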