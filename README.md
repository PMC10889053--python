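# pthl — persistent topological hyperdigraph Laplacians for protein–ligand complexes

`pthl` converts 3D protein–ligand complexes into fixed-shape **topological
sequences** that sequence models can consume, and provides the surrounding
tooling: a transformer interface over those sequences, CASF-style
evaluation metrics (scoring, ranking, docking, screening), and seeded
synthetic generators so the whole pipeline runs without external data.

It is aimed at structure-based drug-discovery work: scoring functions for
binding affinity, pose ranking, and virtual screening, where the input is a
protein pocket plus a ligand and the obstacle is that 3D structure does not
fit sequential architectures.

## The method

A complex is reduced to its heavy atoms and the interaction region is
carved out: all ligand atoms plus every protein atom within a cutoff
(20 Å or 12 Å presets). For each of 143 element-set combinations — 11
protein sets over {C, N, O, S} times 13 ligand sets over
{C, N, O, S, P, F, Cl, Br, I} — a cross-distance matrix D keeps Euclidean
distances only between opposite-origin atom pairs whose elements are both
active, and is +∞ elsewhere.

Sweeping a filtration parameter d over a grid builds a nested family of
Vietoris–Rips **hyperdigraphs**: every vertex subset with diameter ≤ d
becomes one directed hyperedge (k+1 ordered vertices for a k-edge, oriented
by descending electronegativity). On the admissible chain space
Ω_k = {x ∈ span(F_k) : ∂x ∈ span(F_{k−1})} the combinatorial Laplacian is

    L_k = B_{k+1} B_{k+1}ᵀ + B_kᵀ B_k,      L_0 = B_1 B_1ᵀ,

a PSD matrix whose zero-eigenvalue multiplicity is the Betti number β_k and
whose positive spectrum carries geometry. For nested scales a ≤ b the
persistent Laplacian Δ_k^{a,b} couples the two complexes; dim ker Δ_k^{a,b}
is the persistent Betti number. Six statistics of the L_0 spectrum — zero
multiplicity, then mean / std / min / max / sum of the positive
eigenvalues — are recorded per combination per grid value, giving a tensor
of shape **(T, 143, 6)** with T = 100 (large preset, 0→10 Å by 0.1) or
T = 50 (small preset, 2→12 Å by 0.2).

A transformer (scaled dot-product attention softmax(QKᵀ/√d_k)V, per-step
convolutional flattening of the 143×6 matrix, trainable multiscale position
embedding) is pretrained by masked reconstruction of unlabeled sequences
and fine-tuned with a scalar regression head on the first-position encoder
output. Attention scores (mean attention weight per filtration scale) and
saliency maps (input gradients) expose which interaction scales drive a
prediction.

## Worked example

The smallest instructive complex: one protein carbon 3.0 Å from one ligand
carbon.

```python
import numpy as np
from pthl import embed_complex, element_scheme
from pthl.structure import Atom, ComplexRegion, PROTEIN, LIGAND

region = ComplexRegion(
    atoms=[Atom(0, "C", (0.0, 0.0, 0.0), PROTEIN),
           Atom(1, "C", (3.0, 0.0, 0.0), LIGAND)],
    cutoff=12.0, source_id="demo")
seq = embed_complex(region, preset_name="small")
print("tensor shape:", seq.tensor.shape)
ci = element_scheme().combo_index(0, 0)        # protein {C} x ligand {C}
grid = seq.schedule.grid
for d in (2.8, 3.0, 3.2):
    ti = int(np.argmin(np.abs(grid - d)))
    print(f"d = {grid[ti]:.1f} A ->", seq.tensor[ti, ci])
```

prints

```
tensor shape: (50, 143, 6)
d = 2.8 A -> [2. 0. 0. 0. 0. 0.]
d = 3.0 A -> [1. 2. 0. 2. 2. 2.]
d = 3.2 A -> [1. 2. 0. 2. 2. 2.]
```

Below 3.0 Å the two atoms are disconnected (two zero eigenvalues, no
positive spectrum); once the filtration reaches the interatomic distance
the K₂ graph appears and its Laplacian spectrum {0, 2} yields one component
and positive-eigenvalue statistics (2, 0, 2, 2, 2). Exactly the 25
combinations containing carbon on both sides show this signature; the
other 118 stay zero.

The estimators compose in the usual sklearn way:

```python
from pthl import TopologicalEmbedder, TopologicalSequenceRegressor, scoring_metrics
from pthl.synthetic import synthetic_complex

complexes = [synthetic_complex(n_protein=20, n_ligand=6, box=12.0, seed=s)
             for s in range(16)]
embedder = TopologicalEmbedder(preset="small").fit()
X = embedder.transform(complexes)                  # (16, 50, 143, 6)
y = 4.0 + X[:, -1, :, 5].mean(axis=1)              # geometry-derived demo target
reg = TopologicalSequenceRegressor(finetune_steps=400, learning_rate=3e-3,
                                   batch_size=8, seed=0).fit(X, y)
fit = scoring_metrics(reg.predict(X), y)
print(f"training PCC = {fit.pcc:.3f}, RMSE = {fit.rmse:.3f} "
      f"({fit.rmse_kcal:.3f} kcal/mol)")
```

prints `training PCC = 0.979, RMSE = 1.069 (1.457 kcal/mol)`.

A CLI covers the same ground from a shell: `pthl region`, `pthl embed`,
`pthl fixtures`, `pthl eval ranking|docking|screening`, `pthl pretrain`,
`pthl finetune`, `pthl explain`.

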