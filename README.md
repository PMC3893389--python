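# distmap

Inter-residue **distance maps** as an intermediate representation for
protein structure work: build real-valued, binary and 4-class Cα maps from
structures, predict maps from sequence features with a 2D recursive neural
network, reconstruct Cα traces from (possibly noisy or predicted) maps by
simulated annealing, and score the results with Kabsch RMSD, GDT_TS and
TM-score.

## The problem

A protein's contact map — the boolean matrix of residue pairs closer than
a cutoff — is a popular translation/rotation-invariant intermediate for
structure prediction, but it is a heavily unbalanced classification target
(few contacts, many non-contacts) and throws away most geometric
information. This package works with the *real-valued* distance map
`d_ij = |r_i − r_j|` between Cα atoms instead, alongside its binary
(contact ⇔ d ≤ 12 Å) and 4-class (thresholds 8/13/19 Å) quantizations, so
the value of the extra information can be measured directly.

Three components:

1. **Maps and metrics** (`distmap.maps`, `distmap.metrics`) — map
   construction, controlled uniform noise injection (±a Å per residue
   pair, symmetric, clamped at 0.1 Å), and the standard structure
   similarity scores.
2. **Reconstruction** (`distmap.reconstruct`) — recover coordinates from a
   map plus a 3-state secondary-structure string by Metropolis annealing
   over the pseudo-energy

   ```
   E(S) = α₀α₁ Σ_{i<j} |d_ij − d_ij^map|            map restraints
        + Σ_{|i−j|=1} (d_ij − D_B)²                  virtual bonds, D_B = 3.803 Å
        + α₂ Σ_{|i−j|>1} 10·max(0, D_CL − d_ij)      clashes, D_CL = 4 Å
        + α₃ Σ_strands dist(d^strand, [D_min, D_max])²   strand end-to-end
   ```

   with α₀ = 0.2, α₁ = 0.025, α₂ = 0.5, α₃ = 2.0. Moves rotate one residue
   about the axis through its sequence neighbours (both neighbour
   distances are preserved exactly); coarse maps enter through flat-bottom
   interval penalties. Because a distance map carries no chirality, each
   run ends by refining the mirror image and keeping the lower-energy one.
3. **Prediction** (`distmap.encoders`, `distmap.rnn2d`) — a grid-to-grid
   2D-RNN with four hidden planes sweeping from the four map corners, fed
   with per-pair feature vectors (MSA column profiles, secondary
   structure, solvent accessibility and contact-density classes: 58 units;
   a 7-class physicochemical variant: 32; plus optional Göbel
   correlated-mutation and identity³-weighted template units), trained by
   seeded batched gradient descent, with checkpoint ensembling and a
   residual filtering network.

All fixtures are synthetic (`distmap.synthetic`): deterministic
protein-like folds (ideal helices, zigzag strands, compact self-avoiding
coils obeying the 4 Å clash floor), MSAs with controllable conservation and
co-mutation, and template hits with controllable noise/coverage/identity.

## Worked example

Reconstruct a 36-residue synthetic fold from its distance map corrupted by
±3 Å uniform noise:

```python
from distmap.synthetic import FoldSpec, make_fold
from distmap import (distance_map, add_noise, reconstruct,
                     AnnealingConfig, gdt_ts, tm_score)

spec = FoldSpec((("C", 3), ("H", 10), ("C", 4), ("E", 5), ("C", 4),
                 ("H", 8), ("C", 2)), seed=7)
native, ss = make_fold(spec)
noisy = add_noise(distance_map(native), amplitude=3.0, seed=11)
result = reconstruct(noisy, ss, config=AnnealingConfig(n_runs=10, seed=42),
                     native=native)
best = result.best_by_rmsd
print(f"best RMSD   {result.best_rmsd:.2f} A")
print(f"GDT_TS      {gdt_ts(best, native):.2f}")
print(f"TM-score    {tm_score(best, native):.2f}")
```

prints

```
best RMSD   1.63 A
GDT_TS      0.83
TM-score    0.65
```

i.e. even with ±3 Å of noise on every pair distance the best of ten
annealing runs recovers the fold to 1.6 Å with 83% of residues placeable
within the GDT cutoffs — the map's pairwise redundancy averages the noise
away. With the exact map the same protocol reaches ~0.5 Å.

The same workflow is available from the shell:

```bash
distmap fixtures --preset small --out fx/
distmap maps --pdb fx/fold00.pdb --kind distance --noise 3 --seed 11 -o noisy.map
distmap reconstruct --map noisy.map --ss fx/fold00.ss --native fx/fold00.pdb \
                    --runs 10 --seed 42 -o model.pdb --report runs.tsv
distmap score --model model.pdb --native fx/fold00.pdb
```

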