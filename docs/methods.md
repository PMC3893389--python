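# Methods

This note records the models implemented in `distmap`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Maps

The central object is the symmetric L×L matrix of Euclidean Cα–Cα
distances in Å. Binary maps use contact ⇔ d ≤ 12 Å (a 12 Å cutoff
reconstructs better than the more common 8 Å one); 4-class maps use the
half-open intervals [0,8), [8,13), [13,19), [19,∞) Å, with ties at a
threshold assigned to the lower class.

Noise injection draws one ε ~ Uniform(−a, +a) per unordered residue pair
and adds it to both (i,j) and (j,i), preserving symmetry. Uniform is the
maximum-entropy choice for an error budget stated as "±a Å"; the
distribution is isolated in one function and can be swapped. Perturbed
distances are clamped at 0.1 Å rather than resampled — a perturbed short
distance is information lost either way, and clamping keeps the draw
count independent of the map content (simpler reproducibility). Noisy
binary/4-class maps are defined as thresholded views of one noisy
distance map, so all three kinds of a given protein share the same
perturbed distances and kind comparisons are paired.

## Pseudo-energy and reconstruction

```
E(S) = α₀α₁ Σ_{i<j} |d_ij − d_ij^map|
     + Σ_{|i−j|=1} (d_ij − D_B)²
     + α₂ Σ_{|i−j|>1} 10·max(0, D_CL − d_ij)
     + α₃ Σ_strands dist(d^strand, [D_min(l), D_max(l)])²
```

Defaults: α₀ = 0.2, α₁ = 0.025 (distance penalty), α₂ = 0.5 (clashes),
α₃ = 2.0 (strand length), D_B = 3.803 Å (virtual Cα–Cα bond), D_CL = 4 Å
(clash floor). Choices needing comment:

* **Map term.** Absolute deviation, not squared — the L1 form is robust
  to the large per-pair errors of noisy maps. For coarse maps the term
  becomes the distance to the class/contact interval (zero inside, linear
  outside); the open top class of the 4-class map penalizes only
  distances below 19 Å. α₀ multiplies only the map term.
* **Clash term.** `10·max(0, D_CL − d)`: only violations are penalized,
  with slope 10 per Å. An exponential alternative `10^(D_CL − d)`
  (smoothly decaying outside the floor) is available via
  `PseudoEnergyParams(clash_form="exp10")`.
* **Strand term.** The allowed end-to-end distance of a β-strand is
  `3.436·l − 0.05107·l ∓ 0.04·l²` with `l` the number of virtual *bonds*
  spanned by the strand (run length − 1). Parameterized by residue count
  the interval is unreachable for short strands — three bonds of at most
  3.873 Å cannot reach the 12.9 Å the formula would demand — so native
  structures would violate their own constraints; with the bond-count
  reading a native strand with the canonical ~3.4 Å rise per bond sits
  inside its interval at every length. Two-residue runs carry no strand
  constraint (their single bond is already constrained).

**Initialization.** Conformations grow sequentially: bonds of length
Uniform(3.803 ± 0.07) Å in random directions, except that every maximal
helix run is placed as an ideal α-helix (rise 1.5 Å/residue, radius
2.3 Å, 100°/residue) in a random rigid orientation continuing from the
previous residue. Strand residues are initialized like coil — their
geometry is driven entirely by the strand term during refinement.

**Moves.** One residue moves per step, rotating about the axis through
its two sequence neighbours (Rodrigues rotation), which preserves both
neighbour distances exactly; chain ends rotate about a random axis
through their single neighbour at fixed bond length. Consequently the
multiset of bond lengths is an invariant of the whole refinement.

**Schedule.** 10,000 × L proposals per run. The starting temperature is
calibrated on 1,000 probe proposals from the start conformation so that
the mean uphill move would be accepted with probability ½
(T₀ = mean ΔE⁺ / ln 2); the temperature then decays geometrically to
10⁻⁵·T₀. The move amplitude θ_max shrinks from 180° to 5° linearly in the
*iteration count* (equivalently, linearly in log T). This pairing was
selected by a grid experiment on 30-residue exact-map fixtures:
amplitude-linear-in-T collapses θ within the first fifth of the schedule
(T decays geometrically) and stalls at 4–6 Å RMSD, while
iteration-linear θ with the deeper cooling floor converges to ~0.5 Å.

**Chirality.** Mirror images share the distance map, hence the energy
cannot distinguish them. Each run therefore reflects its result, refines
the mirror for 5,000 proposals (gentle: θ from 30°, temperature scaled
down tenfold) and keeps the lower-energy image; with ten independent runs
at least one correct-handedness conformation is essentially guaranteed.
Blind mode returns the lowest-energy conformation over runs (correct up
to chirality); evaluation mode, used by the benchmark, additionally
reports the best-by-RMSD run against a supplied native.

## Structure scores

* **Kabsch RMSD**: SVD-based least-squares superposition with the
  determinant correction, so the rotation is always proper.
* **GDT_TS**: mean over cutoffs 1/2/4/8 Å of the largest residue fraction
  superposable within the cutoff, where a set counts if its own
  least-squares fit keeps every member inside. Chains of ≤10 residues are
  scored by exact subset enumeration; longer chains use an
  iterative-extension search seeded from all contiguous segments of
  lengths 3/5/7 plus the global superposition, certifying at each round
  the largest deviation-ranked prefix whose refit stays within the
  cutoff. This is an LGA-style approximation; it matches the exact
  enumeration on small chains but is not the CASP reference
  implementation.
* **TM-score**: d₀ = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å for L ≤ 15;
  the same extension search over segment seeds of lengths L/2 and L/4,
  reporting the maximum.
* **Map RMSD**: RMS difference over pairs i<j, with optional sequence
  separation bands 6–11, 12–23 and ≥24.

## Input encodings

Per-pair vectors concatenate [profile_j, profile_k, ss_j, ss_k, rsa_j,
rsa_k, cd_j, cd_k]: 20-way MSA column frequencies (gaps excluded from the
denominator; an all-gap column degrades to a query one-hot) or the
7-class physicochemical clustering {AFILMV | NQSTWY | DE | HKR | C | G |
P}, 3-state secondary structure, 2-class solvent accessibility
(buried 0–25%, exposed 25–100%) and a 4-class contact density — 58 or 32
units. The correlation variant appends the Göbel correlated-mutation
score (59): the Pearson correlation, over sequence pairs, of PAM70
substitution scores at the two columns, with uniform sequence weights;
completely conserved columns and columns with >20% gaps score 0. The
template variant appends (60) the identity³-weighted template distance
d^T = Σ w_p d^p / Σ w_p and coverage c^T, with w_p = q_p·id_p³ and
q_p = 1/(resolution + R/20) for X-ray, 1/(resolution + R/10) for NMR;
pairs no template covers get the sentinel (0, 0), with c^T = 0 flagging
"no template information".

The filtering network sees 18 units per pair: the raw predicted distance,
the sequence separation, the protein length, and 15 means of 11×11
patches — one centred on (j,k) and 14 sliding along the
constant-separation diagonal at offsets ±11…±77, clipped at the map
edges, with fully off-map patches reusing the central mean. The patch
layout is isolated behind one function so it can be swapped.

## 2D-RNN

Four hidden planes of tanh units sweep the grid from its four corners;
plane p at (j,k) is fed by the cell input and the plane's own states at
its two upstream neighbours, so any output cell can depend on any input
cell. The output unit is *linear* in the distance (distances are
unbounded while tanh saturates; "all units tanh" is read as hidden
units), with a scaled-tanh alternative of range [0, 60] Å behind a
config switch. Predictions are symmetrized as (O+Oᵀ)/2 and clamped ≥0.
Hidden size defaults to 7 units per plane — desk-scale; configurable.

Training minimizes the squared distance error summed over i<j. The
optimizer is batched gradient descent over two-protein blocks with epoch
shuffling, a three-regime gradient-norm rescaling (tiny norms boosted,
mid-range passed, large norms clipped — the plateau-escape role of the
piecewise-linear update this architecture family historically used) plus
heavy-ball momentum 0.9; plain descent alone memorized the 5-protein
fixture only marginally (0.8–1.1 Å across init seeds) while momentum
reaches 0.3–0.5 Å robustly. The learning rate halves after 50
non-improving epochs; checkpoints are kept every 5 epochs; the last three
checkpoints of a run (and, across k-fold training, of every fold) are
ensembled by output averaging. Weights initialize zero-mean uniform with
per-unit fan-in scaling; the output bias starts at the mean target
distance. The filter network is residual (output = raw distance +
correction) with its output weights initialized to zero — an exact
pass-through at initialization — and is trained after freezing the
2D-RNN. Proteins longer than 200 residues are excluded by default:
training cost is quadratic in length.

## Synthetic data

`make_fold` emits geometric, not physical, folds: ideal α-helices, zigzag
strands (3.4 Å rise per bond, lateral amplitude chosen so bonds are
exactly 3.803 Å), coil bonds of exactly 3.803 Å, grown with a
centroid-biased orientation search under a hard 4 Å non-adjacent clash
floor, restarting deterministically from a sub-seed when growth
dead-ends. The compactness target is anchored to the empirical globular
scaling R_g ≈ 2.2·N^0.38 Å (measured mean at N=60: 10.4 Å vs 10.4
expected). Sequences are drawn from state-biased amino-acid propensities.
Solvent-accessibility and contact-density labels are derived from
contact counts — synthetic stand-ins for DSSP-style annotations, not
predictions. MSAs mutate the query i.i.d. per column with optional
coupled column pairs (drawn from a fixed list of residue couples) to
imprint a positive Göbel signal; templates are noisy, partially covered
copies of the native map with identity capped at 0.95.

What passing benchmarks on these fixtures shows: the annealer recovers
structures to the information limit of the map (it reaches energies at or
below the native's under the same constraints), the quantization and
noise orderings behave as expected at this scale, and the trainer can fit
its targets. What it does not show: performance on real proteins — real
maps have correlated errors, real strands pair into sheets, real MSAs
have phylogenetic structure, none of which the generator emulates.

A scale caveat worth stating explicitly: on 60-residue compact folds only
~19% of residue pairs exceed 19 Å, so a 4-class map retains nearly all of
the structural information and its 5–6 Å class intervals absorb ±6 Å
noise; the clear superiority of real-valued maps over 4-class maps under
heavy noise is a property of larger proteins (where most pairs fall in
the uninformative open top class) and appears here only as a statistical
tie at ±6 Å.

## Numerical notes

* Annealing runs in a compiled kernel with incremental ΔE bookkeeping,
  resynchronized against the full O(L²) energy every 2¹⁸ proposals and at
  the end, so reported energies are exact; all randomness flows through
  explicitly seeded generators and results are bitwise reproducible.
* The pseudo-energy of a native under its own exact map with ideal bonds
  vanishes identically in the map/clash/strand terms; the bond term keeps
  double-precision roundoff (~10⁻²⁸) because no floating-point coordinate
  set reproduces 3.803 bit-exactly through a square root.
* 2D-RNN gradients are analytic (reverse sweeps over the four planes) and
  agree with central finite differences to ~10⁻¹⁰ in directional tests.

## Known limitations

* Blind reconstruction cannot determine handedness from a map alone; the
  mirror step guarantees only a correct fold up to reflection.
* The GDT search is a documented approximation above 10 residues.
* The trainer is desk-scale; reproducing full-database training results
  is out of scope, and the 2D-RNN here is validated by memorization and
  gradient correctness, not by predictive benchmarks on real data.
* Chains are treated as contiguous; residue-numbering gaps only trigger a
  warning when consecutive Cα are >4.2 Å apart.
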