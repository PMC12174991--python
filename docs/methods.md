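# Methods

## The model

`xtalformer` predicts scalar properties of molecular crystals with a
multi-modal transformer encoder. A crystal enters along two routes:

* **Local modality — atom tokens.** The P1 cell is turned into a periodic
  interatomic graph (union of the covalent bond graph, bonds declared at
  ≤ 1.2 × the covalent-radius sum under periodic minimum image, and each
  atom's 8 nearest periodic neighbours within 8 Å). Two rounds of
  edge-gated message passing run on this graph, interleaved with
  line-graph updates that inject bond-angle information (angles between
  each atom's 6 shortest incident edges, expanded in a 16-Gaussian cosine
  basis). Each atom's graph embedding is concatenated with a positional
  embedding and projected to the encoder width.
* **Global modality — persistence-image tokens.** Growing spheres on the
  atom positions of a replicated supercell produces persistence diagrams
  of 1-D classes (channels) and 2-D classes (voids) under an alpha-complex
  filtration. Each diagram is scaled by its own maximum birth and maximum
  persistence onto [0, 1]², rasterized as a sum of unit-mass Gaussians
  (std = `spread`, default 0.15 in scaled units) on a `resolution`²
  grid (default 50×50), cut into `patch`² patches (default 5×5 → 100
  patches per image), and each patch is linearly projected to a token.
  Because per-image scaling discards the absolute scale, the two maxima
  follow each image as two [SCL] scalar tokens. Patch pixel values are
  rescaled by `resolution` before projection (unit-mass rasterization
  leaves pixels at ~1/resolution², which would make image tokens invisible
  next to the other embeddings), and each patch token carries a learned
  position embedding for its location in the image — that location encodes
  the (birth, persistence) coordinates.

Token order is `[CLS] ATOM×n [SEP] PATCH1D×100 SCL SCL [SEP] PATCH2D×100
SCL SCL`; with images disabled the sequence ends after the first [SEP].
The encoder is a BERT-shaped pre-norm transformer (defaults L=12, H=768,
A=12). `[CLS]` carries the whole-crystal representation.

## Positional embeddings

The default ("relative") positional embedding is built from the randomly
perturbed structure (i.i.d. Gaussian displacements, σ = 0.05 Å, fresh seed
each epoch): for every atom, (a) its sorted periodic distances to its k = 8
nearest neighbours and (b) its 4 shortest periodic-image distances to each
of 8 *anchor atoms* drawn at random per structure per epoch (the same
anchors for all atoms), every distance expanded in a fixed 16-Gaussian
radial basis on 0–8 Å and linearly projected. All ingredients are
interatomic distances, so the embedding is exactly invariant under rigid
rotations and translations; the deeper anchor image shells carry cell
geometry (lengths of lattice-vector combinations).

The anchor block deserves a note. Features that are per-atom invariants
make symmetry-equivalent atoms of a Z′ = 1 crystal *identical*, and any
question that must separate equivalent copies — notably "do these two
atoms belong to the same molecule?" — becomes unanswerable in principle.
Distances to shared random reference atoms break that degeneracy while
preserving rigid-motion invariance, and they give the encoder a handle on
which atoms are mutually close. Empirically this is what makes the
atom-pair classification task learnable on single-component crystals.

The "absolute" mode (an ablation) discretises each fractional coordinate
into 100 bins, looks each axis up in its own embedding table and sums. It
deliberately violates translational invariance; it exists to measure the
cost of that violation.

## Pre-training

Four self-supervised tasks, summed with unit weights:

* **MAP** (masked atom prediction): `max(1, round(0.15 n))` atoms are
  selected per crystal; each selected atom is replaced by the [MASK]
  identity with probability 0.8, by a random *different* element with 0.1,
  and left unchanged with 0.1 (i.i.d. draws). The mask applies both at the
  token and at the graph level, so a hidden element cannot leak through
  messages. Softmax cross-entropy over the element vocabulary.
* **APC** (atom pair classification): 200 pairs per crystal, exactly half
  intra- and half inter-molecular, sampled uniformly with replacement
  (molecule labels are connected components of the periodic bond graph).
  The logit is `g([h_i;h_j]) + g([h_j;h_i])` with a shared two-layer head
  `g`, exactly symmetric by construction. Cells with a single molecule
  disable the task (zero loss contribution).
* **CDP** (crystal density prediction): one dense layer on [CLS]; squared
  error on z-scored density (the head is affine, so z-scoring is a pure
  reparametrisation); MAE reported in g cm⁻³.
* **SEP** (symmetry element prediction): 7-dim multi-hot label — in fixed
  bit order *(no element, inversion center, mirror plane, rotation axis,
  screw axis, rotoinversion axis, glide plane)* — derived by classifying
  every operation of the space group (intrinsic translation = the
  translation component averaged over the cyclic group of the rotation
  part, reduced mod 1; tolerance 1e-6). Per-element binary cross-entropy
  with inverse-frequency weights w_i ∝ p_i^(−1/ε), ε = 1.1, computed over
  the training set with add-one smoothing and normalised to mean 1. When a
  corpus contains no example at all of some element class (the toy corpus
  uses only space groups 1, 2, 4, 19), the absent classes' smoothed
  weights are enormous yet their loss terms vanish almost immediately; the
  pipeline therefore rescales the weight vector so the *observed* classes
  average to 1, which preserves the rare-is-heavier ordering and keeps the
  informative classes trained. The metric is exact match: all seven
  thresholded bits must equal the label.

Optimisation follows the production recipe: AdamW (weight decay 1e-2),
learning-rate warm-up over the first 5% of steps, then linear decay to
zero. Production defaults are 50 epochs at batch 512 and peak lr 1e-4.

## Fine-tuning, few-shot, metrics

Fine-tuning re-initialises a single dense head on [CLS] and trains all
weights (default 50 epochs, batch 32, same optimiser and schedule);
property tables are split 80/10/10 at random with a stored seed, sorted by
structure id first so the split is order-invariant; the best-validation-MAE
epoch is evaluated on the test split. Metrics: MAE, R² = 1 − SS_res/SS_tot,
and top-n overlap (|top-n(pred) ∩ top-n(true)|, direction `lowest` for
energies and `highest` for capacities, ties broken by stable record
order).

The few-shot protocol holds out one molecular family: stage 1 fine-tunes
on the remaining families (90/10 train/val); stage 2 further fine-tunes on
k sampled holdout records (k = 0 is zero-shot; when k ≥ 20, 10% of the k
are carved out for validation) and always evaluates on the untouched
holdout remainder.

## Attribution

Attention rollout: per layer, heads are averaged, a residual identity is
mixed in (A' = 0.5 I + 0.5 A, rows renormalised) and the matrices are
multiplied across layers; the [CLS] row of the product scores every token.
Scores are normalised over non-special tokens (atoms, patches, [SCL]) so
modality shares are comparable; exported overlays clip atom scores below
0.005. Representative cycles recorded during the boundary-matrix reduction
map high-persistence diagram points back to the atoms of the original cell
(supercell indices folded modulo replication).

## Numerical implementation

The neural components run on a small tape-based reverse-mode autodiff
engine over float32 numpy arrays written for this package (operations:
broadcasting arithmetic, matmul, softmax with additive masks, layer norm,
GELU/sigmoid/tanh, gather/scatter/segment-sum; AdamW). At the problem
sizes this package targets a CPU covers training comfortably, and the
absence of a heavyweight framework keeps the install surface small.
Determinism: all randomness flows through explicitly seeded
`numpy.random.Generator` instances; two runs with the same seeds produce
identical logs on one thread (losses to float32 accumulation order).

Persistent homology is computed from `scipy.spatial.Delaunay`
triangulations: alpha values are assigned top-down (a face is Gabriel if
its smallest circumsphere contains no opposite Delaunay vertex, else it
inherits the minimum over cofaces), followed by a monotone cleanup pass,
and pairs come from standard Z/2 boundary-matrix reduction. Correctness is
pinned by an independent brute-force Čech filtration (minimum enclosing
spheres + naive reduction) in the test suite; the two filtrations describe
the same union of balls and must agree exactly. Degenerate inputs: clouds
with fewer than 5 points yield empty diagrams; zero-persistence pairs are
dropped at 1e-9 Å.

The supercell for the filtration replicates the cell until every
perpendicular width reaches `min_extent` (default 20 Å) — a finite-window
approximation to true periodic (torus) homology, adequate for features up
to roughly half the window and consistent with sphere-growing tooling used
in this field, at bounded cost.

## The synthetic crystal generator

Fixtures place a rigid template (N₂, Cl₂, bent water, 6-ring, 12-ring) at
a random general position of space group 1, 2, 4 or 19, expand to P1, and
jitter the asymmetric unit (σ = 0.03 Å). These four groups realise three
distinct label classes (no element / inversion only / screw only). Cell
angles follow the crystal system the group mandates (triclinic, monoclinic
with β ∈ 95–115°, orthorhombic); cell volumes are drawn so densities span
roughly the real solids' ranges (N₂ 0.6–1.0, Cl₂ 1.0–1.6, water 0.65–1.0
g cm⁻³). Placements with intermolecular contacts under 2.6 Å are retried;
this floor is a realistic van der Waals contact and guarantees
intra-molecular distances (≤ 2.0 Å) are separable from intermolecular
ones, so molecule-membership ground truth is well-posed. Pore fixtures
stack 12-membered rings into straight channels whose radius (ring-centre
to atom-centre) is set by construction.

What the generator does **not** emulate: real chemistry (no force field —
placements are geometric), conformational flexibility, Z′ > 1,
multi-component cells, disorder, and realistic space-group statistics.
Passing tests on these fixtures demonstrates that the machinery —
featurization, sequence assembly, four-task optimisation, transfer — works
end to end and that the advertised invariances hold exactly; it does not
demonstrate chemical accuracy on experimental crystals.

## Desk-scale study conditions

The end-to-end checks run one fixed recipe (`xtalformer.toy`): 240
fixtures (200 train / 40 held out; N₂, Cl₂, water over the four groups —
four element types), reduced encoder L=2, H=64, A=4 with 2× feed-forward
width, 30×30 persistence images (5×5 patches) on a 12 Å supercell extent,
50 pre-training epochs. Sampling-scheme constants stay at production
values (15% masking, 80/10/10, 200 pairs, ε = 1.1, wd 1e-2, 5% warm-up);
the optimisation scale is sized to the corpus — batch 8, peak lr 2e-3 —
because 50 epochs of a 200-structure corpus at batch 512/lr 1e-4 is ~50
optimisation steps, far short of convergence for any model. The
fine-tuning comparison (pre-trained vs random initialisation) uses 100
density-labelled fixtures, 12 epochs, five seeds, reporting the median
test MAE of both arms.

At this scale the four self-supervised tasks do not converge equally: the
masked-atom, pair-classification and density tasks reach their targets
comfortably, while symmetry-element exact match plateaus around 0.7–0.85
across seeds. The residual errors are concentrated in separating
inversion-only from screw-only two-molecule cells, for which the
rotation/translation-invariant features carry only weak evidence at this
corpus size; the no-element and screw-only four-molecule classes are
classified essentially perfectly.

## Known limitations

* The alpha filtration assumes points in general position; highly
  degenerate inputs (exact grids) rely on Qhull's tie-breaking and the
  monotone cleanup, and representative cycles are whatever the reduction
  produces — homologous but not geometrically minimal.
* The finite supercell window truncates features larger than
  ~`min_extent`/2 and can split a periodic channel's class into boundary
  artefacts; `min_extent` trades cost against fidelity.
* The relative positional scheme is this package's concrete construction
  (distance k-NN + random anchors) satisfying the stated invariances;
  other constructions with the same contract are possible.
* Space-group detection (`symmetry.detect_space_group`) tests standard
  settings with the origin as given — a fixture-validation oracle, not a
  general symmetry finder.
* The transformer trains on CPU at toy scale; production-scale
  pre-training (10⁵–10⁶ structures, H=768) would require a GPU framework
  backend, which is outside this package's scope.
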