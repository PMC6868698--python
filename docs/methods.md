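# Methods

## The model

The package predicts unknown drug–disease associations from a binary
adjacency matrix `A` (rows = diseases, columns = drugs) plus two side
similarity sources: chemical-structure similarity between drugs and
semantic similarity between diseases. The pipeline has four stages.

**1. Interaction-profile sigmoid kernels.** Each drug's interaction
profile is its column of `A` (a 0/1 vector over diseases); each disease's
profile is its row. The drug kernel is

    Kr(i, j) = tanh( a · ⟨V(dᵢ), V(dⱼ)⟩ + r ),   a = 1/N,  r = 0,

with `N` the profile length (number of diseases); the disease kernel `Ki`
uses `b = 1/M` (number of drugs) and `z = 0`. With these defaults entries
lie in `[0, tanh 1]`. The kernel is the only stage that sees the
association labels, so it is recomputed per cross-validation fold from a
training view of `A`.

**2. Side-similarity adjustment and cohesive-module boosting.** Raw drug
structure similarity is the Tanimoto coefficient of path-based molecular
fingerprints (RDKit `RDKitFP`, 2048 bits; drugs without parseable SMILES
get zero rows and rely on the kernel branch). Disease semantic similarity
(MimMiner-style) is consumed as a precomputed matrix. Both are passed
through a logistic contrast map

    L(x) = 1 / (1 + exp(c·x + f)),   c = −15,  f = ln 9999,

which sends `L(0) = 10⁻⁴` and `L(1) ≈ 0.997`: weak similarities collapse
towards zero, strong ones are amplified, and the ordering is preserved
(monotone for `c < 0`). A weighted co-association graph is then built on
each axis (edge weight = number of shared partners in the training view),
and cohesive modules are found by a deterministic greedy ClusterONE-style
search maximising

    f(C) = W_in(C) / ( W_in(C) + W_bound(C) + p·|C| ),

with per-vertex penalty `p = 2`, seeds in descending weighted-degree
order, single best add/remove moves, transitive merging of grown groups
with overlap score `|C₁∩C₂|²/(|C₁||C₂|) > 0.8`, and a density filter that
defaults to keeping everything. Pairs co-resident in a module get their
similarity multiplied by `(1 + f(C))` (maximum f over shared modules);
any value at or above 0.99 is emitted as exactly 0.99, so the cap is
idempotent and every matrix that reaches the encoder lives in `[0, 0.99]`.

**3. Fusion and pair descriptors.** A pair takes the kernel value when
both entities have non-empty training profiles, and the enhanced side
value otherwise — the standard fallback for entities with no known
associations, whose kernel row is uninformatively `tanh 0 = 0`. Matrix
diagonals follow the side matrix (0.99 after the cap) so self-similarity
survives uniformly. The descriptor of a pair is the concatenation of its
fused drug-similarity row and disease-similarity row, zero-padded to the
next perfect square and reshaped row-major to an `s×s` grid,
`s = ceil(√(n_drugs + n_diseases))`.

**4. Encoder and classifier.** A small convolutional network — valid
convolution with an `k×k` kernel bank, sigmoid activations, `2×2` max
pooling (ceil mode at ragged edges), a sigmoid dense layer and a logistic
output unit — is trained on binary cross-entropy plus an L2 weight
penalty `(λ/2)‖W‖²`, with Adam (plain SGD available). The penultimate
dense activations are the learned feature vectors; a random forest
(500 trees, √-features per split) classifies them. The network is
implemented directly on numpy (im2col convolution, exact backprop), which
keeps every stage checkable against brute-force oracles and makes runs
bit-reproducible from a single seed; gradients are verified against
central finite differences in the test suite.

## Evaluation protocol

Positives are all known associations; an equal number of negatives is
drawn uniformly from the zero cells once per experiment (balanced 1:1,
seedable). Stratified tenfold cross-validation zeroes each fold's test
positives out of the association matrix and recomputes kernels, modules,
fusion, encoder and classifier from that training view only; a marker
test asserts that a positive planted in a test fold leaves no trace in
the training-view matrices. `paper_mode=True` instead derives
similarities once from the full matrix — the optimistic variant some
published protocols use — and is exposed deliberately so the difference
is measurable. Accuracy, precision, recall and F1 are computed at a 0.5
probability threshold (zero-denominator conventions: precision 0 with a
warning, F1 0); AUC uses the midrank Mann–Whitney estimator. The
case-study protocol removes every association of one target disease from
training, trains on the rest plus balanced negatives (never sampling from
the target's row), and ranks all drugs for that disease.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| kernel scale / offset | 1/dim, 0 | sigmoid-kernel bandwidth over profiles |
| logistic c, f | −15, ln 9999 | contrast of the side-similarity rescaling |
| cluster penalty p | 2 per vertex | unobserved-edge penalty in f(C) |
| overlap / density thresholds | 0.8 / 0 | module merging and filtering |
| conv kernel | 16 (auto-shrunk) | convolution window side |
| n_filters / dense_units | 16 / 64 | encoder widths |
| epochs / batch / lr / λ | 200 / 32 / 5·10⁻³ / 10⁻⁴ | encoder training |
| n_trees | 500 | random-forest size |

The 16×16 convolution window is used whenever the descriptor grid allows
(e.g. 593 drugs + 313 diseases → 31×31 grids). `EncoderConfig.for_grid`
shrinks it to `min(16, s−4)` (floor 2) on smaller grids so a non-trivial
feature map survives pooling; the default synthetic benchmark (10×10
grids) trains with a 6×6 window. The training length and learning rate
were tuned on the synthetic benchmark: 50 epochs at lr 10⁻³ leaves the
sigmoid network grossly underfit (training loss barely moves), while 200
epochs at 5·10⁻³ fits it well; λ ≥ 10⁻³ collapses the encoder to chance,
so λ = 10⁻⁴ is kept.

## The synthetic benchmark and what it can show

`synthgen` plants equal-sized co-blocks (round-robin assignment) over
drugs and diseases: matched-block pairs associate with probability 0.4,
others with 0.02 (60 drugs × 40 diseases, 4 blocks by default), and side
similarities equal 0.6 × same-block indicator plus Gaussian noise
(sd 0.1), symmetrised, clipped to [0, 1], unit diagonal. This exercises
every stage — kernels see real profile structure, ClusterONE has true
modules to find, low rates leave some entities with empty profiles so the
fusion fallback fires — while remaining fully reproducible.

Its deliberate idealisation has a quantifiable consequence: the generator
has no per-entity propensity variation, so conditional on block
membership the association entries are independent coin flips, and the
Bayes-optimal score for a held-out pair is the block-match indicator.
With the default rates the expected positive/negative within-block
fractions are 240/276 and 360/2124, giving an expected oracle AUC of
0.850 (measured 0.853 on the seed-0 splits with true block labels). The
learned pipeline reaches mean CV AUC ≈ 0.78–0.83, i.e. close to but
necessarily below that ceiling; `scripts/acceptance.py` reports the
honest measured value. Passing tests on this benchmark therefore
demonstrate correct mechanics and leakage-free protocol, not the
absolute accuracy attainable on real pharmacological data, where entity
heterogeneity gives the kernels far more to work with. The case-study
fixture plants one well-annotated disease (its full 15-drug co-block plus
5 random out-of-block drugs, 20 positives) and checks that
leave-one-disease-out ranking recovers ≥ 15 of them in the top 20;
out-of-block plants are by construction nearly unrecoverable, mirroring
the partial-confirmation structure of real case studies.

Test and acceptance problem sizes (10-fold CV on the 60×40 default, 3-fold
reduced-epoch runs for comparative checks) are the package's chosen
desk-scale conditions; full-size benchmark matrices are read through the
same `dataio` layout when available (see README).

## Numerical and degenerate-input choices

- Similarity matrices must be symmetric to 10⁻⁹; readers can average
  `S` and `Sᵀ` on request (logged). Values outside [0, 1] by ≤ 10⁻⁶ are
  clipped silently, larger excursions with a warning.
- Kernel matrices are exactly symmetrised (`(K+Kᵀ)/2`) against float
  round-off.
- Greedy module growth requires a strict cohesiveness gain (> 10⁻¹²), so
  it terminates; ties prefer adds over removals and lexicographically
  smaller vertices, making clustering exactly deterministic.
- Max-pool ties route gradients to the first maximum; pooling pads ragged
  edges with −∞ (ceil mode).
- Empty-union Tanimoto is 0; empty graphs yield empty cluster sets;
  single-class training labels raise.
- Ranked outputs break score ties lexicographically by drug id, so files
  are stable across runs.
- A single experiment seed fans out to per-stage seeds via CRC32 of
  `"stage:seed"`, keeping all stage seeds below 2³¹ and letting stages be
  rerun in isolation.

## Known limitations

- One conv/pool block; a depth parameter is not exposed because grids of
  practical size (≤ 33×33) leave no room for a second 16×16 stage.
- The SVM comparator uses `SVC(probability=True)` (Platt scaling), whose
  probabilities are only approximately calibrated.
- Disease semantic similarity is an input; the package does not recompute
  it from MeSH text.
- The per-fold similarity recomputation is quadratic in entity counts and
  runs ClusterONE twice per fold; on very large matrices `paper_mode` or
  cached fused matrices (`drugrelink similarity`) are the practical route.
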