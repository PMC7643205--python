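# Methods

## Problem setting

`molscreen` treats drug–target interaction (DTI) prediction as per-target
binary classification: for a fixed target protein, a model maps a small
molecule to *active* (interacting) or *inactive*. Instead of precomputed
descriptors such as circular fingerprints, the featurization is the
molecule's own 2-D skeletal drawing, rasterized to a square pixel grid, and
the classifier is a deep convolutional network that learns binding-relevant
substructure directly from the image. The package covers the full
workflow around that idea — bioactivity curation, rendering, training and
model selection, bias-aware benchmarking, evaluation statistics, and batch
screening — plus synthetic generators so every stage can be exercised
offline with known ground truth.

## Curation pipeline

Raw ChEMBL-style measurement tables are reduced to per-target labelled sets
in five stages:

1. **Attribute filters.** Keep records with target type `single_protein`,
   an allowed taxon, assay type `binding` (functional assays are ambiguous
   about physical binding and are discarded), an allowed standard type
   (IC50, EC50, AC50, Ki, Kd, Potency), and — by default — a pChEMBL value,
   which marks a curated, comparable measurement.
2. **Median aggregation.** Replicate measurements of the same
   (compound, target) pair, pooled across standard types, collapse to their
   median value; the surviving record's provenance fields come from the
   replicate closest to the median (ties to the earliest record). Even
   counts use the mean of the central pair. The operation is idempotent.
3. **Threshold labelling.** Active iff value ≤ 10 µM, inactive iff
   ≥ 20 µM; the (10, 20) µM gray zone is excluded. Censored relations are
   resolved conservatively: `<`/`<=` can only support an active call,
   `>`/`>=` only an inactive call; contradictory records are dropped. A
   missing relation is treated as `=`.
4. **Target selection.** Only targets with ≥ 100 actives are modelled
   (configurable; the tests use smaller floors on toy data).
5. **Negative enrichment / balancing.** Targets with more inactives than
   actives are down-sampled (seeded). Targets short of inactives borrow
   known inactives of sequence-similar targets in descending identity
   order, with a 20% identity floor, never duplicating a compound the
   recipient already holds; ties at equal identity break lexicographically
   by target id. If eligible donors run out, a shortfall flag is set rather
   than padding with arbitrary compounds.

Sequence similarity is percent identity over the full alignment length of a
global Needleman–Wunsch alignment (match +1, mismatch −1, affine gaps:
open −4, extend −2; Biopython `PairwiseAligner`). The affine penalties were
chosen so that point-mutated sequence pairs align gap-free, making percent
identity equal the fraction of conserved positions; a cheap-gap scheme
inflates identity between distant sequences by manufacturing spurious
matched columns. An external search tool could be substituted behind the
same interface; only the ordering of donors matters downstream.

## Image featurization

Rendering must be a pure function of the molecular graph. The input SMILES
is canonicalized with stereochemistry stripped (stereo is unreliable in
bulk bioactivity data and is deliberately ignored), re-parsed so the atom
order is canonical, and 2-D coordinates are computed from that canonical
order. The depiction style is pinned: anti-aliased 1-pixel bond lines,
double/triple bonds as parallel lines offset 0.18 coordinate units,
heteroatoms as filled disks whose radius follows covalent-size ordering
(S, Cl, Br, I larger than N, O, F), carbons implicit. The grid is single
channel in [0, 1] with 1 = ink, fitted with an 8% margin and a capped
scale so single atoms are not magnified absurdly. Two SMILES spellings of
one molecule therefore produce bit-identical grids, which is the contract
the training determinism rests on. Default side is 200 px (100 and 400 are
the other studied sizes; 100 trains ~4× faster and is used for the smoke
tests, at some cost in resolving large molecules).

## Network architecture and training

The classifier is five convolution + max-pooling blocks followed by one
fully connected layer and a two-unit softmax. Convolutions use stride 1 and
no padding, so an N×N input under an f×f filter yields (N−f+1)×(N−f+1);
pooling is 2×2 stride 2 with floor semantics. Filter sizes clamp to the
current side length, which keeps the five-block stack feasible down to
64-px inputs. ReLU follows each convolution and the dense layer; dropout
(keep probability 0.5–0.8) acts on the dense layer during training only.

Training minimizes mini-batch binary cross-entropy with Adam
(β₁ = 0.9, β₂ = 0.999). Defaults: learning rate 1e-3, batch 32, 20 epochs,
filter counts (8, 16, 32, 32, 32), f = 5, dense width 128. The
implementation is pure NumPy: forward convolutions are one GEMM over an
im2col patch matrix; input gradients accumulate with one GEMM per filter
offset (f² small matrix products instead of a scatter-add, which keeps the
backward pass BLAS-bound). Max-pool gradients split equally among tied
maxima. All parameters are float32; weight init is He-normal. Every
stochastic choice — init, shuffling, dropout masks, splits — derives from
one integer seed, so identical (data, config, seed) reproduces identical
loss traces bit for bit. Gradients were verified against central finite
differences in float64 (max relative error ~2e-7).

Model selection is a grid search maximizing validation MCC. The data split
is stratified 80/20 into train+validation vs test, then 80/20 again into
train vs validation. The test partition is tagged at split time and never
read during search — only the final evaluation touches it. Ties prefer
fewer parameters, then the lower grid index. The selected model is the
validation-best fit as-is; retraining on train+validation is available but
not the default. The default grid (learning rate {1e-3, 1e-4} × dropout
keep {0.5, 0.8} × dense width {128, 256}, 20 epochs) is a desk-scale
stand-in for a cluster-scale sweep. The classification threshold is fixed
at 0.5 (softmax symmetry), overridable at screening time. Alternative
backbones can be supplied by conforming to the same
build/train/predict_proba surface; only the in-house network ships.

## Evaluation statistics

Confusion-count metrics (accuracy, precision, recall, F1, MCC) are
evaluated from their defining formulas; any zero product in a denominator
yields 0 rather than NaN so leaderboards stay total-ordered. AUROC is the
rank-based (Mann–Whitney) form with tied scores counted one half.
Cross-validation is stratified k-fold (default k = 10), seeded, with each
compound tested exactly once. Method comparisons use two-sided t-tests at
a Bonferroni-corrected threshold α/m; the paired variant is the default
because folds are matched across methods (Welch's unpaired form is a
flag). Agreement between per-target performance profiles uses Spearman
rank correlation with average ranks for ties.

## Benchmarks and bias diagnostics

*Scaffold split.* Murcko scaffold groups (ring systems plus linkers; the
empty scaffold pools all acyclic molecules) are packed greedily into the
test bin, largest group first with seeded tie-breaks, until the requested
fraction would be overshot. Disjointness of scaffolds across train/test is
exact by construction; the achieved fraction is only as fine as the group
sizes. A library with a single scaffold cannot be split and raises. Greedy
largest-first was preferred over random group assignment because it is
deterministic and lands nearer the requested fraction on skewed scaffold
distributions.

*Temporal split.* Records before the cutoff year (default 2013) train;
records at or after it test. Missing years are excluded with a warning.
Raising the cutoff never moves a compound out of train (monotonicity).

*Negative-selection-bias filter.* An inactive compound whose every
measurement against every target lies in the inactive range is removed:
one active-range data point anywhere is accepted as evidence the molecule
is not a universal non-binder.

*Similarity audit.* For one target's training set, mean ECFP4 Tanimoto
similarity over all inactive–inactive pairs is compared with the mean over
all active–inactive pairs (distinct compounds only; a molecule present in
both sets contributes no self-pair), with Welch's t-test at 95%
confidence. Inactives significantly more self-similar than they are
similar to actives indicate a negative set separable for structure-only
reasons. All pairs are used by default, with an optional subsampling cap
for very large sets.

*Scaffold enrichment.* Each scaffold's occurrences in the active and
inactive sets of two target groups form a 2×2 table tested with a
two-sided Fisher exact test; significance is strict p < 1e-5 and the
direction of enrichment is reported separately (the test itself is
two-sided because no direction is privileged a priori). Generalized
scaffolds (atom types and bond orders collapsed) are supported through the
same interface.

## Screening and conversions

`screen_library` streams a SMILES library in fixed-size batches, renders
each parseable compound once per required image size, scores it against
every model, and emits either all calls or actives only; unparseable
entries are logged and skipped, and output is order-independent as a set.
Conversions: Kd = exp(ΔG/RT) with RT defaulting to 0.5905 kcal/mol
(~297 K) — the single RT consistent with the standard docking-report
conversions this package reproduces, with a 298.15 K preset available —
and pChEMBL→nM as 10^(9−p).

## Synthetic fixtures

The molecule generator decorates a pool of ring scaffolds (benzene,
pyridine, pyrimidine, cyclohexane, piperidine, naphthalene, …) with 1–3
substituents from a fixed sulfur-free fragment alphabet; actives
additionally receive a planted sulfonamide group (S(=O)(=O)N), verified by
substructure match, which no inactive can contain by construction. The
planted group is visually salient in the renderer (a large sulfur disk
flanked by two oxygens), so a zero-noise library is separable by the image
classifier by design — the learnability smoke test checks that the model
recovers a signal the fixture guarantees exists. Optional label noise is
applied after generation and the flipped ids recorded. What these fixtures
do **not** emulate: realistic ChEMBL value distributions, assay ontology,
activity cliffs, or chemotype diversity — passing tests demonstrate the
machinery is correct, not that real-data performance matches any particular
level.

The bioactivity-table generator plants exactly one defect per defective
record (wrong target type, wrong taxon, functional assay, wrong standard
type, missing pChEMBL), plus gray-zone values and replicate triples with a
known median, and derives every stage's expected survivor count from the
construction plan alone — the manifest is an oracle computed without
running the pipeline it audits.

The sequence generator realizes requested percent identities **to the
first (reference) sequence** by point-mutating a star topology; arbitrary
pairwise identity matrices are not generally achievable by independent
mutation and are out of scope. Realized identities match requests within
rounding for identities above the alignment-noise floor (~20%); fully
mutated sequences still measure a few percent identity through chance
alignment matches.

## Problem sizes and numerical choices

The test suite trains the full five-block network at 100×100 on a
400-molecule fixture (the learnability check) and at 64×64 for determinism
checks; the Fisher enumeration covers every 2×2 table with all margins
≤ 30 (164 176 tables) against an exact `math.comb` hypergeometric oracle.
These sizes were chosen so the whole suite runs on a single CPU in a few
minutes while still exercising every code path at full depth. Degenerate
inputs are contracts, not accidents: empty batches score to empty arrays,
single-class truth vectors make AUROC raise, all-zero enrichment tables
raise, and an unsplittable single-scaffold library raises rather than
silently leaking.

## Known limitations

- The renderer draws heteroatoms as element-coded disks rather than glyph
  labels; models trained on these rasters are not transferable to
  letter-labelled depictions.
- Grid search retrains one model per grid point sequentially; there is no
  parallel executor.
- Negative enrichment recomputes pairwise identities per recipient without
  caching across targets; for hundreds of targets an external search tool
  behind the same interface is the right substitution.
- The conversion RT is a convention, not a measured temperature; both RT
  presets are approximations of unstated experimental conditions.
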