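# Methods

`enhancerkit` implements a two-stage sequence-modelling strategy for
tissue-specific enhancers, exercised end-to-end on a synthetic genome with a
known regulatory grammar.

## The modelling strategy

**Stage 1 — sequence-to-accessibility.** A compact CNN regresses
log-scaled chromatin accessibility, `log2(mean signal + 1)`, from 1,001 bp
one-hot DNA windows (A=[1,0,0,0], C=[0,1,0,0], G=[0,0,1,0], T=[0,0,0,1];
all-zero rows for N). Training data are peak regions resized to 1,001 bp
plus inaccessible control bins sampled at ≥ 1.5 kb from every peak or
annotated element; windows are tiled around region centers (5 windows at
200 bp stride, or 17 at 50 bp stride for the dense mode), every sequence
gains a reverse-complement twin, and controls are down-sampled to ~1.5×
the augmented positives. Loss is MSE (Adam, batch 128, early stopping on
validation loss with best-weight restoration).

**Stage 2 — sequence-to-activity.** The regression weights initialize a
classifier with a sigmoid head (implemented as a linear output unit plus
sigmoid, so pre-sigmoid logits stay directly extractable). All layers are
fine-tuned with binary cross-entropy on per-tissue enhancer activity bits.
A direct-training baseline (same architecture, random initialization) and a
scaled-accessibility baseline (regression outputs min-max scaled to [0,1]
and used as activity scores) quantify what transfer learning adds.

**Cross-validation.** Regions are grouped into gap-linked blocks
(neighbours < 1.5 kb apart share a block) and blocks are distributed
greedily — largest first, into the currently smallest fold — over 20 folds,
so no two regions < 1.5 kb apart can land in different folds. One
chromosome is excluded from training and validation entirely and serves as
the fixed shared test set. Augmentation happens after fold assignment.

**Evaluation.** Per-tissue Pearson correlation on the holdout chromosome;
delta-PCC on tissue-pair differences (sensitive to tissue-specific
signal); K-means (k=6, 10 restarts) on z-scored observed values with
predicted values assigned to the observed centroids; and for classifiers a
precision-first criterion: PPV = TP/(TP+FP) scanned over a 1,001-point
threshold grid, reporting the maximum subject to ≥ 100 predicted
positives. The activity test set is the tiled holdout windows plus their
reverse complements. Control rejection is the fraction of random and of
inaccessible-genomic sequences scored below the max-PPV threshold.

**Attribution.** Nucleotide contribution scores are expected gradients:
for each of `n_refs` dinucleotide-shuffled references (exact Eulerian-trail
shuffles, so the dinucleotide count multiset is conserved), gradients are
averaged along the straight-line path from reference to input and
projected so that the *actual* scores satisfy the completeness identity
`sum(actual) ≈ f(x) − mean_ref f(ref)`. Scores are averaged over ensemble
members. Path discretization controls the completeness error (O(1/steps));
the defaults (100 references, 20 steps) keep it within a few percent on
trained models, and tests verify < 5% on motif-rich sequences.

**Motif-level summaries.** PWMs are scanned by log2 odds against a
background estimated from the scanned sequences, with the per-PWM score
threshold set by exact dynamic programming over the discretized score
distribution at p ≤ 5×10⁻⁵ (both strands; probabilities get a 10⁻³
pseudocount). Per-instance mean contribution scores are averaged per PWM
and z-scored across PWMs per tissue and task; PWMs with max z ≥ 2 are
kept, one representative per redundancy group (highest z), clipped at the
5th/95th percentiles, and clustered (complete-linkage, Euclidean, 4-way
cut). TF-set enrichment uses Fisher's exact test with Benjamini–Hochberg
FDR over all cluster × category pairs.

**Design.** Seed sequences are drawn from a first-order Markov chain
matched to the pooled dinucleotide frequencies of a reference set. A
continuous relaxation of the one-hot input (per-position softmax over
unconstrained logits) is optimized with Adam to minimize

    (f_acc(x) − t_acc)² + (f_act(x) − t_act)² + λ·D(x, seed)

where both model terms use raw (pre-sigmoid) outputs to avoid gradient
saturation, D is the categorical cross-entropy to the seed and λ = 0.1 by
default. The returned sequence is the per-position argmax at the best-loss
iterate; designs that fail to beat their seed on *both* models return the
seed with a no-improvement flag, so every accepted design is guaranteed to
score at least its seed. Specificity selection keeps designs whose
target-tissue activity logit exceeds a per-tissue cutoff while every
off-target logit stays below 0. Novelty is an exact k-mer screen (k = 24,
both strands) against the training genome; a random 1,001-mer collides
with a desk-scale genome with probability ≈ L·G/4²⁴ ≪ 1, so only genuine
copies fail. External BLAST can be layered on for production use.

## The synthetic genome

The generator emulates the structure, not the biology, of real inputs.
Chromosomes are uniform-random ACGT; 1,001 bp regions are planted on a
regular pitch (≥ 6 kb apart, so the 1.5 kb fold-gap logic and control
sampling are both exercisable) across all chromosomes including the
holdout. Each tissue region carries k ~ U{0..5} instances of its tissue's
consensus motif (8-mers; one per tissue) on random strands; *shared*
regions carry a motif that drives signal and activity in every tissue; and
*open* regions carry an accessibility-only motif that raises signal in
every tissue but never confers activity — the synthetic counterpart of
broadly bound insulator/pioneer factors, and the reason accessibility alone
cannot predict activity on this genome. True accessibility is
`baseline + signal_gain·k` (defaults 1.0 and 2.0), observed tracks add
log-normal noise (σ = 0.3 on the log scale), and a region is active in a
tissue iff it carries ≥ 2 activity-conferring motifs for that tissue.
Labels, signals and instance coordinates are emitted as ground truth
(JSON) alongside FASTA / bedGraph / BED / activity-table fixtures.

What the generator does **not** emulate: nucleosome or fragment-length
structure, read-level noise, sequence composition biases (CpG islands,
repeats), degenerate motifs (consensi are near-exact), cooperative or
positional motif syntax, and inter-species orthology. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
the models can recover a planted additive motif grammar — not that they
would reach the same accuracy on real chromatin data.

## Problem sizes and the desk-scale profile

The default pipeline profile uses 3 tissues × 300 regions (plus 150
shared, 150 open), a 4 × 2.2 Mb genome, 300 training controls, 20 folds,
and small ensembles (1 accessibility member, 1 activity member per
tissue). These sizes let a full run (generation through design) complete
in minutes on one CPU while keeping every stage statistically meaningful;
ensembles, replicates and the full-size architecture are configuration
away.

Two profiles of the architecture exist:

* the full-size stack (default `ArchitectureSpec()`): four conv blocks
  (256/120/60/60 filters, kernels 7/3/3/3, batch norm, ReLU, max-pool 3)
  and two dense blocks (64/256 units, batch norm, ReLU, dropout 0.5);
* the compact desk-scale variant (`ArchitectureSpec.compact()`): a
  32-filter kernel-8 motif-detector layer, max-pool 10, a 16-filter
  kernel-1 thresholding layer (its ReLU suppresses near-miss background
  responses before they are summed), max-pool 10 again, a global average
  pool and a linear readout — without batch norm and with conv biases
  initialized to −0.5.

The compact variant is not merely a smaller copy: with only a few hundred
distinct training regions, a flatten-plus-dense stack can interpolate the
training set through arbitrary flank features and generalize at chance.
The compact net's readout sees only per-filter occupancy sums (max within
10 bp preserves instance counts; the global average is translation
invariant), which makes region memorization impossible and forces motif
learning. Sparse initial activations (negative conv bias, no batch-norm
re-centering) make rare-motif filters emerge much faster. Desk-scale
training uses lr 0.02 / patience 25 (regression) and lr 10⁻³ / patience 20
(classification); the full-size profile keeps the conventional
lr 0.005 / patience 5 and lr 10⁻⁴ / patience 20.

Per-tissue design selection cutoffs are derived from each classifier's
max-PPV operating point (the logit of that threshold) rather than fixed
constants, since logit scales depend on training scale; the off-target
cutoff stays at 0 (= response 0.5).

## Numerical choices and degenerate inputs

* Resizing uses 0-based half-open coordinates throughout; fixed-length
  resizing requires an odd target (symmetric flanks); windows that would
  exit a chromosome are dropped, not clipped.
* Signal scaling `log2(signal/total × 10⁶)` removes regions strictly above
  the per-tissue 99.95th percentile; an all-zero tissue is an error.
* The PWM p-value DP discretizes log-odds at 0.01; thresholds are exact
  for the discretized scores.
* PPV is NA where nothing is predicted positive; single-class label sets
  warn and report NA.
* Dinucleotide shuffling of a homopolymer returns the input (unique
  Eulerian trail) with a warning.
* Ties in per-position argmax discretization resolve to the
  lowest-index base (numpy argmax); all RNG flows from explicit seeds, and
  each pipeline stage derives its stream from the global seed and the
  stage name.

## Known limitations

The numpy engine is single-device and eager; training the full-size
architecture at genome scale is out of scope. Expected-gradient
completeness is exact only in the many-steps limit; the default
discretization trades a few percent of the identity for speed. The exact
k-mer novelty screen is stricter than BLAST locally (any 24-mer match
fails a design) but blind to gapped or degenerate similarity. The
synthetic grammar is additive; none of the tests probe saturating or
cooperative enhancer logic.
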