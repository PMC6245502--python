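# Methods

`squigglebin` implements signal-space demultiplexing of barcoded
nanopore reads: a convolutional classifier assigns each read's raw
current trace to one of 12 barcode bins (or none) without basecalling.
Because the package must be exercisable end-to-end on a laptop, it pairs
the method with a seeded squiggle simulator that produces libraries with
known barcode truth.  This note records the model, the simulator's
assumptions, the parameters that matter, and the design decisions that
were genuinely open.

## The squiggle simulator

A nanopore read is a time series of current measurements taken at
4 kHz while DNA translocates at ~450 bases/s, i.e. ~8.9 samples per
base on average.  The simulator emulates this with:

- **Pore model.**  A table mapping each 6-mer to an expected current
  level.  Levels are drawn i.i.d. standard normal from a fixed seed, so
  "current" is dimensionless with inter-6-mer spread 1.  Real pore
  chemistries have structured level tables; nothing downstream depends
  on that structure, only on levels being distinguishable above noise.
- **Dwell.**  Each 6-mer emits a geometrically distributed number of
  samples with minimum 1 and mean 4000/450.  The geometric law is the
  natural memoryless choice when only the average rate is known.  A
  40 bp barcode construct (35 consecutive 6-mers) therefore yields
  ~311 samples on average, inside the typical 250–600 range for such
  constructs.
- **Noise.**  Per-sample additive Gaussian noise, sd 0.25 — a quarter of
  the inter-6-mer level spread.  By default the noise is scaled per read
  by 10^((12−q)/40) where q is the read's simulated mean Phred quality,
  so low-quality reads have noisier signal and quality-stratified
  evaluation is meaningful.  Amplitude drift is not simulated; the
  classifier's training-time Gaussian-noise layer plays that role.
- **Read layout.**  open-pore pad (50–2000 samples at a high current
  level) + 30 bp adapter + 40 bp barcode construct (8 bp flank + 24 bp
  core + 8 bp flank) + insert + reverse-complement construct + adapter +
  open-pore pad.  Raw values are mapped affinely to device-like units
  (offset 460, scale 40), giving an open-pore level of ~660 against a
  signal mean of ~460; the default open-pore trim threshold is 560.
- **Inserts.**  Twelve fixed random 800 bp reference "amplicons".  800 bp
  keeps one end's 6144-sample classification span clear of the other
  end's barcode, as with the multi-kbp amplicons such experiments use,
  while keeping desk-scale runtimes.  A configurable fraction of reads
  (default 10%) carries no barcode construct at all, and a small
  fraction (default 0.3%, matching rates reported for real libraries)
  are cross-barcode chimeras joining two inserts.
- **Barcode↔insert coupling.**  In the evaluation design each barcode
  always carries its own reference (that is what makes alignment-based
  ground truth possible).  Training libraries instead draw inserts at
  random (`barcode_ref_coupling="random"`): a classifier trained on
  coupled reads learns to read the *insert*, not the barcode, and then
  bins barcode-less reads by their insert content.  This mirrors the
  real training/evaluation separation, where training reads come from
  many unrelated genomes.
- **Basecalls.**  The emitted FASTQ applies uniform substitutions at the
  error rate implied by each read's simulated q (drawn N(12, 2.5),
  clipped to [5, 20]), so mean q-score tracks true identity.

What the simulator does *not* emulate: real pore level tables,
homopolymer dwell structure, amplitude drift/wander, stalls, and real
basecaller error profiles.  Passing tests therefore demonstrate that the
method's machinery is correct and recoverable under its stated
assumptions, not that a desk-trained model transfers to real flow-cell
data — the published full-scale regime (below) exists for that.

## Barcode location by semi-global DTW

Training windows need the construct's position.  When truth tables are
unavailable (real reads), the construct is located by semi-global
dynamic time warping of the expected adapter+construct signal (built
from the pore model, z-normalised, fixed dwell 9) against the
z-normalised read: the template aligns end-to-end, the read's ends are
free, local distance |a−b|, symmetric three-step pattern, full DP table.

A match is accepted when two conditions hold:

1. normalised cost — total cost divided by alignment path length —
   below 0.23, and
2. the matched construct spans 120–700 read samples.

Both were calibrated on dedicated simulated runs.  Cost per *path step*
rather than per template sample is used because warping lets noise
"absorb" whole constant-level template runs with single samples, which
per-template normalisation rewards.  The span gate exists for the same
reason: the cheapest noise matches compress the construct to 42–68
samples, while genuine matches span 142–363 — dwell statistics make a
sub-120-sample 40 bp construct implausible.  With the joint rule,
clean-read location recall is ≈98–99% with zero acceptance of Gaussian-
or Perlin-noise reads.

## Training-set construction

Training windows are 1024 samples (the smallest power of two that
reliably covers a 250–600-sample construct), z-normalised per window,
labelled with one of 13 classes (barcodes 1–12 or no-barcode):

- **Barcode windows** fully contain the construct, with the construct's
  position jittered uniformly inside the window so position cannot be
  memorised.  Read-end windows are cut from the reversed trailing
  signal, giving both ends one orientation so one architecture serves
  either end (separate start and end models are still trained).
- **Partial windows.**  The classifier's sliding windows routinely clip
  constructs at window edges.  One window per read is therefore cut so
  only 60–95% of the construct is inside, still barcode-labelled; and
  harvested no-barcode windows may contain up to 20% of a construct.
  Without these, clipped constructs at classification time are
  out-of-distribution and get confidently misread.
- **No-barcode windows** make up one quarter of the set, mixing five
  subtypes: non-barcode stretches of real (simulated) reads — the hard
  negatives, 50% of the mix — adapter-only signal, flat signal, Gaussian
  noise and Perlin noise (1-D gradient noise, lattice spacing 64; a
  smooth coherent signal unlike Gaussian noise).
- **Augmentation** distorts the temporal axis only: values at a quarter
  of the positions are duplicated and at a disjoint quarter deleted,
  preserving length.  The default augmentation factor of 2 (one
  distorted copy per original, training partition only) follows the
  published recipe; amplitude distortion is left to the network's noise
  layer.  The duplication and deletion sets are kept disjoint so length
  is preserved exactly in one pass.
- **Refinement.**  `refine_by_cross_split` trains on three quarters of
  the data and classifies the fourth, discarding samples whose
  prediction disagrees with their label — a standard purge of ambiguous
  or mislabelled samples.

## The classifier network

A 1-D CNN mapping a 1024-sample window to 13 softmax probabilities:
input Gaussian noise (sd 0.02, training only) → six groups of
[same-padded conv (kernel 9, constant filter count) → 2× max pool →
batch norm → dropout 0.15], halving the trace 1024 → 512 → … → 16, with
one inception-style module after group 3 (a 1-wide path, a bottlenecked
stacked-conv path, and a pooled path, concatenated above the base filter
count) → global average pooling → dense softmax.  The reference filter
count is 48 (~253 k parameters); a `scale` knob shrinks it.  The layer
dimensions within this topology are this package's concretisation — only
the topology's ingredients and the constant-48-filters rule are fixed by
the published description.

The network is implemented directly in numpy (im2col/GEMM convolutions,
analytic gradients verified against finite differences), with Adam
(lr 3×10⁻³, halved after 3 plateau epochs), categorical cross-entropy,
and a 95:5 train:validation split.  Because augmentation, input noise
and dropout act on training batches only, validation metrics routinely
exceed training metrics.

Several training choices compensate for desk-scale data volumes.  Their
common motive: the multi-window merge (next section) takes per-class
*maxima* over ~11 windows of which ~10 are barcode-free, so a single
confidently wrong window spoils a read — the per-window probability of a
confident false barcode must be pushed into the low percents.

- **No-barcode loss weight 3.**  Training sets are ~75% barcode windows
  while classification windows are ~85% barcode-free; the weight
  rebalances that prior so ambiguous barcode-free signal is not nudged
  toward a barcode class.  (The data composition itself stays at the
  one-quarter no-barcode rate.)
- **Label smoothing 0.05**, tempering over-confident single-window
  errors.
- **Hard-negative mining.**  After initial training, the model is run
  over the training library's own classification windows; barcode-free
  windows (by the truth table) that still receive barcode probability
  above 0.12 are added to the set as no-barcode samples, and training
  continues for a short second round at a lower learning rate.
  Retraining on exactly the windows the model misreads is far more
  effective than more randomly drawn negatives: in development runs it
  tripled read-level recall at unchanged barcode-less rejection.
- **Desk-scale defaults** of 12 epochs × 6000 samples/epoch plus a
  6-epoch mining round, with a scale-⅓ (16-filter, ~16 k-parameter)
  model, train a start+end model pair in ~12 minutes on one CPU.  The
  published regime (1000 epochs × 100 000 samples on GPU, 48 filters)
  is reachable through `NetworkConfig`/`TrainConfig` but is not the
  test target; desk-scale problem sizes throughout the tests were
  chosen to keep the full suite in the tens of minutes.

## Read classification

Open-pore signal is trimmed from both read ends.  Each end is examined
with up to 11 overlapping 1024-sample windows at stride 512 (6144
samples; reads shorter than one window are binned none — padding would
fabricate signal).  Windows are z-normalised independently because they
can straddle amplitude regimes.

Per-end window probabilities merge into one vector: each barcode class
keeps its **maximum** across windows; the no-barcode class keeps its
**minimum** (a read is barcode-free only if every window is); the
result is renormalised.  Keeping the no-barcode maximum instead would
let the barcode-free windows that trail every genuine barcode drown the
barcode's own evidence and unbin essentially everything.

A barcode is called when the top probability exceeds the runner-up by
strictly more than 0.5 and the top class is not no-barcode; exact ties
give gap 0 and therefore none, deterministically.  Start/end calls
combine as: either end suffices (default); both ends must agree
(stringent); end ignored (start-only).  Conflicting non-none ends flag
the read as a cross-barcode chimera and bin it none.

## Evaluation

Ground truth from alignments uses the standard thresholds: the longest
alignment must span ≥ min(100 bp, 10% of read length) in read
coordinates, else the read is unknown; an alignment to a *different*
reference spanning ≥ max(50 bp, 5% of read length) marks a chimera
(within-reference secondary alignments do not — the method cannot see
within-bin chimeras).  Simulated truth maps directly.

Metrics: precision = correct/binned and recall = correct/all, both over
known-truth reads; binned fraction over all reads; unknown-truth and
chimeric reads tracked as separate binned fractions; q-score range =
2.5th–97.5th percentile of binned reads' mean q, where mean q is always
computed in error-probability space.  Reads binned none are excluded
from q statistics.  With zero binned reads precision is reported as NaN
(undefined), never 0 or 1.  `consensus_bins` intersects call tables
(agree-or-none), trading recall for precision.

## Numerical and degenerate-input conventions

Signal indexing is 0-based, half-open.  Constant signal z-normalises to
zeros (with a warning) rather than erroring, so flat training signals
share the normal path.  The open-pore threshold falls back to
median + 5×MAD of the read when not given.  All randomness flows through
seeded `numpy` generators; training is deterministic for a fixed seed on
a fixed thread count.  Model save/load round-trips weights, batch-norm
statistics and the architecture config exactly.

## Pipeline protocol

`squigglebin run` trains on a library simulated at a seed derived from
the global one and evaluates by demultiplexing a separately simulated
library at the global seed, so no evaluation read contributes training
windows — the analogue of the published rule that no test-set reads
enter training.

## Known limitations

- Simulator realism limits (listed above); in particular, barcode cores
  here are random 24-mers, not sequences designed for mutual
  distinguishability.
- The desk-scale model's per-window confidence is far below the
  published full-scale models'; since the merge-and-gap rule needs the
  wrong-class maxima across ~10 barcode-free windows to stay small,
  desk-scale read-level recall is sensitive to training volume in a way
  the published GPU-scale models are not.
- DTW thresholds are calibrated on this simulator's noise model; real
  signal would need recalibration.
- The fast5 reader covers single- and multi-read layouts only (no bulk
  fast5, no POD5).
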