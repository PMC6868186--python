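# Methods

## Problem and data model

An LC-MS run of a digested protein sample is a set of MS1 spectra: at each
retention time (RT) the instrument records peak intensity versus m/z. A
peptide ion appears as a *feature*: several isotopic traces at m/z spacings
of exactly 1.00335/z (the C13–C12 mass difference over the charge), each
trace eluting with a bell-shaped profile around a common apex, with peak
heights decaying along the isotope index. The tasks are to find every
feature, report its monoisotopic m/z, charge, per-isotope RT ranges, and an
intensity equal to the summed areas under the isotope elution curves.

`pepfeat` rasterises the run into a sparse greyscale image — one row per MS
scan, one column per 0.01 m/z bin, grey = intensity scaled to 0–255 — and
runs two learned stages over it.

### Grey scaling

Intensities span several orders of magnitude, so the default scaling is
per-map `round(255·log1p(I)/log1p(I_max))`, with non-zero cells floored at
grey 1 so that grey 0 always means "no signal"; a linear variant is
available (`scaling="linear"`). This choice affects only what the networks
see; quantification always integrates raw intensities.

## Stage 1: charge-state detection (FC-RNN)

Each m/z column is scanned along RT as a sequence of 15-scan × 211-bin
frames anchored with the column at the left edge ("deep scan"). The width
(2.11 m/z) guarantees the *second* isotope of any feature with charge 1–9
is visible to the right of the anchor, so the charge can be read from the
spacing without a bidirectional recurrence. Per step the network emits one
of ten classes: 0 (nothing) or the charge 1–9.

Architecture: three valid-padded conv layers (tanh), **no pooling** — the
detector must stay translation-equivariant so isotope boundaries stay
sharp — then a dense embedding layer *i* (dropout 0.5 after conv3 and
layer *i*), and a recurrent dense layer *o* whose activation is the state:

    f_t = tanh(W_io·X_it + W_hh·f_{t−1} + b_o),   state size 4,

followed by a linear 10-way classifier on `f_t`. A plain recurrent cell
(not an LSTM) suffices because the state only needs to persist across one
isotope's elution. At scans where a frame holds no acquired peaks the state
is passed through unchanged and the network is not evaluated.

Training uses Adam at initial learning rate 0.01 with sparse softmax
cross-entropy per frame, minibatches of 128 twenty-frame sequences,
shuffling each epoch, validation every 10 minibatches, early stop after 5
epochs without progress, and checkpoint selection by validation macro class
sensitivity. Padded frames are masked from the loss. Gradients are clipped
at global norm 5 (Adam at lr 0.01 on a tanh network occasionally spikes
early in training; clipping stabilises it without changing the recipe).
Small tanh networks sometimes start in a basin where several classes stay
dead and validation sensitivity never leaves its floor; with ``n_init > 1``
the fit abandons an initialisation whose validation score is still below
0.6 and has improved by less than 0.05 after six epochs, and reseeds
(deterministically), keeping the best run overall.

Positive sequences are aligned with monoisotopes; the same local pattern
(isotope at the anchor, partner at Δ(z)) recurs at interior isotopes, which
is what lets one alignment generalise to all isotopes of a feature.
Negatives come from noise traces and blank regions. Rare charges can be
oversampled with jittered duplicates (`augment_rare_charges`) or,
equivalently in effect, weighted up in the loss
(`class_weight="balanced"`, inverse-frequency frame weights capped at 10);
the desk-scale benchmark uses the weighted loss, which costs no extra
compute. With neither, plain cross-entropy simply ignores classes that
make up a few percent of the frames.

### Full-map scanning and the anchor short-circuit

Columns are independent, so one RT step classifies all active columns as a
batch; batching cannot change results. By default (`anchor_bins=2`) a frame
is evaluated only if its two leading bins hold signal somewhere in the
15-scan span: a feature anchored at the left edge must put signal there,
and every detection the downstream stages use is anchored that way. This
extends the pass-through rule for empty frames from "no peaks anywhere in
the frame" to "no peaks at the anchor" and reduces full-map compute by
roughly the frame width (~200×). `anchor_bins=None` restores the literal
any-peak-in-span rule (the per-column `deep_scan` contract, used in tests).

## Intermediate step: records and clusters

Per column, maximal runs of a constant class become provisional isotopes;
runs in adjacent bins with equal charge and overlapping RT are merged (wide
isotopes span several bins) with intensity-weighted centroid m/z. Records
are filed into nine per-charge hash tables keyed by centroid m/z.

Records of one table whose spacing is Δ(z) ± 0.01 Da with ≥1 shared scan
are chained into clusters, implemented as connected components of that join
predicate — exactly the transitive closure, verified against a brute-force
oracle. Clusters are unbounded in size and may hold several features (e.g.
adjacent features continuing one ladder); separating them is the next
stage's job. Batches of 500 clusters feed the grouping stage. (Viewed
purely as a batching device this step would be optional; here the chaining
itself is what tells the grouping stage where candidate isotopes sit, so
the step always runs and "skipping" it would only remove batching.)

## Stage 2: isotope grouping (attention-gated RNN)

For a cluster of charge z, a round starting at isotope s builds five
15×10-bin frames centered RT-wise on isotope s's apex scan and m/z-wise on
the successive isotope positions (blank past the cluster tail), and emits
one class: 0 = no feature starts at s; k∈{1..4} = last isotope in frame k,
with 4 also meaning "five or more".

Architecture: four same-padded 3×3 conv layers (tanh), 2×2 max pooling
after the first two (here translation *invariance* is welcome), dense layer
*i* with the detected charge appended as a 9-dim one-hot, dense layer *o*
(dropout 0.5 after each dense layer), then an attention-gated state of size
8:

    f′_t = tanh(W_hh·f_{t−1} + W_oh·X_ot + b_h)
    a_t  = σ(W_a·f′_t + b_a)
    f_t  = (1 − a_t)·f_{t−1} + a_t·f′_t

and a 5-way linear classifier on `f_5`. The scalar gate lets the model
weight the frames that matter (the monoisotope and the last isotope).

Rounds walk left to right: class 0 advances one isotope; k∈{1..3} emits the
span (s, s+k) and continues past it; k=4 starts an overlapping continuation
round at the provisional last isotope, extending while it keeps answering,
which is how >5-isotope features and multi-feature clusters are resolved.
Continuation rounds re-center RT on their own first isotope.

Three consequences of the detection stage's structural blindness to a
feature's *last* isotope (its frame shows no companion to the right, so it
is indistinguishable from a noise trace and never enters the hash tables)
shape this stage: window frames past the cluster's last record are read
from the map at the extrapolated ladder position rather than blanked;
singleton clusters still get a round (a two-isotope feature arrives as a
single record); and a span may end past the record list, in which case the
assembly stage materialises the tail isotope's record from map signal over
the anchor's elution range, rejecting a candidate brighter than 1.1× its
predecessor (envelopes decay; a brighter "tail" is the next feature's
monoisotope). The same envelope-decay property truncates spans at recorded
intensity resets — an isotope noticeably brighter than its predecessor
starts the next feature in a shared ladder, and the next round begins
exactly there. This is what separates adjacent features.

Training uses Adagrad at initial learning rate 0.07 with softmax
cross-entropy on the final step and the same loop mechanics as stage 1.
Checkpoint selection maximises a *feature-level* validation score rather
than raw class accuracy: a prediction is accepted when it agrees with the
truth about whether a feature starts at the first frame and, for real
features, places the last isotope within one frame of truth — monoisotope
and high-intensity isotopes matter most downstream, the tail isotope least.
Negative training sequences include windows starting at the *second*
isotope of a feature (labeled 0), which is what teaches the model not to
start features mid-ladder. A `retrain` pass can append hard cases (e.g.
adjacent features) to a fitted model.

Four instances differing in initial weights, learning rate (0.07/0.08),
state size and second-dense-layer width vote by averaging their class
distributions (soft voting).

## Assembly and evaluation

Each reported span of ≥2 isotopes becomes a feature: monoisotopic m/z =
centroid of the first record, RT range = union of the isotope ranges (the
reported range deliberately covers every isotope), intensity = Σ
trapezoidal AUC of the per-scan raw intensities against RT minutes. A
single-scan isotope contributes its point intensity × local scan spacing
(a bare trapezoid would erase it). No curve family is fitted: the trapezoid
is assumption-free and converges quadratically to the analytic area as scan
spacing shrinks. Duplicates (same charge, monoisotope within one bin,
overlapping mono RT) keep the higher-intensity entry.

Feature lists are scored against identification lists by tolerance matching
(defaults 0.01 m/z, 0.2 min, charge enforced when both sides carry one;
ties broken by m/z then RT distance), consensus intersection (10 ppm,
0.03 min) for manufacturing training labels from two independent lists,
Pearson correlation of matched intensities, and top-k high-intensity
matching (the "high-confidence list" reading: k most *intense* features).

## Synthetic maps: what they emulate and what they do not

The simulator is the package's ground-truth source. It renders features
with exact Δ(z) spacings, Gaussian elution (σ ~ U(0.03, 0.07) min,
truncated at 1% of each trace's own apex), Poisson ("averagine"-like)
envelopes with rate tied to the neutral mass (a monoisotope-dominant preset
exists), log-uniform apex intensities (3·10⁴–10⁶), per-scan m/z jitter
(σ = 0.002 Da), single-bin noise traces (1.25 per Da·min, 10²–3·10³),
randomly dropped scans (5%, "broken signals"), 10% overlapping features and
10% adjacent features that continue another feature's ladder at the same
charge. Charge frequencies (z = 1–4 at 11/58/29/2%) follow the empirical
charge distribution of tryptic peptides. Defaults: 3 min × 40 Da maps, one
scan per 0.01 min, 100 features.

True isotope areas are the *analytic* Gaussian integrals, not integrals of
the rendered trace, so downstream recovery error measures the pipeline.

Not emulated: chromatographic tailing, mass-calibration drift, profile-mode
peak shape in m/z, detector saturation, real co-elution chemistry, MS/MS.
Passing the recovery suite therefore demonstrates that the machinery learns
and inverts this generative family at desk scale — not instrument-grade
performance on real runs, which would require training on real labeled
maps at full scale.

## Desk-scale benchmark and numerical choices

The reference study (`pepfeat.benchmark.run_benchmark`) simulates 20 maps
(~100 features each), trains on 15 and evaluates the full pipeline on 5
held-out maps. The networks are reduced-width instances chosen to train on
one CPU in minutes: detector conv channels 4/6/8 with a (1,5)-stride first
layer and 32 embedding units; groupers with channels 4/8/8/8 and 16-unit
embedding. Training caps: 800 positive + 800 negative detection sequences,
16 epochs (grouping 30), up to three restarts per model via the
stalled-basin detector; all seeds derive from one user seed.
Measured quantities: percent of planted features matched at 0.01 m/z /
0.2 min, Pearson r between recovered and true intensities, monoisotope-miss
versus last-isotope-confusion rates, and ensemble-versus-member accuracy on
held-out grouping sequences. The error-structure criterion rates are
module-level (held-out grouping sequences); per-feature end-to-end rates
(unmatched fraction, isotope-count disagreement) are reported alongside: a
monoisotope miss there means the feature is absent from the
final table at the matching tolerances; a last-isotope confusion means it
was matched but with the wrong number of isotopes (typically the faint
tail isotope falling below the detection stage's sensitivity).

Other numerical choices: float32 network arithmetic; Glorot-uniform
initialisation; inverted dropout; max-pool gradient routed to the first
maximal cell; half-open m/z bins with 0-based scan/bin indices; the
detection label at step t is attributed to the frame's *first* scan;
all-zero maps rasterise with `I_max` treated as 1. Determinism: fixed seeds
make simulation, training and inference reproducible on one machine with a
single BLAS thread; inference is sampling-free.

## Known limitations

* A detection run shorter than the true elution range (tails below the
  network's sensitivity) biases AUC slightly low; dropped scans inside a
  run lower the trapezoid further. Both effects are roughly proportional,
  which is why intensity *correlation* stays high while absolute areas run
  a few percent under truth.
* Charges 5–9 are supported throughout but the default simulator
  conditions do not exercise them; training them needs oversampling
  (`augment_rare_charges`).
* Closely residing features whose monoisotopes fall within ~1 bin merge at
  the 0.01 m/z raster and cannot be separated by the detector.
* The anchor short-circuit assumes centroided peaks: profile-mode data
  would put signal in many adjacent bins and defeat the skip heuristic
  (and the single-bin trace assumption generally).
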