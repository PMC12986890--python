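# Methods

## Problem and model

The package decodes multichannel motor-imagery EEG by treating each trial as
a functional brain network rather than a time series.  A trial (C electrodes
x T samples) becomes a graph G = (V, E, H): electrodes are nodes, edges come
from phase synchronization, and each node carries a spectral fingerprint.

**Graph construction.**  Instantaneous phases are extracted per electrode
with the Hilbert transform (after an optional zero-phase bandpass; the
default restricts phases to 8-40 Hz).  The phase-locking value

    PLV_ij = | (1/T) sum_t exp(i (theta_i(t) - theta_j(t))) |

measures pairwise synchronization in [0, 1].  The C x C PLV matrix is
z-scored by the mean and standard deviation of all C^2 entries (diagonal
included; epsilon = 1e-8 guards a zero spread), its diagonal is zeroed, and
entries at or below a threshold tau (default 0 — "above-average locking")
are removed.  Surviving entries keep their standardized value as the edge
weight; with tau < 0 negative weights are possible and are tolerated
downstream (degree terms use |w|).  Node features are filter-bank band
powers: zero-phase 4th-order Butterworth bandpass filters over 8-40 Hz in
4 Hz steps (B = 8 bands), each sub-band's power estimated by Welch's method
(1 s Hann segments, 50% overlap) and integrated over the band.  Band
integration uses the rectangular rule over bins in [f_low, f_high), under
which contiguous bands exactly partition total signal power.

**Network.**  An input GATv2 layer (dynamic attention: LeakyReLU before the
attention vector) lifts the B = 8 features to 128 channels (4 heads x 32).
Three evolution blocks follow; each applies GATv2 -> ReLU -> batch norm,
then a graph autoencoder — GCN encoder to a 32-d latent space with a latent
batch norm, inner-product + sigmoid decoder — that scores every electrode
pair with an edge probability P_ij.  A binary mask sparsifies the adjacency
(Hadamard product): during training the mask is Monte Carlo-sampled,
M = I(P > R) with R uniform i.i.d. on the upper triangle and mirrored;
during evaluation it is thresholded deterministically at tau_eval = 0.5.
Masks only remove edges, so edge support shrinks monotonically with depth.
The classifier head is GATv2 -> batch norm -> global mean pooling over
nodes -> dropout (p = 0.5, train only) -> linear -> softmax.  Self-loops
are always present for attention and GCN propagation and are never masked,
so a fully pruned node stays well-defined.

Component sizes (input GATv2 2560; per block: GATv2 33,280 + batch norm 256
+ GAE 4192; classifier GATv2 33,280 + batch norm 256 + linear 516) total
149,796 trainable parameters (~0.15M).  A GATv2 layer counts two input
projections with biases, per-head attention vectors, and one output bias on
the concatenated heads.

## Gradients through the discrete mask

The sampled mask is discrete and has no derivative.  Three estimators are
implemented (`ModelConfig.edge_gradient`):

* `prob-scale` (default): during training retained edges carry the weight
  A_ij * P_ij, and attention consumes |w| as a multiplicative prior on the
  softmax scores (self-loops weigh 1).  The classification loss then
  reaches the autoencoder through the attention of every later layer.
* `ste`: straight-through — the forward pass sees A * M, the backward pass
  treats dA'/dP = A.
* `none`: the mask is a pure guided-DropEdge regularizer; the autoencoder
  keeps its initialization and scores pairs by random-projection feature
  similarity.

Two design points deserve emphasis.  First, `prob-scale` only works if some
differentiable path consumes edge weights: with topology-only attention the
probability-scaled weights reach no computation that touches the loss, and
all autoencoder parameters are gradient-dead (we verified this directly).
For that reason `edge_weight_mode` defaults to `weighted`; `topology`
restores the classical unweighted-attention contract and is useful together
with `ste`.  Second, training under `prob-scale` tends to push retained-edge
probabilities toward 1 (pruning an informative edge raises the loss), so
late-training eval-time graphs can be only mildly sparsified; the `none`
estimator produces the most aggressive sparsification.  This trade-off is
inherent to training without an auxiliary reconstruction loss — the loss is
categorical cross-entropy alone.

## Training and evaluation

Mini-batch SGD (lr 0.01, batch 64, weight decay 1e-3, categorical
cross-entropy; reference protocol 500 epochs).  All stochasticity —
initialization (Glorot uniform, zero biases), batch order, dropout, mask
sampling — flows from a single seeded generator, so runs are bit-for-bit
reproducible.

After the last epoch we recalibrate batch-norm running statistics with one
equal-weighted pass over the training data.  This is required, not
cosmetic: batch norm is scale-invariant to its input, so weight decay
steadily contracts pre-normalization activations without changing the
function; exponential running estimates then lag the current activation
scale by a roughly constant factor and eval-mode outputs diverge from
train-mode ones.  The recalibration ("precise BN") removes the lag exactly.

Protocols: session-level holdout (one model trained on all subjects' first
sessions pooled, per-subject metrics on second sessions) and
leave-one-subject-out cross-validation.  Metrics: accuracy, macro
precision, macro F1 (per-class values averaged; empty denominators give 0),
and Cohen's kappa.  The final-epoch model is evaluated — no validation
split or best-epoch selection.

Ablation variants: PLV-GAT (no autoencoder/masking machinery at all),
FE-GAT (autoencoder present but masking disabled — adjacency fixed),
SFE-GCN (attention layers replaced by graph convolutions), R-GAT and
R-SFE-GAT (adjacency replaced by one shared symmetric Bernoulli(0.3) random
graph, without/with the evolution mechanism).

## Synthetic study conditions

The generator plants exactly the two structures the pipeline extracts.
Per band, each channel's phase follows a random walk (drift 2*pi*f/fs,
diffusion 0.3 rad/sample — a ~3.6 Hz Lorentzian line that fits inside a
4 Hz analysis band while uncoupled channels decorrelate within a 4 s
trial).  A coupled pair (i, j, c) replaces channel j's phase with the
circular mixture of channel i's trajectory (weight c, fixed per-trial
offset) and an independent walk, so expected PLV grows monotonically with
c.  Channels sum their band oscillations plus white noise.

The default four-class cohort (22 channels, 250 Hz, 4 s trials) gives every
class a dominant rhythm band expressed on its own ~5-channel subset with a
modest amplitude contrast (0.8 vs 0.5 uV, ~2 dB) over a shared alpha
background, three phase-coupled pairs (coupling 0.85) chained through that
subset, white noise of 1 uV, and mean-one lognormal per-trial amplitude
jitter (sigma 0.3).  The modest spectral contrast is deliberate: real
motor-imagery band-power effects are small against trial-to-trial
variability, so class information is carried chiefly by the coupling
structure — the regime the architecture targets.  Subject-level jitter
(10%, multiplicative on couplings and amplitudes, never on pair
identities) makes cross-subject transfer possible but imperfect.

What the generator does **not** emulate: volume conduction, 1/f background,
eye/muscle artifacts, electrode drift, nonstationarity within a session.
Passing tests therefore demonstrate that the pipeline recovers planted
synchronization/spectral class structure end-to-end, not that it attains
any particular accuracy on real recordings.

The test suite uses scaled problem sizes chosen to keep a full run
practical on one CPU: the end-to-end recovery cohort uses 72 trials/class
per session at low noise (0.1 uV, amplitude jitter 0.1, coupling 0.9) and
60 training epochs; the ablation comparison uses 12-channel cohorts,
20 trials/class and 60 epochs over 10 paired seeds.

## Numerical choices

* Double precision throughout the network; gradient correctness is tested
  against central finite differences (worst relative error ~1e-6).
* Dense batched message passing ((N, C, C) adjacency tensors): at C = 22
  electrodes dense attention is faster and simpler than sparse gather.
* Attention softmax is computed with a max-shift; masked pairs get an
  additive -1e30 before exponentiation.
* GCN propagation uses the symmetric normalization D^-1/2 (A + I) D^-1/2
  with degrees from |w| + 1, which stays defined for negative edge weights.
* Welch band selection is inclusive-low/exclusive-high so that contiguous
  bands partition the spectrum; a band containing no bin raises.
* Batch-norm: biased variance for normalization, unbiased for running
  estimates, momentum 0.1; eval before any train batch is an error.
* t-SNE projections (perplexity 30, clamped below the sample count; fixed
  seed 42) precede the silhouette / Davies-Bouldin scores, with raw-space
  scores reported alongside.
* Cluster scores operate on one mean-pooled vector per trial; stage 0 is
  the constructed band-power features.

## Known limitations

* Training the GAE solely through the classification loss (no
  reconstruction term) leaves the learned edge probabilities close to 1
  for informative graphs; eval-time sparsification is then mild.  An
  auxiliary reconstruction loss would change this but is outside the
  training objective used here.
* The GAT-ordering variant (`attention="gat"`) uses split source/target
  attention vectors and so has slightly more parameters than the GATv2
  layout; the reference parameter table applies to the GATv2 default.
* GDF reading requires the optional `mne` dependency; only cue events
  (four motor-imagery classes) are mapped.
* LOSO uses the same hyperparameters as holdout.
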