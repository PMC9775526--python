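# Methods

`sleepgan` augments scarce sleep-EEG training data along two axes: the
*content* axis (30 s single-channel EEG epochs, generated per sleep stage
by progressive Wasserstein-divergence GANs) and the *context* axis
(sleep-stage transition sequences, generated by a relational-memory
autoregressive model).  The two are combined by pairing each symbol of a
generated stage sequence with a generated epoch of that stage, giving
labeled epoch sequences usable by both convolutional and recurrent
sleep-staging classifiers.  This note records the models, their
assumptions, the numerical choices, and what the synthetic test bed does
and does not establish.

## Data model and preprocessing

The atomic unit is an **epoch**: 3000 samples of one EEG channel at
100 Hz (30 s) with an AASM stage label in {W, N1, N2, N3, REM}.
R&K-scored hypnograms are cleaned by merging S3/S4 into N3, dropping
MOVEMENT/UNKNOWN epochs, and keeping wake epochs only within 30 min (60
epochs) of the sleep period, operationally the span from the first to the
last non-wake epoch.  Removal is index-tracked so co-indexed signal
epochs stay aligned.  A recording containing no sleep at all is kept
whole — there is no boundary to trim against.  No filtering, artifact
rejection or resampling is applied.

**Normalization.** Generators train on dimensionless epochs.  For an
epoch `x` we store the triple (mean, max, min) and output
`y = (x − mean) / s` with `s = max(max − mean, mean − min)`.  Centering
by the mean with the larger one-sided excursion as the scale is the only
simple rule that simultaneously gives a zero-mean output, a range inside
[−1, 1] with one endpoint attaining |y| = 1, and exact invertibility from
the stored triple.  Denormalization is the pure affine inverse; no
clipping is applied when resampled factor sets imply excursions outside
the recorded extrema (the map stays exactly affine and invertible).

## Progressive WGAN-div epoch generators

One independent generator/critic pair per sleep stage (no label
conditioning — few-shot budgets make five small models more robust than
one conditional model).  The critic loss is the Wasserstein divergence

    L_D = E[D(x_f)] − E[D(x_r)] + k · E[ ‖∇_{x̂} D(x̂)‖₂^p ],   k = 2, p = 6
    L_G = E[D(x_r)] − E[D(G(z))]

with x̂ per-sample random interpolates between real and fake batches.
On any fixed batch with a shared fake set, `L_G = penalty − L_D` — an
algebraic identity the tests assert.

**Progressive schedule.** The generator starts from a length-100 latent
vector and grows in N = 4 stages to the 3000-sample target.  With
`r = (S_n/S_r)^(1/(N−1))` the per-stage lengths are
`floor(S_r · r^(((M−1)/ln M)·ln(M−i)+1))`, `M = N−1`, final stage exactly
`S_r`; defaults give [100, 230, 965, 3000].  The floor (not round) in the
intermediate sizes is load-bearing: rounding would give 231 at stage 1.

**Architecture.** Each generator stage is three conv blocks (kernel 9,
32 channels, batch-norm, leaky-ReLU 0.05).  Growth to stage n+1 linearly
upsamples the stage-n features, adds Gaussian feature noise (amplitude
0.1, for sample diversity), passes them through the new blocks, and adds
the *un-noised* upsampled features back (residual).  A shared kernel-9
conv + tanh head maps features to a single channel in [−1, 1] at every
resolution.  The critic is three conv + leaky-ReLU blocks and a linear
conv head; its value is the mean of the full-length output map.  The
critic has no normalization layers and is resolution-agnostic, so the
warm start across stages is literal parameter reuse.

**Training.** Per iteration: 3 critic updates then 3 generator updates
(the doubled "inner steps 3" is read as 3 of each), Adam (0.5, 0.999),
2000 iterations per scale at full scale, learning rate ×0.1 at iteration
1600.  Only the last 3 stages receive gradients; while stage t is the
top, stage m trains at `5e-4 × 0.1^(t−m)` — the top stage always at the
base rate, which reproduces the printed per-stage rates in the final
phase and is the reading under which stage 0 can train at all during its
own phase.  Frozen stages run in eval mode (batch-norm uses its stored
running statistics).  Real epochs are downscaled to intermediate lengths
by linear interpolation, mirroring the generator's upsampler; few-shot
batches (64) are filled by sampling training epochs with replacement.
The critic at stage 0 is randomly initialized (no former stage exists).

**Gradient penalty without double backprop.**  The critic is piecewise
linear, so ∇_x D is computed exactly by the transposed-convolution chain
with the leaky-ReLU masks recorded at the forward pass.  Building that
chain over the live weight tensors makes `k·mean(‖∇‖^p)` an ordinary
first-order function of the weights; since leaky-ReLU's second derivative
vanishes almost everywhere, first-order differentiation of this graph
equals what double backprop computes.  The tests verify this against
central finite differences.  A small epsilon (1e−24) inside the norm's
square root guards the p ≥ 2 gradient at exactly zero.

**Amplitude restoration.**  Generated epochs get microvolt amplitudes by
inverting the normalization with either (a) a factor triple drawn
uniformly from the per-stage bank recorded at training time, or (b) a
SMOTE-synthesized triple: random entry, one of its k = 5 nearest
neighbours (Euclidean on the raw triples — all coordinates share µV
units), mixed with a single scalar λ ~ U(0,1).  One λ for all three
coordinates keeps every synthetic triple on the segment between its
parents, which preserves min ≤ mean ≤ max by convexity and makes the
geometry testable.  k is clamped to bank size − 1 for tiny banks.  Which
strategy produced better downstream results is not established; both are
first-class and selectable.

## Relational-memory sequence generator

Stage transition sequences are generated autoregressively by a
relational-memory cell: memory matrix `M_t` (1 slot × 128 units = 2
heads × 64), updated per step by multi-head attention of the memory over
[memory; embedded input] with residual + layer norm, an MLP block with
residual + layer norm, and forget/input gates:

    f = σ(W_f e + U_f tanh(M_t) + b_f),  i = σ(W_i e + U_i tanh(M_t) + b_i)
    M_{t+1} = f ⊙ M_t + i ⊙ tanh(PA)

The next-stage distribution is a softmax readout of the flattened
updated memory.  The exact gate wiring and the memory-as-query
convention follow the relational-memory architecture this design derives
from; the block diagram alone underdetermines them, so they are stated
here and in the code as the package's chosen equations.

Training is **supervised only** (adversarial sequence training is
deliberately omitted — it added nothing for this five-symbol task):
teacher forcing with inputs (start, I_1 … I_{T−1}) and targets
(I_1 … I_T), mean negative log-likelihood `−(1/T) Σ_t log O_t[I_{t+1}]`
(the normalizer is read as the sequence length; the loss is reported per
time-step), Adam at 1e−3, 200 epochs, batch 64, sequence length 180
(≈ one 90 min sleep cycle; whole-night generation is out of scope).  The
start token is a sixth vocabulary symbol that is never emitted.
Generation rolls out from the start token, sampling each next stage from
the temperature-scaled distribution (greedy decoding is available and is
what the deterministic-cycle tests use).  A zero model probability at an
observed target yields an infinite loss — surfaced, never masked.

## Synthetic test bed

The fixtures module generates the study conditions for every test:

* **Epochs** — three random-frequency sinusoids inside the stage's
  characteristic band (W: 8–12 Hz; N1/REM: 4–7 Hz; N2: 4–7 Hz plus one
  Hann-windowed 12–14 Hz spindle burst of 0.5–1.5 s; N3: 0.5–2 Hz),
  peak amplitude uniform in 20–60 µV times a stage factor (N3 ×2.2,
  REM ×0.5), plus white Gaussian noise at 20% of signal RMS — the
  simplest noise model that keeps the 1-NN calibration meaningful.
  K-complexes, EOG/EMG, and artifacts are deliberately absent: a spindle
  burst is enough structure for N2.
* **Hypnograms** — a fixed first-order chain over the five stages with
  diagonal ≥ 0.75 and a W→N1→N2→N3→N2→REM cyclic bias, sampled by
  inverse-CDF so the draw count is path-independent.

Passing tests on this bed shows the machinery is correct (losses,
schedules, invertibility, recovery of a known transition structure,
two-sample calibration); it does *not* show that generated epochs are
physiologically realistic, nor does it reproduce downstream classifier
gains, which require real polysomnography and an external sleep-staging
network and are out of scope here.

## Problem sizes used by the test suite

Full-scale defaults (2000 iterations/scale, 32 channels, batch 64, 200
sequence-model epochs) are the checked-in configuration defaults.  The
test and acceptance runs use the package's documented smoke scale: GAN
runs with 8 channels, batches of 8 and tens of iterations per scale;
sequence-model runs with a 2×16 or 2×64 memory on corpora of tens to two
hundred short hypnograms.  The transition-recovery check trains the
default-size memory on 200 sixty-epoch hypnograms at a 2e−3 learning
rate for 60 epochs — at this reduced corpus scale the faster rate
reaches the chain's conditional entropy in a fraction of the full
schedule; the full-scale default stays at 1e−3 for 200 epochs.
The single-epoch overfit check trains stage 0
for 300 iterations and asks only that the best generated sample
correlate with the training epoch better than a white-noise baseline — a
directional sanity check, not a fidelity claim.

## Numerical choices and edge cases

* All randomness flows through `numpy.random.Generator`; one root seed
  derives per-step seeds via `SeedSequence([root, step_index])`, kept
  below 2^31.  Identical seeds give bit-identical runs.
* 1-NN two-sample uses leave-one-out over the pooled set (the two-sample
  literature's convention; the protocol split is otherwise unspecified),
  Euclidean distance on mean-normalized epochs by default — amplitude is
  resampled from real factors, so normalized shape is what the generator
  actually contributes; raw-signal distance is exposed as an option by
  passing restored epochs.  Distance ties break towards the smaller
  pooled index (deterministic across platforms).
* Per-class F1 for a stage absent from both truth and prediction is
  undefined: excluded from the macro average with a warning rather than
  counted as zero.
* Constant epochs cannot be normalized (zero excursion) and are rejected
  by name; unknown stage symbols and R&K labels are rejected with their
  position.
* Batch-norm statistics of frozen generator stages are frozen with the
  parameters (eval mode); trainable stages use batch statistics.
* The schedule formula guards `floor` with a 1e−9 epsilon so exact
  integer endpoints are not lost to floating-point droop.

## Known limitations

* The numerical engine is NumPy-based and single-threaded; full-scale
  training (2000 iterations/scale at 3000 samples) is hours, not
  minutes.  The smoke scale demonstrates correctness, not capacity.
* Five independent per-stage GANs cannot share cross-stage structure;
  rare stages (N1) get no help from abundant ones.
* The sequence model is trained and evaluated on 180-symbol windows;
  whole-night structure (multiple cycles with drifting composition) is
  explicitly out of scope.
* EDF+ reading is a thin optional adapter (`mne`); it is not exercised
  by the test suite, which runs entirely on the synthetic bed.
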