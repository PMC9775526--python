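# sleepgan

Few-shot data augmentation for single-channel sleep-EEG staging.

Automatic sleep staging needs large labeled training sets, but overnight
polysomnography is expensive to record and score — often only one or two
nights from a patient are available.  `sleepgan` expands such few-shot
training sets along both axes a sleep-staging classifier cares about:

* **EEG epochs** — one progressive 1D Wasserstein-divergence GAN per
  sleep stage (W, N1, N2, N3, REM) learns to map a length-100 Gaussian
  latent vector to a 30 s, 3000-sample mean-normalized epoch, growing
  through resolutions 100 → 230 → 965 → 3000.  Microvolt amplitudes are
  restored by inverting the stored normalization with factor triples
  drawn from the real recordings, or with new triples synthesized by
  SMOTE interpolation.
* **Stage transition sequences** — a relational-memory autoregressive
  model (memory matrix updated by multi-head attention plus
  forget/input gates) is trained by maximum likelihood on hypnograms and
  rolled out to sample plausible 180-epoch stage sequences (about one
  90 min sleep cycle).
* **Labeled epoch sequences** — each symbol of a generated sequence is
  paired with a generated epoch of that stage, yielding sequence-shaped
  training data for recurrent classifiers.
* **Diagnostics** — a leave-one-out 1-NN two-sample test (matched
  distributions score ≈ 50%) and standard staging metrics
  (accuracy, per-class F1, macro F1, Cohen's κ).

The critic objective is the Wasserstein divergence

```
L_D = E[D(x_f)] − E[D(x_r)] + k·E[‖∇_x̂ D(x̂)‖₂^p]      (k = 2, p = 6)
L_G = E[D(x_r)] − E[D(G(z))]
```

with `x̂` random interpolates between real and fake samples; the
sequence model minimizes the mean negative log-likelihood
`−(1/T) Σ_t log O_t[I_{t+1}]` with teacher forcing.  Models are built on
a small NumPy reverse-mode autodiff engine included in the package (see
`docs/methods.md` for how the gradient penalty is differentiated exactly
without second-order autodiff).

Everything runs on a built-in synthetic test bed (stage-characteristic
band-limited epochs and Markov hypnograms), so no data download is
needed; SleepEDF-style EDF+ recordings are supported through an optional
`mne`-based reader (`pip install sleepgan[edf]`).

## Worked example

Train a deliberately tiny (desk-scale) N3 generator on eight synthetic
epochs, restore amplitudes, and check the generated set against the real
one:

```python
import numpy as np
from sleepgan import (
    FixtureSpec, GanConfig, FactorBank,
    normalize_epoch, train_progressive, sample_epochs,
    one_nn_two_sample,
)
from sleepgan.fixtures import generate_fixture_set
from sleepgan.restore import restore_pool

real = generate_fixture_set(FixtureSpec(n_per_stage=8, seed=0))["N3"]
norm = np.stack([normalize_epoch(e).samples for e in real])

cfg = GanConfig(channels=8, batch_size=8, epochs_per_scale=20,
                scheduler_milestone=16)
gen, critic, traces = train_progressive("N3", norm, cfg, seed=1)
fake = sample_epochs(gen, n_samples=8, seed=2)

bank = FactorBank.from_epochs(real)
restored = restore_pool(fake, bank, strategy="smote", seed=3)

print("final critic loss:", round(traces[-1].d_losses[-1], 3))
print("generated length:", len(restored[0].samples),
      "peak µV:", round(max(abs(e.samples).max() for e in restored), 1))
print("1-NN vs real:", one_nn_two_sample(norm, [f.samples for f in fake]).accuracy)
```

```
final critic loss: 0.297
generated length: 3000 peak µV: 122.8
1-NN vs real: 0.6875
```

At this smoke scale the critic loss is finite and the artifacts are
well-formed (3000 samples, realistic peak amplitudes), but the 1-NN test
still largely separates real from generated (0.69 rather than the ~0.5
of matched distributions) — twenty iterations per scale is a plumbing
check, not a trained model.  At full scale
(`GanConfig()` defaults: 32 channels, 2000 iterations per scale) the
1-NN accuracy is the quantity to watch: values near 0.5 mean the
generated distribution has become indistinguishable from the real one.

The same pipeline is available from the shell:

```
sleepgan fixtures --seed 0 --n-per-stage 8 --out fx/
sleepgan run-all --config desk.yaml --seed 1 --out run/
sleepgan evaluate --real fx/ --generated run/ --trials 10 --seed 2 --out eval/
```

Every run writes a `manifest.json` (command, config snapshot, seeds,
package version); replaying a manifest's config and seed reproduces its
outputs bit-for-bit.

## Layout

| module | contents |
| --- | --- |
| `sleepgan.signal` | epoch/factor types, normalization contract, R&K→AASM hypnogram cleaning, optional EDF+ reader |
| `sleepgan.fixtures` | synthetic stage-conditional epochs and Markov hypnograms |
| `sleepgan.gan` | resolution schedule, WGAN-div losses, progressive generator/critic, training |
| `sleepgan.restore` | factor banks, random and SMOTE amplitude restoration |
| `sleepgan.relmem` | relational-memory cell, MLE training, sequence sampling |
| `sleepgan.synthesis` | stage-sequence → labeled epoch-sequence assembly |
| `sleepgan.evaluate` | 1-NN two-sample test, staging metrics |
| `sleepgan.autodiff`, `sleepgan.nn` | NumPy reverse-mode autodiff and layers |
| `sleepgan.cli`, `sleepgan.config`, `sleepgan.pipeline` | CLI, YAML config, seed derivation, manifests |
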