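# eeg-augkit

Signal-domain EEG augmentation, compact CNN baselines, and leakage-free
stratified cross-validation for two clinical EEG classification tasks:
**deep-sleep (N3) detection** from 30-s polysomnography epochs and
**epileptic-focus localisation** from 20-s intracranial EEG segments.

Deep networks for EEG are data-limited: annotated recordings are scarce and
models overfit idiosyncratic signal realisations. This toolkit implements the
standard countermeasure — lightweight, physiologically motivated augmentation
applied online during training — together with everything needed to evaluate
it honestly: three CNN baselines, stratified k-fold cross-validation with
Student-t confidence intervals, instrumented leakage guards, and a synthetic
EEG generator so the full pipeline runs on a laptop with no downloads.

## The model

Three operators perturb a training segment x(t) of length T:

* time shift: x'(t) = x((t + Δt) mod T), Δt ~ U{−⌊0.3T⌋, …, +⌊0.3T⌋}
* amplitude scale: x'(t) = α·x(t), α ~ U(0.8, 1.2)
* noise addition: x'(t) = x(t) + ε(t), ε ~ N(0, σ²), σ = u·std(x), u ~ U(0.01, 0.05)

During training, each drawn sample is (with probability 0.5) perturbed by one
method chosen uniformly from the enabled set; validation folds are never
touched. Fold accuracies M_1..M_k are reported as

    M̄ ± t_{0.975, k−1} · s / √k,   s² = Σ(M_i − M̄)²/(k−1)

with t_{0.975,9} = 2.262 for the default k = 10.

The baselines are a five-stage DeepConvNet (~1.1 M parameters at the reference
2×3000 geometry), a two-layer ShallowConvNet (~35 K) and an EEGNet-style
spatio-spectral network (~96 K), all built on a small in-package numpy
layer toolkit with full backprop and Adam. See `docs/methods.md` for the
exact layer schedules and every default.

## Worked example

```python
import numpy as np
from eeg_augkit import (SyntheticConfig, build_subset, Dataset, ModelSpec,
                        ExperimentCondition, TrainConfig,
                        apply_label_scheme, run_cross_validation)

cfg = SyntheticConfig(task="sleep", duration_s=5.0,
                      composition={"N3": 200, "Wake": 50, "REM": 50,
                                   "N1": 50, "N2": 50})
data = Dataset.from_segments(build_subset(cfg, np.random.default_rng(0)))
data = apply_label_scheme(data, "binary-N3")     # N3 vs everything else

spec = ModelSpec("eegnet", data.n_channels, data.n_samples, 2)
config = TrainConfig(batch_size=64, max_epochs=15, early_stop_patience=5, seed=0)
summary = run_cross_validation(data, spec,
                               ExperimentCondition.from_tag("raw+ts"),
                               config, k=10)
print(f"accuracy {100*summary.mean:.2f} ± {100*summary.std:.2f}%  "
      f"95% CI [{100*summary.ci_low:.2f}, {100*summary.ci_high:.2f}]")
```

Output:

```
accuracy 100.00 ± 0.00%  95% CI [100.00, 100.00]
```

Every fold classifies the held-out synthetic epochs perfectly: the generator's
N3 epochs carry a dominant 0.5–2 Hz delta rhythm (relative delta power ≈ 0.95)
that an EEGNet-style model separates from the other stages easily. On real
recordings this task is substantially harder; the generator's role is to
exercise the protocol, not to emulate real-data difficulty.

The same experiment grid is available from the shell:

```bash
eeg-augkit generate --task sleep --out data/ --seed 0 --n-per-class 50
eeg-augkit train-cv --config experiment.yaml
eeg-augkit report --run runs/example
```

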