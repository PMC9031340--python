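# thcpred

Parameterized entropy losses for cancer-recurrence prediction: the
Tsallis–Havrda–Charvat (THC) cross-entropy family, a multitask 3-D
encoder–decoder that predicts post-treatment recurrence from a CT-like
volume plus clinical covariates, and the five-fold evaluation protocol
that asks whether any THC order α beats the usual Shannon cross-entropy.

## Who this is for

Researchers studying loss functions for small-sample medical prediction.
Binary classifiers are almost universally trained with Shannon binary
cross-entropy; the THC family generalizes it with one order parameter,

    H_α(p)   = (1 − Σᵢ pᵢ^α) / (α − 1),          α > 0,
    H_α(q:p) = (1 − Σᵢ qᵢ^{α−1} pᵢ) / (α − 1),

recovering the Shannon forms as α → 1 (natural logarithms).  The binary
loss used for training on labels pₙ ∈ {0,1} and predicted probabilities
qₙ is

    L_pred,α = (1/(α−1)) (1 − (1/N) Σₙ [qₙ^{α−1} pₙ + (1−qₙ)^{α−1} (1−pₙ)]).

The package implements this family exactly (with analytic gradients), a
multitask network trained on `L_total = L_rec + L_pred,α` (reconstruction
plus prediction), a synthetic-cohort generator with a controllable
planted signal standing in for the private patient data, and the
comparison protocol: shared five-fold splits, per-α fold accuracies,
mean ± sample SD, and a paired test against the α = 1 baseline with the
acceptance rule *average above Shannon AND p < 0.05*.

## Worked example

```python
import numpy as np
from thcpred import (CohortConfig, NetworkConfig, RecurrenceModel,
                     generate_cohort, kfold_split, alpha_sweep)

cohort = generate_cohort(CohortConfig(n_patients=40, volume_shape=(16, 16, 8),
                                      signal_strength=5.0, seed=7))
cfg = NetworkConfig(volume_shape=(16, 16, 8), encoder_channels=(4, 8, 16),
                    bottleneck_dim=16, fc_widths=(16, 8), alpha=2.0,
                    epochs=2, seed=7)
results = RecurrenceModel.from_cohort(cohort, config=cfg).fit()
print(results.summary())
```

prints

```
Multitask recurrence model results
==================================================
volume shape        : (16, 16, 8)
encoder channels    : (4, 8, 16)
alpha (loss order)  : 2.0
epochs / batch / lr : 2 / 4 / 0.001
patients            : 40
--------------------------------------------------
loss (epoch 1)      : rec 29.5721  pred 0.4964  total 30.0685
loss (final)        : rec 12.3092  pred 0.4791  total 12.7883
training accuracy   : 0.625
==================================================
```

`rec` is the mean per-patient summed squared voxel error of the
reconstruction task, `pred` the binary THC loss of the recurrence head,
and `total` their unweighted sum — the quantity training minimizes.
At this two-epoch toy scale the autoencoder loss has fallen sharply and
the head is only starting to pick up the planted signal; the acceptance
runs (200 patients, 32×32×16, six epochs) reach held-out accuracy
around 0.81 against a Bayes bound of 0.89.

The sweep over α on one shared five-fold split:

```python
report = alpha_sweep(cohort, cfg, alphas=(0.5, 1.0, 2.0),
                     split=kfold_split(len(cohort), 5, seed=7))
print(report.render_table())
```

renders a table in the familiar layout (`alpha, fold1..fold5, average,
sd, p_value`), with the α = 1 row marked `N/A` and rows satisfying the
acceptance rule flagged `*`.  The same protocol is available from the
shell via the `thcpred` CLI (`generate`, `train`, `sweep`, `report`
subcommands on a YAML config; see `thcpred --help`).

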