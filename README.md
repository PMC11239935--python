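# eetss — eigen-entropy time series signatures

`eetss` classifies multivariate time series — physiological recordings
such as multi-lead vital signs, gait force sensors or EEG channels — by
tracking how strongly the channels co-move, rather than by the shape of
any individual channel. It targets binary disease-detection problems
where the classes differ in their inter-channel correlation structure
and where recall (not missing a diseased subject) is the metric that
matters.

## Method

For an `n × m` window **X** (n time points, m channels), each channel is
standardized with its population mean μ_j and standard deviation σ_j,
the standardized deviations are replaced by their absolute values, and
the Gram matrix

&nbsp;&nbsp;&nbsp;&nbsp;C\* = (1/n) X\*ᵀ X\*,&nbsp;&nbsp;&nbsp;
X\*_{ij} = |x_{ij} − μ_j| / σ_j

is the *correlation-magnitude matrix*: symmetric, positive
semi-definite, unit diagonal, blind to the sign of the correlation.
Its eigenvalues λ_i (Σλ_i = m) define the **eigen-entropy**

&nbsp;&nbsp;&nbsp;&nbsp;EE = −Σ_i (λ_i/m) log (λ_i/m),

which is maximal (log m) when all λ_i = 1 and shrinks toward 0 as
channels co-move and the spectrum concentrates. EE decreases as the
correlation magnitude c grows.

A *cumulative moving window* (CMW) schedule of prefixes of length
SS, 2·SS, …, N — with SS = max(2, ⌊N/50⌋) — yields an EE profile
EE_1 … EE_K. The **time series signatures** are

&nbsp;&nbsp;&nbsp;&nbsp;TSS_k = (EE_k − EE_1) / k,&nbsp;&nbsp; k = 2 … K,

computed at every scale factor τ ∈ {0.5, 1.0, …, 5.0} of a dense
multiscale coarse-graining (integer τ: block means of τ raw points;
fractional τ: zero-insertion upsampling, fourth-order zero-phase
Butterworth interpolation, then block means of length Q = τ/α).
The concatenated TSS vector feeds a standard evaluation protocol:
train-only min-max scaling, recursive feature elimination, a
six-classifier bank (SVM, RF, KNN, NB, LR, XGB) tuned by stratified
5-fold grid search refit on recall, repeated over 30 stratified 80:20
splits with seeds 0–29. Dependent-DTW 1-NN and multivariate multiscale
permutation entropy are included as baselines.

## Worked example

```python
import numpy as np
from eetss import (GeneratorConfig, gen_correlation_shift, extract_signatures,
                   evaluate_protocol, reduced_classifier_bank, SplitProtocol)

# 40 control + 40 case instances of 4 correlated Gaussian channels;
# the case class shifts its equicorrelation from 0.1 to 0.8 mid-series
collection = gen_correlation_shift(GeneratorConfig(seed=0))
matrix = extract_signatures(collection)
print(matrix.features.shape)

report = evaluate_protocol(matrix, reduced_classifier_bank(),
                           SplitProtocol(seeds=tuple(range(30))))
print(report.best_classifier, round(report.mean_recall[report.best_classifier], 3),
      round(report.mean_auc[report.best_classifier], 3))
```

prints

```
(80, 509)
SVM 1.0 1.0
```

80 instances, 509 TSS features (one per CMW per scale factor), and a
mean recall/AUC of 1.0 for the best classifier over the 30 repeated
splits — the correlation shift in the case class drives EE down after
the changepoint, so the late-window signatures separate the classes
essentially perfectly at this effect size.

The same pipeline runs from the shell:

```sh
eetss simulate --preset strong --out data.ts --seed 0
eetss extract --input data.ts --positive 1 --out sigs.csv
eetss evaluate --sigs sigs.csv --positive 1 --bank reduced --out report.json
```

For real datasets, `eetss extract --input Heartbeat_TRAIN.ts ...` accepts
UEA-archive `.ts` files, and `eetss.io.read_delimited` reads
whitespace-delimited sensor tables (e.g. PhysioNet gait recordings,
typically preprocessed with `block_average(series, 10)` and
`pad_to_length`).

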