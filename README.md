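# pscnn

Compound identification in ¹H NMR spectra of mixtures with a
pseudo-Siamese 1D convolutional network.

## The problem

1D ¹H NMR is reproducible and nondestructive, which makes it a natural
tool for analyzing mixtures of small molecules — flavors, metabolite
extracts, reaction products — without separation.  But deciding *which*
library compounds a mixture contains is hard: peaks of different
components overlap, and the chemical shifts of one compound move slightly
from sample to sample (matrix, pH, concentration, instrument), so naive
spectral similarity fails.

`pscnn` addresses this with a two-branch convolutional classifier.  Each
input is a *spectral pair* — the spectrum of a pure compound `D_i` from a
library **D** and the spectrum of a mixture **x** — and the output is the
probability that the mixture contains the compound:

```
D_i ──► conv(32×5)+pool ×6 ─┐
                            ├─ concat → flatten → dense(100)+dropout(0.2) → σ → P(D_i ∈ x)
x  ──► conv(32×5)+pool ×6 ─┘
```

The two branches share their architecture but **not** their weights
(pure and mixture spectra come from different distributions — hence
*pseudo*-Siamese).  Convolution + max pooling give the learned features
translation tolerance along the ppm axis, which is what makes the
prediction robust to chemical-shift variation.  Training data are
generated by *augmentation*: because NMR signals are additive, realistic
mixture spectra are synthesized as ratio-weighted sums (ratios uniform on
0.2–1.0, 2–5 components) of library spectra plus Gaussian noise; pairs
containing the target compound are labeled 1, pairs without it 0.
Performance is reported as accuracy, sensitivity and false-positive rate:

```
ACC = (TP+TN)/(TP+TN+FP+FN)    TPR = TP/(TP+FN)    FPR = FP/(TN+FP)
```

A built-in simulator (Lorentzian multiplets, first-order s/d/t/q
patterns, 400 MHz conventions) generates synthetic pure-compound
libraries so the entire pipeline is testable without acquired data; real
spectra are read from Bruker processed-1D directories, JCAMP-DX files or
two-column ppm/intensity text.  The network itself — convolution as
cross-correlation, max pooling, dense head, Adam, binary cross-entropy,
forward and backward — is implemented in numpy and verified against
brute-force oracles in the test suite.

## Worked example

```python
from pscnn.benchmark import run_benchmark, recovery_rate
from pscnn.identify import identify

# 24-compound synthetic library, 4,000 augmented pairs (3,200/400/400),
# depth 6, 32 kernels of size 5, lr 1e-4 — everything seeded.
result = run_benchmark(seed=1)
m = result.test_metrics
print(f"test ACC={m.acc:.4f} TPR={m.tpr:.4f} FPR={m.fpr:.4f}")

# screen fresh mixtures against the library
rate, details = recovery_rate(result, n_mixtures=20)
print(f"recovered {rate:.0%} of held-out mixtures")
```

which prints (seed 1, ~12 minutes on one CPU):

```
test ACC=0.9100 TPR=0.8922 FPR=0.0714
recovered 15% of held-out mixtures
```

ACC/TPR/FPR are computed on the 400 held-out test pairs at threshold 0.5;
the recovery rate is the fraction of 20 freshly synthesized mixtures
whose candidate set (entries with probability > 0.5) equals the true
composition *exactly* — a much stricter bar, since one false positive
among the ~20 negative comparisons per mixture spoils it.  At this
desk-scale pair budget the classifier generalizes to the low-to-mid 90s;
the full-scale protocol (22,000 pairs, 100 epochs) is where the
high-99% regime lives.  `docs/methods.md` discusses the gap.  The same
trained model is robust to chemical-shift displacement: all 28
mixture/component scan pairs hold probability > 0.5 across mixture
shifts of at least ±0.009 ppm.

The same workflow is available from the shell:

```bash
pscnn simulate-library --n 24 --seed 1 --out lib.h5
pscnn augment --library lib.h5 --seed 1 --out data.h5
pscnn train --data data.h5 --epochs 100 --lr 1e-4 --seed 1 --out model/
pscnn identify --model model/ --library lib.h5 --mixture sample.dx --threshold 0.5
pscnn scan-shifts --model model/ --library lib.h5 --seed 1 --out scan.csv
```

Full-scale defaults (22,000 pairs on a 16,384-point grid, 100 epochs)
apply unless overridden by a YAML config or flags; `pscnn run` executes
the whole pipeline and writes a manifest per stage for exact re-runs.

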