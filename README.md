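# myovis

Classification of electromyography (EMG) epochs as **normal**, **neuropathic
(ALS)** or **myopathic** through weighted vertical visibility networks.

EMG recordings from healthy, ALS and myopathy subjects look deceptively alike
in both the time and the frequency domain, yet neurologists tell them apart by
time-domain burst morphology: a healthy muscle response shows a single pulse of
roughly 400 μV over 15 ms, an ALS response two pulses near 1400 μV over 20 ms
each, and a myopathic response three smaller pulses near 300 μV over 10 ms.
`myovis` encodes that morphology as the structure of a complex network and
classifies it with standard machine-learning tools.

## Method

1. **Preprocessing.** Muscle-response epochs are detected by scanning outward
   from each supra-threshold peak of the rectified signal until the envelope
   slope flattens out (the inter-burst "zero-slope" region); each epoch is
   rectified and normalized so its peak amplitude is exactly 1.
2. **Network construction.** Every sample *xᵢ* of a normalized epoch becomes a
   node. Nodes *i* < *j* are linked when they are adjacent or when every
   intermediate sample stays strictly below the chord joining them,

       xₙ < xⱼ + (xⱼ − xᵢ)(n − j)/(j − i),   i < n < j,

   and the linked pair gets weight **Wᵢⱼ = |xᵢ − xⱼ| + 1** (zero when
   unlinked). The adjacency clause keeps the chain 1–2–…–N intact, so every
   graph is connected and equal-amplitude plateaus cannot isolate a node.
3. **Network measurements.** Thirteen scalars per epoch: average degree
   AD = 2L/N, average (weighted) clustering coefficient, transitivity,
   assortativity, density, central point dominance, mean closeness, average
   shortest path, global efficiency, diameter, average weight AW = ΣᵢⱼWᵢⱼ/N,
   and the skewness and kurtosis of the weight matrix elements.
4. **Feature selection.** One-way ANOVA across the three classes keeps the
   measures with *p* < 0.001; the canonical effective set is
   {AD, ACC, Den, AW, skewness, kurtosis}.
5. **Classification.** k-NN, a multilayer perceptron and an RBF support vector
   machine are evaluated with repeated stratified hold-out at test fractions
   20–80%, features standardized on training data only, reporting specificity,
   per-disease sensitivity and total accuracy as mean ± sd over repeats.

A seeded synthetic-EMG generator reproduces the three burst morphologies with
configurable noise and jitter, providing ground truth for every stage.

## Worked example

Build the visibility network of a nine-sample epoch and read off its measures:

```python
import numpy as np
from myovis import build_weighted_adjacency, compute_all, link_set

x = np.array([0.87, 0.49, 0.64, 0.91, 1.00, 0.72, 0.55, 0.83, 0.60])
W = build_weighted_adjacency(x)
print("links L =", link_set(W).L)
print("W[0,1] =", round(W[0, 1], 2))
for name, value in compute_all(W).items():
    print(f"{name:>9s} = {value:.3f}")
```

```
links L = 15
W[0,1] = 1.38
       AD = 3.333
      ACC = 0.855
        T = 0.675
       As = 3.689
      Den = 0.417
      CPD = 13.875
       CC = 0.500
      ASP = 2.336
        E = 0.541
        D = 4.910
       AW = 4.089
 skewness = 0.582
 kurtosis = 1.403
```

The first two samples 0.87 and 0.49 are adjacent, so their link weight is
|0.87 − 0.49| + 1 = 1.38; with L = 15 links over N = 9 nodes the average
degree is 2·15/9 ≈ 3.33 and the density 15/36 ≈ 0.42.

A complete synthetic study — generate recordings, segment, build networks,
select features, evaluate classifiers:

```python
from myovis import PipelineConfig, run_study

cfg = PipelineConfig(n_per_class=30, decimation_factor=4, repeats=5,
                     test_fractions=[0.2, 0.5], seed=1)
result = run_study(cfg)
print(result["report"].to_wide().to_string())
```

```
classifier                                      knn          mlpnn            svm
test_fraction metric
0.2           sensitivity_myopathy    100.00 ± 0.00  100.00 ± 0.00  100.00 ± 0.00
              sensitivity_neuropathy  100.00 ± 0.00  100.00 ± 0.00  100.00 ± 0.00
              specificity             100.00 ± 0.00  100.00 ± 0.00  100.00 ± 0.00
              total_accuracy          100.00 ± 0.00  100.00 ± 0.00  100.00 ± 0.00
0.5           sensitivity_myopathy    100.00 ± 0.00  100.00 ± 0.00  100.00 ± 0.00
              sensitivity_neuropathy  100.00 ± 0.00  100.00 ± 0.00  100.00 ± 0.00
              specificity              97.33 ± 3.65   97.33 ± 3.65  100.00 ± 0.00
              total_accuracy           99.11 ± 1.22   99.11 ± 1.22  100.00 ± 0.00
```

All thirteen candidate measures separate the three synthetic classes at
*p* < 0.001, and each classifier recovers the class labels essentially
perfectly at these noise levels; accuracy decays gracefully as the held-out
fraction or the baseline noise grows.

The same pipeline is available from the shell:

```sh
myovis simulate -n 10 --seed 1 --out-dir sim     # labeled recordings + ground truth
myovis segment sim/normal-synthetic-000.txt --rate 10000 --out-dir epochs
myovis graph epochs/epoch-000.txt --out adj.csv
myovis measure adj.csv --out measures.csv
myovis run-all --seed 1 --out-dir run            # everything, end to end
```

Real recordings go in through the same door: plain-text amplitude files (one
amplitude per row, or `time,amplitude` pairs) read by `myovis.read_signal`.

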