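# emgsynergy

Which matrix-factorisation method should you use to extract muscle
synergies from gait EMG?  `emgsynergy` implements the full comparison
pipeline for the four methods most used in the motor-control literature —
non-negative matrix factorisation (NMF), principal component analysis
(PCA), independent component analysis (ICA) and factor analysis (FA) — and
scores them not only by reconstruction accuracy but by whether their
excitation primitives *distribute* like the muscle activations they were
fitted to.

It is written for movement scientists and biomedical engineers who work
with multi-channel surface EMG of walking and running, and for anyone who
needs a clean, tested reference implementation of the synergy-extraction
stack: linear-envelope preprocessing, the four factorisations under one
contract, and ECDF-based distribution metrics.

## The model and the metrics

Muscle activation patterns form an L×N matrix **x** (L = 10 muscles,
N = 200 time points per gait cycle, entries in [0, 1]). Each method solves

  min ‖x − W·H‖²  with  x̂ = W·H (+ per-muscle mean for centring methods),

where W (L×K) holds the synergy weights and H (K×N) the excitation
primitives, under the method's own constraint (non-negativity for NMF,
orthogonality for PCA, fourth-order independence for ICA, eigen-structured
loadings for FA). Methods are compared at a common K by three metrics:

* **VAF** = 1 − Σ(x−x̂)²/Σx², with K chosen as the smallest value in 2…6
  giving VAF > 85% for every method;
* **maximum dissimilarity D** — the largest two-sample Kolmogorov–Smirnov
  statistic sup|F_l(x) − F_k(h)| over all muscle–primitive pairs (the
  worst-case distribution mismatch);
* **occurrence of agreement** — the percentage of muscle–primitive pairs
  whose KS test fails to reject distributional equality at p < 0.05.

Because no public gait-EMG dataset accompanies this problem, the package
ships a first-class synthetic generator: channels are generalized-Gaussian
carriers (shape β interpolating Laplacian → Gaussian) modulated by
burst-like gait envelopes, calibrated so the pooled excess kurtosis of raw
trials falls from ≈1.75 (walk) to ≈1.1 (fast run), mirroring the
documented speed dependence of real EMG amplitude distributions.

## Worked example

```python
import emgsynergy as es

# ground-truth data: 3 non-negative synergies, 10 muscles, mild noise
truth, act = es.generate_synergy_dataset(L=10, K_true=3, N=200,
                                         noise_sd=0.05, seed=3)

K = es.select_num_synergies(act, seed=0)
print("selected K:", K)
for method in es.METHODS:
    dec = es.fit_method(act, method, K, seed=0)
    comp = es.compare_primitives_to_activations(act, dec)
    print(f"{method}: VAF={es.vaf(act, dec.x_hat):.3f}  "
          f"D_max={comp.D_max:.3f}  agreement={comp.agreement_pct:.0f}%")
```

prints

```
selected K: 3
NMF: VAF=0.984  D_max=0.340  agreement=0%
PCA: VAF=0.984  D_max=0.735  agreement=0%
ICA: VAF=0.984  D_max=0.325  agreement=0%
FA: VAF=0.984  D_max=0.735  agreement=0%
```

All four methods reconstruct this low-rank dataset almost equally well
(VAF ≈ 0.98, comfortably above the 85% selection threshold at K = 3), but
the distribution metric separates them: the burst-like primitives of NMF
and ICA distribute much more like the activations (D_max ≈ 0.33) than the
signed, mean-removed primitives of PCA and FA (D_max ≈ 0.74). The
agreement percentage is 0 here because 200-point KS tests are powerful and
these idealised burst distributions differ measurably — on such data the
method *ordering*, not the absolute agreement, is the informative output.

## The full analysis

The numbered drivers under `analysis/` run the whole study end to end and
write their tables under `results/`:

```sh
python analysis/01_simulate.py --seed 0     # 4 conditions x 4 subjects x 5 trials
python analysis/02_preprocess.py            # envelopes -> 10x200 activation matrices
python analysis/03_decompose.py --seed 0    # K selection + all four factorisations
python analysis/04_compare.py               # KS metrics -> scores.csv
python analysis/05_report.py                # RM-ANOVA + comparison figure
```

`02_preprocess` prints the per-condition distribution table (pooled raw-EMG
excess kurtosis ≈ 1.75 / 1.48 / 1.33 / 1.08 from walk to fast run with
near-zero skewness); `05_report` runs the repeated-measures ANOVA across
methods per condition with Bonferroni-corrected pairwise tests and draws
the three-panel method-comparison figure. Library equivalents
(`es.simulate_dataset`, `es.run_pipeline`) wire the same stages
programmatically from a `RunConfig`.

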