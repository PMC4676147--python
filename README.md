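# wpla — robust recurrent-CNV recovery by weighted penalized low-rank approximation

`wpla` recovers **recurrent copy-number variation** (CNV) from multi-sample
aCGH log2-ratio matrices. It is aimed at analysts who have an *n* samples ×
*p* probes matrix **D** of log2 test/reference intensities and want the
copy-number signal that is *shared across samples*, without being misled by
individual-specific CNVs or grossly contaminated probes.

## Model

The observed matrix is `d_ij = x_ij + ε_ij` where the noise variance is
cellwise, `Var(ε_ij) = σ²/w_ij²` with weights `0 < w_ij ≤ 1`: a weight of 1
marks a clean cell, a weight below 1 an outlying one (individual CNV,
experimental artifact, heavy-tailed error). The estimator solves

```
min_{X,W}  ½‖W ∘ (D − X)‖²_F + α₁‖X‖_* + α₂ Σᵢ ‖xᵢ‖_TV + β‖log W‖₁
s.t.       0 < w_ij ≤ 1
```

where `∘` is the elementwise product, `‖X‖_*` the nuclear norm (few distinct
recurrent patterns ⇒ low rank), `‖xᵢ‖_TV = Σⱼ|x_{i,j} − x_{i,j−1}|` the
row-wise total variation (piecewise-constant profiles along the genome), and
the log-weight penalty pulls weights to 1 except where residuals are large.
Profiling out **W** turns the data term into a *redescending* M-estimator
loss — quadratic for small residuals, logarithmic beyond `√β` — so a probe's
influence is bounded no matter how wild its value. That is what lets the
method keep working under Cauchy-scale contamination, where plain
least-squares low-rank fits fail.

The solver alternates a closed-form weight update
(`w = √β/|residual|` where `|residual| > √β`, else 1) with an ADMM solve of
the convex X-subproblem (singular-value thresholding + exact 1-D fused-lasso
prox per row), enforcing monotone descent of the objective. Two deterministic
starts (the raw matrix and a row-wise running median) are fitted and the
lower-objective one returned, which protects against outlier masking on
heavily contaminated inputs. An adaptive second pass with cellwise penalties
`β_ij = β/√|log w⁰_ij|` is available.

## Worked example

```bash
# 1. generate a benchmark dataset: 50 samples x 300 probes, two recurrent
#    loss/gain regions plus per-sample 20-probe individual CNVs
wpla simulate --case 3 --seed 1 --out demo/sim

# 2. fit with data-driven tuning and export calls
wpla fit --input demo/sim/D.tsv --out demo/fit
# -> fit: converged=True outer_iter=4 effective_rank=2

# 3. score against the ground truth
wpla evaluate --fit demo/fit --truth demo/sim --out demo/metrics.tsv
# -> {"individual_auc": 0.984034..., "recurrent_auc": 1.0}
```

The fit prints the effective rank of the recovered signal matrix (2: the
scenario has one loss pattern and one gain pattern) and the evaluation prints
probe-level areas under the ROC curve: 1.0 for recurrent-CNV detection
(every truly recurrent probe ranks above every null probe by `|x̂|`) and 0.98
for individual-CNV detection (scored by `1 − ŵ`). `demo/fit/segments.bed`
holds the called segments — for this case losses spanning probes 76–95 in
samples 1–20 and gains at 96–125 in samples 21–50 — and
`demo/fit/frequency.tsv` the per-probe gain/loss frequency profile (fraction
of samples called at `|x̂| > 0.225`).

The same machinery is available as a library:

```python
from wpla import simulate_dataset, solve_wpla, recurrent_roc, auc

sim = simulate_dataset(case_id=3, seed=1)
fit = solve_wpla(sim.D.values)          # data-driven defaults
auc(recurrent_roc(fit.X_hat, sim.X_true))
```

`wpla benchmark --cases 1-12 --seeds 1-5 --out bench/` reruns the full
12-scenario study (six recurrent layouts × Gaussian σ=0.3 or heavy-tailed
0.5·t(1) noise) and writes tidy per-cutoff metrics plus an AUC summary.

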