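# mgrm — parameter recovery for the multidimensional graded response model

Likert-type rating scales measure psychological, educational and medical
outcomes on several correlated constructs at once. The natural item
response model for ordered categorical responses on multiple scales is the
multidimensional graded response model (MGRM): respondent *i* has latent
traits θ ~ MVN(0, Σ) (unit variances, correlation Σ), and item *j* with
discriminations a_j and ordered boundaries b_j1 < … < b_jK responds in
category k or above with probability

    P*_jk(θ) = 1 / (1 + exp(−D Σ_h a_jh (θ_h − b_jk))),   P_jk = P*_jk − P*_j(k+1).

Before fielding such an instrument — or building an item bank for
computerized adaptive testing — one wants to know how many respondents it
takes to calibrate the items accurately. This package answers that with a
fully synthetic simulation pipeline:

* **generate** simple-structure item banks (a ~ U[1.1, 2.8], boundaries on
  the thirds of [−2, 2] with adjacent gaps ≥ 0.5), correlated normal
  simulees, and multinomial responses;
* **calibrate** by confirmatory marginal maximum likelihood EM with
  bounded tensor-grid quadrature, including the latent correlation matrix
  and outer-product-of-gradients standard errors;
* **evaluate** recovery per replication and parameter class (bias, RMSE,
  Pearson correlation of true vs. estimated parameters);
* **summarize** factorial designs (test length L × sample size N × scale
  correlation r) with three-way ANOVA effect sizes η² = SS/SS_total,
  running-mean pilot diagnostics and marginal summaries.

The library lives in `src/mgrm` (modules `model`, `synthetic`,
`calibrate`, `recovery`, `study`, `io`, `cli`); the numbered scripts in
`analysis/` are thin narrative drivers that run the study at desk scale
and leave their tables under `results/`.

## Worked example

`python analysis/01_single_condition_demo.py` generates one 30-item,
3-dimensional bank with 4 response categories, simulates 500 respondents
at r = 0.5, calibrates, and prints the replication's recovery indices:

```
generated: 30 items, 500 simulees, categories 0..3
calibrated in 65 EM cycles (converged=True, failed=False), final loglik -15124.9
latent correlations (true 0.5): [0.565 0.504 0.526]

recovery indices for this replication:
class      bias     rmse  correlation  failed
  a_1 -0.017782 0.203791     0.934517   False
  a_2  0.150463 0.306080     0.763549   False
  a_3  0.128459 0.198921     0.972117   False
  b_1  0.031021 0.103135     0.965551   False
  b_2 -0.013113 0.073429     0.984090   False
  b_3 -0.063485 0.128266     0.958779   False
```

Reading the output: each row compares the generating ("true") parameters
with their estimates within one parameter class — the ten discriminations
loading each dimension (a_1…a_3) and each boundary position across all 30
items (b_1…b_3). At N = 500 discriminations are recovered with RMSE ≈ 0.2
on the logit scale and boundaries with RMSE ≈ 0.1; single-replication
correlations bounce around their means (the a_2 dip above is one item with
a large sampling error — class means settle near 0.95 across
replications). The estimated latent correlations sit within ±0.06 of the
generating 0.5.

The remaining drivers scale this up: `02_reduced_design.py` runs a
reduced L × N × r grid and writes the long-format index table,
`03_anova_eta_squared.py` turns it into η² tables (sample size dominates
RMSE and correlation; the scale correlation r does essentially nothing),
`04_sample_size_curves.py` tabulates the diminishing returns beyond
N = 1000, and `05_long_bias_L240.py` (hours of CPU; not run by default)
reproduces the L = 240 bias signature and the N = 500 estimation
failures. The same pipeline is scriptable via the `mgrm` CLI
(`mgrm generate|calibrate|simulate|study|anova|report`).

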