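# noiseprop

Condition-dependent gene-expression noise and its propagation through a
regulatory network.

Genome-wide reporter libraries (a GFP fusion per promoter, read out by flow
cytometry across growth conditions) show that transcriptional noise is not a
fixed property of a promoter: absolute noise decreases with growth rate, and
the *relative* noise of promoters reshuffles across conditions. `noiseprop`
implements the analysis chain that quantifies this and attributes the
condition-dependent part to noise propagation from transcription factors
(TFs) to their targets:

1. **Expression summaries** — each promoter x condition event set (natural-log
   fluorescence) is fit with a Gaussian + uniform mixture by EM; the Gaussian
   mean `m_pc` and variance `v_pc` are the summary, the uniform weight absorbs
   outliers.
2. **Noise floor and noise levels** — per condition, the minimal variance as a
   function of mean is fit as `v_min(m) = a_c + b_c·e^(−m)` (extrinsic floor
   `a_c` plus a Poissonian measurement term `b_c`); the noise level is
   `N_pc = v_pc − v_min(m_pc)`, and `a_c` is regressed on growth rate.
3. **Noise propagation** — with a binary TF→promoter annotation `S_pr`, the
   centered linear model

       N_pc − N̄_c = ε + Σ_r (S_pr − S̄_r) · A_rc

   is fit per condition with a Gaussian prior on the noise-propagating
   activities `A_rc` (ridge; posterior mean and error bars `δA_rc`), with the
   fraction of variance explained calibrated against a row-shuffled
   permutation null. Regulators with `A_rc > δA_rc` in exactly one condition
   are condition-specific propagators; the top `|Ā_r/δĀ_r|` with `Ā_r > δĀ_r`
   are the consistent ones.
4. **Regulatory statistics** — expression/noise plasticity (variance across
   conditions), cutoff curves of regulatory inputs vs noise, Welch tests
   between input-count groups and constitutive vs regulated sets.
5. **Gene-feature PCA** — pairwise-complete correlation matrix of 10 gene
   features and its eigendecomposition, separating an absolute-expression
   axis from a regulation/noise axis.

A synthetic-data generator (`noiseprop.synth`) produces studies with known
ground truth — network, activities, floors, events — at the scale of the real
experiment (1,810 promoters x 8 conditions, ~50,000 events per promoter), so
every stage is benchmarked against truth without any download. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

The numbered drivers under `analysis/` run the study end to end (default: a
quick 600-promoter subset; add `--full` for library scale):

```bash
python analysis/01_simulate_study.py --seed 0
python analysis/02_summarize_expression.py --seed 0
python analysis/03_fit_noise_floor.py --seed 0
python analysis/04_infer_noise_propagation.py --seed 0
python analysis/05_regulatory_statistics.py --seed 0
python analysis/06_feature_pca.py --seed 0
```

Output of the chain at seed 0 (abridged):

```
simulated 600 promoters x 8 conditions, 40 regulators (seed 0)
  constitutive promoters: 42.8% (Poisson zero class exp(-0.9) = 40.7%)
  noise floors a_c: 0.032 (fastest growth) to 0.156 (slowest)
fitted 4800 promoter x condition mixtures (100.0% converged)
  median outlier weight: 0.020 (injected fraction 0.02)
  replicate R^2 of means (c1): 1.0000
noise floor vs growth rate: slope=-0.0765/h, intercept=0.1557, R^2=0.989
noise levels c1 (median 0.0049) vs c8 (median 0.0108): rank-sum p = 1.24e-27
prior strength lambda = 0.1 (out-of-fold FOV 0.840)
  c1: FOV 87.6% vs shuffled 6.92% +/- 0.17%
recovery: Pearson r(true, inferred activities) = 0.995
condition-specific calls: [...] (planted [...]; 4 recovered)
top consistent propagators: ['tf09', 'tf12', 'tf20', 'tf21', 'tf32', 'tf33']
  (planted ['tf09', 'tf12', 'tf20', 'tf21', 'tf32', 'tf33']; 6 recovered)
fraction regulated: 57.2% overall, 100.0% among high-noise promoters
max Welch t (inputs above vs below cutoff): 7.0
top-2 components carry 64.2% of the total variance
```

Reading this: the fitted noise floor falls linearly with growth rate and
noise levels are lower in fast-growth conditions (rank-sum p ≈ 1e−27); the
propagation model recovers the planted activities almost exactly (r = 0.995)
and explains ~85–90% of noise-level variance on this idealized data versus
~7% after shuffling; noisier promoters have more known regulatory inputs;
and the feature PCA splits expression-related from regulation-related
features on its top two axes. The condition-specific propagator list
recovers 4 of 5 planted TFs but also contains a few one-error-bar false
calls — an expected property of the `A > δA` convention (see
`docs/methods.md`).

The same pipeline runs from files (`noiseprop run --config config.yaml`, or
per-stage subcommands `simulate | summarize | floor | noise | propagate |
stats | pca`), consuming TSV event tables, edge lists and growth rates, and
writing every result as a tidy TSV plus a run manifest with the seed.

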