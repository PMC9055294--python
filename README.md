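# traitassembly

Trait-based null models for plant community assembly along successional
chronosequences — built for ecologists asking *which process put this
community together*: environmental filtering, dispersal limitation,
competition / limiting similarity, or chance.

The package targets space-for-time designs (e.g. vegetation recovering on
abandoned mine land) where plots from sites of different successional age
are compared. It implements the full analysis chain:

* **Functional trait space (FTS)** of establishment leaf traits
  (LA, SLA, LDMC) as an n-dimensional hypervolume — one-class SVM
  boundary, Monte Carlo volume, Jaccard overlap and centroid distances
  between stages.
* **Mean pairwise Gower distance (MFD)** over mixed continuous/ordinal
  regenerative traits (seed mass, longevity class, phenology), with
  pairwise-deletion handling of missing values and regression-tree
  imputation.
* **Permutation null models** for both statistics — resampling individual
  trait records (FTS) or species (MFD) from the pooled species pool — and
  the permutation effect size **ES = 2(P − 0.5) ∈ [−1, 1]**, where P is
  the tie-corrected proportion of null statistics below the observed
  value. ES ≤ −0.95 reads as trait convergence (filtering / dispersal
  limitation), ES ≥ +0.95 as divergence (competition), |ES| < 0.95 as
  stochastic assembly.
* **Grime CSR strategy scores** from the three leaf traits (C + S + R =
  100), stage-mean strategies and ternary coordinates.
* **Soil–strategy association**: per-property Mantel tests on a-priori
  log-dissimilarity matrices with BH adjustment, gating beta regressions
  of strategy proportions on the significant soil drivers.
* A **synthetic chronosequence generator** with controllable assembly
  regimes and recorded ground truth, so every statistic is testable
  end-to-end without field data.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
import traitassembly as ta

# a four-stage chronosequence with known ground truth
ds = ta.simulate_dataset(ta.AssemblyConfig(seed=11))

print(ta.stage_summary(ds.community).round(3).to_string(index=False))

# does stage 1 occupy less trait space than random draws from the pool?
res = ta.FTSNullModel(ds.leaf, 1).fit(n_sims=999, seed=0)
print(res.summary().round(3).to_string(index=False))
```

```
 stage  n_plots  richness_mean  richness_se  shannon_mean  shannon_se  whittaker_beta
     1        3          6.667        1.202         1.410       0.129           0.800
     2        3          9.000        1.155         1.536       0.057           0.444
     3        3         15.333        0.333         2.282       0.052           0.109
     4        3         17.000        0.000         2.156       0.053           0.118

 statistic   trait_class   unit  stage  observed  null_mean  null_sd  n_sims     P     ES          interpretation
FTS_volume establishment stage1      1     2.744       4.73    1.181     999 0.014 -0.972 environmental filtering
```

Reading the output: richness and Shannon H′ rise along succession while
Whittaker turnover β_w falls (plots within a stage become more alike).
Stage 1's observed hypervolume (2.74 in standardized units³) sits below
986 of 999 null volumes, giving P = 0.014 and ES = −0.97: the stage-1
leaf traits are strongly convergent, the signature of environmental
filtering — exactly the regime the generator used for stage 1
(`ds.truth["regime_establishment"]`).

The same analysis runs end-to-end from the shell:

```sh
traitassembly simulate --out data/ --seed 11
traitassembly run --config config.yml --out results/
```

where `config.yml` can hold input paths or a `simulate:` block plus
null-model, CSR and Mantel settings. The result bundle contains the
diversity tables, the stage × trait-class ES table with assembly-process
labels, hypervolume overlap matrices, CSR scores, the Mantel screen, beta
regression fits, and a manifest recording every seed and convention.

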