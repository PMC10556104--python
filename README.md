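# cyclestage

Molecular staging of cyclic bulk transcriptomes: assign every sample of a
gene-expression cohort a continuous position on a recurring biological
cycle, normalize expression for cycle stage, and test covariates with the
cycle properly modelled.

## The problem

Tissues governed by a biological cycle — the motivating case is the human
endometrium over the menstrual cycle — remodel their transcriptome so
strongly that cycle position dominates gene expression. Histopathology dates
such samples only coarsely (seven stages, with poor inter-observer agreement
on the post-ovulatory day), so any comparison between samples, or any test
for covariates such as age, is confounded by unknown cycle position.
`cyclestage` turns the problem around: because thousands of genes change in
a synchronized way, the transcriptome itself is a precise clock.

## The model

For each gene *g*, expected log2 expression is modelled as a penalized
(cyclic) cubic regression spline *f<sub>g</sub>(d)* of a coarse training
time axis *d* (pathologist post-ovulatory day; 3 secretory stages; or the 7
cycle stages on a circle). A sample with observed expression
*y<sub>g</sub>* is placed at the cycle time minimizing the global loss

$$L(d) = \sum_{g \in G} \left(y_g - f_g(d)\right)^2,$$

i.e. the time whose expected transcriptome is closest in mean squared error
across **all** genes simultaneously. Under the assumption that the cohort is
sampled uniformly around the cycle, assigned times are then *uniformized*:
samples are ranked in cyclic order and placed equidistantly on a 0–100
scale read as "percent of the way through the cycle" (sample *i* of *n*
gets 100·(rank − ½)/*n*). Gene curves are refit on the percentage axis with
a richer cyclic basis (k = 30), which supports:

* **cycle normalization** — residual from the curve plus the gene mean, so
  any two samples can be compared with cycle stage removed;
* **staging new cohorts**, including other platforms, after per-gene median
  centering;
* **an unsupervised validation route** (PCA → k-means → cluster ordering →
  cyclic fit) that never sees pathology labels;
* **cycle-aware differential expression** — gene-wise linear models with a
  cycle-time spline covariate, empirical-Bayes moderated *t* and *treat*
  tests (fold-change threshold), Benjamini–Hochberg correction, a
  sliding-window scan for genes changing within a short span of the cycle,
  and weighted-Fisher meta-analysis across studies.

Phases on the percentage scale default to menstrual [0, 8), proliferative
[8, 58) and secretory [58, 100).

## Worked example

Everything is testable without real data: the `simulate` module generates
cohorts with known truth (smooth periodic per-gene curves built from random
Fourier harmonics, a flat-gene fraction, Gaussian log2 noise, jittered
7-stage pathology labels and noisy post-ovulatory-day calls).

```python
from cyclestage import simulate_cycle, run_full_pipeline
from cyclestage.simulate import label_with_pathology
from cyclestage.metrics import circular_rank_correlation
from cyclestage.unsupervised import unsupervised_stage, align_and_compare

em, truth = simulate_cycle(n_samples=120, n_genes=1500, seed=11)
ann = label_with_pathology(truth)
result = run_full_pipeline(em, ann)

print(result.assignments[["model_time", "percentage", "phase"]].head(4).round(3))
r = circular_rank_correlation(result.assignments["percentage"], truth.true_percentage)
print(f"truth recovery (circular rank r): {r:.4f}")

uns = unsupervised_stage(em, seed=0)
rep = align_and_compare(uns["percentage"], result.assignments["percentage"],
                        ref_ann=result.annotation)
print(f"unsupervised concordance: r = {rep.circular_pearson_r:.4f}, "
      f"mean |diff| = {rep.mean_abs_circular_diff:.2f}%")
```

prints

```
           model_time  percentage          phase
sample_id
S0001           1.875      18.750  proliferative
S0002           4.180      61.250      secretory
S0003           4.740      67.083      secretory
S0004           7.875       5.417      menstrual
truth recovery (circular rank r): 0.9942
unsupervised concordance: r = 0.9995, mean |diff| = 1.71%
```

`model_time` is the raw position on the cyclic 7-stage axis (period 7,
stage 1 ≈ menstruation); `percentage` is the uniformized 0–100 cycle
position; the circular rank correlation of 0.994 says the pipeline
recovered the generative cycle order almost perfectly despite noisy
expression and jittered stage labels, and the label-free model lands within
~1.7 percentage points of the supervised one after aligning the arbitrary
origin and direction.

The same workflows are available from the shell:

```
cyclestage simulate --out-dir sim --seed 11
cyclestage stage fit --expression sim/expression.tsv --annotation sim/annotation.tsv --out-dir run
cyclestage stage unsupervised --expression sim/expression.tsv \
    --annotation run/annotation_reassigned.tsv --reference run/assignments.tsv --out unsup.tsv
cyclestage dge scan --expression sim/expression.tsv --assignments run/assignments.tsv --out scan.tsv
```

## Layout

* `cyclestage.splines` — penalized cubic / cyclic-cubic regression spline
  bases, GCV smoothing selection, vectorized per-gene fitting.
* `cyclestage.staging` — `MolecularStager` (fit/predict estimator), the
  secretory and whole-cycle workflows, uniformization, normalization,
  cross-validation, model application.
* `cyclestage.unsupervised` — `UnsupervisedStager` and two-model alignment.
* `cyclestage.dge` — gene-wise OLS, moderated t / treat, BH, window scan,
  weighted Fisher, reference-list overlap.
* `cyclestage.io` — TSV/CSV matrices, low-expression filter, TMM log2-CPM,
  probe collapsing.
* `cyclestage.simulate` — the synthetic cohort generator with truth.
* `cyclestage.pipeline`, `cyclestage.report`, `cyclestage.cli` — the
  end-to-end bundle, figures, and the command-line interface.

See `docs/methods.md` for the modelling details, parameter defaults and
known limitations.
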