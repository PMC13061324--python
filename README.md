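# cnaware

Copy-number-aware differential gene expression analysis for aneuploid
tumor–normal RNA-seq comparisons.

## The problem

In aneuploid cancers, copy-number variation (CNV) changes gene dosage across
large parts of the genome. A standard differential-expression (DE) test then
conflates two very different biological signals: expression shifts that are a
passive consequence of gene dosage (an amplified gene transcribed from more
template copies) and active regulatory changes that are independent of — or
even oppose — the dosage. `cnaware` separates them by fitting the same
negative-binomial GLM twice, once ignoring CN (the *CN-naive* model, the
conventional analysis) and once with a per-gene, per-sample CN dosage offset
(the *CN-aware* model), and classifying each gene from the joint outcome.

## The model

Counts for gene *g* in sample *n* follow a negative binomial with dispersion
α<sub>g</sub> (Var = μ + αμ²) and mean

    mu_{g,n} = s_n * (CN_{g,n} / 2) * exp( sum_f x_{n,f} beta_{g,f} )

where *s<sub>n</sub>* is a median-of-ratios size factor, CN/2 the absolute
copy number relative to the diploid reference (CN = 2 for all normal
samples), and X the design matrix (intercept + tumor/normal condition +
optional covariates). With CN ≡ 2 the dosage term is 1 and the model reduces
to the standard NB GLM. Fitting follows the empirical-Bayes recipe familiar
from DESeq2-class tools: Cox–Reid-adjusted gene-wise dispersion ML, a
parametric α(μ̄) = a₀ + a₁/μ̄ trend, MAP shrinkage of log-dispersion toward
the trend, IRLS coefficient estimation, a heavy-tailed (Cauchy) prior MAP
estimate of the condition log₂FC, and a Wald test of the condition contrast.

The two models' p-values are combined gene-wise with a stage-wise
multiple-testing scheme: a Simes omnibus p-value
p<sup>S</sup> = min(2·min(p<sup>N</sup>, p<sup>A</sup>), max(p<sup>N</sup>, p<sup>A</sup>))
screens the gene-level global null with a single Benjamini–Hochberg pass;
screened genes get per-model Holm confirmation. A gene is called DE under a
model when its confirmed decision holds and its shrunken |log₂FC| > 1.
The joint bits map to four classes:

| naive | aware | class | interpretation |
|---|---|---|---|
| 1 | 0 | **DSG** | dosage-sensitive: change explained by CN |
| 1 | 1 | **DIG** | dosage-insensitive: regulatory change, CN-independent |
| 0 | 1 | **DCG** | dosage-compensated: CN altered, expression buffered |
| 0 | 0 | non-DEG | no significant change |

## Worked example

```python
import numpy as np
from cnaware import SimConfig, simulate_dataset, analyze

cfg = SimConfig(
    n_genes=2000, n_per_condition=20,
    class_proportions={"DSG": 0.15, "DIG": 0.25, "DCG": 0.15, "nonDEG": 0.45},
)
ds = simulate_dataset(cfg, rng=np.random.default_rng(7))
res = analyze(ds.counts, ds.cn, ds.design, alpha=0.05, lfc_threshold=1.0)
print(res.summary.round(1))
```

```
              count  percent
dosage_class
DSG             162      8.3
DIG             474     24.4
DCG             221     11.4
nonDEG         1085     55.9
```

2000 simulated genes (after the mean-normal-count ≥ 10 filter, 1942 remain)
are classified from the dual fits. Comparing with the simulator's ground
truth, every DSG/DIG/DCG call is correct here; the classes are only
under-called (e.g. 132 of 294 true DSGs land in non-DEG because their tumor
CN of 4 implies a dosage log₂FC of exactly 1, which the strict > 1 gate
rejects about half the time). Per-gene output lives in `res.table`
(log₂FC under both models, Simes/BH-adjusted p, class, CN state).

The same workflow runs from the shell:

```bash
cnaware simulate --config sim.yaml --out data/ --seed 7
cnaware fit --counts data/counts.tsv --cn data/cn.tsv \
            --design data/design.csv --out results/
cnaware benchmark --suite de --out bench/ --seed 0
```

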