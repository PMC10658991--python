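# reosig

Discovery and application of **relative-expression-ordering (REO) gene-pair
prognostic signatures** for survival cohorts, with a focus on recurrence risk
in early-onset colorectal cancer (EOCRC, diagnosis before age 50).

## The problem and the method

Quantitative expression signatures are fragile: absolute expression values
shift with platform, normalization and batch. A REO signature instead uses
only the *within-sample ordering* of two genes: for an oriented pair
(G<sub>i</sub>, G<sub>j</sub>) the binary indicator

&nbsp;&nbsp;&nbsp;&nbsp;x = **1**{ G<sub>i</sub> > G<sub>j</sub> }

votes "high risk" when the ordering matches the risk-associated direction.
Because any strictly increasing per-sample transform f<sub>s</sub> preserves
within-sample orderings, every quantity the classifier computes is invariant
to batch distortions and normalization choices — a property this package
tests exhaustively.

Signature discovery runs a funnel over two independent training cohorts,
each containing an early-onset (< 50 y) and a late-onset (> 60 y) stratum:

1. **Age-related genes** — genes differentially expressed between the age
   strata (two-sided Wilcoxon rank-sum, p < 0.05) in *both* cohorts.
2. **REO pair encoding** — every unordered pair of age-related genes becomes
   a per-sample binary indicator.
3. **Cox screen** — each indicator is fitted in a univariate Cox
   proportional-hazards model against relapse-free survival in the
   surgery-only population of each cohort (Wald p < 0.05); survivors are
   orientation-canonicalized so the high-risk ordering has HR > 1.
4. **Consistency** — pairs significant with the same orientation in both
   cohorts.
5. **De-redundancy** — among pairs sharing a gene, keep the one with the
   most significant (worst-cohort) p-value; the result is gene-disjoint.
6. **Forward-stepwise selection** — starting from the single pair with the
   highest Harrell concordance index on the surgery-only EOCRC stratum,
   greedily add the pair that most increases the C-index of the signature's
   vote score until no addition improves it.

The frozen signature of k pairs classifies a sample **high-risk iff more
than k/2 pairs vote high-risk** (strict majority; for k = 6 that means at
least 4 votes). Evaluation uses Kaplan–Meier curves, the log-rank test,
uni-/multivariate Cox models and Fisher's exact association tests.

## Worked example

Because real cohorts cannot ship with the package, the built-in generator
produces study-shaped synthetic data: two training cohorts and a validation
cohort sharing five planted gene-disjoint pairs whose REO state multiplies
the recurrence hazard by 3, ~20% censoring, and a *different* monotone batch
distortion applied to each cohort.

```python
from reosig import (SyntheticConfig, generate_study,
                    GenePairSignatureModel, SURGERY_ONLY_EOCRC)

config = SyntheticConfig(seed=1, n_samples_per_cohort=300, n_planted_pairs=5)
study = generate_study(config, batch_transforms=(
    "log", {"kind": "affine", "slope": 3, "offset": 5}, "pwl"))
train_a, train_b, validation = (study[k][0] for k in
                                ("train_a", "train_b", "validation"))

results = GenePairSignatureModel(train_a, train_b).fit()
print(results.summary())
```

```
Funnel:
  age_related_genes            70
  cox_screen[train_a]          224
  cox_screen[train_b]          200
  consistent_pairs             45
  deredundant_pairs            6
  signature_pairs              6

Signature: k=6 pairs, rule high-risk iff votes > 3, training C-index 0.6874
gene_high gene_low  HR[train_a] p[train_a]  HR[train_b] p[train_b]
    G0059    G0458        2.225   2.16e-09        2.017   1.50e-07
    ...
```

The funnel found 70 age-related genes, screened the 2415 pairs they form,
and selected a 6-pair signature containing all 5 planted pairs (the sixth is
a correlated passenger). Applying it to the independent, differently
distorted validation cohort:

```python
report = results.evaluate(validation, population=SURGERY_ONLY_EOCRC)
```

prints `log-rank p = 2.2e-14, HR = 5.33 (95% CI 3.32–8.56), C-index =
0.617`: the high-risk group of the early-onset surgery-only validation
stratum recurs about five times faster, despite the validation cohort never
being seen during discovery and carrying its own batch distortion.

The same pipeline is available from the shell:

```bash
reosig simulate --config sim.yaml --out-dir data/
reosig discover --expr-a data/train_a.expression.tsv --clin-a data/train_a.clinical.tsv \
                --expr-b data/train_b.expression.tsv --clin-b data/train_b.clinical.tsv \
                --out-dir run/
reosig classify --signature run/signature.json \
                --expr data/validation.expression.tsv --clin data/validation.clinical.tsv \
                --out run/calls.tsv
reosig evaluate --calls run/calls.tsv --expr data/validation.expression.tsv \
                --clin data/validation.clinical.tsv --population eocrc_surgery_only \
                --out run/report.json
```

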