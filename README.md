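# signsum — heterogeneity-robust gene ranking with sign-sum statistics

`signsum` ranks genes (or any features measured on two groups of
samples) by **subsample sign-sum statistics**: instead of comparing the
two group means once, it compares the means of many small subsamples —
`a` disease samples against `b` normal samples — and records the
fraction of comparisons in which the disease subsample wins,

```
U^S_j = (1 / (k0 k1)) * sum over subsample pairs of H(Xbar_j1 - Xbar_j0),
```

with `H` the Heaviside step (`H(0) = 1`). The score lives in `[0, 1]`;
`a = b = 1` recovers the classical Mann–Whitney pair proportion.

## Why

In expression data a disease group is often *heterogeneous*: only a
fraction of the disease samples actually responds (an up-shifted
mixture component), while the rest look like normals. A two-sample
t-statistic sees only the overall mean and variance, so a gene that is
uniformly shifted in every disease sample ("homo") and a gene shifted
strongly in only part of them ("hetero") can have *exactly equal* t —
yet the homo gene is usually the better biomarker. The sign-sum
statistic with a small disease subset (`a = 1`) and a larger normal
subset (`b = 5` or `10`) separates the two: on calibrated synthetic
data where t is blind by construction, `s_{1,10}` recovers roughly 83
of the 100 homo genes in the top 100 at n = 200 (and 98 at n = 1000),
versus 50 — chance level among the shifted genes — for t.

The package provides:

- **Core statistics** (`signsum.core`): Welch t, subsample-t `t_{a,b}`,
  and sign-sum `s_{a,b}`, each with an exact enumeration mode and a
  seeded Monte-Carlo mode with standard errors and a top-k convergence
  check; signed ranking with deterministic tie-breaking.
- **Asymptotics** (`signsum.asymptotics`): the limiting mean and
  variance of `U^S` under normal-mixture two-group models, confidence
  intervals, and the homo-vs-hetero upper-confidence-limit gap as a
  function of `(a, b)`.
- **Simulation study** (`signsum.simulation`): the calibrated
  homo/hetero/null generator (hetero shift solved in closed form so
  homo and hetero genes have equal asymptotic t) and the ranking study
  that counts recovered homo genes.
- **Evaluation** (`signsum.evaluation`): split-half reproducibility
  (top-k overlap and its chance-normalised ratio, ORRS) and DLDA
  classification AUC from the selected genes.
- **CLI** (`signsum rank | simulate | reproducibility | asymptotics`).

## Worked example

Rank a small synthetic dataset (3 homo, 3 hetero, 14 null genes,
30 + 30 samples) with the sign-sum statistic `s_{1,5}`:

```python
from signsum import GeneRanking
from signsum.simulation import SimulationConfig, generate_dataset

data = generate_dataset(SimulationConfig(p_homo=3, p_hetero=3, p_null=14,
                                         n0=30, n1=30, master_seed=7), 0)
res = GeneRanking(data.matrix).fit(statistic="sign_sum", a=1, b=5, seed=0)
print(res.summary())
print("top 5:", res.top_genes(5))
```

Output:

```
Gene ranking results
====================================================
statistic:      sign_sum
genes:          20
samples:        60 (disease 30, normal 30)
orientation:    signed
subset sizes:   a=1, b=5 (exact)
----------------------------------------------------
 gene_id statistic    score  rank
hetero05  sign_sum 0.911772     1
  homo00  sign_sum 0.880352     2
  homo02  sign_sum 0.875364     3
  homo01  sign_sum 0.853057     4
hetero03  sign_sum 0.847392     5
hetero04  sign_sum 0.725212     6
  null16  sign_sum 0.628058     7
  null10  sign_sum 0.595060     8
  null12  sign_sum 0.583592     9
  null08  sign_sum 0.541261    10

top 5: ['hetero05', 'homo00', 'homo02', 'homo01', 'hetero03']
```

`GeneRanking.from_dataframe(frame, labels)` accepts a genes × samples
`DataFrame` plus a sample → {0, 1} label mapping; `res.to_tsv(path)`
writes the ranking. The same works from the command line on TSV/CSV
files:

```bash
signsum rank expr.tsv labels.tsv --stat sign_sum --a 1 --b 10 \
    --seed 3 --out scores.tsv
```

### Theory in three lines

Under the calibrated half-responding mixture (where homo and hetero
genes have identical asymptotic t), the limiting sign-sum means and the
gap between the two genes' 95% upper confidence limits at n = 200:

```python
from signsum.asymptotics import TwoGroupModel, signsum_ci, ucl_difference
from signsum.simulation import solve_hetero_mean

m2 = solve_hetero_mean(1.0, 0.5)        # 2.828427
homo = TwoGroupModel.homo(mu1=1.0)
het = TwoGroupModel.hetero(tau1=0.5, m2=m2)
for b in (1, 5, 10):
    print(f"b={b:>2}: homo E[U^S]={signsum_ci(homo, 1, b, n=200).center:.4f}  "
          f"hetero E[U^S]={signsum_ci(het, 1, b, n=200).center:.4f}  "
          f"UCL gap={ucl_difference(homo, het, 1, b, n=200):.4f}")
```

```
b= 1: homo E[U^S]=0.7602  hetero E[U^S]=0.7386  UCL gap=0.0173
b= 5: homo E[U^S]=0.8193  hetero E[U^S]=0.7475  UCL gap=0.0644
b=10: homo E[U^S]=0.8298  hetero E[U^S]=0.7482  UCL gap=0.0734
```

The gap is positive and grows with `b` — exactly the regime in which
the simulation study shows `s_{1,10}` beating t.

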