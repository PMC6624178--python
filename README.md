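# clearf

Supervised feature scoring for continuous omics data via **class-wise
low-dimensional embedding and reconstruction error**.

Given a samples × features matrix X with class labels y (disease subtypes,
case/control, ...), ClearF scores every feature j by

```
score_j = Recon_all(F_j) − Σ_c Recon_c(F_j)
```

where `Recon_all(F_j)` is feature j's squared reconstruction error after
embedding the *pooled* data into k components and reconstructing it, and
`Recon_c(F_j)` is the same quantity computed on the samples of class c
alone, with the same k. The construction mirrors mutual information
I(X;Y) = H(X) − H(X|Y): the pooled reconstruction error plays the role of
the entropy H(X), the class-wise sum the role of the conditional entropy
H(X|Y). A feature scores high when its variation is hard to compress in the
pooled data but easy to compress within each class — exactly the features
that separate the classes. Unlike discretization-based mutual-information
estimators, the score works directly on continuous values and costs only
C + 1 PCA (or kernel PCA) fits for C classes, making it a fast filter method
for biomarker ranking in expression-like data (the intended regime is many
features, a modest number of which are to be selected).

The package provides:

- `ClearF` — a scikit-learn selector (`fit(X, y)`, `transform`,
  `get_support`, `scores_`, `ranking_`) with linear-PCA, RBF- and
  polynomial-kernel-PCA backends, composable with sklearn pipelines;
- the component-size search (candidates `{1, Cmin/4, Cmin/2, 3·Cmin/4,
  Cmin}` from the smallest class count, chosen on an inner validation
  split) and the 10-fold cross-validated accuracy benchmark with an
  RBF-SVM (`cross_validate`);
- the two validation simulations: the entropy↔reconstruction-error
  correlation study and the separated-vs-overlapping two-feature study
  (`simulations` module);
- delimited-text dataset I/O and a `clearf` command line
  (`score`, `benchmark`, `simulate entropy`, `simulate twoclass`).

## Worked example

```python
import numpy as np
from clearf import ClearF, generate_informative

# 120 samples, 2 classes; 3 features shifted by 3 within-class SDs
# between classes, 50 pure-noise features
d = generate_informative(n_samples=120, n_informative=3, n_noise=50,
                         shift=3.0, seed=42)
sel = ClearF(n_features_to_select=3).fit(d.X, d.y)
for name, s, r in sorted(zip(d.feature_names, sel.scores_, sel.ranking_),
                         key=lambda t: t[2])[:5]:
    print(f"{name:8s} score={s:8.4f} rank={r}")
print("selected:", [d.feature_names[j] for j in np.flatnonzero(sel.get_support())])
```

prints

```
inf2     score= -0.1620 rank=1
inf1     score= -0.2553 rank=2
inf0     score= -0.3081 rank=3
noise30  score= -0.5282 rank=4
noise37  score= -0.6896 rank=5
selected: ['inf0', 'inf1', 'inf2']
```

All three class-shifted features outrank the 50 noise features. Absolute
score values can be negative (with the default per-class *mean* squared
error the class-wise term is summed over classes); only differences and
the induced ranking matter.

The two-feature applicability study, from the shell:

```sh
clearf simulate twoclass --kind separated --samples 500 --seed 0 --output sep.tsv
clearf score --input sep.tsv --aggregation sum --no-standardize --output sep_scores.tsv
cat sep_scores.tsv
```

```
feature	score	rank
x2	451.119539324	1
x1	428.798452754	2
```

On the matched *overlapping* dataset the same command yields scores of
0.14 and 0.13 — three orders of magnitude smaller, because nothing about
the two classes is easier to compress separately than jointly.

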