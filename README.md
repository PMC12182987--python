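# dmharmonize

Distribution-matching (DM) harmonization of multi-site structural brain
connectivity.

## The problem

Structural connectomes — symmetric non-negative matrices whose entries
quantify white-matter connection strength between brain region pairs — are
highly sensitive to scanner hardware and acquisition protocol. Pooling
subjects from several imaging sites therefore confounds biological effects
with site effects. Standard batch-correction tools built on Gaussian
location/scale models (ComBat, CovBat) are a poor fit for connectivity: the
data are non-negative, strongly skewed, and sparse (many region pairs have
exactly zero connectivity), and Gaussian corrections can produce negative
values or turn zeros into non-zeros.

`dmharmonize` is for researchers pooling connectomes across scanners who need
a harmonization that respects this structure.

## The model

Each connection's value $c \ge 0$ at one site is modeled as a zero-inflated
gamma (ZIG) mixture: a point mass at zero with weight $\lambda$ plus a gamma
density on the positive values,

$$f(c) = \lambda\,\delta_+(c) + (1-\lambda)\, g_{\beta,\gamma}(c),
\qquad
g_{\beta,\gamma}(c) = \frac{1}{\Gamma(\gamma)\beta^{\gamma}}
c^{\gamma-1} e^{-c/\beta},$$

with CDF $F(c) = \lambda u(c) + (1-\lambda) G_{\beta,\gamma}(c)$, where the
step $u$ satisfies $u(0)=0$, and closed-form inverse

$$F^{-1}(p) = \begin{cases} 0 & p \le \lambda \\
G^{-1}_{\beta,\gamma}\!\big(\tfrac{p-\lambda}{1-\lambda}\big) & p > \lambda.
\end{cases}$$

Harmonizing a new site $N$ onto a reference site $R$ maps each value to the
reference value with the same percentile:

$$T_{N\to R} = F_R^{-1} \circ F_N,$$

fitted and applied independently per connection (per sex group, optionally),
on $\log(1+c)$, with $\lambda$ the empirical zero fraction and $(\beta,
\gamma)$ the gamma MLE over positive values. Because $u(0)=0$, zeros always
map to zeros, outputs stay non-negative, and the map is monotone, so
within-site subject ranking is preserved.

The package also provides: augmentation of a connectivity matrix with
indirect (multi-synaptic) pathways via effective conductance on the
connection graph (Laplacian pseudoinverse), the evaluation battery used to
judge harmonization (bounded transform $c \mapsto 1-e^{-c/\bar c}$, Pearson
correlation per connection, one-sided Wilcoxon signed-rank on $|r|$,
Bonferroni accounting, $\Delta s$ ranking with $s = -\log p$, subsampling
stability of the ZIG fit), and a synthetic multi-site generator so everything
is testable without imaging data.

## Worked example

Generate a two-site synthetic study in which a covariate ("score") acts on 20
of 210 connections identically at both sites, while the sites differ strongly
in scale and sparsity; harmonize the new site onto the reference and compare
pooled correlations:

```python
import numpy as np
import pandas as pd
from dmharmonize import (
    SubjectMetadata, ConnectivityTable, default_study_specs,
    generate_paired_sites, fit_harmonization, apply_harmonization,
    correlate, compare_to_baseline,
)

spec_ref, spec_new = default_study_specs(seed=42)
(ref, meta_ref), (new, meta_new) = generate_paired_sites(spec_ref, spec_new)
meta = SubjectMetadata(pd.concat([meta_ref.frame, meta_new.frame]).reset_index())

model = fit_harmonization(ref, new, meta)      # per-connection ZIG pairs
harmonized = apply_harmonization(model, new, meta)

ids = ref.subject_ids + new.subject_ids
pooled_pre = ConnectivityTable(np.vstack([ref.values, new.values]), ids, ref.n_regions)
pooled_post = ConnectivityTable(np.vstack([ref.values, harmonized.values]), ids, ref.n_regions)
pre = correlate(pooled_pre, meta, "score")
post = correlate(pooled_post, meta, "score")
summary = compare_to_baseline(post, pre)

print(f"zeros preserved: {(harmonized.values[new.values == 0] == 0).all()}")
print(f"signal-connection mean |r| before: {pre['r'].abs()[:20].mean():.4f}")
print(f"signal-connection mean |r| after DM: {post['r'].abs()[:20].mean():.4f}")
print(f"overall mean |r| before / after: {pre['r'].abs().mean():.4f} / {summary.mean_abs_r:.4f}")
print(f"connections significant after Bonferroni: {summary.n_significant}")
```

prints

```
zeros preserved: True
signal-connection mean |r| before: 0.1868
signal-connection mean |r| after DM: 0.2270
overall mean |r| before / after: 0.0553 / 0.0565
connections significant after Bonferroni: 17
```

The site shift attenuates the pooled correlation on the 20 signal-carrying
connections; distribution matching aligns the two sites' per-connection
distributions and recovers correlation strength there (0.19 → 0.23), while
null connections stay near zero, so the overall mean |r| moves only slightly.
Zeros remain exactly zero throughout.

The same workflow is available from the shell:

```sh
dmharmonize simulate --out-dir data --seed 42
dmharmonize fit data/ref.tsv data/new.tsv data/metadata.tsv --out model.json
dmharmonize apply model.json data/new.tsv data/metadata.tsv --out harmonized.tsv
dmharmonize evaluate harmonized.tsv data/metadata.tsv --covariate score --out post.tsv
```

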