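# rumenmark

Rumen microbial biomarkers of enteric methane emission, and partitioning of
methane-trait variance into host-genetic and microbial components.

## The problem

Enteric methane production by dairy cattle is shaped jointly by the rumen
microbial community and by host genetics. Given 16S OTU count tables, SNP
genotypes and individual methane phenotypes (methane yield
CH4y = CH4 / DMI, g per kg dry matter intake), this package implements an
integrative analysis that:

1. **Types the community** ("ruminotypes"): genus-level relative-abundance
   profiles are compared with the square-root Jensen-Shannon divergence
   (a metric), clustered by partitioning around medoids (PAM), with the
   number of clusters chosen by the Calinski-Harabasz index, silhouette
   widths reported alongside, and cluster-wise Jaccard bootstrap stability.
   Clusters are tested against the adjusted phenotype with least-squares
   means and Tukey-adjusted pairwise contrasts.
2. **Screens taxa** between ruminotypes with a zero-inflated Gaussian (ZIG)
   mixture on cumulative-sum-scaled (CSS) log2 abundances — observed zeros
   may be "structural" with probability following a logistic model on log
   library size, fitted by EM — and with a presence-absence Fisher exact
   test.
3. **Selects biomarkers** with sparse partial least squares on clr-transformed
   OTU abundances: a discriminant model (sPLS-DA, one-hot ruminotype labels,
   max.dist prediction, per-class AUROC) and a regression model on CH4y,
   keeping only the OTUs *common to both* selections.
4. **Partitions variance** with a Bayesian two-kernel mixed model

       y = 1μ + g + b + ε,   g ~ N(0, G σg²),   b ~ N(0, B σb²)

   where G is the VanRaden genomic relationship matrix and B a microbial
   relationship matrix (1 − Bray-Curtis similarity, or the covariance of the
   log-transformed standardised OTU table). A Gibbs sampler (default 30,000
   iterations, 2,000 burn-in) yields posterior means (SD) of heritability
   h² = σg²/(σg²+σb²+σe²) and microbiability m² = σb²/(σg²+σb²+σe²).

Because real data of this kind are typically access-restricted, the package
ships a synthetic-study generator (`rumenmark.synthetic`) reproducing the
statistical structure of such an experiment — 65 cows in three contemporary
groups, ~1,200 OTUs in ~100 genera with three latent community types of
sizes 30/16/19, ~2,000 HWE SNPs, and a phenotype with genetic/microbial
variance fractions 0.15/0.20 — with full ground truth, so every stage can be
validated end to end.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
import rumenmark as rm
from rumenmark.data_model import aggregate_taxon, filter_otus, prepare_phenotypes, to_relative
from rumenmark.ruminotyping import jaccard_bootstrap
from rumenmark.varcomp import McmcConfig, gibbs_two_kernel, mrm_bray
from rumenmark.data_model import genotype_qc

study = rm.simulate_study(rm.ScenarioConfig(seed=1000004))
genus = aggregate_taxon(filter_otus(study.community), "genus")
d = rm.jsd_distance(to_relative(genus))
quality = rm.select_k(d, range(2, 9))
labels = quality.solutions[quality.chosen_k].labels
print("chosen k:", quality.chosen_k)
print("ARI vs truth:", adjusted_rand_score(study.truth["labels"], labels))
print("stability:", np.round(jaccard_bootstrap(d, 3, seed=0).per_cluster, 3))

pheno = prepare_phenotypes(study.phenotypes, "CH4y")
y = pheno.data["adj_CH4y"].to_numpy()
G = rm.grm_vanraden(genotype_qc(study.genotypes)[0])
B = mrm_bray(filter_otus(study.community))
post = gibbs_two_kernel(y, G, B, McmcConfig(seed=0))
print(f"h2 = {post.mean['h2']:.3f} ({post.sd['h2']:.2f}),",
      f"m2 = {post.mean['m2']:.3f} ({post.sd['m2']:.2f})")
```

prints

```
chosen k: 3
ARI vs truth: 1.0
stability: [1. 1. 1.]
h2 = 0.283 (0.20), m2 = 0.384 (0.20)
```

The clustering recovers the three simulated community types exactly and they
are bootstrap-stable. The posterior variance fractions carry wide posterior
SDs, as expected from 65 animals: single-study point estimates at this size
are noisy even when the model is correct (the package's tests verify
calibration at n = 300, where the posterior means land within a few points
of the simulated truth).

The same pipeline is scriptable from the shell:

```bash
rumenmark simulate --outdir run --seed 1
rumenmark enterotype run/counts.tsv --outdir run --k-range 2:8
rumenmark full-run --outdir run --seed 1
```

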