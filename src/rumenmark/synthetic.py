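"""Synthetic rumen-microbiome study generator with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, at the dimensions of a typical methane-phenotyping experiment on
lactating dairy cows:

* ~65 animals in three contemporary-group cells (two pens measured in an
  early period, a third in a later one),
* ~1,200 OTUs nested in ~100 genera; each sample's genus profile is drawn
  from one of three cluster-specific Dirichlet distributions ("ruminotypes",
  default sizes 30/16/19), counts multinomial at a lognormal sequencing
  depth (CV about 50 %, which exercises zero-inflation and scaling),
* ~2,000 independent HWE SNPs with uniform allele frequencies,
* a methane-yield-like phenotype y = mu + batch-period effect + g + m + e
  with an additive-genetic part g (small effects on centred dosages), a
  microbial part m acting through the clr abundances of a set of causal OTUs
  plus a per-cluster shift, and Gaussian noise. Variances are solved so the
  *expected* genetic and microbial fractions equal the targets (defaults
  0.15 / 0.20); the realised fractions of every draw are recorded in the
  ground truth rather than assumed.

Everything is deterministic under a fixed seed, including the order in which
the community, genotypes and phenotype consume their independent substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import CountTable, GenotypeMatrix, PhenotypeTable, clr

__all__ = [
    "ScenarioConfig",
    "SyntheticStudy",
    "generate_community",
    "generate_genotypes",
    "generate_phenotype",
    "simulate_study",
]


@dataclass
class ScenarioConfig:
    """Study-design parameters of a synthetic experiment.

    ``separation`` scales the enrichment of each cluster's driver genera in
    its Dirichlet base measure; ``dirichlet_alpha`` (clusters x genera) may be
    given explicitly to bypass the built-in construction. ``layout`` is a list
    of ``(batch, period, n)`` contemporary-group cells summing to
    ``n_samples`` (``None`` reproduces the default three-cell design).
    """

    n_samples: int = 65
    n_otus: int = 1200
    n_genera: int = 100
    n_clusters: int = 3
    cluster_mixing: tuple | None = None  # default (30, 16, 19)/65 for 3 clusters
    dirichlet_alpha: np.ndarray | None = None
    separation: float = 4.0
    n_driver_genera: int = 10
    concentration: float = 45.0
    depth_lognormal: tuple = (10.0, 0.47)  # mean log depth ~e^10 = 22k reads, CV ~50 %
    n_snps: int = 2000
    maf_range: tuple = (0.05, 0.5)
    h2_true: float = 0.15
    m2_true: float = 0.20
    n_causal_otus: int = 30
    causal_from_drivers: bool = True  # draw causal OTUs from cluster-driver genera
    cluster_phenotype_shift: tuple | None = None  # default (0, +2, 0) g/kg for 3 clusters
    pheno_mean: float = 24.1  # CH4y g/kg DMI
    pheno_sd: float = 3.1
    dmi_mean: float = 21.2  # kg/day
    dmi_sd: float = 2.2
    batch_sd: float = 1.0  # SD of contemporary-group effects, g/kg
    layout: list | None = None
    seed: int = 0

    def __post_init__(self):
        if self.h2_true + self.m2_true >= 1:
            raise ValueError("h2_true + m2_true must be < 1")
        if self.h2_true < 0 or self.m2_true < 0:
            raise ValueError("variance fractions must be nonnegative")
        if self.cluster_mixing is None:
            if self.n_clusters == 3:
                self.cluster_mixing = (30 / 65, 16 / 65, 19 / 65)
            else:
                self.cluster_mixing = tuple(1 / self.n_clusters for _ in range(self.n_clusters))
        mix = np.asarray(self.cluster_mixing, dtype=float)
        if len(mix) != self.n_clusters or not np.isclose(mix.sum(), 1.0):
            raise ValueError("cluster_mixing must have n_clusters entries summing to 1")
        if self.cluster_phenotype_shift is None:
            shift = np.zeros(self.n_clusters)
            if self.n_clusters >= 2:
                shift[1] = 2.0  # one high-emitting community type by default
            self.cluster_phenotype_shift = tuple(shift)
        if len(self.cluster_phenotype_shift) != self.n_clusters:
            raise ValueError("cluster_phenotype_shift must have n_clusters entries")
        if self.dirichlet_alpha is not None:
            a = np.asarray(self.dirichlet_alpha, dtype=float)
            if a.shape != (self.n_clusters, self.n_genera) or (a <= 0).any():
                raise ValueError("dirichlet_alpha must be positive, clusters x genera")
            self.dirichlet_alpha = a

    def cluster_alphas(self) -> np.ndarray:
        """Cluster-specific Dirichlet parameters over genera.

        The base measure follows a Zipf-like rank-abundance curve; each
        cluster multiplies a disjoint set of ``n_driver_genera`` genera
        (interleaved among the most abundant ranks) by ``1 + separation``.
        """
        if self.dirichlet_alpha is not None:
            return self.dirichlet_alpha
        ranks = np.arange(self.n_genera)
        w = 1.0 / (ranks + 1.0)
        w /= w.sum()
        base = self.concentration * w
        alphas = np.tile(base, (self.n_clusters, 1))
        for c in range(self.n_clusters):
            drivers = np.arange(c, self.n_clusters * self.n_driver_genera, self.n_clusters)
            drivers = drivers[drivers < self.n_genera]
            alphas[c, drivers] *= 1.0 + self.separation
        return alphas

    def cell_layout(self) -> list:
        if self.layout is not None:
            cells = [tuple(c) for c in self.layout]
            if sum(c[2] for c in cells) != self.n_samples:
                raise ValueError("layout cell sizes must sum to n_samples")
            return cells
        n = self.n_samples
        n1 = n // 3
        n2 = n // 3
        n3 = n - n1 - n2
        return [("B1", "P1", n1), ("B2", "P1", n2), ("B3", "P2", n3)]


@dataclass
class SyntheticStudy:
    config: ScenarioConfig
    community: CountTable
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict = field(repr=False, default_factory=dict)


def _largest_remainder_counts(n: int, probs: np.ndarray) -> np.ndarray:
    raw = probs * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def _rngs(cfg: ScenarioConfig):
    ss = np.random.SeedSequence(cfg.seed)
    return [np.random.default_rng(c) for c in ss.spawn(3)]


def generate_community(cfg: ScenarioConfig, rng=None) -> tuple[CountTable, np.ndarray]:
    """Dirichlet-multinomial community with latent cluster labels.

    Cluster sizes follow ``cluster_mixing`` by largest remainder (so the
    default design realises exactly 30/16/19) and are shuffled over sample
    positions. Genus profiles are Dirichlet draws from the cluster's alpha;
    OTU counts split each genus with a fixed within-genus composition and are
    sampled multinomially at a lognormal depth.
    """
    rng = rng if rng is not None else _rngs(cfg)[0]
    n, G, O = cfg.n_samples, cfg.n_genera, cfg.n_otus
    alphas = cfg.cluster_alphas()

    sizes = _largest_remainder_counts(n, np.asarray(cfg.cluster_mixing))
    labels = np.repeat(np.arange(cfg.n_clusters), sizes)
    labels = labels[rng.permutation(n)]

    # OTUs per genus proportional to genus base abundance, at least one each
    w = 1.0 / (np.arange(G) + 1.0)
    w /= w.sum()
    otus_per_genus = rng.multinomial(O - G, w) + 1
    otu_genus = np.repeat(np.arange(G), otus_per_genus)
    splits = np.concatenate([rng.dirichlet(np.ones(k)) for k in otus_per_genus])

    mu_log, sd_log = cfg.depth_lognormal
    depths = np.maximum(rng.lognormal(mu_log, sd_log, size=n), 100).astype(int)

    counts = np.zeros((O, n), dtype=np.int64)
    for j in range(n):
        p_genus = rng.dirichlet(alphas[labels[j]])
        p_otu = p_genus[otu_genus] * splits
        counts[:, j] = rng.multinomial(depths[j], p_otu / p_otu.sum())

    fam_of_genus = np.arange(G) % max(G // 10, 1)
    taxonomy = {}
    feature_ids = []
    for i in range(O):
        g = otu_genus[i]
        fid = f"OTU_{i + 1:04d}"
        feature_ids.append(fid)
        taxonomy[fid] = (
            f"Bacteria;Phylum_{fam_of_genus[g] % 5 + 1};Class_{fam_of_genus[g] % 7 + 1};"
            f"Order_{fam_of_genus[g] % 9 + 1};Family_{fam_of_genus[g] + 1};Genus_{g + 1:03d}"
        )
    sample_ids = [f"cow_{j + 1:03d}" for j in range(n)]
    table = CountTable(feature_ids, sample_ids, counts, taxonomy, "otu")
    return table, labels


def generate_genotypes(cfg: ScenarioConfig, rng=None) -> GenotypeMatrix:
    """Independent SNPs in Hardy-Weinberg proportions, MAF uniform in ``maf_range``."""
    rng = rng if rng is not None else _rngs(cfg)[1]
    p = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    dos = rng.binomial(2, p[:, None], size=(cfg.n_snps, cfg.n_samples))
    return GenotypeMatrix(
        [f"cow_{j + 1:03d}" for j in range(cfg.n_samples)],
        [f"SNP_{i + 1:05d}" for i in range(cfg.n_snps)],
        dos,
        chrom=np.repeat(np.arange(1, 30), int(np.ceil(cfg.n_snps / 29)))[: cfg.n_snps],
        pos=np.arange(1, cfg.n_snps + 1) * 1000,
        a1=np.repeat("A", cfg.n_snps),
        a2=np.repeat("B", cfg.n_snps),
    )


def generate_phenotype(
    cfg: ScenarioConfig,
    community: CountTable,
    genotypes: GenotypeMatrix,
    labels: np.ndarray,
    rng=None,
) -> tuple[PhenotypeTable, dict]:
    """Phenotype from the generative animal model, with realised-fraction truth.

    The microbial variance budget m2 * pheno_sd^2 is split between the
    cluster shift (its realised variance) and continuous causal-OTU effects
    on clr abundances; the genetic budget is spread over all SNPs. Residual
    variance absorbs the remaining (1 - h2 - m2) share. The reported truth
    contains the realised (sample-variance) fractions, not the targets.
    """
    rng = rng if rng is not None else _rngs(cfg)[2]
    n = cfg.n_samples
    var_p = cfg.pheno_sd**2
    sg2 = cfg.h2_true * var_p
    sb2_total = cfg.m2_true * var_p
    se2 = (1.0 - cfg.h2_true - cfg.m2_true) * var_p

    shift = np.asarray(cfg.cluster_phenotype_shift, dtype=float)[labels]
    var_shift = shift.var()
    sb2_cont = sb2_total - var_shift
    if sb2_cont < 0:
        raise ValueError(
            "cluster_phenotype_shift variance exceeds the microbial budget m2_true * sd^2"
        )

    # genetic component: small effects on centred dosages
    D = genotypes.dosages.astype(float)
    p_hat = D.mean(axis=1) / 2.0
    Zc = (D - 2 * p_hat[:, None]).T
    if cfg.h2_true == 0:
        u = np.zeros(cfg.n_snps)
    else:
        het = 2.0 * np.sum(p_hat * (1 - p_hat))
        u = rng.normal(0.0, np.sqrt(sg2 / max(het, 1e-12)), size=cfg.n_snps)
    g = Zc @ u

    # microbial component: causal OTUs act through clr abundances. The
    # community types differ in their driver genera, so by default the causal
    # OTUs are drawn from those genera: the microbial signal is then both
    # compositional (OTU abundances) and structural (community type), which
    # is the joint association the biomarker search exploits.
    C = clr(community).values  # features x samples
    pool = np.arange(community.n_features)
    if cfg.causal_from_drivers and community.taxonomy and cfg.dirichlet_alpha is None:
        n_driver = cfg.n_clusters * cfg.n_driver_genera
        driver_names = {f"Genus_{g + 1:03d}" for g in range(min(n_driver, cfg.n_genera))}
        in_driver = np.array(
            [
                community.taxonomy.get(f, "").split(";")[-1] in driver_names
                for f in community.feature_ids
            ]
        )
        if in_driver.sum() >= cfg.n_causal_otus:
            pool = np.flatnonzero(in_driver)
    causal_idx = np.sort(rng.choice(pool, cfg.n_causal_otus, replace=False))
    if sb2_cont == 0 or cfg.n_causal_otus == 0:
        beta = np.zeros(len(causal_idx))
    else:
        clr_var = C[causal_idx].var(axis=1)
        total_var = clr_var.sum()
        beta = rng.normal(0.0, np.sqrt(sb2_cont / max(total_var, 1e-12)), size=len(causal_idx))
    m_cont = C[causal_idx].T @ beta
    m = m_cont + shift

    cells = cfg.cell_layout()
    batch = np.concatenate([[c[0]] * c[2] for c in cells])
    period = np.concatenate([[c[1]] * c[2] for c in cells])
    cell_effects = {(c[0], c[1]): rng.normal(0.0, cfg.batch_sd) for c in cells}
    bp = np.array([cell_effects[(batch[j], period[j])] for j in range(n)])

    e = rng.normal(0.0, np.sqrt(se2), size=n)
    ch4y = cfg.pheno_mean + bp + g + (m - m.mean()) + e
    dmi = rng.normal(cfg.dmi_mean, cfg.dmi_sd, size=n)
    dmi = np.maximum(dmi, 5.0)
    df = pd.DataFrame(
        {
            "animal_id": community.sample_ids,
            "batch": batch,
            "period": period,
            "CH4": ch4y * dmi,
            "DMI": dmi,
            "CH4y": ch4y,
        }
    )

    var_g, var_m, var_e = g.var(ddof=1), m.var(ddof=1), e.var(ddof=1)
    tot = var_g + var_m + var_e
    truth = {
        "labels": labels,
        "causal_otu_ids": [community.feature_ids[i] for i in causal_idx],
        "causal_effects": beta,
        "snp_effects": u,
        "components": {"genetic": g, "microbial": m, "residual": e, "batch_period": bp},
        "realized_h2": float(var_g / tot),
        "realized_m2": float(var_m / tot),
        "target_h2": cfg.h2_true,
        "target_m2": cfg.m2_true,
    }
    return PhenotypeTable(df), truth


def simulate_study(cfg: ScenarioConfig | None = None, **overrides) -> SyntheticStudy:
    """Generate a full study (community, genotypes, phenotypes, truth)."""
    if cfg is None:
        cfg = ScenarioConfig(**overrides)
    elif overrides:
        cfg = ScenarioConfig(**{**asdict(cfg), **overrides})
    rng_c, rng_g, rng_p = _rngs(cfg)
    community, labels = generate_community(cfg, rng_c)
    genotypes = generate_genotypes(cfg, rng_g)
    phenotypes, truth = generate_phenotype(cfg, community, genotypes, labels, rng_p)
    return SyntheticStudy(cfg, community, genotypes, phenotypes, truth)
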