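"""End-to-end orchestration: simulate/load -> filter -> ruminotype -> DA/PA ->
sPLS-DA + sPLS regression -> biomarker intersection -> variance components.

A run is driven by a :class:`PipelineConfig` (round-trippable to YAML); every
stage writes plain TSV/JSON artifacts into the run directory and registers
them, together with parameters, seeds and surviving feature counts, in a
``manifest.json``. All randomness flows from the single global seed through
named per-stage substreams, so a rerun with the same config is bit-identical
for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    aggregate_taxon,
    clr,
    filter_otus,
    genotype_qc,
    prepare_phenotypes,
    read_count_table,
    read_genotypes,
    read_phenotypes,
    to_relative,
    write_count_table,
    write_genotypes,
)
from .differential import fit_zig, presence_absence
from .diversity import rv_coefficient, shannon_per_sample, whittaker_beta
from .ruminotyping import cluster_phenotype_assoc, jaccard_bootstrap, jsd_distance, select_k
from .spls import SparsePLS, SparsePLSDA, auroc, intersect_biomarkers
from .synthetic import ScenarioConfig, simulate_study
from .varcomp import McmcConfig, grm_vanraden, variance_report

__all__ = ["PipelineConfig", "run_full", "stability_report"]

_STAGES = ("simulate", "filter", "enterotype", "da", "spls", "varcomp")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    # either a synthetic scenario ...
    scenario: dict | None = None
    # ... or paths to user data
    counts_path: str | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    # stage parameters
    k_min: int = 2
    k_max: int = 8
    n_boot: int = 100
    trait: str = "CH4y"
    keepx_da: tuple = (200, 31)
    keepx_reg: tuple = (200,)
    ncomp_da: int = 2
    ncomp_reg: int = 1
    css_quantile: float = 0.5
    mcmc_iters: int = 30000
    mcmc_burnin: int = 2000

    def __post_init__(self):
        for s in _STAGES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key in ("keepx_da", "keepx_reg"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("scenario"):
            kwargs["scenario"] = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs["scenario"].items()
            }
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("keepx_da", "keepx_reg"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _stage_seed(global_seed: int, stage: str) -> int:
    # crc32 is stable across processes (unlike hash()), keeping reruns identical
    import zlib

    ss = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def stability_report(table_t1, table_t2, normalization="relative"):
    """Temporal-stability report between two time-point tables of the same animals.

    Returns per-sample Shannon alpha diversity at each time point, the
    Whittaker beta diversity within each time point, and the RV coefficient
    between the two normalised abundance tables (shared samples, matched
    order).
    """
    shared = [s for s in table_t1.sample_ids if s in set(table_t2.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples between time points")
    t1 = table_t1.subset_samples(shared)
    t2 = table_t2.subset_samples(shared)
    if normalization == "clr":
        x1, x2 = clr(t1), clr(t2)
    else:
        x1, x2 = to_relative(t1), to_relative(t2)
    return {
        "shannon_t1": shannon_per_sample(t1),
        "shannon_t2": shannon_per_sample(t2),
        "whittaker_t1": whittaker_beta(t1),
        "whittaker_t2": whittaker_beta(t2),
        "rv": rv_coefficient(x1, x2),
        "n_shared": len(shared),
    }


def run_full(cfg: PipelineConfig) -> Path:
    """Execute the configured stages in dependency order; returns the run directory."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "stages": {},
    }

    def record(stage, **info):
        manifest["stages"][stage] = info

    # ---------------------------------------------------------------- inputs
    truth = None
    if cfg.stages.get("simulate", True) and cfg.counts_path is None:
        scen = ScenarioConfig(**{**(cfg.scenario or {}), "seed": cfg.seed})
        study = simulate_study(scen)
        counts, genotypes, phenotypes = study.community, study.genotypes, study.phenotypes
        truth = study.truth
        write_count_table(counts, out / "counts.tsv")
        write_genotypes(genotypes, out / "genotypes.tsv")
        phenotypes.data.to_csv(out / "phenotypes.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "labels": study.truth["labels"].tolist(),
                    "causal_otu_ids": study.truth["causal_otu_ids"],
                    "realized_h2": study.truth["realized_h2"],
                    "realized_m2": study.truth["realized_m2"],
                },
                fh,
                indent=2,
            )
        record("simulate", n_samples=counts.n_samples, n_otus=counts.n_features,
               outputs=["counts.tsv", "genotypes.tsv", "phenotypes.csv", "truth.json"])
    else:
        counts = read_count_table(cfg.counts_path)
        genotypes = read_genotypes(cfg.genotypes_path) if cfg.genotypes_path else None
        phenotypes = read_phenotypes(cfg.phenotypes_path) if cfg.phenotypes_path else None
        record("load", n_samples=counts.n_samples, n_otus=counts.n_features)

    # ---------------------------------------------------------------- filter
    if cfg.stages.get("filter", True):
        n_before = counts.n_features
        counts = filter_otus(counts)
        record("filter", n_before=n_before, n_after=counts.n_features)

    phenotypes = prepare_phenotypes(phenotypes, cfg.trait)
    adjusted = phenotypes.data[f"adj_{cfg.trait}"].to_numpy()

    # ------------------------------------------------------------ enterotype
    labels = None
    if cfg.stages.get("enterotype", True):
        genus = aggregate_taxon(counts, "genus") if counts.taxonomy else counts
        d = jsd_distance(to_relative(genus))
        quality = select_k(d, range(cfg.k_min, cfg.k_max + 1))
        labels = quality.solutions[quality.chosen_k].labels
        stab = jaccard_bootstrap(
            d, quality.chosen_k, n_boot=cfg.n_boot, seed=_stage_seed(cfg.seed, "bootstrap")
        )
        assoc = cluster_phenotype_assoc(labels, adjusted)
        pd.DataFrame({"sample_id": counts.sample_ids, "cluster": labels}).to_csv(
            out / "ruminotypes.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"k": quality.ks, "ch_index": quality.ch, "silhouette": quality.silhouette_mean}
        ).to_csv(out / "cluster_quality.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"cluster": np.arange(quality.chosen_k), "jaccard_stability": stab.per_cluster}
        ).to_csv(out / "cluster_stability.tsv", sep="\t", index=False)
        assoc["contrasts"].to_csv(out / "cluster_phenotype_contrasts.tsv", sep="\t", index=False)
        record("enterotype", chosen_k=int(quality.chosen_k),
               cluster_sizes=np.bincount(labels).tolist(),
               outputs=["ruminotypes.tsv", "cluster_quality.tsv", "cluster_stability.tsv",
                        "cluster_phenotype_contrasts.tsv"])

    # -------------------------------------------------------------------- da
    if cfg.stages.get("da", True) and labels is not None:
        genus = aggregate_taxon(counts, "genus") if counts.taxonomy else counts
        zig = fit_zig(genus, labels, css_quantile=cfg.css_quantile)
        pa = presence_absence(genus, labels)
        zig.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)
        pa.to_csv(out / "presence_absence.tsv", sep="\t", index=False)
        record("da", n_da_hits=int((zig["p_adjusted"] < 0.05).sum()),
               n_pa_hits=int((pa["p_adjusted"] < 0.05).sum()),
               outputs=["differential_abundance.tsv", "presence_absence.tsv"])

    # ------------------------------------------------------------------ spls
    biomarkers = None
    if cfg.stages.get("spls", True) and labels is not None:
        X = clr(counts).values.T  # samples x features
        p = X.shape[1]
        keep_da = tuple(min(k, p) for k in cfg.keepx_da)
        keep_reg = tuple(min(k, p) for k in cfg.keepx_reg)
        da_model = SparsePLSDA(n_components=cfg.ncomp_da, keep_x=keep_da).fit(X, labels)
        reg_model = SparsePLS(n_components=cfg.ncomp_reg, keep_x=keep_reg).fit(X, adjusted)
        aucs = auroc(da_model, X, labels)
        biomarkers = intersect_biomarkers(da_model, reg_model, counts.feature_ids)
        da_model.selection_table(counts.feature_ids).to_csv(
            out / "splsda_selection.tsv", sep="\t", index=False
        )
        reg_model.selection_table(counts.feature_ids).to_csv(
            out / "spls_regression_selection.tsv", sep="\t", index=False
        )
        biomarkers.table.to_csv(out / "biomarkers.tsv", sep="\t", index=False)
        record("spls", n_common=len(biomarkers),
               auroc={str(k): v for k, v in aucs.items()},
               outputs=["splsda_selection.tsv", "spls_regression_selection.tsv",
                        "biomarkers.tsv"])

    # --------------------------------------------------------------- varcomp
    if cfg.stages.get("varcomp", True) and genotypes is not None:
        qc_geno, qc_report = genotype_qc(genotypes)
        G = grm_vanraden(qc_geno)
        mcmc = McmcConfig(
            n_iter=cfg.mcmc_iters, burn_in=cfg.mcmc_burnin,
            seed=_stage_seed(cfg.seed, "varcomp"),
        )
        selected = biomarkers.common if biomarkers is not None and len(biomarkers) else None
        report, _ = variance_report({cfg.trait: adjusted}, G, counts, selected, mcmc)
        report.to_csv(out / "variance_components.tsv", sep="\t", index=False)
        record("varcomp", genotype_qc=qc_report, outputs=["variance_components.tsv"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
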