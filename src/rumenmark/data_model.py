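"""Typed containers and preparation rules for microbiome, genotype and phenotype data.

Orientation convention throughout the package: **features in rows, samples in
columns** for count/abundance tables, and SNPs in rows, animals in columns for
genotype matrices.

The module covers the data-preparation steps that precede every analysis stage:

* OTU retention (doubleton removal, then a 0.001 % relative-total floor),
* taxonomic aggregation of OTUs to a named rank (typically genus),
* SNP quality control (MAF, missingness, Hardy-Weinberg),
* abundance transforms (relative, centred log-ratio, cumulative-sum scaling),
* phenotype derivation (methane yield CH4y = CH4/DMI) and contemporary-group
  adjustment (residual from the batch x period cell mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TAXONOMIC_RANKS",
    "MISSING_DOSAGE",
    "CountTable",
    "AbundanceTable",
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_count_table",
    "write_count_table",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "filter_otus",
    "aggregate_taxon",
    "genotype_qc",
    "to_relative",
    "clr",
    "css_normalize",
    "css_scaling_factors",
    "prepare_phenotypes",
]

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: sentinel for a missing genotype call in the integer dosage matrix
MISSING_DOSAGE = -1


def _check_unique(ids, what):
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")
    return ids


@dataclass
class CountTable:
    """Integer feature x sample count matrix with optional taxonomy.

    ``level`` records the feature granularity (``otu``, ``genus``, ``mgs`` or
    ``kegg_module``); ``taxonomy`` maps feature id to a ``;``-delimited lineage
    string ordered as :data:`TAXONOMIC_RANKS`.
    """

    feature_ids: list
    sample_ids: list
    counts: np.ndarray
    taxonomy: dict | None = None
    level: str = "otu"

    def __post_init__(self):
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if counts.size and np.issubdtype(counts.dtype, np.floating):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValueError("non-integral count")
        if counts.size and (counts < 0).any():
            raise ValueError("negative counts")
        self.counts = counts.astype(np.int64)

    @property
    def n_features(self):
        return len(self.feature_ids)

    @property
    def n_samples(self):
        return len(self.sample_ids)

    def feature_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def sample_depths(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_features(self, keep_mask_or_ids) -> "CountTable":
        if isinstance(keep_mask_or_ids, np.ndarray) and keep_mask_or_ids.dtype == bool:
            idx = np.flatnonzero(keep_mask_or_ids)
        else:
            pos = {f: i for i, f in enumerate(self.feature_ids)}
            idx = np.array([pos[f] for f in keep_mask_or_ids], dtype=int)
        fids = [self.feature_ids[i] for i in idx]
        tax = {f: self.taxonomy[f] for f in fids if f in self.taxonomy} if self.taxonomy else None
        return CountTable(fids, list(self.sample_ids), self.counts[idx], tax, self.level)

    def subset_samples(self, sample_ids) -> "CountTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return CountTable(
            list(self.feature_ids), list(sample_ids), self.counts[:, idx], self.taxonomy, self.level
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        return df


@dataclass
class AbundanceTable:
    """Real-valued feature x sample matrix tagged with its transform."""

    feature_ids: list
    sample_ids: list
    values: np.ndarray
    transform: str
    taxonomy: dict | None = None
    level: str = "otu"
    scale_factors: np.ndarray | None = None  # css per-sample scaling, when applicable

    _TRANSFORMS = ("relative", "clr", "css_log2", "log_std")

    def __post_init__(self):
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.transform not in self._TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lists")
        if vals.size:
            colsum = vals.sum(axis=0)
            if self.transform == "relative" and not np.allclose(colsum, 1.0, atol=1e-9):
                raise ValueError("relative abundance columns must sum to 1")
            if self.transform == "clr" and not np.allclose(colsum, 0.0, atol=1e-9):
                raise ValueError("clr columns must sum to 0")
        self.values = vals

    @property
    def n_features(self):
        return len(self.feature_ids)

    @property
    def n_samples(self):
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        return df


@dataclass
class GenotypeMatrix:
    """SNP x animal dosage matrix coded 0/1/2 with :data:`MISSING_DOSAGE` for no-calls."""

    animal_ids: list
    snp_ids: list
    dosages: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    a1: np.ndarray | None = None
    a2: np.ndarray | None = None

    def __post_init__(self):
        self.animal_ids = _check_unique(self.animal_ids, "animal")
        self.snp_ids = _check_unique(self.snp_ids, "snp")
        d = np.asarray(self.dosages)
        if d.shape != (len(self.snp_ids), len(self.animal_ids)):
            raise ValueError("dosage shape does not match id lists")
        ok = np.isin(d, (0, 1, 2, MISSING_DOSAGE))
        if d.size and not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self.dosages = d.astype(np.int8)

    @property
    def n_snps(self):
        return len(self.snp_ids)

    @property
    def n_animals(self):
        return len(self.animal_ids)

    def subset_snps(self, mask) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask)
        pick = lambda arr: arr[idx] if arr is not None else None  # noqa: E731
        return GenotypeMatrix(
            list(self.animal_ids),
            [self.snp_ids[i] for i in idx],
            self.dosages[idx],
            pick(self.chrom),
            pick(self.pos),
            pick(self.a1),
            pick(self.a2),
        )


@dataclass
class PhenotypeTable:
    """Per-animal phenotype records (batch, period, CH4 g/day, DMI kg/day, CH4y g/kg)."""

    data: pd.DataFrame

    REQUIRED = ("animal_id", "batch", "period")

    def __post_init__(self):
        df = self.data.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        if df["animal_id"].duplicated().any():
            # repeated records (an animal measured in two periods) are allowed
            pass
        if "CH4y" in df.columns and {"CH4", "DMI"} <= set(df.columns):
            both = df["CH4"].notna() & df["DMI"].notna() & df["CH4y"].notna()
            if both.any() and not np.allclose(
                df.loc[both, "CH4y"], df.loc[both, "CH4"] / df.loc[both, "DMI"], atol=1e-9
            ):
                raise ValueError("CH4y must equal CH4 / DMI")
        self.data = df

    def adjusted(self, trait: str) -> pd.Series:
        col = f"adj_{trait}"
        if col not in self.data.columns:
            raise KeyError(f"trait {trait!r} has not been adjusted; run prepare_phenotypes")
        return self.data.set_index("animal_id")[col]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(path, orientation_hint=None, level="otu") -> CountTable:
    """Read a TSV count table (header = sample ids, first column = feature ids).

    An optional last column named ``taxonomy`` carries lineage strings. When
    ``orientation_hint`` is absent, features-in-rows is assumed unless a
    taxonomy column proves it.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = None
    tax_cols = [c for c in df.columns if str(c).lower() == "taxonomy"]
    if tax_cols:
        taxonomy = df[tax_cols[0]].astype(str).to_dict()
        df = df.drop(columns=tax_cols)
    if orientation_hint == "samples_in_rows":
        if taxonomy is not None:
            raise ValueError("taxonomy column implies features in rows")
        df = df.T
    elif orientation_hint not in (None, "features_in_rows"):
        raise ValueError(f"unknown orientation hint {orientation_hint!r}")
    counts = df.to_numpy()
    if counts.size and not np.issubdtype(counts.dtype, np.number):
        raise ValueError("non-numeric cells in count table")
    if counts.size and np.issubdtype(counts.dtype, np.floating):
        if np.any(~np.isfinite(counts)) or np.any(counts != np.floor(counts)):
            raise ValueError("non-integral count")
    return CountTable(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        counts.astype(np.int64) if counts.size else counts.reshape(df.shape),
        taxonomy,
        level,
    )


def write_count_table(table: CountTable, path) -> None:
    df = table.to_dataframe()
    if table.taxonomy is not None:
        df = df.assign(taxonomy=[table.taxonomy.get(f, "") for f in table.feature_ids])
    df.to_csv(path, sep="\t")


def read_genotypes(path) -> GenotypeMatrix:
    """Read a genotype TSV ``snp_id, chrom, pos, a1, a2, <animal ids...>`` with NA missing."""
    df = pd.read_csv(path, sep="\t")
    meta = ["snp_id", "chrom", "pos", "a1", "a2"]
    if list(df.columns[:5]) != meta:
        raise ValueError(f"genotype TSV must start with columns {meta}")
    animals = [str(c) for c in df.columns[5:]]
    dos = df[df.columns[5:]].to_numpy(dtype=float)
    dos = np.where(np.isnan(dos), MISSING_DOSAGE, dos)
    return GenotypeMatrix(
        animals,
        [str(s) for s in df["snp_id"]],
        dos,
        df["chrom"].to_numpy(),
        df["pos"].to_numpy(),
        df["a1"].to_numpy(),
        df["a2"].to_numpy(),
    )


def write_genotypes(g: GenotypeMatrix, path) -> None:
    n = g.n_snps
    df = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "chrom": g.chrom if g.chrom is not None else np.ones(n, dtype=int),
            "pos": g.pos if g.pos is not None else np.arange(1, n + 1),
            "a1": g.a1 if g.a1 is not None else ["A"] * n,
            "a2": g.a2 if g.a2 is not None else ["B"] * n,
        }
    )
    dos = g.dosages.astype(float)
    dos[dos == MISSING_DOSAGE] = np.nan
    for j, a in enumerate(g.animal_ids):
        df[a] = dos[:, j]
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")


def read_vcf(path) -> GenotypeMatrix:
    """Minimal read-only VCF path: GT fields mapped to ALT-allele dosage."""
    try:
        from cyvcf2 import VCF  # optional dependency
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError("cyvcf2 is required for VCF input") from exc
    vcf = VCF(str(path))
    animals = list(vcf.samples)
    snp_ids, chrom, pos, a1, a2, rows = [], [], [], [], [], []
    for i, var in enumerate(vcf):
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        a1.append(var.REF)
        a2.append(var.ALT[0] if var.ALT else ".")
        gt = np.asarray(var.gt_types)  # 0=hom ref,1=het,2=unknown,3=hom alt
        row = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING_DOSAGE)
        rows.append(row)
    return GenotypeMatrix(
        animals, snp_ids, np.array(rows), np.array(chrom), np.array(pos), np.array(a1), np.array(a2)
    )


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype CSV with header ``animal_id,batch,period,CH4,DMI``."""
    df = pd.read_csv(path)
    df["animal_id"] = df["animal_id"].astype(str)
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# filtering / aggregation / QC
# ---------------------------------------------------------------------------

def filter_otus(table: CountTable, min_total=2, min_fraction=1e-5) -> CountTable:
    """Retain OTUs after doubleton removal and a relative-total floor.

    Features with total count <= ``min_total`` (doubletons and below) are
    dropped first; the remaining features must each represent more than
    ``min_fraction`` (0.001 %) of the remaining grand total. Order preserved;
    idempotent.
    """
    if table.level != "otu":
        raise ValueError("filter_otus expects an OTU-level table")
    totals = table.feature_totals()
    keep = totals > min_total
    sub_totals = totals[keep]
    grand = sub_totals.sum()
    if grand > 0:
        keep[keep] = sub_totals / grand > min_fraction
    return table.subset_features(keep)


def _lineage_at_rank(lineage: str, rank_idx: int) -> str:
    parts = [p.strip() for p in lineage.split(";")]
    parts = [p for p in parts if p != ""]
    if len(parts) > rank_idx and parts[rank_idx]:
        return parts[rank_idx]
    parent = parts[-1] if parts else "root"
    return f"unclassified_{parent}"


def aggregate_taxon(table: CountTable, rank="genus") -> CountTable:
    """Sum counts over features sharing the lineage label at ``rank``.

    Features whose lineage stops above ``rank`` are pooled into an
    ``unclassified_<deepest known rank>`` bucket. Conserves the grand total.
    """
    if table.taxonomy is None:
        raise ValueError("aggregate_taxon requires taxonomy")
    if rank not in TAXONOMIC_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {TAXONOMIC_RANKS}")
    rank_idx = TAXONOMIC_RANKS.index(rank)
    order, rows, lineages = [], {}, {}
    for i, fid in enumerate(table.feature_ids):
        lineage = table.taxonomy.get(fid, "")
        name = _lineage_at_rank(lineage, rank_idx)
        if name not in rows:
            order.append(name)
            rows[name] = np.zeros(table.n_samples, dtype=np.int64)
            parts = [p.strip() for p in lineage.split(";") if p.strip()]
            lineages[name] = ";".join(parts[: rank_idx + 1])
        rows[name] += table.counts[i]
    counts = np.array([rows[name] for name in order]) if order else np.zeros((0, table.n_samples))
    return CountTable(order, list(table.sample_ids), counts, lineages or None, rank)


def genotype_qc(
    g: GenotypeMatrix, maf_min=0.05, max_missing=0.10, hwe_alpha=0.001
) -> tuple[GenotypeMatrix, dict]:
    """SNP quality control: MAF >= ``maf_min``, missing rate <= ``max_missing``
    and Hardy-Weinberg 1-df chi-square p >= ``hwe_alpha``.

    Each rule is evaluated on the full input (removal sets are independent of
    SNP order); any failure removes the SNP. Returns the filtered matrix and a
    per-rule report.
    """
    d = g.dosages
    observed = d != MISSING_DOSAGE
    n_obs = observed.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(observed, d, 0).sum(axis=1)
        p = np.where(n_obs > 0, alt / np.maximum(2 * n_obs, 1), 0.0)
        maf = np.minimum(p, 1 - p)
        miss_rate = 1 - n_obs / g.n_animals

        n0 = ((d == 0) & observed).sum(axis=1)
        n1 = (d == 1).sum(axis=1)
        n2 = (d == 2).sum(axis=1)
        exp = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1) * n_obs[:, None]
        obs = np.stack([n0, n1, n2], axis=1)
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(axis=1)
    hwe_p = stats.chi2.sf(chi2, df=1)

    fail_maf = maf < maf_min
    fail_miss = miss_rate > max_missing
    fail_hwe = hwe_p < hwe_alpha
    keep = ~(fail_maf | fail_miss | fail_hwe)
    out = g.subset_snps(keep)

    kept_p = p[keep]
    if keep.any() and np.all((kept_p <= 0) | (kept_p >= 1)):
        warnings.warn("all retained SNPs are monomorphic", stacklevel=2)
    report = {
        "n_input": g.n_snps,
        "n_retained": int(keep.sum()),
        "removed_maf": int(fail_maf.sum()),
        "removed_missing": int(fail_miss.sum()),
        "removed_hwe": int(fail_hwe.sum()),
    }
    return out, report


# ---------------------------------------------------------------------------
# abundance transforms
# ---------------------------------------------------------------------------

def _require_counts(table):
    if not isinstance(table, CountTable):
        raise TypeError("expected a CountTable of raw counts")


def to_relative(table: CountTable) -> AbundanceTable:
    """Divide each sample column by its library size."""
    _require_counts(table)
    depths = table.sample_depths().astype(float)
    if (depths == 0).any():
        raise ValueError("zero library size")
    vals = table.counts / depths
    return AbundanceTable(
        list(table.feature_ids), list(table.sample_ids), vals, "relative",
        table.taxonomy, table.level,
    )


def clr(table: CountTable, pseudocount=1.0) -> AbundanceTable:
    """Centred log-ratio transform: ln(count + pseudocount) minus the sample mean log."""
    _require_counts(table)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(table.counts + float(pseudocount))
    vals = logs - logs.mean(axis=0, keepdims=True)
    return AbundanceTable(
        list(table.feature_ids), list(table.sample_ids), vals, "clr",
        table.taxonomy, table.level,
    )


def css_scaling_factors(table: CountTable, quantile=0.5) -> np.ndarray:
    """Cumulative-sum scaling factor per sample.

    The factor is the sum of the sample's counts that do not exceed the chosen
    quantile of its nonzero count distribution (linear-interpolated quantile).
    """
    scales = np.empty(table.n_samples)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {table.sample_ids[j]!r} has no nonzero counts")
        qval = np.quantile(nz, quantile)
        scales[j] = col[col <= qval].sum()
    return scales


def _adaptive_css_quantile(table: CountTable, rel_tol=0.1) -> float:
    # relative-difference rule: walk the quantile grid of per-sample nonzero
    # count distributions and stop where the median across-sample deviation
    # from the reference quantile curve starts changing by more than rel_tol.
    grid = np.linspace(0.05, 0.95, 19)
    qmat = np.empty((table.n_samples, grid.size))
    for j in range(table.n_samples):
        nz = table.counts[:, j][table.counts[:, j] > 0]
        if nz.size == 0:
            raise ValueError("sample with no nonzero counts")
        qmat[j] = np.quantile(nz, grid)
    ref = np.median(qmat, axis=0)
    dev = np.median(np.abs(qmat - ref), axis=1)
    rel = np.abs(np.diff(dev)) / np.maximum(dev[1:], 1e-12)
    hits = np.flatnonzero(rel > rel_tol)
    return float(grid[hits[0]]) if hits.size else 0.5


def css_normalize(table: CountTable, quantile=0.5) -> AbundanceTable:
    """Cumulative-sum scaling with a log2 stabilisation.

    values = log2(count / scale * 1000 + 1). ``quantile="adaptive"`` applies a
    relative-difference rule for the quantile choice; the fixed default 0.5 is
    the reproducible baseline.
    """
    _require_counts(table)
    if quantile == "adaptive":
        quantile = _adaptive_css_quantile(table)
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    scales = css_scaling_factors(table, quantile)
    vals = np.log2(table.counts / scales * 1000.0 + 1.0)
    return AbundanceTable(
        list(table.feature_ids), list(table.sample_ids), vals, "css_log2",
        table.taxonomy, table.level, scale_factors=scales,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def prepare_phenotypes(pheno: PhenotypeTable, trait="CH4y") -> PhenotypeTable:
    """Derive CH4y where absent and adjust ``trait`` for the contemporary group.

    The adjusted trait is the residual of a one-way fixed-effect model on the
    batch x period cell: value minus its cell mean. Residuals therefore sum to
    zero within every cell; a single-animal cell yields residual 0 (warned).
    """
    df = pheno.data.copy()
    if "CH4y" not in df.columns and {"CH4", "DMI"} <= set(df.columns):
        df["CH4y"] = df["CH4"] / df["DMI"]
    elif "CH4y" in df.columns and {"CH4", "DMI"} <= set(df.columns):
        need = df["CH4y"].isna()
        df.loc[need, "CH4y"] = df.loc[need, "CH4"] / df.loc[need, "DMI"]
    if trait not in df.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    cell = df.groupby(["batch", "period"])[trait]
    sizes = cell.transform("size")
    if (sizes == 1).any():
        warnings.warn("batch x period cell with a single animal: residual set to 0", stacklevel=2)
    df[f"adj_{trait}"] = df[trait] - cell.transform("mean")
    return PhenotypeTable(df)
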