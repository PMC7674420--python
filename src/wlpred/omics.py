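"""Omics feature engineering: abundance normalization, taxon ranking,
SNP encoding and pruning, genetic risk scores and per-SNP association."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Abundances
# ---------------------------------------------------------------------------

def shotgun_relative_abundance(read_count, ref_size_bp):
    """Relative abundance of a shotgun-mapped species in percent.

    ``100 * read_count / (ref_size_bp * 2)`` — the factor 2 accounts for
    paired-end reads.  Vectorized over array inputs.
    """
    read_count = np.asarray(read_count, dtype=float)
    ref_size_bp = np.asarray(ref_size_bp, dtype=float)
    if np.any(ref_size_bp <= 0):
        raise ValueError("reference sizes must be > 0")
    if np.any(read_count < 0):
        raise ValueError("read counts must be >= 0")
    out = 100.0 * read_count / (ref_size_bp * 2.0)
    return float(out) if out.ndim == 0 else out


def relative_abundance_16s(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances: each count over the sample total.

    Rows are samples.  All-zero samples are flagged and emitted as missing
    (a row of NaN) rather than raising.
    """
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d all-zero samples emitted as missing", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts.div(totals.replace(0, np.nan), axis=0)
    return frac


def rank_taxa(
    table: pd.DataFrame,
    participants: pd.Series,
    prevalence_min: int = 5,
    k: int = 250,
) -> pd.DataFrame:
    """Rank taxa by between-visit variance, restricted by prevalence.

    Parameters
    ----------
    table:
        sample x taxon relative abundances, covering multiple visits per
        participant (one row per visit sample).
    participants:
        participant id per sample, aligned with ``table.index``.
    prevalence_min:
        minimum number of samples in which a taxon must be present (> 0).
    k:
        number of top taxa to return (k in {10, 250} typically).

    Returns an ordered frame (taxon, prevalence, variance), variance
    descending.  Between-visit variance is the mean over participants of the
    per-participant variance across that participant's visits; taxa are
    tie-broken by prevalence then name for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    participants = pd.Series(np.asarray(participants), index=table.index)
    prevalence = (table > 0).sum(axis=0)
    kept = prevalence[prevalence >= prevalence_min].index
    grouped = table.loc[:, kept].groupby(participants.to_numpy())
    per_participant_var = grouped.var(ddof=0)
    variance = per_participant_var.mean(axis=0).fillna(0.0)
    ranking = pd.DataFrame(
        {"taxon": kept, "prevalence": prevalence[kept].to_numpy(), "variance": variance[kept].to_numpy()}
    ).sort_values(["variance", "prevalence", "taxon"], ascending=[False, False, True], kind="mergesort")
    if k > len(ranking):
        logger.info("k=%d exceeds pool of %d retained taxa; returning all", k, len(ranking))
        k = len(ranking)
    return ranking.head(k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def encode_snp_binary(dosage):
    """Encode a minor-allele dosage as (minor_present, major_present).

    0 -> (0, 1); 1 -> (1, 1); 2 -> (1, 0).  Vectorized.
    """
    d = np.asarray(dosage)
    if not np.all(np.isin(d, (0, 1, 2))):
        raise ValueError("dosages must be integral in {0, 1, 2}")
    minor = (d >= 1).astype(int)
    major = (d <= 1).astype(int)
    if np.ndim(dosage) == 0:
        return int(minor), int(major)
    return minor, major


def encode_genotype_block(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Two indicator columns per SNP: ``<snp>_minor`` and ``<snp>_major``."""
    cols = {}
    for snp in genotypes.columns:
        minor, major = encode_snp_binary(genotypes[snp].to_numpy())
        cols[f"{snp}_minor"] = minor
        cols[f"{snp}_major"] = major
    return pd.DataFrame(cols, index=genotypes.index)


def _vif(X: np.ndarray, j: int) -> float:
    """VIF of column j regressed on the remaining columns: 1 / (1 - R^2)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0  # monomorphic: no variance to inflate
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    r2 = min(r2, 1.0 - 1e-12)
    return 1.0 / (1.0 - r2)


def vif_prune(
    genotypes: pd.DataFrame,
    positions=None,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 1.0,
    window_kb: float | None = None,
    tol: float = 1e-8,
) -> list[str]:
    """Sliding-window VIF pruning of correlated SNPs.

    SNPs are ordered by position; within each window the SNP with the
    largest VIF is removed iteratively while any VIF exceeds
    ``vif_threshold`` (strict ``>`` with numerical tolerance ``tol``, so
    orthogonal SNPs survive a threshold of 1).  The window then advances by
    ``step`` SNPs.  ``window`` counts SNPs by default; pass ``window_kb``
    for a physical-distance window instead.  Removal is permanent across
    windows; surviving ids are returned in position order.
    """
    if window < 2:
        raise ValueError("window must cover >= 2 SNPs")
    snps = list(genotypes.columns)
    if len(snps) < 2:
        return snps
    if positions is None:
        positions = pd.Series(range(len(snps)), index=snps)
    else:
        positions = pd.Series(positions, index=snps) if not isinstance(positions, pd.Series) else positions
    order = sorted(snps, key=lambda s: positions[s])
    removed: set[str] = set()
    start = 0
    while start < len(order):
        if window_kb is not None:
            w0 = positions[order[start]]
            win = [s for s in order[start:] if positions[s] - w0 <= window_kb * 1000]
        else:
            win = order[start:start + window]
        active = [s for s in win if s not in removed]
        while len(active) >= 2:
            X = genotypes[active].to_numpy(dtype=float)
            vifs = np.array([_vif(X, j) for j in range(len(active))])
            worst = int(np.argmax(vifs))
            if vifs[worst] > vif_threshold + tol:
                removed.add(active[worst])
                active.pop(worst)
            else:
                break
        if start + (window if window_kb is None else len(win)) >= len(order):
            break
        start += step
    return [s for s in order if s not in removed]


@dataclass(frozen=True)
class GRSDefinition:
    """Weighted genetic risk score: per-SNP effect sizes."""

    weights: dict[str, float]

    def __post_init__(self):
        if not self.weights:
            raise ValueError("GRS definition needs >= 1 SNP")

    @classmethod
    def from_tsv(cls, path) -> "GRSDefinition":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float))))


def grs(genotypes: pd.DataFrame, definition: GRSDefinition) -> pd.Series:
    """Per-sample weighted sum of minor-allele dosages."""
    missing = [s for s in definition.weights if s not in genotypes.columns]
    if missing:
        raise KeyError(f"GRS SNPs absent from genotype matrix: {missing}")
    snps = list(definition.weights)
    w = np.array([definition.weights[s] for s in snps], dtype=float)
    score = genotypes[snps].to_numpy(dtype=float) @ w
    return pd.Series(score, index=genotypes.index, name="grs")


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def rank_z_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (midranks, Blom-style offsets)."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.5) / len(x))


def per_snp_association(
    genotypes: pd.DataFrame,
    phenotype,
    covariates: pd.DataFrame | None = None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP linear association of a phenotype with additive dosage.

    A Shapiro-Wilk gate at ``normality_alpha`` decides whether the phenotype
    is rank-z-transformed before fitting.  Each SNP is fit by OLS
    ``phenotype ~ dosage + covariates``; monomorphic SNPs yield NaN rows.

    Returns a frame indexed by SNP with columns ``beta``, ``se``, ``p``.
    """
    y = np.asarray(phenotype, dtype=float)
    if covariates is not None:
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.empty((len(y), 0))
    if len(y) != len(genotypes):
        raise ValueError("phenotype length must match genotype rows")
    sw_p = stats.shapiro(y).pvalue if 3 <= len(y) <= 5000 else stats.normaltest(y).pvalue
    if sw_p < normality_alpha:
        y = rank_z_transform(y)
    base = np.column_stack([np.ones(len(y)), C])
    out = {}
    for snp in genotypes.columns:
        g = genotypes[snp].to_numpy(dtype=float)
        if np.ptp(g) == 0:
            logger.debug("monomorphic SNP %s: association undefined", snp)
            out[snp] = (np.nan, np.nan, np.nan)
            continue
        A = np.column_stack([base, g])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        dof = len(y) - A.shape[1]
        if dof <= 0:
            out[snp] = (np.nan, np.nan, np.nan)
            continue
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.pinv(A.T @ A)
        beta = coef[-1]
        se = np.sqrt(cov[-1, -1])
        t = beta / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), dof) if np.isfinite(t) else np.nan
        out[snp] = (beta, se, p)
    df = pd.DataFrame.from_dict(out, orient="index", columns=["beta", "se", "p"])
    df.index.name = "snp"
    return df


def grs_from_association(
    genotypes: pd.DataFrame,
    phenotype,
    covariates: pd.DataFrame | None = None,
    p_threshold: float = 1e-4,
) -> GRSDefinition | None:
    """Build a GRS from per-SNP association betas at ``p < p_threshold``."""
    assoc = per_snp_association(genotypes, phenotype, covariates)
    hits = assoc[assoc["p"] < p_threshold]
    if hits.empty:
        return None
    return GRSDefinition(dict(zip(hits.index, hits["beta"])))


# ---------------------------------------------------------------------------
# VCF I/O (optional)
# ---------------------------------------------------------------------------

def read_vcf_dosages(path) -> pd.DataFrame:
    """Minor-allele dosage matrix from a VCF (GT field; biallelic sites only).

    Multi-allelic sites are skipped with a warning.  Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic site %s", var.ID or f"{var.CHROM}:{var.POS}")
            continue
        name = var.ID or f"{var.CHROM}:{var.POS}"
        gts = var.genotypes  # [allele_a, allele_b, phased]
        data[name] = np.array([a + b if a >= 0 and b >= 0 else -1 for a, b, *_ in gts])
    df = pd.DataFrame(data, index=samples)
    return df.replace(-1, np.nan)


def write_vcf(genotypes: pd.DataFrame, path, positions=None, chrom: str = "1") -> None:
    """Write a dosage matrix as a minimal VCF 4.2 with GT-only records."""
    samples = list(genotypes.index)
    if positions is None:
        positions = {snp: 1000 * (i + 1) for i, snp in enumerate(genotypes.columns)}
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for snp in genotypes.columns:
            calls = [
                gt_map.get(int(d), "./.") if np.isfinite(d) else "./."
                for d in genotypes[snp].to_numpy(dtype=float)
            ]
            fh.write(f"{chrom}\t{positions[snp]}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")
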