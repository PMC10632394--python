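"""Expression/genotype quality control, normalization and confounder removal.

Two expression versions are maintained deliberately: ``expression_net``
(covariate-adjusted only) feeds the transcriptome-wide causal stages, while
``expression_iv`` (additionally adjusted for top genotype principal
components) is used only for local cis-association scans, where population
stratification would otherwise inflate associations.  Removing genotype PCs
from the network version would strip genuine trans-regulatory signal, so it
is left unadjusted for them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryDataset",
    "filter_genes_gtex",
    "filter_genes_tcga",
    "tmm_normalize",
    "vst_substitute",
    "hwe_exact_test",
    "filter_variants",
    "impute_major_allele",
    "adjust_confounders",
    "genotype_pca",
    "read_expression_tsv",
    "read_dosage_tsv",
    "read_vcf_dosages",
    "read_bed",
    "read_gtf",
]


@dataclass
class RegulatoryDataset:
    """Aligned, QC'd inputs for network inference.

    ``expression_net`` and ``expression_iv`` share shape and gene order;
    ``genotypes`` has no missing values after imputation.  ``qc_log`` is an
    ordered record of every filter applied with the number of items removed.
    """

    expression_net: np.ndarray  # (n, p)
    expression_iv: np.ndarray  # (n, p)
    genotypes: np.ndarray  # (n, q), complete
    gene_annotation: pd.DataFrame
    variant_annotation: pd.DataFrame
    sample_ids: list[str]
    qc_log: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.sample_ids)
        if self.expression_net.shape != self.expression_iv.shape:
            raise ValueError("expression versions must share shape")
        if self.expression_net.shape[0] != n or self.genotypes.shape[0] != n:
            raise ValueError("matrices must be row-aligned on sample_ids")
        if np.isnan(self.genotypes).any():
            raise ValueError("genotypes contain missing values after QC")


def _log(qc_log: list[dict] | None, step: str, before: int, after: int) -> None:
    if qc_log is not None:
        qc_log.append(
            {"step": step, "in": before, "removed": before - after, "out": after}
        )


# ---------------------------------------------------------------------------
# gene filters
# ---------------------------------------------------------------------------


def filter_genes_gtex(
    counts: np.ndarray,
    tpm: np.ndarray,
    tpm_cut: float = 0.1,
    frac: float = 0.2,
    read_cut: int = 6,
    qc_log: list[dict] | None = None,
) -> np.ndarray:
    """Expression filter used for count+TPM inputs.

    A gene is kept iff TPM strictly above ``tpm_cut`` in at least ``frac``
    of samples AND at least ``read_cut`` reads in at least ``frac`` of
    samples.  Returns indices of kept genes (axis 0 = genes).
    """
    counts = np.asarray(counts)
    tpm = np.asarray(tpm)
    if counts.shape != tpm.shape:
        raise ValueError("counts and tpm must share shape and gene order")
    n = counts.shape[1]
    ok_tpm = (tpm > tpm_cut).sum(axis=1) >= frac * n
    ok_reads = (counts >= read_cut).sum(axis=1) >= frac * n
    keep = np.nonzero(ok_tpm & ok_reads)[0]
    _log(qc_log, "filter_genes_gtex", counts.shape[0], len(keep))
    return keep


def filter_genes_tcga(
    counts: np.ndarray,
    total_cut: float = 2.5e6,
    missing_frac: float = 0.8,
    qc_log: list[dict] | None = None,
) -> np.ndarray:
    """Total-count / missingness filter for raw-count inputs.

    A gene is removed iff its total count across samples is below
    ``total_cut`` or it is zero (treated as missing) in more than
    ``missing_frac`` of samples.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    n = counts.shape[1]
    total_ok = counts.sum(axis=1) >= total_cut
    missing_ok = (counts == 0).sum(axis=1) <= missing_frac * n
    keep = np.nonzero(total_ok & missing_ok)[0]
    _log(qc_log, "filter_genes_tcga", counts.shape[0], len(keep))
    return keep


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def tmm_normalize(
    counts: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    log_offset: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Trimmed-mean-of-M-values normalization of a genes x samples count matrix.

    The reference library is the one whose upper quartile of relative counts
    is closest to the mean upper quartile.  Each library's factor is the
    weighted, doubly trimmed mean of gene-wise log2 ratios against the
    reference (30% of M-values and 5% of A-values trimmed from each tail;
    inverse asymptotic-variance weights), and factors are rescaled so their
    geometric mean is one.  Returns ``(factors, log2_matrix)`` where the
    matrix is log2 of counts rescaled to the mean effective library size,
    with a +``log_offset`` inside the log.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >= 2 samples")
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("a library has zero total count")

    rel = counts / lib
    uq = np.array([np.quantile(rel[:, j][counts[:, j] > 0], 0.75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(counts[:, j], counts[:, ref], lib[j], lib[ref], trim_m, trim_a)

    factors /= np.exp(np.mean(np.log(factors)))
    eff_lib = lib * factors
    scaled = counts / eff_lib * eff_lib.mean()
    return factors, np.log2(scaled + log_offset)


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float, trim_m: float, trim_a: float
) -> float:
    ok = (obs > 0) & (ref > 0)
    if ok.sum() == 0:
        return 1.0
    po, pr = obs[ok] / n_obs, ref[ok] / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic variance of M for binomial counts
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    if np.max(np.abs(m)) < 1e-10:  # identical composition
        return 1.0
    n = len(m)
    lo_m, hi_m = np.quantile(m, trim_m), np.quantile(m, 1 - trim_m)
    lo_a, hi_a = np.quantile(a, trim_a), np.quantile(a, 1 - trim_a)
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if keep.sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def vst_substitute(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median-of-ratios size factors followed by a log2(x/s + 1) transform.

    A light-weight variance-stabilizing substitute: the size factor of a
    sample is the median across all-positive genes of the ratio of its
    counts to the gene-wise geometric mean.  Returns ``(size_factors,
    log2_matrix)`` for a genes x samples input.
    """
    counts = np.asarray(counts, dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with all-positive counts; size factors undefined")
    logref = np.mean(np.log(counts[allpos]), axis=1)
    sf = np.exp(np.median(np.log(counts[allpos]) - logref[:, None], axis=0))
    return sf, np.log2(counts / sf + 1.0)


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, heterozygote counts follow
    the HWE exact distribution; the p-value sums the probabilities of all
    heterozygote counts no more probable than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("counts must be nonnegative with positive total")
    n = n_AA + n_Aa + n_aa
    n_minor = 2 * min(n_AA, n_aa) + n_Aa
    # log-probability of each feasible het count (same parity as n_minor)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homr = (n_minor - hets) // 2
    homc = n - hets - homr
    logp = (
        math.lgamma(n + 1)
        - np.array([math.lgamma(h + 1) for h in hets])
        - np.array([math.lgamma(r + 1) for r in homr])
        - np.array([math.lgamma(c + 1) for c in homc])
        + hets * math.log(2.0)
        + math.lgamma(n_minor + 1)
        + math.lgamma(2 * n - n_minor + 1)
        - math.lgamma(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.nonzero(hets == n_Aa)[0][0]]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    obs = col[~np.isnan(col)]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def filter_variants(
    genotypes: np.ndarray,
    sample_missing_cut: float = 0.1,
    variant_missing_cut: float = 0.1,
    mac_cut: int = 5,
    hwe_alpha: float = 1e-4,
    qc_log: list[dict] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype QC: sample missingness, variant missingness, HWE, MAC.

    Steps, in order: drop samples with missing rate above
    ``sample_missing_cut``; drop variants with missing rate above
    ``variant_missing_cut`` among remaining samples; drop variants with HWE
    exact p below ``hwe_alpha``; drop variants with minor-allele count below
    ``mac_cut``.  Returns ``(filtered_matrix, kept_sample_idx,
    kept_variant_idx)``.
    """
    G = np.asarray(genotypes, dtype=float)
    n, q = G.shape

    smiss = np.isnan(G).mean(axis=1)
    keep_s = np.nonzero(smiss <= sample_missing_cut)[0]
    _log(qc_log, "sample_missing", n, len(keep_s))
    G = G[keep_s]

    vmiss = np.isnan(G).mean(axis=0)
    keep_v = np.nonzero(vmiss <= variant_missing_cut)[0]
    _log(qc_log, "variant_missing", q, len(keep_v))
    G = G[:, keep_v]

    hwe_ok = []
    for j in range(G.shape[1]):
        aa, ab, bb = _genotype_counts(G[:, j])
        hwe_ok.append(hwe_exact_test(aa, ab, bb) >= hwe_alpha)
    hwe_ok = np.asarray(hwe_ok)
    _log(qc_log, "hwe", len(keep_v), int(hwe_ok.sum()))
    keep_v = keep_v[hwe_ok]
    G = G[:, hwe_ok]

    mac = []
    for j in range(G.shape[1]):
        obs = G[:, j][~np.isnan(G[:, j])]
        alt = obs.sum()
        mac.append(min(alt, 2 * len(obs) - alt))
    mac_ok = np.asarray(mac) >= mac_cut
    _log(qc_log, "mac", len(keep_v), int(mac_ok.sum()))
    keep_v = keep_v[mac_ok]
    G = G[:, mac_ok]

    if G.size == 0:
        raise ValueError("no variants (or samples) survive genotype QC")
    return G, keep_s, keep_v


def impute_major_allele(genotypes: np.ndarray) -> np.ndarray:
    """Replace missing dosages with the homozygous major genotype (0 or 2)."""
    G = np.asarray(genotypes, dtype=float).copy()
    for j in range(G.shape[1]):
        col = G[:, j]
        obs = col[~np.isnan(col)]
        if len(obs) == 0:
            raise ValueError(f"variant {j} has no observed calls")
        fill = 2.0 if obs.mean() > 1.0 else 0.0
        col[np.isnan(col)] = fill
    return G


# ---------------------------------------------------------------------------
# confounder adjustment
# ---------------------------------------------------------------------------


def _design_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, drop_first=True).to_numpy(float)
                cols.append(dummies)
            else:
                cols.append(col.to_numpy(float)[:, None])
    return np.hstack(cols)


def _drop_collinear(D: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    q, r, piv = scipy.linalg.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    keep = np.sort(piv[:rank])
    if rank < D.shape[1]:
        logger.warning("dropping %d collinear design column(s)", D.shape[1] - rank)
    return D[:, keep]


def adjust_confounders(
    expression: np.ndarray,
    covariates: pd.DataFrame | None,
    genotype_pcs: np.ndarray | None = None,
) -> np.ndarray:
    """OLS residuals of each gene's expression on [intercept | covariates
    (| genotype PCs)].

    Categorical covariates are one-hot encoded (first level dropped).
    Rank-deficient designs are repaired by dropping collinear columns.
    """
    Y = np.asarray(expression, dtype=float)
    D = _design_matrix(covariates, Y.shape[0])
    if genotype_pcs is not None:
        D = np.hstack([D, np.asarray(genotype_pcs, dtype=float)])
    D = _drop_collinear(D)
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    return Y - D @ beta


def genotype_pca(genotypes: np.ndarray, k: int = 3) -> np.ndarray:
    """Scores of the top-k PCs of the column-standardized dosage matrix.

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so results are reproducible across platforms.
    """
    G = np.asarray(genotypes, dtype=float)
    if np.isnan(G).any():
        raise ValueError("genotype matrix must be complete for PCA")
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (G - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((S > 1e-10 * S[0]).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank}")
    flip = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    return (U[:, :k] * S[:k]) * flip[:k]


# ---------------------------------------------------------------------------
# readers (plain-text standard formats)
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an expression TSV, auto-detecting orientation.

    Returns ``(matrix n x p, sample_ids, gene_ids)``.  Orientation is
    resolved by the index name: ``gene`` means genes x samples (the writer's
    default); ``sample`` means samples x genes.  Without a recognizable
    label the wider axis is assumed to be genes.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    label = (df.index.name or "").lower()
    genes_by_samples = label.startswith("gene") or (
        not label.startswith("sample") and df.shape[0] >= df.shape[1]
    )
    if genes_by_samples:
        return df.to_numpy(float).T, list(df.columns), list(df.index)
    return df.to_numpy(float), list(df.index), list(df.columns)


def read_dosage_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Variants x samples dosage TSV -> (n x q matrix, sample_ids, variant_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float).T, list(df.columns), list(df.index)


def read_vcf_dosages(path: str | Path) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Read GT fields of a (plain-text) VCF into an n x q dosage matrix.

    ``./.`` becomes NaN.  Returns ``(dosages, sample_ids, variant_annotation)``.
    """
    rows, ids, chroms, poss = [], [], [], []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            ids.append(parts[2])
            gt_idx = parts[8].split(":").index("GT")
            row = []
            for cell in parts[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    row.append(np.nan)
                else:
                    row.append(sum(int(a) > 0 for a in gt.split("/")))
            rows.append(row)
    ann = pd.DataFrame({"variant": ids, "chrom": chroms, "pos": poss})
    return np.asarray(rows, dtype=float).T, samples, ann


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (0-based half-open) -> annotation normalized to 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"] + 1
    return df[["gene", "chrom", "start", "end"]]


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Minimal GTF reader: gene features -> (gene, chrom, start, end)."""
    recs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            gene = None
            for kv in f[8].split(";"):
                kv = kv.strip()
                if kv.startswith("gene_id"):
                    gene = kv.split(None, 1)[1].strip('"')
            recs.append({"gene": gene, "chrom": f[0], "start": int(f[3]), "end": int(f[4])})
    return pd.DataFrame(recs)
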