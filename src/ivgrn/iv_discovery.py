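"""Cis genotypic instrumental-variable discovery.

For each gene, variants inside the gene body plus a 1 kb flank are
stratified by minor-allele frequency.  Common variants (MAF >= 0.05) are
tested marginally by simple linear regression; low-MAF and rare variants
are pooled into an adaptive burden score (the aSum test) whose significance
is assessed by phenotype permutation.  Significant candidates are then
greedily thinned to at most three mutually decorrelated instruments per
gene (pairwise |r| < 0.3 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "IvInstrument",
    "IvMap",
    "IvConfig",
    "cis_window",
    "categorize_maf",
    "marginal_iv_test",
    "asum_test",
    "select_ivs",
    "discover_ivs",
]

COMMON_MAF = 0.05
LOW_MAF = 0.01


@dataclass
class IvConfig:
    flank: int = 1000
    alpha: float = 0.05
    max_ivs: int = 3
    cor_cut: float = 0.3
    asum_alpha0: float = 0.1
    n_perm: int = 1000
    pool_rare_with_low: bool = True
    bonferroni: bool = False
    seed: int = 0


@dataclass
class IvInstrument:
    """One selected instrument: a single variant or an aggregated burden score."""

    name: str
    column: np.ndarray  # (n,) dosage or burden score
    members: list[int]  # variant indices backing the column
    stratum: str  # "common" or "burden"
    p_value: float
    position: int  # genomic position used for tie-breaking


class IvMap:
    """Per-gene ordered instrument lists; the contract between IV discovery
    and the two-stage estimator."""

    def __init__(self, entries: dict[int, list[IvInstrument]] | None = None):
        self.entries: dict[int, list[IvInstrument]] = entries or {}

    def __getitem__(self, gene: int) -> list[IvInstrument]:
        return self.entries.get(gene, [])

    def genes_with_ivs(self) -> list[int]:
        return sorted(g for g, e in self.entries.items() if e)

    def instrument_matrix(self, gene: int) -> np.ndarray | None:
        """Columns of gene's instruments as an n x s matrix (None if none)."""
        entry = self[gene]
        if not entry:
            return None
        return np.column_stack([iv.column for iv in entry])

    def pooled_matrix(self) -> tuple[np.ndarray, list[tuple[int, str]]]:
        """Genome-wide IV pool: all instrument columns of all genes."""
        cols, labels = [], []
        for g in sorted(self.entries):
            for iv in self.entries[g]:
                cols.append(iv.column)
                labels.append((g, iv.name))
        if not cols:
            raise ValueError("IV map is empty; no instruments anywhere")
        return np.column_stack(cols), labels

    def to_frame(self, gene_names: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for g in sorted(self.entries):
            for iv in self.entries[g]:
                rows.append(
                    {
                        "gene": gene_names[g] if gene_names else g,
                        "instrument": iv.name,
                        "members": ",".join(map(str, iv.members)),
                        "stratum": iv.stratum,
                        "p_value": iv.p_value,
                    }
                )
        return pd.DataFrame(rows, columns=["gene", "instrument", "members", "stratum", "p_value"])


def cis_window(
    gene: pd.Series | dict,
    variants: pd.DataFrame,
    flank: int = 1000,
) -> np.ndarray:
    """Indices of variants within [start - flank, end + flank] (clamped at 1)
    on the gene's chromosome.  Coordinates are 1-based inclusive."""
    chrom = str(gene["chrom"])
    lo = max(1, int(gene["start"]) - flank)
    hi = int(gene["end"]) + flank
    on_chrom = variants["chrom"].astype(str) == chrom
    if not on_chrom.any():
        logger.warning("no variants on chromosome %s", chrom)
        return np.array([], dtype=int)
    pos = variants["pos"].to_numpy()
    return np.nonzero(on_chrom.to_numpy() & (pos >= lo) & (pos <= hi))[0]


def categorize_maf(dosages: np.ndarray) -> str:
    """MAF stratum: common (>= 0.05), low (>= 0.01), rare (< 0.01)."""
    mean = float(np.mean(dosages)) / 2.0
    maf = min(mean, 1.0 - mean)
    if maf >= COMMON_MAF:
        return "common"
    if maf >= LOW_MAF:
        return "low"
    return "rare"


def marginal_iv_test(expression: np.ndarray, dosages: np.ndarray) -> tuple[float, float]:
    """Simple-regression slope of expression on dosage and its t-test p."""
    if np.std(dosages) == 0:
        raise ValueError("constant dosage; marginal test undefined")
    res = stats.linregress(dosages, expression)
    return float(res.slope), float(res.pvalue)


def _marginal_grid(y_cols: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized slopes/p-values of each column of ``y_cols`` (n x P) on each
    column of ``G`` (n x m).  Returns (slope[m, P], p[m, P])."""
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    Yc = y_cols - y_cols.mean(axis=0)
    gss = (Gc**2).sum(axis=0)
    yss = (Yc**2).sum(axis=0)
    cross = Gc.T @ Yc  # m x P
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(gss[:, None] > 0, cross / gss[:, None], 0.0)
        den = np.outer(gss, yss)
        r2 = np.where(den > 0, cross**2 / np.where(den > 0, den, 1.0), 0.0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        t2 = r2 * (n - 2) / (1.0 - r2)
    p = stats.f.sf(t2, 1, n - 2)
    return slope, p


def asum_test(
    expression: np.ndarray,
    rare_dosages: np.ndarray,
    alpha0: float = 0.1,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Data-adaptive burden (aSum) test for a block of low-frequency variants.

    Variants whose marginal effect on the phenotype is negative with
    marginal p < ``alpha0`` have their (centered) coding flipped before the
    burden score is formed, avoiding power loss when effects go in opposite
    directions.  Because the flip is data-adaptive, significance comes from
    re-running the whole procedure on phenotype permutations; the p-value
    uses add-one smoothing (r+1)/(n_perm+1), ties counted as >= observed.

    Returns ``(burden_score_vector, p_value)``.
    """
    G = np.atleast_2d(np.asarray(rare_dosages, dtype=float))
    if G.ndim == 2 and G.shape[0] == len(expression) and G.shape[1] >= 1:
        pass
    else:
        G = G.T
    if G.shape[1] < 1 or G.shape[0] != len(expression):
        raise ValueError("need an n x m matrix with m >= 1 rare variants")
    y = np.asarray(expression, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)

    Gc = G - G.mean(axis=0)

    def _stat(y_cols: np.ndarray) -> np.ndarray:
        # y_cols: n x P. Flip per (variant, phenotype), then score = corr^2
        slope, p = _marginal_grid(y_cols, G)
        signs = np.where((slope < 0) & (p < alpha0), -1.0, 1.0)  # m x P
        S = Gc @ signs  # n x P burden scores (already centered)
        Yc = y_cols - y_cols.mean(axis=0)
        num = (S * Yc).sum(axis=0) ** 2
        den = (S**2).sum(axis=0) * (Yc**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(den > 0, num / den, 0.0)
        return r2

    obs = _stat(y[:, None])[0]
    # observed burden column (for use as an instrument downstream)
    slope, p = _marginal_grid(y[:, None], G)
    signs = np.where((slope[:, 0] < 0) & (p[:, 0] < alpha0), -1.0, 1.0)
    burden = Gc @ signs

    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = y[rng.permutation(n)]
    null = _stat(perms)
    pval = (1.0 + np.sum(null >= obs - 1e-15)) / (n_perm + 1.0)
    return burden, float(pval)


def select_ivs(
    candidates: list[IvInstrument],
    alpha: float = 0.05,
    max_ivs: int = 3,
    cor_cut: float = 0.3,
) -> list[IvInstrument]:
    """Greedy decorrelated selection among significant candidates.

    Candidates with p < ``alpha`` are sorted by p (ties broken by genomic
    position, then by name); each is accepted iff its absolute Pearson
    correlation with every already-accepted column is below ``cor_cut``,
    stopping at ``max_ivs``.
    """
    sig = [c for c in candidates if c.p_value < alpha]
    sig.sort(key=lambda c: (c.p_value, c.position, c.name))
    chosen: list[IvInstrument] = []
    for cand in sig:
        if len(chosen) >= max_ivs:
            break
        ok = True
        for acc in chosen:
            r = np.corrcoef(cand.column, acc.column)[0, 1]
            if abs(r) >= cor_cut:
                ok = False
                break
        if ok:
            chosen.append(cand)
    return chosen


def discover_ivs(
    expression_iv: np.ndarray,
    genotypes: np.ndarray,
    gene_annotation: pd.DataFrame,
    variant_annotation: pd.DataFrame,
    config: IvConfig | None = None,
) -> IvMap:
    """Full per-gene IV discovery over the transcriptome.

    For each gene: scan the cis window, test common variants marginally,
    pool low-MAF/rare variants into one aSum burden candidate, then apply
    the significance gate and greedy decorrelation.
    """
    cfg = config or IvConfig()
    ivmap = IvMap()
    n_genes = expression_iv.shape[1]
    for k in range(n_genes):
        y = expression_iv[:, k]
        idx = cis_window(gene_annotation.iloc[k], variant_annotation, cfg.flank)
        candidates: list[IvInstrument] = []
        lowrare: list[int] = []
        n_common = 0
        for j in idx:
            col = genotypes[:, j]
            if np.std(col) == 0:
                logger.info("variant %d constant; skipped", j)
                continue
            stratum = categorize_maf(col)
            if stratum == "common":
                n_common += 1
            else:
                lowrare.append(int(j))
        alpha = cfg.alpha
        if cfg.bonferroni and n_common + bool(lowrare) > 0:
            alpha = cfg.alpha / (n_common + (1 if lowrare else 0))
        for j in idx:
            col = genotypes[:, j]
            if np.std(col) == 0 or categorize_maf(col) != "common":
                continue
            _, p = marginal_iv_test(y, col)
            candidates.append(
                IvInstrument(
                    name=str(variant_annotation.iloc[j]["variant"]),
                    column=col.astype(float),
                    members=[int(j)],
                    stratum="common",
                    p_value=p,
                    position=int(variant_annotation.iloc[j]["pos"]),
                )
            )
        if lowrare:
            blocks = [lowrare] if cfg.pool_rare_with_low else [
                [j for j in lowrare if categorize_maf(genotypes[:, j]) == "low"],
                [j for j in lowrare if categorize_maf(genotypes[:, j]) == "rare"],
            ]
            for bi, block in enumerate(b for b in blocks if b):
                burden, p = asum_test(
                    y,
                    genotypes[:, block],
                    alpha0=cfg.asum_alpha0,
                    n_perm=cfg.n_perm,
                    seed=cfg.seed * 100003 + k * 31 + bi,
                )
                if np.std(burden) == 0:
                    continue
                candidates.append(
                    IvInstrument(
                        name=f"burden_g{k}_{bi}",
                        column=burden,
                        members=block,
                        stratum="burden",
                        p_value=p,
                        position=int(variant_annotation.iloc[block[0]]["pos"]),
                    )
                )
        ivmap.entries[k] = select_ivs(candidates, alpha, cfg.max_ivs, cfg.cor_cut)
    return ivmap
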