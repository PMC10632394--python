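"""Synthetic structural-equation datasets for causal network inference.

Generates ground-truth linear cyclic systems

    Y = Y @ Gamma + X @ Psi + eps,

where ``Gamma`` (p x p, zero diagonal) holds directed gene-gene regulatory
effects, ``Psi`` (q x p) holds sparse cis-genetic effects, and ``eps`` is
Gaussian disturbance independent of the genotypes ``X``.  Because the graph
may contain cycles, the observed expression is the reduced form

    Y = (X @ Psi + eps) @ inv(I - Gamma),

which exists whenever the spectral radius of ``Gamma`` is below one.

Everything here is deterministic under a fixed seed and writes plain-text
fixtures (TSV / VCF / BED / GTF / JSON) so downstream stages can be tested
without controlled-access data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SemParameters",
    "SyntheticDataset",
    "make_gene_annotation",
    "simulate_network",
    "simulate_genotypes",
    "simulate_expression",
    "render_counts",
    "simulate_dataset",
    "inject_missing",
    "write_dataset",
]

#: missing-genotype sentinel used throughout the package (dosage matrices
#: are floats; missing entries are NaN)
MISSING = np.nan

DEFAULT_SPECTRAL_BOUND = 0.8


# ---------------------------------------------------------------------------
# ground-truth model
# ---------------------------------------------------------------------------


@dataclass
class SemParameters:
    """Ground-truth parameters of the linear structural system.

    Attributes
    ----------
    gamma : (p, p) ndarray
        Regulatory effects; ``gamma[j, k]`` is the effect of gene *j* on
        gene *k* (so column *k* collects the regulators of gene *k*).
        Diagonal is structurally zero.
    psi : (q, p) ndarray
        Cis-genetic effects; nonzero entries of column *k* lie on the
        variants assigned to gene *k*.
    noise_sd : (p,) ndarray
        Disturbance standard deviation per gene.
    iv_assignment : dict[int, ndarray]
        Gene index -> indices of its cis variants.
    """

    gamma: np.ndarray
    psi: np.ndarray
    noise_sd: np.ndarray
    iv_assignment: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def gene_count(self) -> int:
        return self.gamma.shape[0]

    @property
    def variant_count(self) -> int:
        return self.psi.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.gamma))))

    def edge_set(self) -> set[tuple[int, int]]:
        """Set of (regulator, target) pairs with nonzero effect."""
        j, k = np.nonzero(self.gamma)
        return set(zip(j.tolist(), k.tolist()))

    def validate(self, spectral_bound: float = 1.0) -> None:
        p, q = self.gene_count, self.variant_count
        if self.gamma.shape != (p, p):
            raise ValueError("gamma must be square")
        if np.any(np.diag(self.gamma) != 0):
            raise ValueError("gamma diagonal must be exactly zero")
        if self.psi.shape != (q, p):
            raise ValueError("psi must be q x p")
        rho = self.spectral_radius()
        if rho >= spectral_bound:
            raise ValueError(
                f"spectral radius {rho:.4f} >= bound {spectral_bound}; "
                "reduced form is not guaranteed"
            )
        for k in range(p):
            owned = set(np.asarray(self.iv_assignment.get(k, [])).tolist())
            nz = set(np.nonzero(self.psi[:, k])[0].tolist())
            if not nz <= owned:
                raise ValueError(f"gene {k}: cis effects outside its variant block")


@dataclass
class SyntheticDataset:
    """A complete simulated study: genotypes, expression and annotations."""

    genotypes: np.ndarray  # (n, q) dosages in {0,1,2} (float; NaN if masked)
    expression: np.ndarray  # (n, p)
    epsilon: np.ndarray  # (n, p) stored disturbance draw
    gene_annotation: pd.DataFrame  # gene, chrom, start, end  (1-based inclusive)
    variant_annotation: pd.DataFrame  # variant, chrom, pos
    covariates: pd.DataFrame
    truth: SemParameters
    seed: int
    raw_counts: np.ndarray | None = None  # (n, p) nonnegative integers

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def gene_names(self) -> list[str]:
        return list(self.gene_annotation["gene"])

    def structural_residual(self) -> float:
        """Max abs of Y(I - Gamma) - X Psi - eps; ~0 by construction."""
        g = self.truth
        lhs = self.expression @ (np.eye(g.gene_count) - g.gamma)
        rhs = np.nan_to_num(self.genotypes) @ g.psi + self.epsilon
        return float(np.max(np.abs(lhs - rhs)))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_gene_annotation(
    p: int, gene_length: int = 2000, spacing: int = 50_000, chrom: str = "1"
) -> pd.DataFrame:
    """Disjoint, well-separated gene intervals on one chromosome.

    Spacing is much larger than the cis flank so that each variant can be
    cis to at most one gene.
    """
    starts = 1 + spacing * np.arange(p)
    return pd.DataFrame(
        {
            "gene": [f"G{i:04d}" for i in range(p)],
            "chrom": chrom,
            "start": starts,
            "end": starts + gene_length - 1,
        }
    )


def simulate_network(
    p: int,
    edge_density: float | None = None,
    effect_range: tuple[float, float] = (0.4, 0.8),
    ivs_per_gene: int = 3,
    allow_cycles: bool = True,
    seed: int | None = None,
    *,
    n_edges: int | None = None,
    reciprocal_pairs: int = 0,
    cis_effect_range: tuple[float, float] = (0.7, 1.2),
    noise_sd: float = 1.0,
    spectral_bound: float = DEFAULT_SPECTRAL_BOUND,
    max_retries: int = 20,
) -> SemParameters:
    """Sample a sparse directed (possibly cyclic) regulation structure.

    Either ``edge_density`` (each ordered off-diagonal pair is an edge
    independently with this probability) or an exact ``n_edges`` count must
    be given.  ``reciprocal_pairs`` forces that many mutual pairs i<->j into
    the graph (requires ``allow_cycles``).  Effect magnitudes are uniform on
    ``effect_range`` with random sign; if the sampled ``Gamma`` has spectral
    radius above ``spectral_bound`` it is rescaled (support preserved) to
    sit just below the bound.
    """
    if p < 2:
        raise ValueError("need at least two genes")
    if (edge_density is None) == (n_edges is None):
        raise ValueError("give exactly one of edge_density or n_edges")
    if edge_density is not None and not 0 <= edge_density < 1:
        raise ValueError("edge_density must be in [0, 1)")
    lo, hi = effect_range
    if not 0 < lo <= hi:
        raise ValueError("effect_range must satisfy 0 < low <= high")
    if reciprocal_pairs and not allow_cycles:
        raise ValueError("reciprocal pairs require allow_cycles=True")

    rng = np.random.default_rng(seed)

    for _ in range(max_retries):
        gamma = np.zeros((p, p))
        edges: set[tuple[int, int]] = set()

        if reciprocal_pairs:
            genes = rng.choice(p, size=2 * reciprocal_pairs, replace=False)
            for a, b in genes.reshape(-1, 2):
                edges.add((int(a), int(b)))
                edges.add((int(b), int(a)))

        if n_edges is not None:
            extra = n_edges - len(edges)
            if extra < 0:
                raise ValueError("n_edges smaller than forced reciprocal edges")
            pool = [
                (j, k)
                for j in range(p)
                for k in range(p)
                if j != k and (j, k) not in edges and (allow_cycles or j < k)
            ]
            idx = rng.choice(len(pool), size=extra, replace=False)
            edges.update(pool[i] for i in idx)
        else:
            for j in range(p):
                for k in range(p):
                    if j == k or (j, k) in edges:
                        continue
                    if not allow_cycles and j >= k:
                        continue
                    if rng.random() < edge_density:
                        edges.add((j, k))

        for j, k in sorted(edges):
            mag = rng.uniform(lo, hi)
            gamma[j, k] = mag * rng.choice([-1.0, 1.0])

        rho = float(np.max(np.abs(np.linalg.eigvals(gamma)))) if edges else 0.0
        if rho >= spectral_bound:
            gamma *= 0.999 * spectral_bound / rho
        if np.abs(np.linalg.det(np.eye(p) - gamma)) > 1e-10:
            break
    else:
        raise RuntimeError("could not sample an invertible (I - Gamma) system")

    q = p * ivs_per_gene
    psi = np.zeros((q, p))
    clo, chi = cis_effect_range
    iv_assignment = {}
    for k in range(p):
        cols = np.arange(k * ivs_per_gene, (k + 1) * ivs_per_gene)
        iv_assignment[k] = cols
        psi[cols, k] = rng.uniform(clo, chi, size=ivs_per_gene) * rng.choice(
            [-1.0, 1.0], size=ivs_per_gene
        )

    params = SemParameters(
        gamma=gamma,
        psi=psi,
        noise_sd=np.full(p, float(noise_sd)),
        iv_assignment=iv_assignment,
    )
    params.validate(spectral_bound=1.0)
    return params


def simulate_genotypes(
    n: int,
    variant_maf_targets: np.ndarray | list[float],
    seed: int | None = None,
    gene_annotation: pd.DataFrame | None = None,
    iv_assignment: dict[int, np.ndarray] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Hardy-Weinberg dosages: each variant ~ Binomial(2, MAF) per sample.

    If a gene annotation and an IV assignment are supplied, each variant is
    positioned inside its owning gene's interval so cis-window scanning sees
    realistic geometry; otherwise variants are laid out sequentially.
    """
    mafs = np.asarray(variant_maf_targets, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("target MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    q = len(mafs)
    dosages = rng.binomial(2, mafs, size=(n, q)).astype(float)

    chroms = np.full(q, "1", dtype=object)
    positions = np.zeros(q, dtype=int)
    if gene_annotation is not None and iv_assignment is not None:
        for k, cols in iv_assignment.items():
            row = gene_annotation.iloc[k]
            cols = np.asarray(cols)
            span = int(row["end"] - row["start"])
            offs = rng.choice(span + 1, size=len(cols), replace=False)
            positions[cols] = int(row["start"]) + np.sort(offs)
            chroms[cols] = row["chrom"]
    else:
        positions[:] = 1 + 1000 * np.arange(q)

    var_ann = pd.DataFrame(
        {"variant": [f"v{i:05d}" for i in range(q)], "chrom": chroms, "pos": positions}
    )
    return dosages, var_ann


def simulate_expression(
    params: SemParameters,
    genotypes: np.ndarray,
    seed: int | None = None,
    confounder: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the structural system for expression given genotypes.

    Returns ``(Y, eps)`` with ``Y = (X Psi + eps) inv(I - Gamma)``.  An
    optional ``confounder`` term (n x p) is folded into the disturbance, so
    the structural identity still holds for the returned ``eps``.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.shape[1] != params.variant_count:
        raise ValueError("genotype column count does not match psi rows")
    p = params.gene_count
    i_minus_g = np.eye(p) - params.gamma
    if np.abs(np.linalg.det(i_minus_g)) < 1e-12:
        raise ValueError("(I - Gamma) is singular; system has no reduced form")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, params.noise_sd, size=(X.shape[0], p))
    if confounder is not None:
        eps = eps + confounder
    Y = np.linalg.solve(i_minus_g.T, (X @ params.psi + eps).T).T
    return Y, eps


def render_counts(
    expression: np.ndarray,
    library_sizes: np.ndarray | list[float],
    dispersion: float = 0.05,
    seed: int | None = None,
) -> np.ndarray:
    """Render log-scale expression as negative-binomial sequencing counts.

    Per sample, relative abundance is proportional to ``2**expression``;
    the expected count is that abundance share times the sample's library
    size.  Counts are drawn gamma-Poisson with the given dispersion
    (variance mu + dispersion * mu^2), which emulates the heteroscedastic
    mean-variance relationship of RNA-seq counts.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    expr = np.asarray(expression, dtype=float)
    if lib.shape[0] != expr.shape[0]:
        raise ValueError("one library size per sample required")
    rng = np.random.default_rng(seed)
    base = 2.0 ** expr
    mu = lib[:, None] * base / base.sum(axis=1, keepdims=True)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam).astype(np.int64)


def inject_missing(
    genotypes: np.ndarray, rate: float, seed: int | None = None
) -> np.ndarray:
    """Mask a fraction of genotype entries (returns a copy with NaNs)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = np.asarray(genotypes, dtype=float).copy()
    mask = rng.random(out.shape) < rate
    out[mask] = MISSING
    return out


def simulate_dataset(
    n: int = 500,
    p: int = 30,
    n_edges: int = 25,
    reciprocal_pairs: int = 2,
    effect_range: tuple[float, float] = (0.4, 0.8),
    cis_effect_range: tuple[float, float] = (0.7, 1.2),
    ivs_per_gene: int = 3,
    noise_sd: float = 1.0,
    maf_range: tuple[float, float] = (0.1, 0.45),
    seed: int = 0,
    *,
    params: SemParameters | None = None,
    missing_rate: float = 0.0,
    confounder_sd: float = 0.0,
    with_counts: bool = False,
) -> SyntheticDataset:
    """One-call benchmark dataset.

    The defaults define the package's standard recovery benchmark: 30 genes,
    25 true regulations (two reciprocal pairs), three common cis variants
    per gene with strong effects, 500 samples, unit disturbance.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = simulate_network(
            p,
            n_edges=n_edges,
            reciprocal_pairs=reciprocal_pairs,
            effect_range=effect_range,
            cis_effect_range=cis_effect_range,
            ivs_per_gene=ivs_per_gene,
            noise_sd=noise_sd,
            allow_cycles=True,
            seed=rng.integers(2**31),
        )
    genes = make_gene_annotation(params.gene_count)
    mafs = rng.uniform(*maf_range, size=params.variant_count)
    X, var_ann = simulate_genotypes(
        n,
        mafs,
        seed=rng.integers(2**31),
        gene_annotation=genes,
        iv_assignment=params.iv_assignment,
    )

    covariates = pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], size=n),
            "platform": rng.choice(["A", "B"], size=n),
        },
        index=[f"S{i:04d}" for i in range(n)],
    )
    confounder = None
    if confounder_sd > 0:
        # shared component + covariate shifts folded into the disturbance
        z = rng.normal(0, 1, size=(n, 1))
        load = rng.normal(0, confounder_sd, size=(1, params.gene_count))
        sexeff = (covariates["sex"] == "M").to_numpy(float)[:, None] * rng.normal(
            0, confounder_sd, size=(1, params.gene_count)
        )
        confounder = z @ load + sexeff

    Y, eps = simulate_expression(
        params, X, seed=rng.integers(2**31), confounder=confounder
    )
    counts = None
    if with_counts:
        lib = rng.uniform(0.8e6, 1.2e6, size=n)
        counts = render_counts(Y - Y.min() + 1.0, lib, seed=rng.integers(2**31))
    if missing_rate > 0:
        X = inject_missing(X, missing_rate, seed=rng.integers(2**31))

    return SyntheticDataset(
        genotypes=X,
        expression=Y,
        epsilon=eps,
        gene_annotation=genes,
        variant_annotation=var_ann,
        covariates=covariates,
        truth=params,
        seed=seed,
        raw_counts=counts,
    )


# ---------------------------------------------------------------------------
# plain-text writers
# ---------------------------------------------------------------------------


def _dosage_to_gt(d: float) -> str:
    if np.isnan(d):
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the whole fixture as TSV/VCF/BED/GTF plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = list(ds.covariates.index)
    genes = ds.gene_names
    files: dict[str, str] = {}

    expr = pd.DataFrame(ds.expression.T, index=genes, columns=samples)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    files["expression"] = "expression.tsv"

    if ds.raw_counts is not None:
        pd.DataFrame(ds.raw_counts.T, index=genes, columns=samples).to_csv(
            outdir / "counts.tsv", sep="\t", index_label="gene"
        )
        files["counts"] = "counts.tsv"

    dose = pd.DataFrame(
        ds.genotypes.T, index=ds.variant_annotation["variant"], columns=samples
    )
    dose.to_csv(outdir / "genotypes.tsv", sep="\t", index_label="variant")
    files["genotypes_tsv"] = "genotypes.tsv"

    with open(outdir / "genotypes.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i, row in ds.variant_annotation.iterrows():
            gts = "\t".join(_dosage_to_gt(d) for d in ds.genotypes[:, i])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )
    files["genotypes_vcf"] = "genotypes.vcf"

    ann = ds.gene_annotation
    with open(outdir / "genes.bed", "w") as fh:  # BED: 0-based half-open
        for _, r in ann.iterrows():
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{r['gene']}\n")
    files["genes_bed"] = "genes.bed"
    with open(outdir / "genes.gtf", "w") as fh:  # GTF: 1-based inclusive
        for _, r in ann.iterrows():
            fh.write(
                f"{r['chrom']}\tivgrn\tgene\t{r['start']}\t{r['end']}\t.\t+\t.\t"
                f'gene_id "{r["gene"]}";\n'
            )
    files["genes_gtf"] = "genes.gtf"

    with open(outdir / "truth_edges.tsv", "w") as fh:
        fh.write("regulator\ttarget\teffect\n")
        for j, k in sorted(ds.truth.edge_set()):
            fh.write(f"{genes[j]}\t{genes[k]}\t{ds.truth.gamma[j, k]:.6g}\n")
    files["truth_edges"] = "truth_edges.tsv"

    ds.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index_label="sample")
    files["covariates"] = "covariates.tsv"

    manifest = {
        "seed": ds.seed,
        "n_samples": ds.n_samples,
        "gene_count": ds.truth.gene_count,
        "variant_count": ds.truth.variant_count,
        "n_edges": len(ds.truth.edge_set()),
        "spectral_radius": ds.truth.spectral_radius(),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    files["manifest"] = "manifest.json"
    return files
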