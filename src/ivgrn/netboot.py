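"""Bootstrap aggregation of network estimates into edge-confidence scores.

Each replicate resamples the samples with replacement (expression and
genotype rows jointly), re-runs the full pipeline — IV discovery by default,
then the two-stage estimator — and binarizes the coefficient matrix into an
adjacency matrix A(b).  The edge confidence is the componentwise average
Abar = (1/B) sum_b A(b); thresholding Abar at a cutoff yields the reported
network.  Replicates are seeded independently of execution order via a
counter-based scheme and can be cached to disk, so interrupted runs resume
to bit-identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .iv_discovery import IvConfig, IvInstrument, IvMap, discover_ivs
from .netanalysis import ThresholdedNetwork
from .twostage import FitConfig, fit_network

__all__ = [
    "BootstrapEnsemble",
    "bootstrap_networks",
    "aggregate",
    "threshold_network",
]


@dataclass
class BootstrapEnsemble:
    """Accumulated bootstrap adjacency counts (sparse: only pairs seen at
    least once are stored)."""

    B: int
    p: int
    counts: dict[tuple[int, int], int]  # (regulator, target) -> #replicates
    replicate_seeds: list[int] = field(default_factory=list)
    gene_names: list[str] | None = None

    def frequency(self) -> dict[tuple[int, int], float]:
        """Abar as a sparse mapping; entries not present are exactly zero."""
        return {e: c / self.B for e, c in self.counts.items()}

    def frequency_matrix(self) -> np.ndarray:
        """Dense p x p Abar with Abar[i, j] the frequency of j -> i."""
        A = np.zeros((self.p, self.p))
        for (j, i), c in self.counts.items():
            A[i, j] = c / self.B
        return A


def _replicate_seed(master: int, b: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master), int(b)]))


def _resample_ivmap(ivmap: IvMap, idx: np.ndarray) -> IvMap:
    out = IvMap()
    for g, entry in ivmap.entries.items():
        out.entries[g] = [
            IvInstrument(
                name=iv.name,
                column=iv.column[idx],
                members=iv.members,
                stratum=iv.stratum,
                p_value=iv.p_value,
                position=iv.position,
            )
            for iv in entry
        ]
    return out


def bootstrap_networks(
    expression_net: np.ndarray,
    expression_iv: np.ndarray,
    genotypes: np.ndarray,
    gene_annotation: pd.DataFrame,
    variant_annotation: pd.DataFrame,
    B: int,
    seed: int = 0,
    iv_config: IvConfig | None = None,
    fit_config: FitConfig | None = None,
    reselect_ivs: bool = True,
    ivmap: IvMap | None = None,
    cache_dir: str | Path | None = None,
    max_retries: int = 3,
    gene_names: list[str] | None = None,
) -> BootstrapEnsemble:
    """Run B bootstrap replicates of the full inference and accumulate
    adjacency indicators.

    With ``reselect_ivs`` (default) IV discovery is repeated on every
    bootstrap sample; with ``reselect_ivs=False`` a precomputed ``ivmap``
    is frozen and only its instrument columns are resampled (faster).  A
    failed replicate is retried with a fresh derived seed a bounded number
    of times, never silently skipped.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    if not reselect_ivs and ivmap is None:
        raise ValueError("frozen-IV mode requires a precomputed ivmap")
    n, p = expression_net.shape
    icfg = iv_config or IvConfig()
    fcfg = fit_config or FitConfig()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    counts: dict[tuple[int, int], int] = {}
    seeds: list[int] = []
    for b in range(B):
        edges = _load_cached(cache, b) if cache is not None else None
        if edges is None:
            edges = _run_replicate(
                b, expression_net, expression_iv, genotypes, gene_annotation,
                variant_annotation, seed, icfg, fcfg, reselect_ivs, ivmap, max_retries,
            )
            if cache is not None:
                _store_cached(cache, b, edges)
        seeds.append(b)
        for e in edges:
            counts[e] = counts.get(e, 0) + 1
    return BootstrapEnsemble(B=B, p=p, counts=counts, replicate_seeds=seeds, gene_names=gene_names)


def _run_replicate(
    b, expression_net, expression_iv, genotypes, gene_annotation, variant_annotation,
    seed, icfg, fcfg, reselect_ivs, ivmap, max_retries,
) -> set[tuple[int, int]]:
    n = expression_net.shape[0]
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng = _replicate_seed(seed, b * 1000 + attempt)
        idx = rng.integers(0, n, size=n)
        try:
            if reselect_ivs:
                sub_icfg = IvConfig(**{**icfg.__dict__, "seed": icfg.seed + b + 1})
                rep_map = discover_ivs(
                    expression_iv[idx], genotypes[idx], gene_annotation,
                    variant_annotation, sub_icfg,
                )
            else:
                rep_map = _resample_ivmap(ivmap, idx)
            rep_fcfg = FitConfig(**{**fcfg.__dict__, "seed": int(rng.integers(2**31))})
            C = fit_network(expression_net[idx], rep_map, rep_fcfg)
            return C.edge_set()
        except Exception as err:  # noqa: BLE001 - retried with a fresh seed
            last_err = err
    raise RuntimeError(f"bootstrap replicate {b} failed after {max_retries} attempts") from last_err


def _cache_path(cache: Path, b: int) -> Path:
    return cache / f"replicate_{b:05d}.json"


def _load_cached(cache: Path, b: int) -> set[tuple[int, int]] | None:
    f = _cache_path(cache, b)
    if not f.exists():
        return None
    return {tuple(e) for e in json.loads(f.read_text())}


def _store_cached(cache: Path, b: int, edges: set[tuple[int, int]]) -> None:
    _cache_path(cache, b).write_text(json.dumps(sorted(edges)))


def aggregate(adjacencies: list[np.ndarray]) -> np.ndarray:
    """Componentwise mean of binary adjacency matrices."""
    if not adjacencies:
        raise ValueError("need at least one adjacency matrix")
    mats = [np.asarray(a) for a in adjacencies]
    shape = mats[0].shape
    for a in mats:
        if a.shape != shape:
            raise ValueError("adjacency shapes differ")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency matrices must be binary")
    return np.mean(mats, axis=0)


def threshold_network(
    ensemble: BootstrapEnsemble, cutoff: float
) -> ThresholdedNetwork:
    """Edges with bootstrap frequency >= cutoff; nodes are incident genes.

    Zero-frequency pairs are never materialized, so a cutoff of 0 returns
    exactly the pairs identified in at least one replicate.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    freq = ensemble.frequency()
    edges = {e for e, f in freq.items() if f >= cutoff}
    nodes = sorted({i for e in edges for i in e})
    return ThresholdedNetwork(
        nodes=nodes,
        edges=edges,
        cutoff=cutoff,
        edge_frequency={e: freq[e] for e in edges},
        gene_names=ensemble.gene_names,
    )
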