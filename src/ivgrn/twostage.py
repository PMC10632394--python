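"""Two-stage penalized least squares (2SPLS) network estimation.

Stage 1 predicts every gene's expression from the genome-wide pool of
selected instruments: the pool is first reduced by iterative sure
independence screening (ISIS), then ridge regression with the tuning
parameter chosen by generalized cross-validation (GCV) produces the
prediction Y-hat_j.

Stage 2 treats each gene k separately.  Its own instrument columns X_Sk
are projected out with the residual-maker H_k = I - X_Sk (X_Sk' X_Sk)^-1
X_Sk', and the regulators of gene k are selected by adaptive LASSO in

    H_k Y_k  ~  H_k Yhat_{-k},

whose nonzero coefficients estimate the corresponding column of the
regulation matrix.  Both stages are embarrassingly parallel over genes and
are deterministic given (data, config, seed) regardless of worker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from joblib import Parallel, delayed
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .iv_discovery import IvMap

__all__ = [
    "FitConfig",
    "Stage1Fit",
    "Stage2Fit",
    "CoefficientMatrix",
    "Projection",
    "isis_screen",
    "ridge_gcv",
    "stage1_predict",
    "make_projection",
    "adaptive_lasso",
    "fit_gene",
    "fit_network",
]


@dataclass
class FitConfig:
    """Tuning knobs of the two-stage estimator (defaults are the package's
    standard settings; see docs/methods.md for rationale)."""

    isis_target_size: int | None = None  # default: floor(n / log n)
    isis_batch: int | None = None  # default: ceil(target / 3)
    ridge_grid: np.ndarray | None = None  # explicit lambda grid override
    ridge_grid_size: int = 50
    ridge_grid_span: tuple[float, float] = (1e-4, 1e4)
    lasso_folds: int = 10
    lasso_lambda: float | str = "cv"  # "cv", or a fixed value (0 = OLS limit)
    lasso_rule: str = "1se"  # "1se" (default) or "min" CV-curve rule
    require_iv: bool = True  # candidate regulators must have >= 1 IV
    include_own_ivs: bool = True  # keep gene's own IVs in the stage-1 pool
    n_jobs: int = 1
    seed: int = 0


@dataclass
class RidgeFit:
    coef: np.ndarray
    intercept: float
    fitted: np.ndarray
    lam: float
    gcv: dict[float, float]


@dataclass
class Stage1Fit:
    predicted: np.ndarray  # (n, p) Y-hat
    residuals: np.ndarray  # (n, p)
    screened: dict[int, np.ndarray]  # gene -> retained pool column indices
    ridge_lambda: dict[int, float]
    pool_labels: list[tuple[int, str]]


@dataclass
class Stage2Fit:
    gene: int
    gamma: np.ndarray  # (p,) sparse-in-content regulator effects; gamma[k]=0
    residuals: np.ndarray
    candidates: np.ndarray  # candidate gene indices used as design columns


@dataclass
class CoefficientMatrix:
    """p x p sparse matrix C; C[i, j] = estimated effect of gene j on gene i."""

    matrix: sp.csr_matrix
    gene_names: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def edge_set(self) -> set[tuple[int, int]]:
        """(regulator, target) pairs with nonzero estimated effect."""
        coo = self.matrix.tocoo()
        return {(int(j), int(i)) for i, j, v in zip(coo.row, coo.col, coo.data) if v != 0}

    def adjacency(self) -> sp.csr_matrix:
        A = self.matrix.copy()
        A.data = (A.data != 0).astype(np.int8)
        A.eliminate_zeros()
        return A


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------


def isis_screen(
    target: np.ndarray,
    iv_pool: np.ndarray,
    target_size: int,
    batch: int | None = None,
    max_iter: int = 25,
) -> np.ndarray:
    """Iterative sure independence screening.

    Repeatedly ranks the not-yet-retained pool columns by absolute Pearson
    correlation with the current residual, keeps the top ``batch`` of them,
    refits (ridge with GCV) on everything retained and recomputes the
    residual — so predictors masked by conditioning, invisible to one-pass
    marginal screening, can enter on later sweeps.  Deterministic given its
    inputs.  Returns retained column indices (sorted).
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    n, Q = iv_pool.shape
    if Q <= target_size:
        return np.arange(Q)
    if batch is None:
        batch = max(1, math.ceil(target_size / 3))

    sd = iv_pool.std(axis=0)
    usable = sd > 0
    Z = np.zeros_like(iv_pool)
    Z[:, usable] = (iv_pool[:, usable] - iv_pool[:, usable].mean(axis=0)) / sd[usable]

    active: list[int] = []
    resid = target - target.mean()
    for _ in range(max_iter):
        if len(active) >= target_size:
            break
        rnorm = np.linalg.norm(resid)
        if rnorm < 1e-12:
            break
        cors = np.abs(Z.T @ resid) / (rnorm * math.sqrt(n))
        cors[active] = -1.0
        cors[~usable] = -1.0
        take = min(batch, target_size - len(active))
        order = np.argsort(-cors, kind="stable")[:take]
        if cors[order[0]] <= 1e-12:
            break
        active.extend(int(i) for i in order)
        fit = ridge_gcv(target, iv_pool[:, active])
        resid = target - fit.fitted
    return np.array(sorted(active), dtype=int)


def ridge_gcv(
    target: np.ndarray,
    design: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    grid_size: int = 50,
    grid_span: tuple[float, float] = (1e-4, 1e4),
) -> RidgeFit:
    """Ridge regression with the penalty chosen by generalized cross-validation.

    GCV(lambda) = n * RSS(lambda) / (n - tr(S_lambda))^2, with the trace of
    the ridge smoother counting one extra degree of freedom for the
    (unpenalized, handled by centering) intercept.  The default grid is 50
    log-spaced values spanning ``grid_span`` times the mean squared singular
    value of the centered design, so coverage is scale-free.  Ties on the
    GCV curve resolve to the smaller lambda; lambda = 0 (exact least
    squares via the pseudo-inverse) is honored if present in the grid.
    """
    y = np.asarray(target, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    s2 = s**2
    if lambda_grid is None:
        scale = float(s2.mean()) if s2.size else 1.0
        lambda_grid = np.geomspace(grid_span[0] * scale, grid_span[1] * scale, grid_size)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))

    c = U.T @ yc
    yss = float(yc @ yc)
    gcv: dict[float, float] = {}
    best_lam, best_val = None, np.inf
    for lam in lambda_grid:
        if lam == 0:
            shrink = (s2 > 1e-12 * max(s2.max(), 1.0)).astype(float)
        else:
            shrink = s2 / (s2 + lam)
        rss = yss - float(((2 * shrink - shrink**2) * c**2).sum())
        rss = max(rss, 0.0)
        df = 1.0 + float(shrink.sum())
        if n - df <= 0:
            continue
        val = n * rss / (n - df) ** 2
        gcv[float(lam)] = val
        if val < best_val - 1e-15:
            best_val, best_lam = val, float(lam)
    if best_lam is None:
        raise ValueError("no lambda in the grid leaves positive residual df")

    if best_lam == 0:
        inv = np.where(s > 1e-12 * max(s.max(), 1.0), 1.0 / np.where(s > 0, s, 1.0), 0.0)
        coef = Vt.T @ (inv * c)
    else:
        coef = Vt.T @ ((s / (s2 + best_lam)) * c)
    intercept = ym - float(xm @ coef)
    fitted = X @ coef + intercept
    return RidgeFit(coef=coef, intercept=intercept, fitted=fitted, lam=best_lam, gcv=gcv)


def stage1_predict(
    expression: np.ndarray,
    ivmap: IvMap,
    config: FitConfig | None = None,
) -> Stage1Fit:
    """Predict every gene's expression from the genome-wide IV pool.

    Genes are processed independently; the result does not depend on the
    processing order or worker count.
    """
    cfg = config or FitConfig()
    Y = np.asarray(expression, dtype=float)
    n, p = Y.shape
    pool, labels = ivmap.pooled_matrix()
    target_size = cfg.isis_target_size or max(2, int(n / math.log(n)))

    def _one(j: int):
        cols = np.arange(pool.shape[1])
        if not cfg.include_own_ivs:
            cols = np.array([i for i, (g, _) in enumerate(labels) if g != j], dtype=int)
            if cols.size == 0:
                return np.full(n, Y[:, j].mean()), np.array([], dtype=int), 0.0
        sub = pool[:, cols]
        kept = isis_screen(Y[:, j], sub, target_size, cfg.isis_batch)
        fit = ridge_gcv(
            Y[:, j], sub[:, kept], cfg.ridge_grid, cfg.ridge_grid_size, cfg.ridge_grid_span
        )
        return fit.fitted, cols[kept], fit.lam

    results = Parallel(n_jobs=cfg.n_jobs)(delayed(_one)(j) for j in range(p))
    predicted = np.column_stack([r[0] for r in results])
    screened = {j: results[j][1] for j in range(p)}
    lams = {j: float(results[j][2]) for j in range(p)}
    return Stage1Fit(
        predicted=predicted,
        residuals=Y - predicted,
        screened=screened,
        ridge_lambda=lams,
        pool_labels=labels,
    )


# ---------------------------------------------------------------------------
# stage 2
# ---------------------------------------------------------------------------


class Projection:
    """Residual-maker H = I - X (X'X)^-1 X', held as an orthonormal basis of
    the column space (never a dense n x n matrix).  With no columns it is
    the identity."""

    def __init__(self, X: np.ndarray | None):
        if X is None or X.size == 0 or X.shape[1] == 0:
            self.basis = None
            return
        q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int((diag > 1e-10 * max(diag[0], 1.0)).sum()) if diag.size else 0
        if rank == 0:
            raise ValueError("instrument block is numerically zero")
        self.basis = q[:, :rank]

    @property
    def rank(self) -> int:
        return 0 if self.basis is None else self.basis.shape[1]

    def apply(self, v: np.ndarray) -> np.ndarray:
        if self.basis is None:
            return np.asarray(v, dtype=float).copy()
        v = np.asarray(v, dtype=float)
        return v - self.basis @ (self.basis.T @ v)


def make_projection(X_Sk: np.ndarray | None) -> Projection:
    """Projection onto the orthogonal complement of span(X_Sk).

    Collinear columns are pruned by pivoted QR.  ``None`` or an empty block
    yields the identity operator (a gene without instruments keeps its full
    response)."""
    return Projection(X_Sk)


def adaptive_lasso(
    response: np.ndarray,
    design: np.ndarray,
    config: FitConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Adaptive LASSO with ridge-GCV initial weights.

    Columns are centered and standardized internally; weights are
    1/|beta_init| with beta_init from ridge-GCV on the standardized design
    (entries below 1e-10 in magnitude are excluded outright).  The penalty
    level is chosen by k-fold cross-validation unless
    ``config.lasso_lambda`` fixes it; a fixed value of 0 returns the
    unpenalized (weighted least-squares) limit.  By default the largest
    penalty within one standard error of the CV minimum is used (the
    "1-SE" rule), which is what makes the selected support reliable —
    the plain CV minimum optimizes prediction and systematically admits
    spurious regulators (``lasso_rule="min"`` restores it).  Coefficients
    are returned on the original scale.
    """
    cfg = config or FitConfig()
    if seed is None:
        seed = cfg.seed
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    n, m = X.shape
    out = np.zeros(m)

    ym = y.mean()
    yc = y - ym
    xm = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 1e-12
    if not ok.any():
        return out
    Xs = (X[:, ok] - xm[ok]) / sd[ok]

    init = ridge_gcv(yc, Xs).coef
    finite = np.abs(init) >= 1e-10
    if not finite.any():
        return out
    Xw = Xs[:, finite] * np.abs(init[finite])  # beta_j = |init_j| * alpha_j

    lam = cfg.lasso_lambda
    if lam == "cv":
        k = min(cfg.lasso_folds, n)
        cv = KFold(n_splits=k, shuffle=True, random_state=seed)
        model = LassoCV(cv=cv, fit_intercept=False, alphas=100, max_iter=50_000)
        model.fit(Xw, yc)
        if cfg.lasso_rule == "1se":
            mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1) / math.sqrt(model.mse_path_.shape[1])
            i_min = int(mse.argmin())
            alpha = float(model.alphas_[mse <= mse[i_min] + se[i_min]].max())
            refit = Lasso(alpha=alpha, fit_intercept=False, max_iter=50_000)
            refit.fit(Xw, yc)
            alpha_coef = refit.coef_
        elif cfg.lasso_rule == "min":
            alpha_coef = model.coef_
        else:
            raise ValueError(f"unknown lasso_rule {cfg.lasso_rule!r}")
    elif float(lam) == 0.0:
        alpha_coef, *_ = np.linalg.lstsq(Xw, yc, rcond=None)
    else:
        model = Lasso(alpha=float(lam), fit_intercept=False, max_iter=50_000)
        model.fit(Xw, yc)
        alpha_coef = model.coef_

    beta_std = np.zeros(ok.sum())
    beta_std[finite] = alpha_coef * np.abs(init[finite])
    out[ok] = beta_std / sd[ok]
    return out


def _gene_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence([master, k]).generate_state(1)[0] % (2**31))


def fit_gene(
    k: int,
    expression: np.ndarray,
    stage1: Stage1Fit,
    ivmap: IvMap,
    config: FitConfig | None = None,
) -> Stage2Fit:
    """Identify the regulators of gene k by projected adaptive LASSO."""
    cfg = config or FitConfig()
    Y = np.asarray(expression, dtype=float)
    p = Y.shape[1]
    # center the instrument block: every regression here carries an
    # unpenalized intercept via mean-centering, so the residual-maker must
    # annihilate span(1, X_Sk) jointly for exact 2SLS equivalence
    X_Sk = ivmap.instrument_matrix(k)
    if X_Sk is not None:
        X_Sk = X_Sk - X_Sk.mean(axis=0)
    H = make_projection(X_Sk)

    if cfg.require_iv:
        cand = np.array([j for j in ivmap.genes_with_ivs() if j != k], dtype=int)
    else:
        cand = np.array([j for j in range(p) if j != k], dtype=int)

    gamma = np.zeros(p)
    if cand.size:
        resp = H.apply(Y[:, k])
        design = H.apply(stage1.predicted[:, cand])
        coefs = adaptive_lasso(resp, design, cfg, seed=_gene_seed(cfg.seed, k))
        gamma[cand] = coefs
        resid = resp - design @ coefs
    else:
        resid = H.apply(Y[:, k])
    return Stage2Fit(gene=k, gamma=gamma, residuals=resid, candidates=cand)


def fit_network(
    expression: np.ndarray,
    ivmap: IvMap,
    config: FitConfig | None = None,
    gene_names: list[str] | None = None,
) -> CoefficientMatrix:
    """Full 2SPLS: stage-1 prediction, then per-gene regulator selection.

    Returns the sparse coefficient matrix C with C[i, j] the effect of gene
    j on gene i.  Identical results for any worker count or gene order.
    """
    cfg = config or FitConfig()
    Y = np.asarray(expression, dtype=float)
    p = Y.shape[1]
    stage1 = stage1_predict(Y, ivmap, cfg)
    fits = Parallel(n_jobs=cfg.n_jobs)(
        delayed(fit_gene)(k, Y, stage1, ivmap, cfg) for k in range(p)
    )
    rows, cols, vals = [], [], []
    for fit in fits:
        nz = np.nonzero(fit.gamma)[0]
        for j in nz:
            rows.append(fit.gene)  # target
            cols.append(int(j))  # regulator
            vals.append(fit.gamma[j])
    C = sp.csr_matrix((vals, (rows, cols)), shape=(p, p))
    return CoefficientMatrix(matrix=C, gene_names=gene_names, provenance={"seed": cfg.seed})
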