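"""Per-gene SNP -> APA-usage (PDUI) weight training.

Four estimators are trained per gene — ridge-BLUP over all cis SNPs,
elastic net (mixing 0.5), LASSO, and TOP1 (single best marginal SNP) —
each scored by five-fold cross-validated squared Pearson correlation, and
the best model's coefficient vector is exported unchanged as the diagonal
weight matrix consumed by the kernel association stage.

Genotype columns are standardized inside the fitters; exported coefficients
are mapped back to raw-dosage scale, so ``prediction = sum_i W_i * G_i``
(plus an intercept that the association stage never needs).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV

METHODS = ("blup", "enet", "lasso", "top1")
#: tie-break priority when cv_r2 values are equal
METHOD_ORDER = ("enet", "lasso", "blup", "top1")

_RIDGE_GRID = np.logspace(-2, 3, 8)

__all__ = [
    "METHODS",
    "METHOD_ORDER",
    "WeightModelFit",
    "GeneWeightModel",
    "DiagonalWeights",
    "fit_weight_model",
    "cross_validate",
    "select_best_model",
    "build_weight_matrix",
    "train_gene",
]


@dataclass
class WeightModelFit:
    method: str
    weights: np.ndarray  # dosage-scale coefficients, aligned to snp_ids
    cv_r2: float = float("nan")
    fold_assignments: np.ndarray | None = None
    hyper: dict = field(default_factory=dict)


@dataclass
class GeneWeightModel:
    gene_id: str
    snp_ids: list[str]
    fits: dict[str, WeightModelFit]
    best_method: str

    @property
    def best_fit(self) -> WeightModelFit:
        return self.fits[self.best_method]


@dataclass
class DiagonalWeights:
    """Diagonal weight-matrix spec W = diag(W_1 .. W_n) for the kernel stage."""

    snp_ids: list[str]
    weights: np.ndarray
    all_zero: bool


def _as_array(G) -> np.ndarray:
    if hasattr(G, "dosages"):
        return np.asarray(G.dosages, dtype=float)
    return np.asarray(G, dtype=float)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def _fold_assignments(n: int, seed: int, sample_ids: list[str] | None = None) -> np.ndarray:
    """Five near-equal folds.

    With *sample_ids*, each sample's fold is derived from a keyed hash of its
    id, so cv_r2 is invariant to sample reordering; otherwise a seeded
    shuffle of indices is used.
    """
    if sample_ids is not None:
        keys = [
            hashlib.blake2b(f"{seed}:{s}".encode(), digest_size=8).digest() for s in sample_ids
        ]
        order = np.argsort([k.hex() for k in keys], kind="stable")
    else:
        order = np.random.default_rng(seed).permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % 5
    return folds


def _fit_ridge(Xs: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge coefficients on standardized X via p x p normal equations."""
    p = Xs.shape[1]
    yc = y - y.mean()
    A = Xs.T @ Xs + alpha * np.eye(p)
    return np.linalg.solve(A, Xs.T @ yc)


def _select_ridge_alpha(Xs: np.ndarray, y: np.ndarray, folds: np.ndarray) -> float:
    best_alpha, best_err = _RIDGE_GRID[0], np.inf
    for alpha in _RIDGE_GRID:
        sse = 0.0
        for k in range(5):
            tr, te = folds != k, folds == k
            beta = _fit_ridge(Xs[tr], y[tr], alpha)
            pred = Xs[te] @ beta + y[tr].mean()
            sse += float(np.sum((y[te] - pred) ** 2))
        if sse < best_err:
            best_err, best_alpha = sse, alpha
    return float(best_alpha)


def _fit_top1(Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Marginal-R^2 scan: OLS slope of the single best SNP, zeros elsewhere."""
    yc = y - y.mean()
    num = Xs.T @ yc  # n * cov since columns are standardized
    ss_x = (Xs**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_x > 0, num**2 / (ss_x * max((yc**2).sum(), 1e-300)), -np.inf)
    j = int(np.argmax(r2))  # argmax takes the lowest index on ties
    beta = np.zeros(Xs.shape[1])
    if ss_x[j] > 0:
        beta[j] = num[j] / ss_x[j]
    return beta


def _sk_model(method: str, alpha: float):
    if method == "lasso":
        return Lasso(alpha=alpha, max_iter=5000)
    return ElasticNet(alpha=alpha, l1_ratio=0.5, max_iter=5000)


def _select_penalty(method: str, Xs: np.ndarray, y: np.ndarray, folds: np.ndarray) -> float:
    cv = [(np.where(folds != k)[0], np.where(folds == k)[0]) for k in range(5)]
    cls = LassoCV if method == "lasso" else ElasticNetCV
    kwargs = {} if method == "lasso" else {"l1_ratio": 0.5}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = cls(alphas=20, cv=cv, max_iter=5000, **kwargs).fit(Xs, y)
    return float(model.alpha_)


def fit_weight_model(
    G,
    pdui: np.ndarray,
    method: str,
    hyper: dict | None = None,
    seed: int = 0,
) -> WeightModelFit:
    """Fit one weight model on the full sample; returns dosage-scale weights.

    *hyper* may carry ``alpha`` (penalty); if absent it is chosen by an
    internal seeded five-fold CV.  Constant PDUI yields all-zero weights with
    a warning rather than an error.
    """
    X = _as_array(G)
    y = np.asarray(pdui, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("genotypes and PDUI are not sample-aligned")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if X.shape[1] < 1:
        raise ValueError("need at least 1 SNP")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    hyper = dict(hyper or {})

    if np.std(y) == 0:
        warnings.warn("constant PDUI: returning all-zero weights", RuntimeWarning)
        return WeightModelFit(method=method, weights=np.zeros(X.shape[1]), hyper=hyper)

    Xs, _, sd = _standardize(X)
    folds = _fold_assignments(X.shape[0], seed) if X.shape[0] >= 5 else None

    if method == "top1":
        beta_std = _fit_top1(Xs, y)
    elif method == "blup":
        alpha = hyper.get("alpha")
        if alpha is None:
            if folds is None:
                raise ValueError("need >=5 samples to select the ridge penalty by CV")
            alpha = _select_ridge_alpha(Xs, y, folds)
            hyper["alpha"] = alpha
        beta_std = _fit_ridge(Xs, y, alpha)
    else:  # lasso / enet
        alpha = hyper.get("alpha")
        if alpha is None:
            if folds is None:
                raise ValueError("need >=5 samples to select the penalty by CV")
            alpha = _select_penalty(method, Xs, y, folds)
            hyper["alpha"] = alpha
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta_std = _sk_model(method, alpha).fit(Xs, y).coef_

    weights = beta_std / sd  # back to dosage scale
    return WeightModelFit(method=method, weights=np.asarray(weights, dtype=float), hyper=hyper)


def cross_validate(
    G,
    pdui: np.ndarray,
    method: str,
    hyper: dict | None = None,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> float:
    """Five-fold CV performance: squared Pearson correlation of out-of-fold
    predictions with observed PDUI (0 when predictions have zero variance)."""
    X = _as_array(G)
    y = np.asarray(pdui, dtype=float).ravel()
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"cannot form 5 folds from {n} samples")
    hyper = dict(hyper or {})
    if np.std(y) == 0:
        warnings.warn("constant PDUI: cv_r2 = 0", RuntimeWarning)
        return 0.0
    if method in ("lasso", "enet", "blup") and "alpha" not in hyper:
        # penalty fixed once on the full sample, then reused in every fold
        Xs, _, _ = _standardize(X)
        folds0 = _fold_assignments(n, seed, sample_ids)
        if method == "blup":
            hyper["alpha"] = _select_ridge_alpha(Xs, y, folds0)
        else:
            hyper["alpha"] = _select_penalty(method, Xs, y, folds0)

    folds = _fold_assignments(n, seed, sample_ids)
    preds = np.empty(n)
    for k in range(5):
        tr, te = folds != k, folds == k
        fit = fit_weight_model(X[tr], y[tr], method, hyper=hyper, seed=seed)
        preds[te] = X[te] @ fit.weights  # intercept shift cancels in Pearson r
    if np.std(preds) == 0:
        warnings.warn(f"{method}: zero-variance CV predictions, cv_r2 = 0", RuntimeWarning)
        return 0.0
    r = float(np.corrcoef(preds, y)[0, 1])
    return r * r


def select_best_model(
    fits: list[WeightModelFit], gene_id: str = "", snp_ids: list[str] | None = None
) -> GeneWeightModel:
    """Pick the fit with maximal cv_r2 (ties: enet > lasso > blup > top1)."""
    if not fits:
        raise ValueError("no fits supplied")
    by_method = {f.method: f for f in fits}

    def key(f: WeightModelFit):
        r2 = f.cv_r2 if np.isfinite(f.cv_r2) else -np.inf
        rank = METHOD_ORDER.index(f.method) if f.method in METHOD_ORDER else len(METHOD_ORDER)
        return (-r2, rank)

    best = min(fits, key=key)
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(best.weights.size)]
    return GeneWeightModel(gene_id=gene_id, snp_ids=list(snp_ids), fits=by_method, best_method=best.method)


def build_weight_matrix(model: GeneWeightModel) -> DiagonalWeights:
    """Best fit's coefficients as a diagonal-matrix spec, signs preserved,
    with no standardization or rescaling applied."""
    w = np.asarray(model.best_fit.weights, dtype=float)
    all_zero = bool(np.all(w == 0))
    if all_zero:
        warnings.warn(f"gene {model.gene_id!r}: all weights zero", RuntimeWarning)
    return DiagonalWeights(snp_ids=list(model.snp_ids), weights=w, all_zero=all_zero)


def train_gene(
    G,
    pdui: np.ndarray,
    gene_id: str = "",
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> GeneWeightModel:
    """Full per-gene training: fit every method, cross-validate, select best."""
    X = _as_array(G)
    snp_ids = G.snp_ids if hasattr(G, "snp_ids") else [f"snp{j}" for j in range(X.shape[1])]
    y = np.asarray(pdui, dtype=float).ravel()
    folds = _fold_assignments(X.shape[0], seed, sample_ids)
    fits = []
    for method in methods:
        fit = fit_weight_model(X, y, method, seed=seed)
        fit.cv_r2 = cross_validate(X, y, method, hyper=fit.hyper, seed=seed, sample_ids=sample_ids)
        fit.fold_assignments = folds
        fits.append(fit)
    return select_best_model(fits, gene_id=gene_id, snp_ids=snp_ids)
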