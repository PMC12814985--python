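"""Gene-trait association: the weighted-kernel Q test and the linear baseline.

The kernel test is a variance-component score test: with null residuals
r = y - mu_hat, the statistic is Q = r' K_w r where K_w = G W G' carries the
per-gene APA weight diagonal W.  Under the null, Q is distributed as a
mixture sum_i lambda_i chi^2_1 with lambda the eigenvalues of the
null-projected, variance-scaled kernel; signed weights produce signed
eigenvalues, which the characteristic-function inversion handles directly.

When the retained spectrum has negative total mass (e.g. a single SNP whose
trained weight is negative), the spectrum and the observed Q are jointly
negated before taking the upper tail: the alternative then shifts Q downward,
so the lower tail is the powered direction.  The rule depends only on the
kernel, never on y, so null p-values stay exactly uniform, and the test
reduces to the marginal score test for single-SNP genes of either weight
sign.

The linear baseline combines per-SNP GWAS z-scores with the same weights:
Z_apa = w'z / sqrt(w' R w) with R the LD (dosage correlation) matrix of a
reference genotype slice, tested against N(0, 1) two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kernels import KernelMatrix, KernelSpec, compute_kernel
from .pvalues import mixture_tail
from .weights import DiagonalWeights

__all__ = [
    "NullModel",
    "AssociationResult",
    "ZScores",
    "DegenerateKernelError",
    "fit_null_model",
    "q_statistic",
    "mixture_chisq_pvalue",
    "astwas_test",
    "linear_twas_test",
    "ld_matrix",
]


class DegenerateKernelError(ValueError):
    """All null-projected kernel eigenvalues are zero; p undefined."""


@dataclass
class NullModel:
    """Intercept-only null fit (no covariates)."""

    trait_type: str  # {quantitative, binary}
    fitted_mean: np.ndarray  # per-sample mu_hat
    variance_scale: float  # sigma^2 (quantitative) or mu(1-mu) (binary)
    n: int


@dataclass
class AssociationResult:
    gene_id: str
    statistic_q: float
    p_value: float
    method: str  # {astwas, linear_twas}
    kernel_kind: str = "weighted_linear"
    p_method: str = "davies"
    flags: list[str] = field(default_factory=list)


@dataclass
class ZScores:
    snp_ids: list[str]
    z: np.ndarray
    ld: np.ndarray  # SNP x SNP correlation, unit diagonal

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.ld = np.asarray(self.ld, dtype=float)
        if self.ld.shape != (self.z.size, self.z.size):
            raise ValueError("LD matrix does not match the z vector")


def fit_null_model(y: np.ndarray, trait_type: str = "quantitative") -> NullModel:
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if trait_type == "quantitative":
        var = float(np.var(y, ddof=1))
        if var == 0:
            raise ValueError("constant quantitative phenotype: zero variance")
        return NullModel("quantitative", np.full(n, y.mean()), var, n)
    if trait_type == "binary":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("binary phenotype must be coded 0/1")
        mu = float(y.mean())
        if mu in (0.0, 1.0):
            raise ValueError("binary phenotype has a single class")
        # intercept-only logistic MLE is the case fraction
        return NullModel("binary", np.full(n, mu), mu * (1.0 - mu), n)
    raise ValueError(f"unknown trait_type {trait_type!r}")


def q_statistic(y: np.ndarray, K: KernelMatrix | np.ndarray, null: NullModel) -> float:
    """Q = r' K r with r = y - mu_hat (raw y' K y when mu_hat = 0)."""
    y = np.asarray(y, dtype=float).ravel()
    Km = K.matrix if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if Km.shape[0] != y.size:
        raise ValueError(f"kernel is {Km.shape[0]}x{Km.shape[0]} but y has {y.size} samples")
    r = y - null.fitted_mean
    return float(r @ Km @ r)


def _oriented_tail(q: float, lam: np.ndarray) -> tuple[float, str]:
    scale = np.max(np.abs(lam)) if lam.size else 0.0
    if scale == 0:
        raise DegenerateKernelError("all kernel eigenvalues are zero")
    keep = lam[np.abs(lam) >= 1e-10 * scale]
    if keep.sum() < 0:  # orientation: test the direction the alternative moves Q
        keep, q = -keep, -q
    return mixture_tail(q, keep)


def mixture_chisq_pvalue(
    q_obs: float, K: KernelMatrix | np.ndarray, null: NullModel
) -> tuple[float, str]:
    """Mixture-of-chi-squares p-value for an observed Q.

    Eigenvalues are those of v * C K C where C is the intercept-removing
    projection and v the null variance scale (for an intercept-only model
    the general projection V - VX(X'VX)^-1 X'V collapses to v * C).
    """
    Km = K.matrix if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    Km = (Km + Km.T) / 2.0
    n = Km.shape[0]
    # C K C without forming C: doubly center the kernel
    row = Km.mean(axis=0, keepdims=True)
    A = Km - row - row.T + row.mean()
    lam = np.linalg.eigvalsh((A + A.T) / 2.0) * null.variance_scale
    return _oriented_tail(q_obs, lam)


def _weighted_linear_eigs(Gc: np.ndarray, w: np.ndarray, v: float) -> np.ndarray:
    """Eigenvalues of v * Gc W Gc' via the p x p symmetric reduction."""
    M = Gc.T @ Gc
    evals, U = np.linalg.eigh((M + M.T) / 2.0)
    evals = np.clip(evals, 0.0, None)
    S = np.sqrt(evals)[:, None] * U.T  # M = S'S
    B = (S * w) @ S.T
    return np.linalg.eigvalsh((B + B.T) / 2.0) * v


def astwas_test(
    G,
    weights: DiagonalWeights | np.ndarray,
    y: np.ndarray,
    trait_type: str = "quantitative",
    spec: KernelSpec | None = None,
    gene_id: str = "",
    mafs: np.ndarray | None = None,
) -> AssociationResult:
    """Weighted-kernel Q test of one gene against a phenotype.

    Composes the intercept-only null fit, kernel construction, the Q
    statistic, and the mixture p-value.  An all-zero weight vector carries no
    signal and yields p = 1 with a warning.  For the default weighted-linear
    kernel the eigenvalue problem is solved in SNP space (p x p), so the test
    scales to large cohorts.
    """
    spec = spec or KernelSpec()
    X = np.asarray(G.dosages if hasattr(G, "dosages") else G, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("phenotype not aligned to genotype samples")

    if isinstance(weights, DiagonalWeights):
        w = weights.weights
        all_zero = weights.all_zero
    else:
        w = None if weights is None else np.asarray(weights, dtype=float)
        all_zero = w is not None and bool(np.all(w == 0))
    if spec.kind == "weighted_linear" and all_zero:
        warnings.warn(f"gene {gene_id!r}: all-zero weights, p set to 1", RuntimeWarning)
        return AssociationResult(gene_id, 0.0, 1.0, "astwas", spec.kind, "davies", ["zero_weights"])

    null = fit_null_model(y, trait_type)
    r = y - null.fitted_mean

    if spec.kind == "weighted_linear":
        Gc = X - X.mean(axis=0)  # centering G commutes with centering r in r'GWG'r
        u = X.T @ r
        q = float((u * w) @ u)
        lam = _weighted_linear_eigs(Gc, w, null.variance_scale)
        p, p_method = _oriented_tail(q, lam)
    else:
        K = compute_kernel(X, spec, diag_weights=w, mafs=mafs)
        q = q_statistic(y, K, null)
        p, p_method = mixture_chisq_pvalue(q, K, null)
    return AssociationResult(gene_id, q, p, "astwas", spec.kind, p_method)


def ld_matrix(G) -> np.ndarray:
    """Pearson correlation of dosage columns (unit diagonal, symmetric)."""
    X = np.asarray(G.dosages if hasattr(G, "dosages") else G, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for LD")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.where(sd == 0)[0][0])
        snp = G.snp_ids[j] if hasattr(G, "snp_ids") else f"column {j}"
        raise ValueError(f"constant dosage column: {snp}")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def linear_twas_test(
    weights: DiagonalWeights | np.ndarray,
    z: ZScores,
    gene_id: str = "",
) -> AssociationResult:
    """Linear APA-TWAS: Z_apa = w'z / sqrt(w' R w), two-sided normal p."""
    w = weights.weights if isinstance(weights, DiagonalWeights) else np.asarray(weights, float)
    if w.size != z.z.size:
        raise ValueError("weights not aligned to z-scores")
    if np.all(w == 0):
        raise ValueError("all-zero weights: linear statistic undefined")
    denom = float(w @ z.ld @ w)
    if denom <= 0:
        raise ValueError(f"non-positive weighted LD variance {denom}")
    z_apa = float(w @ z.z) / np.sqrt(denom)
    p = float(2.0 * stats.norm.sf(abs(z_apa)))
    return AssociationResult(gene_id, z_apa, p, "linear_twas", "none", "normal")
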