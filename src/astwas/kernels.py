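"""Sample-similarity kernels built from a genotype slice.

Six kinds are supported: ``linear`` (G G'), ``weighted_linear`` (G W G' with
the signed APA-weight diagonal used as-is), ``quadratic`` ((1 + G G')^2),
``twoway_ix`` (main effects plus all pairwise SNP interactions), ``ibs``
(average allele sharing), and ``weighted_ibs`` (allele sharing with
Beta(MAF; 1, 25)^2 per-SNP weights).  Every kernel is symmetrized as
(K + K') / 2 before return; a weighted linear kernel with signed weights may
be indefinite, which the association stage handles through signed-eigenvalue
mixture p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

KERNEL_KINDS = ("linear", "weighted_linear", "quadratic", "twoway_ix", "ibs", "weighted_ibs")

__all__ = ["KERNEL_KINDS", "KernelSpec", "KernelMatrix", "maf_beta_weights", "compute_kernel"]


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "weighted_linear"
    weight_source: str = "apa_weights"  # {apa_weights, maf_beta, none}

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind in ("weighted_linear",) and self.weight_source == "none":
            raise ValueError(f"{self.kind} kernel requires a weight source")


@dataclass
class KernelMatrix:
    matrix: np.ndarray
    spec: KernelSpec
    snp_count: int

    def __post_init__(self):
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError(f"kernel must be square, got {K.shape}")
        if not np.all(np.isfinite(K)):
            raise ValueError("kernel has non-finite entries")
        self.matrix = (K + K.T) / 2.0

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


def maf_beta_weights(mafs: np.ndarray) -> np.ndarray:
    """Squared Beta(1, 25) density evaluated at each MAF.

    The standard variance-component-test convention for an MAF-derived
    diagonal weight matrix: rarer variants get (much) larger weight.
    """
    m = np.asarray(mafs, dtype=float)
    if np.any(m <= 0) or np.any(m > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]; monomorphic SNPs must be filtered upstream")
    return stats.beta.pdf(m, 1, 25) ** 2


def _ibs_kernel(G: np.ndarray, snp_weights: np.ndarray | None) -> np.ndarray:
    """Allele-sharing kernel sum_k w_k (2 - |g_ik - g_jk|) / (2 sum_k w_k)."""
    n, p = G.shape
    w = np.ones(p) if snp_weights is None else np.asarray(snp_weights, dtype=float)
    K = np.zeros((n, n))
    for k in range(p):  # accumulate per SNP to avoid an n x n x p intermediate
        d = np.abs(G[:, k, None] - G[None, :, k])
        K += w[k] * (2.0 - d)
    return K / (2.0 * w.sum())


def _twoway_ix_kernel(G: np.ndarray) -> np.ndarray:
    """Linear kernel of the main-effect + pairwise-interaction design.

    Uses the closed form sum_{k<l} (x_k x_l)(y_k y_l) =
    ((x.y)^2 - sum_k x_k^2 y_k^2) / 2 instead of materializing the expanded
    design matrix.
    """
    lin = G @ G.T
    sq = (G**2) @ (G**2).T
    return lin + (lin**2 - sq) / 2.0


def compute_kernel(
    G,
    spec: KernelSpec,
    diag_weights: np.ndarray | None = None,
    mafs: np.ndarray | None = None,
) -> KernelMatrix:
    """Build the n x n kernel for *spec* from a sample x SNP dosage matrix.

    ``weighted_linear`` needs *diag_weights* (signed APA weights, applied
    unmodified); ``weighted_ibs`` needs *mafs* (or *diag_weights* already on
    the weight scale).
    """
    X = np.asarray(G.dosages if hasattr(G, "dosages") else G, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("genotype slice must have >=1 sample and >=1 SNP")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite dosages: impute before building kernels")
    p = X.shape[1]

    if spec.kind == "linear":
        K = X @ X.T
    elif spec.kind == "weighted_linear":
        if diag_weights is None:
            raise ValueError("weighted_linear kernel requires diag_weights")
        w = np.asarray(diag_weights, dtype=float)
        if w.size != p:
            raise ValueError(f"{w.size} weights for {p} SNPs")
        K = (X * w) @ X.T
    elif spec.kind == "quadratic":
        K = (1.0 + X @ X.T) ** 2
    elif spec.kind == "twoway_ix":
        K = _twoway_ix_kernel(X)
    elif spec.kind == "ibs":
        K = _ibs_kernel(X, None)
    elif spec.kind == "weighted_ibs":
        if diag_weights is not None:
            w = np.asarray(diag_weights, dtype=float)
        elif mafs is not None:
            w = maf_beta_weights(mafs)
        else:
            raise ValueError("weighted_ibs kernel requires mafs or diag_weights")
        if np.any(w < 0):
            raise ValueError("IBS weights must be nonnegative")
        K = _ibs_kernel(X, w)
    else:  # pragma: no cover - guarded by KernelSpec
        raise ValueError(spec.kind)

    return KernelMatrix(matrix=K, spec=spec, snp_count=p)
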