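"""Synthetic genotype / PDUI / phenotype generation.

The generator emulates the study conditions of the power framework:

* genotypes with configurable MAF and AR(1)-style pairwise LD, drawn by
  thresholding two latent Gaussian gametes at the MAF quantile;
* seven genetic architectures — additive with 2/5/10 causal SNPs and four
  non-additive rules (single, epistatic, heterogeneous, compensatory) on
  carrier indicators (dosage >= 1);
* two causal assumptions — *causality* (genotype -> PDUI -> phenotype chain)
  and *pleiotropy* (genotype affects PDUI and phenotype in parallel with
  independent noise);
* heritability control per stage via sigma_e^2 = sigma_g^2 (1 - h2) / h2
  with sigma_g^2 the empirical variance of the realized genetic value;
* liability-threshold binary traits; and
* the pure-null design (transcriptome and phenotype iid N(0, 1), independent
  of any genotype) used for type-I-error calibration.

All randomness flows from a single scenario seed through
``numpy.random.SeedSequence`` spawning, so every dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .genotype import GeneRegion, GenotypeMatrix, VariantRecord, extract_cis_window

ARCHITECTURES = (
    "additive2",
    "additive5",
    "additive10",
    "single",
    "epistatic",
    "heterogeneous",
    "compensatory",
)
ASSUMPTIONS = ("causality", "pleiotropy")

__all__ = [
    "ARCHITECTURES",
    "ASSUMPTIONS",
    "SimScenario",
    "HeritabilitySpec",
    "SimDataset",
    "ScenarioInfeasibleError",
    "n_causal_for",
    "simulate_genotypes",
    "select_causal_snps",
    "genetic_value",
    "apply_effect",
    "add_environmental_noise",
    "simulate_dataset",
    "binarize_liability",
    "simulate_null_dataset",
]


class ScenarioInfeasibleError(ValueError):
    """The requested scenario cannot be realized on the given data."""


def n_causal_for(architecture: str) -> int:
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    if architecture.startswith("additive"):
        return int(architecture.removeprefix("additive"))
    return 1 if architecture == "single" else 2


@dataclass
class SimScenario:
    assumption: str
    architecture: str
    h2_pheno: float
    h2_apa: float
    trait_type: str = "quantitative"
    prevalence: float = 0.5
    ld_mode: str = "random"  # {random, high_ld, low_ld}
    n_samples: int = 670
    seed: int = 0

    def __post_init__(self):
        if self.assumption not in ASSUMPTIONS:
            raise ValueError(f"unknown assumption {self.assumption!r}")
        self.n_causal = n_causal_for(self.architecture)
        for h2 in (self.h2_pheno, self.h2_apa):
            if not 0 < h2 <= 1:
                raise ValueError(f"heritability {h2} outside (0, 1]")
        if self.trait_type == "binary" and not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class HeritabilitySpec:
    """Variance decomposition sigma_p^2 = sigma_g^2 + sigma_e^2, h2 = g/p."""

    sigma_g2: float
    sigma_e2: float

    @property
    def sigma_p2(self) -> float:
        return self.sigma_g2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return self.sigma_g2 / self.sigma_p2


@dataclass
class SimDataset:
    genotypes: GenotypeMatrix
    pdui: np.ndarray
    phenotype: np.ndarray
    causal_snp_ids: list[str]
    scenario: SimScenario
    effect_spec: dict = field(default_factory=dict)
    apa_spec: HeritabilitySpec | None = None
    pheno_spec: HeritabilitySpec | None = None


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_spec=0.3,
    ld_rho: float = 0.0,
    seed: int = 0,
    chromosome: str = "1",
    position_start: int = 1,
    position_step: int = 1000,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes with AR(1) latent LD.

    Per gamete, a latent AR(1) Gaussian chain with coefficient *ld_rho* is
    thresholded at the upper MAF quantile; the dosage is the sum over the two
    independent gametes, so entries lie in {0, 1, 2} and adjacent SNPs are
    correlated.  *maf_spec* may be a scalar, a (lo, hi) range sampled per
    SNP, or a length-n_snps vector; MAFs must lie in the post-QC regime
    [0.05, 0.5].
    """
    if n_samples < 1 or n_snps < 1:
        raise ValueError("n_samples and n_snps must be positive")
    if not 0 <= ld_rho < 1:
        raise ValueError(f"ld_rho {ld_rho} outside [0, 1)")
    rng = np.random.default_rng(seed)
    if np.isscalar(maf_spec):
        mafs = np.full(n_snps, float(maf_spec))
    elif isinstance(maf_spec, tuple) and len(maf_spec) == 2:
        mafs = rng.uniform(maf_spec[0], maf_spec[1], size=n_snps)
    else:
        mafs = np.asarray(maf_spec, dtype=float)
        if mafs.size != n_snps:
            raise ValueError("maf_spec vector length != n_snps")
    if np.any(mafs < 0.05) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in [0.05, 0.5]")

    thresholds = stats.norm.ppf(1.0 - mafs)  # carrier iff latent > threshold
    dosage = np.zeros((n_samples, n_snps))
    for _gamete in range(2):
        z = rng.standard_normal((n_samples, n_snps))
        lat = np.empty_like(z)
        lat[:, 0] = z[:, 0]
        c = np.sqrt(1.0 - ld_rho**2)
        for k in range(1, n_snps):
            lat[:, k] = ld_rho * lat[:, k - 1] + c * z[:, k]
        dosage += (lat > thresholds).astype(float)

    variants = [
        VariantRecord(
            snp_id=f"snp{j}",
            chromosome=chromosome,
            position=position_start + j * position_step,
        )
        for j in range(n_snps)
    ]
    gm = GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)], variants=variants, dosages=dosage
    )
    gm.refresh_stats()
    return gm


def select_causal_snps(
    gm: GenotypeMatrix,
    region: GeneRegion | None,
    n_causal: int,
    ld_mode: str = "random",
    seed: int = 0,
) -> list[str]:
    """Pick causal SNP ids from the gene's cis window.

    ``random``: uniform without replacement.  ``high_ld`` / ``low_ld``: a
    seeded random qualifying pair with empirical r^2 > 0.8 / < 0.2.
    """
    window = extract_cis_window(gm, region) if region is not None else gm
    ids = window.snp_ids
    rng = np.random.default_rng(seed)
    if ld_mode == "random":
        if len(ids) < n_causal:
            raise ScenarioInfeasibleError(
                f"window has {len(ids)} SNPs, need {n_causal} causal"
            )
        pick = rng.choice(len(ids), size=n_causal, replace=False)
        return [ids[j] for j in sorted(pick)]
    if ld_mode not in ("high_ld", "low_ld"):
        raise ValueError(f"unknown ld_mode {ld_mode!r}")
    if n_causal != 2:
        raise ScenarioInfeasibleError("LD-aware selection is defined for causal pairs")
    X = window.dosages
    sd = X.std(axis=0)
    usable = np.where(sd > 0)[0]
    pairs, best = [], -np.inf
    for a, b in combinations(usable, 2):
        r = np.corrcoef(X[:, a], X[:, b])[0, 1]
        r2 = r * r
        qualifies = r2 > 0.8 if ld_mode == "high_ld" else r2 < 0.2
        if qualifies:
            pairs.append((a, b))
        score = r2 if ld_mode == "high_ld" else -r2
        best = max(best, score)
    if not pairs:
        best_r2 = best if ld_mode == "high_ld" else -best
        raise ScenarioInfeasibleError(
            f"no SNP pair with r^2 {'>' if ld_mode == 'high_ld' else '<'} "
            f"{0.8 if ld_mode == 'high_ld' else 0.2}; best available r^2 = {best_r2:.3f}"
        )
    a, b = pairs[rng.integers(len(pairs))]
    return [ids[a], ids[b]]


def genetic_value(
    G_causal, architecture: str, seed: int = 0
) -> tuple[np.ndarray, dict]:
    """Per-sample genetic value under an architecture; returns (g, effect_spec).

    Additive: g = sum_j w_j G_j with w_j ~ N(0, 1).  Non-additive rules act
    on carrier indicators c_j = 1{dosage_j >= 1}: single -> c1;
    epistatic -> c1 AND c2; heterogeneous -> c1 OR c2;
    compensatory -> c1 XOR c2 (both carriers cancel).
    """
    X = np.asarray(G_causal.dosages if hasattr(G_causal, "dosages") else G_causal, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    need = n_causal_for(architecture)
    if X.shape[1] != need:
        raise ValueError(f"{architecture} needs {need} causal SNPs, got {X.shape[1]}")
    spec: dict = {"architecture": architecture}
    if architecture.startswith("additive"):
        w = np.random.default_rng(seed).standard_normal(need)
        spec["weights"] = w
        return X @ w, spec
    return apply_effect(X, spec), spec


def apply_effect(G_causal, effect_spec: dict) -> np.ndarray:
    """Re-apply a frozen effect spec to a (possibly different) cohort."""
    X = np.asarray(G_causal.dosages if hasattr(G_causal, "dosages") else G_causal, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    arch = effect_spec["architecture"]
    if arch.startswith("additive"):
        return X @ np.asarray(effect_spec["weights"], dtype=float)
    c = (X >= 1).astype(float)
    if arch == "single":
        return c[:, 0]
    if arch == "epistatic":
        return c[:, 0] * c[:, 1]
    if arch == "heterogeneous":
        return np.maximum(c[:, 0], c[:, 1])
    if arch == "compensatory":
        return np.abs(c[:, 0] - c[:, 1])  # XOR on indicators
    raise ValueError(f"unknown architecture {arch!r}")


def add_environmental_noise(
    g: np.ndarray, h2: float, seed: int = 0
) -> tuple[np.ndarray, HeritabilitySpec]:
    """x = g + e with e ~ N(0, sigma_g^2 (1 - h2) / h2); h2 = 1 gives x = g."""
    g = np.asarray(g, dtype=float).ravel()
    if not 0 < h2 <= 1:
        raise ValueError(f"h2 {h2} outside (0, 1]")
    sigma_g2 = float(np.var(g))
    if sigma_g2 == 0:
        raise ScenarioInfeasibleError("constant genetic value: reselect causal SNPs")
    sigma_e2 = sigma_g2 * (1.0 - h2) / h2
    spec = HeritabilitySpec(sigma_g2=sigma_g2, sigma_e2=sigma_e2)
    if sigma_e2 == 0:
        return g.copy(), spec
    rng = np.random.default_rng(seed)
    return g + rng.normal(0.0, np.sqrt(sigma_e2), size=g.size), spec


def simulate_dataset(
    scenario: SimScenario,
    gm: GenotypeMatrix,
    region: GeneRegion | None = None,
    effect_spec: dict | None = None,
    causal_snp_ids: list[str] | None = None,
) -> SimDataset:
    """PDUI and phenotype for one gene under a scenario.

    *causality*: PDUI = g + e1 at h2_apa, phenotype y = PDUI + e2 scaled so
    var(g)/var(y) = h2_pheno (requires h2_pheno <= h2_apa).  *pleiotropy*:
    PDUI = g + e1 at h2_apa and y = g + e2 at h2_pheno with independent
    noise.  Binary traits keep y as the liability, binarized downstream.

    Pass *effect_spec* and *causal_snp_ids* from a previous dataset to apply
    the same causal rule to a second cohort (train/test designs).
    """
    ss = np.random.SeedSequence(scenario.seed)
    seed_sel, seed_eff, seed_apa, seed_phe = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(4))

    if causal_snp_ids is None:
        causal_snp_ids = select_causal_snps(
            gm, region, scenario.n_causal, scenario.ld_mode, seed_sel
        )
    idx = [gm.snp_ids.index(s) for s in causal_snp_ids]
    Xc = gm.dosages[:, idx]

    if effect_spec is None:
        g, effect_spec = genetic_value(Xc, scenario.architecture, seed_eff)
    else:
        g = apply_effect(Xc, effect_spec)
    if np.var(g) == 0:
        raise ScenarioInfeasibleError("constant genetic value in this cohort")

    pdui, apa_spec = add_environmental_noise(g, scenario.h2_apa, seed_apa)
    rng_phe = np.random.default_rng(seed_phe)

    if scenario.assumption == "pleiotropy":
        sigma_e2 = apa_spec.sigma_g2 * (1.0 - scenario.h2_pheno) / scenario.h2_pheno
        y = g + rng_phe.normal(0.0, np.sqrt(sigma_e2), size=g.size)
        pheno_spec = HeritabilitySpec(apa_spec.sigma_g2, sigma_e2)
    else:  # causality: y = PDUI + e2 with end-to-end var(g)/var(y) = h2_pheno
        sigma_g2 = apa_spec.sigma_g2
        sigma_y2 = sigma_g2 / scenario.h2_pheno
        sigma_e2 = sigma_y2 - sigma_g2 - apa_spec.sigma_e2
        if sigma_e2 < -1e-12:
            raise ScenarioInfeasibleError(
                f"causality chain infeasible: h2_pheno={scenario.h2_pheno} > "
                f"h2_apa={scenario.h2_apa}"
            )
        sigma_e2 = max(sigma_e2, 0.0)
        y = pdui + rng_phe.normal(0.0, np.sqrt(sigma_e2), size=g.size)
        pheno_spec = HeritabilitySpec(sigma_g2, apa_spec.sigma_e2 + sigma_e2)

    return SimDataset(
        genotypes=gm,
        pdui=pdui,
        phenotype=y,
        causal_snp_ids=list(causal_snp_ids),
        scenario=scenario,
        effect_spec=effect_spec,
        apa_spec=apa_spec,
        pheno_spec=pheno_spec,
    )


def binarize_liability(liability: np.ndarray, prevalence: float) -> np.ndarray:
    """Case/control labels by thresholding at the (1 - prevalence) quantile."""
    x = np.asarray(liability, dtype=float).ravel()
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if np.all(x == x[0]):
        raise ValueError("degenerate liability: all values equal")
    n_cases = int(np.floor(x.size * prevalence))
    order = np.argsort(x, kind="stable")
    labels = np.zeros(x.size)
    if n_cases > 0:
        labels[order[-n_cases:]] = 1.0
    return labels


def simulate_null_dataset(
    n_genes: int, n_samples: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pure-null design: per gene, transcriptome and phenotype iid N(0, 1)."""
    if n_genes < 1 or n_samples < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    return [
        (rng.standard_normal(n_samples), rng.standard_normal(n_samples))
        for _ in range(n_genes)
    ]
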