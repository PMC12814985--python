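"""Experiment drivers: power, type-I error, empirical cutoffs, thresholds.

Power follows the two-cohort design of the simulation framework: per gene,
weights are trained on a training cohort's genotypes and simulated PDUI,
then both tests run against an independent test cohort — the kernel Q test
on individual-level phenotypes, the linear baseline on per-SNP GWAS z-scores
computed from the same test cohort.  Power is the fraction of genes whose
p-value falls strictly below the Bonferroni threshold alpha / n_genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .association import ZScores, astwas_test, ld_matrix, linear_twas_test
from .kernels import KernelSpec
from .simulate import (
    ScenarioInfeasibleError,
    SimScenario,
    binarize_liability,
    simulate_dataset,
    simulate_genotypes,
    simulate_null_dataset,
)
from .weights import build_weight_matrix, train_gene

__all__ = [
    "PowerResult",
    "bonferroni_threshold",
    "compute_power",
    "empirical_cutoff",
    "type1_error_rate",
    "expand_grid",
    "marginal_z_scores",
    "run_power_cell",
    "run_null_gene",
    "run_experiment",
]


@dataclass
class PowerResult:
    scenario: SimScenario
    method: str
    n_genes: int
    n_detected: int
    power: float
    threshold_used: float


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m over m gene tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def compute_power(p_values: np.ndarray, threshold: float) -> tuple[int, float]:
    """(n_detected, power): fraction of p-values strictly below threshold."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    n_detected = int(np.sum(p < threshold))
    return n_detected, n_detected / p.size


def empirical_cutoff(p_values_null: np.ndarray, top_fraction: float = 0.05) -> float:
    """Most-significant top-fraction boundary: ascending rank ceil(f * N)."""
    p = np.sort(np.asarray(p_values_null, dtype=float))
    if p.size == 0:
        raise ValueError("no null p-values supplied")
    rank = max(1, math.ceil(top_fraction * p.size))
    return float(p[rank - 1])


def type1_error_rate(p_values_null: np.ndarray, alpha: float = 0.05) -> float:
    """Fraction of null p-values below alpha."""
    p = np.asarray(p_values_null, dtype=float)
    if p.size == 0:
        raise ValueError("no null p-values supplied")
    return float(np.mean(p < alpha))


def expand_grid(config: dict) -> list[SimScenario]:
    """Expand a grid config into the full list of scenario cells.

    Keys: assumption, architectures, h2_pheno (list), h2_apa (list),
    trait_type, prevalence, ld_mode, n_samples, seed.  Cells are ordered
    architecture-major, then h2_pheno, then h2_apa.
    """
    scenarios = []
    base_seed = int(config.get("seed", 0))
    for ai, arch in enumerate(config["architectures"]):
        for pi, h2p in enumerate(config["h2_pheno"]):
            for qi, h2a in enumerate(config["h2_apa"]):
                scenarios.append(
                    SimScenario(
                        assumption=config["assumption"],
                        architecture=arch,
                        h2_pheno=float(h2p),
                        h2_apa=float(h2a),
                        trait_type=config.get("trait_type", "quantitative"),
                        prevalence=float(config.get("prevalence", 0.5)),
                        ld_mode=config.get("ld_mode", "random"),
                        n_samples=int(config.get("n_samples", 670)),
                        seed=base_seed + 1000 * ai + 50 * pi + qi,
                    )
                )
    return scenarios


def marginal_z_scores(G, y: np.ndarray) -> np.ndarray:
    """Per-SNP GWAS score-test z-statistics of y on each dosage column."""
    X = np.asarray(G.dosages if hasattr(G, "dosages") else G, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xc = X - X.mean(axis=0)
    r = y - y.mean()
    sigma2 = np.var(y, ddof=1)
    ss = (Xc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (Xc.T @ r) / np.sqrt(sigma2 * ss)
    return np.where(ss > 0, z, 0.0)


def run_power_cell(
    scenario: SimScenario,
    n_genes: int,
    n_snps: int = 20,
    n_train: int | None = None,
    n_test: int | None = None,
    maf_spec=(0.05, 0.5),
    ld_rho: float = 0.2,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, PowerResult]]:
    """Simulate *n_genes* genes under one scenario and test with both methods.

    Returns per-method p-value arrays and PowerResult rows at the Bonferroni
    threshold alpha / n_genes.
    """
    root = np.random.SeedSequence(scenario.seed if seed is None else seed)
    p_ast, p_lin = [], []
    spec = KernelSpec("weighted_linear")
    n_train = n_train or scenario.n_samples
    n_test = n_test or scenario.n_samples
    for gene_ss in root.spawn(n_genes):
        s_train, s_test, s_data = (int(s.generate_state(1)[0] >> 1) for s in gene_ss.spawn(3))
        gm_train = simulate_genotypes(n_train, n_snps, maf_spec, ld_rho, seed=s_train)
        gm_test = simulate_genotypes(n_test, n_snps, maf_spec, ld_rho, seed=s_test)

        sc = SimScenario(**{**asdict(scenario), "seed": s_data})
        try:
            ds_train = simulate_dataset(sc, gm_train)
            ds_test = simulate_dataset(
                SimScenario(**{**asdict(sc), "seed": s_data + 1}),
                gm_test,
                effect_spec=ds_train.effect_spec,
                causal_snp_ids=ds_train.causal_snp_ids,
            )
        except ScenarioInfeasibleError:
            continue

        y = ds_test.phenotype
        trait = scenario.trait_type
        if trait == "binary":
            y = binarize_liability(y, scenario.prevalence)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = train_gene(gm_train, ds_train.pdui, gene_id="g", seed=s_data)
            w = build_weight_matrix(model)
            res_a = astwas_test(gm_test, w, y, trait_type=trait, spec=spec)
        p_ast.append(res_a.p_value)

        if not w.all_zero:
            z = marginal_z_scores(gm_test, y)
            R = ld_matrix(gm_test)
            try:
                res_l = linear_twas_test(w, ZScores(gm_test.snp_ids, z, R))
                p_lin.append(res_l.p_value)
            except ValueError:
                p_lin.append(1.0)
        else:
            p_lin.append(1.0)

    pvals = {"astwas": np.asarray(p_ast), "linear_twas": np.asarray(p_lin)}
    threshold = bonferroni_threshold(alpha, n_genes)
    results = {}
    for method, p in pvals.items():
        if p.size:
            n_det, power = compute_power(p, threshold)
        else:
            n_det, power = 0, 0.0
        results[method] = PowerResult(scenario, method, p.size, n_det, power, threshold)
    return pvals, results


def run_null_gene(
    rng_or_seed,
    n_samples: int = 300,
    n_snps: int = 20,
    maf_spec=(0.05, 0.5),
    ld_rho: float = 0.2,
) -> tuple[float, float, bool]:
    """One pure-null gene through both full pipelines.

    Returns (p_ast, p_lin, tested): transcriptome and phenotype are iid
    N(0, 1), independent of the genotypes; weights are trained on the null
    transcriptome, the kernel Q test runs on the null phenotype, and the
    linear baseline consumes null GWAS z-scores drawn from their exact null
    law z ~ MVN(0, R).  *tested* is False when the selected model has no
    nonzero weight — such genes carry no usable model and are excluded from
    calibration rates, as association pipelines only test genes with a
    trained model.
    """
    ss = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(rng_or_seed))
    )
    s_geno, s_null, s_z = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(3))
    gm = simulate_genotypes(n_samples, n_snps, maf_spec, ld_rho, seed=s_geno)
    rng = np.random.default_rng(s_null)
    transcriptome = rng.standard_normal(n_samples)
    phenotype = rng.standard_normal(n_samples)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = train_gene(gm, transcriptome, gene_id="null", seed=s_null)
        w = build_weight_matrix(model)
        p_ast = astwas_test(gm, w, phenotype).p_value
    if w.all_zero:
        return p_ast, 1.0, False
    R = ld_matrix(gm)
    evals, U = np.linalg.eigh(R)
    L = U * np.sqrt(np.clip(evals, 0.0, None))
    z = L @ np.random.default_rng(s_z).standard_normal(n_snps)
    p_lin = linear_twas_test(w, ZScores(gm.snp_ids, z, R)).p_value
    return p_ast, p_lin, True


def run_type1_experiment(
    n_genes: int,
    n_samples: int = 300,
    n_snps: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full-pipeline null calibration for both methods."""
    root = np.random.SeedSequence(seed)
    rows = []
    for ss in root.spawn(n_genes):
        rows.append(run_null_gene(ss, n_samples=n_samples, n_snps=n_snps))
    df = pd.DataFrame(rows, columns=["p_astwas", "p_linear", "tested"])
    sub = df[df["tested"]]
    df.attrs["type1_astwas"] = type1_error_rate(sub["p_astwas"].to_numpy(), alpha)
    df.attrs["type1_linear"] = type1_error_rate(sub["p_linear"].to_numpy(), alpha)
    df.attrs["cutoff_astwas"] = empirical_cutoff(sub["p_astwas"].to_numpy())
    df.attrs["cutoff_linear"] = empirical_cutoff(sub["p_linear"].to_numpy())
    return df


def run_experiment(config: dict, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Drive a grid experiment from a config dict; returns tidy results.

    ``mode: power`` expands the scenario grid and runs both methods per
    cell; infeasible cells are recorded with status ``skipped``.
    ``mode: type1`` runs the pure-null design.
    """
    mode = config.get("mode", "power")
    rows = []
    if mode == "type1":
        df = run_type1_experiment(
            n_genes=int(config.get("n_genes", 1000)),
            n_samples=int(config.get("n_samples", 300)),
            n_snps=int(config.get("n_snps", 20)),
            seed=int(config.get("seed", 0)),
        )
        out = pd.DataFrame(
            {
                "method": ["astwas", "linear_twas"],
                "type1_error": [df.attrs["type1_astwas"], df.attrs["type1_linear"]],
                "empirical_cutoff": [df.attrs["cutoff_astwas"], df.attrs["cutoff_linear"]],
                "n_genes": [len(df)] * 2,
                "seed": [config.get("seed", 0)] * 2,
            }
        )
    elif mode == "power":
        n_genes = int(config.get("n_genes", 100))
        for cell in expand_grid(config):
            try:
                _, results = run_power_cell(
                    cell,
                    n_genes=n_genes,
                    n_snps=int(config.get("n_snps", 20)),
                    n_train=config.get("n_train"),
                    n_test=config.get("n_test"),
                )
            except ScenarioInfeasibleError as exc:
                for method in ("astwas", "linear_twas"):
                    rows.append(
                        {**_cell_row(cell), "method": method, "status": f"skipped: {exc}"}
                    )
                continue
            for method, pr in results.items():
                rows.append(
                    {
                        **_cell_row(cell),
                        "method": method,
                        "n_genes": pr.n_genes,
                        "n_detected": pr.n_detected,
                        "power": pr.power,
                        "threshold": pr.threshold_used,
                        "status": "ok",
                    }
                )
        out = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out.to_csv(out_dir / f"{mode}_results.tsv", sep="\t", index=False)
    return out


def _cell_row(s: SimScenario) -> dict:
    return {
        "assumption": s.assumption,
        "architecture": s.architecture,
        "h2_pheno": s.h2_pheno,
        "h2_apa": s.h2_apa,
        "trait_type": s.trait_type,
        "ld_mode": s.ld_mode,
        "seed": s.seed,
    }
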