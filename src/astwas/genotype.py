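"""Genotype containers, loaders, quality control, and cis-window slicing.

Dosage matrices are stored sample-major as float arrays with ``np.nan``
marking missing calls; entries are additive minor/alt-allele counts in
{0, 1, 2} before imputation and real-valued afterwards.  Coordinates are
1-based and cis windows are closed intervals anchored on the gene start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CIS_FLANK_BP = 150_000

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "GeneRegion",
    "GenotypeFormatError",
    "GenotypeValidationError",
    "EmptyAfterQCError",
    "EmptyWindowError",
    "compute_maf",
    "compute_missing_rate",
    "load_genotypes",
    "write_plink",
    "write_tsv",
    "qc_filter",
    "mean_impute",
    "extract_cis_window",
]


class GenotypeFormatError(ValueError):
    """Malformed genotype file (names the offending record where possible)."""


class GenotypeValidationError(ValueError):
    """Dosage values outside {0, 1, 2, missing} or inconsistent dimensions."""


class EmptyAfterQCError(ValueError):
    """All SNPs or all samples were removed by QC; carries the QC report."""

    def __init__(self, message: str, report: pd.DataFrame):
        super().__init__(message)
        self.report = report


class EmptyWindowError(ValueError):
    """A gene's cis window contains no variants."""


@dataclass
class VariantRecord:
    snp_id: str
    chromosome: str
    position: int
    allele_ref: str = "A"
    allele_alt: str = "B"
    maf: float = float("nan")
    missing_rate: float = float("nan")


@dataclass
class GeneRegion:
    """A gene anchor with its closed cis window [start-150kb, start+150kb]."""

    gene_id: str
    chromosome: str
    start: int
    window_lo: int = field(init=False)
    window_hi: int = field(init=False)

    def __post_init__(self) -> None:
        self.window_lo = max(1, self.start - CIS_FLANK_BP)
        self.window_hi = self.start + CIS_FLANK_BP

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.window_lo <= position <= self.window_hi


@dataclass
class GenotypeMatrix:
    """Sample x SNP dosage matrix with per-variant metadata."""

    samples: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray  # float array, np.nan = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise GenotypeValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            bad = obs[(obs < 0) | (obs > 2)][0]
            raise GenotypeValidationError(f"dosage {bad} outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [v.snp_id for v in self.variants],
                "chromosome": [v.chromosome for v in self.variants],
                "position": [v.position for v in self.variants],
                "maf": [v.maf for v in self.variants],
                "missing_rate": [v.missing_rate for v in self.variants],
            }
        )

    def refresh_stats(self) -> None:
        """Recompute per-variant MAF and missing rate from current dosages."""
        for j, v in enumerate(self.variants):
            col = self.dosages[:, j]
            v.missing_rate = compute_missing_rate(col)
            v.maf = compute_maf(col) if v.missing_rate < 1.0 else float("nan")

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[replace(self.variants[j]) for j in idx],
            dosages=self.dosages[:, idx].copy(),
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=[replace(v) for v in self.variants],
            dosages=self.dosages[idx, :].copy(),
        )


def compute_maf(dosage_column: np.ndarray) -> float:
    """Minor allele frequency of one dosage column, missing calls excluded.

    f = (sum of non-missing dosages) / (2 * non-missing count); returns
    min(f, 1-f) so the value always lies in [0, 0.5].
    """
    col = np.asarray(dosage_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise GenotypeValidationError("MAF undefined: all calls missing")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def compute_missing_rate(dosage_column: np.ndarray) -> float:
    col = np.asarray(dosage_column, dtype=float)
    return float(np.isnan(col).mean()) if col.size else 1.0


# ---------------------------------------------------------------------------
# Loaders / writers


def load_genotypes(path: str | Path, format_tag: str = "plink") -> GenotypeMatrix:
    """Load genotypes from a PLINK bed/bim/fam triple or a dosage TSV.

    ``format_tag='plink'``: *path* is the prefix of a .bed/.bim/.fam triple
    (bed v1.00, SNP-major).  Dosages count the bim A1 allele.

    ``format_tag='tsv'``: header row of SNP ids, first column sample ids,
    cells in {0, 1, 2, NA}.  TSV input carries no coordinates; variants get
    chromosome "0" and position = column index (1-based).
    """
    if format_tag == "plink":
        return _load_plink(Path(path))
    if format_tag == "tsv":
        return _load_tsv(Path(path))
    raise ValueError(f"unknown format_tag {format_tag!r}")


def _load_tsv(path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise GenotypeFormatError(f"{path}: no SNP columns found")
    vals = df.to_numpy()
    dosages = np.full(vals.shape, np.nan)
    allowed = {"0": 0.0, "1": 1.0, "2": 2.0}
    for (i, j), cell in np.ndenumerate(vals):
        cell = str(cell).strip()
        if cell in ("NA", "nan", ""):
            continue
        if cell not in allowed:
            raise GenotypeValidationError(
                f"{path}: row {df.index[i]!r} column {df.columns[j]!r}: "
                f"dosage {cell!r} not in {{0,1,2,NA}}"
            )
        dosages[i, j] = allowed[cell]
    variants = [
        VariantRecord(snp_id=str(c), chromosome="0", position=j + 1)
        for j, c in enumerate(df.columns)
    ]
    gm = GenotypeMatrix(samples=[str(s) for s in df.index], variants=variants, dosages=dosages)
    gm.refresh_stats()
    return gm


def write_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.dosages, index=gm.samples, columns=gm.snp_ids)
    out = df.map(lambda x: "NA" if np.isnan(x) else str(int(x)) if float(x).is_integer() else str(x))
    out.to_csv(path, sep="\t", index_label="sample")


_BED_MAGIC = b"\x6c\x1b\x01"  # bed v1.00, SNP-major
# 2-bit codes -> A1-allele dosage: 00=2 (hom A1), 01=missing, 10=1 (het), 11=0
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def _load_plink(prefix: Path) -> GenotypeMatrix:
    bed, bim, fam = (Path(str(prefix) + s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"PLINK triple incomplete: {f} missing")

    samples: list[str] = []
    with open(fam) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 2:
                raise GenotypeFormatError(f"{fam}:{ln}: expected >=2 fields")
            samples.append(parts[1])

    variants: list[VariantRecord] = []
    with open(bim) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise GenotypeFormatError(f"{bim}:{ln}: expected 6 fields, got {len(parts)}")
            chrom, snp_id, _cm, pos, a1, a2 = parts
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise GenotypeFormatError(f"{bim}:{ln}: bad position {pos!r}") from exc
            variants.append(
                VariantRecord(snp_id=snp_id, chromosome=chrom, position=pos_i, allele_ref=a2, allele_alt=a1)
            )

    n, p = len(samples), len(variants)
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeFormatError(f"{bed}: bad magic bytes {raw[:3]!r} (want bed v1.00 SNP-major)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * p
    if len(raw) != expected:
        raise GenotypeFormatError(f"{bed}: size {len(raw)} != expected {expected}")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bytes_per_snp)
    # unpack 2-bit pairs, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, -1)[:, :n]  # p x n
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T.copy()  # n x p
    gm = GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)
    gm.refresh_stats()
    return gm


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a bed/bim/fam triple (bed v1.00 SNP-major); A1 = alt allele."""
    prefix = Path(prefix)
    with open(str(prefix) + ".fam", "w") as fh:
        for s in gm.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(str(prefix) + ".bim", "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chromosome} {v.snp_id} 0 {v.position} {v.allele_alt} {v.allele_ref}\n")
    n = gm.n_samples
    bytes_per_snp = (n + 3) // 4
    with open(str(prefix) + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(gm.n_snps):
            col = gm.dosages[:, j]
            buf = bytearray(bytes_per_snp)
            for i, d in enumerate(col):
                code = 0b01 if np.isnan(d) else _DOSAGE_TO_CODE[float(d)]
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))


# ---------------------------------------------------------------------------
# QC / imputation / windowing


def qc_filter(
    gm: GenotypeMatrix,
    snp_missing_max: float = 0.05,
    sample_missing_max: float = 0.05,
    maf_min: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Standard marker/sample QC in fixed order.

    1. drop SNPs with missing rate > *snp_missing_max*;
    2. drop samples with missing rate > *sample_missing_max*;
    3. drop SNPs with MAF (recomputed on surviving samples) < *maf_min*.

    Returns the filtered matrix and a stage-by-stage report
    (stage, items_removed, items_remaining).
    """
    if gm.n_samples == 0 or gm.n_snps == 0:
        raise GenotypeValidationError("empty genotype matrix")
    rows: list[tuple[str, int, int]] = []

    miss_snp = np.isnan(gm.dosages).mean(axis=0)
    keep_snp = np.where(miss_snp <= snp_missing_max)[0]
    rows.append(("snp_missingness", gm.n_snps - keep_snp.size, keep_snp.size))
    out = gm.take_variants(keep_snp) if keep_snp.size else None

    if out is not None:
        miss_sample = np.isnan(out.dosages).mean(axis=1)
        keep_sample = np.where(miss_sample <= sample_missing_max)[0]
        rows.append(("sample_missingness", out.n_samples - keep_sample.size, keep_sample.size))
        out = out.take_samples(keep_sample) if keep_sample.size else None

    if out is not None:
        mafs = np.array(
            [
                compute_maf(out.dosages[:, j]) if not np.all(np.isnan(out.dosages[:, j])) else -1.0
                for j in range(out.n_snps)
            ]
        )
        keep_maf = np.where(mafs >= maf_min)[0]
        rows.append(("maf", out.n_snps - keep_maf.size, keep_maf.size))
        out = out.take_variants(keep_maf) if keep_maf.size else None

    report = pd.DataFrame(rows, columns=["stage", "items_removed", "items_remaining"])
    if out is None or out.n_snps == 0 or out.n_samples == 0:
        raise EmptyAfterQCError("QC removed all SNPs or all samples", report)
    out.refresh_stats()
    return out, report


def mean_impute(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace residual missing calls with the column mean of observed dosages."""
    dos = gm.dosages.copy()
    col_means = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
    idx = np.where(np.isnan(dos))
    dos[idx] = col_means[idx[1]]
    out = GenotypeMatrix(
        samples=list(gm.samples), variants=[replace(v) for v in gm.variants], dosages=dos
    )
    out.refresh_stats()
    return out


def extract_cis_window(gm: GenotypeMatrix, region: GeneRegion) -> GenotypeMatrix:
    """Sub-matrix of variants inside the gene's closed cis window."""
    chroms = np.array([v.chromosome for v in gm.variants])
    if region.chromosome not in chroms:
        raise EmptyWindowError(
            f"chromosome {region.chromosome!r} of gene {region.gene_id!r} absent from genotypes"
        )
    pos = np.array([v.position for v in gm.variants])
    keep = np.where(
        (chroms == region.chromosome) & (pos >= region.window_lo) & (pos <= region.window_hi)
    )[0]
    if keep.size == 0:
        raise EmptyWindowError(
            f"no SNPs in window [{region.window_lo}, {region.window_hi}] of gene {region.gene_id!r}"
        )
    return gm.take_variants(keep)
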