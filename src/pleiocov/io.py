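"""Genotype and phenotype ingestion: PLINK bed/bim/fam, QC, imputation, trait preadjustment.

Dosages count copies of the bim A1 allele (0, 1, 2) with -1 marking a missing
call.  Local (co)variance magnitudes are orientation-invariant but effect signs
are not, so the A1 convention is recorded here once and for all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypePanel",
    "TraitTable",
    "read_plink",
    "write_plink",
    "qc_filter",
    "impute_center",
    "preadjust_traits",
    "read_trait_table",
    "align_samples",
]


@dataclass(eq=False)
class GenotypePanel:
    """An n_individuals x n_snps dosage matrix plus its SNP map.

    ``dosages`` is int8 with values in {0, 1, 2, MISSING}.  ``snp_map`` is a
    DataFrame with columns ``snp`` (identifier), ``chrom`` (1-22), ``pos``
    (bp), ``a1``, ``a2``; it must be sorted by (chrom, pos) with strictly
    increasing positions within each chromosome.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape[1] != len(self.snp_map):
            raise ValueError(
                f"snp_map has {len(self.snp_map)} rows but dosage matrix has "
                f"{self.dosages.shape[1]} columns"
            )
        if not self.sample_ids:
            self.sample_ids = [f"id{i}" for i in range(self.dosages.shape[0])]
        vals = np.unique(self.dosages)
        bad = set(vals.tolist()) - {0, 1, 2, MISSING}
        if bad:
            raise ValueError(f"dosage values outside {{0,1,2,missing}}: {sorted(bad)}")
        chrom = self.snp_map["chrom"].to_numpy()
        pos = self.snp_map["pos"].to_numpy()
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def chromosomes(self) -> np.ndarray:
        return np.unique(self.snp_map["chrom"].to_numpy())


@dataclass(eq=False)
class TraitTable:
    """Two preadjusted quantitative traits (residual scale, mean ~ 0)."""

    values: np.ndarray
    trait_names: tuple = ("trait1", "trait2")
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("TraitTable.values must be n x 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TraitTable.values contains missing/non-finite entries")


# ---------------------------------------------------------------------------
# PLINK 1 bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B])
# 2-bit codes in a SNP-major bed, per byte from the low bits up:
# 00 -> hom A1 (dosage 2), 01 -> missing, 10 -> het (1), 11 -> hom A2 (0)
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix) -> GenotypePanel:
    """Read a PLINK 1 fileset ``prefix``.bed/.bim/.fam into a GenotypePanel.

    Dosages count the bim A1 allele.  Raises ``ValueError`` on a bad magic
    number, a sample-major bed, or a payload whose size disagrees with the
    fam/bim dimensions.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"snp": str},
    )
    n, p = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a PLINK 1 bed file (bad magic bytes)")
    if raw[2] != 0x01:
        raise ValueError(f"{prefix}.bed: only SNP-major bed files are supported")
    stride = (n + 3) // 4
    if len(raw) - 3 != stride * p:
        raise ValueError(
            f"{prefix}.bed: payload is {len(raw) - 3} bytes but fam/bim imply "
            f"{stride * p} ({n} individuals x {p} SNPs)"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, stride)
    # unpack 2-bit codes: individual i lives in bits (2*(i%4), +1) of byte i//4
    codes = np.zeros((p, stride * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (payload >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    snp_map = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypePanel(dosages=dosages, snp_map=snp_map, sample_ids=fam["iid"].tolist())


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a GenotypePanel as a PLINK 1 SNP-major bed/bim/fam fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = panel.n_individuals, panel.n_snps
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in panel.sample_ids:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    sm = panel.snp_map
    a1 = sm["a1"] if "a1" in sm else pd.Series(["A"] * p)
    a2 = sm["a2"] if "a2" in sm else pd.Series(["G"] * p)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(p):
            fh.write(
                f"{sm['chrom'].iat[j]} {sm['snp'].iat[j]} 0 {sm['pos'].iat[j]} "
                f"{a1.iat[j]} {a2.iat[j]}\n"
            )
    stride = (n + 3) // 4
    out = np.zeros((p, stride), dtype=np.uint8)
    dos = panel.dosages
    for i in range(n):
        byte, shift = divmod(i, 4)
        col = np.array([_DOSAGE_TO_CODE[int(v)] for v in dos[i, :]], dtype=np.uint8)
        out[:, byte] |= col << (2 * shift)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(out.tobytes())


# ---------------------------------------------------------------------------
# QC, imputation, preadjustment
# ---------------------------------------------------------------------------

def qc_filter(panel: GenotypePanel, maf_min: float = 0.01, miss_max: float = 0.05):
    """Drop SNPs with minor allele frequency < ``maf_min`` or missing call
    rate > ``miss_max``.

    Returns ``(filtered_panel, n_kept, n_dropped)``.  SNP order is preserved.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= miss_max <= 1.0):
        raise ValueError("miss_max must be in [0, 1]")
    dos = panel.dosages
    observed = dos != MISSING
    n_obs = observed.sum(axis=0)
    miss_rate = 1.0 - n_obs / dos.shape[0]
    with np.errstate(invalid="ignore"):
        freq = np.where(observed, dos, 0).sum(axis=0) / np.maximum(2 * n_obs, 1)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf >= maf_min) & (miss_rate <= miss_max) & (n_obs > 0)
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError("QC removed every SNP; nothing left to analyse")
    out = GenotypePanel(
        dosages=dos[:, keep],
        snp_map=panel.snp_map.loc[keep].reset_index(drop=True),
        sample_ids=panel.sample_ids,
    )
    return out, n_kept, panel.n_snps - n_kept


def impute_center(panel: GenotypePanel) -> np.ndarray:
    """Mean-impute missing dosages per SNP, then mean-center each column.

    Returns a float64 matrix; monomorphic (zero-variance) columns are retained
    as all-zero columns — they contribute nothing to any window variance.
    """
    dos = panel.dosages.astype(np.float64)
    missing = panel.dosages == MISSING
    dos[missing] = np.nan
    col_mean = np.nanmean(dos, axis=0)
    inds = np.where(missing)
    dos[inds] = col_mean[inds[1]]
    X = dos - dos.mean(axis=0)
    return X


def preadjust_traits(
    raw: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    trait_names=("trait1", "trait2"),
    log_transform: bool = True,
    covariate_names=None,
) -> TraitTable:
    """OLS-residualise (optionally log-transformed) traits on an intercept plus
    covariates, one trait at a time.

    ``raw`` is n x 2 and must be strictly positive when ``log_transform``.
    ``covariates`` is n x c (age, sex, principal components ...); an intercept
    is always added.  Residuals are orthogonal to every covariate column.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[1] != 2:
        raise ValueError("raw traits must be n x 2")
    if log_transform:
        bad = np.where(~(raw > 0))
        if bad[0].size:
            raise ValueError(
                f"non-positive trait value at row {int(bad[0][0])} "
                "(log transform requires strictly positive values)"
            )
        y = np.log(raw)
    else:
        y = raw.copy()
    n = y.shape[0]
    if covariates is None:
        Z = np.ones((n, 1))
        names = ["intercept"]
    else:
        if isinstance(covariates, pd.DataFrame):
            covariate_names = list(covariates.columns)
            covariates = covariates.to_numpy(dtype=np.float64)
        covariates = np.asarray(covariates, dtype=np.float64)
        if not np.all(np.isfinite(covariates)):
            raise ValueError("covariates contain missing values; complete cases only")
        Z = np.column_stack([np.ones(n), covariates])
        names = ["intercept"] + (
            covariate_names or [f"cov{i}" for i in range(covariates.shape[1])]
        )
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # name the columns involved in the collinearity via QR pivoting
        from scipy.linalg import qr

        _, _, piv = qr(Z, pivoting=True, mode="economic")
        dropped = [names[i] for i in piv[rank:]]
        raise ValueError(f"covariate design is rank-deficient (collinear: {dropped})")
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coef
    return TraitTable(values=resid, trait_names=tuple(trait_names))


# ---------------------------------------------------------------------------
# Delimited phenotype tables
# ---------------------------------------------------------------------------

def read_trait_table(path, id_col: str = "iid", sep: str = "\t") -> pd.DataFrame:
    """Read a delimited phenotype/covariate table with a header and a
    sample-identifier column."""
    df = pd.read_csv(path, sep=sep, dtype={id_col: str})
    if id_col not in df.columns:
        raise ValueError(f"{path}: no '{id_col}' column")
    return df.set_index(id_col)


def align_samples(panel: GenotypePanel, *tables: pd.DataFrame):
    """Intersect panel sample ids with every table's index; returns the panel
    restricted to the shared ids (in panel order) and the reordered tables."""
    ids = [i for i in panel.sample_ids if all(i in t.index for t in tables)]
    if not ids:
        raise ValueError("no samples shared between genotypes and phenotype tables")
    idx = [panel.sample_ids.index(i) for i in ids]
    sub = GenotypePanel(
        dosages=panel.dosages[idx, :], snp_map=panel.snp_map, sample_ids=ids
    )
    return (sub, *[t.loc[ids] for t in tables])
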