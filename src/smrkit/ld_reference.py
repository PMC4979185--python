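"""LD estimation from a reference genotype panel.

The HEIDI test needs the correlation r_ij between the cis-SNPs' genotype
dosages, signed consistently with the harmonized effect alleles.  The
panel can be a PLINK1 .bed/.bim/.fam triplet (SNP-major) or a plain
dosage TSV (``sample_id`` column plus one ``snp_id:a1`` column per SNP).

Missing genotypes are excluded pairwise when computing correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "LdMatrix",
    "load_genotypes",
    "compute_ld",
    "write_dosage_tsv",
    "write_plink",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK1 SNP-major
# 2-bit genotype -> dosage of the .bim A1 allele; 0b01 is the missing code
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class GenotypeMatrix:
    """Reference-panel genotypes: individuals x SNPs dosages of allele a1.

    ``dosages`` is float with NaN for missing calls; ``snp_meta`` has one
    row per column with snp_id, chrom, bp, a1, a2 (chrom/bp/a2 may be
    missing for dosage-TSV panels, which carry only ``snp_id:a1`` headers).
    """

    sample_ids: list
    snp_meta: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_meta)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_meta)} SNPs"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def snp_ids(self) -> list:
        return self.snp_meta["snp_id"].tolist()


@dataclass
class LdMatrix:
    """Signed Pearson LD matrix over an ordered SNP list."""

    snp_ids: list
    r: np.ndarray

    def __post_init__(self):
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def subset(self, snp_ids: Sequence[str]) -> "LdMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LdMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def r2(self) -> np.ndarray:
        return self.r ** 2


def load_genotypes(path, format: str = "plink-bed") -> GenotypeMatrix:
    """Load a reference panel.

    ``format="plink-bed"``: ``path`` is the file-set prefix (without
    extension); dosages count the .bim A1 allele.
    ``format="dosage-tsv"``: ``path`` is a TSV whose header is
    ``sample_id`` followed by ``snp_id:a1`` columns; empty cells or ``NA``
    are missing.
    """
    if format == "plink-bed":
        return _load_plink(path)
    if format == "dosage-tsv":
        return _load_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    sample_ids = df["sample_id"].tolist()
    snp_ids, a1s = [], []
    for col in df.columns[1:]:
        snp, _, a1 = col.partition(":")
        if not a1:
            raise ValueError(f"{path}: column {col!r} not in 'snp_id:a1' form")
        snp_ids.append(snp)
        a1s.append(a1.upper())
    meta = pd.DataFrame({"snp_id": snp_ids, "chrom": pd.NA, "bp": pd.NA,
                         "a1": a1s, "a2": pd.NA})
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(sample_ids, meta, dosages)


def _load_plink(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
                      dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    n, m = len(fam), len(bim)
    data = Path(prefix.with_suffix(".bed")).read_bytes()
    if data[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK1 .bed file")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(data, dtype=np.uint8, offset=3)
    if len(body) != m * bytes_per_snp:
        raise ValueError(
            f"{prefix}.bed: size {len(body)} bytes inconsistent with "
            f"{n} samples x {m} SNPs from .fam/.bim"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample index varies fastest within a byte
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T
    meta = bim[["snp_id", "chrom", "bp", "a1", "a2"]].copy()
    meta["a1"] = meta["a1"].str.upper()
    meta["a2"] = meta["a2"].str.upper()
    return GenotypeMatrix(fam["iid"].tolist(), meta, dosages)


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    cols = {"sample_id": geno.sample_ids}
    for j, row in geno.snp_meta.iterrows():
        col = geno.dosages[:, j]
        cols[f"{row['snp_id']}:{row['a1']}"] = [
            "NA" if np.isnan(v) else int(v) for v in col
        ]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """Write the panel as a PLINK1 SNP-major .bed/.bim/.fam triplet."""
    prefix = Path(prefix)
    meta = geno.snp_meta
    bim = pd.DataFrame({
        "chrom": meta["chrom"].fillna("0"), "snp_id": meta["snp_id"],
        "cm": 0, "bp": meta["bp"].fillna(0).astype(int),
        "a1": meta["a1"], "a2": meta["a2"].fillna("N"),
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": geno.sample_ids, "iid": geno.sample_ids,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = geno.n_samples
    dos = geno.dosages
    code = np.full(dos.shape, 0b01, dtype=np.uint8)  # missing
    code[dos == 2.0] = 0b00
    code[dos == 1.0] = 0b10
    code[dos == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.vstack([code, np.full((pad, code.shape[1]), 0b01, np.uint8)])
    code = code.T.reshape(len(geno.snp_meta), -1, 4)
    packed = (code[:, :, 0] | (code[:, :, 1] << 2)
              | (code[:, :, 2] << 4) | (code[:, :, 3] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def compute_ld(
    genotypes: GenotypeMatrix,
    snp_ids: Sequence[str],
    harmonized_alleles: Optional[Mapping[str, str]] = None,
) -> LdMatrix:
    """Pairwise-complete Pearson correlation of dosage columns.

    Columns whose panel a1 differs from the harmonized effect allele are
    flipped (dosage -> 2 - dosage) first, so r carries the sign structure
    of the harmonized betas.  Monomorphic SNPs are excluded with a warning;
    SNPs absent from the panel raise KeyError.
    """
    index = {s: i for i, s in enumerate(genotypes.snp_ids)}
    missing = [s for s in snp_ids if s not in index]
    if missing:
        raise KeyError(f"SNP(s) absent from reference panel: {missing[:5]}")
    cols = [index[s] for s in snp_ids]
    dos = genotypes.dosages[:, cols].astype(float).copy()

    if harmonized_alleles is not None:
        panel_a1 = genotypes.snp_meta["a1"].to_numpy()
        panel_a2 = genotypes.snp_meta["a2"].to_numpy()
        for k, s in enumerate(snp_ids):
            want = harmonized_alleles[s].upper()
            have = panel_a1[index[s]]
            if want == have:
                continue
            other = panel_a2[index[s]]
            if isinstance(other, str) and want != other.upper():
                raise ValueError(
                    f"SNP {s}: harmonized allele {want} matches neither panel "
                    f"allele ({have}/{other})"
                )
            dos[:, k] = 2.0 - dos[:, k]

    variances = pd.DataFrame(dos).var(skipna=True).to_numpy()
    poly = variances > 0
    if not poly.all():
        mono = [s for s, ok in zip(snp_ids, poly) if not ok]
        warnings.warn(f"excluding monomorphic SNP(s) from LD: {mono}", stacklevel=2)
    kept_ids = [s for s, ok in zip(snp_ids, poly) if ok]
    r = pd.DataFrame(dos[:, poly]).corr(min_periods=2).to_numpy()
    np.fill_diagonal(r, 1.0)
    return LdMatrix(kept_ids, r)
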