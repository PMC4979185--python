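"""Reading, validation and allele harmonization of summary statistics.

GWAS tables follow the GCTA ``.ma`` convention (``SNP A1 A2 freq b se p N``,
whitespace-delimited).  eQTL tables are flat TSVs with probe metadata
(``probe_id gene probe_chr probe_bp snp_id chr bp a1 a2 freq b se p``).
A1 is always the effect allele: betas are per copy of A1 and ``freq`` is
the A1 frequency.

Harmonization aligns the GWAS record of every SNP to the eQTL effect
allele: records whose alleles are swapped get their beta sign flipped and
frequency complemented; records whose allele sets do not match are dropped.
All drops are accounted for in a :class:`QcReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GWAS_COLUMNS",
    "EQTL_COLUMNS",
    "QcReport",
    "HarmonizedLocus",
    "P_FLOOR",
    "read_gwas_ma",
    "read_eqtl_flat",
    "write_gwas_ma",
    "write_eqtl_flat",
    "harmonize",
]

#: smallest representable p-value; inputs printed as "<1.0E-300" or stored
#: as exact zero are clamped here so chi-square quantiles stay finite
P_FLOOR = 1e-300

GWAS_COLUMNS = ["snp_id", "a1", "a2", "freq_a1", "b_zy", "se_zy", "p_gwas", "n"]
EQTL_COLUMNS = [
    "probe_id", "gene", "probe_chrom", "probe_bp",
    "snp_id", "chrom", "bp", "a1", "a2", "freq_a1",
    "b_zx", "se_zx", "p_eqtl",
]

_MA_HEADER = {"snp": "snp_id", "a1": "a1", "a2": "a2", "freq": "freq_a1",
              "b": "b_zy", "se": "se_zy", "p": "p_gwas", "n": "n"}
_EQTL_HEADER = {"probe_id": "probe_id", "gene": "gene", "probe_chr": "probe_chrom",
                "probe_bp": "probe_bp", "snp_id": "snp_id", "chr": "chrom",
                "bp": "bp", "a1": "a1", "a2": "a2", "freq": "freq_a1",
                "b": "b_zx", "se": "se_zx", "p": "p_eqtl"}

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class QcReport:
    """Accounting of records dropped or flagged during IO/harmonization."""

    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )
    flagged: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def counts(self) -> dict:
        return self.dropped["reason"].value_counts().to_dict()

    def add_dropped(self, snp_ids, reason: str) -> None:
        if len(snp_ids):
            new = pd.DataFrame({"snp_id": list(snp_ids), "reason": reason})
            self.dropped = (
                pd.concat([self.dropped, new], ignore_index=True)
                if len(self.dropped) else new
            )

    def add_flagged(self, snp_ids, reason: str) -> None:
        if len(snp_ids):
            new = pd.DataFrame({"snp_id": list(snp_ids), "reason": reason})
            self.flagged = (
                pd.concat([self.flagged, new], ignore_index=True)
                if len(self.flagged) else new
            )

    def write(self, path) -> None:
        """Write the dropped-record report as a TSV of (snp_id, reason)."""
        self.dropped.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedLocus:
    """All overlapping SNPs of one probe, allele-aligned across both studies.

    ``snps`` holds one row per SNP with both the eQTL fields (b_zx, se_zx,
    p_eqtl, freq_eqtl) and the GWAS fields aligned to the eQTL effect allele
    (b_zy, se_zy, p_gwas, freq_gwas, n).  ``top_index`` is the positional
    index of the instrument: the SNP with the smallest p_eqtl.
    """

    probe_id: str
    gene: str
    probe_chrom: str
    probe_bp: int
    snps: pd.DataFrame
    top_index: Optional[int]
    qc: QcReport = field(default_factory=QcReport)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def is_empty(self) -> bool:
        return self.n_snps == 0

    @property
    def top(self) -> pd.Series:
        if self.top_index is None:
            raise ValueError(f"locus {self.probe_id} has no SNPs")
        return self.snps.iloc[self.top_index]

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Re-emit the locus as (gwas, eqtl) tables in canonical column form."""
        s = self.snps
        gwas = pd.DataFrame({
            "snp_id": s["snp_id"], "a1": s["a1"], "a2": s["a2"],
            "freq_a1": s["freq_gwas"], "b_zy": s["b_zy"], "se_zy": s["se_zy"],
            "p_gwas": s["p_gwas"], "n": s["n"],
        })
        eqtl = pd.DataFrame({
            "probe_id": self.probe_id, "gene": self.gene,
            "probe_chrom": self.probe_chrom, "probe_bp": self.probe_bp,
            "snp_id": s["snp_id"], "chrom": s["chrom"], "bp": s["bp"],
            "a1": s["a1"], "a2": s["a2"], "freq_a1": s["freq_eqtl"],
            "b_zx": s["b_zx"], "se_zx": s["se_zx"], "p_eqtl": s["p_eqtl"],
        })
        return gwas.reset_index(drop=True), eqtl.reset_index(drop=True)


def _clamp_p(df: pd.DataFrame, col: str, qc: QcReport) -> pd.DataFrame:
    zero = df[col] == 0
    if zero.any():
        df = df.copy()
        df.loc[zero, col] = P_FLOOR
        qc.add_flagged(df.loc[zero, "snp_id"], f"{col}_clamped_to_{P_FLOOR:g}")
    return df


def _validate(df: pd.DataFrame, se_col: str, p_col: str, qc: QcReport,
              check_freq: bool = True) -> pd.DataFrame:
    """Drop rows violating basic invariants, recording reasons."""
    checks = [
        (df[se_col].isna() | (df[se_col] <= 0), "nonpositive_se"),
        ((df[p_col] < 0) | (df[p_col] > 1) | df[p_col].isna(), "p_out_of_range"),
        (df["a1"].astype(str) == df["a2"].astype(str), "identical_alleles"),
        (df["b_zy" if se_col == "se_zy" else "b_zx"].isna(), "missing_beta"),
    ]
    if check_freq:
        checks.append(
            ((df["freq_a1"] <= 0) | (df["freq_a1"] >= 1) | df["freq_a1"].isna(),
             "freq_out_of_range"))
    bad = np.zeros(len(df), dtype=bool)
    for mask, reason in checks:
        new = np.asarray(mask) & ~bad
        qc.add_dropped(df.loc[new, "snp_id"], reason)
        bad |= new
    return df.loc[~bad].reset_index(drop=True)


def read_gwas_ma(path, dialect: Optional[dict] = None) -> tuple[pd.DataFrame, QcReport]:
    """Read a GCTA-``.ma``-style GWAS summary table.

    Returns the validated table (canonical columns) and a QC report of
    dropped rows.  Missing mandatory columns or zero valid rows are hard
    errors.
    """
    dialect = dialect or {}
    raw = pd.read_csv(path, sep=dialect.get("sep", r"\s+"), dtype={"SNP": str})
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [k for k in _MA_HEADER if k not in raw.columns]
    if missing:
        raise ValueError(f"GWAS table {path} missing mandatory column(s): {missing}")
    df = raw.rename(columns=_MA_HEADER)[GWAS_COLUMNS].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    for c in ("a1", "a2"):
        df[c] = df[c].astype(str).str.upper()
    qc = QcReport()
    df = _clamp_p(df, "p_gwas", qc)
    df = _validate(df, "se_zy", "p_gwas", qc)
    if (df["n"] < 1).any():
        qc.add_dropped(df.loc[df["n"] < 1, "snp_id"], "n_below_1")
        df = df.loc[df["n"] >= 1].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"GWAS table {path}: no valid rows after QC")
    return df, qc


def read_eqtl_flat(path) -> tuple[pd.DataFrame, QcReport]:
    """Read a flat cis-eQTL summary table (one row per probe-SNP pair)."""
    raw = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "snp_id": str,
                                             "probe_chr": str, "chr": str})
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [k for k in _EQTL_HEADER if k not in raw.columns]
    if missing:
        raise ValueError(f"eQTL table {path} missing mandatory column(s): {missing}")
    df = raw.rename(columns=_EQTL_HEADER)[EQTL_COLUMNS].copy()
    for c in ("probe_id", "gene", "probe_chrom", "snp_id", "chrom"):
        df[c] = df[c].astype(str)
    for c in ("a1", "a2"):
        df[c] = df[c].astype(str).str.upper()
    qc = QcReport()
    df = _clamp_p(df, "p_eqtl", qc)
    df = _validate(df, "se_zx", "p_eqtl", qc)
    if df.empty:
        raise ValueError(f"eQTL table {path}: no valid rows after QC")
    return df, qc


def write_gwas_ma(df: pd.DataFrame, path) -> None:
    out = df[GWAS_COLUMNS].rename(columns={v: k for k, v in _MA_HEADER.items()})
    out.columns = ["SNP", "A1", "A2", "freq", "b", "se", "p", "n"]
    out.to_csv(path, sep="\t", index=False)


def write_eqtl_flat(df: pd.DataFrame, path) -> None:
    out = df[EQTL_COLUMNS].rename(columns={v: k for k, v in _EQTL_HEADER.items()})
    out.to_csv(path, sep="\t", index=False)


def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> np.ndarray:
    pairs = [frozenset((x, y)) for x, y in zip(a1, a2)]
    return np.array([p in AMBIGUOUS_PAIRS for p in pairs])


def harmonize(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    probe_id: str,
    cis_window: int = 1_000_000,
    freq_qc: float = 0.2,
    drop_ambiguous: bool = False,
    ambiguous_freq_max: float = 0.2,
) -> HarmonizedLocus:
    """Build the allele-aligned working set for one probe.

    The SNP set is the intersection of both tables within ``cis_window`` bp
    of the probe position (closed interval, 1-based coordinates).  GWAS
    records whose alleles are swapped relative to the eQTL orientation have
    their beta sign flipped and frequency complemented; mismatched allele
    sets and records with |freq_eqtl - freq_gwas| > freq_qc are dropped.
    Strand-ambiguous SNPs (A/T, C/G) are kept with a warning while the
    frequency difference is below ``ambiguous_freq_max``, or dropped
    wholesale under ``drop_ambiguous``.

    An empty intersection yields a locus with ``top_index=None`` (check
    ``is_empty``) rather than an exception.
    """
    e = eqtl.loc[eqtl["probe_id"] == probe_id].copy()
    if e.empty:
        raise KeyError(f"probe {probe_id!r} not present in eQTL table")
    meta = e.iloc[0]
    probe_bp = int(meta["probe_bp"])
    qc = QcReport()

    in_cis = (e["bp"] - probe_bp).abs() <= cis_window
    qc.add_dropped(e.loc[~in_cis, "snp_id"], "outside_cis_window")
    e = e.loc[in_cis]
    # deterministic resolution of duplicate probe-SNP rows: keep smallest p
    e = e.sort_values(["p_eqtl", "snp_id"], kind="mergesort").drop_duplicates("snp_id")

    m = e.merge(gwas, on="snp_id", how="inner", suffixes=("_eqtl", "_gwas"))
    if m.empty:
        return HarmonizedLocus(probe_id=probe_id, gene=str(meta["gene"]),
                               probe_chrom=str(meta["probe_chrom"]),
                               probe_bp=probe_bp, snps=_empty_snps(),
                               top_index=None, qc=qc)

    same = (m["a1_gwas"] == m["a1_eqtl"]) & (m["a2_gwas"] == m["a2_eqtl"])
    swapped = (m["a1_gwas"] == m["a2_eqtl"]) & (m["a2_gwas"] == m["a1_eqtl"])
    mismatched = ~(same | swapped)
    qc.add_dropped(m.loc[mismatched, "snp_id"], "allele_mismatch")
    m = m.loc[~mismatched].copy()
    swapped = swapped.loc[m.index]

    m.loc[swapped, "b_zy"] = -m.loc[swapped, "b_zy"]
    m.loc[swapped, "freq_a1_gwas"] = 1.0 - m.loc[swapped, "freq_a1_gwas"]

    ambiguous = _is_ambiguous(m["a1_eqtl"], m["a2_eqtl"])
    dfreq = (m["freq_a1_eqtl"] - m["freq_a1_gwas"]).abs().to_numpy()
    if drop_ambiguous:
        qc.add_dropped(m.loc[ambiguous, "snp_id"], "strand_ambiguous")
        keep = ~ambiguous
    else:
        bad_amb = ambiguous & (dfreq >= ambiguous_freq_max)
        qc.add_dropped(m.loc[bad_amb, "snp_id"], "strand_ambiguous_freq_diff")
        if (ambiguous & ~bad_amb).any():
            warnings.warn(
                f"probe {probe_id}: {int((ambiguous & ~bad_amb).sum())} "
                "strand-ambiguous SNP(s) retained (frequency-concordant)",
                stacklevel=2,
            )
        keep = ~bad_amb
    m = m.loc[keep]
    dfreq = dfreq[keep]

    freq_bad = dfreq > freq_qc
    qc.add_dropped(m.loc[freq_bad, "snp_id"], "freq_mismatch")
    m = m.loc[~freq_bad]

    snps = pd.DataFrame({
        "snp_id": m["snp_id"].astype(str),
        "chrom": m["chrom"].astype(str),
        "bp": m["bp"].astype(int),
        "a1": m["a1_eqtl"], "a2": m["a2_eqtl"],
        "freq_eqtl": m["freq_a1_eqtl"], "freq_gwas": m["freq_a1_gwas"],
        "b_zx": m["b_zx"], "se_zx": m["se_zx"], "p_eqtl": m["p_eqtl"],
        "b_zy": m["b_zy"], "se_zy": m["se_zy"], "p_gwas": m["p_gwas"],
        "n": m["n"],
    })
    snps = snps.sort_values(["chrom", "bp", "snp_id"], kind="mergesort")
    snps = snps.reset_index(drop=True)

    if snps.empty:
        top = None
    else:
        # instrument choice: smallest p_eqtl; ties broken by largest |z|,
        # then lexicographic snp_id, so output is deterministic
        order = snps.assign(absz=-(snps["b_zx"] / snps["se_zx"]).abs())
        order = order.sort_values(["p_eqtl", "absz", "snp_id"], kind="mergesort")
        top = int(order.index[0])

    return HarmonizedLocus(
        probe_id=probe_id, gene=str(meta["gene"]),
        probe_chrom=str(meta["probe_chrom"]), probe_bp=probe_bp,
        snps=snps, top_index=top, qc=qc,
    )


def _empty_snps() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "snp_id", "chrom", "bp", "a1", "a2", "freq_eqtl", "freq_gwas",
        "b_zx", "se_zx", "p_eqtl", "b_zy", "se_zy", "p_gwas", "n",
    ])
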