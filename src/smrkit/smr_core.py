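"""The SMR gene-trait association test.

Two-sample Mendelian randomization on summary statistics: a cis-eQTL is
the instrument Z, gene expression X the exposure, the GWAS trait Y the
outcome.  The Wald-ratio estimate of the expression-on-trait effect is

    b_XY = b_ZY / b_ZX

and the SMR test statistic combines the two marginal chi-squares,

    T_SMR = (z_GWAS^2 * z_eQTL^2) / (z_GWAS^2 + z_eQTL^2),

compared against a 1-df chi-square.  T_SMR is bounded above by the
smaller of the two marginal chi-squares, so P_SMR >= max(P_GWAS, P_eQTL):
a gene-trait association can never look stronger than the weaker of the
instrument's two component associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "SmrResult",
    "NullInstrumentError",
    "chi2_from_p",
    "p_from_chi2",
    "estimate_bxy",
    "smr_test",
    "bonferroni_threshold",
]


class NullInstrumentError(ValueError):
    """Raised when the instrument's eQTL effect is exactly zero (b_ZX = 0)."""


@dataclass(frozen=True)
class SmrResult:
    """Per-probe outcome of the SMR test."""

    probe_id: str
    gene: str
    top_snp_id: str
    b_xy: float
    se_xy: float
    t_smr: float
    p_smr: float
    p_eqtl_top: float
    p_gwas_top: float


def chi2_from_p(p):
    """1-df chi-square statistic equivalent to a two-sided p-value.

    Accurate down to p = 1e-300 (scipy's inverse survival function works
    in the extreme tail).  Accepts scalars or arrays; p must lie in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    out = stats.chi2.isf(p, df=1)
    return float(out) if out.ndim == 0 else out


def p_from_chi2(t):
    """Two-sided p-value for a 1-df chi-square statistic (survival function)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("chi-square statistic must be >= 0")
    out = stats.chi2.sf(t, df=1)
    return float(out) if out.ndim == 0 else out


def estimate_bxy(b_zy, se_zy, b_zx, se_zx):
    """Wald-ratio estimate b_XY = b_ZY / b_ZX with delta-method SE.

    se_XY = |b_XY| * sqrt(se_ZY^2/b_ZY^2 + se_ZX^2/b_ZX^2) to first order.
    At b_ZY = 0 the formula degenerates; the leading-order term se_ZY/|b_ZX|
    is returned instead so the output stays finite.

    Returns
    -------
    (b_xy, se_xy) : tuple of floats (or arrays, broadcasting elementwise).
    """
    b_zy = np.asarray(b_zy, dtype=float)
    se_zy = np.asarray(se_zy, dtype=float)
    b_zx = np.asarray(b_zx, dtype=float)
    se_zx = np.asarray(se_zx, dtype=float)
    if np.any(b_zx == 0):
        raise NullInstrumentError("b_ZX = 0: instrument has no expression effect")
    if np.any(se_zy <= 0) or np.any(se_zx <= 0):
        raise ValueError("standard errors must be > 0")
    b_xy = b_zy / b_zx
    with np.errstate(divide="ignore", invalid="ignore"):
        se_xy = np.abs(b_xy) * np.sqrt(
            (se_zy / b_zy) ** 2 + (se_zx / b_zx) ** 2
        )
    se_xy = np.where(b_zy == 0, se_zy / np.abs(b_zx), se_xy)
    if b_xy.ndim == 0:
        return float(b_xy), float(se_xy)
    return b_xy, se_xy


def smr_statistic(chi2_gwas, chi2_eqtl):
    """T_SMR from the two marginal 1-df chi-squares (vectorized)."""
    cg = np.asarray(chi2_gwas, dtype=float)
    ce = np.asarray(chi2_eqtl, dtype=float)
    denom = cg + ce
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, cg * ce / denom, 0.0)
    return float(t) if t.ndim == 0 else t


def smr_test(top_eqtl: Mapping, top_gwas: Mapping) -> SmrResult:
    """Run the SMR test at a probe's top cis-eQTL.

    Parameters
    ----------
    top_eqtl : mapping with keys probe_id, gene, snp_id, b_zx, se_zx, p_eqtl
        The instrument's expression association (alleles already harmonized
        with the GWAS record).
    top_gwas : mapping with keys snp_id, b_zy, se_zy, p_gwas
        The same SNP's trait association.

    The chi-squares entering T_SMR are derived from the p-values, so results
    printed to a few significant figures can be replayed exactly; when b/se
    are consistent with p the two routes agree to >=6 significant digits.
    """
    if top_eqtl["snp_id"] != top_gwas["snp_id"]:
        raise ValueError("instrument SNP differs between eQTL and GWAS records")
    p_eqtl = float(top_eqtl["p_eqtl"])
    p_gwas = float(top_gwas["p_gwas"])
    ce = chi2_from_p(p_eqtl)
    cg = chi2_from_p(p_gwas)
    t = smr_statistic(cg, ce)
    b_xy, se_xy = estimate_bxy(
        top_gwas["b_zy"], top_gwas["se_zy"], top_eqtl["b_zx"], top_eqtl["se_zx"]
    )
    return SmrResult(
        probe_id=str(top_eqtl.get("probe_id", "")),
        gene=str(top_eqtl.get("gene", "")),
        top_snp_id=str(top_eqtl["snp_id"]),
        b_xy=b_xy,
        se_xy=se_xy,
        t_smr=t,
        p_smr=p_from_chi2(t),
        p_eqtl_top=p_eqtl,
        p_gwas_top=p_gwas,
    )


def bonferroni_threshold(n_probes: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_probes."""
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_probes
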