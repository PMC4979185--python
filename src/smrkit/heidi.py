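"""The HEIDI test: heterogeneity in dependent instruments.

A significant SMR association can arise from a single variant affecting
both expression and trait (pleiotropy/causality) or from two distinct
causal variants in LD (linkage).  Under the single-variant null, b_XY
estimated at *any* cis-SNP associated with expression equals b_XY at the
top cis-eQTL; HEIDI tests for heterogeneity of these estimates.

For each member SNP i the difference d_i = b_XY(i) - b_XY(top) is formed.
The d_i are correlated both through LD (the b_ZX and b_ZY estimates at
linked SNPs are correlated with coefficient r_ij within each cohort) and
through the shared top-SNP term; a first-order delta-method covariance
accounts for both.  The statistic T_HEIDI = sum_i (d_i / sd(d_i))^2
follows a weighted sum of 1-df chi-squares under the null, with weights
equal to the eigenvalues of the d-correlation matrix; the tail is
evaluated by Imhof characteristic-function inversion (Satterthwaite
two-moment matching and a Monte-Carlo mode are available for
cross-validation).  Small P_HEIDI (< 0.05) indicates heterogeneity,
i.e. linkage, and the probe is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .ld_reference import LdMatrix
from .sumstats_io import HarmonizedLocus

__all__ = [
    "HeidiParams",
    "HeidiSnpSet",
    "HeidiResult",
    "select_heidi_snps",
    "zd_covariance",
    "weighted_chi2_sf",
    "heidi_test",
]

#: eQTL inclusion threshold for member SNPs: p < 1.6e-3, i.e. chi-square > 10
DEFAULT_P_INCLUSION = 1.6e-3


@dataclass
class HeidiParams:
    """Tunables of the HEIDI test; only p_incl has a canonical value."""

    p_incl: float = DEFAULT_P_INCLUSION
    r2_prune_high: float = 0.9
    r2_min_with_top: Optional[float] = None
    max_snps: Optional[int] = None
    min_snps: int = 3
    eig_rtol: float = 1e-8  # eigenvalues below eig_rtol * max are zeroed
    null_method: str = "imhof"  # or "satterthwaite" | "mc"
    mc_draws: int = 10 ** 6
    mc_seed: int = 0


@dataclass
class HeidiSnpSet:
    """Member SNPs entering HEIDI (positions into the locus table).

    ``top_index`` is the reference instrument; ``member_indices`` exclude
    it.  Every member has p_eqtl below the inclusion threshold.
    """

    top_index: int
    member_indices: list = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.member_indices)

    def all_indices(self) -> list:
        return [self.top_index] + list(self.member_indices)


@dataclass(frozen=True)
class HeidiResult:
    probe_id: str
    t_heidi: float
    p_heidi: Optional[float]
    nsnp_used: int
    status: str  # ok | too_few_snps | singular_ld


def select_heidi_snps(
    locus: HarmonizedLocus,
    ld: LdMatrix,
    p_incl: float = DEFAULT_P_INCLUSION,
    r2_prune_high: float = 0.9,
    r2_min_with_top: Optional[float] = None,
    max_snps: Optional[int] = None,
) -> HeidiSnpSet:
    """Choose the member SNPs for the heterogeneity test.

    Keep SNPs with p_eqtl < ``p_incl``; greedily drop the later-ranked SNP
    (rank = ascending p_eqtl, top SNP first) of any pair with r^2 >
    ``r2_prune_high``; optionally require r^2 >= ``r2_min_with_top``
    against the instrument; optionally truncate to the ``max_snps`` best
    by p_eqtl.  The top SNP is always retained as the reference.
    """
    snps = locus.snps
    top = locus.top_index
    if top is None:
        raise ValueError("locus has no SNPs")
    sub = ld.subset(snps["snp_id"].tolist())
    r2 = sub.r2()

    candidates = [i for i in range(len(snps))
                  if i != top and snps["p_eqtl"].iloc[i] < p_incl]
    # ascending p_eqtl with deterministic tie-break on snp_id
    candidates.sort(key=lambda i: (snps["p_eqtl"].iloc[i], snps["snp_id"].iloc[i]))

    kept: list[int] = []
    for i in candidates:
        if r2[i, top] > r2_prune_high:
            continue
        if any(r2[i, j] > r2_prune_high for j in kept):
            continue
        kept.append(i)

    if r2_min_with_top is not None:
        kept = [i for i in kept if r2[i, top] >= r2_min_with_top]
    if max_snps is not None:
        kept = kept[:max_snps]
    return HeidiSnpSet(top_index=top, member_indices=kept)


def _bxy_gradient_terms(snps, idx):
    """u_i = se_zy/b_zx and v_i = b_zy*se_zx/b_zx^2 at the given rows.

    First-order expansion of b_xy = b_zy/b_zx:
    delta b_xy = (1/b_zx) delta b_zy - (b_zy/b_zx^2) delta b_zx,
    so cov(b_xy_i, b_xy_j) = r_ij (u_i u_j + v_i v_j) with independent
    eQTL and GWAS cohorts (the same LD correlation r_ij applies to the
    sampling correlation of betas at linked SNPs within each cohort).
    """
    b_zx = snps["b_zx"].to_numpy()[idx]
    se_zx = snps["se_zx"].to_numpy()[idx]
    b_zy = snps["b_zy"].to_numpy()[idx]
    se_zy = snps["se_zy"].to_numpy()[idx]
    if np.any(b_zx == 0):
        raise ValueError("member SNP with b_zx = 0 cannot enter HEIDI")
    u = se_zy / b_zx
    v = b_zy * se_zx / b_zx ** 2
    return u, v


def zd_covariance(
    locus: HarmonizedLocus,
    snpset: HeidiSnpSet,
    ld: LdMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Delta-method covariance of d_i = b_xy_i - b_xy_top.

    Returns ``(corr, var)``: the correlation matrix of the standardized
    differences (unit diagonal) and the raw variances.  A non-positive
    variance signals a numerically singular LD configuration and raises
    ValueError; callers map it to status ``singular_ld``.
    """
    if snpset.n_members == 0:
        raise ValueError("empty HEIDI SNP set")
    snps = locus.snps
    idx = np.array(snpset.all_indices())
    sub = ld.subset(snps["snp_id"].iloc[idx].tolist())
    r = sub.r
    u, v = _bxy_gradient_terms(snps, idx)
    # cov(b_xy_i, b_xy_j) over the reference-then-members ordering
    c = r * (np.outer(u, u) + np.outer(v, v))
    # d_i = b_xy_i - b_xy_top: subtract the shared top-SNP row/column
    cm = c[1:, 1:]
    ct = c[0, 1:]
    cov_d = cm - ct[:, None] - ct[None, :] + c[0, 0]
    var = np.diag(cov_d).copy()
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        raise ValueError("non-positive variance of d: singular LD structure")
    denom = np.sqrt(np.outer(var, var))
    corr = cov_d / denom
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    return corr, var


def _satterthwaite_sf(t: float, lam: np.ndarray) -> float:
    s1, s2 = lam.sum(), (lam ** 2).sum()
    scale = s2 / s1
    df = s1 ** 2 / s2
    return float(stats.chi2.sf(t / scale, df=df))


def _imhof_sf(t: float, lam: np.ndarray) -> float:
    """Numerical inversion of the characteristic function (Imhof, 1961)."""
    from scipy import integrate

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * t * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=500)
    p = 0.5 + val / np.pi
    if p < 1e-6:
        # inversion accuracy is absolute (~1e-4); deep in the tail the
        # two-moment approximation has the better relative behaviour
        p = max(p, _satterthwaite_sf(t, lam))
    return float(min(max(p, 0.0), 1.0))


def weighted_chi2_sf(
    t: float,
    weights: Sequence[float],
    method: str = "imhof",
    mc_draws: int = 10 ** 6,
    seed: int = 0,
) -> float:
    """Survival probability of Q = sum_k lambda_k * chi2_1 at ``t``.

    ``imhof`` (default): numerical inversion of the characteristic
    function, accurate to ~1e-4 absolute across the whole distribution.
    ``satterthwaite``: two-moment matching to a scaled chi-square
    (scale = sum(l^2)/sum(l), df = (sum l)^2 / sum(l^2)) — cheap, but off
    by up to ~0.01 in the body for skewed weight vectors.  ``mc``:
    empirical tail over ``mc_draws`` draws, used to cross-validate the
    approximations.
    """
    lam = np.asarray(weights, float)
    if np.any(lam < 0):
        raise ValueError("weights must be >= 0")
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("all weights are zero")
    if t <= 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(t / lam[0], df=1))
    if method == "imhof":
        return _imhof_sf(t, lam)
    if method == "satterthwaite":
        return _satterthwaite_sf(t, lam)
    if method == "mc":
        rng = np.random.default_rng(seed)
        q = np.zeros(mc_draws)
        for lk in lam:  # loop keeps memory at O(draws) for long weight vectors
            q += lk * rng.standard_normal(mc_draws) ** 2
        # add-one tail estimate, never exactly zero
        return float((np.count_nonzero(q >= t) + 1) / (mc_draws + 1))
    raise ValueError(f"unknown method {method!r}")


def heidi_test(
    locus: HarmonizedLocus,
    ld: LdMatrix,
    params: Optional[HeidiParams] = None,
) -> HeidiResult:
    """Run the heterogeneity test at one probe.

    T_HEIDI = sum_i z_d_i^2 with z_d_i = d_i / sd(d_i); the null tail is
    a weighted chi-square with weights the eigenvalues of the
    d-correlation matrix.  Probes with fewer than ``min_snps`` members get
    status ``too_few_snps`` (p undefined); a degenerate LD structure gives
    ``singular_ld``.
    """
    params = params or HeidiParams()
    snpset = select_heidi_snps(
        locus, ld, p_incl=params.p_incl, r2_prune_high=params.r2_prune_high,
        r2_min_with_top=params.r2_min_with_top, max_snps=params.max_snps,
    )
    if snpset.n_members < params.min_snps:
        return HeidiResult(locus.probe_id, float("nan"), None,
                           snpset.n_members, "too_few_snps")

    snps = locus.snps
    idx = np.array(snpset.all_indices())
    b_zx = snps["b_zx"].to_numpy()[idx]
    b_zy = snps["b_zy"].to_numpy()[idx]
    b_xy = b_zy / b_zx
    d = b_xy[1:] - b_xy[0]

    try:
        corr, var = zd_covariance(locus, snpset, ld)
    except ValueError:
        return HeidiResult(locus.probe_id, float("nan"), None,
                           snpset.n_members, "singular_ld")

    z_d = d / np.sqrt(var)
    t_heidi = float((z_d ** 2).sum())
    lam = np.linalg.eigvalsh(corr)
    lam = np.where(lam < params.eig_rtol * lam.max(), 0.0, lam)
    p = weighted_chi2_sf(t_heidi, lam, method=params.null_method,
                         mc_draws=params.mc_draws, seed=params.mc_seed)
    return HeidiResult(locus.probe_id, t_heidi, min(p, 1.0),
                       snpset.n_members, "ok")
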