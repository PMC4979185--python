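"""Synthetic cohorts and summary-statistic fixtures.

Generates genotypes for three independent cohorts (eQTL study, GWAS,
LD reference panel) sharing one LD structure, phenotypes under three
generative models, and per-SNP summary statistics in the exact dialects
the IO modules consume.  The three models are

* causality:  Z -> X -> Y  (the SNP affects the trait through expression)
* pleiotropy: Z -> X and Z -> Y  (one variant, two direct effects)
* linkage:    Z1 -> X, Z2 -> Y with Z1, Z2 in LD  (two distinct variants)

Genotypes are drawn as two haplotypes per individual from a latent-Gaussian
threshold model with AR(1) correlation ``ld_decay`` between adjacent SNPs,
which yields smoothly decaying LD at controllable MAFs.  Expression is
standardized to unit variance analytically (the environmental noise SD is
chosen so var(X) = 1 given b_zx and the causal MAF), so effect sizes are in
"per expression SD" units and b_ZY = b_XY * b_ZX holds exactly under
causality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .ld_reference import GenotypeMatrix, write_dosage_tsv, write_plink
from .sumstats_io import P_FLOOR, write_eqtl_flat, write_gwas_ma

__all__ = [
    "SimScenario",
    "FixturePaths",
    "simulate_genotypes",
    "simulate_phenotypes",
    "summarize_cohort",
    "make_fixture",
]

MODELS = ("causality", "pleiotropy", "linkage")


@dataclass
class SimScenario:
    """One probe's generative model.

    Defaults mirror a well-powered blood-eQTL / GWAS setting: a strong top
    cis-eQTL (b_zx ~ 0.5 SD per allele, i.e. chi-square in the hundreds at
    n_eqtl = 5000) and a modest downstream trait effect detectable at
    n_gwas = 10000.
    """

    model: str = "causality"
    n_snps: int = 30
    maf: Optional[Union[float, Sequence[float]]] = None  # None -> U(0.1, 0.5)
    ld_decay: float = 0.8
    causal_index: Optional[int] = None  # default: middle SNP
    second_causal_index: Optional[int] = None  # linkage only; default +3
    b_zx_true: float = 0.5
    b_xy_true: float = 0.2
    b_zy_true: float = 0.1
    n_eqtl: int = 5000
    n_gwas: int = 10000
    n_ref: int = 500
    noise_sd_y: float = 1.0
    seed: int = 0
    probe_id: str = "probe1"
    gene: str = "GENE1"
    chrom: str = "1"
    probe_bp: int = 1_000_000
    snp_spacing: int = 2000
    snp_prefix: str = "rs"

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.causal_index is None:
            self.causal_index = self.n_snps // 2
        if self.model == "linkage" and self.second_causal_index is None:
            self.second_causal_index = min(self.causal_index + 3, self.n_snps - 1)
        for idx in filter(lambda i: i is not None,
                          (self.causal_index, self.second_causal_index)):
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal index {idx} out of range [0, {self.n_snps})")
        for name in ("n_eqtl", "n_gwas", "n_ref"):
            if getattr(self, name) < 30:
                raise ValueError(f"{name} must be >= 30")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must lie in [0, 1)")

    def resolved_maf(self) -> np.ndarray:
        """Per-SNP MAFs; drawn U(0.1, 0.5) from the scenario seed if unset."""
        if self.maf is None:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0]))
            return rng.uniform(0.1, 0.5, self.n_snps)
        maf = np.broadcast_to(np.asarray(self.maf, float), (self.n_snps,)).copy()
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError("MAFs must lie in (0, 0.5]")
        return maf

    def snp_meta(self) -> pd.DataFrame:
        bp = self.probe_bp + (np.arange(self.n_snps) - self.n_snps // 2) \
            * self.snp_spacing
        return pd.DataFrame({
            "snp_id": [f"{self.snp_prefix}{j + 1}" for j in range(self.n_snps)],
            "chrom": self.chrom, "bp": bp, "a1": "A", "a2": "G",
        })

    def expression_noise_sd(self) -> float:
        """Noise SD making var(X) = 1 under the scenario's causal effect."""
        p = self.resolved_maf()[self.causal_index]
        explained = self.b_zx_true ** 2 * 2 * p * (1 - p)
        if explained >= 1:
            raise ValueError("b_zx_true too large: explains >= 100% of var(X)")
        return float(np.sqrt(1.0 - explained))


def simulate_genotypes(scenario: SimScenario, cohort_size: int, seed) -> GenotypeMatrix:
    """Draw a cohort's genotypes: 2 haplotypes/individual, AR(1) latent LD."""
    rng = np.random.default_rng(seed)
    maf = scenario.resolved_maf()
    rho = scenario.ld_decay
    m = scenario.n_snps
    n_hap = 2 * cohort_size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1 - rho ** 2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    alleles = (z < stats.norm.ppf(maf)).astype(np.int8)
    dosages = (alleles[0::2] + alleles[1::2]).astype(float)
    sample_ids = [f"id{i + 1}" for i in range(cohort_size)]
    return GenotypeMatrix(sample_ids, scenario.snp_meta(), dosages)


def simulate_phenotypes(
    geno_eqtl: GenotypeMatrix,
    geno_gwas: GenotypeMatrix,
    scenario: SimScenario,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Expression for the eQTL cohort and trait for the GWAS cohort.

    The two cohorts' noise draws are independent; under causality the GWAS
    cohort carries its own (unobserved) expression realization.
    """
    rng = np.random.default_rng(seed)
    sd_x = scenario.expression_noise_sd()
    gc_x = geno_eqtl.dosages[:, scenario.causal_index]
    x = scenario.b_zx_true * gc_x + sd_x * rng.standard_normal(len(gc_x))

    gc_y = geno_gwas.dosages[:, scenario.causal_index]
    e_y = scenario.noise_sd_y * rng.standard_normal(geno_gwas.n_samples)
    if scenario.model == "causality":
        x_latent = scenario.b_zx_true * gc_y \
            + sd_x * rng.standard_normal(len(gc_y))
        y = scenario.b_xy_true * x_latent + e_y
    elif scenario.model == "pleiotropy":
        y = scenario.b_zy_true * gc_y + e_y
    else:  # linkage
        gc2_y = geno_gwas.dosages[:, scenario.second_causal_index]
        y = scenario.b_zy_true * gc2_y + e_y
    return x, y


def summarize_cohort(genotypes: GenotypeMatrix, phenotype: np.ndarray) -> pd.DataFrame:
    """Per-SNP simple linear regression of phenotype on dosage.

    Returns snp_id, chrom, bp, a1, a2, freq, b, se, p, n.  Two-sided p from
    the t statistic; underflows below 1e-300 are clamped.  Monomorphic SNPs
    are dropped with a warning.
    """
    y = np.asarray(phenotype, float)
    if len(y) != genotypes.n_samples:
        raise ValueError("phenotype length does not match cohort size")
    g = genotypes.dosages
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc ** 2).sum(axis=0)
    poly = sxx > 0
    if not poly.all():
        mono = [s for s, ok in zip(genotypes.snp_ids, poly) if not ok]
        warnings.warn(f"dropping monomorphic SNP(s): {mono}", stacklevel=2)
    sxy = gc.T @ yc
    syy = (yc ** 2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        resid_var = np.maximum(syy - slope * sxy, 0.0) / (n - 2)
        se = np.sqrt(resid_var / sxx)
        tstat = np.where(se > 0, slope / se, np.inf)
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, P_FLOOR, 1.0)
    out = pd.DataFrame({
        "snp_id": genotypes.snp_ids,
        "chrom": genotypes.snp_meta["chrom"].to_numpy(),
        "bp": genotypes.snp_meta["bp"].to_numpy(),
        "a1": genotypes.snp_meta["a1"].to_numpy(),
        "a2": genotypes.snp_meta["a2"].to_numpy(),
        "freq": g.mean(axis=0) / 2, "b": slope, "se": se, "p": p, "n": n,
    })
    return out.loc[poly].reset_index(drop=True)


def simulate_locus(scenario: SimScenario, seed=None):
    """One probe end to end, in memory.

    Returns (eqtl summary table, gwas summary table, reference
    GenotypeMatrix) with harmonizable canonical columns; the workhorse for
    simulation studies where file round-trips would dominate runtime.
    """
    seed = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(seed).spawn(4)
    geno_e = simulate_genotypes(scenario, scenario.n_eqtl, ss[0])
    geno_g = simulate_genotypes(scenario, scenario.n_gwas, ss[1])
    geno_r = simulate_genotypes(scenario, scenario.n_ref, ss[2])
    x, y = simulate_phenotypes(geno_e, geno_g, scenario, ss[3])

    eq = summarize_cohort(geno_e, x)
    eq = eq.rename(columns={"freq": "freq_a1", "b": "b_zx", "se": "se_zx",
                            "p": "p_eqtl"}).drop(columns="n")
    eq.insert(0, "probe_bp", scenario.probe_bp)
    eq.insert(0, "probe_chrom", scenario.chrom)
    eq.insert(0, "gene", scenario.gene)
    eq.insert(0, "probe_id", scenario.probe_id)

    gw = summarize_cohort(geno_g, y)
    gw = gw.rename(columns={"freq": "freq_a1", "b": "b_zy", "se": "se_zy",
                            "p": "p_gwas"}).drop(columns=["chrom", "bp"])
    return eq, gw, geno_r


@dataclass
class FixturePaths:
    gwas: Path
    eqtl: Path
    dosage_tsv: Path
    plink_prefix: Path
    gws_hits: Path
    truth: Path


def make_fixture(
    scenarios: Union[SimScenario, Sequence[SimScenario]],
    out_dir,
    seed: int = 0,
) -> FixturePaths:
    """Write a multi-probe fixture: GWAS .ma, eQTL TSV, reference panel
    (dosage TSV + PLINK triplet), GWS-hit list and truth JSON.

    Each scenario becomes one probe on its own chromosome so loci are
    independent; per-probe sub-seeds are spawned from ``seed``.  The
    GWS-hit list records the most significant SNP of every locus reaching
    p < 5e-8 in the simulated GWAS, emulating the primary GWAS paper's
    reported hits.
    """
    if isinstance(scenarios, SimScenario):
        scenarios = [scenarios]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(scenarios)) \
        % (2 ** 31)

    eqtl_parts, gwas_parts, truth, hits = [], [], [], []
    ref_parts = []
    for i, base in enumerate(scenarios):
        sc = SimScenario(**{**asdict(base),
                            "chrom": str(i + 1),
                            "snp_prefix": f"rs{i + 1}_",
                            "seed": int(child_seeds[i])})
        eq, gw, geno_r = simulate_locus(sc)
        eqtl_parts.append(eq)
        gwas_parts.append(gw)
        ref_parts.append(geno_r)
        truth.append({
            "probe_id": sc.probe_id, "gene": sc.gene, "model": sc.model,
            "chrom": sc.chrom, "probe_bp": sc.probe_bp,
            "b_zx_true": sc.b_zx_true, "b_xy_true": sc.b_xy_true,
            "b_zy_true": sc.b_zy_true,
            "causal_snp": sc.snp_meta()["snp_id"][sc.causal_index],
            "second_causal_snp": (
                None if sc.second_causal_index is None
                else sc.snp_meta()["snp_id"][sc.second_causal_index]),
            "n_eqtl": sc.n_eqtl, "n_gwas": sc.n_gwas, "n_ref": sc.n_ref,
            "seed": sc.seed,
        })
        gws = eq[["snp_id", "chrom", "bp"]].copy()
        gws["p"] = gw.set_index("snp_id").loc[gws["snp_id"], "p_gwas"].to_numpy()
        gws = gws.loc[gws["p"] < 5e-8].sort_values("p")
        if len(gws):
            hits.append(gws.iloc[0][["snp_id", "chrom", "bp"]])

    ref = GenotypeMatrix(
        ref_parts[0].sample_ids,
        pd.concat([g.snp_meta for g in ref_parts], ignore_index=True),
        np.hstack([g.dosages for g in ref_parts]),
    )

    paths = FixturePaths(
        gwas=out_dir / "gwas.ma", eqtl=out_dir / "eqtl.tsv",
        dosage_tsv=out_dir / "ref_panel.tsv",
        plink_prefix=out_dir / "ref_panel",
        gws_hits=out_dir / "gws_hits.tsv", truth=out_dir / "truth.json",
    )
    write_gwas_ma(pd.concat(gwas_parts, ignore_index=True), paths.gwas)
    write_eqtl_flat(pd.concat(eqtl_parts, ignore_index=True), paths.eqtl)
    write_dosage_tsv(ref, paths.dosage_tsv)
    write_plink(ref, paths.plink_prefix)
    hits_df = pd.DataFrame(hits, columns=["snp_id", "chrom", "bp"])
    hits_df.rename(columns={"chrom": "chr"}).to_csv(
        paths.gws_hits, sep="\t", index=False)
    with open(paths.truth, "w") as fh:
        json.dump({"seed": seed, "probes": truth}, fh, indent=1)
    return paths
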