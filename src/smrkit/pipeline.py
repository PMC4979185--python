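"""Transcriptome-wide SMR screen: orchestration, thresholds, annotation.

For every probe with a qualifying instrument (top cis-eQTL at
p_eqtl < 5e-8) the SMR test is run; probes passing the Bonferroni
threshold alpha / n_probes_tested get the HEIDI test; retained hits
(P_HEIDI >= 0.05) can be annotated for novelty against a list of
genome-wide-significant GWAS SNPs and aggregated across traits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .heidi import HeidiParams, heidi_test
from .ld_reference import GenotypeMatrix, compute_ld
from .smr_core import bonferroni_threshold, estimate_bxy, smr_test
from .sumstats_io import harmonize

__all__ = [
    "ScreenConfig",
    "RESULT_COLUMNS",
    "run_screen",
    "filter_significant",
    "annotate_novelty",
    "cross_trait_summary",
    "funnel_counts",
    "read_gws_hits",
]

#: per-probe outcome codes, in funnel order
STATUS_CODES = ["no_instrument", "smr_not_sig", "heidi_rejected",
                "heidi_undefined", "retained"]

RESULT_COLUMNS = [
    "probe_id", "gene", "probe_chr", "probe_bp", "trait", "top_snp",
    "a1", "a2", "freq", "b_eqtl", "se_eqtl", "p_eqtl",
    "b_gwas", "se_gwas", "p_gwas", "b_xy", "se_xy", "p_smr",
    "p_heidi", "nsnp_heidi", "heidi_status", "status",
]


@dataclass
class ScreenConfig:
    """Thresholds and windows of the screen.

    ``n_tests`` overrides the Bonferroni denominator (normally the number
    of probes with a qualifying instrument in this run) so published
    full-scale denominators can be replayed on subsets.
    """

    instrument_p_max: float = 5e-8
    alpha: float = 0.05
    heidi_alpha: float = 0.05
    cis_window: int = 1_000_000
    novelty_window: int = 1_000_000
    freq_qc: float = 0.2
    n_tests: Optional[int] = None
    heidi: HeidiParams = field(default_factory=HeidiParams)

    def __post_init__(self):
        for name in ("instrument_p_max", "alpha", "heidi_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.cis_window <= 0 or self.novelty_window <= 0:
            raise ValueError("windows must be > 0")

    def manifest(self, seed=None) -> dict:
        d = asdict(self)
        return {"config": d, "smrkit_version": __version__, "seed": seed}


def run_screen(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    ld_panel: GenotypeMatrix,
    config: Optional[ScreenConfig] = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Screen every probe of one trait; one output row per probe.

    Probes whose top cis-eQTL misses ``instrument_p_max`` are reported
    with status ``no_instrument`` and excluded from the Bonferroni
    denominator.  HEIDI runs only for probes with
    p_smr < alpha / n_probes_tested.  Per-probe failures are recorded in
    the status column, never aborting the run.  Row order is
    deterministic: (probe_id, trait).
    """
    config = config or ScreenConfig()
    rows = []
    loci = {}
    for probe_id in sorted(eqtl["probe_id"].unique()):
        locus = harmonize(gwas, eqtl, probe_id,
                          cis_window=config.cis_window, freq_qc=config.freq_qc)
        row = {c: np.nan for c in RESULT_COLUMNS}
        row.update(probe_id=probe_id, gene=locus.gene,
                   probe_chr=locus.probe_chrom, probe_bp=locus.probe_bp,
                   trait=trait, heidi_status="", status="no_instrument",
                   nsnp_heidi=0)
        if not locus.is_empty:
            top = locus.top
            row.update(top_snp=top["snp_id"], a1=top["a1"], a2=top["a2"],
                       freq=top["freq_eqtl"], b_eqtl=top["b_zx"],
                       se_eqtl=top["se_zx"], p_eqtl=top["p_eqtl"],
                       b_gwas=top["b_zy"], se_gwas=top["se_zy"],
                       p_gwas=top["p_gwas"])
            if top["p_eqtl"] < config.instrument_p_max:
                res = smr_test(
                    {"probe_id": probe_id, "gene": locus.gene,
                     "snp_id": top["snp_id"], "b_zx": top["b_zx"],
                     "se_zx": top["se_zx"], "p_eqtl": top["p_eqtl"]},
                    {"snp_id": top["snp_id"], "b_zy": top["b_zy"],
                     "se_zy": top["se_zy"], "p_gwas": top["p_gwas"]},
                )
                row.update(b_xy=res.b_xy, se_xy=res.se_xy, p_smr=res.p_smr,
                           status="smr_not_sig")
                loci[probe_id] = locus
        rows.append(row)

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    tested = results["status"] != "no_instrument"
    n_tested = int(tested.sum())
    if n_tested == 0:
        warnings.warn("no probe has a qualifying instrument; empty screen",
                      stacklevel=2)
        return results
    threshold = bonferroni_threshold(config.n_tests or n_tested, config.alpha)
    results.attrs["n_probes_tested"] = n_tested
    results.attrs["smr_threshold"] = threshold

    for i, row in results.iterrows():
        if row["status"] == "no_instrument" or not row["p_smr"] < threshold:
            continue
        locus = loci[row["probe_id"]]
        try:
            ld = compute_ld(ld_panel, locus.snps["snp_id"].tolist(),
                            dict(zip(locus.snps["snp_id"], locus.snps["a1"])))
        except KeyError:
            results.loc[i, ["heidi_status", "status"]] = \
                ("panel_missing_snps", "heidi_undefined")
            continue
        hres = heidi_test(locus, ld, config.heidi)
        results.loc[i, "nsnp_heidi"] = hres.nsnp_used
        results.loc[i, "heidi_status"] = hres.status
        if hres.status != "ok":
            results.loc[i, "status"] = "heidi_undefined"
        else:
            results.loc[i, "p_heidi"] = hres.p_heidi
            results.loc[i, "status"] = (
                "retained" if hres.p_heidi >= config.heidi_alpha
                else "heidi_rejected")
    return results.sort_values(["probe_id", "trait"],
                               kind="mergesort").reset_index(drop=True)


def filter_significant(results: pd.DataFrame,
                       config: Optional[ScreenConfig] = None) -> pd.DataFrame:
    """Rows passing both the SMR Bonferroni screen and HEIDI retention.

    Retention keeps p_heidi >= heidi_alpha (the boundary counts as
    retained).  Rows where HEIDI was undefined are excluded; their count
    is exposed as ``attrs['n_heidi_undefined']``.
    """
    config = config or ScreenConfig()
    threshold = results.attrs.get(
        "smr_threshold",
        bonferroni_threshold(
            config.n_tests
            or max(int((results["status"] != "no_instrument").sum()), 1),
            config.alpha))
    smr_sig = results["p_smr"] < threshold
    retained = smr_sig & (results["p_heidi"] >= config.heidi_alpha)
    out = results.loc[retained.fillna(False)].reset_index(drop=True)
    out.attrs["n_heidi_undefined"] = int(
        (smr_sig & results["p_heidi"].isna()).sum())
    out.attrs["smr_threshold"] = threshold
    return out


def funnel_counts(results: pd.DataFrame) -> dict:
    """Audit counts of the screen funnel, keyed by status code."""
    counts = results["status"].value_counts().to_dict()
    return {code: int(counts.get(code, 0)) for code in STATUS_CODES}


def read_gws_hits(path) -> pd.DataFrame:
    """Read a user-supplied list of genome-wide-significant GWAS SNPs
    (TSV with header ``snp_id chr bp``)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chr": str})
    for col in ("snp_id", "chr", "bp"):
        if col not in df.columns:
            raise ValueError(f"GWS-hit table {path} missing column {col!r}")
    return df


def annotate_novelty(results: pd.DataFrame, gws_hits: pd.DataFrame,
                     window: int = 1_000_000) -> pd.DataFrame:
    """Flag probes with no known GWS SNP within ``window`` bp (closed
    interval, same chromosome) of the probe position as novel."""
    out = results.copy()
    chrom = gws_hits["chr"].astype(str).to_numpy()
    bp = gws_hits["bp"].to_numpy()

    def is_novel(row):
        near = (chrom == str(row["probe_chr"])) & \
            (np.abs(bp - int(row["probe_bp"])) <= window)
        return not near.any()

    out["novel"] = [is_novel(r) for _, r in out.iterrows()] \
        if len(out) else pd.Series(dtype=bool)
    return out


def cross_trait_summary(per_trait: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes retained for two or more traits.

    ``per_trait`` maps trait label -> filtered results table.  Returns one
    row per shared gene with the sorted trait list, ordered by gene.
    """
    if len(per_trait) < 2:
        raise ValueError("cross-trait summary needs >= 2 trait tables")
    gene_traits: dict[str, set] = {}
    for trait, table in per_trait.items():
        for gene in table["gene"].unique():
            gene_traits.setdefault(gene, set()).add(trait)
    rows = [{"gene": g, "traits": ",".join(sorted(ts)), "n_traits": len(ts)}
            for g, ts in sorted(gene_traits.items()) if len(ts) >= 2]
    return pd.DataFrame(rows, columns=["gene", "traits", "n_traits"])


def write_manifest(path, config: ScreenConfig, seed=None) -> None:
    with open(path, "w") as fh:
        json.dump(config.manifest(seed=seed), fh, indent=1, default=str)
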