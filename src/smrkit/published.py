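"""Reference rows from a published whole-blood transcriptome-wide SMR screen.

Each row is a novel gene-trait association reported with the instrument's
eQTL and GWAS p-values alongside the SMR and HEIDI p-values (all printed
to two significant figures).  Because T_SMR is a function of the two
marginal chi-squares alone, the printed (P_eQTL, P_GWAS) pairs can be
replayed through the test and the resulting P_SMR compared with the
printed one — an end-to-end check of the statistic on real screen output.

Rows whose P_eQTL was printed only as an upper bound ("<1.0E-300") carry
``p_eqtl=None`` and cannot be replayed exactly.
"""

#: (trait, probe_id, gene, top_snp, p_eqtl, p_gwas, p_smr, p_heidi, nsnp)
NOVEL_GENE_ROWS = [
    ("BIP1", "ILMN_1665280", "SPCS1", "rs998909", 2.1e-39, 6.8e-7, 3.4e-6, 0.15, 155),
    ("CAD", "ILMN_1713380", "EIF2B2", "rs175016", 1.8e-278, 4.7e-6, 5.6e-6, 0.23, 189),
    ("CAD", "ILMN_1712430", "ATP5G1", "rs1962412", 1.3e-44, 7.4e-7, 3.0e-6, 0.27, 127),
    ("CD", "ILMN_1718852", "PLCL1", "rs2117339", 6.7e-30, 8.0e-7, 6.0e-6, 0.14, 216),
    ("CD", "ILMN_2122952", "CISD1", "rs1199098", None, 1.5e-6, 1.7e-6, 0.17, 241),
    ("CD", "ILMN_2122953", "CISD1", "rs1550773", None, 2.0e-6, 2.2e-6, 0.13, 217),
    ("COLLEGE", "ILMN_1723684", "DARC", "rs12075", 4.8e-107, 3.3e-6, 5.4e-6, 0.47, 110),
    ("EDUYEARS", "ILMN_1718023", "APEH", "rs3197999", 1.1e-27, 5.7e-7, 5.5e-6, 0.08, 88),
    ("EDUYEARS", "ILMN_2343048", "ABCB9", "rs1615350", 9.1e-43, 2.0e-6, 7.2e-6, 0.75, 53),
    ("EDUYEARS", "ILMN_1738369", "TUFM", "rs8049439", None, 1.5e-7, 1.7e-7, 0.11, 37),
    ("HDL", "ILMN_1684227", "GPR146", "rs1997243", 2.2e-300, 2.4e-7, 3.1e-7, 0.22, 130),
    ("IBD", "ILMN_1697409", "TNFRSF14", "rs734999", 2.1e-90, 2.3e-7, 5.4e-7, 0.98, 64),
    ("IBD", "ILMN_1727709", "GPBAR1", "rs2292550", 8.3e-43, 6.3e-8, 4.9e-7, 0.24, 109),
    ("IBD", "ILMN_1684628", "ZFP90", "rs1182968", None, 3.3e-6, 3.6e-6, 0.90, 311),
    ("LDL", "ILMN_1718706", "ERAL1", "rs901975", 6.5e-46, 2.2e-6, 6.9e-6, 0.19, 66),
    ("UC", "ILMN_1744713", "PARK7", "rs3766606", 1.1e-53, 5.7e-8, 3.0e-7, 0.09, 195),
    ("UC", "ILMN_1727709", "GPBAR1", "rs2292550", 8.3e-43, 1.2e-7, 8.1e-7, 0.12, 109),
    ("UC", "ILMN_1683811", "TNPO3", "rs3807306", 1.4e-150, 2.3e-6, 3.3e-6, 0.69, 125),
]

#: number of expression probes tested in the published screen; its
#: Bonferroni threshold 0.05/5967 rounds to 8.4e-6
N_PROBES_PUBLISHED = 5967


def replayable_rows():
    """Rows with a finite printed P_eQTL, usable for exact replay."""
    return [r for r in NOVEL_GENE_ROWS if r[4] is not None]
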