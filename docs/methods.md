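# Methods

## The SMR test

For one expression probe, let b_ZX (SE s_ZX) be the top cis-eQTL's effect
on expression and b_ZY (SE s_ZY) the same SNP's effect on the trait,
estimated in two independent cohorts. The Wald ratio b_XY = b_ZY/b_ZX
estimates the effect of expression on the trait under the instrumental
variable assumptions; its delta-method SE is
|b_XY|·√(s_ZY²/b_ZY² + s_ZX²/b_ZX²), with the degenerate b_ZY = 0 case
defined as s_ZY/|b_ZX| (the leading-order term) so output stays finite.

The test statistic is T_SMR = z_Y²z_X²/(z_Y² + z_X²) where z² are the
marginal 1-df chi-squares, referred to χ²₁. We derive z² from the
p-values (χ²₁ inverse survival function) rather than from (b/se)²: the
two routes agree to at least 6 significant digits on consistent input,
but the p-value route also works when only rounded published p-values
are available, which is how the replay validation in
`smrkit.published` operates. T_SMR ≤ min(z_Y², z_X²), hence
P_SMR ≥ max(P_GWAS, P_eQTL) always — this bound is enforced as a
property test.

## The HEIDI test

Member SNPs are the cis-SNPs with p_eQTL < 1.6×10⁻³ (χ² > 10), pruned so
that no retained pair (including the top SNP) has r² > 0.9 — the
later-ranked SNP by ascending p_eQTL is dropped — with optional
r²-with-top and count caps (both off by default). At least 3 members are
required, otherwise the probe is reported `too_few_snps` with p
undefined.

For member i, d_i = b_XY(i) − b_XY(top). Writing the first-order
expansion δb_XY = δb_ZY/b_ZX − (b_ZY/b_ZX²)δb_ZX and using that betas at
linked SNPs within one cohort have sampling correlation r_ij (the LD
correlation, estimated from the reference panel) while the two cohorts
are independent,

    cov(b_XY_i, b_XY_j) = r_ij (u_i u_j + v_i v_j),
    u_i = s_ZY,i / b_ZX,i,   v_i = b_ZY,i s_ZX,i / b_ZX,i²,

and cov(d_i, d_j) follows by subtracting the shared top-SNP row/column
and adding its variance. This matrix is validated entrywise against the
empirical covariance of 20,000 direct draws of the summary statistics at
a fixed locus (within 3 Monte-Carlo standard errors).

T_HEIDI = Σ z_d,i² with z_d,i = d_i/sd(d_i). Under the null, z_d is
multivariate normal with correlation matrix R, so T_HEIDI is distributed
as Σ λ_k χ²₁ with λ the eigenvalues of R (eigenvalues below 1e-8 × max
are truncated to zero for numerical stability). Probes with
P_HEIDI < 0.05 are rejected as linkage; the boundary 0.05 counts as
retained.

### Null tail evaluation

The default tail evaluator is Imhof's characteristic-function inversion
(numerical quadrature), accurate to ~1e-4 absolute across the whole
distribution; below p = 1e-6 the Satterthwaite value is used as a floor
because quadrature accuracy is absolute while two-moment matching has
the better relative tail behaviour. Satterthwaite two-moment matching
(scale Σλ²/Σλ, df (Σλ)²/Σλ²) and a 10⁶-draw Monte-Carlo mode are kept as
alternatives; we measured the two-moment approximation to deviate from
Monte-Carlo by up to ~0.012 in the distribution body for skewed weight
vectors, which is why it is not the default — decisions at the 0.05
boundary would be distorted by more than the Monte-Carlo error itself.
The default-vs-Monte-Carlo agreement (< 0.005 absolute for p ≥ 0.01) is
asserted over a fixed grid of weight vectors in the test suite.

## Harmonization and QC

Records are keyed by SNP id; the GWAS record is re-oriented to the eQTL
effect allele (beta sign flip + frequency complement when the allele
pair is swapped), allele-set mismatches are dropped, and records with
|freq_eQTL − freq_GWAS| > 0.2 (configurable) are dropped. Strand-
ambiguous SNPs (A/T, C/G) are retained with a warning while the
frequency difference is < 0.2, or dropped wholesale in `drop_ambiguous`
mode; ambiguous-SNP policy and the frequency threshold are defaults, not
canon. p-values stored as 0 (printed "<1e-300" upstream) are clamped to
1e-300 and flagged, keeping chi-square quantiles finite. The cis window
is ±1 Mb around the probe position, closed interval, 1-based
coordinates. Ties for the top eQTL are broken by largest |b/se| then
lexicographic SNP id, making every output deterministic. All drops are
itemized with reason codes in a QC report.

## LD reference

LD is the pairwise-complete Pearson correlation of dosage columns,
signed with respect to the harmonized effect alleles (panel columns
whose a1 differs are flipped as 2 − dosage). Missing genotypes are
excluded pairwise rather than mean-imputed — simpler to verify and
adequate at reference-panel scale; monomorphic SNPs are excluded with a
warning. Near-singular LD is handled downstream by the HEIDI pruning and
eigenvalue truncation, not here. Panels load from PLINK1
.bed/.bim/.fam (SNP-major, 2-bit codec implemented in
`ld_reference`) or from a plain dosage TSV; the two formats are
cross-checked against each other in the tests.

## The screen

Per trait: every probe's top cis-eQTL must reach p_eQTL < 5×10⁻⁸ to
qualify as an instrument; the Bonferroni threshold is
α / n_probes_tested with n recomputed per run (a `--n-tests` override
allows replaying a published denominator such as 5967); HEIDI runs only
on probes below that threshold. Each probe carries one of the status
codes `no_instrument`, `smr_not_sig`, `heidi_rejected`,
`heidi_undefined`, `retained`, so the screen funnel is auditable and is
checked against an independent re-application of the three thresholds.
Novelty means no known genome-wide-significant SNP (user-supplied list)
within a closed ±1 Mb window of the probe position on the same
chromosome; the window is measured from the probe midpoint and is
configurable. Cross-trait aggregation reports genes retained for ≥ 2
traits. Each trait is processed independently; removing one trait
cannot change another's rows.

## Synthetic data

The generator emulates two independent cohorts plus a reference panel
sharing one LD structure. Genotypes: two haplotypes per individual from
a latent-Gaussian threshold model with AR(1) correlation `ld_decay`
between adjacent SNPs (default 0.8), thresholded at Φ⁻¹(MAF); MAFs
default to U(0.1, 0.5). This gives smoothly decaying LD at controllable
frequencies without needing a haplotype map; note the genotype-scale
correlation is attenuated relative to the latent AR(1) parameter
(tetrachoric-type attenuation), e.g. latent 0.8³ ≈ 0.51 between SNPs
three apart yields genotype r ≈ 0.3.

Phenotypes: expression x = b_ZX·g_c + e with the noise SD chosen
analytically so var(x) = 1 given b_ZX and the causal MAF — effect sizes
are thus in per-expression-SD units and b_ZY = b_XY·b_ZX holds exactly
under causality, which makes the recovery oracle unbiased. Under
causality the GWAS cohort carries its own unobserved expression
realization; under pleiotropy the SNP affects the trait directly; under
linkage a second SNP (default 3 positions away) drives the trait.
Sub-seeds for the three cohorts are spawned from one master seed, so
fixtures are byte-identical under a fixed seed and cohort noise vectors
are independent by construction.

Defaults (n_eqtl = 5000, n_gwas = 10,000, n_ref = 500, b_ZX = 0.5,
b_XY = 0.2, b_ZY = 0.1, 30 SNPs per locus) represent a well-powered
blood-eQTL study paired with a moderate GWAS: the top eQTL chi-square is
in the hundreds and the trait signal is just past genome-wide
significance, the regime the screen is designed for.

What the simulation does *not* emulate: real human haplotype structure,
allele-frequency spectra, case-control (liability-threshold) traits,
population stratification, or overlapping cohorts. Passing tests
therefore demonstrate the statistics are computed and calibrated
correctly under the stated models, not robustness to those real-data
complications.

## Simulation sizes used in tests and the acceptance script

Calibration studies shrink cohorts to n_eqtl = 3000 / n_gwas = 5000 /
n_ref = 500, which keeps instruments strong (the regime where the
delta-method null is accurate) while letting thousands of replicates
run: HEIDI type-I error is estimated from 2000 pleiotropy replicates and
linkage power from 150–200 replicates. Wald-ratio recovery uses 200
seeds at n = 10,000 in both cohorts with 3-SNP loci. The
null-uniformity check of P_SMR uses 2000 replicates at n = 2000.
Measured outcomes at these sizes: type-I ≈ 0.03–0.05 across seed
streams (slightly conservative, consistent with the delta-method
variance being an overestimate at members barely past the inclusion
chi-square), linkage power ≈ 0.60–0.65, recovery bias ≈ 0.002.

## Known limitations

- Single-instrument MR only: no IVW/Egger multi-instrument estimators,
  no causality-vs-pleiotropy distinction (impossible with cis-eQTLs
  alone).
- The delta-method HEIDI covariance assumes reasonably strong member
  eQTLs; with members barely past χ² = 10 the ratio b_ZY/b_ZX is noisy
  and the normal approximation degrades.
- The published HEIDI p-values in `smrkit.published` are not replayed:
  they depend on the full per-SNP summary data and the original
  software's weighted-sum approximation and SNP handling, which are not
  fully specified by the published screen output. The published `nsnp`
  column's definition (HEIDI members vs all cis-SNPs tested) is also
  ambiguous; this package reports its own HEIDI member count.
- The PLINK reader supports SNP-major PLINK1 .bed only (no .pgen).
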