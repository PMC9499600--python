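"""Published Taiwan Biobank PCSK9 summary statistics.

These are the published per-variant summary statistics for the seven PCSK9
variants independently associated with LDL-C in 75,441 Taiwan Biobank
participants, together with the weighted-genetic-risk-score (WGRS)
regression coefficients used in the two-stage least-squares Mendelian
randomization of LDL-C against prevalent diabetes.  Individual-level data
are not publicly deposited; these printed summaries parameterise the
synthetic-cohort generator and serve as inputs for summary-level analyses.

Per-variant effects (``beta``) are per alternate allele on log10 LDL-C,
adjusted for age, sex, BMI and current smoking.  ``genotype_counts`` are
(hom-ref, het, hom-alt); ``ldl_cell_means`` are untransformed mg/dL means
per genotype class (None where no carriers of that class were observed).
"""

from __future__ import annotations

#: analysed cohort size after QC
N_COHORT = 75_441

#: overall LDL-C distribution (mg/dL) the cohort emulates
LDL_MEAN_MGDL = 120.9
LDL_SD_MGDL = 31.0

#: SD of log10 LDL-C implied by the lognormal approximation of the above
LDL_LOG10_SD = 0.11

#: mg/dL per mmol/L of LDL cholesterol
MMOL_TO_MGDL = 38.67

PCSK9_VARIANTS = [
    dict(id="rs10788994", chrom="1", pos=55_500_976, ref="C", alt="T",
         annotation="intergenic:BSND;PCSK9",
         maf=0.3475, beta=-0.0047, se=0.0006,
         genotype_counts=(31_728, 33_743, 9_015),
         ldl_cell_means=(121.80, 120.41, 119.23),
         hwe_p=0.7616,
         stepwise_r2_tc=0.0007, stepwise_r2_ldl=0.0009),
    dict(id="rs151193009", chrom="1", pos=55_509_585, ref="C", alt="T",
         annotation="exon2:c.C277T:p.R93C",
         maf=0.0027, beta=-0.0579, se=0.0057,
         genotype_counts=(73_449, 405, 0),
         ldl_cell_means=(120.98, 106.76, None),
         hwe_p=0.4419,
         stepwise_r2_tc=0.0013, stepwise_r2_ldl=0.0014),
    dict(id="rs557211", chrom="1", pos=55_514_215, ref="T", alt="G",
         annotation="intronic",
         maf=0.1916, beta=-0.0052, se=0.0007,
         genotype_counts=(49_044, 23_300, 2_740),
         ldl_cell_means=(121.42, 119.81, 119.30),
         hwe_p=0.8433,
         stepwise_r2_tc=0.0001, stepwise_r2_ldl=0.0001),
    dict(id="rs768846693", chrom="1", pos=55_518_412, ref="C", alt="A",
         annotation="exon5:c.C747A:p.S249R",
         maf=0.0004, beta=-0.1301, se=0.0143,
         genotype_counts=(75_324, 63, 0),
         ldl_cell_means=(120.88, 91.73, None),
         hwe_p=0.9078,
         stepwise_r2_tc=0.0006, stepwise_r2_ldl=0.0011),
    dict(id="rs757143429", chrom="1", pos=55_523_828, ref="C", alt="T",
         annotation="exon8:c.C1300T:p.R434W",
         maf=0.0011, beta=-0.0509, se=0.0086,
         genotype_counts=(75_239, 175, 0),
         ldl_cell_means=(120.89, 107.81, None),
         hwe_p=0.7454,
         stepwise_r2_tc=0.0004, stepwise_r2_ldl=0.0005),
    dict(id="rs565436", chrom="1", pos=55_524_601, ref="G", alt="A",
         annotation="intronic",
         maf=0.1033, beta=-0.0067, se=0.0010,
         genotype_counts=(60_123, 13_901, 780),
         ldl_cell_means=(121.22, 119.41, 118.19),
         hwe_p=0.3577,
         stepwise_r2_tc=0.0005, stepwise_r2_ldl=0.0005),
    dict(id="rs505151", chrom="1", pos=55_529_187, ref="G", alt="A",
         annotation="exon12:c.G2009A:p.G670E",
         maf=0.0534, beta=0.0065, se=0.0013,
         genotype_counts=(67_530, 7_603, 215),
         ldl_cell_means=(119.0, 120.00, 121.00),
         hwe_p=0.9202,
         stepwise_r2_tc=0.0002, stepwise_r2_ldl=0.0003),
]

#: the three rare loss-of-function coding variants (MAF < 0.01)
RARE_VARIANT_IDS = ("rs151193009", "rs768846693", "rs757143429")

#: published MR regression coefficients for the 7-variant PCSK9 WGRS
#: (log10 LDL-C exposure, prevalent diabetes outcome; adjusted estimates)
WGRS_PCSK9_7SNV = dict(
    observational=dict(beta=-1.9993, se=0.1185),   # DM ~ log10 LDL-C
    first_stage=dict(beta=0.5599, se=0.0301),      # log10 LDL-C ~ WGRS
    reduced_form=dict(beta=-2.3685, se=0.8918),    # DM ~ WGRS
    iv=dict(beta=-4.2294, se=1.5926),              # two-stage estimate
)

#: same coefficients for the genome-wide 41-variant LDL-C WGRS
WGRS_LDL_41SNV = dict(
    observational=dict(beta=-1.9993, se=0.1185),
    first_stage=dict(beta=0.9823, se=0.0202),
    reduced_form=dict(beta=-1.9743, se=0.6972),
    iv=dict(beta=-1.9710, se=0.6961),
)

#: published observational association of LDL-C with diabetes
OBSERVATIONAL_OR = dict(per_mmol=0.78, per_mgdl=0.99)

#: causal (IV) log-odds of diabetes per unit log10 LDL-C; the generator's
#: default structural parameter
THETA_CAUSAL = WGRS_PCSK9_7SNV["iv"]["beta"]
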