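"""Synthetic cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: Hardy-Weinberg genotypes at specified minor-allele frequencies
(optionally correlated within LD blocks via a latent Gaussian copula),
a lognormal LDL-C distribution with additive per-allele genetic effects on
the log10 scale, covariates (age, sex, BMI, smoking), an unobserved
confounder loading on both LDL-C and diabetes, and diabetes drawn from a
logistic model in which LDL-C mediates the genetic effect:

    log10(LDL) = log10(mu) + sum_j beta_j g_j + covariate terms + c*U + eps
    logit P(DM) = b0 + theta * log10(LDL) + c_dm * U

Defaults emulate the Taiwan Biobank PCSK9 analysis: the seven published
variants (MAF 0.0004-0.35, per-allele log10-LDL effects -0.13 to +0.0065),
LDL-C 120.9 +/- 31 mg/dL, causal log-odds theta = -4.2294 per unit log10
LDL-C, and confounder loadings that bias the observational LDL-DM slope
toward the published -2.0.  Everything is reproducible bit-for-bit from
the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from . import reference
from .io import Cohort, compute_variant_stats

# covariate population model (Taiwan Biobank-like adult cohort)
AGE_MEAN, AGE_SD, AGE_RANGE = 50.0, 11.0, (30.0, 70.0)
BMI_MEAN, BMI_SD, BMI_RANGE = 24.5, 3.5, (15.0, 45.0)
SEX_P = 0.5
SMOKING_P = 0.27

DEFAULT_COVARIATE_EFFECTS = {"age": 0.0015, "sex": 0.0, "bmi": 0.0051, "smoking": 0.0}


@dataclass(frozen=True)
class VariantSim:
    """Generative spec of one variant: frequency and per-allele effect."""

    id: str
    maf: float
    beta_log10_ldl: float
    chrom: str = "1"
    pos: int = 0
    ref: str = "A"
    alt: str = "G"
    annotation: str = ""


@dataclass
class SimParams:
    """Parameters of the generative model; defaults are the study conditions.

    ``ldl_log10_sd`` is the residual SD of log10 LDL-C (0.11 matches the
    lognormal approximation of 120.9 +/- 31 mg/dL).  ``confounder_strength``
    is the loading of a standard-normal confounder U on log10 LDL-C;
    ``confounder_dm_logodds`` its loading on the diabetes log-odds.  With
    ``confounder_strength = 0`` observational and causal effects coincide
    in expectation.  ``ld_blocks`` lists (variant ids, target pairwise
    dosage correlation) groups generated through a latent Gaussian copula.
    """

    n_samples: int = reference.N_COHORT
    variants: Sequence[VariantSim] = field(default_factory=lambda: default_variants())
    ldl_mean: float = reference.LDL_MEAN_MGDL
    ldl_log10_sd: float = reference.LDL_LOG10_SD
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    theta_causal: float = reference.THETA_CAUSAL
    dm_baseline_logodds: float = 6.22
    confounder_strength: float = 0.055
    confounder_dm_logodds: float = 0.49
    missing_rate: float = 0.0
    seed: int = 1
    ld_blocks: Sequence[tuple[Sequence[str], float]] = ()

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not np.isfinite(self.ldl_log10_sd) or self.ldl_log10_sd <= 0:
            raise ValueError("ldl_log10_sd must be positive and finite")
        for name in ("ldl_mean", "theta_causal", "dm_baseline_logodds",
                     "confounder_strength", "confounder_dm_logodds"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        for v in self.variants:
            if not 0.0 < v.maf < 1.0:
                raise ValueError(f"{v.id}: maf must be in (0, 1), got {v.maf}")
            if not np.isfinite(v.beta_log10_ldl):
                raise ValueError(f"{v.id}: effect must be finite")
        known = set(ids)
        for block_ids, r in self.ld_blocks:
            unknown = set(block_ids) - known
            if unknown:
                raise ValueError(f"ld_block references unknown variants: {sorted(unknown)}")
            if not -1.0 < r < 1.0:
                raise ValueError("ld_block correlation target must be in (-1, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variants"] = [dataclasses.asdict(v) for v in self.variants]
        d["ld_blocks"] = [[list(ids), r] for ids, r in self.ld_blocks]
        return d


def default_variants() -> list[VariantSim]:
    """The seven published PCSK9 variants as generative specs."""
    out = []
    for v in reference.PCSK9_VARIANTS:
        out.append(VariantSim(id=v["id"], maf=v["maf"], beta_log10_ldl=v["beta"],
                              chrom=v["chrom"], pos=v["pos"], ref=v["ref"],
                              alt=v["alt"], annotation=v["annotation"]))
    return out


# ---------------------------------------------------------------------------
# latent Gaussian copula for LD blocks
# ---------------------------------------------------------------------------

def _genotype_thresholds(maf: float) -> tuple[float, float]:
    q = 1.0 - maf
    return (sps.norm.ppf(q * q), sps.norm.ppf(q * q + 2.0 * q * maf))


def _dosage_from_latent(z: np.ndarray, maf: float) -> np.ndarray:
    t1, t2 = _genotype_thresholds(maf)
    return (z > t1).astype(float) + (z > t2)


def _dosage_corr_given_latent(rho: float, maf_a: float, maf_b: float) -> float:
    """Exact dosage correlation implied by latent correlation rho."""
    ta = _genotype_thresholds(maf_a)
    tb = _genotype_thresholds(maf_b)
    cov_mat = np.array([[1.0, rho], [rho, 1.0]])
    mvn = sps.multivariate_normal(mean=[0.0, 0.0], cov=cov_mat, allow_singular=True)
    e_gg = 0.0
    for a in ta:
        for b in tb:
            # P(Z1 > a, Z2 > b) by inclusion-exclusion on the lower CDF
            e_gg += 1.0 - sps.norm.cdf(a) - sps.norm.cdf(b) + float(mvn.cdf([a, b]))
    cov = e_gg - 4.0 * maf_a * maf_b
    denom = np.sqrt(2 * maf_a * (1 - maf_a) * 2 * maf_b * (1 - maf_b))
    return cov / denom


def _latent_rho_for_target(target_r: float, maf_a: float, maf_b: float) -> float:
    """Solve (by bisection) for the latent correlation hitting a dosage correlation."""
    if target_r == 0.0:
        return 0.0
    lo, hi = (0.0, 0.999) if target_r > 0 else (-0.999, 0.0)
    attain = _dosage_corr_given_latent(hi if target_r > 0 else lo, maf_a, maf_b)
    if (target_r > 0 and attain < target_r) or (target_r < 0 and attain > target_r):
        raise ValueError(
            f"target dosage correlation {target_r} unattainable for MAFs "
            f"({maf_a}, {maf_b}); maximum magnitude ~{abs(attain):.3f}"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _dosage_corr_given_latent(mid, maf_a, maf_b) < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    if w.min() >= 0:
        return mat
    w = np.clip(w, 1e-8, None)
    out = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(out))
    return out / np.outer(d, d)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _draw_genotypes(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_samples
    mafs = {v.id: v.maf for v in params.variants}
    in_block = {vid for ids, _ in params.ld_blocks for vid in ids}
    cols: dict[str, np.ndarray] = {}
    for v in params.variants:  # fixed draw order for reproducibility
        if v.id not in in_block:
            cols[v.id] = rng.binomial(2, v.maf, size=n).astype(float)
    for ids, r in params.ld_blocks:
        ids = list(ids)
        m = len(ids)
        latent = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                latent[i, j] = latent[j, i] = _latent_rho_for_target(
                    r, mafs[ids[i]], mafs[ids[j]])
        latent = _nearest_psd(latent)
        z = rng.multivariate_normal(np.zeros(m), latent, size=n,
                                    method="cholesky")
        for k, vid in enumerate(ids):
            cols[vid] = _dosage_from_latent(z[:, k], mafs[vid])
    return pd.DataFrame({v.id: cols[v.id] for v in params.variants})


def simulate_cohort(params: SimParams | None = None) -> Cohort:
    """Draw one cohort from the generative model; reproducible from the seed."""
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)

    genotypes = _draw_genotypes(params, rng)
    n = params.n_samples

    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, n), *AGE_RANGE)
    sex = rng.binomial(1, SEX_P, n).astype(float)
    bmi = np.clip(rng.normal(BMI_MEAN, BMI_SD, n), *BMI_RANGE)
    smoking = rng.binomial(1, SMOKING_P, n).astype(float)
    confounder = rng.standard_normal(n)
    eps = rng.normal(0.0, params.ldl_log10_sd, n)

    ce = params.covariate_effects
    log10_ldl = (
        np.log10(params.ldl_mean)
        + genotypes.to_numpy() @ np.array([v.beta_log10_ldl for v in params.variants])
        + ce.get("age", 0.0) * (age - AGE_MEAN)
        + ce.get("sex", 0.0) * (sex - SEX_P)
        + ce.get("bmi", 0.0) * (bmi - BMI_MEAN)
        + ce.get("smoking", 0.0) * (smoking - SMOKING_P)
        + params.confounder_strength * confounder
        + eps
    )
    ldl = 10.0 ** log10_ldl

    logit_dm = (params.dm_baseline_logodds
                + params.theta_causal * log10_ldl
                + params.confounder_dm_logodds * confounder)
    dm = rng.binomial(1, expit(logit_dm)).astype(int)

    dosages = genotypes.copy()
    if params.missing_rate > 0:
        mask = rng.random(dosages.shape) < params.missing_rate
        vals = dosages.to_numpy()
        vals[mask] = np.nan
        dosages = pd.DataFrame(vals, columns=dosages.columns)

    variants = pd.DataFrame(
        {"chrom": [v.chrom for v in params.variants],
         "pos": [v.pos for v in params.variants],
         "ref": [v.ref for v in params.variants],
         "alt": [v.alt for v in params.variants],
         "annotation": [v.annotation for v in params.variants]},
        index=pd.Index([v.id for v in params.variants], name="id"),
    )
    variants = variants.join(compute_variant_stats(dosages))

    phenotypes = pd.DataFrame({"ldl_mgdl": ldl, "dm": dm, "age": age,
                               "sex": sex, "bmi": bmi, "smoking": smoking})
    return Cohort(dosages, variants, phenotypes,
                  extras={"params": params, "confounder": confounder,
                          "log10_ldl": log10_ldl, "genotypes": genotypes})


def spike_pleiotropy(cohort: Cohort, variant_id: str, direct_dm_logodds: float,
                     seed: int | None = None) -> Cohort:
    """Re-draw diabetes adding a direct (LDL-bypassing) genetic effect.

    A test fixture for the exclusion-restriction filter: the variant's
    dosage enters the diabetes linear predictor directly with coefficient
    ``direct_dm_logodds``.  At 0 the re-draw is distributionally identical
    to the original model.  Requires a generator-produced cohort (the
    confounder draw and parameters ride along in ``extras``).
    """
    if variant_id not in cohort.dosages.columns:
        raise KeyError(f"unknown variant id: {variant_id}")
    try:
        params: SimParams = cohort.extras["params"]
        confounder = cohort.extras["confounder"]
        log10_ldl = cohort.extras["log10_ldl"]
        genotypes: pd.DataFrame = cohort.extras["genotypes"]
    except KeyError as exc:
        raise ValueError("spike_pleiotropy requires a simulate_cohort() cohort "
                         f"(missing extras entry {exc})") from None
    rng = np.random.default_rng(params.seed + 1_000_003 if seed is None else seed)
    g = genotypes[variant_id].to_numpy()
    logit_dm = (params.dm_baseline_logodds
                + params.theta_causal * log10_ldl
                + params.confounder_dm_logodds * confounder
                + direct_dm_logodds * g)
    phenotypes = cohort.phenotypes.copy()
    phenotypes["dm"] = rng.binomial(1, expit(logit_dm)).astype(int)
    extras = dict(cohort.extras)
    extras["spiked"] = {"variant_id": variant_id,
                        "direct_dm_logodds": direct_dm_logodds}
    return Cohort(cohort.dosages.copy(), cohort.variants.copy(), phenotypes, extras)
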