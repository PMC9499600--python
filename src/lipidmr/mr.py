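"""Causal inference: genetic risk scores, 2SLS and summary-level MR.

The exposure throughout is log10 LDL-C and the outcome is binary diabetes,
so causal effects are log-odds of diabetes per unit log10 LDL-C.  The
module provides weighted genetic risk score (WGRS) construction, the
exclusion-restriction (pleiotropy) filter, two-stage least squares with a
logistic second stage, the first-stage F statistic, and the summary-level
estimator battery: Wald ratio, inverse-variance weighting with Cochran's Q,
MR-Egger regression, and simple/weighted median estimators with bootstrap
standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import assoc
from .io import Cohort

logger = logging.getLogger("lipidmr")

Z95 = 1.96

#: mg/dL per mmol/L of LDL cholesterol
MMOL_TO_MGDL = 38.67


@dataclass
class GRSWeights:
    """Per-variant weights for a genetic risk score.

    ``table`` columns: id, effect_allele, weight (the exposure beta for the
    effect allele).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"id", "effect_allele", "weight"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"GRSWeights table missing columns: {sorted(missing)}")
        if not np.isfinite(self.table["weight"].to_numpy(dtype=float)).all():
            raise ValueError("weights must be finite")

    @classmethod
    def from_instruments(cls, instruments, variants: pd.DataFrame) -> "GRSWeights":
        """Weights from an instrument table (effect allele = alt of the scan)."""
        tbl = instruments.table if hasattr(instruments, "table") else instruments
        rows = [{"id": r["id"], "effect_allele": variants.loc[r["id"], "alt"],
                 "weight": r["beta"]} for _, r in tbl.iterrows()]
        return cls(pd.DataFrame(rows))


@dataclass
class MRSummarySet:
    """Aligned per-variant exposure and outcome summary statistics."""

    table: pd.DataFrame  # id, beta_exp, se_exp, beta_out, se_out [, effect_allele]
    aligned: bool = True

    def __post_init__(self) -> None:
        need = {"id", "beta_exp", "se_exp", "beta_out", "se_out"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"MRSummarySet missing columns: {sorted(missing)}")
        if len(self.table) < 1:
            raise ValueError("need at least one instrument")
        for col in ("se_exp", "se_out"):
            if not (self.table[col].to_numpy(dtype=float) > 0).all():
                raise ValueError(f"{col} must be positive")

    def __len__(self) -> int:
        return len(self.table)

    def oriented(self) -> "MRSummarySet":
        """Flip alleles so every exposure beta is positive (exposure-raising)."""
        t = self.table.copy()
        flip = t["beta_exp"] < 0
        t.loc[flip, ["beta_exp", "beta_out"]] *= -1.0
        return MRSummarySet(t, aligned=self.aligned)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MRSummarySet":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class MREstimate:
    """One causal estimate with its uncertainty and diagnostics."""

    method: str
    beta: float
    se: float
    p: float
    ci95: tuple[float, float] = (float("nan"), float("nan"))
    q_statistic: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    f_statistic: float | None = None
    n_instruments: int | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isnan(self.ci95[0]) and np.isfinite(self.beta) and np.isfinite(self.se):
            self.ci95 = (self.beta - Z95 * self.se, self.beta + Z95 * self.se)

    def to_dict(self) -> dict:
        return {"method": self.method, "beta": self.beta, "se": self.se,
                "p": self.p, "ci95": list(self.ci95),
                "q_statistic": self.q_statistic, "q_df": self.q_df, "q_p": self.q_p,
                "f_statistic": self.f_statistic, "n_instruments": self.n_instruments,
                "notes": list(self.notes)}


# ---------------------------------------------------------------------------
# weighted genetic risk score
# ---------------------------------------------------------------------------

def build_wgrs(cohort: Cohort, weights: GRSWeights) -> pd.Series:
    """Per-sample weighted genetic risk score.

    Each variant is flipped so its effect allele is the exposure-raising
    allele (all weights positive after flipping), then the score is the
    weighted sum of effect-allele dosages.  Missing dosages are filled with
    the variant's expected dosage 2·aaf (mean imputation); the number of
    fills is logged.
    """
    score = np.zeros(len(cohort.dosages))
    n_filled = 0
    for _, row in weights.table.iterrows():
        vid, allele, w = row["id"], row["effect_allele"], float(row["weight"])
        if vid not in cohort.dosages.columns:
            raise KeyError(f"weight variant not in cohort: {vid}")
        g = cohort.dosages[vid].to_numpy(dtype=float)
        aaf = float(cohort.variants.loc[vid, "aaf"])
        miss = ~np.isfinite(g)
        if miss.any():
            g = np.where(miss, 2.0 * aaf, g)
            n_filled += int(miss.sum())
        ref, alt = cohort.variants.loc[vid, ["ref", "alt"]]
        if allele == alt:
            pass
        elif allele == ref:
            g, w = 2.0 - g, w  # dosage of the reference allele
        else:
            raise ValueError(f"{vid}: effect allele {allele!r} is neither "
                             f"ref ({ref}) nor alt ({alt})")
        if w < 0:  # flip to the exposure-raising allele
            g, w = 2.0 - g, -w
        score += w * g
    if n_filled:
        logger.info("build_wgrs: mean-imputed %d missing dosages", n_filled)
    return pd.Series(score, index=cohort.dosages.index, name="wgrs")


# ---------------------------------------------------------------------------
# exclusion-restriction (pleiotropy) filter
# ---------------------------------------------------------------------------

def pleiotropy_filter(
    cohort: Cohort,
    candidate_instruments: Sequence[str],
    exposure,
    outcome,
    covariates: Sequence[str] = assoc.DEFAULT_COVARIATES,
    alpha: float = 0.01,
) -> tuple[list[tuple[str, float]], list[tuple[str, float, str]]]:
    """Flag instruments with outcome association not mediated by the exposure.

    For each candidate, fits logistic ``outcome ~ dosage + covariates +
    exposure``; a variant still associated with the outcome after
    conditioning on the exposure (p < ``alpha``) violates the exclusion
    restriction and is excluded.  Non-converged fits are excluded with a
    ``nonconverged`` reason code.  Returns (kept, excluded) with p-values.
    """
    exposure = np.asarray(exposure, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    cov = cohort.phenotypes[list(covariates)].astype(float).reset_index(drop=True)
    kept: list[tuple[str, float]] = []
    excluded: list[tuple[str, float, str]] = []
    for vid in candidate_instruments:
        g = cohort.dosages[vid].to_numpy(dtype=float)
        mask = np.isfinite(g) & np.isfinite(exposure) & np.isfinite(outcome)
        mask &= np.isfinite(cov.to_numpy()).all(axis=1)
        X = pd.concat([pd.Series(g[mask], name=vid).reset_index(drop=True),
                       cov[mask].reset_index(drop=True),
                       pd.Series(exposure[mask], name="exposure").reset_index(drop=True)],
                      axis=1)
        fit = assoc.fit_logistic(outcome[mask], X)
        if not fit.converged:
            excluded.append((vid, float("nan"), "nonconverged"))
            continue
        p = float(fit.pvalues[vid])
        if p < alpha:
            excluded.append((vid, p, "outcome_associated"))
        else:
            kept.append((vid, p))
    return kept, excluded


# ---------------------------------------------------------------------------
# two-stage least squares (predictor substitution, logistic second stage)
# ---------------------------------------------------------------------------

def two_stage_ls(
    cohort: Cohort,
    instrument,
    exposure,
    outcome,
    covariates: Sequence[str] = assoc.DEFAULT_COVARIATES,
    weak_f_threshold: float = 10.0,
) -> MREstimate:
    """Two-stage instrumental-variable estimate of the exposure effect.

    Stage 1 regresses the (log10-transformed) exposure on the instrument
    (a WGRS vector or a variant id) plus covariates; stage 2 fits a
    logistic model of the binary outcome on the stage-1 fitted exposure
    plus covariates.  The instrument's first-stage strength is summarised
    by F = R²(n−2)/(1−R²) on its incremental R².  The reported SE is the
    naive stage-2 SE (flagged "uncorrected"): it ignores first-stage
    estimation error.
    """
    if isinstance(instrument, str):
        inst = cohort.dosages[instrument].to_numpy(dtype=float)
        inst_name = instrument
    else:
        inst = np.asarray(instrument, dtype=float)
        inst_name = getattr(instrument, "name", None) or "instrument"
    exposure = np.asarray(exposure, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    cov = cohort.phenotypes[list(covariates)].astype(float).reset_index(drop=True)
    mask = (np.isfinite(inst) & np.isfinite(exposure) & np.isfinite(outcome)
            & np.isfinite(cov.to_numpy()).all(axis=1))
    if np.nanvar(inst[mask]) == 0:
        raise ValueError("instrument is constant on the analysis samples")

    X1 = pd.concat([pd.Series(inst[mask], name=inst_name).reset_index(drop=True),
                    cov[mask].reset_index(drop=True)], axis=1)
    stage1 = assoc.fit_linear(exposure[mask], X1)
    coefs = np.array([stage1.params[c] for c in X1.columns])
    import statsmodels.api as sm
    fitted = sm.add_constant(X1, has_constant="add").to_numpy() @ np.concatenate(
        [[stage1.params["const"]], coefs])
    r2_incr = float(stage1.partial_r2[inst_name])
    f_stat = f_statistic(r2_incr, stage1.n)

    X2 = pd.concat([pd.Series(fitted, name="fitted_exposure"),
                    cov[mask].reset_index(drop=True)], axis=1)
    stage2 = assoc.fit_logistic(outcome[mask], X2)
    notes = ["uncorrected stage-2 SE"]
    if not stage2.converged:
        notes.append(f"stage-2 logistic did not converge: {stage2.message}")
    if f_stat < weak_f_threshold:
        notes.append(f"weak instrument: first-stage F = {f_stat:.2f} < {weak_f_threshold}")
        logger.warning(notes[-1])
    return MREstimate(
        method="2SLS",
        beta=float(stage2.params["fitted_exposure"]),
        se=float(stage2.bse["fitted_exposure"]),
        p=float(stage2.pvalues["fitted_exposure"]),
        f_statistic=f_stat,
        notes=notes,
    )


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F statistic: F = R²(n−2)/(1−R²)."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return float(r2 * (n - 2) / (1.0 - r2))


# ---------------------------------------------------------------------------
# summary-level estimators
# ---------------------------------------------------------------------------

def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-instrument causal estimate: ratio of outcome to exposure betas.

    SE by the first-order delta method including the exposure-uncertainty
    term: sqrt(se_y²/βx² + βy²·se_x²/βx⁴).
    """
    if beta_x == 0:
        raise ValueError("wald ratio undefined: exposure beta is zero")
    beta = beta_y / beta_x
    se = float(np.sqrt(se_y ** 2 / beta_x ** 2
                       + beta_y ** 2 * se_x ** 2 / beta_x ** 4))
    z = beta / se if se > 0 else np.inf
    return MREstimate(method="wald", beta=float(beta), se=se,
                      p=float(2.0 * sps.norm.sf(abs(z))), n_instruments=1)


def _ratios_and_weights(summary: MRSummarySet) -> tuple[np.ndarray, np.ndarray]:
    t = summary.table
    bx = t["beta_exp"].to_numpy(dtype=float)
    by = t["beta_out"].to_numpy(dtype=float)
    sey = t["se_out"].to_numpy(dtype=float)
    if (bx == 0).any():
        bad = t.loc[bx == 0, "id"].tolist()
        raise ValueError(f"exposure beta is zero for instruments: {bad}")
    return by / bx, bx ** 2 / sey ** 2  # first-order weights


def ivw(summary: MRSummarySet) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate with Cochran's Q.

    Per-variant Wald ratios are pooled with first-order weights βx²/se_y².
    Q = Σ wj (ratio_j − β_IVW)² on m−1 df measures heterogeneity of the
    per-variant causal estimates.  With a single instrument this is by
    definition the Wald ratio (Q undefined at 0 df).
    """
    if len(summary) == 1:
        row = summary.table.iloc[0]
        est = wald_ratio(row["beta_exp"], row["se_exp"], row["beta_out"], row["se_out"])
        est.method = "ivw"
        est.q_statistic, est.q_df, est.q_p = 0.0, 0, None
        return est
    ratios, w = _ratios_and_weights(summary)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - beta) ** 2))
    q_df = len(ratios) - 1
    z = beta / se
    return MREstimate(method="ivw", beta=beta, se=se,
                      p=float(2.0 * sps.norm.sf(abs(z))),
                      q_statistic=q, q_df=q_df,
                      q_p=float(sps.chi2.sf(q, q_df)),
                      n_instruments=len(ratios))


def egger(summary: MRSummarySet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Weighted least squares of outcome betas on exposure betas with an
    unconstrained intercept, weights 1/se_y², after orienting all
    instruments to the exposure-raising allele.  The slope estimates the
    causal effect under the InSIDE assumption; the intercept estimates the
    average directional pleiotropy.  SEs carry the estimated residual
    dispersion (t inference on m−2 df).
    """
    if len(summary) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    t = summary.oriented().table
    bx = t["beta_exp"].to_numpy(dtype=float)
    by = t["beta_out"].to_numpy(dtype=float)
    w = 1.0 / t["se_out"].to_numpy(dtype=float) ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    m = len(bx)
    sigma2 = float(np.sum(w * resid ** 2) / (m - 2))
    cov = sigma2 * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore"):
        pvals = 2.0 * sps.t.sf(np.abs(coef / se), df=m - 2)
    slope = MREstimate(method="egger_slope", beta=float(coef[1]), se=float(se[1]),
                       p=float(pvals[1]), n_instruments=m)
    intercept = MREstimate(method="egger_intercept", beta=float(coef[0]),
                           se=float(se[0]), p=float(pvals[0]), n_instruments=m)
    return slope, intercept


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint convention
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] <= 0.5:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def median_estimators(summary: MRSummarySet, n_boot: int = 1000,
                      seed: int = 0) -> tuple[MREstimate, MREstimate]:
    """Simple and weighted median causal estimates.

    The simple median is the (equal-weight) median of per-variant Wald
    ratios; the weighted median uses IVW weights and is consistent when
    instruments carrying under half the total weight are invalid.  SEs by
    seeded parametric bootstrap: betas are resampled from normal
    distributions centred on the observed values with their SEs.
    """
    if len(summary) < 3:
        raise ValueError("median estimators require at least 3 instruments")
    ratios, w = _ratios_and_weights(summary)
    simple_beta = _weighted_median(ratios, np.ones_like(ratios))
    weighted_beta = _weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    t = summary.table
    bx = t["beta_exp"].to_numpy(dtype=float)
    sx = t["se_exp"].to_numpy(dtype=float)
    by = t["beta_out"].to_numpy(dtype=float)
    sy = t["se_out"].to_numpy(dtype=float)
    boots_s = np.empty(n_boot)
    boots_w = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = np.finfo(float).tiny
        rb = byb / bxb
        wb = bxb ** 2 / sy ** 2
        boots_s[b] = _weighted_median(rb, np.ones_like(rb))
        boots_w[b] = _weighted_median(rb, wb)
    se_s = float(np.std(boots_s, ddof=1))
    se_w = float(np.std(boots_w, ddof=1))
    note = [f"bootstrap SE (n_boot={n_boot}, seed={seed})"]
    simple = MREstimate(method="simple_median", beta=float(simple_beta), se=se_s,
                        p=float(2.0 * sps.norm.sf(abs(simple_beta / se_s))) if se_s > 0 else float("nan"),
                        n_instruments=len(ratios), notes=list(note))
    weighted = MREstimate(method="weighted_median", beta=float(weighted_beta), se=se_w,
                          p=float(2.0 * sps.norm.sf(abs(weighted_beta / se_w))) if se_w > 0 else float("nan"),
                          n_instruments=len(ratios), notes=list(note))
    return simple, weighted


def funnel_data(summary: MRSummarySet) -> pd.DataFrame:
    """Per-variant (ratio, precision) table for funnel plots; no inference."""
    ratios, _ = _ratios_and_weights(summary)
    t = summary.table
    se_ratio = np.sqrt(t["se_out"] ** 2 / t["beta_exp"] ** 2
                       + t["beta_out"] ** 2 * t["se_exp"] ** 2 / t["beta_exp"] ** 4)
    return pd.DataFrame({"id": t["id"], "ratio": ratios,
                         "precision": 1.0 / se_ratio.to_numpy(dtype=float)})


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def or_per_unit(beta_per_log10: float, reference_ldl: float,
                unit: str = "mgdl") -> float:
    """Odds ratio per +1 absolute LDL-C unit implied by a log10-scale slope.

    A change of 1 mg/dL at LDL-C level L corresponds to a log10 change of
    Δ = 1/(ln10·L), so OR = exp(β·Δ); for mmol/L the unit is 38.67 mg/dL.
    The conversion is local to the reference level (the log scale is
    nonlinear in absolute units).
    """
    if reference_ldl <= 0:
        raise ValueError("reference LDL must be positive")
    unit_mgdl = {"mgdl": 1.0, "mmol": MMOL_TO_MGDL}.get(unit)
    if unit_mgdl is None:
        raise ValueError(f"unknown unit {unit!r}; use 'mgdl' or 'mmol'")
    delta_log10 = unit_mgdl / (np.log(10.0) * reference_ldl)
    return float(np.exp(beta_per_log10 * delta_log10))


def or_change_units(or_value: float, from_unit: str, to_unit: str) -> float:
    """Rescale an odds ratio between per-mmol/L and per-mg/dL units.

    An OR per X mg/dL equals (OR per 1 mg/dL)^X, so the exponent rescales
    by the ratio of unit sizes.
    """
    sizes = {"mgdl": 1.0, "mmol": MMOL_TO_MGDL}
    try:
        factor = sizes[from_unit] / sizes[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown unit {exc}") from None
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    return float(or_value ** (1.0 / factor)) if factor != 1.0 else float(or_value)
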