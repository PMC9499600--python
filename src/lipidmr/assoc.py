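"""Core association statistics.

Additive-model linear and logistic association, Hardy-Weinberg and allele
frequency arithmetic, composite LD r², per-variant variance explained, and
the log10 trait transform that every lipid analysis in this package runs on.

All regressions code genotypes additively (dosage = count of alternate
alleles), so a negative beta means the alternate allele lowers the trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

logger = logging.getLogger("lipidmr")

#: genome-wide significance threshold for single-variant association
GENOME_WIDE_ALPHA = 5e-8

#: default adjustment set used throughout the pipeline
DEFAULT_COVARIATES = ("age", "sex", "bmi", "smoking")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class AssocStat:
    """Per-variant regression output on the transformed trait."""

    variant_id: str
    beta: float
    se: float
    p: float
    n: int
    r2_partial: float
    n_het: int | None = None
    n_hom: int | None = None
    note: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.beta)


@dataclass
class RegressionFit:
    """Coefficients, standard errors and fit diagnostics for one model.

    ``partial_r2[name]`` is the incremental r² of that predictor, i.e.
    (RSS without it − RSS with it) / TSS for linear models.
    """

    params: Mapping[str, float]
    bse: Mapping[str, float]
    pvalues: Mapping[str, float]
    n: int
    resid_var: float | None = None
    r2: float | None = None
    partial_r2: Mapping[str, float] = field(default_factory=dict)
    converged: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# trait transformation
# ---------------------------------------------------------------------------

def log10_trait(values) -> np.ndarray:
    """log10-transform a strictly positive trait (e.g. LDL-C in mg/dL).

    Lipid traits are right-skewed and are analysed on the log10 scale; the
    inverse transform is ``10 ** x``.

    Raises ``ValueError`` naming the first offending sample if any value is
    non-positive or non-finite.
    """
    arr = np.asarray(values, dtype=float)
    bad = ~(np.isfinite(arr) & (arr > 0))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        if isinstance(values, pd.Series):
            idx = values.index[idx]
        raise ValueError(
            f"trait must be strictly positive and finite; offending sample: {idx!r}"
        )
    return np.log10(arr)


# ---------------------------------------------------------------------------
# allele-frequency and HWE arithmetic
# ---------------------------------------------------------------------------

def maf_from_counts(n_mm_major: int, n_het: int, n_mm_minor: int) -> tuple[float, float]:
    """Alt-allele and minor-allele frequency from genotype counts.

    Arguments are the counts of reference homozygotes, heterozygotes and
    alternate homozygotes.  Returns ``(aaf, maf)`` with
    ``aaf = (het + 2·hom_alt) / (2·total)`` and ``maf = min(aaf, 1 − aaf)``.
    """
    counts = np.array([n_mm_major, n_het, n_mm_minor], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all genotype counts are zero")
    aaf = (counts[1] + 2.0 * counts[2]) / (2.0 * total)
    return float(aaf), float(min(aaf, 1.0 - aaf))


def hwe_test(n_mm_major: int, n_het: int, n_mm_minor: int, *, exact: bool = False) -> float:
    """Hardy-Weinberg equilibrium test p-value from genotype counts.

    Default is the 1-df chi-squared goodness-of-fit test against the p²,
    2pq, q² expectations without continuity correction.  ``exact=True``
    switches to the mid-p-free exact test (sum of probabilities of
    heterozygote counts at most as likely as the observed one, conditional
    on allele counts), useful at low minor-allele counts.

    Returns 1.0 when a genotype class is structurally empty (monomorphic
    site): a fixed site cannot violate HWE.
    """
    obs = np.array([n_mm_major, n_het, n_mm_minor], dtype=float)
    if (obs < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = obs.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    aaf = (obs[1] + 2.0 * obs[2]) / (2.0 * n)
    if aaf == 0.0 or aaf == 1.0:
        return 1.0
    if exact:
        return _hwe_exact(int(n_het), int(round(2 * n * min(aaf, 1 - aaf))), int(n))
    p = 1.0 - aaf
    expected = n * np.array([p * p, 2.0 * p * aaf, aaf * aaf])
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return float(sps.chi2.sf(chi2, df=1))


def _hwe_exact(n_het: int, n_minor_alleles: int, n: int) -> float:
    """Exact HWE test conditional on the minor-allele count."""
    # enumerate heterozygote counts with the same parity as the allele count
    hets = np.arange(n_minor_alleles % 2, n_minor_alleles + 1, 2)
    hets = hets[(n_minor_alleles - hets) % 2 == 0]
    hets = hets[(n_minor_alleles - hets) // 2 + hets <= n]
    logp = np.array([_hwe_log_prob(h, n_minor_alleles, n) for h in hets])
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs_p = prob[hets == n_het]
    if obs_p.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele count")
    return float(min(1.0, prob[prob <= obs_p[0] + 1e-12].sum()))


def _hwe_log_prob(n_het: int, n_rare: int, n: int) -> float:
    from scipy.special import gammaln

    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n - n_het - n_hom_rare
    n_common = 2 * n - n_rare
    return (
        n_het * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(n_hom_common + 1)
        - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(n_common + 1))
    )


def genotype_counts(dosages) -> tuple[int, int, int]:
    """Count (hom-ref, het, hom-alt) genotypes in a dosage vector, ignoring missing."""
    arr = np.asarray(dosages, dtype=float)
    arr = arr[np.isfinite(arr)]
    return (int((arr == 0).sum()), int((arr == 1).sum()), int((arr == 2).sum()))


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

def _design(X: pd.DataFrame, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if add_intercept and "const" not in X.columns:
        X = sm.add_constant(X, has_constant="add")
    return X


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns from the pivoted QR diagonal
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps
        bad = [str(c) for c, d in zip(X.columns, diag) if d <= tol]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {mat.shape[1]}); "
            f"collinear columns: {bad or list(map(str, X.columns))}"
        )


def fit_linear(y, X, *, add_intercept: bool = True) -> RegressionFit:
    """Ordinary least squares with per-predictor partial r².

    The solution uses a numerically stable orthogonal decomposition (the
    QR/SVD path of ``statsmodels`` OLS), two-sided t-test p-values, and
    partial r² computed as the drop in residual sum of squares when the
    predictor is removed, divided by the total sum of squares.
    """
    X = _design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} observations, got {len(y)}")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(res.ssr)
    partial: dict[str, float] = {}
    for col in X.columns:
        if col == "const":
            continue
        reduced = sm.OLS(y, X.drop(columns=[col])).fit()
        partial[col] = max(0.0, (float(reduced.ssr) - rss) / tss) if tss > 0 else 0.0
    return RegressionFit(
        params=dict(res.params),
        bse=dict(res.bse),
        pvalues=dict(res.pvalues),
        n=int(res.nobs),
        resid_var=float(res.ssr / res.df_resid) if res.df_resid > 0 else 0.0,
        r2=float(res.rsquared) if tss > 0 else 0.0,
        partial_r2=partial,
    )


def fit_logistic(y, X, *, add_intercept: bool = True, maxiter: int = 100) -> RegressionFit:
    """Binary logistic regression by Newton-type IRLS with Wald inference.

    Complete separation (or any other failure to converge) is reported via
    ``converged=False`` with an explanatory message rather than silently
    returning diverged estimates; callers decide whether to drop the fit.
    """
    X = _design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if len(y) <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} observations, got {len(y)}")
    _check_rank(X)
    import warnings

    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(disp=0, maxiter=maxiter, tol=1e-10)
        messages = [str(w.message) for w in caught]
        separated = any("separation" in m.lower() for m in messages)
        converged = bool(res.mle_retvals.get("converged", False)) and not separated
        bad = ~np.isfinite(np.asarray(res.bse))
        if bad.any():
            converged = False
        return RegressionFit(
            params=dict(res.params),
            bse=dict(res.bse),
            pvalues=dict(res.pvalues),
            n=int(res.nobs),
            converged=converged,
            message="; ".join(m for m in messages if m) if not converged else "",
        )
    except Exception as exc:  # statsmodels raises on perfect separation
        return RegressionFit(
            params={c: float("nan") for c in X.columns},
            bse={c: float("nan") for c in X.columns},
            pvalues={c: float("nan") for c in X.columns},
            n=len(y),
            converged=False,
            message=f"logistic fit failed: {exc}",
        )


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def assoc_scan(
    cohort,
    trait,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    variants: Iterable[str] | None = None,
    condition_on: Sequence[str] = (),
) -> list[AssocStat]:
    """Additive-model linear association of each variant with a transformed trait.

    ``trait`` is a per-sample vector already on the analysis scale (use
    :func:`log10_trait` for lipids).  ``covariates`` name phenotype columns;
    ``condition_on`` names variants whose dosages are added as covariates
    (serial conditional analysis).  Each variant is fit on its own
    complete cases, so per-variant n differs under missingness.

    Monomorphic variants yield an ``AssocStat`` with NaN effect and a note
    instead of raising.
    """
    trait = pd.Series(np.asarray(trait, dtype=float), index=cohort.dosages.index)
    cov = cohort.phenotypes[list(covariates)].astype(float)
    cond = cohort.dosages[list(condition_on)] if condition_on else None
    ids = list(variants) if variants is not None else list(cohort.dosages.columns)
    out: list[AssocStat] = []
    for vid in ids:
        g = cohort.dosages[vid].astype(float)
        mask = np.isfinite(g.to_numpy()) & np.isfinite(trait.to_numpy())
        mask &= np.isfinite(cov.to_numpy()).all(axis=1)
        if cond is not None:
            mask &= np.isfinite(cond.to_numpy()).all(axis=1)
        gm = g[mask]
        nmm, nhet, nhom = genotype_counts(gm)
        if gm.size == 0 or np.nanvar(gm) == 0:
            out.append(AssocStat(vid, np.nan, np.nan, np.nan, int(mask.sum()),
                                 np.nan, nhet, nhom, note="monomorphic"))
            continue
        X = pd.DataFrame({vid: gm})
        X = pd.concat([X.reset_index(drop=True), cov[mask].reset_index(drop=True)], axis=1)
        if cond is not None:
            X = pd.concat([X, cond[mask].reset_index(drop=True)], axis=1)
        try:
            fit = fit_linear(trait[mask].to_numpy(), X)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("variant %s skipped: %s", vid, exc)
            out.append(AssocStat(vid, np.nan, np.nan, np.nan, int(mask.sum()),
                                 np.nan, nhet, nhom, note=f"collinear: {exc}"))
            continue
        out.append(AssocStat(
            variant_id=vid,
            beta=float(fit.params[vid]),
            se=float(fit.bse[vid]),
            p=float(fit.pvalues[vid]),
            n=fit.n,
            r2_partial=float(fit.partial_r2[vid]),
            n_het=nhet,
            n_hom=nhom,
        ))
    return out


def assoc_table(stats: Sequence[AssocStat], variants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy per-variant summary-statistic table (effect allele = alt)."""
    rows = []
    for s in stats:
        row = {"id": s.variant_id, "n": s.n, "beta": s.beta, "se": s.se,
               "p": s.p, "r2": s.r2_partial, "note": s.note}
        if variants is not None and s.variant_id in variants.index:
            v = variants.loc[s.variant_id]
            row.update({"chrom": v["chrom"], "pos": v["pos"],
                        "ref": v["ref"], "alt": v["alt"]})
        rows.append(row)
    cols = ["id", "chrom", "pos", "ref", "alt", "n", "beta", "se", "p", "r2", "note"]
    df = pd.DataFrame(rows)
    return df[[c for c in cols if c in df.columns]]


# ---------------------------------------------------------------------------
# LD and variance explained
# ---------------------------------------------------------------------------

def ld_r2(dosage_a, dosage_b) -> float:
    """Composite LD: squared Pearson correlation of dosages.

    Uses pairwise-complete samples; no phasing is attempted.  Raises if
    fewer than two complete pairs remain or either vector is constant.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 2:
        raise ValueError("need at least 2 complete dosage pairs")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("LD r² undefined: a dosage vector has zero variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def variance_explained(maf: float, beta: float, trait_var: float) -> float:
    """Fraction of trait variance explained by one additive variant.

    Under HWE a variant with minor-allele frequency ``p`` and per-allele
    effect ``beta`` contributes ``2·p·(1−p)·beta²`` of variance, expressed
    here as a fraction of ``trait_var`` (trait variance on the same scale
    as ``beta``, i.e. log10 for lipids).
    """
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must be in (0, 1)")
    if trait_var <= 0:
        raise ValueError("trait_var must be positive")
    return 2.0 * maf * (1.0 - maf) * beta * beta / trait_var


def log10_var_from_mean_sd(mean: float, sd: float) -> float:
    """Variance of log10(X) for a lognormal X with the given mean and SD.

    var(log10 X) = ln(1 + CV²) / ln(10)², CV = sd/mean.  Used to convert a
    trait summarised on the raw scale (e.g. LDL-C 120.9 ± 31 mg/dL) to the
    log10 analysis scale.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    cv2 = (sd / mean) ** 2
    return float(np.log1p(cv2) / np.log(10.0) ** 2)
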