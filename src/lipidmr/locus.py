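"""Dissection of a locus into independent association signals.

Serial conditional scanning (re-running the association with previously
identified lead variants as covariates), greedy LD pruning of hits,
a rare-variant pass over pre-QC annotated coding variants, and
forward-backward stepwise selection with per-step r² increments.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import assoc
from .assoc import AssocStat, RegressionFit
from .io import Cohort

logger = logging.getLogger("lipidmr")


@dataclass
class ConditionalRound:
    """One round of serial conditional analysis."""

    round_index: int
    conditioning_set: list[str]
    lead_variant: str
    lead_p: float
    n_genomewide_hits: int


@dataclass
class InstrumentSet:
    """Selected instruments with effect sizes and selection provenance.

    ``table`` columns: id, beta, se, p, provenance.  ``r2_matrix`` holds
    pairwise dosage r² among the kept variants.
    """

    table: pd.DataFrame
    r2_matrix: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# serial conditional analysis
# ---------------------------------------------------------------------------

def conditional_scan(
    cohort: Cohort,
    trait,
    covariates: Sequence[str] = assoc.DEFAULT_COVARIATES,
    region_variants: Sequence[str] | None = None,
    alpha: float = assoc.GENOME_WIDE_ALPHA,
    max_rounds: int = 10,
) -> list[ConditionalRound]:
    """Identify independent signals by serial conditional association.

    Round k scans every region variant (outside the conditioning set) with
    the k−1 previous lead variants added as covariates; the best variant
    becomes the next lead if it passes ``alpha``.  Stops when no variant
    passes or after ``max_rounds``.  Ties on p are broken by lower genomic
    position.  Variants collinear with the conditioning set are skipped
    with a log entry (the scan records them as undefined).
    """
    region = list(region_variants) if region_variants is not None else cohort.variant_ids
    rounds: list[ConditionalRound] = []
    conditioning: list[str] = []
    pos = cohort.variants["pos"]
    for k in range(max_rounds):
        scanned = [v for v in region if v not in conditioning]
        if not scanned:
            break
        stats = assoc.assoc_scan(cohort, trait, covariates,
                                 variants=scanned, condition_on=tuple(conditioning))
        defined = [s for s in stats if s.defined]
        for s in stats:
            if not s.defined and s.note:
                logger.info("conditional round %d: %s (%s)", k + 1, s.variant_id, s.note)
        if not defined:
            break
        lead = min(defined, key=lambda s: (s.p, int(pos.get(s.variant_id, 0))))
        n_hits = sum(s.p < alpha for s in defined)
        if lead.p >= alpha:
            logger.info("conditional scan stopped after %d rounds "
                        "(best remaining p = %.3g)", k, lead.p)
            break
        rounds.append(ConditionalRound(
            round_index=k + 1,
            conditioning_set=list(conditioning),
            lead_variant=lead.variant_id,
            lead_p=lead.p,
            n_genomewide_hits=n_hits,
        ))
        conditioning.append(lead.variant_id)
    return rounds


def rounds_to_json(rounds: Sequence[ConditionalRound], path) -> None:
    payload = [dict(round_index=r.round_index, conditioning_set=r.conditioning_set,
                    lead_variant=r.lead_variant, lead_p=r.lead_p,
                    n_genomewide_hits=r.n_genomewide_hits) for r in rounds]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def prune_by_ld(hits: Sequence[AssocStat], dosages: pd.DataFrame,
                r2_max: float = 0.3, provenance: str = "ld_pruned") -> InstrumentSet:
    """Greedy p-ordered LD pruning.

    Keeps the smallest-p variant, then drops any later variant whose dosage
    r² with a kept variant is at least ``r2_max``.  Deterministic given the
    input; duplicated rows are collapsed first.
    """
    seen: dict[str, AssocStat] = {}
    for h in sorted(hits, key=lambda s: (s.p, s.variant_id)):
        seen.setdefault(h.variant_id, h)
    ordered = list(seen.values())
    kept: list[AssocStat] = []
    for h in ordered:
        in_ld = False
        for k in kept:
            try:
                if assoc.ld_r2(dosages[h.variant_id], dosages[k.variant_id]) >= r2_max:
                    in_ld = True
                    break
            except ValueError:
                continue  # zero-variance pair: undefined LD, treated as unlinked
        if not in_ld:
            kept.append(h)
    table = pd.DataFrame({
        "id": [h.variant_id for h in kept],
        "beta": [h.beta for h in kept],
        "se": [h.se for h in kept],
        "p": [h.p for h in kept],
        "provenance": provenance,
    })
    r2 = pd.DataFrame(np.eye(len(kept)),
                      index=table["id"], columns=table["id"])
    for i, a in enumerate(table["id"]):
        for j, b in enumerate(table["id"]):
            if j <= i:
                continue
            try:
                r2.iloc[i, j] = r2.iloc[j, i] = assoc.ld_r2(dosages[a], dosages[b])
            except ValueError:
                r2.iloc[i, j] = r2.iloc[j, i] = np.nan
    return InstrumentSet(table=table, r2_matrix=r2)


# ---------------------------------------------------------------------------
# rare-variant pass
# ---------------------------------------------------------------------------

_MISSENSE_RE = re.compile(r"p\.([A-Z])\d+([A-Z])")


def _is_nonsynonymous(annotation: str) -> bool:
    if "nonsynonymous" in annotation.lower():
        return True
    m = _MISSENSE_RE.search(annotation or "")
    return bool(m and m.group(1) != m.group(2))


def rare_variant_pass(
    cohort_preqc: Cohort,
    trait,
    covariates: Sequence[str] = assoc.DEFAULT_COVARIATES,
    maf_max: float = 0.01,
    annotation_filter: str = "nonsynonymous",
) -> list[AssocStat]:
    """Association of rare annotated coding variants on pre-QC data.

    Rare variants are excluded by the MAF filter in standard QC, so this
    pass runs on the pre-QC cohort, restricted to variants below
    ``maf_max`` whose annotation matches the filter ("nonsynonymous"
    matches an explicit token or a protein change like ``p.R93C``).
    Carrier counts ride along on each statistic; zero-carrier variants are
    flagged and excluded.
    """
    selected = []
    for vid, row in cohort_preqc.variants.iterrows():
        maf = row.get("maf", np.nan)
        if not np.isfinite(maf) or maf >= maf_max:
            continue
        ann = str(row.get("annotation", "") or "")
        if annotation_filter == "nonsynonymous":
            if not _is_nonsynonymous(ann):
                continue
        elif annotation_filter and annotation_filter not in ann:
            continue
        selected.append(vid)
    stats = assoc.assoc_scan(cohort_preqc, trait, covariates, variants=selected)
    out = []
    for s in stats:
        carriers = (s.n_het or 0) + (s.n_hom or 0)
        if carriers == 0:
            logger.info("rare-variant pass: %s has no carriers, excluded", s.variant_id)
            continue
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    """Entry order, per-step r² increments and the final fit."""

    entered: list[str]
    entry_p: dict[str, float]
    r2_increment: dict[str, float]
    removed: list[str]
    fit: RegressionFit
    warning: str = ""


def stepwise_select(
    y,
    candidate_predictors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
) -> StepwiseResult:
    """Forward-backward stepwise linear regression.

    Covariates are always in the model; candidates enter one at a time by
    smallest p while p < ``p_enter``, and any entered candidate whose p
    rises above ``p_remove`` is dropped.  Each retained candidate's r²
    increment at entry (drop in RSS over TSS) is reported.  An oscillation
    guard stops after ``max_steps`` steps with a warning.
    """
    y = np.asarray(y, dtype=float)
    cand = pd.DataFrame(candidate_predictors).astype(float)
    cov = pd.DataFrame(covariates).astype(float) if covariates is not None else \
        pd.DataFrame(index=cand.index)
    tss = float(((y - y.mean()) ** 2).sum())

    entered: list[str] = []
    entry_p: dict[str, float] = {}
    r2_inc: dict[str, float] = {}
    removed: list[str] = []
    warning = ""

    def current_fit(cols: list[str]) -> RegressionFit:
        X = pd.concat([cov, cand[cols]], axis=1)
        return assoc.fit_linear(y, X)

    steps = 0
    changed = True
    while changed and steps < max_steps:
        changed = False
        steps += 1
        # forward step: best candidate by p-value
        best = None
        for name in cand.columns:
            if name in entered:
                continue
            try:
                fit = current_fit(entered + [name])
            except (np.linalg.LinAlgError, ValueError):
                continue
            p = fit.pvalues[name]
            if np.isfinite(p) and (best is None or p < best[1]):
                best = (name, p, fit)
        if best is not None and best[1] < p_enter:
            name, p, fit = best
            rss_before = _rss(y, pd.concat([cov, cand[entered]], axis=1))
            rss_after = _rss(y, pd.concat([cov, cand[entered + [name]]], axis=1))
            entered.append(name)
            entry_p[name] = p
            r2_inc[name] = max(0.0, (rss_before - rss_after) / tss) if tss > 0 else 0.0
            changed = True
        # backward step: worst entered candidate
        while entered:
            fit = current_fit(entered)
            worst = max(entered, key=lambda c: fit.pvalues[c])
            if fit.pvalues[worst] > p_remove:
                entered.remove(worst)
                removed.append(worst)
                r2_inc.pop(worst, None)
                changed = True
            else:
                break
    if steps >= max_steps:
        warning = f"stepwise selection stopped after {max_steps} steps (oscillation guard)"
        logger.warning(warning)
    return StepwiseResult(entered=entered, entry_p=entry_p, r2_increment=r2_inc,
                          removed=removed, fit=current_fit(entered), warning=warning)


def _rss(y: np.ndarray, X: pd.DataFrame) -> float:
    import statsmodels.api as sm

    Xc = sm.add_constant(pd.DataFrame(X).astype(float), has_constant="add")
    res = sm.OLS(y, Xc).fit()
    return float(res.ssr)
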