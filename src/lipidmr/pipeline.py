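"""Config-driven orchestration of the full analysis.

Runs the whole flow on a synthetic or user-supplied cohort: QC (with a
rare-variant pass on the pre-QC data), exposure association scan, serial
conditional analysis plus LD pruning, stepwise selection, the
exclusion-restriction filter, WGRS construction, two-stage least squares,
and the summary-level sensitivity battery.  The result is a
machine-readable report in which every number is traceable to an operation
output; identical seed and config reproduce the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import assoc, locus, mr, synthetic
from . import io as cio

logger = logging.getLogger("lipidmr")

#: stable per-stage offsets for deriving stage seeds from the config seed
_STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "median_bootstrap": 1,
    "spike": 2,
}


def stage_seed(seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation (stable across reruns)."""
    return int(np.random.SeedSequence([seed, _STAGE_SEED_OFFSETS[stage]])
               .generate_state(1)[0] % (2 ** 31))


def bonferroni_alpha(global_alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-corrected significance threshold: global_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return global_alpha / n_tests


@dataclass
class PipelineConfig:
    """All thresholds, inputs and the seed for one pipeline run.

    Exactly one of ``sim_params`` (synthetic cohort) or ``genotype_path`` +
    ``phenotype_path`` (user data) must be given.  ``instrument_alpha`` is
    the entry threshold for conditional rounds; it is kept separate from
    the genome-wide reporting threshold ``alpha_gw`` because locus
    dissection customarily retains conditionally independent signals
    slightly below genome-wide significance.
    """

    sim_params: synthetic.SimParams | None = None
    genotype_path: str | None = None
    genotype_format: str = "vcf"
    phenotype_path: str | None = None
    covariates: Sequence[str] = assoc.DEFAULT_COVARIATES
    alpha_gw: float = assoc.GENOME_WIDE_ALPHA
    instrument_alpha: float = 1e-6
    r2_max: float = 0.3
    pleiotropy_alpha: float = 0.01
    rare_maf_max: float = 0.01
    variant_call_rate_min: float = 0.97
    sample_call_rate_min: float = 0.97
    maf_min: float = 0.01
    hwe_alpha: float = 1e-6
    bonferroni_traits: int = 33
    n_boot: int = 1000
    seed: int = 1
    outdir: str | None = None
    spike_variant: str | None = None
    spike_dm_logodds: float = 0.0

    def __post_init__(self) -> None:
        has_sim = self.sim_params is not None
        has_paths = self.genotype_path is not None and self.phenotype_path is not None
        if has_sim == has_paths:
            raise ValueError("give exactly one of sim_params or "
                             "genotype_path+phenotype_path")
        for name in ("alpha_gw", "instrument_alpha", "r2_max", "pleiotropy_alpha",
                     "rare_maf_max", "variant_call_rate_min", "sample_call_rate_min",
                     "maf_min", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bonferroni_traits < 1:
            raise ValueError("bonferroni_traits must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim_params is not None:
            d["sim_params"] = self.sim_params.to_dict()
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sp = d.get("sim_params")
        if sp is not None:
            sp = dict(sp)
            sp["variants"] = [synthetic.VariantSim(**v) for v in sp.get("variants", [])]
            sp["ld_blocks"] = [(tuple(ids), r) for ids, r in sp.get("ld_blocks", [])]
            d["sim_params"] = synthetic.SimParams(**sp)
        d["covariates"] = tuple(d.get("covariates", assoc.DEFAULT_COVARIATES))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stats_payload(stats) -> list[dict]:
    return [{"id": s.variant_id, "beta": _num(s.beta), "se": _num(s.se),
             "p": _num(s.p), "n": s.n, "r2_partial": _num(s.r2_partial),
             "n_het": s.n_het, "n_hom": s.n_hom, "note": s.note}
            for s in stats]


def _num(x):
    x = float(x)
    return None if not np.isfinite(x) else x


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow; returns the run report as a plain dict.

    Stage failures are recorded under ``errors`` with the stage name and
    the partial report is preserved.  If ``config.outdir`` is set, the
    report JSON, per-stage TSVs and the resolved config are written there.
    """
    report: dict = {"config": config.to_dict(), "stages": {}, "errors": []}
    stages = report["stages"]

    def run_stage(name, fn):
        try:
            stages[name] = fn()
            return True
        except Exception as exc:
            logger.exception("stage %s failed", name)
            report["errors"].append({"stage": name, "error": str(exc)})
            return False

    state: dict = {}

    # --- cohort acquisition -------------------------------------------------
    def acquire():
        if config.sim_params is not None:
            params = dataclasses.replace(config.sim_params,
                                         seed=stage_seed(config.seed, "simulate"))
            cohort = synthetic.simulate_cohort(params)
            if config.spike_variant is not None:
                cohort = synthetic.spike_pleiotropy(
                    cohort, config.spike_variant, config.spike_dm_logodds,
                    seed=stage_seed(config.seed, "spike"))
            src = "synthetic"
        else:
            cohort = cio.read_cohort(config.genotype_path, config.phenotype_path,
                                     config.genotype_format)
            src = str(config.genotype_path)
        state["preqc"] = cohort
        return {"source": src, "n_samples": cohort.n_samples,
                "n_variants": cohort.n_variants}

    if not run_stage("cohort", acquire):
        return _finalise(report, config)

    # --- QC ------------------------------------------------------------------
    def qc():
        preqc = state["preqc"]
        rare_ids = [vid for vid, row in preqc.variants.iterrows()
                    if np.isfinite(row.get("maf", np.nan))
                    and row["maf"] < config.rare_maf_max
                    and locus._is_nonsynonymous(str(row.get("annotation", "") or ""))]
        cohort, qc_report = cio.apply_qc(
            preqc,
            variant_call_rate_min=config.variant_call_rate_min,
            sample_call_rate_min=config.sample_call_rate_min,
            maf_min=config.maf_min,
            hwe_alpha=config.hwe_alpha,
            keep_rare=rare_ids,
        )
        state["cohort"] = cohort
        state["rare_ids"] = rare_ids
        return {"report": qc_report.to_dict(), "rare_exempt": rare_ids}

    if not run_stage("qc", qc):
        return _finalise(report, config)

    cohort = state["cohort"]
    trait = assoc.log10_trait(cohort.phenotypes["ldl_mgdl"])
    state["trait"] = trait
    covs = tuple(config.covariates)

    # --- exposure scan -------------------------------------------------------
    def scan():
        stats = assoc.assoc_scan(cohort, trait, covs)
        state["scan"] = {s.variant_id: s for s in stats}
        return {"assoc": _stats_payload(stats),
                "bonferroni_alpha": bonferroni_alpha(0.05, config.bonferroni_traits)}

    run_stage("exposure_scan", scan)

    # --- locus dissection ----------------------------------------------------
    def dissect():
        common = [vid for vid in cohort.variant_ids
                  if cohort.variants.loc[vid, "maf"] >= config.maf_min]
        rounds = locus.conditional_scan(cohort, trait, covs, common,
                                        alpha=config.instrument_alpha)
        lead_stats = [state["scan"][r.lead_variant] for r in rounds
                      if r.lead_variant in state["scan"]]
        pruned = locus.prune_by_ld(lead_stats, cohort.dosages, config.r2_max,
                                   provenance="conditional")
        rare_stats = locus.rare_variant_pass(state["preqc"], assoc.log10_trait(
            state["preqc"].phenotypes["ldl_mgdl"]), covs,
            maf_max=config.rare_maf_max)
        rare_sig = [s for s in rare_stats if s.defined and s.p < config.alpha_gw]
        instrument_rows = pruned.table.copy()
        extra = pd.DataFrame({
            "id": [s.variant_id for s in rare_sig],
            "beta": [s.beta for s in rare_sig],
            "se": [s.se for s in rare_sig],
            "p": [s.p for s in rare_sig],
            "provenance": "rare_pass",
        })
        extra = extra[~extra["id"].isin(instrument_rows["id"])]
        instruments = locus.InstrumentSet(
            table=pd.concat([instrument_rows, extra], ignore_index=True))
        state["rounds"] = rounds
        state["instruments"] = instruments
        return {
            "conditional_rounds": [dataclasses.asdict(r) for r in rounds],
            "rare_pass": _stats_payload(rare_stats),
            "instruments": instruments.table.to_dict(orient="records"),
        }

    run_stage("locus_dissection", dissect)

    # --- stepwise variance partition ----------------------------------------
    def stepwise():
        inst_ids = [v for v in state["instruments"].variant_ids
                    if v in cohort.dosages.columns]
        cand = cohort.dosages[inst_ids].apply(
            lambda col: col.fillna(2.0 * cohort.variants.loc[col.name, "aaf"]))
        res = locus.stepwise_select(trait, cand,
                                    cohort.phenotypes[list(covs)].astype(float))
        return {"entered": res.entered,
                "r2_increment": {k: _num(v) for k, v in res.r2_increment.items()},
                "genetic_r2_total": _num(sum(res.r2_increment.values())),
                "removed": res.removed, "warning": res.warning}

    run_stage("stepwise", stepwise)

    # --- exclusion-restriction filter ----------------------------------------
    def pleio():
        inst_ids = [v for v in state["instruments"].variant_ids
                    if v in cohort.dosages.columns]
        kept, excluded = mr.pleiotropy_filter(
            cohort, inst_ids, trait, cohort.phenotypes["dm"], covs,
            alpha=config.pleiotropy_alpha)
        state["kept_ids"] = [k for k, _ in kept]
        return {"kept": [{"id": k, "p": _num(p)} for k, p in kept],
                "excluded": [{"id": k, "p": _num(p), "reason": r}
                             for k, p, r in excluded]}

    run_stage("pleiotropy_filter", pleio)

    # --- WGRS + two-stage least squares --------------------------------------
    def iv_stage():
        kept_ids = state.get("kept_ids", [])
        if not kept_ids:
            raise ValueError("no instruments survive the pleiotropy filter")
        inst = state["instruments"].table
        inst = inst[inst["id"].isin(kept_ids)]
        weights = mr.GRSWeights.from_instruments(
            locus.InstrumentSet(table=inst), cohort.variants)
        score = mr.build_wgrs(cohort, weights)
        est = mr.two_stage_ls(cohort, score, trait, cohort.phenotypes["dm"], covs)
        state["score"] = score
        state["kept_table"] = inst
        return {"weights": weights.table.to_dict(orient="records"),
                "two_stage_ls": est.to_dict()}

    run_stage("iv_analysis", iv_stage)

    # --- summary-level sensitivity battery ------------------------------------
    def sensitivity():
        inst = state["kept_table"]
        rows = []
        for _, r in inst.iterrows():
            g = cohort.dosages[r["id"]].astype(float)
            g = g.fillna(2.0 * cohort.variants.loc[r["id"], "aaf"])
            X = pd.concat([g.rename(r["id"]).reset_index(drop=True),
                           cohort.phenotypes[list(covs)].astype(float)
                           .reset_index(drop=True)], axis=1)
            fit = assoc.fit_logistic(cohort.phenotypes["dm"].to_numpy(dtype=float), X)
            if not fit.converged:
                logger.warning("outcome scan for %s did not converge; skipped", r["id"])
                continue
            rows.append({"id": r["id"], "beta_exp": r["beta"], "se_exp": r["se"],
                         "beta_out": float(fit.params[r["id"]]),
                         "se_out": float(fit.bse[r["id"]])})
        summary = mr.MRSummarySet(pd.DataFrame(rows))
        state["summary"] = summary
        out = {"summary": summary.table.to_dict(orient="records")}
        out["ivw"] = mr.ivw(summary).to_dict()
        if len(summary) >= 3:
            slope, intercept = mr.egger(summary)
            out["egger_slope"] = slope.to_dict()
            out["egger_intercept"] = intercept.to_dict()
            simple, weighted = mr.median_estimators(
                summary, n_boot=config.n_boot,
                seed=stage_seed(config.seed, "median_bootstrap"))
            out["simple_median"] = simple.to_dict()
            out["weighted_median"] = weighted.to_dict()
        out["funnel"] = mr.funnel_data(summary).to_dict(orient="records")
        return out

    run_stage("sensitivity", sensitivity)

    return _finalise(report, config)


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a run report."""
    return json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"


def _finalise(report: dict, config: PipelineConfig) -> dict:
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "run_report.json").write_text(report_json(report))
        config.to_yaml(outdir / "config.yaml")
        sens = report["stages"].get("sensitivity")
        if sens:
            pd.DataFrame(sens["summary"]).to_csv(outdir / "mr_summary.tsv",
                                                 sep="\t", index=False)
            pd.DataFrame(sens["funnel"]).to_csv(outdir / "funnel.tsv",
                                                sep="\t", index=False)
    return report
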