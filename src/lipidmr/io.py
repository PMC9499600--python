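"""Cohort container, file formats and quality control.

A :class:`Cohort` couples a sample × variant dosage matrix (alternate-allele
counts 0/1/2, NaN for missing) with a variant table and a phenotype table.
Genotypes are read from minimal biallelic VCF 4.2 (GT field, via cyvcf2) or
from a dosage TSV (variants as rows, samples as columns, ``NA`` missing —
defined here because no standard dialect exists).  QC applies the standard
filters: sample call rate, variant call rate, Hardy-Weinberg equilibrium
and minor-allele frequency, in that order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import assoc

logger = logging.getLogger("lipidmr")

PHENOTYPE_COLUMNS = ("ldl_mgdl", "dm", "age", "sex", "bmi", "smoking")

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "annotation",
                   "call_rate", "aaf", "maf", "hwe_p")


@dataclass
class VariantRecord:
    """Identity, annotation and QC statistics of one biallelic variant."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    annotation: str = ""
    call_rate: float = float("nan")
    aaf: float = float("nan")
    maf: float = float("nan")
    hwe_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be 1-based (got {self.pos})")


@dataclass
class QCReport:
    """Counts of variants and samples removed by each QC filter."""

    n_variants_in: int = 0
    n_removed_callrate: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_samples_in: int = 0
    n_samples_removed_callrate: int = 0

    @property
    def n_variants_kept(self) -> int:
        return (self.n_variants_in - self.n_removed_callrate
                - self.n_removed_maf - self.n_removed_hwe)

    @property
    def n_samples_kept(self) -> int:
        return self.n_samples_in - self.n_samples_removed_callrate

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_variants_kept"] = self.n_variants_kept
        d["n_samples_kept"] = self.n_samples_kept
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


@dataclass
class Cohort:
    """The analytic unit: dosages, variant metadata and phenotypes.

    ``dosages``: DataFrame (samples × variants), entries in {0, 1, 2, NaN}.
    ``variants``: DataFrame indexed by variant id with VARIANT_COLUMNS.
    ``phenotypes``: DataFrame with PHENOTYPE_COLUMNS, same index as dosages.
    ``extras``: generator-side state (confounder draws, parameters) carried
    along so fixtures like pleiotropy spiking can re-draw outcomes.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame
    phenotypes: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.dosages) != len(self.phenotypes):
            raise ValueError(
                f"dosage rows ({len(self.dosages)}) != phenotype rows ({len(self.phenotypes)})"
            )
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        ldl = self.phenotypes["ldl_mgdl"].to_numpy(dtype=float)
        if not (ldl > 0).all():
            raise ValueError("ldl_mgdl must be strictly positive")

    @property
    def n_samples(self) -> int:
        return len(self.dosages)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def variant_records(self) -> list[VariantRecord]:
        recs = []
        for vid, row in self.variants.iterrows():
            recs.append(VariantRecord(id=str(vid), chrom=str(row["chrom"]),
                                      pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                                      annotation=row.get("annotation", ""),
                                      call_rate=row.get("call_rate", float("nan")),
                                      aaf=row.get("aaf", float("nan")),
                                      maf=row.get("maf", float("nan")),
                                      hwe_p=row.get("hwe_p", float("nan"))))
        return recs

    def subset(self, *, variants: Sequence[str] | None = None,
               samples: Sequence | None = None) -> "Cohort":
        dos, var, phe = self.dosages, self.variants, self.phenotypes
        if variants is not None:
            dos = dos[list(variants)]
            var = var.loc[list(variants)]
        if samples is not None:
            dos = dos.loc[list(samples)]
            phe = phe.loc[list(samples)]
        return Cohort(dos.copy(), var.copy(), phe.copy(), dict(self.extras))


# ---------------------------------------------------------------------------
# per-variant statistics
# ---------------------------------------------------------------------------

def compute_variant_stats(dosages: pd.DataFrame) -> pd.DataFrame:
    """Call rate, alt-allele frequency, MAF and HWE p per variant."""
    rows = {}
    n = len(dosages)
    for vid in dosages.columns:
        g = dosages[vid].to_numpy(dtype=float)
        called = np.isfinite(g)
        counts = assoc.genotype_counts(g)
        if called.sum() == 0:
            rows[vid] = dict(call_rate=0.0, aaf=np.nan, maf=np.nan, hwe_p=np.nan)
            continue
        aaf, maf = assoc.maf_from_counts(*counts)
        rows[vid] = dict(call_rate=called.sum() / n, aaf=aaf, maf=maf,
                         hwe_p=assoc.hwe_test(*counts))
    return pd.DataFrame.from_dict(rows, orient="index")


def refresh_variant_stats(cohort: Cohort) -> Cohort:
    """Recompute QC statistics on the current dosage matrix."""
    stats = compute_variant_stats(cohort.dosages)
    var = cohort.variants.copy()
    for col in stats.columns:
        var[col] = stats[col]
    return Cohort(cohort.dosages, var, cohort.phenotypes, cohort.extras)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(cohort: Cohort, path) -> None:
    """Write genotypes as minimal biallelic VCF 4.2 with GT calls."""
    path = Path(path)
    samples = [f"S{i:06d}" for i in range(cohort.n_samples)]
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANN,Number=1,Type=String,Description="Functional annotation">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(cohort.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = cohort.variants.sort_values(["chrom", "pos"]).index
        for vid in order:
            v = cohort.variants.loc[vid]
            g = cohort.dosages[vid].to_numpy(dtype=float)
            gts = "\t".join(_GT_STRINGS.get(x, "./.") for x in g)
            # percent-encode characters reserved in INFO fields
            from urllib.parse import quote

            ann = quote(str(v.get("annotation", "") or "."), safe=":.,_-/>()")
            fh.write(f"{v['chrom']}\t{int(v['pos'])}\t{vid}\t{v['ref']}\t{v['alt']}"
                     f"\t.\t.\tANN={ann}\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a biallelic SNV VCF into (dosages, variant table).

    Dosage is the alternate-allele count; ``./.`` becomes NaN.  Sample
    order is preserved.  Multiallelic sites and indels are rejected with an
    error naming the site, mirroring an SNV-only pipeline.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosage_cols: dict[str, np.ndarray] = {}
    var_rows: dict[str, dict] = {}
    for rec in vcf:
        site = f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic site not supported: {site} "
                             f"(ALT alleles: {','.join(rec.ALT)})")
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ValueError(f"non-SNV record rejected: {site} {rec.REF}>{rec.ALT[0]}")
        vid = rec.ID or site
        # gts012: 0/1/2 = alt count, 3 = unknown
        g = rec.gt_types.astype(float)
        g[g == 3] = np.nan
        dosage_cols[vid] = g
        from urllib.parse import unquote

        ann = dict(rec.INFO).get("ANN", "")
        var_rows[vid] = dict(chrom=str(rec.CHROM), pos=int(rec.POS),
                             ref=rec.REF, alt=rec.ALT[0],
                             annotation="" if ann in (".", None) else unquote(str(ann)))
    dosages = pd.DataFrame(dosage_cols, index=pd.Index(samples, name="sample"))
    variants = pd.DataFrame.from_dict(var_rows, orient="index")
    stats = compute_variant_stats(dosages)
    variants = variants.join(stats)
    return dosages, variants


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def write_dosage_tsv(cohort: Cohort, path) -> None:
    """Dosage TSV: variants as rows, samples as columns, NA for missing."""
    df = cohort.dosages.T
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_dosage_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    dosages = df.T.astype(float)
    bad = ~(dosages.isna() | dosages.isin([0.0, 1.0, 2.0]))
    if bad.to_numpy().any():
        vid = dosages.columns[bad.any(axis=0)][0]
        raise ValueError(f"dosage TSV contains non-genotype values at variant {vid}")
    variants = pd.DataFrame(index=dosages.columns,
                            data=dict(chrom="NA", pos=1, ref="N", alt="N", annotation=""))
    variants = variants.join(compute_variant_stats(dosages))
    return dosages, variants


def read_genotypes(path, format: str = "vcf") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dispatch genotype reading by format ('vcf' or 'dosage_tsv')."""
    if format == "vcf":
        return read_vcf(path)
    if format == "dosage_tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_phenotypes(cohort: Cohort, path) -> None:
    cohort.phenotypes[list(PHENOTYPE_COLUMNS)].to_csv(path, sep="\t", index=False,
                                                      na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df[list(PHENOTYPE_COLUMNS)]


def write_cohort(cohort: Cohort, outdir, *, params: dict | None = None) -> dict:
    """Write VCF + phenotype TSV (+ optional provenance sidecar JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": outdir / "genotypes.vcf",
             "phenotypes": outdir / "phenotypes.tsv"}
    write_vcf(cohort, paths["vcf"])
    write_phenotypes(cohort, paths["phenotypes"])
    if params is not None:
        paths["params"] = outdir / "sim_params.json"
        Path(paths["params"]).write_text(json.dumps(params, indent=2, sort_keys=True,
                                                    default=str) + "\n")
    return {k: str(v) for k, v in paths.items()}


def read_cohort(genotype_path, phenotype_path, format: str = "vcf") -> Cohort:
    dosages, variants = read_genotypes(genotype_path, format)
    phenotypes = read_phenotypes(phenotype_path)
    if len(phenotypes) != len(dosages):
        raise ValueError(
            f"phenotype rows ({len(phenotypes)}) != genotype samples ({len(dosages)})"
        )
    phenotypes.index = dosages.index
    return Cohort(dosages, variants, phenotypes)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_qc(
    cohort: Cohort,
    variant_call_rate_min: float = 0.97,
    sample_call_rate_min: float = 0.97,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
    keep_rare: Iterable[str] = (),
) -> tuple[Cohort, QCReport]:
    """Standard genotype QC: samples, then variant call rate, HWE, MAF.

    Variants listed in ``keep_rare`` are exempt from the MAF filter only
    (rare coding variants analysed separately on pre-QC data stay available
    downstream); they are still subject to call-rate and HWE filters.
    Filters are applied in a fixed order because the order changes the
    removal counts; statistics are recomputed on retained samples before
    the variant filters run.
    """
    for name, thr in [("variant_call_rate_min", variant_call_rate_min),
                      ("sample_call_rate_min", sample_call_rate_min),
                      ("maf_min", maf_min), ("hwe_alpha", hwe_alpha)]:
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    keep_rare = set(keep_rare)
    report = QCReport(n_variants_in=cohort.n_variants, n_samples_in=cohort.n_samples)

    # 1. sample call rate
    called = cohort.dosages.notna().to_numpy()
    sample_cr = called.mean(axis=1) if cohort.n_variants else np.ones(cohort.n_samples)
    keep_samples = sample_cr >= sample_call_rate_min
    report.n_samples_removed_callrate = int((~keep_samples).sum())
    dosages = cohort.dosages.loc[keep_samples]
    phenotypes = cohort.phenotypes.loc[keep_samples]

    # recompute variant stats on retained samples
    stats = compute_variant_stats(dosages)

    # 2. variant call rate, 3. HWE, 4. MAF (order fixed; each variant is
    # counted against the first filter it fails)
    removed_cr = stats.index[stats["call_rate"] < variant_call_rate_min]
    remaining = stats.drop(index=removed_cr)
    removed_hwe = remaining.index[remaining["hwe_p"] < hwe_alpha]
    remaining = remaining.drop(index=removed_hwe)
    maf_fail = remaining["maf"].fillna(0.0) < maf_min
    removed_maf = [v for v in remaining.index[maf_fail] if v not in keep_rare]

    report.n_removed_callrate = len(removed_cr)
    report.n_removed_hwe = len(removed_hwe)
    report.n_removed_maf = len(removed_maf)

    kept = [v for v in cohort.dosages.columns
            if v not in set(removed_cr) | set(removed_hwe) | set(removed_maf)]
    variants = cohort.variants.loc[kept].copy()
    for col in stats.columns:
        variants[col] = stats.loc[kept, col]
    out = Cohort(dosages[kept].copy(), variants, phenotypes.copy(), dict(cohort.extras))
    logger.info("QC: %d/%d variants, %d/%d samples retained",
                report.n_variants_kept, report.n_variants_in,
                report.n_samples_kept, report.n_samples_in)
    return out, report
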