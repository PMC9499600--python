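import numpy as np
import pandas as pd
import pytest

from lipidmr import Cohort, SimParams, VariantSim, simulate_cohort


def make_cohort(dosages: dict, ldl=None, dm=None, n=None) -> Cohort:
    """Hand-build a small cohort around explicit dosage vectors."""
    dos = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in dosages.items()})
    n = len(dos) if n is None else n
    rng = np.random.default_rng(0)
    variants = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, dos.shape[1] + 1) * 100,
         "ref": "A", "alt": "G", "annotation": ""},
        index=pd.Index(dos.columns, name="id"))
    from lipidmr import compute_variant_stats

    variants = variants.join(compute_variant_stats(dos))
    phenotypes = pd.DataFrame({
        "ldl_mgdl": np.full(n, 120.0) if ldl is None else np.asarray(ldl, float),
        "dm": np.zeros(n, dtype=int) if dm is None else np.asarray(dm, int),
        "age": rng.normal(50, 10, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "bmi": rng.normal(24, 3, n),
        "smoking": rng.integers(0, 2, n).astype(float),
    })
    return Cohort(dos, variants, phenotypes)


@pytest.fixture(scope="session")
def seven_variant_cohort() -> Cohort:
    """One full-size draw from the default seven-variant emulation."""
    return simulate_cohort(SimParams(seed=20240901))


@pytest.fixture(scope="session")
def strong_effect_params() -> SimParams:
    """Small cohort with effects sized for essentially full power."""
    variants = [
        VariantSim("chr1_a", maf=0.30, beta_log10_ldl=0.06, pos=1000),
        VariantSim("chr1_b", maf=0.25, beta_log10_ldl=-0.05, pos=2000),
        VariantSim("chr1_c", maf=0.20, beta_log10_ldl=0.04, pos=3000),
        VariantSim("chr1_rare", maf=0.003, beta_log10_ldl=-0.25, pos=4000,
                   annotation="exon2:c.C10T:p.R4C"),
        VariantSim("chr1_null", maf=0.15, beta_log10_ldl=0.0, pos=5000),
    ]
    return SimParams(n_samples=6000, variants=variants, seed=5)
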