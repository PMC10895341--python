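import numpy as np
import pandas as pd
import pytest

from vdrmr.simulate import CohortData, SimCohortParams, simulate_cohort


def make_cohort(dosages: dict, covariates: pd.DataFrame | None = None,
                status=None, info: float | dict = 1.0,
                study_label: str = "TOY") -> CohortData:
    """Hand-built cohort for unit tests; defaults fill in bland covariates."""
    d = pd.DataFrame(dosages, dtype=float)
    n = len(d)
    d.index = [f"s{i}" for i in range(n)]
    if covariates is None:
        rng = np.random.default_rng(0)
        covariates = pd.DataFrame({
            "sex": np.where(np.arange(n) % 2 == 0, "F", "M"),
            "birth_year": 1950 + (np.arange(n) % 40),
            "hla_count": np.arange(n) % 3,
            **{f"pc{j}": rng.normal(size=n) for j in range(1, 7)},
        }, index=d.index)
    if status is None:
        status = pd.Series((np.arange(n) % 2), index=d.index, name="status")
    else:
        status = pd.Series(status, index=d.index, name="status")
    info_map = info if isinstance(info, dict) else {c: info for c in d.columns}
    meta = pd.DataFrame({
        "chrom": "1",
        "pos": (np.arange(d.shape[1]) + 1) * 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": d.mean(axis=0, skipna=True) / 2.0,
        "info": [info_map[c] for c in d.columns],
        "is_vdr_bv": True,
    }, index=pd.Index(d.columns, name="rsID"))
    return CohortData(study_label=study_label, dosages=d, variant_meta=meta,
                      covariates=covariates, status=status)


@pytest.fixture(scope="session")
def sim_cohort() -> CohortData:
    """A moderate simulated cohort shared across read-only tests."""
    return simulate_cohort(SimCohortParams(n_cases=1500, n_controls=1500,
                                           beta_vdr=np.log(1.3), seed=42))
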