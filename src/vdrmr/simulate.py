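"""Synthetic case-control cohorts and allele-specific ChIP-exo counts.

This module provides the generative counterpart of the analysis models in
:mod:`vdrmr.assoc`: cohorts are drawn from a logistic disease model whose
right-hand side contains genetic instruments for VDR binding (GIV_VDR,
dosage x binding effect), a multi-SNP 25(OH)D genetic score (GIV_25OHD),
their product, and the standard adjustment covariates (sex, birth-year
quintiles, HLA-DRB1*15:01 carriage, six principal components).  Case-control
ascertainment is emulated by simulating a population pool under the model
and sampling the requested numbers of cases and controls from it.

ChIP-exo allelic read counts at heterozygous sites are drawn as
total ~ Poisson(lambda) per site and sample, with the reference-allele
count Binomial(total, pi); pi = 0.5 at null sites and pi != 0.5 at sites
with genuine allele-specific binding.  The ground-truth labels travel in a
separate attribute so that calling code never sees them.

A packaged fixture carries the published per-study case/control summary
counts (sample sizes, sex, HLA carriage, birth year, 25(OH)D score means)
for the four studies (KPNC, UKB, GSA, OMNI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovariateEffects",
    "SimCohortParams",
    "CohortData",
    "SimAsbParams",
    "AsbDataset",
    "CohortSummary",
    "SummaryTable",
    "simulate_cohort",
    "simulate_chipexo",
    "load_cohort_summary",
    "summarize_cohorts",
]

# Population constants used by the generator: allele frequency of
# HLA-DRB1*15:01 in Europeans (~0.15, giving ~28% carriage), female
# population fraction, and the birth-year distribution of the study era.
HLA_ALLELE_FREQ = 0.15
FEMALE_FRACTION = 0.5
BIRTH_YEAR_MEAN = 1960.0
BIRTH_YEAR_SD = 12.0


@dataclass
class CovariateEffects:
    """Log-odds-ratios of the adjustment covariates in the disease model.

    Defaults reflect the epidemiology of multiple sclerosis: roughly
    threefold odds in females and threefold odds per HLA-DRB1*15:01
    carriage, which reproduce the ~75% female and ~55%-case / ~27%-control
    carriage fractions seen in the study populations.  Birth-year quintile
    and PC effects default to zero.
    """

    sex_female: float = float(np.log(3.0))
    hla_carrier: float = float(np.log(3.0))
    birth_year_quintiles: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    pcs: tuple[float, ...] = (0.0,) * 6


@dataclass
class SimCohortParams:
    """Parameters of the generative case-control model for one study.

    ``beta_vdr`` is the log-OR per unit GIV_VDR acting through binding
    (the causal path), ``beta_pleio`` the log-OR acting outside binding
    (horizontal pleiotropy); the two are summed in generation and exist
    separately for scenario control.  Each of ``beta_vdr``, ``beta_pleio``
    and ``beta_interaction`` may be a scalar (broadcast over all VDR
    binding variants) or a vector of length ``n_vdr_bvs``.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    maf_vdr_bv: float | Sequence[float] = 0.3
    n_vdr_bvs: int = 1
    n_score_snps: int = 8
    score_snp_betas: Sequence[float] | None = None
    score_snp_mafs: Sequence[float] | None = None
    beta0: float = 0.0
    beta_vdr: float | Sequence[float] = 0.0
    beta_pleio: float | Sequence[float] = 0.0
    beta_25ohd: float = 0.0
    beta_interaction: float | Sequence[float] = 0.0
    vdr_binding_betas: float | Sequence[float] = 1.0
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    missing_rate: float = 0.0
    seed: int = 0
    study_label: str = "SIM"

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        mafs = np.broadcast_to(np.asarray(self.maf_vdr_bv, float), (self.n_vdr_bvs,))
        if np.any(mafs <= 0) or np.any(mafs > 0.5):
            raise ValueError("maf_vdr_bv must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_vdr_bvs < 1:
            raise ValueError("n_vdr_bvs must be >= 1")
        if self.n_score_snps < 1:
            raise ValueError("n_score_snps must be >= 1")


@dataclass
class CohortData:
    """Individual-level data for one study.

    ``dosages`` holds effect-allele dosages in [0, 2] (NaN where missing),
    one row per individual, one column per variant.  ``variant_meta`` is
    indexed by rsID with columns effect_allele, other_allele, eaf, info and
    an ``is_vdr_bv`` flag; ``covariates`` carries sex ('M'/'F'), birth_year,
    hla_count (0/1/2) and pc1..pc6; ``status`` is the 0/1 case indicator.
    """

    study_label: str
    dosages: pd.DataFrame
    variant_meta: pd.DataFrame
    covariates: pd.DataFrame
    status: pd.Series
    attrs: dict = field(default_factory=dict)

    def validate(self) -> None:
        d = self.dosages.to_numpy(float)
        ok = np.isnan(d) | ((d >= 0) & (d <= 2))
        if not ok.all():
            raise ValueError("dosages must be missing or in [0, 2]")
        if len(self.covariates) != len(self.dosages):
            raise ValueError("covariate rows must match dosage rows")
        s = set(self.status.unique())
        if not {0, 1} <= s:
            raise ValueError("status must contain both cases and controls")

    @property
    def n_cases(self) -> int:
        return int((self.status == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    def vdr_variant_ids(self) -> list[str]:
        return list(self.variant_meta.index[self.variant_meta["is_vdr_bv"]])

    def score_variant_ids(self) -> list[str]:
        return list(self.variant_meta.index[~self.variant_meta["is_vdr_bv"]])


@dataclass
class SimAsbParams:
    """Parameters of the ChIP-exo allelic-count generator.

    ``n_samples`` defaults to 16 heterozygous cell lines; ``mean_coverage``
    is the Poisson read rate per site and sample; ``frac_true_bv`` of the
    sites carry genuine allelic imbalance with reference-allele ratio
    ``pi_alt`` (0.5 elsewhere).
    """

    n_sites: int = 1000
    n_samples: int = 16
    mean_coverage: float = 20.0
    frac_true_bv: float = 0.0
    pi_alt: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if not 0.0 < self.pi_alt < 1.0:
            raise ValueError("pi_alt must lie in (0, 1)")
        if self.pi_alt == 0.5 and self.frac_true_bv > 0:
            raise ValueError("pi_alt = 0.5 makes 'true' sites indistinguishable from null")
        if not 0.0 <= self.frac_true_bv <= 1.0:
            raise ValueError("frac_true_bv must lie in [0, 1]")
        if self.n_sites < 1 or self.n_samples < 1:
            raise ValueError("n_sites and n_samples must be >= 1")


@dataclass
class AsbDataset:
    """Allele-specific read counts at heterozygous sites.

    ``counts`` has one row per site x sample with columns site_id, chrom,
    pos, sample_id, ref_reads, alt_reads; ``sites`` carries per-site
    alleles.  ``truth`` (which may be None for real data) is hidden
    simulation metadata: per-site is_true_bv flag and the generating pi.
    """

    counts: pd.DataFrame
    sites: pd.DataFrame
    truth: pd.DataFrame | None = None


class SimulationError(RuntimeError):
    """Raised when rejection sampling cannot reach the requested counts."""


def _broadcast(value, n: int) -> np.ndarray:
    return np.broadcast_to(np.asarray(value, float), (n,)).copy()


def birth_year_quintile_indicators(birth_year: np.ndarray) -> np.ndarray:
    """Four 0/1 indicator columns for within-sample birth-year quintiles 2-5.

    Quintile 1 is the reference.  Ties at the quintile edges go to the lower
    quintile (pandas ``qcut`` convention with duplicate edges dropped).
    """
    q = pd.qcut(pd.Series(birth_year).rank(method="first"), 5, labels=False)
    return np.column_stack([(q == j).astype(float) for j in range(1, 5)])


def _covariate_lp(cov: pd.DataFrame, eff: CovariateEffects) -> np.ndarray:
    lp = np.zeros(len(cov))
    lp += eff.sex_female * (cov["sex"] == "F").to_numpy(float)
    lp += eff.hla_carrier * (cov["hla_count"] > 0).to_numpy(float)
    quint = birth_year_quintile_indicators(cov["birth_year"].to_numpy(float))
    lp += quint @ np.asarray(eff.birth_year_quintiles, float)
    pcs = cov[[f"pc{j}" for j in range(1, 7)]].to_numpy(float)
    lp += pcs @ np.asarray(eff.pcs, float)
    return lp


def _draw_pool(rng: np.random.Generator, n: int, params: SimCohortParams,
               vdr_mafs: np.ndarray, score_mafs: np.ndarray,
               score_betas: np.ndarray):
    """One chunk of the unascertained population under the disease model."""
    vdr_dos = rng.binomial(2, vdr_mafs, size=(n, params.n_vdr_bvs)).astype(float)
    score_dos = rng.binomial(2, score_mafs, size=(n, params.n_score_snps)).astype(float)
    cov = pd.DataFrame({
        "sex": np.where(rng.random(n) < FEMALE_FRACTION, "F", "M"),
        "birth_year": np.round(rng.normal(BIRTH_YEAR_MEAN, BIRTH_YEAR_SD, n)).astype(int),
        "hla_count": rng.binomial(2, HLA_ALLELE_FREQ, n),
    })
    for j in range(1, 7):
        cov[f"pc{j}"] = rng.normal(size=n)

    binding = _broadcast(params.vdr_binding_betas, params.n_vdr_bvs)
    giv_vdr = vdr_dos * binding  # individuals x variants
    giv_d = score_dos @ score_betas

    b_main = _broadcast(params.beta_vdr, params.n_vdr_bvs) + _broadcast(
        params.beta_pleio, params.n_vdr_bvs)
    b_int = _broadcast(params.beta_interaction, params.n_vdr_bvs)
    lp = params.beta0 + giv_vdr @ b_main + params.beta_25ohd * giv_d
    lp += (giv_vdr * giv_d[:, None]) @ b_int
    lp += _covariate_lp(cov, params.covariate_effects)
    from scipy.special import expit

    status = rng.binomial(1, expit(lp))
    return vdr_dos, score_dos, cov, status


def simulate_cohort(params: SimCohortParams) -> CohortData:
    """Simulate one ascertained case-control study.

    A population pool is drawn under the logistic disease model and the
    requested numbers of cases and controls are sampled from it without
    replacement (additional pool chunks are drawn as needed).  Missing
    dosages are then injected completely at random at ``missing_rate``.
    Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    vdr_mafs = _broadcast(params.maf_vdr_bv, params.n_vdr_bvs)
    if params.score_snp_mafs is None:
        score_mafs = rng.uniform(0.1, 0.5, params.n_score_snps)
    else:
        score_mafs = _broadcast(params.score_snp_mafs, params.n_score_snps)
    if params.score_snp_betas is None:
        # per-SD-scale GWAS effects of a typical 25(OH)D instrument
        score_betas = rng.normal(0.0, 0.05, params.n_score_snps)
    else:
        score_betas = _broadcast(params.score_snp_betas, params.n_score_snps)

    need = params.n_cases + params.n_controls
    chunk = max(2 * need, 2000)
    parts, n_cases_seen, n_ctrl_seen, n_drawn = [], 0, 0, 0
    max_draw = 1000 * need
    while n_cases_seen < params.n_cases or n_ctrl_seen < params.n_controls:
        if n_drawn >= max_draw:
            frac = n_cases_seen / max(1, n_drawn)
            raise SimulationError(
                f"could not ascertain {params.n_cases} cases and "
                f"{params.n_controls} controls after {n_drawn} draws; "
                f"expected case fraction under this model is ~{frac:.4g}")
        parts.append(_draw_pool(rng, chunk, params, vdr_mafs, score_mafs, score_betas))
        n_drawn += chunk
        n_cases_seen = sum(int(p[3].sum()) for p in parts)
        n_ctrl_seen = n_drawn - n_cases_seen

    vdr_dos = np.vstack([p[0] for p in parts])
    score_dos = np.vstack([p[1] for p in parts])
    cov = pd.concat([p[2] for p in parts], ignore_index=True)
    status = np.concatenate([p[3] for p in parts])
    pool_case_fraction = float(status.mean())

    case_idx = np.flatnonzero(status == 1)[: params.n_cases]
    ctrl_idx = np.flatnonzero(status == 0)[: params.n_controls]
    keep = np.concatenate([case_idx, ctrl_idx])
    keep = rng.permutation(keep)

    vdr_ids = [f"rsVDR{j + 1:04d}" for j in range(params.n_vdr_bvs)]
    score_ids = [f"rsD{k + 1:04d}" for k in range(params.n_score_snps)]
    dos = np.hstack([vdr_dos[keep], score_dos[keep]])
    if params.missing_rate > 0:
        mask = rng.random(dos.shape) < params.missing_rate
        dos = dos.copy()
        dos[mask] = np.nan

    sample_ids = [f"{params.study_label}_{i + 1:06d}" for i in range(len(keep))]
    dosages = pd.DataFrame(dos, index=sample_ids, columns=vdr_ids + score_ids)
    covariates = cov.iloc[keep].reset_index(drop=True)
    covariates.index = pd.Index(sample_ids)
    status_s = pd.Series(status[keep], index=sample_ids, name="status")

    eaf = np.nanmean(dos, axis=0) / 2.0
    variant_meta = pd.DataFrame({
        "chrom": ["1"] * params.n_vdr_bvs + ["2"] * params.n_score_snps,
        "pos": (np.arange(params.n_vdr_bvs + params.n_score_snps) + 1) * 100_000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": eaf,
        "info": 1.0,
        "is_vdr_bv": [True] * params.n_vdr_bvs + [False] * params.n_score_snps,
    }, index=pd.Index(vdr_ids + score_ids, name="rsID"))

    binding = _broadcast(params.vdr_binding_betas, params.n_vdr_bvs)
    cohort = CohortData(
        study_label=params.study_label,
        dosages=dosages,
        variant_meta=variant_meta,
        covariates=covariates,
        status=status_s,
        attrs={
            "pool_case_fraction": pool_case_fraction,
            "pool_n": n_drawn,
            "seed": params.seed,
            "vdr_binding_betas": dict(zip(vdr_ids, binding.tolist())),
            "score_snp_betas": dict(zip(score_ids, score_betas.tolist())),
        },
    )
    cohort.validate()
    return cohort


def simulate_chipexo(params: SimAsbParams) -> AsbDataset:
    """Simulate allele-specific ChIP-exo read counts across cell lines.

    Per site and sample the read total is Poisson(``mean_coverage``); the
    reference count is Binomial(total, pi) with pi = ``pi_alt`` at true
    binding-variant sites and 0.5 at null sites.  Deterministic given
    ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_true = int(round(params.frac_true_bv * params.n_sites))
    is_true = np.zeros(params.n_sites, dtype=bool)
    is_true[rng.choice(params.n_sites, size=n_true, replace=False)] = True
    pi = np.where(is_true, params.pi_alt, 0.5)

    site_ids = [f"site{j + 1:05d}" for j in range(params.n_sites)]
    totals = rng.poisson(params.mean_coverage,
                         size=(params.n_sites, params.n_samples))
    refs = rng.binomial(totals, pi[:, None])
    alts = totals - refs

    chrom = np.full(params.n_sites, "1")
    pos = (np.arange(params.n_sites) + 1) * 1000
    counts = pd.DataFrame({
        "site_id": np.repeat(site_ids, params.n_samples),
        "chrom": np.repeat(chrom, params.n_samples),
        "pos": np.repeat(pos, params.n_samples),
        "sample_id": np.tile([f"LCL{s + 1:02d}" for s in range(params.n_samples)],
                             params.n_sites),
        "ref_reads": refs.ravel(),
        "alt_reads": alts.ravel(),
    })
    sites = pd.DataFrame({
        "site_id": site_ids, "chrom": chrom, "pos": pos,
        "ref": "C", "alt": "T",
    }).set_index("site_id")
    truth = pd.DataFrame({"site_id": site_ids, "is_true_bv": is_true, "pi": pi}
                         ).set_index("site_id")
    return AsbDataset(counts=counts, sites=sites, truth=truth)


@dataclass
class CohortSummary:
    """Published per-study, per-group summary counts (Table-style layout)."""

    table: pd.DataFrame

    def validate(self) -> None:
        t = self.table
        if (t["n_female"] > t["n"]).any() or (t["n_hla_carrier"] > t["n"]).any():
            raise ValueError("group counts cannot exceed group size")


def load_cohort_summary() -> CohortSummary:
    """Load the packaged per-study case/control characteristics fixture."""
    ref = resources.files("vdrmr.data") / "cohort_summary.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    expected = {"study", "group", "n", "n_male", "n_female",
                "n_hla_noncarrier", "n_hla_carrier"}
    if not expected <= set(table.columns):
        raise IOError("cohort summary fixture is missing required columns")
    summary = CohortSummary(table=table)
    summary.validate()
    return summary


@dataclass
class SummaryTable:
    """Derived per-group percentages plus across-study totals."""

    table: pd.DataFrame
    totals: dict


def summarize_cohorts(summary: CohortSummary) -> SummaryTable:
    """Recompute group percentages and across-study totals from raw counts.

    Percentages (female %, male %, HLA-carrier and non-carrier %) are
    rounded to one decimal, matching the convention of published
    characteristics tables.
    """
    t = summary.table.copy()
    n = t["n"].astype(float)
    for col, pct in [("n_male", "male_pct"), ("n_female", "female_pct"),
                     ("n_hla_noncarrier", "hla_noncarrier_pct"),
                     ("n_hla_carrier", "hla_carrier_pct")]:
        t[pct] = (100.0 * t[col] / n).round(1)
    by_group = t.groupby("group")["n"].sum()
    totals = {
        "total_cases": int(by_group.get("case", 0)),
        "total_controls": int(by_group.get("control", 0)),
        "total_n": int(t["n"].sum()),
        "n_studies": int(t["study"].nunique()),
    }
    return SummaryTable(table=t, totals=totals)
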