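"""Genetic instrumental variables for VDR binding and 25(OH)D.

A genetic instrumental variable (GIV) is a weighted allele-dosage score
used as a proxy for an exposure in Mendelian randomization.  For VDR
binding the instrument is a single binding variant:

    GIV_VDR[i] = dosage[i] * beta_binding

and for serum 25(OH)D it is the usual multi-SNP weighted sum over
genome-wide significant, LD-clumped GWAS variants:

    GIV_25OHD[i] = sum_k beta_k * dosage[i, k]

Dosages count the effect allele named by each weight; cohorts storing the
opposite allele are flipped (d -> 2 - d) when the allele pair matches
exactly, and strand-ambiguous pairs (A/T, C/G) raise rather than guess.
The module also provides genotype QC (info score, per-SNP and per-sample
missingness, MAF), within-study mean-dosage imputation of residual
missingness, greedy LD clumping of summary statistics, and pairwise r2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .simulate import CohortData

__all__ = [
    "VariantWeight",
    "QcThresholds",
    "ClumpParams",
    "qc_filter",
    "mean_impute",
    "clump",
    "compute_giv_vdr",
    "compute_giv_25ohd",
    "ld_r2",
    "ld_lookup_from_dosages",
    "AlleleMismatchError",
    "EmptyPanelError",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AlleleMismatchError(ValueError):
    """Neither allele of a weight matches the cohort variant, or the pair
    is strand-ambiguous and would require a flip."""


class EmptyPanelError(ValueError):
    """QC removed every variant."""


@dataclass(frozen=True)
class VariantWeight:
    """Per-variant instrument weight (effect size of the effect allele)."""

    rsID: str
    effect_allele: str
    beta: float
    p_value: float = 1.0
    chrom: str = "."
    pos: int = 0
    other_allele: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.pos < 0:
            raise ValueError("position must be nonnegative")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


@dataclass(frozen=True)
class QcThresholds:
    """Genotype QC thresholds; all comparisons are strict as stated."""

    min_info: float = 0.8
    max_snp_missing: float = 0.05
    max_sample_missing: float = 0.05
    min_maf: float = 0.05

    def __post_init__(self):
        for v in (self.min_info, self.max_snp_missing,
                  self.max_sample_missing, self.min_maf):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class ClumpParams:
    """Greedy LD-clumping parameters (p threshold, window, r2 ceiling)."""

    p_threshold: float = 1e-8
    window_kb: int = 10_000
    r2_threshold: float = 0.001

    def __post_init__(self):
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in [0, 1]")


def qc_filter(cohort: CohortData, thresholds: QcThresholds = QcThresholds()
              ) -> CohortData:
    """Drop variants failing info / missingness / MAF and samples failing
    per-sample missingness.

    MAF is min(f, 1 - f) of the effect-allele frequency among non-missing
    calls; variants are kept only when info > min_info, missingness <
    max_snp_missing and MAF > min_maf (strict, as the thresholds are
    stated).  Variant filters are applied first, then samples with too
    many missing calls on the surviving panel are dropped.
    """
    d = cohort.dosages
    n = len(d)
    miss_frac = d.isna().sum(axis=0) / n
    with np.errstate(invalid="ignore"):
        eaf = d.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)
    info = cohort.variant_meta.loc[d.columns, "info"]
    keep_var = (info > thresholds.min_info).to_numpy() \
        & (miss_frac < thresholds.max_snp_missing).to_numpy() \
        & (maf > thresholds.min_maf).to_numpy()
    kept_cols = d.columns[keep_var]
    if len(kept_cols) == 0:
        raise EmptyPanelError("QC removed every variant from the panel")

    d2 = d[kept_cols]
    sample_miss = d2.isna().sum(axis=1) / len(kept_cols)
    keep_sample = sample_miss < thresholds.max_sample_missing
    out = CohortData(
        study_label=cohort.study_label,
        dosages=d2.loc[keep_sample],
        variant_meta=cohort.variant_meta.loc[kept_cols],
        covariates=cohort.covariates.loc[keep_sample],
        status=cohort.status.loc[keep_sample],
        attrs={**cohort.attrs,
               "qc_variants_dropped": int((~keep_var).sum()),
               "qc_samples_dropped": int((~keep_sample).sum())},
    )
    out.validate()
    return out


def mean_impute(cohort: CohortData) -> CohortData:
    """Replace each missing dosage with twice the within-study
    effect-allele frequency among non-missing calls for that variant."""
    d = cohort.dosages
    n_obs = d.notna().sum(axis=0)
    if (n_obs == 0).any():
        bad = list(d.columns[n_obs == 0])
        raise ValueError(f"variants with no observed calls (QC should have "
                         f"removed them): {bad}")
    fill = d.mean(axis=0, skipna=True)  # = 2 * effect-allele frequency
    out = CohortData(
        study_label=cohort.study_label,
        dosages=d.fillna(fill),
        variant_meta=cohort.variant_meta,
        covariates=cohort.covariates,
        status=cohort.status,
        attrs={**cohort.attrs,
               "n_imputed_dosages": int(d.isna().sum().sum())},
    )
    out.validate()
    return out


LdLookup = Callable[[str, str], float]


def _as_ld_fn(ld) -> LdLookup:
    if callable(ld):
        return ld

    def fn(a: str, b: str) -> float:
        if (a, b) in ld:
            return float(ld[(a, b)])
        if (b, a) in ld:
            return float(ld[(b, a)])
        raise KeyError(f"no LD entry for pair ({a}, {b})")

    return fn


def clump(weights: Sequence[VariantWeight], ld, params: ClumpParams = ClumpParams()
          ) -> list[VariantWeight]:
    """Greedy LD clumping of summary statistics.

    Variants are visited in ascending p order (ties broken by chromosome,
    position, rsID); a variant is accepted iff its p-value passes the
    threshold and it has r2 below the ceiling with every already-accepted
    variant on the same chromosome within the window.  ``ld`` is either a
    callable (rsID, rsID) -> r2 or a mapping keyed by rsID pairs.
    """
    ld_fn = _as_ld_fn(ld)
    ordered = sorted(weights, key=lambda w: (w.p_value, w.chrom, w.pos, w.rsID))
    accepted: list[VariantWeight] = []
    window_bp = params.window_kb * 1000
    for w in ordered:
        if not w.p_value < params.p_threshold:
            continue
        ok = True
        for a in accepted:
            if a.chrom != w.chrom or abs(a.pos - w.pos) > window_bp:
                continue
            if ld_fn(a.rsID, w.rsID) >= params.r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(w)
    return accepted


def _oriented_dosage(cohort: CohortData, weight: VariantWeight) -> pd.Series:
    """Dosage of the weight's effect allele, flipping orientation if the
    cohort stores the other allele.  Exact allele-pair matching only."""
    if weight.rsID not in cohort.dosages.columns:
        raise KeyError(f"variant {weight.rsID} absent from cohort "
                       f"{cohort.study_label}")
    meta = cohort.variant_meta.loc[weight.rsID]
    ea, oa = str(meta["effect_allele"]), str(meta["other_allele"])
    d = cohort.dosages[weight.rsID]
    if weight.effect_allele == ea:
        if weight.other_allele is not None and weight.other_allele != oa:
            raise AlleleMismatchError(
                f"{weight.rsID}: allele pair {weight.effect_allele}/"
                f"{weight.other_allele} does not match cohort {ea}/{oa}")
        return d
    if weight.effect_allele == oa:
        ambiguous = COMPLEMENT.get(ea) == oa
        if ambiguous:
            raise AlleleMismatchError(
                f"{weight.rsID}: strand-ambiguous allele pair {ea}/{oa} "
                f"would require a flip; refusing to guess strand")
        if weight.other_allele is not None and weight.other_allele != ea:
            raise AlleleMismatchError(
                f"{weight.rsID}: allele pair does not match cohort {ea}/{oa}")
        return 2.0 - d
    raise AlleleMismatchError(
        f"{weight.rsID}: effect allele {weight.effect_allele} matches "
        f"neither cohort allele ({ea}/{oa})")


def compute_giv_vdr(cohort: CohortData, weight: VariantWeight) -> pd.Series:
    """Single-variant instrument: oriented dosage times the binding beta."""
    score = _oriented_dosage(cohort, weight) * weight.beta
    score.name = f"giv_vdr_{weight.rsID}"
    return score


def compute_giv_25ohd(cohort: CohortData, weights: Sequence[VariantWeight]
                      ) -> pd.DataFrame:
    """Multi-SNP 25(OH)D instrument: plain weighted sum of oriented dosages.

    Returns a frame with the per-individual ``score`` and
    ``n_variants_used``, the number of weight variants found in the cohort
    (PLINK --score semantics with averaging disabled).
    """
    present = [w for w in weights if w.rsID in cohort.dosages.columns]
    if not present:
        raise KeyError("no weight variant overlaps the cohort panel")
    score = pd.Series(0.0, index=cohort.dosages.index)
    for w in present:
        score = score + _oriented_dosage(cohort, w) * w.beta
    return pd.DataFrame({"score": score,
                         "n_variants_used": len(present)})


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosage_a, float)
    b = np.asarray(dosage_b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("dosage vectors must have equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("r2 undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_lookup_from_dosages(dosages: pd.DataFrame) -> LdLookup:
    """LD lookup computed on demand from a reference dosage matrix."""

    def fn(a: str, b: str) -> float:
        return ld_r2(dosages[a].to_numpy(), dosages[b].to_numpy())

    return fn
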