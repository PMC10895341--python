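"""Per-study logistic models for MS risk.

Three models are fitted per study, all on the logit scale and all adjusted
for sex, within-study birth-year quintiles (four indicators, first
quintile as reference), HLA-DRB1*15:01 carriage (0 vs >= 1 allele) and
the first six principal components:

    main (25(OH)D):    logit P(MS) = b0 + b1 * GIV_25OHD      + covariates
    main (VDR):        logit P(MS) = b0 + b1 * GIV_VDR        + covariates
    interaction:       logit P(MS) = b0 + b1 * GIV_VDR + b2 * GIV_25OHD
                                       + b3 * (GIV_VDR x GIV_25OHD) + covariates

b3, the multiplicative interaction between VDR binding at a locus and the
bioavailability of 25(OH)D, is the pleiotropy-robust causal test: a
pleiotropic path from the binding variant to disease that bypasses VDR
binding has no reason to depend on circulating 25(OH)D, so a significantly
non-zero b3 is evidence that the binding variant's association with MS is
causal rather than pleiotropic.

The maximum-likelihood machinery is statsmodels' Logit (Newton iterations,
i.e. iteratively reweighted least squares for the logit link) wrapped with
explicit rank, convergence and separation error contracts.  Inference is
Wald throughout: SE from the inverse observed information and normal-based
95% CIs on the odds-ratio scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

from .simulate import CohortData, birth_year_quintile_indicators

__all__ = [
    "ModelSpec",
    "AssocResult",
    "CaseControlLogit",
    "CaseControlLogitResults",
    "fit_logistic",
    "fit_main_model",
    "fit_interaction_model",
    "ConvergenceError",
    "SeparationError",
    "RankDeficiencyError",
]

ADJUSTMENT_COLUMNS = ("sex_F", "byq2", "byq3", "byq4", "byq5",
                      "hla_carrier", "pc1", "pc2", "pc3", "pc4", "pc5", "pc6")


class ConvergenceError(RuntimeError):
    pass


class SeparationError(RuntimeError):
    pass


class RankDeficiencyError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Ordered predictor terms plus the standard adjustment set."""

    terms: tuple[str, ...]
    adjust: bool = True

    def __post_init__(self):
        product = [t for t in self.terms if ":" in t]
        for t in product:
            a, b = t.split(":", 1)
            if a not in self.terms or b not in self.terms:
                raise ValueError(
                    "interaction model must contain both main terms "
                    f"of the product {t}")


@dataclass
class AssocResult:
    """One model term in one study: log-OR, SE, Wald p, 95% CI."""

    term: str
    log_or: float
    se: float
    p_value: float
    or_ci95: tuple[float, float]
    study_label: str = ""
    n_cases: int = 0
    n_controls: int = 0

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))


def _adjustment_design(cohort: CohortData) -> pd.DataFrame:
    cov = cohort.covariates
    quint = birth_year_quintile_indicators(cov["birth_year"].to_numpy(float))
    out = pd.DataFrame(index=cov.index)
    out["sex_F"] = (cov["sex"] == "F").astype(float)
    for j in range(4):
        out[["byq2", "byq3", "byq4", "byq5"][j]] = quint[:, j]
    out["hla_carrier"] = (cov["hla_count"] > 0).astype(float)
    for j in range(1, 7):
        out[f"pc{j}"] = cov[f"pc{j}"].astype(float)
    return out


def fit_logistic(design: pd.DataFrame, outcome, tol: float = 1e-8,
                 max_iter: int = 50) -> pd.DataFrame:
    """Maximum-likelihood logistic fit with explicit failure contracts.

    Returns a coefficient table (index = design columns) with estimate,
    se, z and p_value.  Raises ``RankDeficiencyError`` for a singular
    design, ``SeparationError`` when the data are (quasi-)separated and
    ``ConvergenceError`` when Newton fails to converge in ``max_iter``.
    """
    X = np.asarray(design, float)
    y = np.asarray(outcome, float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes coded 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=max_iter,
                                     tol=tol, disp=0, warn_convergence=False)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"separation detected: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix during Newton iteration "
                f"(separation or collinearity): {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"Newton did not converge within {max_iter} iterations")
    fitted = res.predict()
    if ((fitted < 1e-10) | (fitted > 1 - 1e-10)).any() \
            and np.abs(res.params).max() > 20:
        raise SeparationError("fitted probabilities within 1e-10 of 0/1 "
                              "with diverging coefficients")
    est = res.params
    se = res.bse
    z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"estimate": est, "se": se, "z": z, "p_value": p},
                        index=list(design.columns))


class CaseControlLogit:
    """Logistic case-control model of MS risk on genetic instruments.

    Parameters
    ----------
    cohort
        Individual-level study data (post QC/imputation).
    giv_vdr, giv_25ohd
        Per-individual instrument scores aligned to the cohort index.
        Supply one for a main-effect model, both (with
        ``interaction=True``) for the interaction model.
    interaction
        Add the GIV_VDR x GIV_25OHD product term.
    standardize_25ohd
        Standardize GIV_25OHD within study before entering the model
        (off by default: raw scores).
    """

    def __init__(self, cohort: CohortData, giv_vdr: pd.Series | None = None,
                 giv_25ohd: pd.Series | None = None, interaction: bool = False,
                 standardize_25ohd: bool = False, adjust: bool = True):
        if giv_vdr is None and giv_25ohd is None:
            raise ValueError("supply at least one instrument score")
        if interaction and (giv_vdr is None or giv_25ohd is None):
            raise ValueError("interaction model needs both instruments")
        self.cohort = cohort
        self.standardize_25ohd = standardize_25ohd
        design = pd.DataFrame(index=cohort.dosages.index)
        design["const"] = 1.0
        terms = ["const"]
        if giv_vdr is not None:
            design["giv_vdr"] = np.asarray(giv_vdr, float)
            terms.append("giv_vdr")
        if giv_25ohd is not None:
            d = np.asarray(giv_25ohd, float)
            if standardize_25ohd:
                d = (d - d.mean()) / d.std(ddof=1)
            design["giv_25ohd"] = d
            terms.append("giv_25ohd")
        if interaction:
            design["giv_vdr:giv_25ohd"] = (design["giv_vdr"]
                                           * design["giv_25ohd"])
            terms.append("giv_vdr:giv_25ohd")
        if adjust:
            adj = _adjustment_design(cohort)
            design = pd.concat([design, adj], axis=1)
        self.spec = ModelSpec(terms=tuple(terms), adjust=adjust)
        self.design = design
        self.outcome = cohort.status.astype(float)

    def fit(self, tol: float = 1e-8, max_iter: int = 50
            ) -> "CaseControlLogitResults":
        table = fit_logistic(self.design, self.outcome, tol=tol,
                             max_iter=max_iter)
        return CaseControlLogitResults(self, table)


class CaseControlLogitResults:
    """Fitted per-study model: estimates, Wald SEs and a summary table."""

    def __init__(self, model: CaseControlLogit, table: pd.DataFrame):
        self.model = model
        self.table = table
        self.params = table["estimate"]
        self.bse = table["se"]
        self.pvalues = table["p_value"]

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "low": self.params - z * self.bse,
            "high": self.params + z * self.bse,
        })

    def term_result(self, term: str) -> AssocResult:
        row = self.table.loc[term]
        lo, hi = self.conf_int().loc[term]
        return AssocResult(
            term=term, log_or=float(row["estimate"]), se=float(row["se"]),
            p_value=float(row["p_value"]),
            or_ci95=(float(np.exp(lo)), float(np.exp(hi))),
            study_label=self.model.cohort.study_label,
            n_cases=self.model.cohort.n_cases,
            n_controls=self.model.cohort.n_controls)

    def summary(self) -> str:
        ci = self.conf_int()
        out = self.table.copy()
        out["or"] = np.exp(out["estimate"])
        out["or_ci_low"] = np.exp(ci["low"])
        out["or_ci_high"] = np.exp(ci["high"])
        c = self.model.cohort
        head = (f"Case-control logistic model [{c.study_label}] "
                f"({c.n_cases} cases / {c.n_controls} controls)\n")
        return head + out.to_string(float_format=lambda v: f"{v:.6g}")


def fit_main_model(cohort: CohortData, giv: pd.Series, term: str = "giv",
                   standardize_25ohd: bool = False, **fit_kw) -> AssocResult:
    """Main-effect model for a single instrument with full adjustment.

    ``term`` names the instrument in the result ('giv_vdr' or
    'giv_25ohd'-style labels are conventional).
    """
    if term == "giv_25ohd" or standardize_25ohd:
        model = CaseControlLogit(cohort, giv_25ohd=giv,
                                 standardize_25ohd=standardize_25ohd)
        res = model.fit(**fit_kw).term_result("giv_25ohd")
    else:
        model = CaseControlLogit(cohort, giv_vdr=giv)
        res = model.fit(**fit_kw).term_result("giv_vdr")
    res.term = term
    return res


def fit_interaction_model(cohort: CohortData, giv_vdr: pd.Series,
                          giv_25ohd: pd.Series,
                          standardize_25ohd: bool = False,
                          **fit_kw) -> dict[str, AssocResult]:
    """Interaction model; returns results for b1, b2 and the b3 product term."""
    model = CaseControlLogit(cohort, giv_vdr=giv_vdr, giv_25ohd=giv_25ohd,
                             interaction=True,
                             standardize_25ohd=standardize_25ohd)
    res = model.fit(**fit_kw)
    return {t: res.term_result(t)
            for t in ("giv_vdr", "giv_25ohd", "giv_vdr:giv_25ohd")}
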