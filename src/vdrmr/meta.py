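"""DerSimonian-Laird random-effects meta-analysis and BH FDR.

Study-specific log-odds-ratios theta_i with standard errors se_i are
pooled with the moment-based DerSimonian-Laird estimator of the
between-study variance tau^2:

    w_i   = 1 / se_i^2                         (fixed-effect weights)
    Q     = sum w_i (theta_i - theta_FE)^2     (Cochran's Q)
    tau^2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w))
    w*_i  = 1 / (se_i^2 + tau^2)               (random-effects weights)

with the pooled estimate sum(w* theta) / sum(w*), pooled SE
1 / sqrt(sum w*), heterogeneity p from the chi-square survival function of
Q at k - 1 df, and I^2 = max(0, (Q - df) / Q) * 100 on the percent scale.
With a single study the pooled result is the study itself (tau^2 = Q = 0,
p_Q = 1, I^2 = 0).  Q uses fixed-effect weights and is not iterated, and
no small-sample (Hartung-Knapp) adjustment is applied.

Families of meta-analyzed p-values (for example all single-variant VDR
instruments under one model, or all interaction terms for one 25(OH)D
instrument) are corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssocResult

__all__ = ["MetaResult", "dl_meta", "bh_adjust", "meta_analyze_family"]


@dataclass
class MetaResult:
    """Pooled random-effects estimate with heterogeneity statistics."""

    pooled_log_or: float
    pooled_se: float
    p_value: float
    tau2: float
    Q: float
    df: int
    p_Q: float
    I2: float
    k: int

    @property
    def or_ci95(self) -> tuple[float, float]:
        lo = self.pooled_log_or - 1.96 * self.pooled_se
        hi = self.pooled_log_or + 1.96 * self.pooled_se
        return float(np.exp(lo)), float(np.exp(hi))

    @property
    def pooled_or(self) -> float:
        return float(np.exp(self.pooled_log_or))

    def summary(self) -> str:
        lo, hi = self.or_ci95
        return (f"Random-effects meta-analysis (DerSimonian-Laird), "
                f"k={self.k} studies\n"
                f"  OR {self.pooled_or:.4f} (95% CI {lo:.4f}-{hi:.4f}), "
                f"p={self.p_value:.3g}\n"
                f"  tau2={self.tau2:.4g}, Q={self.Q:.4g} (df={self.df}, "
                f"p_Q={self.p_Q:.3g}), I2={self.I2:.1f}%")


def dl_meta(estimates: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Pool per-study log-ORs by DerSimonian-Laird random effects."""
    theta = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    if theta.size == 0:
        raise ValueError("at least one study is required")
    if theta.shape != se.shape:
        raise ValueError("estimates and ses must have equal length")
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("all standard errors must be positive and finite")
    k = theta.size
    if k == 1:
        est, pse = float(theta[0]), float(se[0])
        p = float(2 * stats.norm.sf(abs(est / pse)))
        return MetaResult(est, pse, p, tau2=0.0, Q=0.0, df=0, p_Q=1.0,
                          I2=0.0, k=1)
    w = 1.0 / se**2
    theta_fe = float((w * theta).sum() / w.sum())
    Q = float((w * (theta - theta_fe) ** 2).sum())
    df = k - 1
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - df) / denom)
    ws = 1.0 / (se**2 + tau2)
    pooled = float((ws * theta).sum() / ws.sum())
    pooled_se = float(1.0 / np.sqrt(ws.sum()))
    p = float(2 * stats.norm.sf(abs(pooled / pooled_se)))
    p_q = float(stats.chi2.sf(Q, df))
    i2 = 0.0 if Q <= df or Q == 0 else (Q - df) / Q * 100.0
    return MetaResult(pooled, pooled_se, p, tau2=float(tau2), Q=Q, df=df,
                      p_Q=p_q, I2=float(i2), k=k)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    p~_(i) = min_{j >= i} min(1, p_(j) * m / j) over the ascending order
    statistics; monotone and idempotent.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def meta_analyze_family(results: Mapping[str, Sequence[AssocResult]],
                        family: str = "") -> pd.DataFrame:
    """Meta-analyze each instrument and BH-correct across the family.

    ``results`` maps instrument labels to their per-study results (>= 1
    each).  Returns one row per instrument with the pooled estimate,
    heterogeneity statistics and ``p_fdr``; row order follows the sorted
    instrument labels, so permuting the input leaves the output unchanged.
    """
    rows = []
    for instrument in sorted(results):
        per_study = results[instrument]
        if len(per_study) == 0:
            raise ValueError(f"instrument {instrument} has no study results")
        mr = dl_meta([r.log_or for r in per_study],
                     [r.se for r in per_study])
        lo, hi = mr.or_ci95
        rows.append({
            "family": family, "instrument": instrument, "k": mr.k,
            "pooled_log_or": mr.pooled_log_or, "pooled_se": mr.pooled_se,
            "pooled_or": mr.pooled_or, "ci_low": lo, "ci_high": hi,
            "p": mr.p_value, "tau2": mr.tau2, "Q": mr.Q, "p_Q": mr.p_Q,
            "I2_percent": mr.I2,
        })
    table = pd.DataFrame(rows)
    table["p_fdr"] = bh_adjust(table["p"].to_numpy())
    return table
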