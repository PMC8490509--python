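"""Stem-cell frequency estimation from limiting-dilution assays.

A limiting-dilution assay (LDA) seeds decreasing cell doses (here 1-500
cells/well in vitro, 1-1,000 for tumor-derived cells) and scores each well
positive/negative for an outgrowth response.  Under the single-hit Poisson
model every cell responds independently with probability f (the active-cell
frequency), so

    P(well at dose d responds) = 1 - exp(-f * d).

This is a binomial GLM with a complementary log-log link and log(dose)
offset: cloglog(p) = log f + log d.  The MLE of log f, its Wald 95% CI and
a deviance goodness-of-fit against the saturated per-dose model follow from
the GLM fit; boundary designs (no responding wells, or every well
responding) get one-sided profile-likelihood bounds instead.  Two groups
are compared by a likelihood-ratio test of a shared f versus group-specific
frequencies (df = 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "DilutionGroup",
    "FrequencyEstimate",
    "fit_single_hit",
    "compare_frequencies",
]

_CHI2_95 = 3.841458820694124  # chi2.ppf(0.95, 1)


@dataclass(frozen=True)
class DilutionGroup:
    """One limiting-dilution design: dose, wells tested, wells responding."""

    dose: np.ndarray
    tested: np.ndarray
    responding: np.ndarray
    label: str = "group"

    def __post_init__(self) -> None:
        d = np.asarray(self.dose)
        n = np.asarray(self.tested)
        y = np.asarray(self.responding)
        if not (len(d) == len(n) == len(y)) or len(d) == 0:
            raise ValueError("need >= 1 aligned (dose, tested, responding) rows")
        if np.any(d < 1) or np.any(d != np.floor(d)):
            raise ValueError("doses must be integers >= 1")
        if np.any(n < 1):
            raise ValueError("tested must be >= 1")
        if np.any(y < 0) or np.any(y > n):
            raise ValueError("responding must satisfy 0 <= y <= tested")
        object.__setattr__(self, "dose", d.astype(float))
        object.__setattr__(self, "tested", n.astype(float))
        object.__setattr__(self, "responding", y.astype(float))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "group") -> "DilutionGroup":
        return cls(
            dose=df["dose"].to_numpy(),
            tested=df["tested"].to_numpy(),
            responding=df["responding"].to_numpy(),
            label=label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose": self.dose.astype(int), "tested": self.tested.astype(int),
             "responding": self.responding.astype(int)}
        )

    @property
    def all_negative(self) -> bool:
        return bool(np.all(self.responding == 0))

    @property
    def all_positive(self) -> bool:
        return bool(np.all(self.responding == self.tested))


@dataclass(frozen=True)
class FrequencyEstimate:
    """Fitted active-cell frequency with 95% CI and fit diagnostics."""

    f_hat: float
    ci_lower: float
    ci_upper: float
    log_likelihood: float
    deviance: float
    deviance_df: int
    boundary: str | None = None  # None | "all_negative" | "all_positive"
    label: str = "group"

    @property
    def one_in(self) -> float:
        """Frequency as '1 in N' (inf at the zero boundary)."""
        return math.inf if self.f_hat == 0 else 1.0 / self.f_hat

    def as_dict(self) -> dict[str, float]:
        return {
            "frequency": self.f_hat,
            "one_in": self.one_in,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "log_likelihood": self.log_likelihood,
            "deviance": self.deviance,
            "deviance_df": self.deviance_df,
            "boundary": self.boundary or "",
        }


def _loglik(f: float, groups: list[DilutionGroup]) -> float:
    """Binomial log-likelihood at frequency f (no combinatorial constants)."""
    if f < 0:
        return -math.inf
    ll = 0.0
    for g in groups:
        lam = f * g.dose
        p = -np.expm1(-lam)
        pos = g.responding > 0
        if f == 0 and np.any(pos):
            return -math.inf
        with np.errstate(divide="ignore"):
            ll += float(np.sum(np.where(pos, g.responding * np.log(np.maximum(p, 1e-300)), 0.0)))
        ll -= float(np.sum((g.tested - g.responding) * lam))
    return ll


def _fit_mle(groups: list[DilutionGroup]) -> tuple[float, float | None]:
    """MLE of f (and SE of log f) via the cloglog-link binomial GLM."""
    dose = np.concatenate([g.dose for g in groups])
    n = np.concatenate([g.tested for g in groups])
    y = np.concatenate([g.responding for g in groups])
    endog = np.column_stack([y, n - y])
    exog = np.ones((len(dose), 1))
    model = sm.GLM(
        endog, exog,
        family=sm.families.Binomial(link=sm.families.links.CLogLog()),
        offset=np.log(dose),
    )
    with warnings.catch_warnings():
        # single-dose designs have zero residual df; the scale is fixed at 1
        # for the binomial family, so the estimate-of-scale warning is moot
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(tol=1e-12, maxiter=200)
    beta = float(res.params[0])
    se = float(res.bse[0])
    return math.exp(beta), se


def _saturated_loglik(groups: list[DilutionGroup]) -> float:
    ll = 0.0
    for g in groups:
        p = g.responding / g.tested
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(g.responding > 0, g.responding * np.log(p), 0.0) + np.where(
                g.tested - g.responding > 0, (g.tested - g.responding) * np.log(1 - p), 0.0
            )
        ll += float(np.sum(term))
    return ll


def fit_single_hit(group: DilutionGroup) -> FrequencyEstimate:
    """Estimate the active-cell frequency of one limiting-dilution group.

    Interior designs use the GLM MLE with a Wald 95% CI on log f.  With no
    responding wells f_hat is 0 with a one-sided 95% profile upper bound
    (closed form 1.921 / sum(n*d)); with every well responding f_hat is
    reported at the upper boundary 1 with a one-sided profile lower bound,
    both flagged.
    """
    if group.all_negative:
        upper = min(1.0, (_CHI2_95 / 2.0) / float(np.sum(group.tested * group.dose)))
        return FrequencyEstimate(
            0.0, 0.0, upper, 0.0, 0.0, len(group.dose),
            boundary="all_negative", label=group.label,
        )
    if group.all_positive:
        # profile lower bound: smallest f whose LR against the boundary
        # supremum (loglik -> 0) stays within the 95% chi-square band
        def dev(logf: float) -> float:
            return -2.0 * _loglik(math.exp(logf), [group]) - _CHI2_95

        hi = 0.0  # f = 1
        lo = math.log(1e-12)
        lower = math.exp(optimize.brentq(dev, lo, hi)) if dev(lo) > 0 else 0.0
        return FrequencyEstimate(
            1.0, lower, 1.0, _loglik(1.0, [group]), 0.0, len(group.dose),
            boundary="all_positive", label=group.label,
        )
    f_hat, se = _fit_mle([group])
    z = stats.norm.ppf(0.975)
    lo = f_hat * math.exp(-z * se)
    hi = f_hat * math.exp(z * se)
    ll = _loglik(f_hat, [group])
    deviance = 2.0 * (_saturated_loglik([group]) - ll)
    return FrequencyEstimate(
        min(f_hat, 1.0), min(lo, 1.0), min(hi, 1.0), ll,
        max(deviance, 0.0), len(group.dose) - 1, label=group.label,
    )


def _group_max_loglik(group: DilutionGroup) -> float:
    if group.all_negative:
        return 0.0
    if group.all_positive:
        return 0.0  # supremum as f -> inf
    f_hat, _ = _fit_mle([group])
    return _loglik(f_hat, [group])


def compare_frequencies(a: DilutionGroup, b: DilutionGroup) -> tuple[float, int, float]:
    """Likelihood-ratio test of shared vs group-specific frequency.

    Returns (chi-square statistic, df=1, p-value).  Undefined when both
    groups are degenerate (all wells negative, or all wells positive).
    """
    a_deg = a.all_negative or a.all_positive
    b_deg = b.all_negative or b.all_positive
    if a_deg and b_deg:
        raise ValueError("test undefined: both groups are degenerate")
    ll_sep = _group_max_loglik(a) + _group_max_loglik(b)
    # at most one group is degenerate, so the pooled MLE is interior
    f_pool, _ = _fit_mle([a, b])
    ll_pool = _loglik(f_pool, [a, b])
    stat = max(0.0, 2.0 * (ll_sep - ll_pool))
    return stat, 1, float(stats.chi2.sf(stat, 1))
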