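"""Country-by-factor interaction analysis.

Whether a prognostic factor acts differently in the two countries is tested
by comparing two nested federated Cox fits on identical cohorts and event
grids: the reduced model with all main effects, and the full model adding
the block of country x factor product columns. The likelihood-ratio
statistic 2(ll_full - ll_reduced) is referred to a chi-square with one
degree of freedom per interaction column (a factor with L levels contributes
L-1 columns against the single country dummy). The test is joint over the
factor's whole interaction block, one factor at a time, with every other
main effect kept as adjustment.

From the full model, per-country hazard ratios follow by composing
coefficients: with Taiwan the reference country and level l of the factor,

    HR_TW(l) = exp(beta_l)
    HR_NL(l) = exp(beta_country + beta_l + beta_{country x l})

relative to the (reference level, Taiwan) cell; standard errors come from
the delta method on the coefficient sum (a linear form, so the variance is
g' Sigma g with g the 0/1 selector of the summed coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fed_cox import Z_95, CoxFit, FitOptions, fit_federated_cox
from .fed_infra import FederatedServer
from .registry_model import ModelSpec

__all__ = [
    "LRTResult",
    "fit_interaction_model",
    "lrt",
    "country_specific_hrs",
]


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of an interaction block."""

    statistic: float
    df: int
    p_value: float
    factor: str


def fit_interaction_model(
    server: FederatedServer,
    base_spec: ModelSpec,
    factor: str,
    sites: list[str] | None = None,
    options: FitOptions = FitOptions(),
    country_var: str = "country",
) -> tuple[CoxFit, CoxFit]:
    """Fit the full (with country x factor block) and reduced models.

    Both fits run federatedly on the same sites, hence identical cohorts and
    event grids; the reduced model is ``base_spec`` itself.
    """
    variables = [b.variable for b in base_spec.covariate_blocks]
    if factor not in variables:
        raise ValueError(f"factor {factor!r} is not a main effect of the base model")
    if country_var not in variables:
        raise ValueError(f"{country_var!r} is not a main effect of the base model")
    reduced = fit_federated_cox(server, base_spec, sites=sites, options=options)
    full_spec = base_spec.with_interaction(factor, country_var)
    full = fit_federated_cox(server, full_spec, sites=sites, options=options)
    return full, reduced


def lrt(full: CoxFit, reduced: CoxFit, factor: str = "") -> LRTResult:
    """Likelihood-ratio test of the columns present in full but not reduced."""
    if not set(reduced.labels) <= set(full.labels):
        extra = sorted(set(reduced.labels) - set(full.labels))
        raise ValueError(f"models are not nested; reduced-only columns: {extra}")
    df = len(full.labels) - len(reduced.labels)
    if df < 1:
        raise ValueError("full model adds no columns over the reduced model")
    statistic = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p_value = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return LRTResult(statistic=statistic, df=df, p_value=p_value, factor=factor)


def country_specific_hrs(
    full: CoxFit,
    factor: str,
    spec: ModelSpec,
    level: float = 0.95,
    country_var: str = "country",
) -> pd.DataFrame:
    """Per-country hazard ratios for every level of *factor*.

    All HRs are relative to the (reference level, reference country) cell,
    which is exactly 1. Requires the full model's covariance matrix.
    """
    if full.covariance is None:
        raise ValueError("fit carries no covariance matrix")
    cblock = spec.block(country_var)
    fblock = spec.block(factor)
    if len(cblock.dummy_levels) != 1:
        raise ValueError("country must be binary for per-country tables")
    other_country = cblock.dummy_levels[0]
    z = Z_95 if abs(level - 0.95) < 1e-12 else float(stats.norm.ppf(0.5 + level / 2.0))
    idx = {lab: i for i, lab in enumerate(full.labels)}

    def combine(labels: list[str]) -> tuple[float, float]:
        g = np.zeros(len(full.labels))
        for lab in labels:
            if lab not in idx:
                raise ValueError(f"label {lab!r} missing from the full model")
            g[idx[lab]] = 1.0
        est = float(g @ full.beta)
        var = float(g @ full.covariance @ g)
        return est, var

    rows = []
    for lev in fblock.levels:
        for country, labels in (
            (cblock.reference, [] if lev == fblock.reference else [f"{factor}={lev}"]),
            (
                other_country,
                [f"{country_var}={other_country}"]
                + ([] if lev == fblock.reference
                   else [f"{factor}={lev}", f"{country_var}={other_country}:{factor}={lev}"]),
            ),
        ):
            if not labels:  # the reference cell
                rows.append(
                    {"factor": factor, "level": lev, "country": country,
                     "hr": 1.0, "ci_low": 1.0, "ci_high": 1.0, "reference": True}
                )
                continue
            est, var = combine(labels)
            se = np.sqrt(var)
            rows.append(
                {
                    "factor": factor,
                    "level": lev,
                    "country": country,
                    "hr": float(np.exp(est)),
                    "ci_low": float(np.exp(est - z * se)),
                    "ci_high": float(np.exp(est + z * se)),
                    "reference": False,
                }
            )
    return pd.DataFrame(rows)
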