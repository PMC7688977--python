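"""Federated descriptive statistics and chi-square comparisons.

Each node returns level counts (for a categorical variable) or a (sum,
count) pair (for a numeric one); the server assembles frequency tables with
column percentages and runs Pearson chi-square tests between countries. No
continuity correction is applied and small cells are not suppressed; a
configurable minimum-cell-size warning (default 10) is logged but never
enforced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fed_infra import FederatedServer, FederationError

__all__ = [
    "FrequencyTable",
    "ChiSquareResult",
    "federated_frequency_table",
    "chi_square",
    "federated_mean",
]

logger = logging.getLogger(__name__)

MIN_CELL_WARNING = 10


@dataclass
class FrequencyTable:
    """Per-site level counts with column percentages."""

    variable: str
    counts: pd.DataFrame  # index: levels, columns: site ids

    @property
    def levels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def percentages(self) -> pd.DataFrame:
        totals = self.totals.replace(0, np.nan)
        return 100.0 * self.counts / totals

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        pct = self.percentages
        for col in self.counts.columns:
            out[f"{col}_pct"] = pct[col].round(1)
        out.insert(0, "variable", self.variable)
        return out.reset_index(names="level")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def federated_frequency_table(
    server: FederatedServer,
    variable: str,
    sites: list[str] | None = None,
    levels: list[str] | None = None,
) -> FrequencyTable:
    """Assemble a frequency table from per-node level counts only.

    If *levels* is given it fixes the row order and levels absent at a site
    count zero; otherwise the union of observed levels is used, but a level
    observed at one site and impossible at another (outside the union logic)
    surfaces naturally as a zero.
    """
    results = server.run("level_counts", payload={"variable": variable}, sites=sites)
    per_site: dict[str, pd.Series] = {}
    observed: set[str] = set()
    for res in results:
        s = pd.Series(
            np.asarray(res.aggregate["counts"], float),
            index=[str(l) for l in res.aggregate["levels"]],
        )
        per_site[res.site_id] = s
        observed.update(s.index)
    if levels is None:
        row_order = sorted(observed)
    else:
        unexpected = observed - set(levels)
        if unexpected:
            raise FederationError(
                f"variable {variable!r}: levels {sorted(unexpected)} observed "
                f"but not in the declared level list"
            )
        row_order = list(levels)
    counts = pd.DataFrame(
        {site: s.reindex(row_order).fillna(0.0) for site, s in per_site.items()}
    )
    small = counts[(counts > 0) & (counts < MIN_CELL_WARNING)]
    if small.notna().to_numpy().any():
        logger.warning(
            "frequency table for %r has cells below %d", variable, MIN_CELL_WARNING
        )
    return FrequencyTable(variable=variable, counts=counts)


def chi_square(table: FrequencyTable | np.ndarray | pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square on an observed table, no continuity correction.

    Expected counts come from the row/column margins; a zero margin is an
    error (the test is undefined).
    """
    obs = table.counts.to_numpy(float) if isinstance(table, FrequencyTable) else np.asarray(table, float)
    if obs.ndim != 2:
        raise FederationError("chi-square needs a 2-D table")
    if np.any(obs.sum(axis=0) <= 0):
        raise FederationError("zero column margin: test undefined")
    obs = obs[obs.sum(axis=1) > 0]  # levels observed nowhere carry no information
    if min(obs.shape) < 2:
        raise FederationError("chi-square needs at least a 2x2 table with positive margins")
    stat, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if np.any(expected <= 0):
        raise FederationError("zero expected cell count")
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def federated_mean(
    server: FederatedServer, variable: str, sites: list[str] | None = None
) -> tuple[float, int]:
    """Pooled mean of a numeric variable from per-site (sum, count) pairs."""
    results = server.run("sum_count", payload={"variable": variable}, sites=sites)
    total = sum(r.aggregate["sum"] for r in results)
    n = sum(r.aggregate["count"] for r in results)
    if n <= 0:
        raise FederationError(f"variable {variable!r}: zero total count")
    return total / n, int(n)
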