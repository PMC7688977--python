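"""Federated Cox proportional-hazards estimation with Breslow ties.

The Cox partial likelihood under Breslow's treatment of ties decomposes over
distinct event times t_k into sums over events and risk sets:

    ll(beta) = sum_k [ beta' s_k  -  d_k * log S0_k(beta) ]

with, at each distinct event time t_k,

    d_k  = number of events at t_k,
    s_k  = sum of covariate vectors of subjects with an event at t_k,
    S0_k = sum_{i: time_i >= t_k} exp(beta' z_i)            (scalar),
    S1_k = sum_{i: time_i >= t_k} z_i exp(beta' z_i)        (length p),
    S2_k = sum_{i: time_i >= t_k} z_i z_i' exp(beta' z_i)   (p x p).

Every one of these quantities is a sum over subjects, so it is additive
across sites: each node computes its own d_k, s_k, S0/S1/S2 on the shared
event-time grid and ships only those aggregates; the server sums them
element-wise and takes a Newton-Raphson step

    U(beta) = sum_k [ s_k - d_k * S1_k / S0_k ]
    I(beta) = sum_k d_k * [ S2_k/S0_k - (S1_k/S0_k)(S1_k/S0_k)' ]
    beta   <- beta + I(beta)^{-1} U(beta)

starting from beta = 0, until the difference between the sums of the
previous and updated hazard ratios, |sum_j exp(beta_j_new) - sum_j
exp(beta_j_old)|, falls below 1e-8 (a max|delta beta| criterion is
selectable). Follow-up is expressed in years with one decimal, which keeps
the event-time grid short (K is tens, not thousands) at the cost of more
ties — which Breslow's method absorbs.

Censored subjects with time equal to an event time stay in the risk set at
that time. Covariates are centered at their federated means before the
linear predictor is formed; the partial likelihood, score, information and
estimates are all invariant to that shift, it only conditions the
exponentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .fed_infra import FederatedServer, FederationError, Node
from .registry_model import ModelSpec, build_design_matrix

__all__ = [
    "EventGrid",
    "SiteAggregates",
    "CoxFit",
    "FitOptions",
    "register_cohort_operations",
    "build_event_grid",
    "local_event_stats",
    "local_aggregates",
    "sum_aggregates",
    "newton_step",
    "partial_loglik",
    "fit_federated_cox",
    "hazard_ratios",
    "format_hr_table",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EventGrid:
    """Distinct event times of the whole federation, in tenths of a year.

    Times are stored as integers (tenths) so grid membership is exact; the
    ``times`` property exposes them in years.
    """

    tenths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.tenths:
            raise ValueError("no events anywhere in the federation: model not estimable")
        if list(self.tenths) != sorted(set(self.tenths)):
            raise ValueError("event grid must be sorted and unique")

    @property
    def K(self) -> int:
        return len(self.tenths)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.tenths, dtype=float) / 10.0


@dataclass
class SiteAggregates:
    """Per-event-time Breslow sums — the only payloads that cross sites."""

    d: np.ndarray  # (K,) event counts
    s: np.ndarray  # (K, p) covariate sums over events
    S0: np.ndarray  # (K,)
    S1: np.ndarray  # (K, p)
    S2: np.ndarray  # (K, p, p)


@dataclass
class CoxFit:
    """Result of a (federated) Cox fit."""

    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    loglik_null: float
    iterations: int
    converged: bool
    labels: list[str]
    n_events: int
    n_at_risk: int
    grid_size: int
    trace: list[dict[str, float]] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def coef(self, label: str) -> float:
        return float(self.beta[self.labels.index(label)])


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 50
    tol: float = 1e-8
    # "hr_sum": |sum exp(beta_new) - sum exp(beta_old)| < tol
    # "max_delta": max_j |beta_new_j - beta_old_j| < tol
    criterion: str = "hr_sum"
    step_halving: bool = False  # safeguard, off by default: plain Newton


# ---------------------------------------------------------------------------
# Node-side computations (pure functions of local arrays)
# ---------------------------------------------------------------------------

def _to_tenths(times: np.ndarray) -> np.ndarray:
    tenths = np.rint(np.asarray(times, dtype=float) * 10.0).astype(np.int64)
    if not np.allclose(tenths / 10.0, times, atol=1e-9):
        raise ValueError("follow-up times must be multiples of 0.1 years")
    return tenths


def local_event_stats(times, events, Z, grid: EventGrid) -> tuple[np.ndarray, np.ndarray]:
    """d_k and s_k for one site on the shared grid (beta-independent)."""
    tenths = _to_tenths(times)
    events = np.asarray(events, dtype=int)
    Z = np.asarray(Z, dtype=float)
    K, p = grid.K, Z.shape[1]
    d = np.zeros(K)
    s = np.zeros((K, p))
    grid_arr = np.asarray(grid.tenths)
    pos = np.searchsorted(grid_arr, tenths)
    on_grid = (pos < K) & (grid_arr[np.minimum(pos, K - 1)] == tenths)
    ev = (events == 1) & on_grid
    if ev.any():
        np.add.at(d, pos[ev], 1.0)
        np.add.at(s, pos[ev], Z[ev])
    return d, s


def local_aggregates(times, events, Z, grid: EventGrid, beta) -> SiteAggregates:
    """Breslow risk-set sums S0/S1/S2 at every grid time, plus d and s.

    The risk set at t_k is {i : time_i >= t_k} (censored subjects at t_k
    included). Sites contribute zeros at grid times past their last
    follow-up. Cost O(n p^2 + K p^2): subjects are bucketed into the K+1
    grid intervals and suffix sums accumulated from the latest time down.
    """
    tenths = _to_tenths(times)
    Z = np.asarray(Z, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n, p = Z.shape
    K = grid.K
    lp = Z @ beta
    if not np.all(np.isfinite(lp)):
        raise FederationError("non-finite linear predictor")
    with np.errstate(over="ignore"):
        w = np.exp(lp)
    if not np.all(np.isfinite(w)):
        raise FederationError(
            f"exp(linear predictor) overflowed; max |lp| = {np.abs(lp).max():.3g}"
        )

    order = np.argsort(tenths, kind="stable")
    t_sorted = tenths[order]
    Z_sorted = Z[order]
    w_sorted = w[order]
    grid_arr = np.asarray(grid.tenths)
    # boundaries[k] = first sorted index with time >= grid[k]
    boundaries = np.searchsorted(t_sorted, grid_arr, side="left")
    boundaries = np.append(boundaries, n)

    S0 = np.zeros(K)
    S1 = np.zeros((K, p))
    S2 = np.zeros((K, p, p))
    acc0, acc1, acc2 = 0.0, np.zeros(p), np.zeros((p, p))
    for k in range(K - 1, -1, -1):
        lo, hi = boundaries[k], boundaries[k + 1]
        if hi > lo:
            wseg = w_sorted[lo:hi]
            Zseg = Z_sorted[lo:hi]
            Zw = Zseg * wseg[:, None]
            acc0 += float(wseg.sum())
            acc1 = acc1 + Zw.sum(axis=0)
            acc2 = acc2 + Zw.T @ Zseg
        S0[k] = acc0
        S1[k] = acc1
        S2[k] = acc2

    d, s = local_event_stats(times, events, Z, grid)
    return SiteAggregates(d=d, s=s, S0=S0, S1=S1, S2=S2)


# ---------------------------------------------------------------------------
# Server-side combination and Newton-Raphson
# ---------------------------------------------------------------------------

def sum_aggregates(parts: list[SiteAggregates]) -> SiteAggregates:
    """Element-wise sum across sites (all Breslow sums are additive)."""
    return SiteAggregates(
        d=sum(p.d for p in parts),
        s=sum(p.s for p in parts),
        S0=sum(p.S0 for p in parts),
        S1=sum(p.S1 for p in parts),
        S2=sum(p.S2 for p in parts),
    )


def _score_information(agg: SiteAggregates) -> tuple[np.ndarray, np.ndarray]:
    has_events = agg.d > 0
    if np.any(has_events & (agg.S0 <= 0)):
        raise FederationError("zero risk-set mass at a grid time with events")
    S0 = np.where(agg.S0 > 0, agg.S0, 1.0)
    Ebar = agg.S1 / S0[:, None]  # (K, p)
    U = (agg.s - agg.d[:, None] * Ebar).sum(axis=0)
    V = agg.S2 / S0[:, None, None] - Ebar[:, :, None] * Ebar[:, None, :]
    I = np.tensordot(agg.d, V, axes=(0, 0))
    I = 0.5 * (I + I.T)
    return U, I


def newton_step(agg: SiteAggregates, beta) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Newton-Raphson update from the combined aggregates.

    Returns (beta_new, score U, observed information I). A numerically
    singular information matrix raises, naming near-collinear columns.
    """
    beta = np.asarray(beta, dtype=float)
    U, I = _score_information(agg)
    try:
        delta = np.linalg.solve(I, U)
    except np.linalg.LinAlgError:
        diag = np.sqrt(np.clip(np.diag(I), 1e-300, None))
        corr = I / np.outer(diag, diag)
        np.fill_diagonal(corr, 0.0)
        j, k = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise FederationError(
            f"singular information matrix; columns {j} and {k} are "
            f"near-collinear (|corr| = {abs(corr[j, k]):.6f})"
        ) from None
    return beta + delta, U, I


def partial_loglik(agg: SiteAggregates, beta) -> float:
    """Breslow partial log-likelihood from the combined aggregates."""
    beta = np.asarray(beta, dtype=float)
    has_events = agg.d > 0
    if np.any(has_events & (agg.S0 <= 0)):
        raise FederationError("zero risk-set mass at a grid time with events")
    S0 = np.where(has_events, agg.S0, 1.0)
    return float((agg.s @ beta - agg.d * np.log(S0))[has_events].sum())


# ---------------------------------------------------------------------------
# Federated orchestration
# ---------------------------------------------------------------------------

def _spec_payload(spec: ModelSpec) -> dict[str, Any]:
    return {
        "blocks": [
            {"variable": b.variable, "levels": list(b.levels), "reference": b.reference}
            for b in spec.covariate_blocks
        ],
        "interactions": [list(pair) for pair in spec.interaction_blocks],
        "label": spec.label,
    }


def _spec_from_payload(payload: dict[str, Any]) -> ModelSpec:
    from .registry_model import CovariateBlock

    return ModelSpec(
        covariate_blocks=tuple(
            CovariateBlock(b["variable"], tuple(b["levels"]), b["reference"])
            for b in payload["blocks"]
        ),
        interaction_blocks=tuple((a, b) for a, b in payload["interactions"]),
        label=payload.get("label", ""),
    )


def _node_design(data: pd.DataFrame, payload: dict[str, Any]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    spec = _spec_from_payload(payload["spec"])
    X, _ = build_design_matrix(data, spec)
    means = payload.get("means")
    if means is not None:
        X = X - np.asarray(means, dtype=float)
    return data["time"].to_numpy(float), data["event"].to_numpy(int), X


# node operations ------------------------------------------------------------

def _op_distinct_event_times(data: pd.DataFrame, payload: dict[str, Any]) -> dict[str, Any]:
    times = data.loc[data["event"] == 1, "time"].to_numpy(float)
    tenths = np.unique(np.rint(times * 10.0).astype(np.int64))
    return {"event_tenths": tenths}


def _op_column_moments(data: pd.DataFrame, payload: dict[str, Any]) -> dict[str, Any]:
    spec = _spec_from_payload(payload["spec"])
    X, _ = build_design_matrix(data, spec)
    return {"column_sums": X.sum(axis=0), "n": float(len(data))}


def _op_event_stats(data: pd.DataFrame, payload: dict[str, Any]) -> dict[str, Any]:
    times, events, X = _node_design(data, payload)
    grid = EventGrid(tuple(payload["grid_tenths"]))
    d, s = local_event_stats(times, events, X, grid)
    return {"d": d, "s": s}


def _op_cox_aggregates(data: pd.DataFrame, payload: dict[str, Any]) -> dict[str, Any]:
    times, events, X = _node_design(data, payload)
    grid = EventGrid(tuple(payload["grid_tenths"]))
    agg = local_aggregates(times, events, X, grid, payload["beta"])
    return {"d": agg.d, "s": agg.s, "S0": agg.S0, "S1": agg.S1, "S2": agg.S2}


def _op_level_counts(data: pd.DataFrame, payload: dict[str, Any]) -> dict[str, Any]:
    variable = payload["variable"]
    counts = data[variable].value_counts()
    return {"levels": list(counts.index.astype(str)), "counts": counts.to_numpy(float)}


def _op_sum_count(data: pd.DataFrame, payload: dict[str, Any]) -> dict[str, Any]:
    values = data[payload["variable"]].to_numpy(float)
    return {"sum": float(values.sum()), "count": float(len(values))}


STANDARD_OPERATIONS = {
    "distinct_event_times": _op_distinct_event_times,
    "column_moments": _op_column_moments,
    "event_stats": _op_event_stats,
    "cox_aggregates": _op_cox_aggregates,
    "level_counts": _op_level_counts,
    "sum_count": _op_sum_count,
}


def register_cohort_operations(node: Node) -> None:
    """Register the standard survival/descriptive operations at a node."""
    for name, fn in STANDARD_OPERATIONS.items():
        node.register(name, fn)


def build_event_grid(server: FederatedServer, sites: list[str] | None = None) -> EventGrid:
    """One round trip: union of every site's distinct event times, sorted."""
    results = server.run("distinct_event_times", sites=sites)
    tenths: set[int] = set()
    for res in results:
        tenths.update(int(t) for t in np.asarray(res.aggregate["event_tenths"]))
    if not tenths:
        raise FederationError("no events anywhere in the federation: model not estimable")
    return EventGrid(tuple(sorted(tenths)))


def _collect_aggregates(server, sites, spec_payload, grid, means, beta) -> SiteAggregates:
    results = server.run(
        "cox_aggregates",
        payload={
            "spec": spec_payload,
            "grid_tenths": list(grid.tenths),
            "means": means,
            "beta": np.asarray(beta, float),
        },
        sites=sites,
    )
    parts = [
        SiteAggregates(
            d=np.asarray(r.aggregate["d"], float),
            s=np.asarray(r.aggregate["s"], float),
            S0=np.asarray(r.aggregate["S0"], float),
            S1=np.asarray(r.aggregate["S1"], float),
            S2=np.asarray(r.aggregate["S2"], float),
        )
        for r in results
    ]
    return sum_aggregates(parts)


def fit_federated_cox(
    server: FederatedServer,
    spec: ModelSpec,
    sites: list[str] | None = None,
    options: FitOptions = FitOptions(),
) -> CoxFit:
    """Fit the Breslow-ties Cox model across the federation.

    Rounds: (1) shared event-time grid; (2) federated column means for
    centering; (3) Newton-Raphson from beta = 0, one aggregate round per
    iteration, until the hazard-ratio-sum criterion (default) or max|delta|
    falls below ``options.tol``; (4) one final round at the estimate for the
    log-likelihood, score check and covariance = inverse observed
    information. Estimates are invariant to the centering.
    """
    site_list = sites if sites is not None else server.site_ids
    labels = spec.column_labels()
    p = len(labels)
    spec_payload = _spec_payload(spec)

    grid = build_event_grid(server, site_list)

    moments = server.run("column_moments", payload={"spec": spec_payload}, sites=site_list)
    total_n = sum(r.aggregate["n"] for r in moments)
    col_sums = sum(np.asarray(r.aggregate["column_sums"], float) for r in moments)
    means = (col_sums / total_n).tolist()

    beta = np.zeros(p)
    loglik_null = None
    trace: list[dict[str, float]] = []
    converged = False
    iterations = 0

    for it in range(1, options.max_iter + 1):
        agg = _collect_aggregates(server, site_list, spec_payload, grid, means, beta)
        ll = partial_loglik(agg, beta)
        if loglik_null is None:
            loglik_null = ll  # first iteration evaluates at beta = 0
        beta_new, U, I = newton_step(agg, beta)
        if options.step_halving:
            step = beta_new - beta
            scale = 1.0
            while scale > 1e-4:
                cand = beta + scale * step
                cand_agg = _collect_aggregates(server, site_list, spec_payload, grid, means, cand)
                if partial_loglik(cand_agg, cand) >= ll - 1e-12:
                    beta_new = cand
                    break
                scale /= 2.0
        if options.criterion == "hr_sum":
            gap = abs(np.exp(beta_new).sum() - np.exp(beta).sum())
        elif options.criterion == "max_delta":
            gap = float(np.abs(beta_new - beta).max())
        else:
            raise ValueError(f"unknown convergence criterion {options.criterion!r}")
        trace.append(
            {"iteration": it, "loglik": ll, "max_score": float(np.abs(U).max()), "gap": gap}
        )
        iterations = it
        beta = beta_new
        if gap < options.tol:
            converged = True
            break

    if not converged:
        raise FederationError(
            f"Newton-Raphson did not converge in {options.max_iter} iterations; "
            f"trace: {trace}"
        )

    final = _collect_aggregates(server, site_list, spec_payload, grid, means, beta)
    loglik = partial_loglik(final, beta)
    _, I = _score_information(final)
    covariance = np.linalg.inv(I)
    covariance = 0.5 * (covariance + covariance.T)

    return CoxFit(
        beta=beta,
        covariance=covariance,
        loglik=loglik,
        loglik_null=float(loglik_null),
        iterations=iterations,
        converged=True,
        labels=labels,
        n_events=int(round(final.d.sum())),
        n_at_risk=int(round(total_n)),
        grid_size=grid.K,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def hazard_ratios(fit: CoxFit, level: float = 0.95) -> pd.DataFrame:
    """Hazard ratios exp(beta) with Wald confidence intervals."""
    if not fit.converged:
        raise FederationError("refusing to report hazard ratios from a non-converged fit")
    z = Z_95 if abs(level - 0.95) < 1e-12 else float(stats.norm.ppf(0.5 + level / 2.0))
    se = fit.se
    return pd.DataFrame(
        {
            "label": fit.labels,
            "coef": fit.beta,
            "se": se,
            "hr": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - z * se),
            "ci_high": np.exp(fit.beta + z * se),
        }
    )


def format_hr_table(fit: CoxFit, spec: ModelSpec, level: float = 0.95) -> pd.DataFrame:
    """Long-format HR table with reference rows rendered as "1.00, –"."""
    hr = hazard_ratios(fit, level).set_index("label")
    rows = []
    for b in spec.covariate_blocks:
        for lev in b.levels:
            label = f"{b.variable}={lev}"
            if lev == b.reference:
                rows.append(
                    {
                        "variable": b.variable,
                        "level": lev,
                        "hr": "1.00",
                        "ci": "–",
                        "reference": True,
                    }
                )
            else:
                r = hr.loc[label]
                rows.append(
                    {
                        "variable": b.variable,
                        "level": lev,
                        "hr": f"{r['hr']:.2f}",
                        "ci": f"{r['ci_low']:.2f}–{r['ci_high']:.2f}",
                        "reference": False,
                    }
                )
    return pd.DataFrame(rows)
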