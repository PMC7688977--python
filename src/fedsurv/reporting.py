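"""End-to-end study orchestration.

Runs the whole analysis the way the multi-registry study is structured:
descriptive frequency tables with between-country chi-square tests, one
univariable Cox fit per prognostic factor (per-country fits as single-site
federations plus a combined multi-site fit, all through the same code path),
the multivariable fit on the full 18-column design, and the five
country-by-factor interaction analyses. Every output table is written as a
delimited file and listed, with a checksum, in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .descriptives import chi_square, federated_frequency_table, federated_mean
from .fed_cox import FitOptions, fit_federated_cox, format_hr_table, hazard_ratios
from .fed_infra import FederatedServer, Node
from .interaction import country_specific_hrs, fit_interaction_model, lrt
from .registry_model import ModelSpec, multivariable_spec
from .fed_cox import register_cohort_operations

__all__ = ["RunManifest", "build_federation", "run_study", "INTERACTION_FACTORS"]

logger = logging.getLogger(__name__)

# The five factors examined for country-differential effects.
INTERACTION_FACTORS = ["age_cat", "stage_group", "grade_cat", "treatment", "volume_cat"]

DESCRIPTIVE_VARIABLES = [
    "age_cat", "sex", "period", "stage_group", "location",
    "grade_cat", "treatment", "volume_cat",
]


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    software_version: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages: list[str] = field(default_factory=list)
    convergence: dict[str, dict] = field(default_factory=dict)
    error: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_federation(
    site_tables: dict[str, pd.DataFrame], audit_path=None
) -> FederatedServer:
    """One node per site over its cohort table, standard operations registered."""
    server = FederatedServer(audit_path=audit_path)
    for site_id, table in site_tables.items():
        node = Node(site_id, table.reset_index(drop=True))
        register_cohort_operations(node)
        server.register_node(node)
    return server


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    manifest.outputs[str(path)] = _sha256(path)


def run_study(
    site_tables: dict[str, pd.DataFrame],
    out_dir,
    spec: ModelSpec | None = None,
    options: FitOptions = FitOptions(),
    seed: int = 0,
    config_hash: str = "",
) -> RunManifest:
    """Full pipeline on already-derived cohort tables; returns the manifest.

    Any stage failure aborts with the stage recorded; the partial manifest is
    still written so completed outputs remain accounted for.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or multivariable_spec()
    manifest = RunManifest(seed=seed, config_hash=config_hash, software_version=__version__)
    server = build_federation(site_tables, audit_path=out / "audit.jsonl")
    stage = "setup"
    try:
        # -- descriptives ----------------------------------------------------
        stage = "descriptives"
        desc_rows = []
        for variable in DESCRIPTIVE_VARIABLES:
            block = spec.block(variable)
            table = federated_frequency_table(server, variable, levels=list(block.levels))
            frame = table.to_frame()
            res = chi_square(table)
            frame["chi2_p"] = res.p_value
            desc_rows.append(frame)
        mean_time, n_total = federated_mean(server, "time")
        desc = pd.concat(desc_rows, ignore_index=True)
        _write(desc, out / "descriptives.csv", manifest)
        manifest.convergence["descriptives"] = {"n_total": n_total, "mean_follow_up": mean_time}
        manifest.stages.append(stage)

        # -- univariable fits ------------------------------------------------
        stage = "univariable"
        uni_rows = []
        for block in spec.covariate_blocks:
            one = ModelSpec((block,), label=f"uni:{block.variable}")
            combined = fit_federated_cox(server, one, options=options)
            t = format_hr_table(combined, one)
            t.insert(0, "model", "combined")
            uni_rows.append(t)
            manifest.convergence[f"uni:{block.variable}:combined"] = {
                "iterations": combined.iterations, "loglik": combined.loglik,
            }
            if block.variable == "country":
                continue  # country is inestimable within one country
            for site in server.site_ids:
                local = fit_federated_cox(server, one, sites=[site], options=options)
                t = format_hr_table(local, one)
                t.insert(0, "model", site)
                uni_rows.append(t)
        _write(pd.concat(uni_rows, ignore_index=True), out / "univariable.csv", manifest)
        manifest.stages.append(stage)

        # -- multivariable fit -----------------------------------------------
        stage = "multivariable"
        fit = fit_federated_cox(server, spec, options=options)
        t = format_hr_table(fit, spec)
        t.insert(0, "model", "combined")
        multi = [t]
        site_spec = ModelSpec(
            tuple(b for b in spec.covariate_blocks if b.variable != "country"),
            label="multivariable:within-site",
        )
        for site in server.site_ids:
            local = fit_federated_cox(server, site_spec, sites=[site], options=options)
            t = format_hr_table(local, site_spec)
            t.insert(0, "model", site)
            multi.append(t)
        _write(pd.concat(multi, ignore_index=True), out / "multivariable.csv", manifest)
        manifest.convergence["multivariable:combined"] = {
            "iterations": fit.iterations,
            "loglik": fit.loglik,
            "loglik_null": fit.loglik_null,
            "n_events": fit.n_events,
            "columns": len(fit.labels),
            "criterion": options.criterion,
            "tol": options.tol,
        }
        manifest.stages.append(stage)

        # -- interaction analyses ---------------------------------------------
        stage = "interactions"
        lrt_rows, hr_rows = [], []
        for factor in INTERACTION_FACTORS:
            full, reduced = fit_interaction_model(server, spec, factor, options=options)
            res = lrt(full, reduced, factor=factor)
            lrt_rows.append(
                {"factor": factor, "statistic": res.statistic, "df": res.df, "p_value": res.p_value}
            )
            hr_rows.append(country_specific_hrs(full, factor, spec))
            manifest.convergence[f"interaction:{factor}"] = {
                "iterations_full": full.iterations, "df": res.df,
            }
        _write(pd.DataFrame(lrt_rows), out / "interaction_lrt.csv", manifest)
        _write(pd.concat(hr_rows, ignore_index=True), out / "country_hrs.csv", manifest)
        manifest.stages.append(stage)

        # audit file is an output too
        audit_file = out / "audit.jsonl"
        if audit_file.exists():
            manifest.outputs[str(audit_file)] = _sha256(audit_file)
    except Exception as exc:
        manifest.error = f"stage {stage!r} failed: {exc}"
        logger.error(manifest.error)
        (out / "manifest.json").write_text(manifest.to_json())
        raise
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
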