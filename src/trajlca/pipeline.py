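"""End-to-end pipeline: simulate/load -> filter -> fit -> collapse -> regress.

Stages mirror the published analysis: single-process LLCA fits for each
symptom process, the parallel-process joint model, collapse of the 16
joint classes into 4 composite clinical groups, and bias-adjusted
three-step multinomial regressions of composite membership on risk
factors.  All tabular output is comma-separated text with a versioned
schema header line so results can be audited and re-read.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, collapse as collapse_mod, lca, parallel, threestep
from .panel import (
    ResponsePanel,
    apply_inclusion_filter_pair,
    read_panel,
    write_panel,
)
from .simulate import GeneratorConfig, apply_missingness, generate_cohort

SCHEMA_VERSION = 1

__all__ = ["PipelineConfig", "run_pipeline", "write_table", "read_table"]


@dataclass
class PipelineConfig:
    """Settings resolvable before any stage executes."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    soiling_path: str | None = None  # read panels instead of simulating
    constipation_path: str | None = None
    covariates_path: str | None = None
    n_classes: int = 4
    min_waves: int = 3
    single_starts: int = 10
    parallel_starts: int = 4
    tol: float = 1e-8
    max_iter: int = 5000
    seed: int = 0
    regressions: list[str] = field(default_factory=list)
    out_dir: str = "trajlca_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        gen = doc.pop("generator", None)
        cfg = cls(**doc)
        if gen is not None:
            cfg.generator = GeneratorConfig(
                **{
                    k: (np.asarray(v) if isinstance(v, list) else v)
                    for k, v in gen.items()
                }
            )
        return cfg


# ---------------------------------------------------------------------------
# schema-versioned delimited text


def write_table(df: pd.DataFrame, path, name: str) -> None:
    """Write a CSV with a versioned schema header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# trajlca-schema v{SCHEMA_VERSION} {name}\n")
        df.to_csv(fh, index=False)


def read_table(path, name: str | None = None) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, checking the schema header."""
    with open(path) as fh:
        header = fh.readline().strip()
        parts = header.split()
        if len(parts) < 3 or parts[0] != "#" or parts[1] != "trajlca-schema":
            raise ValueError(f"{path}: missing trajlca schema header")
        if parts[2] != f"v{SCHEMA_VERSION}":
            raise ValueError(
                f"{path}: schema version {parts[2]} != expected v{SCHEMA_VERSION}"
            )
        if name is not None and parts[3] != name:
            raise ValueError(f"{path}: schema name {parts[3]!r} != expected {name!r}")
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# pipeline


def _load_or_simulate(config: PipelineConfig, log: list[str]):
    if config.soiling_path and config.constipation_path:
        log.append(f"loading panels from {config.soiling_path}, {config.constipation_path}")
        soil = read_panel(config.soiling_path, process_name="soiling")
        con = read_panel(config.constipation_path, process_name="constipation")
        cov = (
            pd.read_csv(config.covariates_path)
            if config.covariates_path
            else pd.DataFrame({"child_id": soil.child_ids})
        )
        return soil, con, cov, None
    log.append(f"simulating cohort of n={config.generator.n_children} (seed {config.generator.seed})")
    cohort = generate_cohort(config.generator)
    soil = apply_missingness(
        cohort.soiling,
        config.generator.response_prob,
        config.generator.dropout_hazard,
        seed=config.generator.seed + 1,
    )
    con = apply_missingness(
        cohort.constipation,
        config.generator.response_prob,
        config.generator.dropout_hazard,
        seed=config.generator.seed + 2,
    )
    return soil, con, cohort.covariates, cohort.labels


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write machine- and human-readable results.

    Returns a bundle dict with the fitted objects and output paths.
    Any stage failure raises with the stage name; files written by earlier
    stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"trajlca pipeline, master seed {config.seed}"]
    bundle: dict = {"out_dir": str(out)}
    t0 = time.time()

    stage = "simulate/load"
    try:
        soil, con, covariates, labels = _load_or_simulate(config, log)
        write_panel(soil, out / "panel_soiling.csv")
        write_panel(con, out / "panel_constipation.csv")
        if labels is not None:
            write_table(labels.as_frame(), out / "true_labels.csv", "true_labels")

        stage = "filter"
        soil_f, con_f = apply_inclusion_filter_pair(soil, con, config.min_waves)
        log.append(
            f"inclusion filter (>= {config.min_waves} waves, both processes): "
            f"{soil.n_children} -> {soil_f.n_children} children"
        )
        prev = collapse_mod.marginal_prevalence_table(soil, con)
        write_table(prev, out / "prevalence_table.csv", "prevalence_table")

        stage = "fit-lca"
        ss = np.random.SeedSequence(config.seed)
        seeds = [s.generate_state(1)[0] % (2**31) for s in ss.spawn(3)]
        single_fits = {}
        for panel, s in ((soil_f, seeds[0]), (con_f, seeds[1])):
            params, post = lca.em_fit(
                panel,
                config.n_classes,
                n_starts=config.single_starts,
                tol=config.tol,
                max_iter=config.max_iter,
                seed=s,
            )
            single_fits[panel.process_name] = (params, post)
            log.append(
                f"single-process fit [{panel.process_name}]: loglik {params.loglik:.2f}, "
                f"weights {np.round(params.class_weights, 4).tolist()}, "
                f"converged={params.converged}"
            )
        single_rows = []
        for proc, (params, post) in single_fits.items():
            names = lca.label_classes(params)
            for c in range(params.n_classes):
                single_rows.append(
                    {
                        "process": proc,
                        "class_index": c,
                        "class_label": names[c],
                        "weight": params.class_weights[c],
                        **{
                            f"rho_w{t}": params.item_probs[c, t]
                            for t in range(params.n_waves)
                        },
                    }
                )
        write_table(
            pd.DataFrame(single_rows), out / "single_class_weights.csv", "single_class_weights"
        )

        stage = "fit-parallel"
        pparams, jpost = parallel.fit_parallel(
            soil_f,
            con_f,
            n_classes=config.n_classes,
            n_starts=config.parallel_starts,
            tol=config.tol,
            max_iter=config.max_iter,
            seed=seeds[2],
        )
        log.append(
            f"parallel fit: loglik {pparams.loglik:.2f}, converged={pparams.converged}"
        )
        jt = parallel.joint_class_table(pparams)
        write_table(
            jt.reset_index(names="constipation_class"),
            out / "joint_table.csv",
            "joint_table",
        )

        stage = "collapse"
        comp = collapse_mod.collapse_posterior(jpost)
        shares = collapse_mod.composite_proportions(pparams.joint_weights * 100.0)
        write_table(
            pd.DataFrame(
                {"composite_class": comp.labels, "percent": np.round(shares, 1)}
            ),
            out / "composite_shares.csv",
            "composite_shares",
        )

        stage = "regress"
        reg_rows = []
        if config.regressions:
            modal = threestep.modal_assign(comp)
            d = threestep.error_matrix(comp)
            cov_aligned = covariates.set_index("child_id").loc[comp.child_ids].reset_index()
            for term in config.regressions:
                result = threestep.fit_threestep(modal, d, cov_aligned, [term])
                table = threestep.wald_intervals(result)
                table = table[table["term"] != "intercept"].copy()
                table.insert(0, "risk_factor", term)
                table["omnibus_p"] = threestep.omnibus_test(result, term)
                table["n_used"] = result.n_used
                reg_rows.append(table)
                log.append(
                    f"three-step regression [{term}]: n={result.n_used}, "
                    f"grad_norm={result.gradient_norm:.2e}"
                )
        reg_table = (
            pd.concat(reg_rows, ignore_index=True)
            if reg_rows
            else pd.DataFrame(
                columns=[
                    "risk_factor", "class", "term", "coef", "se",
                    "or", "ci_low", "ci_high", "omnibus_p", "n_used",
                ]
            )
        )
        write_table(reg_table, out / "regressions.csv", "regressions")

        stage = "report"
        report = _render_report(prev, single_fits, jt, comp.labels, shares, reg_table)
        (out / "report.txt").write_text(report)
        log.append(f"finished in {time.time() - t0:.1f} s")
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
        (out / "run_meta.json").write_text(
            json.dumps({"seed": config.seed, "schema": SCHEMA_VERSION}, indent=2)
        )
    except Exception as err:
        (out / "run_log.txt").write_text("\n".join(log) + f"\nFAILED at stage {stage}: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    bundle.update(
        single_fits=single_fits,
        parallel_params=pparams,
        joint_posterior=jpost,
        composite=comp,
        composite_shares=shares,
        regressions=reg_table,
        prevalence=prev,
        labels=labels,
    )
    return bundle


def _render_report(prev, single_fits, joint_table, comp_labels, shares, reg_table) -> str:
    lines = ["Constipation and soiling trajectory classes", "=" * 44, ""]
    lines.append("Per-wave prevalence (>=3 non-missing waves, both processes):")
    sub = prev[prev["sample"] == "ge3_both"]
    for _, r in sub.iterrows():
        lines.append(
            f"  {r['process']:<13} {r['wave_label']:<6} "
            f"{r['n_with_symptom']:>5} / {r['n_observed']:>5}  ({r['percent']}%)"
        )
    lines.append("")
    for proc, (params, post) in single_fits.items():
        names = lca.label_classes(params)
        lines.append(f"Single-process {proc} classes (entropy {post.entropy_quality:.2f}):")
        for c in range(params.n_classes):
            lines.append(
                f"  {names[c]:<11} {100 * params.class_weights[c]:5.1f}%"
            )
        lines.append("")
    lines.append("Joint class distribution (% of children; rows constipation, cols soiling):")
    lines.append(joint_table.round(1).to_string())
    lines.append("")
    lines.append("Composite clinical groups:")
    for name, share in zip(comp_labels, shares):
        lines.append(f"  {name:<26} {collapse_mod.format_percent_cell(share):>6}%")
    split = collapse_mod.soiler_split(shares)
    lines.append(f"  soiling alone among soilers: {split[0]}% (with constipation {split[1]}%)")
    lines.append(
        f"  any constipation: {collapse_mod.any_constipation_prevalence(shares):.1f}%"
    )
    lines.append("")
    if len(reg_table):
        lines.append("Risk-factor odds ratios (reference: normative class):")
        for _, r in reg_table.iterrows():
            lines.append(
                f"  {r['risk_factor']:<18} {r['class']:<26} {r['term']:<22} "
                f"OR {r['or']:.2f} ({r['ci_low']:.2f} to {r['ci_high']:.2f}), "
                f"omnibus p={r['omnibus_p']:.3g}"
            )
    return "\n".join(lines) + "\n"
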