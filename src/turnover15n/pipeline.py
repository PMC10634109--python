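"""End-to-end orchestration: simulate -> RIA -> turnover -> abundance stats.

A :class:`RunConfig` collects every threshold the analysis uses (coverage
rules, RSTDE and R^2 filters, the FCP responsiveness gate, turnover class
cut-offs, test levels) together with the simulation parameters and the
seed.  :func:`run_pipeline` executes the stages in order, writes every
table as TSV under the output directory and records a manifest with the
config hash, per-stage row counts and filter attrition, so an identical
config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import (
    average_injections,
    compute_pqi,
    fold_change,
    hcluster_profiles,
    linear_rsq,
    median_fcp,
    protein_transcript_ratio,
    sam_permutation_fdr,
    ttest_vs_reference,
    zscore_rows,
)
from .isotopes import DEFAULT_ENRICHMENT_GRID, composition_from_sequence, estimate_ria
from .synthetic import (
    ExperimentDesign,
    SimulatedExperiment,
    default_protein_panel,
    simulate_experiment,
)
from .turnover import (
    C2_TIMES_H,
    KS_C2_TIMES_H,
    aggregate_protein_ria,
    estimate_steady_state,
    fit_fcp_model,
    fit_kd_transition,
    fit_kdil,
    ks_timecourse_transition,
    qc_turnover,
)

logger = logging.getLogger("turnover15n")

__all__ = [
    "RunConfig",
    "run_pipeline",
    "validate_tables",
    "ria_from_envelopes",
    "steady_state_table",
    "transition_table",
    "TABLE_SCHEMAS",
]

TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "peptide_ria": {
        "peptide_sequence": "str", "protein_id": "str", "replicate": "int",
        "time_h": "float", "ria": "float",
    },
    "envelopes": {
        "peptide_sequence": "str", "protein_id": "str", "replicate": "int",
        "time_h": "float", "isotope_index": "int", "intensity": "float",
    },
    "growth": {"time_h": "float", "replicate": "int", "weight_g": "float"},
    "auc": {
        "protein_id": "str", "peptide_sequence": "str", "replicate": "int",
        "injection": "int", "time_h": "float", "auc": "float",
    },
    "transcripts": {
        "gene_id": "str", "replicate": "int", "time_h": "float", "rel_expression": "float",
    },
}


@dataclass
class RunConfig:
    """All knobs of one reproducible analysis run (rates in day^-1, times in h)."""

    seed: int = 0
    outdir: str = "results/pipeline"
    # simulation
    n_proteins: int = 20
    kdil: float = 0.25
    noise_cv: float = 0.1
    missing_p: float = 0.0
    enrichment: float = 0.98
    treated_fraction: float = 0.5
    # filters
    coverage_min: dict = field(default_factory=lambda: {"C1": 5, "C2": 4, "C3": 5})
    rstde_max_pct: float = 40.0
    r2_min: float = 0.5
    fcp_gate: tuple = (0.75, 1.5)
    class_cutoffs: tuple = (0.055, 0.22)
    ks_eval_days: float = 2.0
    # statistics
    alpha: float = 0.05
    s0: float = 0.1
    fdr: float = 0.05
    n_perm: int = 1000
    # optional pre-existing inputs (TSV paths keyed by schema name + condition)
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fcp_gate", "class_cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Load a TSV and enforce its documented schema.

    Raises with the file name and the offending column on any violation.
    """
    schema = TABLE_SCHEMAS[schema_name]
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = set(schema) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col, kind in schema.items():
        if kind in ("int", "float"):
            try:
                table[col] = pd.to_numeric(table[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: column {col!r} is not numeric") from exc
    return table


def validate_tables(paths: dict[str, str]) -> dict[str, list[str]]:
    """Schema and range checks over a set of input tables.

    ``paths`` maps schema names (see :data:`TABLE_SCHEMAS`) to TSV files.
    Returns ``{"errors": [...], "warnings": [...]}`` with coordinates for
    every violation; fatal schema problems surface as errors.
    """
    errors: list[str] = []
    warnings: list[str] = []
    for name, path in paths.items():
        try:
            table = read_table(path, name)
        except (ValueError, KeyError, FileNotFoundError) as exc:
            errors.append(str(exc))
            continue
        def _flag(mask: pd.Series, message: str) -> None:
            for idx in table.index[mask][:20]:
                errors.append(f"{path}: line {idx + 2}: {message}")
        if name == "peptide_ria":
            _flag((table["ria"] < 0) | (table["ria"] > 1), "RIA outside [0, 1]")
        elif name == "growth":
            _flag(table["weight_g"] <= 0, "non-positive weight_g")
        elif name == "auc":
            _flag(table["auc"] < 0, "negative AUC")
        elif name == "envelopes":
            _flag(table["intensity"] < 0, "negative intensity")
        elif name == "transcripts":
            _flag(table["rel_expression"] <= 0, "non-positive expression")
    return {"errors": errors, "warnings": warnings}


def ria_from_envelopes(
    envelopes: pd.DataFrame, enrichment_grid=None
) -> pd.DataFrame:
    """Peptide RIA table from an isotope-envelope table (mixture fit per cell)."""
    if enrichment_grid is None:
        enrichment_grid = DEFAULT_ENRICHMENT_GRID
    rows = []
    comps: dict[str, object] = {}
    for (pep, protein, rep, t), grp in envelopes.groupby(
        ["peptide_sequence", "protein_id", "replicate", "time_h"]
    ):
        comp = comps.setdefault(pep, composition_from_sequence(pep))
        ordered = grp.sort_values("isotope_index")["intensity"].to_numpy()
        est = estimate_ria(ordered, comp, enrichment_grid)
        rows.append((pep, protein, rep, t, est.ria))
    return pd.DataFrame(
        rows, columns=["peptide_sequence", "protein_id", "replicate", "time_h", "ria"]
    )


def _format_rates(table: pd.DataFrame) -> pd.DataFrame:
    rate_cols = [c for c in table.columns if c.split("_")[0] in ("kloss", "kd", "ks", "kdil", "r2", "rstde")]
    out = table.copy()
    for col in rate_cols:
        out[col] = out[col].map(lambda v: round(v, 3) if pd.notna(v) else v)
    return out


def steady_state_table(
    protein_ria: pd.DataFrame,
    kdil: float,
    condition: str,
    config: RunConfig,
    times_h: tuple | None = None,
) -> pd.DataFrame:
    """Per-protein steady-state turnover table (conditions C1/C3)."""
    rows = []
    for protein, series in protein_ria.groupby("protein_id"):
        est = estimate_steady_state(
            protein, series, kdil, condition, times_h,
            ks_time_days=config.ks_eval_days,
            rstde_max_pct=config.rstde_max_pct, r2_min=config.r2_min,
        )
        row = {"protein_id": protein, "condition": condition, "kdil": kdil}
        for i, fit in enumerate(est.replicate_fits, start=1):
            row[f"kloss_rep{i}"] = fit.slope
            row[f"r2_rep{i}"] = fit.r2
        row.update(
            kloss=est.kloss, kd=est.kd, ks=est.ks,
            rstde_pct=est.qc.rstde_pct, qc_pass=est.qc.passed,
            qc_reason=est.qc.reason, turnover_class=est.turnover_class,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def transition_table(
    protein_ria: pd.DataFrame,
    fcp: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Per-protein transition-phase (C2) K_d and K_s time-course table.

    ``fcp`` holds replicate-median linear FCP per (protein_id, time_h); the
    quadratic model is fitted on the abundance sampling points and shared
    across replicates, and rate constants are only reported for proteins
    passing the responsiveness gate and the C2 QC rules.
    """
    rows = []
    fcp_by_protein = {p: dict(zip(g["time_h"], g["fcp"])) for p, g in fcp.groupby("protein_id")}
    for protein, series in protein_ria.groupby("protein_id"):
        row: dict = {"protein_id": protein, "condition": "C2"}
        med = fcp_by_protein.get(protein)
        if med is None:
            row.update(qc_pass=False, qc_reason="no abundance data")
            rows.append(row)
            continue
        try:
            model = fit_fcp_model(med, protein, gate=config.fcp_gate)
        except ValueError as exc:
            row.update(qc_pass=False, qc_reason=str(exc))
            rows.append(row)
            continue
        row.update(fcp_a=model.a, fcp_b=model.b, fcp_c=model.c, fcp_r2=model.r2,
                   fcp_responsive=model.responsive)
        if not model.responsive:
            row.update(qc_pass=False, qc_reason="FCP within 0.75-1.5 gate")
            rows.append(row)
            continue
        fits = fit_kd_transition(series, model, times_h=C2_TIMES_H)
        for i, fit in enumerate(fits, start=1):
            row[f"kd_rep{i}"] = fit.slope
            row[f"r2_rep{i}"] = fit.r2
        qc = qc_turnover(
            [f.slope for f in fits], [f.r2 for f in fits], "C2",
            rstde_max_pct=config.rstde_max_pct, r2_min=config.r2_min,
        )
        row.update(rstde_pct=qc.rstde_pct, qc_pass=qc.passed, qc_reason=qc.reason)
        if qc.passed:
            kd = float(np.mean([f.slope for f in fits]))
            row["kd"] = kd
            if kd != 0:
                for t_h, ks in ks_timecourse_transition(kd, model, KS_C2_TIMES_H).items():
                    row[f"ks_{int(t_h)}h"] = ks
        rows.append(row)
    return pd.DataFrame(rows)


def _write(table: pd.DataFrame, path: Path, comment: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        _format_rates(table).to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run manifest.

    Simulates one untreated (C1) and one elicitor-treated (C2/C3)
    experiment from the config seed, estimates all rate constants with the
    QC filters, computes abundance statistics, clustering and
    protein-transcript integration, and writes every table plus
    ``manifest.json`` under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    design = ExperimentDesign()

    def stage(name: str, **info) -> None:
        logger.info("stage %s: %s", name, info)
        stages.append({"stage": name, **info})

    # --- simulate -------------------------------------------------------
    panel = default_protein_panel(
        config.n_proteins, config.kdil, np.random.default_rng(config.seed),
        treated_fraction=config.treated_fraction,
        noise_cv=config.noise_cv, missing_p=config.missing_p,
    )
    untreated = simulate_experiment(
        design, panel, config.kdil, seed=config.seed, condition="C1",
        enrichment=config.enrichment,
    )
    treated = simulate_experiment(
        design, panel, config.kdil, seed=config.seed + 1, condition="treated",
        enrichment=config.enrichment,
    )
    untreated.write(outdir / "sim_untreated")
    treated.write(outdir / "sim_treated")
    stage("simulate", proteins=config.n_proteins,
          ria_rows_untreated=len(untreated.peptide_ria),
          ria_rows_treated=len(treated.peptide_ria))

    # --- growth dilution ------------------------------------------------
    kdil_c1 = fit_kdil(untreated.growth)
    kdil_c3 = fit_kdil(treated.growth, times_h=tuple(t for t in design.c3_times_h))
    stage("kdil", c1=kdil_c1, c3=kdil_c3)

    # --- steady-state turnover (C1, C3) ---------------------------------
    ria_c1 = aggregate_protein_ria(untreated.peptide_ria, config.coverage_min["C1"])
    c1 = steady_state_table(ria_c1, kdil_c1, "C1", config,
                            times_h=tuple(t for t in design.c1_times_h if t >= 0))
    _write(c1, outdir / "turnover_C1.tsv", "rates in day^-1, times in hours")
    stage("turnover_C1", proteins_in=config.n_proteins,
          proteins_covered=c1.shape[0],
          qc_passed=int(c1["qc_pass"].sum()) if not c1.empty else 0)

    ria_c3 = aggregate_protein_ria(treated.peptide_ria, config.coverage_min["C3"])
    c3 = steady_state_table(ria_c3, kdil_c3, "C3", config, times_h=design.c3_times_h)
    _write(c3, outdir / "turnover_C3.tsv", "rates in day^-1, times in hours")
    stage("turnover_C3", proteins_covered=c3.shape[0],
          qc_passed=int(c3["qc_pass"].sum()) if not c3.empty else 0)

    # --- abundance ------------------------------------------------------
    pqi = compute_pqi(treated.auc)
    pqi_bio = average_injections(pqi)
    fc = fold_change(pqi_bio)
    med = median_fcp(fc)
    _write(pqi, outdir / "pqi.tsv", "PQI = log2 median peptide AUC")
    _write(fc, outdir / "fcp.tsv", "log2 fold change of protein abundance vs 0 h")
    stage("abundance", pqi_rows=len(pqi), fcp_rows=len(fc))

    # --- transition turnover (C2) ---------------------------------------
    ria_c2 = aggregate_protein_ria(treated.peptide_ria, config.coverage_min["C2"])
    ria_c2 = ria_c2[ria_c2["time_h"].isin(C2_TIMES_H)]
    c2 = transition_table(ria_c2, med, config)
    _write(c2, outdir / "turnover_C2.tsv", "rates in day^-1, times in hours")
    stage("turnover_C2", proteins_covered=c2.shape[0],
          qc_passed=int(c2["qc_pass"].sum()) if not c2.empty else 0)

    # --- statistics: t tests vs 0 h, permutation FDR on C1 vs C3 kd -----
    stats_rows = []
    for (protein, t), grp in fc.groupby(["protein_id", "time_h"]):
        if t == 0 or len(grp) < 2:
            continue
        res = ttest_vs_reference(grp["log2_fcp"], np.zeros(len(grp)), config.alpha)
        stats_rows.append(
            {"protein_id": protein, "time_h": t, "test": "student_t_vs_0h",
             "statistic": res.statistic, "p": res.p_value, "significant": res.significant}
        )
    stats = pd.DataFrame(stats_rows)
    _write(stats, outdir / "stats.tsv", "two-sided equal-variance Student t vs 0 h")
    stage("stats", tests=len(stats),
          significant=int(stats["significant"].sum()) if not stats.empty else 0)

    # --- clustering of Z-scored log2 FCP profiles -----------------------
    wide = fc.pivot_table(index="protein_id", columns="time_h", values="log2_fcp",
                          aggfunc="median")
    wide = wide.dropna()
    clusters = pd.DataFrame(columns=["protein_id", "cluster"])
    if wide.shape[0] >= 2:
        z, _ = zscore_rows(wide.to_numpy())
        labels, _ = hcluster_profiles(z, k=2)
        clusters = pd.DataFrame({"protein_id": wide.index, "cluster": labels})
    _write(clusters, outdir / "clusters.tsv", "hierarchical clusters of Z-scored log2 FCP")
    stage("clusters", rows=len(clusters))

    # --- protein:transcript ratios and correlation ----------------------
    expr = (
        treated.transcripts.groupby(["gene_id", "time_h"], as_index=False)["rel_expression"].mean()
    )
    prot_lin = med.assign(gene_id=med["protein_id"])
    ratio_rows = []
    rsq_rows = []
    shared_times = sorted(set(expr["time_h"]) & set(prot_lin["time_h"]))
    for gene, egrp in expr.groupby("gene_id"):
        pgrp = prot_lin[prot_lin["gene_id"] == gene]
        e = egrp.set_index("time_h")["rel_expression"].reindex(shared_times)
        p = pgrp.set_index("time_h")["fcp"].reindex(shared_times)
        if e.isna().any() or p.isna().any():
            continue
        ratios = protein_transcript_ratio(p.to_numpy(), e.to_numpy())
        for t, r in zip(shared_times, ratios):
            ratio_rows.append({"gene_id": gene, "time_h": t, "ratio": r})
    ratios = pd.DataFrame(ratio_rows)
    _write(ratios, outdir / "ratios.tsv", "protein:transcript ratio (log10, Z, +5 transformed)")
    for t in shared_times:
        sub_e = expr[expr["time_h"] == t].set_index("gene_id")["rel_expression"]
        sub_p = prot_lin[prot_lin["time_h"] == t].set_index("gene_id")["fcp"]
        genes = sub_e.index.intersection(sub_p.index)
        if len(genes) >= 3 and np.var(np.log10(sub_e[genes])) > 0:
            slope, intercept, r2 = linear_rsq(
                np.log10(sub_e[genes]), np.log10(sub_p[genes])
            )
            rsq_rows.append({"time_h": t, "slope": slope, "r2": r2})
    rsq = pd.DataFrame(rsq_rows)
    _write(rsq, outdir / "transcript_protein_r2.tsv", "OLS of log10 protein on log10 transcript per time")
    stage("ratios", genes=ratios["gene_id"].nunique() if not ratios.empty else 0)

    manifest = {
        "package": "turnover15n",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "stages": stages,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
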