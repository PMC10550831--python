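"""End-to-end orchestration: QC -> phenotyping -> cohort linkage -> association.

A single config drives either real input files (genotypes, events,
prescriptions, participants) or the synthetic generator, and produces a
``RunReport`` holding the QC table, the phenotype frequency table, the
cohort-flow counts, the baseline-comparison table, the stratified event
table, and every requested regression variant (primary categorical,
PC-adjusted, sensitivity-reclassified, LOF-allele-dose). Formatted reports
round percentages to 1 decimal, odds ratios to 2 decimals and p-values to 3
decimals with a "<0.001" floor; machine-readable outputs keep full precision.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from cyp2c19pgx.qc import (
    QCThresholds,
    load_genotypes,
    qc_filter,
    qc_report_frame,
)
from cyp2c19pgx.phenotyping import (
    PhenotypeConfig,
    phenotype_frequencies,
    phenotype_table,
)
from cyp2c19pgx.cohort import (
    DEFAULT_CODE_LISTS,
    build_analysis_table,
    select_analysis_cohort,
)
from cyp2c19pgx.association import (
    ExposureCoding,
    LogisticFit,
    baseline_comparison,
    metabolizer_association,
)
from cyp2c19pgx.simulate import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Exactly one of ``input_paths`` / ``simulation`` must be set."""

    input_paths: dict[str, str] | None = None
    simulation: SimulationConfig | None = None
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    info_scores: list[float] | None = None
    adjust_pcs: bool = True
    sensitivity_reclass: bool = True
    lof_dose: bool = True
    strict: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.simulation is None):
            raise ValueError("set exactly one of input_paths / simulation")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if isinstance(self.qc_thresholds, dict):
            self.qc_thresholds = QCThresholds(**self.qc_thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if seed is not None:
            cfg.seed = seed
            if cfg.simulation is not None:
                cfg.simulation.seed = seed
        return cfg


@dataclass
class RunReport:
    qc: pd.DataFrame
    phenotype_freq: pd.DataFrame
    flow: dict[str, int]
    linkage_log: dict[str, int]
    baseline: pd.DataFrame
    stratified: pd.DataFrame
    fits: dict[str, LogisticFit]
    analysis_rows: pd.DataFrame
    config_echo: dict
    version: str = ""
    warnings: list[str] = field(default_factory=list)


def format_percent(k: float, n: float) -> str:
    """Stratified-table percentage, 1 decimal: 3/11 -> '27.3%'."""
    if n == 0:
        return "0.0%"
    return f"{100.0 * k / n:.1f}%"


def format_or(value: float) -> str:
    return f"{value:.2f}"


def format_p(value: float) -> str:
    """3 decimals with a display floor: values below 0.001 print '<0.001'."""
    if value != value:  # NaN
        return "NA"
    if value < 0.001:
        return "<0.001"
    return f"{value:.3f}"


def stratified_event_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Events per metabolizer stratum: cohort n, recurrent-MI n, percentage."""
    order = ["PM", "IM", "NM", "RM", "UM"]
    records = []
    for cls in order:
        sub = rows[rows["metabolizer"] == cls]
        k = int(sub["recurrent_mi"].sum())
        records.append(
            {
                "stratum": cls,
                "acute_mi": len(sub),
                "recurrent_mi": k,
                "percentage": format_percent(k, len(sub)),
            }
        )
    k = int(rows["recurrent_mi"].sum())
    records.append(
        {
            "stratum": "Total",
            "acute_mi": len(rows),
            "recurrent_mi": k,
            "percentage": format_percent(k, len(rows)),
        }
    )
    return pd.DataFrame(records)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and collect a RunReport.

    Regression variants: ``primary`` (categorical exposure), ``pc_adjusted``
    (+20 PCs), ``sensitivity_reclass`` (one-LOF *17 carriers reclassified to
    NM before refitting), ``lof_dose`` (per-LOF-allele, UM excluded, +PCs).
    """
    from cyp2c19pgx import __version__

    warnings_log: list[str] = []
    if config.simulation is not None:
        cohort = generate_cohort(config.simulation)
        genotypes = cohort.genotypes
        events, prescriptions, participants = (
            cohort.events,
            cohort.prescriptions,
            cohort.participants,
        )
    else:
        paths = config.input_paths
        try:
            genotypes = load_genotypes(paths["genotypes"])
            events = pd.read_csv(paths["events"], sep="\t", dtype={"participant_id": str})
            prescriptions = pd.read_csv(
                paths["prescriptions"], sep="\t", dtype={"participant_id": str}
            )
            participants = pd.read_csv(
                paths["participants"], sep="\t", dtype={"participant_id": str}
            )
        except Exception as exc:
            raise RuntimeError(f"stage=load: {exc}") from exc

    try:
        site_qc, genotypes_pass = qc_filter(
            genotypes, config.info_scores, config.qc_thresholds
        )
        qc_frame = qc_report_frame(site_qc)
    except Exception as exc:
        raise RuntimeError(f"stage=qc: {exc}") from exc
    for r in site_qc:
        if r.hwe_flag:
            warnings_log.append(
                f"site {r.site.rsid} departs from HWE (p={r.hwe_p:.3g}); retained"
            )

    try:
        pheno = phenotype_table(genotypes_pass, PhenotypeConfig())
        freq = phenotype_frequencies(pheno["metabolizer"])
    except Exception as exc:
        raise RuntimeError(f"stage=phenotyping: {exc}") from exc

    try:
        cohort_ids, flow = select_analysis_cohort(
            participants, events, prescriptions, DEFAULT_CODE_LISTS
        )
        ordered = [
            pid for pid in participants["participant_id"] if pid in cohort_ids
        ]
        rows, linkage_log = build_analysis_table(
            ordered, pheno, events, participants, DEFAULT_CODE_LISTS
        )
    except Exception as exc:
        raise RuntimeError(f"stage=cohort_linkage: {exc}") from exc

    try:
        baseline = baseline_comparison(rows)
        stratified = stratified_event_table(rows)
        fits: dict[str, LogisticFit] = {}
        fits["primary"] = metabolizer_association(
            rows, ExposureCoding("categorical"), adjust_pcs=False
        )
        if config.adjust_pcs:
            fits["pc_adjusted"] = metabolizer_association(
                rows, ExposureCoding("categorical"), adjust_pcs=True
            )
        if config.sensitivity_reclass:
            pheno_reclass = phenotype_table(
                genotypes_pass, PhenotypeConfig(sensitivity_reclass=True)
            )
            rows_reclass, _ = build_analysis_table(
                ordered, pheno_reclass, events, participants, DEFAULT_CODE_LISTS
            )
            fits["sensitivity_reclass"] = metabolizer_association(
                rows_reclass, ExposureCoding("categorical"), adjust_pcs=False
            )
        if config.lof_dose:
            fits["lof_dose"] = metabolizer_association(
                rows, ExposureCoding("lof_dose"), adjust_pcs=config.adjust_pcs
            )
    except Exception as exc:
        raise RuntimeError(f"stage=association: {exc}") from exc

    if config.strict and warnings_log:
        raise RuntimeError(f"strict mode: {warnings_log[0]}")

    echo: dict = {
        "seed": config.seed,
        "adjust_pcs": config.adjust_pcs,
        "sensitivity_reclass": config.sensitivity_reclass,
        "lof_dose": config.lof_dose,
        "qc_thresholds": dataclasses.asdict(config.qc_thresholds),
    }
    if config.simulation is not None:
        echo["simulation"] = config.simulation.to_dict()
    else:
        echo["input_paths"] = dict(config.input_paths)

    return RunReport(
        qc=qc_frame,
        phenotype_freq=freq,
        flow=flow,
        linkage_log=linkage_log,
        baseline=baseline,
        stratified=stratified,
        fits=fits,
        analysis_rows=rows,
        config_echo=echo,
        version=__version__,
        warnings=warnings_log,
    )


def _format_fit(fit: LogisticFit) -> pd.DataFrame:
    df = fit.summary_frame()
    out = pd.DataFrame(
        {
            "term": df["term"],
            "or": df["or"].map(format_or),
            "ci95": [
                f"{lo:.2f}-{hi:.2f}" for lo, hi in zip(df["ci_lower"], df["ci_upper"])
            ],
            "p": df["p"].map(format_p),
        }
    )
    return out


def _format_baseline(baseline: pd.DataFrame) -> pd.DataFrame:
    out = baseline.copy()
    formatted = []
    for _, r in out.iterrows():
        if r["method"] == "fisher_exact":
            formatted.append(
                {
                    "characteristic": r["characteristic"],
                    "no_recurrence": f"{format_percent(r['no_recurrence_n'], r['no_recurrence_denom'])}"
                    f" ({int(r['no_recurrence_n'])})",
                    "recurrence": f"{format_percent(r['recurrence_n'], r['recurrence_denom'])}"
                    f" ({int(r['recurrence_n'])})",
                    "p": format_p(r["p_value"]),
                }
            )
        else:
            formatted.append(
                {
                    "characteristic": r["characteristic"],
                    "no_recurrence": f"{r['no_recurrence_n']}",
                    "recurrence": f"{r['recurrence_n']}",
                    "p": format_p(r["p_value"]),
                }
            )
    return pd.DataFrame(formatted)


def report_tables(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Write formatted and machine-readable report tables under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    save("qc", report.qc)
    save("phenotype_frequencies", report.phenotype_freq)
    save("baseline_comparison", _format_baseline(report.baseline))
    save("baseline_comparison_raw", report.baseline)
    save("stratified_events", report.stratified)
    for name, fit in report.fits.items():
        save(f"regression_{name}", _format_fit(fit))
        save(f"regression_{name}_raw", fit.summary_frame())
    flow_df = pd.DataFrame(
        list(report.flow.items()) + list(report.linkage_log.items()),
        columns=["stage", "count"],
    )
    save("cohort_flow", flow_df)
    summary = {
        "version": report.version,
        "config": report.config_echo,
        "warnings": report.warnings,
        "fits": {
            name: {
                "n_used": fit.n_used,
                "converged": fit.converged,
                "iterations": fit.iterations,
                "separation": fit.separation,
                "dropped": fit.dropped,
            }
            for name, fit in report.fits.items()
        },
    }
    p = out_dir / "run_summary.yaml"
    with open(p, "wt") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    paths["run_summary"] = p
    return paths
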