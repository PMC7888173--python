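"""End-to-end orchestration: simulate -> preprocess -> per-cohort EWAS ->
meta-analysis -> replication -> persistence -> enrichment -> classification.

A single :class:`PipelineConfig` (YAML-loadable) drives the run; every
stage writes its table under the output directory and the run ends with a
machine-readable ``summary.json``. All randomness flows from one master
seed, so an identical config reproduces every output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .classify import PanelSpec, combine_datasets, evaluate_panels
from .datatypes import MethylationDataset, ProbeManifest, SyntheticTruth, ValidationError
from .enrichment import ANNOTATION_FAMILIES, annotation_enrichment, enrichment_table
from .ewas import run_cohort_ewas
from .meta import run_meta
from .preprocess import filter_probes
from .replication import persistence_analysis, test_replication
from .simulate import SimulationConfig, generate_cohorts, generate_manifest, replication_config

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; thresholds default to the study's choices."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    fdr_level: float = 0.01
    het_qp: float = 0.10
    het_i2: float = 50.0
    maf_threshold: float = 0.05
    missingness_threshold: float = 0.05
    nominal_m: int | None = None
    replication_scale: float = 1.0
    run_replication: bool = True
    run_persistence: bool = True
    run_classifier: bool = True
    classifier_exclude: tuple = ("C1958B",)
    n_splits: int = 20
    train_fraction: float = 0.6
    write_datasets: bool = False
    seed: int = 0
    outdir: str = "ewaskit_run"

    def validate(self) -> None:
        for name in ("alpha", "fdr_level", "het_qp", "maf_threshold",
                     "missingness_threshold", "train_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if not 0 < self.het_i2 < 100:
            raise ValidationError("het_i2 must lie in (0, 100)")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(simulation=sim, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _default_panels(truth: SyntheticTruth, betas_index: pd.Index) -> list[PanelSpec]:
    """Panels derived from the simulation ground truth.

    Mirrors the study's panel families: the single strongest CpG, the
    strongest novel-style CpG, their combination (current vs never), a
    5-CpG ever-smoker panel drawn from the most persistent spiked probes,
    and a null panel of unspiked probes as a calibration control.
    """
    sp = truth.spiked[truth.spiked.index.isin(betas_index)]
    if sp.empty:
        return []
    by_eff = sp.reindex(sp["true_effect"].abs().sort_values(ascending=False).index)
    top = by_eff.index[0]
    second = by_eff.index[1] if len(by_eff) > 1 else top
    panels = [
        PanelSpec("top_cpg", [top], "current_vs_never"),
        PanelSpec("second_cpg", [second], "current_vs_never"),
        PanelSpec("top_two_cpgs", list(dict.fromkeys([top, second])), "current_vs_never"),
    ]
    persistent = by_eff[by_eff["persistence_fraction"] >= 0.5]
    ever = list(persistent.index[:5]) or list(by_eff.index[:5])
    panels.append(PanelSpec("ever_panel", ever, "ever_vs_never"))
    null_pool = betas_index.difference(truth.spiked.index)
    if len(null_pool) >= 5:
        panels.append(PanelSpec("null_panel", list(null_pool[:5]), "current_vs_never"))
    return panels


def _replication_manifest(manifest: ProbeManifest, probes) -> ProbeManifest:
    return ProbeManifest(manifest.table.loc[list(probes)])


def run_pipeline(config: PipelineConfig, panels: list[PanelSpec] | None = None) -> dict:
    """Execute every stage, write intermediate tables, return the summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    manifest = generate_manifest(sim.n_probes, seed=config.seed)
    datasets, truth = generate_cohorts(sim, manifest)
    truth.to_json(outdir / "truth.json")
    io.write_manifest(manifest, outdir / "manifest.csv")
    if config.write_datasets:
        for d in datasets:
            io.write_dataset(d, outdir / "datasets", d.name)

    # --- preprocess -------------------------------------------------------
    filtered: list[MethylationDataset] = []
    filter_reports = {}
    for d in datasets:
        fd, rep = filter_probes(
            d,
            maf_threshold=config.maf_threshold,
            missingness_threshold=config.missingness_threshold,
        )
        filtered.append(fd)
        filter_reports[d.name] = rep.to_dict()
    with open(outdir / "filter_reports.json", "w") as fh:
        json.dump(filter_reports, fh, indent=1)

    # --- per-cohort EWAS (current vs never) -------------------------------
    cohort_results = []
    for i, d in enumerate(filtered):
        mixed = bool(sim.family_cohort[i])
        res = run_cohort_ewas(
            d, "current_vs_never", use_mixed=mixed, include_age=mixed
        )
        io.write_results_table(res.table, outdir / f"ewas_{d.name}_current.tsv")
        cohort_results.append(res)

    # --- meta-analysis ----------------------------------------------------
    meta = run_meta(
        cohort_results,
        manifest=manifest,
        het_qp=config.het_qp,
        het_i2=config.het_i2,
        alpha=config.alpha,
        fdr_level=config.fdr_level,
        nominal_m=config.nominal_m,
    )
    io.write_results_table(meta.table, outdir / "meta_current_vs_never.tsv")
    dmps = meta.dmp_probes
    if len(dmps):
        io.export_bed(list(dmps), manifest, outdir / "dmps.bed")
    summary: dict = {"meta": meta.summary(), "filter_reports": filter_reports}
    summary["n_dmps_in_fdr_set"] = int(meta.table.loc[dmps, "fdr_sig"].sum())

    novel = meta.table.index[
        meta.table["bonferroni_sig"]
        & ~meta.table["het_excluded"]
        & meta.table["novel_epic_only"]
    ]

    # --- replication of novel DMPs ---------------------------------------
    if config.run_replication and len(novel):
        rep_cfg = replication_config(
            seed=config.seed + 1, n_probes=len(novel), scale=config.replication_scale
        )
        rep_manifest = _replication_manifest(manifest, novel)
        rep_truth = SyntheticTruth(
            spiked=truth.spiked[truth.spiked.index.isin(novel)],
            covariate_effects=truth.covariate_effects,
            seed=rep_cfg.seed,
        )
        rep_datasets, _ = generate_cohorts(rep_cfg, rep_manifest, truth=rep_truth)
        rep_results = []
        for i, d in enumerate(rep_datasets):
            mixed = bool(rep_cfg.family_cohort[i])
            rep_results.append(
                run_cohort_ewas(d, "current_vs_never", use_mixed=mixed, include_age=True)
            )
        rep_report = test_replication(meta, rep_results, alpha=config.alpha)
        io.write_results_table(rep_report.table, outdir / "replication.tsv")
        summary["replication"] = rep_report.summary()

    # --- persistence (former vs never at the DMPs) ------------------------
    if config.run_persistence and len(dmps):
        former_results = []
        for i, d in enumerate(filtered):
            sub = d.subset_probes(dmps)
            mixed = bool(sim.family_cohort[i])
            try:
                former_results.append(
                    run_cohort_ewas(
                        sub, "former_vs_never", use_mixed=mixed, include_age=mixed
                    )
                )
            except ValidationError as exc:
                logger.warning("former-vs-never skipped for %s: %s", d.name, exc)
        pers = persistence_analysis(
            dmps, former_results, discovery=meta, alpha=config.alpha
        )
        io.write_results_table(pers.table, outdir / "persistence.tsv")
        summary["persistence"] = pers.summary()

    # --- annotation enrichment --------------------------------------------
    if len(dmps):
        tested = meta.table.index
        enr = {}
        for fam in ANNOTATION_FAMILIES:
            res = annotation_enrichment(dmps, tested, manifest, fam)
            tab = enrichment_table(res)
            io.write_results_table(tab, outdir / f"enrichment_{fam}.tsv")
            enr[fam] = {
                c: {
                    "log2_fold_change": float(tab.at[c, "log2_fold_change"]),
                    "fisher_p": float(tab.at[c, "fisher_p"]),
                }
                for c in tab.index
            }
        summary["enrichment"] = enr

    # --- classifier panels -------------------------------------------------
    if config.run_classifier:
        combined = combine_datasets(filtered, exclude_cohorts=list(config.classifier_exclude))
        use_panels = panels if panels is not None else _default_panels(
            truth, combined.betas.index
        )
        if use_panels:
            reports = evaluate_panels(
                combined,
                use_panels,
                n_splits=config.n_splits,
                train_fraction=config.train_fraction,
                seed=config.seed,
            )
            summary["classifier"] = {r.panel.name: r.to_dict() for r in reports}

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
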