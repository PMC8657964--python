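"""End-to-end pipeline: preprocess -> differential -> classify -> enrichment.

`run_pipeline` executes the full analysis from a :class:`PipelineConfig`,
writing every stage artifact plus a JSON run report with the stage counts,
parameters and timings.  Enrichment runs only when an ontology and an
annotation map are supplied (the expression stages are self-contained).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import classify as _classify
from . import differential as _diff
from . import enrichment as _enrich
from . import io as _io
from . import preprocess as _pre
from .dataset import ExpressionDataset, POST_INJURY_TIMES

logger = logging.getLogger("mptriage")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Threshold defaults are the published operating points: BH-adjusted ANOVA
    gate and Tukey significance at 0.05, duplicate-CV cutoff 50% with at
    least 16 passing pairs, and GO testing over levels 3-9 at alpha 0.05.
    """

    matrix_path: str | None = None
    samples_path: str | None = None
    obo_path: str | None = None
    annotation_path: str | None = None
    annotation_format: str = "tsv"  # "tsv" | "gaf"
    out_dir: str = "mptriage_out"

    fdr_alpha: float = 0.05
    tukey_alpha: float = 0.05
    cv_threshold: float = 50.0
    min_pass_pairs: int = 16
    cv_scale: str = "linear"
    enrichment_alpha: float = 0.05
    levels: tuple[int, ...] = _enrich.DEFAULT_LEVELS
    times: tuple[int, ...] = POST_INJURY_TIMES
    per_gene_centering: bool = False
    tukey_exact_p: bool = True
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_alpha", "tukey_alpha", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not all(2 <= lv <= 15 for lv in self.levels):
            raise ValueError(f"levels must lie within 2..15, got {self.levels}")
        if self.cv_scale not in ("linear", "log2"):
            raise ValueError(f"cv_scale must be 'linear' or 'log2', got {self.cv_scale!r}")


def run_pipeline(
    config: PipelineConfig, dataset: ExpressionDataset | None = None
) -> dict:
    """Run every stage on ``dataset`` (or the configured matrix) and write artifacts.

    Returns the run report: per-stage counts, parameters and timings.  Any
    stage failure propagates with the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            "fdr_alpha": config.fdr_alpha,
            "tukey_alpha": config.tukey_alpha,
            "cv_threshold": config.cv_threshold,
            "min_pass_pairs": config.min_pass_pairs,
            "cv_scale": config.cv_scale,
            "enrichment_alpha": config.enrichment_alpha,
            "levels": list(config.levels),
            "times": list(config.times),
            "seed": config.seed,
        },
        "stages": {},
    }

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = _stage("load")
        if dataset is None:
            if config.matrix_path is None or config.samples_path is None:
                raise ValueError("no dataset given and no matrix/samples paths configured")
            dataset = _io.read_expression_tsv(config.matrix_path, config.samples_path)
        report["stages"]["load"] = {
            "n_genes": dataset.n_genes,
            "n_samples": dataset.n_samples,
            "seconds": round(time.perf_counter() - t0, 3),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load' failed: {exc}") from exc

    try:
        t0 = _stage("preprocess")
        ds = _pre.normalize(dataset, per_gene=config.per_gene_centering)
        ds, outlier_report = _pre.remove_outlier_samples(ds)
        ds, cv_report = _pre.filter_noisy_genes(
            ds,
            cv_threshold=config.cv_threshold,
            min_pass_pairs=config.min_pass_pairs,
            cv_scale=config.cv_scale,
        )
        _io.write_json(outlier_report.to_dict(), out_dir / "outlier_report.json")
        _io.write_json(cv_report.to_dict(), out_dir / "cv_filter_report.json")
        if outlier_report.pca_coordinates is not None:
            outlier_report.pca_coordinates.to_csv(
                out_dir / "sample_pca.tsv", sep="\t", index_label="sample_id"
            )
        _io.write_gene_list(ds.genes, out_dir / "tested_universe.txt")
        report["stages"]["preprocess"] = {
            "removed_samples": sorted(outlier_report.removed_samples),
            "genes_before": cv_report.genes_before,
            "genes_after": cv_report.genes_after,
            "seconds": round(time.perf_counter() - t0, 3),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'preprocess' failed: {exc}") from exc

    try:
        t0 = _stage("differential")
        tables, quads = _diff.differential_all_times(
            ds,
            times=config.times,
            fdr_alpha=config.fdr_alpha,
            tukey_alpha=config.tukey_alpha,
            exact_p=config.tukey_exact_p,
        )
        _io.write_stats_tables(tables, out_dir / "stats")
        _io.write_deg_quads(quads, out_dir / "deg_quads.json")
        report["stages"]["differential"] = {
            "deg_set_sizes": {
                str(t): {lab: len(q[lab]) for lab in _diff.CONTRAST_LABELS}
                for t, q in quads.items()
            },
            "seconds": round(time.perf_counter() - t0, 3),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'differential' failed: {exc}") from exc

    try:
        t0 = _stage("classify")
        universe = set(ds.genes)
        assignments = _classify.assignments_from_quads(quads, universe)
        summaries = _classify.aggregate_phases(assignments, analyzed_times=config.times)
        _classify.assignments_table(assignments).to_csv(
            out_dir / "class_assignments.tsv", sep="\t", index=False
        )
        _classify.phase_summary_table(summaries).to_csv(
            out_dir / "phase_summary.tsv", sep="\t", index_label="gene_class"
        )
        profiles = _classify.export_profiles(ds, assignments)
        profiles.to_csv(out_dir / "class_profiles.tsv", sep="\t", index=False)
        if config.make_plots and not profiles.empty:
            _classify.plot_class_profiles(profiles, str(out_dir / "class_profiles.png"))
        report["stages"]["classify"] = {
            "phase_counts": {s.phase: s.counts() for s in summaries},
            "n_assignments": len(assignments),
            "seconds": round(time.perf_counter() - t0, 3),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'classify' failed: {exc}") from exc

    if config.obo_path and config.annotation_path:
        try:
            t0 = _stage("enrichment")
            dag = _enrich.load_ontology(config.obo_path)
            reader = (
                _io.read_annotation_gaf
                if config.annotation_format == "gaf"
                else _io.read_annotation_tsv
            )
            raw = reader(config.annotation_path)
            annot, skipped = _enrich.propagate_annotations(raw, dag)
            enrich_counts = {}
            all_rows = []
            for summary in summaries:
                for cls in _classify.GENE_CLASSES:
                    class_genes = summary.genes[cls] & universe
                    if not class_genes:
                        continue
                    rog = universe - class_genes
                    records = _enrich.nested_inclusive_analysis(
                        class_genes,
                        rog,
                        dag,
                        annot,
                        levels=config.levels,
                        alpha=config.enrichment_alpha,
                    )
                    df = _enrich.records_table(records)
                    if not df.empty:
                        df.insert(0, "phase", summary.phase)
                        df.insert(1, "gene_class", cls)
                        all_rows.append(df)
                    enrich_counts[f"{summary.phase}/{cls}"] = sum(
                        r.deepest for r in records
                    )
            if all_rows:
                import pandas as pd

                full = pd.concat(all_rows, ignore_index=True)
                full.to_csv(out_dir / "enrichment_full.tsv", sep="\t", index=False)
                full[full["deepest"]].to_csv(
                    out_dir / "enrichment_deepest.tsv", sep="\t", index=False
                )
            report["stages"]["enrichment"] = {
                "deepest_term_counts": enrich_counts,
                "skipped_annotations": skipped,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'enrichment' failed: {exc}") from exc
    else:
        report["stages"]["enrichment"] = {"skipped": "no ontology/annotation supplied"}

    _io.write_json(report, out_dir / "run_report.json")
    return report
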