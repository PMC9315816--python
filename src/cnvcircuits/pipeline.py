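"""End-to-end orchestration of the gene-to-circuit-to-behavior pipeline.

Stage order: map CNVs to genes -> assemble the initial dataset ->
pathway over-representation -> PPI filter -> co-expression filter ->
developmental-expression mapping -> circuit assignment -> behavioral
association scan (plus a pathway re-annotation of each circuit's gene
list).  Every stage persists its output so single stages are resumable
and independently inspectable, and the report carries the gene-count
audit trail through the stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import association as assoc
from . import development as dev
from . import enrichment as enr
from . import io as cio
from .cnvmap import assemble_initial_dataset, cohort_gene_union
from .core import (
    AnnotationTable,
    CircuitMap,
    GeneSetCollection,
    PipelineConfig,
    SubjectRecord,
    default_circuit_map,
)
from .network import filter_by_coexpression, filter_by_ppi

logger = logging.getLogger(__name__)

STAGES = (
    "map_genes",
    "assemble",
    "enrich",
    "filter_ppi",
    "filter_coexpr",
    "map_expression",
    "assign_circuits",
    "associate",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial report."""

    def __init__(self, stage: str, cause: Exception, report: "PipelineReport"):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial_report = report


@dataclass
class PipelineReport:
    """Audit trail of a pipeline run: per-stage gene counts and outputs."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    seed: int = 0
    outputs: dict[str, str] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stage_counts": self.stage_counts,
            "config": self.config_echo,
            "seed": self.seed,
            "outputs": self.outputs,
            "completed_stages": self.completed_stages,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def run_pipeline(
    config: PipelineConfig,
    inputs: Mapping[str, str | Path],
    outdir: str | Path,
) -> PipelineReport:
    """Run every stage in order, persisting each stage's output.

    ``inputs`` must name: ``subjects_tsv``, ``genes_bed``,
    ``pathways_gmt``, ``ppi_tsv``, ``expression_matrix``,
    ``expression_meta``; optionally ``background_txt``,
    ``neurodev_genes_txt``, ``circuit_map`` (defaults to the built-in
    five-system map) and ``annotation_dialect``.

    The run is fully deterministic for a given config and inputs; two
    runs write byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(
        config_echo=dataclasses.asdict(config), seed=config.rng_seed
    )

    def _out(name: str) -> Path:
        path = outdir / name
        report.outputs[name] = str(path)
        return path

    stage = "load_inputs"
    try:
        subjects = cio.read_subjects(inputs["subjects_tsv"])
        annotation = cio.read_annotation(
            inputs["genes_bed"], dialect=str(inputs.get("annotation_dialect", "bed"))
        )
        collection = cio.read_gmt(inputs["pathways_gmt"])
        if "background_txt" in inputs:
            collection = GeneSetCollection(
                sets=dict(collection.sets),
                background=frozenset(cio.read_gene_list(inputs["background_txt"])),
            )
        edges = cio.read_ppi_edges(inputs["ppi_tsv"])
        bundle = cio.read_expression_bundle(
            inputs["expression_matrix"], inputs["expression_meta"]
        )
        circuit_map = (
            cio.read_circuit_map(inputs["circuit_map"])
            if "circuit_map" in inputs
            else default_circuit_map()
        )
        neurodev = (
            cio.read_gene_list(inputs["neurodev_genes_txt"])
            if "neurodev_genes_txt" in inputs
            else set()
        )

        stage = "map_genes"
        cnv_genes = cohort_gene_union(
            subjects, annotation, min_overlap_bp=config.min_overlap_bp
        )
        cio.write_gene_list(cnv_genes, _out("cnv_genes.txt"))

        stage = "assemble"
        initial = assemble_initial_dataset(cnv_genes, neurodev)
        cio.write_gene_list(initial, _out("initial_dataset.txt"))
        report.stage_counts["initial"] = len(initial)

        stage = "enrich"
        results = enr.enrich(
            initial, collection, alpha=config.enrichment_alpha, mtc=config.mtc_method
        )
        enr.write_results(results, _out("enrichment.tsv"))
        enriched = enr.significant_gene_union(results, config.enrichment_alpha)
        cio.write_gene_list(enriched, _out("enriched_genes.txt"))
        report.stage_counts["post_enrichment"] = len(enriched)

        stage = "filter_ppi"
        ppi_report = filter_by_ppi(
            enriched, edges, min_conf=config.ppi_min_confidence
        )
        ppi_report.write(_out("ppi_genes.txt"), _out("ppi_report.json"))
        report.stage_counts["post_ppi"] = len(ppi_report.retained_genes)

        stage = "filter_coexpr"
        coexpr_report = filter_by_coexpression(
            ppi_report.retained_genes, bundle, threshold=config.coexpr_threshold
        )
        coexpr_report.write(_out("coexpr_genes.txt"), _out("coexpr_report.json"))
        report.stage_counts["post_coexpression"] = len(coexpr_report.retained_genes)

        stage = "map_expression"
        mapping = dev.map_gene_set(
            coexpr_report.retained_genes, bundle, boundaries=config.epoch_boundaries
        )
        dev.write_sites(mapping, _out("gene_sites.tsv"))
        report.stage_counts["mapped"] = len(mapping.sites)

        stage = "assign_circuits"
        assignments = assoc.assign_circuits(mapping.sites, circuit_map)
        _write_assignments(assignments, _out("circuit_assignments.tsv"))
        report.stage_counts["circuit_assigned"] = sum(
            1 for a in assignments if a.circuits
        )

        stage = "associate"
        comparisons = assoc.run_association_scan(
            subjects, assignments, circuit_map, annotation, config=config
        )
        assoc.write_results(comparisons, _out("associations.tsv"))
        circuit_paths = assoc.annotate_circuit_pathways(
            assignments, collection, alpha=config.enrichment_alpha,
            mtc=config.mtc_method,
        )
        _write_circuit_pathways(
            circuit_paths, config.enrichment_alpha, _out("circuit_pathways.tsv")
        )
        report.completed_stages = list(STAGES)
        report.to_json(_out("report.json"))
        return report
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        report.completed_stages = _completed_before(stage)
        raise StageError(stage, exc, report) from exc


def _completed_before(stage: str) -> list[str]:
    if stage not in STAGES:
        return []
    return list(STAGES[: STAGES.index(stage)])


def _write_assignments(assignments, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tvia_region\tepoch\tcircuits\n")
        for a in sorted(assignments, key=lambda a: a.gene):
            fh.write(
                f"{a.gene}\t{a.via_region}\t{a.epoch.value}\t"
                f"{','.join(sorted(a.circuits))}\n"
            )


def _write_circuit_pathways(circuit_paths, alpha: float, path: Path) -> None:
    """Circuit -> over-represented pathways, one row per significant hit."""
    with open(path, "w") as fh:
        fh.write("circuit\tpathway\tk\tK\tp\tadjusted_p\toverlap_genes\n")
        for circuit in sorted(circuit_paths):
            for r in circuit_paths[circuit]:
                if enr.is_significant(r, alpha):
                    adj = "" if r.adjusted_p is None else f"{r.adjusted_p:.6g}"
                    fh.write(
                        f"{circuit}\t{r.pathway}\t{r.k}\t{r.K}\t{r.p_value:.6g}\t"
                        f"{adj}\t{','.join(sorted(r.overlap_genes))}\n"
                    )
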