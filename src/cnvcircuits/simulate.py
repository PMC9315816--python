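"""Synthetic study generator: a gene universe with planted structure and
a subject cohort with a planted behavioral effect.

The generator emulates, at desk scale, the statistical structure the
pipeline assumes in real data:

* a gene universe laid out on synthetic chromosomes with non-overlapping
  intervals,
* pathway membership with one designated *causal* pathway whose genes
  (i) form a high-confidence PPI clique, (ii) load on a shared latent
  expression factor (so their pairwise Pearson correlation has a known
  closed form, loading^2 / (loading^2 + noise^2)), and (iii) peak in one
  planted (region, epoch) expression cell,
* a cohort of normal-microarray and CNV subjects (defaults 47 and 90),
  where a configurable fraction of CNV subjects carry a CNV overlapping
  a causal gene, and carriers' scores on one target behavioral item are
  shifted by a configurable effect size in pooled-SD units.

Everything is driven by a single seed through named substreams, so the
same design always produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    AnnotationTable,
    CircuitMap,
    DEFAULT_REGION_VOCAB,
    Epoch,
    ExpressionBundle,
    GeneAnnotation,
    GeneSetCollection,
    GenomicInterval,
    PPIEdge,
    SubjectRecord,
    ValidationError,
    canon,
    default_circuit_map,
)
from . import io as cio

_EPOCH_AGE_RANGES = {
    Epoch.TRIMESTER1: ("pcw", 6.0, 13.0),
    Epoch.TRIMESTER2: ("pcw", 14.0, 26.0),
    Epoch.TRIMESTER3: ("pcw", 27.0, 38.0),
    Epoch.POSTNATAL: ("postnatal_days", 30.0, 3650.0),
}

GENE_LENGTH = 10_000
GENE_SPACING = 20_000
CNV_MARGIN = 100


class DesignError(ValidationError):
    """The simulation design is internally infeasible."""


@dataclass
class SimulationDesign:
    """Parameters of the synthetic study.

    The cohort defaults (47 normal-microarray, 90 CNV subjects; Vineland
    interviews for 30 and 87 of them) mirror the clinical study's group
    sizes.  ``coexpr_latent_loading`` of 2.0 with unit noise plants a
    pairwise causal-gene correlation of 2^2/(2^2+1) = 0.8, comfortably
    above the 0.7 co-expression threshold; ``ppi_within_confidence`` of
    0.95 puts the causal clique above the 0.9 PPI threshold.
    ``effect_size_sd`` is the carriers' shift on the target behavioral
    item in pooled-SD units.
    """

    # universe
    n_genes: int = 400
    genes_per_chrom: int = 50
    n_pathways: int = 25
    pathway_size_range: tuple[int, int] = (8, 25)
    causal_pathway_size: int = 20
    # PPI
    ppi_within_confidence: float = 0.95
    ppi_within_sd: float = 0.02
    ppi_background_confidence: float = 0.40
    ppi_background_sd: float = 0.15
    ppi_background_edges_per_gene: int = 3
    # expression
    coexpr_latent_loading: float = 2.0
    noise_sd: float = 1.0
    expression_peak_gain: float = 8.0
    samples_per_cell: int = 4
    baseline_mean: float = 50.0
    baseline_sd: float = 5.0
    cell_effect_sd: float = 2.0
    coexpr_threshold_check: float = 0.7
    # planted site
    target_circuit: str = "Positive Valence"
    target_region: str = "STR"
    target_epoch: Epoch = Epoch.TRIMESTER1
    # cohort
    n_normal: int = 47
    n_cnv: int = 90
    carrier_fraction: float = 0.5
    bystander_max: int = 5
    effect_size_sd: float = 1.0
    target_item: str = "PCQ3"
    n_pcq_items: int = 8
    likert_range: tuple[int, int] = (1, 5)
    pcq_latent_mean: float = 2.5
    pcq_latent_sd: float = 1.0
    vineland_subscales: tuple[str, ...] = ("ADL", "Motor", "Social")
    vineland_mean: float = 75.0
    vineland_sd: float = 10.0
    vineland_n: tuple[int, int] = (30, 87)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_epoch is not None and not isinstance(self.target_epoch, Epoch):
            self.target_epoch = Epoch(self.target_epoch)
        for name in ("n_genes", "n_pathways", "causal_pathway_size",
                     "n_normal", "n_cnv", "samples_per_cell"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be positive")
        if self.causal_pathway_size > self.n_genes:
            raise DesignError("causal_pathway_size exceeds the universe size")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi <= self.n_genes):
            raise DesignError("pathway_size_range infeasible for the universe")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise DesignError("carrier_fraction must lie in [0, 1]")
        if self.coexpr_latent_loading > 0 and (
            self.implied_pairwise_r <= self.coexpr_threshold_check
        ):
            raise DesignError(
                f"latent loading {self.coexpr_latent_loading} implies pairwise "
                f"r = {self.implied_pairwise_r:.3f}, not above the co-expression "
                f"threshold {self.coexpr_threshold_check}"
            )
        if self.vineland_n[0] > self.n_normal or self.vineland_n[1] > self.n_cnv:
            raise DesignError("vineland_n exceeds the group sizes")

    @property
    def implied_pairwise_r(self) -> float:
        """Closed-form pairwise correlation between two causal genes that
        share the latent factor (ignoring the planted peak)."""
        l2 = self.coexpr_latent_loading**2
        return l2 / (l2 + self.noise_sd**2)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_epoch"] = self.target_epoch.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        d = dict(d)
        for key in ("pathway_size_range", "likert_range", "vineland_n"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "vineland_subscales" in d and d["vineland_subscales"] is not None:
            d["vineland_subscales"] = tuple(d["vineland_subscales"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticUniverse:
    """Everything generate_universe plants: data plus its ground truth."""

    annotation: AnnotationTable
    collection: GeneSetCollection
    edges: list[PPIEdge]
    bundle: ExpressionBundle
    circuit_map: CircuitMap
    causal_genes: frozenset[str]
    causal_pathway: str
    design: SimulationDesign


def _substream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


# ---------------------------------------------------------------------------
# Universe
# ---------------------------------------------------------------------------

def generate_universe(design: SimulationDesign) -> SyntheticUniverse:
    """Generate the full synthetic universe for a design (deterministic in
    the design's seed)."""
    circuit_map = default_circuit_map()
    if design.target_region.upper() not in {
        r.upper() for r in circuit_map.circuits.get(design.target_circuit, ())
    }:
        raise DesignError(
            f"target region {design.target_region} not in circuit "
            f"{design.target_circuit!r}"
        )

    rng_layout = _substream(design.rng_seed, 1)
    rng_paths = _substream(design.rng_seed, 2)
    rng_ppi = _substream(design.rng_seed, 3)
    rng_expr = _substream(design.rng_seed, 4)

    # --- gene layout on synthetic chromosomes, non-overlapping intervals
    symbols = [f"G{i + 1:04d}" for i in range(design.n_genes)]
    genes = []
    for i, sym in enumerate(symbols):
        chrom = f"chrS{i // design.genes_per_chrom + 1:02d}"
        start = (i % design.genes_per_chrom) * GENE_SPACING
        genes.append(
            GeneAnnotation(sym, GenomicInterval(chrom, start, start + GENE_LENGTH))
        )
    annotation = AnnotationTable(genes)

    causal_idx = np.sort(
        rng_layout.choice(design.n_genes, size=design.causal_pathway_size, replace=False)
    )
    causal_genes = frozenset(symbols[i] for i in causal_idx)

    # --- pathways: one causal (exactly the causal genes), decoys sampled
    # without replacement from the whole universe (sets may share genes)
    names = [f"PW{i + 1:02d}" for i in range(design.n_pathways)]
    causal_pathway = names[int(rng_paths.integers(design.n_pathways))]
    lo, hi = design.pathway_size_range
    sets: dict[str, frozenset[str]] = {}
    for name in names:
        if name == causal_pathway:
            sets[name] = causal_genes
        else:
            size = int(rng_paths.integers(lo, hi + 1))
            members = rng_paths.choice(design.n_genes, size=size, replace=False)
            sets[name] = frozenset(symbols[i] for i in members)
    collection = GeneSetCollection(sets=sets, background=frozenset(symbols))

    # --- PPI: high-confidence clique over causal genes + noisy background
    edges: list[PPIEdge] = []
    causal_list = sorted(causal_genes)
    for i in range(len(causal_list)):
        for j in range(i + 1, len(causal_list)):
            conf = float(
                np.clip(
                    rng_ppi.normal(design.ppi_within_confidence, design.ppi_within_sd),
                    0.0, 1.0,
                )
            )
            edges.append(PPIEdge(causal_list[i], causal_list[j], conf))
    n_bg = design.ppi_background_edges_per_gene * design.n_genes
    ia = rng_ppi.integers(design.n_genes, size=n_bg)
    ib = rng_ppi.integers(design.n_genes, size=n_bg)
    confs = np.clip(
        rng_ppi.normal(design.ppi_background_confidence, design.ppi_background_sd, n_bg),
        0.0, 1.0,
    )
    for a, b, conf in zip(ia, ib, confs):
        if a != b:
            edges.append(PPIEdge(symbols[a], symbols[b], float(conf)))

    # --- expression: regions x epochs grid, shared latent factor + peak
    bundle = _generate_expression(design, symbols, causal_idx, rng_expr)

    return SyntheticUniverse(
        annotation=annotation,
        collection=collection,
        edges=edges,
        bundle=bundle,
        circuit_map=circuit_map,
        causal_genes=causal_genes,
        causal_pathway=causal_pathway,
        design=design,
    )


def _generate_expression(
    design: SimulationDesign,
    symbols: Sequence[str],
    causal_idx: np.ndarray,
    rng: np.random.Generator,
) -> ExpressionBundle:
    regions = list(DEFAULT_REGION_VOCAB)
    epochs = [Epoch.TRIMESTER1, Epoch.TRIMESTER2, Epoch.TRIMESTER3, Epoch.POSTNATAL]
    meta_rows = []
    in_target = []
    k = 0
    for region in regions:
        for epoch in epochs:
            unit, lo, hi = _EPOCH_AGE_RANGES[epoch]
            for _ in range(design.samples_per_cell):
                k += 1
                age = float(np.round(rng.uniform(lo, hi), 2))
                meta_rows.append(
                    {"sample_id": f"S{k:04d}", "region_code": region,
                     "age_value": age, "age_unit": unit}
                )
                in_target.append(
                    region.upper() == design.target_region.upper()
                    and epoch is design.target_epoch
                )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    n_samples = len(meta)
    in_target = np.asarray(in_target)

    n_genes = len(symbols)
    baseline = np.maximum(
        rng.normal(design.baseline_mean, design.baseline_sd, n_genes), 10.0
    )
    is_causal = np.zeros(n_genes, dtype=bool)
    is_causal[causal_idx] = True

    latent = rng.normal(0.0, 1.0, n_samples)  # shared factor, one value/sample
    noise = rng.normal(0.0, design.noise_sd, (n_genes, n_samples))
    # non-causal genes get an independent random (region, epoch) profile so
    # their argmax cell is arbitrary; causal genes get the latent factor
    # plus the planted peak instead
    epoch_labels = [
        _classify(a, u).value for a, u in zip(meta["age_value"], meta["age_unit"])
    ]
    cell_ids = [f"{r}|{e}" for r, e in zip(meta["region_code"], epoch_labels)]
    cell_codes, cell_index = np.unique(cell_ids, return_inverse=True)
    cell_effects = rng.normal(0.0, design.cell_effect_sd, (n_genes, len(cell_codes)))

    mat = baseline[:, None] + noise
    mat[~is_causal] += cell_effects[~is_causal][:, cell_index]
    mat[is_causal] += design.coexpr_latent_loading * latent[None, :]
    mat[is_causal] += design.expression_peak_gain * in_target[None, :]
    np.maximum(mat, 0.0, out=mat)  # expression is non-negative

    matrix = pd.DataFrame(np.round(mat, 6), index=list(symbols), columns=meta.index)
    return ExpressionBundle(matrix=matrix, sample_meta=meta)


def _classify(age_value: float, age_unit: str) -> Epoch:
    # local epoch classifier with the default boundaries (avoids an import
    # cycle with the mapping stage)
    if age_unit == "postnatal_days":
        return Epoch.POSTNATAL
    if age_value <= 13.0:
        return Epoch.TRIMESTER1
    if age_value <= 26.0:
        return Epoch.TRIMESTER2
    if age_value <= 38.0:
        return Epoch.TRIMESTER3
    return Epoch.POSTNATAL


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    design: SimulationDesign,
    annotation: AnnotationTable,
    causal_genes: Iterable[str],
    seed: int | None = None,
) -> list[SubjectRecord]:
    """Generate the subject cohort with the planted behavioral effect.

    Carriers (a ``carrier_fraction`` share of the CNV group) receive a CNV
    overlapping one causal gene plus 0-``bystander_max`` neighbouring
    bystander genes; causal genes are dealt to carriers round-robin so
    each causal gene is covered whenever there are at least as many
    carriers as causal genes.  Non-carrier CNV subjects receive a CNV over
    non-causal genes only.  Carriers' target-item scores are shifted by
    ``effect_size_sd`` pooled SDs; every other item is exchangeable
    between groups.

    ``seed`` overrides the design seed (useful for replicate cohorts over
    a fixed universe).
    """
    causal = {canon(g) for g in causal_genes}
    if not causal <= annotation.symbols:
        raise DesignError("causal genes must be annotated")
    rng = _substream(design.rng_seed if seed is None else seed, 11)

    # neighbour structure for CNV windows
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.interval.start)
    position = {
        canon(g.symbol): (chrom, i)
        for chrom, gs in by_chrom.items()
        for i, g in enumerate(gs)
    }
    noncausal_syms = sorted(annotation.symbols - causal)

    n_carriers = int(round(design.carrier_fraction * design.n_cnv))
    carrier_flags = np.zeros(design.n_cnv, dtype=bool)
    carrier_flags[rng.permutation(design.n_cnv)[:n_carriers]] = True
    causal_order = list(rng.permutation(sorted(causal)))

    subjects: list[SubjectRecord] = []
    intervals: list[list[GenomicInterval]] = []
    carrier_of: list[bool] = []
    j = 0
    for i in range(design.n_cnv):
        if carrier_flags[i] and causal_order:
            gene = causal_order[j % len(causal_order)]
            j += 1
            iv = _cnv_window(gene, by_chrom, position, rng, design, avoid=None)
        else:
            gene = noncausal_syms[int(rng.integers(len(noncausal_syms)))]
            iv = _cnv_window(gene, by_chrom, position, rng, design, avoid=causal)
        intervals.append([iv])
        carrier_of.append(bool(carrier_flags[i]) and bool(causal_order))

    # --- behavioral scores (vectorised, then packed per subject)
    n_total = design.n_normal + design.n_cnv
    is_carrier = np.concatenate(
        [np.zeros(design.n_normal, dtype=bool), np.asarray(carrier_of)]
    )
    pcq_items = [f"PCQ{i + 1}" for i in range(design.n_pcq_items)]
    latent = rng.normal(
        design.pcq_latent_mean, design.pcq_latent_sd, (n_total, design.n_pcq_items)
    )
    if design.target_item in pcq_items:
        col = pcq_items.index(design.target_item)
        latent[is_carrier, col] += design.effect_size_sd * design.pcq_latent_sd
    lo, hi = design.likert_range
    pcq_scores = np.clip(np.rint(latent), lo, hi).astype(int)

    vin = rng.normal(
        design.vineland_mean, design.vineland_sd,
        (n_total, len(design.vineland_subscales)),
    )
    if design.target_item in design.vineland_subscales:
        col = design.vineland_subscales.index(design.target_item)
        vin[is_carrier, col] += design.effect_size_sd * design.vineland_sd
    vlo, vhi = SubjectRecord.VINELAND_RANGE
    vin = np.clip(np.round(vin, 4), vlo, vhi)

    # Vineland coverage per group (interviews were not obtained for all)
    has_vineland = np.zeros(n_total, dtype=bool)
    has_vineland[rng.permutation(design.n_normal)[: design.vineland_n[0]]] = True
    has_vineland[
        design.n_normal + rng.permutation(design.n_cnv)[: design.vineland_n[1]]
    ] = True

    for i in range(design.n_normal):
        subjects.append(
            SubjectRecord(
                subject_id=f"N{i + 1:03d}",
                microarray_status="normal",
                pcq={item: int(pcq_scores[i, k]) for k, item in enumerate(pcq_items)},
                vineland=(
                    {s: float(vin[i, k]) for k, s in enumerate(design.vineland_subscales)}
                    if has_vineland[i] else {}
                ),
            )
        )
    for i in range(design.n_cnv):
        row = design.n_normal + i
        subjects.append(
            SubjectRecord(
                subject_id=f"C{i + 1:03d}",
                microarray_status="cnv",
                cnv_intervals=intervals[i],
                pcq={item: int(pcq_scores[row, k]) for k, item in enumerate(pcq_items)},
                vineland=(
                    {s: float(vin[row, k]) for k, s in enumerate(design.vineland_subscales)}
                    if has_vineland[row] else {}
                ),
            )
        )
    return subjects


def _cnv_window(
    gene: str,
    by_chrom: dict[str, list[GeneAnnotation]],
    position: dict[str, tuple[str, int]],
    rng: np.random.Generator,
    design: SimulationDesign,
    avoid: set[str] | None,
) -> GenomicInterval:
    """A single CNV interval covering ``gene`` plus 0..bystander_max
    neighbours; never extends over a gene in ``avoid``."""
    chrom, idx = position[canon(gene)]
    row = by_chrom[chrom]
    n_by = int(rng.integers(0, design.bystander_max + 1))
    want_left = int(rng.integers(0, n_by + 1))
    want_right = n_by - want_left
    left = idx
    while left > idx - want_left and left > 0:
        if avoid and canon(row[left - 1].symbol) in avoid:
            break
        left -= 1
    right = idx
    while right < idx + want_right and right < len(row) - 1:
        if avoid and canon(row[right + 1].symbol) in avoid:
            break
        right += 1
    start = max(0, row[left].interval.start - CNV_MARGIN)
    end = row[right].interval.end + CNV_MARGIN
    return GenomicInterval(chrom, start, end)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixture(
    universe: SyntheticUniverse,
    subjects: Sequence[SubjectRecord],
    outdir: str | Path,
) -> dict[str, str]:
    """Write the full fixture bundle in the pipeline's file formats.

    Returns a manifest (also written to ``manifest.json``) recording the
    design, the seed, the planted ground truth and every file path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_bed": outdir / "genes.bed",
        "pathways_gmt": outdir / "pathways.gmt",
        "background_txt": outdir / "background_genes.txt",
        "ppi_tsv": outdir / "ppi_edges.tsv",
        "expression_matrix": outdir / "expression_matrix.tsv",
        "expression_meta": outdir / "expression_meta.tsv",
        "circuit_map": outdir / "circuit_map.yaml",
        "subjects_tsv": outdir / "subjects.tsv",
    }
    cio.write_annotation(universe.annotation, paths["genes_bed"])
    cio.write_gmt(universe.collection, paths["pathways_gmt"])
    cio.write_gene_list(universe.collection.effective_background(), paths["background_txt"])
    cio.write_ppi_edges(universe.edges, paths["ppi_tsv"])
    cio.write_expression_bundle(
        universe.bundle, paths["expression_matrix"], paths["expression_meta"]
    )
    cio.write_circuit_map(universe.circuit_map, paths["circuit_map"])
    cio.write_subjects(subjects, paths["subjects_tsv"])
    manifest = {
        "design": universe.design.to_dict(),
        "causal_pathway": universe.causal_pathway,
        "causal_genes": sorted(universe.causal_genes),
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
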