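"""Core domain types shared by every pipeline stage.

The pipeline reasons about five kinds of objects: genomic intervals and
gene annotations (where CNVs and genes live), gene-set collections
(pathway membership), PPI edges (interaction evidence), expression
bundles (genes x brain samples with region/age metadata) and subject
records (microarray status, CNV loci, behavioral scores).  All
coordinates are stored 0-based half-open; gene symbols are
case-preserved but compared case-insensitively.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


class ParseError(ValueError):
    """A file could not be parsed into a valid object."""


def canon(symbol: str) -> str:
    """Canonical (case-insensitive) form of a gene symbol."""
    return symbol.strip().upper()


def canon_set(symbols: Iterable[str]) -> frozenset[str]:
    return frozenset(canon(s) for s in symbols)


# ---------------------------------------------------------------------------
# Genomic intervals and gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome label must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene symbol with its genomic interval."""

    symbol: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ValidationError("gene symbol must be non-empty")


class AnnotationTable:
    """An indexed table of gene annotations, the lookup target for CNV loci.

    Symbols must be unique (case-insensitively).  Per-chromosome start/end
    arrays are pre-built so that interval overlap queries are vectorised;
    a cohort of subjects can be mapped without quadratic Python loops.
    """

    def __init__(self, genes: Iterable[GeneAnnotation]):
        self.genes: list[GeneAnnotation] = list(genes)
        self._by_symbol: dict[str, GeneAnnotation] = {}
        for g in self.genes:
            key = canon(g.symbol)
            if key in self._by_symbol:
                raise ValidationError(f"duplicate gene symbol {g.symbol!r}")
            self._by_symbol[key] = g
        # chrom -> (starts, ends, symbols) sorted by start
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[GeneAnnotation]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.interval.start, g.interval.end))
            self._index[chrom] = (
                np.array([g.interval.start for g in gs], dtype=np.int64),
                np.array([g.interval.end for g in gs], dtype=np.int64),
                np.array([g.symbol for g in gs], dtype=object),
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return canon(symbol) in self._by_symbol

    def __getitem__(self, symbol: str) -> GeneAnnotation:
        try:
            return self._by_symbol[canon(symbol)]
        except KeyError:
            raise KeyError(f"gene {symbol!r} not in annotation") from None

    @property
    def symbols(self) -> frozenset[str]:
        """Canonical symbols of all annotated genes."""
        return frozenset(self._by_symbol)

    def overlapping(
        self, query: GenomicInterval, min_overlap_bp: int = 1
    ) -> set[str]:
        """Canonical symbols of genes overlapping ``query`` by >= ``min_overlap_bp``."""
        if min_overlap_bp < 1:
            raise ValidationError("min_overlap_bp must be >= 1")
        idx = self._index.get(query.chrom)
        if idx is None:
            return set()
        starts, ends, symbols = idx
        ov = np.minimum(ends, query.end) - np.maximum(starts, query.start)
        hit = ov >= min_overlap_bp
        return {canon(s) for s in symbols[hit]}


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named pathways over a gene universe; the enrichment reference.

    ``background`` is the reference universe (e.g. the whole genome in the
    clinical analysis).  When supplied, every set must be contained in it.
    Symbols are canonicalised on construction.
    """

    sets: dict[str, frozenset[str]]
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {name: canon_set(genes) for name, genes in self.sets.items()}
        if self.background is not None:
            self.background = canon_set(self.background)
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if self.background is not None and not genes <= self.background:
                extra = sorted(genes - self.background)[:5]
                raise ValidationError(
                    f"gene set {name!r} has members outside the background: {extra}"
                )

    def effective_background(self) -> frozenset[str]:
        """The declared background, else the union of all sets."""
        if self.background is not None:
            return self.background
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Protein-protein interaction edges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PPIEdge:
    """An undirected interaction with a confidence score in [0, 1]."""

    gene_a: str
    gene_b: str
    confidence: float

    def __post_init__(self) -> None:
        if canon(self.gene_a) == canon(self.gene_b):
            raise ValidationError(f"self-edge on {self.gene_a!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(
                f"confidence must lie in [0, 1], got {self.confidence}"
            )


# ---------------------------------------------------------------------------
# Developmental epochs and expression bundles
# ---------------------------------------------------------------------------

class Epoch(str, enum.Enum):
    """A developmental epoch: one of the three trimesters or postnatal life."""

    TRIMESTER1 = "trimester1"
    TRIMESTER2 = "trimester2"
    TRIMESTER3 = "trimester3"
    POSTNATAL = "postnatal"

    @property
    def is_antenatal(self) -> bool:
        return self is not Epoch.POSTNATAL

    @property
    def order(self) -> int:
        """Chronological index, used for deterministic tie-breaking."""
        return _EPOCH_ORDER[self]


_EPOCH_ORDER = {
    Epoch.TRIMESTER1: 0,
    Epoch.TRIMESTER2: 1,
    Epoch.TRIMESTER3: 2,
    Epoch.POSTNATAL: 3,
}

AGE_UNITS = ("pcw", "postnatal_days")

#: Region codes seeded from the printed circuit/region tables; callers may
#: extend this vocabulary when loading their own data.
DEFAULT_REGION_VOCAB = (
    "ACC", "Amy", "STR", "Ocx", "DLPFC", "MD",
    "A1C", "IPC", "V1C", "ITC", "VLPFC", "MPFC",
)


class ExpressionBundle:
    """A non-negative genes x samples matrix with per-sample brain metadata.

    ``matrix`` is a DataFrame indexed by gene symbol with one column per
    sample; ``sample_meta`` has one row per sample (same order as the
    matrix columns) with columns ``region_code``, ``age_value`` and
    ``age_unit`` ("pcw" or "postnatal_days").
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        sample_meta: pd.DataFrame,
        region_vocab: Sequence[str] = DEFAULT_REGION_VOCAB,
    ):
        required = {"region_code", "age_value", "age_unit"}
        missing = required - set(sample_meta.columns)
        if missing:
            raise ValidationError(f"sample metadata lacks columns {sorted(missing)}")
        mat_ids = list(matrix.columns)
        meta_ids = list(sample_meta.index)
        if mat_ids != meta_ids:
            only_mat = sorted(set(mat_ids) - set(meta_ids))
            only_meta = sorted(set(meta_ids) - set(mat_ids))
            raise ValidationError(
                "matrix/metadata sample ids differ; "
                f"matrix-only: {only_mat}, metadata-only: {only_meta}"
            )
        if (matrix.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        if (sample_meta["age_value"] <= 0).any():
            bad = sample_meta.index[sample_meta["age_value"] <= 0].tolist()
            raise ValidationError(f"non-positive age for samples {bad}")
        bad_units = set(sample_meta["age_unit"]) - set(AGE_UNITS)
        if bad_units:
            raise ValidationError(f"unknown age units {sorted(bad_units)}")
        vocab = {r.upper() for r in region_vocab}
        unknown = {
            r for r in sample_meta["region_code"] if str(r).upper() not in vocab
        }
        if unknown:
            raise ValidationError(f"unknown region codes {sorted(unknown)}")
        self.matrix = matrix
        self.sample_meta = sample_meta
        self.region_vocab = tuple(region_vocab)
        self._canon_index = {canon(g): g for g in matrix.index}

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, gene: str) -> bool:
        return canon(gene) in self._canon_index

    def profile(self, gene: str) -> np.ndarray:
        """Expression profile across samples; KeyError if absent."""
        try:
            row = self._canon_index[canon(gene)]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression bundle") from None
        return self.matrix.loc[row].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# RDoC circuit map
# ---------------------------------------------------------------------------

@dataclass
class CircuitMap:
    """RDoC neural circuit -> brain-region-code memberships.

    A region may belong to several circuits (the striatum, for instance,
    sits in the Positive Valence, Cognitive and Social Processes systems).
    Region membership is compared case-insensitively.
    """

    circuits: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, regions in self.circuits.items():
            if not regions:
                raise ValidationError(f"circuit {name!r} has no regions")
        self._membership: dict[str, frozenset[str]] = {
            name: frozenset(r.upper() for r in regions)
            for name, regions in self.circuits.items()
        }

    def circuits_for_region(self, region_code: str) -> frozenset[str]:
        code = region_code.upper()
        return frozenset(
            name for name, regions in self._membership.items() if code in regions
        )

    def __len__(self) -> int:
        return len(self.circuits)


def default_circuit_map() -> CircuitMap:
    """The five-system RDoC circuit map used by default.

    The Positive Valence, Cognitive and Social Processes region sets follow
    the printed circuit/region associations; Negative Valence and
    Sensorimotor memberships are conventions chosen from the RDoC construct
    descriptions (no region list is printed for them).
    """
    return CircuitMap(
        circuits={
            "Negative Valence": frozenset({"MPFC", "ACC", "Amy"}),
            "Positive Valence": frozenset({"MPFC", "ACC", "Amy", "STR"}),
            "Cognitive": frozenset(
                {"ACC", "Ocx", "DLPFC", "MD", "A1C", "IPC", "STR", "V1C", "VLPFC"}
            ),
            "Social Processes": frozenset(
                {"IPC", "ACC", "Ocx", "ITC", "V1C", "A1C", "STR"}
            ),
            "Sensorimotor": frozenset({"MD", "IPC"}),
        }
    )


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

MICROARRAY_STATUSES = ("normal", "cnv")


@dataclass
class SubjectRecord:
    """One study subject: microarray status, CNV loci and behavioral scores.

    ``pcq`` maps PCQ item id -> Likert score (ordinal integer); ``vineland``
    maps subscale id -> standard score.  Either mapping may be empty (e.g.
    Vineland interviews were not obtained for every subject).
    """

    subject_id: str
    microarray_status: str
    cnv_intervals: list[GenomicInterval] = field(default_factory=list)
    pcq: dict[str, int] = field(default_factory=dict)
    vineland: dict[str, float] = field(default_factory=dict)

    PCQ_RANGE = (1, 5)
    VINELAND_RANGE = (20.0, 160.0)

    def __post_init__(self) -> None:
        if self.microarray_status not in MICROARRAY_STATUSES:
            raise ValidationError(
                f"microarray_status must be one of {MICROARRAY_STATUSES}, "
                f"got {self.microarray_status!r}"
            )
        if self.microarray_status == "normal" and self.cnv_intervals:
            raise ValidationError(
                f"subject {self.subject_id}: normal microarray but CNV intervals given"
            )
        if self.microarray_status == "cnv" and not self.cnv_intervals:
            raise ValidationError(
                f"subject {self.subject_id}: CNV status requires >= 1 interval"
            )
        lo, hi = self.PCQ_RANGE
        for item, score in self.pcq.items():
            if not (lo <= score <= hi):
                raise ValidationError(
                    f"subject {self.subject_id}: PCQ {item} score {score} "
                    f"outside [{lo}, {hi}]"
                )
        vlo, vhi = self.VINELAND_RANGE
        for sub, score in self.vineland.items():
            if not (np.isnan(score) or vlo <= score <= vhi):
                raise ValidationError(
                    f"subject {self.subject_id}: Vineland {sub} score {score} "
                    f"outside [{vlo}, {vhi}]"
                )

    @property
    def has_cnv(self) -> bool:
        return self.microarray_status == "cnv"


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, defaulting to the study settings.

    enrichment_alpha
        Significance level for pathway over-representation (0.001).
    ppi_min_confidence
        Minimum interaction confidence retained, inclusive (0.9, the
        STRING "highest confidence" tier).
    coexpr_threshold
        |Pearson r| must strictly exceed this for a co-expression edge (0.7).
    min_overlap_bp
        Minimum CNV/gene overlap in bases for a gene to count as affected.
    epoch_boundaries
        Trimester cut points on the post-conceptional-week axis.
    """

    enrichment_alpha: float = 0.001
    ppi_min_confidence: float = 0.9
    coexpr_threshold: float = 0.7
    min_overlap_bp: int = 1
    epoch_boundaries: tuple[float, float, float] = (13.0, 26.0, 38.0)
    test_method: str = "welch"
    mtc_method: str = "none"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.enrichment_alpha <= 1:
            raise ValidationError("enrichment_alpha must lie in (0, 1]")
        if not 0 <= self.ppi_min_confidence <= 1:
            raise ValidationError("ppi_min_confidence must lie in [0, 1]")
        if not 0 <= self.coexpr_threshold < 1:
            raise ValidationError("coexpr_threshold must lie in [0, 1)")
        if self.min_overlap_bp < 1:
            raise ValidationError("min_overlap_bp must be >= 1")
        b = self.epoch_boundaries
        if len(b) != 3 or not (0 < b[0] < b[1] < b[2]):
            raise ValidationError("epoch_boundaries must be three increasing pcw values")
        if self.test_method not in ("welch", "pooled"):
            raise ValidationError("test_method must be 'welch' or 'pooled'")
        if self.mtc_method not in ("none", "bh"):
            raise ValidationError("mtc_method must be 'none' or 'bh'")
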