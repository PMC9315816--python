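"""CNV-to-gene mapping: turn each subject's CNV loci into the gene list
that seeds the enrichment query."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .core import AnnotationTable, GenomicInterval, SubjectRecord, canon_set

logger = logging.getLogger(__name__)


def map_cnv_to_genes(
    cnv: GenomicInterval,
    annotation: AnnotationTable,
    min_overlap_bp: int = 1,
) -> set[str]:
    """Genes whose interval overlaps the CNV by at least ``min_overlap_bp`` bases.

    Only same-chromosome genes can overlap; an empty result is valid.
    Deletions and duplications are treated identically: a gene inside the
    affected locus counts either way.
    """
    return annotation.overlapping(cnv, min_overlap_bp=min_overlap_bp)


def cohort_gene_union(
    subjects: Iterable[SubjectRecord],
    annotation: AnnotationTable,
    min_overlap_bp: int = 1,
) -> set[str]:
    """Union over all CNV subjects of their affected genes.

    Each gene is counted once no matter how many subjects' CNVs hit it —
    the cohort total is a deduplicated gene list.
    """
    out: set[str] = set()
    for subject in subjects:
        for cnv in subject.cnv_intervals:
            out |= map_cnv_to_genes(cnv, annotation, min_overlap_bp=min_overlap_bp)
    return out


def assemble_initial_dataset(
    cnv_genes: Iterable[str], neurodev_genes: Iterable[str]
) -> set[str]:
    """Union the CNV-derived genes with a curated neurodevelopmental list.

    This is the pipeline's initial enrichment query (in the clinical
    analysis, 594 CNV genes joined 2037 neurodevelopmental genes for a
    2631-gene initial dataset).  Symbols are compared case-insensitively.
    """
    a, b = canon_set(cnv_genes), canon_set(neurodev_genes)
    union = set(a | b)
    logger.info(
        "initial dataset: %d CNV genes + %d neurodevelopmental genes -> %d total",
        len(a), len(b), len(union),
    )
    return union
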