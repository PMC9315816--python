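"""Circuit assignment, subject grouping and behavioral group comparisons.

Genes enter a neural circuit when their maximal-expression brain region
belongs to that circuit's RDoC region set.  For each circuit, subjects
split into Group 1 (normal microarray) and Group 2 (carriers of a CNV
overlapping a circuit gene), and each behavioral item is compared
between groups with a two-sample t-test (Welch by default).  Summary
-statistic helpers reproduce the same contrast from printed means/SEs,
and ``percent_change`` covers the derived percent-decrease arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cnvmap import map_cnv_to_genes
from .core import (
    AnnotationTable,
    CircuitMap,
    PipelineConfig,
    SubjectRecord,
    ValidationError,
    canon_set,
)
from .core import Epoch
from .development import GeneSite
from .enrichment import EnrichmentResult, enrich

logger = logging.getLogger(__name__)

#: Pseudo-circuit label for the whole-cohort normal-vs-CNV contrast.
INTER_GROUP = "inter-group"

_TINY_P = 5e-324  # smallest positive subnormal double; p underflow guard


@dataclass(frozen=True)
class CircuitAssignment:
    """The circuits a gene joins through its argmax region."""

    gene: str
    circuits: frozenset[str]
    via_region: str
    epoch: Epoch


@dataclass
class ComparisonResult:
    """One behavioral contrast between Group 1 (normal microarray) and
    Group 2 (circuit-variant carriers)."""

    behavior_item: str
    circuit: str
    n1: int
    mean1: float
    se1: float
    n2: int
    mean2: float
    se2: float
    t_statistic: float
    df: float
    p_value: float
    adjusted_p: float | None = None
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValidationError("each group needs >= 2 subjects for a test")
        if self.se1 < 0 or self.se2 < 0:
            raise ValidationError("standard errors must be non-negative")
        if not 0 < self.p_value <= 1:
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


# ---------------------------------------------------------------------------
# Circuit assignment and subject grouping
# ---------------------------------------------------------------------------

def assign_circuits(
    sites: Sequence[GeneSite], circuit_map: CircuitMap
) -> list[CircuitAssignment]:
    """Assign each gene to every circuit containing its argmax region.

    Multi-membership is expected (a striatal gene joins every circuit
    listing STR); a region outside the circuit map yields an empty
    assignment, logged but not fatal.
    """
    known = {r for regions in circuit_map.circuits.values() for r in regions}
    known_upper = {r.upper() for r in known}
    out = []
    for site in sites:
        circuits = circuit_map.circuits_for_region(site.region)
        if site.region.upper() not in known_upper:
            logger.info(
                "region %s (gene %s) is in no circuit", site.region, site.gene
            )
        out.append(
            CircuitAssignment(
                gene=site.gene,
                circuits=circuits,
                via_region=site.region,
                epoch=site.epoch,
            )
        )
    return out


def circuit_gene_lists(
    assignments: Sequence[CircuitAssignment],
) -> dict[str, frozenset[str]]:
    """Invert assignments into circuit -> gene set (circuits may be empty)."""
    out: dict[str, set[str]] = {}
    for a in assignments:
        for c in a.circuits:
            out.setdefault(c, set()).add(a.gene)
    return {c: frozenset(genes) for c, genes in out.items()}


def group_subjects(
    subjects: Sequence[SubjectRecord],
    circuit_genes: Iterable[str],
    annotation: AnnotationTable,
    min_overlap_bp: int = 1,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Split the cohort for one circuit's contrast.

    Group 1 is every normal-microarray subject.  Group 2 is every CNV
    subject whose CNVs overlap at least one circuit gene; CNV subjects
    carrying no circuit gene sit out the contrast entirely.
    """
    wanted = canon_set(circuit_genes)
    group1 = [s for s in subjects if s.microarray_status == "normal"]
    group2 = []
    for s in subjects:
        if s.microarray_status != "cnv":
            continue
        hit = set()
        for cnv in s.cnv_intervals:
            hit |= map_cnv_to_genes(cnv, annotation, min_overlap_bp=min_overlap_bp)
            if hit & wanted:
                break
        if hit & wanted:
            group2.append(s)
    return group1, group2


# ---------------------------------------------------------------------------
# Two-sample comparisons
# ---------------------------------------------------------------------------

def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def compare_groups(
    scores1: Sequence[float],
    scores2: Sequence[float],
    method: str = "welch",
) -> ComparisonResult:
    """Two-sided two-sample comparison of behavioral scores.

    ``welch`` (default) uses the unequal-variance t-test with
    Satterthwaite degrees of freedom; ``pooled`` the classic equal
    -variance test with n1+n2-2 df; ``mannwhitney`` a rank-sum
    alternative for ordinal items (the U statistic is stored in the
    ``t_statistic`` slot with df = nan).  Non-finite scores are dropped
    listwise within the item.
    """
    x = np.asarray(scores1, dtype=float)
    y = np.asarray(scores2, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 finite scores")

    base = dict(
        behavior_item="", circuit="",
        n1=len(x), mean1=float(x.mean()), se1=_sem(x),
        n2=len(y), mean2=float(y.mean()), se2=_sem(y),
    )
    if method == "mannwhitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return ComparisonResult(
            **base, t_statistic=float(res.statistic), df=float("nan"),
            p_value=float(res.pvalue),
        )
    if method not in ("welch", "pooled"):
        raise ValidationError(f"unknown method {method!r}")

    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # degenerate: no within-group variance
        if x.mean() == y.mean():
            return ComparisonResult(
                **base, t_statistic=0.0, df=float(len(x) + len(y) - 2), p_value=1.0
            )
        return ComparisonResult(
            **base, t_statistic=float("inf") if x.mean() > y.mean() else float("-inf"),
            df=float(len(x) + len(y) - 2), p_value=_TINY_P,
        )
    res = stats.ttest_ind(x, y, equal_var=(method == "pooled"))
    p = float(res.pvalue)
    return ComparisonResult(
        **base,
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=max(p, _TINY_P),
    )


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    """Satterthwaite df from squared standard errors v = se**2."""
    num = (v1 + v2) ** 2
    den = v1**2 / (n1 - 1) + v2**2 / (n2 - 1)
    return num / den if den > 0 else float(n1 + n2 - 2)


def welch_from_summary(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t-test from printed summary statistics (mean, SE, n) per group.

    Returns (t, Satterthwaite df, two-sided p).  This is the contrast a
    reader can recompute from a published group-comparison table.
    """
    if se1 < 0 or se2 < 0:
        raise ValidationError("standard errors must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    v1, v2 = se1**2, se2**2
    if v1 == 0 and v2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        t = float("inf") if mean1 > mean2 else float("-inf")
        return t, float(n1 + n2 - 2), _TINY_P
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = _welch_df(v1, n1, v2, n2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), max(p, _TINY_P)


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Signed percent change of ``comparison`` relative to ``reference``.

    100 * (comparison - reference) / reference; negative for a decrease.
    """
    if reference_mean == 0:
        raise ValidationError("reference mean must be nonzero")
    return 100.0 * (comparison_mean - reference_mean) / reference_mean


def percent_change_magnitude(reference_mean: float, comparison_mean: float) -> int:
    """|percent change| rounded to the nearest integer, as reports print it."""
    return round(abs(percent_change(reference_mean, comparison_mean)))


# ---------------------------------------------------------------------------
# The association scan
# ---------------------------------------------------------------------------

def _item_scores(subjects: Sequence[SubjectRecord], item: str) -> np.ndarray:
    """Scores for one behavioral item, skipping subjects who lack it."""
    vals = []
    for s in subjects:
        if item in s.pcq:
            vals.append(float(s.pcq[item]))
        elif item in s.vineland:
            vals.append(float(s.vineland[item]))
    return np.asarray(vals, dtype=float)


def behavioral_items(subjects: Sequence[SubjectRecord]) -> list[str]:
    """All PCQ items and Vineland subscales seen in the cohort, sorted."""
    pcq = sorted({i for s in subjects for i in s.pcq})
    vin = sorted({i for s in subjects for i in s.vineland})
    return pcq + vin


def run_association_scan(
    subjects: Sequence[SubjectRecord],
    assignments: Sequence[CircuitAssignment],
    circuit_map: CircuitMap,
    annotation: AnnotationTable,
    items: Sequence[str] | None = None,
    config: PipelineConfig | None = None,
    mtc: str | None = None,
) -> list[ComparisonResult]:
    """Compare Group 1 vs Group 2 for every (circuit, behavior item) cell.

    Emits one whole-cohort "inter-group" contrast per item (all normal vs
    all CNV subjects) followed by one contrast per circuit with a
    non-empty gene list.  Items whose groups have fewer than two scored
    subjects are skipped with a logged reason.  Ordering is deterministic:
    inter-group first, then circuits alphabetically, items in the given
    order within each.  ``mtc="bh"`` adds BH-adjusted p-values across the
    whole scan (off by default: published circuit tables print raw p).
    """
    config = config or PipelineConfig()
    mtc = mtc if mtc is not None else config.mtc_method
    # canonical subject order makes the scan exactly invariant to the
    # caller's ordering (float summation order would otherwise leak in)
    subjects = sorted(subjects, key=lambda s: s.subject_id)
    if items is None:
        items = behavioral_items(subjects)
    per_circuit = circuit_gene_lists(assignments)
    active = sorted(c for c, genes in per_circuit.items() if genes)

    results: list[ComparisonResult] = []
    normals = [s for s in subjects if s.microarray_status == "normal"]
    carriers_all = [s for s in subjects if s.microarray_status == "cnv"]

    def add_contrast(circuit: str, g1, g2, genes: tuple[str, ...]) -> None:
        for item in items:
            x, y = _item_scores(g1, item), _item_scores(g2, item)
            if len(x) < 2 or len(y) < 2:
                logger.info(
                    "skipping %s / %s: fewer than 2 scored subjects in a group",
                    circuit, item,
                )
                continue
            r = compare_groups(x, y, method=config.test_method)
            r.behavior_item, r.circuit, r.genes = item, circuit, genes
            results.append(r)

    add_contrast(INTER_GROUP, normals, carriers_all, ())
    for circuit in active:
        genes = tuple(sorted(per_circuit[circuit]))
        _, group2 = group_subjects(
            subjects, genes, annotation, min_overlap_bp=config.min_overlap_bp
        )
        if len(group2) < 2:
            logger.info("circuit %s: fewer than 2 carriers; skipped", circuit)
            continue
        add_contrast(circuit, normals, group2, genes)

    if mtc == "bh" and results:
        _, adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    return results


def annotate_circuit_pathways(
    assignments: Sequence[CircuitAssignment],
    collection,
    alpha: float = 0.001,
    mtc: str = "none",
) -> dict[str, list[EnrichmentResult]]:
    """Re-run pathway over-representation on each circuit's gene list.

    This annotates each circuit with its over-represented pathways, the
    way published circuit tables list a pathway column next to the gene
    variants.
    """
    out = {}
    for circuit, genes in sorted(circuit_gene_lists(assignments).items()):
        if genes:
            out[circuit] = enrich(genes, collection, alpha=alpha, mtc=mtc)
    return out


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "behavior": [r.behavior_item for r in results],
            "circuit": [r.circuit for r in results],
            "n1": [r.n1 for r in results],
            "mean1": [r.mean1 for r in results],
            "se1": [r.se1 for r in results],
            "n2": [r.n2 for r in results],
            "mean2": [r.mean2 for r in results],
            "se2": [r.se2 for r in results],
            "t": [r.t_statistic for r in results],
            "df": [r.df for r in results],
            "p": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "related_genes": [",".join(r.genes) for r in results],
        }
    )


def write_results(results: Sequence[ComparisonResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
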