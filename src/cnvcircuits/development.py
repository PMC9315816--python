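"""Developmental brain-expression mapping.

Each gene is assigned its *site of maximal expression*: the
(brain region, developmental epoch) cell with the highest mean
expression across the bundle's samples.  Epochs are the three obstetric
trimesters (delimited on the post-conceptional-week axis) plus
postnatal life; a gene whose expression peaks postnatally receives a
postnatal site — the postnatal epoch competes in the argmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Epoch, ExpressionBundle, ValidationError, canon

logger = logging.getLogger(__name__)

DEFAULT_EPOCH_BOUNDARIES = (13.0, 26.0, 38.0)


@dataclass(frozen=True)
class GeneSite:
    """A gene's argmax (region, epoch) expression cell."""

    gene: str
    region: str
    epoch: Epoch
    mean_expression: float

    @property
    def is_antenatal(self) -> bool:
        return self.epoch.is_antenatal


def classify_epoch(
    age_value: float,
    age_unit: str,
    boundaries: Sequence[float] = DEFAULT_EPOCH_BOUNDARIES,
) -> Epoch:
    """Classify a sample age into a developmental epoch.

    Post-conceptional weeks map onto trimesters at the ``boundaries`` cut
    points (inclusive on the left epoch: 13 pcw is still first
    trimester); a pcw beyond term, or any postnatal-days age, is
    postnatal.
    """
    if age_value <= 0:
        raise ValidationError(f"age must be positive, got {age_value}")
    if age_unit == "postnatal_days":
        return Epoch.POSTNATAL
    if age_unit != "pcw":
        raise ValidationError(f"unknown age unit {age_unit!r}")
    b1, b2, b3 = boundaries
    if age_value <= b1:
        return Epoch.TRIMESTER1
    if age_value <= b2:
        return Epoch.TRIMESTER2
    if age_value <= b3:
        return Epoch.TRIMESTER3
    return Epoch.POSTNATAL


def cell_means(
    bundle: ExpressionBundle,
    boundaries: Sequence[float] = DEFAULT_EPOCH_BOUNDARIES,
) -> pd.DataFrame:
    """Mean expression of every gene in every populated (region, epoch) cell.

    Returns a genes x cells DataFrame whose columns are (region, epoch)
    tuples, ordered by (epoch chronology, region code) — the same order
    used for deterministic argmax tie-breaking.  Cells with no samples do
    not appear and are therefore never argmax candidates.
    """
    epochs = [
        classify_epoch(a, u, boundaries)
        for a, u in zip(bundle.sample_meta["age_value"], bundle.sample_meta["age_unit"])
    ]
    regions = [str(r) for r in bundle.sample_meta["region_code"]]
    cells: dict[tuple[str, Epoch], list[int]] = {}
    for i, (region, epoch) in enumerate(zip(regions, epochs)):
        cells.setdefault((region, epoch), []).append(i)
    ordered = sorted(cells, key=lambda c: (c[1].order, c[0].upper()))
    mat = bundle.matrix.to_numpy(dtype=float)
    data = {cell: mat[:, cells[cell]].mean(axis=1) for cell in ordered}
    out = pd.DataFrame(data, index=bundle.matrix.index)
    out.columns = pd.MultiIndex.from_tuples(ordered, names=["region", "epoch"])
    return out


def max_expression_site(
    gene: str,
    bundle: ExpressionBundle,
    boundaries: Sequence[float] = DEFAULT_EPOCH_BOUNDARIES,
) -> GeneSite:
    """The (region, epoch) cell where ``gene``'s mean expression is maximal.

    Ties are broken deterministically toward the earlier epoch, then the
    lexicographically smaller region code.
    """
    if gene not in bundle:
        raise KeyError(f"gene {gene!r} not in expression bundle")
    means = cell_means(bundle, boundaries)
    return _argmax_site(gene, means)


def _argmax_site(gene: str, means: pd.DataFrame) -> GeneSite:
    row_label = next(g for g in means.index if canon(g) == canon(gene))
    values = means.loc[row_label].to_numpy(dtype=float)
    best = int(np.argmax(values))  # columns are in tie-break order; first max wins
    region, epoch = means.columns[best]
    return GeneSite(
        gene=str(row_label),
        region=region,
        epoch=epoch,
        mean_expression=float(values[best]),
    )


@dataclass
class SiteMapping:
    """Gene sites for a query set, plus the genes the bundle lacks."""

    sites: list[GeneSite]
    skipped: list[str]


def map_gene_set(
    genes: Iterable[str],
    bundle: ExpressionBundle,
    boundaries: Sequence[float] = DEFAULT_EPOCH_BOUNDARIES,
) -> SiteMapping:
    """Map every gene present in the bundle to its argmax site.

    Output order is by canonical gene symbol, independent of the input's
    iteration order.  Absent genes go to the skip report.
    """
    wanted = sorted({canon(g) for g in genes})
    present = [g for g in wanted if g in bundle]
    skipped = [g for g in wanted if g not in bundle]
    if skipped:
        logger.info("expression mapping: %d genes absent from the bundle", len(skipped))
    if not present:
        return SiteMapping(sites=[], skipped=skipped)
    means = cell_means(bundle, boundaries)
    sites = [_argmax_site(g, means) for g in present]
    return SiteMapping(sites=sites, skipped=skipped)


def write_sites(mapping: SiteMapping, path: str | Path) -> None:
    rows = [
        {
            "gene": s.gene,
            "region": s.region,
            "epoch": s.epoch.value,
            "mean_expression": f"{s.mean_expression:.6f}",
            "is_antenatal": s.is_antenatal,
        }
        for s in mapping.sites
    ]
    pd.DataFrame(
        rows, columns=["gene", "region", "epoch", "mean_expression", "is_antenatal"]
    ).to_csv(path, sep="\t", index=False)
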