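"""Peak-to-gene annotation.

A peak overlapping a promoter window — the region within `window` bp of an
annotated TSS (default 1000) — is a promoter element of the overlapped
gene(s).  Otherwise, a peak overlapping the distal anchor of a
promoter-capture interaction record is an enhancer element of that record's
gene(s).  Peaks matching neither are reported as unannotated.  Interaction
linkage is preferred over plain genomic proximity for expression
integration; nearest-gene lookup exists only for the gene-set annotation
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_core import GenomicInterval, InteractionMap, PeakSet, validate_gene_table

CLASS_PROMOTER = "promoter"
CLASS_ENHANCER = "enhancer"

LINK_INTERACTION = "interaction"
LINK_PROMOTER_WINDOW = "promoter_window"
LINK_NEAREST = "nearest"


@dataclass(frozen=True)
class RegulatoryElement:
    """Annotation of one peak: its class, the genes it is linked to, and how
    the link was established."""

    element_id: str
    interval: GenomicInterval
    element_class: str
    gene_ids: tuple[str, ...]
    link_source: str

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("regulatory element without linked genes")


def _promoter_trees(gene_table: pd.DataFrame, window: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for _, row in gene_table.iterrows():
        lo = max(0, int(row["tss"]) - window)
        hi = int(row["tss"]) + window + 1
        trees.setdefault(str(row["chrom"]), IntervalTree()).addi(
            lo, hi, str(row["gene_id"])
        )
    return trees


def classify_promoter(
    peak: GenomicInterval, gene_table: pd.DataFrame, window: int = 1000
) -> tuple[bool, list[str]]:
    """Does the peak overlap [tss - window, tss + window + 1) of any gene?

    Strand locates the TSS only; it never gates the overlap.  Returns the
    flag plus all overlapped gene ids (gene-table order).
    """
    if window <= 0:
        # window = 0: only peaks containing the TSS position itself
        hits = gene_table[
            (gene_table["chrom"] == peak.chrom)
            & (gene_table["tss"] >= peak.start)
            & (gene_table["tss"] < peak.end)
        ]
        return bool(len(hits)), list(hits["gene_id"])
    sub = gene_table[gene_table["chrom"] == peak.chrom]
    tss = sub["tss"].to_numpy()
    hit = (tss >= peak.start - window) & (tss < peak.end + window)
    return bool(hit.any()), list(sub.loc[hit, "gene_id"])


def link_peaks_to_genes(
    peaks: PeakSet,
    interaction_map: InteractionMap,
    gene_table: pd.DataFrame,
    window: int = 1000,
) -> tuple[list[RegulatoryElement], list[str]]:
    """Annotate every peak, promoter-window overlap taking precedence over
    interaction-anchor overlap.

    Returns (annotated elements, unannotated peak names).  Every peak lands
    in exactly one of the two lists.
    """
    gene_table = validate_gene_table(gene_table)
    anchor_trees: dict[str, IntervalTree] = {}
    for rec in interaction_map:
        d = rec.distal_anchor
        anchor_trees.setdefault(d.chrom, IntervalTree()).addi(
            d.start, d.end, rec.gene_ids
        )
    tss_by_chrom = {
        str(c): (g["tss"].to_numpy(), g["gene_id"].to_numpy())
        for c, g in gene_table.groupby("chrom", sort=False)
    }

    elements: list[RegulatoryElement] = []
    unannotated: list[str] = []
    for name, iv in peaks:
        genes: list[str] = []
        chrom_tss = tss_by_chrom.get(iv.chrom)
        if chrom_tss is not None:
            tss, gids = chrom_tss
            if window <= 0:
                hit = (tss >= iv.start) & (tss < iv.end)
            else:
                hit = (tss >= iv.start - window) & (tss < iv.end + window)
            genes = list(gids[hit])
        if genes:
            elements.append(
                RegulatoryElement(name, iv, CLASS_PROMOTER, tuple(genes),
                                  LINK_PROMOTER_WINDOW)
            )
            continue
        tree = anchor_trees.get(iv.chrom)
        if tree is not None:
            linked: list[str] = []
            for node in sorted(tree.overlap(iv.start, iv.end)):
                for g in node.data:
                    if g not in linked:
                        linked.append(g)
            if linked:
                elements.append(
                    RegulatoryElement(name, iv, CLASS_ENHANCER, tuple(linked),
                                      LINK_INTERACTION)
                )
                continue
        unannotated.append(name)
    return elements, unannotated


def nearest_k_genes(
    peak: GenomicInterval,
    gene_table: pd.DataFrame,
    k: int = 2,
    distance: str = "midpoint",
) -> list[str]:
    """The k genes with smallest peak-to-TSS distance on the peak's
    chromosome; ties broken by lexicographic gene_id.

    `distance` is "midpoint" (peak midpoint to TSS, default) or "edge"
    (nearest peak edge to TSS; 0 when the TSS lies inside the peak).
    """
    sub = gene_table[gene_table["chrom"] == peak.chrom]
    if sub.empty:
        return []
    tss = sub["tss"].to_numpy(dtype=float)
    if distance == "midpoint":
        d = np.abs(tss - peak.midpoint)
    elif distance == "edge":
        d = np.maximum.reduce([peak.start - tss, tss - (peak.end - 1),
                               np.zeros_like(tss)])
    else:
        raise ValueError(f"unknown distance mode {distance!r}")
    gids = sub["gene_id"].to_numpy()
    order = sorted(range(len(gids)), key=lambda i: (d[i], gids[i]))
    return [gids[i] for i in order[: min(k, len(gids))]]


def annotation_table(
    elements: list[RegulatoryElement], unannotated: list[str]
) -> pd.DataFrame:
    """Flat per-peak annotation table, including an 'unannotated' row class."""
    rows = [
        {
            "peak_id": e.element_id,
            "element_class": e.element_class,
            "gene_ids": ",".join(e.gene_ids),
            "link_source": e.link_source,
        }
        for e in elements
    ]
    rows += [
        {"peak_id": name, "element_class": "unannotated", "gene_ids": "",
         "link_source": ""}
        for name in unannotated
    ]
    return pd.DataFrame(rows, columns=["peak_id", "element_class", "gene_ids",
                                       "link_source"])
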