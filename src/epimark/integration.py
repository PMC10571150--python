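"""ChIP/RNA integration: Fisher's exact association between mark
redistribution and transcriptional modulation, the promoter/outside split of
differential peaks, and the per-treatment activation matrix of regulatory
elements driven by H3K27ac.

The gene universe for the association test defaults to all genes present in
the expression matrix after the all-zero filter; "modulated peaks" reach
genes only through interaction/promoter-window links, never nearest-gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CLASS_ENHANCER, CLASS_PROMOTER, RegulatoryElement
from .differential import STATUS_GAINED, STATUS_LOST, STATUS_UNCHANGED
from .io_core import GenomicInterval, ValidationError

ACTIVATED = "activated"
REPRESSED = "repressed"
AMBIGUOUS = "ambiguous"
UNCHANGED = "unchanged"

_STATUS_CODE = {ACTIVATED: "A", REPRESSED: "R", AMBIGUOUS: "X", UNCHANGED: "."}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a = genes both DP-linked and DEG, b = DP-linked only, c = DEG only,
    d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency entries must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def crosstab_dp_deg(
    dp_linked_genes: set[str], deg_genes: set[str], universe: set[str]
) -> ContingencyTable2x2:
    dp = set(dp_linked_genes)
    deg = set(deg_genes)
    if not dp <= universe:
        raise ValidationError(
            f"DP-linked genes outside universe: {sorted(dp - universe)[:5]}"
        )
    if not deg <= universe:
        raise ValidationError(
            f"DEG genes outside universe: {sorted(deg - universe)[:5]}"
        )
    a = len(dp & deg)
    b = len(dp - deg)
    c = len(deg - dp)
    d = len(universe) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    p = sum of hypergeometric probabilities (over all tables with the same
    margins) no larger than that of the observed table.  Probabilities share
    the denominator C(N, a+b), so the comparison is done on exact integer
    numerators C(a+b, a') * C(c+d, c') — ties are decided exactly, with no
    floating-point tolerance.  Odds ratio = ad/bc (inf when bc = 0 < ad,
    NaN when both products vanish).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d  # row margins
    k = a + c              # first-column margin
    lo, hi = max(0, k - r2), min(k, r1)
    obs = math.comb(r1, a) * math.comb(r2, c)
    num = 0
    for x in range(lo, hi + 1):
        w = math.comb(r1, x) * math.comb(r2, k - x)
        if w <= obs:
            num += w
    denom = math.comb(r1 + r2, k)
    p = num / denom if denom else 1.0
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("inf") if ad > 0 else float("nan")
    else:
        odds = ad / bc
    return odds, min(1.0, p)


def promoter_fraction(
    dp_ids: list[str], annotations: pd.DataFrame
) -> tuple[float, float]:
    """Fractions of differential peaks within / outside promoter regions.

    "Outside" counts both enhancer-linked and unannotated peaks; the two
    fractions sum to 1.  Raises on an empty DP set (undefined).
    """
    if not dp_ids:
        raise ValidationError("promoter fraction undefined for empty DP set")
    cls = annotations.set_index("peak_id")["element_class"]
    missing = [p for p in dp_ids if p not in cls.index]
    if missing:
        raise ValidationError(f"DPs missing from annotation table: {missing[:5]}")
    n_prom = sum(cls[p] == CLASS_PROMOTER for p in dp_ids)
    f_in = n_prom / len(dp_ids)
    return f_in, 1.0 - f_in


@dataclass(frozen=True)
class ActivationCall:
    element_id: str
    treatment: str
    status: str
    supporting_dps: tuple[str, ...]


@dataclass
class ElementGroup:
    """A merged regulatory element: the union of overlapping interaction
    anchors (enhancers) or of one gene's promoter windows, with the H3K27ac
    peaks annotated to it."""

    element_id: str
    element_class: str
    interval: GenomicInterval
    gene_ids: tuple[str, ...]
    peak_ids: tuple[str, ...] = field(default_factory=tuple)


def build_elements(peak_annotations: list[RegulatoryElement]) -> list[ElementGroup]:
    """Merge per-peak annotations into regulatory elements.

    Promoter peaks sharing a gene become that gene's promoter element
    (interval = union of the member peaks).  Enhancer peak intervals on the
    same chromosome are merged when they overlap; gene links are unioned.
    """
    elements: list[ElementGroup] = []
    promoters: dict[str, list[RegulatoryElement]] = {}
    for e in peak_annotations:
        if e.element_class == CLASS_PROMOTER:
            for g in e.gene_ids:
                promoters.setdefault(g, []).append(e)
    for gene in sorted(promoters):
        members = promoters[gene]
        chrom = members[0].interval.chrom
        iv = GenomicInterval(
            chrom,
            min(m.interval.start for m in members),
            max(m.interval.end for m in members),
        )
        elements.append(
            ElementGroup(
                element_id=f"prom:{gene}",
                element_class=CLASS_PROMOTER,
                interval=iv,
                gene_ids=(gene,),
                peak_ids=tuple(sorted(m.element_id for m in members)),
            )
        )

    enhancers = [e for e in peak_annotations if e.element_class == CLASS_ENHANCER]
    by_chrom: dict[str, list[RegulatoryElement]] = {}
    for e in enhancers:
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    n_enh = 0
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda e: (e.interval.start,
                                                         e.interval.end))
        cluster: list[RegulatoryElement] = []
        cluster_end = -1

        def flush(cluster):
            nonlocal n_enh
            if not cluster:
                return
            n_enh += 1
            genes: list[str] = []
            for m in cluster:
                for g in m.gene_ids:
                    if g not in genes:
                        genes.append(g)
            iv = GenomicInterval(
                chrom,
                min(m.interval.start for m in cluster),
                max(m.interval.end for m in cluster),
            )
            elements.append(
                ElementGroup(
                    element_id=f"enh:{n_enh:05d}",
                    element_class=CLASS_ENHANCER,
                    interval=iv,
                    gene_ids=tuple(genes),
                    peak_ids=tuple(sorted(m.element_id for m in cluster)),
                )
            )

        for e in members:
            if cluster and e.interval.start < cluster_end:
                cluster.append(e)
                cluster_end = max(cluster_end, e.interval.end)
            else:
                flush(cluster)
                cluster = [e]
                cluster_end = e.interval.end
        flush(cluster)
    return elements


def activation_status(
    element: ElementGroup,
    dp_status_by_treatment: dict[str, pd.Series],
) -> list[ActivationCall]:
    """Per-treatment activation call for one element from the H3K27ac DP
    statuses of its member peaks: any gain and no loss -> activated; any loss
    and no gain -> repressed; both -> ambiguous; none -> unchanged."""
    calls = []
    for treat, status in dp_status_by_treatment.items():
        gained = [p for p in element.peak_ids
                  if status.get(p, STATUS_UNCHANGED) == STATUS_GAINED]
        lost = [p for p in element.peak_ids
                if status.get(p, STATUS_UNCHANGED) == STATUS_LOST]
        if gained and lost:
            verdict = AMBIGUOUS
        elif gained:
            verdict = ACTIVATED
        elif lost:
            verdict = REPRESSED
        else:
            verdict = UNCHANGED
        calls.append(
            ActivationCall(element.element_id, treat, verdict,
                           tuple(sorted(gained + lost)))
        )
    return calls


@dataclass
class ActivationMatrix:
    matrix: pd.DataFrame               # elements x treatments, status strings
    elements: list[ElementGroup]       # rows, same order
    linked_genes: dict[str, tuple[str, ...]]
    summary: dict[str, int]

    def coded(self) -> pd.DataFrame:
        """Matrix with single-letter codes (A/R/X/.)."""
        return self.matrix.map(lambda s: _STATUS_CODE[s])


def build_activation_matrix(
    elements: list[ElementGroup],
    dp_status_by_treatment: dict[str, pd.Series],
    deg_by_treatment: dict[str, set[str]] | None = None,
    require_deg: bool = True,
) -> ActivationMatrix:
    """Activation-status matrix of the elements regulated by H3K27ac in at
    least one treatment.

    Rows: elements with a non-unchanged status in >=1 treatment; when
    `require_deg` (default) a row is additionally required to have a linked
    gene that is a DEG in >=1 treatment.  Summary counts regulated
    enhancers, promoters and distinct linked genes.
    """
    treatments = list(dp_status_by_treatment)
    deg_union: set[str] = set()
    if deg_by_treatment:
        for s in deg_by_treatment.values():
            deg_union |= s
    rows = {}
    kept: list[ElementGroup] = []
    for el in elements:
        calls = activation_status(el, dp_status_by_treatment)
        statuses = {c.treatment: c.status for c in calls}
        if all(s == UNCHANGED for s in statuses.values()):
            continue
        if require_deg and not (set(el.gene_ids) & deg_union):
            continue
        kept.append(el)
        rows[el.element_id] = statuses
    matrix = pd.DataFrame(
        [[rows[el.element_id][t] for t in treatments] for el in kept],
        index=pd.Index([el.element_id for el in kept], name="element_id"),
        columns=treatments,
        dtype=object,
    )
    linked = {el.element_id: el.gene_ids for el in kept}
    summary = {
        "regulated_enhancers": sum(
            el.element_class == CLASS_ENHANCER for el in kept
        ),
        "regulated_promoters": sum(
            el.element_class == CLASS_PROMOTER for el in kept
        ),
        "linked_genes": len({g for el in kept for g in el.gene_ids}),
    }
    return ActivationMatrix(matrix, kept, linked, summary)


def association_stats(
    dp_linked_by_treatment: dict[str, set[str]],
    deg_by_treatment: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Fisher association of DP-linked genes vs DEGs, per treatment."""
    rows = []
    for treat, dp_genes in dp_linked_by_treatment.items():
        deg = deg_by_treatment.get(treat, set())
        tab = crosstab_dp_deg(dp_genes & universe, deg & universe, universe)
        odds, p = fisher_exact(tab)
        rows.append(
            {"treatment": treat, "a": tab.a, "b": tab.b, "c": tab.c,
             "d": tab.d, "odds_ratio": odds, "pvalue": p}
        )
    return pd.DataFrame(rows)
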