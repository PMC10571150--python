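"""Broad H3K9me2 domain (KDD) analysis from binned coverage.

Domains are called per chromosome as runs of bins whose robust z-score
(versus the chromosome's median/MAD) clears a threshold, merged across short
gaps and filtered on a minimum length.  Domain size changes between
conditions use greedy 1:1 matching by overlap, and the question of whether
differentially expressed genes concentrate around changed domains is
answered with a label-permutation test (DEG labels reassigned uniformly over
all genes), which preserves gene-density structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GenomicInterval, ValidationError

NEG_INF = float("-inf")


@dataclass(frozen=True)
class KDDomain:
    interval: GenomicInterval
    mean_enrichment: float
    n_bins: int

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class DomainChange:
    control_domain: KDDomain
    treatment_domain: KDDomain | None
    size_log2_ratio: float
    changed: bool


def call_kdd(
    coverage_bins: pd.DataFrame,
    bin_size: int,
    z_threshold: float = 1.5,
    max_gap_bins: int = 2,
    min_domain_length: int = 50_000,
) -> list[KDDomain]:
    """Call enriched domains from a (chrom, start, end, value) bin table.

    z-scores use per-chromosome median and MAD (scaled by 1.4826), so the
    call is invariant to constant shifts of the track.  Runs of bins with
    z >= z_threshold are merged when separated by <= max_gap_bins below-
    threshold bins, then filtered at min_domain_length.
    """
    domains: list[KDDomain] = []
    for chrom, sub in coverage_bins.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        widths = (sub["end"] - sub["start"]).to_numpy()
        if not (widths == bin_size).all():
            # allow a short final bin at the chromosome end
            if not (widths[:-1] == bin_size).all() or widths[-1] > bin_size:
                raise ValidationError(f"{chrom}: non-uniform bin widths")
        vals = sub["value"].to_numpy(dtype=float)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med)) * 1.4826
        if mad == 0:
            mad = np.std(vals) or 1.0
        z = (vals - med) / mad
        marked = z >= z_threshold
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()

        runs: list[tuple[int, int]] = []  # [i0, i1] inclusive bin-index runs
        i = 0
        n = len(vals)
        while i < n:
            if not marked[i]:
                i += 1
                continue
            j = i
            gap = 0
            last_marked = i
            while j + 1 < n:
                if marked[j + 1]:
                    j += 1
                    last_marked = j
                    gap = 0
                elif gap < max_gap_bins:
                    j += 1
                    gap += 1
                else:
                    break
            runs.append((i, last_marked))
            i = last_marked + 1
        for i0, i1 in runs:
            length = int(ends[i1] - starts[i0])
            if length < min_domain_length:
                continue
            domains.append(
                KDDomain(
                    interval=GenomicInterval(str(chrom), int(starts[i0]),
                                             int(ends[i1])),
                    mean_enrichment=float(vals[i0 : i1 + 1].mean()),
                    n_bins=i1 - i0 + 1,
                )
            )
    return domains


def _overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def compare_domains(
    control_domains: list[KDDomain],
    treatment_domains: list[KDDomain],
    size_change_threshold: float = 0.2,
) -> tuple[list[DomainChange], dict[str, float]]:
    """Greedy 1:1 matching of treatment to control domains by descending
    overlap; a control domain is 'changed' when |log2(len_t/len_c)| exceeds
    the threshold, or when it finds no match (ratio reported as -inf).

    The summary reports total KDD bp per condition and their ratio.
    """
    pairs = []
    for i, cd in enumerate(control_domains):
        for j, td in enumerate(treatment_domains):
            ov = _overlap(cd.interval, td.interval)
            if ov > 0:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_c: set[int] = set()
    used_t: set[int] = set()
    match: dict[int, int] = {}
    for ov, i, j in pairs:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        match[i] = j

    changes: list[DomainChange] = []
    for i, cd in enumerate(control_domains):
        if i in match:
            td = treatment_domains[match[i]]
            ratio = float(np.log2(td.length / cd.length))
            changes.append(
                DomainChange(cd, td, ratio, abs(ratio) > size_change_threshold)
            )
        else:
            changes.append(DomainChange(cd, None, NEG_INF, True))
    bp_c = sum(d.length for d in control_domains)
    bp_t = sum(d.length for d in treatment_domains)
    summary = {
        "control_bp": float(bp_c),
        "treatment_bp": float(bp_t),
        "bp_ratio": float(bp_t / bp_c) if bp_c else float("nan"),
    }
    return changes, summary


def deg_proximity_test(
    changed_domains: list[KDDomain],
    deg_genes: set[str],
    all_genes: pd.DataFrame,
    flank: int = 100_000,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[int, float]:
    """Permutation test for clustering of DEGs around changed domains.

    Observed statistic: number of DEGs whose TSS lies within a changed domain
    extended by `flank` on both sides.  Null: DEG labels reassigned uniformly
    at random (without replacement) over all genes, n_perm times;
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    deg_genes = set(deg_genes)
    known = set(all_genes["gene_id"])
    if not deg_genes <= known:
        raise ValidationError(
            f"DEGs not in gene table: {sorted(deg_genes - known)[:5]}"
        )
    if not changed_domains:
        return 0, 1.0

    in_window = np.zeros(len(all_genes), dtype=bool)
    chroms = all_genes["chrom"].to_numpy()
    tss = all_genes["tss"].to_numpy()
    for dom in changed_domains:
        iv = dom.interval
        in_window |= (
            (chroms == iv.chrom)
            & (tss >= iv.start - flank)
            & (tss < iv.end + flank)
        )
    is_deg = all_genes["gene_id"].isin(deg_genes).to_numpy()
    observed = int((in_window & is_deg).sum())

    rng = np.random.default_rng(seed)
    n_deg = int(is_deg.sum())
    n_genes = len(all_genes)
    null = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        idx = rng.choice(n_genes, size=n_deg, replace=False)
        null[b] = int(in_window[idx].sum())
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return observed, float(p)
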