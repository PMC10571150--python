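"""Sample-similarity analysis (classical MDS on rank-correlation distances)
and a generic over-representation test that stands in for gene-ontology
enrichment with user-supplied gene sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .differential import ContractError, adjust_bh
from .io_core import CountMatrix, ValidationError

_PRIOR = 0.5


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix shape mismatch")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValidationError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise ValidationError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValidationError("negative distances")
        self.values = v


def sample_distances(counts: CountMatrix, top_n: int = 500) -> DistanceMatrix:
    """1 - Spearman correlation between samples on log-CPM (prior 0.5),
    restricted to the top_n features by variance."""
    if counts.shape[1] < 2:
        raise ContractError("need at least two samples")
    mat = counts.values.astype(float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = [s for s, t in zip(counts.sample_ids, lib) if t == 0]
        raise ValidationError(f"samples with zero total count: {bad}")
    logcpm = np.log2((mat + _PRIOR) / lib * 1e6)
    var = logcpm.var(axis=1)
    keep = np.argsort(var)[::-1][: min(top_n, len(var))]
    sub = logcpm[np.sort(keep)]
    for j, sid in enumerate(counts.sample_ids):
        if np.ptp(sub[:, j]) == 0:
            raise ValidationError(
                f"sample {sid!r} is constant on the selected features; "
                "rank correlation undefined"
            )
    rho = stats.spearmanr(sub).statistic
    if np.isscalar(rho):  # two samples
        rho = np.array([[1.0, rho], [rho, 1.0]])
    d = 1.0 - np.asarray(rho)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return DistanceMatrix(list(counts.sample_ids), d)


def classical_mds(dist: DistanceMatrix, k: int = 2) -> pd.DataFrame:
    """Torgerson classical MDS: double-centre the squared distances, take the
    top-k eigenpairs, scale eigenvectors by sqrt(max(eigenvalue, 0)).

    Axis signs are fixed so each axis's largest-magnitude loading is
    positive, making the embedding fully deterministic.
    """
    n = len(dist.sample_ids)
    if k >= n:
        raise ContractError(f"k={k} must be smaller than n_samples={n}")
    d2 = dist.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    for axis in range(k):
        col = coords[:, axis]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return pd.DataFrame(
        coords,
        index=pd.Index(dist.sample_ids, name="sample_id"),
        columns=[f"dim{i + 1}" for i in range(k)],
    )


# ---------------------------------------------------------------------------
# over-representation


def read_gene_sets(path) -> dict[str, tuple[str, list[str]]]:
    """GMT-like TSV: set_id <tab> description <tab> member <tab> member ..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: need set_id, description, >=1 member"
                )
            members = list(dict.fromkeys(c for c in cols[2:] if c))
            if not members:
                raise ValidationError(f"{path}:{lineno}: empty gene set")
            sets[cols[0]] = (cols[1], members)
    return sets


def write_gene_sets(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for set_id in sets:
            desc, members = sets[set_id]
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def _hypergeom_upper_tail(overlap: int, universe: int, set_size: int,
                          query_size: int) -> float:
    """P(X >= overlap), X ~ Hypergeom(universe, set_size, query_size),
    computed as an exact rational then converted to float."""
    hi = min(set_size, query_size)
    num = sum(
        math.comb(set_size, x) * math.comb(universe - set_size, query_size - x)
        for x in range(overlap, hi + 1)
    )
    return float(Fraction(num, math.comb(universe, query_size)))


def overrepresentation(
    query_genes: set[str],
    gene_sets: dict[str, tuple[str, list[str]]],
    universe: set[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene list in
    each gene set, BH-corrected across sets.

    Sets are intersected with the universe before testing; the query must be
    a subset of the universe.
    """
    query = set(query_genes)
    universe = set(universe)
    if not universe or not query:
        raise ContractError("universe and query must be non-empty")
    if not query <= universe:
        raise ValidationError(
            f"query genes outside universe: {sorted(query - universe)[:5]}"
        )
    rows = []
    n_u, n_q = len(universe), len(query)
    for set_id in gene_sets:
        desc, members = gene_sets[set_id]
        in_universe = set(members) & universe
        overlap = len(in_universe & query)
        expected = len(in_universe) * n_q / n_u
        if in_universe:
            p = _hypergeom_upper_tail(overlap, n_u, len(in_universe), n_q)
        else:
            p = 1.0
        rows.append(
            {"set_id": set_id, "description": desc, "set_size": len(in_universe),
             "overlap": overlap, "expected": expected, "pvalue": p}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = adjust_bh(out["pvalue"].to_numpy()) if len(out) else []
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def positional_gene_sets(
    gene_table: pd.DataFrame, genes_per_set: int = 50
) -> dict[str, tuple[str, list[str]]]:
    """Generic gene sets built from genomic position (consecutive blocks of
    genes per chromosome) — a neutral stand-in collection for exercising the
    over-representation machinery without any external annotation database."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for chrom, sub in gene_table.groupby("chrom", sort=True):
        ordered = sub.sort_values("tss")["gene_id"].tolist()
        for i in range(0, len(ordered), genes_per_set):
            block = ordered[i : i + genes_per_set]
            if not block:
                continue
            sid = f"{chrom}_block{i // genes_per_set + 1:03d}"
            sets[sid] = (f"genes in {chrom} block {i // genes_per_set + 1}", block)
    return sets
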