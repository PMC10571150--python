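"""Fully labelled synthetic datasets with the statistical structure the
downstream inference assumes.

The generator emulates a nanoparticle-exposure study design: four treatments
plus an untreated control, replicated ChIP-seq count matrices for four histone
marks (H3K27ac, H3K4me1, H3K9me2, H3K27me3), RNA-seq gene counts whose planted
expression shifts are coupled to planted H3K27ac shifts at interaction-linked
enhancers or promoter peaks, and broad H3K9me2 domains in binned coverage
tracks.  Counts follow a negative-binomial model with a common dispersion.
Every planted effect is recorded in a SimulationTruth object so parameter
recovery can be scored exactly.

Identical config + seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io_core import (
    CountMatrix,
    GenomicInterval,
    InteractionMap,
    InteractionRecord,
    PeakSet,
    ValidationError,
    validate_sample_sheet,
)

MARKS = ("H3K27ac", "H3K4me1", "H3K9me2", "H3K27me3")
DEFAULT_CONDITIONS = ("control", "Fe2O3", "Fe2O3Co", "FeSO4", "CoCl2")


class CapacityError(ValueError):
    """The simulated genome is too small for the requested feature counts."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults are "study-shaped": 4 treatments + control, 2 replicates,
    4 marks with 2,000 peaks each, 2,000 genes, NB counts with dispersion
    0.1 around a mean depth of ~200 reads per peak/gene.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 30_000_000
    n_genes: int = 2000
    n_peaks_per_mark: dict[str, int] = field(
        default_factory=lambda: {m: 2000 for m in MARKS}
    )
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS  # first entry = control
    replicates_per_condition: int = 2
    frac_dp: float = 0.05            # fraction of peaks with planted shifts, per treatment x mark
    effect_log2fc: float = 1.5       # magnitude of planted shifts; sign random
    nb_dispersion: float = 0.1
    baseline_logmean_mu: float = float(np.log(200.0))
    baseline_logmean_sd: float = 1.0
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    frac_promoter_peaks: float = 0.3  # peaks placed inside promoter windows
    frac_enhancer_linked: float = 0.5  # distal H3K27ac peaks entered in the interaction map
    couple_prob: float = 0.5         # P(linked gene of a planted H3K27ac DP is a DEG)
    frac_deg_background: float = 0.02
    n_kdd: int = 20
    kdd_length_range: tuple[int, int] = (100_000, 300_000)
    kdd_signal: float = 3.0          # domain elevation in background SDs
    kdd_effect: float = 0.3          # fractional length change of altered domains
    frac_kdd_changed: float = 0.5
    bin_size: int = 5000
    promoter_window: int = 1000

    def __post_init__(self) -> None:
        fracs = {
            "frac_dp": self.frac_dp,
            "frac_promoter_peaks": self.frac_promoter_peaks,
            "frac_enhancer_linked": self.frac_enhancer_linked,
            "couple_prob": self.couple_prob,
            "frac_deg_background": self.frac_deg_background,
            "frac_kdd_changed": self.frac_kdd_changed,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name}={val} outside [0, 1]")
        if self.replicates_per_condition < 2:
            raise ValidationError("replicates_per_condition must be >= 2")
        if self.effect_log2fc <= 0:
            raise ValidationError("effect_log2fc must be positive")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be non-negative")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ValidationError("lib_size_range must be positive and ordered")
        if len(self.conditions) < 2:
            raise ValidationError("need a control plus at least one treatment")
        self.conditions = tuple(self.conditions)
        self.lib_size_range = tuple(self.lib_size_range)
        self.kdd_length_range = tuple(self.kdd_length_range)

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def treatments(self) -> tuple[str, ...]:
        return self.conditions[1:]

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["lib_size_range"] = list(self.lib_size_range)
        d["kdd_length_range"] = list(self.kdd_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class SimulationTruth:
    """Planted ground truth: everything recovery tests need, keyed by the
    same feature ids the fixture files use."""

    # (mark, treatment) -> {peak_id: +1/-1}
    dp: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    # treatment -> {gene_id: +1/-1}
    deg: dict[str, dict[str, int]] = field(default_factory=dict)
    # H3K27ac peak_id -> linked gene ids (via interaction map or promoter window)
    links: dict[str, tuple[str, ...]] = field(default_factory=dict)
    # treatment -> {H3K27ac peak_id: "activated"|"repressed"} for linked planted peaks
    activation: dict[str, dict[str, str]] = field(default_factory=dict)
    # condition -> list of KDD intervals (control first)
    kdd_domains: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    # treatment -> indices (into control list) of domains with altered size
    kdd_changed: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "dp": {
                f"{mark}|{treat}": signs
                for (mark, treat), signs in sorted(self.dp.items())
            },
            "deg": {t: signs for t, signs in sorted(self.deg.items())},
            "links": {p: list(g) for p, g in sorted(self.links.items())},
            "activation": {
                t: dict(sorted(status.items()))
                for t, status in sorted(self.activation.items())
            },
            "kdd_domains": {
                cond: [[iv.chrom, iv.start, iv.end] for iv in domains]
                for cond, domains in sorted(self.kdd_domains.items())
            },
            "kdd_changed": {t: idx for t, idx in sorted(self.kdd_changed.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        truth = cls()
        for key, signs in payload["dp"].items():
            mark, treat = key.split("|")
            truth.dp[(mark, treat)] = {k: int(v) for k, v in signs.items()}
        truth.deg = {
            t: {g: int(s) for g, s in signs.items()}
            for t, signs in payload["deg"].items()
        }
        truth.links = {p: tuple(g) for p, g in payload["links"].items()}
        truth.activation = payload["activation"]
        truth.kdd_domains = {
            cond: [GenomicInterval(c, s, e) for c, s, e in domains]
            for cond, domains in payload["kdd_domains"].items()
        }
        truth.kdd_changed = {t: list(map(int, v)) for t, v in payload["kdd_changed"].items()}
        return truth


# ---------------------------------------------------------------------------
# genome / peak geometry


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, PeakSet], InteractionMap]:
    """Place genes, per-mark peak atlases and a promoter-capture style
    interaction map on a synthetic genome.

    Genes sit on a 5 kb grid (uniform draw without replacement), guaranteeing
    the >=5 kb spacing.  Per mark, `frac_promoter_peaks` of peaks are centred
    inside a promoter window; the rest are distal (rejection-sampled away from
    every promoter window).  `frac_enhancer_linked` of the distal H3K27ac
    peaks become distal anchors of interaction records pointing at sampled
    same-chromosome genes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = config.chrom_names
    spacing = 5000
    slots_per_chrom = (config.chrom_length - 2 * spacing) // spacing
    if slots_per_chrom * config.n_chroms < config.n_genes:
        raise CapacityError(
            f"genome too small: {config.n_genes} genes need "
            f"{config.n_genes * spacing} bp of 5 kb slots"
        )

    # genes spread round-robin across chromosomes
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    rows = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        slots = np.arange(1, slots_per_chrom + 1) * spacing
        tss = np.sort(rng.choice(slots, size=n, replace=False))
        strands = rng.choice(["+", "-"], size=n)
        for t, s in zip(tss, strands):
            gid += 1
            rows.append(
                {
                    "gene_id": f"gene_{gid:05d}",
                    "gene_name": f"Gm{gid:05d}",
                    "chrom": chrom,
                    "tss": int(t),
                    "strand": s,
                }
            )
    genes = pd.DataFrame(rows)

    tss_by_chrom = {
        c: np.sort(g["tss"].to_numpy()) for c, g in genes.groupby("chrom")
    }
    win = config.promoter_window

    def in_promoter_window(chrom: str, start: int, end: int) -> bool:
        tss = tss_by_chrom.get(chrom)
        if tss is None or len(tss) == 0:
            return False
        # overlap [tss - win, tss + win + 1): tss >= start - win and tss < end + win
        i = np.searchsorted(tss, start - win, side="left")
        j = np.searchsorted(tss, end + win, side="left")
        return j > i

    peaks: dict[str, PeakSet] = {}
    distal_by_mark: dict[str, list[int]] = {}
    for mark in config.n_peaks_per_mark:
        n_peaks = config.n_peaks_per_mark[mark]
        n_prom = int(round(config.frac_promoter_peaks * n_peaks))
        gene_rows = genes.sample(
            n=n_prom, random_state=int(rng.integers(2**31)),
            replace=n_prom > len(genes),
        ).reset_index(drop=True)
        intervals: list[GenomicInterval] = []
        placement: list[str] = []
        for _, row in gene_rows.iterrows():
            width = int(rng.integers(300, 700))
            centre = int(row["tss"] + rng.integers(-win // 2, win // 2 + 1))
            start = max(0, centre - width // 2)
            intervals.append(GenomicInterval(str(row["chrom"]), start, start + width))
            placement.append("promoter")
        n_distal = n_peaks - n_prom
        placed = 0
        attempts = 0
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        while placed < n_distal:
            attempts += 1
            if attempts > 50 * max(n_distal, 1):
                raise CapacityError(
                    f"could not place {n_distal} distal peaks for {mark}"
                )
            chrom = chroms[int(rng.integers(config.n_chroms))]
            width = int(rng.integers(300, 1500))
            start = int(rng.integers(0, config.chrom_length - width))
            if in_promoter_window(chrom, start, start + width):
                continue
            if any(start < e and s < start + width for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, start + width))
            intervals.append(GenomicInterval(chrom, start, start + width))
            placement.append("distal")
            placed += 1
        names = [f"{mark}_peak_{i + 1:05d}" for i in range(len(intervals))]
        peaks[mark] = PeakSet(intervals, names)
        distal_by_mark[mark] = [
            i for i, p in enumerate(placement) if p == "distal"
        ]

    records: list[InteractionRecord] = []
    if "H3K27ac" in peaks and config.frac_enhancer_linked > 0:
        distal_idx = distal_by_mark["H3K27ac"]
        n_link = int(round(config.frac_enhancer_linked * len(distal_idx)))
        chosen = rng.choice(len(distal_idx), size=n_link, replace=False)
        for k in sorted(chosen):
            i = distal_idx[k]
            iv = peaks["H3K27ac"].intervals[i]
            same_chrom = genes[genes["chrom"] == iv.chrom]
            row = same_chrom.iloc[int(rng.integers(len(same_chrom)))]
            tss = int(row["tss"])
            prom = GenomicInterval(iv.chrom, max(0, tss - win), tss + win + 1)
            records.append(InteractionRecord(prom, (str(row["gene_id"]),), iv))
    imap = InteractionMap(records)
    return genes, peaks, imap


def plant_dp_truth(
    config: SimulationConfig,
    peaks: dict[str, PeakSet],
    rng: np.random.Generator,
) -> SimulationTruth:
    """Draw the planted differential-peak assignments for every mark x
    treatment: a `frac_dp` subset of peaks, each with a random +/- sign."""
    truth = SimulationTruth()
    for mark, pset in peaks.items():
        n = len(pset)
        n_dp = int(round(config.frac_dp * n))
        for treat in config.treatments:
            idx = rng.choice(n, size=n_dp, replace=False)
            signs = rng.choice([-1, 1], size=n_dp)
            truth.dp[(mark, treat)] = {
                pset.names[i]: int(s) for i, s in sorted(zip(idx, signs))
            }
    return truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB(mean, dispersion) with Var = mean + dispersion * mean^2; Poisson
    limit when dispersion ~ 0."""
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def _make_sheet(config: SimulationConfig, assay: str) -> pd.DataFrame:
    rows = []
    for cond in config.conditions:
        for rep in range(1, config.replicates_per_condition + 1):
            rows.append(
                {
                    "sample_id": f"{assay}_{cond}_r{rep}",
                    "condition": cond,
                    "replicate": rep,
                    "assay": assay,
                }
            )
    return validate_sample_sheet(pd.DataFrame(rows))


def simulate_chip_counts(
    config: SimulationConfig,
    peaks: PeakSet,
    truth: SimulationTruth,
    mark: str,
    rng: np.random.Generator,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts per peak x sample.

    count_ij ~ NB(mean = L_j * q_i * 2^(s * effect * 1[i planted in sample j's
    treatment]), dispersion), with lognormal per-peak baselines q_i and
    uniform relative library sizes L_j.  Control samples never carry effects.
    """
    sheet = _make_sheet(config, mark)
    n_feat, n_samp = len(peaks), len(sheet)
    q = np.exp(
        rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sd, n_feat)
    )
    lib = rng.uniform(*config.lib_size_range, size=n_samp)
    name_to_idx = {n: i for i, n in enumerate(peaks.names)}
    fc = np.ones((n_feat, n_samp))
    for j, cond in enumerate(sheet["condition"]):
        if cond == config.control:
            continue
        for pid, sign in truth.dp.get((mark, cond), {}).items():
            fc[name_to_idx[pid], j] = 2.0 ** (sign * config.effect_log2fc)
    mean = q[:, None] * lib[None, :] * fc
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    df = pd.DataFrame(counts, index=pd.Index(peaks.names, name="feature_id"),
                      columns=list(sheet["sample_id"]))
    return CountMatrix(df), sheet


def _linked_genes_for_k27ac(
    config: SimulationConfig,
    gene_table: pd.DataFrame,
    peaks_k27ac: PeakSet,
    interaction_map: InteractionMap,
) -> dict[str, tuple[str, ...]]:
    """Map each H3K27ac peak to the genes it can regulate: genes whose
    promoter window it overlaps, else genes of interaction records whose
    distal anchor it overlaps."""
    win = config.promoter_window
    tss_sorted = {
        c: g.sort_values("tss") for c, g in gene_table.groupby("chrom")
    }
    anchors = [(rec.distal_anchor, rec.gene_ids) for rec in interaction_map]
    links: dict[str, tuple[str, ...]] = {}
    for name, iv in peaks_k27ac:
        genes_hit: list[str] = []
        sub = tss_sorted.get(iv.chrom)
        if sub is not None:
            tss = sub["tss"].to_numpy()
            i = np.searchsorted(tss, iv.start - win, side="left")  # tss >= start - win
            j = np.searchsorted(tss, iv.end + win, side="left")  # tss < end + win
            if j > i:
                genes_hit = list(sub["gene_id"].to_numpy()[i:j])
        if not genes_hit:
            for anchor, gids in anchors:
                if iv.overlaps(anchor):
                    genes_hit.extend(g for g in gids if g not in genes_hit)
        if genes_hit:
            links[name] = tuple(genes_hit)
    return links


def simulate_rna_counts(
    config: SimulationConfig,
    gene_table: pd.DataFrame,
    interaction_map: InteractionMap,
    peaks_k27ac: PeakSet,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Plant DEG truth coupled to planted H3K27ac shifts at linked elements,
    add independent background DEGs, then draw NB gene counts.

    A gene linked (interaction map or promoter window) to a planted H3K27ac
    gain/loss becomes a true DEG with the matching sign with probability
    `couple_prob`.  Updates `truth` in place.
    """
    truth.links = _linked_genes_for_k27ac(
        config, gene_table, peaks_k27ac, interaction_map
    )
    gene_ids = list(gene_table["gene_id"])
    for treat in config.treatments:
        deg: dict[str, int] = {}
        act: dict[str, str] = {}
        planted = truth.dp.get(("H3K27ac", treat), {})
        for pid in sorted(planted):
            sign = planted[pid]
            genes_hit = truth.links.get(pid)
            if not genes_hit:
                continue
            act[pid] = "activated" if sign > 0 else "repressed"
            for g in genes_hit:
                if g in deg:
                    continue
                if rng.random() < config.couple_prob:
                    deg[g] = sign
        n_bg = int(round(config.frac_deg_background * len(gene_ids)))
        if n_bg:
            pool = [g for g in gene_ids if g not in deg]
            idx = rng.choice(len(pool), size=min(n_bg, len(pool)), replace=False)
            signs = rng.choice([-1, 1], size=len(idx))
            for i, s in zip(idx, signs):
                deg[pool[i]] = int(s)
        truth.deg[treat] = deg
        truth.activation[treat] = act

    sheet = _make_sheet(config, "RNA")
    n_feat, n_samp = len(gene_ids), len(sheet)
    q = np.exp(
        rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sd, n_feat)
    )
    lib = rng.uniform(*config.lib_size_range, size=n_samp)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    fc = np.ones((n_feat, n_samp))
    for j, cond in enumerate(sheet["condition"]):
        if cond == config.control:
            continue
        for g, sign in truth.deg.get(cond, {}).items():
            fc[gidx[g], j] = 2.0 ** (sign * config.effect_log2fc)
    mean = q[:, None] * lib[None, :] * fc
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="feature_id"),
                      columns=list(sheet["sample_id"]))
    return CountMatrix(df), sheet


def simulate_kdd_coverage(
    config: SimulationConfig,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Binned H3K9me2 log-enrichment tracks per condition.

    Background bins ~ Normal(0, 1); bins inside a domain are shifted by
    +kdd_signal.  In each treatment a `frac_kdd_changed` subset of domains
    shrinks or grows by `kdd_effect` of its length.
    """
    bs = config.bin_size
    chroms = config.chrom_names
    # place non-overlapping control domains
    domains: list[GenomicInterval] = []
    lo, hi = config.kdd_length_range
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(domains) < config.n_kdd:
        attempts += 1
        if attempts > 200 * max(config.n_kdd, 1):
            raise CapacityError("could not place requested KDDs without overlap")
        chrom = chroms[int(rng.integers(config.n_chroms))]
        length = int(rng.integers(lo, hi + 1)) // bs * bs
        length = max(length, bs)
        if length >= config.chrom_length:
            raise CapacityError("KDD longer than chromosome")
        start = int(rng.integers(0, (config.chrom_length - length) // bs)) * bs
        if any(start < e and s < start + length for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, start + length))
        domains.append(GenomicInterval(chrom, start, start + length))
    domains.sort(key=lambda iv: (iv.chrom, iv.start))
    truth.kdd_domains[config.control] = domains

    for treat in config.treatments:
        n_changed = int(round(config.frac_kdd_changed * len(domains)))
        changed = sorted(
            rng.choice(len(domains), size=n_changed, replace=False).tolist()
        ) if n_changed else []
        tdomains: list[GenomicInterval] = []
        for i, iv in enumerate(domains):
            if i in changed and config.kdd_effect > 0:
                delta = int(round(config.kdd_effect * iv.length / bs)) * bs
                if rng.random() < 0.5:
                    new_end = max(iv.start + bs, iv.end - delta)
                else:
                    new_end = min(config.chrom_length, iv.end + delta)
                tdomains.append(GenomicInterval(iv.chrom, iv.start, new_end))
            else:
                tdomains.append(iv)
        truth.kdd_domains[treat] = tdomains
        truth.kdd_changed[treat] = changed if config.kdd_effect > 0 else []

    n_bins = config.chrom_length // bs
    starts = np.arange(n_bins) * bs
    tracks: dict[str, pd.DataFrame] = {}
    for cond in config.conditions:
        frames = []
        for chrom in chroms:
            vals = rng.normal(0.0, 1.0, n_bins)
            for iv in truth.kdd_domains[cond]:
                if iv.chrom != chrom:
                    continue
                i0, i1 = iv.start // bs, -(-iv.end // bs)
                vals[i0:i1] += config.kdd_signal
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": starts + bs, "value": vals}
                )
            )
        tracks[cond] = pd.concat(frames, ignore_index=True)
    return tracks


@dataclass
class SimulationBundle:
    config: SimulationConfig
    genes: pd.DataFrame
    peaks: dict[str, PeakSet]
    interactions: InteractionMap
    chip_counts: dict[str, CountMatrix]
    rna_counts: CountMatrix
    sample_sheet: pd.DataFrame
    coverage: dict[str, pd.DataFrame]
    truth: SimulationTruth


def simulate_dataset(config: SimulationConfig) -> SimulationBundle:
    """Run the full generator in a fixed draw order from a single RNG."""
    rng = np.random.default_rng(config.seed)
    genes, peaks, imap = simulate_genome(config, rng)
    truth = plant_dp_truth(config, peaks, rng)
    chip: dict[str, CountMatrix] = {}
    sheets = []
    for mark in config.n_peaks_per_mark:
        cm, sheet = simulate_chip_counts(config, peaks[mark], truth, mark, rng)
        chip[mark] = cm
        sheets.append(sheet)
    k27 = peaks.get("H3K27ac", PeakSet([], []))
    rna, rna_sheet = simulate_rna_counts(config, genes, imap, k27, truth, rng)
    sheets.append(rna_sheet)
    coverage = simulate_kdd_coverage(config, truth, rng)
    sheet = pd.concat(sheets, ignore_index=True)
    return SimulationBundle(
        config=config,
        genes=genes,
        peaks=peaks,
        interactions=imap,
        chip_counts=chip,
        rna_counts=rna,
        sample_sheet=sheet,
        coverage=coverage,
        truth=truth,
    )


def write_bundle(bundle: SimulationBundle, outdir) -> None:
    """Write the fixture files (genes.tsv, interactions.bedpe, per-mark
    peaks/counts, rna_counts.tsv, sample_sheet.tsv, coverage tracks,
    truth.json, config.yaml) into `outdir`."""
    from pathlib import Path

    from . import io_core

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_core.write_gene_table(bundle.genes, out / "genes.tsv")
    io_core.write_bedpe_interactions(bundle.interactions, out / "interactions.bedpe")
    for mark, pset in bundle.peaks.items():
        io_core.write_bed(pset, out / f"peaks_{mark}.bed")
        bundle.chip_counts[mark].to_tsv(out / f"counts_{mark}.tsv")
    bundle.rna_counts.to_tsv(out / "rna_counts.tsv")
    io_core.write_sample_sheet(bundle.sample_sheet, out / "sample_sheet.tsv")
    for cond, track in bundle.coverage.items():
        io_core.write_bedgraph(track, out / f"kdd_coverage_{cond}.tsv")
    bundle.truth.to_json(out / "truth.json")
    bundle.config.to_yaml(out / "config.yaml")
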