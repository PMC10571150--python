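"""End-to-end orchestration: simulate (optional) -> differential calling for
every mark and for expression -> peak annotation -> ChIP/RNA integration ->
KDD analysis -> MDS -> over-representation, driven by one YAML config.

Stage outputs are plain TSV/BED/BEDPE/JSON files and every stage can be
re-run independently through the library API with identical results.  Data
files never contain timestamps, so a rerun with the same config and seed is
byte-identical; log lines go to run.log and stderr only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, annotation, differential, integration, io_core, kdd, similarity
from .differential import Contrast
from .synthetic import MARKS, SimulationConfig, simulate_dataset, write_bundle

logger = logging.getLogger("epimark")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class Thresholds:
    fdr_chip: float = 0.1
    lfc_chip: float = 0.3
    fdr_rna: float = 0.1
    ora_fdr: float = 0.05
    promoter_window: int = 1000

    def __post_init__(self) -> None:
        for name in ("fdr_chip", "lfc_chip", "fdr_rna", "ora_fdr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.promoter_window <= 0:
            raise ValueError("promoter_window must be positive")


@dataclass
class PipelineConfig:
    """Inputs are either explicit paths or a `simulate` block (a
    SimulationConfig) that generates them into the run directory."""

    output_dir: str
    seed: int = 0
    simulate: SimulationConfig | None = None
    genes: str | None = None
    interactions: str | None = None
    sample_sheet: str | None = None
    peaks: dict[str, str] = field(default_factory=dict)        # mark -> BED
    chip_counts: dict[str, str] = field(default_factory=dict)  # mark -> TSV
    rna_counts: str | None = None
    kdd_coverage: dict[str, str] = field(default_factory=dict)  # condition -> TSV
    gene_sets: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    contrasts: list[dict] = field(default_factory=list)  # [{treatment, control}]
    kdd_bin_size: int = 5000
    kdd_flank: int = 100_000
    kdd_n_perm: int = 1000
    mds_top_n: int = 500

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if "thresholds" in raw and raw["thresholds"] is not None:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("output_dir", None)  # hash the analysis, not the destination
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _preflight(config: PipelineConfig) -> None:
    if config.simulate is not None:
        return
    required = [config.genes, config.sample_sheet, config.rna_counts]
    paths = [p for p in required if p] + list(config.peaks.values()) + list(
        config.chip_counts.values()
    ) + list(config.kdd_coverage.values())
    if config.interactions:
        paths.append(config.interactions)
    if config.gene_sets:
        paths.append(config.gene_sets)
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise PipelineError("preflight", f"missing input paths: {missing}")
    if not config.genes or not config.sample_sheet:
        raise PipelineError("preflight", "genes and sample_sheet are required")


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    A stage failure aborts with the stage name while keeping the outputs of
    completed stages on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "python": sys.version.split()[0],
        "stages": {},
    }
    stage = "preflight"
    try:
        _preflight(config)

        # ---- simulate ---------------------------------------------------
        stage = "simulate"
        if config.simulate is not None:
            logger.info("stage simulate: seed=%d", config.simulate.seed)
            bundle = simulate_dataset(config.simulate)
            simdir = out / "simulated"
            write_bundle(bundle, simdir)
            config.genes = str(simdir / "genes.tsv")
            config.interactions = str(simdir / "interactions.bedpe")
            config.sample_sheet = str(simdir / "sample_sheet.tsv")
            config.rna_counts = str(simdir / "rna_counts.tsv")
            config.peaks = {
                m: str(simdir / f"peaks_{m}.bed")
                for m in config.simulate.n_peaks_per_mark
            }
            config.chip_counts = {
                m: str(simdir / f"counts_{m}.tsv")
                for m in config.simulate.n_peaks_per_mark
            }
            config.kdd_coverage = {
                c: str(simdir / f"kdd_coverage_{c}.tsv")
                for c in config.simulate.conditions
            }
            manifest["stages"]["simulate"] = {
                "genes": len(bundle.genes),
                "marks": list(config.peaks),
            }

        genes = io_core.read_gene_table(config.genes)
        sheet = io_core.read_sample_sheet(config.sample_sheet)
        if config.interactions:
            imap = io_core.read_bedpe_interactions(config.interactions, genes)
        else:
            imap = io_core.InteractionMap([])
        conditions = list(dict.fromkeys(sheet["condition"]))
        if config.contrasts:
            contrasts = [(c["treatment"], c["control"]) for c in config.contrasts]
        else:
            control = conditions[0]
            contrasts = [(c, control) for c in conditions[1:]]
        th = config.thresholds

        # ---- differential ------------------------------------------------
        stage = "diff"
        dp_tables: dict[tuple[str, str], pd.DataFrame] = {}
        marks = list(config.chip_counts)
        for mark in marks:
            counts = io_core.read_counts(
                config.chip_counts[mark], sheet[sheet["assay"] == mark]
            )
            for treat, ctrl in contrasts:
                res = differential.run_contrast(
                    counts, sheet, Contrast(treat, ctrl, mark),
                    fdr_threshold=th.fdr_chip, lfc_threshold=th.lfc_chip,
                )
                res.to_csv(out / f"dp_{mark}_{treat}_vs_{ctrl}.tsv", sep="\t",
                           index=False, lineterminator="\n")
                dp_tables[(mark, treat)] = res
        deg_tables: dict[str, pd.DataFrame] = {}
        rna = io_core.read_counts(config.rna_counts, sheet[sheet["assay"] == "RNA"])
        for treat, ctrl in contrasts:
            res = differential.run_contrast(
                rna, sheet, Contrast(treat, ctrl, "RNA"),
                fdr_threshold=th.fdr_rna, lfc_threshold=0.0,
            )
            res.to_csv(out / f"deg_{treat}_vs_{ctrl}.tsv", sep="\t",
                       index=False, lineterminator="\n")
            deg_tables[treat] = res
        manifest["stages"]["diff"] = {
            f"{m}|{t}": int((tab["status"] != "unchanged").sum())
            for (m, t), tab in dp_tables.items()
        } | {
            f"RNA|{t}": int((tab["status"] != "unchanged").sum())
            for t, tab in deg_tables.items()
        }
        logger.info("stage diff: %d DP tables, %d DEG tables",
                    len(dp_tables), len(deg_tables))

        # ---- annotate ----------------------------------------------------
        stage = "annotate"
        ann_tables: dict[str, pd.DataFrame] = {}
        elements_by_mark = {}
        for mark in marks:
            pset = io_core.read_bed(config.peaks[mark])
            elements, unann = annotation.link_peaks_to_genes(
                pset, imap, genes, window=th.promoter_window
            )
            tab = annotation.annotation_table(elements, unann)
            tab.to_csv(out / f"annotation_{mark}.tsv", sep="\t", index=False,
                       lineterminator="\n")
            ann_tables[mark] = tab
            elements_by_mark[mark] = elements
        manifest["stages"]["annotate"] = {
            m: len(t) for m, t in ann_tables.items()
        }

        # ---- integrate ---------------------------------------------------
        stage = "integrate"
        universe = set(rna.feature_ids)
        deg_sets = {
            t: set(tab.loc[tab["status"] != "unchanged", "feature_id"])
            for t, tab in deg_tables.items()
        }
        assoc_rows = []
        for mark in marks:
            gene_links = {
                e.element_id: e.gene_ids for e in elements_by_mark[mark]
            }
            dp_linked = {}
            for treat, _ in contrasts:
                tab = dp_tables[(mark, treat)]
                dps = tab.loc[tab["status"] != "unchanged", "feature_id"]
                linked = set()
                for p in dps:
                    linked.update(gene_links.get(p, ()))
                dp_linked[treat] = linked
            assoc = integration.association_stats(dp_linked, deg_sets, universe)
            assoc.insert(0, "mark", mark)
            assoc_rows.append(assoc)
        assoc_all = pd.concat(assoc_rows, ignore_index=True)
        assoc_all.to_csv(out / "association_stats.tsv", sep="\t", index=False,
                         lineterminator="\n")

        split_rows = []
        for mark in marks:
            for treat, _ in contrasts:
                tab = dp_tables[(mark, treat)]
                dps = list(tab.loc[tab["status"] != "unchanged", "feature_id"])
                if not dps:
                    split_rows.append(
                        {"mark": mark, "treatment": treat, "n_dp": 0,
                         "frac_promoter": float("nan"),
                         "frac_outside": float("nan")}
                    )
                    continue
                fin, fout = integration.promoter_fraction(dps, ann_tables[mark])
                split_rows.append(
                    {"mark": mark, "treatment": treat, "n_dp": len(dps),
                     "frac_promoter": fin, "frac_outside": fout}
                )
        pd.DataFrame(split_rows).to_csv(out / "promoter_split.tsv", sep="\t",
                                        index=False, lineterminator="\n")

        k27_elements = integration.build_elements(
            elements_by_mark.get("H3K27ac", [])
        )
        dp_status = {
            treat: dp_tables[("H3K27ac", treat)].set_index("feature_id")["status"]
            for treat, _ in contrasts
            if ("H3K27ac", treat) in dp_tables
        }
        act = integration.build_activation_matrix(
            k27_elements, dp_status, deg_sets, require_deg=True
        )
        act.coded().to_csv(out / "activation_matrix.tsv", sep="\t",
                           lineterminator="\n")
        pd.DataFrame(
            [{"element_id": e, "gene_ids": ",".join(g)}
             for e, g in act.linked_genes.items()]
        ).to_csv(out / "linked_genes.tsv", sep="\t", index=False,
                 lineterminator="\n")
        manifest["stages"]["integrate"] = act.summary
        logger.info("stage integrate: %s", act.summary)

        # ---- kdd ---------------------------------------------------------
        stage = "kdd"
        if config.kdd_coverage:
            control = conditions[0]
            cov_ctrl = io_core.read_bedgraph(config.kdd_coverage[control])
            dom_ctrl = kdd.call_kdd(cov_ctrl, config.kdd_bin_size)
            _write_domains(dom_ctrl, out / f"domains_{control}.bed")
            change_rows = []
            prox = {}
            for treat, _ in contrasts:
                if treat not in config.kdd_coverage:
                    continue
                cov_t = io_core.read_bedgraph(config.kdd_coverage[treat])
                dom_t = kdd.call_kdd(cov_t, config.kdd_bin_size)
                _write_domains(dom_t, out / f"domains_{treat}.bed")
                changes, summary = kdd.compare_domains(dom_ctrl, dom_t)
                for ch in changes:
                    change_rows.append(
                        {"treatment": treat,
                         "chrom": ch.control_domain.interval.chrom,
                         "start": ch.control_domain.interval.start,
                         "end": ch.control_domain.interval.end,
                         "size_log2_ratio": ch.size_log2_ratio,
                         "changed": ch.changed}
                    )
                changed = [c.control_domain for c in changes if c.changed]
                degs = deg_sets.get(treat, set())
                if degs:
                    obs, p = kdd.deg_proximity_test(
                        changed, degs, genes, flank=config.kdd_flank,
                        n_perm=config.kdd_n_perm, seed=config.seed,
                    )
                else:
                    obs, p = 0, 1.0
                prox[treat] = {"observed": obs, "pvalue": p,
                               "n_changed_domains": len(changed),
                               "bp_ratio": summary["bp_ratio"]}
            pd.DataFrame(change_rows).to_csv(
                out / "domain_changes.tsv", sep="\t", index=False,
                lineterminator="\n"
            )
            with open(out / "deg_proximity.json", "w") as fh:
                json.dump(prox, fh, indent=1, sort_keys=True)
                fh.write("\n")
            manifest["stages"]["kdd"] = {
                "control_domains": len(dom_ctrl),
            }
            logger.info("stage kdd: %d control domains", len(dom_ctrl))

        # ---- mds ---------------------------------------------------------
        stage = "mds"
        for mark in marks:
            counts = io_core.read_counts(
                config.chip_counts[mark], sheet[sheet["assay"] == mark]
            )
            coords = similarity.classical_mds(
                similarity.sample_distances(counts, top_n=config.mds_top_n), k=2
            )
            coords.to_csv(out / f"mds_{mark}.tsv", sep="\t", lineterminator="\n")
        manifest["stages"]["mds"] = {"marks": marks}

        # ---- ora ---------------------------------------------------------
        stage = "ora"
        if config.gene_sets:
            gene_sets = similarity.read_gene_sets(config.gene_sets)
        else:
            gene_sets = similarity.positional_gene_sets(genes)
        ora_rows = []
        for treat, _ in contrasts:
            degs = deg_sets.get(treat, set()) & universe
            if not degs:
                continue
            res = similarity.overrepresentation(
                degs, gene_sets, universe, fdr_threshold=th.ora_fdr
            )
            res.insert(0, "treatment", treat)
            ora_rows.append(res)
        if ora_rows:
            pd.concat(ora_rows, ignore_index=True).to_csv(
                out / "ora.tsv", sep="\t", index=False, lineterminator="\n"
            )
        manifest["stages"]["ora"] = {"gene_sets": len(gene_sets)}

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        logger.info("run complete: %s", out)
        return out
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_domains(domains, path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(domains, start=1):
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}"
                f"\tkdd_{i:04d}\t{d.mean_enrichment:.4f}\t.\n"
            )
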