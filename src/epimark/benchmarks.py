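"""Self-contained evaluation experiments on synthetic data with known truth.

Each function builds its own simulation scenario, runs the relevant part of
the pipeline from scratch and returns summary metrics: false-call behaviour
under the null, planted-effect recovery, ChIP/RNA association and activation
recovery, KDD domain recovery and permutation-test calibration, and
replicate clustering in MDS space.  The problem sizes are chosen so the full
battery runs in a couple of minutes on one core; docs/methods.md documents
each scenario.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import annotation, integration, kdd, similarity
from .differential import Contrast, run_contrast
from .synthetic import SimulationConfig, simulate_dataset


def _derive_seed(base_seed: int, offset: int) -> int:
    return int((base_seed * 100_003 + offset) % (2**31 - 1))


# ---------------------------------------------------------------------------
# differential calling


def _chip_only_config(seed: int, **overrides) -> SimulationConfig:
    base = dict(
        seed=seed,
        n_chroms=2,
        chrom_length=10_000_000,
        n_genes=50,
        n_peaks_per_mark={"H3K27ac": 2000},
        conditions=("control", "treated"),
        replicates_per_condition=3,
        nb_dispersion=0.1,
        couple_prob=0.0,
        frac_deg_background=0.0,
        n_kdd=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def fdr_null_experiment(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """All-null ChIP simulations (no planted effects): every differential
    call is false.

    Returns the mean false-call proportion — the fraction of features
    falsely given a non-unchanged status call at the FDR<0.1, |log2FC|>0.3
    gate — plus, for transparency, the per-seed call counts and the mean
    false-discovery proportion V/max(R,1) (which on an all-null simulation
    is the any-rejection indicator and therefore a far noisier statistic).
    """
    fdps = []
    fracs = []
    calls = []
    for i in range(n_seeds):
        cfg = _chip_only_config(_derive_seed(base_seed, i), frac_dp=0.0)
        bundle = simulate_dataset(cfg)
        res = run_contrast(
            bundle.chip_counts["H3K27ac"], bundle.sample_sheet,
            Contrast("treated", "control", "H3K27ac"),
        )
        r = int((res["status"] != "unchanged").sum())
        calls.append(r)
        fracs.append(r / len(res))
        fdps.append(1.0 if r > 0 else 0.0)
    return {
        "mean_false_call_proportion": float(np.mean(fracs)),
        "mean_fdp": float(np.mean(fdps)),
        "calls_per_seed": calls,
        "n_features": 2000,
        "n_seeds": n_seeds,
    }


def recovery_experiment(n_seeds: int = 3, base_seed: int = 0) -> dict:
    """Planted |log2FC| = 1.5 at dispersion 0.1 and mean depth ~200:
    sensitivity, sign accuracy among detected true peaks, and the mean
    signed bias of the log2FC estimate over all planted peaks."""
    tp = fn = 0
    sign_ok = sign_n = 0
    biases = []
    for i in range(n_seeds):
        cfg = _chip_only_config(
            _derive_seed(base_seed, 1000 + i), frac_dp=0.05, effect_log2fc=1.5
        )
        bundle = simulate_dataset(cfg)
        res = run_contrast(
            bundle.chip_counts["H3K27ac"], bundle.sample_sheet,
            Contrast("treated", "control", "H3K27ac"),
        ).set_index("feature_id")
        truth = bundle.truth.dp[("H3K27ac", "treated")]
        for pid, sign in truth.items():
            row = res.loc[pid]
            called = row["status"] != "unchanged"
            tp += int(called)
            fn += int(not called)
            if called:
                sign_n += 1
                sign_ok += int(np.sign(row["log2fc"]) == sign)
            biases.append(row["log2fc"] * sign - cfg.effect_log2fc)
    return {
        "sensitivity": tp / (tp + fn),
        "sign_accuracy": sign_ok / max(sign_n, 1),
        "log2fc_bias": float(np.mean(biases)),
        "n_planted": tp + fn,
    }


# ---------------------------------------------------------------------------
# integration


def _strong_coupling_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_chroms=2,
        chrom_length=10_000_000,
        n_genes=1000,
        n_peaks_per_mark={"H3K27ac": 1000},
        conditions=("control", "Fe2O3", "Fe2O3Co"),
        replicates_per_condition=3,
        frac_dp=0.1,
        effect_log2fc=2.0,
        nb_dispersion=0.05,
        couple_prob=1.0,
        frac_deg_background=0.0,
        n_kdd=0,
    )


def integration_experiment(base_seed: int = 0) -> dict:
    """Forced coupling (couple_prob = 1) with strong effects: Fisher
    association of DP-linked genes with DEGs, activation-status recovery
    against planted truth, and the promoter/outside split of called DPs."""
    cfg = _strong_coupling_config(_derive_seed(base_seed, 2000))
    bundle = simulate_dataset(cfg)
    sheet = bundle.sample_sheet
    elements, unann = annotation.link_peaks_to_genes(
        bundle.peaks["H3K27ac"], bundle.interactions, bundle.genes,
        window=cfg.promoter_window,
    )
    ann_tab = annotation.annotation_table(elements, unann)
    gene_links = {e.element_id: e.gene_ids for e in elements}
    universe = set(bundle.rna_counts.feature_ids)

    dp_results = {}
    deg_sets = {}
    for treat in cfg.treatments:
        dp_results[treat] = run_contrast(
            bundle.chip_counts["H3K27ac"], sheet,
            Contrast(treat, cfg.control, "H3K27ac"),
        )
        deg = run_contrast(
            bundle.rna_counts, sheet, Contrast(treat, cfg.control, "RNA"),
            lfc_threshold=0.0,
        )
        deg_sets[treat] = set(deg.loc[deg["status"] != "unchanged", "feature_id"])

    fisher_ps = []
    all_dps: list[str] = []
    for treat in cfg.treatments:
        tab = dp_results[treat]
        dps = list(tab.loc[tab["status"] != "unchanged", "feature_id"])
        all_dps.extend(dps)
        linked: set[str] = set()
        for p in dps:
            linked.update(gene_links.get(p, ()))
        ct = integration.crosstab_dp_deg(
            linked & universe, deg_sets[treat] & universe, universe
        )
        fisher_ps.append(integration.fisher_exact(ct)[1])

    # activation-status recovery on merged elements
    merged = integration.build_elements(elements)
    dp_status = {
        t: dp_results[t].set_index("feature_id")["status"]
        for t in cfg.treatments
    }
    predicted = integration.build_activation_matrix(
        merged, dp_status, deg_sets, require_deg=False
    )
    pred = predicted.matrix
    peak_of_element = {el.element_id: el.peak_ids for el in merged}
    agree = total = 0
    for el in merged:
        for treat in cfg.treatments:
            planted = bundle.truth.dp[("H3K27ac", treat)]
            signs = {planted[p] for p in peak_of_element[el.element_id]
                     if p in planted}
            if signs == {1}:
                expected = integration.ACTIVATED
            elif signs == {-1}:
                expected = integration.REPRESSED
            elif signs:
                expected = integration.AMBIGUOUS
            else:
                expected = integration.UNCHANGED
            got = (pred.loc[el.element_id, treat]
                   if el.element_id in pred.index else integration.UNCHANGED)
            if expected == got == integration.UNCHANGED:
                continue
            total += 1
            agree += int(expected == got)

    fin, fout = integration.promoter_fraction(sorted(set(all_dps)), ann_tab)
    return {
        "fisher_max_p": float(max(fisher_ps)),
        "activation_agreement": agree / max(total, 1),
        "n_scored_statuses": total,
        "frac_outside_promoters": fout,
        "expected_frac_outside": 1.0 - cfg.frac_promoter_peaks,
        "n_dp": len(set(all_dps)),
    }


# ---------------------------------------------------------------------------
# KDD


def kdd_recovery_experiment(base_seed: int = 0) -> dict:
    """100 kb domains planted at +3 SD: bin-level Jaccard between called and
    planted domains on the control track."""
    cfg = SimulationConfig(
        seed=_derive_seed(base_seed, 3000),
        n_genes=100,
        n_peaks_per_mark={"H3K27ac": 100},
        n_kdd=20,
        kdd_length_range=(100_000, 100_000),
        kdd_signal=3.0,
        couple_prob=0.0,
        frac_deg_background=0.0,
    )
    bundle = simulate_dataset(cfg)
    called = kdd.call_kdd(bundle.coverage["control"], cfg.bin_size)

    def bin_set(intervals):
        out = set()
        for iv in intervals:
            out.update(
                (iv.chrom, b)
                for b in range(iv.start // cfg.bin_size, iv.end // cfg.bin_size)
            )
        return out

    a = bin_set([d.interval for d in called])
    b = bin_set(bundle.truth.kdd_domains["control"])
    return {
        "jaccard": len(a & b) / len(a | b),
        "n_called": len(called),
        "n_planted": len(b) and len(bundle.truth.kdd_domains["control"]),
    }


def kdd_null_calibration(
    n_datasets: int = 200, n_perm: int = 200, base_seed: int = 0
) -> dict:
    """DEG labels drawn independently of domains: the permutation p-values
    must be uniform.  Returns the KS statistic and p against U(0,1).

    The scenario uses a compact genome where domain flanks cover ~25-30% of
    gene positions and 15% of genes are DEGs, keeping the count statistic's
    discreteness small relative to the KS resolution."""
    cfg = SimulationConfig(
        seed=_derive_seed(base_seed, 4000),
        n_chroms=2,
        chrom_length=15_000_000,
        n_genes=1000,
        n_peaks_per_mark={"H3K27ac": 100},
        n_kdd=20,
        kdd_length_range=(150_000, 250_000),
        couple_prob=0.0,
        frac_deg_background=0.0,
    )
    bundle = simulate_dataset(cfg)
    domains = [
        kdd.KDDomain(iv, 1.0, iv.length // cfg.bin_size)
        for iv in bundle.truth.kdd_domains["control"]
    ]
    genes = bundle.genes
    gene_ids = genes["gene_id"].to_numpy()
    rng = np.random.default_rng(_derive_seed(base_seed, 4001))
    n_deg = 150
    pvals = []
    for i in range(n_datasets):
        degs = set(rng.choice(gene_ids, size=n_deg, replace=False))
        _, p = kdd.deg_proximity_test(
            domains, degs, genes, flank=100_000, n_perm=n_perm,
            seed=_derive_seed(base_seed, 4100 + i),
        )
        pvals.append(p)
    ks = stats.kstest(pvals, "uniform")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_datasets": n_datasets,
    }


# ---------------------------------------------------------------------------
# MDS


def mds_clustering_experiment(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Treatment-shaped fixtures (5 conditions x 2 replicates, planted
    effects): fraction of seeds where every pair of same-condition
    replicates are mutual nearest neighbours in MDS space.

    The embedding uses k = 4 components: five condition centroids span at
    most four dimensions, so this is the faithful MDS representation of the
    between-sample geometry (a 2-D scatter is only its visualisation and
    can superimpose well-separated clusters)."""
    hits = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=_derive_seed(base_seed, 5000 + i),
            n_chroms=2,
            chrom_length=10_000_000,
            n_genes=50,
            n_peaks_per_mark={"H3K27ac": 2000},
            replicates_per_condition=2,
            frac_dp=0.05,
            effect_log2fc=1.5,
            nb_dispersion=0.1,
            couple_prob=0.0,
            frac_deg_background=0.0,
            n_kdd=0,
        )
        bundle = simulate_dataset(cfg)
        cm = bundle.chip_counts["H3K27ac"]
        coords = similarity.classical_mds(
            similarity.sample_distances(cm, top_n=500), k=4
        )
        sheet = bundle.sample_sheet[bundle.sample_sheet["assay"] == "H3K27ac"]
        cond_of = dict(zip(sheet["sample_id"], sheet["condition"]))
        xy = coords.to_numpy()
        ids = list(coords.index)
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        nn = d.argmin(axis=1)
        ok = all(
            cond_of[ids[j]] == cond_of[ids[int(nn[j])]]
            and int(nn[int(nn[j])]) == j
            for j in range(len(ids))
        )
        hits += int(ok)
    return {"fraction_clustered": hits / n_seeds, "n_seeds": n_seeds}
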