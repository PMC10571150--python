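import json

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from epimark.synthetic import (
    CapacityError,
    SimulationConfig,
    SimulationTruth,
    simulate_dataset,
    simulate_genome,
    write_bundle,
)


class TestGenomeGeometry:
    def test_gene_count_bounds_and_spacing(self, small_bundle):
        genes = small_bundle.genes
        cfg = small_bundle.config
        assert len(genes) == cfg.n_genes
        assert (genes["tss"] < cfg.chrom_length).all()
        for _, sub in genes.groupby("chrom"):
            assert np.diff(np.sort(sub["tss"])).min() >= 5000

    def test_no_enhancer_links_when_fraction_zero(self):
        cfg = small_config(frac_enhancer_linked=0.0)
        _, _, imap = simulate_genome(cfg)
        assert len(imap) == 0

    def test_capacity_error_on_tiny_genome(self):
        cfg = small_config(n_chroms=1, chrom_length=20_000, n_genes=300)
        with pytest.raises(CapacityError):
            simulate_genome(cfg)

    def test_interaction_anchors_are_distal_peaks(self, small_bundle):
        k27 = {
            name: iv for name, iv in small_bundle.peaks["H3K27ac"]
        }
        for rec in small_bundle.interactions:
            assert any(iv == rec.distal_anchor for iv in k27.values())


class TestDeterminism:
    def test_identical_config_gives_identical_bundle(self, tmp_path):
        cfg = small_config(seed=42)
        a = tmp_path / "a"
        b = tmp_path / "b"
        write_bundle(simulate_dataset(cfg), a)
        write_bundle(simulate_dataset(small_config(seed=42)), b)
        for f in sorted(p.name for p in a.iterdir()):
            assert (a / f).read_bytes() == (b / f).read_bytes(), f

    def test_different_seed_changes_counts(self):
        a = simulate_dataset(small_config(seed=1))
        b = simulate_dataset(small_config(seed=2))
        assert not np.array_equal(
            a.chip_counts["H3K27ac"].values, b.chip_counts["H3K27ac"].values
        )


class TestTruth:
    def test_null_config_has_empty_truth(self):
        bundle = simulate_dataset(
            small_config(frac_dp=0.0, couple_prob=0.0, frac_deg_background=0.0)
        )
        assert all(len(v) == 0 for v in bundle.truth.dp.values())
        assert all(len(v) == 0 for v in bundle.truth.deg.values())

    def test_dp_truth_size_matches_fraction(self, small_bundle):
        cfg = small_bundle.config
        for (mark, _), signs in small_bundle.truth.dp.items():
            assert len(signs) == round(cfg.frac_dp * cfg.n_peaks_per_mark[mark])
            assert set(signs.values()) <= {-1, 1}

    def test_forced_coupling_makes_every_linked_planted_gene_a_deg(self):
        bundle = simulate_dataset(
            small_config(couple_prob=1.0, frac_deg_background=0.0)
        )
        for treat in bundle.config.treatments:
            planted = bundle.truth.dp[("H3K27ac", treat)]
            expected = {}
            for pid in sorted(planted):
                for g in bundle.truth.links.get(pid, ()):
                    expected.setdefault(g, planted[pid])
            assert bundle.truth.deg[treat] == expected

    def test_no_coupling_no_background_means_no_degs(self):
        bundle = simulate_dataset(
            small_config(couple_prob=0.0, frac_deg_background=0.0)
        )
        assert all(len(v) == 0 for v in bundle.truth.deg.values())

    def test_truth_json_round_trip(self, small_bundle, tmp_path):
        p = tmp_path / "truth.json"
        small_bundle.truth.to_json(p)
        back = SimulationTruth.from_json(p)
        assert back.dp == small_bundle.truth.dp
        assert back.deg == small_bundle.truth.deg
        assert back.kdd_domains == small_bundle.truth.kdd_domains


class TestCountModel:
    def test_planted_log2fc_recovered_analytically(self):
        # near-zero dispersion and high depth: empirical group-mean ratios of
        # planted peaks must sit at +/- the configured effect
        cfg = small_config(
            nb_dispersion=1e-9,
            baseline_logmean_mu=float(np.log(2000.0)),
            baseline_logmean_sd=0.2,
            effect_log2fc=2.0,
            frac_dp=0.2,
            lib_size_range=(1.0, 1.0),
            replicates_per_condition=3,
        )
        bundle = simulate_dataset(cfg)
        cm = bundle.chip_counts["H3K27ac"]
        sheet = bundle.sample_sheet
        sheet = sheet[sheet["assay"] == "H3K27ac"]
        treat = "Fe2O3"
        cols_t = list(sheet.loc[sheet["condition"] == treat, "sample_id"])
        cols_c = list(sheet.loc[sheet["condition"] == "control", "sample_id"])
        planted = bundle.truth.dp[("H3K27ac", treat)]
        errs = []
        for pid, sign in planted.items():
            row = cm.data.loc[pid]
            lfc = np.log2(row[cols_t].mean() / row[cols_c].mean())
            errs.append(lfc - sign * cfg.effect_log2fc)
        assert np.abs(np.mean(errs)) < 0.05
        assert np.max(np.abs(errs)) < 0.25

    def test_effects_touch_only_their_own_treatment(self):
        # a peak planted in one treatment but not another shows the shift
        # only in the contrast where it was planted
        cfg = small_config(
            nb_dispersion=1e-9,
            baseline_logmean_mu=float(np.log(2000.0)),
            baseline_logmean_sd=0.2,
            effect_log2fc=2.0,
            frac_dp=0.2,
            lib_size_range=(1.0, 1.0),
            replicates_per_condition=3,
        )
        bundle = simulate_dataset(cfg)
        cm = bundle.chip_counts["H3K27ac"]
        sheet = bundle.sample_sheet[bundle.sample_sheet["assay"] == "H3K27ac"]
        cols = {
            cond: list(sheet.loc[sheet["condition"] == cond, "sample_id"])
            for cond in cfg.conditions
        }
        in_a_only = set(bundle.truth.dp[("H3K27ac", "Fe2O3")]) - set(
            bundle.truth.dp[("H3K27ac", "FeSO4")]
        )
        assert in_a_only
        for pid in in_a_only:
            row = cm.data.loc[pid]
            lfc_other = np.log2(
                row[cols["FeSO4"]].mean() / row[cols["control"]].mean()
            )
            assert abs(lfc_other) < 0.3


class TestKddCoverage:
    def test_domain_bins_elevated(self, small_bundle):
        cfg = small_bundle.config
        track = small_bundle.coverage["control"]
        dom = small_bundle.truth.kdd_domains["control"][0]
        inside = track[
            (track["chrom"] == dom.chrom)
            & (track["start"] >= dom.start)
            & (track["end"] <= dom.end)
        ]
        assert len(inside) == dom.length // cfg.bin_size
        assert inside["value"].mean() > cfg.kdd_signal - 1.0

    def test_no_domains_gives_flat_background(self):
        bundle = simulate_dataset(small_config(n_kdd=0))
        track = bundle.coverage["control"]
        assert abs(track["value"].mean()) < 0.1
        assert abs(track["value"].std() - 1.0) < 0.1

    def test_zero_effect_keeps_domains_identical_across_conditions(self):
        bundle = simulate_dataset(small_config(kdd_effect=0.0))
        ctrl = bundle.truth.kdd_domains["control"]
        for treat in bundle.config.treatments:
            assert bundle.truth.kdd_domains[treat] == ctrl
            assert bundle.truth.kdd_changed[treat] == []


def test_invalid_config_rejected():
    with pytest.raises(Exception):
        SimulationConfig(frac_dp=1.5)
    with pytest.raises(Exception):
        SimulationConfig(replicates_per_condition=1)
    with pytest.raises(Exception):
        SimulationConfig(effect_log2fc=0.0)


def test_config_yaml_round_trip(tmp_path):
    cfg = small_config(seed=7)
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    assert SimulationConfig.from_yaml(p) == cfg
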