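import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimark import integration
from epimark.annotation import RegulatoryElement
from epimark.integration import (
    ActivationMatrix,
    ContingencyTable2x2,
    activation_status,
    build_activation_matrix,
    build_elements,
    crosstab_dp_deg,
    fisher_exact,
    promoter_fraction,
)
from epimark.io_core import GenomicInterval, ValidationError


def brute_force_fisher_p(a, b, c, d):
    """Independent oracle: exact rational hypergeometric enumeration."""
    r1, r2, k = a + b, c + d, a + c
    denom = math.comb(r1 + r2, k)
    obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, k - r2), min(k, r1) + 1):
        pr = Fraction(math.comb(r1, x) * math.comb(r2, k - x), denom)
        if pr <= obs:
            total += pr
    return float(min(total, Fraction(1)))


class TestCrosstab:
    def test_set_arithmetic(self):
        t = crosstab_dp_deg({"g1", "g2"}, {"g2", "g3"},
                            {"g1", "g2", "g3", "g4", "g5"})
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 2)

    def test_disjoint_sets(self):
        t = crosstab_dp_deg({"g1"}, {"g2"}, {"g1", "g2", "g3"})
        assert t.a == 0

    def test_full_overlap(self):
        u = {"g1", "g2"}
        t = crosstab_dp_deg(u, u, u)
        assert (t.b, t.c, t.d) == (0, 0, 0)

    def test_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            crosstab_dp_deg({"gX"}, set(), {"g1"})


class TestFisherExact:
    def test_symmetric_table(self):
        _, p = fisher_exact(ContingencyTable2x2(3, 1, 1, 3))
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_perfectly_separated_table(self):
        odds, p = fisher_exact(ContingencyTable2x2(0, 5, 5, 0))
        assert p == pytest.approx(2 / math.comb(10, 5), abs=1e-12)
        assert odds == 0.0

    def test_degenerate_margin_gives_p_one(self):
        odds, p = fisher_exact(ContingencyTable2x2(0, 0, 5, 5))
        assert p == 1.0
        assert math.isnan(odds)

    def test_odds_ratio_conventions(self):
        odds, _ = fisher_exact(ContingencyTable2x2(2, 0, 1, 3))
        assert odds == float("inf")
        odds, _ = fisher_exact(ContingencyTable2x2(6, 2, 3, 4))
        assert odds == pytest.approx(24 / 6)

    def test_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 11, size=4)
            _, p = fisher_exact(ContingencyTable2x2(a, b, c, d))
            assert p == brute_force_fisher_p(a, b, c, d), (a, b, c, d)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 30, size=4)
            _, p = fisher_exact(ContingencyTable2x2(a, b, c, d))
            p_scipy = stats.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(p_scipy, rel=1e-6), (a, b, c, d)


def ann_table(rows):
    return pd.DataFrame(rows, columns=["peak_id", "element_class", "gene_ids",
                                       "link_source"])


class TestPromoterFraction:
    def test_counts_outside_as_enhancer_plus_unannotated(self):
        tab = ann_table(
            [("p1", "promoter", "g1", "promoter_window"),
             ("p2", "enhancer", "g2", "interaction"),
             ("p3", "enhancer", "g3", "interaction"),
             ("p4", "unannotated", "", "")]
        )
        fin, fout = promoter_fraction(["p1", "p2", "p3", "p4"], tab)
        assert (fin, fout) == (0.25, 0.75)

    def test_all_promoter(self):
        tab = ann_table([("p1", "promoter", "g1", "promoter_window")])
        assert promoter_fraction(["p1"], tab) == (1.0, 0.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(10)
        classes = rng.choice(["promoter", "enhancer", "unannotated"], 50)
        tab = ann_table([(f"p{i}", c, "", "") for i, c in enumerate(classes)])
        fin, fout = promoter_fraction([f"p{i}" for i in range(50)], tab)
        assert fin + fout == pytest.approx(1.0, abs=1e-12)

    def test_empty_dp_set_rejected(self):
        with pytest.raises(ValidationError):
            promoter_fraction([], ann_table([]))


def element(eid, cls, start, end, genes, chrom="chr1"):
    return RegulatoryElement(
        eid, GenomicInterval(chrom, start, end), cls, tuple(genes),
        "promoter_window" if cls == "promoter" else "interaction",
    )


class TestElements:
    def test_overlapping_enhancer_peaks_merge(self):
        peaks = [
            element("p1", "enhancer", 100, 500, ["g1"]),
            element("p2", "enhancer", 400, 900, ["g2"]),
            element("p3", "enhancer", 5000, 5500, ["g1"]),
        ]
        els = build_elements(peaks)
        enh = [e for e in els if e.element_class == "enhancer"]
        assert len(enh) == 2
        merged = next(e for e in enh if len(e.peak_ids) == 2)
        assert merged.interval == GenomicInterval("chr1", 100, 900)
        assert set(merged.gene_ids) == {"g1", "g2"}

    def test_promoter_peaks_group_by_gene(self):
        peaks = [
            element("p1", "promoter", 100, 500, ["g1"]),
            element("p2", "promoter", 600, 900, ["g1"]),
        ]
        els = build_elements(peaks)
        assert len(els) == 1
        assert els[0].element_id == "prom:g1"
        assert els[0].peak_ids == ("p1", "p2")


class TestActivation:
    def status(self, mapping):
        return pd.Series(mapping)

    def test_gain_means_activated(self):
        el = build_elements([element("p1", "enhancer", 0, 100, ["g1"])])[0]
        calls = activation_status(el, {"T": self.status({"p1": "gained"})})
        assert calls[0].status == "activated"

    def test_mixed_gain_loss_is_ambiguous(self):
        els = build_elements(
            [element("p1", "enhancer", 0, 100, ["g1"]),
             element("p2", "enhancer", 50, 200, ["g1"])]
        )
        calls = activation_status(
            els[0], {"T": self.status({"p1": "gained", "p2": "lost"})}
        )
        assert calls[0].status == "ambiguous"

    def test_unaffected_elements_excluded_from_matrix(self):
        els = build_elements(
            [element("p1", "enhancer", 0, 100, ["g1"]),
             element("p2", "enhancer", 5000, 5100, ["g2"])]
        )
        act = build_activation_matrix(
            els,
            {"T": self.status({"p1": "gained"})},
            {"T": {"g1"}},
            require_deg=True,
        )
        assert list(act.matrix.index) == [
            e.element_id for e in els if "p1" in e.peak_ids
        ]
        assert act.summary["regulated_enhancers"] == 1
        assert act.summary["linked_genes"] == 1

    def test_require_deg_filters_elements_without_deg_link(self):
        els = build_elements([element("p1", "enhancer", 0, 100, ["g1"])])
        act = build_activation_matrix(
            els, {"T": self.status({"p1": "lost"})}, {"T": set()},
            require_deg=True,
        )
        assert len(act.matrix) == 0
        act2 = build_activation_matrix(
            els, {"T": self.status({"p1": "lost"})}, {"T": set()},
            require_deg=False,
        )
        assert act2.matrix.loc[els[0].element_id, "T"] == "repressed"
        assert act2.coded().loc[els[0].element_id, "T"] == "R"
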