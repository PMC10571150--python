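import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimark.differential import (
    Contrast,
    ContractError,
    NormalizationError,
    adjust_bh,
    call_status,
    estimate_common_dispersion,
    estimate_dispersion,
    normalize_counts,
    run_contrast,
)
from epimark.differential import test_differential as nb_wald_test
from epimark.io_core import CountMatrix, ValidationError


def matrix(arr, features=None, samples=None):
    arr = np.asarray(arr)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=features, columns=samples))


def sheet_for(samples, conditions, assay="mark"):
    reps: dict = {}
    rows = []
    for s, c in zip(samples, conditions):
        reps[c] = reps.get(c, 0) + 1
        rows.append({"sample_id": s, "condition": c, "replicate": reps[c],
                     "assay": assay})
    return pd.DataFrame(rows)


def nb_matrix(rng, n, mus, dispersion, libs=None):
    """NB counts with Var = mu + dispersion mu^2 per sample."""
    libs = np.ones(len(mus[0])) if libs is None else libs
    mean = np.asarray(mus) * libs
    if dispersion < 1e-8:
        return matrix(rng.poisson(mean))
    size = 1.0 / dispersion
    return matrix(rng.negative_binomial(size, size / (size + mean)))


class TestNormalization:
    def test_identical_samples_give_unit_factors(self):
        cm = matrix([[10, 10], [5, 5], [100, 100]])
        assert np.allclose(normalize_counts(cm), [1.0, 1.0])

    def test_proportional_columns_give_unit_factors(self):
        # doubling depth changes the library size, not the composition
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=200)
        cm = matrix(np.column_stack([base, 2 * base, 5 * base]))
        factors = normalize_counts(cm)
        assert np.allclose(factors, 1.0, atol=1e-12)
        eff = cm.values.sum(axis=0) * factors
        assert np.allclose(eff / eff[0], [1, 2, 5])

    def test_all_zero_rows_ignored(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 500, size=200)
        with_zeros = np.vstack(
            [np.column_stack([base, 2 * base]), np.zeros((50, 2), dtype=int)]
        )
        f1 = normalize_counts(matrix(np.column_stack([base, 2 * base])))
        f2 = normalize_counts(matrix(with_zeros))
        assert np.allclose(f1, f2)

    def test_disjoint_support_raises(self):
        # samples share no nonzero features with the reference
        cm = matrix([[5, 5, 0], [7, 6, 0], [0, 0, 9], [0, 0, 4]])
        with pytest.raises(NormalizationError):
            normalize_counts(cm)

    def test_factors_have_unit_geometric_mean(self):
        rng = np.random.default_rng(2)
        cm = matrix(rng.integers(0, 300, size=(500, 4)))
        f = normalize_counts(cm)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank, _ in enumerate(order):
        q_sorted[rank] = min(
            m * p[order[j]] / (j + 1) for j in range(rank, m)
        )
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_degenerate_vectors(self):
        assert np.allclose(adjust_bh([0.2]), [0.2])
        assert np.allclose(adjust_bh([1.0] * 7), [1.0] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.2])
        with pytest.raises(ValidationError):
            adjust_bh([-0.1])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=60,
        )
    )
    def test_matches_brute_force_step_up(self, p):
        assert np.allclose(adjust_bh(p), brute_force_bh(p), rtol=0, atol=1e-12)


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        mus = np.tile(rng.uniform(500, 2000, 1000)[:, None], (1, 6))
        cm = nb_matrix(rng, 1000, mus, 0.0)
        sh = sheet_for(cm.sample_ids, ["t"] * 3 + ["c"] * 3)
        d = estimate_dispersion(cm, sh, Contrast("t", "c", "mark"))
        assert np.median(d) <= 0.05

    def test_constant_counts_hit_floor(self):
        cm = matrix(np.full((10, 4), 7))
        sh = sheet_for(cm.sample_ids, ["t", "t", "c", "c"])
        d = estimate_dispersion(cm, sh, Contrast("t", "c", "mark"))
        assert np.allclose(d, 1e-4)

    def test_common_dispersion_recovered_within_tolerance(self):
        rng = np.random.default_rng(4)
        true = 0.2
        mus = np.tile(np.exp(rng.normal(np.log(200), 1.0, 2000))[:, None], (1, 6))
        cm = nb_matrix(rng, 2000, mus, true)
        sh = sheet_for(cm.sample_ids, ["t"] * 3 + ["c"] * 3)
        est = estimate_common_dispersion(cm, sh, Contrast("t", "c", "mark"))
        assert abs(est - true) < 0.05


class TestWaldTest:
    def test_identical_groups_give_null_result(self):
        arr = np.tile([[10], [100], [7]], (1, 4))
        cm = matrix(arr)
        sh = sheet_for(cm.sample_ids, ["t", "t", "c", "c"])
        res = nb_wald_test(cm, sh, Contrast("t", "c", "mark"),
                                dispersions=np.full(3, 0.1))
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_all_zero_features_dropped(self):
        cm = matrix([[5, 6, 4, 5], [0, 0, 0, 0]])
        sh = sheet_for(cm.sample_ids, ["t", "t", "c", "c"])
        res = nb_wald_test(cm, sh, Contrast("t", "c", "mark"),
                                dispersions=np.full(2, 0.1))
        assert list(res["feature_id"]) == ["f0"]

    def test_swapping_groups_negates_lfc_and_keeps_p(self):
        rng = np.random.default_rng(5)
        mus = np.tile(rng.uniform(50, 500, 300)[:, None], (1, 6))
        cm = nb_matrix(rng, 300, mus, 0.1)
        sh_fwd = sheet_for(cm.sample_ids, ["a"] * 3 + ["b"] * 3)
        fwd = run_contrast(cm, sh_fwd, Contrast("a", "b", "mark"))
        rev = run_contrast(cm, sh_fwd, Contrast("b", "a", "mark"))
        fwd = fwd.set_index("feature_id")
        rev = rev.set_index("feature_id").loc[fwd.index]
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_too_few_replicates_rejected(self):
        cm = matrix([[5, 6, 4]])
        sh = sheet_for(cm.sample_ids, ["t", "c", "c"])
        with pytest.raises(ContractError):
            nb_wald_test(cm, sh, Contrast("t", "c", "mark"))

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(6)
        n, planted = 1000, 100
        base = np.exp(rng.normal(np.log(200), 1.0, n))
        fc = np.ones((n, 6))
        signs = np.zeros(n)
        idx = rng.choice(n, planted, replace=False)
        signs[idx] = rng.choice([-1, 1], planted)
        fc[idx, :3] = 2.0 ** (signs[idx, None] * 1.5)
        cm = nb_matrix(rng, n, base[:, None] * fc, 0.1)
        sh = sheet_for(cm.sample_ids, ["t"] * 3 + ["c"] * 3)
        res = run_contrast(cm, sh, Contrast("t", "c", "mark")).set_index("feature_id")
        true_ids = [f"f{i}" for i in idx]
        est = res.loc[true_ids, "log2fc"].to_numpy() * signs[idx]
        assert abs(est.mean() - 1.5) < 0.15


class TestStatusCall:
    @pytest.mark.parametrize(
        "fdr,log2fc,expected",
        [
            (0.05, 0.5, "gained"),
            (0.05, -0.5, "lost"),
            (0.05, 0.2, "unchanged"),   # fails the |log2FC| > 0.3 gate
            (0.15, 2.0, "unchanged"),   # fails the FDR < 0.1 gate
        ],
    )
    def test_two_gate_rule(self, fdr, log2fc, expected, monkeypatch):
        res = pd.DataFrame(
            {"feature_id": ["x"], "mean_logcpm": [5.0], "log2fc": [log2fc],
             "pvalue": [fdr]}
        )
        # single feature: BH leaves the p-value unchanged
        out = call_status(res, fdr_threshold=0.1, lfc_threshold=0.3)
        assert out.loc[0, "status"] == expected

    def test_rna_mode_uses_fdr_gate_only(self):
        res = pd.DataFrame(
            {"feature_id": ["x"], "mean_logcpm": [5.0], "log2fc": [0.2],
             "pvalue": [0.01]}
        )
        out = call_status(res, fdr_threshold=0.1, lfc_threshold=0.0)
        assert out.loc[0, "status"] == "gained"

    def test_status_consistent_with_gates(self):
        rng = np.random.default_rng(7)
        res = pd.DataFrame(
            {
                "feature_id": [f"f{i}" for i in range(500)],
                "mean_logcpm": np.zeros(500),
                "log2fc": rng.normal(0, 1, 500),
                "pvalue": rng.uniform(0, 1, 500),
            }
        )
        out = call_status(res)
        called = out[out["status"] != "unchanged"]
        assert (called["fdr"] < 0.1).all()
        assert (called["log2fc"].abs() > 0.3).all()
        assert (
            np.sign(called["log2fc"])
            == called["status"].map({"gained": 1, "lost": -1})
        ).all()
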