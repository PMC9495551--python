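import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernamod import diffexpr
from .conftest import small_config
from cernamod.simulate import generate_dataset

# edgeR 4.0.16 calcNormFactors(method="TMM") on the matrix built below
EDGER_FACTORS = [
    1.0825805367, 0.7138543872, 1.0502490872, 1.0794848667, 1.0704060522, 1.0662835891,
]


def composition_shift_matrix() -> pd.DataFrame:
    """60 x 6 Poisson matrix; sample 2 has 10% of features 8-fold up."""
    rng = np.random.default_rng(12345)
    mu = np.exp(rng.uniform(np.log(10), np.log(500), size=60))
    lib = np.array([1.0, 1.3, 0.8, 1.1, 0.6, 1.5])
    m = mu[:, None] * lib[None, :]
    m[:6, 1] *= 8
    return pd.DataFrame(rng.poisson(m))


def brute_force_tmm(counts: pd.DataFrame) -> np.ndarray:
    """Direct, sort-based transcription of the trimmed-mean definition."""
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    q = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(q - q.mean())))
    out = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        keep = (x[:, j] > 0) & (x[:, ref] > 0)
        obs, r = x[keep, j], x[keep, ref]
        m = np.log2((obs / lib[j]) / (r / lib[ref]))
        a = 0.5 * (np.log2(obs / lib[j]) + np.log2(r / lib[ref]))
        w = 1.0 / ((lib[j] - obs) / (lib[j] * obs) + (lib[ref] - r) / (lib[ref] * r))
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        import scipy.stats

        rm, ra = scipy.stats.rankdata(m), scipy.stats.rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        out[j] = 2.0 ** (np.sum(m[sel] * w[sel]) / np.sum(w[sel]))
    return out / np.exp(np.mean(np.log(out)))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 80, 13, 0, 400, 7])
        counts = pd.DataFrame(np.tile(col[:, None], (1, 4)))
        f = diffexpr.compute_tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_matches_edger_on_composition_shift(self):
        f = diffexpr.compute_tmm_factors(composition_shift_matrix())
        assert np.allclose(f.to_numpy(), EDGER_FACTORS, atol=1e-8)

    def test_matches_brute_force_reimplementation(self):
        counts = composition_shift_matrix()
        f = diffexpr.compute_tmm_factors(counts)
        assert np.allclose(f.to_numpy(), brute_force_tmm(counts), atol=1e-12)

    def test_invariant_to_global_scaling(self):
        counts = composition_shift_matrix()
        f1 = diffexpr.compute_tmm_factors(counts)
        f2 = diffexpr.compute_tmm_factors(counts * 3)
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-9)

    def test_all_zero_sample_names_sample(self):
        counts = pd.DataFrame({"ok": [1, 2, 3], "dead": [0, 0, 0]})
        with pytest.raises(ValueError, match="dead"):
            diffexpr.compute_tmm_factors(counts)

    def test_doubling_one_library_leaves_logcpm_unchanged(self):
        # depth cancels in x/N, so trimmed ratios are depth-free; exact with
        # unweighted factors (precision weights depend on absolute depth)
        counts = composition_shift_matrix()
        doubled = counts.copy()
        doubled[1] = doubled[1] * 2
        l1 = diffexpr.normalize_logcpm(
            counts, diffexpr.compute_tmm_factors(counts, weighted=False)
        )
        l2 = diffexpr.normalize_logcpm(
            doubled, diffexpr.compute_tmm_factors(doubled, weighted=False)
        )
        assert np.allclose(l1[1], l2[1], atol=1e-6)
        # with the default weights the shift is a sub-1% constant offset
        w1 = diffexpr.normalize_logcpm(counts, diffexpr.compute_tmm_factors(counts))
        w2 = diffexpr.normalize_logcpm(doubled, diffexpr.compute_tmm_factors(doubled))
        assert np.abs(w1[1] - w2[1]).max() < 0.01

    def test_global_scaling_leaves_logcpm_unchanged(self):
        counts = composition_shift_matrix()
        l1 = diffexpr.normalize_logcpm(counts, diffexpr.compute_tmm_factors(counts))
        l2 = diffexpr.normalize_logcpm(counts * 4, diffexpr.compute_tmm_factors(counts * 4))
        assert np.allclose(l1.to_numpy(), l2.to_numpy(), atol=1e-6)


class TestLogCPM:
    def test_closed_form_unit_library(self):
        counts = pd.DataFrame({"s": [10**6]})
        f = pd.Series([1.0], index=["s"])
        val = diffexpr.normalize_logcpm(counts, f).iloc[0, 0]
        assert val == pytest.approx(np.log2(10**6 + 0.5), abs=1e-9)  # ~19.93

    def test_zero_count_is_finite(self):
        counts = pd.DataFrame({"s1": [0, 100], "s2": [3, 50]})
        vals = diffexpr.normalize_logcpm(counts, diffexpr.compute_tmm_factors(counts))
        assert np.isfinite(vals.to_numpy()).all()

    def test_permuting_samples_permutes_columns(self):
        counts = composition_shift_matrix()
        f = diffexpr.compute_tmm_factors(counts)
        l1 = diffexpr.normalize_logcpm(counts, f)
        perm = [3, 0, 5, 1, 4, 2]
        l2 = diffexpr.normalize_logcpm(counts[perm], f[perm])
        pd.testing.assert_frame_equal(l2, l1[perm])


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(diffexpr.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert diffexpr.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_ties_all_equal(self):
        assert np.allclose(diffexpr.bh_adjust([0.2] * 5), 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([0.1, 1.5])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        adj = diffexpr.bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_brute_force_step_up(self, pvals):
        p = np.asarray(pvals)
        assert np.allclose(diffexpr.bh_adjust(p), brute_force_bh(p), atol=1e-12)


def _paired_dataset(seed=0, n_pairs=50, n_features=200, planted=None):
    """Small paired count matrix with optional planted log2 fold changes."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(30), np.log(300), size=n_features))
    shift = np.zeros(n_features)
    if planted:
        for idx, lfc in planted.items():
            shift[idx] = lfc
    cols, names, meta = [], [], []
    for cond, sgn in (("tumor", 0.5), ("normal", -0.5)):
        mean = mu[:, None] * 2 ** (shift[:, None] * sgn)
        cols.append(rng.poisson(np.tile(mean, (1, n_pairs))))
        names += [f"{cond[0]}{i}" for i in range(n_pairs)]
        meta += [(f"{cond[0]}{i}", cond, f"p{i}") for i in range(n_pairs)]
    counts = pd.DataFrame(np.hstack(cols), columns=names)
    samples = pd.DataFrame(meta, columns=["sample_id", "condition", "pair_id"])
    return counts, samples


class TestDifferential:
    def test_planted_positive_effect_called_up(self):
        counts, samples = _paired_dataset(seed=1, planted={0: 2.0, 1: -2.0})
        table = diffexpr.test_differential(counts, samples)
        assert table.iloc[0]["direction"] == "up"
        assert table.iloc[1]["direction"] == "down"
        assert table.iloc[0]["log2fc"] == pytest.approx(2.0, abs=0.4)

    def test_small_fold_change_gated_out_despite_significance(self):
        counts, samples = _paired_dataset(seed=2, n_pairs=300, planted={0: 0.5})
        table = diffexpr.test_differential(counts, samples)
        row = table.iloc[0]
        assert row["pvalue"] < 1e-6 and abs(row["log2fc"]) < 1.0
        assert row["direction"] == "none"

    def test_constant_normalized_expression_p_one(self):
        # identical columns: every per-pair difference is exactly zero
        _, samples = _paired_dataset(seed=3, n_pairs=10, n_features=5)
        col = np.array([7, 80, 13, 200, 4])
        counts = pd.DataFrame(
            np.tile(col[:, None], (1, 20)), columns=samples["sample_id"]
        )
        table = diffexpr.test_differential(counts, samples)
        assert (table["pvalue"] == 1.0).all()
        assert (table["direction"] == "none").all()

    def test_fdr_dominates_p_and_directions_respect_thresholds(self):
        counts, samples = _paired_dataset(seed=4, planted={i: 2.0 for i in range(5)})
        t = diffexpr.test_differential(counts, samples)
        assert (t["fdr"] >= t["pvalue"] - 1e-12).all()
        called = t["direction"] != "none"
        assert ((t.loc[called, "fdr"] < 0.05) & (t.loc[called, "log2fc"].abs() > 1)).all()

    def test_requires_three_pairs(self):
        counts, samples = _paired_dataset(seed=5, n_pairs=2, n_features=10)
        with pytest.raises(ValueError, match="3"):
            diffexpr.test_differential(counts, samples)


class TestStability:
    def test_single_round_full_fraction_equals_single_pass(self):
        counts, samples = _paired_dataset(seed=6, planted={0: 2.0, 3: 2.0})
        single = diffexpr.test_differential(counts, samples)
        stab = diffexpr.stability_select(counts, samples, rounds=1, fraction=1.0, seed=9)
        assert (stab["stable"] == (single["direction"] != "none")).all()

    def test_intersection_monotone_in_rounds(self):
        counts, samples = _paired_dataset(seed=7, planted={i: 1.2 for i in range(10)})
        sets = []
        for rounds in (2, 5, 9):
            t = diffexpr.stability_select(counts, samples, rounds=rounds, fraction=0.8, seed=5)
            sets.append(set(t.index[t["stable"]]))
        assert sets[2] <= sets[1] <= sets[0]

    def test_subsample_too_small_rejected(self):
        counts, samples = _paired_dataset(seed=8, n_pairs=3, n_features=10)
        with pytest.raises(ValueError, match="small"):
            diffexpr.stability_select(counts, samples, rounds=2, fraction=0.5, seed=0)


def test_missing_value_filter_counts_na_not_zero():
    mat = pd.DataFrame(np.ones((4, 6)))
    mat.iloc[0, :3] = np.nan   # half missing
    mat.iloc[1, :] = 0.0       # zeros are observations
    kept = diffexpr.drop_missing_features(mat, max_missing_fraction=1 / 3)
    assert list(kept.index) == [1, 2, 3]
    kept2 = diffexpr.drop_missing_features(mat, max_missing=2)
    assert list(kept2.index) == [1, 2, 3]
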