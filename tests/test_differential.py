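"""Moderated-t machinery: shrinkage estimation, closed forms, BH adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phosphosig.differential import (
    EBHyperparams,
    PairedDiffMatrix,
    bh_adjust,
    estimate_eb_hyperparams,
    moderated_t,
    pair_differences,
    paired_moderated_t,
    trigamma_inverse,
    two_group_contrast,
)
from phosphosig.errors import DesignError, FormatError
from phosphosig.io_formats import FeatureRecord, IntensityMatrix, SampleDesign


def _diffs(deltas, features=None):
    deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
    features = features or [f"F{i}" for i in range(deltas.shape[0])]
    pairs = [f"P{j}" for j in range(deltas.shape[1])]
    return PairedDiffMatrix(features, pairs, deltas)


class TestPairDifferences:
    def _matrix_and_design(self, be_vals, adj_vals):
        n = len(be_vals)
        feats = [FeatureRecord("F0", "G0", "protein")]
        samples, design, cols = [], [], []
        for i, (b, a) in enumerate(zip(be_vals, adj_vals)):
            design.append(SampleDesign(f"P{i}_BE", f"P{i}", "BE", "discovery", f"c{2 * i}"))
            design.append(SampleDesign(f"P{i}_ADJ", f"P{i}", "ADJ", "discovery", f"c{2 * i + 1}"))
            samples += [f"P{i}_BE", f"P{i}_ADJ"]
            cols += [b, a]
        m = IntensityMatrix(feats, samples, np.array([cols], dtype=float), scale="log2")
        return m, design

    def test_delta_is_be_minus_adj(self):
        m, design = self._matrix_and_design([5.0], [3.0])
        diffs = pair_differences(m, design)
        assert diffs.deltas[0, 0] == 2.0

    def test_pair_with_member_missing_from_matrix_rejected(self):
        m, design = self._matrix_and_design([5.0], [3.0])
        incomplete = m.subset_samples(["P0_BE"])
        with pytest.raises(DesignError):
            pair_differences(incomplete, design)

    def test_identical_be_and_adj_gives_zero(self):
        m, design = self._matrix_and_design([4.0, 7.0], [4.0, 7.0])
        diffs = pair_differences(m, design)
        np.testing.assert_array_equal(diffs.deltas, 0.0)

    def test_one_column_per_pair(self):
        m, design = self._matrix_and_design([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        diffs = pair_differences(m, design)
        assert diffs.n_pairs == 3
        assert diffs.pairs == ["P0", "P1", "P2"]


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.05, 0.3, 1.0, 4.0, 40.0])
    def test_round_trip(self, x):
        from scipy.special import polygamma

        y = float(polygamma(1, x))
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestHyperparamEstimation:
    def test_identical_variances_give_infinite_prior_df(self):
        """Zero spread of log s^2 means infinite shrinkage; the prior scale
        applies the Fisher-consistent log-variance bias correction
        exp(log(d/2) - digamma(d/2)) to the common value."""
        from scipy.special import digamma

        hyper = estimate_eb_hyperparams(np.full(100, 0.25), d=4)
        assert np.isinf(hyper.d0)
        correction = np.exp(np.log(2.0) - digamma(2.0))
        assert hyper.s0_sq == pytest.approx(0.25 * correction)

    def test_heterogeneous_variances_give_finite_prior_df(self):
        hyper = estimate_eb_hyperparams(np.array([1e-3, 1.0, 10.0, 0.2]), d=4)
        assert np.isfinite(hyper.d0) and hyper.d0 > 0

    def test_recovers_generating_hyperparameters(self):
        """Hierarchical model s^2 ~ s0^2 * d0/chi2(d0) * chi2(d)/d with
        s0^2 = 1, d0 = 8, d = 4: moment matching recovers both."""
        rng = np.random.default_rng(42)
        n, d, d0_true, s0_true = 20000, 4, 8.0, 1.0
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=n)
        s2 = sigma2 * rng.chisquare(d, size=n) / d
        hyper = estimate_eb_hyperparams(s2, d=d)
        assert hyper.s0_sq == pytest.approx(s0_true, rel=0.05)
        assert hyper.d0 == pytest.approx(d0_true, rel=0.25)

    def test_too_few_features_rejected(self):
        with pytest.raises(FormatError):
            estimate_eb_hyperparams(np.array([0.5]), d=4)

    def test_non_positive_variance_rejected(self):
        with pytest.raises(FormatError):
            estimate_eb_hyperparams(np.array([0.5, 0.0]), d=4)


class TestModeratedT:
    def test_closed_form_with_infinite_shrinkage(self):
        res = moderated_t(_diffs([[1.0, 1.0, 1.0]]),
                          EBHyperparams(d0=float("inf"), s0_sq=0.25))
        t_expected = 1.0 / (0.5 / np.sqrt(3))
        assert res[0].t_mod == pytest.approx(t_expected)
        assert res[0].p_value == pytest.approx(2 * stats.norm.sf(t_expected))

    def test_zero_deltas_flagged_with_p_one(self):
        res = moderated_t(_diffs([[0.0, 0.0, 0.0]]),
                          EBHyperparams(d0=4.0, s0_sq=0.25))
        assert res[0].zero_variance
        assert res[0].p_value == 1.0

    def test_no_shrinkage_limit_equals_classical_paired_t(self):
        """d0 -> inf with s0^2 set to each feature's own variance reproduces
        the ordinary paired t-statistic."""
        rng = np.random.default_rng(0)
        deltas = rng.normal(0.3, 1.0, size=(200, 6))
        s2 = deltas.var(axis=1, ddof=1)
        res = moderated_t(_diffs(deltas), EBHyperparams(d0=float("inf"), s0_sq=s2))
        t_classic = stats.ttest_1samp(deltas, 0.0, axis=1).statistic
        np.testing.assert_allclose([r.t_mod for r in res], t_classic, atol=1e-10)

    def test_monotone_in_effect_at_fixed_variance(self):
        hyper = EBHyperparams(d0=4.0, s0_sq=0.25)
        base = np.array([-1.0, 0.0, 1.0])  # variance fixed, mean 0
        ts = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            res = moderated_t(_diffs([base + shift]), hyper)
            ts.append(abs(res[0].t_mod))
        assert np.all(np.diff(ts) > 0)

    def test_single_pair_rejected(self):
        with pytest.raises(DesignError):
            moderated_t(_diffs([[1.0]]), EBHyperparams(d0=1.0, s0_sq=1.0))


class TestBH:
    def test_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_p_values_unchanged(self):
        q = bh_adjust(np.full(7, 0.2))
        np.testing.assert_allclose(q, 0.2)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]])
    def test_out_of_domain_rejected(self, bad):
        with pytest.raises(FormatError):
            bh_adjust(np.array(bad))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 60))
        q = bh_adjust(p)
        # independent brute force: q_i = min_{p_(j) >= p_i} m * p_(j) / j
        m = p.size
        order = np.argsort(p)
        sorted_p = p[order]
        expected = np.empty(m)
        for i in range(m):
            candidates = [
                m * sorted_p[j] / (j + 1) for j in range(m) if sorted_p[j] >= p[i] - 1e-15
            ]
            expected[i] = min(1.0, min(candidates))
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestTwoGroupContrast:
    def _dataset(self, seed=0, **kw):
        from conftest import tiny_config
        from phosphosig import simulate_dataset
        from phosphosig.preprocessing import preprocess_matrix

        cfg = tiny_config(seed=seed, **kw)
        proteome, _, design, *_ = simulate_dataset(cfg)
        disc = [d.sample_id for d in design if d.cohort == "discovery"]
        norm, _ = preprocess_matrix(proteome.subset_samples(disc), design)
        return norm, design

    def test_identical_group_means_give_zero_t(self):
        feats = [FeatureRecord(f"F{i}", f"G{i}", "protein") for i in range(3)]
        rng = np.random.default_rng(3)
        half = rng.normal(size=(3, 3))
        vals = np.column_stack([half, half])  # NONBE samples mirror ADJ exactly
        design = [
            SampleDesign(f"A{i}", f"pa{i}", "ADJ", "discovery", f"c{i}") for i in range(3)
        ] + [
            SampleDesign(f"N{i}", f"pn{i}", "NONBE", "discovery", f"d{i}") for i in range(3)
        ]
        # ADJ requires a BE partner; use NONBE-vs-NONBE-like classes via design
        # with valid pairing: give each ADJ patient a BE sample not in matrix
        design += [
            SampleDesign(f"B{i}", f"pa{i}", "BE", "discovery", f"e{i}") for i in range(3)
        ]
        m = IntensityMatrix(feats, [f"A{i}" for i in range(3)] + [f"N{i}" for i in range(3)],
                            vals, scale="log2")
        res = two_group_contrast(m, design, "ADJ", "NONBE")
        assert all(r.log2fc == pytest.approx(0.0) for r in res)
        assert all(abs(r.t_mod) < 1e-10 or r.zero_variance for r in res)

    def test_replicate_biopsies_collapse_to_patients(self):
        norm, design = self._dataset()
        res = two_group_contrast(norm, design, "ADJ", "NONBE")
        assert len(res) == norm.n_features
        # discovery: 3 ADJ patients vs 2 control patients -> d = 3
        assert all(np.isfinite(r.p_value) for r in res)

    def test_class_with_single_unit_rejected(self):
        norm, design = self._dataset()
        with pytest.raises(DesignError):
            two_group_contrast(norm, design, "ADJ", "BE_MISSING")


def test_paired_moderated_t_null_pvalues_roughly_uniform(tiny_normalized):
    """Sanity screen on the tiny fixture: planted features are ~1%, so the
    bulk of p-values should look uniform (coarse bound; the rigorous KS
    check runs on a dedicated null simulation in the acceptance suite)."""
    norm, _, design = tiny_normalized
    res, hyper = paired_moderated_t(pair_differences(norm, design))
    p = np.array([r.p_value for r in res if not r.zero_variance])
    assert hyper.d0 > 0
    assert 0.25 < (p < 0.5).mean() / 0.5 < 1.75
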