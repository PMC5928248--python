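"""GLM fitting, contrasts, cluster inference and decoding metrics."""

import numpy as np
import pytest
from scipy import stats

from rtnf.decoder import DecisionTrace
from rtnf.errors import DesignError
from rtnf.glm import (
    GLM,
    build_design,
    cluster_inference,
    contrast_t,
    drop_initial,
    paired_compare,
    tpv_and_accuracy,
)
from rtnf.paradigm import Condition, default_paradigm
from rtnf.phantom import canonical_hrf


class TestDropInitial:
    def test_paper_discard_leaves_250(self, paper_paradigm):
        series = np.zeros((4, 4, 3, 255))
        out, labels = drop_initial(series, 5, paper_paradigm.labels)
        assert out.shape[-1] == 250
        assert len(labels) == 250
        assert labels[0] is paper_paradigm.labels[5]

    def test_zero_is_identity(self):
        series = np.arange(24.0).reshape(2, 2, 2, 3)
        np.testing.assert_array_equal(drop_initial(series, 0), series)

    def test_dropping_everything_rejected(self):
        with pytest.raises(ValueError):
            drop_initial(np.zeros((2, 2, 2, 10)), 10)


def simple_fit(n=40, n_vox=30, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.linspace(-1, 1, n), np.ones(n)])
    beta_true = rng.normal(0, 2, (2, n_vox))
    Y = X @ beta_true + noise * rng.standard_normal((n, n_vox))
    from rtnf.glm import DesignMatrix

    design = DesignMatrix(X, ["slope", "intercept"])
    return GLM(Y=Y, design=design).fit(), beta_true


class TestFitGlm:
    def test_noiseless_recovery_is_exact(self):
        fit, beta_true = simple_fit(noise=0.0)
        np.testing.assert_allclose(fit.beta, beta_true, atol=1e-8)
        np.testing.assert_allclose(fit.sigma2, 0, atol=1e-16)

    def test_duplicated_regressor_rejected_by_name(self):
        from rtnf.glm import DesignMatrix

        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(DesignError, match="collinear"):
            DesignMatrix(X, ["a", "a_copy"])

    def test_type_one_error_calibrated(self):
        """Pure-noise t-statistics exceed the alpha=0.001 threshold at rate 0.001."""
        n, n_vox = 250, 4000
        rng = np.random.default_rng(3)
        from rtnf.glm import DesignMatrix

        X = np.column_stack([rng.standard_normal(n), np.ones(n)])
        design = DesignMatrix(X, ["reg", "intercept"])
        fit = GLM(Y=rng.standard_normal((n, n_vox)), design=design).fit()
        cm = fit.contrast([1.0, 0.0])
        alpha = 0.001
        crit = stats.t.ppf(1 - alpha / 2, fit.df)
        rate = (np.abs(cm.t) > crit).mean()
        se = np.sqrt(alpha * (1 - alpha) / n_vox)
        assert abs(rate - alpha) < 3 * se

    def test_residuals_orthogonal_to_design(self):
        fit, _ = simple_fit(noise=2.0)
        xr = fit.design.matrix.T @ fit.residuals
        scale = np.abs(fit.design.matrix).sum() * np.abs(fit.residuals).max()
        assert np.abs(xr).max() / scale < 1e-6


class TestContrast:
    def test_zero_contrast_gives_zero_t(self):
        fit, _ = simple_fit()
        cm = fit.contrast([0.0, 0.0])
        assert np.all(cm.t == 0)

    def test_sign_flip_negates_t_exactly(self):
        fit, _ = simple_fit()
        t_pos = fit.contrast([1.0, 0.0]).t
        t_neg = fit.contrast([-1.0, 0.0]).t
        np.testing.assert_array_equal(t_neg, -t_pos)

    def test_two_sample_t_matches_hand_oracle(self):
        # y = [1,2,3,4] on intercept + group indicator equals pooled two-sample t
        y = np.array([1.0, 2.0, 3.0, 4.0])[:, None]
        X = np.column_stack([np.ones(4), np.array([0.0, 0, 1, 1])])
        from rtnf.glm import DesignMatrix

        fit = GLM(Y=y, design=DesignMatrix(X, ["intercept", "group"])).fit()
        t_glm = fit.contrast([0.0, 1.0]).t[0]
        g1, g2 = y[:2, 0], y[2:, 0]
        sp2 = (np.var(g1, ddof=1) + np.var(g2, ddof=1)) / 2
        t_hand = (g2.mean() - g1.mean()) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        assert t_glm == pytest.approx(t_hand, rel=1e-12)


def masked_noise_fit(seed, shape=(12, 12, 8), n=120, signal=None):
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=bool)
    series = rng.standard_normal(shape + (n,))
    labels = default_paradigm().labels[:n]
    if signal is not None:
        conv = np.convolve((labels == Condition.LGO).astype(float),
                           canonical_hrf(2.0))[:n]
        series[signal] += 20 * conv
    design = build_design(labels, 2.0)
    return GLM.from_series(series, mask, design).fit(), design


class TestClusterInference:
    def test_subthreshold_map_gives_empty_table(self):
        fit, design = masked_noise_fit(0)
        cm = fit.contrast(design.contrast_vector({"LGO": 1.0}))
        cm.t = np.zeros_like(cm.t)   # force everything below threshold
        table = cluster_inference(cm, n_perm=100, seed=0)
        assert table.empty

    def test_cubic_blob_detected_as_single_cluster_of_27(self):
        sig = (slice(4, 7), slice(4, 7), slice(2, 5), slice(None))
        fit, design = masked_noise_fit(1, signal=sig)
        cm = fit.contrast(design.contrast_vector({"LGO": 1.0}))
        table = cluster_inference(cm, n_perm=150, seed=1)
        big = table[table["size"] >= 5]
        assert len(big) == 1
        assert big.iloc[0]["size"] == 27
        assert big.iloc[0]["significant"]

    def test_corrected_p_monotone_in_cluster_size(self):
        sig = (slice(4, 7), slice(4, 7), slice(2, 5), slice(None))
        fit, design = masked_noise_fit(2, signal=sig)
        cm = fit.contrast(design.contrast_vector({"LGO": 1.0}))
        table = cluster_inference(cm, cdt_p=0.05, n_perm=150, seed=2)
        ordered = table.sort_values("size", ascending=False)
        p = ordered["p_corrected"].to_numpy()
        assert (np.diff(p) >= 0).all()

    def test_small_n_perm_warns(self):
        fit, design = masked_noise_fit(3)
        cm = fit.contrast(design.contrast_vector({"LGO": 1.0}))
        with pytest.warns(UserWarning, match="n_perm"):
            cluster_inference(cm, n_perm=50, seed=0)


def make_trace(true, predicted, contrast="REST_vs_LGO"):
    n = len(true)
    return DecisionTrace(
        contrast=contrast,
        volume=np.arange(n),
        raw=np.zeros(n),
        detrended=np.zeros(n),
        predicted=np.array([Condition(c) for c in predicted], dtype=object),
        true_condition=np.array([Condition(c) for c in true], dtype=object),
    )


class TestMetrics:
    def test_tpv_definition_arithmetic(self):
        true = ["LGO"] * 120 + ["REST"] * 80
        predicted = ["LGO"] * 96 + ["REST"] * 24 + ["REST"] * 80
        m = tpv_and_accuracy(make_trace(true, predicted))
        assert m["tpv"] == pytest.approx(96 / 120)

    def test_perfect_classifier(self):
        true = ["LGO"] * 30 + ["REST"] * 30
        m = tpv_and_accuracy(make_trace(true, true))
        assert m["tpv"] == 1.0 and m["accuracy"] == 1.0

    def test_task_task_contrast_accuracy(self):
        true = ["LGO"] * 60 + ["RGO"] * 60
        predicted = ["LGO"] * 40 + ["RGO"] * 20 + ["RGO"] * 30 + ["LGO"] * 30
        m = tpv_and_accuracy(make_trace(true, predicted, "LGO_vs_RGO"))
        assert m["accuracy"] == pytest.approx(70 / 120)

    def test_other_condition_volumes_excluded(self):
        true = ["LGO"] * 10 + ["RGO"] * 10 + ["REST"] * 10
        predicted = ["LGO"] * 30
        m = tpv_and_accuracy(make_trace(true, predicted, "REST_vs_LGO"))
        assert m["n_scored"] == 20   # RGO volumes are not scored
        assert m["tpv"] == 1.0

    def test_no_task_volumes_rejected(self):
        true = ["REST"] * 10
        with pytest.raises(ValueError):
            tpv_and_accuracy(make_trace(true, true))


class TestPairedCompare:
    def test_identical_inputs(self):
        assert paired_compare([1.0, 2, 3], [1.0, 2, 3]) == (0.0, 1.0)

    def test_closed_form_example(self):
        t, p = paired_compare([2.0, 4, 6], [1.0, 2, 3])
        assert t == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-4)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(0.0742, abs=5e-4)

    def test_antisymmetric(self):
        a, b = [1.0, 3, 2], [0.5, 1, 4]
        t1, p1 = paired_compare(a, b)
        t2, p2 = paired_compare(b, a)
        assert t1 == -t2 and p1 == p2

    def test_degenerate_constant_nonzero_difference(self):
        with pytest.warns(UserWarning):
            t, p = paired_compare([2.0, 2, 2], [1.0, 1, 1])
        assert p == 0.0
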