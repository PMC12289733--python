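"""Task harness: protocols, bias/unity metrics, Gaussian fits, model fitting."""

import numpy as np
import pandas as pd
import pytest

from msimodels import (
    auditory_bias,
    default_task,
    fit_gaussian,
    fit_model,
    get_contract,
    run_task,
    sweep_metric,
)


class TestDefaultTask:
    def test_implicit_spatial_protocol(self):
        t = default_task("implicit_spatial")
        assert t.anchor == 45.0
        assert sorted(abs(d) for d in t.disparities) == [3, 3, 6, 6, 12, 12, 24, 24]
        assert len(t.disparities) == 8
        assert t.noise == 0.0  # single noiseless presentation per condition

    def test_explicit_temporal_protocol(self):
        t = default_task("explicit_temporal")
        assert t.anchor == 160.0
        assert len(t.disparities) == 8
        assert set(t.disparities) == {0, 20, -20, 80, -80, 150, -150, 250}

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown task kind"):
            default_task("implicit_temporal")

    def test_temporal_stimuli_colocated(self):
        t = default_task("explicit_temporal")
        stims = t.stimuli(250.0)
        by_mod = {s.modality: s for s in stims}
        assert by_mod["auditory"].position == by_mod["visual"].position
        assert by_mod["auditory"].onset == 410.0
        assert by_mod["visual"].onset == 160.0


class TestAuditoryBias:
    @pytest.mark.parametrize(
        "est,expected", [(45.0, 0.0), (51.0, 1.0), (48.0, 0.5)]
    )
    def test_normalized_shift(self, est, expected):
        assert auditory_bias(est, 45.0, 51.0) == expected

    def test_zero_disparity_undefined(self):
        with pytest.raises(ZeroDivisionError):
            auditory_bias(45.0, 45.0, 45.0)


class TestRunTask:
    def test_forced_fusion_equal_reliability_bias_half(self):
        """p_common = 1 with matched sigmas and an uninformative position
        prior is forced fusion: the auditory estimate lands midway."""
        table = run_task(
            get_contract("bci"),
            default_task("implicit_spatial"),
            {
                "p_common": 1.0,
                "auditory_sigma": 3.0,
                "visual_sigma": 3.0,
                "sigma_p": 1e6,
            },
        )
        assert np.allclose(table["bias"], 0.5, atol=1e-6)

    def test_decoupled_network_unity_flat(self):
        """With the multisensory layer cut off from its inputs, the unity
        readout stays at the no-integration baseline at every disparity."""
        contract = get_contract("net_stci", n_neurons=90, duration=250)
        table = run_task(
            contract,
            default_task("explicit_spatial"),
            {"W0_mc": 0.0},
        )
        assert table["unity"].std() == pytest.approx(0.0, abs=1e-6)
        assert table["unity"].max() < 1e-3

    def test_segregating_prior_zero_unity(self):
        table = run_task(
            get_contract("bci", dimension="time"),
            default_task("explicit_temporal"),
            {"p_common": 0.0},
        )
        assert (table["unity"] == 0.0).all()

    def test_static_model_rejects_temporal_task(self):
        with pytest.raises(ValueError, match="static"):
            run_task(get_contract("mle"), default_task("explicit_temporal"))

    def test_mle_unity_nan_without_threshold_rule(self):
        table = run_task(get_contract("mle"), default_task("explicit_spatial"))
        assert table["unity"].isna().all()

    def test_mle_unity_with_threshold_rule(self):
        table = run_task(
            get_contract("mle"),
            default_task("explicit_spatial"),
            mle_unity_threshold=10.0,
        )
        assert set(table["unity"]) <= {0.0, 1.0}

    def test_mle_constant_vs_bci_decreasing_bias(self):
        """The computational contrast between the two observers: reliability
        weighting ignores disparity, causal inference discounts large ones."""
        mle_t = run_task(get_contract("mle"), default_task("implicit_spatial"))
        assert mle_t["bias"].std() == pytest.approx(0.0, abs=1e-12)
        bci_t = run_task(
            get_contract("bci"),
            default_task("implicit_spatial"),
            {"p_common": 0.5},
        ).set_index("disparity")["bias"]
        for mags in ([3, 6, 12, 24],):
            vals = [bci_t[float(m)] for m in mags]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_bci_temporal_unity_unimodal(self):
        table = run_task(
            get_contract("bci", dimension="time"),
            default_task("explicit_temporal"),
            {"p_common": 0.5},
        ).sort_values("disparity")
        unity = table.set_index("disparity")["unity"]
        assert unity.idxmax() == 0.0
        neg = unity[unity.index <= 0]
        pos = unity[unity.index >= 0]
        assert neg.is_monotonic_increasing
        assert pos.is_monotonic_decreasing


class TestFitGaussian:
    DISPARITIES = np.array([-150.0, -80.0, -20.0, 0.0, 20.0, 80.0, 150.0, 250.0])

    def test_exact_recovery_noiseless(self):
        a, mu, w = 0.9, 5.0, 20.0
        p = a * np.exp(-((self.DISPARITIES - mu) ** 2) / (2 * w**2))
        fit = fit_gaussian(self.DISPARITIES, p)
        assert fit.amplitude == pytest.approx(a, abs=1e-6)
        assert fit.mean == pytest.approx(mu, abs=1e-6)
        assert fit.width == pytest.approx(w, abs=1e-6)
        assert fit.rss < 1e-12

    def test_noisy_amplitude_recovery(self):
        rng = np.random.default_rng(123)
        a, mu, w = 0.7, 0.0, 10.0
        d = self.DISPARITIES
        p = np.clip(
            a * np.exp(-(d - mu) ** 2 / (2 * w**2)) + rng.normal(0, 0.02, d.size),
            0.0,
            1.0,
        )
        fit = fit_gaussian(d, p)
        assert fit.amplitude == pytest.approx(a, abs=0.05)

    def test_constant_curve_flagged_degenerate(self):
        fit = fit_gaussian(self.DISPARITIES, np.full(8, 0.4))
        assert fit.degenerate
        assert np.isnan(fit.width)

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(0)
        d = self.DISPARITIES
        p = 0.8 * np.exp(-(d**2) / (2 * 30.0**2))
        perm = rng.permutation(d.size)
        f1 = fit_gaussian(d, p)
        f2 = fit_gaussian(d[perm], p[perm])
        assert f1.amplitude == pytest.approx(f2.amplitude, rel=1e-9)
        assert f1.width == pytest.approx(f2.width, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_gaussian([0, 1, 2], [0.1, 0.2, 0.1])


class TestSweepMetric:
    def test_bias_increases_with_prior(self):
        table = sweep_metric(
            get_contract("bci"),
            default_task("implicit_spatial"),
            "p_common",
            [0.1, 0.3, 0.5, 0.7, 0.9],
        )
        assert table["bias"].is_monotonic_increasing
        assert table["bias"].nunique() == 5

    def test_explicit_task_returns_gaussian_columns(self):
        table = sweep_metric(
            get_contract("bci", dimension="time"),
            default_task("explicit_temporal"),
            "p_common",
            [0.3, 0.7],
        )
        assert {"amplitude", "mean", "width"} <= set(table.columns)
        # a stronger common-cause prior raises the unity ceiling
        assert table["amplitude"].iloc[1] > table["amplitude"].iloc[0]

    def test_single_value_single_row(self):
        table = sweep_metric(
            get_contract("bci"),
            default_task("implicit_spatial"),
            "p_common",
            [0.5],
        )
        assert len(table) == 1


class TestFitModel:
    def _observed(self, p_common=0.7):
        contract = get_contract("bci", dimension="time")
        gen = run_task(contract, default_task("explicit_temporal"), {"p_common": p_common})
        return pd.DataFrame({"disparity": gen["disparity"], "value": gen["unity"]})

    def test_self_recovery_of_prior(self):
        contract = get_contract("bci", dimension="time")
        fit = fit_model(
            contract,
            self._observed(0.7),
            {"p_common": (0.0, 1.0)},
            default_task("explicit_temporal"),
            budget=2000,
            seed=42,
        )
        assert fit.params["p_common"] == pytest.approx(0.7, abs=0.05)
        assert fit.n_evaluations <= 2000

    def test_zero_free_parameters_returns_loss(self):
        contract = get_contract("bci", dimension="time")
        fit = fit_model(
            contract,
            self._observed(0.5),
            {},
            default_task("explicit_temporal"),
            fixed_params={"p_common": 0.5},
            seed=0,
        )
        assert fit.loss == pytest.approx(0.0, abs=1e-12)
        assert "unchanged" in fit.message

    def test_bounds_excluding_truth_yield_boundary_loss(self):
        contract = get_contract("bci", dimension="time")
        fit = fit_model(
            contract,
            self._observed(0.7),
            {"p_common": (0.0, 0.3)},
            default_task("explicit_temporal"),
            budget=400,
            seed=1,
        )
        assert fit.loss > 0.0
        assert fit.params["p_common"] <= 0.3 + 1e-9
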