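"""NLS fitting, bootstrap intervals, diagnostics and model selection."""

import math

import numpy as np
import pandas as pd
import pytest

from graftkit import (
    FitConfig,
    GrowthModel,
    GrowthSimSpec,
    IllPosedError,
    NoiseModel,
    RetentionModel,
    RetentionSimSpec,
    fit_growth,
    fit_retention,
    goodness_of_fit,
    growth_rate,
    model_selection_gamma,
    residual_trend,
    retention_at_depth,
    sensitivity_sweep,
    simulate_growth,
    simulate_retention,
    ul_to_um3,
)


# ------------------------------------------------------------------ gof


@pytest.mark.parametrize(
    "observed, predicted, r2, mae, rmse",
    [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0, 0.0, 0.0),
        ([0.0, 1.0], [0.5, 0.5], 0.0, 0.5, 0.5),
        ([1.0, 2.0, 3.0], [1.0, 2.0, 4.0], 0.5, 1 / 3, 1 / math.sqrt(3)),
    ],
)
def test_goodness_of_fit_hand_examples(observed, predicted, r2, mae, rmse):
    g = goodness_of_fit(observed, predicted)
    assert g["r_squared"] == pytest.approx(r2)
    assert g["mae"] == pytest.approx(mae)
    assert g["rmse"] == pytest.approx(rmse)


def test_goodness_of_fit_zero_variance_is_nan_not_minus_inf():
    g = goodness_of_fit([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
    assert math.isnan(g["r_squared"])


# ------------------------------------------------------------ trend test


@pytest.mark.parametrize(
    "residuals, predictor, rho",
    [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
        ([3.0, 1.0, 2.0], [1.0, 2.0, 3.0], -0.5),
        ([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], 0.0),
    ],
)
def test_residual_trend_rho_examples(residuals, predictor, rho):
    t = residual_trend(residuals, predictor)
    assert t["spearman_rho"] == pytest.approx(rho)


def test_residual_trend_constant_residuals_not_flagged():
    t = residual_trend([0.5] * 6, list(range(6)))
    assert t["spearman_rho"] == 0.0 and not t["flagged"]


def test_residual_trend_exact_permutation_matches_known_p():
    # perfect monotone trend of n=5: p = 2/5! two-sided
    t = residual_trend([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert t["p_value"] == pytest.approx(2 / 120)
    assert t["flagged"]


def test_residual_trend_large_sample_flags_strong_trend():
    rng = np.random.default_rng(0)
    x = np.linspace(0, 1, 30)
    t = residual_trend(x + rng.normal(0, 0.05, 30), x)
    assert t["flagged"]


# --------------------------------------------------------- retention fit


def test_fit_retention_noiseless_recovers_beta(noiseless_retention, quick_cfg):
    spec, df = noiseless_retention
    res = fit_retention(df, quick_cfg)
    assert res.estimates["beta"] == pytest.approx(spec.beta_true, abs=1e-6)
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)
    assert res.mae == pytest.approx(0.0, abs=1e-9)
    assert res.rmse == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.residuals["residual"], 0.0, atol=1e-8)
    lo, hi = res.ci["beta"]
    assert hi - lo < 1e-6  # degenerate interval on noise-free data
    assert lo - 1e-6 <= res.estimates["beta"] <= hi + 1e-6


def test_fit_retention_other_generative_beta():
    df = simulate_retention(
        RetentionSimSpec(beta_true=0.4, noise=NoiseModel("gaussian_additive", 0.0), seed=3)
    )
    res = fit_retention(df, FitConfig(n_boot=0))
    assert res.estimates["beta"] == pytest.approx(0.4, abs=1e-6)


def test_fit_retention_matches_grid_search_oracle():
    df = simulate_retention(
        RetentionSimSpec(beta_true=0.24, noise=NoiseModel("gaussian_additive", 0.05), seed=9)
    )
    res = fit_retention(df, FitConfig(n_boot=0))
    sub = df[df.value_kind == "fraction"]
    d = sub.depth_mm.to_numpy()
    y = sub.value.to_numpy()
    grid = np.arange(0.0, 2.0 + 1e-12, 1e-4)
    sse = ((y[None, :] - (1 - np.exp(-grid[:, None] * d[None, :]))) ** 2).sum(axis=1)
    beta_grid = grid[int(np.argmin(sse))]
    assert abs(res.estimates["beta"] - beta_grid) <= 1e-4


def test_fit_retention_signal_mode_requires_reference():
    df = pd.DataFrame(
        {
            "site_id": ["a", "b", "c"],
            "depth_mm": [0.5, 1.5, 3.0],
            "value": [1131.0, 3023.0, 5132.0],
            "value_kind": "signal",
            "qc_pass": True,
        }
    )
    with pytest.raises(ValueError):
        fit_retention(df, FitConfig(n_boot=0))
    res = fit_retention(df, FitConfig(n_boot=0), reference=10_000.0)
    assert res.estimates["beta"] == pytest.approx(0.24, abs=5e-3)


def test_fit_retention_honors_qc_column():
    df = simulate_retention(
        RetentionSimSpec(beta_true=0.24, noise=NoiseModel("gaussian_additive", 0.0), seed=2)
    )
    bad = df.copy()
    bad.loc[0, "value"] = 0.99  # gross outlier excluded by QC
    bad.loc[0, "qc_pass"] = False
    res = fit_retention(bad, FitConfig(n_boot=0))
    assert res.estimates["beta"] == pytest.approx(0.24, abs=1e-6)
    assert res.n_sites == len(df[df.value_kind == "fraction"]) - 1


def test_fit_retention_ill_posed_inputs():
    base = dict(value_kind="fraction", qc_pass=True)
    one_depth = pd.DataFrame(
        {"site_id": list("abc"), "depth_mm": 1.0, "value": [0.2, 0.25, 0.22], **base}
    )
    with pytest.raises(IllPosedError):
        fit_retention(one_depth, FitConfig(n_boot=0))
    no_qc = pd.DataFrame(
        {"site_id": list("ab"), "depth_mm": [1.0, 2.0], "value": [0.2, 0.4],
         "value_kind": "fraction", "qc_pass": False}
    )
    with pytest.raises(IllPosedError):
        fit_retention(no_qc, FitConfig(n_boot=0))


def test_bootstrap_is_deterministic_given_seed():
    df = simulate_retention(
        RetentionSimSpec(noise=NoiseModel("gaussian_additive", 0.05), seed=4)
    )
    cfg = FitConfig(n_boot=200, seed=123)
    a = fit_retention(df, cfg)
    b = fit_retention(df, cfg)
    assert a.ci["beta"] == b.ci["beta"]
    assert a.estimates["beta"] == b.estimates["beta"]


def test_estimator_rmse_shrinks_with_noise():
    """RMSE of beta-hat over replicates is nonincreasing as sigma drops."""
    rmses = []
    for sigma in (0.1, 0.05, 0.01):
        errs = []
        for i in range(200):
            df = simulate_retention(
                RetentionSimSpec(
                    beta_true=0.24,
                    noise=NoiseModel("gaussian_additive", sigma),
                    seed=1000 + i,
                )
            )
            res = fit_retention(df, FitConfig(n_boot=0))
            errs.append(res.estimates["beta"] - 0.24)
        rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
    assert rmses[0] >= rmses[1] >= rmses[2]


# ------------------------------------------------------------ growth fit


def test_fit_growth_noiseless_recovers_gmax_and_gamma(noiseless_growth):
    spec, df = noiseless_growth
    res = fit_growth(df, FitConfig(n_boot=0, gamma_mode="free", gmax_mode="free"))
    assert res.estimates["gmax"] == pytest.approx(spec.g_max_true, rel=1e-5)
    assert res.estimates["gamma"] == pytest.approx(spec.gamma_true, rel=1e-5)
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fit_growth_fixed_gamma_closed_form_gmax(noiseless_growth):
    _, df = noiseless_growth
    res = fit_growth(df, FitConfig(n_boot=0, gamma_mode="fixed:3", gmax_mode="free"))
    assert res.estimates["gamma"] == 3.0
    assert res.estimates["gmax"] == pytest.approx(2.0, rel=1e-9)


def test_fit_growth_flat_design_flags_gamma():
    # all volumes below the threshold volume (~4.2 nL): model is flat
    df = pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(6)],
            "volume_ul": [0.001, 0.002, 0.003, 0.001, 0.002, 0.003],
            "value": [2.1, 1.9, 2.0, 2.05, 1.95, 2.0],
            "value_kind": "growth",
            "qc_pass": True,
        }
    )
    res = fit_growth(df, FitConfig(n_boot=0, gamma_mode="free", gmax_mode="free"))
    assert "gamma_unidentifiable" in res.flags
    assert res.estimates["gmax"] == pytest.approx(2.0, abs=0.01)  # mean readout
    assert math.isnan(res.estimates["gamma"])


def test_fit_growth_hypor_readout_recovers_margin():
    volumes = np.array([0.05, 0.1, 0.25, 0.5, 1.0])
    from graftkit import hypoperfused_fraction_volume

    df = pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(5)],
            "volume_ul": volumes,
            "value": [float(hypoperfused_fraction_volume(ul_to_um3(v), 100.0)) for v in volumes],
            "value_kind": "hypor",
            "qc_pass": True,
        }
    )
    res = fit_growth(df, FitConfig(n_boot=0, margin_mode="free"))
    assert res.estimates["margin"] == pytest.approx(100.0, rel=1e-4)


def test_fit_growth_bootstrap_degenerate_on_noiseless(noiseless_growth):
    _, df = noiseless_growth
    res = fit_growth(df, FitConfig(n_boot=100, seed=5, gamma_mode="free"))
    lo, hi = res.ci["gamma"]
    assert hi - lo < 1e-4


def test_fit_growth_rejects_mixed_kinds(noiseless_growth):
    _, df = noiseless_growth
    df = df.copy()
    df.loc[0, "value_kind"] = "hypor"
    with pytest.raises(ValueError):
        fit_growth(df, FitConfig(n_boot=0))


# -------------------------------------------------------- model selection


def test_model_selection_prefers_generative_gamma_noiseless(noiseless_growth):
    _, df = noiseless_growth
    ranked = model_selection_gamma(df, ["fixed:1", "fixed:2", "fixed:3", "free"], FitConfig(n_boot=0))
    assert ranked[0].label == "fixed:3"
    assert ranked[0].result.rmse == pytest.approx(0.0, abs=1e-9)


def test_model_selection_single_candidate_returned_as_is(noiseless_growth):
    _, df = noiseless_growth
    ranked = model_selection_gamma(df, [2], FitConfig(n_boot=0))
    assert len(ranked) == 1 and ranked[0].label == "fixed:2"


def test_model_selection_gamma1_data_ranks_gamma1_first():
    df = simulate_growth(
        GrowthSimSpec(
            g_max_true=2.0, gamma_true=1.0, noise=NoiseModel("lognormal_multiplicative", 0.0), seed=2
        )
    )
    ranked = model_selection_gamma(df, ["fixed:1", "fixed:3"], FitConfig(n_boot=0))
    assert ranked[0].label == "fixed:1"


def test_model_selection_under_lognormal_noise_ranks_truth_above_gamma1():
    df = simulate_growth(
        GrowthSimSpec(
            g_max_true=2.0, gamma_true=3.0, noise=NoiseModel("lognormal_multiplicative", 0.15), seed=7
        )
    )
    ranked = model_selection_gamma(df, ["fixed:1", "fixed:3", "free"], FitConfig(n_boot=0))
    labels = [c.label for c in ranked]
    winner = ranked[0]
    assert labels.index("fixed:3") < labels.index("fixed:1")
    if winner.label == "free":
        assert 2.0 <= winner.result.estimates["gamma"] <= 4.0


def test_model_selection_survives_failing_candidate(noiseless_growth):
    _, df = noiseless_growth
    ranked = model_selection_gamma(df, ["fixed:3", "fixed:-1"], FitConfig(n_boot=0))
    assert ranked[0].label == "fixed:3" and ranked[0].error is None
    assert ranked[-1].error is not None


# ------------------------------------------------------------ sensitivity


def test_sensitivity_sweep_zero_fraction_is_baseline():
    table = sensitivity_sweep(RetentionModel(0.24), fraction=0.0, n_points=3)
    base = table[table.multiplier == 1.0]
    assert np.allclose(table.prediction.to_numpy().reshape(-1, len(base)), base.prediction.to_numpy())


def test_sensitivity_sweep_beta_endpoints_at_3mm():
    table = sensitivity_sweep(RetentionModel(0.24), fraction=0.2, n_points=3, grid=np.array([3.0]))
    lo = table[table.multiplier == 0.8].prediction.iloc[0]
    hi = table[table.multiplier == 1.2].prediction.iloc[0]
    assert lo == pytest.approx(1 - math.exp(-0.576), abs=1e-6)
    assert hi == pytest.approx(1 - math.exp(-0.864), abs=1e-6)
    assert lo == pytest.approx(0.4380, abs=1e-3)
    assert hi == pytest.approx(0.5785, abs=1e-3)


def test_sensitivity_sweep_scaled_beta_increases_retention():
    table = sensitivity_sweep(RetentionModel(0.24), fraction=0.2, n_points=5, grid=np.array([1.0]))
    up = table[table.multiplier > 1.0].prediction
    base = table[table.multiplier == 1.0].prediction.iloc[0]
    assert (up > base).all()


def test_sensitivity_sweep_growth_model_covers_both_parameters():
    table = sensitivity_sweep(GrowthModel(g_max=2.0, gamma=3.0), fraction=0.2, n_points=5)
    assert set(table.parameter) == {"g_max", "gamma"}
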