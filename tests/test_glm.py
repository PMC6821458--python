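"""Gamma GLM fitting: oracle agreement, recovery, nesting, selection."""

import numpy as np
import pytest
from scipy import stats as st

from glmcfc.glm import (aic_select_n, design_joint, fit_alow_model,
                        fit_condition_models, fit_joint_model, fit_phi_model,
                        gamma_gof_check)
from glmcfc.splines import PeriodicSplineBasis, spline_design_matrix

BASIS = PeriodicSplineBasis(10, 0.5)


def _gamma_noise(rng, mu, nu):
    """Gamma draws with mean mu and shape nu."""
    return rng.gamma(nu, mu / nu)


def test_constant_response_fits_flat_surface():
    rng = np.random.default_rng(0)
    phi = rng.uniform(-np.pi, np.pi, 5000)
    fit = fit_phi_model(np.full(5000, 2.5), phi, BASIS)
    grid = spline_design_matrix(np.linspace(-np.pi, np.pi, 64), BASIS)
    mu = np.exp(grid @ fit.beta)
    assert np.allclose(mu, 2.5, rtol=0.01)


def test_matches_statsmodels_gamma_glm(pac_decomposition):
    """Independent cross-check: statsmodels IRLS on the same design."""
    sm = pytest.importorskip("statsmodels.api")
    d = pac_decomposition
    sl = slice(0, None, 8)  # thin the series to keep the reference fit quick
    y = d.a_high[sl]
    X = design_joint(d.phi_low[sl], d.a_low[sl], BASIS)
    mine = fit_joint_model(y, d.phi_low[sl], d.a_low[sl], BASIS)
    ref = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit()
    assert np.allclose(mine.beta, ref.params, rtol=1e-5, atol=1e-7)
    assert np.allclose(np.diag(mine.cov_beta), np.diag(ref.cov_params()),
                       rtol=1e-3)
    assert np.isclose(1.0 / mine.nu, ref.scale, rtol=1e-3)
    assert np.isclose(mine.deviance, ref.deviance, rtol=1e-6)


def test_alow_model_recovers_known_coefficients():
    rng = np.random.default_rng(3)
    a_low = rng.uniform(0.0, 2.0, 20_000)
    mu = np.exp(0.5 + 0.3 * a_low)
    fit = fit_alow_model(_gamma_noise(rng, mu, 5.0), a_low)
    se = np.sqrt(np.diag(fit.cov_beta))
    assert abs(fit.beta[0] - 0.5) < 3 * se[0]
    assert abs(fit.beta[1] - 0.3) < 3 * se[1]


def test_alow_model_null_coverage():
    """With independent response, the slope CI covers 0 most of the time."""
    rng = np.random.default_rng(4)
    hits = 0
    n_rep = 20
    for _ in range(n_rep):
        a_low = rng.uniform(0.0, 2.0, 2000)
        y = _gamma_noise(rng, np.full(2000, 1.5), 4.0)
        fit = fit_alow_model(y, a_low)
        se = np.sqrt(fit.cov_beta[1, 1])
        hits += abs(fit.beta[1]) < 1.96 * se
    assert hits >= 0.8 * n_rep


def test_phi_model_parameter_recovery_within_ci():
    """Self-generated spline-GLM data: >=90% of coefficients inside 95% CI."""
    rng = np.random.default_rng(5)
    beta_true = rng.normal(0.0, 0.3, BASIS.n)
    phi = rng.uniform(-np.pi, np.pi, 20_000)
    mu = np.exp(spline_design_matrix(phi, BASIS) @ beta_true)
    fit = fit_phi_model(_gamma_noise(rng, mu, 4.0), phi, BASIS)
    se = np.sqrt(np.diag(fit.cov_beta))
    inside = np.abs(fit.beta - beta_true) < 1.96 * se
    assert inside.sum() >= 9


def test_constant_alow_raises_rank_deficiency():
    rng = np.random.default_rng(6)
    y = rng.gamma(2.0, 1.0, 1000)
    with pytest.raises(ValueError, match="rank deficient"):
        fit_alow_model(y, np.full(1000, 1.3))


def test_nested_deviances(pac_decomposition):
    """The joint model never fits worse than either nested model."""
    d = pac_decomposition
    f_phi = fit_phi_model(d.a_high, d.phi_low, BASIS)
    f_alow = fit_alow_model(d.a_high, d.a_low)
    f_joint = fit_joint_model(d.a_high, d.phi_low, d.a_low, BASIS)
    assert f_joint.deviance <= f_phi.deviance + 1e-6
    assert f_joint.deviance <= f_alow.deviance + 1e-6
    # coefficient-count contracts and the AIC definition
    assert len(f_phi.beta) == 10 and len(f_alow.beta) == 2 and len(f_joint.beta) == 13
    for f in (f_phi, f_alow, f_joint):
        assert f.aic == pytest.approx(f.deviance + 2 * len(f.beta))


def test_condition_model_shapes_and_errors(pac_decomposition):
    d = pac_decomposition
    P = (np.arange(len(d)) >= len(d) // 2).astype(int)
    full, amp = fit_condition_models(d.a_high, d.phi_low, d.a_low, P, BASIS)
    assert len(full.beta) == 2 * BASIS.n + 4
    assert len(amp.beta) == BASIS.n + 4
    with pytest.raises(ValueError, match="constant"):
        fit_condition_models(d.a_high, d.phi_low, d.a_low, np.zeros(len(d)), BASIS)
    with pytest.raises(ValueError, match="binary"):
        fit_condition_models(d.a_high, d.phi_low, d.a_low,
                             np.full(len(d), 0.5), BASIS)


def test_naive_model_comparison_overrejects():
    """Deviance-based nested tests fire far above nominal on plain noise,
    which is why the surface statistics exist."""
    from glmcfc.decompose import decompose
    from glmcfc.simulate import simulate_pac

    rejections = 0
    n_rep = 12
    for seed in range(n_rep):
        sim = simulate_pac(i_pac=0.0, duration=20.0, seed=seed)
        d = decompose(sim.v, sim.fs).trimmed(1.0)
        f_alow = fit_alow_model(d.a_high, d.a_low)
        f_joint = fit_joint_model(d.a_high, d.phi_low, d.a_low, BASIS)
        lr = (f_alow.deviance - f_joint.deviance) * f_joint.nu
        df = len(f_joint.beta) - len(f_alow.beta)
        rejections += st.chi2.sf(lr, df) < 0.05
    assert rejections / n_rep > 0.2


def test_aic_selects_small_n_for_flat_data():
    rng = np.random.default_rng(8)
    phi = rng.uniform(-np.pi, np.pi, 8000)
    y = _gamma_noise(rng, np.full(8000, 1.0), 5.0)
    best, profile = aic_select_n(y, phi, n_range=range(4, 16))
    assert best == 4
    assert set(profile) == set(range(4, 16))
    # definitional: the profile stores deviance + 2n
    fit4 = fit_phi_model(y, phi, PeriodicSplineBasis(4, 0.5))
    assert profile[4] == pytest.approx(fit4.deviance + 8, rel=1e-9)


def test_gamma_gof_distinguishes_distributions():
    rng = np.random.default_rng(9)
    gamma_draws = rng.gamma(3.0, 0.5, 20_000)
    uniform_draws = rng.uniform(1.0, 2.0, 20_000)
    g = gamma_gof_check(gamma_draws)
    u = gamma_gof_check(uniform_draws)
    assert g.ks_p > 0.05
    assert u.ks_stat > g.ks_stat
    assert g.mean == pytest.approx(gamma_draws.mean(), rel=0.01)
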