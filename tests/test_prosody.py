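"""Gamma-mixture EM, density-crossing binarization, and the
stimulus-level association tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prosodecode.prosody import (
    GammaMixtureFit,
    classify_strength,
    fit_gamma_mixture,
    mixture_boundary,
    mixture_loglik,
)
from prosodecode.prosody import test_association as run_association
from prosodecode.synth import SynthConfig, gen_word_table


def _mixture_sample(n, rng, w=0.5, a1=1.1, r1=2.8, a2=14.0, r2=10.7):
    comp = rng.random(n) < w
    return np.where(
        comp, rng.gamma(a2, 1 / r2, n), rng.gamma(a1, 1 / r1, n)
    )


@pytest.fixture(scope="module")
def reference_fit():
    rng = np.random.default_rng(2024)
    x = _mixture_sample(20000, rng)
    return x, fit_gamma_mixture(x, rng=1)


def test_em_recovers_generating_parameters(reference_fit):
    """EM on 20k draws from the equal-weight reference mixture recovers
    shapes 1.1 / 14 and rates 2.8 / 10.7 within 10%."""
    _, fit = reference_fit
    assert fit.shape[0] == pytest.approx(1.1, rel=0.10)
    assert fit.rate[0] == pytest.approx(2.8, rel=0.10)
    assert fit.shape[1] == pytest.approx(14.0, rel=0.10)
    assert fit.rate[1] == pytest.approx(10.7, rel=0.10)
    assert fit.w[0] == pytest.approx(0.5, abs=0.03)


def test_em_loglik_monotone(reference_fit):
    _, fit = reference_fit
    assert np.all(np.diff(fit.loglik_path) >= -1e-7 * np.abs(fit.loglik_path[:-1]))


def test_fit_dominates_true_parameters(reference_fit):
    """MLE dominance: fitted log-likelihood is at least that of the
    generating parameters evaluated directly on the sample."""
    x, fit = reference_fit
    true_ll = mixture_loglik(x, [0.5, 0.5], [1.1, 14.0], [2.8, 10.7])
    assert fit.loglik >= true_ll


def test_single_component_data_degenerates_gracefully():
    """On data from a single Gamma(2, 1) the two-component fit collapses
    to (essentially) the one-component solution: its likelihood dominates
    the single-gamma MLE and the mixture mean tracks the sample mean."""
    rng = np.random.default_rng(3)
    x = rng.gamma(2.0, 1.0, 5000)
    fit = fit_gamma_mixture(x, rng=0)
    a, _, scale = sps.gamma.fit(x, floc=0)
    single_ll = sps.gamma.logpdf(x, a, scale=scale).sum()
    assert fit.loglik >= single_ll - 1e-6  # nested-model dominance
    mix_mean = float(fit.w @ fit.means)
    assert mix_mean == pytest.approx(x.mean(), rel=0.02)
    assert np.all(np.diff(fit.loglik_path) >= -1e-7 * np.abs(fit.loglik_path[:-1]))


def test_input_validation():
    with pytest.raises(ValueError, match="positive"):
        fit_gamma_mixture([1.0, -1.0] * 10)
    with pytest.raises(ValueError, match="at least 10"):
        fit_gamma_mixture([1.0] * 5)


def test_boundary_matches_grid_oracle():
    """Bisection boundary equals a dense-grid argmin of |w1 f1 - w2 f2|."""
    fit = GammaMixtureFit(
        w=np.array([0.5, 0.5]),
        shape=np.array([1.1, 14.0]),
        rate=np.array([2.8, 10.7]),
        loglik=0.0,
        n_iter=0,
        converged=True,
    )
    b = mixture_boundary(fit)
    grid = np.linspace(fit.means[0], fit.means[1], 2_000_001)
    dens = fit.component_pdf(grid)
    oracle = grid[np.argmin(np.abs(dens[:, 0] - dens[:, 1]))]
    assert b == pytest.approx(oracle, abs=1e-6)
    # equal-posterior definition holds at the boundary
    post = fit.posterior(np.array([b]))[0]
    assert post[0] == pytest.approx(0.5, abs=1e-6)
    # boundary lies strictly between the component means
    assert fit.means[0] < b < fit.means[1]


def test_boundary_error_on_identical_components():
    fit = GammaMixtureFit(
        w=np.array([0.5, 0.5]),
        shape=np.array([2.0, 2.0]),
        rate=np.array([1.0, 1.0]),
        loglik=0.0,
        n_iter=0,
        converged=True,
    )
    with pytest.raises(ValueError, match="distinct"):
        mixture_boundary(fit)


def test_classify_strength_rules():
    labels = classify_strength([0.5, 2.0, 1.01], boundary=1.01)
    assert list(labels) == ["weak", "strong", "weak"]  # tie classified weak
    with pytest.raises(ValueError, match="zero"):
        classify_strength([0.5, 0.0], boundary=1.01)


def test_classify_strength_monotone_and_order_invariant():
    rng = np.random.default_rng(0)
    x = rng.gamma(2, 1, 200) + 1e-6
    lab = classify_strength(x, 1.0)
    # raising any strength never flips strong -> weak
    lab2 = classify_strength(x * 1.5, 1.0)
    assert not np.any((lab == "strong") & (lab2 == "weak"))
    perm = rng.permutation(200)
    assert list(classify_strength(x[perm], 1.0)) == list(lab[perm])


def _labeled_table(n=5000, seed=11, p_strong=0.72, p_weak=0.44):
    cfg = SynthConfig(
        n_words=n,
        seed=seed,
        p_closing_given_strong=p_strong,
        p_closing_given_weak=p_weak,
    )
    t = gen_word_table(cfg)
    t["prosody_class"] = t["latent_class"]
    return t


def test_association_detects_planted_effect():
    """Binomial GLM z is positive and significant on planted data, with
    the sign agreeing with a Fisher-exact oracle on the 2x2 table."""
    t = _labeled_table()
    res = run_association(t)
    assert res.binomial_z > 0 and res.binomial_p < 0.001
    assert res.gamma_glm_p < 0.001
    ct = res.contingency
    odds, p_fisher = sps.fisher_exact(ct.to_numpy())
    assert p_fisher < 0.001
    # Gamma-GLM direction: strength greater for closing tokens
    means = t.groupby("closing")["strength"].mean()
    assert means[1] > means[0]


def test_association_null_case():
    t = _labeled_table(seed=21, p_strong=0.5, p_weak=0.5)
    res = run_association(t)
    assert abs(res.binomial_z) < 3


def test_association_single_level_errors():
    t = _labeled_table(n=200)
    t["closing"] = 1
    with pytest.raises(ValueError, match="two levels"):
        run_association(t)
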