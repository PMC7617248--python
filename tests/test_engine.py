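"""NMA engine: conjugate oracles, reductions, diagnostics, identities."""

import numpy as np
import pytest

from nmabridge import (
    IdentifiabilityError,
    MCMCSettings,
    ModelSpec,
    PosteriorSamples,
    ValidationError,
    fit_nma,
    fit_pairwise_ma,
    fit_shared_het_pairwise,
    gelman_rubin,
    observed_smd,
    pooled_sd,
    relative_effect_draws,
    relative_effects,
)
from nmabridge._sampler import contrast_het_scale

from conftest import make_dataset, make_study


def normal_normal_posterior(x, v, prior_mean=0.0, prior_var=1e4):
    """Closed-form posterior for one normal observation, known variance."""
    post_var = 1.0 / (1.0 / prior_var + 1.0 / v)
    return post_var * (prior_mean / prior_var + x / v), post_var


def test_conjugate_oracle_single_study(two_arm_study, fast_mcmc):
    """With tau = 0 the posterior must match the normal-normal closed form."""
    ds = make_dataset([two_arm_study])
    fit = fit_nma(ds, ModelSpec(reference="Placebo"), fast_mcmc, tau_fixed=0.0)
    smd = observed_smd(two_arm_study).entries["DrugA"]
    sp = pooled_sd(two_arm_study).value
    v = (2.0**2 / 50 + 2.0**2 / 50) / sp**2
    mean, var = normal_normal_posterior(smd, v)
    a = fit.array("mu[DrugA]")
    mcse = fit.mc_se("mu[DrugA]")
    assert abs(a.mean() - mean) < 3 * mcse
    assert a.var(ddof=1) == pytest.approx(var, rel=0.15)


def test_naive_equals_standard_on_concatenation(fast_mcmc):
    """Naive synthesis of two subgroups == standard NMA of the pooled data."""
    from dataclasses import replace

    s1 = [make_study("a1", [("P", 60, 0.0, 2.0), ("A", 60, 0.9, 2.0)], subgroup="P1"),
          make_study("a2", [("P", 60, 0.1, 2.0), ("A", 60, 0.8, 2.0)], subgroup="P1")]
    s2 = [make_study("b1", [("P", 60, 0.0, 2.0), ("A", 60, 1.1, 2.0)], subgroup="P2"),
          make_study("b2", [("P", 60, -0.1, 2.0), ("A", 60, 0.9, 2.0)], subgroup="P2")]
    ds1 = make_dataset(s1, subgroup="P1")
    ds2 = make_dataset(s2, subgroup="P2")
    merged = make_dataset(
        [replace(s, subgroup="P") for s in s1 + s2], subgroup="P"
    )
    spec_std = ModelSpec(kind="standard", reference="P")
    naive = fit_nma([ds1, ds2], ModelSpec(kind="naive", reference="P"), fast_mcmc)
    std = fit_nma(merged, spec_std,
                  MCMCSettings(iterations=1500, burnin=400, seed=99))
    tol = 3 * (naive.mc_se("mu[A]") + std.mc_se("mu[A]"))
    assert abs(naive.array("mu[A]").mean() - std.array("mu[A]").mean()) < tol


def test_relative_effect_identities(triangle_ds, fast_mcmc):
    fit = fit_nma(triangle_ds, ModelSpec(reference="Placebo"), fast_mcmc)
    # pair (j, j) is identically zero
    assert np.all(relative_effect_draws(fit, "DrugA", "DrugA") == 0.0)
    # antisymmetry draw-wise
    ab = relative_effect_draws(fit, "DrugA", "DrugB")
    ba = relative_effect_draws(fit, "DrugB", "DrugA")
    np.testing.assert_allclose(ab, -ba)
    # consistency identity holds exactly per draw
    pa = relative_effect_draws(fit, "Placebo", "DrugA")
    pb = relative_effect_draws(fit, "Placebo", "DrugB")
    np.testing.assert_allclose(ab, pb - pa, atol=1e-12)
    df = relative_effects(fit, [("DrugA", "DrugB")])
    assert df.loc["DrugB vs DrugA", "mean"] == pytest.approx(ab.mean())


def test_relative_effects_unknown_treatment(triangle_ds, fast_mcmc):
    fit = fit_nma(triangle_ds, ModelSpec(reference="Placebo"), fast_mcmc)
    with pytest.raises(KeyError):
        relative_effects(fit, [("DrugA", "DrugZ")])


def test_gelman_rubin_same_distribution():
    rng = np.random.default_rng(0)
    samples = PosteriorSamples(
        draws={"mu[A]": rng.standard_normal((2, 10_000)),
               "tau": np.abs(rng.standard_normal((2, 10_000)))},
        reference="P",
        treatments=["P", "A"],
    )
    rep = gelman_rubin(samples)
    assert rep.converged
    assert all(v < 1.01 for v in rep.rhat.values())


def test_gelman_rubin_disjoint_chains():
    samples = PosteriorSamples(
        draws={"mu[A]": np.vstack([np.zeros(100), np.ones(100) * 5])},
        reference="P",
        treatments=["P", "A"],
    )
    rep = gelman_rubin(samples)
    assert not rep.converged
    assert rep.rhat["mu[A]"] > 1.1


def test_gelman_rubin_needs_two_chains():
    samples = PosteriorSamples(
        draws={"mu[A]": np.zeros((1, 100))}, reference="P", treatments=["P", "A"]
    )
    with pytest.raises(ValidationError):
        gelman_rubin(samples)


def test_pairwise_single_study_conjugate(fast_mcmc):
    s = make_study("s", [("P", 40, 0.0, 2.0), ("A", 40, 0.8, 2.0)])
    ds = make_dataset([s])
    fit = fit_pairwise_ma(ds, ("P", "A"), fast_mcmc, tau_fixed=0.0)
    smd = observed_smd(s).entries["A"]
    assert abs(fit.array("u").mean() - smd) < 3 * fit.mc_se("u") + 1e-3


def test_pairwise_two_identical_studies(fast_mcmc):
    arms = [("P", 40, 0.0, 2.0), ("A", 40, 0.8, 2.0)]
    ds = make_dataset([make_study("s1", arms), make_study("s2", arms)])
    fit = fit_pairwise_ma(ds, ("P", "A"), fast_mcmc)
    smd = observed_smd(ds.studies[0]).entries["A"]
    assert fit.array("u").mean() == pytest.approx(smd, abs=0.05)


def test_pairwise_requires_direct_study(triangle_ds, fast_mcmc):
    with pytest.raises(ValidationError, match="directly"):
        fit_pairwise_ma(triangle_ds, ("Placebo", "DrugZ"), fast_mcmc)


def test_shared_het_symmetry(fast_mcmc):
    arms = [("P", 60, 0.0, 2.0), ("A", 60, 1.0, 2.0)]
    ds1 = make_dataset([make_study("x", arms)], subgroup="P1")
    ds2 = make_dataset([make_study("y", arms, subgroup="P2")], subgroup="P2")
    fit = fit_shared_het_pairwise(ds1, ds2, ("P", "A"), fast_mcmc)
    diff = fit.array("u_P2") - fit.array("u_P1")
    assert abs(diff.mean()) < 0.08  # identical data: difference centered at 0


def test_shared_het_requires_both_sides(fast_mcmc):
    ds1 = make_dataset([make_study("x", [("P", 9, 0, 1), ("A", 9, 0, 1)])])
    ds2 = make_dataset(
        [make_study("y", [("P", 9, 0, 1), ("B", 9, 0, 1)], subgroup="P2")],
        subgroup="P2",
    )
    with pytest.raises(ValidationError):
        fit_shared_het_pairwise(ds1, ds2, ("P", "A"), fast_mcmc)


def test_disconnected_network_needs_priors(fast_mcmc):
    ds = make_dataset(
        [
            make_study("s1", [("P", 30, 0.0, 2.0), ("A", 30, 0.5, 2.0)]),
            make_study("s2", [("B", 30, 0.0, 2.0), ("C", 30, 0.5, 2.0)]),
        ]
    )
    with pytest.raises(IdentifiabilityError):
        fit_nma(ds, ModelSpec(reference="P"), fast_mcmc)
    # informative priors on the orphan component make the model proper
    spec = ModelSpec(
        reference="P", basic_priors={"B": (0.0, 0.25), "C": (0.4, 0.25)}
    )
    fit = fit_nma(ds, spec, fast_mcmc)
    assert "mu[B]" in fit.names()


def test_multiarm_covariance_positive_definite():
    """tau^2 * S must be positive definite for any block size."""
    for k in range(1, 6):
        s = contrast_het_scale(k)
        assert np.linalg.eigvalsh(s).min() > 0
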