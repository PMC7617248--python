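"""Stage-1 extrapolation: scale priors, location shifts, predictive export."""

import numpy as np
import pytest

from nmabridge import (
    FixedWeight,
    LocationPrior,
    ModelSpec,
    ScalePriorSpec,
    ValidationError,
    WeightPrior,
    assign_scale_priors,
    common_subnetwork,
    fit_nma,
    fit_stage1,
    summarize_scale_prior,
)

from conftest import make_dataset, make_study

SPEC = ModelSpec(reference="Placebo")


def dense_fixture(rob=None):
    studies = [
        make_study("d1", [("Placebo", 80, 0.0, 2.0), ("DrugA", 80, 0.9, 2.0)],
                   subgroup="P2", rob=rob and "high"),
        make_study("d2", [("Placebo", 80, 0.1, 2.0), ("DrugA", 80, 1.0, 2.0)],
                   subgroup="P2", rob=rob and "low"),
        make_study("d3", [("Placebo", 80, 0.0, 2.0), ("DrugB", 80, 1.3, 2.0)],
                   subgroup="P2", rob=rob and "low"),
        make_study("d4", [("DrugA", 80, 0.0, 2.0), ("DrugB", 80, 0.5, 2.0)],
                   subgroup="P2", rob=rob and "high"),
    ]
    return make_dataset(studies, subgroup="P2")


def point_priors(mean, var=1e-10):
    return [LocationPrior("DrugA", "Placebo", mean, var, "data"),
            LocationPrior("DrugB", "Placebo", mean, var, "data")]


def test_scheme_none_gives_unit_weights():
    ds = dense_fixture()
    out = assign_scale_priors(ds, ScalePriorSpec(scheme="none"))
    assert all(fam == FixedWeight(1.0) for fam in out.values())


def test_scheme_rob_targets_high_rob_only():
    ds = dense_fixture(rob=True)
    fam = WeightPrior("beta", 3, 3)
    out = assign_scale_priors(ds, ScalePriorSpec(scheme="rob", family=fam))
    assert out["d1"] == fam and out["d4"] == fam
    assert out["d2"] == FixedWeight(1.0) and out["d3"] == FixedWeight(1.0)


def test_scheme_rob_requires_ratings():
    ds = dense_fixture()
    with pytest.raises(ValidationError, match="risk-of-bias"):
        assign_scale_priors(ds, ScalePriorSpec(scheme="rob"))


def test_scheme_nct_downweights_out_of_bridge():
    ds = dense_fixture()
    fam = WeightPrior("beta", 3, 3)
    out = assign_scale_priors(
        ds, ScalePriorSpec(scheme="nct", family=fam), t_c=["Placebo", "DrugA"]
    )
    assert out["d3"] == fam and out["d4"] == fam  # contain DrugB, not in T_c
    assert out["d1"] == FixedWeight(1.0)


def test_beta33_summary():
    mean, (lo, hi) = summarize_scale_prior(WeightPrior("beta", 3, 3))
    assert mean == pytest.approx(0.5)
    assert round(lo, 3) == 0.147
    assert round(hi, 2) == 0.85


def test_uniform_summary():
    mean, (lo, hi) = summarize_scale_prior(WeightPrior("uniform", 0.4, 0.6))
    assert mean == pytest.approx(0.5)
    assert (round(lo, 3), round(hi, 3)) == (0.405, 0.595)


def test_common_subnetwork_restriction():
    ds = dense_fixture()
    sub = common_subnetwork(ds, ["Placebo", "DrugA"])
    assert {s.study_id for s in sub.studies} == {"d1", "d2"}


def test_reduction_to_standard_nma(fast_mcmc):
    """beta pinned at 0, w = 1 reproduces the plain NMA posterior."""
    ds = dense_fixture()
    assignment = assign_scale_priors(ds, ScalePriorSpec(scheme="none"))
    s1 = fit_stage1(ds, point_priors(0.0), assignment, SPEC, fast_mcmc,
                    t_c=["Placebo", "DrugA", "DrugB"])
    std = fit_nma(ds, SPEC, fast_mcmc)
    for t in ("DrugA", "DrugB"):
        tol = 3 * (std.mc_se(f"mu[{t}]") + s1.posterior.mc_se(f"mu[{t}]"))
        assert abs(
            s1.mu_star[t].mean() - std.array(f"mu[{t}]").mean()
        ) < tol


def test_location_shift_identity(fast_mcmc):
    """A point-mass beta of c shifts the extrapolated mean by -c."""
    ds = dense_fixture()
    assignment = assign_scale_priors(ds, ScalePriorSpec(scheme="none"))
    base = fit_stage1(ds, point_priors(0.0), assignment, SPEC, fast_mcmc,
                      t_c=["Placebo", "DrugA", "DrugB"])
    shifted = fit_stage1(ds, point_priors(0.3), assignment, SPEC, fast_mcmc,
                         t_c=["Placebo", "DrugA", "DrugB"])
    for t in ("DrugA", "DrugB"):
        assert shifted.mu_star[t].mean() == pytest.approx(
            base.mu_star[t].mean() - 0.3, abs=0.05
        )


def test_flipped_beta_sign_convention(fast_mcmc):
    """The equivalent P1-minus-P2 convention negates the shift."""
    ds = dense_fixture()
    assignment = assign_scale_priors(ds, ScalePriorSpec(scheme="none"))
    a = fit_stage1(ds, point_priors(0.3), assignment, SPEC, fast_mcmc,
                   t_c=["Placebo", "DrugA"], beta_sign="p2_minus_p1")
    b = fit_stage1(ds, point_priors(-0.3), assignment, SPEC, fast_mcmc,
                   t_c=["Placebo", "DrugA"], beta_sign="p1_minus_p2")
    assert a.mu_star["DrugA"].mean() == pytest.approx(
        b.mu_star["DrugA"].mean(), abs=0.05
    )


def test_monotone_variance_inflation(fast_mcmc):
    """Downweighting every study can only widen the posterior."""
    ds = dense_fixture()
    sds = {}
    for w in (1.0, 0.5, 0.1):
        assignment = {s.study_id: FixedWeight(w) for s in ds.studies}
        s1 = fit_stage1(ds, point_priors(0.0), assignment, SPEC, fast_mcmc,
                        t_c=["Placebo", "DrugA", "DrugB"])
        sds[w] = {t: s1.mu_star[t].std() for t in ("DrugA", "DrugB")}
    for t in ("DrugA", "DrugB"):
        assert sds[0.5][t] >= sds[1.0][t] * 0.95
        assert sds[0.1][t] > sds[1.0][t]


def test_predictive_variance_dominates_mu_star(fast_mcmc):
    ds = dense_fixture()
    assignment = assign_scale_priors(ds, ScalePriorSpec(scheme="none"))
    s1 = fit_stage1(ds, point_priors(0.0), assignment, SPEC, fast_mcmc,
                    t_c=["Placebo", "DrugA", "DrugB"])
    for p in s1.predictive:
        assert p.variance >= s1.mu_star[p.treatment].var(ddof=1)


def test_stochastic_weights_stay_in_unit_interval(fast_mcmc):
    ds = dense_fixture(rob=True)
    fam = WeightPrior("beta", 3, 3)
    assignment = assign_scale_priors(ds, ScalePriorSpec(scheme="rob", family=fam))
    s1 = fit_stage1(ds, point_priors(0.0), assignment, SPEC, fast_mcmc,
                    t_c=["Placebo", "DrugA", "DrugB"])
    w_names = [nm for nm in s1.posterior.names() if nm.startswith("w[")]
    assert set(w_names) == {"w[d1]", "w[d4]"}
    for nm in w_names:
        w = s1.posterior.array(nm)
        assert np.all((w > 0) & (w <= 1))


def test_missing_location_prior_warns(fast_mcmc):
    ds = dense_fixture()
    assignment = assign_scale_priors(ds, ScalePriorSpec(scheme="none"))
    with pytest.warns(UserWarning, match="jointly identified"):
        fit_stage1(ds, [point_priors(0.0)[0]], assignment, SPEC, fast_mcmc,
                   t_c=["Placebo", "DrugA", "DrugB"])
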