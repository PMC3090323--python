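"""Multistage dose-response fitting, benchmark dose, and profile BMDL.

The three-group dataset admits a saturated degree-2 fit whose parameters
solve a linear system exactly; that analytic solution is the independent
oracle for the optimizer.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

import riskfuse as rf
from riskfuse.bmd import _ll_constant, _neg_ll, bmd_from_fit, multistage_prob
from riskfuse.fixtures_io import BioassayDataset, BioassayGroup

ONE_SIDED_95_CUTOFF = 1.352771727  # chi2(1, 0.90)/2


def saturated_degree2_oracle(data):
    """Analytic ML solution when a degree-2 model interpolates 3 groups."""
    g = data.n_affected[0] / data.n_examined[0]
    d1, d2 = data.doses[1], data.doses[2]
    p = [a / n for a, n in zip(data.n_affected[1:], data.n_examined[1:])]
    hazards = [-np.log(1 - (pi - g) / (1 - g)) for pi in p]
    M = np.array([[d1, d1**2], [d2, d2**2]])
    b1, b2 = np.linalg.solve(M, hazards)
    return g, (b1, b2)


def test_multistage_prob_basics():
    assert multistage_prob(0.05, (1e-4, 1e-8), 0.0) == 0.05
    assert multistage_prob(0.07, (0.0, 0.0), 1000.0) == pytest.approx(0.07)
    # 1 - exp(-1e-4 * 1053.605) = 0.1000
    assert multistage_prob(0.0, (1e-4, 0.0), 1053.605) == pytest.approx(0.1, abs=1e-6)


def test_predicted_probabilities_nondecreasing_in_dose():
    doses = np.linspace(0, 3000, 200)
    p = multistage_prob(0.014, (4e-5, 3e-8), doses)
    assert np.all(np.diff(p) >= 0)
    assert np.all((p >= 0) & (p <= 1))


@pytest.mark.parametrize(
    "betas, bmr, expected",
    [
        ((1e-4, 0.0), 0.1, 1053.605),  # linear closed form A/b1
        ((0.0, 1e-6), 0.1, 324.593),  # pure quadratic sqrt(A/b2)
    ],
)
def test_bmd_closed_forms(betas, bmr, expected):
    fit = rf.MultistageFit(2, 0.0, betas, 0.0, 0.0, 3, ())
    assert bmd_from_fit(fit, bmr) == pytest.approx(expected, abs=5e-3)


def test_bmd_requires_dose_response():
    fit = rf.MultistageFit(2, 0.1, (0.0, 0.0), 0.0, 0.0, 3, ())
    with pytest.raises(ValueError, match="no dose response"):
        bmd_from_fit(fit, 0.1)


def test_fit_matches_saturated_analytic_solution(bioassays, nikula_fit):
    """Three groups + three parameters: ML must interpolate exactly."""
    data = bioassays["nikula"]
    g, (b1, b2) = saturated_degree2_oracle(data)
    n = np.array(data.n_examined, float)
    x = np.array(data.n_affected, float)
    p = x / n
    ll_sat = float(np.sum(x * np.log(p) + (n - x) * np.log(1 - p))) + _ll_constant(n, x)
    assert nikula_fit.log_likelihood == pytest.approx(ll_sat, abs=1e-4)
    assert nikula_fit.gamma == pytest.approx(g, abs=1e-5)
    assert nikula_fit.betas[0] == pytest.approx(b1, rel=1e-3)
    assert nikula_fit.betas[1] == pytest.approx(b2, rel=1e-3)
    bmd_analytic = bmd_from_fit(rf.MultistageFit(2, g, (b1, b2), 0, 0, 3, ()), 0.1)
    assert bmd_from_fit(nikula_fit, 0.1) == pytest.approx(bmd_analytic, rel=1e-4)


def test_grid_search_never_beats_optimizer(bioassays, nikula_fit):
    """Dense grid over (γ, θ1, θ2) in scaled-dose space vs the optimizer."""
    data = bioassays["nikula"]
    d = np.array(data.doses, float)
    n = np.array(data.n_examined, float)
    x = np.array(data.n_affected, float)
    u = d / d.max()
    gs = np.linspace(0.005, 0.03, 12)
    t1s = np.linspace(0.0, 0.3, 25)
    t2s = np.linspace(0.0, 0.4, 25)
    best = np.inf
    for g in gs:
        for t1 in t1s:
            for t2 in t2s:
                best = min(best, _neg_ll(np.array([g, t1, t2]), u, n, x))
    ll_kernel = nikula_fit.log_likelihood - _ll_constant(n, x)
    assert -best <= ll_kernel + 1e-3


def test_flat_data_gives_zero_slope():
    data = BioassayDataset(
        "flat",
        (
            BioassayGroup(0, 100, 10),
            BioassayGroup(100, 100, 10),
            BioassayGroup(1000, 100, 10),
        ),
    )
    fit = rf.fit_multistage(data, 2)
    assert fit.gamma == pytest.approx(0.1, abs=1e-3)
    assert multistage_prob(fit.gamma, fit.betas, 1000.0) == pytest.approx(0.1, abs=2e-3)


def test_degree_two_selected_for_all_shipped_datasets(bioassays):
    for data in bioassays.values():
        sel = rf.select_degree(data, 2)
        assert sel.chosen == 2, data.label
        assert sel.fits[2].aic < sel.fits[1].aic
        assert 2 in sel.lrt_pvalues


def test_degree_one_selected_for_linear_data():
    data = rf.gen_bioassay(
        rf.BioassaySpec(
            gamma=0.01, betas=(1e-4,), doses=(0.0, 400.0, 1000.0, 2000.0),
            n_per_group=20_000, seed=9,
        )
    )
    assert rf.select_degree(data, 2).chosen == 1


def test_max_degree_one_is_trivial(bioassays):
    assert rf.select_degree(bioassays["nikula"], 1).chosen == 1


def test_aic_consistent_with_parameters(nikula_fit):
    assert nikula_fit.aic == pytest.approx(
        2 * nikula_fit.n_params - 2 * nikula_fit.log_likelihood, rel=1e-12
    )
    assert nikula_fit.n_params == 3


def test_bmd_invariant_under_dose_rescaling(bioassays):
    """Rescaling doses by c rescales betas by c^-j and leaves the BMD ratio."""
    data = bioassays["mauderly"]
    c = 10.0
    scaled = BioassayDataset(
        data.label,
        tuple(BioassayGroup(g.dose / c, g.n_examined, g.n_affected) for g in data.groups),
    )
    fit = rf.fit_multistage(data, 2)
    fit_scaled = rf.fit_multistage(scaled, 2)
    assert fit_scaled.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-6)
    bmd = bmd_from_fit(fit, 0.1)
    bmd_scaled = bmd_from_fit(fit_scaled, 0.1)
    assert bmd_scaled * c == pytest.approx(bmd, rel=1e-3)


def test_bmdl_below_bmd_for_all_datasets(bioassays):
    for data in bioassays.values():
        result = rf.benchmark_dose(data, degree=2)
        assert 0 < result.bmdl < result.bmd


def test_profile_property_at_the_bmdl(bioassays, nikula_fit):
    """Pinning the BMD at the returned BMDL drops the maximum log-likelihood
    by exactly the one-sided-95% cutoff (independent SLSQP check)."""
    data = bioassays["nikula"]
    bmdl = rf.bmdl_profile(data, nikula_fit, 0.1)
    d = np.array(data.doses, float)
    n = np.array(data.n_examined, float)
    x = np.array(data.n_affected, float)
    dmax = d.max()
    u, bs = d / dmax, bmdl / dmax
    A = -np.log(0.9)
    cons = {"type": "eq", "fun": lambda t: t[1] * bs + t[2] * bs**2 - A}
    best = np.inf
    for s0 in ([0.014, 0.7 * A / bs, 0.3 * A / bs**2], [0.01, A / bs, 0.0]):
        r = minimize(
            lambda t: _neg_ll(np.asarray(t), u, n, x),
            s0,
            method="SLSQP",
            bounds=[(0, 0.999), (0, None), (0, None)],
            constraints=[cons],
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        best = min(best, r.fun)
    ll_kernel_max = nikula_fit.log_likelihood - _ll_constant(n, x)
    assert -best == pytest.approx(ll_kernel_max - ONE_SIDED_95_CUTOFF, abs=1e-4)


def test_bmd_recovery_on_synthetic_bioassay():
    spec = rf.BioassaySpec(
        gamma=0.014, betas=(4e-5, 3e-8), doses=(0.0, 500.0, 1200.0, 2400.0),
        n_per_group=10_000, seed=5,
    )
    true_bmd = bmd_from_fit(rf.MultistageFit(2, spec.gamma, spec.betas, 0, 0, 3, ()), 0.1)
    fit = rf.fit_multistage(rf.gen_bioassay(spec), 2)
    assert bmd_from_fit(fit, 0.1) == pytest.approx(true_bmd, rel=0.10)


def test_bmdl_coverage_below_analytic_bmd():
    """Across seeded replicates the BMDL stays below the generating model's
    analytic BMD in at least 94% of cases."""
    spec_betas = (4e-5, 3e-8)
    true_bmd = bmd_from_fit(rf.MultistageFit(2, 0.014, spec_betas, 0, 0, 3, ()), 0.1)
    below = 0
    n_reps = 200
    for rep in range(n_reps):
        data = rf.gen_bioassay(
            rf.BioassaySpec(
                gamma=0.014, betas=spec_betas, doses=(0.0, 500.0, 1200.0, 2400.0),
                n_per_group=300, seed=50_000 + rep,
            )
        )
        fit = rf.fit_multistage(data, 2)
        try:
            bmdl = rf.bmdl_profile(data, fit, 0.1, rtol=1e-4)
        except (ValueError, RuntimeError):
            continue
        if bmdl < true_bmd:
            below += 1
    assert below / n_reps >= 0.94
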