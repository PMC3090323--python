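"""Fixed-effect and DerSimonian-Laird pooling on the linear RR scale."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import riskfuse as rf
from riskfuse.fixtures_io import StudyEstimate
from riskfuse.meta import (
    MetaInput,
    as_meta_inputs,
    pool_fixed,
    pool_random_dl,
    reproduce_table7,
    se_from_ci,
)


def make_inputs(rows):
    return [
        MetaInput(
            StudyEstimate(f"s{i}", "RR", est, lo, hi, "human"),
            se_from_ci(est, lo, hi),
        )
        for i, (est, lo, hi) in enumerate(rows)
    ]


@pytest.mark.parametrize(
    "est, lo, hi, expected",
    [
        (1.40, 1.30, 1.51, 0.05357),
        (1.426, 0.95, 1.90, 0.24235),
    ],
)
def test_se_from_ci(est, lo, hi, expected):
    assert se_from_ci(est, lo, hi) == pytest.approx(expected, abs=5e-6)


def test_se_from_inverted_ci_rejected():
    with pytest.raises(ValueError, match="inverted"):
        se_from_ci(1.4, 1.5, 1.3)
    with pytest.raises(ValueError):  # degenerate CI -> zero SE fails MetaInput
        MetaInput(StudyEstimate("x", "RR", 1.4, 1.4, 1.4, "human"), 0.0)


def test_fewer_than_two_studies_rejected():
    inputs = make_inputs([(1.4, 1.3, 1.5)])
    with pytest.raises(ValueError):
        pool_fixed(inputs)
    with pytest.raises(ValueError):
        pool_random_dl(inputs)


def test_animal_pool_fixed_equals_random(meta_inputs):
    inputs = as_meta_inputs(meta_inputs["animal"])
    fixed = pool_fixed(inputs)
    random = pool_random_dl(inputs)
    assert fixed.pooled == pytest.approx(1.365, abs=2e-3)
    assert fixed.ci[0] == pytest.approx(1.075, abs=2e-3)
    assert fixed.ci[1] == pytest.approx(1.654, abs=2e-3)
    assert random.tau2 == 0.0  # Q below its degrees of freedom
    assert random.pooled == fixed.pooled


def test_human_adjusted_pools(meta_inputs):
    inputs = as_meta_inputs(meta_inputs["human_adjusted"])
    fixed = pool_fixed(inputs)
    random = pool_random_dl(inputs)
    assert fixed.pooled == pytest.approx(1.279, abs=4e-3)
    assert random.pooled == pytest.approx(1.594, abs=2e-3)
    assert random.ci[0] == pytest.approx(1.086, abs=2e-3)
    assert random.ci[1] == pytest.approx(2.101, abs=2e-3)
    assert random.tau2 > 0


def test_six_study_pool_and_heterogeneity(meta_inputs):
    inputs = as_meta_inputs(meta_inputs["human_adjusted"] + meta_inputs["animal"])
    random = pool_random_dl(inputs)
    assert random.pooled == pytest.approx(1.492, abs=2e-3)
    assert random.ci[0] == pytest.approx(1.210, abs=2e-3)
    assert random.ci[1] == pytest.approx(1.775, abs=2e-3)
    assert 0.0005 < random.p_heterogeneity < 0.005


def test_unadjusted_human_random_pool_flagged_cell(meta_inputs):
    """The published 1.727 is not what linear-scale DL yields on the printed
    unadjusted inputs; the computed value is ~1.66."""
    inputs = as_meta_inputs(meta_inputs["human_unadjusted"])
    random = pool_random_dl(inputs)
    assert random.pooled == pytest.approx(1.657, abs=5e-3)
    assert abs(random.pooled - 1.727) > 0.05


def test_reproduce_table7_contains_all_pools(meta_inputs):
    pools = reproduce_table7(meta_inputs)
    assert set(pools) == {
        f"{s}_{m}"
        for s in ("human_adjusted", "human_unadjusted", "animal", "all_adjusted", "all_unadjusted")
        for m in ("fixed", "random")
    }
    assert pools["all_adjusted_random"].pooled == pytest.approx(1.492, abs=2e-3)


def test_identical_studies_pool_to_common_value():
    inputs = make_inputs([(1.5, 1.2, 1.8)] * 3)
    fixed = pool_fixed(inputs)
    assert fixed.pooled == pytest.approx(1.5, rel=1e-12)
    assert fixed.q == pytest.approx(0.0, abs=1e-12)


@given(
    effects=st.lists(st.floats(0.5, 3.0), min_size=2, max_size=8),
    se=st.floats(0.05, 0.5),
)
def test_equal_ses_pool_to_arithmetic_mean(effects, se):
    inputs = [
        MetaInput(
            StudyEstimate(f"s{i}", "RR", e, max(e - 1.96 * se, 1e-6), e + 1.96 * se, "human"),
            se,
        )
        for i, e in enumerate(effects)
    ]
    fixed = pool_fixed(inputs)
    assert fixed.pooled == pytest.approx(float(np.mean(effects)), rel=1e-9)
    assert min(effects) - 1e-12 <= fixed.pooled <= max(effects) + 1e-12
    random = pool_random_dl(inputs)
    assert min(effects) - 1e-12 <= random.pooled <= max(effects) + 1e-12
    # random CI is never narrower than fixed
    assert (random.ci[1] - random.ci[0]) >= (fixed.ci[1] - fixed.ci[0]) - 1e-12


def test_log_scale_option(meta_inputs):
    inputs = as_meta_inputs(meta_inputs["animal"], scale="log")
    fixed = pool_fixed(inputs, scale="log")
    assert 1.0 < fixed.pooled < 2.0
    assert fixed.ci[0] < fixed.pooled < fixed.ci[1]


def test_cross_check_against_statsmodels(meta_inputs):
    """Independent oracle: statsmodels' combine_effects on the same inputs."""
    sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
    inputs = as_meta_inputs(meta_inputs["human_adjusted"] + meta_inputs["animal"])
    effects = np.array([i.study.estimate for i in inputs])
    variances = np.array([i.se**2 for i in inputs])
    res = sm_meta.combine_effects(effects, variances, method_re="dl")
    df = res.summary_frame()
    ours_fixed = pool_fixed(inputs)
    ours_random = pool_random_dl(inputs)
    assert ours_fixed.pooled == pytest.approx(
        df.loc["fixed effect", "eff"], rel=1e-10
    )
    assert ours_random.pooled == pytest.approx(
        df.loc["random effect", "eff"], rel=1e-10
    )
    assert ours_random.tau2 == pytest.approx(res.tau2, rel=1e-10)
    assert ours_fixed.q == pytest.approx(res.q, rel=1e-10)


def test_tau2_recovery_on_synthetic_study_sets():
    """Median DL tau^2 over 500 seeded replicates is within 15% of truth."""
    true_tau2 = 0.1
    estimates = [
        rf.pool_random_dl(rf.gen_study_set(20, 1.5, true_tau2, (0.1, 0.3), seed=1000 + rep)).tau2
        for rep in range(500)
    ]
    assert float(np.median(estimates)) == pytest.approx(true_tau2, rel=0.15)
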