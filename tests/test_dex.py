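import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uvdex import (
    Contrast,
    SimConfig,
    bh_adjust,
    call_de,
    compute_pca,
    estimate_marginal_density,
    fit_empirical_null,
    generate_dataset,
    local_fdr,
    overlap_test,
    pairwise_tstats,
    remove_components,
    run_contrast,
    standardize_genes,
    t_to_z,
)
from uvdex.dex import EmpiricalNull, MarginalDensity
from uvdex.errors import DataError, DesignError
from uvdex.matrix import ExpressionMatrix
from uvdex.synthdata import EffectSpec


def _two_group_matrix(a_rows, b_rows):
    a_rows, b_rows = np.atleast_2d(a_rows), np.atleast_2d(b_rows)
    values = np.hstack([a_rows, b_rows])
    cols = [f"T_r{i+1}" for i in range(a_rows.shape[1])] + [
        f"C_r{i+1}" for i in range(b_rows.shape[1])
    ]
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                      columns=cols)
    ann = pd.DataFrame({"group": ["T"] * a_rows.shape[1] + ["C"] * b_rows.shape[1],
                        "zt": 0.0, "batch": "d1"}, index=cols)
    return ExpressionMatrix(df, ann)


# ---------------------------------------------------------------------------
# t statistics


def test_pooled_t_worked_example():
    X = _two_group_matrix([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]])
    res = pairwise_tstats(X, Contrast("T", "C"))
    assert res.loc["g0", "log2fc"] == -3.0
    assert res.loc["g0", "df"] == 4
    assert res.loc["g0", "t"] == pytest.approx(-3 / math.sqrt(2 / 3), abs=1e-9)


def test_identical_groups_give_zero():
    X = _two_group_matrix([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
    res = pairwise_tstats(X, Contrast("T", "C"))
    assert res.loc["g0", "t"] == 0.0
    assert res.loc["g0", "log2fc"] == 0.0


def test_swapping_groups_negates(rng):
    X = _two_group_matrix(rng.normal(size=(40, 5)), rng.normal(size=(40, 4)))
    fwd = pairwise_tstats(X, Contrast("T", "C"))
    rev = pairwise_tstats(X, Contrast("C", "T"))
    assert np.allclose(fwd["t"], -rev["t"], atol=1e-12)
    assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)


def test_matches_scipy_ttest(rng):
    a = rng.normal(size=(30, 6))
    b = rng.normal(0.3, 1.2, size=(30, 7))
    res = pairwise_tstats(_two_group_matrix(a, b), Contrast("T", "C"))
    ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
    assert np.allclose(res["t"], ref.statistic, atol=1e-10)


def test_zero_variance_gene_flagged_and_lfdr_one(rng, quiet):
    a = rng.normal(size=(1500, 5))
    b = rng.normal(size=(1500, 5))
    a[0], b[0] = 1.0, 2.0  # constant, different means: t undefined
    X = _two_group_matrix(a, b)
    res, _, _ = run_contrast(X, Contrast("T", "C"))
    assert np.isnan(res.loc["g0", "t"])
    assert res.loc["g0", "lfdr"] == 1.0


def test_missing_group_is_design_error(rng):
    X = _two_group_matrix(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
    with pytest.raises(DesignError, match="NOPE"):
        pairwise_tstats(X, Contrast("NOPE", "C"))


# ---------------------------------------------------------------------------
# z transformation


def test_t_to_z_properties():
    assert t_to_z(0.0, 4) == pytest.approx(0.0, abs=1e-12)
    # oracle: numerical t-CDF then normal quantile
    expect = stats.norm.ppf(stats.t.cdf(2.0, 4))
    assert t_to_z(2.0, 4) == pytest.approx(expect, abs=1e-9)
    assert t_to_z(2.0, 4) == pytest.approx(1.57, abs=0.01)
    assert abs(t_to_z(1.0, 10_000) - 1.0) < 0.01  # df -> infinity limit
    ts = np.linspace(-6, 6, 41)
    zs = t_to_z(ts, 16)
    assert np.all(np.diff(zs) > 0)
    assert np.all(np.sign(zs) == np.sign(ts))


def test_t_to_z_extreme_values_stay_finite():
    z = t_to_z(np.array([-50.0, 50.0]), 16)
    assert np.isfinite(z).all()


# ---------------------------------------------------------------------------
# marginal density


def test_density_matches_standard_normal(quiet):
    z = np.random.default_rng(0).standard_normal(50_000)
    d = estimate_marginal_density(z)
    grid = np.linspace(-2, 2, 81)
    assert np.max(np.abs(d.evaluate(grid) - stats.norm.pdf(grid))) < 0.02


@pytest.mark.parametrize("seed", [0, 1])
def test_density_integrates_to_one(seed, quiet):
    rng = np.random.default_rng(seed)
    z = np.concatenate([rng.normal(-2, 0.7, 8000), rng.normal(2, 1.2, 4000)])
    d = estimate_marginal_density(z)
    integral = float(np.sum(d.density) * d.bin_width)
    assert abs(integral - 1.0) < 1e-3
    assert np.all(d.density >= 0)


def test_degenerate_z_rejected():
    with pytest.raises(DataError, match="identical"):
        estimate_marginal_density(np.full(5000, 1.3))


def test_small_samples_warn():
    with pytest.warns(UserWarning, match="unstable"):
        estimate_marginal_density(np.random.default_rng(1).normal(size=500))


# ---------------------------------------------------------------------------
# empirical null


def test_null_recovery_pure_gaussian(quiet):
    z = np.random.default_rng(11).standard_normal(50_000)
    null = fit_empirical_null(z)
    assert -0.05 < null.delta0 < 0.05
    assert 0.95 < null.sigma0 < 1.05
    assert 0.95 < null.pi0 <= 1.0


def test_null_recovery_shifted_scaled(quiet):
    z = np.random.default_rng(12).normal(0.5, 1.2, 50_000)
    null = fit_empirical_null(z)
    assert 0.45 < null.delta0 < 0.55
    assert 1.15 < null.sigma0 < 1.25


def test_null_proportion_under_contamination(quiet):
    rng = np.random.default_rng(13)
    z = np.concatenate([rng.normal(0, 1, 18_000), rng.normal(3, 1, 2_000)])
    null = fit_empirical_null(z)
    assert 0.85 < null.pi0 < 0.95


def test_central_mle_agrees_on_clean_data(quiet):
    z = np.random.default_rng(14).normal(0.2, 1.1, 50_000)
    cm = fit_empirical_null(z, method="central-matching")
    mle = fit_empirical_null(z, method="central-mle")
    assert abs(cm.delta0 - mle.delta0) < 0.1
    assert abs(cm.sigma0 - mle.sigma0) < 0.12


def test_non_concave_center_falls_back_to_theoretical(quiet):
    rng = np.random.default_rng(15)
    z = np.concatenate([rng.normal(-3, 0.5, 10_000), rng.normal(3, 0.5, 10_000)])
    with pytest.warns(UserWarning, match="falling back"):
        null = fit_empirical_null(z)
    assert (null.delta0, null.sigma0) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# local fdr


def _analytic_density(fn, lo=-6.0, hi=6.0, n=2048):
    grid = np.linspace(lo, hi, n)
    f = fn(grid)
    return MarginalDensity(grid, np.log(f), grid[1] - grid[0], n=10**6)


def test_pure_null_lfdr_is_one():
    density = _analytic_density(stats.norm.pdf)
    null = EmpiricalNull(0.0, 1.0, 1.0)
    lfdr = local_fdr(np.linspace(-4, 4, 50), null, density)
    assert np.all(lfdr > 0.999)


def test_mixture_lfdr_closed_form_at_z3():
    def mix(z):
        return 0.9 * stats.norm.pdf(z) + 0.1 * stats.norm.pdf(z - 3)

    density = _analytic_density(mix)
    null = EmpiricalNull(0.0, 1.0, 0.9)
    expect = 0.9 * stats.norm.pdf(3) / (0.9 * stats.norm.pdf(3)
                                        + 0.1 * stats.norm.pdf(0))
    got = local_fdr(np.array([3.0]), null, density)[0]
    assert got == pytest.approx(expect, abs=1e-3)
    assert expect == pytest.approx(0.091, abs=0.001)


def test_lfdr_capped_at_one(quiet):
    z = np.random.default_rng(16).standard_normal(5_000)
    d = estimate_marginal_density(z)
    null = fit_empirical_null(z, density=d)
    assert np.max(local_fdr(z, null, d)) <= 1.0


# ---------------------------------------------------------------------------
# BH baseline, calls, overlap


def test_bh_step_up_worked_example():
    q = bh_adjust([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust([1.0, 1.0]), 1.0)


def test_call_sets_split_by_direction_and_nest():
    res = pd.DataFrame(
        {"lfdr": [0.005, 0.05, 0.5, 1.0], "log2fc": [0.4, -0.3, 0.2, -0.1]},
        index=list("abcd"),
    )
    up01, down01 = call_de(res, 0.1)
    up001, down001 = call_de(res, 0.01)
    assert (up01, down01) == ({"a"}, {"b"})
    assert up001 <= up01 and down001 <= down01
    assert call_de(res.assign(lfdr=1.0), 0.1) == (set(), set())
    with pytest.raises(ValueError):
        call_de(res, 1.5)


def test_overlap_disjoint_and_single_term():
    universe = {f"g{i}" for i in range(20)}
    a = {f"g{i}" for i in range(5)}
    b = {f"g{i}" for i in range(5, 10)}
    assert overlap_test(a, b, universe) == (0, 1.0)
    k, p = overlap_test(a, a, universe)
    assert k == 5
    assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)


def test_overlap_matches_enumeration_small_margins():
    for m in (5, 9, 12):
        universe = {f"g{i}" for i in range(m)}
        for na in range(m + 1):
            for nb in range(m + 1):
                a = {f"g{i}" for i in range(na)}
                b = {f"g{i}" for i in range(m - nb, m)}
                k, p = overlap_test(a, b, universe)
                brute = sum(
                    math.comb(na, j) * math.comb(m - na, nb - j)
                    for j in range(k, min(na, nb) + 1)
                ) / math.comb(m, nb)
                assert p == pytest.approx(min(1.0, brute), rel=1e-9, abs=1e-12)


def test_sets_must_lie_in_universe():
    with pytest.raises(DataError):
        overlap_test({"x"}, {"y"}, {"y"})


# ---------------------------------------------------------------------------
# planted-effect recovery (generator truth as oracle)


def test_sensitivity_and_fdp_on_planted_effects(quiet):
    """Strong planted effects (0.5 log2) should be recovered at fdr<0.1
    after single-component removal, with few false calls."""
    contrast = Contrast("FC30'", "CC30'")
    sens, fdp = [], []
    for seed in range(1, 11):
        cfg = SimConfig(
            seed=seed,
            effects=[
                EffectSpec("FC30'", 100, 83, (0.5, 0.5)),
                EffectSpec("RT30'", 100, 83, (0.5, 0.5), share_up_with="FC30'"),
            ],
        )
        X, truth = generate_dataset(cfg)
        planted = set(truth.de_genes["FC30'"])
        Xs = standardize_genes(X)
        Xn = remove_components(Xs, compute_pca(Xs), 1)
        res, _, _ = run_contrast(Xn, contrast)
        up, down = call_de(res, 0.1)
        called = up | down
        sens.append(len(called & planted) / len(planted))
        fdp.append(len(called - planted) / max(len(called), 1))
    assert np.mean(sens) >= 0.8
    assert np.mean(fdp) <= 0.2
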