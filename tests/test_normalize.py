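import numpy as np
import pandas as pd
import pytest

from uvdex import (
    SimConfig,
    compute_pca,
    correlated_pc_module,
    generate_dataset,
    remove_components,
    standardize_genes,
)
from uvdex.errors import DesignError
from uvdex.matrix import ExpressionMatrix
from uvdex.normalize import PcaModel
from uvdex.synthdata import CircadianSpec, FactorSpec


def _matrix(values, columns=None):
    values = np.asarray(values, dtype=float)
    cols = columns or [f"s{i}_r1" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                      columns=cols)
    ann = pd.DataFrame({"group": [c.rsplit("_", 1)[0] for c in cols],
                        "zt": 0.0, "batch": "d1"}, index=cols)
    return ExpressionMatrix(df, ann)


# ---------------------------------------------------------------------------
# standardization


def test_standardize_centers_scales_and_flags():
    X = _matrix([[5, 5, 5], [1, 2, 3]])
    out = standardize_genes(X, scale=True)
    assert np.allclose(out.values.loc["g0"], 0.0)
    assert out.zero_variance_genes == ("g0",)
    assert np.allclose(out.values.loc["g1"], [-1, 0, 1])  # sample sd = 1


def test_standardize_row_means_vanish(rng):
    X = _matrix(rng.normal(5, 2, (50, 10)))
    out = standardize_genes(X)
    assert np.abs(out.values.mean(axis=1)).max() < 1e-12


def test_standardize_requires_two_samples():
    with pytest.raises(DesignError):
        standardize_genes(_matrix([[1.0], [2.0]]))


# ---------------------------------------------------------------------------
# PCA


def test_rank_one_matrix_has_single_component(rng, quiet):
    u = rng.normal(size=30)
    v = rng.normal(size=6)
    model = compute_pca(_matrix(np.outer(u, v)))
    assert model.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all(model.variance_fractions[1:] < 1e-12)


def test_singular_values_match_dense_eigendecomposition(rng, quiet):
    A = rng.normal(size=(4, 3))
    model = compute_pca(_matrix(A))
    eigvals = np.linalg.eigvalsh(A.T @ A)[::-1]
    assert np.allclose(model.singular_values ** 2, eigvals[: len(model.singular_values)],
                       atol=1e-10)


def test_pca_reconstructs_matrix_and_orthonormal_loadings(standardized):
    Xs, model, _ = standardized
    L = model.sample_loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
    recon = model.gene_scores.to_numpy() @ L.T
    assert np.allclose(recon, Xs.values.to_numpy(), atol=1e-8)


def test_pca_warns_on_uncentered_input(rng):
    X = _matrix(rng.normal(8, 1, (20, 5)))
    with pytest.warns(UserWarning, match="centered"):
        compute_pca(X)


def test_deterministic_sign_convention(standardized):
    Xs, model, _ = standardized
    for j in range(3):
        col = model.sample_loadings.iloc[:, j].to_numpy()
        assert col[np.argmax(np.abs(col))] > 0


# ---------------------------------------------------------------------------
# component removal


def test_remove_zero_components_is_identity(standardized):
    Xs, model, _ = standardized
    out = remove_components(Xs, model, 0)
    assert out.values.equals(Xs.values)


def test_rank_one_residual_is_zero(rng, quiet):
    X = _matrix(np.outer(rng.normal(size=20), rng.normal(size=5)))
    model = compute_pca(X)
    resid = remove_components(X, model, 1)
    assert np.abs(resid.values.to_numpy()).max() < 1e-10


def test_removal_is_idempotent_and_orthogonal(standardized):
    Xs, model, _ = standardized
    once = remove_components(Xs, model, 2)
    twice = remove_components(once, model, 2)
    assert np.allclose(once.values, twice.values, atol=1e-10)
    L = model.sample_loadings.to_numpy()[:, :2]
    assert np.abs(once.values.to_numpy() @ L).max() < 1e-8


def test_energy_accounting(standardized):
    Xs, model, _ = standardized
    k = 3
    resid = remove_components(Xs, model, k)
    total = float((Xs.values.to_numpy() ** 2).sum())
    kept = float((resid.values.to_numpy() ** 2).sum())
    removed = float((model.singular_values[:k] ** 2).sum())
    assert abs(total - (kept + removed)) < 1e-8 * total


def test_k_beyond_rank_rejected(standardized):
    Xs, model, _ = standardized
    with pytest.raises(ValueError):
        remove_components(Xs, model, model.n_components + 1)


def test_residual_uncorrelated_with_planted_loadings(quiet):
    cfg = SimConfig(
        factors=[FactorSpec(0.8, module_size=100, module_energy_share=0.5)],
        circadian=CircadianSpec(variance_fraction=0.0),
        effects=[],
        noise_sd=0.05,
        seed=21,
    )
    X, truth = generate_dataset(cfg)
    Xs = standardize_genes(X)
    model = compute_pca(Xs)
    resid = remove_components(Xs, model, 1)
    col_means = resid.values.to_numpy().mean(axis=0)
    planted = truth.factor_loadings["factor1"].to_numpy()
    r = np.corrcoef(col_means, planted)[0, 1]
    assert abs(r) < 0.05


# ---------------------------------------------------------------------------
# correlated module extraction


def test_module_size_under_iid_scores(rng):
    n = 1000
    scores = rng.normal(size=(n, 4))
    model = PcaModel(
        gene_scores=pd.DataFrame(scores, index=[f"g{i}" for i in range(n)],
                                 columns=list("ABCD")),
        sample_loadings=pd.DataFrame(np.eye(4)),
        singular_values=np.array([4.0, 3.0, 2.0, 1.0]),
        variance_fractions=np.array([0.4, 0.3, 0.2, 0.1]),
    )
    got = correlated_pc_module(model, 0, 1, 0.01)
    assert len(got) == int(np.ceil(0.01 * n))


def test_zero_scores_give_empty_module():
    n = 50
    scores = np.zeros((n, 2))
    scores[:, 0] = np.arange(n, dtype=float) + 1
    model = PcaModel(
        gene_scores=pd.DataFrame(scores, index=[f"g{i}" for i in range(n)]),
        sample_loadings=pd.DataFrame(np.eye(2)),
        singular_values=np.array([1.0, 0.0]),
        variance_fractions=np.array([1.0, 0.0]),
    )
    assert correlated_pc_module(model, 0, 1, 0.05) == set()


def test_identical_components_rejected(standardized):
    _, model, _ = standardized
    with pytest.raises(ValueError):
        correlated_pc_module(model, 1, 1, 0.05)


def test_planted_module_recovered_from_score_products():
    recoveries = []
    for seed in (1, 2, 3):
        X, truth = generate_dataset(SimConfig(seed=seed))
        model = compute_pca(standardize_genes(X))
        got = correlated_pc_module(model, 0, 1, 172 / 2000)
        recoveries.append(len(got & truth.unwanted_module) / 172)
    assert np.mean(recoveries) >= 0.8
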