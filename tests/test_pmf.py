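import numpy as np
import pandas as pd
import pytest

from soilrisk import SampleTable, default_source_spec, generate_mixture
from soilrisk.pmf import PMF, build_uncertainty, match_factors, robust_q


@pytest.fixture(scope="module")
def exact_rank2():
    rng = np.random.default_rng(42)
    G0 = rng.uniform(0.5, 2.0, (30, 2))
    F0 = rng.uniform(1.0, 10.0, (2, 6))
    return G0, F0, G0 @ F0


# -- uncertainty rules ------------------------------------------------------


def test_uncertainty_rules_boundary_cases():
    conc = pd.DataFrame({"Cd": [0.6, 2.0, 1.0]})
    unc = build_uncertainty(conc, mdl={"Cd": 1.2})
    # X <= MDL: alpha = (5/6) MDL
    assert unc.alpha.loc[0, "Cd"] == pytest.approx(5 / 6 * 1.2)
    assert unc.rule.loc[0, "Cd"] == "below_mdl"
    # X > MDL: alpha = 0.05 X + MDL
    assert unc.alpha.loc[1, "Cd"] == pytest.approx(0.05 * 2.0 + 1.2)
    assert unc.rule.loc[1, "Cd"] == "above_mdl"
    # X = MDL exactly -> below-detection branch (<= rule)
    assert unc.alpha.loc[2, "Cd"] == pytest.approx(5 / 6 * 1.2)
    assert unc.rule.loc[2, "Cd"] == "below_mdl"


def test_uncertainty_rule_example_from_equations():
    conc = pd.DataFrame({"Pb": [2.0]})
    unc = build_uncertainty(conc, mdl={"Pb": 1.0})
    assert unc.alpha.loc[0, "Pb"] == pytest.approx(1.1)


def test_uncertainty_requires_mdl_for_every_element():
    conc = pd.DataFrame({"Hg": [1.0]})  # no shipped MDL for Hg
    with pytest.raises(Exception, match="Hg"):
        build_uncertainty(conc)


def test_half_mdl_substitution_in_design_matrix():
    data = pd.DataFrame(
        {
            "sample_id": ["a", "b"],
            "land_use": ["PA", "PA"],
            "As": [3.0, 4.0],
            "Cd": [0.001, 0.5],  # first is below the 0.004 MDL
        }
    )
    model = PMF.from_sample_table(SampleTable(data=data))
    j = model.species.index("Cd")
    assert model.X[0, j] == pytest.approx(0.002)
    assert model.X[1, j] == pytest.approx(0.5)


# -- fitting ----------------------------------------------------------------


def test_exact_rank_recovered(exact_rank2):
    _, _, X = exact_rank2
    res = PMF(X, np.ones_like(X)).fit(2, n_runs=5, seed=1, max_iter=20000, tol=1e-12)
    assert res.q_true < 1e-6 * X.size
    assert (res.r2 > 0.999).all()
    # reconstruction identity: X = GF + E by definition of E
    recon = res.fitted.to_numpy() + res.residuals.to_numpy()
    np.testing.assert_allclose(recon, X, rtol=1e-12)


def test_factor_elbow_at_true_rank(exact_rank2):
    _, _, X = exact_rank2
    model = PMF(X, np.ones_like(X))
    q1 = model.fit(1, n_runs=3, seed=2, max_iter=20000, tol=1e-12).q_true
    q2 = model.fit(2, n_runs=3, seed=2, max_iter=20000, tol=1e-12).q_true
    assert q2 < 1e-3 * q1


def test_q_monotone_non_increasing(exact_rank2):
    _, _, X = exact_rank2
    res = PMF(X, np.ones_like(X)).fit(2, n_runs=1, seed=3, max_iter=20000, tol=1e-12)
    assert len(res.q_path) > 100
    diffs = np.diff(res.q_path)
    assert (diffs <= 1e-8 * np.abs(res.q_path[:-1])).all()


def test_same_seed_bit_identical(exact_rank2):
    _, _, X = exact_rank2
    model = PMF(X, np.ones_like(X))
    a = model.fit(2, n_runs=3, seed=7, max_iter=20000, tol=1e-10)
    b = model.fit(2, n_runs=3, seed=7, max_iter=20000, tol=1e-10)
    np.testing.assert_array_equal(a.profiles.to_numpy(), b.profiles.to_numpy())
    np.testing.assert_array_equal(
        a.contributions.to_numpy(), b.contributions.to_numpy()
    )


def test_sample_permutation_equivariance(exact_rank2):
    _, _, X = exact_rank2
    rng = np.random.default_rng(0)
    perm = rng.permutation(X.shape[0])
    res = PMF(X, np.ones_like(X)).fit(2, n_runs=1, seed=5, max_iter=2000, tol=1e-12)
    res_p = PMF(X[perm], np.ones_like(X)).fit(
        2, n_runs=1, seed=5, max_iter=2000, tol=1e-12
    )
    # Q is invariant under row exchange (same basin: same q within tolerance)
    assert res_p.q_true == pytest.approx(res.q_true, rel=1e-3, abs=1e-6)


def test_invalid_inputs_rejected(exact_rank2):
    _, _, X = exact_rank2
    with pytest.raises(Exception, match="[Nn]onnegative|negative"):
        PMF(-X, np.ones_like(X))
    bad = X.copy()
    bad[0, 0] = np.nan
    with pytest.raises(Exception, match="NaN"):
        PMF(bad, np.ones_like(X))
    model = PMF(X, np.ones_like(X))
    with pytest.raises(ValueError):
        model.fit(0)
    with pytest.raises(ValueError):
        model.fit(6)  # >= min(n_samples, n_species)


# -- robust Q ---------------------------------------------------------------


def test_robust_q_caps_outliers():
    scaled = np.array([[1.0, 8.0], [0.5, 2.0]])
    # 8 -> contributes 16 instead of 64
    assert robust_q(scaled, 4.0) == pytest.approx(1 + 16 + 0.25 + 4)
    no_outliers = np.array([[1.0, 2.0]])
    assert robust_q(no_outliers, 4.0) == pytest.approx(float((no_outliers**2).sum()))


def test_robust_q_never_exceeds_true_q(exact_rank2):
    rng = np.random.default_rng(9)
    scaled = rng.standard_normal((50, 6)) * 3
    assert robust_q(scaled, 4.0) <= float((scaled**2).sum())


# -- apportionment ----------------------------------------------------------


def test_single_factor_gets_all_mass(exact_rank2):
    _, _, X = exact_rank2
    res = PMF(X, np.ones_like(X)).fit(1, n_runs=2, seed=11, max_iter=5000, tol=1e-12)
    np.testing.assert_allclose(
        res.factor_contributions().to_numpy(), 100.0, atol=1e-6
    )


def test_disjoint_sources_split_cleanly():
    # two sources emitting disjoint element sets -> 100/0 apportionment,
    # up to the slow boundary decay of the multiplicative updates
    F = np.array([[10.0, 5.0, 0.0, 0.0], [0.0, 0.0, 8.0, 2.0]])
    rng = np.random.default_rng(3)
    G = rng.gamma(0.8, 1.0, (40, 2))
    X = G @ F
    res = PMF(X, np.ones_like(X)).fit(2, n_runs=5, seed=13, max_iter=20000, tol=1e-8)
    shares = res.factor_contributions().to_numpy()
    np.testing.assert_allclose(shares.sum(axis=1), 100.0, atol=1e-9)
    assert ((shares > 97.0) | (shares < 3.0)).all()


def test_three_source_mixture_recovery():
    """Contribution percentages recovered within 10 points of ground truth."""
    spec = default_source_spec()
    table, G_true, F_true = generate_mixture(spec, 120, seed=21)
    model = PMF.from_sample_table(table)
    res = model.fit(3, n_runs=8, seed=22)
    perm = match_factors(res.profiles, spec.profiles)
    est = res.factor_contributions().to_numpy()[:, perm].T  # sources x elements
    mass = G_true.sum(axis=0)[:, None] * F_true
    truth = 100.0 * mass / mass.sum(axis=0)
    assert np.abs(est - truth).max() < 10.0


def test_run_table_and_best_run_selection(exact_rank2):
    _, _, X = exact_rank2
    res = PMF(X, np.ones_like(X)).fit(2, n_runs=4, seed=17, max_iter=2000, tol=1e-10)
    assert list(res.runs.columns) == [
        "run", "seed", "q_true", "q_robust", "converged", "n_iter",
    ]
    assert len(res.runs) == 4
    best = res.runs[res.runs.converged].q_robust.min()
    assert res.q_robust == pytest.approx(best, rel=1e-6)


def test_summary_mentions_key_diagnostics(exact_rank2):
    _, _, X = exact_rank2
    res = PMF(X, np.ones_like(X)).fit(2, n_runs=2, seed=19, max_iter=1000, tol=1e-10)
    text = res.summary()
    for token in ("factors: 2", "Q (true)", "R^2", "apportionment"):
        assert token in text


def test_unweighted_case_agrees_with_sklearn_nmf(exact_rank2):
    """With uniform uncertainties the objective reduces to a plain
    Frobenius NMF; scikit-learn's solver is the independent cross-check."""
    sklearn = pytest.importorskip("sklearn.decomposition")
    _, _, X = exact_rank2
    res = PMF(X, np.ones_like(X)).fit(2, n_runs=3, seed=23, max_iter=20000, tol=1e-12)
    nmf = sklearn.NMF(2, init="random", random_state=0, max_iter=2000, tol=1e-10)
    W = nmf.fit_transform(X)
    frob_sklearn = float(((X - W @ nmf.components_) ** 2).sum())
    assert res.q_true <= frob_sklearn + 1e-6
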