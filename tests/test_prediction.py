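"""RRBLUP marker model, GCA estimation, sliding training window."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweetsim import (RRBLUP, TrainingSet, build_trait, estimate_gca,
                      fit_rrblup, predict_gebv, update_window)
from sweetsim.trait import additive_value, genetic_value

from conftest import make_hwe_population


def _simulate_instance(n, m, lam, rng, n_qtl=None):
    """Data drawn from the ridge model itself: y = mu + Z u + e with
    var(u) = s2m, var(e) = lam * s2m."""
    Z = rng.integers(0, 3, size=(n, m)).astype(float)
    s2m = 1.0
    u = rng.normal(0, np.sqrt(s2m), size=m)
    e = rng.normal(0, np.sqrt(lam * s2m), size=n)
    y = 5.0 + Z @ u + e
    return Z, y, u


# --------------------------------------------------------------------------
# REML / MME correctness
# --------------------------------------------------------------------------

def _mme_solve(Z, y, lam):
    """Direct mixed-model-equation oracle: the full (m+1) x (m+1) system
    [[n, 1'Z], [Z'1, Z'Z + lam I]] [mu; u] = [1'y; Z'y]."""
    n, m = Z.shape
    lhs = np.zeros((m + 1, m + 1))
    lhs[0, 0] = n
    lhs[0, 1:] = Z.sum(axis=0)
    lhs[1:, 0] = Z.sum(axis=0)
    lhs[1:, 1:] = Z.T @ Z + lam * np.eye(m)
    rhs = np.concatenate([[y.sum()], Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[0], sol[1:]


def _reml_loglik_oracle(Z, y, lam):
    """Brute-force restricted log-likelihood (profiled over sigma2_m) via
    dense determinants - independent of the spectral shortcut."""
    n = len(y)
    V = Z @ Z.T + lam * np.eye(n)
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    xvx = one @ Vi @ one
    P = Vi - np.outer(Vi @ one, Vi @ one) / xvx
    quad = y @ P @ y
    sign, logdet = np.linalg.slogdet(V)
    assert sign > 0
    return -0.5 * ((n - 1) * np.log(quad) + logdet + np.log(xvx))


def test_gebv_equals_mme_oracle(rng):
    """Fitted effects reproduce the direct dense MME solve at the REML
    lambda to 1e-6 (n=30, m=100)."""
    Z, y, _ = _simulate_instance(30, 100, 2.0, rng)
    model = RRBLUP().fit(Z, y)
    mu, u = _mme_solve(Z, y, model.lambda_)
    np.testing.assert_allclose(model.predict(Z), mu + Z @ u, atol=1e-6)
    np.testing.assert_allclose(model.u_, u, atol=1e-6)
    assert model.mu_ == pytest.approx(mu, abs=1e-6)


def test_reml_lambda_against_grid_search_oracle(rng):
    """n=400 instance with true lambda=2: the spectral REML optimum falls
    inside the central 99% likelihood region of a dense grid search over
    lambda in [0.01, 100]."""
    Z, y, _ = _simulate_instance(400, 80, 2.0, rng)
    model = RRBLUP().fit(Z, y)
    grid = np.logspace(np.log10(0.01), np.log10(100), 60)
    ll = np.array([_reml_loglik_oracle(Z, y, g) for g in grid])
    lik = np.exp(ll - ll.max())
    lik /= lik.sum()
    cdf = np.cumsum(lik)
    lo = grid[np.searchsorted(cdf, 0.005)]
    hi = grid[min(np.searchsorted(cdf, 0.995), len(grid) - 1)]
    assert lo <= model.lambda_ <= hi
    # and the spectral restricted likelihood agrees with the dense oracle
    # up to an additive constant across lambda values
    f = model._reml_objective
    diffs = [f(np.log10(g)) - (-2.0) * _reml_loglik_oracle(Z, y, g)
             for g in (0.5, 2.0, 8.0)]
    assert np.ptp(diffs) < 1e-6


def test_reml_is_local_optimum(rng):
    """The returned lambda beats 20 random probes of the objective."""
    Z, y, _ = _simulate_instance(120, 60, 1.0, rng)
    model = RRBLUP().fit(Z, y)
    f = model._reml_objective
    best = f(np.log10(model.lambda_))
    probes = 10.0 ** rng.uniform(-5, 5, size=20)
    assert all(best <= f(np.log10(p)) + 1e-8 for p in probes)


def test_constant_response_degenerate_fit(rng):
    Z = rng.integers(0, 3, size=(12, 20)).astype(float)
    y = np.full(12, 3.14)
    model = RRBLUP().fit(Z, y)
    assert model.degenerate_
    assert np.all(model.u_ == 0.0)
    np.testing.assert_allclose(model.predict(Z), 3.14)


def test_input_validation(rng):
    Z = rng.integers(0, 3, size=(10, 5)).astype(float)
    with pytest.raises(ValueError):
        RRBLUP().fit(Z[:1], np.array([1.0]))
    model = RRBLUP().fit(Z, rng.normal(size=10))
    with pytest.raises(ValueError, match="mismatch"):
        model.predict(np.zeros((3, 4)))


def test_shrinkage_limit_large_lambda(rng):
    """As lambda -> inf the effects vanish and predictions collapse to the
    intercept."""
    Z, y, _ = _simulate_instance(50, 30, 1.0, rng)
    big = RRBLUP(lambda_bounds=(1e9, 1e10)).fit(Z, y)
    assert np.abs(big.u_).max() < 1e-4
    np.testing.assert_allclose(big.predict(Z), np.full(50, big.mu_),
                               atol=1e-2)


def test_identical_genotypes_get_identical_gebvs(small_spec, rng):
    pop = make_hwe_population(small_spec, 30, rng)
    trait = build_trait(pop, rng=rng)
    Z = pop.dosage(small_spec.snp_sites).astype(float)
    y = genetic_value(pop, trait) + rng.normal(0, 3, size=30)
    model = RRBLUP().fit(Z, y)
    from sweetsim import Population
    twin = Population(small_spec, pop.haplo[[4, 4, 9]],
                      ids=np.array([100, 101, 102]))
    g = predict_gebv(model, twin)
    assert g[0] == g[1] != g[2]


# --------------------------------------------------------------------------
# predictive value on simulated genetics
# --------------------------------------------------------------------------

def _family_population(spec, founders, n, rng, id_start=1000):
    """Progeny of random founder pairs: markers and QTN co-segregate on
    founder haplotype segments, giving the within-family LD that genomic
    prediction exploits."""
    from sweetsim import cross_pairs
    m = rng.integers(0, founders.n, size=n)
    f = rng.integers(0, founders.n, size=n)
    clash = f == m
    f[clash] = (f[clash] + 1) % founders.n
    return cross_pairs(founders, m, founders, f, rng, id_start=id_start)


def test_gebv_beats_single_rep_phenotype_at_low_heritability(small_spec):
    """With sigma2res=240 and n=400 training individuals from a structured
    (related) population, GEBV ranks candidates closer to their true
    additive values than a single-replicate phenotype does (paired over 20
    simulation replicates)."""
    wins, diffs = 0, []
    for rep in range(20):
        rng = np.random.default_rng(500 + rep)
        founders = make_hwe_population(small_spec, 20, rng)
        pop = _family_population(small_spec, founders, 400, rng)
        trait = build_trait(founders, residual_var=240.0, rng=rng)
        a = additive_value(pop, trait)
        pheno = genetic_value(pop, trait) + rng.normal(0, np.sqrt(240), 400)
        model = RRBLUP().fit(pop.dosage(small_spec.snp_sites).astype(float),
                             pheno)
        gebv = predict_gebv(model, pop)
        c_gebv = np.corrcoef(gebv, a)[0, 1]
        c_ph = np.corrcoef(pheno, a)[0, 1]
        wins += c_gebv > c_ph
        diffs.append(c_gebv - c_ph)
    assert wins >= 15
    assert np.mean(diffs) > 0


def test_accuracy_increases_with_training_size(small_spec):
    """Hold-out accuracy on sibs of the training families is monotone over
    n in {50, 200, 800} within Monte-Carlo slack."""
    acc = {}
    for n in (50, 200, 800):
        vals = []
        for rep in range(8):
            rng = np.random.default_rng(900 + rep)
            founders = make_hwe_population(small_spec, 20, rng)
            train = _family_population(small_spec, founders, n, rng)
            test = _family_population(small_spec, founders, 200, rng,
                                      id_start=10**6)
            trait = build_trait(founders, residual_var=240.0, rng=rng)
            y = genetic_value(train, trait) + rng.normal(0, np.sqrt(240), n)
            model = RRBLUP().fit(
                train.dosage(small_spec.snp_sites).astype(float), y)
            vals.append(np.corrcoef(predict_gebv(model, test),
                                    additive_value(test, trait))[0, 1])
        acc[n] = np.mean(vals)
    assert acc[800] > acc[50]
    assert acc[200] >= acc[50] - 0.03
    assert acc[800] >= acc[200] - 0.03


# --------------------------------------------------------------------------
# GCA
# --------------------------------------------------------------------------

class TestGca:
    def test_single_tester_centering(self):
        df = pd.DataFrame({"parent": [1, 2], "tester": [9, 9],
                           "value": [10.0, 20.0]})
        gca = estimate_gca(df)["gca"]
        assert gca.loc[1] == pytest.approx(-5.0)
        assert gca.loc[2] == pytest.approx(5.0)

    def test_balanced_three_tester_closed_form(self, rng):
        parents, testers = np.arange(8), np.arange(100, 103)
        rows = [dict(parent=p, tester=t,
                     value=float(rng.normal(50 + 3 * p - t, 1)))
                for p in parents for t in testers]
        df = pd.DataFrame(rows)
        gca = estimate_gca(df)["gca"]
        grand = df["value"].mean()
        for p in parents:
            mean_p = df[df.parent == p]["value"].mean()
            assert gca.loc[p] == pytest.approx(mean_p - grand, abs=1e-10)
        assert gca.sum() == pytest.approx(0.0, abs=1e-9)

    def test_unbalanced_two_way_fit_recovers_effects(self, rng):
        """Missing cells: the least-squares main-effects fit still recovers
        the simulated parent effects."""
        p_eff = {0: -3.0, 1: 0.0, 2: 3.0}
        t_eff = {7: -1.0, 8: 1.0}
        rows = [dict(parent=p, tester=t, value=100 + p_eff[p] + t_eff[t])
                for p in p_eff for t in t_eff]
        rows = rows[:-1]  # drop one cell -> unbalanced
        gca = estimate_gca(pd.DataFrame(rows))["gca"]
        centred = {p: v - np.mean(list(p_eff.values()))
                   for p, v in p_eff.items()}
        for p, v in centred.items():
            assert gca.loc[p] == pytest.approx(v, abs=1e-8)

    def test_tc2_layout_produces_one_gca_per_parent(self, rng):
        parents = np.arange(100)
        testers = np.arange(1000, 1003)
        df = pd.DataFrame([dict(parent=p, tester=t, value=rng.normal())
                           for p in parents for t in testers])
        gca = estimate_gca(df)
        assert len(gca) == 100
        assert set(gca["n_testers"]) == {3}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            estimate_gca(pd.DataFrame({"parent": [1], "value": [1.0]}))


# --------------------------------------------------------------------------
# sliding window
# --------------------------------------------------------------------------

class TestWindow:
    def _records(self, years, m=5, n=3):
        rng = np.random.default_rng(0)
        return [(rng.integers(0, 3, (n, m)).astype(float),
                 rng.normal(size=n), np.arange(n) + 10 * y, y)
                for y in years]

    def test_four_year_retention(self):
        train = TrainingSet(window_years=4)
        train = update_window(train, self._records([1, 2, 3, 4, 5]), 5)
        assert train.years == [2, 3, 4, 5]

    def test_empty_update_is_pure_expiry(self):
        train = update_window(TrainingSet(4), self._records([1, 2, 3]), 3)
        out = update_window(train, [], 6)
        assert out.years == [3]
        assert train.years == [1, 2, 3]  # input untouched

    def test_idempotent_for_fixed_year(self):
        train = update_window(TrainingSet(4), self._records([1, 2, 3, 4]), 4)
        again = update_window(train, [], 4)
        assert again.years == train.years
        assert again.n_records == train.n_records

    def test_steady_state_testcross_window_size(self):
        """Yearly additions of 150+100+15 parent records give a steady-state
        window of 4 x 265 = 1,060 records."""
        rng = np.random.default_rng(1)
        train = TrainingSet(4)
        sizes = (150, 100, 15)
        for year in range(1, 11):
            for k in sizes:
                train.add(rng.integers(0, 3, (k, 4)).astype(float),
                          rng.normal(size=k), np.arange(k), year)
            train.prune(year)
        assert train.n_records == 4 * sum(sizes) == 1060

    def test_cached_stats_match_pooled_fit(self):
        """Fitting from per-block cached cross-products equals fitting the
        pooled matrix directly."""
        rng = np.random.default_rng(3)
        train = TrainingSet(4)
        for year in (1, 2, 3):
            Z = rng.integers(0, 3, (30, 25)).astype(float)
            y = rng.normal(size=30) + Z[:, 0]
            train.add(Z, y, np.arange(30) + 100 * year, year)
        model = fit_rrblup(train)
        Z, y = train.pooled()
        direct = RRBLUP().fit(Z, y)
        assert model.lambda_ == pytest.approx(direct.lambda_, rel=1e-6)
        np.testing.assert_allclose(model.u_, direct.u_, atol=1e-8)


def test_effects_table_round_trip(small_spec, rng, tmp_path):
    from sweetsim import write_effects_table
    pop = make_hwe_population(small_spec, 40, rng)
    y = rng.normal(size=40) + pop.dosage(small_spec.snp_sites)[:, 0]
    model = RRBLUP().fit(pop.dosage(small_spec.snp_sites).astype(float), y)
    path = tmp_path / "effects.tsv"
    write_effects_table(model, small_spec, path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    assert len(df) == small_spec.snp_sites.size
    np.testing.assert_array_equal(df["effect"].to_numpy(), model.u_)
    header = {ln.split("\t")[0][2:]: float(ln.split("\t")[1])
              for ln in path.read_text().splitlines() if ln.startswith("#")}
    assert header["mu"] == model.mu_
    assert header["sigma2_error"] == model.sigma2_error_


@settings(max_examples=25, deadline=None, derandomize=True)
@given(years=st.lists(st.integers(1, 15), min_size=1, max_size=12),
       current=st.integers(1, 15))
def test_window_property_only_recent_years_survive(years, current):
    rng = np.random.default_rng(0)
    recs = [(rng.integers(0, 3, (2, 3)).astype(float), rng.normal(size=2),
             np.arange(2), y) for y in years]
    train = update_window(TrainingSet(4), recs, current)
    assert all(y > current - 4 for y in train.years)
    expected = sorted({y for y in years if y > current - 4})
    assert train.years == expected
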