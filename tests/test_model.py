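import numpy as np
import pandas as pd
import pytest

from pathsel.model import (
    ModelSpec,
    StratumData,
    clogit_loglik,
    default_ladder,
    fit_fixed,
    fit_poisson_equivalent,
    fit_random_slopes,
    run_model_ladder,
    waic,
)
from pathsel.synthetic import simulate_strata


def brute_force_loglik(strata, beta):
    """Independent softmax enumeration over every stratum row."""
    total = 0.0
    for s in range(strata.n_strata):
        etas = []
        for m in range(strata.X.shape[1]):
            if not strata.row_valid[s, m]:
                continue
            eta = 0.0
            for p in range(strata.n_terms):
                v = strata.X[s, m, p]
                if not np.isnan(v):
                    eta += v * beta[p]
            etas.append((m, eta))
        denom = sum(np.exp(e) for _, e in etas)
        obs_eta = dict(etas)[strata.obs_idx[s]]
        total += obs_eta - np.log(denom)
    return total


def random_instance(rng, S=3, M=4, P=2, missing_frac=0.0):
    X = rng.standard_normal((S, M, P))
    if missing_frac:
        X[rng.uniform(size=X.shape) < missing_frac] = np.nan
    return StratumData(
        X=X,
        obs_idx=rng.integers(0, M, S),
        animal_codes=np.zeros(S, dtype=int),
        animal_labels=["a"],
        terms=[f"x{i}" for i in range(P)],
        stratum_ids=[f"s{i}" for i in range(S)],
    )


class TestClogitLoglik:
    def test_zero_beta_uniform_softmax(self, rng):
        strata, _ = simulate_strata(np.zeros(3), 20, n_random=10, seed=1)
        assert clogit_loglik(strata, np.zeros(3)) == pytest.approx(-20 * np.log(11))

    def test_shift_invariance_identical_rows(self, rng):
        X = np.tile(rng.standard_normal((1, 1, 2)), (1, 5, 1))
        strata = StratumData(X=X, obs_idx=[2], animal_codes=[0], animal_labels=["a"],
                             terms=["x0", "x1"], stratum_ids=["s"])
        for beta in (np.zeros(2), np.array([3.0, -2.0])):
            assert clogit_loglik(strata, beta) == pytest.approx(-np.log(5))

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(50):
            strata = random_instance(rng, missing_frac=0.2)
            beta = rng.standard_normal(2)
            assert clogit_loglik(strata, beta) == pytest.approx(
                brute_force_loglik(strata, beta), abs=1e-12
            )

    def test_stratum_constant_shift_invariance(self, rng):
        strata = random_instance(rng, S=5, M=6, P=3)
        beta = rng.standard_normal(3)
        base = clogit_loglik(strata, beta)
        shifted = StratumData(
            X=strata.X + rng.standard_normal((5, 1, 3)),  # same shift for all rows
            obs_idx=strata.obs_idx, animal_codes=strata.animal_codes,
            animal_labels=strata.animal_labels, terms=strata.terms,
            stratum_ids=strata.stratum_ids,
        )
        assert clogit_loglik(shifted, beta) == pytest.approx(base, abs=1e-9)


class TestFitFixed:
    def test_paired_logistic_closed_form(self):
        # 2-row strata with covariate differences d = (+1, +1, +1, -1) and
        # the observed row first: the score equation gives sigma(beta) = 3/4,
        # i.e. beta_hat = ln 3
        d = np.array([1.0, 1.0, 1.0, -1.0])
        X = np.zeros((4, 2, 1))
        X[:, 0, 0] = d
        strata = StratumData(X=X, obs_idx=np.zeros(4, dtype=int),
                             animal_codes=np.zeros(4, dtype=int), animal_labels=["a"],
                             terms=["x"], stratum_ids=list("abcd"))
        fm = fit_fixed(strata)
        assert fm.beta[0] == pytest.approx(np.log(3), abs=1e-7)

    def test_parameter_recovery_2000_strata(self):
        strata, _ = simulate_strata(np.array([-1.0, 0.5]), 2000, n_random=10, seed=9)
        fm = fit_fixed(strata)
        for b, t, se in zip(fm.beta, [-1.0, 0.5], fm.se):
            assert abs(b - t) < 3 * se
            assert abs(b - t) < 0.15

    def test_likelihood_never_below_null(self, rng):
        for seed in range(5):
            strata, _ = simulate_strata(rng.standard_normal(2), 50, n_random=5, seed=seed)
            fm = fit_fixed(strata)
            assert fm.loglik >= clogit_loglik(strata, np.zeros(2)) - 1e-9

    def test_missing_column_equals_deleted_column(self, rng):
        strata = random_instance(rng, S=6, M=5, P=2)
        gated = StratumData(
            X=strata.X.copy(), obs_idx=strata.obs_idx, animal_codes=strata.animal_codes,
            animal_labels=strata.animal_labels, terms=strata.terms,
            stratum_ids=strata.stratum_ids,
        )
        gated.X[2, :, 1] = np.nan  # drop x1 from stratum 2 entirely
        beta = rng.standard_normal(2)
        ll_gated = clogit_loglik(gated, beta)
        # oracle: stratum 2 scored with the column removed
        others = np.ones(6, dtype=bool); others[2] = False
        only2 = StratumData(X=strata.X[[2]][:, :, :1], obs_idx=strata.obs_idx[[2]],
                            animal_codes=[0], animal_labels=["a"], terms=["x0"],
                            stratum_ids=["s2"])
        ll_manual = clogit_loglik(strata.subset(others), beta) + clogit_loglik(only2, beta[:1])
        assert ll_gated == pytest.approx(ll_manual, abs=1e-12)


class TestPoissonEquivalence:
    def test_slope_agreement_random_instances(self, rng):
        for seed in range(5):
            strata, _ = simulate_strata(np.array([0.7, -0.4]), 30, n_random=6, seed=seed)
            fa, fb = fit_fixed(strata), fit_poisson_equivalent(strata)
            np.testing.assert_allclose(fa.beta, fb.beta, atol=1e-6)

    def test_single_stratum_minimal_case(self, rng):
        # seed chosen so the observed row is interior (finite MLE)
        strata, _ = simulate_strata(np.array([0.5]), 1, n_random=4, seed=1)
        fa, fb = fit_fixed(strata), fit_poisson_equivalent(strata)
        np.testing.assert_allclose(fa.beta, fb.beta, atol=1e-6)

    def test_profiled_intercepts_reproduce_conditional_likelihood(self, rng):
        # with alpha_s = -log sum exp(eta), the Poisson log-likelihood equals
        # the conditional-logistic one minus exactly one unit per stratum
        strata = random_instance(rng, S=7, M=5, P=2)
        beta = rng.standard_normal(2)
        X0 = np.nan_to_num(strata.X)
        eta = X0 @ beta
        ll_pois = 0.0
        for s in range(7):
            alpha = -np.log(np.exp(eta[s]).sum())
            lam = np.exp(alpha + eta[s])
            y = np.zeros(5); y[strata.obs_idx[s]] = 1
            ll_pois += np.sum(y * (alpha + eta[s]) - lam)
        assert ll_pois == pytest.approx(clogit_loglik(strata, beta) - 7, abs=1e-10)


class TestRandomSlopes:
    def test_nesting_consistency_when_variance_zero(self):
        strata, _ = simulate_strata(
            np.array([-1.0, 0.5]), 600, n_random=10, seed=21, n_animals=15,
            between_sd=np.array([0.0, 0.0]),
        )
        fr = fit_random_slopes(strata, ["x1"], seed=0)
        ff = fit_fixed(strata)
        for br, bf, se in zip(fr.beta, ff.beta, ff.se):
            assert abs(br - bf) < se

    def test_collapsed_variance_is_noted(self):
        strata, _ = simulate_strata(
            np.array([0.8]), 400, n_random=8, seed=3, n_animals=10,
            between_sd=np.array([0.0]),
        )
        fm = fit_random_slopes(strata, ["x1"], seed=0)
        assert fm.random_sd[0] < 0.1 or not fm.notes


class TestWaic:
    def test_point_mass_posterior(self, rng):
        strata, _ = simulate_strata(np.array([0.5, -0.5]), 50, n_random=5, seed=2)
        fm = fit_fixed(strata)
        frozen = fm
        frozen.vcov = np.zeros_like(fm.vcov)
        w, p = waic(frozen, strata, n_draws=200, seed=0)
        assert p == 0.0
        assert w == pytest.approx(-2 * clogit_loglik(strata, fm.beta))

    def test_noise_term_does_not_materially_improve(self):
        hits = 0
        for rep in range(10):
            strata, _ = simulate_strata(np.array([-0.8, 0.6]), 150, n_random=10, seed=400 + rep)
            fm2 = fit_fixed(strata)
            w2, _ = waic(fm2, strata, n_draws=500, seed=rep)
            # add a pure-noise covariate
            rng = np.random.default_rng(rep)
            X3 = np.concatenate([strata.X, rng.standard_normal(strata.X.shape[:2] + (1,))], axis=2)
            strata3 = StratumData(X=X3, obs_idx=strata.obs_idx, animal_codes=strata.animal_codes,
                                  animal_labels=strata.animal_labels, terms=strata.terms + ["noise"],
                                  stratum_ids=strata.stratum_ids)
            fm3 = fit_fixed(strata3)
            w3, _ = waic(fm3, strata3, n_draws=500, seed=rep)
            if w3 - w2 >= -4:
                hits += 1
        assert hits >= 9

    def test_signal_model_beats_null(self):
        wins = 0
        for rep in range(10):
            strata, _ = simulate_strata(np.array([-1.0, 0.8]), 150, n_random=10, seed=500 + rep)
            fm = fit_fixed(strata)
            w_model, _ = waic(fm, strata, n_draws=500, seed=rep)
            null = StratumData(X=strata.X[:, :, :0], obs_idx=strata.obs_idx,
                               animal_codes=strata.animal_codes, animal_labels=strata.animal_labels,
                               terms=[], stratum_ids=strata.stratum_ids)
            w_null, _ = waic(fit_fixed(null), null, n_draws=500, seed=rep)
            wins += w_model < w_null
        assert wins == 10


class TestModelSpec:
    def test_quadratic_requires_linear(self):
        with pytest.raises(ValueError, match="requires linear"):
            ModelSpec(["slope^2"])

    def test_interaction_requires_both_parents(self):
        with pytest.raises(ValueError, match="requires linear"):
            ModelSpec(["road", "road:wash"])

    def test_default_ladder_matches_published_shape(self):
        specs = default_ladder()
        assert len(specs) == 19
        assert specs[-1].label == "Null"
        assert len(specs[0].terms) == 11
        labels = [s.label for s in specs]
        assert len(set(labels)) == 19


class TestLadder:
    def test_null_only_ladder(self, rng):
        strata, _ = simulate_strata(np.array([0.5]), 20, n_random=4, seed=1)
        design = _strata_to_design(strata)
        tab = run_model_ladder(design, specs=[ModelSpec([], label="Null")], n_draws=100)
        assert len(tab) == 1 and tab["delta_waic"].iloc[0] == 0.0

    def test_duplicate_specs_tie_in_input_order(self, rng):
        strata, _ = simulate_strata(np.array([0.5]), 30, n_random=4, seed=2)
        design = _strata_to_design(strata)
        specs = [ModelSpec(["x1"], label="first"), ModelSpec(["x1"], label="second")]
        tab = run_model_ladder(design, specs=specs, n_draws=400, seed=5)
        assert abs(tab["waic"].iloc[0] - tab["waic"].iloc[1]) < 1.0
        assert tab["label"].tolist() == ["first", "second"]


def _strata_to_design(strata) -> pd.DataFrame:
    rows = []
    for s in range(strata.n_strata):
        for m in range(strata.X.shape[1]):
            if not strata.row_valid[s, m]:
                continue
            rows.append(
                {"stratum_id": strata.stratum_ids[s],
                 "animal_id": strata.animal_labels[strata.animal_codes[s]],
                 "role": "observed" if m == strata.obs_idx[s] else "random",
                 **{t: strata.X[s, m, p] for p, t in enumerate(strata.terms)}}
            )
    return pd.DataFrame(rows)
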