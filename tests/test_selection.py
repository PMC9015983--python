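"""Model selection engines against enumeration and marginal-likelihood oracles."""

import numpy as np
import pandas as pd
import pytest
from itertools import product
from scipy.stats import multivariate_normal

from ppsbayes import (
    HypothesisSet,
    ModelSpec,
    classify_evidence,
    run_ivs,
    run_product_space,
    sample_posterior,
)
from ppsbayes.design import build_design


class TestClassifyEvidence:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (1.0, "very-strong-alternative"),
            (0.995, "very-strong-alternative"),
            (0.986, "strong-alternative"),
            (0.96, "strong-alternative"),
            (0.8, "positive-alternative"),
            (0.535, "inconclusive"),
            (0.333, "inconclusive"),
            (0.2, "positive-null"),
            (0.03, "strong-null"),
            (0.0, "very-strong-null"),
            # boundary values fall on the weaker side (strict inequalities)
            (0.99, "strong-alternative"),
            (0.95, "positive-alternative"),
            (0.75, "inconclusive"),
            (0.25, "inconclusive"),
            (0.05, "positive-null"),
            (0.01, "strong-null"),
        ],
    )
    def test_thresholds(self, p, expected):
        assert classify_evidence(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_evidence(1.2)


def enumeration_inclusions(y, cells, fixed_terms, sigma, spec):
    """Exact posterior inclusion by enumerating indicator patterns and
    integrating the conjugate Gaussian marginal likelihood."""
    dm = build_design(cells, fixed_terms)
    blocks = {t: dm.X[:, dm.term_slices[t]] for t in fixed_terms}
    intercept = dm.X[:, dm.term_slices["intercept"]]
    base_cov = sigma**2 * np.eye(len(y)) + spec.intercept_scale**2 * (intercept @ intercept.T)
    terms = list(fixed_terms)
    logws = {}
    for pattern in product([0, 1], repeat=len(terms)):
        cov = base_cov.copy()
        for on, t in zip(pattern, terms):
            if on:
                s = spec.scale_for(t)
                cov += s**2 * blocks[t] @ blocks[t].T
        logws[pattern] = multivariate_normal.logpdf(y, mean=np.zeros(len(y)), cov=cov)
    mx = max(logws.values())
    ws = {k: np.exp(v - mx) for k, v in logws.items()}
    total = sum(ws.values())
    return {
        t: sum(w for k, w in ws.items() if k[i]) / total for i, t in enumerate(terms)
    }


def toy_cells(rng, n_subj=12, effect_d=8.0, effect_l=0.0):
    rows = []
    for p in range(n_subj):
        for d in ["near", "far"]:
            for l in ["low", "high"]:
                mu = 0.0
                mu += effect_d if d == "far" else -effect_d
                mu += effect_l if l == "high" else -effect_l
                rows.append(
                    {
                        "participant": p,
                        "distance": d,
                        "light_location": l,
                        "mean_rt": mu + rng.normal(0, 10.0),
                    }
                )
    return pd.DataFrame(rows)


class TestIvsEnumerationOracle:
    def test_single_factor_matches_closed_form(self, rng):
        cells = toy_cells(rng, effect_d=7.0)
        sigma = 10.0
        spec = ModelSpec(
            response="mean_rt",
            fixed_terms=("distance",),
            random_terms=(),
            prior_scale=15.0,
            intercept_scale=50.0,
            sigma2_fixed=sigma**2,
        )
        exact = enumeration_inclusions(
            cells["mean_rt"].to_numpy(), cells, ("distance",), sigma, spec
        )
        res = run_ivs(cells, spec, chains=2, iterations=6000, warmup=1000, seed=11)
        assert res.inclusion["distance"] == pytest.approx(exact["distance"], abs=0.02)

    def test_two_term_enumeration(self, rng):
        cells = toy_cells(rng, effect_d=6.0, effect_l=2.0)
        sigma = 10.0
        spec = ModelSpec(
            response="mean_rt",
            fixed_terms=("distance", "light"),
            random_terms=(),
            prior_scale=15.0,
            intercept_scale=50.0,
            sigma2_fixed=sigma**2,
        )
        exact = enumeration_inclusions(
            cells["mean_rt"].to_numpy(), cells, ("distance", "light"), sigma, spec
        )
        res = run_ivs(cells, spec, chains=2, iterations=6000, warmup=1000, seed=12)
        for t in ("distance", "light"):
            assert res.inclusion[t] == pytest.approx(exact[t], abs=0.03)


class TestIvsBehaviour:
    def test_pure_noise_shrinks_below_prior(self, rng):
        cells = toy_cells(rng, effect_d=0.0, effect_l=0.0, n_subj=20)
        spec = ModelSpec(
            response="mean_rt", fixed_terms=("distance", "light"), random_terms=(),
            prior_scale=20.0, intercept_scale=50.0,
        )
        res = run_ivs(cells, spec, chains=2, iterations=2000, warmup=500, seed=13)
        assert res.inclusion["distance"] < 0.5
        assert res.inclusion["light"] < 0.5

    def test_all_indicators_on_reproduces_plain_posterior(self, h2_tables):
        """With decisive signal the conditional (indicator-on) coefficients
        must match the plain hierarchical fit."""
        _, to, _ = h2_tables
        spec = ModelSpec(response="mean_rt")
        plain = sample_posterior(spec, to, chains=2, iterations=600, warmup=300, seed=14)
        sel = run_ivs(to, spec, chains=2, iterations=600, warmup=300, seed=14, keep_draws=True)
        assert sel.inclusion["distance"] > 0.95
        j = plain.coef_names.index("distance[D1]")
        active = sel.draws.gamma[:, :, sel.draws.indicator_terms.index("distance")].astype(bool)
        cond = sel.draws.beta[:, :, j][active]
        assert cond.mean() == pytest.approx(plain.beta[:, :, j].mean(), abs=1.5)

    def test_zero_column_indicator_rejected(self, rng):
        cells = toy_cells(rng)
        spec = ModelSpec(response="mean_rt", fixed_terms=("distance",), random_terms=())
        with pytest.raises(ValueError):
            run_ivs(cells, spec, indicator_terms=["tactile"], chains=1, iterations=10, warmup=0)


def psm_toy(rng, regime, n_subj=10, sigma=8.0):
    """Tiny VT/TO tables with a 2-level distance factor, no random effects."""
    rows_vt, rows_to = [], []
    eff = {"near": -6.0, "far": 6.0}
    for p in range(n_subj):
        for d, e in eff.items():
            for _ in range(2):
                rows_vt.append({"participant": p, "distance": d, "mean_rt": 100 + e + rng.normal(0, sigma)})
                if regime == "H0":
                    mu = 100 + e
                elif regime == "H1":
                    mu = 112.0
                else:
                    mu = 100 - 1.5 * e  # opposite profile: clearly its own structure
                rows_to.append({"participant": p, "distance": d, "mean_rt": mu + rng.normal(0, sigma)})
    return pd.DataFrame(rows_vt), pd.DataFrame(rows_to)


def psm_exact(yv, yt, Xv, Xt, spec, tau_scale, sigma):
    """Marginal-likelihood oracle: integrate each candidate analytically."""
    scales = np.array([spec.intercept_scale] + [spec.prior_scale] * (Xv.shape[1] - 1))
    S = np.diag(scales**2)

    def ml(y, X, prior_cov):
        cov = sigma**2 * np.eye(len(y)) + X @ prior_cov @ X.T
        return multivariate_normal.logpdf(y, mean=np.zeros(len(y)), cov=cov)

    X_all = np.vstack([Xv, Xt])
    ml0 = ml(np.concatenate([yv, yt]), X_all, S)
    ml_vt = ml(yv, Xv, S)
    ml1 = ml_vt + ml(yt, np.ones((len(yt), 1)), np.array([[tau_scale**2]]))
    ml2 = ml_vt + ml(yt, Xt, S)
    logp = np.array([ml0, ml1, ml2])
    w = np.exp(logp - logp.max())
    return w / w.sum()


class TestProductSpace:
    @pytest.mark.parametrize("regime,expected", [("H0", 0), ("H1", 1), ("H2", 2)])
    def test_conjugate_oracle_agreement(self, rng, regime, expected):
        """Visit proportions must match the numerically integrated posterior
        model probabilities on a conjugate toy problem."""
        vt, to = psm_toy(rng, regime)
        sigma = 8.0
        spec = ModelSpec(
            response="mean_rt", fixed_terms=("distance",), random_terms=(),
            prior_scale=10.0, intercept_scale=300.0, sigma2_fixed=sigma**2,
        )
        hset = HypothesisSet(spec=spec, tau_scale=300.0)
        dm = build_design(pd.concat([vt, to], ignore_index=True), ("distance",))
        Xv, Xt = dm.X[: len(vt)], dm.X[len(vt):]
        exact = psm_exact(
            vt["mean_rt"].to_numpy(), to["mean_rt"].to_numpy(), Xv, Xt, spec, 300.0, sigma
        )
        res = run_product_space(
            vt, to, hset, chains=2, iterations=3000, warmup=500,
            pilot_iterations=500, pilot_warmup=200, seed=21,
        )
        assert int(np.argmax(exact)) == expected
        for i, h in enumerate(["H0", "H1", "H2"]):
            assert res.p_h[h] == pytest.approx(exact[i], abs=0.1)

    def test_probabilities_sum_to_one_exactly(self, rng):
        vt, to = psm_toy(rng, "H1", n_subj=6)
        spec = ModelSpec(response="mean_rt", fixed_terms=("distance",), random_terms=())
        res = run_product_space(
            vt, to, HypothesisSet(spec=spec, tau_scale=300.0),
            chains=2, iterations=400, warmup=200, seed=22,
        )
        assert sum(res.p_h.values()) == pytest.approx(1.0, abs=1e-12)
        for pc in res.per_chain:
            assert sum(pc.values()) == pytest.approx(1.0, abs=1e-12)

    def test_identical_tables_favour_shared_model(self, h2_tables):
        """TO copied cell-for-cell from VT: H0 must win."""
        vt, _, _ = h2_tables
        to = vt.assign(trial_type="TO")
        res = run_product_space(
            vt, to, chains=2, iterations=500, warmup=250, seed=23,
        )
        assert res.best == "H0"

    def test_mismatched_participants_rejected(self, rng):
        vt, to = psm_toy(rng, "H0", n_subj=4)
        with pytest.raises(ValueError, match="participants"):
            run_product_space(vt, to[to["participant"] > 0], chains=1, iterations=10, warmup=0)
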