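"""Bayesian model selection: product-space comparison and indicator selection.

Two engines discriminate hypotheses about the reaction-time structure:

* Product Space Method (Carlin & Chib): a categorical model index is
  sampled jointly with the parameters of three candidate models of the
  tactile-only (TO) RTs, while the visuo-tactile (VT) sub-model is common:

    H0 - TO and VT share one linear predictor (X beta + Z xi);
    H1 - VT is the full hierarchical model, TO is a single constant tau;
    H2 - VT and TO are full models, TO with its own coefficient vector.

  Because beta, xi, Omega and sigma^2 appear in every candidate with the
  same prior, they are treated as common parameters and need no
  pseudo-priors; only H1's tau and H2's tau-vector are given normal
  pseudo-priors fitted from short pilot runs, which is what makes the index
  chain mix.  The posterior probability of each hypothesis is its visit
  proportion.

* Indicator Variable Selection (Kuo & Mallick): every fixed-effect term's
  coefficient block is multiplied by a Bernoulli indicator; the posterior
  mean of the indicator is the term's inclusion proportion.

Inclusion proportions and model probabilities are mapped to evidence
categories with strict thresholds: > 0.99 / > 0.95 / > 0.75 for very
strong / strong / positive support of the alternative, mirrored below
0.01 / 0.05 / 0.25 for the null, inconclusive in between.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_softmax

from .design import build_design
from .model_core import ModelSpec, PosteriorDraws, hdi, posterior_mode, sample_posterior

__all__ = [
    "HypothesisSet",
    "PSMResult",
    "IVSResult",
    "classify_evidence",
    "run_product_space",
    "run_ivs",
]

HYPOTHESES = ("H0", "H1", "H2")


def classify_evidence(p: float) -> str:
    """Evidence category for an inclusion proportion or model probability.

    Thresholds are strict inequalities, so boundary values (exactly 0.75,
    0.95, 0.99 and their duals) fall on the weaker side.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"proportion {p} outside [0, 1]")
    if p > 0.99:
        return "very-strong-alternative"
    if p > 0.95:
        return "strong-alternative"
    if p > 0.75:
        return "positive-alternative"
    if p < 0.01:
        return "very-strong-null"
    if p < 0.05:
        return "strong-null"
    if p < 0.25:
        return "positive-null"
    return "inconclusive"


@dataclass(frozen=True)
class HypothesisSet:
    """The three candidate structures for the PSM comparison.

    ``spec`` fixes the shared fixed/random structure of the VT sub-model
    (and of the TO sub-model under H0/H2); ``tau_scale`` is the prior sd of
    H1's constant tau (broad, since the TO level sits hundreds of ms from
    zero); ``prior_probs`` default to 1/3 each.
    """

    spec: ModelSpec = field(default_factory=ModelSpec)
    tau_scale: float = 1000.0
    prior_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    shared_random: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.prior_probs) - 1) > 1e-9 or min(self.prior_probs) <= 0:
            raise ValueError("prior model probabilities must be positive and sum to 1")


@dataclass
class PSMResult:
    """Visit proportions of the hypothesis index plus chain diagnostics."""

    p_h: dict[str, float]
    per_chain: list[dict[str, float]]
    n_switches: int
    stuck: bool
    pseudo: dict
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.categories:
            self.categories = {h: classify_evidence(p) for h, p in self.p_h.items()}

    @property
    def best(self) -> str:
        return max(self.p_h, key=self.p_h.get)


@dataclass
class IVSResult:
    """Inclusion proportions per term with categories and conditional effects."""

    inclusion: dict[str, float]
    categories: dict[str, str]
    conditional: pd.DataFrame
    draws: PosteriorDraws | None = None


def _norm_logpdf(x, mean, sd):
    z = (np.asarray(x) - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * np.log(2 * np.pi)


class _PSMSampler:
    """Joint Gibbs sampler over the hypothesis index and all parameters."""

    def __init__(self, vt: pd.DataFrame, to: pd.DataFrame, hset: HypothesisSet):
        spec = hset.spec
        self.spec = spec
        self.hset = hset
        both = pd.concat([vt, to], ignore_index=True)
        dm = build_design(both, spec.fixed_terms, spec.random_terms)
        n_vt = len(vt)
        self.dm = dm
        self.Xv, self.Xt = dm.X[:n_vt], dm.X[n_vt:]
        self.Zv, self.Zt = dm.Z[:n_vt], dm.Z[n_vt:]
        self.sv, self.st = dm.subject[:n_vt], dm.subject[n_vt:]
        self.yv = vt[spec.response].to_numpy(dtype=float)
        self.yt = to[spec.response].to_numpy(dtype=float)
        if np.isnan(self.yv).any() or np.isnan(self.yt).any():
            raise ValueError("response contains NaN")
        self.p = dm.n_coef
        self.q = dm.n_random
        self.S = len(dm.subjects)
        scales = np.array([spec.scale_for(_term_of(dm, j)) for j in range(self.p)])
        self.prior_prec_beta = np.diag(1.0 / scales**2)
        self.beta_scales = scales
        self.XtXv = self.Xv.T @ self.Xv
        self.XtXt = self.Xt.T @ self.Xt
        if self.q:
            self.ZtZv = _subject_gram(self.Zv, self.sv, self.S, self.q)
            self.ZtZt = _subject_gram(self.Zt, self.st, self.S, self.q)
            self.nu0 = self.q + 2
            self.psi0 = np.eye(self.q) * spec.random_scale**2

    # -- state ------------------------------------------------------------
    def init_state(self, rng, m0: int, pseudo: dict) -> dict:
        st = {
            "beta": np.zeros(self.p),
            "xi": np.zeros((self.S, self.q)),
            "xi_to": np.zeros((self.S, self.q)),
            "omega": np.eye(self.q) * self.spec.random_scale**2 if self.q else None,
            "sigma2": self.spec.sigma2_fixed or max(float(np.var(self.yv)), 1.0),
            "tau": float(np.mean(self.yt)),
            "tauvec": np.zeros(self.p),
            "m": m0,
        }
        st["beta"][0] = float(np.mean(self.yv))
        st["tauvec"][0] = float(np.mean(self.yt))
        if pseudo:
            st["tau"] = pseudo["tau"][0]
            st["tauvec"] = pseudo["tauvec"][0].copy()
        return st

    def _zpart(self, Z, subj, xi):
        if not self.q:
            return 0.0
        return np.einsum("ij,ij->i", Z, xi[subj])

    def step(self, st: dict, rng, pseudo: dict, fixed_m: int | None = None) -> None:
        m = st["m"]
        shared = self.hset.shared_random
        s2 = st["sigma2"]
        zv = self._zpart(self.Zv, self.sv, st["xi"])
        zt = self._zpart(self.Zt, self.st, st["xi"] if shared else st["xi_to"])

        # beta: VT rows always, TO rows too under H0
        XtX = self.XtXv + (self.XtXt if m == 0 else 0.0)
        Xty = self.Xv.T @ (self.yv - zv)
        if m == 0:
            Xty = Xty + self.Xt.T @ (self.yt - zt)
        prec = XtX / s2 + self.prior_prec_beta
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Xty / s2)
        st["beta"] = _chol_mvn(rng, mean, L)

        # tau (H1 block)
        if m == 1:
            prec_t = len(self.yt) / s2 + 1.0 / self.hset.tau_scale**2
            mean_t = self.yt.sum() / s2 / prec_t
            st["tau"] = rng.normal(mean_t, np.sqrt(1.0 / prec_t))
        else:
            st["tau"] = rng.normal(pseudo["tau"][0], pseudo["tau"][1])

        # tau vector (H2 block)
        if m == 2:
            prec_v = self.XtXt / s2 + self.prior_prec_beta
            Lv = np.linalg.cholesky(prec_v)
            mean_v = np.linalg.solve(prec_v, self.Xt.T @ (self.yt - zt) / s2)
            st["tauvec"] = _chol_mvn(rng, mean_v, Lv)
        else:
            st["tauvec"] = rng.normal(pseudo["tauvec"][0], pseudo["tauvec"][1])

        # random effects (VT rows always; TO rows under H0/H2)
        if self.q:
            to_resid_fixed = None
            if m == 0:
                to_resid_fixed = self.yt - self.Xt @ st["beta"]
            elif m == 2:
                to_resid_fixed = self.yt - self.Xt @ st["tauvec"]

            r_v = self.yv - self.Xv @ st["beta"]
            b = np.zeros((self.S, self.q))
            np.add.at(b, self.sv, self.Zv * r_v[:, None])
            ZtZ = self.ZtZv.copy()
            if shared and to_resid_fixed is not None:
                np.add.at(b, self.st, self.Zt * to_resid_fixed[:, None])
                ZtZ += self.ZtZt
            omega_inv = np.linalg.inv(st["omega"])
            st["xi"] = _batched_mvn(rng, ZtZ / s2 + omega_inv, b / s2)

            if not shared:
                if to_resid_fixed is not None:
                    b2 = np.zeros((self.S, self.q))
                    np.add.at(b2, self.st, self.Zt * to_resid_fixed[:, None])
                    st["xi_to"] = _batched_mvn(rng, self.ZtZt / s2 + omega_inv, b2 / s2)
                else:  # inactive under H1: refresh from the prior
                    Lo = np.linalg.cholesky(st["omega"])
                    st["xi_to"] = rng.standard_normal((self.S, self.q)) @ Lo.T

            outer = st["xi"].T @ st["xi"]
            n_eff = self.S
            if not shared:
                outer = outer + st["xi_to"].T @ st["xi_to"]
                n_eff += self.S
            st["omega"] = np.atleast_2d(
                stats.invwishart.rvs(df=self.nu0 + n_eff, scale=self.psi0 + outer, random_state=rng)
            )
            zv = self._zpart(self.Zv, self.sv, st["xi"])
            zt = self._zpart(self.Zt, self.st, st["xi"] if shared else st["xi_to"])

        # residual variance over all rows under the active model
        resid_v = self.yv - self.Xv @ st["beta"] - zv
        resid_t = self._to_resid(st, m, zt)
        if self.spec.sigma2_fixed is None:
            rss = resid_v @ resid_v + resid_t @ resid_t
            a = self.spec.residual_a + (len(self.yv) + len(self.yt)) / 2.0
            bshape = self.spec.residual_b + rss / 2.0
            st["sigma2"] = bshape / rng.gamma(a)
            s2 = st["sigma2"]

        # hypothesis index
        if fixed_m is not None:
            st["m"] = fixed_m
            return
        sd = np.sqrt(s2)
        ll = np.empty(3)
        ll[0] = _norm_logpdf(self.yt, self.Xt @ st["beta"] + zt, sd).sum()
        ll[1] = _norm_logpdf(self.yt, st["tau"], sd).sum()
        ll[2] = _norm_logpdf(self.yt, self.Xt @ st["tauvec"] + zt, sd).sum()
        lb = np.zeros(3)
        lb[1] = float(
            _norm_logpdf(st["tau"], 0.0, self.hset.tau_scale)
            - _norm_logpdf(st["tau"], pseudo["tau"][0], pseudo["tau"][1])
        )
        lb[2] = float(
            np.sum(_norm_logpdf(st["tauvec"], 0.0, self.beta_scales))
            - np.sum(_norm_logpdf(st["tauvec"], pseudo["tauvec"][0], pseudo["tauvec"][1]))
        )
        logits = np.log(self.hset.prior_probs) + ll + lb
        probs = np.exp(log_softmax(logits))
        st["m"] = int(rng.choice(3, p=probs))

    def _to_resid(self, st, m, zt):
        if m == 0:
            return self.yt - self.Xt @ st["beta"] - zt
        if m == 1:
            return self.yt - st["tau"]
        return self.yt - self.Xt @ st["tauvec"] - zt

    # -- pilots ------------------------------------------------------------
    def fit_pseudo(self, rng, iterations: int, warmup: int, inflate: float = 1.5) -> dict:
        """Short pilot runs of H1 and H2 to calibrate normal pseudo-priors."""
        blank = {"tau": (0.0, self.hset.tau_scale), "tauvec": (np.zeros(self.p), self.beta_scales)}
        taus, tauvecs = [], []
        for m_fix, sink in ((1, taus), (2, tauvecs)):
            st = self.init_state(rng, m_fix, {})
            for it in range(warmup + iterations):
                self.step(st, rng, blank, fixed_m=m_fix)
                if it >= warmup:
                    sink.append(st["tau"] if m_fix == 1 else st["tauvec"].copy())
        taus = np.asarray(taus)
        tv = np.asarray(tauvecs)
        return {
            "tau": (float(taus.mean()), float(max(taus.std() * inflate, 1e-3))),
            "tauvec": (tv.mean(axis=0), np.maximum(tv.std(axis=0) * inflate, 1e-3)),
        }


def _term_of(dm, j: int) -> str:
    for t, sl in dm.term_slices.items():
        if sl.start <= j < sl.stop:
            return t
    raise IndexError(j)


def _subject_gram(Z, subj, S, q):
    out = np.zeros((S, q, q))
    for s in range(S):
        Zs = Z[subj == s]
        out[s] = Zs.T @ Zs
    return out


def _chol_mvn(rng, mean, prec_chol):
    from scipy.linalg import solve_triangular

    z = rng.standard_normal(mean.shape[0])
    return mean + solve_triangular(prec_chol, z, lower=True, trans="T")


def _batched_mvn(rng, A, b):
    """Per-subject draws from N(A_s^-1 b_s, A_s^-1); A is (S, q, q)."""
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    z = rng.standard_normal((*b.shape, 1))
    return mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[:, :, 0]


def run_product_space(
    vt_cells: pd.DataFrame,
    to_cells: pd.DataFrame,
    hset: HypothesisSet | None = None,
    chains: int = 3,
    iterations: int = 1000,
    warmup: int = 500,
    pilot_iterations: int = 300,
    pilot_warmup: int = 150,
    seed: int = 0,
) -> PSMResult:
    """Posterior probabilities of H0/H1/H2 by product-space MCMC.

    ``vt_cells`` and ``to_cells`` are cell-mean tables (same participants
    and factor columns).  The returned probabilities are exact empirical
    visit frequencies of the hypothesis index over all post-warmup draws.
    """
    hset = hset or HypothesisSet()
    missing = set(vt_cells["participant"]) ^ set(to_cells["participant"])
    if missing:
        raise ValueError(f"participants not covered by both tables: {sorted(missing)}")
    sampler = _PSMSampler(vt_cells, to_cells, hset)
    pilot_rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 9999]))
    pseudo = sampler.fit_pseudo(pilot_rng, pilot_iterations, pilot_warmup)

    counts = np.zeros((chains, 3), dtype=int)
    switches = 0
    resident: list[int] = []
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, c]))
        st = sampler.init_state(rng, c % 3, pseudo)
        prev = st["m"]
        for it in range(warmup + iterations):
            sampler.step(st, rng, pseudo)
            if st["m"] != prev:
                switches += 1
            prev = st["m"]
            if it >= warmup:
                counts[c, st["m"]] += 1
        resident.append(int(np.argmax(counts[c])))

    total = counts.sum()
    p_h = {h: float(counts[:, i].sum() / total) for i, h in enumerate(HYPOTHESES)}
    per_chain = [
        {h: float(counts[c, i] / counts[c].sum()) for i, h in enumerate(HYPOTHESES)}
        for c in range(chains)
    ]
    stuck = switches == 0 and len(set(resident)) > 1
    if stuck:
        warnings.warn(
            "product-space index never switched and chains disagree on the resident "
            "model; pseudo-priors likely mismatched — rerun with longer pilots",
            RuntimeWarning,
            stacklevel=2,
        )
    return PSMResult(
        p_h=p_h,
        per_chain=per_chain,
        n_switches=int(switches),
        stuck=bool(stuck),
        pseudo={
            "tau": [float(pseudo["tau"][0]), float(pseudo["tau"][1])],
            "tauvec_mean": np.asarray(pseudo["tauvec"][0]).tolist(),
            "tauvec_sd": np.asarray(pseudo["tauvec"][1]).tolist(),
        },
    )


def run_ivs(
    cells: pd.DataFrame,
    spec: ModelSpec | None = None,
    indicator_prior: float = 0.5,
    indicator_terms: Sequence[str] | None = None,
    chains: int = 3,
    iterations: int = 1000,
    warmup: int = 500,
    seed: int = 0,
    keep_draws: bool = False,
    min_conditional_draws: int = 100,
) -> IVSResult:
    """Kuo-Mallick indicator selection over the fixed-effect terms.

    By default every non-intercept fixed term of ``spec`` carries its own
    Bernoulli(``indicator_prior``) indicator multiplying the whole
    coefficient block (no heredity constraint: an interaction may stay in
    without its margins).  Conditional effect summaries pool the draws in
    which the term was active.
    """
    spec = spec or ModelSpec()
    terms = list(indicator_terms) if indicator_terms is not None else [
        t for t in spec.fixed_terms
    ]
    draws = sample_posterior(
        spec,
        cells,
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        seed=seed,
        indicator_terms=terms,
        indicator_prior=indicator_prior,
    )
    inclusion = draws.inclusion()
    categories = {t: classify_evidence(p) for t, p in inclusion.items()}
    rows = []
    for j, t in enumerate(draws.indicator_terms):
        active = draws.gamma[:, :, j].astype(bool)
        sl = draws.term_slices[t]
        for k in range(sl.start, sl.stop):
            cond = draws.beta[:, :, k][active]
            if cond.size >= min_conditional_draws:
                lo, hi = hdi(cond)
                mode = min(max(posterior_mode(cond), lo), hi)
                rows.append(
                    {"term": t, "coef": draws.coef_names[k], "mode": mode,
                     "hdi_low": lo, "hdi_high": hi, "n_active_draws": int(cond.size)}
                )
            else:
                rows.append(
                    {"term": t, "coef": draws.coef_names[k], "mode": np.nan,
                     "hdi_low": np.nan, "hdi_high": np.nan, "n_active_draws": int(cond.size)}
                )
    conditional = pd.DataFrame(
        rows, columns=["term", "coef", "mode", "hdi_low", "hdi_high", "n_active_draws"]
    )
    return IVSResult(
        inclusion=inclusion,
        categories=categories,
        conditional=conditional,
        draws=draws if keep_draws else None,
    )
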