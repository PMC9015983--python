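"""Hierarchical Gaussian linear model: priors, Gibbs sampler, summaries.

The model fitted throughout the pipeline is

    y = X beta + Z xi + eps,
    beta_i ~ N(0, sigma_i^2)          (independent, per-coefficient scale)
    xi_s   ~ MN(0, Omega)             (one q-vector per participant)
    Omega  ~ Inverse-Wishart(nu0, Psi0)
    eps    ~ N(0, sigma^2),  sigma^2 ~ Inverse-Gamma(a0, b0)

with y the per-participant cell-mean RTs and X/Z sum-to-zero contrast
matrices.  All full conditionals are conjugate, so posterior draws come
from a blocked Gibbs sampler.  Optionally each fixed-effect term carries a
Bernoulli inclusion indicator gamma_t multiplying its whole coefficient
block (Kuo-Mallick indicator variable selection); when a term is switched
off its coefficients are refreshed from their prior, which keeps the
sampler's stationary distribution exact.

Summaries report the posterior mode (kernel-density argmax, Silverman
bandwidth) and the 95% highest-density interval, plus split-chain R-hat,
effective sample size and Monte-Carlo standard errors via arviz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .design import DesignMatrices, build_design, canonical_term

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "ConvergenceError",
    "sample_posterior",
    "summarize",
    "hdi",
    "posterior_mode",
    "predict_cells",
    "check_convergence",
]

RHAT_GATE = 1.01


class ConvergenceError(RuntimeError):
    """Raised (in strict mode) when chains fail the split-R-hat gate."""


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of one hierarchical linear model.

    ``response`` names the value column of the cell table ("mean_rt" for
    raw VT or TO cell means, "norm_rt" for the normalized dataset).
    ``prior_scale`` is the N(0, scale) sd for non-intercept coefficients
    (ms); the intercept gets its own broad scale since RT levels sit
    hundreds of ms from zero.  ``random_scale`` sets the prior expectation
    of the random-effect sd via the Inverse-Wishart scale matrix.
    """

    response: str = "mean_rt"
    fixed_terms: tuple[str, ...] = ("distance", "light", "tactile")
    random_terms: tuple[str, ...] = ("intercept", "light", "tactile")
    contrast_coding: str = "sum"
    prior_scale: float = 50.0
    intercept_scale: float = 1000.0
    prior_scales: Mapping[str, float] = field(default_factory=dict)
    residual_a: float = 0.01
    residual_b: float = 0.01
    random_scale: float = 20.0
    sigma2_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.contrast_coding != "sum":
            raise ValueError("only sum-to-zero contrast coding is implemented")
        scales = [self.prior_scale, self.intercept_scale, *self.prior_scales.values()]
        if any(s <= 0 for s in scales):
            raise ValueError("prior scales must be positive")

    def scale_for(self, term: str) -> float:
        term = canonical_term(term)
        if term in self.prior_scales:
            return float(self.prior_scales[term])
        return self.intercept_scale if term == "intercept" else self.prior_scale


@dataclass
class PosteriorDraws:
    """MCMC draws (chain-major arrays) plus design bookkeeping."""

    beta: np.ndarray  # (chains, draws, p)
    sigma2: np.ndarray  # (chains, draws)
    coef_names: list[str]
    term_slices: dict[str, slice]
    gamma: np.ndarray | None = None  # (chains, draws, T)
    indicator_terms: list[str] = field(default_factory=list)
    omega: np.ndarray | None = None  # (chains, draws, q, q)
    z_names: list[str] = field(default_factory=list)
    design: DesignMatrices | None = None

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def to_inference_data(self) -> az.InferenceData:
        post = {
            "beta": self.beta,
            "sigma": np.sqrt(self.sigma2),
        }
        if self.gamma is not None:
            post["gamma"] = self.gamma
        if self.omega is not None:
            post["omega_sd"] = np.sqrt(np.diagonal(self.omega, axis1=-2, axis2=-1))
        coords = {"coef": self.coef_names}
        dims = {"beta": ["coef"]}
        if self.gamma is not None:
            coords["term"] = self.indicator_terms
            dims["gamma"] = ["term"]
        if self.omega is not None:
            coords["ranef"] = self.z_names
            dims["omega_sd"] = ["ranef"]
        return az.from_dict(posterior=post, coords=coords, dims=dims)

    def scalars(self) -> dict[str, np.ndarray]:
        """Flat name -> (chains, draws) map of every monitored scalar."""
        out = {name: self.beta[:, :, j] for j, name in enumerate(self.coef_names)}
        out["sigma"] = np.sqrt(self.sigma2)
        if self.omega is not None:
            for j, name in enumerate(self.z_names):
                out[f"sd_{name}"] = np.sqrt(self.omega[:, :, j, j])
        return out

    def inclusion(self) -> dict[str, float]:
        if self.gamma is None:
            return {}
        return {
            t: float(self.gamma[:, :, j].mean()) for j, t in enumerate(self.indicator_terms)
        }


def _invgamma_draw(rng: np.random.Generator, a: float, b: float) -> float:
    return b / rng.gamma(a)


def _mvn_draw(rng, mean: np.ndarray, prec_chol: np.ndarray) -> np.ndarray:
    """Draw N(mean, P^-1) given the Cholesky factor L of the precision P."""
    z = rng.standard_normal(mean.shape[0])
    from scipy.linalg import solve_triangular

    return mean + solve_triangular(prec_chol, z, lower=True, trans="T")


class _GibbsState:
    """Mutable sampler state for one chain (internal)."""

    def __init__(self, y, dm: DesignMatrices, spec: ModelSpec, indicator_terms, rng):
        self.y = y
        self.dm = dm
        self.spec = spec
        self.rng = rng
        p = dm.n_coef
        self.terms = ["intercept"] + [t for t in dm.term_slices if t != "intercept"]
        self.sel = {t: (t in indicator_terms) for t in self.terms}
        self.beta = np.zeros(p)
        self.beta[0] = float(np.mean(y))
        self.gamma = {t: 1 for t in self.terms}
        self.q = dm.n_random
        self.S = max(len(dm.subjects), 1)
        self.xi = np.zeros((self.S, self.q))
        self.omega = np.eye(self.q) * spec.random_scale**2 if self.q else np.zeros((0, 0))
        self.sigma2 = spec.sigma2_fixed or max(float(np.var(y)), 1.0)
        # per-term design blocks and Gram matrices (fixed across iterations)
        self.Xt = {t: dm.X[:, dm.term_slices[t]] for t in self.terms}
        self.XtX = {t: self.Xt[t].T @ self.Xt[t] for t in self.terms}
        self.prior_prec = {
            t: np.eye(self.Xt[t].shape[1]) / spec.scale_for(t) ** 2 for t in self.terms
        }
        # 0.5 * log det(S_t) of each block's prior covariance
        self.half_logdet_prior = {
            t: self.Xt[t].shape[1] * np.log(spec.scale_for(t)) for t in self.terms
        }
        self.contrib = {
            t: self.Xt[t] @ self.beta[dm.term_slices[t]] for t in self.terms
        }
        if self.q:
            self.ZtZ = np.zeros((self.S, self.q, self.q))
            for s in range(self.S):
                Zs = dm.Z[dm.subject == s]
                self.ZtZ[s] = Zs.T @ Zs
            self.nu0 = self.q + 2
            self.psi0 = np.eye(self.q) * spec.random_scale**2
        self.zpart = np.zeros(len(y))

    def fixed_total(self) -> np.ndarray:
        tot = np.zeros(len(self.y))
        for t in self.terms:
            if self.gamma[t]:
                tot += self.contrib[t]
        return tot

    def update_fixed(self, indicator_prior: float) -> None:
        rng, spec, dm = self.rng, self.spec, self.dm
        resid = self.y - self.fixed_total() - self.zpart
        log_prior_odds = np.log(indicator_prior / (1 - indicator_prior))
        for t in self.terms:
            sl = dm.term_slices[t]
            if self.gamma[t]:
                resid = resid + self.contrib[t]  # residual excluding term t
            prec = self.XtX[t] / self.sigma2 + self.prior_prec[t]
            L = np.linalg.cholesky(prec)
            b = self.Xt[t].T @ resid / self.sigma2
            mean = np.linalg.solve(prec, b)
            if self.sel[t]:
                # indicator drawn with the coefficient block integrated out:
                # log ML ratio = 1/2 b'A^{-1}b - 1/2 log|A| - 1/2 log|S|
                half_logdet_A = np.log(np.diag(L)).sum()
                log_ratio = 0.5 * (b @ mean) - half_logdet_A - self.half_logdet_prior[t]
                self.gamma[t] = int(rng.random() < expit(log_prior_odds + log_ratio))
            if self.gamma[t]:
                self.beta[sl] = _mvn_draw(rng, mean, L)
            else:
                self.beta[sl] = rng.standard_normal(sl.stop - sl.start) * spec.scale_for(t)
            self.contrib[t] = self.Xt[t] @ self.beta[sl]
            if self.gamma[t]:
                resid = resid - self.contrib[t]

    def update_random(self) -> None:
        if not self.q:
            return
        rng, dm = self.rng, self.dm
        r = self.y - self.fixed_total()
        b = np.zeros((self.S, self.q))
        np.add.at(b, dm.subject, dm.Z * r[:, None])
        omega_inv = np.linalg.inv(self.omega)
        A = self.ZtZ / self.sigma2 + omega_inv
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b[:, :, None] / self.sigma2)[:, :, 0]
        z = rng.standard_normal((self.S, self.q, 1))
        self.xi = mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[:, :, 0]
        self.zpart = np.einsum("ij,ij->i", dm.Z, self.xi[dm.subject])
        scale = self.psi0 + self.xi.T @ self.xi
        self.omega = stats.invwishart.rvs(df=self.nu0 + self.S, scale=scale, random_state=rng)
        self.omega = np.atleast_2d(self.omega)

    def update_sigma2(self) -> None:
        if self.spec.sigma2_fixed is not None:
            return
        resid = self.y - self.fixed_total() - self.zpart
        a = self.spec.residual_a + len(self.y) / 2.0
        b = self.spec.residual_b + resid @ resid / 2.0
        self.sigma2 = _invgamma_draw(self.rng, a, b)


def sample_posterior(
    spec: ModelSpec,
    cells: pd.DataFrame,
    chains: int = 3,
    iterations: int = 2000,
    warmup: int = 1000,
    seed: int = 0,
    indicator_terms: Sequence[str] | None = None,
    indicator_prior: float = 0.5,
    thin: int = 1,
) -> PosteriorDraws:
    """Draw from the posterior of ``spec`` fitted to a cell-mean table.

    ``iterations`` counts post-warmup draws per chain (before thinning).
    With ``indicator_terms`` set, those fixed-effect terms carry Bernoulli
    inclusion indicators (Kuo-Mallick) with prior ``indicator_prior``.
    """
    if chains < 1:
        raise ValueError("need at least one chain")
    if iterations <= 0 or warmup < 0:
        raise ValueError("iterations must be positive and warmup non-negative")
    if not 0 < indicator_prior < 1:
        raise ValueError("indicator prior must lie in (0, 1)")
    y = cells[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"response column {spec.response!r} contains NaN")
    dm = build_design(cells, spec.fixed_terms, spec.random_terms)
    ind = [canonical_term(t) for t in (indicator_terms or [])]
    for t in ind:
        if t not in dm.term_slices:
            raise ValueError(f"indicator term {t!r} not among fixed terms")
        if dm.term_slices[t].stop == dm.term_slices[t].start:
            raise ValueError(f"indicator term {t!r} has zero design columns")

    kept = iterations // thin
    beta = np.empty((chains, kept, dm.n_coef))
    sig2 = np.empty((chains, kept))
    gam = np.empty((chains, kept, len(ind))) if ind else None
    omg = np.empty((chains, kept, dm.n_random, dm.n_random)) if dm.n_random else None

    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, c]))
        st = _GibbsState(y, dm, spec, ind, rng)
        k = 0
        for it in range(warmup + iterations):
            st.update_fixed(indicator_prior)
            st.update_random()
            st.update_sigma2()
            if it >= warmup and (it - warmup) % thin == 0 and k < kept:
                beta[c, k] = st.beta
                sig2[c, k] = st.sigma2
                if gam is not None:
                    gam[c, k] = [st.gamma[t] for t in ind]
                if omg is not None:
                    omg[c, k] = st.omega
                k += 1
    return PosteriorDraws(
        beta=beta,
        sigma2=sig2,
        coef_names=dm.coef_names,
        term_slices=dm.term_slices,
        gamma=gam,
        indicator_terms=list(ind),
        omega=omg,
        z_names=dm.z_names,
        design=dm,
    )


# ---------------------------------------------------------------------------
# summaries


def hdi(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` posterior mass (unimodal)."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n == 0:
        raise ValueError("no draws")
    m = max(int(np.ceil(prob * n)), 1)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def posterior_mode(draws: np.ndarray, max_points: int = 4000) -> float:
    """KDE argmax with Silverman bandwidth; binned fallback for rough cases."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.std() == 0:
        return float(x[0])
    if len(x) > max_points:  # deterministic thinning for speed
        x_kde = x[:: max(len(x) // max_points, 1)]
    else:
        x_kde = x
    grid = np.linspace(x.min(), x.max(), 512)
    try:
        dens = stats.gaussian_kde(x_kde, bw_method="silverman")(grid)
    except np.linalg.LinAlgError:
        dens, edges = np.histogram(x, bins=64)
        grid = 0.5 * (edges[:-1] + edges[1:])
    return float(grid[int(np.argmax(dens))])


def summarize(draws: PosteriorDraws | Mapping[str, np.ndarray], min_draws: int = 1000) -> pd.DataFrame:
    """Posterior mode, 95% HDI and convergence diagnostics per estimand.

    Requires at least ``min_draws`` pooled post-warmup draws.  The mode is
    clipped into the HDI so the summary always satisfies
    hdi_low <= mode <= hdi_high.
    """
    scalars = draws.scalars() if isinstance(draws, PosteriorDraws) else dict(draws)
    rows = []
    for name, arr in scalars.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.size < min_draws:
            raise ValueError(
                f"{name}: only {arr.size} draws, need >= {min_draws} for a stable summary"
            )
        lo, hi = hdi(arr)
        mode = min(max(posterior_mode(arr), lo), hi)
        const = arr.std() == 0
        rows.append(
            {
                "estimand": name,
                "mode": mode,
                "hdi_low": lo,
                "hdi_high": hi,
                "ess": float("inf") if const else float(az.ess(az.convert_to_dataset(arr))["x"].values),
                "rhat": 1.0 if const else float(az.rhat(az.convert_to_dataset(arr))["x"].values),
                "mcse": 0.0 if const else float(az.mcse(az.convert_to_dataset(arr))["x"].values),
            }
        )
    return pd.DataFrame(rows).set_index("estimand")


def check_convergence(summary: pd.DataFrame, gate: float = RHAT_GATE, strict: bool = False) -> list[str]:
    """Return estimands whose split-R-hat exceeds ``gate``; raise if strict."""
    bad = summary.index[summary["rhat"] > gate].tolist()
    if bad and strict:
        worst = summary.loc[bad, "rhat"].max()
        raise ConvergenceError(f"split-R-hat gate {gate} failed for {bad} (max {worst:.4f})")
    return bad


def predict_cells(draws: PosteriorDraws, newdata: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Posterior draws of fixed-effect cell means for new factor combinations.

    Returns an array of shape (chains, draws, len(newdata)); random effects
    average to zero over participants and are omitted.
    """
    if draws.design is None:
        raise ValueError("draws carry no design information")
    dm = build_design(newdata, spec.fixed_terms, random_terms=(), levels=draws.design.levels)
    if dm.coef_names != draws.coef_names:
        raise ValueError("newdata produces a different coefficient basis")
    return np.einsum("cdp,np->cdn", draws.beta, dm.X)
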