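"""Hierarchical latent-trait EMR model fitted by MCMC.

Individual differences are modelled on the probit scale: person *i*'s value of
free parameter group *j* is

    theta_ij = Phi(mu_j + delta_ij),     delta_i ~ MVN(0, Sigma),

where Phi is the standard-normal CDF, mu_j is the group-level mean and Sigma a
full covariance over a condition's free parameter groups.  Parameters equated
within a condition (e.g. m_s = m_u in the baseline variants) share one latent
trait.  Each condition is fitted separately, so a parameter equated across
conditions in the aggregated ML analysis (r_c) is per-condition here.

Priors: mu_j ~ N(0, 1) on the probit scale; Sigma ~ inverse-Wishart with
identity scale and df = (number of free groups) + 1, a weakly informative
default.  Both are configurable through :class:`McmcOptions`.

Sampling is Metropolis-within-Gibbs: random-walk updates for mu and for the
person deviations (vectorised across persons), and a conjugate
inverse-Wishart draw for Sigma.  Proposal scales adapt toward a 0.44
acceptance rate during burn-in and are frozen afterwards, which keeps the
kept draws a valid Markov chain.  Convergence is monitored with the
Gelman-Rubin potential scale reduction factor R-hat; model fit with the
posterior predictive statistics T1 (mean category frequencies) and T2
(covariance structure of category frequencies across persons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy import stats
from scipy.special import ndtr

from .emr_model import (
    ModelSpec,
    N_PARAMS,
    PARAM_NAMES,
    branch_matrices,
)

__all__ = [
    "McmcOptions",
    "PosteriorSummary",
    "GroupDifference",
    "fit_hierarchical",
    "rhat",
    "posterior_predictive_fit",
    "group_difference",
]

_A, _B, _C = branch_matrices()


@dataclass(frozen=True)
class McmcOptions:
    """Sampler settings; defaults give well-converged chains at study scale."""

    n_chains: int = 4
    n_burn: int = 2000
    n_keep: int = 8000
    adapt_interval: int = 50
    rhat_threshold: float = 1.05
    prior_mu_sd: float = 1.0
    prior_scale: float = 1.0  # inverse-Wishart identity-scale multiplier


@dataclass
class GroupDifference:
    """Posterior of a between-condition difference of a group-level parameter."""

    parameter: str
    draws: np.ndarray
    mean: float
    bci: tuple[float, float]
    bayesian_p: float  # one-tailed: mass on the unpredicted side of zero
    direction: str


@dataclass
class PosteriorSummary:
    """Posterior draws and diagnostics for one condition's hierarchical fit."""

    condition: str
    labels: tuple[str, ...]
    chains: np.ndarray            # (n_chains, n_keep, k) probability scale
    mu_chains: np.ndarray         # (n_chains, n_keep, k) probit scale
    person_draws: np.ndarray      # (n_chains, n_keep_thinned, n, k) prob scale
    person_thin: int
    counts: np.ndarray            # (n_persons, 12) observed category counts
    slot_index: np.ndarray        # (9,) free-group index per canonical slot, -1 fixed
    slot_fixed: np.ndarray        # (9,) fixed values where slot_index == -1
    means: dict[str, float]
    bcis: dict[str, tuple[float, float]]
    rhats: dict[str, float]
    converged: bool
    t1_p: float | None = None
    t2_p: float | None = None
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def flat(self) -> np.ndarray:
        """Probability-scale group draws pooled over chains, (draws, k)."""
        return self.chains.reshape(-1, self.chains.shape[-1])

    def draws_frame(self):
        import pandas as pd
        nc, nk, k = self.chains.shape
        rows = {
            "chain": np.repeat(np.arange(nc), nk * k),
            "draw": np.tile(np.repeat(np.arange(nk), k), nc),
            "parameter": np.tile(list(self.labels), nc * nk),
            "value": self.chains.ravel(),
        }
        return pd.DataFrame(rows)


def _condition_layout(spec: ModelSpec, condition: str
                      ) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Condition-local free groups: slot->group index map and fixed values."""
    group_of = spec._group_of()
    labels: list[str] = []
    idx = np.full(N_PARAMS, -1, dtype=int)
    fval = np.zeros(N_PARAMS)
    for j, p in enumerate(PARAM_NAMES):
        lab = spec.label_for(condition, p)
        if lab in spec.fixed:
            fval[j] = spec.fixed[lab]
            continue
        g = group_of[p]
        if g not in labels:
            labels.append(g)
        idx[j] = labels.index(g)
    return tuple(labels), idx, fval


def _person_counts(data, condition: str | None):
    """Accept an (n, 12) array/DataFrame of per-person counts or a trials
    table (tabulated via the study pipeline)."""
    import pandas as pd
    if isinstance(data, pd.DataFrame) and "pair" in data.columns:
        from .study_pipeline import tabulate_categories
        person, _ = tabulate_categories(data)
        if condition is not None:
            person = person[person["condition"] == condition]
        cols = [f"E{i}" for i in range(1, 13)]
        return person[cols].to_numpy(float), (
            condition or str(person["condition"].iloc[0]))
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 12:
        raise ValueError("expected per-person counts with 12 columns")
    return arr, (condition or "")


def _loglik_rows(counts: np.ndarray, eta: np.ndarray, idx: np.ndarray,
                 fval: np.ndarray) -> np.ndarray:
    """Per-person multinomial log-likelihood given probit-scale person traits."""
    theta = np.empty((eta.shape[0], N_PARAMS))
    free_mask = idx >= 0
    theta[:, free_mask] = np.clip(ndtr(eta)[:, idx[free_mask]], 1e-12, 1 - 1e-12)
    theta[:, ~free_mask] = np.clip(fval[~free_mask], 1e-12, 1 - 1e-12)
    logp = np.log(theta) @ _A.T + np.log1p(-theta) @ _B.T
    p = np.exp(logp) @ _C.T
    return np.sum(counts * np.log(np.clip(p, 1e-300, None)), axis=1)


def _theta_persons(eta: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Probability-scale person traits (n, k) from probit-scale eta."""
    return ndtr(eta)


def fit_hierarchical(data, spec: ModelSpec, condition: str | None = None,
                     options: McmcOptions | None = None, seed: int = 0,
                     ) -> PosteriorSummary:
    """Fit the latent-trait EMR model to one condition's individual data.

    ``data`` is either a trials table for a single condition or an (n, 12)
    per-person category count matrix.  Group-level parameters are reported on
    the probability scale as Phi(mu).  Deterministic given ``seed``.
    """
    options = options or McmcOptions()
    if options.n_chains < 2:
        raise ValueError("at least 2 chains are required for R-hat")
    counts, condition = _person_counts(data, condition)
    n = counts.shape[0]
    labels, idx, fval = _condition_layout(spec, condition)
    k = len(labels)
    nu0 = k + 1
    S0 = options.prior_scale * np.eye(k)

    person_thin = max(1, options.n_keep // 500)
    n_person_kept = options.n_keep // person_thin

    seeds = np.random.SeedSequence(seed).spawn(options.n_chains)
    mu_chains = np.empty((options.n_chains, options.n_keep, k))
    person_draws = np.empty((options.n_chains, n_person_kept, n, k))
    acc_report: dict[str, float] = {}

    for ci in range(options.n_chains):
        rng = np.random.default_rng(seeds[ci])
        mu = rng.normal(0.0, 0.5, size=k)
        delta = rng.normal(0.0, 0.3, size=(n, k))
        Sigma = np.eye(k)
        Lam = np.linalg.inv(Sigma)
        s_mu = np.full(k, 0.15)
        s_de = np.full(k, 0.4)
        acc_mu = np.zeros(k)
        acc_de = np.zeros(k)
        acc_mu_keep = np.zeros(k)
        acc_de_keep = np.zeros(k)
        n_acc_window = 0

        eta = mu + delta
        ll = _loglik_rows(counts, eta, idx, fval)

        total_iter = options.n_burn + options.n_keep
        kept = 0
        for it in range(total_iter):
            adapting = it < options.n_burn
            # --- group means -------------------------------------------------
            for j in range(k):
                prop = mu.copy()
                prop[j] += rng.normal(0.0, s_mu[j])
                eta_p = eta + (prop[j] - mu[j]) * _col(k, j)
                ll_p = _loglik_rows(counts, eta_p, idx, fval)
                dprior = (mu[j] ** 2 - prop[j] ** 2) / (2 * options.prior_mu_sd ** 2)
                if math.log(rng.uniform()) < ll_p.sum() - ll.sum() + dprior:
                    mu = prop
                    eta = eta_p
                    ll = ll_p
                    acc_mu[j] += 1
                    if not adapting:
                        acc_mu_keep[j] += 1
            # --- person deviations ------------------------------------------
            for j in range(k):
                step = rng.normal(0.0, s_de[j], size=n)
                delta_p = delta.copy()
                delta_p[:, j] += step
                eta_p = eta.copy()
                eta_p[:, j] += step
                ll_p = _loglik_rows(counts, eta_p, idx, fval)
                q_old = np.einsum("ij,jk,ik->i", delta, Lam, delta)
                q_new = np.einsum("ij,jk,ik->i", delta_p, Lam, delta_p)
                accept = np.log(rng.uniform(size=n)) < ll_p - ll + 0.5 * (q_old - q_new)
                delta[accept, j] = delta_p[accept, j]
                eta[accept, j] = eta_p[accept, j]
                ll[accept] = ll_p[accept]
                acc_de[j] += accept.mean()
                if not adapting:
                    acc_de_keep[j] += accept.mean()
            # --- joint translation (mu_j up, deviations down) ---------------
            # eta and hence the likelihood are unchanged; only the priors
            # enter.  Decorrelates mu from the person deviations, which the
            # likelihood ties together.
            for j in range(k):
                eps = rng.normal(0.0, 0.3)
                mu_j_new = mu[j] + eps
                dnew = delta[:, j] - eps
                dq = (-2.0 * eps * (delta @ Lam[j]) .sum()
                      + n * eps * eps * Lam[j, j])
                dprior = ((mu[j] ** 2 - mu_j_new ** 2)
                          / (2 * options.prior_mu_sd ** 2) - 0.5 * dq)
                if math.log(rng.uniform()) < dprior:
                    mu[j] = mu_j_new
                    delta[:, j] = dnew
            # --- covariance (conjugate) -------------------------------------
            Sigma = stats.invwishart.rvs(df=nu0 + n, scale=S0 + delta.T @ delta,
                                         random_state=rng)
            Sigma = np.atleast_2d(Sigma)
            Lam = np.linalg.inv(Sigma)

            n_acc_window += 1
            if adapting and n_acc_window == options.adapt_interval:
                rate_mu = acc_mu / n_acc_window
                rate_de = acc_de / n_acc_window
                s_mu *= np.exp(np.clip(rate_mu - 0.44, -0.5, 0.5))
                s_de *= np.exp(np.clip(rate_de - 0.44, -0.5, 0.5))
                acc_mu[:] = 0.0
                acc_de[:] = 0.0
                n_acc_window = 0
            elif not adapting and n_acc_window == options.adapt_interval:
                n_acc_window = 0  # keep counting windows but never rescale

            if not adapting:
                j_keep = it - options.n_burn
                mu_chains[ci, j_keep] = mu
                if j_keep % person_thin == 0 and kept < n_person_kept:
                    person_draws[ci, kept] = _theta_persons(eta, idx)
                    kept += 1
        acc_report[f"chain{ci}_mu"] = float(np.mean(acc_mu_keep) / options.n_keep)
        acc_report[f"chain{ci}_delta"] = float(np.mean(acc_de_keep) / options.n_keep)

    prob_chains = ndtr(mu_chains)
    means, bcis, rhats = {}, {}, {}
    rh = rhat(prob_chains)
    for jj, lab in enumerate(labels):
        flat = prob_chains[:, :, jj].ravel()
        means[lab] = float(flat.mean())
        bcis[lab] = (float(np.percentile(flat, 2.5)), float(np.percentile(flat, 97.5)))
        rhats[lab] = float(rh[jj])
    converged = all(v <= options.rhat_threshold for v in rhats.values())

    return PosteriorSummary(
        condition=condition, labels=labels, chains=prob_chains,
        mu_chains=mu_chains, person_draws=person_draws, person_thin=person_thin,
        counts=counts, slot_index=idx, slot_fixed=fval,
        means=means, bcis=bcis, rhats=rhats, converged=converged,
        acceptance=acc_report,
    )


def _col(k: int, j: int) -> np.ndarray:
    e = np.zeros(k)
    e[j] = 1.0
    return e


def rhat(chains: np.ndarray) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws) or (n_chains, n_draws, n_params);
    returns a scalar array or a per-parameter vector.  Uses the classic PSRF:
    with within-chain variance W and between-chain variance B,
    R-hat = sqrt(((n-1)/n * W + B/n) / W).
    """
    chains = np.asarray(chains, dtype=float)
    squeeze = chains.ndim == 2
    if squeeze:
        chains = chains[:, :, None]
    m, nd, _ = chains.shape
    if m < 2 or nd < 10:
        raise ValueError("R-hat needs >=2 chains with >=10 draws each")
    means = chains.mean(axis=1)                      # (m, k)
    W = chains.var(axis=1, ddof=1).mean(axis=0)      # (k,)
    B_over_n = means.var(axis=0, ddof=1)             # (k,) = B/n
    var_plus = (nd - 1) / nd * W + B_over_n
    out = np.sqrt(var_plus / np.where(W > 0, W, np.inf))
    out = np.where(W > 0, out, np.inf)
    return out[0] if squeeze else out


def _expected_count_stats(theta_slots: np.ndarray, n_pairs: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-person category counts and their expected covariance
    across persons (between-person spread plus mean multinomial noise)."""
    theta_slots = np.clip(theta_slots, 1e-12, 1 - 1e-12)
    logp = np.log(theta_slots) @ _A.T + np.log1p(-theta_slots) @ _B.T
    p = np.exp(logp) @ _C.T                          # (n, 12)
    mu_counts = n_pairs * p
    mean_counts = mu_counts.mean(axis=0)
    between = np.cov(mu_counts.T, ddof=1)
    # multinomial sampling covariance, averaged over persons
    within = n_pairs * (np.diag(p.mean(axis=0)) - (p.T @ p) / p.shape[0])
    return mean_counts, between + within


def posterior_predictive_fit(fit: PosteriorSummary, n_pairs: int = 40,
                             n_draws: int = 200, seed: int = 0,
                             counts: np.ndarray | None = None,
                             ) -> tuple[float, float]:
    """Posterior predictive p-values for the T1 and T2 statistics.

    T1 compares observed vs. expected mean category frequencies,
    T2 compares the observed vs. expected covariance matrix of category
    frequencies across persons; for each posterior draw the same statistic is
    computed for a replicated data set, and p is the fraction of draws with
    T(rep) >= T(obs).  With the default ``counts`` (the fitted data) both
    p-values are stored on ``fit``; passing other counts checks the fitted
    posterior against external data without touching the fit.
    """
    rng = np.random.default_rng(seed)
    external = counts is not None
    counts = fit.counts if counts is None else np.asarray(counts, float)
    nc, nk, n, k = fit.person_draws.shape
    pool = fit.person_draws.reshape(nc * nk, n, k)
    take = rng.choice(pool.shape[0], size=min(n_draws, pool.shape[0]), replace=False)

    idx = fit.slot_index
    fval = fit.slot_fixed
    free_mask = idx >= 0

    obs_cov = np.cov(counts.T, ddof=1)
    t1_obs = np.empty(take.size); t1_rep = np.empty(take.size)
    t2_obs = np.empty(take.size); t2_rep = np.empty(take.size)
    for a, t in enumerate(take):
        traits = pool[t]                              # (n, k) probability scale
        theta = np.empty((n, N_PARAMS))
        theta[:, free_mask] = traits[:, idx[free_mask]]
        theta[:, ~free_mask] = fval[~free_mask]
        mean_exp, cov_exp = _expected_count_stats(theta, n_pairs)
        p = np.exp(np.log(np.clip(theta, 1e-12, 1 - 1e-12)) @ _A.T
                   + np.log1p(-np.clip(theta, 1e-12, 1 - 1e-12)) @ _B.T) @ _C.T
        rep = np.stack([rng.multinomial(n_pairs, pi / pi.sum()) for pi in p])
        denom = np.clip(mean_exp, 1e-6, None)
        t1_obs[a] = np.sum((counts.mean(axis=0) - mean_exp) ** 2 / denom)
        t1_rep[a] = np.sum((rep.mean(axis=0) - mean_exp) ** 2 / denom)
        rep_cov = np.cov(rep.T, ddof=1)
        t2_obs[a] = np.sum((obs_cov - cov_exp) ** 2)
        t2_rep[a] = np.sum((rep_cov - cov_exp) ** 2)
    p1 = float(np.mean(t1_rep >= t1_obs))
    p2 = float(np.mean(t2_rep >= t2_obs))
    if not external:
        fit.t1_p, fit.t2_p = p1, p2
    return p1, p2


def group_difference(fit_a: PosteriorSummary, fit_b: PosteriorSummary,
                     parameter: str, direction: str = "greater",
                     ) -> GroupDifference:
    """Posterior of the group-level difference (A minus B) of ``parameter``.

    ``direction="greater"`` predicts A > B; the one-tailed Bayesian p is the
    posterior mass of the difference on the unpredicted side of zero.
    """
    for f in (fit_a, fit_b):
        if parameter not in f.labels:
            raise KeyError(f"parameter {parameter!r} not in fit for {f.condition!r}")
    da = fit_a.flat[:, fit_a.labels.index(parameter)]
    db = fit_b.flat[:, fit_b.labels.index(parameter)]
    nmin = min(da.size, db.size)
    diff = da[:nmin] - db[:nmin]
    # ties (exact zeros) count half, so identical fits give p = .5
    if direction == "greater":
        p = float(np.mean(diff < 0) + 0.5 * np.mean(diff == 0))
    elif direction == "less":
        p = float(np.mean(diff > 0) + 0.5 * np.mean(diff == 0))
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return GroupDifference(
        parameter=parameter, draws=diff, mean=float(diff.mean()),
        bci=(float(np.percentile(diff, 2.5)), float(np.percentile(diff, 97.5))),
        bayesian_p=p, direction=direction,
    )
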