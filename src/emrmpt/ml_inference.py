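"""Maximum-likelihood fitting of EMR model variants to aggregated counts.

Fitting is done on an unconstrained scale: each free parameter is logit
transformed, the multinomial log-likelihood kernel is maximised with L-BFGS-B
using analytic gradients, and several random restarts guard against local
optima.  Goodness of fit is the likelihood-ratio statistic

    G^2 = 2 * sum_i n_i * log(n_i / (N * p_hat_i)),

with 0*log 0 := 0, referred to a chi-square distribution whose df equals the
number of free category frequencies (11 per condition) minus the number of
free parameters.  Wald confidence intervals come from the inverse observed
Fisher information, delta-transformed to the probability scale and clipped to
[0, 1].

Nested model comparisons use Delta G^2; a single equality constraint admits a
directional (one-tailed) test via z = sign * sqrt(Delta G^2), with the sign
read from the unrestricted estimates.  Power analysis for such 1-df
constraints uses the noncentral chi-square approach: the constrained model is
fitted to the expected frequencies under the alternative, the resulting
per-observation divergence scales linearly with N, and the smallest N meeting
the target power is returned.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .emr_model import (
    CategoryTable,
    ConfigurationError,
    EmrParameterSet,
    ModelSpec,
    PARAM_NAMES,
    branch_matrices,
    degrees_of_freedom,
)

__all__ = [
    "FitOptions",
    "FitResultML",
    "RestrictionTest",
    "IdentifiabilityReport",
    "fit_ml",
    "test_restriction",
    "check_identifiability",
    "mpt_power",
    "restriction_power",
]

_A, _B, _C = branch_matrices()


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings for :func:`fit_ml`."""

    n_restarts: int = 10
    seed: int = 0
    tol: float = 1e-10
    max_iter: int = 500
    compute_ci: bool = True


@dataclass
class FitResultML:
    """Maximum-likelihood fit of an EMR model variant."""

    spec: ModelSpec
    estimates: dict[str, EmrParameterSet]
    free_estimates: dict[str, float]
    standard_errors: dict[str, float]
    confidence_intervals: dict[str, tuple[float, float]]
    log_lik: float
    g2: float
    df: int
    p_value: float
    aic: float
    bic: float
    n_restarts: int
    n_converged: int
    best_objective: float
    gradient_norm: float
    boundary_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "estimates": {c: {n: getattr(p, n) for n in PARAM_NAMES}
                          for c, p in self.estimates.items()},
            "free_estimates": self.free_estimates,
            "standard_errors": self.standard_errors,
            "confidence_intervals": {k: list(v) for k, v in self.confidence_intervals.items()},
            "log_lik": self.log_lik,
            "G2": self.g2,
            "df": self.df,
            "p_value": self.p_value,
            "AIC": self.aic,
            "BIC": self.bic,
            "convergence": {
                "n_restarts": self.n_restarts,
                "n_converged": self.n_converged,
                "best_objective": self.best_objective,
                "gradient_norm": self.gradient_norm,
                "boundary_flags": self.boundary_flags,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class RestrictionTest:
    """Nested-model comparison via the change in G^2."""

    delta_g2: float
    df: int
    z: float | None
    p_one_tailed: float | None
    p_two_tailed: float
    direction_consistent: bool | None
    general: FitResultML
    restricted: FitResultML


@dataclass
class IdentifiabilityReport:
    """Numerical local identifiability of a spec's free parameters."""

    n_free: int
    rank: int
    full_rank: bool
    singular_values: np.ndarray
    deficient_directions: np.ndarray  # (n_deficient, n_free) null-space rows
    labels: tuple[str, ...]


def _counts_arrays(counts, spec: ModelSpec) -> np.ndarray:
    """Stack counts into an (n_conditions, 12) array in spec condition order."""
    if isinstance(counts, Mapping):
        tabs = [counts[c] for c in spec.conditions]
    else:
        by_cond = {t.condition: t for t in counts}
        if set(by_cond) >= set(spec.conditions):
            tabs = [by_cond[c] for c in spec.conditions]
        else:
            tabs = list(counts)
    out = np.stack([np.asarray(t.values if isinstance(t, CategoryTable) else t, float)
                    for t in tabs])
    if out.shape != (len(spec.conditions), 12):
        raise ValueError("counts must provide one 12-category table per condition")
    return out


def _objective_factory(n: np.ndarray, spec: ModelSpec
                       ) -> tuple[Callable, Callable, int]:
    """Negative log-likelihood kernel and gradient on the logit scale."""
    idx, fmask, fval = spec.label_index_matrix()
    k = spec.n_free
    idx_safe = np.where(idx >= 0, idx, 0)

    def theta_of(x: np.ndarray) -> np.ndarray:
        free = expit(x)
        th = np.where(fmask, fval, free[idx_safe])
        return th  # (nc, 9)

    def negloglik_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        th = np.clip(theta_of(x), 1e-12, 1 - 1e-12)
        logpb = np.log(th) @ _A.T + np.log1p(-th) @ _B.T        # (nc, 32)
        pb = np.exp(logpb)
        p = pb @ _C.T                                            # (nc, 12)
        if np.any(p[n > 0] <= 0):
            return math.inf, np.zeros(k)
        ll = float(np.sum(n * np.log(np.where(n > 0, p, 1.0))))
        # w_b = sum_cat n_cat/p_cat * C[cat,b]
        ratio = np.where(n > 0, n / p, 0.0)                      # (nc, 12)
        w = ratio @ _C                                           # (nc, 32)
        # d ll / d theta_j = sum_b w_b pb_b (A_bj/th_j - B_bj/(1-th_j))
        wpb = w * pb
        dll_dth = (wpb @ _A) / th - (wpb @ _B) / (1.0 - th)      # (nc, 9)
        # chain through logit and accumulate onto free labels
        dth_dx = th * (1.0 - th)
        contrib = np.where(fmask, 0.0, dll_dth * dth_dx)
        grad = np.zeros(k)
        np.add.at(grad, idx_safe.ravel(), np.where(fmask, 0.0, contrib).ravel())
        return -ll, -grad

    return theta_of, negloglik_grad, k


def _saturated_loglik(n: np.ndarray) -> float:
    out = 0.0
    for row in n:
        tot = row.sum()
        mask = row > 0
        out += float(np.sum(row[mask] * np.log(row[mask] / tot)))
    return out


def fit_ml(counts, spec: ModelSpec, options: FitOptions | None = None,
           start: Sequence[float] | None = None) -> FitResultML:
    """Fit an EMR model variant to aggregated category counts.

    ``counts`` maps condition labels to :class:`CategoryTable` (or is a
    sequence of tables); ``start`` optionally adds a warm start (probability
    scale, free-label order) to the random restarts.
    """
    options = options or FitOptions()
    n = _counts_arrays(counts, spec)
    theta_of, fg, k = _objective_factory(n, spec)
    rng = np.random.default_rng(options.seed)

    starts = []
    if start is not None:
        starts.append(logit(np.clip(np.asarray(start, float), 1e-6, 1 - 1e-6)))
    starts.append(np.zeros(k))  # all parameters at .5
    while len(starts) < max(options.n_restarts, 1) + (start is not None):
        starts.append(logit(rng.uniform(0.05, 0.95, size=k)))

    best = None
    n_converged = 0
    for x0 in starts:
        res = optimize.minimize(
            fg, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": options.max_iter, "ftol": options.tol,
                     "gtol": 1e-9})
        if res.success or np.isfinite(res.fun):
            n_converged += int(bool(res.success))
            if best is None or res.fun < best.fun - 0.0:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("ML fit failed to converge in all restarts")

    x_hat = best.x
    theta_hat = theta_of(x_hat)
    free_hat = expit(x_hat)
    labels = spec.free_labels()
    estimates = spec.expand(free_hat)

    ll = -float(best.fun)
    g2 = max(0.0, 2.0 * (_saturated_loglik(n) - ll))
    df = degrees_of_freedom(spec)
    p_value = float(stats.chi2.sf(g2, df)) if df > 0 else 1.0
    n_total = float(n.sum())
    aic = -2.0 * ll + 2.0 * k
    bic = -2.0 * ll + k * math.log(n_total)

    boundary = [lab for lab, v in zip(labels, free_hat)
                if v < 1e-4 or v > 1 - 1e-4]

    ses = {lab: math.nan for lab in labels}
    cis = {lab: (math.nan, math.nan) for lab in labels}
    if options.compute_ci:
        try:
            H = _numerical_hessian(fg, x_hat)
            cov_x = np.linalg.pinv(H)
            var_x = np.clip(np.diag(cov_x), 0.0, np.inf)
            se_th = np.sqrt(var_x) * free_hat * (1.0 - free_hat)  # delta method
            for lab, th, se in zip(labels, free_hat, se_th):
                ses[lab] = float(se)
                cis[lab] = (float(np.clip(th - 1.959963984540054 * se, 0, 1)),
                            float(np.clip(th + 1.959963984540054 * se, 0, 1)))
        except np.linalg.LinAlgError:
            pass

    _, grad = fg(x_hat)
    return FitResultML(
        spec=spec,
        estimates=estimates,
        free_estimates=dict(zip(labels, free_hat.tolist())),
        standard_errors=ses,
        confidence_intervals=cis,
        log_lik=ll,
        g2=g2,
        df=df,
        p_value=p_value,
        aic=aic,
        bic=bic,
        n_restarts=len(starts),
        n_converged=n_converged,
        best_objective=float(best.fun),
        gradient_norm=float(np.linalg.norm(grad)),
        boundary_flags=boundary,
    )


def _numerical_hessian(fg: Callable, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    k = x.size
    H = np.zeros((k, k))
    for j in range(k):
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] -= h
        _, gp = fg(xp)
        _, gm = fg(xm)
        H[:, j] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def test_restriction(general: ModelSpec, restricted: ModelSpec, counts,
                     options: FitOptions | None = None,
                     direction: tuple[str, str, str] | None = None,
                     ) -> RestrictionTest:
    """Delta G^2 test of ``restricted`` against ``general``.

    ``direction=(param, larger_condition, smaller_condition)`` declares the
    predicted ordering for a single equality constraint; the one-tailed p uses
    z = sign * sqrt(Delta G^2) with the sign read from the unrestricted
    estimates (p > .5 when the estimates contradict the prediction).
    """
    if not restricted.is_nested_in(general):
        raise ConfigurationError("restricted spec is not nested in the general spec")
    fit_g = fit_ml(counts, general, options)
    fit_r = fit_ml(counts, restricted, options,
                   start=_project_start(fit_g, restricted))
    delta = fit_r.g2 - fit_g.g2
    if delta < -1e-6:
        # restricted beat general numerically: refit general from restricted optimum
        fit_g2 = fit_ml(counts, general, options, start=_project_start(fit_r, general))
        if fit_g2.g2 < fit_g.g2:
            fit_g = fit_g2
        delta = fit_r.g2 - fit_g.g2
    delta = max(0.0, delta)
    df = general.n_free - restricted.n_free
    p_two = float(stats.chi2.sf(delta, df)) if df > 0 else 1.0

    z = p_one = consistent = None
    if df == 1 and direction is not None:
        param, hi, lo = direction
        est_hi = getattr(fit_g.estimates[hi], param)
        est_lo = getattr(fit_g.estimates[lo], param)
        consistent = bool(est_hi >= est_lo)
        z = float((1.0 if consistent else -1.0) * math.sqrt(delta))
        p_one = float(stats.norm.sf(z))
    return RestrictionTest(delta_g2=delta, df=df, z=z, p_one_tailed=p_one,
                           p_two_tailed=p_two, direction_consistent=consistent,
                           general=fit_g, restricted=fit_r)


def _project_start(fit: FitResultML, target: ModelSpec) -> np.ndarray:
    """Warm start for ``target`` by averaging a fit's per-slot estimates."""
    sums: dict[str, list[float]] = {}
    for c in target.conditions:
        est = fit.estimates.get(c)
        if est is None:
            continue
        for p in PARAM_NAMES:
            sums.setdefault(target.label_for(c, p), []).append(getattr(est, p))
    return np.array([np.mean(sums.get(lab, [0.5])) for lab in target.free_labels()])


def check_identifiability(spec: ModelSpec, n_points: int = 5, seed: int = 0,
                          tol: float = 1e-8) -> IdentifiabilityReport:
    """Local identifiability via the numerical Jacobian of the free category
    probabilities (11 per condition) with respect to the free parameters,
    evaluated at random interior points and stacked."""
    rng = np.random.default_rng(seed)
    labels = spec.free_labels()
    k = len(labels)
    idx, fmask, fval = spec.label_index_matrix()
    idx_safe = np.where(idx >= 0, idx, 0)

    def probs(free: np.ndarray) -> np.ndarray:
        th = np.clip(np.where(fmask, fval, free[idx_safe]), 1e-12, 1 - 1e-12)
        p = np.exp(np.log(th) @ _A.T + np.log1p(-th) @ _B.T) @ _C.T
        return p[:, :11].ravel()  # drop the redundant 12th category

    rows = []
    h = 1e-6
    for _ in range(n_points):
        free = rng.uniform(0.2, 0.8, size=k)
        J = np.zeros((probs(free).size, k))
        for j in range(k):
            fp = free.copy(); fp[j] += h
            fm = free.copy(); fm[j] -= h
            J[:, j] = (probs(fp) - probs(fm)) / (2 * h)
        rows.append(J)
    J_all = np.vstack(rows)
    sv = np.linalg.svd(J_all, compute_uv=False)
    rank = int(np.sum(sv > tol * max(1.0, sv[0])))
    if rank < k:
        _, _, vt = np.linalg.svd(J_all)
        deficient = vt[rank:]
    else:
        deficient = np.zeros((0, k))
    return IdentifiabilityReport(n_free=k, rank=rank, full_rank=rank == k,
                                 singular_values=sv, deficient_directions=deficient,
                                 labels=labels)


def _noncentrality_per_pair(spec: ModelSpec, h0_constraint: ModelSpec,
                            h1_params: Mapping[str, EmrParameterSet],
                            allocation: Mapping[str, float] | None,
                            options: FitOptions | None) -> float:
    """Per-pair noncentrality 2 * sum_c w_c * KL(p_H1 || p_H0-fit)."""
    if h0_constraint.n_free >= spec.n_free:
        raise ConfigurationError("h0_constraint must restrict the spec")
    if spec.n_free - h0_constraint.n_free != 1:
        raise ConfigurationError("only single-df constraints are supported")
    conds = spec.conditions
    alloc = ({c: 1.0 / len(conds) for c in conds} if allocation is None
             else dict(allocation))
    w = np.array([alloc[c] for c in conds])
    w = w / w.sum()

    from .emr_model import category_probabilities
    p1 = np.stack([category_probabilities(h1_params[c]).values for c in conds])

    # fit the constrained model to expected frequencies (weighted by allocation)
    scale = 1e6
    pseudo = {c: CategoryTable(c, p1[i] * w[i] * scale) for i, c in enumerate(conds)}
    fit0 = fit_ml(pseudo, h0_constraint,
                  options or FitOptions(n_restarts=6, compute_ci=False))
    q = np.stack([category_probabilities(fit0.estimates[c]).values for c in conds])

    mask = p1 > 0
    return 2.0 * float(np.sum(w[:, None] * np.where(mask, p1 * np.log(
        np.where(mask, p1 / np.clip(q, 1e-300, None), 1.0)), 0.0)))


def restriction_power(spec: ModelSpec, h0_constraint: ModelSpec,
                      h1_params: Mapping[str, EmrParameterSet],
                      n_participants: int, alpha: float = 0.05,
                      pairs_per_participant: int = 40,
                      allocation: Mapping[str, float] | None = None,
                      tails: str = "one",
                      options: FitOptions | None = None) -> float:
    """Asymptotic power of a 1-df Delta G^2 test at total participant N.

    The noncentrality is the per-pair divergence between the H1 frequencies
    and the best-fitting constrained model, scaled by the total number of
    pairs.  ``tails="one"`` uses the signed-root normal approximation
    (z = sqrt(Delta G^2) with the predicted sign); ``"two"`` the noncentral
    chi-square.
    """
    lam1 = _noncentrality_per_pair(spec, h0_constraint, h1_params, allocation,
                                   options)
    if lam1 <= 1e-8:
        raise ValueError("constraint holds under H1: zero noncentrality, "
                         "required N is unbounded")
    lam = lam1 * n_participants * pairs_per_participant
    if tails == "two":
        crit = stats.chi2.ppf(1 - alpha, 1)
        return float(stats.ncx2.sf(crit, 1, lam))
    zcrit = stats.norm.ppf(1 - alpha)
    return float(stats.norm.sf(zcrit - math.sqrt(lam)))


def mpt_power(spec: ModelSpec, h0_constraint: ModelSpec,
              h1_params: Mapping[str, EmrParameterSet],
              alpha: float = 0.05, target_power: float = 0.95,
              pairs_per_participant: int = 40,
              allocation: Mapping[str, float] | None = None,
              tails: str = "one", n_max: int = 5000,
              options: FitOptions | None = None) -> int:
    """Smallest even total participant N for a 1-df Delta G^2 test to reach
    ``target_power`` (see :func:`restriction_power` for the model)."""
    lam1 = _noncentrality_per_pair(spec, h0_constraint, h1_params, allocation,
                                   options)
    if lam1 <= 1e-8:
        raise ValueError("constraint holds under H1: zero noncentrality, "
                         "required N is unbounded")

    def power(n_participants: int) -> float:
        lam = lam1 * n_participants * pairs_per_participant
        if tails == "two":
            crit = stats.chi2.ppf(1 - alpha, 1)
            return float(stats.ncx2.sf(crit, 1, lam))
        zcrit = stats.norm.ppf(1 - alpha)
        return float(stats.norm.sf(zcrit - math.sqrt(lam)))

    for n_tot in range(2, n_max + 1, 2):
        if power(n_tot) >= target_power:
            return n_tot
    raise ValueError(f"target power not reached by N={n_max}")
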