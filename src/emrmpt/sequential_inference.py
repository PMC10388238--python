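"""Design-based analyses: effect sizes, the sequential probability ratio
t test, default-prior Bayes factors and fixed-n sample-size planning.

The SPRT t test accumulates, over looks, the likelihood ratio of a fixed
design effect size d1 against the point null for the two-sample t statistic

    t = d * sqrt(n1 n2 / (n1 + n2)),

where d is the pooled-SD standardized mean difference.  With a noncentral-t
density under H1 (noncentrality delta = d1 * sqrt(n1 n2/(n1+n2))) and the
central-t density under H0,

    LR_n = f_nct(t; df, delta) / f_t(t; df),

sampling stops when LR crosses the lower threshold B = beta/(1-alpha)
(accept H0) or the upper threshold A = (1-beta)/alpha (accept H1).  The
caller fixes the predicted direction by the group order: group 1 is the
condition predicted to score higher, so positive t favours H1.

The Bayes-factor t test replaces the fixed alternative with a Cauchy prior
(default scale sqrt(2)/2) on the standardized effect; BF10 is computed by
numerical integration of the noncentral-t density over the prior.  Both the
two-sided and the directional (positive-truncated) variant are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "GroupSummary",
    "SprtLook",
    "SprtTrace",
    "BayesFactorResult",
    "cohens_d",
    "sprt_t",
    "sprt_trace",
    "jzs_bayes_factor",
    "t_test_sample_size",
    "simulate_sprt_calibration",
    "summarize_groups",
]

DEFAULT_RSCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class GroupSummary:
    """Per-group n, mean and sample SD (n-1 denominator); group 1 first."""

    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]

    def __post_init__(self) -> None:
        if min(self.n) < 2:
            raise ValueError("each group needs n >= 2")
        if min(self.sd) < 0:
            raise ValueError("standard deviations must be non-negative")


def summarize_groups(x1: Sequence[float], x2: Sequence[float]) -> GroupSummary:
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    return GroupSummary(
        n=(len(x1), len(x2)),
        mean=(float(x1.mean()), float(x2.mean())),
        sd=(float(x1.std(ddof=1)), float(x2.std(ddof=1))))


@dataclass(frozen=True)
class SprtLook:
    """One look of the sequential t test."""

    n: tuple[int, int]
    t: float
    lr: float
    lower: float  # B = beta/(1-alpha)
    upper: float  # A = (1-beta)/alpha
    decision: str  # accept_H0 | accept_H1 | continue
    d1: float


@dataclass
class SprtTrace:
    """Looks of a sequential experiment with the terminal decision.

    When sampling continues past the SPRT decision (e.g. for a second
    stopping rule) later looks keep recording LR_n but never revise the
    decision made at termination.
    """

    looks: list[SprtLook]
    decision: str
    decision_look: int | None
    d1: float
    alpha: float
    beta: float


def cohens_d(summary: GroupSummary) -> float:
    """Pooled-SD standardized mean difference, group 1 minus group 2."""
    n1, n2 = summary.n
    s1, s2 = summary.sd
    pooled = math.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    if pooled == 0:
        return 0.0
    return (summary.mean[0] - summary.mean[1]) / pooled


def sprt_t(summary: GroupSummary, d1: float, alpha: float = 0.05,
           beta: float = 0.20) -> SprtLook:
    """One SPRT t-test look; group 1 is the condition predicted larger."""
    if d1 <= 0:
        raise ValueError("design effect size d1 must be positive")
    if not (0 < alpha < 0.5 and 0 < beta < 0.5):
        raise ValueError("alpha and beta must lie in (0, .5)")
    n1, n2 = summary.n
    if summary.sd == (0.0, 0.0):
        raise ValueError("degenerate variance: both group SDs are zero")
    d = cohens_d(summary)
    ne = n1 * n2 / (n1 + n2)
    t = d * math.sqrt(ne)
    df = n1 + n2 - 2
    delta = d1 * math.sqrt(ne)
    lr = float(stats.nct.pdf(t, df, delta) / stats.t.pdf(t, df))
    lower = beta / (1 - alpha)
    upper = (1 - beta) / alpha
    decision = "continue"
    if lr <= lower:
        decision = "accept_H0"
    elif lr >= upper:
        decision = "accept_H1"
    return SprtLook(n=(n1, n2), t=t, lr=lr, lower=lower, upper=upper,
                    decision=decision, d1=d1)


def sprt_trace(looks: Sequence[GroupSummary], d1: float, alpha: float = 0.05,
               beta: float = 0.20) -> SprtTrace:
    """Evaluate a sequence of cumulative looks; the first threshold crossing
    fixes the decision, later looks are recorded without revising it."""
    out: list[SprtLook] = []
    decision = "continue"
    decision_look = None
    for i, s in enumerate(looks):
        look = sprt_t(s, d1, alpha, beta)
        out.append(look)
        if decision == "continue" and look.decision != "continue":
            decision = look.decision
            decision_look = i
    return SprtTrace(looks=out, decision=decision, decision_look=decision_look,
                     d1=d1, alpha=alpha, beta=beta)


@dataclass(frozen=True)
class BayesFactorResult:
    bf10_two_sided: float
    bf10_one_sided: float  # prior truncated to the predicted (positive) side
    t: float
    df: int
    rscale: float


def jzs_bayes_factor(summary: GroupSummary,
                     rscale: float = DEFAULT_RSCALE) -> BayesFactorResult:
    """Two-sample default-prior (JZS) Bayes factor BF10.

    The marginal likelihood under H1 integrates the noncentral-t density of
    the observed t over a Cauchy prior on the standardized effect size
    (scale ``rscale``); H0 is the point null.  The one-sided variant
    truncates the prior to positive effects (group 1 larger).
    """
    if rscale <= 0:
        raise ValueError("rscale must be positive")
    n1, n2 = summary.n
    ne = n1 * n2 / (n1 + n2)
    df = n1 + n2 - 2
    t = cohens_d(summary) * math.sqrt(ne)
    f0 = stats.t.pdf(t, df)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * math.sqrt(ne)) \
            * stats.cauchy.pdf(delta, 0.0, rscale)

    m_two, err2 = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    m_one, err1 = integrate.quad(lambda d: 2.0 * integrand(d), 0.0, np.inf,
                                 limit=200)
    if not (np.isfinite(m_two) and np.isfinite(m_one)) or m_two <= 0:
        raise ArithmeticError(
            f"Bayes factor integration failed (m2={m_two}, err={err2})")
    return BayesFactorResult(bf10_two_sided=float(m_two / f0),
                             bf10_one_sided=float(m_one / f0),
                             t=t, df=df, rscale=rscale)


def t_test_sample_size(d: float, alpha: float = 0.05, power: float = 0.80,
                       tails: str = "one", n_max: int = 100_000) -> int:
    """Smallest even total N (equal groups) whose noncentral-t power for a
    two-sample t test at the given alpha reaches ``power``."""
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not (0 < alpha < 1 and alpha < power < 1):
        raise ValueError("need 0 < alpha < power < 1")

    def achieved(n_total: int) -> float:
        n = n_total // 2
        df = n_total - 2
        delta = d * math.sqrt(n / 2.0)
        if tails == "one":
            crit = stats.t.ppf(1 - alpha, df)
            return float(stats.nct.sf(crit, df, delta))
        crit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(crit, df, delta)
                     + stats.nct.cdf(-crit, df, delta))

    for n_total in range(6, n_max + 1, 2):
        if achieved(n_total) >= power:
            return n_total
    raise ValueError(f"power not reached by N={n_max}")


def simulate_sprt_calibration(d_true: float, d1: float = 0.5,
                              alpha: float = 0.05, beta: float = 0.20,
                              first_look: int = 9, increment: int = 2,
                              n_max_per_group: int = 200,
                              n_experiments: int = 500,
                              seed: int = 0) -> dict:
    """Monte-Carlo error rates of the sequential design.

    Each experiment draws groups sequentially (first look at ``first_look``
    per group, then ``increment`` more per look) from N(d_true, 1) vs. N(0, 1)
    and applies the SPRT until a threshold is crossed or ``n_max_per_group``
    is reached.  Returns acceptance rates and mean terminal sample size.
    """
    rng = np.random.default_rng(seed)
    accept_h1 = accept_h0 = undecided = 0
    n_terminal = []
    for _ in range(n_experiments):
        x1 = rng.normal(d_true, 1.0, size=n_max_per_group)
        x2 = rng.normal(0.0, 1.0, size=n_max_per_group)
        n = first_look
        decision = "continue"
        while n <= n_max_per_group:
            look = sprt_t(summarize_groups(x1[:n], x2[:n]), d1, alpha, beta)
            if look.decision != "continue":
                decision = look.decision
                break
            n += increment
        n_terminal.append(min(n, n_max_per_group))
        if decision == "accept_H1":
            accept_h1 += 1
        elif decision == "accept_H0":
            accept_h0 += 1
        else:
            undecided += 1
    return {
        "accept_H1_rate": accept_h1 / n_experiments,
        "accept_H0_rate": accept_h0 / n_experiments,
        "undecided_rate": undecided / n_experiments,
        "mean_n_per_group": float(np.mean(n_terminal)),
    }
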