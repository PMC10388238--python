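"""Effect sizes, SPRT t test, Bayes factors and sample-size planning.

The frozen reference values are the published summaries of the study that
motivates the package: the N=18 sequential subsample and the N=93 full
sample, group order always (predicted-larger, other).
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from emrmpt import GroupSummary, cohens_d, jzs_bayes_factor, sprt_t, t_test_sample_size
from emrmpt.sequential_inference import (
    simulate_sprt_calibration,
    sprt_trace,
    summarize_groups,
)

# Table summaries: (mean, SD) per group, group 1 = condition predicted larger.
SUB_H1 = GroupSummary(n=(9, 9), mean=(1.67, 2.56), sd=(1.50, 1.81))
SUB_H2 = GroupSummary(n=(9, 9), mean=(9.22, 13.22), sd=(4.60, 5.09))
FULL_H1 = GroupSummary(n=(47, 46), mean=(2.49, 1.72), sd=(2.41, 1.73))
FULL_H2 = GroupSummary(n=(46, 47), mean=(11.57, 10.04), sd=(5.44, 4.66))


class TestCohensD:
    @pytest.mark.parametrize("summary, expected", [
        (SUB_H1, -0.53), (SUB_H2, -0.82), (FULL_H1, 0.37), (FULL_H2, 0.30),
    ])
    def test_published_effect_sizes(self, summary, expected):
        # recomputed from 2-decimal table entries, hence the +-.01 band
        assert cohens_d(summary) == pytest.approx(expected, abs=0.01)

    def test_identical_groups_give_zero(self):
        s = GroupSummary(n=(10, 10), mean=(5.0, 5.0), sd=(2.0, 2.0))
        assert cohens_d(s) == 0.0


class TestSprt:
    def test_thresholds(self):
        look = sprt_t(SUB_H1, d1=0.5, alpha=0.05, beta=0.20)
        assert look.lower == pytest.approx(0.20 / 0.95)  # 0.21
        assert look.upper == pytest.approx(0.80 / 0.05)

    @pytest.mark.parametrize("summary, lr", [(SUB_H1, 0.18), (SUB_H2, 0.11)])
    def test_subsample_likelihood_ratios_accept_null(self, summary, lr):
        look = sprt_t(summary, d1=0.5, alpha=0.05, beta=0.20)
        assert look.lr == pytest.approx(lr, abs=0.01)
        assert look.decision == "accept_H0"

    def test_full_sample_likelihood_ratio(self):
        look = sprt_t(FULL_H1, d1=0.5, alpha=0.05, beta=0.20)
        assert look.lr == pytest.approx(3.84, rel=0.02)
        assert look.decision == "continue"

    def test_data_at_design_alternative_favour_h1(self):
        n = 20
        ne = n * n / (2 * n)
        d1 = 0.5
        # construct a summary whose t equals the design noncentrality
        sd = 1.0
        mean_diff = d1  # with sd 1, d = d1 and t = delta
        s = GroupSummary(n=(n, n), mean=(mean_diff, 0.0), sd=(sd, sd))
        look = sprt_t(s, d1=d1)
        assert look.t == pytest.approx(d1 * math.sqrt(ne))
        assert look.lr > 1

    def test_lr_increasing_in_t(self):
        lrs = []
        for diff in (0.1, 0.3, 0.5, 0.8):
            s = GroupSummary(n=(15, 15), mean=(diff, 0.0), sd=(1.0, 1.0))
            lrs.append(sprt_t(s, d1=0.5).lr)
        assert all(b > a for a, b in zip(lrs, lrs[1:]))

    def test_trace_keeps_recording_after_decision(self):
        looks = [SUB_H1,
                 GroupSummary(n=(20, 20), mean=(1.9, 2.2), sd=(1.6, 1.9)),
                 GroupSummary(n=(47, 46), mean=(2.49, 1.72), sd=(2.41, 1.73))]
        trace = sprt_trace(looks, d1=0.5)
        assert trace.decision == "accept_H0"
        assert trace.decision_look == 0
        assert len(trace.looks) == 3  # later looks recorded, decision fixed

    def test_degenerate_variance_rejected(self):
        s = GroupSummary(n=(5, 5), mean=(1.0, 0.0), sd=(0.0, 0.0))
        with pytest.raises(ValueError, match="variance"):
            sprt_t(s, d1=0.5)

    def test_sequential_error_calibration(self):
        null = simulate_sprt_calibration(d_true=0.0, n_experiments=400, seed=1)
        assert null["accept_H1_rate"] <= 0.06
        alt = simulate_sprt_calibration(d_true=0.5, n_experiments=400, seed=2)
        assert alt["accept_H0_rate"] <= 0.22


def jzs_bf_g_mixture(t: float, n1: int, n2: int, r: float) -> float:
    """Independent oracle: the two-sample JZS Bayes factor via the
    inverse-gamma mixture representation over the prior variance g."""
    N = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2

    def integrand(g):
        return ((1 + N * g) ** -0.5
                * (1 + t * t / ((1 + N * g) * nu)) ** (-(nu + 1) / 2)
                * (2 * math.pi) ** -0.5 * r * g ** -1.5
                * math.exp(-r * r / (2 * g)))

    num, _ = integrate.quad(integrand, 0, np.inf, limit=400)
    den = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return num / den


class TestBayesFactor:
    def test_null_data_favour_h0(self):
        s = GroupSummary(n=(200, 200), mean=(0.0, 0.0), sd=(1.0, 1.0))
        assert jzs_bayes_factor(s).bf10_two_sided < 1

    def test_matches_g_mixture_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            n1, n2 = rng.integers(5, 80, 2)
            s = GroupSummary(n=(int(n1), int(n2)),
                             mean=(float(rng.normal(0, 2)), float(rng.normal(0, 2))),
                             sd=(float(rng.uniform(0.5, 3)), float(rng.uniform(0.5, 3))))
            res = jzs_bayes_factor(s)
            oracle = jzs_bf_g_mixture(res.t, *s.n, res.rscale)
            assert res.bf10_two_sided == pytest.approx(oracle, rel=1e-4)

    def test_published_value_soft_check(self):
        # the printed BF corresponds to the directional variant
        res = jzs_bayes_factor(FULL_H1)
        assert res.bf10_one_sided == pytest.approx(1.63, abs=0.05)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            jzs_bayes_factor(FULL_H1, rscale=0.0)


class TestSampleSize:
    def test_medium_effect_one_tailed_needs_102(self):
        assert t_test_sample_size(d=0.5, alpha=0.05, power=0.80,
                                  tails="one") == 102

    def test_minimality(self):
        n = t_test_sample_size(d=0.4, alpha=0.05, power=0.80, tails="one")

        def achieved(n_total):
            df = n_total - 2
            delta = 0.4 * math.sqrt((n_total // 2) / 2)
            crit = stats.t.ppf(0.95, df)
            return stats.nct.sf(crit, df, delta)

        assert achieved(n) >= 0.80
        assert achieved(n - 2) < 0.80

    def test_monotone_in_effect_size(self):
        n_small = t_test_sample_size(d=0.25, alpha=0.05, power=0.80)
        n_large = t_test_sample_size(d=0.5, alpha=0.05, power=0.80)
        assert n_large < n_small
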