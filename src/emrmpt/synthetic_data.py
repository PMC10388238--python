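"""Synthetic free-then-cued-recall studies with latent-trait heterogeneity.

Generates complete data sets with the structure the analysis pipeline
expects: two between-subjects conditions (alcohol vs. placebo), 40 word pairs
per participant, trial-level outcomes for the immediate cued recall, the
delayed free recall and the final cued recall, plus participant metadata
carrying the questionnaire-based exclusion flags.

Trials are sampled by walking the EMR tree with sequential Bernoulli draws
(encoded? initially retrieved? maintained? associatively retrieved? per-word
production?), deliberately *not* via the analytic branch enumeration, so the
generator and the model module are independent implementations of the same
tree and can cross-validate each other.

Person heterogeneity follows the latent-trait assumption of the hierarchical
model: each participant's free parameter groups deviate from the group-level
probit means by a multivariate-normal draw.  The default probit-scale SD of
0.4 per group with zero cross-correlations gives mid-range person variability
that keeps parameters identifiable at 30-50 participants per condition.
Word identity is abstracted: free recall outcomes are drawn directly at the
both/one/neither level (the two single-word orderings pooled).

Defaults mirror the study that motivates the package: group sizes 46/47,
group-level parameters at the reported posterior means, and flag rates at the
reported questionnaire frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .emr_model import EmrParameterSet, ModelSpec, PARAM_NAMES, redefined_baseline_spec

__all__ = [
    "SyntheticDesign",
    "generate_study",
    "generate_study_fixture",
    "default_design",
]

#: Group-level parameter sets at the published posterior means.
TABLE_PARAMS: dict[str, EmrParameterSet] = {
    "alcohol": EmrParameterSet.from_dict(
        dict(e=0.59, m=0.93, r_f=0.51, r_c=0.98, s=0.05, u_s=0.18, u_u=0.11)),
    "placebo": EmrParameterSet.from_dict(
        dict(e=0.60, m=0.90, r_f=0.43, r_c=0.98, s=0.11, u_s=0.20, u_u=0.11)),
}

#: Reported questionnaire flag frequencies (fraction of the full sample;
#: the placebo <1% guess rate is per placebo participant).
DEFAULT_FLAG_RATES: dict[str, float] = {
    "communicated_about_phase1": 25 / 93,
    "thought_about_pairs": 33 / 93,
    "rehearsed_pairs": 3 / 93,
    "placebo_guessed_below_1pct": 8 / 47,
    "drank_48h_before": 6 / 93,
}


@dataclass(frozen=True)
class SyntheticDesign:
    """Full specification of a synthetic study."""

    n_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"alcohol": 46, "placebo": 47})
    pairs_per_participant: int = 40
    params: Mapping[str, EmrParameterSet] = field(
        default_factory=lambda: dict(TABLE_PARAMS))
    heterogeneity_sd: float | Mapping[str, float] = 0.4
    heterogeneity_corr: np.ndarray | None = None
    flag_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLAG_RATES))
    grouping_spec: ModelSpec = field(default_factory=redefined_baseline_spec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pairs_per_participant < 1:
            raise ValueError("pairs_per_participant must be positive")
        for c, n in self.n_per_condition.items():
            if n < 1:
                raise ValueError(f"n for condition {c!r} must be positive")
            if c not in self.params:
                raise ValueError(f"no parameter set for condition {c!r}")
        for name, r in self.flag_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"flag rate {name}={r} outside [0, 1]")
        sd = self.heterogeneity_sd
        if np.any(np.asarray(list(sd.values()) if isinstance(sd, Mapping) else [sd]) < 0):
            raise ValueError("heterogeneity SDs must be non-negative")

    def to_dict(self) -> dict:
        return {
            "n_per_condition": dict(self.n_per_condition),
            "pairs_per_participant": self.pairs_per_participant,
            "params": {c: {n: getattr(p, n) for n in PARAM_NAMES}
                       for c, p in self.params.items()},
            "heterogeneity_sd": (dict(self.heterogeneity_sd)
                                 if isinstance(self.heterogeneity_sd, Mapping)
                                 else self.heterogeneity_sd),
            "flag_rates": dict(self.flag_rates),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticDesign":
        params = {c: EmrParameterSet.from_dict(v) for c, v in d["params"].items()}
        return cls(
            n_per_condition=dict(d["n_per_condition"]),
            pairs_per_participant=int(d.get("pairs_per_participant", 40)),
            params=params,
            heterogeneity_sd=d.get("heterogeneity_sd", 0.4),
            flag_rates=dict(d.get("flag_rates", DEFAULT_FLAG_RATES)),
            seed=int(d.get("seed", 0)),
        )


def default_design(**overrides) -> SyntheticDesign:
    """The canonical study-like design; keyword overrides replace fields."""
    return replace(SyntheticDesign(), **overrides) if overrides else SyntheticDesign()


def _person_parameters(design: SyntheticDesign, condition: str,
                       rng: np.random.Generator) -> np.ndarray:
    """One participant's 9-slot parameter vector with latent-trait noise."""
    spec = design.grouping_spec
    group_of = spec._group_of()
    groups: list[str] = []
    for p in PARAM_NAMES:
        g = group_of[p]
        if g not in groups:
            groups.append(g)
    sd = design.heterogeneity_sd
    sds = np.array([sd[g] if isinstance(sd, Mapping) else sd for g in groups])
    if design.heterogeneity_corr is not None:
        L = np.linalg.cholesky(np.asarray(design.heterogeneity_corr))
        z = sds * (L @ rng.normal(size=len(groups)))
    else:
        z = sds * rng.normal(size=len(groups))
    base = design.params[condition].as_array()
    theta = np.empty(len(PARAM_NAMES))
    for j, p in enumerate(PARAM_NAMES):
        g = groups.index(group_of[p])
        b = np.clip(base[j], 1e-9, 1 - 1e-9)
        theta[j] = ndtr(ndtri(b) + z[g]) if sds[g] > 0 else base[j]
    return theta


def _sample_trial(theta: np.ndarray, rng: np.random.Generator
                  ) -> tuple[str, str, str]:
    """Walk the EMR tree for one word pair with sequential coin flips."""
    e, m_s, m_u, r_f, r_c, s_s, s_u, u_s, u_u = theta
    if rng.uniform() >= e:  # never encoded
        k = rng.binomial(2, u_u)
        return "incorrect", ("neither", "one", "both")[k], "incorrect"
    initial_ok = rng.uniform() < r_c
    m = m_s if initial_ok else m_u
    initial = "correct" if initial_ok else "incorrect"
    if rng.uniform() < m:  # maintained across retention
        if rng.uniform() < r_f:
            free = "both"
        else:
            s = s_s if initial_ok else s_u
            free = ("neither", "one", "both")[rng.binomial(2, s)]
        final = "correct" if rng.uniform() < r_c else "incorrect"
        return initial, free, final
    u = u_s if initial_ok else u_u
    k = rng.binomial(2, u)
    return initial, ("neither", "one", "both")[k], "incorrect"


def generate_study(design: SyntheticDesign, seed: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate trial-level and participant-level tables for a full study.

    Returns ``(trials, participants)``: trials with columns participant,
    condition, pair, initial_cr, free_recall, final_cr; participants with
    derived performance counts and independently drawn exclusion flags.
    Fully reproducible from the design's master seed (or the ``seed``
    override) via per-participant substreams.
    """
    master = design.seed if seed is None else seed
    root = np.random.SeedSequence(master)
    n_total = sum(design.n_per_condition.values())
    substreams = root.spawn(n_total + 1)
    flag_rng = np.random.default_rng(substreams[-1])

    trial_rows = []
    part_rows = []
    pid = 0
    for condition in design.n_per_condition:
        for _ in range(design.n_per_condition[condition]):
            pid += 1
            rng = np.random.default_rng(substreams[pid - 1])
            theta = _person_parameters(design, condition, rng)
            n_imm = n_fin = n_both = n_one = 0
            for pair in range(1, design.pairs_per_participant + 1):
                initial, free, final = _sample_trial(theta, rng)
                trial_rows.append((f"p{pid:03d}", condition, pair,
                                   initial, free, final))
                n_imm += initial == "correct"
                n_fin += final == "correct"
                n_both += free == "both"
                n_one += free == "one"
            flags = {name: bool(flag_rng.uniform() < rate)
                     for name, rate in design.flag_rates.items()}
            if condition != "placebo":
                flags["placebo_guessed_below_1pct"] = False
            part_rows.append({
                "participant": f"p{pid:03d}",
                "condition": condition,
                "immediate_cr_correct": n_imm,
                "final_cr_correct": n_fin,
                "free_recall_complete_pairs": n_both,
                "free_recall_single_words": 2 * n_both + n_one,
                **flags,
            })

    trials = pd.DataFrame(trial_rows, columns=[
        "participant", "condition", "pair", "initial_cr", "free_recall",
        "final_cr"])
    participants = pd.DataFrame(part_rows)
    return trials, participants


def generate_study_fixture(seed: int = 0
                                ) -> tuple[SyntheticDesign, pd.DataFrame, pd.DataFrame]:
    """Canonical study-like bundle: published posterior-mean parameters,
    46/47 participants, moderate heterogeneity, reported flag rates."""
    design = replace(SyntheticDesign(), seed=seed)
    trials, participants = generate_study(design)
    return design, trials, participants
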