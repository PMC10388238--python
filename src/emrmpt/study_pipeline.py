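"""End-to-end orchestration of the memory-study analysis.

Stages, in the order the analysis runs:

1. categorize each participant x word-pair trial into one of the 12 outcome
   categories E1..E12 and aggregate within conditions;
2. apply exclusion rules (model-related: immediate cued-recall performance
   outside 30-80% correct; procedure-related: questionnaire flags);
3. design-based analyses: sequential probability ratio t tests on the cued
   recall difference (forgetting) and on free-recall complete pairs, plus
   effect sizes and default-prior Bayes factors;
4. model-based analyses: a maximum-likelihood model-selection ladder
   (baseline -> generalized on misfit -> re-restricted baseline), nested
   Delta G^2 tests of the retrieval (r_f) and maintenance (m) parameters,
   and optional hierarchical Bayesian fits per condition with posterior
   difference tests;
5. an exploratory 2 (aggregated vs. individual modelling) x 2 (model-related
   exclusion on/off) x 2 (procedure-related exclusions on/off) multiverse.

Exclusion boundaries read the "<30%" / ">80%" rules strictly: counts below 12
or above 32 of 40 are excluded; 12 and 32 are retained.  Participants who
merely thought about (but did not rehearse) the word pairs are flagged but
only excluded when the rehearsal criterion is selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .emr_model import (
    CategoryTable,
    ModelSpec,
    baseline_spec,
    generalized_spec,
)
from .ml_inference import FitOptions, fit_ml, test_restriction
from .sequential_inference import (
    GroupSummary,
    cohens_d,
    jzs_bayes_factor,
    sprt_t,
)

__all__ = [
    "StudyConfig",
    "tabulate_categories",
    "apply_exclusions",
    "run_study",
    "run_multiverse",
    "score_free_recall",
    "read_trials",
    "read_participants",
    "write_tables",
    "PROCEDURE_CRITERIA",
]

_E_COLS = [f"E{i}" for i in range(1, 13)]

#: Procedure-related exclusion criteria and the participant flag they read.
PROCEDURE_CRITERIA: dict[str, str] = {
    "placebo_guess": "placebo_guessed_below_1pct",
    "communication": "communicated_about_phase1",
    "rehearsal": "rehearsed_pairs",
    "drank_48h": "drank_48h_before",
}


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of :func:`run_study` / :func:`run_multiverse`."""

    sprt_d1: float = 0.5
    sprt_alpha: float = 0.05
    sprt_beta: float = 0.20
    sprt_group_size: int = 9
    pairs_per_participant: int = 40
    alpha: float = 0.05
    model_exclusion: bool = True
    procedure_criteria: tuple[str, ...] = ()
    run_hierarchical: bool = False
    mcmc_chains: int = 2
    mcmc_burn: int = 400
    mcmc_keep: int = 800
    fit_restarts: int = 6
    conditions: tuple[str, str] = ("alcohol", "placebo")
    predicted_larger: str = "alcohol"  # direction of the r_f / m predictions


def _category_index_vec(initial: np.ndarray, free: np.ndarray,
                        final: np.ndarray) -> np.ndarray:
    col = pd.Series(free).map({"both": 0, "one": 1, "neither": 2}).to_numpy()
    if np.any(pd.isna(col)):
        raise ValueError("free_recall must be 'both', 'one' or 'neither'")
    for arr, name in ((initial, "initial_cr"), (final, "final_cr")):
        bad = ~np.isin(arr, ("correct", "incorrect"))
        if bad.any():
            raise ValueError(f"{name} must be 'correct' or 'incorrect'")
    return (6 * (initial == "incorrect") + 3 * (final == "incorrect")
            + col + 1).astype(int)


def tabulate_categories(trials: pd.DataFrame,
                        pairs_per_participant: int = 40,
                        ) -> tuple[pd.DataFrame, dict[str, CategoryTable]]:
    """Per-participant and per-condition 12-category frequency tables.

    Validates that every participant contributes exactly
    ``pairs_per_participant`` uniquely numbered pairs; aggregation sums the
    per-participant tables within condition.
    """
    required = {"participant", "condition", "pair", "initial_cr",
                "free_recall", "final_cr"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials table missing columns: {sorted(missing)}")
    for pid, g in trials.groupby("participant", sort=False):
        if len(g) != pairs_per_participant:
            raise ValueError(
                f"participant {pid} has {len(g)} trials, expected {pairs_per_participant}")
        if g["pair"].nunique() != pairs_per_participant:
            raise ValueError(f"participant {pid} has duplicate pair ids")

    e_idx = _category_index_vec(trials["initial_cr"].to_numpy(),
                                trials["free_recall"].to_numpy(),
                                trials["final_cr"].to_numpy())
    tmp = trials[["participant", "condition"]].copy()
    tmp["E"] = e_idx
    person = (tmp.groupby(["participant", "condition", "E"]).size()
              .unstack("E", fill_value=0)
              .reindex(columns=range(1, 13), fill_value=0))
    person.columns = _E_COLS
    person = person.reset_index()

    condition_tables = {
        str(cond): CategoryTable(str(cond), g[_E_COLS].sum().to_numpy(float))
        for cond, g in person.groupby("condition", sort=False)
    }
    return person, condition_tables


def score_free_recall(produced_words: Sequence[str],
                      pairs: Sequence[tuple[str, str]]) -> list[str]:
    """Score raw free-recall output: a pair counts as 'both' when both of its
    members appear anywhere in the produced list (order and adjacency are
    irrelevant), 'one' when exactly one member appears, else 'neither'."""
    produced = set(produced_words)
    out = []
    for w1, w2 in pairs:
        hits = (w1 in produced) + (w2 in produced)
        out.append(("neither", "one", "both")[hits])
    return out


def apply_exclusions(participants: pd.DataFrame,
                     criteria: Iterable[str] = ("model_related",),
                     pairs_per_participant: int = 40,
                     ) -> tuple[pd.DataFrame, list[dict]]:
    """Apply exclusion criteria; returns the included subset and an audit log.

    ``model_related`` removes immediate cued-recall counts strictly below 30%
    or strictly above 80% of the pairs (11 or fewer / 33 or more of 40);
    the procedure criteria remove participants with the matching flag set.
    Idempotent: re-applying the same criteria leaves the set unchanged.
    """
    criteria = set(criteria)
    unknown = criteria - ({"model_related"} | set(PROCEDURE_CRITERIA))
    if unknown:
        raise ValueError(f"unknown exclusion criteria: {sorted(unknown)}")
    lo = 0.30 * pairs_per_participant
    hi = 0.80 * pairs_per_participant
    audit: list[dict] = []
    keep = np.ones(len(participants), dtype=bool)
    for i, row in participants.reset_index(drop=True).iterrows():
        reasons = []
        if "model_related" in criteria:
            n_ok = row["immediate_cr_correct"]
            if n_ok < lo:
                reasons.append(f"model_related: underperformance ({n_ok}/{pairs_per_participant})")
            elif n_ok > hi:
                reasons.append(f"model_related: overperformance ({n_ok}/{pairs_per_participant})")
        for crit in criteria & set(PROCEDURE_CRITERIA):
            flag = PROCEDURE_CRITERIA[crit]
            if flag in row and bool(row[flag]):
                reasons.append(crit)
        if reasons:
            keep[i] = False
            audit.append({"participant": row["participant"],
                          "condition": row["condition"],
                          "reasons": reasons})
    included = participants.reset_index(drop=True)[keep].reset_index(drop=True)
    for cond in participants["condition"].unique():
        if (included["condition"] == cond).sum() == 0:
            raise ValueError(
                f"condition {cond!r} empty after exclusions {sorted(criteria)}")
    return included, audit


# ---------------------------------------------------------------------------
# Design-based stage
# ---------------------------------------------------------------------------

def _dv_frame(participants: pd.DataFrame) -> pd.DataFrame:
    df = participants.copy()
    df["cued_recall_difference"] = (df["immediate_cr_correct"]
                                    - df["final_cr_correct"])
    return df


def _sequential_sprt(df: pd.DataFrame, dv: str, larger: str, config: StudyConfig
                     ) -> dict:
    """SPRT trace over cumulative looks of ``sprt_group_size`` per condition.

    Once a decision is reached the trace keeps recording the per-look LR (the
    study kept sampling for the model-based stopping rule) without revising
    the decision.
    """
    conds = config.conditions
    smaller = conds[0] if conds[1] == larger else conds[1]
    g_hi = df[df["condition"] == larger][dv].to_numpy(float)
    g_lo = df[df["condition"] == smaller][dv].to_numpy(float)
    looks = []
    decision = "continue"
    decision_n = None
    step = config.sprt_group_size
    n = step
    while True:
        a = g_hi[:n]
        b = g_lo[:n]
        if len(a) < 2 or len(b) < 2:
            break
        summary = GroupSummary(n=(len(a), len(b)),
                               mean=(float(a.mean()), float(b.mean())),
                               sd=(float(a.std(ddof=1)), float(b.std(ddof=1))))
        look = sprt_t(summary, d1=config.sprt_d1, alpha=config.sprt_alpha,
                      beta=config.sprt_beta)
        looks.append({"n_per_group": (len(a), len(b)), "t": look.t,
                      "lr": look.lr, "decision": look.decision})
        if decision == "continue" and look.decision != "continue":
            decision = look.decision
            decision_n = len(a) + len(b)
        if len(a) == len(g_hi) and len(b) == len(g_lo):
            break
        n += step
    full = looks[-1] if looks else None
    return {"dv": dv, "predicted_larger": larger, "looks": looks,
            "decision": decision, "decision_n": decision_n,
            "final_lr": full["lr"] if full else None}


def _design_based(df: pd.DataFrame, config: StudyConfig) -> dict:
    out = {}
    other = [c for c in config.conditions if c != config.predicted_larger][0]
    hypotheses = [
        # forgetting (immediate minus final cued recall) predicted larger in
        # the comparison condition; free-recall pairs larger in the predicted
        ("H1_cued_recall_difference", "cued_recall_difference", other),
        ("H2_free_recall_complete_pairs", "free_recall_complete_pairs",
         config.predicted_larger),
    ]
    for name, dv, larger in hypotheses:
        smaller = [c for c in config.conditions if c != larger][0]
        a = df[df["condition"] == larger][dv].to_numpy(float)
        b = df[df["condition"] == smaller][dv].to_numpy(float)
        summary = GroupSummary(n=(len(a), len(b)),
                               mean=(float(a.mean()), float(b.mean())),
                               sd=(float(a.std(ddof=1)), float(b.std(ddof=1))))
        bf = jzs_bayes_factor(summary)
        out[name] = {
            "predicted_larger": larger,
            "cohens_d": cohens_d(summary),
            "sprt": _sequential_sprt(df, dv, larger, config),
            "bf10_one_sided": bf.bf10_one_sided,
            "bf10_two_sided": bf.bf10_two_sided,
        }
    return out


# ---------------------------------------------------------------------------
# Model-based stage
# ---------------------------------------------------------------------------

def _restrict_families(general: ModelSpec, families: Iterable[str]) -> ModelSpec:
    eq = dict(general.within_equalities)
    for fam in families:
        eq[fam] = (f"{fam}_s", f"{fam}_u")
    return ModelSpec(conditions=general.conditions, within_equalities=eq,
                     shared_across_conditions=general.shared_across_conditions,
                     fixed=general.fixed, name="re-restricted")


def select_model(tables: Mapping[str, CategoryTable], config: StudyConfig,
                 options: FitOptions) -> tuple[ModelSpec, dict]:
    """Model-selection ladder: accept the baseline when its G^2 p > alpha;
    otherwise fit the generalized model and re-restrict each of the m/s/u
    families whose split is not supported by a Delta G^2 test at alpha."""
    log: dict = {}
    base = baseline_spec(config.conditions)
    fit_base = fit_ml(tables, base, options)
    log["baseline"] = {"G2": fit_base.g2, "df": fit_base.df, "p": fit_base.p_value}
    if fit_base.p_value > config.alpha:
        log["selected"] = "baseline"
        return base, log
    gen = generalized_spec(config.conditions)
    fit_gen = fit_ml(tables, gen, options)
    log["generalized"] = {"G2": fit_gen.g2, "df": fit_gen.df, "p": fit_gen.p_value}
    keep_split = []
    for fam in ("m", "s", "u"):
        restricted = _restrict_families(gen, [fam])
        rt = test_restriction(gen, restricted, tables, options)
        log[f"split_{fam}"] = {"delta_G2": rt.delta_g2, "df": rt.df,
                               "p": rt.p_two_tailed}
        if rt.p_two_tailed <= config.alpha:
            keep_split.append(fam)
    collapse = [f for f in ("m", "s", "u") if f not in keep_split]
    final = _restrict_families(gen, collapse)
    log["selected"] = f"re-restricted (split: {keep_split or 'none'})"
    return final, log


def _difference_tests(tables: Mapping[str, CategoryTable], spec: ModelSpec,
                      config: StudyConfig, options: FitOptions) -> dict:
    """One-tailed Delta G^2 tests of r_f and m across conditions."""
    hi = config.predicted_larger
    lo = [c for c in config.conditions if c != hi][0]
    out = {}
    group_of = spec._group_of()
    for fam, canon in (("r_f", "r_f"), ("m", "m_s")):
        g = group_of[canon]
        restricted = ModelSpec(
            conditions=spec.conditions,
            within_equalities=spec.within_equalities,
            shared_across_conditions=spec.shared_across_conditions | {g},
            fixed=spec.fixed, name=f"{spec.name}+{g}_equal")
        rt = test_restriction(spec, restricted, tables, options,
                              direction=(canon, hi, lo))
        out[fam] = {"delta_G2": rt.delta_g2, "df": rt.df, "z": rt.z,
                    "p_one_tailed": rt.p_one_tailed,
                    "p_two_tailed": rt.p_two_tailed,
                    "direction_consistent": rt.direction_consistent,
                    "significant": (rt.p_one_tailed is not None
                                    and rt.p_one_tailed < config.alpha)}
    return out


def _hierarchical_stage(person: pd.DataFrame, spec: ModelSpec,
                        config: StudyConfig, seed: int) -> dict:
    from .hierarchical_bayes import (McmcOptions, fit_hierarchical,
                                     group_difference, posterior_predictive_fit)
    opts = McmcOptions(n_chains=config.mcmc_chains, n_burn=config.mcmc_burn,
                       n_keep=config.mcmc_keep)
    fits = {}
    report: dict = {"conditions": {}}
    for i, cond in enumerate(config.conditions):
        counts = person[person["condition"] == cond][_E_COLS].to_numpy(float)
        fit = fit_hierarchical(counts, spec, condition=cond, options=opts,
                               seed=seed + i)
        p1, p2 = posterior_predictive_fit(fit, config.pairs_per_participant,
                                          seed=seed + 100 + i)
        fits[cond] = fit
        report["conditions"][cond] = {
            "means": fit.means, "bcis": {k: list(v) for k, v in fit.bcis.items()},
            "rhats": fit.rhats, "converged": fit.converged,
            "T1_p": p1, "T2_p": p2,
        }
    hi = config.predicted_larger
    lo = [c for c in config.conditions if c != hi][0]
    for fam in ("r_f", "m"):
        if fam in fits[hi].labels:
            gd = group_difference(fits[hi], fits[lo], fam, "greater")
            report[f"{fam}_difference"] = {
                "mean": gd.mean, "bci": list(gd.bci),
                "bayesian_p": gd.bayesian_p,
                "significant": gd.bayesian_p < config.alpha,
            }
    return report


def run_study(trials: pd.DataFrame, participants: pd.DataFrame,
              config: StudyConfig | None = None, seed: int = 0) -> dict:
    """Execute the full preregistered analysis plan and return a report.

    Deterministic given ``seed``: the same inputs and seed produce a
    byte-identical JSON serialisation of the report.
    """
    config = config or StudyConfig()
    options = FitOptions(n_restarts=config.fit_restarts, seed=seed)
    report: dict = {"seed": seed, "stages": []}

    df = _dv_frame(participants)
    report["stages"].append("design_based")
    report["design_based"] = _design_based(df, config)

    criteria = (("model_related",) if config.model_exclusion else ()) \
        + tuple(config.procedure_criteria)
    included, audit = apply_exclusions(participants, criteria,
                                       config.pairs_per_participant)
    report["stages"].append("exclusions")
    report["exclusions"] = {
        "criteria": list(criteria),
        "n_excluded": len(audit),
        "included_per_condition": included["condition"].value_counts().to_dict(),
        "audit": audit,
    }

    kept_trials = trials[trials["participant"].isin(included["participant"])]
    person, tables = tabulate_categories(kept_trials,
                                         config.pairs_per_participant)
    report["stages"].append("tabulation")
    report["category_counts"] = {c: t.values.tolist() for c, t in tables.items()}

    final_spec, ladder_log = select_model(tables, config, options)
    report["stages"].append("model_selection")
    report["model_selection"] = ladder_log

    fit_final = fit_ml(tables, final_spec, options)
    report["ml_fit"] = {"model": final_spec.name, "G2": fit_final.g2,
                        "df": fit_final.df, "p": fit_final.p_value,
                        "AIC": fit_final.aic, "BIC": fit_final.bic,
                        "estimates": fit_final.free_estimates}
    report["stages"].append("difference_tests")
    report["difference_tests"] = _difference_tests(tables, final_spec, config,
                                                   options)
    if config.run_hierarchical:
        report["stages"].append("hierarchical")
        report["hierarchical"] = _hierarchical_stage(person, final_spec,
                                                     config, seed)
    return report


def run_multiverse(trials: pd.DataFrame, participants: pd.DataFrame,
                   config: StudyConfig | None = None, seed: int = 0,
                   spec: ModelSpec | None = None) -> list[dict]:
    """The 2 x 2 x 2 multiverse: modelling approach x model-related exclusion
    x procedure-related exclusions.  Every cell reports model fit plus the
    r_f and m difference tests."""
    config = config or StudyConfig()
    options = FitOptions(n_restarts=config.fit_restarts, seed=seed)
    proc = tuple(config.procedure_criteria) or tuple(PROCEDURE_CRITERIA)
    cells = []
    for approach in ("aggregated", "individual"):
        for model_excl in (True, False):
            for proc_excl in (True, False):
                criteria = (("model_related",) if model_excl else ()) \
                    + (proc if proc_excl else ())
                included, audit = apply_exclusions(
                    participants, criteria, config.pairs_per_participant)
                kept = trials[trials["participant"].isin(included["participant"])]
                person, tables = tabulate_categories(
                    kept, config.pairs_per_participant)
                cell_spec = spec
                if cell_spec is None:
                    cell_spec, _ = select_model(tables, config, options)
                cell: dict = {
                    "approach": approach,
                    "model_exclusion": model_excl,
                    "procedure_exclusion": proc_excl,
                    "n_included": len(included),
                }
                if approach == "aggregated":
                    fit = fit_ml(tables, cell_spec, options)
                    cell["fit"] = {"G2": fit.g2, "df": fit.df, "p": fit.p_value}
                    cell["tests"] = _difference_tests(tables, cell_spec,
                                                      config, options)
                else:
                    cell["hierarchical"] = _hierarchical_stage(
                        person, cell_spec, config, seed)
                    cell["tests"] = {
                        fam: {"bayesian_p": cell["hierarchical"]
                              .get(f"{fam}_difference", {}).get("bayesian_p"),
                              "significant": cell["hierarchical"]
                              .get(f"{fam}_difference", {}).get("significant")}
                        for fam in ("r_f", "m")}
                cells.append(cell)
    return cells


def simulate_recruitment(design=None, config: StudyConfig | None = None,
                         seed: int = 0, min_included_per_condition: int = 30,
                         max_per_condition: int = 150) -> dict:
    """Simulate sequential recruitment under both stopping rules.

    Participants accrue in group looks; data collection stops only when (a)
    both SPRT t tests have reached a decision and (b) at least
    ``min_included_per_condition`` participants per condition survive the
    model-related exclusion.  Returns the terminal sample sizes, the SPRT
    decisions, and the included-per-condition counts.
    """
    import dataclasses
    from .synthetic_data import SyntheticDesign, generate_study
    config = config or StudyConfig()
    design = design or SyntheticDesign()
    pool_design = dataclasses.replace(
        design, n_per_condition={c: max_per_condition
                                 for c in design.n_per_condition})
    trials, participants = generate_study(pool_design, seed=seed)
    df = _dv_frame(participants)
    by_cond = {c: df[df["condition"] == c].reset_index(drop=True)
               for c in config.conditions}

    step = config.sprt_group_size
    n = step
    while True:
        current = pd.concat([g.iloc[:n] for g in by_cond.values()],
                            ignore_index=True)
        sprt_h1 = _sequential_sprt(current, "cued_recall_difference",
                                   [c for c in config.conditions
                                    if c != config.predicted_larger][0], config)
        sprt_h2 = _sequential_sprt(current, "free_recall_complete_pairs",
                                   config.predicted_larger, config)
        included, _ = apply_exclusions(current, ("model_related",),
                                       config.pairs_per_participant)
        inc = included["condition"].value_counts().to_dict()
        sprt_done = (sprt_h1["decision"] != "continue"
                     and sprt_h2["decision"] != "continue")
        mpt_done = all(inc.get(c, 0) >= min_included_per_condition
                       for c in config.conditions)
        if (sprt_done and mpt_done) or n >= max_per_condition:
            return {
                "n_per_condition": n,
                "n_total": int(len(current)),
                "sprt_decisions": {"H1": sprt_h1["decision"],
                                   "H2": sprt_h2["decision"]},
                "included_per_condition": inc,
                "stopped_by": ("both_rules" if sprt_done and mpt_done
                               else "max_sample"),
            }
        n = min(n + step, max_per_condition) if n < max_per_condition else n + 1


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------

def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for flag in PROCEDURE_CRITERIA.values():
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return df


def write_tables(trials: pd.DataFrame, participants: pd.DataFrame,
                 trials_path, participants_path) -> None:
    trials.to_csv(trials_path, sep="\t", index=False)
    participants.to_csv(participants_path, sep="\t", index=False)


def report_to_json(report, path=None) -> str:
    text = json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
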