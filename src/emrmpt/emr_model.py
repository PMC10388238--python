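"""Encoding-maintenance-retrieval (EMR) multinomial processing tree.

The EMR model describes memory for weakly associated word pairs in the
free-then-cued-recall paradigm: pairs are studied, immediately tested by cued
recall, and after a retention interval tested again by free recall followed by
a final cued recall.  Each pair therefore yields one of 2 x 3 x 2 = 12
observable outcome patterns (initial cued recall correct/incorrect, free
recall both/one/neither word, final cued recall correct/incorrect), labelled
E1..E12.

Latent processes, one Bernoulli step per tree node:

* ``e``    -- the association is encoded at study.
* ``r_c``  -- a stored association is retrieved at (either) cued recall.
* ``m_s``, ``m_u`` -- the association is maintained across the retention
  interval, conditional on successful vs. unsuccessful initial cued recall.
* ``r_f``  -- a maintained association is retrieved as a whole in free recall.
* ``s_s``, ``s_u`` -- per-word single-word production in free recall when the
  association is stored at test (by initial-recall outcome).
* ``u_s``, ``u_u`` -- per-word single-word production when the association is
  not stored at test (by initial-recall outcome); also governs free recall of
  never-encoded pairs (``u_u``).

A branch probability is the product of its step probabilities and a category
probability is the sum of its branch probabilities.  The full tree has 32
branches; the two "exactly one word" orderings are kept distinct so that the
branch count holds, and both land in the same observable column.

Cued recall of an unstored association fails deterministically: the word pairs
are only weakly associated, so successful guessing is negligible and no
guessing parameter is included.

Model variants (equality constraints) are expressed as
:class:`ModelSpec` label-sharing maps over the always-carried 9-parameter set,
so restricted models are views of the same tree, not separate code paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PARAM_NAMES",
    "N_CATEGORIES",
    "EmrParameterSet",
    "Branch",
    "CategoryTable",
    "ModelSpec",
    "enumerate_branches",
    "category_probabilities",
    "category_probability_matrix",
    "log_likelihood",
    "degrees_of_freedom",
    "baseline_spec",
    "generalized_spec",
    "redefined_baseline_spec",
    "full_spec",
]

#: Canonical parameter order used by every array interface in the package.
PARAM_NAMES: tuple[str, ...] = (
    "e", "m_s", "m_u", "r_f", "r_c", "s_s", "s_u", "u_s", "u_u",
)

N_CATEGORIES = 12
N_PARAMS = len(PARAM_NAMES)


class ConfigurationError(ValueError):
    """Raised for malformed model specifications."""


@dataclass(frozen=True)
class EmrParameterSet:
    """The nine latent EMR probabilities, each in [0, 1]."""

    e: float
    m_s: float
    m_u: float
    r_f: float
    r_c: float
    s_s: float
    s_u: float
    u_s: float
    u_u: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"parameter {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "EmrParameterSet":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} values, got {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "EmrParameterSet":
        """Build from a mapping; collapsed names ``m``/``s``/``u`` expand to
        their subscripted pair."""
        expanded: dict[str, float] = {}
        for key, v in values.items():
            if key in ("m", "s", "u"):
                expanded[f"{key}_s"] = v
                expanded[f"{key}_u"] = v
            else:
                expanded[key] = v
        return cls(**expanded)


@dataclass(frozen=True)
class Branch:
    """One root-to-leaf path: factors ``(name, complemented)`` whose product
    is the branch probability, terminating in category 1..12."""

    factors: tuple[tuple[str, bool], ...]
    category: int

    def __post_init__(self) -> None:
        if not (1 <= self.category <= N_CATEGORIES):
            raise ValueError(f"category index {self.category} outside 1..12")
        for name, _ in self.factors:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")

    def probability(self, params: EmrParameterSet) -> float:
        p = 1.0
        for name, complemented in self.factors:
            v = getattr(params, name)
            p *= (1.0 - v) if complemented else v
        return p


def _category_index(initial_correct: bool, final_correct: bool, free: str) -> int:
    # Table layout: initial-correct block E1..E6, initial-incorrect E7..E12;
    # within a block final-correct row first; columns both/one/neither.
    col = {"both": 0, "one": 1, "neither": 2}[free]
    return 6 * (not initial_correct) + 3 * (not final_correct) + col + 1


def _build_branches() -> tuple[Branch, ...]:
    branches: list[Branch] = []

    def word_outcomes(p_name: str) -> list[tuple[tuple[tuple[str, bool], ...], str]]:
        # Two independent per-word draws; the two one-word orderings stay
        # distinct branches but map to the same "one" column.
        return [
            (((p_name, False), (p_name, False)), "both"),
            (((p_name, False), (p_name, True)), "one"),
            (((p_name, True), (p_name, False)), "one"),
            (((p_name, True), (p_name, True)), "neither"),
        ]

    for initial_correct, m_name, s_name, u_name in (
        (True, "m_s", "s_s", "u_s"),
        (False, "m_u", "s_u", "u_u"),
    ):
        stem = (("e", False), ("r_c", not initial_correct))
        # maintained: associative free recall, then final cued recall r_c
        for final_correct in (True, False):
            branches.append(Branch(
                stem + ((m_name, False), ("r_f", False), ("r_c", not final_correct)),
                _category_index(initial_correct, final_correct, "both"),
            ))
        # maintained, no associative retrieval: per-word production s_x,
        # final cued recall still r_c
        for wfac, free in word_outcomes(s_name):
            for final_correct in (True, False):
                branches.append(Branch(
                    stem + ((m_name, False), ("r_f", True)) + wfac
                    + (("r_c", not final_correct),),
                    _category_index(initial_correct, final_correct, free),
                ))
        # not maintained: per-word production u_x, final cued recall fails
        for wfac, free in word_outcomes(u_name):
            branches.append(Branch(
                stem + ((m_name, True),) + wfac,
                _category_index(initial_correct, False, free),
            ))

    # never encoded: both cued recalls fail, per-word production u_u
    for wfac, free in _build_unencoded():
        branches.append(Branch((("e", True),) + wfac,
                               _category_index(False, False, free)))
    return tuple(branches)


def _build_unencoded():
    return [
        ((("u_u", False), ("u_u", False)), "both"),
        ((("u_u", False), ("u_u", True)), "one"),
        ((("u_u", True), ("u_u", False)), "one"),
        ((("u_u", True), ("u_u", True)), "neither"),
    ]


_BRANCHES: tuple[Branch, ...] = _build_branches()

# Exponent matrices: branch b has probability prod_j theta_j^A[b,j] (1-theta_j)^B[b,j].
_A = np.zeros((len(_BRANCHES), N_PARAMS), dtype=float)
_B = np.zeros((len(_BRANCHES), N_PARAMS), dtype=float)
_CAT = np.zeros(len(_BRANCHES), dtype=int)
for _b, _br in enumerate(_BRANCHES):
    _CAT[_b] = _br.category - 1
    for _name, _comp in _br.factors:
        _j = PARAM_NAMES.index(_name)
        if _comp:
            _B[_b, _j] += 1
        else:
            _A[_b, _j] += 1
# category indicator matrix C[cat, branch]
_C = np.zeros((N_CATEGORIES, len(_BRANCHES)), dtype=float)
_C[_CAT, np.arange(len(_BRANCHES))] = 1.0


def branch_matrices() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponent matrices (A, B) and category indicator C of the full tree.

    ``p_branch = prod_j theta_j**A[b,j] * (1-theta_j)**B[b,j]`` and
    ``p_cat = C @ p_branch``.  Used by the fitters for vectorised likelihoods
    and analytic gradients.
    """
    return _A.copy(), _B.copy(), _C.copy()


@dataclass
class CategoryTable:
    """Counts or probabilities over the 12 outcome categories E1..E12."""

    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_CATEGORIES,):
            raise ValueError("CategoryTable needs exactly 12 values")
        if np.any(self.values < 0):
            raise ValueError("category values must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalise an all-zero table")
        return self.values / self.total

    def to_frame(self) -> pd.DataFrame:
        cols = [f"E{i}" for i in range(1, 13)]
        df = pd.DataFrame([self.values], columns=cols)
        df.insert(0, "condition", self.condition)
        return df

    @staticmethod
    def write_tsv(tables: Iterable["CategoryTable"], path) -> None:
        pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
            path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path) -> list["CategoryTable"]:
        df = pd.read_csv(path, sep="\t")
        cols = [f"E{i}" for i in range(1, 13)]
        return [CategoryTable(str(row["condition"]), row[cols].to_numpy(float))
                for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# Model specifications (equality/fixing constraints)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Equality and fixing constraints defining an EMR model variant.

    ``within_equalities`` maps a group label to the canonical parameters it
    collapses within every condition (e.g. ``{"m": ("m_s", "m_u")}``).
    ``shared_across_conditions`` lists group labels whose value is common to
    all conditions.  ``fixed`` maps a free-parameter label (see
    :meth:`label_for`) to a constant.
    """

    conditions: tuple[str, ...] = ("alcohol", "placebo")
    within_equalities: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    shared_across_conditions: frozenset[str] = frozenset()
    fixed: Mapping[str, float] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ConfigurationError("conditions must be unique and non-empty")
        seen: set[str] = set()
        for group, members in self.within_equalities.items():
            for m in members:
                if m not in PARAM_NAMES:
                    raise ConfigurationError(f"unknown parameter {m!r} in group {group!r}")
                if m in seen:
                    raise ConfigurationError(f"parameter {m!r} assigned to two groups")
                seen.add(m)
        groups = self._group_of()
        for label in self.shared_across_conditions:
            if label not in groups.values():
                raise ConfigurationError(f"shared label {label!r} matches no group")
        for label, v in self.fixed.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"fixed value {label}={v} outside [0, 1]")
            if label not in self.free_labels(include_fixed=True):
                raise ConfigurationError(f"fixed label {label!r} not produced by spec")

    def _group_of(self) -> dict[str, str]:
        group = {p: p for p in PARAM_NAMES}
        for g, members in self.within_equalities.items():
            for m in members:
                group[m] = g
        return group

    def label_for(self, condition: str, param: str) -> str:
        """Free-parameter label of canonical ``param`` in ``condition``."""
        g = self._group_of()[param]
        if g in self.shared_across_conditions:
            return g
        return f"{g}[{condition}]"

    def free_labels(self, include_fixed: bool = False) -> tuple[str, ...]:
        labels: list[str] = []
        for c in self.conditions:
            for p in PARAM_NAMES:
                lab = self.label_for(c, p)
                if lab not in labels:
                    labels.append(lab)
        if not include_fixed:
            labels = [l for l in labels if l not in self.fixed]
        return tuple(labels)

    @property
    def n_free(self) -> int:
        return len(self.free_labels())

    def label_index_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-condition mapping from free labels to the 9 canonical slots.

        Returns ``(idx, fixed_mask, fixed_values)`` each of shape
        ``(n_conditions, 9)``; where ``fixed_mask`` is set, the slot takes
        ``fixed_values`` and ``idx`` is -1, otherwise slot j of condition c is
        free parameter ``idx[c, j]`` in :meth:`free_labels` order.
        """
        labels = self.free_labels()
        pos = {l: i for i, l in enumerate(labels)}
        nc = len(self.conditions)
        idx = np.full((nc, N_PARAMS), -1, dtype=int)
        fmask = np.zeros((nc, N_PARAMS), dtype=bool)
        fval = np.zeros((nc, N_PARAMS), dtype=float)
        for ci, c in enumerate(self.conditions):
            for j, p in enumerate(PARAM_NAMES):
                lab = self.label_for(c, p)
                if lab in self.fixed:
                    fmask[ci, j] = True
                    fval[ci, j] = self.fixed[lab]
                else:
                    idx[ci, j] = pos[lab]
        return idx, fmask, fval

    def expand(self, free_values: Sequence[float]) -> dict[str, EmrParameterSet]:
        """Map a free-parameter vector (in :meth:`free_labels` order) to a
        full 9-parameter set per condition."""
        free_values = np.asarray(free_values, dtype=float)
        idx, fmask, fval = self.label_index_matrix()
        out: dict[str, EmrParameterSet] = {}
        for ci, c in enumerate(self.conditions):
            theta = np.where(fmask[ci], fval[ci], free_values[np.where(idx[ci] >= 0, idx[ci], 0)])
            out[c] = EmrParameterSet.from_array(theta)
        return out

    def is_nested_in(self, general: "ModelSpec") -> bool:
        """True when every constraint of ``general`` is implied by this spec
        (checked via label partitions and fixed values)."""
        if self.conditions != general.conditions:
            return False
        mine = {(c, p): self.label_for(c, p) for c in self.conditions for p in PARAM_NAMES}
        theirs = {(c, p): general.label_for(c, p) for c in self.conditions for p in PARAM_NAMES}
        # general's equalities must be respected by the restricted spec
        for a in mine:
            for b in mine:
                if theirs[a] == theirs[b] and mine[a] != mine[b]:
                    return False
        for (c, p), lab in theirs.items():
            if lab in general.fixed:
                lab_r = mine[(c, p)]
                if self.fixed.get(lab_r) != general.fixed[lab]:
                    return False
        return True

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "conditions": list(self.conditions),
            "within_equalities": {g: list(m) for g, m in self.within_equalities.items()},
            "shared_across_conditions": sorted(self.shared_across_conditions),
            "fixed": dict(self.fixed),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            conditions=tuple(d.get("conditions", ("alcohol", "placebo"))),
            within_equalities={g: tuple(m) for g, m in d.get("within_equalities", {}).items()},
            shared_across_conditions=frozenset(d.get("shared_across_conditions", ())),
            fixed=dict(d.get("fixed", {})),
            name=str(d.get("name", "custom")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def baseline_spec(conditions: tuple[str, str] = ("alcohol", "placebo")) -> ModelSpec:
    """Baseline model: per-condition e, m, r_f, s, u with r_c shared."""
    return ModelSpec(
        conditions=conditions,
        within_equalities={"m": ("m_s", "m_u"), "s": ("s_s", "s_u"), "u": ("u_s", "u_u")},
        shared_across_conditions=frozenset({"r_c"}),
        name="baseline",
    )


def generalized_spec(conditions: tuple[str, str] = ("alcohol", "placebo")) -> ModelSpec:
    """Generalized model: m, s, u split by initial-recall outcome; r_c shared."""
    return ModelSpec(
        conditions=conditions,
        within_equalities={},
        shared_across_conditions=frozenset({"r_c"}),
        name="generalized",
    )


def redefined_baseline_spec(conditions: tuple[str, str] = ("alcohol", "placebo")) -> ModelSpec:
    """Redefined baseline: m and s collapsed, u split (u_s, u_u); r_c shared."""
    return ModelSpec(
        conditions=conditions,
        within_equalities={"m": ("m_s", "m_u"), "s": ("s_s", "s_u")},
        shared_across_conditions=frozenset({"r_c"}),
        name="redefined_baseline",
    )


def full_spec(conditions: tuple[str, str] = ("alcohol", "placebo")) -> ModelSpec:
    """All nine parameters free in every condition, nothing shared."""
    return ModelSpec(conditions=conditions, name="full")


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def enumerate_branches(spec: ModelSpec | None = None) -> tuple[Branch, ...]:
    """All 32 branches of the EMR tree.

    Constraints in ``spec`` relabel parameters but never change the tree, so
    the branch list is identical for every well-formed spec; ``spec`` is
    validated if given.
    """
    if spec is not None and not isinstance(spec, ModelSpec):
        raise ConfigurationError("spec must be a ModelSpec")
    return _BRANCHES


def category_probabilities(params: EmrParameterSet,
                           condition: str = "") -> CategoryTable:
    """Analytic probabilities of E1..E12 under ``params``.

    Each category probability is the sum of the probabilities of its branches;
    the twelve values sum to one for any valid parameter set.
    """
    theta = params.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        pb = np.prod(np.power(theta, _A) * np.power(1.0 - theta, _B), axis=1)
    return CategoryTable(condition, _C @ pb)


def category_probability_matrix(theta: np.ndarray) -> np.ndarray:
    """Vectorised category probabilities.

    ``theta`` has shape (..., 9) with entries strictly inside (0, 1); returns
    shape (..., 12).  Log-space evaluation keeps the matmul fast for the MCMC
    and optimiser hot paths.
    """
    theta = np.asarray(theta, dtype=float)
    logp = np.log(theta) @ _A.T + np.log1p(-theta) @ _B.T
    return np.exp(logp) @ _C.T


def log_likelihood(counts: Mapping[str, CategoryTable] | Sequence[CategoryTable],
                   params: Mapping[str, EmrParameterSet] | Sequence[EmrParameterSet],
                   ) -> float:
    """Multinomial log-likelihood kernel sum_i n_i log p_i over conditions.

    Multinomial coefficients are omitted consistently.  A positive count on a
    zero-probability category yields ``-inf`` (degenerate fit).
    """
    if isinstance(counts, Mapping):
        keys = list(counts)
        counts_list = [counts[k] for k in keys]
        params_list = [params[k] for k in keys]
    else:
        counts_list = list(counts)
        params_list = list(params)
    total = 0.0
    for tab, par in zip(counts_list, params_list, strict=True):
        n = tab.values
        p = category_probabilities(par).values
        mask = n > 0
        if np.any(p[mask] <= 0):
            return -math.inf
        total += float(np.sum(n[mask] * np.log(p[mask])))
    return total


def degrees_of_freedom(spec: ModelSpec) -> int:
    """Goodness-of-fit df: 11 free category frequencies per condition minus
    the number of free parameters (22 - k for the usual two-condition specs)."""
    return 11 * len(spec.conditions) - spec.n_free
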