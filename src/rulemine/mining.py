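"""Exhaustive supervised 1D/2D rule mining.

A *rule* is a conjunction of one or two variable conditions — a contiguous
bin range for an ordinal variable, a category set for a nominal one —
describing a subject subgroup enriched for one target modality.  Mining
proceeds in two steps:

1. **Exhaustive generation and selection.**  Every candidate condition
   (all ``k(k+1)/2`` contiguous ranges of an ordinal variable, all non-empty
   category subsets of a nominal one; for 2D, every cross product over a
   variable pair) is scored for each target modality by two quality
   measures: the *rule modality size* (covered subjects carrying the
   modality) and a one-proportion *z-score* comparing the modality
   proportion inside the rule to the whole-population proportion.
   Candidates with modality size >= 10 and z >= 1.96 are kept.

2. **Minimization.**  Redundant nested rules on the same variable set are
   removed: a rule included in a larger rule with z at least as high is
   dominated, as is a rule covering a strictly smaller rule with a strictly
   higher z.  Survivors are exactly the rules maximal under this dominance
   order, and never nest.

All enumeration orders and outputs are deterministic; the module uses no
randomness.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from math import sqrt

import numpy as np

from .dataset import DiscretizedDataset, VariableMeta

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "enumerate_conditions_1d",
    "enumerate_candidates",
    "support",
    "z_score",
    "z_from_counts",
    "select_significant",
    "minimize",
    "mine_rules",
    "DEFAULT_MIN_MODALITY_SIZE",
    "DEFAULT_MIN_Z",
]

DEFAULT_MIN_MODALITY_SIZE = 10
DEFAULT_MIN_Z = 1.96
DEFAULT_MAX_NOMINAL_LEVELS = 6
#: warn when an unrestricted 2D enumeration would exceed this many candidates
CANDIDATE_BUDGET = 2_000_000


@dataclass(frozen=True)
class Condition:
    """One variable condition: a contiguous level-code range ``[lo, hi]``
    for an ordinal variable, or a non-empty category set for a nominal one.
    """

    variable: str
    lo: int | None = None
    hi: int | None = None
    categories: frozenset = None

    def __post_init__(self):
        if self.categories is not None:
            if self.lo is not None or self.hi is not None:
                raise ValueError("a condition is either a range or a category set")
            if not self.categories:
                raise ValueError("nominal condition needs a non-empty category set")
            object.__setattr__(self, "categories", frozenset(self.categories))
        else:
            if self.lo is None or self.hi is None or not (1 <= self.lo <= self.hi):
                raise ValueError(f"invalid range [{self.lo}, {self.hi}]")

    @property
    def is_ordinal(self) -> bool:
        return self.categories is None

    def contains(self, other: "Condition") -> bool:
        """Condition-space containment: does self cover everything other does?"""
        if self.variable != other.variable or self.is_ordinal != other.is_ordinal:
            return False
        if self.is_ordinal:
            return self.lo <= other.lo and other.hi <= self.hi
        return other.categories <= self.categories

    def mask(self, dataset: DiscretizedDataset) -> np.ndarray:
        meta = dataset.variable(self.variable)
        col = dataset.data[self.variable]
        if self.is_ordinal:
            if not meta.is_ordinal:
                raise ValueError(f"range condition on nominal variable {self.variable!r}")
            codes = col.to_numpy()
            return (codes >= self.lo) & (codes <= self.hi)
        # unseen categories simply match no subject
        return col.isin(self.categories).to_numpy()

    def render(self, meta: VariableMeta | None = None) -> str:
        if self.is_ordinal:
            if self.lo == self.hi:
                return f"bin {self.lo}"
            return f"bins {self.lo} to {self.hi}"
        return "{" + ", ".join(sorted(map(str, self.categories))) + "}"


@dataclass(frozen=True)
class Rule:
    """A 1D or 2D rule with its quality statistics."""

    conditions: tuple
    modality: str
    coverage: int = 0
    modality_size: int = 0
    z: float = 0.0

    def __post_init__(self):
        conds = tuple(self.conditions)
        object.__setattr__(self, "conditions", conds)
        if len(conds) not in (1, 2):
            raise ValueError("a rule has 1 or 2 conditions")
        names = [c.variable for c in conds]
        if len(set(names)) != len(names):
            raise ValueError("rule conditions must be on distinct variables")
        if not (0 <= self.modality_size <= self.coverage):
            raise ValueError("need 0 <= modality_size <= coverage")

    @property
    def dimension(self) -> int:
        return len(self.conditions)

    @property
    def variables(self) -> frozenset:
        return frozenset(c.variable for c in self.conditions)

    def identity(self) -> tuple:
        """Hashable identity used for stability comparisons: the exact
        variable conditions plus the modality."""
        parts = tuple(
            sorted(
                (c.variable, c.lo, c.hi, tuple(sorted(map(str, c.categories))) if c.categories else None)
                for c in self.conditions
            )
        )
        return (parts, self.modality)

    def contains(self, other: "Rule") -> bool:
        """Condition-wise containment, defined only on identical variable sets."""
        if self.variables != other.variables or self.modality != other.modality:
            return False
        by_var = {c.variable: c for c in self.conditions}
        return all(by_var[c.variable].contains(c) for c in other.conditions)

    def mask(self, dataset: DiscretizedDataset) -> np.ndarray:
        m = self.conditions[0].mask(dataset)
        for c in self.conditions[1:]:
            m = m & c.mask(dataset)
        return m

    def render(self) -> str:
        parts = []
        for i, c in enumerate(self.conditions):
            tag = "variable" if self.dimension == 1 else f"variable {i + 1}"
            parts.append(f"{tag}: '{c.variable}'; condition: {c.render()}")
        return "{" + " AND ".join(parts) + "}"


@dataclass
class RuleSet:
    """Minimized significant rules for both modalities, with provenance."""

    rules: list
    provenance: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)

    def for_modality(self, modality: str) -> list:
        return [r for r in self.rules if r.modality == modality]

    # -- serialization (JSON lines, one rule per line) ----------------------
    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.rules:
                fh.write(json.dumps(_rule_to_dict(r)) + "\n")

    @classmethod
    def from_jsonl(cls, path, provenance: dict | None = None) -> "RuleSet":
        rules = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    rules.append(_rule_from_dict(json.loads(line)))
        return cls(rules=rules, provenance=provenance or {})


def _rule_to_dict(r: Rule) -> dict:
    conds = []
    for c in r.conditions:
        if c.is_ordinal:
            conds.append({"variable": c.variable, "lo": c.lo, "hi": c.hi})
        else:
            conds.append({"variable": c.variable, "categories": sorted(map(str, c.categories))})
    return {
        "conditions": conds,
        "modality": r.modality,
        "coverage": r.coverage,
        "modality_size": r.modality_size,
        "z": r.z,
    }


def _rule_from_dict(d: dict) -> Rule:
    conds = []
    for c in d["conditions"]:
        if "categories" in c:
            conds.append(Condition(c["variable"], categories=frozenset(c["categories"])))
        else:
            conds.append(Condition(c["variable"], lo=c["lo"], hi=c["hi"]))
    return Rule(
        conditions=tuple(conds),
        modality=d["modality"],
        coverage=d["coverage"],
        modality_size=d["modality_size"],
        z=d["z"],
    )


# ---------------------------------------------------------------------------
# Candidate enumeration


def enumerate_conditions_1d(
    var: VariableMeta, max_nominal_levels: int = DEFAULT_MAX_NOMINAL_LEVELS
) -> list:
    """All 1D conditions of a variable.

    Ordinal: every contiguous range ``[a, b]`` with ``1 <= a <= b <= k`` —
    ``k(k+1)/2`` of them, lexicographic by ``(a, b)``.  Nominal: every
    non-empty category subset (guarded against blow-up).
    """
    if var.is_ordinal:
        k = var.n_levels
        return [Condition(var.name, lo=a, hi=b) for a in range(1, k + 1) for b in range(a, k + 1)]
    if var.n_levels > max_nominal_levels:
        raise ValueError(
            f"nominal variable {var.name!r} has {var.n_levels} categories; subset "
            f"enumeration is guarded at {max_nominal_levels} — pre-group the categories"
        )
    cats = list(var.level_labels)
    out = []
    for size in range(1, len(cats) + 1):
        for combo in itertools.combinations(cats, size):
            out.append(Condition(var.name, categories=frozenset(combo)))
    return out


def enumerate_candidates(
    variables,
    dims: int = 1,
    max_nominal_levels: int = DEFAULT_MAX_NOMINAL_LEVELS,
):
    """Stream candidate condition tuples.

    ``dims=1`` yields a 1-tuple per condition of each variable; ``dims=2``
    yields the cross product of 1D conditions over each unordered variable
    pair, in declared variable order.
    """
    variables = list(variables)
    if dims == 1:
        for var in variables:
            for c in enumerate_conditions_1d(var, max_nominal_levels):
                yield (c,)
    elif dims == 2:
        if len(variables) < 2:
            raise ValueError("dims=2 requires at least 2 variables")
        conds = [enumerate_conditions_1d(v, max_nominal_levels) for v in variables]
        total = sum(
            len(conds[i]) * len(conds[j])
            for i in range(len(variables))
            for j in range(i + 1, len(variables))
        )
        if total > CANDIDATE_BUDGET:
            warnings.warn(
                f"2D enumeration over {len(variables)} variables yields {total} "
                "candidates; consider pre-selecting variables",
                stacklevel=2,
            )
        for i in range(len(variables)):
            for j in range(i + 1, len(variables)):
                for ci in conds[i]:
                    for cj in conds[j]:
                        yield (ci, cj)
    else:
        raise ValueError("dims must be 1 or 2")


def support(conditions, dataset: DiscretizedDataset) -> np.ndarray:
    """Boolean indicator over subjects satisfying every condition (the
    rule's binary *local variable* encoding)."""
    mask = np.ones(dataset.n_subjects, dtype=bool)
    for c in conditions:
        mask &= c.mask(dataset)
    return mask


# ---------------------------------------------------------------------------
# Quality measures


def z_from_counts(n_r: int, k_r: int, n: int, k_mod: int) -> float:
    """One-proportion z statistic for a rule support.

    ``z = (p_r - p_0) / sqrt(p_0 (1 - p_0) / n_r)`` where ``p_r = k_r/n_r``
    is the modality proportion inside the rule and ``p_0 = k_mod/n`` the
    whole-population proportion.  Positive when the rule is enriched.
    """
    if n_r <= 0:
        raise ValueError("rule support must be non-empty")
    p0 = k_mod / n
    if p0 <= 0.0 or p0 >= 1.0:
        raise ValueError("degenerate target: population proportion is 0 or 1")
    p_r = k_r / n_r
    return (p_r - p0) / sqrt(p0 * (1.0 - p0) / n_r)


def z_score(rule_support: np.ndarray, modality: str, dataset: DiscretizedDataset) -> float:
    """z statistic of a support mask for one target modality."""
    rule_support = np.asarray(rule_support, dtype=bool)
    y = dataset.modality_indicator(modality)
    return z_from_counts(
        int(rule_support.sum()),
        int((rule_support & y).sum()),
        dataset.n_subjects,
        int(y.sum()),
    )


# ---------------------------------------------------------------------------
# Selection


def select_significant(
    candidates,
    dataset: DiscretizedDataset,
    min_modality_size: int = DEFAULT_MIN_MODALITY_SIZE,
    min_z: float = DEFAULT_MIN_Z,
) -> list:
    """Score every candidate for each modality; keep those passing both
    thresholds (inclusive).  Reference path — one mask per candidate."""
    if min_modality_size <= 0 or min_z <= 0:
        raise ValueError("thresholds must be positive")
    n = dataset.n_subjects
    indicators = {m: dataset.modality_indicator(m) for m in dataset.modalities}
    totals = {m: int(v.sum()) for m, v in indicators.items()}
    kept = []
    for conds in candidates:
        mask = support(conds, dataset)
        n_r = int(mask.sum())
        if n_r == 0:
            continue
        for modality in dataset.modalities:
            k_r = int((mask & indicators[modality]).sum())
            if k_r < min_modality_size:
                continue
            z = z_from_counts(n_r, k_r, n, totals[modality])
            if z >= min_z:
                kept.append(
                    Rule(
                        conditions=tuple(conds),
                        modality=modality,
                        coverage=n_r,
                        modality_size=k_r,
                        z=z,
                    )
                )
    return kept


# ---------------------------------------------------------------------------
# Minimization


def minimize(rules) -> list:
    """Remove dominated nested rules (same variable set, same modality).

    A rule ``R`` is deleted when a strictly larger rule ``L`` (condition-wise
    containment) exists with ``z(L) >= z(R)``, or when a strictly smaller
    contained rule ``S`` exists with ``z(S) > z(R)``.  The survivors are the
    rules maximal under this dominance order; no two survivors on the same
    variables nest, which makes the operation idempotent.
    """
    rules = list(rules)
    groups: dict = {}
    for idx, r in enumerate(rules):
        groups.setdefault((r.modality, r.variables), []).append(idx)
    keep = np.ones(len(rules), dtype=bool)
    for idxs in groups.values():
        for i in idxs:
            ri = rules[i]
            for j in idxs:
                if i == j:
                    continue
                rj = rules[j]
                if rj.contains(ri) and not ri.contains(rj) and rj.z >= ri.z:
                    keep[i] = False  # included in a larger rule at least as good
                    break
                if ri.contains(rj) and not rj.contains(ri) and rj.z > ri.z:
                    keep[i] = False  # covers a smaller, strictly better rule
                    break
    return [r for r, k in zip(rules, keep) if k]


# ---------------------------------------------------------------------------
# Fast mining pipeline


def _condition_masks(dataset: DiscretizedDataset, var: VariableMeta, max_nominal_levels: int):
    """All 1D conditions of a variable with their support masks stacked as a
    (n_conditions, n_subjects) boolean matrix."""
    conds = enumerate_conditions_1d(var, max_nominal_levels)
    if var.is_ordinal:
        codes = dataset.data[var.name].to_numpy()
        masks = np.stack([(codes >= c.lo) & (codes <= c.hi) for c in conds])
    else:
        col = dataset.data[var.name]
        masks = np.stack([col.isin(c.categories).to_numpy() for c in conds])
    return conds, masks


def _vectorized_z(cov, mod, n, total, min_modality_size, min_z):
    """Selection mask and z values for arrays of (coverage, modality count)."""
    p0 = total / n
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mod / np.maximum(cov, 1) - p0) / np.sqrt(p0 * (1 - p0) / np.maximum(cov, 1))
    keep = (mod >= min_modality_size) & (cov > 0) & (z >= min_z)
    return keep, z


def _dominance_survivors(bounds: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Vectorized dominance filter for ordinal boxes within one group.

    ``bounds`` is (g, 2d): per rule the (lo, hi) of each of its d range
    conditions in a fixed variable order.  Returns the boolean survivor
    mask: a rule falls when a strictly larger box has z at least as high,
    or a strictly smaller box has strictly higher z.
    """
    g, width = bounds.shape
    d = width // 2
    lo = bounds[:, :d]
    hi = bounds[:, d:]
    # contains[i, j]: box i contains box j (componentwise, not necessarily strict)
    contains = np.ones((g, g), dtype=bool)
    for k in range(d):
        contains &= lo[:, k][:, None] <= lo[:, k][None, :]
        contains &= hi[:, k][:, None] >= hi[:, k][None, :]
    equal = contains & contains.T
    strict = contains & ~equal
    z_ge = z[:, None] >= z[None, :]
    z_gt = z[:, None] > z[None, :]
    removed = (strict & z_ge).any(axis=0)  # larger box at least as good
    removed |= (strict.T & z_gt).any(axis=0)  # smaller box strictly better
    return ~removed


def mine_rules(
    dataset: DiscretizedDataset,
    variables=None,
    dims=(1, 2),
    min_modality_size: int = DEFAULT_MIN_MODALITY_SIZE,
    min_z: float = DEFAULT_MIN_Z,
    max_nominal_levels: int = DEFAULT_MAX_NOMINAL_LEVELS,
) -> RuleSet:
    """Mine, score, select and minimize rules for both target modalities.

    ``variables`` restricts mining to a subset (for the local models, the
    chi2-preselected variables); ``dims`` is an iterable subset of {1, 2}.
    Deterministic given its inputs.  Scoring and minimization are
    vectorized for all-ordinal candidate groups (condition masks stacked,
    2D boxes scored with mask matrix products, dominance filtered by
    broadcasting), so Rule objects are only materialized for survivors;
    groups involving nominal variables fall back to the generic object
    path.  A test asserts agreement with the per-candidate reference
    (`select_significant` + `minimize`).
    """
    dims = sorted(set(int(d) for d in (dims if np.iterable(dims) else [dims])))
    if not set(dims) <= {1, 2}:
        raise ValueError("dims must be a subset of {1, 2}")
    if dims == [2] and (variables is not None and len(list(variables)) < 2):
        raise ValueError("dims=2 requires at least 2 variables")
    names = list(variables) if variables is not None else dataset.variable_names
    metas = [dataset.variable(n) for n in names]
    n = dataset.n_subjects
    indicators = {m: dataset.modality_indicator(m).astype(np.float64) for m in dataset.modalities}
    totals = {m: int(v.sum()) for m, v in indicators.items()}
    for m, t in totals.items():
        if t in (0, n):
            raise ValueError("degenerate target: one modality is empty")

    per_var = [_condition_masks(dataset, v, max_nominal_levels) for v in metas]
    minimized: list = []
    n_selected = 0

    def _make_rule(conds, modality, cov, k_r):
        return Rule(
            conditions=tuple(conds),
            modality=modality,
            coverage=int(cov),
            modality_size=int(k_r),
            z=z_from_counts(int(cov), int(k_r), n, totals[modality]),
        )

    def _finish_group(conds_list, bounds, modality, cov, mod, keep):
        """Vectorized dominance on an all-ordinal group; emit survivors."""
        nonlocal n_selected
        idx = np.nonzero(keep)[0]
        n_selected += len(idx)
        if len(idx) == 0:
            return
        _, z = _vectorized_z(cov, mod, n, totals[modality], 0, -np.inf)
        surv = _dominance_survivors(bounds[idx], z[idx])
        for i in idx[surv]:
            minimized.append(_make_rule(conds_list[i], modality, cov[i], mod[i]))

    if 1 in dims:
        for (conds, masks), meta in zip(per_var, metas):
            fmask = masks.astype(np.float64)
            cov = fmask.sum(axis=1)
            for modality in dataset.modalities:
                mod = fmask @ indicators[modality]
                keep, _ = _vectorized_z(cov, mod, n, totals[modality], min_modality_size, min_z)
                if meta.is_ordinal:
                    bounds = np.array([[c.lo, c.hi] for c in conds])
                    _finish_group([(c,) for c in conds], bounds, modality, cov, mod, keep)
                else:
                    group = [
                        _make_rule((conds[i],), modality, cov[i], mod[i])
                        for i in np.nonzero(keep)[0]
                    ]
                    n_selected += len(group)
                    minimized.extend(minimize(group))

    if 2 in dims:
        for a in range(len(metas)):
            conds_a, masks_a = per_var[a]
            fa = masks_a.astype(np.float64)
            for b in range(a + 1, len(metas)):
                conds_b, masks_b = per_var[b]
                fb = masks_b.astype(np.float64)
                cov = (fa @ fb.T).ravel()
                ordinal_pair = metas[a].is_ordinal and metas[b].is_ordinal
                if ordinal_pair:
                    bounds = np.empty((len(conds_a) * len(conds_b), 4), dtype=np.int64)
                    la = np.array([c.lo for c in conds_a])
                    ha = np.array([c.hi for c in conds_a])
                    lb = np.array([c.lo for c in conds_b])
                    hb = np.array([c.hi for c in conds_b])
                    bounds[:, 0] = np.repeat(la, len(conds_b))
                    bounds[:, 1] = np.tile(lb, len(conds_a))
                    bounds[:, 2] = np.repeat(ha, len(conds_b))
                    bounds[:, 3] = np.tile(hb, len(conds_a))
                pairs = [(ca, cb) for ca in conds_a for cb in conds_b]
                for modality in dataset.modalities:
                    mod = ((fa * indicators[modality]) @ fb.T).ravel()
                    keep, _ = _vectorized_z(
                        cov, mod, n, totals[modality], min_modality_size, min_z
                    )
                    if ordinal_pair:
                        _finish_group(pairs, bounds, modality, cov, mod, keep)
                    else:
                        group = [
                            _make_rule(pairs[i], modality, cov[i], mod[i])
                            for i in np.nonzero(keep)[0]
                        ]
                        n_selected += len(group)
                        minimized.extend(minimize(group))

    provenance = {
        "variables": names,
        "dims": dims,
        "min_modality_size": min_modality_size,
        "min_z": min_z,
        "n_candidates_selected": n_selected,
    }
    return RuleSet(rules=minimized, provenance=provenance)
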