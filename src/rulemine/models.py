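"""Predictive models on discretized data.

Three model types share a variable-selection step and an L2-penalized
logistic classification step:

* ``global`` — chi2 test of independence (levels x target) with a
  Bonferroni-corrected 0.05 threshold, then logistic regression on the
  selected raw variables (ordinal level codes as numeric columns, nominal
  variables one-hot encoded).
* ``local_1d`` — rule mining restricted to dimension 1 on the
  chi2-selected variables; the classifier sees one binary column per rule.
* ``local_1and2d`` — the same with 1D and 2D rules.

Model *complexity* is the number of selected features (variables for the
global model, rules for the local ones).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .dataset import DiscretizedDataset
from .mining import (
    DEFAULT_MIN_MODALITY_SIZE,
    DEFAULT_MIN_Z,
    Rule,
    RuleSet,
    _rule_from_dict,
    _rule_to_dict,
    mine_rules,
)

__all__ = [
    "FittedModel",
    "chi2_select",
    "rules_to_features",
    "fit_l2_logistic",
    "build_model",
    "predict",
    "MODEL_TYPES",
]

logger = logging.getLogger(__name__)

MODEL_TYPES = ("global", "local_1d", "local_1and2d")

SOLVER_TOL = 1e-8
SOLVER_MAX_ITER = 5000


def chi2_select(train: DiscretizedDataset, alpha: float = 0.05) -> list:
    """Variables whose levels-x-target chi2 independence test passes a
    Bonferroni-corrected threshold ``alpha / m_tested``.

    Constant variables (a single occupied level on the training data) are
    skipped, not errors.  The statistic is the classical Pearson chi2 on the
    observed contingency table, without continuity correction.
    """
    y = train.modality_indicator(train.modalities[0]).astype(np.int64)
    n = train.n_subjects
    n1 = int(y.sum())
    pvals = {}
    for meta in train.variables:
        codes = train.codes(meta.name)
        levels, inv = np.unique(codes, return_inverse=True)
        if len(levels) < 2:
            continue
        # 2 x L contingency via bincount
        obs1 = np.bincount(inv, weights=y, minlength=len(levels))
        tot = np.bincount(inv, minlength=len(levels))
        obs0 = tot - obs1
        exp1 = tot * (n1 / n)
        exp0 = tot * ((n - n1) / n)
        stat = float(((obs1 - exp1) ** 2 / exp1).sum() + ((obs0 - exp0) ** 2 / exp0).sum())
        dof = len(levels) - 1
        pvals[meta.name] = float(chi2_dist.sf(stat, dof))
    m = len(pvals)
    if m == 0:
        return []
    cutoff = alpha / m
    return [name for name in (v.name for v in train.variables) if name in pvals and pvals[name] <= cutoff]


def rules_to_features(rules, dataset: DiscretizedDataset) -> np.ndarray:
    """Binary feature matrix: one column per rule, entry 1 iff the subject
    is in the rule's support.  Column order follows the rule list."""
    rule_list = list(rules)
    if not rule_list:
        return np.zeros((dataset.n_subjects, 0), dtype=np.float64)
    return np.stack([r.mask(dataset).astype(np.float64) for r in rule_list], axis=1)


def fit_l2_logistic(features: np.ndarray, target01: np.ndarray, C: float):
    """Maximize the L2-penalized binomial log-likelihood (inverse penalty
    strength ``C``, intercept unpenalized).  Returns ``(weights, intercept)``.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    features = np.asarray(features, dtype=np.float64)
    if features.shape[1] == 0:
        raise ValueError("need at least one feature")
    # default penalty is ridge (L2); intercept is unpenalized
    clf = LogisticRegression(C=C, solver="lbfgs", tol=SOLVER_TOL, max_iter=SOLVER_MAX_ITER)
    clf.fit(features, np.asarray(target01, dtype=np.int64))
    return clf.coef_[0].copy(), float(clf.intercept_[0])


@dataclass
class FittedModel:
    """A fitted classifier with its selected features.

    The positive class of the linear score is the first modality (renal
    failure by default); prediction thresholds the logistic probability at
    0.5.  Rule features are recomputed on new subjects from the stored
    conditions, so the model applies to any dataset carrying its variables.
    """

    model_type: str
    modalities: tuple
    selected_variables: list
    rules: RuleSet | None
    C: float
    weights: np.ndarray
    intercept: float
    provenance: dict = field(default_factory=dict)

    @property
    def selected_features(self):
        if self.model_type == "global":
            return list(self.selected_variables)
        return list(self.rules.rules) if self.rules is not None else []

    @property
    def complexity(self) -> int:
        return len(self.selected_features)

    def feature_identities(self) -> set:
        """Identifiers entering stability comparisons: variable names for the
        global model, exact rule conditions for local models."""
        if self.model_type == "global":
            return set(self.selected_variables)
        return {r.identity() for r in self.selected_features}

    def feature_matrix(self, dataset: DiscretizedDataset) -> np.ndarray:
        if self.model_type == "global":
            return _encode_global(dataset, self.selected_variables)[0]
        return rules_to_features(self.selected_features, dataset)

    def decision_scores(self, dataset: DiscretizedDataset) -> np.ndarray:
        if self.complexity == 0:
            return np.full(dataset.n_subjects, self.intercept)
        return self.feature_matrix(dataset) @ self.weights + self.intercept

    def predict(self, dataset: DiscretizedDataset) -> pd.Series:
        pos, neg = self.modalities[0], self.modalities[1]
        prob = expit(self.decision_scores(dataset))
        labels = np.where(prob >= 0.5, pos, neg)
        return pd.Series(labels, index=dataset.data.index)

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "model_type": self.model_type,
            "modalities": list(self.modalities),
            "selected_variables": list(self.selected_variables),
            "rules": [_rule_to_dict(r) for r in self.rules.rules] if self.rules is not None else None,
            "rules_provenance": self.rules.provenance if self.rules is not None else None,
            "C": self.C,
            "weights": list(map(float, np.atleast_1d(self.weights))),
            "intercept": self.intercept,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            d = json.load(fh)
        rules = None
        if d["rules"] is not None:
            rules = RuleSet(
                rules=[_rule_from_dict(r) for r in d["rules"]],
                provenance=d.get("rules_provenance") or {},
            )
        return cls(
            model_type=d["model_type"],
            modalities=tuple(d["modalities"]),
            selected_variables=d["selected_variables"],
            rules=rules,
            C=d["C"],
            weights=np.asarray(d["weights"], dtype=float),
            intercept=d["intercept"],
            provenance=d.get("provenance", {}),
        )


def _encode_global(dataset: DiscretizedDataset, variable_names):
    """Global-model design matrix: ordinal level codes as single numeric
    columns, nominal variables one-hot over their declared categories."""
    cols, names = [], []
    for name in variable_names:
        meta = dataset.variable(name)
        if meta.is_ordinal:
            cols.append(dataset.data[name].to_numpy(dtype=np.float64))
            names.append(name)
        else:
            col = dataset.data[name]
            for lab in meta.level_labels:
                cols.append((col == lab).to_numpy(dtype=np.float64))
                names.append(f"{name}={lab}")
    if not cols:
        return np.zeros((dataset.n_subjects, 0)), []
    return np.stack(cols, axis=1), names


@dataclass
class _Prepared:
    """Feature-selection state shared across C values (mining does not
    depend on C, so the inner CV reuses it)."""

    model_type: str
    modalities: tuple
    selected_variables: list
    rules: RuleSet | None
    features: np.ndarray
    target01: np.ndarray
    provenance: dict


def prepare_features(
    train: DiscretizedDataset,
    model_type: str,
    alpha: float = 0.05,
    min_modality_size: int = DEFAULT_MIN_MODALITY_SIZE,
    min_z: float = DEFAULT_MIN_Z,
    max_nominal_levels: int = 6,
    mine_variables=None,
) -> _Prepared:
    """Run the feature-selection step of one model type.

    ``mine_variables`` controls which variables the local models mine:
    ``None`` (default) mines the chi2-selected variables — the standard
    protocol; ``"all"`` mines every variable (needed to surface pairwise
    interactions whose margins carry no 1D signal, which chi2 cannot see);
    a list mines exactly those variables.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model_type {model_type!r}")
    selected = chi2_select(train, alpha=alpha)
    target01 = train.modality_indicator(train.modalities[0]).astype(np.int64)
    rules = None
    if model_type == "global":
        features, _ = _encode_global(train, selected)
    else:
        dims = (1,) if model_type == "local_1d" else (1, 2)
        if mine_variables is None:
            to_mine = selected
        elif mine_variables == "all":
            to_mine = train.variable_names
        else:
            to_mine = list(mine_variables)
        if to_mine:
            rules = mine_rules(
                train,
                variables=to_mine,
                dims=dims,
                min_modality_size=min_modality_size,
                min_z=min_z,
                max_nominal_levels=max_nominal_levels,
            )
        else:
            rules = RuleSet(rules=[], provenance={"variables": [], "dims": list(dims)})
        features = rules_to_features(rules.rules, train)
    return _Prepared(
        model_type=model_type,
        modalities=train.modalities,
        selected_variables=selected,
        rules=rules,
        features=features,
        target01=target01,
        provenance={
            "alpha": alpha,
            "min_modality_size": min_modality_size,
            "min_z": min_z,
            "n_chi2_selected": len(selected),
        },
    )


def fit_prepared(prep: _Prepared, C: float) -> FittedModel:
    if prep.features.shape[1] == 0:
        # nothing selected: intercept-only majority model
        logger.warning("no features after selection; falling back to intercept-only model")
        p = prep.target01.mean()
        p = min(max(p, 1e-12), 1 - 1e-12)
        intercept = float(np.log(p / (1 - p)))
        return FittedModel(
            model_type=prep.model_type,
            modalities=prep.modalities,
            selected_variables=[],
            rules=RuleSet(rules=[], provenance=prep.rules.provenance) if prep.rules is not None else None,
            C=C,
            weights=np.zeros(0),
            intercept=intercept,
            provenance=dict(prep.provenance, fallback="intercept_only"),
        )
    weights, intercept = fit_l2_logistic(prep.features, prep.target01, C)
    return FittedModel(
        model_type=prep.model_type,
        modalities=prep.modalities,
        selected_variables=prep.selected_variables,
        rules=prep.rules,
        C=C,
        weights=weights,
        intercept=intercept,
        provenance=dict(prep.provenance),
    )


def build_model(
    train: DiscretizedDataset,
    model_type: str,
    C: float = 1.0,
    alpha: float = 0.05,
    min_modality_size: int = DEFAULT_MIN_MODALITY_SIZE,
    min_z: float = DEFAULT_MIN_Z,
    max_nominal_levels: int = 6,
    mine_variables=None,
) -> FittedModel:
    """Select features (chi2, plus rule mining for local models) on the
    training data and fit the L2-logistic classifier at penalty ``C``."""
    prep = prepare_features(
        train,
        model_type,
        alpha=alpha,
        min_modality_size=min_modality_size,
        min_z=min_z,
        max_nominal_levels=max_nominal_levels,
        mine_variables=mine_variables,
    )
    return fit_prepared(prep, C)


def predict(model: FittedModel, data: DiscretizedDataset) -> pd.Series:
    """Per-subject predicted modality (thin wrapper over the method)."""
    return model.predict(data)
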