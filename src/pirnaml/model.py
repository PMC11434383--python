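"""Multinomial naive Bayes for descriptor vectors, plus alternate classifiers.

The multinomial NB classifier treats a descriptor vector x as event counts:
for class c with prior pi_c and smoothed event probabilities theta_c,

    log P(c | x)  ∝  log pi_c + sum_i x_i log theta_ci
    theta_ci = (sum_{rows in c} x_i + alpha) / (sum_{rows in c} sum_j x_j + alpha d)

with Laplace pseudo-count alpha (default 1) and d descriptors. Fractional
descriptor values (frequencies, mean mass) are accepted as fractional event
counts. Everything runs in log space, so vectors with values up to ~1e4
across a thousand descriptors neither overflow nor underflow.

The model/results split follows the statsmodels convention:
``MultinomialNBModel`` is built from data, ``fit()`` returns a
``MultinomialNBResults`` carrying the estimates, prediction methods and a
``summary()`` table. ``fit_nb``/``predict``/``predict_proba`` are functional
aliases over the same objects.

Alternate classifiers (random forest, multilayer perceptron, AdaBoost and a
depth-limited decision tree standing in for a decision table) are wrapped
behind the same fit/predict_proba contract via :func:`make_classifier`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import split_features
from .errors import DataError, SchemaMismatchError

POSITIVE_CLASS = "selected"

SUPPORTED_CLASSIFIERS = (
    "nb_multinomial", "random_forest", "mlp", "adaboost", "decision_table_like",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """Name + parameters + seed identifying a classifier configuration."""

    name: str = "nb_multinomial"
    params: dict = field(default_factory=dict)
    seed: int = 1

    def __post_init__(self):
        if self.name not in SUPPORTED_CLASSIFIERS:
            raise DataError(
                f"unknown classifier {self.name!r}; supported: "
                + ", ".join(SUPPORTED_CLASSIFIERS)
            )

    def to_dict(self):
        return {"name": self.name, "params": dict(self.params), "seed": self.seed}


def _check_nonnegative(X: pd.DataFrame) -> None:
    mins = X.min(axis=0)
    bad = mins[mins < 0]
    if len(bad):
        raise DataError(
            f"negative feature values in descriptor(s): {', '.join(bad.index[:5])}"
        )


class MultinomialNBModel:
    """Multinomial naive Bayes model specification.

    Parameters
    ----------
    X : DataFrame of shape (n_instances, n_descriptors)
        Non-negative descriptor values, columns named.
    y : Series or array of class labels
        At least two classes must be present.
    """

    def __init__(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y), index=X.index, name="label")
        if X.empty:
            raise DataError("cannot fit on an empty table")
        _check_nonnegative(X)
        classes = _ordered_classes(y)
        if len(classes) < 2:
            raise DataError("fitting requires at least two classes")
        for c in classes:
            if (y == c).sum() == 0:
                raise DataError(f"class {c!r} has no instances")
        self.X = X
        self.y = y
        self.classes = classes
        self.descriptor_names = list(X.columns)

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame) -> "MultinomialNBModel":
        X, y = split_features(table)
        return cls(X, y)

    def fit(self, alpha: float = 1.0) -> "MultinomialNBResults":
        """Estimate priors and smoothed event probabilities."""
        if alpha < 0:
            raise DataError("alpha must be >= 0")
        n, d = self.X.shape
        log_priors = {}
        log_theta = {}
        for c in self.classes:
            rows = self.X[self.y == c].to_numpy(dtype=float)
            log_priors[c] = np.log(rows.shape[0] / n)
            totals = rows.sum(axis=0)
            denom = totals.sum() + alpha * d
            if denom <= 0:
                raise DataError(
                    f"class {c!r} has zero total counts and alpha=0; "
                    "cannot normalize"
                )
            log_theta[c] = np.log((totals + alpha) / denom)
        return MultinomialNBResults(
            model=self,
            classes=self.classes,
            log_priors=pd.Series(log_priors),
            log_theta=pd.DataFrame(log_theta, index=self.descriptor_names).T,
            alpha=alpha,
            descriptor_names=self.descriptor_names,
        )


class MultinomialNBResults:
    """Fitted multinomial NB: class priors and per-class event probabilities.

    ``log_theta`` is a classes x descriptors DataFrame of natural-log
    smoothed probabilities; per class the probabilities sum to one.
    """

    def __init__(self, *, classes, log_priors, log_theta, alpha,
                 descriptor_names, model=None):
        self.model = model
        self.classes = list(classes)
        self.log_priors = log_priors
        self.log_theta = log_theta
        self.alpha = alpha
        self.descriptor_names = list(descriptor_names)

    # ---- prediction -----------------------------------------------------

    def _align(self, X) -> np.ndarray:
        if isinstance(X, dict):
            X = pd.DataFrame([X])
        elif isinstance(X, pd.Series):
            X = X.to_frame().T
        elif not isinstance(X, pd.DataFrame):
            arr = np.atleast_2d(np.asarray(X, dtype=float))
            if arr.shape[1] != len(self.descriptor_names):
                raise SchemaMismatchError(
                    missing=[f"<{len(self.descriptor_names)} columns expected, "
                             f"got {arr.shape[1]}>"])
            return arr
        missing = [c for c in self.descriptor_names if c not in X.columns]
        extra = [c for c in X.columns
                 if c not in self.descriptor_names and c != "label"]
        if missing or extra:
            raise SchemaMismatchError(missing=missing, extra=extra)
        return X[self.descriptor_names].to_numpy(dtype=float)

    def predict_proba(self, X) -> pd.DataFrame:
        """Posterior class probabilities, rows summing to one.

        Accepts a DataFrame aligned to the fitted descriptors, a single
        vector (Series/dict), or a bare array in descriptor order.
        """
        arr = self._align(X)
        if (arr < 0).any():
            raise DataError("descriptor values must be >= 0")
        log_t = self.log_theta.loc[self.classes].to_numpy()  # C x d
        log_p = self.log_priors[self.classes].to_numpy()
        joint = arr @ log_t.T + log_p  # n x C, log space
        joint -= joint.max(axis=1, keepdims=True)
        probs = np.exp(joint)
        probs /= probs.sum(axis=1, keepdims=True)
        index = X.index if isinstance(X, pd.DataFrame) else None
        return pd.DataFrame(probs, columns=self.classes, index=index)

    def predict(self, X) -> np.ndarray:
        """Argmax-posterior labels; ties go to the first class in
        ``self.classes`` (the positive class when present)."""
        probs = self.predict_proba(X).to_numpy()
        return np.asarray(self.classes, dtype=object)[probs.argmax(axis=1)]

    # ---- reporting ------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        """Plain-text summary: priors and the most class-discriminative
        descriptors by absolute log-probability ratio."""
        lines = ["Multinomial Naive Bayes results",
                 "=" * 47,
                 f"classes:      {', '.join(self.classes)}",
                 f"descriptors:  {len(self.descriptor_names)}",
                 f"alpha:        {self.alpha}",
                 "priors:       " + ", ".join(
                     f"{c}={np.exp(v):.3f}" for c, v in self.log_priors.items()),
                 "-" * 47]
        if len(self.classes) == 2:
            a, b = self.classes
            ratio = (self.log_theta.loc[a] - self.log_theta.loc[b]).sort_values(
                key=np.abs, ascending=False)
            lines.append(f"top descriptors by |log theta_{a} - log theta_{b}|:")
            for name, v in ratio.head(top).items():
                lines.append(f"  {name:<12} {v:+.4f}")
        lines.append("=" * 47)
        return "\n".join(lines)

    # ---- persistence ----------------------------------------------------

    def to_json(self, path=None):
        payload = {
            "classes": self.classes,
            "log_priors": [float(self.log_priors[c]) for c in self.classes],
            "log_theta": [
                [float(v) for v in self.log_theta.loc[c]] for c in self.classes
            ],
            "alpha": self.alpha,
            "descriptor_names": self.descriptor_names,
            "format_version": 1,
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path_or_str) -> "MultinomialNBResults":
        if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("{"):
            payload = json.loads(path_or_str)
        else:
            with open(path_or_str) as fh:
                payload = json.load(fh)
        classes = payload["classes"]
        return cls(
            classes=classes,
            log_priors=pd.Series(dict(zip(classes, payload["log_priors"]))),
            log_theta=pd.DataFrame(payload["log_theta"], index=classes,
                                   columns=payload["descriptor_names"]),
            alpha=payload["alpha"],
            descriptor_names=payload["descriptor_names"],
        )


def _ordered_classes(y) -> list[str]:
    """Classes with the positive class first, then the rest alphabetically."""
    present = sorted(set(np.asarray(y).tolist()))
    if POSITIVE_CLASS in present:
        present.remove(POSITIVE_CLASS)
        present.insert(0, POSITIVE_CLASS)
    return present


# ---- functional aliases (statsmodels-style objects underneath) ----------

def fit_nb(table: pd.DataFrame, alpha: float = 1.0) -> MultinomialNBResults:
    """Fit multinomial NB on a labeled feature table."""
    return MultinomialNBModel.from_feature_table(table).fit(alpha=alpha)


def predict_proba(results: MultinomialNBResults, X) -> pd.DataFrame:
    return results.predict_proba(X)


def predict(results: MultinomialNBResults, X) -> np.ndarray:
    return results.predict(X)


# ---- pluggable classifier contract --------------------------------------

class _NBAdapter:
    """fit/predict_proba wrapper over the in-package NB implementation."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.results = None
        self.classes = None

    def fit(self, X: pd.DataFrame, y):
        self.results = MultinomialNBModel(X, y).fit(
            alpha=self.spec.params.get("alpha", 1.0))
        self.classes = self.results.classes
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.results.predict_proba(X).to_numpy()

    def predict(self, X) -> np.ndarray:
        return self.results.predict(X)


class _SklearnAdapter:
    """Wraps an sklearn estimator, fixing class-column order to ours."""

    def __init__(self, estimator, spec: ClassifierSpec):
        self.estimator = estimator
        self.spec = spec
        self.classes = None

    def fit(self, X: pd.DataFrame, y):
        _check_nonnegative(pd.DataFrame(X))
        self.classes = _ordered_classes(y)
        self.estimator.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict_proba(self, X) -> np.ndarray:
        raw = self.estimator.predict_proba(np.asarray(X, dtype=float))
        cols = {c: i for i, c in enumerate(self.estimator.classes_)}
        return raw[:, [cols[c] for c in self.classes]]

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.asarray(self.classes, dtype=object)[probs.argmax(axis=1)]


def make_classifier(spec: ClassifierSpec):
    """Build a classifier honoring the fit/predict_proba contract.

    ``nb_multinomial`` uses the in-package implementation; the rest wrap
    standard scikit-learn estimators seeded from ``spec.seed``.
    ``decision_table_like`` is a depth-limited decision tree: a shallow tree
    over the selected descriptors enumerates outcome rules much like a
    decision table does.
    """
    p = dict(spec.params)
    if spec.name == "nb_multinomial":
        return _NBAdapter(spec)
    if spec.name == "random_forest":
        from sklearn.ensemble import RandomForestClassifier
        est = RandomForestClassifier(
            n_estimators=p.pop("n_estimators", 100), random_state=spec.seed, **p)
    elif spec.name == "mlp":
        from sklearn.neural_network import MLPClassifier
        est = MLPClassifier(
            hidden_layer_sizes=p.pop("hidden_layer_sizes", (32,)),
            max_iter=p.pop("max_iter", 2000), random_state=spec.seed, **p)
    elif spec.name == "adaboost":
        from sklearn.ensemble import AdaBoostClassifier
        est = AdaBoostClassifier(
            n_estimators=p.pop("n_estimators", 50), random_state=spec.seed, **p)
    elif spec.name == "decision_table_like":
        from sklearn.tree import DecisionTreeClassifier
        est = DecisionTreeClassifier(
            max_depth=p.pop("max_depth", 3), random_state=spec.seed, **p)
    else:  # pragma: no cover - ClassifierSpec already validates
        raise DataError(f"unknown classifier {spec.name!r}")
    return _SklearnAdapter(est, spec)
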