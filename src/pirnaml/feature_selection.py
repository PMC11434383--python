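"""Information-gain descriptor ranking with MDL supervised discretization.

Numeric descriptors are discretized per-attribute by the Fayyad-Irani
recursive entropy-minimization method: the cut that minimizes the weighted
class entropy is accepted only when its information gain clears the
minimum-description-length threshold

    gain > [log2(n - 1) + log2(3^c - 2) - c*E(S) + c1*E(S1) + c2*E(S2)] / n

with c the number of classes present in a set and E the class entropy in
bits, then both halves are split recursively. The information gain of the
resulting binning, H(labels) - sum_v p(v) H(labels | bin v), ranks the
descriptors; an attribute that never earns a cut scores zero. With two
classes the gain lives in [0, 1] bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import split_features
from .errors import DataError

__all__ = [
    "InfoGainRanking", "mdl_discretize", "info_gain",
    "rank_descriptors", "select", "equal_frequency_cuts",
]


@dataclass(frozen=True)
class InfoGainRanking:
    """Per-descriptor information gain in bits, sorted descending.

    Ties are broken by canonical schema (column) order so the ranking is
    deterministic.
    """

    entries: tuple  # ((name, gain), ...) sorted by gain desc, schema-order ties

    def __len__(self):
        return len(self.entries)

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.entries[:k]]

    def gains(self) -> dict[str, float]:
        return dict(self.entries)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["descriptor", "gain_bits"])
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df


def _entropy(labels: np.ndarray) -> float:
    """Class entropy in bits."""
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def _mdl_split(values: np.ndarray, labels: np.ndarray, cuts: list) -> None:
    """Recursively append accepted Fayyad-Irani cut points (sorted input)."""
    n = values.size
    if n < 2:
        return
    # candidate boundaries: midpoints between adjacent distinct values
    distinct_idx = np.nonzero(np.diff(values))[0]
    if distinct_idx.size == 0:
        return
    ent_s = _entropy(labels)
    best_gain, best_i = -1.0, -1
    for i in distinct_idx:
        left, right = labels[: i + 1], labels[i + 1 :]
        cond = (left.size * _entropy(left) + right.size * _entropy(right)) / n
        gain = ent_s - cond
        if gain > best_gain + 1e-12:
            best_gain, best_i = gain, i
    left, right = labels[: best_i + 1], labels[best_i + 1 :]
    c = np.unique(labels).size
    c1, c2 = np.unique(left).size, np.unique(right).size
    delta = np.log2(3.0**c - 2.0) - (
        c * ent_s - c1 * _entropy(left) - c2 * _entropy(right)
    )
    threshold = (np.log2(n - 1) + delta) / n
    if best_gain <= threshold:
        return
    cut = (values[best_i] + values[best_i + 1]) / 2.0
    _mdl_split(values[: best_i + 1], left, cuts)
    cuts.append(cut)
    _mdl_split(values[best_i + 1 :], right, cuts)


def mdl_discretize(values, labels) -> list[float]:
    """Fayyad-Irani MDL cut points for one numeric attribute.

    Returns ascending cut points; an attribute whose best split never clears
    the MDL threshold gets none.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise DataError(
            f"values ({values.size}) and labels ({labels.size}) differ in length"
        )
    order = np.argsort(values, kind="stable")
    cuts: list[float] = []
    _mdl_split(values[order], labels[order], cuts)
    return cuts  # recursion emits them in ascending order


def equal_frequency_cuts(values, n_bins: int = 4) -> list[float]:
    """Unsupervised alternative binning (sensitivity checks only)."""
    values = np.asarray(values, dtype=float)
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return sorted(set(q for q in qs if values.min() < q < values.max()))


def info_gain(values, labels, cuts) -> float:
    """Information gain in bits of the binning induced by ``cuts``.

    Empty ``cuts`` means a single bin, hence zero gain.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise DataError(
            f"values ({values.size}) and labels ({labels.size}) differ in length"
        )
    if not cuts:
        return 0.0
    bins = np.searchsorted(np.asarray(cuts, dtype=float), values, side="right")
    gain = _entropy(labels)
    for b in np.unique(bins):
        mask = bins == b
        gain -= mask.sum() / labels.size * _entropy(labels[mask])
    return float(max(gain, 0.0))


def rank_descriptors(table: pd.DataFrame, discretizer: str = "mdl") -> InfoGainRanking:
    """Rank every descriptor column of a labeled feature table by gain.

    ``discretizer`` is ``"mdl"`` (default) or ``"equal_frequency"``.
    """
    X, y = split_features(table)
    if len(X) < 2:
        raise DataError("ranking needs at least 2 instances")
    labels = y.to_numpy()
    if np.unique(labels).size < 2:
        raise DataError("ranking needs both classes present")
    gains = np.zeros(X.shape[1])
    values = X.to_numpy(dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        if col.min() == col.max():  # constant column: no candidate boundary
            continue
        if discretizer == "mdl":
            cuts = mdl_discretize(col, labels)
        elif discretizer == "equal_frequency":
            cuts = equal_frequency_cuts(col)
        else:
            raise DataError(f"unknown discretizer {discretizer!r}")
        gains[j] = info_gain(col, labels, cuts)
    order = np.lexsort((np.arange(len(gains)), -gains))  # gain desc, schema order
    entries = tuple((X.columns[j], float(gains[j])) for j in order)
    return InfoGainRanking(entries=entries)


def select(table: pd.DataFrame, ranking: InfoGainRanking,
           rule: str = "positive_gain", k: int = 27) -> pd.DataFrame:
    """Reduce a feature table to its most informative descriptors.

    ``rule="top_k"`` keeps the ``k`` highest-gain descriptors;
    ``rule="positive_gain"`` (default) keeps every descriptor with gain > 0.
    Column (schema) order is preserved; the label column is untouched.
    """
    X, y = split_features(table)
    if rule == "top_k":
        if k < 1:
            raise DataError("k must be >= 1")
        if k > X.shape[1]:
            raise DataError(f"k={k} exceeds the {X.shape[1]} available descriptors")
        chosen = set(ranking.top(k))
    elif rule == "positive_gain":
        chosen = {name for name, gain in ranking.entries if gain > 0}
        if not chosen:
            raise DataError("positive_gain selection is empty: every descriptor "
                            "has zero information gain")
    else:
        raise DataError(f"unknown selection rule {rule!r}")
    keep = [c for c in X.columns if c in chosen]
    out = table[keep].copy()
    out["label"] = y
    return out
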