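"""Shared fixtures and independent brute-force oracles.

The oracle helpers here are deliberately naive re-implementations (plain
Python loops, math.log2) kept independent of the package's code paths so
they can serve as ground truth.
"""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from pirnaml import build_schema
from pirnaml.sequence_io import PiRNARecord

ALPHABET = "ACGU"


@pytest.fixture(scope="session")
def schema():
    return build_schema()


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


def random_sequence(rng, lo=5, hi=40):
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(ALPHABET), size=length))


@pytest.fixture
def toy_table():
    """Tiny two-class feature table with closed-form NB estimates:
    class 'selected' totals {m1: 4, m2: 0}, class 'random' {m1: 0, m2: 4}."""
    return pd.DataFrame(
        {
            "m1": [2.0, 2.0, 0.0, 0.0],
            "m2": [0.0, 0.0, 2.0, 2.0],
            "label": ["selected", "selected", "random", "random"],
        },
        index=["s1", "s2", "r1", "r2"],
    )


# ---------------- independent oracles ----------------


def naive_kmer_count(seq: str, motif: str) -> int:
    """Rescan count of an exact motif, overlap-aware, by sliding window."""
    k = len(motif)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == motif)


def entropy_bits(labels) -> float:
    labels = list(labels)
    out = 0.0
    for c in set(labels):
        p = labels.count(c) / len(labels)
        out -= p * math.log2(p)
    return out


def brute_force_gain(values, labels, cuts) -> float:
    """Information gain of a fixed binning, by explicit partition."""
    if not cuts:
        return 0.0
    bins = {}
    for v, lab in zip(values, labels):
        b = sum(v > c for c in cuts)
        bins.setdefault(b, []).append(lab)
    gain = entropy_bits(labels)
    for members in bins.values():
        gain -= len(members) / len(labels) * entropy_bits(members)
    return gain


def brute_force_mdl(values, labels):
    """Naive recursive Fayyad-Irani MDL discretization."""
    pairs = sorted(zip(values, labels), key=lambda t: t[0])
    vs = [p[0] for p in pairs]
    ls = [p[1] for p in pairs]

    def split(vs, ls):
        n = len(vs)
        best = None
        for i in range(n - 1):
            if vs[i] == vs[i + 1]:
                continue
            left, right = ls[: i + 1], ls[i + 1 :]
            gain = entropy_bits(ls) - (
                len(left) * entropy_bits(left) + len(right) * entropy_bits(right)
            ) / n
            if best is None or gain > best[0] + 1e-12:
                best = (gain, i)
        if best is None:
            return []
        gain, i = best
        left, right = ls[: i + 1], ls[i + 1 :]
        c = len(set(ls))
        delta = math.log2(3**c - 2) - (
            c * entropy_bits(ls)
            - len(set(left)) * entropy_bits(left)
            - len(set(right)) * entropy_bits(right)
        )
        if gain <= (math.log2(n - 1) + delta) / n:
            return []
        cut = (vs[i] + vs[i + 1]) / 2
        return (
            split(vs[: i + 1], ls[: i + 1]) + [cut] + split(vs[i + 1 :], ls[i + 1 :])
        )

    return split(vs, ls)


def concordant_pair_auc(scores, labels, positive="selected") -> float:
    """AUC as the tie-corrected fraction of concordant (pos, neg) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def make_records(seqs, label="unknown", prefix="r"):
    return [PiRNARecord(f"{prefix}{i}", s, label) for i, s in enumerate(seqs)]
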