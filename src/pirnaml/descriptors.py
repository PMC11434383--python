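"""The 1020-dimensional piRNA sequence descriptor system.

Every sequence maps to a fixed, ordered vector of 1020 numeric descriptors:

* 12 global descriptors: length N, per-nucleotide counts (A, G, C, U),
  per-nucleotide frequencies (A/N, G/N, C/N, U/N), mean nucleobase mass
  (Mass/N, daltons), total Watson-Crick hydrogen-bond capacity (Hbonds,
  A/U -> 2, G/C -> 3), and Symmetry (positions at which the sequence equals
  its own reversal);
* 336 overlapping k-mer counts over the full sequence (16 dimers + 64
  trimers + 256 tetramers, enumerated lexicographically over A < C < G < U);
* the same 336 motifs counted only in the first five nucleotides
  (``5s``-prefixed names);
* and again in the last five nucleotides (``5e``-prefixed names).

12 + 3 x 336 = 1020. Motif counts use overlapping windows (step 1), so e.g.
``GGGGG`` contains four GG dimers. Sequences shorter than five nucleotides
use the whole sequence as both terminal windows; real piRNAs are 24-31 nt so
this only matters for degenerate inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import DataError, DuplicateIdError
from .sequence_io import PiRNARecord, RNA_ALPHABET

#: average nucleobase (not nucleotide) masses in daltons; configurable via
#: build_schema(masses=...) since descriptor systems differ on whether the
#: sugar-phosphate backbone is included
DEFAULT_MASSES = {"A": 135.13, "G": 151.13, "C": 111.10, "U": 112.09}

#: Watson-Crick pairing capacity
DEFAULT_HBONDS = {"A": 2, "U": 2, "G": 3, "C": 3}

GLOBAL_NAMES = (
    "N", "A", "G", "C", "U",
    "A/N", "G/N", "C/N", "U/N",
    "Mass/N", "Hbonds", "Symmetry",
)

TERMINAL_WINDOW = 5  # first/last-5-nt motif windows


def _enumerate_motifs() -> list[str]:
    """All 2-, 3- and 4-mers in lexicographic order over A < C < G < U."""
    return ["".join(p) for k in (2, 3, 4) for p in product(RNA_ALPHABET, repeat=k)]


@dataclass(frozen=True)
class DescriptorSchema:
    """The canonical ordered list of 1020 descriptor names plus the physical
    constants (masses, hydrogen-bond counts) the global block uses."""

    names: tuple = ()
    masses: dict = field(default_factory=dict)
    hbonds: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.names)

    @property
    def hash(self) -> str:
        payload = json.dumps(
            {"names": list(self.names), "masses": self.masses, "hbonds": self.hbonds},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"names": list(self.names), "masses": self.masses,
                 "hbonds": self.hbonds, "hash": self.hash},
                fh, indent=1,
            )


def build_schema(masses=None, hbonds=None) -> DescriptorSchema:
    """Build the canonical 1020-descriptor schema.

    Order: the 12 global names, the 336 full-sequence motifs, the same
    motifs prefixed ``5s``, then prefixed ``5e``.
    """
    motifs = _enumerate_motifs()
    names = (
        list(GLOBAL_NAMES)
        + motifs
        + ["5s" + m for m in motifs]
        + ["5e" + m for m in motifs]
    )
    assert len(names) == 1020 and len(set(names)) == 1020
    return DescriptorSchema(
        names=tuple(names),
        masses=dict(masses or DEFAULT_MASSES),
        hbonds=dict(hbonds or DEFAULT_HBONDS),
    )


def count_kmers(seq: str, k: int) -> dict[str, int]:
    """Overlapping k-mer counts for every motif of length k over {A,C,G,U}.

    Motifs absent from ``seq`` map to 0; the counts sum to
    ``max(0, len(seq) - k + 1)``.
    """
    if k not in (2, 3, 4):
        raise DataError(f"k must be 2, 3 or 4, got {k}")
    counts = {"".join(p): 0 for p in product(RNA_ALPHABET, repeat=k)}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    return counts


def symmetry(seq: str) -> int:
    """Number of positions at which the sequence matches its own reversal."""
    return sum(a == b for a, b in zip(seq, reversed(seq)))


def global_descriptors(seq: str, schema: DescriptorSchema) -> list[float]:
    """The 12-value global block, in ``GLOBAL_NAMES`` order."""
    if not seq:
        raise DataError("cannot compute descriptors of an empty sequence")
    n = len(seq)
    counts = {nt: seq.count(nt) for nt in ("A", "G", "C", "U")}
    mass = sum(schema.masses[c] for c in seq) / n
    hbonds = sum(schema.hbonds[c] for c in seq)
    return [
        float(n),
        float(counts["A"]), float(counts["G"]), float(counts["C"]), float(counts["U"]),
        counts["A"] / n, counts["G"] / n, counts["C"] / n, counts["U"] / n,
        mass, float(hbonds), float(symmetry(seq)),
    ]


def featurize(record: PiRNARecord, schema: DescriptorSchema) -> np.ndarray:
    """Map one record to its 1020-value descriptor vector (schema order)."""
    seq = record.sequence
    head = seq[:TERMINAL_WINDOW] if len(seq) >= TERMINAL_WINDOW else seq
    tail = seq[-TERMINAL_WINDOW:] if len(seq) >= TERMINAL_WINDOW else seq
    values = global_descriptors(seq, schema)
    for window in (seq, head, tail):
        for k in (2, 3, 4):
            counts = count_kmers(window, k)
            values.extend(float(counts[m]) for m in sorted(counts))
    vec = np.asarray(values, dtype=float)
    assert vec.shape == (len(schema),)
    return vec


def featurize_all(records, schema: DescriptorSchema) -> pd.DataFrame:
    """Featurize a list of records into a table: one row per record, columns
    = schema names + ``label``, indexed by record id, input order kept."""
    records = list(records)
    if not records:
        raise DataError("no records to featurize")
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise DuplicateIdError(dupes)
    matrix = np.vstack([featurize(r, schema) for r in records])
    table = pd.DataFrame(matrix, index=pd.Index(ids, name="id"),
                         columns=list(schema.names))
    table["label"] = [r.label for r in records]
    return table


def split_features(table: pd.DataFrame):
    """Split a feature table into (X, y): descriptor columns and labels."""
    if "label" not in table.columns:
        raise DataError("feature table lacks a 'label' column")
    return table.drop(columns="label"), table["label"]
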