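"""Reading, validating and normalizing piRNA sequences.

piRNAs are ~24-31 nt RNAs; public catalogs serve them in both DNA (T) and
RNA (U) alphabets, so every sequence is normalized to uppercase RNA on the
way in. Feature tables travel as TSV with one descriptor per column and a
final ``label`` column; packaged piRNA identifier lists are plain text, one
id per line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import AlphabetError, DataError, DuplicateIdError

RNA_ALPHABET = ("A", "C", "G", "U")
LABELS = ("selected", "random", "unknown")

#: packaged identifier lists -> (resource file, expected size)
#: ``random_training`` is a frozen synthetic stand-in: the 13 background ids
#: used in the original study were drawn at random from a public piRNA
#: catalog and never published, so a fixed, clearly-labelled fixture is
#: packaged in its place (see the file name).
_PACKAGED_LISTS = {
    "crc_training": ("crc_training.txt", 13),
    "random_training": ("random_training_synthetic.txt", 13),
    "crc_independent": ("crc_independent.txt", 7),
    "breast_independent": ("breast_independent.txt", 9),
}

_ID_RE = re.compile(r"piR-[0-9]+")


@dataclass(frozen=True)
class PiRNARecord:
    """One identified, normalized RNA sequence with an optional class label."""

    id: str
    sequence: str
    label: str = "unknown"

    def __post_init__(self):
        if not self.id:
            raise DataError("record id must be non-empty")
        if not self.sequence:
            raise DataError(f"record {self.id!r}: sequence must be non-empty")
        if self.label not in LABELS:
            raise DataError(
                f"record {self.id!r}: label {self.label!r} not one of {LABELS}"
            )
        for pos, char in enumerate(self.sequence, start=1):
            if char not in RNA_ALPHABET:
                raise AlphabetError(char, pos, context=self.id)


@dataclass(frozen=True)
class IdList:
    """A named, ordered list of piRNA identifiers."""

    name: str
    ids: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateIdError([i for i in self.ids if list(self.ids).count(i) > 1])

    def __len__(self):
        return len(self.ids)


def normalize_sequence(raw: str, context: str = "") -> str:
    """Return the canonical RNA form: uppercased, T->U, whitespace stripped.

    Raises :class:`AlphabetError` naming the first offending character if
    anything other than A/C/G/U remains.
    """
    if not raw:
        raise DataError("cannot normalize an empty sequence")
    seq = "".join(raw.split()).upper().replace("T", "U")
    for pos, char in enumerate(seq, start=1):
        if char not in RNA_ALPHABET:
            raise AlphabetError(char, pos, context=context)
    return seq


def read_fasta(path, label: str = "unknown") -> list[PiRNARecord]:
    """Read a FASTA file into normalized records, all given the same label.

    Order is preserved; the record id is the first whitespace-delimited token
    of the header. Empty files and duplicate ids are errors.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rid = header.split()[0] if header.split() else ""
            records.append(
                PiRNARecord(rid, normalize_sequence(seq, context=rid), label)
            )
    if not records:
        raise DataError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise DuplicateIdError(dupes)
    return records


def write_fasta(records: Iterable[PiRNARecord], path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.sequence}\n")


def read_labels(path) -> dict[str, str]:
    """Read a two-column (id, label) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"], dtype=str)
    bad = sorted(set(df["label"]) - set(LABELS))
    if bad:
        raise DataError(f"unknown labels {bad}; expected one of {LABELS}")
    return dict(zip(df["id"], df["label"]))


def write_labels(records: Iterable[PiRNARecord], path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f"{rec.id}\t{rec.label}\n")


def load_packaged_id_list(name: str) -> IdList:
    """Load one of the packaged piRNA identifier lists by name.

    Valid names: ``crc_training`` (13 CRC-associated training ids),
    ``random_training`` (13 ids; synthetic stand-in fixture, see module
    docstring), ``crc_independent`` (7 independent CRC ids),
    ``breast_independent`` (9 breast-cancer ids).
    """
    try:
        fname, expected = _PACKAGED_LISTS[name]
    except KeyError:
        raise DataError(
            f"unknown id list {name!r}; valid names: "
            + ", ".join(sorted(_PACKAGED_LISTS))
        ) from None
    text = resources.files("pirnaml.data").joinpath(fname).read_text()
    ids = tuple(line.strip() for line in text.splitlines() if line.strip())
    assert len(ids) == expected, f"packaged list {name} corrupt"
    return IdList(name=name, ids=ids)


def read_feature_table(path) -> pd.DataFrame:
    """Read a TSV feature table (descriptor columns + final ``label`` column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if "label" not in df.columns:
        raise DataError(f"{path}: feature table lacks a 'label' column")
    return df


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="id")
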