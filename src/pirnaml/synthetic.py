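"""Synthetic piRNA-like sequence sets with planted class-specific motifs.

Sequences are drawn i.i.d. from a background nucleotide distribution with
lengths uniform on 24-31 nt (the piRNA size range). Positive-class
("selected") sequences optionally receive planted motifs, each written into
a chosen region — anywhere, the first five nucleotides, or the last five —
with a per-motif insertion probability. Insertion overwrites background
letters at a uniformly chosen in-region start, so sequence length never
leaks the label. A single seeded NumPy generator drives every draw in a
fixed, documented order (per record: length, letters, then per motif in
config order: insertion coin, position), making each dataset bit-reproducible
from its config.

The generator emulates the selected-vs-random two-class design used for
descriptor-based biomarker screens; it does not model real piRNA biogenesis
signals (e.g. the 1U/10A bias) beyond what planted motifs express.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import build_schema, featurize_all
from .errors import DataError
from .sequence_io import PiRNARecord, RNA_ALPHABET

__all__ = ["GeneratorConfig", "generate", "benchmark_dataset", "PRESETS"]

REGIONS = ("anywhere", "first5", "last5")

#: preset motifs; the three planted motifs echo descriptor names that a
#: terminal-motif-aware screen would surface (one per region kind)
_PRESET_MOTIFS = [("CAG", "first5", 0.9), ("UGA", "last5", 0.9),
                  ("AGGC", "anywhere", 0.9)]


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that determines a synthetic dataset.

    ``planted_motifs`` is a list of (motif, region, insertion probability)
    triples applied to positive-class sequences only.
    """

    n_per_class: int = 13
    length_range: tuple = (24, 31)
    background_freqs: dict = field(
        default_factory=lambda: {nt: 0.25 for nt in RNA_ALPHABET})
    planted_motifs: tuple = ()
    seed: int = 1

    def __post_init__(self):
        lo, hi = self.length_range
        if lo < 5 or hi < lo:
            raise DataError("length_range must satisfy 5 <= lo <= hi")
        total = sum(self.background_freqs.get(nt, 0.0) for nt in RNA_ALPHABET)
        if abs(total - 1.0) > 1e-9:
            raise DataError("background_freqs must sum to 1 over A,C,G,U")
        for motif, region, p in self.planted_motifs:
            if region not in REGIONS:
                raise DataError(f"unknown region {region!r}; one of {REGIONS}")
            if any(c not in RNA_ALPHABET for c in motif):
                raise DataError(f"motif {motif!r} must be over A,C,G,U")
            if region in ("first5", "last5") and len(motif) > 5:
                raise DataError(f"motif {motif!r} longer than its 5-nt region")
            if len(motif) > lo:
                raise DataError(f"motif {motif!r} longer than shortest sequence")
            if not 0.0 <= p <= 1.0:
                raise DataError("insertion probability must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_per_class": self.n_per_class,
            "length_range": list(self.length_range),
            "background_freqs": dict(self.background_freqs),
            "planted_motifs": [list(m) for m in self.planted_motifs],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            n_per_class=d["n_per_class"],
            length_range=tuple(d["length_range"]),
            background_freqs=dict(d["background_freqs"]),
            planted_motifs=tuple(tuple(m) for m in d["planted_motifs"]),
            seed=d["seed"],
        )


def _plant(seq: list, motif: str, region: str, rng, occupied: list) -> None:
    """Write ``motif`` at a uniform in-region start over background letters.

    Starts that would overwrite an earlier planted motif are excluded, so
    every planted motif survives with exactly its insertion probability.
    """
    length = len(seq)
    if region == "first5":
        lo, hi = 0, min(5, length) - len(motif)
    elif region == "last5":
        lo, hi = max(0, length - 5), length - len(motif)
    else:
        lo, hi = 0, length - len(motif)
    starts = [
        s for s in range(lo, hi + 1)
        if all(s + len(motif) <= a or s >= b for a, b in occupied)
    ]
    if not starts:
        raise DataError(
            f"motif {motif!r} does not fit region {region!r} without "
            "overwriting an earlier planted motif")
    start = starts[int(rng.integers(len(starts)))]
    seq[start : start + len(motif)] = motif
    occupied.append((start, start + len(motif)))


def _draw(rng, config: GeneratorConfig, label: str, index: int,
          avoid_motifs=False) -> PiRNARecord:
    lo, hi = config.length_range
    alphabet = list(RNA_ALPHABET)
    probs = [config.background_freqs[nt] for nt in alphabet]
    while True:
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(alphabet, size=length, p=probs))
        if label == "selected":
            occupied: list = []
            for motif, region, p in config.planted_motifs:
                if rng.random() < p:
                    _plant(seq, motif, region, rng, occupied)
        s = "".join(seq)
        if avoid_motifs and any(m in s for m, _, _ in config.planted_motifs):
            continue  # separable preset: scrub chance motif hits from negatives
        prefix = "sel" if label == "selected" else "rnd"
        return PiRNARecord(f"{prefix}-{index + 1:04d}", s, label)


def generate(config: GeneratorConfig, scrub_negatives: bool = False
             ) -> list[PiRNARecord]:
    """Generate ``2 * n_per_class`` labeled records, positives first.

    With ``scrub_negatives`` the negative class is resampled until free of
    every planted motif, making the classes separable by construction.
    """
    rng = np.random.default_rng(config.seed)
    records = [_draw(rng, config, "selected", i)
               for i in range(config.n_per_class)]
    records += [_draw(rng, config, "random", i, avoid_motifs=scrub_negatives)
                for i in range(config.n_per_class)]
    return records


PRESETS = {
    # mirrors the 13-selected + 13-random training-set scale
    "paper_like": dict(
        config=GeneratorConfig(n_per_class=13,
                               planted_motifs=tuple(_PRESET_MOTIFS), seed=1),
        scrub_negatives=False),
    # deterministic motif presence/absence: insertion probability 1 and
    # motif-free negatives
    "separable": dict(
        config=GeneratorConfig(
            n_per_class=13,
            planted_motifs=tuple((m, r, 1.0) for m, r, _ in _PRESET_MOTIFS),
            seed=1),
        scrub_negatives=True),
    # no planted signal at all
    "null": dict(
        config=GeneratorConfig(n_per_class=13, planted_motifs=(), seed=1),
        scrub_negatives=False),
}


def preset_records(preset: str, seed: int | None = None) -> list[PiRNARecord]:
    """Records for a named preset, optionally re-seeded."""
    try:
        entry = PRESETS[preset]
    except KeyError:
        raise DataError(
            f"unknown preset {preset!r}; valid: {', '.join(sorted(PRESETS))}"
        ) from None
    config = entry["config"]
    if seed is not None:
        config = GeneratorConfig.from_dict({**config.to_dict(), "seed": seed})
    return generate(config, scrub_negatives=entry["scrub_negatives"])


def benchmark_dataset(preset: str, seed: int | None = None) -> pd.DataFrame:
    """Featurized benchmark table for a named preset
    (``paper_like`` | ``separable`` | ``null``)."""
    return featurize_all(preset_records(preset, seed), build_schema())
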