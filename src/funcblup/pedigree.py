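"""Pedigree container and validation.

A pedigree is an ordered list of (animal, sire, dam) records.  Unknown
parents are coded ``0`` (the conventional missing-parent code in animal
breeding files).  Records must be topologically ordered: every known
parent appears as an animal in an earlier record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN = "0"


class PedigreeError(ValueError):
    """Raised for unordered, cyclic or otherwise invalid pedigrees."""


@dataclass
class Pedigree:
    """Ordered animal/sire/dam triples.

    Parameters
    ----------
    records
        List of ``(animal_id, sire_id, dam_id)`` string triples in
        topological order; ``"0"`` marks an unknown parent.
    """

    records: list[tuple[str, str, str]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for i, (animal, sire, dam) in enumerate(self.records):
            if animal == UNKNOWN:
                raise PedigreeError(f"record {i}: animal id may not be '{UNKNOWN}'")
            if animal in self._index:
                raise PedigreeError(f"record {i}: duplicate animal id {animal!r}")
            for parent in (sire, dam):
                if parent == animal:
                    raise PedigreeError(f"record {i}: animal {animal!r} is its own parent")
                if parent != UNKNOWN and parent not in self._index:
                    raise PedigreeError(
                        f"record {i}: parent {parent!r} of animal {animal!r} "
                        "does not precede it (pedigree must be topologically ordered)"
                    )
            self._index[animal] = i

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) integer array of sire/dam row indices, -1 for unknown."""
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for i, (_, sire, dam) in enumerate(self.records):
            if sire != UNKNOWN:
                out[i, 0] = self._index[sire]
            if dam != UNKNOWN:
                out[i, 1] = self._index[dam]
        return out

    @property
    def founder_mask(self) -> np.ndarray:
        par = self.parent_indices()
        return (par[:, 0] < 0) & (par[:, 1] < 0)

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["animal", "sire", "dam"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        cols = [c.lower() for c in df.columns]
        if cols[:3] != ["animal", "sire", "dam"]:
            df.columns = ["animal", "sire", "dam"] + list(df.columns[3:])
        recs = [
            (str(a), str(s), str(d))
            for a, s, d in zip(df["animal"], df["sire"], df["dam"])
        ]
        return cls(recs)
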