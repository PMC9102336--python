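"""Per-bull trait records: deregressed proofs with EDC weights."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class TraitData:
    """DRP phenotypes of one trait with effective daughter contributions.

    The residual of bull *i* in the SNP mixed model has variance
    ``sigma2_e / edc[i]``; EDC must be strictly positive.
    """

    animal_ids: list[str]
    drp: np.ndarray
    edc: np.ndarray
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.drp = np.asarray(self.drp, dtype=float)
        self.edc = np.asarray(self.edc, dtype=float)
        if not (len(self.animal_ids) == len(self.drp) == len(self.edc)):
            raise ValueError("animal_ids, drp and edc lengths differ")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal records for one trait")
        if np.any(self.edc <= 0) or not np.all(np.isfinite(self.edc)):
            bad = [self.animal_ids[i] for i in np.flatnonzero(~(self.edc > 0))[:5]]
            raise ValueError(f"non-positive EDC for animals {bad}")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animal_ids, "trait": self.trait,
             "drp": self.drp, "edc": self.edc}
        )


def write_phenotypes_tsv(traits: list[TraitData], path: str | Path) -> None:
    pd.concat([t.to_frame() for t in traits]).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> dict[str, TraitData]:
    """Read a (animal, trait, drp, edc) TSV into one TraitData per trait."""
    df = pd.read_csv(path, sep="\t", dtype={"animal": str, "trait": str}, comment="#")
    out: dict[str, TraitData] = {}
    for name, grp in df.groupby("trait", sort=False):
        out[str(name)] = TraitData(
            list(grp["animal"]), grp["drp"].to_numpy(), grp["edc"].to_numpy(), str(name)
        )
    return out
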