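"""Core in-memory containers shared by every pipeline stage.

Coordinates are 1-based inclusive base pairs throughout; 1 Mb bins are
half-open ``[start, start + 1_000_000)``.  Genotypes are allele-dosage codes
counting the A1 allele (0, 1, 2) with ``-1`` for missing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass(frozen=True)
class Chromosome:
    chrom_id: str
    length_bp: int
    centromere_bp: int = 0
    acrocentric: bool = True

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"{self.chrom_id}: length_bp must be positive")
        if not (0 <= self.centromere_bp <= self.length_bp):
            raise ValidationError(
                f"{self.chrom_id}: centromere_bp {self.centromere_bp} outside "
                f"[0, {self.length_bp}]"
            )


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths and centromere positions.

    ``L_k = length_bp_k / total_length_bp`` are the squared-length weights of
    the intra-chromosomal shuffling statistic, so the physical lengths here are
    load-bearing, not cosmetic.
    """

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        ids = [c.chrom_id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate chromosome ids in genome spec")
        if not self.chromosomes:
            raise ValidationError("genome spec has no chromosomes")

    @property
    def chrom_ids(self) -> list[str]:
        return [c.chrom_id for c in self.chromosomes]

    @property
    def total_length_bp(self) -> int:
        return int(sum(c.length_bp for c in self.chromosomes))

    def __getitem__(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.chrom_id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def __contains__(self, chrom_id: str) -> bool:
        return any(c.chrom_id == chrom_id for c in self.chromosomes)

    def length_fractions(self) -> dict[str, float]:
        tot = self.total_length_bp
        return {c.chrom_id: c.length_bp / tot for c in self.chromosomes}


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered biallelic SNP panel.

    Markers are sorted by (chromosome, position); positions are unique within
    a chromosome.  ``a1``/``a2`` are the allele codes dosages count against.
    """

    marker_ids: tuple[str, ...]
    chrom_ids: tuple[str, ...]
    pos_bp: tuple[int, ...]
    a1: tuple[str, ...] = ()
    a2: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.marker_ids)
        if not (len(self.chrom_ids) == len(self.pos_bp) == n):
            raise ValidationError("marker panel columns have unequal lengths")
        if len(set(self.marker_ids)) != n:
            raise ValidationError("duplicate marker ids in panel")
        if not self.a1:
            object.__setattr__(self, "a1", tuple("A" for _ in range(n)))
        if not self.a2:
            object.__setattr__(self, "a2", tuple("B" for _ in range(n)))
        seen: dict[str, int] = {}
        for chrom, pos in zip(self.chrom_ids, self.pos_bp):
            if chrom in seen and pos <= seen[chrom]:
                raise ValidationError(
                    f"markers not sorted / positions not unique on {chrom}"
                )
            seen[chrom] = pos

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom_ids:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def indices_for(self, chrom_id: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chrom_ids) == chrom_id)

    def positions_for(self, chrom_id: str) -> np.ndarray:
        return np.asarray(self.pos_bp)[self.indices_for(chrom_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chrom": self.chrom_ids,
                "pos_bp": self.pos_bp,
                "a1": self.a1,
                "a2": self.a2,
            }
        )


def even_panel(genome: GenomeSpec, markers_per_chrom: int, prefix: str = "snp") -> MarkerPanel:
    """Evenly spaced panel with markers at both chromosome ends."""
    mids: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    for c in genome.chromosomes:
        if markers_per_chrom == 1:
            p = np.array([c.length_bp // 2])
        else:
            p = np.linspace(1, c.length_bp, markers_per_chrom).round().astype(int)
            p = np.unique(p)
        for i, bp in enumerate(p):
            mids.append(f"{prefix}_{c.chrom_id}_{i}")
            chroms.append(c.chrom_id)
            pos.append(int(bp))
    return MarkerPanel(tuple(mids), tuple(chroms), tuple(pos))


SEXES = ("male", "female", "unknown")


@dataclass
class Pedigree:
    """Pedigree rows (id, sire, dam, sex); missing parents are ``None``."""

    table: pd.DataFrame

    REQUIRED = ("id", "sire", "dam", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"pedigree missing columns: {missing}")
        t = self.table
        if t["id"].duplicated().any():
            raise ValidationError("duplicate individual ids in pedigree")
        bad = ~t["sex"].isin(SEXES)
        if bad.any():
            raise ValidationError(f"unknown sex codes: {sorted(t.loc[bad, 'sex'].unique())}")
        self._check_acyclic()
        sexes = dict(zip(t["id"], t["sex"]))
        for role, want in (("sire", "male"), ("dam", "female")):
            for parent in t[role].dropna():
                if sexes.get(parent, want) not in (want, "unknown"):
                    raise ValidationError(f"{role} {parent} has sex {sexes[parent]}")

    def _check_acyclic(self) -> None:
        parents = {
            row.id: [p for p in (row.sire, row.dam) if pd.notna(p)]
            for row in self.table.itertuples()
        }
        state: dict[str, int] = {}

        def visit(node: str, stack: list[str]) -> None:
            if state.get(node) == 2:
                return
            if state.get(node) == 1:
                raise ValidationError(f"pedigree cycle through {node}")
            state[node] = 1
            for p in parents.get(node, []):
                visit(p, stack + [node])
            state[node] = 2

        for ind in parents:
            visit(ind, [])

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def sex_of(self, ind: str) -> str:
        row = self.table.loc[self.table["id"] == ind]
        return str(row["sex"].iloc[0]) if len(row) else "unknown"


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix (int8; -1 missing)."""

    ids: list[str]
    panel: MarkerPanel
    dosages: np.ndarray  # (n_ind, n_markers) int8

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.ids), len(self.panel)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.panel)} markers"
            )
        valid = np.isin(self.dosages, (-1, 0, 1, 2))
        if not valid.all():
            raise ValidationError("dosages outside {-1, 0, 1, 2}")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate individual ids in genotype matrix")
        self._index = {ind: i for i, ind in enumerate(self.ids)}

    @property
    def call_rate(self) -> float:
        if self.dosages.size == 0:
            return 1.0
        return float((self.dosages >= 0).mean())

    def row(self, ind: str) -> np.ndarray:
        return self.dosages[self._index[ind]]

    def has(self, ind: str) -> bool:
        return ind in self._index

    def subset(self, inds: Sequence[str]) -> "GenotypeMatrix":
        rows = [self._index[i] for i in inds]
        return GenotypeMatrix(list(inds), self.panel, self.dosages[rows].copy())
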