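"""Chromatin contacts: the atom of the pipeline.

A *leg* is one end of a proximity-ligation contact — a (chromosome, bp
coordinate, haplotype) triple.  A *contact* joins two legs.  Haplotypes are
maternal (``MAT``), paternal (``PAT``) or unphased (``UNKNOWN``).

:class:`ContactSet` stores all contacts of one cell column-wise in numpy
arrays (chromosome index codes, bp positions, haplotype codes) so that the
voting and distance computations downstream are vectorizable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .genome import GenomeSpec

__all__ = ["Haplotype", "Leg", "Contact", "ContactSet", "MAT", "PAT", "UNKNOWN"]


class Haplotype(enum.IntEnum):
    MAT = 0
    PAT = 1
    UNKNOWN = -1

    @classmethod
    def from_symbol(cls, s: str) -> "Haplotype":
        try:
            return _SYMBOLS[s]
        except KeyError:
            raise ValueError(f"unknown haplotype symbol {s!r}") from None

    @property
    def symbol(self) -> str:
        return {MAT: "mat", PAT: "pat", UNKNOWN: "."}[self]


MAT = Haplotype.MAT
PAT = Haplotype.PAT
UNKNOWN = Haplotype.UNKNOWN
_SYMBOLS = {"mat": MAT, "pat": PAT, ".": UNKNOWN, "0": MAT, "1": PAT}


class Leg(NamedTuple):
    chrom: str
    pos: int
    hap: Haplotype = UNKNOWN


class Contact(NamedTuple):
    """A canonical contact: ``leg_a <= leg_b`` by (chromosome index, position)."""

    leg_a: Leg
    leg_b: Leg

    @property
    def is_intra(self) -> bool:
        return self.leg_a.chrom == self.leg_b.chrom

    @property
    def separation(self) -> int:
        if not self.is_intra:
            raise ValueError("separation undefined for interchromosomal contact")
        return abs(self.leg_b.pos - self.leg_a.pos)


STAGES = ("raw", "imputed", "cleaned")


@dataclass
class ContactSet:
    """Column-wise contact list of one cell.

    ``chrom_a``/``chrom_b`` are integer codes into ``genome.names``;
    ``hap_a``/``hap_b`` use :class:`Haplotype` values (-1 = unknown).
    Contacts are kept canonical: ``(chrom_a, pos_a) <= (chrom_b, pos_b)``,
    with haplotype as tie-break at identical positions.
    """

    genome: GenomeSpec
    chrom_a: np.ndarray
    pos_a: np.ndarray
    hap_a: np.ndarray
    chrom_b: np.ndarray
    pos_b: np.ndarray
    hap_b: np.ndarray
    cell_id: str = "cell"
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        n = len(self.chrom_a)
        for name in ("pos_a", "hap_a", "chrom_b", "pos_b", "hap_b"):
            if len(getattr(self, name)) != n:
                raise ValueError("ragged contact columns")
        for name in ("chrom_a", "pos_a", "hap_a", "chrom_b", "pos_b", "hap_b"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self._canonicalize()

    def _canonicalize(self) -> None:
        swap = (self.chrom_a > self.chrom_b) | (
            (self.chrom_a == self.chrom_b)
            & (
                (self.pos_a > self.pos_b)
                | ((self.pos_a == self.pos_b) & (self.hap_a > self.hap_b))
            )
        )
        for a, b in (("chrom_a", "chrom_b"), ("pos_a", "pos_b"), ("hap_a", "hap_b")):
            va, vb = getattr(self, a), getattr(self, b)
            va_new = np.where(swap, vb, va)
            vb_new = np.where(swap, va, vb)
            setattr(self, a, va_new)
            setattr(self, b, vb_new)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_contacts(
        cls,
        contacts: Iterable[Contact],
        genome: GenomeSpec,
        cell_id: str = "cell",
        stage: str = "raw",
    ) -> "ContactSet":
        rows = list(contacts)
        cols = {k: [] for k in ("ca", "pa", "ha", "cb", "pb", "hb")}
        for c in rows:
            for leg in (c.leg_a, c.leg_b):
                genome.validate_position(leg.chrom, leg.pos)
            cols["ca"].append(genome.index(c.leg_a.chrom))
            cols["pa"].append(c.leg_a.pos)
            cols["ha"].append(int(c.leg_a.hap))
            cols["cb"].append(genome.index(c.leg_b.chrom))
            cols["pb"].append(c.leg_b.pos)
            cols["hb"].append(int(c.leg_b.hap))
        return cls(
            genome,
            np.array(cols["ca"], dtype=np.int64),
            np.array(cols["pa"], dtype=np.int64),
            np.array(cols["ha"], dtype=np.int64),
            np.array(cols["cb"], dtype=np.int64),
            np.array(cols["pb"], dtype=np.int64),
            np.array(cols["hb"], dtype=np.int64),
            cell_id=cell_id,
            stage=stage,
        )

    @classmethod
    def empty(cls, genome: GenomeSpec, cell_id: str = "cell", stage: str = "raw"):
        z = np.empty(0, dtype=np.int64)
        return cls(genome, z, z, z, z, z, z, cell_id=cell_id, stage=stage)

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.chrom_a)

    def __getitem__(self, i: int) -> Contact:
        g = self.genome.names
        return Contact(
            Leg(g[self.chrom_a[i]], int(self.pos_a[i]), Haplotype(int(self.hap_a[i]))),
            Leg(g[self.chrom_b[i]], int(self.pos_b[i]), Haplotype(int(self.hap_b[i]))),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def select(self, mask: np.ndarray, stage: str | None = None) -> "ContactSet":
        return ContactSet(
            self.genome,
            self.chrom_a[mask],
            self.pos_a[mask],
            self.hap_a[mask],
            self.chrom_b[mask],
            self.pos_b[mask],
            self.hap_b[mask],
            cell_id=self.cell_id,
            stage=stage or self.stage,
        )

    def copy(self, stage: str | None = None) -> "ContactSet":
        return ContactSet(
            self.genome,
            self.chrom_a.copy(),
            self.pos_a.copy(),
            self.hap_a.copy(),
            self.chrom_b.copy(),
            self.pos_b.copy(),
            self.hap_b.copy(),
            cell_id=self.cell_id,
            stage=stage or self.stage,
        )

    def with_stage(self, stage: str) -> "ContactSet":
        order = {s: i for i, s in enumerate(STAGES)}
        if order[stage] < order[self.stage]:
            raise ValueError(f"stage may only advance ({self.stage} -> {stage})")
        out = self.copy()
        out.stage = stage
        return out

    # -- derived masks ----------------------------------------------------
    @property
    def is_intra(self) -> np.ndarray:
        return self.chrom_a == self.chrom_b

    @property
    def n_unknown_legs(self) -> int:
        return int((self.hap_a == UNKNOWN).sum() + (self.hap_b == UNKNOWN).sum())

    @property
    def fully_phased(self) -> np.ndarray:
        return (self.hap_a != UNKNOWN) & (self.hap_b != UNKNOWN)

    def interchrom_fraction(self) -> float:
        if len(self) == 0:
            return float("nan")
        return float((~self.is_intra).mean())
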