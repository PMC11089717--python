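"""Diploid particle models of the nucleus.

A :class:`Structure3D` holds one particle per (chromosome, haplotype, bin):
a bead-on-a-string polymer model where each bead covers ``resolution`` bp of
one parental chromosome copy.  Coordinates are in model units (the backbone
bond length is the natural unit); the nominal particle radius is carried as
metadata so neighborhood-based statistics can be expressed in particle radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import MAT, PAT, Haplotype
from .genome import GenomeSpec

__all__ = ["Structure3D"]


@dataclass
class Structure3D:
    """Particle cloud of one cell.

    ``chrom`` holds integer codes into ``genome.names``; ``hap`` is 0 (MAT) or
    1 (PAT); ``bin_start`` is the bp start of each particle's bin; ``coords``
    is an (N, 3) float array.
    """

    genome: GenomeSpec
    resolution: int
    chrom: np.ndarray
    hap: np.ndarray
    bin_start: np.ndarray
    coords: np.ndarray
    radius: float = 0.5
    cell_id: str = "cell"

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.hap = np.asarray(self.hap, dtype=np.int64)
        self.bin_start = np.asarray(self.bin_start, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chrom)
        if not (len(self.hap) == len(self.bin_start) == len(self.coords) == n):
            raise ValueError("ragged particle columns")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite particle coordinates")
        if np.any((self.hap != int(MAT)) & (self.hap != int(PAT))):
            raise ValueError("particle haplotype must be MAT or PAT")
        keys = self._key_array()
        if len(np.unique(keys)) != n:
            dup = self._first_duplicate()
            raise ValueError(f"duplicate particle key {dup}")
        self._index = {int(k): i for i, k in enumerate(keys)}

    def _key_array(self) -> np.ndarray:
        nbins = max(self.genome.lengths.values()) // self.resolution + 2
        return (self.chrom * 2 + self.hap) * nbins + self.bin_start // self.resolution

    def _first_duplicate(self):
        seen = set()
        for i in range(len(self.chrom)):
            k = (int(self.chrom[i]), int(self.hap[i]), int(self.bin_start[i]))
            if k in seen:
                name = self.genome.names[k[0]]
                return (name, Haplotype(k[1]).symbol, k[2])
            seen.add(k)

    def __len__(self) -> int:
        return len(self.chrom)

    def lookup(self, chrom: int | str, hap: int, bin_start: int) -> int | None:
        """Particle row index for (chromosome, haplotype, bin start), or None."""
        if isinstance(chrom, str):
            chrom = self.genome.index(chrom)
        nbins = max(self.genome.lengths.values()) // self.resolution + 2
        key = (chrom * 2 + hap) * nbins + bin_start // self.resolution
        return self._index.get(int(key))

    def chain_ids(self) -> np.ndarray:
        """Integer id of the chromosome *copy* (chromosome x haplotype)."""
        return self.chrom * 2 + self.hap

    def chains(self):
        """Yield (chrom_code, hap, row-index array sorted by bin) per copy."""
        ids = self.chain_ids()
        for cid in np.unique(ids):
            rows = np.flatnonzero(ids == cid)
            rows = rows[np.argsort(self.bin_start[rows])]
            yield int(cid) // 2, int(cid) % 2, rows

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure3D":
        """Apply a rigid motion (optionally improper, i.e. a reflection)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return Structure3D(
            self.genome, self.resolution, self.chrom.copy(), self.hap.copy(),
            self.bin_start.copy(), xyz, radius=self.radius, cell_id=self.cell_id,
        )

    def pairwise_distances(self) -> np.ndarray:
        from scipy.spatial.distance import pdist

        return pdist(self.coords)
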