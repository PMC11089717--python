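"""Genome coordinate conventions shared by every other module.

Coordinates are 0-based base pairs; bins are half-open ``[k*size, (k+1)*size)``.
A :class:`GenomeSpec` fixes the ordered chromosome universe so that contact
files, structures and tracks can be validated against a single reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["GenomeSpec", "CpGTrack", "bin_of"]


def bin_of(coordinate: int | np.ndarray, bin_size: int) -> int | np.ndarray:
    """Map a bp coordinate to its bin index (half-open bins).

    >>> bin_of(999_999, 1_000_000)
    0
    >>> bin_of(1_000_000, 1_000_000)
    1
    """
    if bin_size <= 0:
        raise ValueError(f"bin size must be positive, got {bin_size}")
    if np.any(np.asarray(coordinate) < 0):
        raise ValueError("coordinates must be non-negative")
    return np.floor_divide(coordinate, bin_size)


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names and lengths (bp).

    Parameters
    ----------
    names : ordered chromosome names, unique.
    lengths : mapping name -> length in bp (> 0).
    """

    names: tuple[str, ...]
    lengths: Mapping[str, int]

    def __post_init__(self):
        names = tuple(self.names)
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if not names:
            raise ValueError("genome must contain at least one chromosome")
        for name in names:
            if name not in self.lengths:
                raise ValueError(f"missing length for chromosome {name!r}")
            if self.lengths[name] <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "lengths", dict(self.lengths))
        object.__setattr__(
            self, "_index", {name: i for i, name in enumerate(names)}
        )

    @classmethod
    def uniform(cls, n_chrom: int, length: int, prefix: str = "chr") -> "GenomeSpec":
        names = tuple(f"{prefix}{i + 1}" for i in range(n_chrom))
        return cls(names, {n: length for n in names})

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in genome spec") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def length_of(self, name: str) -> int:
        return self.lengths[name]

    def n_bins(self, name: str, bin_size: int) -> int:
        return int(-(-self.lengths[name] // bin_size))

    def total_bins(self, bin_size: int) -> int:
        return sum(self.n_bins(n, bin_size) for n in self.names)

    def validate_position(self, name: str, pos: int) -> None:
        if name not in self:
            raise KeyError(f"chromosome {name!r} not in genome spec")
        if not (0 <= pos < self.lengths[name]):
            raise ValueError(
                f"coordinate {pos} outside [0, {self.lengths[name]}) on {name}"
            )


@dataclass
class CpGTrack:
    """Per-bin CpG frequency along the genome (one bin size genome-wide).

    ``values[chrom]`` is a float array of length ``genome.n_bins(chrom, bin_size)``
    with non-negative entries.  CpG frequency is the field's standard proxy for
    euchromatin: CpG-rich bins are gene-dense and open, CpG-poor bins are
    heterochromatic.
    """

    genome: GenomeSpec
    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        for chrom in self.genome.names:
            if chrom not in self.values:
                raise ValueError(f"CpG track missing chromosome {chrom!r}")
            arr = np.asarray(self.values[chrom], dtype=float)
            n = self.genome.n_bins(chrom, self.bin_size)
            if arr.shape != (n,):
                raise ValueError(
                    f"{chrom}: expected {n} bins, got shape {arr.shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative CpG frequency")
            self.values[chrom] = arr

    def at(self, chrom: str, pos: int | np.ndarray) -> float | np.ndarray:
        """CpG frequency of the bin containing ``pos``."""
        idx = bin_of(pos, self.bin_size)
        return self.values[chrom][idx]

    def at_bin(self, chrom: str, bin_index: int | np.ndarray):
        return self.values[chrom][bin_index]

    def rebinned(self, bin_size: int) -> "CpGTrack":
        """Average into coarser bins (``bin_size`` a multiple of the current)."""
        if bin_size == self.bin_size:
            return self
        if bin_size % self.bin_size:
            raise ValueError("target bin size must be a multiple of current")
        k = bin_size // self.bin_size
        out = {}
        for chrom, arr in self.values.items():
            n_out = self.genome.n_bins(chrom, bin_size)
            pad = n_out * k - arr.size
            padded = np.concatenate([arr, np.full(pad, np.nan)]) if pad else arr
            with np.errstate(invalid="ignore"):
                out[chrom] = np.nanmean(padded.reshape(n_out, k), axis=1)
        return CpGTrack(self.genome, bin_size, out)

    @property
    def min(self) -> float:
        return min(float(v.min()) for v in self.values.values() if v.size)

    @property
    def max(self) -> float:
        return max(float(v.max()) for v in self.values.values() if v.size)

    def flat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.genome.names])
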