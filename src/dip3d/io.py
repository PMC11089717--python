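"""On-disk formats: contact lists, 3DG structures, bedGraph tracks, BED loci.

Dialects
--------
contacts : whitespace-delimited, 6 columns per line:
    ``chromA posA hapA chromB posB hapB`` with haplotype ``mat``/``pat``/``.``.
3DG : tab-delimited 5 columns: chromosome name with the haplotype encoded as
    a ``(mat)``/``(pat)`` suffix, bp coordinate of the bin start, x, y, z.
CpG track : bedGraph (``chrom start end value``), fixed bin size genome-wide.
loci : BED4 (``chrom start end name``), 0-based half-open.
"""

from __future__ import annotations

import os
import numpy as np
import pandas as pd

from .contacts import MAT, PAT, UNKNOWN, ContactSet, Haplotype
from .genome import CpGTrack, GenomeSpec
from .structure import Structure3D

__all__ = [
    "read_contacts", "write_contacts",
    "read_3dg", "write_3dg",
    "read_cpg_bedgraph", "write_cpg_bedgraph",
    "read_loci_bed",
]

_HAP_SUFFIX = {int(MAT): "(mat)", int(PAT): "(pat)"}


class ParseError(ValueError):
    """Malformed line in an on-disk file; carries the 1-based line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------- contacts
def read_contacts(path, genome: GenomeSpec, cell_id: str | None = None) -> ContactSet:
    """Read a contact list; contacts are canonicalized on load."""
    ca, pa, ha, cb, pb, hb = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(path, lineno, f"expected 6 fields, got {len(fields)}")
            try:
                for chrom, pos, hap, cs, ps, hs in (
                    (fields[0], fields[1], fields[2], ca, pa, ha),
                    (fields[3], fields[4], fields[5], cb, pb, hb),
                ):
                    position = int(pos)
                    genome.validate_position(chrom, position)
                    cs.append(genome.index(chrom))
                    ps.append(position)
                    hs.append(int(Haplotype.from_symbol(hap)))
            except (ValueError, KeyError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return ContactSet(
        genome,
        np.array(ca, dtype=np.int64), np.array(pa, dtype=np.int64),
        np.array(ha, dtype=np.int64), np.array(cb, dtype=np.int64),
        np.array(pb, dtype=np.int64), np.array(hb, dtype=np.int64),
        cell_id=cell_id or os.path.splitext(os.path.basename(path))[0],
        stage="raw",
    )


def write_contacts(contacts: ContactSet, path) -> None:
    names = contacts.genome.names
    with open(path, "w") as fh:
        for i in range(len(contacts)):
            fh.write(
                f"{names[contacts.chrom_a[i]]}\t{contacts.pos_a[i]}\t"
                f"{Haplotype(int(contacts.hap_a[i])).symbol}\t"
                f"{names[contacts.chrom_b[i]]}\t{contacts.pos_b[i]}\t"
                f"{Haplotype(int(contacts.hap_b[i])).symbol}\n"
            )


# ---------------------------------------------------------------- 3DG
def write_3dg(structure: Structure3D, path) -> None:
    """Write tab-delimited ``chrom(hap)  bp  x  y  z`` rows."""
    names = structure.genome.names
    with open(path, "w") as fh:
        for i in range(len(structure)):
            chrom = names[structure.chrom[i]] + _HAP_SUFFIX[int(structure.hap[i])]
            x, y, z = structure.coords[i]
            fh.write(f"{chrom}\t{structure.bin_start[i]}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_3dg(path, genome: GenomeSpec, resolution: int,
             radius: float = 0.5, cell_id: str | None = None) -> Structure3D:
    chroms, haps, starts, coords = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(path, lineno, f"expected 5 fields, got {len(fields)}")
            name = fields[0]
            if name.endswith("(mat)"):
                hap, name = int(MAT), name[:-5]
            elif name.endswith("(pat)"):
                hap, name = int(PAT), name[:-5]
            else:
                raise ParseError(path, lineno, f"missing haplotype suffix in {name!r}")
            if name not in genome:
                raise ParseError(path, lineno, f"chromosome {name!r} not in genome spec")
            try:
                start = int(fields[1])
                xyz = [float(v) for v in fields[2:5]]
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            chroms.append(genome.index(name))
            haps.append(hap)
            starts.append(start)
            coords.append(xyz)
    return Structure3D(
        genome, resolution,
        np.array(chroms, dtype=np.int64), np.array(haps, dtype=np.int64),
        np.array(starts, dtype=np.int64), np.array(coords, dtype=float),
        radius=radius,
        cell_id=cell_id or os.path.splitext(os.path.basename(path))[0],
    )


# ---------------------------------------------------------------- tracks / loci
def write_cpg_bedgraph(track: CpGTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            vals = track.values[chrom]
            length = track.genome.length_of(chrom)
            for k, v in enumerate(vals):
                start = k * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def read_cpg_bedgraph(path, genome: GenomeSpec, bin_size: int) -> CpGTrack:
    values = {
        chrom: np.zeros(genome.n_bins(chrom, bin_size)) for chrom in genome.names
    }
    seen = {chrom: np.zeros(genome.n_bins(chrom, bin_size), bool) for chrom in genome.names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(path, lineno, f"expected 4 fields, got {len(fields)}")
            chrom, start, end, value = fields
            if chrom not in genome:
                raise ParseError(path, lineno, f"chromosome {chrom!r} not in genome spec")
            try:
                start, value = int(start), float(value)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            if start % bin_size:
                raise ParseError(path, lineno, f"interval not aligned to {bin_size}-bp bins")
            k = start // bin_size
            values[chrom][k] = value
            seen[chrom][k] = True
    for chrom in genome.names:
        if not seen[chrom].all():
            missing = int((~seen[chrom]).sum())
            raise ValueError(f"{path}: {missing} bins missing on {chrom}")
    return CpGTrack(genome, bin_size, values)


def read_loci_bed(path, genome: GenomeSpec) -> pd.DataFrame:
    """BED4 loci as a DataFrame with columns chrom/start/end/name."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected >= 4 fields, got {len(fields)}")
            chrom, start, end, name = fields[:4]
            if chrom not in genome:
                raise ParseError(path, lineno, f"chromosome {chrom!r} not in genome spec")
            start, end = int(start), int(end)
            if not (0 <= start <= end <= genome.length_of(chrom)):
                raise ParseError(path, lineno, "locus outside chromosome bounds")
            rows.append((chrom, start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
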