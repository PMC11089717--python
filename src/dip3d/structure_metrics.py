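"""Structure-derived nuclear-architecture statistics.

All metrics operate on a :class:`~dip3d.structure.Structure3D` and are
invariant to rigid motions (and reflection) of the coordinates: distances are
measured to the cell's own center of mass and neighborhoods with a KD-tree.

The central quantities:

* **intermingling index** — per particle, the fraction of spatial neighbors
  that belong to a different chromosome; the cell mean quantifies how much
  chromosome territories mix.
* **compartmentalization score** — Spearman correlation between each
  particle's own CpG frequency and the mean CpG of its spatial neighbors;
  high when euchromatin and heterochromatin are spatially sorted.
* **radial CpG statistics** — shell profiles and the per-1-Mb-bin correlation
  between normalized radial position and CpG frequency, whose sign separates
  "inside-out" (positive, primed-like) from "out-inside" (negative,
  naive-like) nuclear architectures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr, spearmanr

from .genome import CpGTrack, bin_of
from .structure import Structure3D

__all__ = [
    "NeighborContext", "RadialProfile",
    "intermingling_index", "compartment_score", "radial_positions",
    "radial_cpg_profile", "radial_cpg_correlation", "locus_radial_position",
    "cross_sections",
]


@dataclass(frozen=True)
class NeighborContext:
    """Spatial neighborhood definition: radius in multiples of the particle
    radius (the "nearby particles" of the intermingling/compartment scores).
    Maternal and paternal copies of the same chromosome count as the *same*
    chromosome by default (territory mixing is between chromosomes);
    set ``homologs_foreign=True`` to count them as foreign."""

    radius_particle_units: float = 3.0
    homologs_foreign: bool = False

    def radius(self, structure: Structure3D) -> float:
        if self.radius_particle_units <= 0:
            raise ValueError("neighbor radius must be positive")
        return self.radius_particle_units * structure.radius


def _neighbor_lists(structure: Structure3D, radius: float):
    tree = cKDTree(structure.coords)
    return tree.query_ball_point(structure.coords, radius)


def intermingling_index(
    structure: Structure3D, context: NeighborContext = NeighborContext()
) -> tuple[np.ndarray, float]:
    """Per-particle fraction of nearby particles from a different chromosome.

    Returns (per-particle values with NaN where a particle has no neighbors,
    cell mean over particles that do have neighbors).
    """
    radius = context.radius(structure)
    group = structure.chain_ids() if context.homologs_foreign else structure.chrom
    neighbors = _neighbor_lists(structure, radius)
    values = np.full(len(structure), np.nan)
    for i, nb in enumerate(neighbors):
        nb = [j for j in nb if j != i]
        if not nb:
            continue
        values[i] = np.mean(group[np.asarray(nb)] != group[i])
    mean = float(np.nanmean(values)) if np.any(np.isfinite(values)) else float("nan")
    return values, mean


def _cpg_per_particle(structure: Structure3D, cpg: CpGTrack) -> np.ndarray:
    out = np.empty(len(structure))
    names = structure.genome.names
    for ci in np.unique(structure.chrom):
        mask = structure.chrom == ci
        idx = bin_of(structure.bin_start[mask], cpg.bin_size)
        vals = cpg.values[names[ci]]
        if np.any(idx >= len(vals)):
            raise ValueError(
                f"CpG track missing bins on {names[ci]} "
                f"(needs up to bin {int(idx.max())}, has {len(vals)})"
            )
        out[mask] = vals[idx]
    return out


def compartment_score(
    structure: Structure3D, cpg: CpGTrack,
    context: NeighborContext = NeighborContext(),
) -> tuple[float, bool]:
    """Spearman correlation between own CpG and mean neighbor CpG.

    Returns (score, degenerate flag).  Constant inputs give (0.0, True).
    """
    radius = context.radius(structure)
    c = _cpg_per_particle(structure, cpg)
    neighbors = _neighbor_lists(structure, radius)
    own, nb_mean = [], []
    for i, nb in enumerate(neighbors):
        nb = [j for j in nb if j != i]
        if not nb:
            continue
        own.append(c[i])
        nb_mean.append(c[np.asarray(nb)].mean())
    if len(own) < 10:
        raise ValueError("fewer than 10 particles with neighbors")
    own = np.asarray(own)
    nb_mean = np.asarray(nb_mean)
    if own.std() == 0 or nb_mean.std() == 0:
        return 0.0, True
    return float(spearmanr(own, nb_mean).statistic), False


def radial_positions(structure: Structure3D) -> np.ndarray:
    """Distance of each particle to the cell's center of mass, normalized by
    the cell mean distance (output mean is exactly 1)."""
    if len(structure) == 0:
        raise ValueError("empty structure")
    r = np.linalg.norm(structure.coords - structure.coords.mean(axis=0), axis=1)
    mean = r.mean()
    if mean == 0:
        return np.ones_like(r)
    return r / mean


@dataclass
class RadialProfile:
    """Mean CpG per concentric shell of normalized radius, per cell and
    cohort-averaged (unweighted mean over cells)."""

    shell_edges: np.ndarray
    per_cell: pd.DataFrame       # rows cells, columns shells, NaN where empty
    cohort_mean: np.ndarray
    counts: pd.DataFrame


def radial_cpg_profile(
    structures: Sequence[Structure3D], cpg: CpGTrack, n_shells: int = 20
) -> RadialProfile:
    if n_shells < 2:
        raise ValueError("need at least 2 shells")
    if not structures:
        raise ValueError("need at least one structure")
    rmax = max(radial_positions(s).max() for s in structures)
    edges = np.linspace(0.0, rmax * (1 + 1e-12), n_shells + 1)
    rows, cnts, ids = [], [], []
    for s in structures:
        r = radial_positions(s)
        c = _cpg_per_particle(s, cpg)
        which = np.clip(np.digitize(r, edges) - 1, 0, n_shells - 1)
        mean = np.full(n_shells, np.nan)
        count = np.zeros(n_shells, dtype=int)
        for k in range(n_shells):
            m = which == k
            count[k] = m.sum()
            if count[k]:
                mean[k] = c[m].mean()
        rows.append(mean)
        cnts.append(count)
        ids.append(s.cell_id)
    per_cell = pd.DataFrame(rows, index=ids)
    counts = pd.DataFrame(cnts, index=ids)
    return RadialProfile(edges, per_cell, per_cell.mean(axis=0).to_numpy(), counts)


def radial_cpg_correlation(
    structure: Structure3D, cpg: CpGTrack, bin_size: int = 1_000_000,
    method: str = "spearman",
) -> tuple[float, pd.DataFrame]:
    """Correlation between per-bin mean normalized radius and per-bin CpG.

    Haplotypes are pooled: both copies' particles of a genomic bin contribute
    to that bin's mean radial position.  Positive = "inside-out" (CpG-rich
    chromatin peripheral, primed-like); negative = "out-inside" (naive-like).
    """
    if bin_size % structure.resolution:
        raise ValueError("analysis bin size must be a multiple of the resolution")
    r = radial_positions(structure)
    track = cpg if cpg.bin_size == bin_size else cpg.rebinned(bin_size)
    names = structure.genome.names
    key = structure.chrom * (2**33) + bin_of(structure.bin_start, bin_size)
    order = np.argsort(key, kind="stable")
    uniq, starts = np.unique(key[order], return_index=True)
    rows = []
    for u, lo, hi in zip(uniq, starts, np.append(starts[1:], len(key))):
        ci = int(u // 2**33)
        b = int(u % 2**33)
        rows.append(
            (names[ci], b, float(r[order[lo:hi]].mean()),
             float(track.values[names[ci]][b]), hi - lo)
        )
    table = pd.DataFrame(rows, columns=["chrom", "bin", "mean_radius", "cpg", "n_particles"])
    if len(table) < 5:
        raise ValueError("fewer than 5 analysis bins")
    if method == "spearman":
        rho = spearmanr(table["mean_radius"], table["cpg"]).statistic
    elif method == "pearson":
        rho = pearsonr(table["mean_radius"], table["cpg"]).statistic
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(rho), table


def locus_radial_position(
    structure: Structure3D, loci: pd.DataFrame
) -> pd.DataFrame:
    """Normalized radial position of BED loci, per homolog and pooled.

    A locus maps to the particles whose bins it overlaps (for a zero-length
    locus, the bin containing its coordinate).  Loci falling in a particle
    gap get NaN.
    """
    r = radial_positions(structure)
    res = structure.resolution
    out = []
    for row in loci.itertuples(index=False):
        ci = structure.genome.index(row.chrom)
        lo = bin_of(row.start, res)
        hi = bin_of(max(row.start, row.end - 1), res)
        sel = (
            (structure.chrom == ci)
            & (structure.bin_start >= lo * res)
            & (structure.bin_start <= hi * res)
        )
        vals = {"mat": np.nan, "pat": np.nan}
        for hap, label in ((0, "mat"), (1, "pat")):
            m = sel & (structure.hap == hap)
            if m.any():
                vals[label] = float(r[m].mean())
        pooled = float(r[sel].mean()) if sel.any() else np.nan
        out.append((row.name, row.chrom, row.start, row.end,
                    vals["mat"], vals["pat"], pooled))
    return pd.DataFrame(
        out, columns=["name", "chrom", "start", "end", "radius_mat", "radius_pat", "radius"]
    )


def cross_sections(
    structure: Structure3D, cpg: CpGTrack | None = None,
    spacing_particle_radii: float = 7.5, axis: int = 2,
) -> pd.DataFrame:
    """Partition particles into parallel serial sections along an axis.

    Default spacing 7.5 particle radii.  Returns one row per particle with
    its slab index (slabs are disjoint and cover all particles) and, when a
    CpG track is given, the particle's CpG frequency for coloring.
    """
    if spacing_particle_radii <= 0:
        raise ValueError("slab spacing must be positive")
    spacing = spacing_particle_radii * structure.radius
    z = structure.coords[:, axis]
    slab = np.floor((z - z.min()) / spacing).astype(int)
    df = pd.DataFrame(
        {
            "slab": slab,
            "chrom": [structure.genome.names[c] for c in structure.chrom],
            "hap": structure.hap,
            "bin_start": structure.bin_start,
            "x": structure.coords[:, 0],
            "y": structure.coords[:, 1],
            "z": structure.coords[:, 2],
        }
    )
    if cpg is not None:
        df["cpg"] = _cpg_per_particle(structure, cpg)
    return df
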