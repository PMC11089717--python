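"""Contact-space analyses that need no 3D model.

These statistics work directly on single-cell contact lists, ruling out
artifacts of the modeling step:

* **contacting CpG** — the single-cell chromatin-compartment proxy: each
  1-Mb bin is scored by the contact-weighted mean CpG frequency of the
  *other* bins it touches.  Euchromatic bins contact euchromatic partners,
  so this recovers compartment structure from one cell, with the two
  alleles of each locus kept as separate loci in diploid mode.
* **PCA + 2-means clustering** of the per-cell contacting-CpG vectors —
  unsupervised cell-type separation without bulk data.
* **interchromosomal statistics** — fraction of contacts joining different
  chromosomes (the contact-space intermingling measure) and the
  chromosome-pair contact matrix.
* **binned contact heatmaps** with a depth-normalized differential view.
* **A/B compartments** on pooled contacts by the classic eigenvector
  method: observed/expected normalization by diagonal means, Pearson
  correlation matrix, leading eigenvector, sign oriented so A (positive)
  is the CpG-rich compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .contacts import UNKNOWN, ContactSet
from .genome import CpGTrack, GenomeSpec, bin_of

__all__ = [
    "CompartmentVector", "ContactMatrix", "PCAReport", "ABResult",
    "contacting_cpg", "compartment_pca", "interchrom_stats",
    "contact_heatmap", "differential_heatmap", "ab_compartments",
]


# ------------------------------------------------------------ contacting CpG
@dataclass
class CompartmentVector:
    """Per-bin contacting-CpG values of one cell.

    ``values`` is indexed by (chrom, hap, bin) in diploid mode (hap -1 rows
    in cell-type mode, where alleles are pooled); bins a cell never observes
    are absent (missing).
    """

    cell_id: str
    bin_size: int
    mode: str
    values: pd.Series


def contacting_cpg(
    cell: ContactSet,
    cpg: CpGTrack,
    bin_size: int = 1_000_000,
    mode: str = "diploid",
    drop_half_phased: bool = False,
) -> CompartmentVector:
    """Contact-weighted mean CpG of each bin's partners, excluding self.

    ``mode="diploid"``: haplotype-resolved legs only, alleles separate.
    ``mode="celltype"``: all contacts, alleles pooled.  A partner's CpG is
    its genomic bin's track value; a partner in the *same* genomic bin is
    excluded ("excluding self").  In diploid mode a contact with one unknown
    leg contributes through its known leg only (or is dropped entirely with
    ``drop_half_phased``).
    """
    if mode not in ("diploid", "celltype"):
        raise ValueError("mode must be 'diploid' or 'celltype'")
    track = cpg if cpg.bin_size == bin_size else cpg.rebinned(bin_size)
    genome = cell.genome

    ca, cb = cell.chrom_a, cell.chrom_b
    ba = np.asarray(bin_of(cell.pos_a, bin_size))
    bb = np.asarray(bin_of(cell.pos_b, bin_size))
    ha, hb = cell.hap_a, cell.hap_b
    self_bin = (ca == cb) & (ba == bb)

    cpg_a = np.array([track.values[genome.names[c]][b] for c, b in zip(ca, ba)])
    cpg_b = np.array([track.values[genome.names[c]][b] for c, b in zip(cb, bb)])

    acc: dict[tuple, list] = {}

    def add(chrom, hap, b, partner_cpg, ok):
        for c, h, k, v, m in zip(chrom, hap, b, partner_cpg, ok):
            if not m:
                continue
            key = (genome.names[c], int(h), int(k))
            s = acc.setdefault(key, [0.0, 0])
            s[0] += v
            s[1] += 1

    if mode == "diploid":
        known_a = ha != UNKNOWN
        known_b = hb != UNKNOWN
        if drop_half_phased:
            known_a = known_b = known_a & known_b
        add(ca, ha, ba, cpg_b, known_a & ~self_bin)
        add(cb, hb, bb, cpg_a, known_b & ~self_bin)
    else:
        pooled = np.full(len(ca), -1)
        add(ca, pooled, ba, cpg_b, ~self_bin)
        add(cb, pooled, bb, cpg_a, ~self_bin)

    if acc:
        index = pd.MultiIndex.from_tuples(sorted(acc), names=["chrom", "hap", "bin"])
        vals = [acc[k][0] / acc[k][1] for k in sorted(acc)]
    else:
        index = pd.MultiIndex.from_tuples([], names=["chrom", "hap", "bin"])
        vals = []
    return CompartmentVector(cell.cell_id, bin_size, mode, pd.Series(vals, index=index))


# ------------------------------------------------------------ PCA clustering
@dataclass
class PCAReport:
    cell_ids: list[str]
    embedding: np.ndarray
    explained_variance_ratio: np.ndarray
    labels: np.ndarray
    agreement: float | None = None
    n_features: int = 0


def compartment_pca(
    vectors: Sequence[CompartmentVector],
    n_components: int = 2,
    seed: int = 0,
    true_labels: Sequence | None = None,
    missing: str = "drop",
) -> PCAReport:
    """Project cells on principal components of their compartment vectors
    and split them with seeded 2-means.

    Bins missing in any cell are dropped (default) or mean-imputed.  When a
    cohort manifest is supplied, ``agreement`` is the best label-permutation
    match between the 2-means labels and the manifest.
    """
    if len(vectors) < 4:
        raise ValueError("need at least 4 cells")
    frame = pd.DataFrame({v.cell_id: v.values for v in vectors}).T
    if missing == "drop":
        frame = frame.dropna(axis=1)
    elif missing == "mean":
        frame = frame.fillna(frame.mean(axis=0))
    else:
        raise ValueError("missing must be 'drop' or 'mean'")
    if frame.shape[1] < len(vectors):
        raise ValueError(
            f"only {frame.shape[1]} complete bins for {len(vectors)} cells"
        )
    x = frame.to_numpy()
    n_components = min(n_components, len(vectors) - 1, x.shape[1])
    pca = PCA(n_components=n_components, random_state=seed)
    emb = pca.fit_transform(x)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(emb)
    labels = km.labels_
    agreement = None
    if true_labels is not None:
        t = pd.factorize(np.asarray(true_labels))[0]
        match = max(np.mean(labels == t), np.mean(labels == 1 - t))
        agreement = float(match)
    return PCAReport(
        list(frame.index), emb, pca.explained_variance_ratio_, labels,
        agreement, frame.shape[1],
    )


# ------------------------------------------------------------ interchromosomal
def interchrom_stats(cell: ContactSet) -> tuple[float, pd.DataFrame]:
    """Fraction of interchromosomal contacts and the chromosome-pair count
    matrix (haplotype-pooled, symmetric)."""
    names = cell.genome.names
    n = len(names)
    matrix = np.zeros((n, n), dtype=np.int64)
    if len(cell):
        np.add.at(matrix, (cell.chrom_a, cell.chrom_b), 1)
        matrix = matrix + matrix.T - np.diag(np.diag(matrix))
    frac = cell.interchrom_fraction()
    return frac, pd.DataFrame(matrix, index=names, columns=names)


# ------------------------------------------------------------ heatmaps
@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix over the concatenated genome."""

    genome: GenomeSpec
    bin_size: int
    matrix: np.ndarray
    normalization: str = "raw"

    def bin_labels(self) -> list[tuple[str, int]]:
        out = []
        for chrom in self.genome.names:
            out.extend((chrom, k) for k in range(self.genome.n_bins(chrom, self.bin_size)))
        return out


def _genome_offsets(genome: GenomeSpec, bin_size: int) -> dict[str, int]:
    offsets, total = {}, 0
    for chrom in genome.names:
        offsets[chrom] = total
        total += genome.n_bins(chrom, bin_size)
    return offsets


def contact_heatmap(
    cells: Sequence[ContactSet], bin_size: int = 100_000
) -> ContactMatrix:
    """Pooled binned contact counts (symmetric; diagonal counts once)."""
    if not cells:
        raise ValueError("no cells given")
    genome = cells[0].genome
    offsets = _genome_offsets(genome, bin_size)
    n = genome.total_bins(bin_size)
    m = np.zeros((n, n))
    off = np.array([offsets[c] for c in genome.names])
    for cell in cells:
        if cell.genome.names != genome.names:
            raise ValueError("incompatible genomes across cells")
        i = off[cell.chrom_a] + np.asarray(bin_of(cell.pos_a, bin_size))
        j = off[cell.chrom_b] + np.asarray(bin_of(cell.pos_b, bin_size))
        np.add.at(m, (i, j), 1.0)
    m = m + m.T - np.diag(np.diag(m))
    return ContactMatrix(genome, bin_size, m, "raw")


def differential_heatmap(
    a: ContactMatrix, b: ContactMatrix, epsilon: float = 1.0,
    scale_total: float = 1e6,
) -> np.ndarray:
    """log2 ratio of two cohort maps after depth normalization.

    Each matrix is scaled to a *fixed* total (counts per ``scale_total``), so
    sequencing depth cancels exactly, then ``log2((A + eps) / (B + eps))``
    with a pseudo-count of one scaled unit for stability at sparse bins.
    """
    if a.bin_size != b.bin_size or a.genome.names != b.genome.names:
        raise ValueError("incompatible contact matrices")
    ta, tb = a.matrix.sum(), b.matrix.sum()
    if ta == 0 or tb == 0:
        raise ValueError("empty contact matrix")
    ma = a.matrix * (scale_total / ta)
    mb = b.matrix * (scale_total / tb)
    return np.log2((ma + epsilon) / (mb + epsilon))


# ------------------------------------------------------------ A/B compartments
@dataclass
class ABResult:
    """Per-chromosome compartment call from pooled contacts."""

    chrom: str
    eigenvector: np.ndarray          # NaN at masked bins
    labels: np.ndarray               # +1 A, -1 B, 0 masked
    explained_variance: float
    weak_signal: bool


def ab_compartments(
    pooled: ContactSet,
    cpg: CpGTrack,
    bin_size: int = 1_000_000,
    min_bins: int = 20,
    weak_variance: float = 0.20,
) -> dict[str, ABResult]:
    """Eigenvector A/B compartments per chromosome.

    Intrachromosomal contacts are binned, normalized to observed/expected by
    the mean count at each diagonal offset, turned into a Pearson
    correlation matrix, and the leading eigenvector is extracted; its sign
    is oriented so that positive values correlate positively with CpG
    ("A" = CpG-rich/open).  Bins with no coverage are masked.  The result is
    invariant to scaling the contact counts by any positive factor.
    """
    genome = pooled.genome
    track = cpg if cpg.bin_size == bin_size else cpg.rebinned(bin_size)
    out: dict[str, ABResult] = {}
    intra = pooled.is_intra
    for ci, chrom in enumerate(genome.names):
        n = genome.n_bins(chrom, bin_size)
        if n < min_bins:
            raise ValueError(f"{chrom}: {n} bins < required {min_bins}")
        rows = np.flatnonzero(intra & (pooled.chrom_a == ci))
        m = np.zeros((n, n))
        if len(rows):
            i = np.asarray(bin_of(pooled.pos_a[rows], bin_size))
            j = np.asarray(bin_of(pooled.pos_b[rows], bin_size))
            np.add.at(m, (i, j), 1.0)
            m = m + m.T - np.diag(np.diag(m))
        covered = m.sum(axis=1) > 0
        if covered.sum() < 3:
            raise ValueError(f"{chrom}: contact matrix has (near-)zero rank")
        sub = m[np.ix_(covered, covered)]
        # observed / expected by diagonal means
        k = covered.sum()
        idx = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        expected = np.array([sub.diagonal(d).mean() for d in range(k)])
        expected[expected == 0] = np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = sub / expected[idx]
        oe[~np.isfinite(oe)] = 0.0
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(oe)
        corr[~np.isfinite(corr)] = 0.0
        evals, evecs = np.linalg.eigh(corr)
        lead = evecs[:, -1]
        ev_share = float(evals[-1] / np.trace(corr)) if np.trace(corr) > 0 else 0.0
        cvals = track.values[chrom][covered]
        orient = np.corrcoef(lead, cvals)[0, 1] if np.std(cvals) > 0 else 1.0
        if np.isfinite(orient) and orient < 0:
            lead = -lead
        vec = np.full(n, np.nan)
        vec[covered] = lead
        labels = np.zeros(n, dtype=int)
        labels[covered] = np.where(lead >= 0, 1, -1)
        out[chrom] = ABResult(chrom, vec, labels, ev_share, ev_share < weak_variance)
    return out
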