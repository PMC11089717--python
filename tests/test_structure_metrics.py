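"""Structure-derived statistics: values on constructed geometries and
invariance under rigid motions."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import ortho_group

from dip3d import (
    CpGTrack, GenomeSpec, NeighborContext, Structure3D, compartment_score,
    cross_sections, intermingling_index, locus_radial_position,
    radial_cpg_correlation, radial_cpg_profile, radial_positions,
    simulate_structure,
)
from dip3d.simulate import NAIVE_LIKE, PRIMED_LIKE
import pandas as pd


def lattice_structure(genome, n_per_chrom=27, spacing=1.0):
    """Two chromosomes' particles interleaved on a dense cubic lattice."""
    side = round((2 * n_per_chrom) ** (1 / 3))
    pts = np.array(
        [(x, y, z) for x in range(side) for y in range(side) for z in range(side)],
        dtype=float,
    )[: 2 * n_per_chrom] * spacing
    chrom = np.arange(2 * n_per_chrom) % 2
    hap = np.zeros(2 * n_per_chrom, dtype=int)
    bins = np.repeat(np.arange(n_per_chrom), 2)[: 2 * n_per_chrom] * 20_000
    # make keys unique per chromosome
    bins = np.concatenate([np.arange((chrom == c).sum()) * 20_000 for c in (0, 1)])
    order = np.argsort(chrom, kind="stable")
    return Structure3D(genome, 20_000, chrom[order], hap[order],
                       bins, pts[order])


@pytest.fixture(scope="module")
def genome2():
    return GenomeSpec.uniform(2, 2_000_000)


# ------------------------------------------------------------ intermingling
def test_intermingling_single_chromosome_copy(genome2):
    coords = np.random.default_rng(0).normal(size=(20, 3))
    s = Structure3D(genome2, 20_000, np.zeros(20, int), np.zeros(20, int),
                    np.arange(20) * 20_000, coords)
    values, mean = intermingling_index(s, NeighborContext(100.0))
    assert mean == 0.0 and np.nanmax(values) == 0.0


def test_intermingling_disjoint_territories(genome2):
    rng = np.random.default_rng(1)
    a = rng.normal(size=(15, 3)) * 0.1
    b = rng.normal(size=(15, 3)) * 0.1 + [100, 0, 0]
    s = Structure3D(
        genome2, 20_000,
        np.r_[np.zeros(15, int), np.ones(15, int)], np.zeros(30, int),
        np.r_[np.arange(15), np.arange(15)] * 20_000, np.vstack([a, b]),
    )
    values, mean = intermingling_index(s, NeighborContext(4.0))
    assert mean == 0.0


def test_intermingling_dense_lattice_matches_count(genome2):
    s = lattice_structure(genome2)
    n = len(s)
    # radius covering everything: each particle sees all others
    values, mean = intermingling_index(
        s, NeighborContext(radius_particle_units=1000.0)
    )
    n_other = (s.chrom == 1).sum()
    expected_chr0 = n_other / (n - 1)
    np.testing.assert_allclose(values[s.chrom == 0], expected_chr0)


def test_intermingling_homolog_handling(genome2):
    """Homologs count as the same chromosome by default, foreign on request."""
    rng = np.random.default_rng(2)
    coords = rng.normal(size=(20, 3)) * 0.1
    s = Structure3D(genome2, 20_000, np.zeros(20, int),
                    np.r_[np.zeros(10, int), np.ones(10, int)],
                    np.r_[np.arange(10), np.arange(10)] * 20_000, coords)
    _, same = intermingling_index(s, NeighborContext(1000.0))
    _, foreign = intermingling_index(
        s, NeighborContext(1000.0, homologs_foreign=True)
    )
    assert same == 0.0 and foreign > 0.4


# ------------------------------------------------------------ compartment score
def test_compartment_score_sorted_configuration(genome2):
    """High-CpG particles clustered together -> strongly positive score."""
    rng = np.random.default_rng(3)
    n = 50
    cpg_vals = {c: np.linspace(0.2, 2.0, 100) for c in genome2.names}
    cpg = CpGTrack(genome2, 20_000, cpg_vals)
    # place low-CpG bins near origin, high-CpG bins far away, per chromosome
    coords = np.concatenate([
        np.linspace(0, 30, 100)[:, None] * np.array([1.0, 0, 0])
        + rng.normal(scale=0.2, size=(100, 3))
        for _ in range(2)
    ])
    s = Structure3D(genome2, 20_000,
                    np.repeat([0, 1], 100), np.zeros(200, int),
                    np.tile(np.arange(100), 2) * 20_000, coords)
    score, degenerate = compartment_score(s, cpg, NeighborContext(6.0))
    assert not degenerate and score > 0.8


def test_compartment_score_permutation_null(toy):
    genome, cpg = toy
    s = simulate_structure(genome, cpg, replace(NAIVE_LIKE, seed=0))
    rng = np.random.default_rng(0)
    scores = []
    for _ in range(20):
        perm_vals = {c: rng.permutation(cpg.values[c]) for c in genome.names}
        perm = CpGTrack(genome, cpg.bin_size, perm_vals)
        scores.append(compartment_score(s, perm)[0])
    assert np.mean(np.abs(scores)) < 0.2


def test_compartment_score_constant_track_degenerate(genome2, small_cell):
    structure, _, _, _ = small_cell
    genome = structure.genome
    const = CpGTrack(genome, 20_000,
                     {c: np.ones(genome.n_bins(c, 20_000)) for c in genome.names})
    score, degenerate = compartment_score(structure, const)
    assert score == 0.0 and degenerate


# ------------------------------------------------------------ radial positions
def test_radial_positions_sphere_symmetry(genome2):
    rng = np.random.default_rng(4)
    dirs = rng.normal(size=(15, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = np.vstack([dirs, -dirs])          # antipodal pairs: centroid is 0
    s = Structure3D(genome2, 20_000, np.zeros(30, int), np.zeros(30, int),
                    np.arange(30) * 20_000, dirs * 5.0)
    r = radial_positions(s)
    np.testing.assert_allclose(r, 1.0, atol=1e-9)


def test_radial_positions_translation_invariant(small_cell):
    structure, _, _, _ = small_cell
    r1 = radial_positions(structure)
    r2 = radial_positions(structure.transformed(translation=[10, -4, 2]))
    np.testing.assert_allclose(r1, r2, atol=1e-9)


def test_radial_positions_two_particles(genome2):
    s = Structure3D(genome2, 20_000, [0, 0], [0, 0], [0, 20_000],
                    [[1.0, 0, 0], [3.0, 0, 0]])
    # distances to centroid (2,0,0) are 1 and 1; use off-axis case instead
    s = Structure3D(genome2, 20_000, [0, 0, 0, 0], [0, 0, 0, 0],
                    np.arange(4) * 20_000,
                    [[1, 0, 0], [-1, 0, 0], [3, 0, 0], [-3, 0, 0]])
    r = radial_positions(s)
    np.testing.assert_allclose(sorted(r), [0.5, 0.5, 1.5, 1.5])
    assert r.mean() == pytest.approx(1.0, abs=1e-12)


# ------------------------------------------------------------ radial profiles
def test_radial_profile_reduces_to_global_mean(small_cell, small):
    genome, cpg = small
    structure, _, _, _ = small_cell
    profile = radial_cpg_profile([structure], cpg, n_shells=2)
    from dip3d.structure_metrics import _cpg_per_particle
    total = _cpg_per_particle(structure, cpg)
    r = radial_positions(structure)
    inner = total[r <= profile.shell_edges[1]].mean()
    assert profile.per_cell.iloc[0, 0] == pytest.approx(inner)


def test_radial_profile_cohort_contrast(toy):
    genome, cpg = toy
    naive = [simulate_structure(genome, cpg, replace(NAIVE_LIKE, seed=s))
             for s in range(3)]
    primed = [simulate_structure(genome, cpg, replace(PRIMED_LIKE, seed=s))
              for s in range(3)]
    pn = radial_cpg_profile(naive, cpg, n_shells=8).cohort_mean
    pp = radial_cpg_profile(primed, cpg, n_shells=8).cohort_mean
    # naive-like: CpG-rich center -> profile decreasing over inner shells
    inner = slice(0, 4)
    assert np.nanmean(np.diff(pn[inner])) < 0
    assert np.nanmean(np.diff(pp[inner])) > 0


def test_radial_profile_needs_two_shells(small_cell, small):
    _, cpg = small
    structure, _, _, _ = small_cell
    with pytest.raises(ValueError):
        radial_cpg_profile([structure], cpg, n_shells=1)


# ------------------------------------------------------------ radial-CpG corr
def test_radial_cpg_correlation_signs(toy):
    genome, cpg = toy
    sn = simulate_structure(genome, cpg, replace(NAIVE_LIKE, seed=1))
    sp = simulate_structure(genome, cpg, replace(PRIMED_LIKE, seed=1))
    assert radial_cpg_correlation(sn, cpg)[0] < 0      # "out-inside"
    assert radial_cpg_correlation(sp, cpg)[0] > 0      # "inside-out"


def test_radial_cpg_correlation_shuffle_null(toy):
    genome, cpg = toy
    s = simulate_structure(genome, cpg, replace(PRIMED_LIKE, seed=2))
    rng = np.random.default_rng(1)
    rhos = []
    for _ in range(20):
        shuffled = CpGTrack(
            genome, cpg.bin_size,
            {c: rng.permutation(cpg.values[c]) for c in genome.names},
        )
        # finer analysis bins: enough bins for a stable null on the toy genome
        rhos.append(radial_cpg_correlation(s, shuffled, bin_size=100_000)[0])
    assert np.mean(np.abs(rhos)) < 0.2


def test_radial_cpg_correlation_requires_bins(small_cell, small):
    _, cpg = small
    structure, _, _, _ = small_cell
    with pytest.raises(ValueError, match="bins"):
        radial_cpg_correlation(structure, cpg, bin_size=400_000)


# ------------------------------------------------------------ loci
def test_locus_radial_position_single_particle(small_cell):
    structure, _, _, _ = small_cell
    loci = pd.DataFrame(
        [("chr1", 40_000, 60_000, "single_bin")],
        columns=["chrom", "start", "end", "name"],
    )
    out = locus_radial_position(structure, loci)
    r = radial_positions(structure)
    row = np.flatnonzero(
        (structure.chrom == 0) & (structure.hap == 0) & (structure.bin_start == 40_000)
    )[0]
    assert out.loc[0, "radius_mat"] == pytest.approx(r[row])


def test_locus_zero_length_at_boundary(small_cell):
    structure, _, _, _ = small_cell
    loci = pd.DataFrame(
        [("chr1", 40_000, 40_000, "point")],
        columns=["chrom", "start", "end", "name"],
    )
    out = locus_radial_position(structure, loci)
    # half-open rule: coordinate 40_000 belongs to bin starting at 40_000
    rows = (structure.chrom == 0) & (structure.bin_start == 40_000)
    r = radial_positions(structure)
    assert out.loc[0, "radius"] == pytest.approx(r[rows].mean())


def test_locus_marker_gene_radial_contrast(toy):
    """A CpG-rich marker locus sits centrally in naive-like cells and
    peripherally in primed-like cells."""
    genome, cpg = toy
    # the most CpG-rich bin in the genome is the marker locus
    best = max(
        ((c, int(np.argmax(cpg.values[c]))) for c in genome.names),
        key=lambda t: cpg.values[t[0]][t[1]],
    )
    loci = pd.DataFrame(
        [(best[0], best[1] * 20_000, (best[1] + 1) * 20_000, "marker")],
        columns=["chrom", "start", "end", "name"],
    )
    naive_pos = np.mean([
        locus_radial_position(
            simulate_structure(genome, cpg, replace(NAIVE_LIKE, seed=s)), loci
        ).loc[0, "radius"]
        for s in range(3)
    ])
    primed_pos = np.mean([
        locus_radial_position(
            simulate_structure(genome, cpg, replace(PRIMED_LIKE, seed=s)), loci
        ).loc[0, "radius"]
        for s in range(3)
    ])
    assert naive_pos < 1 < primed_pos


# ------------------------------------------------------------ cross-sections
def test_cross_sections_partition(small_cell, small):
    _, cpg = small
    structure, _, _, _ = small_cell
    df = cross_sections(structure, cpg)
    assert len(df) == len(structure)                   # all particles, once
    extent = np.ptp(structure.coords[:, 2])
    spacing = 7.5 * structure.radius
    assert df["slab"].nunique() <= int(np.ceil(extent / spacing)) + 1
    assert "cpg" in df.columns


def test_cross_sections_single_slab(small_cell):
    structure, _, _, _ = small_cell
    df = cross_sections(structure, spacing_particle_radii=1e6)
    assert df["slab"].nunique() == 1


def test_cross_sections_bad_spacing(small_cell):
    structure, _, _, _ = small_cell
    with pytest.raises(ValueError):
        cross_sections(structure, spacing_particle_radii=0)


# ------------------------------------------------------------ invariance
def test_metrics_invariant_under_rigid_motions(toy):
    genome, cpg = toy
    s = simulate_structure(genome, cpg, replace(NAIVE_LIKE, seed=5))
    rng = np.random.default_rng(0)
    base = (
        intermingling_index(s)[1],
        compartment_score(s, cpg)[0],
        radial_cpg_correlation(s, cpg)[0],
    )
    for _ in range(3):
        q = ortho_group.rvs(3, random_state=rng)      # includes reflections
        t = rng.normal(scale=50, size=3)
        moved = s.transformed(rotation=q, translation=t)
        np.testing.assert_allclose(radial_positions(moved), radial_positions(s),
                                   atol=1e-9)
        got = (
            intermingling_index(moved)[1],
            compartment_score(moved, cpg)[0],
            radial_cpg_correlation(moved, cpg)[0],
        )
        np.testing.assert_allclose(got, base, atol=1e-9)


def test_metric_ranges(small_cell, small):
    _, cpg = small
    structure, _, _, _ = small_cell
    values, mean = intermingling_index(structure)
    finite = values[np.isfinite(values)]
    assert ((finite >= 0) & (finite <= 1)).all()
    score, _ = compartment_score(structure, cpg)
    assert -1 <= score <= 1
    assert radial_positions(structure).mean() == pytest.approx(1.0, abs=1e-9)
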