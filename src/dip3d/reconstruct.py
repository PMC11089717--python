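"""Restraint-based diploid 3D reconstruction by simulated annealing.

Haplotype-resolved contacts become distance restraints between (chromosome,
haplotype, bin) particles; the structure is found by temperature-laddered
stochastic gradient descent (Langevin-style annealing) through a
multi-resolution schedule: the chain is first solved at a coarse binning,
then interpolated and refined at successively finer binnings (the classic
single-cell annealing protocol, "-temps 20" with a bin-size ladder).

Energy terms (minimal functional forms):

* backbone — harmonic at *all* extensions, ``k (d - b)^2`` between
  consecutive bins of a chromosome copy (keeping the spring harmonic for
  large d limits the damage of mis-imputed contacts);
* contact — half-harmonic upper bound, ``w k max(0, d - d_c)^2``: a
  restraint pulls a pair together only while it is farther than the target
  contact distance, and duplicated contacts raise ``w``;
* confinement — half-harmonic spherical wall at the nuclear radius.

After each reconstruction round the structure itself imputes more
haplotypes (:func:`impute3d`): an unknown leg is assigned to whichever
parental copy sits closer to the partner leg's particle, when the
near/far distance ratio is decisive.  Reconstruction and 3D imputation
alternate (3 coarse + 2 fine rounds by default).

A contact map cannot determine chirality: solutions are defined up to a
rigid motion and a global reflection, and every downstream metric is
invariant to those.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .contacts import MAT, PAT, UNKNOWN, ContactSet
from .genome import GenomeSpec, bin_of
from .structure import Structure3D

__all__ = [
    "RestraintSet", "AnnealSchedule", "ReconstructionConfig",
    "build_restraints", "anneal", "impute3d", "reconstruct_pipeline",
]

logger = logging.getLogger(__name__)

_BOND = 1.0
_PARTICLE_RADIUS = 0.5
_K_BACKBONE = 10.0
_K_CONTACT = 5.0
_K_CONF = 10.0
_CONTACT_DISTANCE = 2.0  # target upper bound for a contact, model units
_MAX_MOVE = 0.2          # displacement cap per descent iteration, model units
_K_REPEL = 20.0
_PACKING_FRACTION = 0.15


@dataclass
class RestraintSet:
    """Particles plus the three restraint families acting on them."""

    genome: GenomeSpec
    resolution: int
    chrom: np.ndarray
    hap: np.ndarray
    bin_start: np.ndarray
    backbone_pairs: np.ndarray      # (m, 2) int rows into the particle table
    backbone_length: float
    contact_pairs: np.ndarray       # (k, 2)
    contact_weight: np.ndarray      # (k,)
    contact_distance: float
    confinement_radius: float
    n_excluded_contacts: int = 0

    def __post_init__(self):
        n = len(self.chrom)
        for pairs in (self.backbone_pairs, self.contact_pairs):
            if len(pairs) and pairs.max() >= n:
                raise ValueError("restraint references missing particle")


@dataclass(frozen=True)
class AnnealSchedule:
    """Temperature and multi-resolution plan.

    ``ladder`` is a non-increasing sequence of bin-size multipliers
    (relative to the target resolution) ending at 1: each entry is one
    refinement stage, solved coarse-to-fine with backbone interpolation in
    between.  ``n_temps`` temperatures per stage, geometric from ``t_start``
    to ``t_end``.
    """

    n_temps: int = 20
    ladder: tuple[int, ...] = (8, 4, 2, 1)
    iters_per_temp: int = 30
    t_start: float = 5.0
    t_end: float = 0.02
    step: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_temps < 2 or self.t_end >= self.t_start:
            raise ValueError("need >= 2 strictly decreasing temperatures")
        if list(self.ladder) != sorted(self.ladder, reverse=True) or self.ladder[-1] != 1:
            raise ValueError("ladder must be non-increasing and end at 1")

    def temperatures(self) -> np.ndarray:
        return np.geomspace(self.t_start, self.t_end, self.n_temps)


def _nucleus_radius(n_particles: int) -> float:
    v = n_particles * (4 / 3) * np.pi * _PARTICLE_RADIUS**3
    return (v / _PACKING_FRACTION * 3 / (4 * np.pi)) ** (1 / 3)


# ------------------------------------------------------------ restraints
def build_restraints(
    contacts: ContactSet, genome: GenomeSpec, resolution: int
) -> RestraintSet:
    """Turn haplotype-resolved contacts into a restraint system.

    Contacts with any unknown leg are excluded (and counted); duplicate
    particle pairs collapse into a single restraint with weight equal to the
    multiplicity.  Particles cover every bin of both copies of every
    chromosome; backbone restraints join consecutive bins of a copy.
    """
    chroms, haps, starts = [], [], []
    index = {}
    backbone = []
    for ci, chrom in enumerate(genome.names):
        n = genome.n_bins(chrom, resolution)
        for hap in (int(MAT), int(PAT)):
            for b in range(n):
                index[(ci, hap, b)] = len(chroms)
                chroms.append(ci)
                haps.append(hap)
                starts.append(b * resolution)
                if b:
                    backbone.append((len(chroms) - 2, len(chroms) - 1))

    ok = contacts.fully_phased
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError(
            f"no usable contacts: {n_excluded}/{len(contacts)} excluded as unphased"
        )
    pi = np.array([
        index[(int(c), int(h), int(b))]
        for c, h, b in zip(
            contacts.chrom_a[ok], contacts.hap_a[ok],
            bin_of(contacts.pos_a[ok], resolution),
        )
    ])
    pj = np.array([
        index[(int(c), int(h), int(b))]
        for c, h, b in zip(
            contacts.chrom_b[ok], contacts.hap_b[ok],
            bin_of(contacts.pos_b[ok], resolution),
        )
    ])
    lo = np.minimum(pi, pj)
    hi = np.maximum(pi, pj)
    self_pair = lo == hi
    lo, hi = lo[~self_pair], hi[~self_pair]
    key = lo.astype(np.int64) * len(chroms) + hi
    uniq, counts = np.unique(key, return_counts=True)
    pairs = np.stack([uniq // len(chroms), uniq % len(chroms)], axis=1)

    return RestraintSet(
        genome=genome,
        resolution=resolution,
        chrom=np.array(chroms, dtype=np.int64),
        hap=np.array(haps, dtype=np.int64),
        bin_start=np.array(starts, dtype=np.int64),
        backbone_pairs=np.array(backbone, dtype=np.int64).reshape(-1, 2),
        backbone_length=_BOND,
        contact_pairs=pairs,
        contact_weight=counts.astype(float),
        contact_distance=_CONTACT_DISTANCE,
        confinement_radius=_nucleus_radius(len(chroms)),
        n_excluded_contacts=n_excluded,
    )


# ------------------------------------------------------------ annealing
def _energy_and_grad(xyz, rs: RestraintSet, scale: float):
    grad = np.zeros_like(xyz)
    energy = 0.0
    b_target = rs.backbone_length * scale
    c_target = rs.contact_distance * scale
    for pairs, k, target, w, half in (
        (rs.backbone_pairs, _K_BACKBONE, b_target, None, False),
        (rs.contact_pairs, _K_CONTACT, c_target, rs.contact_weight, True),
    ):
        if len(pairs) == 0:
            continue
        diff = xyz[pairs[:, 0]] - xyz[pairs[:, 1]]
        d = np.linalg.norm(diff, axis=1)
        d = np.maximum(d, 1e-9)
        ext = d - target
        if half:
            ext = np.maximum(ext, 0.0)
        wt = w if w is not None else 1.0
        energy += float(np.sum(wt * k * ext**2))
        f = (wt * 2.0 * k * ext / d)[:, None] * diff
        np.add.at(grad, pairs[:, 0], f)
        np.add.at(grad, pairs[:, 1], -f)
    r = np.linalg.norm(xyz, axis=1)
    over = np.maximum(r - rs.confinement_radius, 0.0)
    energy += float(np.sum(_K_CONF * over**2))
    rr = np.maximum(r, 1e-9)
    grad += (_K_CONF * 2.0 * over / rr)[:, None] * xyz

    # soft-core excluded volume: without it, collapsing everything into one
    # ball satisfies every upper-bound restraint and is a degenerate minimum
    d_rep = 2.0 * _PARTICLE_RADIUS * scale
    tree = cKDTree(xyz)
    close = tree.query_pairs(d_rep, output_type="ndarray")
    if len(close):
        diff = xyz[close[:, 0]] - xyz[close[:, 1]]
        d = np.maximum(np.linalg.norm(diff, axis=1), 1e-9)
        gap = d_rep - d
        energy += float(np.sum(_K_REPEL * gap**2))
        f = (-_K_REPEL * 2.0 * gap / d)[:, None] * diff
        np.add.at(grad, close[:, 0], f)
        np.add.at(grad, close[:, 1], -f)
    return energy, grad


def _coarsen(rs: RestraintSet, factor: int) -> tuple[RestraintSet, np.ndarray]:
    """Merge every ``factor`` consecutive bins of a copy into one bead.

    Returns the coarse restraint set and, for each fine particle, the row of
    its coarse bead (for interpolation back to fine).
    """
    if factor == 1:
        return rs, np.arange(len(rs.chrom))
    coarse_key = {}
    fine_to_coarse = np.empty(len(rs.chrom), dtype=np.int64)
    chroms, haps, starts = [], [], []
    for i in range(len(rs.chrom)):
        key = (int(rs.chrom[i]), int(rs.hap[i]),
               int(rs.bin_start[i] // (rs.resolution * factor)))
        if key not in coarse_key:
            coarse_key[key] = len(chroms)
            chroms.append(key[0])
            haps.append(key[1])
            starts.append(key[2] * rs.resolution * factor)
        fine_to_coarse[i] = coarse_key[key]

    def remap(pairs, weights=None):
        if len(pairs) == 0:
            return pairs, (weights if weights is not None else None)
        p = fine_to_coarse[pairs]
        lo = np.minimum(p[:, 0], p[:, 1])
        hi = np.maximum(p[:, 0], p[:, 1])
        ok = lo != hi
        lo, hi = lo[ok], hi[ok]
        w = (weights[ok] if weights is not None else np.ones(len(lo)))
        key = lo.astype(np.int64) * len(chroms) + hi
        uniq, inv = np.unique(key, return_inverse=True)
        wsum = np.zeros(len(uniq))
        np.add.at(wsum, inv, w)
        out = np.stack([uniq // len(chroms), uniq % len(chroms)], axis=1)
        return out, wsum

    bb, _ = remap(rs.backbone_pairs)
    cp, cw = remap(rs.contact_pairs, rs.contact_weight)
    coarse = RestraintSet(
        genome=rs.genome, resolution=rs.resolution * factor,
        chrom=np.array(chroms, dtype=np.int64),
        hap=np.array(haps, dtype=np.int64),
        bin_start=np.array(starts, dtype=np.int64),
        backbone_pairs=bb, backbone_length=rs.backbone_length,
        contact_pairs=cp,
        contact_weight=cw if cw is not None else np.ones(len(cp)),
        contact_distance=rs.contact_distance,
        confinement_radius=rs.confinement_radius,
    )
    return coarse, fine_to_coarse


def anneal(
    restraints: RestraintSet,
    schedule: AnnealSchedule = AnnealSchedule(),
    return_log: bool = False,
):
    """Minimize the restraint energy by multi-resolution annealing.

    Deterministic under ``schedule.seed``; different seeds give solutions
    equivalent up to rigid motion and reflection.  Raises if the energy
    diverges (NaN), reporting the stage.
    """
    rng = np.random.default_rng(schedule.seed)
    log = []
    xyz = None
    prev_f2c = None
    for stage, factor in enumerate(schedule.ladder):
        rs, fine_to_coarse = _coarsen(restraints, int(factor))
        scale = float(np.sqrt(factor))
        if xyz is None:
            xyz = rng.normal(scale=rs.confinement_radius / 2, size=(len(rs.chrom), 3))
        else:
            # seed this stage from the previous (coarser) solution: each bead
            # starts at its parent bead's position, slightly jittered
            parent_xyz = xyz[prev_f2c]                  # per target-resolution particle
            counts = np.bincount(fine_to_coarse, minlength=len(rs.chrom)).astype(float)
            acc = np.zeros((len(rs.chrom), 3))
            np.add.at(acc, fine_to_coarse, parent_xyz)
            xyz = acc / counts[:, None]
            xyz += rng.normal(scale=0.05, size=xyz.shape)
        e0 = None
        for T in schedule.temperatures():
            lr = schedule.step
            for _ in range(schedule.iters_per_temp):
                energy, grad = _energy_and_grad(xyz, rs, scale)
                if not np.isfinite(energy):
                    raise FloatingPointError(
                        f"annealing diverged at stage {stage} (factor {factor})"
                    )
                if e0 is None:
                    e0 = energy
                step = lr * grad
                # cap per-particle displacement: keeps stiff, heavily
                # weighted coarse restraints from destabilizing the descent
                norms = np.linalg.norm(step, axis=1, keepdims=True)
                step *= np.minimum(1.0, _MAX_MOVE / np.maximum(norms, 1e-12))
                noise = rng.normal(size=xyz.shape)
                xyz = xyz - step + np.sqrt(2 * lr * T) * noise
        energy, _ = _energy_and_grad(xyz, rs, scale)
        log.append({"stage": stage, "factor": int(factor),
                    "particles": len(rs.chrom),
                    "energy_start": e0, "energy_end": energy})
        prev_f2c = fine_to_coarse
    xyz_fine = xyz

    structure = Structure3D(
        restraints.genome, restraints.resolution,
        restraints.chrom, restraints.hap, restraints.bin_start,
        xyz_fine, radius=_PARTICLE_RADIUS,
    )
    return (structure, log) if return_log else structure


# ------------------------------------------------------------ 3D imputation
def impute3d(
    contacts: ContactSet,
    structure: Structure3D,
    ratio_threshold: float = 0.5,
) -> ContactSet:
    """Resolve unknown legs from the reconstructed geometry.

    For a contact with exactly one unknown leg, the two candidate particles
    (maternal and paternal copy of the unknown leg's bin) are compared by
    distance to the known partner leg's particle; the nearer copy is
    assigned iff near/far <= ``ratio_threshold``.  Contacts with both legs
    unknown are skipped.  Known haplotypes are never overwritten.
    """
    out = contacts.copy()
    res = structure.resolution
    ha = out.hap_a.copy()
    hb = out.hap_b.copy()
    for unknown_side in ("a", "b"):
        if unknown_side == "a":
            u_ch, u_pos, u_hap = out.chrom_a, out.pos_a, ha
            p_ch, p_pos, p_hap = out.chrom_b, out.pos_b, out.hap_b
        else:
            u_ch, u_pos, u_hap = out.chrom_b, out.pos_b, hb
            p_ch, p_pos, p_hap = out.chrom_a, out.pos_a, out.hap_a
        rows = np.flatnonzero((u_hap == UNKNOWN) & (p_hap != UNKNOWN))
        for i in rows:
            partner = structure.lookup(
                int(p_ch[i]), int(p_hap[i]), int(p_pos[i] // res * res)
            )
            cand = [
                structure.lookup(int(u_ch[i]), h, int(u_pos[i] // res * res))
                for h in (int(MAT), int(PAT))
            ]
            if partner is None or cand[0] is None or cand[1] is None:
                continue
            d = [np.linalg.norm(structure.coords[c] - structure.coords[partner])
                 for c in cand]
            near, far = (0, 1) if d[0] <= d[1] else (1, 0)
            if far == near or d[far] == 0:
                continue
            if d[near] / d[far] <= ratio_threshold:
                u_hap[i] = near
    out.hap_a = ha
    out.hap_b = hb
    return out


# ------------------------------------------------------------ pipeline
@dataclass(frozen=True)
class ReconstructionConfig:
    """Round plan: ``coarse_rounds`` at ``coarse_factor`` x the base
    resolution with 3D imputation after each, then ``fine_rounds`` at the
    base resolution, likewise followed by 3D imputation."""

    coarse_rounds: int = 3
    fine_rounds: int = 2
    coarse_factor: int = 5
    ratio_threshold: float = 0.5
    schedule: AnnealSchedule = AnnealSchedule()


def reconstruct_pipeline(
    contacts: ContactSet,
    genome: GenomeSpec,
    resolution: int,
    config: ReconstructionConfig = ReconstructionConfig(),
    return_log: bool = False,
):
    """Alternate annealing and 3D haplotype imputation.

    ``contacts`` should be the cleaned output of the 2D imputation (it may
    still contain unknown legs; those are excluded from restraints and are
    candidates for 3D imputation).  Returns the final fine-resolution
    structure (and a per-round log when requested).
    """
    current = contacts.copy()
    log = []
    structure = None
    plan = [(config.coarse_factor, config.coarse_rounds),
            (1, config.fine_rounds)]
    round_no = 0
    for factor, rounds in plan:
        res = resolution * factor
        for _ in range(rounds):
            round_no += 1
            rs = build_restraints(current, genome, res)
            sched = replace(config.schedule, seed=config.schedule.seed + round_no)
            structure, stage_log = anneal(rs, sched, return_log=True)
            before = current.n_unknown_legs
            current = impute3d(current, structure, config.ratio_threshold)
            log.append({
                "round": round_no, "resolution": res,
                "energy_end": stage_log[-1]["energy_end"],
                "excluded_unphased": rs.n_excluded_contacts,
                "newly_imputed_legs": before - current.n_unknown_legs,
            })
    if structure is None:
        raise ValueError("round plan contains no reconstruction rounds")
    return (structure, current, log) if return_log else structure
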