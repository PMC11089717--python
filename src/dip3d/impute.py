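"""Neighborhood-vote haplotype imputation of single-cell contacts.

Diploid single-cell Hi-C leaves most contact legs unphased: only legs that
happen to cover a heterozygous SNP carry a parental haplotype.  Because a
contact between two chromosomes makes *further* contacts nearby far more
likely on the same pair of homologs, the unphased legs can be imputed from
their phased neighbors.

Neighborhood is measured with the L^0.5 dissimilarity between two contacts
on the same chromosome pair,

    d(c1, c2) = (sqrt(|dx|) + sqrt(|dy|))**2,

the order-0.5 Minkowski form (not a norm): simultaneously large dx and dy
are penalized, matching the empirical conditional contact density
p(dx, dy) ~ d**-1, i.e. proportional to (sqrt(dx)+sqrt(dy))**-2 — contacting
chromosomes protrude into each other rather than fully intermingle.  The
naive alternative for fully intermingled chromosomes would be the L1 form
p ~ (dx + dy)**-1; :func:`conditional_density` fits both and reports which
law the data prefer.

The voting rule per target contact: enumerate the haplotype tuples
compatible with its known legs; every fully phased contact on the same
chromosome pair within 10 Mb (L^0.5) that is compatible with exactly one
enumerated tuple casts one vote for it; the winner is imputed if it has
>= 3 votes and >= 90% of all votes.  Intrachromosomal contacts get special
treatment (intrahomologous shortcut at <= 10 Mb separation, interhomologous
assignments accepted only at >= 100 Mb separation, both-leg-unknown targets
never imputed), and isolated contacts (< 2 same-haplotype neighbors within
10 Mb) are removed after the voting rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .contacts import MAT, PAT, UNKNOWN, Contact, ContactSet

__all__ = [
    "ImputationParams", "ImputationResult",
    "l05_distance", "enumerate_tuples", "vote",
    "impute_round", "remove_isolated", "impute_pipeline",
    "conditional_density", "fit_conditional_density",
]

logger = logging.getLogger(__name__)

_CHUNK = 2048  # target rows per vectorized voting block


@dataclass(frozen=True)
class ImputationParams:
    """Voting thresholds; all inequalities are inclusive.

    Defaults are the published Dip-C values: 10-Mb evidence window in L^0.5
    distance, >= 3 votes and >= 90% of votes to win, intrahomologous shortcut
    at <= 10 Mb separation, interhomologous acceptance at >= 100 Mb, three
    voting rounds, and isolation cleaning (< 2 same-haplotype neighbors
    within 10 Mb).
    """

    window_bp: float = 10e6
    min_votes: int = 3
    win_fraction: float = 0.90
    intra_shortcut_bp: float = 10e6
    interhomolog_min_sep_bp: float = 100e6
    rounds: int = 3
    isolation_window_bp: float = 10e6
    isolation_min_neighbors: int = 2

    def __post_init__(self):
        if min(self.window_bp, self.intra_shortcut_bp,
               self.interhomolog_min_sep_bp) <= 0:
            raise ValueError("windows and separations must be positive")
        if not (0 < self.win_fraction <= 1):
            raise ValueError("win fraction must be in (0, 1]")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")


# ------------------------------------------------------------ primitives
def _l05(dx, dy):
    return (np.sqrt(np.abs(dx)) + np.sqrt(np.abs(dy))) ** 2


def l05_distance(contact1: Contact, contact2: Contact) -> float:
    """L^0.5 dissimilarity between two contacts on the same chromosome pair.

    Legs are paired by chromosome; for intrachromosomal contacts the pairing
    minimizing the distance is used.  Symmetric and >= 0; the triangle
    inequality does not hold (order-0.5 Minkowski is not a norm).
    """
    pair1 = frozenset((contact1.leg_a.chrom, contact1.leg_b.chrom))
    pair2 = frozenset((contact2.leg_a.chrom, contact2.leg_b.chrom))
    if pair1 != pair2:
        raise ValueError("contacts join different chromosome pairs")
    a1, b1 = contact1.leg_a, contact1.leg_b
    a2, b2 = contact2.leg_a, contact2.leg_b
    if contact1.is_intra:
        d_id = _l05(a1.pos - a2.pos, b1.pos - b2.pos)
        d_sw = _l05(a1.pos - b2.pos, b1.pos - a2.pos)
        return float(min(d_id, d_sw))
    if a1.chrom != a2.chrom:  # align legs by chromosome
        a2, b2 = b2, a2
    return float(_l05(a1.pos - a2.pos, b1.pos - b2.pos))


def enumerate_tuples(target: Contact) -> list[tuple[int, int]]:
    """All (hap_a, hap_b) in {MAT, PAT}^2 consistent with the known legs.

    Fully phased targets give an empty list (nothing to impute).
    """
    ha, hb = target.leg_a.hap, target.leg_b.hap
    if ha != UNKNOWN and hb != UNKNOWN:
        return []
    opts_a = (MAT, PAT) if ha == UNKNOWN else (ha,)
    opts_b = (MAT, PAT) if hb == UNKNOWN else (hb,)
    return [(int(a), int(b)) for a in opts_a for b in opts_b]


def vote(
    target: Contact,
    evidence: Iterable[Contact],
    params: ImputationParams = ImputationParams(),
) -> tuple[tuple[int, int] | None, dict[tuple[int, int], int]]:
    """Single-target voting (scalar reference API; rounds use the vectorized
    path).  Returns (winning tuple or None, vote counts per tuple)."""
    tuples = enumerate_tuples(target)
    counts = {t: 0 for t in tuples}
    if not tuples:
        return None, counts
    for ev in evidence:
        if not (ev.leg_a.hap != UNKNOWN and ev.leg_b.hap != UNKNOWN):
            continue
        combo = _evidence_combo(target, ev, params.window_bp)
        if combo is not None and combo in counts:
            counts[combo] += 1
    return _winner(counts, params), counts


def _evidence_combo(target: Contact, ev: Contact, window: float):
    """Oriented haplotype pair of an in-window evidence contact, or None.

    Orientation aligns evidence legs with the target's legs (chromosome
    alignment for interchromosomal pairs, minimal-distance pairing for
    intrachromosomal ones; an exact pairing tie with conflicting haplotype
    orientations is ambiguous and casts no vote).
    """
    pair_t = frozenset((target.leg_a.chrom, target.leg_b.chrom))
    pair_e = frozenset((ev.leg_a.chrom, ev.leg_b.chrom))
    if pair_t != pair_e:
        return None
    a, b = ev.leg_a, ev.leg_b
    if target.is_intra:
        d_id = _l05(target.leg_a.pos - a.pos, target.leg_b.pos - b.pos)
        d_sw = _l05(target.leg_a.pos - b.pos, target.leg_b.pos - a.pos)
        if min(d_id, d_sw) > window:
            return None
        if d_id < d_sw:
            return (int(a.hap), int(b.hap))
        if d_sw < d_id:
            return (int(b.hap), int(a.hap))
        if a.hap == b.hap:
            return (int(a.hap), int(b.hap))
        return None  # tied pairing, conflicting orientations
    if a.chrom != target.leg_a.chrom:
        a, b = b, a
    if _l05(target.leg_a.pos - a.pos, target.leg_b.pos - b.pos) > window:
        return None
    return (int(a.hap), int(b.hap))


def _winner(counts: dict, params: ImputationParams):
    total = sum(counts.values())
    if total == 0:
        return None
    best = max(counts.values())
    if best < params.min_votes or best < params.win_fraction * total:
        return None
    winners = [t for t, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else None


# ------------------------------------------------------------ round (vectorized)
def _group_keys(cs: ContactSet) -> np.ndarray:
    n = len(cs.genome.names)
    return cs.chrom_a * n + cs.chrom_b  # canonical: chrom_a <= chrom_b


def impute_round(
    targets: ContactSet,
    evidence: ContactSet,
    params: ImputationParams = ImputationParams(),
) -> ContactSet:
    """One synchronous voting round.

    Every target with at least one unknown leg is resolved against the frozen
    ``evidence`` set; assignments are applied only after all votes are
    counted, so the result is independent of iteration order.  Known
    haplotypes are never overwritten; input order is preserved.
    """
    out = targets.copy(stage=targets.stage)
    new_ha = out.hap_a.copy()
    new_hb = out.hap_b.copy()

    unknown = (out.hap_a == UNKNOWN) | (out.hap_b == UNKNOWN)
    intra = out.is_intra
    sep = np.abs(out.pos_b - out.pos_a)

    # intrachromosomal shortcut: assume intrahomologous without voting
    shortcut = unknown & intra & (sep <= params.intra_shortcut_bp) & (
        (out.hap_a != UNKNOWN) | (out.hap_b != UNKNOWN)
    )
    known_hap = np.where(out.hap_a != UNKNOWN, out.hap_a, out.hap_b)
    new_ha[shortcut] = known_hap[shortcut]
    new_hb[shortcut] = known_hap[shortcut]

    # both-unknown intrachromosomal targets are never imputed in 2D
    votable = unknown & ~shortcut & ~(
        intra & (out.hap_a == UNKNOWN) & (out.hap_b == UNKNOWN)
    )

    ev_ok = evidence.fully_phased
    ev_keys = _group_keys(evidence)
    t_keys = _group_keys(out)

    for key in np.unique(t_keys[votable]):
        t_rows = np.flatnonzero(votable & (t_keys == key))
        e_rows = np.flatnonzero(ev_ok & (ev_keys == key))
        if len(e_rows) == 0:
            continue
        is_intra_group = bool(intra[t_rows[0]])
        counts = _group_counts(out, t_rows, evidence, e_rows,
                               params.window_bp, is_intra_group)
        _apply_votes(out, t_rows, counts, params, new_ha, new_hb)

    out.hap_a = new_ha
    out.hap_b = new_hb
    return out


def _group_counts(targets, t_rows, evidence, e_rows, window, is_intra):
    """Vote counts (len(t_rows) x 4) for one chromosome-pair group; tuple
    index is 2*hap_a + hap_b in target leg orientation."""
    pa_e = evidence.pos_a[e_rows].astype(float)
    pb_e = evidence.pos_b[e_rows].astype(float)
    combo1 = (2 * evidence.hap_a[e_rows] + evidence.hap_b[e_rows]).astype(np.int64)
    combo2 = (2 * evidence.hap_b[e_rows] + evidence.hap_a[e_rows]).astype(np.int64)
    onehot1 = np.zeros((len(e_rows), 4), dtype=np.float32)
    onehot1[np.arange(len(e_rows)), combo1] = 1.0
    onehot2 = np.zeros((len(e_rows), 4), dtype=np.float32)
    onehot2[np.arange(len(e_rows)), combo2] = 1.0

    counts = np.zeros((len(t_rows), 4), dtype=np.int64)
    for lo in range(0, len(t_rows), _CHUNK):
        rows = t_rows[lo:lo + _CHUNK]
        pa_t = targets.pos_a[rows].astype(float)[:, None]
        pb_t = targets.pos_b[rows].astype(float)[:, None]
        d1 = _l05(pa_t - pa_e[None, :], pb_t - pb_e[None, :])
        if is_intra:
            d2 = _l05(pa_t - pb_e[None, :], pb_t - pa_e[None, :])
            use1 = (d1 < d2) | ((d1 == d2) & (combo1 == combo2)[None, :])
            use2 = d2 < d1
            block = (
                (use1 & (d1 <= window)).astype(np.float32) @ onehot1
                + (use2 & (d2 <= window)).astype(np.float32) @ onehot2
            )
        else:
            block = (d1 <= window).astype(np.float32) @ onehot1
        counts[lo:lo + _CHUNK] = np.rint(block).astype(np.int64)
    return counts


def _apply_votes(targets, t_rows, counts, params, new_ha, new_hb):
    ha = targets.hap_a[t_rows]
    hb = targets.hap_b[t_rows]
    allowed = np.ones((len(t_rows), 4), dtype=bool)
    combos_a = np.array([1, 1, 0, 0], dtype=bool)  # hap_a of combo k = k >> 1
    combos_b = np.array([1, 0, 1, 0], dtype=bool)  # rows below use k = 2a+b
    k_a = np.array([0, 0, 1, 1])
    k_b = np.array([0, 1, 0, 1])
    known_a = ha != UNKNOWN
    known_b = hb != UNKNOWN
    allowed[known_a] &= (k_a[None, :] == ha[known_a, None])
    allowed[known_b] &= (k_b[None, :] == hb[known_b, None])

    masked = np.where(allowed, counts, 0)
    total = masked.sum(axis=1)
    best = masked.max(axis=1)
    n_best = (masked == best[:, None]).sum(axis=1)
    win = (
        (total > 0)
        & (best >= params.min_votes)
        & (best >= params.win_fraction * total)
        & (n_best == 1)
    )
    winner_k = masked.argmax(axis=1)
    win_a = k_a[winner_k]
    win_b = k_b[winner_k]

    # interhomologous intrachromosomal winners need large separation
    intra = targets.chrom_a[t_rows] == targets.chrom_b[t_rows]
    sep = np.abs(targets.pos_b[t_rows] - targets.pos_a[t_rows])
    interhom = win_a != win_b
    win &= ~(intra & interhom & (sep < params.interhomolog_min_sep_bp))

    rows = t_rows[win]
    new_ha[rows] = win_a[win]
    new_hb[rows] = win_b[win]


# ------------------------------------------------------------ cleaning
def remove_isolated(
    contacts: ContactSet,
    params: ImputationParams = ImputationParams(),
) -> ContactSet:
    """Drop contacts with < ``isolation_min_neighbors`` same-haplotype
    neighbors within the isolation window (L^0.5).

    Neighbor haplotypes must match on the matched legs under the same leg
    pairing that realizes the distance; unknown legs never match, so
    unresolved contacts are always dropped.  The filter is evaluated
    simultaneously on the input set (order-independent).
    """
    n = len(contacts)
    keep = np.zeros(n, dtype=bool)
    resolved = contacts.fully_phased
    keys = _group_keys(contacts)
    win = params.isolation_window_bp
    for key in np.unique(keys[resolved]):
        rows = np.flatnonzero(resolved & (keys == key))
        if len(rows) == 0:
            continue
        is_intra = contacts.chrom_a[rows[0]] == contacts.chrom_b[rows[0]]
        pa = contacts.pos_a[rows].astype(float)
        pb = contacts.pos_b[rows].astype(float)
        ha = contacts.hap_a[rows]
        hb = contacts.hap_b[rows]
        neigh = np.zeros(len(rows), dtype=np.int64)
        for lo in range(0, len(rows), _CHUNK):
            sl = slice(lo, lo + _CHUNK)
            d1 = _l05(pa[sl, None] - pa[None, :], pb[sl, None] - pb[None, :])
            same1 = (ha[sl, None] == ha[None, :]) & (hb[sl, None] == hb[None, :])
            if is_intra:
                d2 = _l05(pa[sl, None] - pb[None, :], pb[sl, None] - pa[None, :])
                same2 = (ha[sl, None] == hb[None, :]) & (hb[sl, None] == ha[None, :])
                use1 = d1 <= d2
                match = np.where(use1, (d1 <= win) & same1, (d2 <= win) & same2)
            else:
                match = (d1 <= win) & same1
            neigh[sl] = match.sum(axis=1)
        # subtract self-match (distance 0, identical haplotypes)
        neigh -= 1
        keep[rows] = neigh >= params.isolation_min_neighbors
    return contacts.select(keep)


# ------------------------------------------------------------ pipeline
@dataclass
class ImputationResult:
    """Outcome of the full 2D imputation pipeline.

    ``contacts`` is the cleaned, haplotype-resolved set used downstream.
    ``hap_a``/``hap_b`` hold the final assignment for *every* input contact
    in input order (pre-cleaning), so recovery can be scored against a
    simulation truth including contacts the cleaning step dropped.
    """

    contacts: ContactSet
    hap_a: np.ndarray
    hap_b: np.ndarray
    log: list[dict] = field(default_factory=list)

    @property
    def n_unknown_legs(self) -> int:
        return int((self.hap_a == UNKNOWN).sum() + (self.hap_b == UNKNOWN).sum())


def impute_pipeline(
    raw: ContactSet,
    params: ImputationParams = ImputationParams(),
) -> ImputationResult:
    """Run the full 2D pipeline: ``rounds`` voting rounds (each using the
    previous round's output as the new evidence set), isolation cleaning,
    then one final round imputing interchromosomal both-unknown contacts
    against the cleaned evidence."""
    if raw.stage != "raw":
        raise ValueError("impute_pipeline expects a raw contact set")
    log: list[dict] = []
    current = raw.copy(stage="raw")
    if len(raw) == 0:
        logger.warning("empty contact set: nothing to impute")
        return ImputationResult(raw.copy(stage="cleaned"), raw.hap_a.copy(),
                                raw.hap_b.copy(), log)

    for r in range(params.rounds):
        before = current.n_unknown_legs
        current = impute_round(current, current, params)
        current.stage = "imputed"
        log.append({
            "round": r + 1, "kind": "vote",
            "unknown_before": before, "unknown_after": current.n_unknown_legs,
            "imputed": before - current.n_unknown_legs,
        })
    if current.stage == "raw":
        current = current.with_stage("imputed")

    cleaned = remove_isolated(current, params).with_stage("cleaned")
    log.append({
        "kind": "clean", "kept": len(cleaned),
        "removed": len(current) - len(cleaned),
    })

    # final round: interchromosomal both-unknown targets vs cleaned evidence
    final_mask = (
        ~current.is_intra
        & (current.hap_a == UNKNOWN)
        & (current.hap_b == UNKNOWN)
    )
    hap_a = current.hap_a.copy()
    hap_b = current.hap_b.copy()
    final_new = ContactSet.empty(raw.genome, raw.cell_id, "cleaned")
    if final_mask.any() and len(cleaned):
        targets = current.select(final_mask)
        voted = impute_round(targets, cleaned, params)
        rows = np.flatnonzero(final_mask)
        hap_a[rows] = voted.hap_a
        hap_b[rows] = voted.hap_b
        resolved = voted.fully_phased
        final_new = voted.select(resolved, stage="cleaned")
        log.append({
            "kind": "final_interchromosomal",
            "targets": int(final_mask.sum()),
            "imputed": int(resolved.sum()),
        })

    merged = ContactSet(
        raw.genome,
        np.concatenate([cleaned.chrom_a, final_new.chrom_a]),
        np.concatenate([cleaned.pos_a, final_new.pos_a]),
        np.concatenate([cleaned.hap_a, final_new.hap_a]),
        np.concatenate([cleaned.chrom_b, final_new.chrom_b]),
        np.concatenate([cleaned.pos_b, final_new.pos_b]),
        np.concatenate([cleaned.hap_b, final_new.hap_b]),
        cell_id=raw.cell_id, stage="cleaned",
    )
    log.append({"kind": "done", "contacts_out": len(merged),
                "unknown_legs_unresolved": int((hap_a == UNKNOWN).sum()
                                               + (hap_b == UNKNOWN).sum())})
    return ImputationResult(merged, hap_a, hap_b, log)


# ------------------------------------------------------------ density law
def fit_conditional_density(
    dx: np.ndarray,
    dy: np.ndarray,
    n_bins: int = 12,
    d_min: float | None = None,
    d_max: float | None = None,
) -> dict:
    """Fit the conditional contact-density law from displacement samples.

    (dx, dy) pairs are histogrammed into log-spaced 2D bins; the empirical
    density is regressed (least squares in log-log space) on the L^0.5
    metric (sqrt(dx)+sqrt(dy))**2 and on the L1 metric dx+dy.  Returns both
    exponents and which law fits better by residual sum of squares.
    """
    dx = np.abs(np.asarray(dx, dtype=float))
    dy = np.abs(np.asarray(dy, dtype=float))
    ok = (dx > 0) & (dy > 0)
    dx, dy = dx[ok], dy[ok]
    if len(dx) < 10:
        raise ValueError("insufficient displacement pairs")
    if d_min is None:
        d_min = min(dx.min(), dy.min())
    if d_max is None:
        d_max = max(dx.max(), dy.max())
    if not d_max > d_min:
        raise ValueError("degenerate support: all pairs at one displacement")
    edges = np.geomspace(d_min, d_max * (1 + 1e-9), n_bins + 1)
    hist, _, _ = np.histogram2d(dx, dy, bins=[edges, edges])
    widths = np.diff(edges)
    area = widths[:, None] * widths[None, :]
    centers = np.sqrt(edges[:-1] * edges[1:])
    cx = centers[:, None] + 0 * centers[None, :]
    cy = centers[None, :] + 0 * centers[:, None]
    filled = hist > 0
    if filled.sum() < 4:
        raise ValueError("degenerate support: too few occupied bins")
    dens = hist[filled] / area[filled]
    log_d = np.log10(dens / dens.sum())
    out = {}
    for name, metric in (
        ("l05", (np.sqrt(cx) + np.sqrt(cy)) ** 2),
        ("l1", cx + cy),
    ):
        x = np.log10(metric[filled])
        coef = np.polyfit(x, log_d, 1)
        resid = log_d - np.polyval(coef, x)
        out[name] = {"exponent": float(coef[0]), "rss": float(resid @ resid)}
    out["preferred"] = "l05" if out["l05"]["rss"] <= out["l1"]["rss"] else "l1"
    return out


def conditional_density(
    contacts: ContactSet,
    n_bins: int = 12,
    max_pairs: int = 500_000,
    seed: int = 0,
    min_separation: float = 0.0,
) -> dict:
    """Empirical conditional density of contact displacements.

    For ordered pairs of contacts sharing a chromosome pair, accumulates the
    leg displacements (dx, dy) (canonical leg alignment) and fits the two
    candidate density laws; see :func:`fit_conditional_density`.
    """
    keys = _group_keys(contacts)
    rng = np.random.default_rng(seed)
    dxs, dys = [], []
    for key in np.unique(keys):
        rows = np.flatnonzero(keys == key)
        if len(rows) < 2:
            continue
        m = len(rows) * (len(rows) - 1) // 2
        if m > max_pairs:
            i = rng.integers(0, len(rows), size=max_pairs)
            j = rng.integers(0, len(rows), size=max_pairs)
            sel = i < j
            i, j = i[sel], j[sel]
        else:
            i, j = np.triu_indices(len(rows), k=1)
        ri, rj = rows[i], rows[j]
        dxs.append(np.abs(contacts.pos_a[ri] - contacts.pos_a[rj]))
        dys.append(np.abs(contacts.pos_b[ri] - contacts.pos_b[rj]))
    if not dxs:
        raise ValueError("no contact pairs share a chromosome pair")
    dx = np.concatenate(dxs).astype(float)
    dy = np.concatenate(dys).astype(float)
    sel = (dx >= min_separation) & (dy >= min_separation)
    return fit_conditional_density(dx[sel], dy[sel], n_bins=n_bins)
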