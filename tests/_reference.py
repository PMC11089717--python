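"""Naive O(n^2) reference implementations of the voting and cleaning rules.

Written independently of the package's vectorized code paths, in plain
Python over (chrom, pos, hap, chrom, pos, hap) tuples, as an oracle for
equivalence tests.  Haplotypes: 0 = maternal, 1 = paternal, -1 = unknown.
"""

from __future__ import annotations

import math

UNK = -1


def l05(dx, dy):
    return (math.sqrt(abs(dx)) + math.sqrt(abs(dy))) ** 2


def ref_impute_round(contacts, params):
    """contacts: list of (ca, pa, ha, cb, pb, hb) canonical tuples.
    Returns the new list after one synchronous round (self-evidence set)."""
    return ref_impute_targets(contacts, contacts, params)


def ref_impute_targets(targets, evidence, params):
    out = []
    for t in targets:
        ca, pa, ha, cb, pb, hb = t
        if ha != UNK and hb != UNK:
            out.append(t)
            continue
        intra = ca == cb
        sep = abs(pb - pa)
        if intra and sep <= params.intra_shortcut_bp and (ha != UNK or hb != UNK):
            known = ha if ha != UNK else hb
            out.append((ca, pa, known, cb, pb, known))
            continue
        if intra and ha == UNK and hb == UNK:
            out.append(t)
            continue
        tuples = [
            (x, y)
            for x in ((0, 1) if ha == UNK else (ha,))
            for y in ((0, 1) if hb == UNK else (hb,))
        ]
        counts = {tp: 0 for tp in tuples}
        for e in evidence:
            eca, epa, eha, ecb, epb, ehb = e
            if eha == UNK or ehb == UNK:
                continue
            if {eca, ecb} != {ca, cb}:
                continue
            if intra:
                d_id = l05(pa - epa, pb - epb)
                d_sw = l05(pa - epb, pb - epa)
                if min(d_id, d_sw) > params.window_bp:
                    continue
                if d_id < d_sw:
                    combo = (eha, ehb)
                elif d_sw < d_id:
                    combo = (ehb, eha)
                elif eha == ehb:
                    combo = (eha, ehb)
                else:
                    continue
            else:
                if eca == ca:
                    x_pos, y_pos, x_hap, y_hap = epa, epb, eha, ehb
                else:
                    x_pos, y_pos, x_hap, y_hap = epb, epa, ehb, eha
                if l05(pa - x_pos, pb - y_pos) > params.window_bp:
                    continue
                combo = (x_hap, y_hap)
            if combo in counts:
                counts[combo] += 1
        total = sum(counts.values())
        win = None
        if total > 0:
            best = max(counts.values())
            winners = [tp for tp, c in counts.items() if c == best]
            if (
                best >= params.min_votes
                and best >= params.win_fraction * total
                and len(winners) == 1
            ):
                win = winners[0]
        if win is not None and intra and win[0] != win[1] and (
            sep < params.interhomolog_min_sep_bp
        ):
            win = None
        if win is None:
            out.append(t)
        else:
            out.append((ca, pa, win[0], cb, pb, win[1]))
    return out


def ref_remove_isolated(contacts, params):
    """Simultaneous all-pairs isolation filter."""
    kept = []
    for i, t in enumerate(contacts):
        ca, pa, ha, cb, pb, hb = t
        if ha == UNK or hb == UNK:
            continue
        n = 0
        for j, e in enumerate(contacts):
            if i == j:
                continue
            eca, epa, eha, ecb, epb, ehb = e
            if eha == UNK or ehb == UNK:
                continue
            if {eca, ecb} != {ca, cb}:
                continue
            if ca == cb:
                d_id = l05(pa - epa, pb - epb)
                d_sw = l05(pa - epb, pb - epa)
                if d_id <= d_sw:
                    same = d_id <= params.isolation_window_bp and (ha, hb) == (eha, ehb)
                else:
                    same = d_sw <= params.isolation_window_bp and (ha, hb) == (ehb, eha)
            else:
                if eca == ca:
                    combo = (eha, ehb)
                    d = l05(pa - epa, pb - epb)
                else:
                    combo = (ehb, eha)
                    d = l05(pa - epb, pb - epa)
                same = d <= params.isolation_window_bp and (ha, hb) == combo
            if same:
                n += 1
        if n >= params.isolation_min_neighbors:
            kept.append(t)
    return kept
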