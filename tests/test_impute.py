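"""Voting-imputation rules, cleaning, and the conditional density law."""

import numpy as np
import pytest

from dip3d import (
    Contact, ContactSet, GenomeSpec, ImputationParams, Leg, enumerate_tuples,
    impute_pipeline, impute_round, l05_distance, remove_isolated, vote,
)
from dip3d.contacts import MAT, PAT, UNKNOWN
from dip3d.impute import fit_conditional_density

from _reference import ref_impute_round, ref_remove_isolated

BIG = GenomeSpec.uniform(4, 200_000_000)
PARAMS = ImputationParams()
MB = 1_000_000


def contact(ca, pa, ha, cb, pb, hb):
    return Contact(Leg(ca, pa, ha), Leg(cb, pb, hb))


def cs(rows, genome=BIG, **kw):
    return ContactSet.from_contacts([contact(*r) for r in rows], genome, **kw)


def rows_of(contacts):
    return [
        (int(a), int(b), int(c), int(d), int(e), int(f))
        for a, b, c, d, e, f in zip(
            contacts.chrom_a, contacts.pos_a, contacts.hap_a,
            contacts.chrom_b, contacts.pos_b, contacts.hap_b,
        )
    ]


def random_set(rng, n, genome=BIG):
    """Mixed intra/inter contacts with clustered neighborhoods and random
    phasing, as a voting stress case."""
    ca = rng.integers(0, 4, n)
    cb = rng.integers(0, 4, n)
    pa = rng.integers(0, 200_000_000, n)
    pb = rng.integers(0, 200_000_000, n)
    m = n // 2
    centers = rng.integers(0, 190_000_000, (8, 2))
    which = rng.integers(0, 8, m)
    pa[:m] = centers[which, 0] + rng.integers(0, 4_000_000, m)
    pb[:m] = centers[which, 1] + rng.integers(0, 4_000_000, m)
    ca[:m] = rng.integers(0, 2, m)
    cb[:m] = ca[:m] + rng.integers(0, 2, m)
    ha = rng.choice([-1, 0, 1], n, p=[0.5, 0.25, 0.25])
    hb = rng.choice([-1, 0, 1], n, p=[0.5, 0.25, 0.25])
    return ContactSet(genome, ca, pa, ha, cb, pb, hb)


# ------------------------------------------------------------ L^0.5
@pytest.mark.parametrize(
    "dx, dy, expected",
    [
        (0, 0, 0.0),
        (4 * MB, 0, 4 * MB),                  # one-sided: reduces to |dx|
        (MB, MB, 4 * MB),                     # (sqrt(1M)+sqrt(1M))^2 = 4M
    ],
)
def test_l05_values(dx, dy, expected):
    c1 = contact("chr1", 10 * MB, MAT, "chr2", 20 * MB, MAT)
    c2 = contact("chr1", 10 * MB + dx, MAT, "chr2", 20 * MB + dy, MAT)
    assert l05_distance(c1, c2) == pytest.approx(expected)
    assert l05_distance(c2, c1) == pytest.approx(expected)   # symmetry


def test_l05_requires_same_chromosome_pair():
    c1 = contact("chr1", 0, MAT, "chr2", 0, MAT)
    c2 = contact("chr1", 0, MAT, "chr3", 0, MAT)
    with pytest.raises(ValueError):
        l05_distance(c1, c2)


def test_l05_intra_uses_minimizing_pairing():
    c1 = contact("chr1", 10 * MB, MAT, "chr1", 50 * MB, MAT)
    c2 = contact("chr1", 50 * MB, MAT, "chr1", 10 * MB, MAT)  # same, swapped
    assert l05_distance(c1, c2) == 0.0


# ------------------------------------------------------------ tuples & votes
def test_enumerate_tuples():
    assert len(enumerate_tuples(contact("chr1", 0, UNKNOWN, "chr2", 0, UNKNOWN))) == 4
    assert enumerate_tuples(contact("chr1", 0, MAT, "chr2", 0, UNKNOWN)) == [
        (0, 0), (0, 1)
    ]
    assert enumerate_tuples(contact("chr1", 0, MAT, "chr2", 0, PAT)) == []


def evidence_at(n, ha, hb, x=10 * MB, y=20 * MB):
    return [contact("chr1", x + i * 1000, ha, "chr2", y + i * 1000, hb)
            for i in range(n)]


@pytest.mark.parametrize(
    "votes, expect_win",
    [
        ([(3, PAT, MAT)], True),            # 3 votes, 100%
        ([(2, PAT, MAT)], False),           # 2 votes, 100% -> below min votes
        ([(9, PAT, MAT), (1, MAT, MAT)], True),   # 9 of 10 = 90%, inclusive
        ([(8, PAT, MAT), (2, MAT, MAT)], False),  # 80% < 90%
        ([(5, PAT, MAT), (5, MAT, PAT)], False),  # tie -> no winner
    ],
)
def test_vote_thresholds_inclusive(votes, expect_win):
    target = contact("chr1", 10 * MB, UNKNOWN, "chr2", 20 * MB, UNKNOWN)
    evidence = []
    for n, ha, hb in votes:
        evidence += evidence_at(n, ha, hb)
    winner, counts = vote(target, evidence, PARAMS)
    if expect_win:
        assert winner == (int(votes[0][1]), int(votes[0][2]))
    else:
        assert winner is None


def test_vote_window_excludes_far_evidence():
    target = contact("chr1", 10 * MB, UNKNOWN, "chr2", 20 * MB, UNKNOWN)
    far = evidence_at(5, MAT, MAT, x=100 * MB, y=150 * MB)
    winner, counts = vote(target, far, PARAMS)
    assert winner is None and sum(counts.values()) == 0


def test_half_phased_evidence_does_not_vote():
    target = contact("chr1", 10 * MB, UNKNOWN, "chr2", 20 * MB, UNKNOWN)
    ev = evidence_at(5, MAT, UNKNOWN)
    winner, counts = vote(target, ev, PARAMS)
    assert winner is None and sum(counts.values()) == 0


# ------------------------------------------------------------ round rules
def test_intra_shortcut_no_votes_needed():
    s = cs([("chr1", 10 * MB, MAT, "chr1", 15 * MB, UNKNOWN)])
    out = impute_round(s, ContactSet.empty(BIG), PARAMS)
    assert rows_of(out) == [(0, 10 * MB, 0, 0, 15 * MB, 0)]


def test_intra_both_unknown_never_imputed():
    rows = [("chr1", 10 * MB, UNKNOWN, "chr1", 60 * MB, UNKNOWN)]
    ev_rows = [("chr1", 10 * MB + i * 1000, MAT, "chr1", 60 * MB + i * 1000, MAT)
               for i in range(5)]
    out = impute_round(cs(rows), cs(ev_rows), PARAMS)
    assert out[0].leg_a.hap == UNKNOWN and out[0].leg_b.hap == UNKNOWN


def test_interhomologous_needs_large_separation():
    # winning vote is interhomologous but separation 50 Mb < 100 Mb
    rows = [("chr1", 10 * MB, MAT, "chr1", 60 * MB, UNKNOWN)]
    ev = [("chr1", 10 * MB + i * 1000, MAT, "chr1", 60 * MB + i * 1000, PAT)
          for i in range(5)]
    out = impute_round(cs(rows), cs(ev), PARAMS)
    assert out[0].leg_b.hap == UNKNOWN
    # at 150 Mb separation the same vote is accepted
    rows = [("chr1", 10 * MB, MAT, "chr1", 160 * MB, UNKNOWN)]
    ev = [("chr1", 10 * MB + i * 1000, MAT, "chr1", 160 * MB + i * 1000, PAT)
          for i in range(5)]
    out = impute_round(cs(rows), cs(ev), PARAMS)
    assert out[0].leg_b.hap == PAT


def test_inter_both_unknown_fully_imputed_by_unanimous_evidence():
    rows = [("chr1", 10 * MB, UNKNOWN, "chr2", 20 * MB, UNKNOWN)]
    ev = [("chr1", 10 * MB + i * 1000, PAT, "chr2", 20 * MB + i * 1000, MAT)
          for i in range(5)]
    out = impute_round(cs(rows), cs(ev), PARAMS)
    assert (out[0].leg_a.hap, out[0].leg_b.hap) == (PAT, MAT)


def test_known_haplotypes_never_overwritten(toy):
    rng = np.random.default_rng(3)
    s = random_set(rng, 400)
    known_a = s.hap_a != UNKNOWN
    known_b = s.hap_b != UNKNOWN
    out = impute_round(s, s, PARAMS)
    assert np.array_equal(out.hap_a[known_a], s.hap_a[known_a])
    assert np.array_equal(out.hap_b[known_b], s.hap_b[known_b])


def test_unknown_count_monotone_across_rounds():
    rng = np.random.default_rng(4)
    s = random_set(rng, 500)
    prev = s.n_unknown_legs
    for _ in range(3):
        s = impute_round(s, s, PARAMS)
        assert s.n_unknown_legs <= prev
        prev = s.n_unknown_legs


def test_impute_round_matches_bruteforce_oracle():
    rng = np.random.default_rng(11)
    for _ in range(8):
        s = random_set(rng, rng.integers(50, 400))
        assert rows_of(impute_round(s, s, PARAMS)) == ref_impute_round(
            rows_of(s), PARAMS
        )


# ------------------------------------------------------------ cleaning
def test_singleton_removed():
    s = cs([("chr1", 10 * MB, MAT, "chr2", 20 * MB, MAT)])
    assert len(remove_isolated(s, PARAMS)) == 0


def test_two_neighbors_at_9mb_suffice():
    base = [("chr1", 10 * MB, MAT, "chr2", 20 * MB, MAT)]
    # neighbors at L0.5 distance 9 Mb (dx = 9 Mb, dy = 0)
    nb = [("chr1", 10 * MB + 9 * MB, MAT, "chr2", 20 * MB, MAT),
          ("chr1", 10 * MB - 9 * MB, MAT, "chr2", 20 * MB, MAT)]
    out = remove_isolated(cs(base + nb), PARAMS)
    kept = rows_of(out)
    assert (0, 10 * MB, 0, 1, 20 * MB, 0) in kept


def test_far_contact_removed_close_cluster_kept():
    cluster = [("chr1", 10 * MB + i * MB, MAT, "chr2", 20 * MB, MAT)
               for i in range(3)]
    far = [("chr1", 150 * MB, MAT, "chr2", 180 * MB, MAT)]
    out = remove_isolated(cs(cluster + far), PARAMS)
    assert len(out) == 3
    assert all(r[1] < 100 * MB for r in rows_of(out))


def test_different_haplotypes_do_not_count_as_neighbors():
    rows = [("chr1", 10 * MB, MAT, "chr2", 20 * MB, MAT),
            ("chr1", 11 * MB, PAT, "chr2", 20 * MB, MAT),
            ("chr1", 12 * MB, MAT, "chr2", 20 * MB, PAT)]
    assert len(remove_isolated(cs(rows), PARAMS)) == 0


def test_remove_isolated_matches_oracle_and_is_order_independent():
    rng = np.random.default_rng(7)
    for _ in range(6):
        s = random_set(rng, rng.integers(50, 250))
        fast = sorted(rows_of(remove_isolated(s, PARAMS)))
        slow = sorted(ref_remove_isolated(rows_of(s), PARAMS))
        assert fast == slow
        perm = rng.permutation(len(s))
        shuffled = s.select(perm)
        assert sorted(rows_of(remove_isolated(shuffled, PARAMS))) == fast


# ------------------------------------------------------------ full pipeline
def test_fully_phased_input_only_cleaned():
    rows = [("chr1", 10 * MB + i * MB, MAT, "chr2", 20 * MB, MAT) for i in range(3)]
    rows += [("chr1", 150 * MB, MAT, "chr2", 180 * MB, MAT)]     # isolated
    result = impute_pipeline(cs(rows))
    assert len(result.contacts) == 3
    assert result.contacts.stage == "cleaned"


def test_empty_input_warns_and_returns_empty():
    result = impute_pipeline(ContactSet.empty(BIG))
    assert len(result.contacts) == 0


def test_zero_rounds_still_cleans_and_runs_final_round():
    rows = [("chr1", 10 * MB + i * MB, MAT, "chr2", 20 * MB, MAT) for i in range(4)]
    rows += [("chr1", 11 * MB, UNKNOWN, "chr2", 20 * MB, UNKNOWN)]
    result = impute_pipeline(cs(rows), ImputationParams(rounds=0))
    kinds = [e["kind"] for e in result.log]
    assert "vote" not in kinds
    assert "clean" in kinds and "final_interchromosomal" in kinds
    # final round resolved the interchromosomal both-unknown contact
    assert result.n_unknown_legs == 0


def test_pipeline_requires_raw_stage(small_cell):
    _, contacts, _, _ = small_cell
    with pytest.raises(ValueError):
        impute_pipeline(contacts.with_stage("imputed"))


# ------------------------------------------------------------ density law
def _rejection_sample(n, rng, weight, wmax, lo, hi):
    """Draw from p(dx, dy) ~ weight(dx, dy)/(dx*dy) on [lo, hi]^2 by
    rejection from a log-uniform proposal (whose density is ~1/(dx*dy))."""
    xs, ys = np.empty(0), np.empty(0)
    while len(xs) < n:
        dx = np.exp(rng.uniform(np.log(lo), np.log(hi), 400_000))
        dy = np.exp(rng.uniform(np.log(lo), np.log(hi), 400_000))
        w = weight(dx, dy)
        keep = rng.random(len(w)) < w / wmax
        xs = np.concatenate([xs, dx[keep]])
        ys = np.concatenate([ys, dy[keep]])
    return xs[:n], ys[:n]


def sample_l05_law(n, rng, lo=1e4, hi=1e7):
    """p(dx, dy) ~ (sqrt(dx)+sqrt(dy))**-2 on [lo, hi]^2."""
    return _rejection_sample(
        n, rng, lambda x, y: x * y / (np.sqrt(x) + np.sqrt(y)) ** 4, 1 / 16, lo, hi
    )


def sample_l1_law(n, rng, lo=1e4, hi=1e7):
    """p(dx, dy) ~ (dx + dy)**-1 on [lo, hi]^2."""
    return _rejection_sample(
        n, rng, lambda x, y: x * y / (x + y), hi / 2, lo, hi
    )


def test_density_law_recovered_and_model_selected():
    rng = np.random.default_rng(0)
    dx, dy = sample_l05_law(30_000, rng)
    fit = fit_conditional_density(dx, dy)
    assert fit["preferred"] == "l05"
    assert fit["l05"]["exponent"] == pytest.approx(-2.0, abs=0.3)

    dx, dy = sample_l1_law(30_000, rng)
    fit = fit_conditional_density(dx, dy)
    assert fit["preferred"] == "l1"
    assert fit["l1"]["exponent"] == pytest.approx(-1.0, abs=0.3)


def test_density_degenerate_support_rejected():
    dx = np.full(100, 1e6)
    dy = np.full(100, 1e6)
    with pytest.raises(ValueError, match="degenerate"):
        fit_conditional_density(dx, dy)
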