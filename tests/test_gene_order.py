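"""Signed gene-order analysis, checked against brute-force oracles."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_signed_order
from mitoarch import datasets
from mitoarch.errors import AnchorError, EmptyOrderError, IncomparableError
from mitoarch.gene_order import (
    CLUSTER1,
    CLUSTER2,
    SignedGeneOrder,
    adjacency_set,
    canonicalize,
    classify_cluster_orientation,
    classify_clusters,
    detect_trna_complex,
    diff_orders,
    extract_gene_order,
    find_conserved_blocks,
)
from mitoarch.synthetic import RearrangementEvent, apply_events


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_canonicalize(order: SignedGeneOrder, anchor: str) -> SignedGeneOrder:
    """Enumerate all rotations of the order and of its reflection; return the
    unique variant that starts with the anchor on the plus strand."""
    candidates = []
    for variant in (order, order.reflected()):
        for k in range(len(variant)):
            rot = variant.rotated(k)
            if rot.genes[0][0] == anchor and rot.genes[0][1] == 1:
                candidates.append(rot)
    assert len(candidates) == 1
    return candidates[0]


def brute_adjacencies(order: SignedGeneOrder) -> set:
    """All signed neighbor pairs, closed under reading direction."""
    out = set()
    genes = order.genes
    n = len(genes)
    for i in range(n):
        a, b = genes[i], genes[(i + 1) % n]
        out.add((a, b))
        out.add(((b[0], -b[1]), (a[0], -a[1])))
    return out


def brute_conserved_windows(orders, min_len):
    """Every cyclic window of the first order that appears, contiguously and
    with the same relative order and signs (possibly globally reflected), in
    every other order; maximal windows only."""

    def occurs(window, order):
        k = len(window)
        for variant in (order, order.reflected()):
            doubled = variant.genes + variant.genes
            for i in range(len(variant)):
                if tuple(doubled[i:i + k]) == tuple(window):
                    return True
        return False

    ref = orders[0]
    n = len(ref)
    wins = []
    for length in range(min_len, n + 1):
        for start in range(n):
            if length == n and start > 0:
                continue
            window = tuple(ref.rotated(start).genes[:length])
            if all(occurs(window, o) for o in orders[1:]):
                wins.append(window)

    def contained(small, big):
        ss = [g for g, _s in small]
        big_toks = [g for g, _s in big]
        # the full-circle window wraps; shorter windows are linear
        sb = big_toks + big_toks if len(big) == n else big_toks
        return any(sb[i:i + len(ss)] == ss
                   for i in range(len(sb) - len(ss) + 1))

    maximal = {tuple(g for g, _s in w) for w in wins
               if not any(len(o) > len(w) and contained(w, o) for o in wins)}
    return maximal


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 10_000), st.integers(3, 10))
def test_canonical_form_invariant_under_rotation_and_reflection(seed, n):
    rng = random.Random(seed)
    order = random_signed_order(rng, n)
    anchor = order.genes[rng.randrange(n)][0]
    reference = canonicalize(order, anchor)
    assert reference.genes == brute_canonicalize(order, anchor).genes
    for k in range(n):
        assert canonicalize(order.rotated(k), anchor).genes == reference.genes
        assert canonicalize(order.rotated(k).reflected(), anchor).genes \
            == reference.genes


def test_canonicalize_is_idempotent_and_anchor_fallbacks_work():
    rng = random.Random(7)
    order = random_signed_order(rng, 8)
    c = canonicalize(order, order.genes[0][0])
    assert canonicalize(c, order.genes[0][0]).genes == c.genes

    no_cox = SignedGeneOrder("x", (("trnA", 1), ("cob", -1), ("trnM", 1)))
    assert canonicalize(no_cox).genes[0] == ("cob", 1)  # fallback chain
    with pytest.raises(AnchorError):
        canonicalize(SignedGeneOrder("x", (("trnA", 1), ("trnM", 1))))
    with pytest.raises(EmptyOrderError):
        canonicalize(SignedGeneOrder("x", ()))


def test_extract_gene_order_views(antarctica):
    full = extract_gene_order(antarctica)
    assert len(full) == 37
    pcg_rrna = extract_gene_order(antarctica, {"PCG", "rRNA"})
    assert len(pcg_rrna) == 15
    with pytest.raises(EmptyOrderError):
        extract_gene_order(datasets.ground_pattern(), {"tRNA"})


# ---------------------------------------------------------------------------
# cluster orientation (ground-pattern comparison)
# ---------------------------------------------------------------------------

def pcg_rrna_order(record):
    return extract_gene_order(record, {"PCG", "rRNA"})


@pytest.mark.parametrize("maker, expected", [
    (datasets.ground_pattern, ("forward", "forward")),
    (datasets.laevipilina_antarctica, ("inverted", "forward")),
    (datasets.vema_ewingi, ("inverted", "forward")),
    (datasets.sypharochiton, ("inverted", "forward")),
    (datasets.katharina_tunicata, ("forward", "inverted")),
])
def test_cluster_orientation_reproduces_published_arrow_table(maker, expected):
    calls = classify_clusters(pcg_rrna_order(maker()))
    assert (calls["cluster1"].call, calls["cluster2"].call) == expected


def test_partial_call_for_genome_missing_atp8(hyalina):
    calls = classify_clusters(pcg_rrna_order(hyalina))
    assert calls["cluster1"].call == "partial_inverted"
    assert calls["cluster1"].genes_missing == ("atp8",)
    assert calls["cluster2"].call == "forward"


def test_absent_and_disrupted_calls():
    only_c2 = SignedGeneOrder("x", tuple(
        (g, 1) for g in CLUSTER2.genes))
    assert classify_cluster_orientation(only_c2, CLUSTER1).call == "absent"
    shuffled = SignedGeneOrder("x", (
        ("cox3", 1), ("nad2", 1), ("nad3", 1), ("cox1", 1), ("cox2", 1),
        ("atp8", 1), ("atp6", 1)))
    assert classify_cluster_orientation(shuffled, CLUSTER1).call == "disrupted"


def test_single_synthetic_inversion_flips_only_cluster1():
    ground = pcg_rrna_order(datasets.ground_pattern())
    calls0 = classify_clusters(ground)
    assert {c.call for c in calls0.values()} == {"forward"}
    inverted = apply_events(ground, [
        RearrangementEvent("inversion", CLUSTER1.genes)])
    calls1 = classify_clusters(inverted)
    assert calls1["cluster1"].call == "inverted"
    assert calls1["cluster2"].call == "forward"


# ---------------------------------------------------------------------------
# adjacency differences
# ---------------------------------------------------------------------------

def test_diff_identity_and_symmetry(antarctica, vema):
    a = canonicalize(extract_gene_order(antarctica))
    v = canonicalize(extract_gene_order(vema))
    assert diff_orders(a, a).breakpoints == 0
    assert diff_orders(a, a).differing_genes == ()
    assert diff_orders(a, v).breakpoints == diff_orders(v, a).breakpoints


def test_published_difference_between_the_two_complete_genomes(antarctica, vema):
    d = diff_orders(canonicalize(extract_gene_order(antarctica)),
                    canonicalize(extract_gene_order(vema)))
    assert d.differing_genes == ("trnC",)
    assert d.breakpoints == 3  # old site, new site and the vacated junction


def test_breakpoints_match_brute_force_after_block_inversion():
    rng = random.Random(20240917)
    for _ in range(25):
        order = random_signed_order(rng, 12)
        start = rng.randrange(12)
        block = tuple(g for g, _s in order.rotated(start).genes[:3])
        mutated = apply_events(order, [RearrangementEvent("inversion", block)])
        a, b = canonicalize(order, order.genes[0][0]), \
            canonicalize(mutated, order.genes[0][0])
        d = diff_orders(a, b)
        brute = {adj for adj in brute_adjacencies(a)} \
            - {adj for adj in brute_adjacencies(b)}
        # count neutral-representative pairs only (each adjacency appears
        # twice in the closed brute set)
        assert d.breakpoints == len(brute) // 2


def test_incomparable_orders_raise():
    a = SignedGeneOrder("a", (("cox1", 1), ("cob", 1)))
    b = SignedGeneOrder("b", (("trnA", 1), ("trnM", 1)))
    with pytest.raises(IncomparableError):
        diff_orders(a, b)


# ---------------------------------------------------------------------------
# conserved blocks
# ---------------------------------------------------------------------------

def test_single_order_duplicated_gives_whole_order_as_block():
    rng = random.Random(5)
    order = random_signed_order(rng, 8)
    blocks = find_conserved_blocks([order, order])
    assert blocks == [order.tokens]


def test_published_conserved_block_present_in_monoplacophora():
    orders = [pcg_rrna_order(r) for r in datasets.monoplacophora()]
    blocks = find_conserved_blocks(orders)
    joined = ["-".join(b) for b in blocks]
    assert any("rrnS-rrnL-nad1-nad6-cob" in s for s in joined)
    # second conserved lophotrochozoan block, modulo tRNAs
    assert any("nad4L-nad4-nad5" in s for s in joined)


def test_conserved_blocks_match_window_enumeration_oracle():
    rng = random.Random(424242)
    for _ in range(20):
        base = random_signed_order(rng, 9)
        perturbed = []
        for _k in range(3):
            start = rng.randrange(9)
            block = tuple(g for g, _s in base.rotated(start).genes[:2])
            perturbed.append(apply_events(base, [
                RearrangementEvent("inversion", block)]))
        orders = [base] + perturbed
        got = set(find_conserved_blocks(orders, min_len=2))
        expected = brute_conserved_windows(orders, min_len=2)
        assert got == expected


def test_planted_block_recovered_from_random_orders():
    from mitoarch.nomenclature import ALL_TOKENS

    rng = random.Random(99)
    planted = ("rrnS", "rrnL", "nad1", "nad6")
    orders = []
    others = [t for t in ALL_TOKENS if t not in planted][:8]
    for i in range(20):
        rest = others[:]
        rng.shuffle(rest)
        insert_at = rng.randrange(len(rest) + 1)
        sign = rng.choice((1, -1))
        if sign == 1:
            block = [(g, 1) for g in planted]
        else:
            block = [(g, -1) for g in reversed(planted)]
        genes = [(g, rng.choice((1, -1))) for g in rest]
        genes[insert_at:insert_at] = block
        orders.append(SignedGeneOrder(f"t{i}", tuple(genes)))
    blocks = find_conserved_blocks(orders, min_len=3)
    assert any(set(planted) <= set(b) for b in blocks)

    # every reported block must be contiguous (in some reading direction)
    # in every single input order
    def contiguous_in(block, order):
        toks = [g for g, _s in order.genes]
        doubled = toks + toks
        fwd = list(block)
        rev = list(reversed(block))
        return any(doubled[i:i + len(block)] in (fwd, rev)
                   for i in range(len(toks)))

    for b in blocks:
        assert all(contiguous_in(b, o) for o in orders)
    # no two blocks share a gene
    seen = [g for b in blocks for g in b]
    assert len(seen) == len(set(seen))


# ---------------------------------------------------------------------------
# tRNA complexes
# ---------------------------------------------------------------------------

def test_trna_complexes_of_published_arrangements(antarctica, vema):
    full_v = extract_gene_order(vema)
    hit = detect_trna_complex(full_v, "GEWDCYKNM")
    assert hit["orientation"] == "forward"
    assert hit["found_as"] == ["trnG", "trnE", "trnW", "trnD", "trnC",
                               "trnY", "trnK", "trnN", "trnM"]
    full_a = extract_gene_order(antarctica)
    assert detect_trna_complex(full_a, "ARI")["orientation"] == "forward"
    assert detect_trna_complex(full_a, "KARNI")["orientation"] == "absent"
    # reversed reading is reported as such
    assert detect_trna_complex(full_a, "IRA")["orientation"] == "reversed"


def test_complex_absent_when_member_missing_or_interrupted():
    toy = SignedGeneOrder("t", (("trnA", 1), ("cox1", 1), ("trnQ", 1)))
    assert detect_trna_complex(toy, "WQ")["orientation"] == "absent"
    # a protein-coding gene between the members breaks the complex
    split = SignedGeneOrder("t", (("trnW", 1), ("cox1", 1), ("trnQ", 1),
                                  ("nad1", 1)))
    assert detect_trna_complex(split, "WQ")["orientation"] == "absent"
    toy2 = SignedGeneOrder("t", (("trnW", 1), ("trnA", 1), ("trnQ", 1)))
    hit = detect_trna_complex(toy2, "WQ")
    assert hit["orientation"] == "forward"
    assert hit["interlopers"] == ["trnA"]  # reported, not silently tolerated
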