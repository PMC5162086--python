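"""Rearrangement simulation and synthetic-genome generation.

Event application is checked against independent naive list surgery; full
genomes are checked for determinism, length conservation and exact recovery
of the planted architecture by the analysis modules.
"""

import random

import pytest

from conftest import random_signed_order
from mitoarch.errors import EventError, SpecError
from mitoarch.gene_order import (
    SignedGeneOrder,
    classify_clusters,
    extract_gene_order,
)
from mitoarch.motifs import MOTIF1, at_repeat_runs, scan_motif
from mitoarch.noncoding import extract_ncrs, gc_content
from mitoarch.synthetic import (
    PlantedNcr,
    RearrangementEvent,
    SyntheticSpec,
    apply_events,
    generate_genome,
)


# ---------------------------------------------------------------------------
# naive oracle: linear list surgery on non-wrapping targets
# ---------------------------------------------------------------------------

def naive_apply(genes, event):
    genes = list(genes)
    toks = [g for g, _s in genes]
    m = len(event.target)
    start = None
    for i in range(len(toks) - m + 1):
        if toks[i:i + m] == list(event.target):
            start = i
            break
    assert start is not None, "oracle only handles non-wrapping forward runs"
    seg = genes[start:start + m]
    if event.kind == "inversion":
        genes[start:start + m] = [(g, -s) for g, s in reversed(seg)]
    elif event.kind == "translocation":
        rest = genes[:start] + genes[start + m:]
        d = event.destination % (len(rest) + 1)
        genes = rest[:d] + seg + rest[d:]
    else:
        first = [g for g, k in zip(seg, event.keep) if k == 1]
        second = [g for g, k in zip(seg, event.keep) if k == 2]
        genes[start:start + m] = first + second
    return tuple(genes)


def random_event(rng, order, start, m):
    target = tuple(g for g, _s in order.genes[start:start + m])
    kind = rng.choice(["inversion", "translocation", "tdrl"])
    if kind == "inversion":
        return RearrangementEvent("inversion", target)
    if kind == "translocation":
        return RearrangementEvent("translocation", target,
                                  destination=rng.randrange(len(order) - m + 1))
    return RearrangementEvent(
        "tdrl", target, keep=tuple(rng.choice((1, 2)) for _ in target))


def test_event_application_matches_naive_list_surgery():
    rng = random.Random(1234)
    for _ in range(60):
        order = random_signed_order(rng, 10)
        current = order
        expected = order.genes
        for _k in range(rng.randint(1, 3)):
            n = len(current)
            m = rng.randint(1, 3)
            start = rng.randrange(n - m)  # non-wrapping for the oracle
            ev = random_event(rng, current, start, m)
            expected = naive_apply(expected, ev)
            current = apply_events(current, [ev])
        assert current.genes == expected


def test_inversion_is_an_involution_and_empty_events_identity():
    rng = random.Random(9)
    order = random_signed_order(rng, 8)
    target = tuple(g for g, _s in order.genes[2:5])
    ev = RearrangementEvent("inversion", target)
    once = apply_events(order, [ev])
    # after inversion the run reads in the opposite direction
    twice = apply_events(once, [RearrangementEvent(
        "inversion", tuple(reversed(target)))])
    assert twice.genes == order.genes
    assert apply_events(order, []).genes == order.genes


def test_event_errors():
    order = SignedGeneOrder("t", (("cox1", 1), ("cob", 1), ("nad1", 1),
                                  ("atp6", 1)))
    with pytest.raises(EventError):
        apply_events(order, [RearrangementEvent(
            "inversion", ("cox1", "nad1"))])  # not contiguous
    with pytest.raises(EventError):
        apply_events(order, [RearrangementEvent("inversion", ("trnA",))])
    with pytest.raises(EventError):
        RearrangementEvent("tdrl", ("cox1",), keep=None)
    with pytest.raises(EventError):
        RearrangementEvent("translocation", ("cox1",))


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def control_region_spec(seed=42):
    return SyntheticSpec(
        base_order="laevipilina_antarctica",
        ncrs=[PlantedNcr("trnF", 2000, motif_id="motif1", motif_offset=893),
              PlantedNcr("trnG", 181, at_units=7, at_offset=50),
              PlantedNcr("nad2", 478, motif_id="motif2", motif_offset=23)],
        overlaps=[(("trnY", "trnK"), 5), (("trnM", "rrnS"), 2)],
        gc_target=0.355, seed=seed)


def test_generation_is_deterministic_for_fixed_seed(tmp_path):
    from mitoarch.io_annotations import write_genbank

    rec1, _ = generate_genome(control_region_spec())
    rec2, _ = generate_genome(control_region_spec())
    assert rec1.sequence == rec2.sequence
    p1, p2 = tmp_path / "a.gb", tmp_path / "b.gb"
    write_genbank(rec1, p1)
    write_genbank(rec2, p2)
    assert p1.read_text() == p2.read_text()
    rec3, _ = generate_genome(control_region_spec(seed=43))
    assert rec3.sequence != rec1.sequence


def test_planted_architecture_recovered_exactly():
    rec, truth = generate_genome(control_region_spec())
    assert extract_gene_order(rec).genes == truth.order.genes

    ncrs, overlaps = extract_ncrs(rec)
    got_overlaps = {(o.gene_a, o.gene_b): o.overlap_length for o in overlaps}
    assert got_overlaps == {(d["gene_a"], d["gene_b"]): d["overlap_length"]
                            for d in truth.overlaps}
    got_ncrs = {(r.flank5, r.flank3): r.length for r in ncrs}
    for d in truth.ncrs:
        assert got_ncrs[(d["flank5"], d["flank3"])] == d["length"]

    by_flanks = {(r.flank5, r.flank3): r for r in ncrs}
    for d in truth.ncrs:
        region = by_flanks[(d["flank5"], d["flank3"])]
        if "motif_id" in d:
            from mitoarch.motifs import DEFAULT_MOTIFS
            motif = next(m for m in DEFAULT_MOTIFS if m.id == d["motif_id"])
            hits = scan_motif(region.sequence, motif)
            assert any(h.start_in_ncr == d["motif_offset"] for h in hits)
        if "at_units" in d:
            runs = at_repeat_runs(region.sequence)
            assert any(r.unit_count == d["at_units"]
                       and r.start_in_ncr == d["at_offset"] for r in runs)


def test_cluster_calls_in_truth_match_classifier():
    spec = SyntheticSpec(base_order="ground_pattern", seed=7, events=[
        RearrangementEvent("inversion", (
            "cox3", "nad3", "nad2", "cox1", "cox2", "atp8", "atp6"))])
    rec, truth = generate_genome(spec)
    calls = classify_clusters(extract_gene_order(rec, {"PCG", "rRNA"}))
    assert {k: c.call for k, c in calls.items()} == truth.cluster_calls
    assert truth.cluster_calls == {"cluster1": "inverted",
                                   "cluster2": "forward"}


def test_length_conservation_over_seeded_sweep():
    rng = random.Random(2024)
    for seed in range(30):
        spec = SyntheticSpec(
            base_order="ground_pattern", seed=seed,
            ncrs=[PlantedNcr("nad5", 120 + seed),
                  PlantedNcr("cox2", 35)],
            overlaps=[(("rrnS", "rrnL"), 1 + seed % 20)],
            gc_target=0.25 + (seed % 10) * 0.05)
        rec, _ = generate_genome(spec)
        ncrs, overlaps = extract_ncrs(rec)
        total = sum(f.length for f in rec.features) \
            + sum(r.length for r in ncrs) \
            - sum(o.overlap_length for o in overlaps)
        assert total == rec.length


def test_gc_target_hit_within_tolerance():
    for seed, gc in ((1, 0.25), (2, 0.36), (3, 0.5)):
        spec = SyntheticSpec(base_order="laevipilina_antarctica",
                             gc_target=gc, seed=seed)
        rec, _ = generate_genome(spec)
        assert rec.length >= 10_000
        assert abs(gc_content(rec.sequence) - gc) < 0.02


def test_spec_validation_errors():
    with pytest.raises(SpecError):
        generate_genome(SyntheticSpec(base_order="nonsense"))
    with pytest.raises(SpecError):
        generate_genome(SyntheticSpec(
            base_order="ground_pattern",
            overlaps=[(("cox1", "cob"), 4)]))   # not adjacent
    with pytest.raises(SpecError):
        generate_genome(SyntheticSpec(
            base_order="ground_pattern",
            ncrs=[PlantedNcr("cox1", 10, motif_id="motif1")]))  # too short
    with pytest.raises(SpecError):
        generate_genome(SyntheticSpec(base_order="ground_pattern",
                                      gc_target=1.5))


def test_write_read_round_trip_of_generated_genome(tmp_path):
    from mitoarch.io_annotations import read_genbank, write_genbank

    rec, truth = generate_genome(control_region_spec())
    path = tmp_path / "syn.gb"
    write_genbank(rec, path)
    back = read_genbank(path)
    assert back.length == rec.length
    assert back.sequence == rec.sequence
    assert [(f.name, f.strand, f.start, f.end, f.copy_index)
            for f in back.features] == \
        [(f.name, f.strand, f.start, f.end, f.copy_index)
         for f in rec.features]
    assert extract_gene_order(back).genes == truth.order.genes
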