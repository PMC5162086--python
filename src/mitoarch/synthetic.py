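"""Synthetic annotated mitogenomes with known architecture.

A :class:`SyntheticSpec` describes a circular genome as a base signed gene
order, a list of rearrangement events (inversion, translocation, tandem
duplication random loss), per-gene lengths, planted intergenic NCRs
(optionally carrying a motif instance and/or an ``(AT)_n`` repeat at known
offsets), planted feature overlaps, and a GC target.  The generator emits a
fully sequenced :class:`~mitoarch.records.MitogenomeRecord` plus a
:class:`SyntheticTruth` carrying everything the analysis modules should
recover -- so every pipeline stage can be validated against ground truth
without any downloads.

All randomness comes from one ``numpy`` generator seeded by ``spec.seed``;
the same spec always produces byte-identical output.

TDRL semantics: the target run is duplicated in tandem; the keep-pattern
chooses, per gene, whether the first or the second tandem copy survives
(genes marked 1 keep the first copy, 2 the second), which reproduces the
classic tandem-duplication--random-loss move on gene orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EventError, SpecError
from .gene_order import SignedGeneOrder, REFERENCE_CLUSTERS
from .motifs import DEFAULT_MOTIFS, MotifDefinition
from .nomenclature import TRNA, strip_copy_suffix, token_kind
from .records import GeneFeature, MitogenomeRecord
from . import datasets

#: default gene lengths (bp), loosely following typical molluscan mtDNA
DEFAULT_GENE_LENGTHS = {
    "cox1": 1536, "cox2": 690, "cox3": 780, "cob": 1140,
    "nad1": 930, "nad2": 1050, "nad3": 351, "nad4": 1377,
    "nad4L": 297, "nad5": 1719, "nad6": 501,
    "atp6": 678, "atp8": 159, "rrnS": 840, "rrnL": 1280,
}
DEFAULT_TRNA_LENGTH = 65

NAMED_BASE_ORDERS = {
    "ground_pattern": lambda: datasets.ground_pattern(),
    "laevipilina_antarctica": lambda: datasets.laevipilina_antarctica(),
    "vema_ewingi": lambda: datasets.vema_ewingi(),
}


@dataclass(frozen=True)
class RearrangementEvent:
    """One rearrangement applied to a signed circular gene order.

    kind='inversion': ``target`` genes (a contiguous run) are reversed and
    strand-flipped in place.
    kind='translocation': the run is excised and reinserted unchanged at
    ``destination`` (an index into the order after excision).
    kind='tdrl': the run is duplicated in tandem, then ``keep`` (sequence of
    1/2 per target gene) selects the surviving copy of each gene.
    """

    kind: str
    target: tuple[str, ...]
    destination: int | None = None
    keep: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("inversion", "translocation", "tdrl"):
            raise EventError(f"unknown event kind {self.kind!r}")
        if not self.target:
            raise EventError("event target is empty")
        if self.kind == "translocation" and self.destination is None:
            raise EventError("translocation needs a destination index")
        if self.kind == "tdrl":
            if self.keep is None or len(self.keep) != len(self.target):
                raise EventError("tdrl needs one keep choice per target gene")
            if any(k not in (1, 2) for k in self.keep):
                raise EventError("tdrl keep-pattern entries must be 1 or 2")


@dataclass
class PlantedNcr:
    after_gene: str
    length: int
    motif_id: str | None = None
    motif_offset: int | None = None     # 1-based within the NCR
    at_units: int | None = None
    at_offset: int | None = None        # 1-based within the NCR


@dataclass
class SyntheticSpec:
    base_order: str | SignedGeneOrder = "ground_pattern"
    events: list[RearrangementEvent] = field(default_factory=list)
    gene_lengths: dict[str, int] = field(default_factory=dict)
    ncrs: list[PlantedNcr] = field(default_factory=list)
    overlaps: list[tuple[tuple[str, str], int]] = field(default_factory=list)
    gc_target: float = 0.36
    seed: int = 0
    taxon: str = "synthetic"
    intergenic_spacer: int = 2   # bp of plain spacer between non-overlapping genes

    def resolve_base(self) -> SignedGeneOrder:
        if isinstance(self.base_order, SignedGeneOrder):
            return self.base_order
        try:
            record = NAMED_BASE_ORDERS[self.base_order]()
        except KeyError:
            raise SpecError(f"unknown base order {self.base_order!r}")
        from .gene_order import extract_gene_order
        return extract_gene_order(record)


@dataclass
class SyntheticTruth:
    order: SignedGeneOrder
    cluster_calls: dict[str, str]
    ncrs: list[dict]            # flank5, flank3, length, motif/repeat positions
    overlaps: list[dict]
    gc_target: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "taxon": self.order.taxon,
            "arrangement": self.order.arrangement_string(),
            "signs": [s for _g, s in self.order.genes],
            "cluster_calls": self.cluster_calls,
            "ncrs": self.ncrs,
            "overlaps": self.overlaps,
            "gc_target": self.gc_target,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# event application
# ---------------------------------------------------------------------------

def _find_run(genes: tuple[tuple[str, int], ...],
              target: tuple[str, ...]) -> list[int]:
    """Indices of a contiguous cyclic run matching the target tokens, in
    either reading direction.  Raises EventError if absent/non-contiguous."""
    n = len(genes)
    toks = [g for g, _s in genes]
    m = len(target)
    if m > n:
        raise EventError(f"target {target} longer than order")
    for start in range(n):
        fwd = [toks[(start + k) % n] for k in range(m)]
        if fwd == list(target):
            return [(start + k) % n for k in range(m)]
        rev = [toks[(start - k) % n] for k in range(m)]
        if rev == list(target):
            return [(start - k) % n for k in range(m)]
    missing = [t for t in target if t not in toks]
    if missing:
        raise EventError(f"target genes absent from order: {missing}")
    raise EventError(f"target {target} is not a contiguous run in the order")


def apply_events(order: SignedGeneOrder,
                 events: list[RearrangementEvent]) -> SignedGeneOrder:
    """Apply rearrangement events in list order to a signed circular order."""
    genes = list(order.genes)
    for ev in events:
        idx = _find_run(tuple(genes), ev.target)
        if ev.kind == "inversion":
            segment = [genes[i] for i in idx]
            flipped = [(g, -s) for g, s in reversed(segment)]
            for i, new in zip(idx, flipped):
                genes[i] = new
        elif ev.kind == "translocation":
            segment = [genes[i] for i in idx]
            remaining = [g for i, g in enumerate(genes) if i not in set(idx)]
            dest = ev.destination % (len(remaining) + 1)
            genes = remaining[:dest] + segment + remaining[dest:]
        else:  # tdrl
            segment = [genes[i] for i in idx]
            keep = ev.keep
            first = [g for g, k in zip(segment, keep) if k == 1]
            second = [g for g, k in zip(segment, keep) if k == 2]
            replacement = first + second
            # replace the run in place (run order follows idx)
            ordered_idx = idx
            out = []
            placed = False
            idx_set = set(ordered_idx)
            for i, g in enumerate(genes):
                if i in idx_set:
                    if not placed:
                        out.extend(replacement)
                        placed = True
                else:
                    out.append(g)
            genes = out
    return SignedGeneOrder(order.taxon, tuple(genes), order.included_kinds)


# ---------------------------------------------------------------------------
# sequence assembly
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _ncr_sequence(rng: np.random.Generator, planted: PlantedNcr,
                  gc: float) -> tuple[str, dict]:
    """Assemble one NCR sequence with its planted signals; returns the
    sequence and the truth entry fragment."""
    seq = list(_random_seq(rng, planted.length, gc))
    truth: dict = {"length": planted.length}

    def blank_region(lo: int, hi: int):
        # keep planted signals unambiguous: no accidental AT dinucleotide
        # alternation or motif echo directly adjacent
        for k in range(max(0, lo), min(len(seq), hi)):
            seq[k] = "G" if rng.random() < 0.5 else "C"

    if planted.at_units:
        run_len = 2 * planted.at_units
        off = planted.at_offset or int(rng.integers(1, max(2, planted.length - run_len)))
        if off + run_len - 1 > planted.length:
            raise SpecError(
                f"(AT)_{planted.at_units} at offset {off} exceeds NCR length "
                f"{planted.length}")
        blank_region(off - 3, off + run_len + 1)
        for k in range(planted.at_units):
            seq[off - 1 + 2 * k] = "A"
            seq[off + 2 * k] = "T"
        truth["at_units"] = planted.at_units
        truth["at_offset"] = off

    if planted.motif_id:
        motif = next((m for m in DEFAULT_MOTIFS if m.id == planted.motif_id), None)
        if motif is None:
            raise SpecError(f"unknown planted motif {planted.motif_id!r}")
        mlen = len(motif)
        if mlen > planted.length:
            raise SpecError(
                f"motif {motif.id} ({mlen} bp) longer than NCR "
                f"({planted.length} bp)")
        off = planted.motif_offset or int(rng.integers(1, planted.length - mlen + 2))
        if off + mlen - 1 > planted.length:
            raise SpecError(
                f"motif {motif.id} at offset {off} exceeds NCR length "
                f"{planted.length}")
        instance = "".join(sorted(pos)[int(rng.integers(len(pos)))]
                           for pos in motif.positions())
        blank_region(off - mlen - 1, off - 1)
        blank_region(off + mlen - 1, off + 2 * mlen)
        seq[off - 1:off - 1 + mlen] = list(instance)
        truth["motif_id"] = motif.id
        truth["motif_offset"] = off
        truth["motif_instance"] = instance
    return "".join(seq), truth


def generate_genome(spec: SyntheticSpec
                    ) -> tuple[MitogenomeRecord, SyntheticTruth]:
    """Emit a sequenced record and its ground truth from a spec."""
    if spec.gc_target <= 0 or spec.gc_target >= 1:
        raise SpecError("gc_target must be in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    base = spec.resolve_base()
    order = apply_events(base, spec.events)

    lengths = dict(DEFAULT_GENE_LENGTHS)
    lengths.update(spec.gene_lengths)

    def gene_length(token: str) -> int:
        base_tok = strip_copy_suffix(token)
        if base_tok in lengths:
            return lengths[base_tok]
        if token_kind(base_tok) == TRNA:
            return DEFAULT_TRNA_LENGTH
        return 300

    ncr_after: dict[str, PlantedNcr] = {}
    for planted in spec.ncrs:
        if planted.after_gene in ncr_after:
            raise SpecError(f"two NCRs planted after {planted.after_gene}")
        if planted.after_gene not in order.tokens:
            raise SpecError(
                f"NCR after {planted.after_gene!r}: gene not in final order")
        if planted.length < 1:
            raise SpecError("NCR length must be >= 1")
        ncr_after[planted.after_gene] = planted

    overlap_after: dict[str, int] = {}
    toks = order.tokens
    n = len(toks)
    for (ga, gb), bp in spec.overlaps:
        if bp < 1:
            raise SpecError("overlap length must be >= 1")
        i = toks.index(ga) if ga in toks else -1
        if i < 0 or toks[(i + 1) % n] != gb:
            raise SpecError(f"overlap pair ({ga}, {gb}) not adjacent in order")
        if i == n - 1:
            raise SpecError("overlap across the origin is not supported")
        if bp >= gene_length(ga) or bp >= gene_length(gb):
            raise SpecError(f"overlap ({ga}, {gb}) longer than a member gene")
        if ga in ncr_after:
            raise SpecError(f"both an NCR and an overlap follow {ga}")
        overlap_after[ga] = bp

    # lay out the circle; every junction carries either a planted NCR, a
    # planted overlap, or the default spacer
    features: list[GeneFeature] = []
    seq_parts: list[str] = []
    truth_ncrs: list[dict] = []
    pos = 0
    name_counter: dict[str, int] = {}
    for i, (tok, sign) in enumerate(order.genes):
        glen = gene_length(tok)
        base_tok = strip_copy_suffix(tok)
        if "." in tok:
            # explicit copy suffix in the order wins over positional counting
            name_counter[base_tok] = int(tok.rsplit(".", 1)[1])
        else:
            name_counter[base_tok] = name_counter.get(base_tok, 0) + 1
        overlap = overlap_after.get(toks[i - 1]) if i > 0 else None
        if overlap:
            pos -= overlap
            seq_parts.append(_random_seq(rng, glen - overlap, spec.gc_target))
        else:
            seq_parts.append(_random_seq(rng, glen, spec.gc_target))
        features.append(GeneFeature(
            name=base_tok, kind=token_kind(base_tok), strand=sign,
            start=pos, end=pos + glen, copy_index=name_counter[base_tok]))
        pos += glen
        # junction after every gene, including the wrap back to the origin
        nxt = toks[(i + 1) % n]
        if tok in ncr_after:
            planted = ncr_after[tok]
            ncr_seq, truth = _ncr_sequence(rng, planted, spec.gc_target)
            seq_parts.append(ncr_seq)
            truth.update({"flank5": tok, "flank3": nxt, "start": pos})
            truth_ncrs.append(truth)
            pos += planted.length
        elif tok in overlap_after:
            pass  # next gene starts inside this one
        elif spec.intergenic_spacer > 0 and i < n - 1:
            seq_parts.append(_random_seq(rng, spec.intergenic_spacer,
                                         spec.gc_target))
            truth_ncrs.append({"flank5": tok, "flank3": nxt,
                               "length": spec.intergenic_spacer,
                               "start": pos})
            pos += spec.intergenic_spacer

    length = pos
    sequence = "".join(seq_parts)
    if len(sequence) != length:
        raise SpecError("internal layout error")  # pragma: no cover

    record = MitogenomeRecord(
        taxon=spec.taxon, length=length, circular=True,
        sequence=sequence, features=features,
        accession=f"SYN{spec.seed:06d}",
    )

    truth_overlaps = [
        {"gene_a": ga, "gene_b": toks[(toks.index(ga) + 1) % n],
         "overlap_length": bp}
        for ga, bp in overlap_after.items()
    ]
    truth = SyntheticTruth(
        order=order,
        cluster_calls={p.id: _expected_cluster_call(order, p.genes)
                       for p in REFERENCE_CLUSTERS},
        ncrs=truth_ncrs,
        overlaps=truth_overlaps,
        gc_target=spec.gc_target,
        seed=spec.seed,
    )
    return record, truth


def _expected_cluster_call(order: SignedGeneOrder,
                           pattern: tuple[str, ...]) -> str:
    """Minimal independent re-derivation of the cluster call for the truth
    object: positional order of the pattern genes vs the pattern."""
    found = [strip_copy_suffix(g) for g, _s in order.genes
             if strip_copy_suffix(g) in pattern]
    if not found:
        return "absent"
    reduced = [g for g in pattern if g in found]
    if len(found) != len(set(found)):
        return "disrupted"
    k = len(found)
    doubled = found + found
    fwd = any(doubled[i:i + k] == reduced for i in range(k))
    rev_found = list(reversed(found))
    doubled_r = rev_found + rev_found
    rev = any(doubled_r[i:i + k] == reduced for i in range(k))
    full = len(found) == len(pattern)
    if fwd:
        return "forward" if full else "partial_forward"
    if rev:
        return "inverted" if full else "partial_inverted"
    return "disrupted"


# ---------------------------------------------------------------------------
# YAML spec I/O
# ---------------------------------------------------------------------------

def load_spec_yaml(path, seed: int | None = None) -> SyntheticSpec:
    """Read a SyntheticSpec from YAML; ``seed`` overrides the file's seed."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    events = [
        RearrangementEvent(
            kind=e["kind"], target=tuple(e["target"]),
            destination=e.get("destination"),
            keep=tuple(e["keep"]) if e.get("keep") else None,
        )
        for e in doc.get("events", [])
    ]
    ncrs = [
        PlantedNcr(
            after_gene=d["after_gene"], length=int(d["length"]),
            motif_id=d.get("motif_id"), motif_offset=d.get("motif_offset"),
            at_units=d.get("at_units"), at_offset=d.get("at_offset"),
        )
        for d in doc.get("ncrs", [])
    ]
    overlaps = [((a, b), int(bp)) for (a, b), bp in
                [((o["gene_a"], o["gene_b"]), o["bp"])
                 for o in doc.get("overlaps", [])]]
    return SyntheticSpec(
        base_order=doc.get("base_order", "ground_pattern"),
        events=events,
        gene_lengths={k: int(v) for k, v in doc.get("gene_lengths", {}).items()},
        ncrs=ncrs,
        overlaps=overlaps,
        gc_target=float(doc.get("gc_target", 0.36)),
        seed=int(seed if seed is not None else doc.get("seed", 0)),
        taxon=str(doc.get("taxon", "synthetic")),
        intergenic_spacer=int(doc.get("intergenic_spacer", 2)),
    )
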