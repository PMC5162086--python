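"""Intergenic non-coding regions, feature overlaps and GC content.

NCRs are the positive circular gaps between consecutive annotated features
(by start position, strand-agnostic); negative gaps are overlaps.  Only
features of kind PCG/rRNA/tRNA bound NCRs -- annotation fragments of kind
'other' (e.g. residual gene parts inside a control region) do not split an
NCR and are recorded as sub-annotations instead.

The bookkeeping identity

    sum(feature lengths) + sum(NCR lengths) - sum(overlap lengths) = genome length

holds exactly for every circular record, because consecutive-pair gaps
telescope around the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import NotFoundError, UndefinedGCError
from .gene_order import extract_gene_order
from .nomenclature import OTHER, PCG, RRNA, TRNA, strip_copy_suffix
from .records import GeneFeature, MitogenomeRecord

BOUNDING_KINDS = {PCG, RRNA, TRNA}


@dataclass(frozen=True)
class NonCodingRegion:
    taxon: str
    flank5: str
    flank3: str
    start: int
    end: int          # may exceed genome length when the gap wraps the origin
    length: int
    sequence: str | None = None
    sub_annotations: tuple[str, ...] = ()   # 'other'-kind fragments inside
    terminal_gap: bool = False              # linear record's artificial gap

    @property
    def flank_pair(self) -> tuple[str, str]:
        """Flank tokens without copy suffixes, for cross-taxon matching."""
        return (strip_copy_suffix(self.flank5), strip_copy_suffix(self.flank3))


@dataclass(frozen=True)
class OverlapRegion:
    taxon: str
    gene_a: str
    gene_b: str
    overlap_length: int


@dataclass(frozen=True)
class NcrSizeBins:
    """NCR counts in the three size classes: <10 bp, 10-100 bp, >100 bp."""
    n_small: int
    n_mid: int
    n_large: int

    @property
    def total(self) -> int:
        return self.n_small + self.n_mid + self.n_large


def extract_ncrs(record: MitogenomeRecord
                 ) -> tuple[list[NonCodingRegion], list[OverlapRegion]]:
    """Catalogue all intergenic gaps and overlaps of a record.

    Features are chained in start order around the circle; each consecutive
    pair contributes its raw gap (positive -> NCR, negative -> overlap,
    zero -> nothing).  On a non-circular record the wrap gap between the last
    and first feature is still reported but flagged ``terminal_gap``.
    """
    bounding = [f for f in record.features if f.kind in BOUNDING_KINDS]
    fragments = [f for f in record.features if f.kind == OTHER]
    if not bounding:
        raise NotFoundError(f"{record.taxon}: no bounding features")

    name_counts: dict[str, int] = {}
    for f in bounding:
        name_counts[f.name] = name_counts.get(f.name, 0) + 1

    def tok(f: GeneFeature) -> str:
        return f.name if name_counts[f.name] == 1 else f"{f.name}.{f.copy_index}"

    ncrs: list[NonCodingRegion] = []
    overlaps: list[OverlapRegion] = []
    n = len(bounding)
    for i in range(n):
        a = bounding[i]
        b = bounding[(i + 1) % n]
        if i + 1 < n:
            gap = b.start - a.end
            gap_start, gap_end = a.end, b.start
            terminal = False
        else:
            gap = b.start + record.length - a.end
            gap_start, gap_end = a.end, b.start + record.length
            terminal = not record.circular
        if gap > 0:
            seq = (record.slice_circular(gap_start, gap_end)
                   if record.sequence is not None else None)
            subs = tuple(
                f.name for f in fragments
                if gap_start <= f.start and f.end <= gap_end
            )
            ncrs.append(NonCodingRegion(
                taxon=record.taxon, flank5=tok(a), flank3=tok(b),
                start=gap_start % record.length, end=gap_end,
                length=gap, sequence=seq, sub_annotations=subs,
                terminal_gap=terminal,
            ))
        elif gap < 0:
            overlaps.append(OverlapRegion(
                taxon=record.taxon, gene_a=tok(a), gene_b=tok(b),
                overlap_length=-gap,
            ))
    return ncrs, overlaps


def bin_ncrs(ncrs: list[NonCodingRegion]) -> NcrSizeBins:
    """Size classes <10 / 10-100 / >100 bp (both boundaries in the middle bin)."""
    small = sum(1 for r in ncrs if r.length < 10)
    mid = sum(1 for r in ncrs if 10 <= r.length <= 100)
    large = sum(1 for r in ncrs if r.length > 100)
    return NcrSizeBins(small, mid, large)


def largest_ncr(record: MitogenomeRecord) -> NonCodingRegion:
    """The longest NCR; ties broken by smallest start coordinate."""
    ncrs, _ = extract_ncrs(record)
    if not ncrs:
        raise NotFoundError(f"{record.taxon}: record has no NCRs")
    return max(ncrs, key=lambda r: (r.length, -r.start))


def _oriented_flank_pairs(record: MitogenomeRecord,
                          anchor: str = "cox1") -> set[tuple[str, str]]:
    """NCR flank pairs of a record, ordered in the record's canonical
    orientation (flanks swap when canonicalization reflects the genome)."""
    from .gene_order import ANCHOR_FALLBACKS

    ncrs, _ = extract_ncrs(record)
    # canonicalization reflects the record iff the anchor (or its first
    # present fallback) reads on the minus strand
    flipped = False
    order = extract_gene_order(record)
    base = order.base_tokens()
    for a in (anchor,) + tuple(x for x in ANCHOR_FALLBACKS if x != anchor):
        if a in base:
            flipped = order.genes[base.index(a)][1] == -1
            break
    pairs = set()
    for r in ncrs:
        p = r.flank_pair
        pairs.add((p[1], p[0]) if flipped else p)
    return pairs


def shared_ncr_boundaries(records: list[MitogenomeRecord],
                          mode: str = "strict") -> dict:
    """Cross-taxon matching of NCRs by their flanking genes.

    ``strict`` matches ordered (flank5, flank3) token pairs after orienting
    every record to its canonical reading direction.  ``relaxed``
    additionally projects flank genes absent from the common annotation onto
    the nearest annotated flank before matching, so a gene missing from one
    genome's annotation does not spoil the match.

    Returns ``{"per_ncr": {pair: [taxa]}, "all_taxa": count,
    "pairwise": {(taxon_a, taxon_b): count}}``.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"mode must be strict or relaxed, got {mode!r}")
    if len(records) < 2:
        raise NotFoundError("need at least two records to compare")

    if mode == "relaxed":
        common_genes = None
        for rec in records:
            toks = {strip_copy_suffix(f.token) for f in rec.features
                    if f.kind in BOUNDING_KINDS}
            common_genes = toks if common_genes is None else common_genes & toks
    taxa_pairs: dict[str, set[tuple[str, str]]] = {}
    for rec in records:
        pairs = _oriented_flank_pairs(rec)
        if mode == "relaxed":
            order = extract_gene_order(rec)
            base = list(order.base_tokens())
            n = len(base)

            def project(g: str, direction: int) -> str:
                if g in common_genes or g not in base:
                    return g
                i = base.index(g)
                for step in range(1, n):
                    cand = base[(i + direction * step) % n]
                    if cand in common_genes:
                        return cand
                return g

            pairs = {(project(f5, -1), project(f3, +1)) for f5, f3 in pairs}
        taxa_pairs[rec.taxon] = pairs

    per_ncr: dict[tuple[str, str], list[str]] = {}
    for taxon, pairs in taxa_pairs.items():
        for p in pairs:
            per_ncr.setdefault(p, []).append(taxon)
    all_count = sum(1 for taxa in per_ncr.values() if len(taxa) == len(records))
    pairwise = {}
    names = [r.taxon for r in records]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            pairwise[(a, b)] = len(taxa_pairs[a] & taxa_pairs[b])
    return {"per_ncr": per_ncr, "all_taxa": all_count, "pairwise": pairwise}


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T), case-insensitive; ambiguity codes are excluded from
    both numerator and denominator."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise UndefinedGCError("GC content undefined for empty/ambiguous sequence")
    return gc / (gc + at)


def at_content(sequence: str) -> float:
    return 1.0 - gc_content(sequence)


def feature_gc(record: MitogenomeRecord, feature: GeneFeature) -> float:
    """GC content of one feature's circular interval."""
    return gc_content(record.feature_sequence(feature))


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def ncr_table(record: MitogenomeRecord) -> str:
    """TSV NCR catalogue: taxon, flank5, flank3, start1, end1, length,
    is_largest."""
    ncrs, _ = extract_ncrs(record)
    best = max(ncrs, key=lambda r: (r.length, -r.start)) if ncrs else None
    lines = ["taxon\tflank5\tflank3\tstart1\tend1\tlength\tis_largest"]
    for r in ncrs:
        end1 = (r.end - 1) % record.length + 1
        lines.append(
            f"{r.taxon}\t{r.flank5}\t{r.flank3}\t{r.start + 1}\t{end1}\t"
            f"{r.length}\t{int(r is best)}"
        )
    return "\n".join(lines) + "\n"


def overlap_table(record: MitogenomeRecord) -> str:
    _, overlaps = extract_ncrs(record)
    lines = ["taxon\tgene_a\tgene_b\toverlap_length"]
    for o in overlaps:
        lines.append(f"{o.taxon}\t{o.gene_a}\t{o.gene_b}\t{o.overlap_length}")
    return "\n".join(lines) + "\n"
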