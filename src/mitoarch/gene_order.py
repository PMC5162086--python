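"""Signed circular gene orders and comparative arrangement analysis.

The object of study is the cyclic sequence of strand-signed genes of a
mitochondrial genome.  This module canonicalizes such orders (rotation to an
anchor gene, reflection so the anchor reads forward), classifies the
orientation of the two conserved lophotrochozoan protein-coding/rRNA clusters
against the ground pattern, computes signed-adjacency (breakpoint)
differences between arrangements, finds gene blocks conserved across a set of
arrangements, and locates named tRNA complexes.

Cluster-orientation semantics
-----------------------------
The two reference clusters are

* cluster 1: ``cox3-nad3-nad2-cox1-cox2-atp8-atp6``
* cluster 2: ``rrnS-rrnL-nad1-nad6-cob-nad4L-nad4-nad5``

both read forward in the lophotrochozoan ground pattern.  A cluster's call is
made from the *positional* order of its genes along the genome in the
record's own strand frame, after deleting every gene not in the cluster
pattern (tRNAs and the other cluster never break contiguity): pattern order
means ``forward``, reversed pattern order means ``inverted``.  The consensus
transcription strand of the cluster genes is reported separately; with MITOS
and GenBank annotations the strand labelling is a convention of the deposit,
and basing the call on positional order keeps it independent of that choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AnchorError, EmptyOrderError, IncomparableError, UnknownGeneError
from .nomenclature import PCG, RRNA, TRNA, strip_copy_suffix, trna_tokens_for_letter
from .records import MitogenomeRecord

#: anchor fallback chain used when the requested anchor is missing
ANCHOR_FALLBACKS = ("cox1", "cox2", "cox3", "cob", "rrnS")


@dataclass(frozen=True)
class SignedGeneOrder:
    """A cyclic sequence of (token, sign) pairs; sign is +1/-1."""

    taxon: str
    genes: tuple[tuple[str, int], ...]
    included_kinds: frozenset[str] = frozenset({PCG, RRNA, TRNA})

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(g for g, _s in self.genes)

    def base_tokens(self) -> tuple[str, ...]:
        """Tokens with copy suffixes stripped."""
        return tuple(strip_copy_suffix(g) for g, _s in self.genes)

    def sign_of(self, token: str) -> int:
        for g, s in self.genes:
            if g == token:
                return s
        raise KeyError(token)

    def rotated(self, k: int) -> "SignedGeneOrder":
        k %= len(self.genes)
        return SignedGeneOrder(self.taxon, self.genes[k:] + self.genes[:k],
                               self.included_kinds)

    def reflected(self) -> "SignedGeneOrder":
        """The same circular molecule read on the other strand:
        order reversed, every sign flipped."""
        return SignedGeneOrder(
            self.taxon,
            tuple((g, -s) for g, s in reversed(self.genes)),
            self.included_kinds,
        )

    def restrict(self, tokens: set[str]) -> "SignedGeneOrder":
        """Delete genes (by suffix-stripped token) not in ``tokens``."""
        kept = tuple((g, s) for g, s in self.genes
                     if strip_copy_suffix(g) in tokens)
        return SignedGeneOrder(self.taxon, kept, self.included_kinds)

    def arrangement_string(self) -> str:
        return "-".join(self.tokens)


@dataclass(frozen=True)
class ClusterPattern:
    id: str
    genes: tuple[str, ...]
    reference_sign: int = 1


CLUSTER1 = ClusterPattern(
    "cluster1", ("cox3", "nad3", "nad2", "cox1", "cox2", "atp8", "atp6"))
CLUSTER2 = ClusterPattern(
    "cluster2", ("rrnS", "rrnL", "nad1", "nad6", "cob", "nad4L", "nad4", "nad5"))
REFERENCE_CLUSTERS = (CLUSTER1, CLUSTER2)

FORWARD = "forward"
INVERTED = "inverted"
PARTIAL_FORWARD = "partial_forward"
PARTIAL_INVERTED = "partial_inverted"
DISRUPTED = "disrupted"
ABSENT = "absent"


@dataclass(frozen=True)
class ClusterOrientationCall:
    cluster_id: str
    call: str
    genes_found: tuple[str, ...]
    genes_missing: tuple[str, ...]
    strand: int = 0  # +1 / -1 consensus transcription strand, 0 if mixed/NA

    @property
    def arrow(self) -> str:
        return {FORWARD: "→", INVERTED: "←",
                PARTIAL_FORWARD: "(→)", PARTIAL_INVERTED: "(←)",
                DISRUPTED: "x", ABSENT: "∅"}[self.call]

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "call": self.call,
            "genes_found": list(self.genes_found),
            "genes_missing": list(self.genes_missing),
            "strand": self.strand,
        }


@dataclass(frozen=True)
class AdjacencyDiff:
    shared_adjacencies: frozenset
    breakpoints: int
    differing_genes: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "shared_adjacencies": sorted(
                ["|".join(f"{g}{'+' if s == 1 else '-'}" for g, s in adj)
                 for adj in self.shared_adjacencies]
            ),
            "breakpoints": self.breakpoints,
            "differing_genes": list(self.differing_genes),
        }


# ---------------------------------------------------------------------------
# construction & canonical form
# ---------------------------------------------------------------------------

def extract_gene_order(record: MitogenomeRecord,
                       include_kinds: set[str] | None = None) -> SignedGeneOrder:
    """Signed gene order of a record in circular positional order.

    Duplicated genes become distinct suffixed tokens (``trnK.1``/``trnK.2``);
    a gene present once keeps its plain token.
    """
    kinds = frozenset(include_kinds) if include_kinds else frozenset({PCG, RRNA, TRNA})
    feats = [f for f in record.features if f.kind in kinds]
    if not feats:
        raise EmptyOrderError(
            f"{record.taxon}: no features of kinds {sorted(kinds)}")
    name_counts: dict[str, int] = {}
    for f in feats:
        name_counts[f.name] = name_counts.get(f.name, 0) + 1
    genes = tuple(
        (f.name if name_counts[f.name] == 1 else f"{f.name}.{f.copy_index}",
         f.strand)
        for f in feats
    )
    return SignedGeneOrder(record.taxon, genes, kinds)


def canonicalize(order: SignedGeneOrder, anchor: str = "cox1") -> SignedGeneOrder:
    """Deterministic canonical form: rotate so the anchor gene is first and,
    if the anchor reads on the minus strand, reflect the whole order (reverse
    and flip all signs) so the anchor reads forward.

    Falls back along ``ANCHOR_FALLBACKS`` when the anchor is absent.
    Idempotent and invariant under every rotation and under global
    reflection of the input.
    """
    if len(order) == 0:
        raise EmptyOrderError(f"{order.taxon}: cannot canonicalize empty order")
    base = order.base_tokens()
    chain = (anchor,) + tuple(a for a in ANCHOR_FALLBACKS if a != anchor)
    for a in chain:
        if a in base:
            idx = base.index(a)
            if order.genes[idx][1] == -1:
                order = order.reflected()
                base = order.base_tokens()
                idx = base.index(a)
            return order.rotated(idx)
    raise AnchorError(
        f"{order.taxon}: anchor {anchor!r} and fallbacks "
        f"{ANCHOR_FALLBACKS} all absent")


# ---------------------------------------------------------------------------
# cluster-orientation classification
# ---------------------------------------------------------------------------

def _rotations(seq: tuple) -> list[tuple]:
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def _order_direction(observed: tuple[str, ...],
                     pattern: tuple[str, ...]) -> str | None:
    """'forward' if some rotation of the observed cyclic token sequence equals
    the pattern, 'inverted' if some rotation of its reversal does, else None.
    """
    if len(observed) != len(pattern):
        return None
    if len(observed) == 1:
        return FORWARD
    if pattern in _rotations(observed):
        return FORWARD
    if pattern in _rotations(tuple(reversed(observed))):
        return INVERTED
    return None


def classify_cluster_orientation(
    order: SignedGeneOrder,
    pattern: ClusterPattern,
    preferred_copies: dict[str, int] | None = None,
) -> ClusterOrientationCall:
    """Classify one reference cluster in a signed gene order (see module
    docstring for the orientation semantics).

    Duplicated genes enter with the copy given in ``preferred_copies``
    (default: copy 1).
    """
    wanted = set(pattern.genes)
    picks: list[tuple[str, int]] = []
    for g, s in order.genes:
        base = strip_copy_suffix(g)
        if base not in wanted:
            continue
        if "." in g:
            copy = int(g.rsplit(".", 1)[1])
            want_copy = (preferred_copies or {}).get(base, 1)
            if copy != want_copy:
                continue
        picks.append((base, s))

    found = tuple(t for t, _s in picks)
    missing = tuple(g for g in pattern.genes if g not in found)
    if not found:
        return ClusterOrientationCall(pattern.id, ABSENT, (), tuple(pattern.genes))

    signs = {s for _t, s in picks}
    strand = picks[0][1] if len(signs) == 1 else 0

    if not missing:
        direction = _order_direction(found, pattern.genes)
        if direction == FORWARD:
            return ClusterOrientationCall(pattern.id, FORWARD, found, (), strand)
        if direction == INVERTED:
            return ClusterOrientationCall(pattern.id, INVERTED, found, (), strand)
        return ClusterOrientationCall(pattern.id, DISRUPTED, found, (), strand)

    reduced_pattern = tuple(g for g in pattern.genes if g in found)
    if len(found) == 1:
        call = PARTIAL_FORWARD if picks[0][1] == pattern.reference_sign else PARTIAL_INVERTED
        return ClusterOrientationCall(pattern.id, call, found, missing, strand)
    direction = _order_direction(found, reduced_pattern)
    if direction == FORWARD:
        return ClusterOrientationCall(pattern.id, PARTIAL_FORWARD, found, missing, strand)
    if direction == INVERTED:
        return ClusterOrientationCall(pattern.id, PARTIAL_INVERTED, found, missing, strand)
    return ClusterOrientationCall(pattern.id, DISRUPTED, found, missing, strand)


def classify_clusters(order: SignedGeneOrder,
                      patterns=REFERENCE_CLUSTERS,
                      preferred_copies: dict[str, int] | None = None
                      ) -> dict[str, ClusterOrientationCall]:
    return {p.id: classify_cluster_orientation(order, p, preferred_copies)
            for p in patterns}


# ---------------------------------------------------------------------------
# adjacency / breakpoint comparison
# ---------------------------------------------------------------------------

def _neutral_adjacency(a: tuple[str, int], b: tuple[str, int]):
    """Orientation-neutral representation of the signed adjacency a -> b.

    Reading the circle on the other strand, a -> b becomes -b -> -a; both
    reads denote the same physical gene neighborhood and map to one key.
    """
    fwd = (a, b)
    rev = ((b[0], -b[1]), (a[0], -a[1]))
    return min(fwd, rev)


def adjacency_set(order: SignedGeneOrder) -> frozenset:
    if len(order) < 2:
        return frozenset()
    adjacencies = set()
    n = len(order)
    for i in range(n):
        adjacencies.add(_neutral_adjacency(order.genes[i], order.genes[(i + 1) % n]))
    return frozenset(adjacencies)


def diff_orders(a: SignedGeneOrder, b: SignedGeneOrder) -> AdjacencyDiff:
    """Signed-adjacency difference between two circular orders, computed on
    the intersection of their gene sets.

    ``breakpoints`` counts adjacencies of ``a`` absent from ``b``;
    ``differing_genes`` are the genes that moved: genes both of whose
    flanking adjacencies (in either restricted order) are non-shared.
    """
    shared_tokens = set(a.base_tokens()) & set(b.base_tokens())
    if not shared_tokens:
        raise IncomparableError(
            f"{a.taxon} and {b.taxon} share no genes")

    def collapse(order: SignedGeneOrder) -> SignedGeneOrder:
        # keep copy 1 of duplicated genes and strip suffixes, so two-copy
        # genes compare against single-copy annotations of other taxa
        kept = tuple(
            (strip_copy_suffix(g), s) for g, s in order.genes
            if strip_copy_suffix(g) in shared_tokens
            and ("." not in g or g.endswith(".1"))
        )
        return SignedGeneOrder(order.taxon, kept, order.included_kinds)

    ra, rb = collapse(a), collapse(b)
    adj_a, adj_b = adjacency_set(ra), adjacency_set(rb)
    shared = adj_a & adj_b
    breakpoints = len(adj_a - adj_b)

    moved: set[str] = set()
    for order_r, own, other in ((ra, adj_a, adj_b), (rb, adj_b, adj_a)):
        n = len(order_r)
        if n < 2:
            continue
        for i in range(n):
            left = _neutral_adjacency(order_r.genes[(i - 1) % n], order_r.genes[i])
            right = _neutral_adjacency(order_r.genes[i], order_r.genes[(i + 1) % n])
            if left not in other and right not in other:
                moved.add(order_r.genes[i][0])
    return AdjacencyDiff(frozenset(shared), breakpoints, tuple(sorted(moved)))


# ---------------------------------------------------------------------------
# conserved blocks
# ---------------------------------------------------------------------------

def find_conserved_blocks(orders: list[SignedGeneOrder],
                          min_len: int = 2) -> list[tuple[str, ...]]:
    """Maximal gene runs mutually adjacent with identical relative
    orientation in every input order.

    Comparison is on the shared gene set (genes absent from any input are
    deleted from all orders first, so they never break a run).  A run may
    appear globally reversed-and-strand-flipped in some genomes; relative
    orientation within the run must be identical.  Returns blocks as token
    tuples oriented as in the first order, sorted lexicographically.
    """
    if len(orders) < 2:
        raise EmptyOrderError("need at least two orders")
    shared = set(orders[0].base_tokens())
    for o in orders[1:]:
        shared &= set(o.base_tokens())
    if len(shared) < max(min_len, 1):
        return []
    restricted = [o.restrict(shared) for o in orders]
    # keep one entry per base token (drop extra copies) to make tokens unique
    uniq = []
    for o in restricted:
        seen: set[str] = set()
        genes = []
        for g, s in o.genes:
            b = strip_copy_suffix(g)
            if b in seen:
                continue
            seen.add(b)
            genes.append((b, s))
        uniq.append(SignedGeneOrder(o.taxon, tuple(genes), o.included_kinds))

    conserved = adjacency_set(uniq[0])
    for o in uniq[1:]:
        conserved &= adjacency_set(o)
    if not conserved:
        return []

    ref = uniq[0]
    n = len(ref)
    if n < 2:
        return []
    edge_ok = [
        _neutral_adjacency(ref.genes[i], ref.genes[(i + 1) % n]) in conserved
        for i in range(n)
    ]
    if all(edge_ok):
        block = tuple(g for g, _s in ref.genes)
        return [block] if len(block) >= min_len else []

    # chains of consecutive conserved edges in the reference order
    blocks: list[tuple[str, ...]] = []
    # find starts: positions whose incoming edge is broken
    starts = [i for i in range(n) if not edge_ok[(i - 1) % n]]
    for s in starts:
        chain = [ref.genes[s][0]]
        i = s
        while edge_ok[i]:
            i = (i + 1) % n
            chain.append(ref.genes[i][0])
        if len(chain) >= min_len:
            blocks.append(tuple(chain))
    return sorted(blocks)


# ---------------------------------------------------------------------------
# tRNA complexes
# ---------------------------------------------------------------------------

def detect_trna_complex(order: SignedGeneOrder, complex_spec: str) -> dict:
    """Locate a named tRNA complex (one-letter amino-acid codes, e.g.
    ``"GEWDCYKNM"``) in a gene order.

    The named tRNAs must appear consecutively with no non-tRNA gene
    intervening; intervening tRNAs not in the spec are reported in
    ``interlopers`` (and make the match non-exact), never tolerated silently.
    Ambiguous letters (L, S) accept either isoacceptor.

    Returns a dict with ``found_as`` (token list), ``orientation``
    (``forward`` / ``reversed`` / ``absent``) and ``interlopers``.
    """
    if not complex_spec:
        raise UnknownGeneError("empty tRNA complex spec")
    letter_options = [set(trna_tokens_for_letter(ch)) for ch in complex_spec]

    trna_positions = [
        (i, strip_copy_suffix(g))
        for i, (g, _s) in enumerate(order.genes)
        if strip_copy_suffix(g).startswith("trn")
    ]
    if not trna_positions:
        return {"found_as": [], "orientation": ABSENT, "interlopers": []}

    n = len(order)
    m = len(letter_options)

    def try_match(options: list[set[str]]) -> tuple[list[str], list[str]] | None:
        # scan every cyclic start; members must be consecutive up to
        # intervening tRNAs (reported), never a non-tRNA gene
        for start in range(n):
            tokens: list[str] = []
            interlopers: list[str] = []
            i = start
            k = 0
            steps = 0
            while k < m and steps <= n:
                g, _s = order.genes[i % n]
                base = strip_copy_suffix(g)
                if base in options[k]:
                    tokens.append(g)
                    k += 1
                elif tokens and base.startswith("trn"):
                    interlopers.append(g)
                elif tokens:
                    break  # non-tRNA gene interrupts the complex
                elif not base.startswith("trn") or base not in options[0]:
                    break
                i += 1
                steps += 1
            if k == m:
                return tokens, interlopers
        return None

    hit = try_match(letter_options)
    if hit is not None:
        return {"found_as": hit[0], "orientation": "forward",
                "interlopers": hit[1]}
    hit = try_match(list(reversed(letter_options)))
    if hit is not None:
        return {"found_as": hit[0], "orientation": "reversed",
                "interlopers": hit[1]}
    return {"found_as": [], "orientation": ABSENT, "interlopers": []}


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def arrangement_table(order: SignedGeneOrder) -> str:
    """TSV linearization (one row per gene: taxon, position, gene, strand)."""
    lines = ["taxon\tposition\tgene\tstrand"]
    for i, (g, s) in enumerate(order.genes, start=1):
        lines.append(f"{order.taxon}\t{i}\t{g}\t{'+' if s == 1 else '-'}")
    return "\n".join(lines) + "\n"
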