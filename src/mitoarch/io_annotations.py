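"""Reading and writing annotated mitogenomes.

Supported inputs:

* GenBank flat files (via Biopython), with ``join()`` locations spanning the
  origin resolved to a single circular interval;
* MITOS-style BED feature tables (0-based half-open, 6 columns), with split
  gene parts merged when they are adjacent or overlapping on the same strand;
* printed arrangement strings ("trnT-atp6-atp8-..." per strand), which yield
  sequence-free records carrying only order and strand.

All readers normalize gene names onto the canonical 37-token vocabulary and
return features sorted by start with unique ``(name, copy_index)`` pairs.
"""

from __future__ import annotations

import io
from collections import Counter, defaultdict
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import (
    AmbiguityError,
    BoundsError,
    EmptyRecordError,
    FormatError,
    UnknownGeneError,
)
from .nomenclature import OTHER, PCG, RRNA, TRNA, normalize_gene_name, token_kind
from .records import GeneFeature, MitogenomeRecord

_GB_TYPE_FOR_KIND = {PCG: "CDS", RRNA: "rRNA", TRNA: "tRNA", OTHER: "misc_feature"}
_FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "misc_feature", "gene")

#: maximum gap (bp) between same-name, same-strand MITOS parts that are
#: merged into one feature; larger separations are kept as genuine copies
MERGE_GAP = 10


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def _location_to_interval(loc, genome_length: int) -> tuple[int, int]:
    """Collapse a (possibly compound, origin-spanning) location to one
    0-based half-open circular interval with ``end > length`` on wrap."""
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        first, last = parts[0], parts[-1]
        if int(last.end) == genome_length and int(first.start) == 0 and len(parts) == 2:
            # origin-spanning join(a..length,1..b)
            return int(last.start), genome_length + int(first.end)
        return int(first.start), int(last.end)
    return int(loc.start), int(loc.end)


def _feature_name(feat) -> str | None:
    for key in ("gene", "product", "note", "label", "locus_tag"):
        if key in feat.qualifiers:
            val = feat.qualifiers[key][0]
            if val:
                return str(val)
    return None


def _assign_copies(raw: list[tuple[str, str, int, int, int]]) -> list[GeneFeature]:
    """Turn (name, kind, strand, start, end) tuples into features with
    ascending copy indices per name, ordered by start."""
    raw = sorted(raw, key=lambda t: (t[3], t[4]))
    counter: Counter[str] = Counter()
    feats = []
    for name, kind, strand, start, end in raw:
        counter[name] += 1
        feats.append(GeneFeature(name=name, kind=kind, strand=strand,
                                 start=start, end=end,
                                 copy_index=counter[name]))
    return feats


def read_genbank(path, synonyms: dict[str, str] | None = None) -> MitogenomeRecord:
    """Read one annotated mitogenome from a GenBank flat file.

    Typed features (CDS/rRNA/tRNA) take precedence over their paired plain
    ``gene`` lines; features whose name cannot be normalized are kept with
    ``kind='other'`` under their raw name.  A sequence consisting only of N
    is treated as absent.
    """
    path = Path(path)
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad files
        raise FormatError(f"{path}: not a parseable GenBank file ({exc})") from exc

    length = len(seqrec.seq)
    if length == 0:
        raise FormatError(f"{path}: record has no sequence length")

    typed: list[tuple[str, str, int, int, int]] = []
    plain_gene: list[tuple[str, str, int, int, int]] = []
    typed_spans: set[tuple[int, int]] = set()
    for feat in seqrec.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        raw_name = _feature_name(feat)
        if raw_name is None:
            continue
        start, end = _location_to_interval(feat.location, length)
        strand = -1 if feat.location.strand == -1 else 1
        try:
            token, kind = normalize_gene_name(raw_name, synonyms)
        except UnknownGeneError:
            token, kind = raw_name, OTHER
        entry = (token, kind, strand, start, end)
        if feat.type == "gene":
            plain_gene.append(entry)
        else:
            typed.append(entry)
            typed_spans.add((start, end))
    # keep plain gene lines only where no typed feature covers the same span
    for entry in plain_gene:
        if (entry[3], entry[4]) not in typed_spans:
            typed.append(entry)

    if not typed:
        raise EmptyRecordError(f"{path}: GenBank record contains no gene features")

    seq = str(seqrec.seq).upper()
    sequence = None if set(seq) <= {"N"} else seq
    circular = seqrec.annotations.get("topology", "circular") == "circular"
    return MitogenomeRecord(
        taxon=seqrec.annotations.get("organism", seqrec.id) or seqrec.id,
        accession=seqrec.id,
        length=length,
        circular=circular,
        sequence=sequence,
        features=_assign_copies(typed),
    )


def write_genbank(record: MitogenomeRecord, path) -> None:
    """Write a record as a GenBank flat file (1-based inclusive coordinates,
    ``join()`` for origin-spanning features; N-filled sequence if absent)."""
    seq = record.sequence if record.sequence is not None else "N" * record.length
    seqrec = SeqRecord(
        Seq(seq),
        id=record.accession or "MITOARCH",
        name=(record.accession or "MITOARCH")[:16],
        description=record.taxon,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.taxon,
        },
    )
    for f in record.features:
        if f.end <= record.length:
            loc = SimpleLocation(f.start, f.end, strand=f.strand)
        else:
            part1 = SimpleLocation(f.start, record.length, strand=f.strand)
            part2 = SimpleLocation(0, f.end % record.length, strand=f.strand)
            loc = CompoundLocation([part1, part2])
        qualifiers = {"gene": [f.name]}
        if f.copy_index > 1:
            qualifiers["note"] = [f"copy {f.copy_index}"]
        seqrec.features.append(
            SeqFeature(loc, type=_GB_TYPE_FOR_KIND.get(f.kind, "misc_feature"),
                       qualifiers=qualifiers)
        )
    with open(path, "w") as fh:
        SeqIO.write([seqrec], fh, "genbank")


# ---------------------------------------------------------------------------
# MITOS BED
# ---------------------------------------------------------------------------

def read_mitos_bed(path, genome_length: int, circular: bool = True,
                   taxon: str | None = None,
                   synonyms: dict[str, str] | None = None) -> MitogenomeRecord:
    """Read a MITOS-style BED table (0-based half-open; 6 columns).

    Same-name parts on the same strand separated by at most ``MERGE_GAP`` bp
    (including overlapping or abutting parts) are merged into one feature,
    mirroring the manual combination of split atp6/cob/cox3 annotations;
    distant same-name rows are retained as genuine copies with ascending
    ``copy_index``.
    """
    path = Path(path)
    rows: list[tuple[str, str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 6 BED columns, got {len(cols)}"
                )
            _chrom, s, e, name, _score, strand_sym = cols[:6]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if strand_sym == "+":
                strand = 1
            elif strand_sym == "-":
                strand = -1
            else:
                raise FormatError(
                    f"{path}:{lineno}: unknown strand symbol {strand_sym!r}"
                )
            if not (0 <= start < genome_length) or not (start < end <= genome_length):
                raise BoundsError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside "
                    f"[0, {genome_length})"
                )
            token, kind = normalize_gene_name(name, synonyms)
            rows.append((token, kind, strand, start, end))

    if not rows:
        raise EmptyRecordError(f"{path}: BED table contains no features")

    # merge nearby same-name same-strand parts
    grouped: dict[tuple[str, int], list[tuple[int, int]]] = defaultdict(list)
    kinds: dict[str, str] = {}
    for token, kind, strand, start, end in rows:
        grouped[(token, strand)].append((start, end))
        kinds[token] = kind
    merged: list[tuple[str, str, int, int, int]] = []
    for (token, strand), spans in grouped.items():
        spans.sort()
        current = list(spans[0])
        out = []
        for s, e in spans[1:]:
            if s - current[1] <= MERGE_GAP:
                current[1] = max(current[1], e)
            else:
                out.append(tuple(current))
                current = [s, e]
        out.append(tuple(current))
        for s, e in out:
            merged.append((token, kinds[token], strand, s, e))

    return MitogenomeRecord(
        taxon=taxon or path.stem,
        length=genome_length,
        circular=circular,
        features=_assign_copies(merged),
    )


# ---------------------------------------------------------------------------
# arrangement strings
# ---------------------------------------------------------------------------

def _parse_token(tok: str) -> tuple[str, int | None]:
    tok = tok.strip()
    copy = None
    if "." in tok:
        base, suffix = tok.rsplit(".", 1)
        if suffix.isdigit():
            tok, copy = base, int(suffix)
    name, _kind = normalize_gene_name(tok)
    return name, copy


def parse_arrangement_string(plus: str, minus: str = "",
                             taxon: str = "arrangement") -> MitogenomeRecord:
    """Build a sequence-free record from hyphen-separated gene strings.

    Both strings are read in genome positional order (the convention of
    linearized arrangement figures): the concatenation plus-then-minus is the
    circular gene order, with the second string's genes on the minus strand.
    Features get synthetic unit-length coordinates in listed order.
    """
    entries: list[tuple[str, int | None, int]] = []
    for strand, text in ((1, plus), (-1, minus)):
        if not text or not text.strip():
            continue
        for tok in text.split("-"):
            if not tok.strip():
                continue
            name, copy = _parse_token(tok)
            entries.append((name, copy, strand))
    if not entries:
        raise EmptyRecordError("both arrangement strings are empty")

    counts = Counter(name for name, _c, _s in entries)
    explicit = {name for name, c, _s in entries if c is not None}
    for name, n in counts.items():
        if n > 1 and name not in explicit:
            raise AmbiguityError(
                f"token {name!r} appears {n} times without a copy suffix "
                f"(use e.g. {name}.1 / {name}.2)"
            )

    counter: Counter[str] = Counter()
    features = []
    for pos, (name, copy, strand) in enumerate(entries):
        counter[name] += 1
        features.append(GeneFeature(
            name=name, kind=token_kind(name),
            strand=strand, start=pos, end=pos + 1,
            copy_index=copy if copy is not None else counter[name],
        ))
    return MitogenomeRecord(taxon=taxon, length=len(entries), features=features)


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def write_feature_table(record: MitogenomeRecord, path_or_buf) -> None:
    """Write a TSV feature table: taxon, gene, kind, strand, start1, end1,
    length (1-based inclusive coordinates; wrap-around ends reduced modulo
    genome length)."""
    own = isinstance(path_or_buf, (str, Path))
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write("taxon\tgene\tkind\tstrand\tstart1\tend1\tlength\n")
        for f in record.features:
            end1 = (f.end - 1) % record.length + 1
            fh.write(
                f"{record.taxon}\t{f.token}\t{f.kind}\t"
                f"{'+' if f.strand == 1 else '-'}\t{f.start + 1}\t{end1}\t"
                f"{f.length}\n"
            )
    finally:
        if own:
            fh.close()


def feature_table_string(record: MitogenomeRecord) -> str:
    buf = io.StringIO()
    write_feature_table(record, buf)
    return buf.getvalue()
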