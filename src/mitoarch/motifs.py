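"""Control-region signatures in non-coding regions.

Three scanners:

* :func:`scan_motif` -- exact character-class patterns (each position a
  literal base or a bracketed alternative set), no mismatches, leftmost
  non-overlapping matches, 1-based starts within the NCR;
* :func:`at_repeat_runs` -- maximal AT-dinucleotide repetitions ``(AT)_n``,
  phase-free (TATA... counts the same units as ATAT...) with an optional
  single-dinucleotide interruption bridge;
* :func:`find_shared_motifs` -- maximal exact substrings shared between NCRs
  of different taxa, the evidence used for cross-species control-region
  motifs.

The two built-in motif definitions are the AT-rich control-region pattern
(motif 1) and the exact 18-mer shared marker (motif 2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import FormatError
from .records import MitogenomeRecord


@dataclass(frozen=True)
class MotifDefinition:
    """A character-class pattern over {A,C,G,T}: literals and ``[...]`` sets."""

    id: str
    pattern: str

    def __post_init__(self):
        self.positions()  # validate eagerly

    def positions(self) -> list[frozenset[str]]:
        """Per-position allowed base sets."""
        out: list[frozenset[str]] = []
        i, pat = 0, self.pattern.upper()
        while i < len(pat):
            ch = pat[i]
            if ch == "[":
                j = pat.find("]", i)
                if j < 0:
                    raise FormatError(f"{self.id}: unclosed '[' in pattern")
                alts = pat[i + 1:j]
                if not alts or any(c not in "ACGT" for c in alts):
                    raise FormatError(f"{self.id}: bad alternative set [{alts}]")
                out.append(frozenset(alts))
                i = j + 1
            elif ch in "ACGT":
                out.append(frozenset(ch))
                i += 1
            else:
                raise FormatError(f"{self.id}: illegal pattern character {ch!r}")
        if not out:
            raise FormatError(f"{self.id}: empty pattern")
        return out

    def __len__(self) -> int:
        return len(self.positions())

    @property
    def regex(self) -> str:
        return self.pattern.upper()


#: AT-rich control-region pattern, 20 positions
MOTIF1 = MotifDefinition("motif1", "TATA[TC]ATATATA[GT]A[CT][AT][TA][AT][TCG][GC]")
#: exact shared 18-mer
MOTIF2 = MotifDefinition("motif2", "CCTCGAAATCGTTGCATC")
DEFAULT_MOTIFS = (MOTIF1, MOTIF2)


@dataclass(frozen=True)
class MotifHit:
    taxon: str
    ncr: tuple[str, str]      # (flank5, flank3)
    motif_id: str
    start_in_ncr: int         # 1-based position of the first matched base
    matched: str


@dataclass(frozen=True)
class RepeatRun:
    unit_count: int           # n of (AT)_n
    start_in_ncr: int         # 1-based
    interruptions: tuple[tuple[int, str], ...] = ()  # (1-based pos, dinucleotide)

    @property
    def is_perfect(self) -> bool:
        return not self.interruptions


# ---------------------------------------------------------------------------

def scan_motif(ncr_sequence: str, motif: MotifDefinition,
               taxon: str = "", ncr: tuple[str, str] = ("", ""),
               both_strands: bool = False) -> list[MotifHit]:
    """All non-overlapping leftmost matches of a pattern in an NCR sequence.

    Scanning is single-strand (the NCR as annotated) unless ``both_strands``
    is set, in which case reverse-complement hits are reported with the
    position of the first matched base on the given strand.
    """
    seq = ncr_sequence.upper()
    rx = re.compile(motif.regex)
    hits = [
        MotifHit(taxon, ncr, motif.id, m.start() + 1, m.group(0))
        for m in rx.finditer(seq)
    ]
    if both_strands:
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        for m in re.compile(motif.regex).finditer(rc):
            start = len(seq) - m.end() + 1
            hits.append(MotifHit(taxon, ncr, motif.id, start, m.group(0)))
        hits.sort(key=lambda h: h.start_in_ncr)
    return hits


# ---------------------------------------------------------------------------

def _alternating_stretches(seq: str) -> list[tuple[int, int]]:
    """Maximal stretches (0-based start, length >= 2) of alternating A/T."""
    s = seq.upper()
    out = []
    i, n = 0, len(s)
    while i < n - 1:
        if s[i] in "AT" and s[i + 1] in "AT" and s[i] != s[i + 1]:
            j = i + 1
            while j + 1 < n and s[j + 1] in "AT" and s[j + 1] != s[j]:
                j += 1
            out.append((i, j - i + 1))
            i = j + 1
        else:
            i += 1
    return out


def at_repeat_runs(sequence: str, allow_interruption: bool = False
                   ) -> list[RepeatRun]:
    """Maximal ``(AT)_n`` repeat runs in a sequence.

    Perfect mode reports each maximal alternating A/T stretch as
    ``n = floor(stretch_length / 2)`` complete AT units (phase-free).  With
    ``allow_interruption``, two stretches separated by exactly one non-AT
    dinucleotide are bridged into one run whose unit count is the sum of the
    two parts and whose interruption (position, dinucleotide) is recorded.
    Runs shorter than one full unit are not reported.
    """
    stretches = _alternating_stretches(sequence)
    if not allow_interruption:
        return [RepeatRun(length // 2, start + 1)
                for start, length in stretches if length >= 2]

    runs: list[RepeatRun] = []
    i = 0
    while i < len(stretches):
        start, length = stretches[i]
        if i + 1 < len(stretches):
            nstart, nlength = stretches[i + 1]
            gap = nstart - (start + length)
            if gap == 2:
                dinuc = sequence[start + length:start + length + 2].upper()
                runs.append(RepeatRun(
                    length // 2 + nlength // 2, start + 1,
                    ((start + length + 1, dinuc),),
                ))
                i += 2
                continue
            if gap == 1:
                # dinucleotide framing: the interrupting unit absorbs the
                # first base of the following stretch (e.g. TATA|CA|TATATATA)
                dinuc = sequence[start + length:start + length + 2].upper()
                runs.append(RepeatRun(
                    length // 2 + (nlength - 1) // 2, start + 1,
                    ((start + length + 1, dinuc),),
                ))
                i += 2
                continue
        runs.append(RepeatRun(length // 2, start + 1))
        i += 1
    return [r for r in runs if r.unit_count >= 1]


# ---------------------------------------------------------------------------

def find_shared_motifs(ncrs: list[tuple[str, str]], min_len: int = 18
                       ) -> list[dict]:
    """Maximal exact substrings (length >= ``min_len``) present in NCRs of at
    least two distinct taxa.

    ``ncrs`` is a list of (taxon, NCR sequence).  A reported motif is never a
    substring of another reported motif with the same taxon set.  Returns
    dicts with ``motif``, ``taxa`` and ``positions`` (1-based start per
    taxon; first occurrence).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    taxa = sorted({t for t, _s in ncrs})
    if len(taxa) < 2:
        return []
    seqs: dict[str, list[str]] = {}
    for t, s in ncrs:
        seqs.setdefault(t, []).append(s.upper())

    # candidate substrings of length min_len that occur in >= 2 taxa, then
    # extended greedily to maximal shared strings
    occ: dict[str, set[str]] = {}
    for t, slist in seqs.items():
        seen: set[str] = set()
        for s in slist:
            for i in range(len(s) - min_len + 1):
                seen.add(s[i:i + min_len])
        for k in seen:
            occ.setdefault(k, set()).add(t)
    shared_seeds = {k: v for k, v in occ.items() if len(v) >= 2}
    if not shared_seeds:
        return []

    def taxa_containing(sub: str) -> frozenset[str]:
        return frozenset(t for t, slist in seqs.items()
                         if any(sub in s for s in slist))

    def extensions(sub: str) -> list[str]:
        """Single-character left/right extensions occurring in >= 2 taxa."""
        out = []
        chars_r: set[str] = set()
        chars_l: set[str] = set()
        for slist in seqs.values():
            for s in slist:
                i = s.find(sub)
                while i >= 0:
                    if i + len(sub) < len(s):
                        chars_r.add(s[i + len(sub)])
                    if i > 0:
                        chars_l.add(s[i - 1])
                    i = s.find(sub, i + 1)
        for c in sorted(chars_r):
            cand = sub + c
            if len(taxa_containing(cand)) >= 2:
                out.append(cand)
        for c in sorted(chars_l):
            cand = c + sub
            if len(taxa_containing(cand)) >= 2:
                out.append(cand)
        return out

    def grow_same_support(sub: str) -> str:
        """Greedy extension while the supporting taxa set is unchanged."""
        tx = taxa_containing(sub)
        grew = True
        while grew:
            grew = False
            for cand in extensions(sub):
                if taxa_containing(cand) == tx:
                    sub, grew = cand, True
                    break
        return sub

    # seeds are grown to maximality for their own support level; when an
    # extension drops support (but stays shared), it starts a new branch, so
    # both the widely-shared core and its longer, less-shared extensions are
    # reported
    results: dict[str, frozenset[str]] = {}
    work = sorted(shared_seeds)
    seen: set[str] = set()
    while work:
        sub = work.pop()
        sub = grow_same_support(sub)
        if sub in seen:
            continue
        seen.add(sub)
        tx = taxa_containing(sub)
        exts = extensions(sub)
        if not any(taxa_containing(e) == tx for e in exts):
            results[sub] = tx
        for e in exts:
            if e not in seen:
                work.append(e)

    # suppress substrings of longer reported motifs (only when the longer
    # motif is shared by at least the same taxa, so no sharing info is lost)
    motifs = sorted(results, key=len, reverse=True)
    kept: list[str] = []
    for m in motifs:
        if not any(m in longer and results[m] <= results[longer]
                   for longer in kept):
            kept.append(m)

    out = []
    for m in sorted(kept):
        mtaxa = sorted(results[m])
        positions = {}
        for t in mtaxa:
            for s in seqs[t]:
                i = s.find(m)
                if i >= 0:
                    positions[t] = i + 1
                    break
        out.append({"motif": m, "taxa": mtaxa, "positions": positions})
    return out


# ---------------------------------------------------------------------------

def motif_position_table(records: list[MitogenomeRecord],
                         motifs=DEFAULT_MOTIFS) -> list[MotifHit]:
    """One row per (motif, taxon, NCR) hit over all records with sequence,
    mirroring a motif-occurrence table (motif id, taxon, NCR border, 1-based
    start within the NCR, matched sequence).  Sequence-free records are
    skipped."""
    from .noncoding import extract_ncrs

    rows: list[MotifHit] = []
    for rec in records:
        if rec.sequence is None:
            continue
        ncrs, _ = extract_ncrs(rec)
        for region in ncrs:
            if region.sequence is None:
                continue
            for motif in motifs:
                rows.extend(scan_motif(
                    region.sequence, motif, taxon=rec.taxon,
                    ncr=(region.flank5, region.flank3)))
    rows.sort(key=lambda h: (h.motif_id, h.taxon, h.ncr, h.start_in_ncr))
    return rows


def motif_table_tsv(rows: list[MotifHit]) -> str:
    lines = ["motif\ttaxon\tncr_border\tstart_in_ncr\tmatched"]
    for h in rows:
        lines.append(
            f"{h.motif_id}\t{h.taxon}\t{h.ncr[0]}/{h.ncr[1]}\t"
            f"{h.start_in_ncr}\t{h.matched}")
    return "\n".join(lines) + "\n"


def load_motifs_yaml(path) -> list[MotifDefinition]:
    """User motif definitions from YAML: ``{id: pattern, ...}``."""
    import yaml

    with open(path) as fh:
        table = yaml.safe_load(fh) or {}
    if not isinstance(table, dict):
        raise FormatError(f"motif file {path} is not a mapping")
    return [MotifDefinition(str(k), str(v)) for k, v in table.items()]
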