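"""Normalization of mitochondrial gene names onto the canonical 37-token set.

Metazoan mitogenomes carry 13 protein-coding genes, two rRNAs and 22 tRNAs,
but annotation sources spell them many ways (COI vs cox1, cytb vs cob,
12S vs rrnS, tRNA-Leu(UUR) vs trnL2...).  This module maps any recognized
spelling deterministically onto one vocabulary so that gene orders from
different pipelines are comparable.  Unknown names raise
:class:`~mitoarch.errors.UnknownGeneError` -- they are never silently dropped.
"""

from __future__ import annotations

import re
from typing import Iterable

from .errors import UnknownGeneError

PCG = "PCG"
RRNA = "rRNA"
TRNA = "tRNA"
OTHER = "other"

#: the 13 protein-coding genes
PCG_TOKENS = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
#: the two ribosomal RNAs
RRNA_TOKENS = ("rrnS", "rrnL")
#: the 22 tRNAs; leucine and serine each have two isoacceptors
TRNA_TOKENS = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)
ALL_TOKENS = PCG_TOKENS + RRNA_TOKENS + TRNA_TOKENS

KIND_OF: dict[str, str] = {}
KIND_OF.update({t: PCG for t in PCG_TOKENS})
KIND_OF.update({t: RRNA for t in RRNA_TOKENS})
KIND_OF.update({t: TRNA for t in TRNA_TOKENS})

_AA3 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# anticodon -> isoacceptor number for the two split amino acids
# (leucine: tag=L1 / taa=L2; serine: tct=S1 / tga=S2, MITOS convention)
_SPLIT_ANTICODON = {
    ("L", "tag"): "trnL1", ("L", "taa"): "trnL2",
    ("L", "cun"): "trnL1", ("L", "uur"): "trnL2",
    ("S", "tct"): "trnS1", ("S", "tga"): "trnS2",
    ("S", "agn"): "trnS1", ("S", "ucn"): "trnS2",
    ("S", "agy"): "trnS1",
}

_SYNONYMS = {
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
    "cytb": "cob", "cytochromeb": "cob", "cob": "cob",
    "12s": "rrnS", "16s": "rrnL",
    "12srrna": "rrnS", "16srrna": "rrnL",
    "srrna": "rrnS", "lrrna": "rrnL",
    "smallsubunitribosomalrna": "rrnS",
    "largesubunitribosomalrna": "rrnL",
    "rrn12": "rrnS", "rrn16": "rrnL",
    "atpase6": "atp6", "atpase8": "atp8",
    "nadh1": "nad1", "nadh2": "nad2", "nadh3": "nad3", "nadh4": "nad4",
    "nadh4l": "nad4L", "nadh5": "nad5", "nadh6": "nad6",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "ndh4l": "nad4L",
}

_CANON_LOWER = {t.lower(): t for t in ALL_TOKENS}

# one-letter amino-acid code -> candidate tRNA tokens (for complex specs)
AA_TO_TRNA: dict[str, tuple[str, ...]] = {}
for _t in TRNA_TOKENS:
    _letter = _t[3].upper()
    AA_TO_TRNA.setdefault(_letter, ())
    AA_TO_TRNA[_letter] = AA_TO_TRNA[_letter] + (_t,)


def _strip(raw: str) -> str:
    return re.sub(r"[\s_\-\.]+", "", raw.lower())


def normalize_gene_name(
    raw: str, extra_synonyms: dict[str, str] | None = None
) -> tuple[str, str]:
    """Map a raw gene name onto ``(token, kind)``.

    Case-insensitive; whitespace, hyphens and underscores are ignored.
    ``extra_synonyms`` (raw spelling -> canonical token) extends but never
    overrides the built-in table.  A trailing MITOS-style part suffix
    (``cox3_a``, ``nad2-1``, ``atp6 part2``) is removed before lookup.

    Raises
    ------
    UnknownGeneError
        if the name cannot be mapped.
    """
    if extra_synonyms:
        lowered = {_strip(k): v for k, v in extra_synonyms.items()}
        key = _strip(raw)
        if key in lowered:
            tok = lowered[key]
            if tok not in KIND_OF:
                raise UnknownGeneError(
                    f"synonym table maps {raw!r} to unknown token {tok!r}"
                )
            return tok, KIND_OF[tok]

    name = raw.strip()
    # strip a MITOS part suffix: "cox3_a", "nad2_1", "cob part2"
    name = re.sub(r"[\s_\-](?:part)?[0-9ab]$", "", name, flags=re.I)

    # tRNA spellings: trnL(tag), trnL2, tRNA-Leu, trn l ...
    m = re.match(
        r"^t(?:rna?)?[\s_\-]?([A-Za-z]{1,3}[12]?)\s*(?:\(([a-zA-Z]{3})\))?$",
        name, flags=re.I,
    )
    if m and (name.lower().startswith("trn") or name.lower().startswith("trna")
              or name.lower().startswith("t-rna") or name.lower().startswith("trna-")):
        body, anticodon = m.group(1), m.group(2)
        body_l = body.lower()
        letter = None
        iso = ""
        if len(body_l) >= 3 and body_l[:3] in _AA3:
            letter = _AA3[body_l[:3]]
            iso = body_l[3:]
        elif body_l[0].upper() in AA_TO_TRNA and len(body_l) <= 2:
            letter = body_l[0].upper()
            iso = body_l[1:]
        if letter is not None:
            if letter in ("L", "S"):
                if iso in ("1", "2"):
                    tok = f"trn{letter}{iso}"
                elif anticodon:
                    tok = _SPLIT_ANTICODON.get((letter, anticodon.lower()))
                    if tok is None:
                        raise UnknownGeneError(
                            f"unrecognized {letter} anticodon in {raw!r}"
                        )
                else:
                    raise UnknownGeneError(
                        f"ambiguous tRNA name {raw!r}: trn{letter} needs an "
                        f"isoacceptor number or anticodon"
                    )
            else:
                tok = f"trn{letter}"
            if tok in KIND_OF:
                return tok, TRNA

    key = _strip(name)
    if key in _CANON_LOWER:
        tok = _CANON_LOWER[key]
        return tok, KIND_OF[tok]
    if key in _SYNONYMS:
        tok = _SYNONYMS[key]
        return tok, KIND_OF[tok]
    raise UnknownGeneError(f"unknown gene name: {raw!r}")


def trna_tokens_for_letter(letter: str) -> tuple[str, ...]:
    """tRNA tokens for a one-letter amino-acid code (L -> trnL1, trnL2)."""
    try:
        return AA_TO_TRNA[letter.upper()]
    except KeyError:
        raise UnknownGeneError(f"no tRNA maps to amino-acid letter {letter!r}")


def load_synonyms_yaml(path) -> dict[str, str]:
    """Read a user synonym table (raw name -> canonical token) from YAML."""
    import yaml

    with open(path) as fh:
        table = yaml.safe_load(fh) or {}
    if not isinstance(table, dict):
        raise UnknownGeneError(f"synonym file {path} is not a mapping")
    return {str(k): str(v) for k, v in table.items()}


def strip_copy_suffix(token: str) -> str:
    """``trnK.2`` -> ``trnK`` (tokens for duplicated genes carry ``.n``)."""
    base = token.split(".", 1)[0]
    return base


def token_kind(token: str) -> str:
    """Kind of a (possibly copy-suffixed) canonical token."""
    return KIND_OF.get(strip_copy_suffix(token), OTHER)


def check_tokens(tokens: Iterable[str]) -> None:
    for t in tokens:
        if strip_copy_suffix(t) not in KIND_OF:
            raise UnknownGeneError(f"unknown gene token: {t!r}")
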