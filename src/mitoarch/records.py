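"""Core containers: annotated circular mitogenomes.

Coordinates are 0-based half-open on the circle.  A feature that spans the
origin is stored with ``end > genome length``; its occupied bases are
``start .. length-1`` followed by ``0 .. end % length - 1``.  This keeps gap
arithmetic (``start_next - end_prev``) valid everywhere on the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import BoundsError, EmptyRecordError
from .nomenclature import OTHER, token_kind


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a circular genome.

    ``name`` is a normalized token (see :mod:`mitoarch.nomenclature`);
    ``copy_index`` distinguishes duplicated genes (two trnK copies -> 1 and 2).
    """

    name: str
    kind: str
    strand: int
    start: int
    end: int
    copy_index: int = 1

    def __post_init__(self):
        if self.strand not in (1, -1):
            raise BoundsError(f"{self.name}: strand must be +1/-1, got {self.strand}")
        if self.end <= self.start:
            raise BoundsError(
                f"{self.name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.copy_index < 1:
            raise BoundsError(f"{self.name}: copy_index must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def token(self) -> str:
        """Token with a ``.n`` copy suffix when this is not the only copy."""
        return self.name if self.copy_index == 1 else f"{self.name}.{self.copy_index}"


@dataclass
class MitogenomeRecord:
    """An annotated, optionally sequenced, (usually circular) mitogenome."""

    taxon: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)
    accession: str = ""
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.length < 1:
            raise BoundsError(f"{self.taxon}: genome length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise BoundsError(
                f"{self.taxon}: sequence length {len(self.sequence)} != "
                f"declared length {self.length}"
            )
        seen: set[tuple[str, int]] = set()
        for f in self.features:
            if not (0 <= f.start < self.length):
                raise BoundsError(
                    f"{self.taxon}/{f.token}: start {f.start} outside "
                    f"[0, {self.length})"
                )
            if f.end > self.start_wrapped_limit(f):
                raise BoundsError(
                    f"{self.taxon}/{f.token}: feature longer than genome"
                )
            key = (f.name, f.copy_index)
            if key in seen:
                raise BoundsError(
                    f"{self.taxon}: duplicate feature {f.name} copy {f.copy_index}"
                )
            seen.add(key)
        self.features.sort(key=lambda f: (f.start, f.end))
        # assign copy suffixes display consistency: nothing to do, copy_index given

    def start_wrapped_limit(self, f: GeneFeature) -> int:
        # a wrap-around feature may extend past the origin but not lap itself
        return f.start + self.length

    # -- convenience -------------------------------------------------------

    def genes(self, kinds: set[str] | None = None) -> list[GeneFeature]:
        """Features in positional order, optionally restricted by kind."""
        if kinds is None:
            return list(self.features)
        return [f for f in self.features if f.kind in kinds]

    def feature_sequence(self, f: GeneFeature) -> str:
        """Bases of a feature, following the circle across the origin.

        The slice is reported on the annotated (plus) strand; no reverse
        complementing is applied.
        """
        if self.sequence is None:
            raise EmptyRecordError(f"{self.taxon}: record carries no sequence")
        if f.end <= self.length:
            return self.sequence[f.start:f.end]
        return self.sequence[f.start:] + self.sequence[: f.end % self.length]

    def slice_circular(self, start: int, end: int) -> str:
        """Sequence of the half-open circular interval [start, end)."""
        if self.sequence is None:
            raise EmptyRecordError(f"{self.taxon}: record carries no sequence")
        start %= self.length
        if end <= self.length and end >= start:
            return self.sequence[start:end]
        end %= self.length
        return self.sequence[start:] + self.sequence[:end]

    def with_features(self, features: list[GeneFeature]) -> "MitogenomeRecord":
        rec = replace(self, features=list(features))
        return rec


def make_feature(name: str, strand: int, start: int, end: int,
                 copy_index: int = 1, kind: str | None = None) -> GeneFeature:
    """Build a :class:`GeneFeature`, inferring the kind from the token."""
    k = kind if kind is not None else token_kind(name)
    if k is None:
        k = OTHER
    return GeneFeature(name=name, kind=k, strand=strand, start=start, end=end,
                       copy_index=copy_index)
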