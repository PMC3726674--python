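"""Paired-end categories and authentic fragment-length range estimation.

A PE is *regular* when both mates map to one contig, *bridging* when the
mates map only to different contigs, *single-mappable-end* when exactly one
mate maps, and *unmapped* otherwise.  A regular placement is *authentic*
when the mates face inward on opposite strands; its fragment length is the
outer distance between the mate ends.  The authentic length range is read
off the fragment-length histogram of all regular PEs: the smallest and
largest lengths whose frequency reaches a cutoff (5 by default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .mapper import MappingHit


class PECategory(str, Enum):
    REGULAR = "regular"
    BRIDGING = "bridging"
    SINGLE = "single_mappable_end"
    UNMAPPED = "unmapped"


class NotAuthentic(ValueError):
    """The two placements cannot come from one inward-facing fragment."""


class InsufficientRegularPEs(RuntimeError):
    pass


def classify_pe(hits1: list[MappingHit], hits2: list[MappingHit]) -> PECategory:
    """Assign one of the four categories from the mates' hit lists.

    A shared contig makes the pair regular even if other contigs are hit
    (regular takes precedence over bridging).
    """
    if not hits1 and not hits2:
        return PECategory.UNMAPPED
    if not hits1 or not hits2:
        return PECategory.SINGLE
    c1 = {h.contig_id for h in hits1}
    c2 = {h.contig_id for h in hits2}
    return PECategory.REGULAR if c1 & c2 else PECategory.BRIDGING


def regular_fragment_length(h1: MappingHit, h2: MappingHit) -> int:
    """Outer distance (end-inclusive span) between two inward-facing mates on
    one contig; raises :class:`NotAuthentic` otherwise."""
    if h1.contig_id != h2.contig_id:
        raise NotAuthentic("hits on different contigs")
    if h1.strand == h2.strand:
        raise NotAuthentic("mates on the same strand")
    plus, minus = (h1, h2) if h1.strand == "+" else (h2, h1)
    if plus.start > minus.start or plus.end > minus.end:
        raise NotAuthentic("mates face outward")
    return minus.end - plus.start


@dataclass
class FragmentLengthRange:
    min_len: int
    max_len: int
    histogram: dict[int, int] = field(default_factory=dict)
    cutoff: int = 5

    def __contains__(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


def estimate_fragment_range(
    lengths: Iterable[int], cutoff: int = 5
) -> FragmentLengthRange:
    """Bound the authentic fragment lengths by the smallest and largest
    histogram bins whose count reaches ``cutoff``."""
    hist = Counter(lengths)
    qualifying = [l for l, n in hist.items() if n >= cutoff]
    if not qualifying:
        raise InsufficientRegularPEs(
            f"insufficient regular PEs: no fragment length reaches frequency {cutoff}"
        )
    return FragmentLengthRange(
        min_len=min(qualifying), max_len=max(qualifying),
        histogram=dict(hist), cutoff=cutoff,
    )


def authentic_pairs(
    hits1: list[MappingHit], hits2: list[MappingHit]
) -> list[tuple[MappingHit, MappingHit, int]]:
    """All same-contig inward-facing hit pairs with their outer distances,
    sorted by (total mismatches, contig, leftmost start)."""
    out = []
    by_contig: dict[str, list[MappingHit]] = {}
    for h in hits2:
        by_contig.setdefault(h.contig_id, []).append(h)
    for h1 in hits1:
        for h2 in by_contig.get(h1.contig_id, []):
            try:
                frag = regular_fragment_length(h1, h2)
            except NotAuthentic:
                continue
            out.append((h1, h2, frag))
    out.sort(key=lambda t: (t[0].mismatches + t[1].mismatches, t[0].contig_id,
                            min(t[0].start, t[1].start)))
    return out
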