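"""Post-assembly consensus correction of contig bases.

Only reads that belong to authentic regular PEs *and* are uniquely mapped
contribute to the pileup.  A contig base is replaced by the consensus base
(strict plurality; ties change nothing) when the base is marked unreliable
(lowercase, any coverage >= 1), or when the consensus holds at least
``min_fraction`` (default 60%) of at least ``min_depth`` (default 10)
covering bases.  Replacements are substitutions only and are emitted in
uppercase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .assembler import Contig, ContigGraph
from .classify import FragmentLengthRange, authentic_pairs
from .mapper import MappingHit, is_unique
from .seqio import PairedEnd, revcomp

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CorrectionConfig:
    min_fraction: float = 0.6
    min_depth: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")


class Pileup:
    """Per-contig, per-position base counts over {A,C,G,T}."""

    def __init__(self, graph: ContigGraph) -> None:
        self.counts: dict[str, np.ndarray] = {
            cid: np.zeros((4, len(c)), dtype=np.uint32)
            for cid, c in graph.contigs.items()
        }

    def add_read(self, hit: MappingHit, sequence: str) -> None:
        seq = sequence.upper() if hit.strand == "+" else revcomp(sequence).upper()
        codes = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        cols = np.arange(hit.start, hit.end)
        ok = codes != 255
        np.add.at(self.counts[hit.contig_id], (codes[ok], cols[ok]), 1)


class Change(NamedTuple):
    contig_id: str
    pos: int
    old: str
    new: str
    depth: int
    fraction: float


def build_pileup(
    graph: ContigGraph,
    pes: list[PairedEnd],
    hits: dict[str, tuple[list[MappingHit], list[MappingHit]]],
    rng: FragmentLengthRange,
) -> Pileup:
    """Pile up the uniquely mapped reads of authentic regular PEs."""
    pileup = Pileup(graph)
    for pe in pes:
        h1, h2 = hits[pe.pe_id]
        if not any(frag in rng for _, _, frag in authentic_pairs(h1, h2)):
            continue
        for mate_hits, read in ((h1, pe.read1), (h2, pe.read2)):
            if is_unique(mate_hits):
                pileup.add_read(mate_hits[0], read.sequence)
    return pileup


def correct_contigs(
    graph: ContigGraph,
    pileup: Pileup,
    cfg: CorrectionConfig = CorrectionConfig(),
) -> tuple[ContigGraph, list[Change]]:
    """Apply consensus corrections; returns a new graph and the change log."""
    out = ContigGraph()
    log: list[Change] = []
    for cid in graph.contigs:
        contig = graph.contigs[cid]
        counts = pileup.counts[cid]
        depth = counts.sum(axis=0)
        maxc = counts.max(axis=0)
        cons = counts.argmax(axis=0)
        strict = (counts == maxc).sum(axis=0) == 1
        arr = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8)
        upper = np.where((arr >= 97) & (arr <= 122), arr - 32, arr)
        is_lower = upper != arr
        differs = _BASES[cons] != upper
        by_case = is_lower & (depth >= 1)
        by_majority = (depth >= cfg.min_depth) & (
            maxc.astype(float) >= cfg.min_fraction * depth.astype(float)
        )
        replace = differs & strict & (by_case | by_majority)
        new_arr = upper.copy()
        keep = ~replace
        new_arr[keep] = arr[keep]  # untouched bases keep their case
        new_arr[replace] = _BASES[cons[replace]]
        for pos in np.flatnonzero(replace):
            d = int(depth[pos])
            log.append(Change(
                contig_id=cid, pos=int(pos), old=chr(arr[pos]),
                new=chr(new_arr[pos]), depth=d,
                fraction=float(maxc[pos]) / d if d else 0.0,
            ))
        out.add_contig(Contig(id=cid, sequence=new_arr.tobytes().decode("ascii"),
                              depth=contig.depth.copy()))
    for edge in graph.edges:
        out.add_edge(*edge)
    return out, log
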