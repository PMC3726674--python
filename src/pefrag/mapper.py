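"""Mismatch-bounded, gapless read placement on contigs.

The contract mirrors a seed-based short-read aligner: a placement is
reported when the read's first ``seed_length`` bases (in the read's own
orientation) align with at most ``seed_max_mm`` mismatches and the full
read aligns with at most ``total_max_mm`` mismatches.  Both strands are
searched and every qualifying placement is returned.

Candidate placements come from a pigeonhole q-gram index: the seed region
is split into ``seed_max_mm + 1`` disjoint chunks, so any placement within
the seed mismatch budget matches at least one chunk exactly.  Chunk lookups
use a sorted integer array over all contig q-grams; candidates are then
verified by direct mismatch counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .assembler import ContigGraph
from .seqio import SeqRecord, revcomp

logger = logging.getLogger("pefrag")

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


@dataclass
class MapConfig:
    seed_length: int = 40
    seed_max_mm: int = 2
    total_max_mm: int = 5

    def __post_init__(self) -> None:
        if self.seed_max_mm > self.total_max_mm:
            raise ValueError("seed_max_mm must be <= total_max_mm")
        if self.seed_length // (self.seed_max_mm + 1) < 6:
            raise ValueError("seed too short for the mismatch budget")


@dataclass(frozen=True)
class MappingHit:
    """A gapless placement of a read on a contig (0-based start)."""

    read_id: str
    contig_id: str
    start: int
    strand: str
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


class ContigIndex:
    """Sorted q-gram index over the uppercase contig sequences."""

    def __init__(self, graph: ContigGraph, cfg: MapConfig = MapConfig()) -> None:
        if not graph.contigs:
            raise ValueError("cannot index an empty contig graph")
        self.cfg = cfg
        self.q = min(cfg.seed_length // (cfg.seed_max_mm + 1), 15)
        self.graph = graph
        self.contig_ids: list[str] = []
        seqs: list[np.ndarray] = []
        n_skipped = 0
        for cid in sorted(graph.contigs):
            c = graph.contigs[cid]
            if len(c) < cfg.seed_length:
                logger.debug("contig %s shorter than seed length; skipped", cid)
                n_skipped += 1
                continue
            self.contig_ids.append(cid)
            seqs.append(
                np.frombuffer(c.sequence.upper().encode("ascii"), dtype=np.uint8)
            )
        if n_skipped:
            logger.warning("%d contigs shorter than the seed length skipped",
                           n_skipped)
        if not self.contig_ids:
            raise ValueError("no contig reaches the seed length")
        self.starts = np.zeros(len(seqs) + 1, dtype=np.int64)
        np.cumsum([len(s) for s in seqs], out=self.starts[1:])
        self.gseq = np.concatenate(seqs)
        codes2 = _LUT[self.gseq]
        q = self.q
        gram_chunks = []
        pos_chunks = []
        for i, s in enumerate(seqs):
            if len(s) < q:
                continue
            c2 = codes2[self.starts[i] : self.starts[i + 1]]
            n = len(c2) - q + 1
            v = np.zeros(n, dtype=np.uint32)
            bad = np.zeros(n, dtype=bool)
            for j in range(q):
                col = c2[j : j + n]
                bad |= col == 255
                v = (v << np.uint32(2)) | col
            v[bad] = np.uint32(0xFFFFFFFF)
            gram_chunks.append(v)
            pos_chunks.append(np.arange(self.starts[i], self.starts[i] + n))
        grams = np.concatenate(gram_chunks)
        gpos = np.concatenate(pos_chunks)
        order = np.argsort(grams, kind="stable")
        self._grams = grams[order]
        self._gpos = gpos[order]

    def lookup(self, code: int) -> np.ndarray:
        """Global start positions of exact occurrences of a q-gram code."""
        lo = np.searchsorted(self._grams, np.uint32(code), side="left")
        hi = np.searchsorted(self._grams, np.uint32(code), side="right")
        return self._gpos[lo:hi]


def build_index(graph: ContigGraph, cfg: MapConfig = MapConfig()) -> ContigIndex:
    return ContigIndex(graph, cfg)


def _encode_chunk(arr: np.ndarray) -> int | None:
    code = 0
    for v in arr:
        if v == 255:
            return None
        code = (code << 2) | int(v)
    return code


def map_read(
    read: SeqRecord, index: ContigIndex, cfg: MapConfig | None = None
) -> list[MappingHit]:
    """All qualifying placements of a read, sorted by
    (mismatches, contig_id, start)."""
    cfg = cfg or index.cfg
    L = len(read)
    if L < cfg.seed_length:
        logger.warning("read %s shorter than the seed length; not mapped", read.id)
        return []
    q = index.q
    nchunks = cfg.seed_max_mm + 1
    hits: dict[tuple[str, int, str], MappingHit] = {}
    starts = index.starts
    gseq = index.gseq
    for strand in "+-":
        s = read.sequence.upper() if strand == "+" else revcomp(read.sequence).upper()
        qarr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        codes2 = _LUT[qarr]
        # chunk offsets covering the seed region in this orientation: the seed
        # is the read's first seed_length bases, which sit at the *end* of the
        # reverse-complemented sequence on the minus strand.
        if strand == "+":
            offs = [j * q for j in range(nchunks)]
            seed_lo, seed_hi = 0, cfg.seed_length
        else:
            offs = [L - (j + 1) * q for j in range(nchunks)]
            seed_lo, seed_hi = L - cfg.seed_length, L
        cand: set[int] = set()
        for o in offs:
            code = _encode_chunk(codes2[o : o + q])
            if code is None:
                continue
            for gp in index.lookup(code):
                cand.add(int(gp) - o)
        for gstart in cand:
            if gstart < 0 or gstart + L > starts[-1]:
                continue
            ci = int(np.searchsorted(starts, gstart, side="right")) - 1
            if gstart + L > starts[ci + 1]:
                continue
            window = gseq[gstart : gstart + L]
            mm = int(np.count_nonzero(window != qarr))
            if mm > cfg.total_max_mm:
                continue
            mm_seed = int(
                np.count_nonzero(window[seed_lo:seed_hi] != qarr[seed_lo:seed_hi])
            )
            if mm_seed > cfg.seed_max_mm:
                continue
            cid = index.contig_ids[ci]
            local = gstart - int(starts[ci])
            hits[(cid, local, strand)] = MappingHit(
                read_id=read.id, contig_id=cid, start=local, strand=strand,
                mismatches=mm, length=L,
            )
    return sorted(hits.values(), key=lambda h: (h.mismatches, h.contig_id, h.start, h.strand))


def is_unique(hits: list[MappingHit]) -> bool:
    """A read is uniquely mapped iff exactly one hit attains the minimal
    mismatch count."""
    if not hits:
        return False
    best = hits[0].mismatches
    return sum(1 for h in hits if h.mismatches == best) == 1
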