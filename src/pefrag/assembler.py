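"""Minimal de Bruijn assembler: unitigs with per-base depth plus the contig
adjacency graph.

K-mers are counted canonically (a k-mer is pooled with its reverse
complement), k-mers below ``min_kmer_count`` are discarded as noise, and
contigs are the maximal non-branching paths (unitigs) of the surviving
graph.  Per-base depth is the mean count of the k-mers covering the base;
bases supported at depth <= ``unreliable_depth`` are written in lowercase to
mark them unreliable.  Unitigs sharing a (k-1)-overlap at a branch are
connected by oriented edges.

The default k is 60% of the read length, rounded down to the nearest odd
integer.  This assembler deliberately performs no tip-clipping or
bubble-popping beyond the k-mer count filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np

from .seqio import SeqRecord, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class AssemblyError(RuntimeError):
    pass


@dataclass
class AssemblyConfig:
    k: Union[int, str] = "auto"
    min_kmer_count: int = 2
    unreliable_depth: int = 1

    def __post_init__(self) -> None:
        if self.k != "auto":
            if int(self.k) % 2 == 0 or int(self.k) < 1:
                raise ValueError("k must be an odd positive integer or 'auto'")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")


def default_k(read_length: int) -> int:
    """Largest odd integer <= 60% of the read length."""
    if read_length < 21:
        raise ValueError(f"read length {read_length} too short (< 21)")
    k = (3 * read_length) // 5
    return k if k % 2 == 1 else k - 1


@dataclass
class Contig:
    """Assembled sequence; lowercase bases are unreliable, ``depth`` is the
    per-base read support."""

    id: str
    sequence: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.depth) != len(self.sequence):
            raise ValueError(f"contig {self.id}: depth/sequence length mismatch")

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())

    def __len__(self) -> int:
        return len(self.sequence)


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


class ContigGraph:
    """Contigs plus oriented overlap edges.

    An edge ``(a, ao, b, bo, n)`` states that the last ``n`` bases of contig
    ``a`` read in orientation ``ao`` equal the first ``n`` bases of ``b``
    read in orientation ``bo``.  Edges are closed under reverse-complement
    symmetry: ``(a,ao,b,bo,n)`` and ``(b,~bo,a,~ao,n)`` are the same edge and
    are stored once, canonically.
    """

    def __init__(self) -> None:
        self.contigs: dict[str, Contig] = {}
        self.edges: set[tuple[str, str, str, str, int]] = set()
        self._adj: dict[tuple[str, str], list[tuple[str, str, int]]] = {}

    def add_contig(self, contig: Contig) -> None:
        if contig.id in self.contigs:
            raise ValueError(f"duplicate contig id {contig.id}")
        self.contigs[contig.id] = contig

    def add_edge(self, frm: str, fo: str, to: str, to_o: str, overlap: int) -> None:
        rep = (frm, fo, to, to_o, overlap)
        sym = (to, _flip(to_o), frm, _flip(fo), overlap)
        canon = min(rep, sym)
        if canon in self.edges:
            return
        self.edges.add(canon)
        self._adj.setdefault((frm, fo), []).append((to, to_o, overlap))
        if rep != sym:
            self._adj.setdefault((to, _flip(to_o)), []).append((frm, _flip(fo), overlap))

    def neighbors(self, cid: str, orient: str) -> list[tuple[str, str, int]]:
        """Successors of the oriented contig (contig, orientation, overlap)."""
        return self._adj.get((cid, orient), [])

    def oriented_sequence(self, cid: str, orient: str) -> str:
        seq = self.contigs[cid].sequence
        return seq if orient == "+" else revcomp(seq)

    def validate_overlaps(self) -> None:
        """Assert every edge's overlap is sequence-consistent."""
        for frm, fo, to, to_o, ov in self.edges:
            a = self.oriented_sequence(frm, fo)
            b = self.oriented_sequence(to, to_o)
            if a[-ov:].upper() != b[:ov].upper():
                raise AssemblyError(
                    f"edge ({frm},{fo})->({to},{to_o}) overlap {ov} is inconsistent"
                )


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------

def _canonical_kmers(seq: str, rc: str, k: int):
    """Yield canonical k-mers of a read; windows containing non-ACGT skipped."""
    n = len(seq)
    if n < k:
        return
    if "N" in seq:
        # restart after every N; rare path
        bad = [i for i, ch in enumerate(seq) if ch not in "ACGT"]
        bad_set = set(bad)
        for i in range(n - k + 1):
            if any(j in bad_set for j in range(i, i + k)):
                continue
            f = seq[i : i + k]
            r = rc[n - k - i : n - i]
            yield f if f <= r else r
    else:
        for i in range(n - k + 1):
            f = seq[i : i + k]
            r = rc[n - k - i : n - i]
            yield f if f <= r else r


def count_kmers(
    reads: Iterable[SeqRecord], k: int, min_count: int = 2
) -> dict[str, int]:
    """Exact counts of canonical k-mers occurring at least ``min_count`` times.

    For ``min_count`` >= 2 a saturating hash-counter prefilter drops the bulk
    of singleton (mostly error) k-mers before exact counting, keeping memory
    proportional to the recurrent k-mer set.
    """
    reads = list(reads)
    if min_count >= 2:
        nslots = 1 << 27
        mask = nslots - 1
        sat = np.zeros(nslots, dtype=np.uint8)
        for rec in reads:
            seq = rec.sequence.upper()
            rc = revcomp(seq)
            for kmer in _canonical_kmers(seq, rc, k):
                idx = hash(kmer) & mask
                v = sat[idx]
                if v < 2:
                    sat[idx] = v + 1
        counts: dict[str, int] = {}
        for rec in reads:
            seq = rec.sequence.upper()
            rc = revcomp(seq)
            for kmer in _canonical_kmers(seq, rc, k):
                if sat[hash(kmer) & mask] >= 2:
                    counts[kmer] = counts.get(kmer, 0) + 1
        return {km: c for km, c in counts.items() if c >= min_count}
    counts = {}
    for rec in reads:
        seq = rec.sequence.upper()
        rc = revcomp(seq)
        for kmer in _canonical_kmers(seq, rc, k):
            counts[kmer] = counts.get(kmer, 0) + 1
    return {km: c for km, c in counts.items() if c >= min_count}


# ---------------------------------------------------------------------------
# unitig construction
# ---------------------------------------------------------------------------

def _right_exts(f: str, r: str, survivors) -> list[tuple[str, str, str]]:
    """Present right extensions of the oriented k-mer (f, r) as
    (next_f, next_r, canonical)."""
    out = []
    f1 = f[1:]
    for c in "ACGT":
        f2 = f1 + c
        r2 = _COMP[c] + r[:-1]
        canon = f2 if f2 <= r2 else r2
        if canon in survivors:
            out.append((f2, r2, canon))
    return out


def _walk_right(f: str, r: str, survivors, visited) -> list[tuple[str, str, str]]:
    """Extend a unitig rightward from (f, r) until a branch or visited node."""
    path = []
    while True:
        exts = _right_exts(f, r, survivors)
        if len(exts) != 1:
            return path
        f2, r2, canon = exts[0]
        # the next node must be joined 1-1: its unique left neighbor is us
        back = _right_exts(r2, f2, survivors)
        if len(back) != 1:
            return path
        if canon in visited:
            return path
        visited.add(canon)
        path.append((f2, r2, canon))
        f, r = f2, r2


def build_contigs(
    reads: Iterable[SeqRecord], cfg: AssemblyConfig = AssemblyConfig()
) -> ContigGraph:
    """Assemble reads into a unitig graph.

    Raises :class:`AssemblyError` when no k-mer survives the count filter.
    """
    reads = list(reads)
    if not reads:
        raise AssemblyError("no assembly: empty read set")
    if cfg.k == "auto":
        k = default_k(min(len(r) for r in reads))
    else:
        k = int(cfg.k)
        if k >= min(len(r) for r in reads):
            raise ValueError("k must be smaller than the shortest read")
    survivors = count_kmers(reads, k, cfg.min_kmer_count)
    if not survivors:
        raise AssemblyError("no assembly: no k-mer survived the count filter")

    visited: set[str] = set()
    unitigs: list[tuple[str, list[int], str, str, str, str]] = []
    # each entry: (sequence, kmer counts along path, first_f, first_r, last_f, last_r)

    def start_node(canon: str) -> Optional[tuple[str, str]]:
        """Return an orientation (f, r) in which `canon` begins a unitig."""
        f = canon
        r = revcomp(canon)
        for fo, ro in ((f, r), (r, f)):
            left = _right_exts(ro, fo, survivors)  # left neighbors of (fo, ro)
            if len(left) != 1:
                return fo, ro
            lf, lr, _ = left[0]
            # unique left neighbor; does it extend uniquely back to us?
            if len(_right_exts(lr, lf, survivors)) != 1:
                return fo, ro
        return None

    def emit(first: tuple[str, str], chain: list[tuple[str, str, str]]) -> None:
        f0, r0 = first
        seq_parts = [f0]
        counts = [survivors[f0 if f0 <= r0 else r0]]
        last_f, last_r = f0, r0
        for f2, r2, canon in chain:
            seq_parts.append(f2[-1])
            counts.append(survivors[canon])
            last_f, last_r = f2, r2
        unitigs.append(("".join(seq_parts), counts, f0, r0, last_f, last_r))

    for canon in survivors:
        if canon in visited:
            continue
        at = start_node(canon)
        if at is None:
            continue
        visited.add(canon)
        emit(at, _walk_right(at[0], at[1], survivors, visited))
    # leftovers are perfect cycles: break each arbitrarily
    for canon in survivors:
        if canon in visited:
            continue
        visited.add(canon)
        f, r = canon, revcomp(canon)
        emit((f, r), _walk_right(f, r, survivors, visited))

    graph = ContigGraph()
    width = len(str(len(unitigs)))
    ends: dict[str, list[tuple[str, str, str]]] = {}
    # endpoint kmer (canonical) -> [(unitig id, 'first'|'last', forward string)]
    for i, (seq, counts, f0, r0, lf, lr) in enumerate(unitigs):
        cid = f"ctg{i + 1:0{width}d}"
        depth = _per_base_depth(counts, k)
        chars = np.array(list(seq))
        low = depth <= cfg.unreliable_depth
        if low.any():
            chars[low] = np.char.lower(chars[low])
            seq = "".join(chars)
        graph.add_contig(Contig(id=cid, sequence=seq, depth=depth))
        ends.setdefault(f0 if f0 <= r0 else r0, []).append((cid, "first", f0))
        ends.setdefault(lf if lf <= lr else lr, []).append((cid, "last", lf))

    for i, (seq, counts, f0, r0, lf, lr) in enumerate(unitigs):
        cid = f"ctg{i + 1:0{width}d}"
        for out_f, out_r, orient in ((lf, lr, "+"), (r0, f0, "-")):
            for f2, r2, canon in _right_exts(out_f, out_r, survivors):
                for vid, where, vf in ends.get(canon, []):
                    if where == "first" and vf == f2:
                        graph.add_edge(cid, orient, vid, "+", k - 1)
                    if where == "last" and vf == r2:
                        graph.add_edge(cid, orient, vid, "-", k - 1)
    return graph


def _per_base_depth(counts: list[int], k: int) -> np.ndarray:
    """Per-base depth of a unitig: mean count of the k-mers covering each base."""
    m = len(counts)
    cs = np.concatenate([[0.0], np.cumsum(counts, dtype=float)])
    j = np.arange(m + k - 1)
    lo = np.maximum(0, j - k + 1)
    hi = np.minimum(j, m - 1) + 1
    return (cs[hi] - cs[lo]) / (hi - lo)
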