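"""Fragment recovery: extract the DNA fragment underlying each paired-end
read, including its unsequenced middle.

Coordinates live in the *fragment frame*: the frame is anchored on the
mapped first mate, oriented so the fragment reads 5'->3' from that mate.
The anchor contig enters the frame in the mate's strand; the fragment
starts at offset ``off`` on it and ends at the second mate's end.  Regular
PEs are extracted directly from one contig; bridging PEs via an
orientation-aware depth-first search for contig paths whose spelled length
keeps the implied fragment within the authentic length range; single
mappable ends by scanning DFS extension sequences for a perfect match to
the head of the unmapped mate (reverse-complemented into the frame).

Whenever several candidates remain the one with the highest length-weighted
mean read coverage wins; ties fall to fewest path steps, then the
lexicographically smallest step list, then the shortest fragment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .assembler import ContigGraph
from .classify import (FragmentLengthRange, PECategory, authentic_pairs,
                       classify_pe, estimate_fragment_range)
from .mapper import ContigIndex, MapConfig, MappingHit, build_index, map_read
from .seqio import PairedEnd, revcomp


@dataclass
class RecoverConfig:
    head_length: int = 10
    max_paths: int = 200
    range_cutoff: int = 5

    def __post_init__(self) -> None:
        if self.head_length < 1:
            raise ValueError("head_length must be >= 1")


@dataclass
class OrientedPath:
    steps: list[tuple[str, str]]
    spelled_length: int
    mean_coverage: float


class PathList(list):
    """List of OrientedPath with a flag set when the search was cut short."""

    truncated: bool = False


@dataclass
class RecoveredFragment:
    pe_id: str
    sequence: str
    category: PECategory
    path: list[tuple[str, str]]
    start: int
    end: int

    @property
    def length(self) -> int:
        return len(self.sequence)


def _frame_anchor(hit: MappingHit, graph: ContigGraph) -> tuple[str, str, int]:
    """Oriented anchor contig and fragment-start offset for a mapped mate."""
    clen = len(graph.contigs[hit.contig_id])
    if hit.strand == "+":
        return hit.contig_id, "+", hit.start
    return hit.contig_id, "-", clen - hit.end


def _frame_target(hit: MappingHit, graph: ContigGraph) -> tuple[str, str, int]:
    """Oriented target contig and mate-end coordinate for the second mate
    (which lies on the frame's minus strand)."""
    clen = len(graph.contigs[hit.contig_id])
    if hit.strand == "-":
        return hit.contig_id, "+", hit.end
    return hit.contig_id, "-", clen - hit.start


def spell_path(graph: ContigGraph, steps: list[tuple[str, str]]) -> str:
    """Sequence spelled by an oriented contig path: the first contig in full,
    then each next contig minus its leading overlap bases."""
    if not steps:
        raise ValueError("empty path")
    cid, orient = steps[0]
    parts = [graph.oriented_sequence(cid, orient)]
    prev = steps[0]
    for cur in steps[1:]:
        ov = _edge_overlap(graph, prev, cur)
        parts.append(graph.oriented_sequence(*cur)[ov:])
        prev = cur
    return "".join(parts)


def _edge_overlap(graph: ContigGraph, a: tuple[str, str], b: tuple[str, str]) -> int:
    for to, to_o, ov in graph.neighbors(*a):
        if (to, to_o) == b:
            return ov
    raise ValueError(f"no edge between {a} and {b}")


def path_mean_coverage(graph: ContigGraph, steps: list[tuple[str, str]]) -> float:
    """Length-weighted mean of per-contig mean depth; weights are the bases
    each contig contributes to the spelled sequence."""
    total = num = 0.0
    prev = None
    for step in steps:
        w = len(graph.contigs[step[0]])
        if prev is not None:
            w -= _edge_overlap(graph, prev, step)
        num += w * graph.contigs[step[0]].mean_depth
        total += w
        prev = step
    return num / total


def _make_path(graph: ContigGraph, steps: list[tuple[str, str]],
               spelled_length: int) -> OrientedPath:
    return OrientedPath(steps=list(steps), spelled_length=spelled_length,
                        mean_coverage=path_mean_coverage(graph, steps))


def find_paths(
    graph: ContigGraph,
    source: tuple[str, str, int],
    target: tuple[str, str],
    max_len: int,
    max_paths: int = 200,
) -> PathList:
    """All oriented contig paths from the source locus to the target contig
    whose spelled extent can still hold a fragment of at most ``max_len``
    bases.  A partial path is abandoned as soon as the spelled length beyond
    the source offset reaches ``max_len``; revisits are allowed (the length
    bound terminates cycles).  At most ``max_paths`` paths are returned, and
    the result is flagged truncated when the cap or the exploration budget
    was hit.
    """
    a, ao, off = source
    out = PathList()
    budget = [100 * max_paths]  # DFS node-expansion guard for tangled graphs

    def dfs(steps: list[tuple[str, str]], start_pos: int) -> None:
        # start_pos: frame coordinate of the current contig's first base
        if budget[0] <= 0:
            out.truncated = True
            return
        budget[0] -= 1
        cur = steps[-1]
        if cur == target:
            end_pos = start_pos + len(graph.contigs[cur[0]])
            out.append(_make_path(graph, steps, end_pos))
            if len(out) >= max_paths:
                out.truncated = True
                return
        for to, to_o, ov in graph.neighbors(*cur):
            nxt_start = start_pos + len(graph.contigs[cur[0]]) - ov
            if nxt_start - off >= max_len:
                continue
            if out.truncated:
                return
            steps.append((to, to_o))
            dfs(steps, nxt_start)
            steps.pop()

    dfs([(a, ao)], 0)
    return out


def recover_regular(
    pe: PairedEnd,
    hits1: list[MappingHit],
    hits2: list[MappingHit],
    graph: ContigGraph,
    rng: FragmentLengthRange,
) -> Optional[RecoveredFragment]:
    """Extract the end-inclusive contig substring between two inward-facing
    mates whose outer distance is in the authentic range; among several
    authentic contigs the one with highest mean depth wins."""
    candidates = []  # (contig mean depth, contig id, h1, h2, frag)
    for h1, h2, frag in authentic_pairs(hits1, hits2):
        if frag in rng:
            candidates.append((graph.contigs[h1.contig_id].mean_depth,
                               h1.contig_id, h1, h2, frag))
    if not candidates:
        return None
    seen = set()
    best = None
    for depth, cid, h1, h2, frag in candidates:
        if cid in seen:
            continue
        seen.add(cid)
        if best is None or depth > best[0]:
            best = (depth, cid, h1, h2, frag)
    _, cid, h1, h2, frag = best
    plus, minus = (h1, h2) if h1.strand == "+" else (h2, h1)
    seq = graph.contigs[cid].sequence[plus.start : minus.end].upper()
    if h1.strand == "-":
        seq = revcomp(seq)
    return RecoveredFragment(
        pe_id=pe.pe_id, sequence=seq, category=PECategory.REGULAR,
        path=[(cid, h1.strand)], start=plus.start, end=minus.end,
    )


def recover_bridging(
    pe: PairedEnd,
    hits1: list[MappingHit],
    hits2: list[MappingHit],
    graph: ContigGraph,
    rng: FragmentLengthRange,
    cfg: RecoverConfig = RecoverConfig(),
) -> Optional[RecoveredFragment]:
    """Recover a fragment spanning two contigs via a connecting oriented
    path; the fragment runs from the first mate's start to the second mate's
    end along the spelled path."""
    candidates = []
    for h1 in hits1:
        for h2 in hits2:
            if h1.contig_id == h2.contig_id:
                continue
            a, ao, off = _frame_anchor(h1, graph)
            b, bo, mate_end = _frame_target(h2, graph)
            paths = find_paths(graph, (a, ao, off), (b, bo), rng.max_len, cfg.max_paths)
            if paths.truncated:
                continue
            for p in paths:
                target_start = p.spelled_length - len(graph.contigs[b])
                frag_len = target_start + mate_end - off
                if frag_len in rng:
                    candidates.append((p, off, frag_len))
    if not candidates:
        return None
    candidates.sort(
        key=lambda t: (-t[0].mean_coverage, len(t[0].steps), t[0].steps, t[2])
    )
    p, off, frag_len = candidates[0]
    seq = spell_path(graph, p.steps)[off : off + frag_len].upper()
    return RecoveredFragment(
        pe_id=pe.pe_id, sequence=seq, category=PECategory.BRIDGING,
        path=p.steps, start=off, end=off + frag_len,
    )


def recover_single(
    pe: PairedEnd,
    mapped_hit: MappingHit,
    unmapped_read,
    graph: ContigGraph,
    rng: FragmentLengthRange,
    cfg: RecoverConfig = RecoverConfig(),
) -> Optional[RecoveredFragment]:
    """Place the unmapped mate by scanning DFS extension sequences from the
    mapped locus for a perfect match to the mate's head, then extract the
    implied fragment."""
    a, ao, off = _frame_anchor(mapped_hit, graph)
    pattern = revcomp(unmapped_read.sequence[: cfg.head_length].upper())
    hlen = cfg.head_length
    candidates = []  # (coverage, frag_len, steps, end)
    budget = [100 * cfg.max_paths]
    truncated = [False]

    def scan(text: str, text_frame_start: int, steps: list[tuple[str, str]]) -> None:
        pos = text.find(pattern)
        while pos != -1:
            e = text_frame_start + pos + hlen
            frag_len = e - off
            if frag_len in rng:
                candidates.append(
                    (path_mean_coverage(graph, steps), frag_len, list(steps), e)
                )
            pos = text.find(pattern, pos + 1)

    def dfs(steps, start_pos, tail: str) -> None:
        # tail: last hlen-1 spelled characters, to catch junction-straddling hits
        if budget[0] <= 0 or len(candidates) >= cfg.max_paths:
            truncated[0] = True
            return
        budget[0] -= 1
        cur = steps[-1]
        for to, to_o, ov in graph.neighbors(*cur):
            nxt_start = start_pos + len(graph.contigs[cur[0]]) - ov
            if nxt_start - off >= rng.max_len:
                continue
            contrib = graph.oriented_sequence(to, to_o).upper()[ov:]
            text = tail + contrib
            frame_start = nxt_start + ov - len(tail)
            scan(text, frame_start, steps + [(to, to_o)])
            dfs(steps + [(to, to_o)], nxt_start, text[max(0, len(text) - hlen + 1):])
            if truncated[0]:
                return

    root = graph.oriented_sequence(a, ao).upper()
    scan(root[off:], off, [(a, ao)])
    dfs([(a, ao)], 0, root[max(off, len(root) - hlen + 1):])
    if truncated[0] or not candidates:
        return None
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    _, frag_len, steps, e = candidates[0]
    seq = spell_path(graph, steps)[off:e].upper()
    return RecoveredFragment(
        pe_id=pe.pe_id, sequence=seq, category=PECategory.SINGLE,
        path=steps, start=off, end=e,
    )


@dataclass
class RecoveryResult:
    fragments: list[RecoveredFragment]
    remaining: list[PairedEnd]
    categories: dict[str, PECategory]
    range: FragmentLengthRange
    report: dict[str, dict[str, int]]


def recover_all(
    pes: list[PairedEnd],
    graph: ContigGraph,
    mapcfg: MapConfig = MapConfig(),
    cfg: RecoverConfig = RecoverConfig(),
    index: Optional[ContigIndex] = None,
    hits: Optional[dict[str, tuple[list[MappingHit], list[MappingHit]]]] = None,
) -> RecoveryResult:
    """Map all reads, estimate the fragment-length range from regular PEs,
    and run the three per-category recovery procedures.  Every PE lands in
    exactly one of ``fragments`` or ``remaining``."""
    if hits is None:
        if index is None:
            index = build_index(graph, mapcfg)
        hits = map_pairs(pes, index, mapcfg)
    categories: dict[str, PECategory] = {}
    lengths = []
    for pe in pes:
        h1, h2 = hits[pe.pe_id]
        cat = classify_pe(h1, h2)
        categories[pe.pe_id] = cat
        if cat is PECategory.REGULAR:
            auth = authentic_pairs(h1, h2)
            if auth:
                lengths.append(auth[0][2])
    rng = estimate_fragment_range(lengths, cfg.range_cutoff)

    fragments: list[RecoveredFragment] = []
    remaining: list[PairedEnd] = []
    for pe in pes:
        h1, h2 = hits[pe.pe_id]
        cat = categories[pe.pe_id]
        frag = None
        if cat is PECategory.REGULAR:
            frag = recover_regular(pe, h1, h2, graph, rng)
        elif cat is PECategory.BRIDGING:
            frag = recover_bridging(pe, h1, h2, graph, rng, cfg)
        elif cat is PECategory.SINGLE:
            if h1:
                frag = recover_single(pe, h1[0], pe.read2, graph, rng, cfg)
            else:
                frag = recover_single(pe, h2[0], pe.read1, graph, rng, cfg)
        if frag is not None:
            fragments.append(frag)
        else:
            remaining.append(pe)

    report = {}
    recovered_by_cat = {}
    for f in fragments:
        recovered_by_cat[f.category] = recovered_by_cat.get(f.category, 0) + 1
    for cat in PECategory:
        n = sum(1 for c in categories.values() if c is cat)
        report[cat.value] = {
            "n_pes": n,
            "n_recovered": recovered_by_cat.get(cat, 0),
        }
    report["total"] = {
        "n_pes": len(pes),
        "n_recovered": len(fragments),
    }
    return RecoveryResult(fragments=fragments, remaining=remaining,
                          categories=categories, range=rng, report=report)


def map_pairs(
    pes: list[PairedEnd], index: ContigIndex, mapcfg: MapConfig
) -> dict[str, tuple[list[MappingHit], list[MappingHit]]]:
    """Map both mates of every pair."""
    out = {}
    for pe in pes:
        out[pe.pe_id] = (map_read(pe.read1, index, mapcfg),
                         map_read(pe.read2, index, mapcfg))
    return out
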