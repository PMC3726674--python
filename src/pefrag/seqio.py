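"""Sequence and graph I/O: FASTA, FASTQ (phred+33), GFA 1.0, paired streams.

All text inputs may be gzip-compressed; compression is detected from the
``.gz`` suffix.  FASTA/FASTQ parsing is delegated to Biopython; GFA 1.0 is
read and written directly (S lines carry sequences whose case is meaningful
-- lowercase marks an unreliable base -- plus an optional ``dp:f`` mean-depth
tag; L lines carry orientations and an ``<n>M`` overlap CIGAR).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SeqParseError(ValueError):
    """Raised when a sequence or graph file does not parse."""


@dataclass
class SeqRecord:
    """A named sequence over {A,C,G,T,N} with optional phred qualities."""

    id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PairedEnd:
    """Two reads sequenced inward from the ends of one DNA fragment."""

    pe_id: str
    read1: SeqRecord
    read2: SeqRecord


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def strip_mate_suffix(read_id: str) -> str:
    """Strip a trailing mate tag: ``/1``, ``/2``, or an SRA-style blank-separated
    ``1``/``2`` comment field.  Anything else is returned unchanged."""
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    head, _, tail = read_id.partition(" ")
    if tail and tail.split(":")[0].split(" ")[0] in ("1", "2"):
        return head
    return read_id


def read_sequences(path, format: str) -> Iterator[SeqRecord]:
    """Stream records from a FASTA or FASTQ file (gzip transparent).

    FASTQ qualities are decoded with offset 33.  Malformed records raise
    :class:`SeqParseError` naming the failing record.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    handle = _open_text(path)
    try:
        n = 0
        try:
            for rec in SeqIO.parse(handle, format):
                n += 1
                quals = None
                if format == "fastq":
                    quals = rec.letter_annotations["phred_quality"]
                desc = rec.description if rec.description != rec.id else rec.id
                yield SeqRecord(id=desc, sequence=str(rec.seq), qualities=quals)
        except ValueError as exc:
            raise SeqParseError(
                f"{path}: parse error at record {n + 1} (~line {_record_line(format, n)}): {exc}"
            ) from exc
    finally:
        handle.close()


def _record_line(format: str, n_parsed: int) -> int:
    return n_parsed * 4 + 1 if format == "fastq" else n_parsed + 1


def write_sequences(records: Iterable[SeqRecord], path, format: str) -> None:
    """Write records as FASTA (case preserved, unwrapped) or FASTQ (phred+33)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    with _open_text(path, "wt") as out:
        for rec in records:
            if format == "fasta":
                out.write(f">{rec.id}\n{rec.sequence}\n")
            else:
                quals = rec.qualities
                if quals is None:
                    quals = [40] * len(rec.sequence)
                qline = "".join(chr(q + 33) for q in quals)
                out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qline}\n")


def pair_streams(
    stream1: Iterable[SeqRecord], stream2: Iterable[SeqRecord]
) -> Iterator[PairedEnd]:
    """Zip two mate streams into PairedEnds, checking ids agree after mate-tag
    stripping and that the streams have equal length."""
    it1, it2 = iter(stream1), iter(stream2)
    sentinel = object()
    n = 0
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise SeqParseError(
                f"paired streams have unequal record counts (failed after {n} pairs)"
            )
        id1 = strip_mate_suffix(r1.id)
        id2 = strip_mate_suffix(r2.id)
        if id1 != id2:
            raise SeqParseError(f"mate id mismatch at pair {n + 1}: {r1.id!r} vs {r2.id!r}")
        n += 1
        yield PairedEnd(pe_id=id1, read1=r1, read2=r2)


def read_pairs(path1, path2, format: str = "fastq") -> Iterator[PairedEnd]:
    """Convenience: pair two FASTA/FASTQ files."""
    return pair_streams(read_sequences(path1, format), read_sequences(path2, format))


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------

def parse_gfa(path) -> "ContigGraph":
    """Parse a GFA 1.0 file into a ContigGraph.

    S lines must carry explicit sequences; lowercase bases are kept (they mark
    unreliable positions).  The optional ``dp:f:<x>`` tag sets the contig's
    mean depth (absent -> 1.0, applied uniformly per base).  L lines must use
    an ``<n>M`` overlap CIGAR and reference known segments.
    """
    from .assembler import Contig, ContigGraph  # deferred: avoids import cycle

    graph = ContigGraph()
    links: list[tuple[str, str, str, str, int]] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3 or fields[2] in ("", "*"):
                    raise SeqParseError(f"{path}:{lineno}: S line without a sequence")
                name, seq = fields[1], fields[2]
                depth = 1.0
                for opt in fields[3:]:
                    if opt.startswith("dp:f:") or opt.startswith("DP:f:"):
                        depth = float(opt[5:])
                graph.add_contig(
                    Contig(id=name, sequence=seq, depth=[depth] * len(seq))
                )
            elif tag == "L":
                if len(fields) < 6:
                    raise SeqParseError(f"{path}:{lineno}: truncated L line")
                _, frm, fo, to, to_o, cigar = fields[:6]
                if fo not in "+-" or to_o not in "+-":
                    raise SeqParseError(f"{path}:{lineno}: bad orientation")
                if not cigar.endswith("M") or not cigar[:-1].isdigit():
                    raise SeqParseError(
                        f"{path}:{lineno}: overlap CIGAR {cigar!r} is not '<n>M'"
                    )
                links.append((frm, fo, to, to_o, int(cigar[:-1])))
    for frm, fo, to, to_o, overlap in links:
        if frm not in graph.contigs or to not in graph.contigs:
            raise SeqParseError(f"{path}: L line references unknown segment {frm}/{to}")
        graph.add_edge(frm, fo, to, to_o, overlap)
    return graph


def emit_gfa(graph: "ContigGraph", path) -> None:
    """Write a ContigGraph as GFA 1.0 (sequences case-preserved, dp tag)."""
    with _open_text(path, "wt") as out:
        out.write("H\tVN:Z:1.0\n")
        for cid in sorted(graph.contigs):
            c = graph.contigs[cid]
            out.write(f"S\t{cid}\t{c.sequence}\tdp:f:{c.mean_depth:.4f}\n")
        for frm, fo, to, to_o, overlap in sorted(graph.edges):
            out.write(f"L\t{frm}\t{fo}\t{to}\t{to_o}\t{overlap}M\n")


# ---------------------------------------------------------------------------
# Truth-table / report TSV
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["pe_id", "genome_id", "start", "end", "strand", "fragment_sequence"]


def write_truth_table(records: Iterable, path) -> None:
    with _open_text(path, "wt") as out:
        out.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in records:
            out.write(
                f"{t.pe_id}\t{t.genome_id}\t{t.start}\t{t.end}\t{t.strand}\t"
                f"{t.fragment_sequence}\n"
            )


def read_truth_table(path) -> dict:
    """Load a simulator truth table keyed by pe_id."""
    from .simulate import TruthRecord  # deferred: avoids import cycle

    out = {}
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise SeqParseError(f"{path}: unexpected truth-table header {header}")
        for line in handle:
            f = line.rstrip("\n").split("\t")
            rec = TruthRecord(
                pe_id=f[0], genome_id=f[1], start=int(f[2]), end=int(f[3]),
                strand=f[4], fragment_sequence=f[5],
            )
            out[rec.pe_id] = rec
    return out
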