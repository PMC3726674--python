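"""Paired-end read simulation with ground truth.

The simulator emulates three features of real Illumina paired-end data:
a read-start profile (non-uniform coverage), fragment lengths drawn from
``Normal(frag_mean, frag_sd)`` with ``frag_sd`` defaulting to 10% of the
mean, and position-dependent substitution errors whose per-cycle rates are
scaled so the expected overall error rate hits ``error_rate``.  Fragments
are drawn until the reads reach ``coverage`` times the genome length
(default 100x).  Read 1 is the first ``read_length`` bases of the
(strand-oriented) fragment; read 2 is the reverse complement of its last
``read_length`` bases.  Qualities encode the per-cycle error rate as phred
scores.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .seqio import PairedEnd, SeqRecord, write_sequences, write_truth_table

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    read_length: int
    frag_mean: float
    frag_sd: Optional[float] = None  # default: 10% of frag_mean
    coverage: float = 100.0
    error_rate: float = 0.01
    start_profile: Union[str, np.ndarray] = "uniform"
    error_profile: Union[str, np.ndarray] = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frag_sd is None:
            self.frag_sd = 0.1 * self.frag_mean
        if self.frag_mean < self.read_length:
            raise ValueError("frag_mean must be >= read_length")


@dataclass
class TruthRecord:
    """Ground truth for one simulated pair (0-based half-open genome span;
    fragment_sequence is strand-oriented)."""

    pe_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    fragment_sequence: str


def make_genome(
    length: int,
    repeat_spec: Sequence[tuple[int, int]] = (),
    gc: float = 0.5,
    seed: int = 0,
) -> SeqRecord:
    """Random genome with the requested GC content and optional exact repeat
    families planted at non-overlapping loci."""
    if sum(rlen * copies for rlen, copies in repeat_spec) > length:
        raise ValueError("repeats do not fit in the genome")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    occupied: list[tuple[int, int]] = []
    for rlen, copies in repeat_spec:
        unit = rng.choice(4, size=rlen, p=p).astype(np.uint8)
        placed = 0
        for _ in range(1000 * copies):
            if placed == copies:
                break
            s = int(rng.integers(0, length - rlen + 1))
            if any(s < e and s + rlen > b for b, e in occupied):
                continue
            codes[s : s + rlen] = unit
            occupied.append((s, s + rlen))
            placed += 1
        if placed < copies:
            raise SimulationError(
                f"could not place {copies} non-overlapping copies of a "
                f"{rlen} bp repeat"
            )
    return SeqRecord(id="genome", sequence=_decode(codes))


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def derive_profiles(
    hits: Optional[Iterable] = None,
    quals: Optional[Iterable[Sequence[int]]] = None,
    genome_len: int = 0,
    read_length: int = 0,
) -> tuple[Union[str, np.ndarray], Union[str, np.ndarray]]:
    """Read-start and per-cycle error profiles from mapped reads / qualities.

    The start profile is proportional to the number of reads starting at
    each base; the error profile averages the per-read error probabilities
    (phred converted to probability before averaging) at each cycle.
    Missing inputs fall back to uniform.
    """
    start_profile: Union[str, np.ndarray] = "uniform"
    if hits is not None:
        counts = np.zeros(genome_len, dtype=float)
        for h in hits:
            if 0 <= h.start < genome_len:
                counts[h.start] += 1
        if counts.sum() > 0:
            start_profile = counts
        else:
            import warnings

            warnings.warn("all-zero start counts; falling back to uniform")
    error_profile: Union[str, np.ndarray] = "uniform"
    if quals is not None:
        quals = list(quals)
        if quals:
            mat = np.array([q[:read_length] for q in quals], dtype=float)
            error_profile = np.power(10.0, -mat / 10.0).mean(axis=0)
    return start_profile, error_profile


def _cycle_error_rates(cfg: SimConfig) -> np.ndarray:
    L = cfg.read_length
    if isinstance(cfg.error_profile, str):
        w = np.ones(L)
    else:
        w = np.asarray(cfg.error_profile, dtype=float)
        if len(w) != L:
            raise ValueError("error_profile length must equal read_length")
    if cfg.error_rate == 0:
        return np.zeros(L)
    rates = w * (cfg.error_rate * L / w.sum())
    if rates.max() > 0.75:
        raise ValueError("per-cycle error rate exceeds 0.75; lower error_rate")
    return rates


def simulate_library(
    genome: SeqRecord, cfg: SimConfig
) -> tuple[list[PairedEnd], list[TruthRecord]]:
    """Simulate a paired-end library with its truth table."""
    G = len(genome.sequence)
    L = cfg.read_length
    if G <= cfg.frag_mean + 6 * cfg.frag_sd:
        raise SimulationError("genome too short for the fragment distribution")
    rng = np.random.default_rng(cfg.seed)
    n = math.ceil(cfg.coverage * G / (2 * L))

    lengths = np.rint(rng.normal(cfg.frag_mean, cfg.frag_sd, size=n)).astype(np.int64)
    clamped = lengths < L
    lengths = np.maximum(lengths, L)

    if isinstance(cfg.start_profile, str):
        starts = rng.integers(0, G, size=n)
    else:
        w = np.asarray(cfg.start_profile, dtype=float)
        if len(w) != G or w.sum() <= 0:
            raise ValueError("start_profile must be per-base non-negative weights")
        cdf = np.cumsum(w / w.sum())
        starts = np.searchsorted(cdf, rng.random(n), side="right")
    # clamp fragments overhanging the genome end to the remainder; a
    # remainder shorter than one read forces a start redraw
    for _ in range(100):
        bad = starts + L > G
        if not bad.any():
            break
        starts[bad] = rng.integers(0, G - L + 1, size=int(bad.sum()))
    over = starts + lengths > G
    clamped |= over
    lengths = np.minimum(lengths, G - starts)
    if clamped.mean() > 0.10:
        raise SimulationError("fragment mean too large for genome")
    ends = starts + lengths
    strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")

    g = _LUT[np.frombuffer(genome.sequence.upper().encode("ascii"), dtype=np.uint8)]
    ar = np.arange(L)
    fwd = g[starts[:, None] + ar]              # first L bases, genome forward
    rev = 3 - g[(ends - 1)[:, None] - ar]      # last L bases, revcomp'd
    plus = strands == "+"
    read1 = np.where(plus[:, None], fwd, rev)
    read2 = np.where(plus[:, None], rev, fwd)

    rates = _cycle_error_rates(cfg)
    for mat in (read1, read2):
        mask = rng.random((n, L)) < rates[None, :]
        shift = rng.integers(1, 4, size=int(mask.sum()))
        mat[mask] = (mat[mask] + shift) % 4

    quals = [
        min(40, int(round(-10 * math.log10(r)))) if r > 0 else 40 for r in rates
    ]
    width = len(str(n))
    pairs: list[PairedEnd] = []
    truth: list[TruthRecord] = []
    for i in range(n):
        pe_id = f"pe{i + 1:0{width}d}"
        r1 = SeqRecord(id=f"{pe_id}/1", sequence=_decode(read1[i]), qualities=quals)
        r2 = SeqRecord(id=f"{pe_id}/2", sequence=_decode(read2[i]), qualities=quals)
        pairs.append(PairedEnd(pe_id=pe_id, read1=r1, read2=r2))
        s, e = int(starts[i]), int(ends[i])
        frag = genome.sequence[s:e].upper()
        if strands[i] == "-":
            frag = _rc(frag)
        truth.append(TruthRecord(
            pe_id=pe_id, genome_id=genome.id, start=s, end=e,
            strand=str(strands[i]), fragment_sequence=frag,
        ))
    return pairs, truth


def _rc(seq: str) -> str:
    from .seqio import revcomp

    return revcomp(seq)


def simulate_to_files(genome: SeqRecord, cfg: SimConfig, prefix: str) -> tuple[str, str, str]:
    """Write ``<prefix>_1.fastq``, ``<prefix>_2.fastq`` and
    ``<prefix>.truth.tsv``; returns the three paths."""
    pairs, truth = simulate_library(genome, cfg)
    p1, p2, pt = f"{prefix}_1.fastq", f"{prefix}_2.fastq", f"{prefix}.truth.tsv"
    write_sequences((pe.read1 for pe in pairs), p1, "fastq")
    write_sequences((pe.read2 for pe in pairs), p2, "fastq")
    write_truth_table(truth, pt)
    return p1, p2, pt
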