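"""Pre-assembly read filtering.

Three filters, applied per pair before assembly:

* drop pairs in which either read contains an N;
* drop pairs in which either read is low-complexity, i.e. one base makes up
  at least ``identity_fraction`` (default 0.8) of the read or the read holds
  a homopolymer run of at least ``run_length`` (default 30) bases;
* optionally cap the library at ``target_coverage`` by keeping pairs from
  the stream head until the kept bases (both mates) reach
  ``target_coverage * genome_size``.

A whole pair is dropped when either mate fails a filter, which keeps the
downstream paired-end bookkeeping exact.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .seqio import PairedEnd


@dataclass
class FilterConfig:
    identity_fraction: float = 0.8
    run_length: int = 30
    drop_n: bool = True
    target_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.identity_fraction <= 1:
            raise ValueError("identity_fraction must be in (0, 1]")
        if self.run_length < 1:
            raise ValueError("run_length must be positive")


def is_low_complexity(seq: str, cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff one base reaches ``identity_fraction`` of the read or a
    homopolymer run reaches ``run_length``."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n = len(s)
    if max(s.count(b) for b in "ACGT") >= cfg.identity_fraction * n:
        return True
    run = best = 1
    for i in range(1, n):
        run = run + 1 if s[i] == s[i - 1] else 1
        if run > best:
            best = run
    return best >= cfg.run_length


def clean_pairs(
    pes: Iterable[PairedEnd],
    cfg: FilterConfig = FilterConfig(),
    genome_size: Optional[int] = None,
):
    """Filter a paired stream; returns ``(kept, log)``.

    ``log`` is a Counter with keys ``input``, ``kept``, ``contains_N``,
    ``low_complexity`` and ``coverage_cap``.  Raises ValueError when a
    coverage target is set without a genome size to scale it by.
    """
    if cfg.target_coverage is not None and genome_size is None:
        raise ValueError("target_coverage requires genome_size")
    cap = (
        cfg.target_coverage * genome_size if cfg.target_coverage is not None else None
    )
    log: Counter = Counter()
    kept: list[PairedEnd] = []
    total_bases = 0
    for pe in pes:
        log["input"] += 1
        if cap is not None and total_bases >= cap:
            log["coverage_cap"] += 1
            continue
        if cfg.drop_n and ("N" in pe.read1.sequence.upper() or "N" in pe.read2.sequence.upper()):
            log["contains_N"] += 1
            continue
        if is_low_complexity(pe.read1.sequence, cfg) or is_low_complexity(pe.read2.sequence, cfg):
            log["low_complexity"] += 1
            continue
        kept.append(pe)
        total_bases += len(pe.read1) + len(pe.read2)
        log["kept"] += 1
    return kept, log
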