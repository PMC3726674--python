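"""Scoring recovered fragments against simulator ground truth.

A recovery is *correct* when its length equals the true fragment length
(bases may still differ) and *perfect* when the sequence is identical to
the truth, allowing reverse-complement equality since fragment orientation
is arbitrary.  Reports follow the per-category layout of the recovery
statistics table: recovered percentages are taken over the category's PE
count, correct/perfect percentages over the recovered count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .classify import PECategory
from .recover import RecoveredFragment
from .seqio import revcomp
from .simulate import TruthRecord

_CATS = [c.value for c in PECategory]
_COLUMNS = {
    "regular": "Regular",
    "bridging": "Bridging",
    "single_mappable_end": "Single-mappable-end",
    "unmapped": "Unmapped",
    "total": "Total",
}


def score_fragment(frag: RecoveredFragment, truth: TruthRecord) -> tuple[bool, bool]:
    """(correct, perfect) for one recovered fragment."""
    if frag.pe_id != truth.pe_id:
        raise ValueError(f"pe_id mismatch: {frag.pe_id} vs {truth.pe_id}")
    seq = frag.sequence.upper()
    ref = truth.fragment_sequence.upper()
    correct = len(seq) == len(ref)
    perfect = correct and (seq == ref or seq == revcomp(ref))
    return correct, perfect


@dataclass
class CategoryStats:
    n_pes: int = 0
    n_recovered: int = 0
    n_correct: int = 0
    n_perfect: int = 0

    @property
    def pct_recovered(self) -> Optional[float]:
        return 100.0 * self.n_recovered / self.n_pes if self.n_pes else None

    @property
    def pct_correct(self) -> Optional[float]:
        return 100.0 * self.n_correct / self.n_recovered if self.n_recovered else None

    @property
    def pct_perfect(self) -> Optional[float]:
        return 100.0 * self.n_perfect / self.n_recovered if self.n_recovered else None


@dataclass
class EvalReport:
    rows: dict[str, CategoryStats] = field(default_factory=dict)

    def to_tsv(self) -> str:
        cols = list(_COLUMNS)
        lines = ["PE read mappings\t" + "\t".join(_COLUMNS[c] for c in cols)]

        def fmt(n: int, pct: Optional[float], na: bool = False) -> str:
            if na:
                return "N.A."
            if pct is None:
                return f"{n} (n/a)"
            return f"{n} ({pct:.2f}%)"

        r = self.rows
        lines.append("No. (%) of PEs\t" + "\t".join(
            fmt(r[c].n_pes, 100.0 * r[c].n_pes / r["total"].n_pes
                if r["total"].n_pes else None) for c in cols))
        for label, nattr, pattr in [
            ("No. (%) of recovered fragments", "n_recovered", "pct_recovered"),
            ("No. (%) of correctly recovered fragments", "n_correct", "pct_correct"),
            ("No. (%) of perfectly recovered fragments", "n_perfect", "pct_perfect"),
        ]:
            lines.append(label + "\t" + "\t".join(
                fmt(getattr(r[c], nattr), getattr(r[c], pattr),
                    na=(c == "unmapped")) for c in cols))
        return "\n".join(lines) + "\n"


def build_report(
    fragments: Iterable[RecoveredFragment],
    truth_table: Mapping[str, TruthRecord],
    categories: Mapping[str, PECategory],
) -> EvalReport:
    """Per-category recovery statistics; every fragment must have a truth
    record and every PE a category."""
    rows = {c: CategoryStats() for c in _CATS + ["total"]}
    for pe_id, cat in categories.items():
        rows[cat.value].n_pes += 1
        rows["total"].n_pes += 1
    missing = [f.pe_id for f in fragments if f.pe_id not in truth_table]
    if missing:
        raise ValueError(f"no truth record for: {', '.join(missing[:10])}"
                         + ("..." if len(missing) > 10 else ""))
    for f in fragments:
        correct, perfect = score_fragment(f, truth_table[f.pe_id])
        for key in (f.category.value, "total"):
            rows[key].n_recovered += 1
            rows[key].n_correct += int(correct)
            rows[key].n_perfect += int(perfect)
    return EvalReport(rows=rows)


def n50(lengths: Iterable[int]) -> int:
    """Largest L such that contigs of length >= L hold at least half of the
    assembled bases."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("n50 of an empty length list")
    if min(ls) <= 0:
        raise ValueError("lengths must be positive")
    half = sum(ls) / 2
    acc = 0
    for l in ls:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")
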