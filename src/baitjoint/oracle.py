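"""Brute-force string recomputation of junction structure.

The production classifier derives joint structure purely from called tlx
coordinates (``b_qend - qstart + 1``).  This module re-derives the same
quantities directly from the read sequence and the reference by maximal
ungapped extension, and serves as the independent oracle in tests and as
the simulator's per-read self check.

Extension semantics (shared by the caller): extend base by base from an
anchor, tolerating up to ``max_mismatch`` total mismatches, stopping when
one more mismatch would exceed the budget, then trim trailing mismatches
so the alignment ends on a match.  A run of ``max_mismatch + 1``
mismatches therefore always terminates extension exactly at its start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .geometry import revcomp
from .tlx import TlxRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def extend_right(
    read: str, ref_base_at: Callable[[int], Optional[str]], start: int, max_mismatch: int
) -> int:
    """Greedy rightward extension; returns the 0-based exclusive end."""
    mismatches = 0
    last_match = start
    i = start
    n = len(read)
    while i < n:
        expected = ref_base_at(i)
        if expected is None:
            break
        if read[i] == expected:
            last_match = i + 1
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                break
        i += 1
    return last_match


def extend_left(
    read: str, ref_base_at: Callable[[int], Optional[str]], start: int, max_mismatch: int
) -> int:
    """Greedy leftward extension from exclusive ``start``; returns 0-based start."""
    mismatches = 0
    first_match = start
    i = start - 1
    while i >= 0:
        expected = ref_base_at(i)
        if expected is None:
            break
        if read[i] == expected:
            first_match = i
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                break
        i -= 1
    return first_match


@dataclass(frozen=True)
class OracleResult:
    kind: str  # {"MH", "direct", "insertion"}
    length: int
    palindromic: bool
    b_qend: int  # 0-based exclusive, recomputed
    qstart: int  # 0-based, recomputed
    overlap: int


def _bait_ref_fn(record: TlxRecord, reference: dict[str, str]) -> Callable[[int], Optional[str]]:
    refseq = reference[record.b_rname]

    def at(q: int) -> Optional[str]:
        offset = q - (record.b_qstart - 1)
        if record.b_strand == "+":
            pos = (record.b_rstart - 1) + offset
            if 0 <= pos < len(refseq):
                return refseq[pos]
        else:
            pos = (record.b_rend - 1) - offset
            if 0 <= pos < len(refseq):
                return _COMP[refseq[pos]]
        return None

    return at


def _prey_ref_fn(record: TlxRecord, reference: dict[str, str]) -> Callable[[int], Optional[str]]:
    refseq = reference[record.rname]

    def at(q: int) -> Optional[str]:
        offset = q - (record.qstart - 1)
        if record.strand == "+":
            pos = (record.rstart - 1) + offset
            if 0 <= pos < len(refseq):
                return refseq[pos]
        else:
            pos = (record.rend - 1) - offset
            if 0 <= pos < len(refseq):
                return _COMP[refseq[pos]]
        return None

    return at


def structure_oracle(
    record: TlxRecord, reference: dict[str, str], max_mismatch: int = 2
) -> OracleResult:
    """Recompute junction structure by direct string comparison.

    Starting from the record's alignment *locations* (not its boundary
    fields), re-extends the bait alignment rightward from the primer and
    the prey alignment leftward from its read-distal end against the
    reference, and reads the structure off the recomputed maximal
    boundaries: positive overlap = microhomology, zero = direct joint,
    negative = inserted bases (palindromic when they reverse-complement
    either junction-proximal flank).
    """
    read = record.seq
    if not read:
        raise ValueError(f"record {record.qname}: oracle requires the read sequence")
    b_qend = extend_right(read, _bait_ref_fn(record, reference), record.b_qstart - 1, max_mismatch)
    qstart = extend_left(read, _prey_ref_fn(record, reference), record.qend, max_mismatch)
    overlap = b_qend - qstart
    if overlap > 0:
        return OracleResult("MH", overlap, False, b_qend, qstart, overlap)
    if overlap == 0:
        return OracleResult("direct", 0, False, b_qend, qstart, 0)
    m = -overlap
    inserted = read[b_qend:qstart]
    bait_flank = read[max(0, b_qend - m) : b_qend]
    prey_flank = read[qstart : qstart + m]
    palindromic = (len(bait_flank) == m and inserted == revcomp(bait_flank)) or (
        len(prey_flank) == m and inserted == revcomp(prey_flank)
    )
    return OracleResult("insertion", m, palindromic, b_qend, qstart, overlap)
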