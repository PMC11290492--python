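"""Bait-anchored junction calling from reads.

Each read is anchored at its bait primer, the bait alignment is extended
toward the DSB, and the remainder of the read is aligned back to the
reference by exact-seed ungapped extension.  The prey alignment defines
the junction: its strand-aware first base is the tlx ``Junction``
coordinate, and the junction-proximal end of the bait alignment is
``B_Junction``.

Alignment semantics are intentionally simple and fully specified (no
heuristic scoring): maximal greedy ungapped extension with a total
mismatch budget (see :mod:`baitjoint.oracle` for the shared extension
contract), seeds of fixed length, and deterministic tie-breaking, so
that calls are byte-reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .geometry import revcomp
from .locus import BaitSpec, LocusSpec
from .oracle import extend_left, extend_right
from .tlx import TlxRecord

SEED_LENGTH = 20

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class AlignmentSegment:
    """One ungapped read-to-reference alignment (all coordinates 0-based).

    ``qstart:qend`` is the half-open aligned query interval; ``rstart:rend``
    the half-open reference interval.  On '-' the query aligns to the
    reverse complement, query base ``qstart`` pairing with reference base
    ``rend - 1``.
    """

    chrom: str
    strand: str
    qstart: int
    qend: int
    rstart: int
    rend: int

    @property
    def length(self) -> int:
        return self.qend - self.qstart


@dataclass
class CallerConfig:
    max_mismatch: int = 2
    min_bait_extension: int = 5  # aligned bases required beyond the primer
    min_prey_length: int = SEED_LENGTH
    seed_length: int = SEED_LENGTH


class SeedIndex:
    """Exact k-mer index over both strands of a reference dict."""

    def __init__(self, reference: dict[str, str], k: int = SEED_LENGTH) -> None:
        self.reference = reference
        self.k = k
        index: dict[str, list[tuple[str, str, int]]] = {}
        for chrom, seq in reference.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((chrom, "+", i))
        for chrom, seq in reference.items():
            rc = revcomp(seq)
            n = len(seq)
            for i in range(len(rc) - k + 1):
                # rc[i:i+k] pairs with forward interval [n-i-k, n-i)
                index.setdefault(rc[i : i + k], []).append((chrom, "-", n - i - k))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, str, int]]:
        return self._index.get(kmer, [])


def _ref_fn(reference: dict[str, str], chrom: str, strand: str, rpos_of_q0: int):
    """Reference base as a function of query index for an ungapped diagonal.

    ``rpos_of_q0`` is the forward-strand reference coordinate pairing with
    query index 0 (for '-' diagonals coordinates decrease with the query).
    """
    seq = reference[chrom]

    def at(q: int) -> Optional[str]:
        pos = rpos_of_q0 + q if strand == "+" else rpos_of_q0 - q
        if 0 <= pos < len(seq):
            base = seq[pos]
            return base if strand == "+" else _COMP[base]
        return None

    return at


def anchor_bait(
    read: str,
    bait: BaitSpec,
    reference: dict[str, str],
    config: CallerConfig,
) -> Optional[AlignmentSegment]:
    """Match the bait primer at the read start and extend toward the DSB.

    Returns None when the primer does not match within the mismatch budget
    or the extension does not clear ``min_bait_extension`` aligned bases
    past the primer.
    """
    seq = reference[bait.chrom]
    primer = (
        seq[bait.primer_start : bait.primer_end]
        if bait.bait_strand == "+"
        else revcomp(seq[bait.primer_start : bait.primer_end])
    )
    n = len(primer)
    if len(read) < n:
        return None
    mismatches = sum(1 for a, b in zip(read[:n], primer) if a != b)
    if mismatches > config.max_mismatch:
        return None
    if bait.bait_strand == "+":
        rpos_of_q0 = bait.primer_start
    else:
        rpos_of_q0 = bait.primer_end - 1
    qend = extend_right(
        read, _ref_fn(reference, bait.chrom, bait.bait_strand, rpos_of_q0),
        n, config.max_mismatch,
    )
    if qend - n < config.min_bait_extension:
        return None
    if bait.bait_strand == "+":
        rstart, rend = rpos_of_q0, rpos_of_q0 + qend
    else:
        rstart, rend = rpos_of_q0 - qend + 1, rpos_of_q0 + 1
    return AlignmentSegment(bait.chrom, bait.bait_strand, 0, qend, rstart, rend)


def _extend_seed(
    read: str,
    reference: dict[str, str],
    chrom: str,
    strand: str,
    q_seed: int,
    r_seed: int,
    k: int,
    lo_limit: int,
    max_mismatch: int,
) -> AlignmentSegment:
    """Maximal ungapped extension of an exact seed match in both directions.

    ``r_seed`` is the forward-strand start of the reference k-mer; on '-'
    query index ``q_seed`` pairs with reference base ``r_seed + k - 1``.
    ``lo_limit`` bounds leftward query extension (end of usable bait part).
    """
    if strand == "+":
        rpos_of_q0 = r_seed - q_seed
    else:
        rpos_of_q0 = r_seed + k - 1 + q_seed
    at = _ref_fn(reference, chrom, strand, rpos_of_q0)
    qend = extend_right(read, at, q_seed + k, max_mismatch)
    qstart = max(lo_limit, extend_left(read, at, q_seed, max_mismatch))
    if strand == "+":
        rstart, rend = rpos_of_q0 + qstart, rpos_of_q0 + qend
    else:
        rstart, rend = rpos_of_q0 - qend + 1, rpos_of_q0 - qstart + 1
    return AlignmentSegment(chrom, strand, qstart, qend, rstart, rend)


def find_prey(
    read: str,
    bait_aln: AlignmentSegment,
    reference: dict[str, str],
    index: SeedIndex,
    config: CallerConfig,
) -> Optional[AlignmentSegment]:
    """Best prey alignment for the read suffix beyond the bait alignment.

    Seeds every exact k-mer of the suffix (allowing seeds to reach back up
    to ``k`` bases into the bait alignment so microhomology junctions are
    seedable), extends each hit, and keeps the longest alignment.  Ties
    break deterministically: leftmost query start, then lowest reference
    start, then '+' strand.
    """
    k = index.k
    start = max(0, bait_aln.qend - k)
    best: Optional[AlignmentSegment] = None
    seen: set[tuple[str, str, int]] = set()
    for q in range(start, len(read) - k + 1):
        for chrom, strand, rpos in index.lookup(read[q : q + k]):
            diag = (chrom, strand, rpos - q if strand == "+" else rpos + q)
            if diag in seen:
                continue
            seen.add(diag)
            aln = _extend_seed(
                read, reference, chrom, strand, q, rpos, k, 0, config.max_mismatch
            )
            if aln.length < config.min_prey_length:
                continue
            if best is None or (
                (-aln.length, aln.qstart, aln.rstart, aln.strand)
                < (-best.length, best.qstart, best.rstart, best.strand)
            ):
                best = aln
    return best


def _same_diagonal(bait_aln: AlignmentSegment, prey_aln: AlignmentSegment) -> bool:
    """True when the prey alignment merely continues the bait alignment."""
    if (prey_aln.chrom, prey_aln.strand) != (bait_aln.chrom, bait_aln.strand):
        return False
    if bait_aln.strand == "+":
        return prey_aln.rstart - prey_aln.qstart == bait_aln.rstart - bait_aln.qstart
    return prey_aln.rend - 1 + prey_aln.qstart == bait_aln.rend - 1 + bait_aln.qstart


def call_junction(
    qname: str,
    read: str,
    bait: BaitSpec,
    reference: dict[str, str],
    index: SeedIndex,
    config: Optional[CallerConfig] = None,
    junc_id: int = 0,
) -> Optional[TlxRecord]:
    """Call the junction of one read; None when no junction is supported.

    A read whose prey alignment is just the uninterrupted continuation of
    the bait alignment (germline molecule) yields no junction.
    """
    config = config or CallerConfig()
    bait_aln = anchor_bait(read, bait, reference, config)
    if bait_aln is None:
        return None
    prey_aln = find_prey(read, bait_aln, reference, index, config)
    if prey_aln is None or _same_diagonal(bait_aln, prey_aln):
        return None
    # Trim a bait alignment overshooting the prey start only in bookkeeping:
    # both maximal extents are reported; the overlap is the structure signal.
    junction = prey_aln.rstart + 1 if prey_aln.strand == "+" else prey_aln.rend
    b_junction = bait_aln.rend if bait_aln.strand == "+" else bait_aln.rstart + 1
    rec = TlxRecord(
        qname=qname,
        junc_id=junc_id,
        rname=prey_aln.chrom,
        junction=junction,
        strand=prey_aln.strand,
        rstart=prey_aln.rstart + 1,
        rend=prey_aln.rend,
        b_rname=bait_aln.chrom,
        b_rstart=bait_aln.rstart + 1,
        b_rend=bait_aln.rend,
        b_strand=bait_aln.strand,
        b_junction=b_junction,
        qstart=prey_aln.qstart + 1,
        qend=prey_aln.qend,
        b_qstart=bait_aln.qstart + 1,
        b_qend=bait_aln.qend,
        qlen=len(read),
        seq=read,
    )
    rec.validate()
    return rec


def call_library(
    reads: Iterable[tuple[str, str]],
    bait: BaitSpec,
    reference: dict[str, str],
    config: Optional[CallerConfig] = None,
    index: Optional[SeedIndex] = None,
) -> list[TlxRecord]:
    """Call junctions for a whole library, numbering JuncID from 1."""
    config = config or CallerConfig()
    if index is None:
        index = SeedIndex(reference, config.seed_length)
    out: list[TlxRecord] = []
    for qname, read in reads:
        rec = call_junction(
            qname, read, bait, reference, index, config, junc_id=len(out) + 1
        )
        if rec is not None:
            out.append(rec)
    return out
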