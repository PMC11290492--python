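"""Read-space geometry around DSB junctions.

A chimeric read runs primer -> bait flank -> (junction) -> prey flank.  Both
flanks are most conveniently handled as *junction lines*: reference-derived
strings already oriented in read direction, indexed so that a single integer
boundary describes where a resected end stops.

For a :class:`JunctionLine`, index ``origin`` is the first base past the cut
in read orientation; the boundary before index ``origin + r`` corresponds to
``r`` bp of resection on that flank.  Genomic coordinates are recovered via
:meth:`JunctionLine.genome_pos`.

Orientation rules (derived from which flank is retained):

* a bait reads from its primer toward the DSB; ``bait_strand`` in
  :class:`~baitjoint.locus.BaitSpec` gives the read direction on the genome;
* a prey enters the read at its junction-proximal base and proceeds *away*
  from its cut site into the retained flank, so the read direction is '-'
  when the retained flank lies left of the cut and '+' when it lies right.
"""

from __future__ import annotations

from dataclasses import dataclass

from .locus import BaitSpec, SegmentAnnotation

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class JunctionLine:
    """A read-oriented reference string through a cut/junction point.

    ``seq[origin]`` is the first base past the cut in read orientation;
    ``strand`` says whether ``seq`` matches the reference forward ('+') or
    reverse-complemented ('-').  ``gstart`` is the genome coordinate of
    ``seq[0]``.
    """

    chrom: str
    seq: str
    origin: int
    strand: str
    gstart: int

    def genome_pos(self, index: int) -> int:
        """Genome coordinate (0-based) of the base at ``index``."""
        return self.gstart + index if self.strand == "+" else self.gstart - index

    def span(self, lo: int, hi: int) -> tuple[int, int]:
        """0-based half-open genome interval covered by seq[lo:hi]."""
        if self.strand == "+":
            return self.gstart + lo, self.gstart + hi
        return self.gstart - hi + 1, self.gstart - lo + 1

    def index_of_genome(self, pos: int) -> int:
        return pos - self.gstart if self.strand == "+" else self.gstart - pos


def junction_line(
    reference: dict[str, str],
    chrom: str,
    cut: int,
    read_strand: str,
    back: int,
    forward: int,
) -> JunctionLine:
    """Build the junction line through ``cut`` in read orientation.

    ``back`` bases precede the cut in read orientation (indices
    ``0..back-1``), ``forward`` bases follow it; the cut boundary sits at
    index ``origin == back``.  Extents are clipped to the chromosome.
    """
    refseq = reference[chrom]
    if read_strand == "+":
        lo = max(0, cut - back)
        hi = min(len(refseq), cut + forward)
        seq = refseq[lo:hi]
        return JunctionLine(chrom, seq, cut - lo, "+", lo)
    lo = max(0, cut - forward)
    hi = min(len(refseq), cut + back)
    seq = revcomp(refseq[lo:hi])
    return JunctionLine(chrom, seq, hi - cut, "-", hi - 1)


def bait_line(
    reference: dict[str, str], bait: BaitSpec, forward: int = 150
) -> JunctionLine:
    """Junction line for a bait: index 0 is the first primer base."""
    if bait.bait_strand == "+":
        back = bait.dsb_coordinate - bait.primer_start
    else:
        back = bait.primer_end - bait.dsb_coordinate
    return junction_line(
        reference, bait.chrom, bait.dsb_coordinate, bait.bait_strand, back, forward
    )


def prey_read_strand(segment: SegmentAnnotation, end_type: str) -> str:
    """Read-orientation of a prey contributing its CE or SE flank.

    The retained flank is the coding flank for CE and the RSS flank for SE;
    the read proceeds away from the cut along that flank.
    """
    side = segment.coding_side if end_type == "CE" else segment.rss_side
    return "+" if side == "right" else "-"


def prey_line(
    reference: dict[str, str],
    segment: SegmentAnnotation,
    end_type: str,
    back: int = 40,
    forward: int = 500,
) -> JunctionLine:
    """Junction line for a prey segment end (CE or SE)."""
    strand = prey_read_strand(segment, end_type)
    return junction_line(
        reference, segment.chrom, segment.cut_site, strand, back, forward
    )
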