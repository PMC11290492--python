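"""Junction classification: category, end type, structure, and offsets.

Everything here is computed from called tlx coordinates alone (plus the
locus annotation); no sequence re-alignment happens.  The independent
sequence-level recomputation lives in :mod:`baitjoint.oracle`.

Classification axes
-------------------
* ``category``: ``rejoin`` (junction inside the bait region), ``V_J``
  (junction within the ±window of a V cut site), ``intra_locus_other``
  (elsewhere on the locus chromosome interval), or ``translocation``
  (any other chromosome), with translocations subdivided into
  ``receptor_locus`` and ``spontaneous``.
* ``end_type`` for V_J junctions: CE when the prey alignment carries the
  coding flank of the V cut, SE when it carries the RSS flank, by
  majority of aligned prey bases on each side of the cut (ties resolved
  toward the junction-containing side and flagged ambiguous).
* ``structure``: microhomology (query overlap > 0), direct (0), or
  insertion (< 0), with palindromic flagging delegated to the oracle.
* ``resection_offset``: strand-normalized distance of the junction
  boundary from the prey cut site (negative into the coding body).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .locus import LocusSpec, SegmentAnnotation, cut_site_offset, stad_of
from .tlx import TlxRecord

#: Structure lengths beyond this are reported in a single out-of-range
#: bucket by the distribution metrics (the per-extreme bin limit).
STRUCTURE_RANGE = 20


@dataclass(frozen=True)
class JointStructure:
    kind: str  # {"MH", "direct", "insertion"}
    length: int

    @property
    def label(self) -> str:
        if self.kind == "direct":
            return "direct"
        prefix = "MH" if self.kind == "MH" else "INS"
        return f"{prefix}{self.length}"

    @property
    def in_range(self) -> bool:
        return self.length <= STRUCTURE_RANGE

    @property
    def is_mmej(self) -> bool:
        """Microhomology-mediated per the >1 bp MH convention."""
        return self.kind == "MH" and self.length > 1


def joint_structure(record: TlxRecord) -> JointStructure:
    """Structure from the query overlap ``b_qend - qstart + 1``."""
    o = record.query_overlap()
    if o > 0:
        return JointStructure("MH", o)
    if o == 0:
        return JointStructure("direct", 0)
    return JointStructure("insertion", -o)


@dataclass
class ClassifiedJunction:
    record: TlxRecord
    category: str  # {"V_J", "rejoin", "intra_locus_other", "translocation"}
    translocation_class: str = "n/a"  # {"receptor_locus", "spontaneous", "n/a"}
    segment: Optional[SegmentAnnotation] = None
    end_type: str = "n/a"  # {"CE", "SE", "n/a"}
    end_type_ambiguous: bool = False
    configuration: str = "n/a"  # {"DEL", "INV", "n/a"}
    orientation_discordant: bool = False
    structure: Optional[JointStructure] = None
    resection_offset: Optional[int] = None
    stad: Optional[str] = None


def categorize(record: TlxRecord, spec: LocusSpec, bait_name: str) -> tuple[str, str, Optional[SegmentAnnotation]]:
    """(category, translocation_class, matched V segment)."""
    bait = spec.bait(bait_name)
    pos = record.junction_base
    if record.rname == bait.chrom and bait.region_start <= pos < bait.region_end:
        return "rejoin", "n/a", None
    for seg in spec.v_segments():
        if spec.v_window(seg).contains(record.rname, pos):
            return "V_J", "n/a", seg
    if spec.locus_interval.contains(record.rname, pos):
        return "intra_locus_other", "n/a", None
    for region in spec.receptor_loci:
        if region.contains(record.rname, pos):
            return "translocation", "receptor_locus", None
    return "translocation", "spontaneous", None


def assign_end_type(record: TlxRecord, segment: SegmentAnnotation) -> tuple[str, bool]:
    """(CE|SE, ambiguous) from the side of the cut the prey alignment covers.

    Counts aligned prey bases on each side of the scission point; the
    majority side names the retained flank.  An exact tie is resolved
    toward the side containing the junction base and flagged ambiguous.
    """
    lo, hi = record.rstart - 1, record.rend  # 0-based half-open
    cut = segment.cut_site
    left = max(0, min(hi, cut) - lo)
    right = max(0, hi - max(lo, cut))
    if left > right:
        side = "left"
        ambiguous = False
    elif right > left:
        side = "right"
        ambiguous = False
    else:
        side = "left" if record.junction_base < cut else "right"
        ambiguous = True
    end_type = "CE" if side == segment.coding_side else "SE"
    return end_type, ambiguous


def configuration_of(
    record: TlxRecord, segment: SegmentAnnotation, end_type: str
) -> tuple[str, bool]:
    """(DEL|INV, discordant) for a V_J junction.

    The configuration is the segment's annotated orientation class; the
    boolean flags a prey strand inconsistent with the geometry expected
    for that configuration and end type (the read proceeds away from the
    cut along the retained flank, so the expected prey strand is '+' when
    that flank lies right of the cut).
    """
    retained = segment.coding_side if end_type == "CE" else segment.rss_side
    expected = "+" if retained == "right" else "-"
    return segment.configuration or "n/a", record.strand != expected


def resection_offset(record: TlxRecord, segment: SegmentAnnotation) -> int:
    """Strand-normalized junction offset from the prey scission point."""
    return cut_site_offset(record.junction_boundary, segment)


def classify_junction(
    record: TlxRecord, spec: LocusSpec, bait_name: str
) -> ClassifiedJunction:
    category, tclass, segment = categorize(record, spec, bait_name)
    out = ClassifiedJunction(
        record=record,
        category=category,
        translocation_class=tclass,
        segment=segment,
        structure=joint_structure(record),
    )
    if category == "V_J" and segment is not None:
        out.end_type, out.end_type_ambiguous = assign_end_type(record, segment)
        out.configuration, out.orientation_discordant = configuration_of(
            record, segment, out.end_type
        )
        out.resection_offset = resection_offset(record, segment)
        out.stad = stad_of(record.rname, segment.cut_site, spec)
    return out


def classify_all(
    records: Iterable[TlxRecord], spec: LocusSpec, bait_name: str
) -> list[ClassifiedJunction]:
    return [classify_junction(r, spec, bait_name) for r in records]


def classification_frame(classified: Iterable[ClassifiedJunction]) -> pd.DataFrame:
    """Flat per-junction table for metrics and export."""
    rows = []
    for c in classified:
        r = c.record
        rows.append(
            {
                "qname": r.qname,
                "rname": r.rname,
                "junction": r.junction,
                "strand": r.strand,
                "b_junction": r.b_junction,
                "category": c.category,
                "translocation_class": c.translocation_class,
                "segment": c.segment.name if c.segment else "n/a",
                "end_type": c.end_type,
                "end_type_ambiguous": c.end_type_ambiguous,
                "configuration": c.configuration,
                "orientation_discordant": c.orientation_discordant,
                "structure_kind": c.structure.kind if c.structure else "n/a",
                "structure_length": c.structure.length if c.structure else 0,
                "structure": c.structure.label if c.structure else "n/a",
                "resection_offset": c.resection_offset,
                "stad": c.stad if c.stad else "n/a",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "qname",
            "rname",
            "junction",
            "strand",
            "b_junction",
            "category",
            "translocation_class",
            "segment",
            "end_type",
            "end_type_ambiguous",
            "configuration",
            "orientation_discordant",
            "structure_kind",
            "structure_length",
            "structure",
            "resection_offset",
            "stad",
        ],
    )
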