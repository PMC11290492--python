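"""Genomic coordinate model for a bait-anchored antigen-receptor locus.

All coordinates are 0-based, half-open internally.  The tlx dialect
(1-based inclusive) is produced only at emission time, in :mod:`baitjoint.tlx`.

The model covers:

* V and J gene segments with their RAG1/2 scission points (``cut_site``),
  strand, and deletional (DEL) vs inversional (INV) orientation relative
  to the J bait;
* bait double-strand-break (DSB) geometry: a coding-end (CE) or signal-end
  (SE) bait is the primer-anchored side of the J DSB;
* the sub-TAD (sTAD) partition of the V region used to bin V usage;
* off-target antigen-receptor partner regions on other chromosomes.

Sign convention for resection offsets: offsets are strand-normalized so
that 0 is the scission point, negative values lie within the coding
segment body (sequence loss by resection into the segment), and positive
values lie on the RSS/flank side.  This lets CE and SE junctions from
either strand overlay on one pooled axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional


class LocusValidationError(ValueError):
    """A locus specification violated a structural invariant."""


@dataclass(frozen=True)
class Interval:
    """A labeled 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise LocusValidationError(
                f"interval {self.label!r} has start >= end ({self.start} >= {self.end})"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentAnnotation:
    """One V or J gene segment.

    ``cut_site`` is the RAG1/2 scission point between the coding flank and
    the RSS heptamer, as a 0-based boundary coordinate.  ``rss_side`` says
    which side of ``cut_site`` the RSS occupies on the reference; it must be
    3' of the coding segment in segment orientation, i.e. ``right`` for
    plus-strand and ``left`` for minus-strand segments.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    role: str  # {"V", "J"}
    cut_site: int
    configuration: Optional[str] = None  # {"DEL", "INV"}; V segments only

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise LocusValidationError(f"segment {self.name}: start >= end")
        if self.strand not in ("+", "-"):
            raise LocusValidationError(f"segment {self.name}: bad strand {self.strand!r}")
        if self.role not in ("V", "J"):
            raise LocusValidationError(f"segment {self.name}: bad role {self.role!r}")
        if not (self.start <= self.cut_site <= self.end):
            raise LocusValidationError(
                f"segment {self.name}: cut_site {self.cut_site} outside [{self.start}, {self.end}]"
            )
        if self.role == "V" and self.configuration not in ("DEL", "INV"):
            raise LocusValidationError(
                f"V segment {self.name}: configuration must be DEL or INV, "
                f"got {self.configuration!r}"
            )
        if self.role == "J" and self.configuration is not None:
            raise LocusValidationError(
                f"J segment {self.name}: configuration defined only for V segments"
            )

    @property
    def rss_side(self) -> str:
        """Reference side of the cut occupied by the RSS ('left' or 'right')."""
        return "right" if self.strand == "+" else "left"

    @property
    def coding_side(self) -> str:
        """Reference side of the cut occupied by the coding flank."""
        return "left" if self.strand == "+" else "right"


@dataclass(frozen=True)
class BaitSpec:
    """The fixed, primer-anchored side of the bait DSB.

    ``side`` is CE when the retained (primer-bearing) flank is the coding
    flank of the bait segment, SE when it is the signal flank.
    ``bait_strand`` gives the direction a read proceeds from the primer
    toward the DSB: '+' for increasing reference coordinate, '-' for
    decreasing.  ``primer_start``/``primer_end`` delimit the priming
    interval on the retained flank; ``region_start``/``region_end`` delimit
    the bait region used to label rejoins.
    """

    name: str
    side: str  # {"CE", "SE"}
    chrom: str
    dsb_coordinate: int
    bait_strand: str
    primer_start: int
    primer_end: int
    region_start: int
    region_end: int

    def __post_init__(self) -> None:
        if self.side not in ("CE", "SE"):
            raise LocusValidationError(f"bait {self.name}: side must be CE or SE")
        if self.bait_strand not in ("+", "-"):
            raise LocusValidationError(f"bait {self.name}: bad strand")
        if self.primer_start >= self.primer_end:
            raise LocusValidationError(f"bait {self.name}: empty primer interval")
        # The primer must sit entirely on the retained flank of the DSB.
        if self.bait_strand == "+" and self.primer_end > self.dsb_coordinate:
            raise LocusValidationError(
                f"bait {self.name}: primer interval crosses the DSB coordinate"
            )
        if self.bait_strand == "-" and self.primer_start < self.dsb_coordinate:
            raise LocusValidationError(
                f"bait {self.name}: primer interval crosses the DSB coordinate"
            )
        if not (self.region_start <= self.dsb_coordinate <= self.region_end):
            raise LocusValidationError(
                f"bait {self.name}: bait region does not contain the DSB"
            )

    @property
    def primer_length(self) -> int:
        return self.primer_end - self.primer_start


@dataclass
class LocusSpec:
    """A validated toy antigen-receptor locus.

    Invariants (checked in :meth:`validate`):

    * sTAD intervals are non-overlapping, on the locus chromosome, and every
      V segment cut site lies in exactly one of them;
    * every bait sits on the locus chromosome;
    * V-segment ±200 bp windows do not overlap each other or a bait region.
    """

    segments: list[SegmentAnnotation]
    baits: list[BaitSpec]
    stads: list[Interval]
    locus_interval: Interval
    receptor_loci: list[Interval] = field(default_factory=list)
    vj_window: int = 200  # half-width of the V-segment extraction window (bp)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        chrom = self.locus_interval.chrom
        for seg in self.segments:
            if seg.chrom != chrom:
                raise LocusValidationError(
                    f"segment {seg.name} on {seg.chrom}, locus on {chrom}"
                )
            if not (self.locus_interval.start <= seg.start and seg.end <= self.locus_interval.end):
                raise LocusValidationError(
                    f"segment {seg.name} outside the locus interval"
                )
        for bait in self.baits:
            if bait.chrom != chrom:
                raise LocusValidationError(
                    f"bait {bait.name} on chromosome {bait.chrom}, "
                    f"but the locus is on {chrom}"
                )
        stads = sorted(self.stads, key=lambda t: t.start)
        for a, b in zip(stads, stads[1:]):
            if b.start < a.end:
                raise LocusValidationError(
                    f"sTADs {a.label!r} and {b.label!r} overlap"
                )
        for seg in self.v_segments():
            hits = [t.label for t in self.stads if t.contains(seg.chrom, seg.cut_site)]
            if len(hits) != 1:
                raise LocusValidationError(
                    f"V segment {seg.name} lies in {len(hits)} sTADs (expected 1)"
                )
            for t in self.stads:
                inside = (t.start <= seg.start < t.end, t.start < seg.end <= t.end)
                if inside[0] != inside[1]:
                    raise LocusValidationError(
                        f"V segment {seg.name} straddles sTAD {t.label!r}"
                    )

    # -- accessors ----------------------------------------------------------

    def v_segments(self) -> list[SegmentAnnotation]:
        return [s for s in self.segments if s.role == "V"]

    def j_segments(self) -> list[SegmentAnnotation]:
        return [s for s in self.segments if s.role == "J"]

    def bait(self, name: str) -> BaitSpec:
        for b in self.baits:
            if b.name == name:
                return b
        raise KeyError(name)

    def segment(self, name: str) -> SegmentAnnotation:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def segments_in_stad(self, label: str) -> list[SegmentAnnotation]:
        stad = next(t for t in self.stads if t.label == label)
        return [s for s in self.v_segments() if stad.contains(s.chrom, s.cut_site)]

    def v_window(self, segment: SegmentAnnotation) -> Interval:
        """The ±vj_window extraction window around a V cut site."""
        return Interval(
            segment.chrom,
            segment.cut_site - self.vj_window,
            segment.cut_site + self.vj_window,
            label=segment.name,
        )


# ---------------------------------------------------------------------------
# coordinate helpers


def cut_site_offset(boundary: int, segment: SegmentAnnotation) -> int:
    """Strand-normalized offset of a junction boundary from the scission point.

    ``boundary`` is a 0-based boundary coordinate (the strand-aware edge of
    the prey alignment nearest the junction).  The returned offset is 0 at
    the scission point, negative within the coding segment body, positive on
    the RSS/flank side, for segments of either strand.
    """
    d = boundary - segment.cut_site
    return -d if segment.strand == "-" else d


def stad_of(chrom: str, position: int, spec: LocusSpec) -> Optional[str]:
    """Label of the unique sTAD containing ``position``; None if outside all."""
    for t in spec.stads:
        if t.contains(chrom, position):
            return t.label
    return None


# ---------------------------------------------------------------------------
# parsing: BED6 segments + flat key-value config


def _parse_bed6(bed_text: str) -> list[SegmentAnnotation]:
    segments = []
    for lineno, line in enumerate(bed_text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise LocusValidationError(
                f"BED line {lineno}: need 6 columns, got {len(fields)}"
            )
        chrom, start, end, name_field, _score, strand = fields[:6]
        parts = name_field.split("|")
        if len(parts) < 3:
            raise LocusValidationError(
                f"BED line {lineno}: name field must be 'name|role|configuration|cut_site', "
                f"got {name_field!r}"
            )
        name, role, conf = parts[0], parts[1], parts[2]
        if len(parts) < 4:
            raise LocusValidationError(
                f"BED line {lineno}: segment {name!r} is missing its cut_site"
            )
        try:
            cut = int(parts[3])
        except ValueError as exc:
            raise LocusValidationError(
                f"BED line {lineno}: non-integer cut_site {parts[3]!r}"
            ) from exc
        segments.append(
            SegmentAnnotation(
                name=name,
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                role=role,
                cut_site=cut,
                configuration=None if conf in ("", ".", "NA") else conf,
            )
        )
    return segments


def _parse_kv(config_text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(config_text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise LocusValidationError(f"config line {lineno}: expected key = value")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def load_locus_spec(config_text: str, bed_text: str) -> LocusSpec:
    """Build a validated :class:`LocusSpec` from BED6 segments and a config.

    The BED name column encodes ``name|role|configuration|cut_site``.  The
    flat key-value config names the locus interval, sTAD boundaries, baits,
    and off-target receptor loci::

        locus = chrL:0-40000
        stad = sTAD5:20000-26000
        bait = Jk1CE:CE:-:30000:30120-30140:29000-31000
        receptor_locus = TcrToy:chrP:3000-7000
        vj_window = 200
    """
    kv_pairs = []
    for lineno, line in enumerate(config_text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise LocusValidationError(f"config line {lineno}: expected key = value")
        key, _, value = line.partition("=")
        kv_pairs.append((key.strip(), value.strip()))

    segments = _parse_bed6(bed_text)

    def chrom_range(text: str) -> tuple[str, int, int]:
        chrom, _, rng = text.partition(":")
        lo, _, hi = rng.partition("-")
        return chrom, int(lo), int(hi)

    locus_interval = None
    stads: list[Interval] = []
    baits: list[BaitSpec] = []
    receptor_loci: list[Interval] = []
    vj_window = 200
    for key, value in kv_pairs:
        if key == "locus":
            chrom, lo, hi = chrom_range(value)
            locus_interval = Interval(chrom, lo, hi, label="locus")
        elif key == "stad":
            label, _, rng = value.partition(":")
            lo, _, hi = rng.partition("-")
            chrom = locus_interval.chrom if locus_interval else segments[0].chrom
            stads.append(Interval(chrom, int(lo), int(hi), label=label))
        elif key == "bait":
            name, side, strand, dsb, primer, region = value.split(":")
            p_lo, _, p_hi = primer.partition("-")
            r_lo, _, r_hi = region.partition("-")
            chrom = locus_interval.chrom if locus_interval else segments[0].chrom
            baits.append(
                BaitSpec(
                    name=name,
                    side=side,
                    chrom=chrom,
                    dsb_coordinate=int(dsb),
                    bait_strand=strand,
                    primer_start=int(p_lo),
                    primer_end=int(p_hi),
                    region_start=int(r_lo),
                    region_end=int(r_hi),
                )
            )
        elif key == "receptor_locus":
            label, chrom_part = value.split(":", 1)
            chrom, lo, hi = chrom_range(chrom_part)
            receptor_loci.append(Interval(chrom, lo, hi, label=label))
        elif key == "vj_window":
            vj_window = int(value)
        else:
            raise LocusValidationError(f"unknown config key {key!r}")

    if locus_interval is None:
        raise LocusValidationError("config is missing the 'locus' interval")
    return LocusSpec(
        segments=segments,
        baits=baits,
        stads=stads,
        locus_interval=locus_interval,
        receptor_loci=receptor_loci,
        vj_window=vj_window,
    )


def dump_locus_spec(spec: LocusSpec) -> tuple[str, str]:
    """Inverse of :func:`load_locus_spec`: (config_text, bed_text)."""
    bed_lines = []
    for seg in spec.segments:
        conf = seg.configuration if seg.configuration else "."
        name = f"{seg.name}|{seg.role}|{conf}|{seg.cut_site}"
        bed_lines.append(
            "\t".join(
                [seg.chrom, str(seg.start), str(seg.end), name, "0", seg.strand]
            )
        )
    cfg_lines = [
        f"locus = {spec.locus_interval.chrom}:{spec.locus_interval.start}-{spec.locus_interval.end}",
        f"vj_window = {spec.vj_window}",
    ]
    for t in spec.stads:
        cfg_lines.append(f"stad = {t.label}:{t.start}-{t.end}")
    for b in spec.baits:
        cfg_lines.append(
            f"bait = {b.name}:{b.side}:{b.bait_strand}:{b.dsb_coordinate}:"
            f"{b.primer_start}-{b.primer_end}:{b.region_start}-{b.region_end}"
        )
    for r in spec.receptor_loci:
        cfg_lines.append(f"receptor_locus = {r.label}:{r.chrom}:{r.start}-{r.end}")
    return "\n".join(cfg_lines) + "\n", "\n".join(bed_lines) + "\n"
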