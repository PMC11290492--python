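"""The tlx junction-record dialect: read, write, project, and filter.

One tlx row describes one called junction: the bait alignment (``b_*``
fields, anchored at the primer) and the prey alignment, with 1-based
inclusive reference and query coordinates.  ``junction`` is the
strand-aware first prey-aligned base (``rstart`` on '+', ``rend`` on '-');
``b_junction`` is the junction-proximal end of the bait alignment
(``b_rend`` on '+', ``b_rstart`` on '-').

Unknown extra columns are carried through as opaque payload so that files
annotated by downstream tools round-trip unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional

from .locus import Interval

#: Mandatory columns, in canonical emission order.
TLX_COLUMNS = [
    "Qname",
    "JuncID",
    "Rname",
    "Junction",
    "Strand",
    "Rstart",
    "Rend",
    "B_Rname",
    "B_Rstart",
    "B_Rend",
    "B_Strand",
    "B_Junction",
    "Qstart",
    "Qend",
    "B_Qstart",
    "B_Qend",
    "Qlen",
    "Seq",
]

_INT_COLUMNS = {
    "JuncID",
    "Junction",
    "Rstart",
    "Rend",
    "B_Rstart",
    "B_Rend",
    "B_Junction",
    "Qstart",
    "Qend",
    "B_Qstart",
    "B_Qend",
    "Qlen",
}


class TlxParseError(ValueError):
    """Malformed tlx input; message carries the 1-based line number."""


@dataclass
class TlxRecord:
    """One called junction (all coordinates 1-based inclusive)."""

    qname: str
    junc_id: int
    rname: str
    junction: int
    strand: str
    rstart: int
    rend: int
    b_rname: str
    b_rstart: int
    b_rend: int
    b_strand: str
    b_junction: int
    qstart: int
    qend: int
    b_qstart: int
    b_qend: int
    qlen: int
    seq: str = ""
    extras: dict[str, str] = field(default_factory=dict)

    def validate(self, line: Optional[int] = None) -> None:
        where = f" at line {line}" if line is not None else ""
        if self.strand not in ("+", "-") or self.b_strand not in ("+", "-"):
            raise TlxParseError(f"strand not in {{+,-}}{where}")
        if self.rstart > self.rend:
            raise TlxParseError(f"rstart > rend{where}")
        if self.b_rstart > self.b_rend:
            raise TlxParseError(f"b_rstart > b_rend{where}")
        if self.qstart > self.qend:
            raise TlxParseError(f"qstart > qend{where}")
        if not (self.b_qstart <= self.b_qend <= self.qlen):
            raise TlxParseError(f"bait query span outside read{where}")
        expected = self.rstart if self.strand == "+" else self.rend
        if self.junction != expected:
            raise TlxParseError(
                f"junction {self.junction} inconsistent with strand-aware "
                f"alignment end {expected}{where}"
            )
        if self.b_qstart >= self.qstart:
            raise TlxParseError(f"bait does not precede prey on the query{where}")

    # -- junction coordinate helpers ---------------------------------------

    @property
    def junction_boundary(self) -> int:
        """0-based boundary form of the strand-aware prey junction.

        For '+' preys this is the boundary before the first aligned base,
        for '-' preys the boundary after the last (junction-proximal) base,
        so that resection offsets read directly in half-open coordinates.
        """
        return self.junction - 1 if self.strand == "+" else self.junction

    @property
    def junction_base(self) -> int:
        """0-based index of the first prey-aligned base."""
        return self.junction - 1

    def query_overlap(self) -> int:
        """Shared bait/prey bases on the query (negative: inserted bases)."""
        return self.b_qend - self.qstart + 1


# ---------------------------------------------------------------------------
# parsing / emission


def _parse_row(
    fields: dict[str, str], lineno: int, extra_cols: list[str]
) -> TlxRecord:
    vals: dict[str, object] = {}
    for col in TLX_COLUMNS:
        raw = fields[col]
        if col in _INT_COLUMNS:
            try:
                vals[col] = int(raw)
            except ValueError as exc:
                raise TlxParseError(
                    f"non-integer {col} value {raw!r} at line {lineno}"
                ) from exc
        else:
            vals[col] = raw
    rec = TlxRecord(
        qname=vals["Qname"],
        junc_id=vals["JuncID"],
        rname=vals["Rname"],
        junction=vals["Junction"],
        strand=vals["Strand"],
        rstart=vals["Rstart"],
        rend=vals["Rend"],
        b_rname=vals["B_Rname"],
        b_rstart=vals["B_Rstart"],
        b_rend=vals["B_Rend"],
        b_strand=vals["B_Strand"],
        b_junction=vals["B_Junction"],
        qstart=vals["Qstart"],
        qend=vals["Qend"],
        b_qstart=vals["B_Qstart"],
        b_qend=vals["B_Qend"],
        qlen=vals["Qlen"],
        seq=vals["Seq"],
        extras={c: fields[c] for c in extra_cols},
    )
    rec.validate(line=lineno)
    return rec


def read_tlx(stream: IO[str] | Iterable[str]) -> list[TlxRecord]:
    """Parse a tlx stream into an ordered list of records.

    The first non-empty line must be a tab-separated header naming all
    mandatory columns; unknown columns are preserved as opaque extras.
    """
    lines = iter(stream)
    header: Optional[list[str]] = None
    lineno = 0
    records: list[TlxRecord] = []
    extra_cols: list[str] = []
    for line in lines:
        lineno += 1
        line = line.rstrip("\n")
        if not line.strip():
            continue
        cols = line.split("\t")
        if header is None:
            header = cols
            missing = [c for c in TLX_COLUMNS if c not in header]
            if missing:
                raise TlxParseError(
                    f"header missing mandatory column(s) {missing} at line {lineno}"
                )
            extra_cols = [c for c in header if c not in TLX_COLUMNS]
            continue
        if len(cols) != len(header):
            raise TlxParseError(
                f"expected {len(header)} fields, got {len(cols)} at line {lineno}"
            )
        records.append(_parse_row(dict(zip(header, cols)), lineno, extra_cols))
    if header is None:
        raise TlxParseError("empty input: no header line")
    return records


def write_tlx(records: Iterable[TlxRecord], stream: IO[str]) -> None:
    """Emit records in the canonical dialect; extras follow in stable order."""
    records = list(records)
    extra_cols: list[str] = []
    for rec in records:
        for col in rec.extras:
            if col not in extra_cols:
                extra_cols.append(col)
    header = TLX_COLUMNS + extra_cols
    stream.write("\t".join(header) + "\n")
    for rec in records:
        row = [
            rec.qname,
            str(rec.junc_id),
            rec.rname,
            str(rec.junction),
            rec.strand,
            str(rec.rstart),
            str(rec.rend),
            rec.b_rname,
            str(rec.b_rstart),
            str(rec.b_rend),
            rec.b_strand,
            str(rec.b_junction),
            str(rec.qstart),
            str(rec.qend),
            str(rec.b_qstart),
            str(rec.b_qend),
            str(rec.qlen),
            rec.seq,
        ]
        row += [rec.extras.get(c, "") for c in extra_cols]
        stream.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# projections


def tlx_to_bedgraph(records: Iterable[TlxRecord]) -> list[tuple[str, int, int, int]]:
    """Per-base junction coverage as sorted bedgraph intervals.

    Each junction contributes 1 to the single base at its strand-aware
    junction coordinate; the summed signal equals the record count.
    """
    counts: dict[tuple[str, int], int] = {}
    for rec in records:
        key = (rec.rname, rec.junction_base)
        counts[key] = counts.get(key, 0) + 1
    out = []
    for (chrom, pos), n in sorted(counts.items()):
        out.append((chrom, pos, pos + 1, n))
    return out


def write_bedgraph(
    track: Iterable[tuple[str, int, int, int]], stream: IO[str]
) -> None:
    for chrom, start, end, value in track:
        stream.write(f"{chrom}\t{start}\t{end}\t{value}\n")


def intersect_regions(
    records: Iterable[TlxRecord], regions: Iterable[Interval]
) -> list[TlxRecord]:
    """Records whose junction base falls in any region (each at most once).

    Intersection is on the junction point only, not the alignment span.
    """
    regions = list(regions)
    out = []
    for rec in records:
        pos = rec.junction_base
        if any(r.contains(rec.rname, pos) for r in regions):
            out.append(rec)
    return out
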