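"""Toy reference genome construction for junction-library simulation.

The toy locus places eight V segments (mixed DEL/INV orientation) across
four sTADs upstream of a single J segment whose RAG1/2 cut site carries the
CE and SE baits, plus one off-target receptor-locus chromosome and one
plain decoy chromosome for spontaneous translocation partners.

Flank guard
-----------
Junction structure (microhomology vs direct vs insertion) is an emergent
sequence property, so chance bait/prey identity near cut sites must be
excluded for it to be controllable.  With ``flank_guard`` on, the 25 bp on
each side of every cut site is drawn from complement-closed disjoint
alphabets: {A, T} on bait-side flanks and {C, G} on prey-side flanks.
Because each alphabet equals its own complement set and the two are
disjoint, a bait base can never equal a prey base in *any* join
orientation, so every junction whose ends both lie within the guard zone
has exactly the intended structure.  The guarantee is re-verified by
exhaustive scan after construction.
"""

from __future__ import annotations

import numpy as np

from .locus import BaitSpec, Interval, LocusSpec, SegmentAnnotation

GUARD_HALF_WIDTH = 25

_BASES = np.array(list("ACGT"))
_BAIT_GUARD = np.array(list("AT"))
_PREY_GUARD = np.array(list("CG"))


class GuardConstructionError(RuntimeError):
    """The flank guard could not be realized for the requested locus."""


def toy_locus_spec() -> LocusSpec:
    """The default toy antigen-receptor locus.

    Eight V segments on chrL with cut sites every ~3 kb, four sTADs
    (sTAD1-2 distal .. sTAD5 J-proximal), a minus-strand J segment at
    30 kb carrying a coding-end and a signal-end bait, one off-target
    receptor region on chrP (RAG cut site at 5 kb), and a decoy
    chromosome chrD for spontaneous partners.
    """
    v_defs = [
        ("V1", 3000, "DEL"),
        ("V2", 6000, "DEL"),
        ("V3", 10000, "INV"),
        ("V4", 13000, "DEL"),
        ("V5", 16000, "INV"),
        ("V6", 19000, "DEL"),
        ("V7", 22000, "DEL"),
        ("V8", 25000, "INV"),
    ]
    segments = []
    for name, cut, conf in v_defs:
        strand = "+" if conf == "DEL" else "-"
        if strand == "+":
            start, end = cut - 300, cut + 60
        else:
            start, end = cut - 60, cut + 300
        segments.append(
            SegmentAnnotation(
                name=name,
                chrom="chrL",
                start=start,
                end=end,
                strand=strand,
                role="V",
                cut_site=cut,
                configuration=conf,
            )
        )
    segments.append(
        SegmentAnnotation(
            name="J1",
            chrom="chrL",
            start=29940,
            end=30300,
            strand="-",
            role="J",
            cut_site=30000,
        )
    )
    baits = [
        BaitSpec(
            name="J1CE",
            side="CE",
            chrom="chrL",
            dsb_coordinate=30000,
            bait_strand="-",
            primer_start=30120,
            primer_end=30140,
            region_start=29500,
            region_end=30500,
        ),
        BaitSpec(
            name="J1SE",
            side="SE",
            chrom="chrL",
            dsb_coordinate=30000,
            bait_strand="+",
            primer_start=29860,
            primer_end=29880,
            region_start=29500,
            region_end=30500,
        ),
    ]
    stads = [
        Interval("chrL", 2000, 8000, "sTAD1-2"),
        Interval("chrL", 8000, 14000, "sTAD3"),
        Interval("chrL", 14000, 20000, "sTAD4"),
        Interval("chrL", 20000, 26000, "sTAD5"),
    ]
    return LocusSpec(
        segments=segments,
        baits=baits,
        stads=stads,
        locus_interval=Interval("chrL", 0, 40000, "locus"),
        receptor_loci=[Interval("chrP", 3000, 7000, "RecA")],
    )


#: Cut sites of off-target receptor loci in the toy genome, keyed by label.
RECEPTOR_CUT_SITES = {"RecA": ("chrP", 5000)}

_CHROM_SIZES = {"chrL": 40000, "chrP": 12000, "chrD": 12000}


def _guard_zones(spec: LocusSpec) -> list[tuple[str, int, str]]:
    """(chrom, cut, kind) for every cut site; kind in {bait, prey}."""
    zones = []
    for seg in spec.v_segments():
        zones.append((seg.chrom, seg.cut_site, "prey"))
    for seg in spec.j_segments():
        zones.append((seg.chrom, seg.cut_site, "bait"))
    for label, (chrom, cut) in RECEPTOR_CUT_SITES.items():
        if any(r.label == label for r in spec.receptor_loci):
            zones.append((chrom, cut, "prey"))
    return zones


def build_toy_genome(
    spec_template: LocusSpec | None = None,
    seed: int = 0,
    flank_guard: bool = True,
) -> tuple[dict[str, str], LocusSpec]:
    """Build the toy reference embedding all segments of the locus.

    Returns a ``{chrom: sequence}`` dict and the (validated) locus spec.
    Deterministic in ``seed``.  With ``flank_guard`` the disjoint-alphabet
    guard is imposed and verified; construction failure raises
    :class:`GuardConstructionError`.
    """
    spec = spec_template if spec_template is not None else toy_locus_spec()
    rng = np.random.Generator(np.random.PCG64(seed))
    arrays: dict[str, np.ndarray] = {}
    for chrom, size in _CHROM_SIZES.items():
        arrays[chrom] = rng.choice(_BASES, size=size)
    if flank_guard:
        zones = _guard_zones(spec)
        for chrom, cut, kind in zones:
            if chrom not in arrays:
                raise GuardConstructionError(f"cut site on unknown chromosome {chrom}")
            alphabet = _BAIT_GUARD if kind == "bait" else _PREY_GUARD
            lo = cut - GUARD_HALF_WIDTH
            hi = cut + GUARD_HALF_WIDTH
            if lo < 0 or hi > len(arrays[chrom]):
                raise GuardConstructionError(
                    f"guard zone around {chrom}:{cut} leaves the chromosome"
                )
            arrays[chrom][lo:hi] = rng.choice(alphabet, size=hi - lo)
        reference = {c: "".join(a) for c, a in arrays.items()}
        worst = verify_flank_guard(reference, spec)
        if worst != 0:
            raise GuardConstructionError(
                f"flank guard verification found a chance identity of length {worst}"
            )
    else:
        reference = {c: "".join(a) for c, a in arrays.items()}
    return reference, spec


def verify_flank_guard(reference: dict[str, str], spec: LocusSpec) -> int:
    """Exhaustively scan all bait/prey cut-site pairs for chance identity.

    For every bait cut and prey cut, compares the 25 bp guard windows base
    by base in both relative orientations (forward and reverse complement)
    at every alignment register, and returns the maximal exact overlap
    found (0 when the guard holds).
    """
    comp = str.maketrans("ACGT", "TGCA")
    bait_windows = []
    prey_windows = []
    for chrom, cut, kind in _guard_zones(spec):
        seq = reference[chrom]
        left = seq[cut - GUARD_HALF_WIDTH : cut]
        right = seq[cut : cut + GUARD_HALF_WIDTH]
        target = bait_windows if kind == "bait" else prey_windows
        target.extend([left, right])

    def max_match_run(a: str, b: str) -> int:
        best = 0
        for variant in (b, b.translate(comp)[::-1]):
            for shift in range(-len(variant) + 1, len(a)):
                run = 0
                for i in range(len(a)):
                    j = i - shift
                    if 0 <= j < len(variant) and a[i] == variant[j]:
                        run += 1
                        best = max(best, run)
                    else:
                        run = 0
        return best

    worst = 0
    for bw in bait_windows:
        for pw in prey_windows:
            worst = max(worst, max_match_run(bw, pw))
            if worst:
                return worst
    return worst


def write_fasta(reference: dict[str, str], stream, width: int = 60) -> None:
    for chrom in sorted(reference):
        stream.write(f">{chrom}\n")
        seq = reference[chrom]
        for i in range(0, len(seq), width):
            stream.write(seq[i : i + width] + "\n")


def read_fasta(stream) -> dict[str, str]:
    reference: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in stream:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                reference[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        reference[name] = "".join(chunks)
    return reference
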