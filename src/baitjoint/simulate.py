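"""Synthetic bait-anchored repair libraries with per-read ground truth.

The generator emulates RAG1/2-initiated DSB repair outcomes read by read:
V-J joints (deletional and inversional, coding and signal prey ends),
rejoins of the bait DSB, translocations (off-target receptor loci and
spontaneous partners), and unjoined (germline) molecules.

Junction structure is *emergent at the sequence level*: a microhomology of
length k exists in a read only where k bases genuinely match both the bait
and the prey reference at the junction register.  Junctions are therefore
placed on the reference where the requested structure exists: the prey-side
resection offset (the quantity all downstream resection metrics measure) is
preserved exactly whenever sequence allows, with the bait-side boundary
moved first, since no summary statistic depends on it.  The deterministic
placement map is exposed to :func:`expected_resection_enrichment`, which
integrates the configured resection mixture over it to give the exact
model-implied enrichment fraction that a perfect analysis should recover.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .genome import GUARD_HALF_WIDTH, RECEPTOR_CUT_SITES
from .geometry import JunctionLine, bait_line, junction_line, prey_line, revcomp
from .locus import BaitSpec, LocusSpec, SegmentAnnotation
from .tlx import TlxRecord

#: Mismatch-run length that is guaranteed to stop caller extension
#: (max_mismatch + 1 for the default caller tolerance of 2).
PLACEMENT_HORIZON = 3

_BASES = "ACGT"


class SimulationConfigError(ValueError):
    """An inconsistent or infeasible simulation configuration."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ResectionModel:
    """Per-end resection length: point mass at 0 plus a truncated geometric.

    ``w0`` is the probability of an unresected end; with probability
    ``1 - w0`` the lost length is geometric with mean ``mean_bp``,
    truncated (renormalized) at ``l_max``.
    """

    w0: float = 0.6
    mean_bp: float = 20.0
    l_max: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.w0 <= 1.0):
            raise SimulationConfigError("resection w0 must lie in [0, 1]")
        if self.l_max > 200:
            raise SimulationConfigError("resection l_max must be <= 200")
        if self.mean_bp <= 0:
            raise SimulationConfigError("resection mean must be positive")

    def pmf(self) -> np.ndarray:
        """P(resection = r) for r = 0..l_max."""
        out = np.zeros(self.l_max + 1)
        out[0] = self.w0
        if self.w0 < 1.0 and self.l_max >= 1:
            q = min(1.0, 1.0 / self.mean_bp)
            r = np.arange(1, self.l_max + 1)
            tail = (1 - q) ** (r - 1) * q
            tail /= tail.sum()
            out[1:] = (1.0 - self.w0) * tail
        return out


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the library generator.

    ``structure_weights`` maps ``direct`` / ``MH<k>`` / ``INS<m>`` to
    probabilities summing to 1; MH and insertion lengths run 1..20.
    ``v_usage`` gives per-sTAD weights (uniform across the V segments of a
    sTAD).  ``vj_rate``/``rejoin_rate``/``translocation_rate`` partition
    read pairs, the remainder being unjoined (germline) molecules.
    """

    n_read_pairs: int = 50_000
    seed: int = 1
    regime: str = "AEJ"
    bait_name: str = "J1CE"
    resection_model: ResectionModel = field(default_factory=ResectionModel)
    structure_weights: dict[str, float] = field(
        default_factory=lambda: {
            "direct": 0.55,
            "MH1": 0.25,
            "MH2": 0.12,
            "MH3": 0.06,
            "MH4": 0.02,
        }
    )
    palindromic_insertion_rate: float = 0.5
    hybrid_rate: float = 1.0 / 3.0
    vj_rate: float = 0.30
    rejoin_rate: float = 0.25
    translocation_rate: float = 0.02
    translocation_split: dict[str, float] = field(
        default_factory=lambda: {"receptor_locus": 0.3, "spontaneous": 0.7}
    )
    v_usage: dict[str, float] = field(
        default_factory=lambda: {
            "sTAD1-2": 0.18,
            "sTAD3": 0.19,
            "sTAD4": 0.25,
            "sTAD5": 0.38,
        }
    )
    error_rate: float = 0.0
    read_length: int = 300
    duplicate_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, probs in [
            ("structure_weights", self.structure_weights),
            ("translocation_split", self.translocation_split),
            ("v_usage", self.v_usage),
        ]:
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationConfigError(f"{name} sums to {total}, expected 1")
            if any(p < 0 for p in probs.values()):
                raise SimulationConfigError(f"{name} has a negative weight")
        rates = self.vj_rate + self.rejoin_rate + self.translocation_rate
        if rates > 1.0 + 1e-9:
            raise SimulationConfigError("event-class rates sum beyond 1")
        for key in self.structure_weights:
            kind, length = parse_structure_key(key)
            if kind != "direct" and not (1 <= length <= 20):
                raise SimulationConfigError(f"structure length out of range in {key!r}")

    @property
    def unjoined_rate(self) -> float:
        return 1.0 - self.vj_rate - self.rejoin_rate - self.translocation_rate


def parse_structure_key(key: str) -> tuple[str, int]:
    if key == "direct":
        return "direct", 0
    if key.startswith("MH"):
        return "MH", int(key[2:])
    if key.startswith("INS"):
        return "insertion", int(key[3:])
    raise SimulationConfigError(f"unknown structure key {key!r}")


def nhej_config(**overrides) -> SimulationConfig:
    """NHEJ-proficient regime: tight resection, direct joints, P-insertions."""
    base = dict(
        regime="NHEJ",
        resection_model=ResectionModel(w0=0.9, mean_bp=4.0, l_max=100),
        structure_weights={
            "direct": 0.68,
            "MH1": 0.12,
            "MH2": 0.04,
            "INS1": 0.08,
            "INS2": 0.05,
            "INS3": 0.03,
        },
        palindromic_insertion_rate=0.6,
        hybrid_rate=0.0012,
        vj_rate=0.45,
        rejoin_rate=0.15,
        translocation_rate=0.005,
        v_usage={"sTAD1-2": 0.11, "sTAD3": 0.18, "sTAD4": 0.26, "sTAD5": 0.45},
    )
    base.update(overrides)
    return SimulationConfig(**base)


def aej_config(**overrides) -> SimulationConfig:
    """Ku70-deficient-like alternative end joining regime (the default)."""
    return SimulationConfig(**overrides)


def mmej_dominant_config(**overrides) -> SimulationConfig:
    """Near-exclusive MMEJ regime: few direct joints, long MH decay."""
    base = dict(
        regime="MMEJ_dominant",
        resection_model=ResectionModel(w0=0.3, mean_bp=30.0, l_max=100),
        structure_weights={
            "direct": 0.18,
            "MH1": 0.22,
            "MH2": 0.25,
            "MH3": 0.18,
            "MH4": 0.10,
            "MH5": 0.05,
            "MH6": 0.02,
        },
        hybrid_rate=0.45,
        vj_rate=0.12,
        rejoin_rate=0.30,
        translocation_rate=0.03,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruthRecord:
    """The simulator's record of one repair event (one read)."""

    read_name: str
    event_class: str  # {"V_J", "rejoin", "translocation", "unjoined"}
    prey_segment: str = ""  # V name, bait name, receptor label, or chrom:pos:strand
    prey_end_type: str = "n/a"  # {"CE", "SE", "n/a"}
    configuration: str = "n/a"  # {"DEL", "INV", "n/a"}
    bait_resection: int = 0  # strand-normalized signed bp (junction convention)
    prey_resection: int = 0
    structure_kind: str = "n/a"  # {"direct", "MH", "insertion", "n/a"}
    structure_length: int = 0
    palindromic: bool = False
    translocation_class: str = "n/a"
    tlx: Optional[TlxRecord] = None

    @property
    def structure_label(self) -> str:
        if self.structure_kind == "direct":
            return "direct"
        if self.structure_kind == "MH":
            return f"MH{self.structure_length}"
        if self.structure_kind == "insertion":
            return f"INS{self.structure_length}"
        return "n/a"


TRUTH_COLUMNS = [
    "read_name",
    "event_class",
    "prey_segment",
    "prey_end_type",
    "configuration",
    "bait_resection",
    "prey_resection",
    "structure",
    "palindromic",
    "translocation_class",
    "rname",
    "junction",
    "strand",
    "b_junction",
]


def write_truth_table(truths: Iterable[GroundTruthRecord], stream) -> None:
    stream.write("\t".join(TRUTH_COLUMNS) + "\n")
    for t in truths:
        row = [
            t.read_name,
            t.event_class,
            t.prey_segment,
            t.prey_end_type,
            t.configuration,
            str(t.bait_resection),
            str(t.prey_resection),
            t.structure_label,
            "1" if t.palindromic else "0",
            t.translocation_class,
            t.tlx.rname if t.tlx else "",
            str(t.tlx.junction) if t.tlx else "",
            t.tlx.strand if t.tlx else "",
            str(t.tlx.b_junction) if t.tlx else "",
        ]
        stream.write("\t".join(row) + "\n")


def read_truth_table(stream) -> list[GroundTruthRecord]:
    header = None
    out = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        if header is None:
            header = line.split("\t")
            continue
        row = dict(zip(header, line.split("\t")))
        kind, length = ("n/a", 0)
        if row["structure"] != "n/a":
            kind, length = parse_structure_key(row["structure"])
        out.append(
            GroundTruthRecord(
                read_name=row["read_name"],
                event_class=row["event_class"],
                prey_segment=row["prey_segment"],
                prey_end_type=row["prey_end_type"],
                configuration=row["configuration"],
                bait_resection=int(row["bait_resection"]),
                prey_resection=int(row["prey_resection"]),
                structure_kind=kind,
                structure_length=length,
                palindromic=row["palindromic"] == "1",
                translocation_class=row["translocation_class"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# junction placement


def _interleave(center: int, lo: int, hi: int):
    """center, center+1, center-1, center+2, ... restricted to [lo, hi)."""
    if lo <= center < hi:
        yield center
    step = 1
    while center + step < hi or center - step >= lo:
        if lo <= center + step < hi:
            yield center + step
        if lo <= center - step < hi:
            yield center - step
        step += 1


class JoinContext:
    """Placement engine for one (bait line, prey line) pair.

    Precomputes the read-space base-match matrix between the two lines and
    per-structure feasibility matrices over (bait resection beta, prey
    resection rho).  Placement is deterministic: the nearest feasible cell,
    ordered by |d rho| first (prey offsets are what resection metrics
    measure), then |d beta|, positive displacement before negative.
    """

    def __init__(
        self,
        bline: JunctionLine,
        pline: JunctionLine,
        beta_max: int,
        rho_max: int,
    ) -> None:
        self.bline = bline
        self.pline = pline
        self.beta_max = beta_max
        self.rho_max = rho_max
        a = np.frombuffer(bline.seq.encode(), dtype="S1")
        b = np.frombuffer(pline.seq.encode(), dtype="S1")
        pad = PLACEMENT_HORIZON + 22  # probe + max structure length headroom
        self._pad = pad
        m = a[:, None] == b[None, :]
        self.M = np.zeros((len(a) + 2 * pad, len(b) + 2 * pad), dtype=bool)
        self.M[pad : pad + len(a), pad : pad + len(b)] = m
        self._feas_cache: dict[tuple[str, int], np.ndarray] = {}
        self._mh_l_cache: dict[int, np.ndarray] = {}

    # -- index helpers ------------------------------------------------------

    def _xs(self) -> np.ndarray:
        return self.bline.origin - np.arange(self.beta_max + 1) + self._pad

    def _diag_ok(self, xs: np.ndarray, ss: np.ndarray, di: int, want: bool) -> np.ndarray:
        sub = self.M[np.ix_(xs + di, ss + di)]
        return sub if want else ~sub

    def _nomatch_run(self, xs: np.ndarray, ss: np.ndarray, start: int) -> np.ndarray:
        out = None
        for i in range(start, start + PLACEMENT_HORIZON):
            term = self._diag_ok(xs, ss, i, want=False)
            out = term if out is None else (out & term)
        return out

    def _match_run(self, xs: np.ndarray, ss: np.ndarray, start: int, length: int) -> np.ndarray:
        out = np.ones((len(xs), len(ss)), dtype=bool)
        for i in range(start, start + length):
            out &= self._diag_ok(xs, ss, i, want=True)
        return out

    # -- feasibility --------------------------------------------------------

    def _feas_mh_split(self, k: int, l: int) -> np.ndarray:
        """Feasibility of MH k with l bases prey-assigned, over (beta, rho)."""
        r = k - l
        xs = self._xs()
        ss = self.pline.origin + np.arange(self.rho_max + 1) + l + self._pad
        feas = self._match_run(xs, ss, -l, l) & self._match_run(xs, ss, 0, r)
        feas &= self._nomatch_run(xs, ss, -l - PLACEMENT_HORIZON)
        feas &= self._nomatch_run(xs, ss, r)
        return feas

    def feasibility(self, kind: str, length: int) -> np.ndarray:
        key = (kind, length)
        if key in self._feas_cache:
            return self._feas_cache[key]
        xs = self._xs()
        if kind == "direct":
            ss = self.pline.origin + np.arange(self.rho_max + 1) + self._pad
            feas = self._nomatch_run(xs, ss, -PLACEMENT_HORIZON) & self._nomatch_run(
                xs, ss, 0
            )
        elif kind == "MH":
            stack = [self._feas_mh_split(length, l) for l in range(length, -1, -1)]
            feas = np.any(stack, axis=0)
            chosen = np.full(feas.shape, -1, dtype=np.int8)
            for idx, l in enumerate(range(length, -1, -1)):
                chosen = np.where((chosen == -1) & stack[idx], l, chosen)
            self._mh_l_cache[length] = chosen
        elif kind == "insertion":
            m = length
            ss = self.pline.origin + np.arange(self.rho_max + 1) + self._pad
            feas = np.ones((len(xs), len(ss)), dtype=bool)
            # probing beyond the insertion must hit mismatches on both sides
            for i in range(m, PLACEMENT_HORIZON):
                feas &= ~self.M[np.ix_(xs + i, ss + i - m)]
            for j in range(m + 1, PLACEMENT_HORIZON + 1):
                feas &= ~self.M[np.ix_(xs - (j - m), ss - j)]
        else:
            raise SimulationConfigError(f"unknown structure kind {kind!r}")
        self._feas_cache[key] = feas
        return feas

    def mh_split(self, length: int, beta: int, rho: int) -> int:
        return int(self._mh_l_cache[length][beta, rho])

    def effective_structure(self, kind: str, length: int) -> tuple[str, int]:
        """Longest realizable structure at or below the requested one.

        A requested microhomology (or insertion) length may have no
        sequence-compatible register anywhere in this context; the
        deterministic fallback ladder degrades MH k -> MH k-1 -> ... ->
        direct (and insertion m -> m-1 -> ... -> direct), so the realized
        structure recorded in truth is always achievable.
        """
        while length > 0 and not self.feasibility(kind, length).any():
            length -= 1
        if length == 0:
            return "direct", 0
        return kind, length

    # -- placement ----------------------------------------------------------

    def place(self, kind: str, length: int, beta0: int, rho0: int):
        """Nearest feasible (beta, rho, l) for the requested structure."""
        feas = self.feasibility(kind, length)
        col_any = feas.any(axis=0)
        for rho in _interleave(rho0, 0, self.rho_max + 1):
            if not col_any[rho]:
                continue
            col = feas[:, rho]
            for beta in _interleave(beta0, 0, self.beta_max + 1):
                if col[beta]:
                    l = self.mh_split(length, beta, rho) if kind == "MH" else 0
                    return beta, rho, l
        return None

    def realized_rho(self, kind: str, length: int, rho0: int) -> Optional[int]:
        """The prey offset the placement map yields for a drawn rho0."""
        col_any = self.feasibility(kind, length).any(axis=0)
        for rho in _interleave(rho0, 0, self.rho_max + 1):
            if col_any[rho]:
                return rho
        return None


# ---------------------------------------------------------------------------
# the simulator


def _cdf(weights: dict[str, float]) -> tuple[list[str], np.ndarray]:
    keys = list(weights)
    return keys, np.cumsum([weights[k] for k in keys])


def _draw(keys, cdf, rng) -> str:
    return keys[min(int(np.searchsorted(cdf, rng.random(), side="right")), len(keys) - 1)]


class LibrarySimulator:
    """Stateful generator for one library (one bait, one configuration)."""

    def __init__(
        self, config: SimulationConfig, spec: LocusSpec, reference: dict[str, str]
    ) -> None:
        self.config = config
        self.spec = spec
        self.reference = reference
        self.bait = spec.bait(config.bait_name)
        l_max = config.resection_model.l_max
        self._beta_max = min(
            l_max, self._bait_back() - self.bait.primer_length - 5
        )
        self._rho_max = l_max
        fwd = config.read_length + 10
        self._bline = bait_line(reference, self.bait, forward=fwd)
        if config.read_length < self._bait_back() + 60:
            raise SimulationConfigError(
                "read_length too short to reach the junction from the primer"
            )
        self._contexts: dict[tuple, JoinContext] = {}
        self._res_pmf = config.resection_model.pmf()
        self._res_cdf = np.cumsum(self._res_pmf)
        self._struct_keys, self._struct_cdf = _cdf(config.structure_weights)
        self._split_keys, self._split_cdf = _cdf(config.translocation_split)
        self._stad_keys, self._stad_cdf = _cdf(config.v_usage)
        self._event_keys, self._event_cdf = _cdf(
            {
                "V_J": config.vj_rate,
                "rejoin": config.rejoin_rate,
                "translocation": config.translocation_rate,
                "unjoined": config.unjoined_rate,
            }
        )
        for label in config.v_usage:
            if not spec.segments_in_stad(label):
                raise SimulationConfigError(f"v_usage names empty sTAD {label!r}")

    def _bait_back(self) -> int:
        if self.bait.bait_strand == "+":
            return self.bait.dsb_coordinate - self.bait.primer_start
        return self.bait.primer_end - self.bait.dsb_coordinate

    # -- contexts -----------------------------------------------------------

    def _prey_forward(self) -> int:
        return self._rho_max + self.config.read_length + 60

    def context_for(self, key: tuple, line_builder) -> JoinContext:
        if key not in self._contexts:
            self._contexts[key] = JoinContext(
                self._bline, line_builder(), self._beta_max, self._rho_max
            )
        return self._contexts[key]

    def vj_context(self, segment: SegmentAnnotation, end_type: str) -> JoinContext:
        return self.context_for(
            ("V_J", segment.name, end_type),
            lambda: prey_line(
                self.reference, segment, end_type, back=40, forward=self._prey_forward()
            ),
        )

    def rejoin_context(self) -> JoinContext:
        return self.context_for(
            ("rejoin",),
            lambda: junction_line(
                self.reference,
                self.bait.chrom,
                self.bait.dsb_coordinate,
                self.bait.bait_strand,
                back=40,
                forward=self._prey_forward(),
            ),
        )

    def receptor_context(self, label: str, retained_side: str) -> JoinContext:
        chrom, cut = RECEPTOR_CUT_SITES[label]
        strand = "+" if retained_side == "right" else "-"
        return self.context_for(
            ("receptor", label, retained_side),
            lambda: junction_line(
                self.reference, chrom, cut, strand, back=40, forward=self._prey_forward()
            ),
        )

    # -- event simulation ---------------------------------------------------

    def _draw_resection(self, rng) -> int:
        return int(np.searchsorted(self._res_cdf, rng.random(), side="right"))

    def _draw_structure(self, rng) -> tuple[str, int]:
        return parse_structure_key(_draw(self._struct_keys, self._struct_cdf, rng))

    def _choose_segment(self, rng) -> SegmentAnnotation:
        label = _draw(self._stad_keys, self._stad_cdf, rng)
        segs = self.spec.segments_in_stad(label)
        return segs[int(rng.integers(len(segs)))]

    def _assemble(
        self,
        ctx: JoinContext,
        kind: str,
        length: int,
        beta: int,
        rho: int,
        l: int,
        rng,
        palindromic_wanted: bool = False,
    ) -> tuple[str, dict]:
        """Build the read and the measured-coordinate bookkeeping."""
        x = ctx.bline.origin - beta
        read_length = self.config.read_length
        bait_part = ctx.bline.seq[:x]
        pal = False
        if kind == "insertion":
            s = ctx.pline.origin + rho
            m = length
            content = None
            if palindromic_wanted and x >= m:
                cand = revcomp(bait_part[-m:])
                ok = all(
                    cand[i] != ctx.bline.seq[x + i]
                    for i in range(min(m, PLACEMENT_HORIZON))
                ) and all(
                    cand[m - j] != ctx.pline.seq[s - j]
                    for j in range(1, min(m, PLACEMENT_HORIZON) + 1)
                )
                if ok:
                    content, pal = cand, True
            if content is None:
                bases = []
                for i in range(m):
                    excluded = set()
                    if i < PLACEMENT_HORIZON:
                        excluded.add(ctx.bline.seq[x + i])
                    if (m - i) <= PLACEMENT_HORIZON:
                        excluded.add(ctx.pline.seq[s - (m - i)])
                    allowed = [b for b in _BASES if b not in excluded]
                    bases.append(allowed[int(rng.integers(len(allowed)))])
                content = "".join(bases)
            prey_take = read_length - x - m
            read = bait_part + content + ctx.pline.seq[s : s + prey_take]
            b_qend_exc, qstart0 = x, x + m
        else:
            s = ctx.pline.origin + rho + l
            prey_take = read_length - x
            read = bait_part + ctx.pline.seq[s : s + prey_take]
            r = length - l if kind == "MH" else 0
            b_qend_exc, qstart0 = x + r, x - l
        prey_lo_index = s - l if kind == "MH" else s
        info = dict(
            x=x,
            s=s,
            b_qend_exc=b_qend_exc,
            qstart0=qstart0,
            prey_lo_index=prey_lo_index,
            palindromic=pal,
        )
        return read, info

    def _make_tlx(
        self, qname: str, junc_id: int, ctx: JoinContext, read: str, info: dict
    ) -> TlxRecord:
        bl, pl = ctx.bline, ctx.pline
        qlen = len(read)
        b_lo, b_hi = bl.span(0, info["b_qend_exc"])
        prey_len = qlen - info["qstart0"]
        p_lo, p_hi = pl.span(info["prey_lo_index"], info["prey_lo_index"] + prey_len)
        junction = p_lo + 1 if pl.strand == "+" else p_hi
        b_junction = b_hi if bl.strand == "+" else b_lo + 1
        return TlxRecord(
            qname=qname,
            junc_id=junc_id,
            rname=pl.chrom,
            junction=junction,
            strand=pl.strand,
            rstart=p_lo + 1,
            rend=p_hi,
            b_rname=bl.chrom,
            b_rstart=b_lo + 1,
            b_rend=b_hi,
            b_strand=bl.strand,
            b_junction=b_junction,
            qstart=info["qstart0"] + 1,
            qend=qlen,
            b_qstart=1,
            b_qend=info["b_qend_exc"],
            qlen=qlen,
            seq=read,
        )

    def simulate_event(self, rng, read_name: str = "R0", junc_id: int = 0):
        """One repair event: (GroundTruthRecord, read sequence)."""
        cfg = self.config
        event = _draw(self._event_keys, self._event_cdf, rng)
        if event == "unjoined":
            read = self._bline.seq[: cfg.read_length]
            truth = GroundTruthRecord(read_name=read_name, event_class="unjoined")
            return truth, read

        if event == "V_J":
            segment = self._choose_segment(rng)
            cognate = self.bait.side
            hybrid = rng.random() < cfg.hybrid_rate
            end_type = ("SE" if cognate == "CE" else "CE") if hybrid else cognate
            ctx = self.vj_context(segment, end_type)
            kind, length = self._draw_structure(rng)
            prey_sign = -1 if end_type == "CE" else 1
            configuration = segment.configuration or "n/a"
            label, tclass = segment.name, "n/a"
        elif event == "rejoin":
            ctx = self.rejoin_context()
            kind, length = self._draw_structure(rng)
            end_type = "SE" if self.bait.side == "CE" else "CE"
            prey_sign = -1 if end_type == "CE" else 1
            configuration, label, tclass = "n/a", self.bait.name, "n/a"
        else:  # translocation
            tclass = _draw(self._split_keys, self._split_cdf, rng)
            kind, length = self._draw_structure(rng)
            end_type, configuration = "n/a", "n/a"
            prey_sign = 1
            if tclass == "receptor_locus":
                label = next(iter(RECEPTOR_CUT_SITES))
                side = "right" if rng.random() < 0.5 else "left"
                ctx = self.receptor_context(label, side)
            else:
                chrom = "chrD"
                margin = self._prey_forward() + 50
                pos = int(rng.integers(margin, len(self.reference[chrom]) - margin))
                strand = "+" if rng.random() < 0.5 else "-"
                label = f"{chrom}:{pos}:{strand}"
                ctx = JoinContext(
                    self._bline,
                    junction_line(
                        self.reference, chrom, pos, strand, back=40,
                        forward=self._prey_forward(),
                    ),
                    self._beta_max,
                    min(self._rho_max, 30),
                )

        beta0 = self._draw_resection(rng)
        rho0 = self._draw_resection(rng)
        if event == "rejoin":
            while beta0 == 0 and rho0 == 0:
                beta0 = self._draw_resection(rng)
                rho0 = self._draw_resection(rng)
        beta0 = min(beta0, ctx.beta_max)
        kind, length = ctx.effective_structure(kind, length)
        placed = ctx.place(kind, length, beta0, rho0)
        if placed is None:
            raise SimulationConfigError(
                f"no sequence-compatible placement for {kind}{length or ''} "
                f"in context {label}; lower the requested structure length"
            )
        beta, rho, l = placed
        pal_wanted = (
            kind == "insertion"
            and self.bait.side == "CE"
            and rng.random() < cfg.palindromic_insertion_rate
        )
        read, info = self._assemble(ctx, kind, length, beta, rho, l, rng, pal_wanted)
        tlx = self._make_tlx(read_name, junc_id, ctx, read, info)
        r = length - l if kind == "MH" else 0
        bait_sign = -1 if self.bait.side == "CE" else 1
        truth = GroundTruthRecord(
            read_name=read_name,
            event_class=event,
            prey_segment=label,
            prey_end_type=end_type if event == "V_J" else "n/a",
            configuration=configuration,
            bait_resection=bait_sign * (beta - r),
            prey_resection=prey_sign * rho,
            structure_kind=kind,
            structure_length=length,
            palindromic=info["palindromic"],
            translocation_class=tclass,
            tlx=tlx,
        )
        return truth, read

    def _apply_errors(self, read: str, rng) -> str:
        e = self.config.error_rate
        if e <= 0:
            return read
        arr = np.frombuffer(read.encode(), dtype="S1").copy()
        hits = np.nonzero(rng.random(len(arr)) < e)[0]
        for i in hits:
            current = arr[i].decode()
            options = [b for b in _BASES if b != current]
            arr[i] = options[int(rng.integers(3))].encode()
        return arr.tobytes().decode()

    def simulate_library(self):
        """All reads and truths; deterministic in ``config.seed``."""
        rng = np.random.Generator(np.random.PCG64(self.config.seed))
        reads: list[tuple[str, str]] = []
        truths: list[GroundTruthRecord] = []
        junc_id = 0
        previous: Optional[tuple[GroundTruthRecord, str]] = None
        for i in range(self.config.n_read_pairs):
            qname = f"R{i:07d}"
            if previous is not None and rng.random() < self.config.duplicate_rate:
                prev_truth, prev_read = previous
                truth = replace(prev_truth, read_name=qname)
                if prev_truth.tlx is not None:
                    truth.tlx = replace(prev_truth.tlx, qname=qname)
                read = prev_read
            else:
                junc_id += 1
                truth, read = self.simulate_event(rng, qname, junc_id)
                previous = (truth, read)
            read = self._apply_errors(read, rng)
            reads.append((qname, read))
            truths.append(truth)
        return reads, truths


def simulate_library(
    config: SimulationConfig, spec: LocusSpec, reference: dict[str, str]
):
    """Convenience wrapper: (reads, truths) for one library."""
    return LibrarySimulator(config, spec, reference).simulate_library()


def emit_truth_tlx(truths: Iterable[GroundTruthRecord]) -> list[TlxRecord]:
    """Ground-truth junction records for all joined events, re-numbered."""
    out = []
    for t in truths:
        if t.tlx is not None:
            out.append(replace(t.tlx, junc_id=len(out) + 1))
    return out


def write_fastq(reads: Iterable[tuple[str, str]], stream) -> None:
    """Sanger FASTQ with a constant Q30 placeholder quality."""
    for qname, seq in reads:
        stream.write(f"@{qname}\n{seq}\n+\n" + "?" * len(seq) + "\n")


def reads_to_fastq(reads: Iterable[tuple[str, str]]) -> str:
    buf = io.StringIO()
    write_fastq(reads, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# model-implied expectations


def expected_resection_enrichment(
    sim: LibrarySimulator, w_inner: int = 10, w_outer: int = 100
) -> float:
    """Exact model-implied resection enrichment among V-J junctions.

    Integrates the configured resection mixture over the deterministic
    junction-placement map for every (segment, prey end, structure)
    context, weighting by V usage, hybrid rate, and structure weights,
    and returns P(|d| <= w_inner) / P(|d| <= w_outer) for the prey offset
    d a perfect analysis would measure.
    """
    cfg = sim.config
    pmf = cfg.resection_model.pmf()
    inner = outer = total = 0.0
    for stad_label, stad_w in cfg.v_usage.items():
        segs = sim.spec.segments_in_stad(stad_label)
        for seg in segs:
            seg_w = stad_w / len(segs)
            for end_type, end_w in [
                (sim.bait.side, 1.0 - cfg.hybrid_rate),
                ("SE" if sim.bait.side == "CE" else "CE", cfg.hybrid_rate),
            ]:
                if end_w == 0.0:
                    continue
                ctx = sim.vj_context(seg, end_type)
                for key, sw in cfg.structure_weights.items():
                    kind, length = ctx.effective_structure(*parse_structure_key(key))
                    w = seg_w * end_w * sw
                    for rho0, p in enumerate(pmf):
                        if p == 0.0:
                            continue
                        rho = ctx.realized_rho(kind, length, rho0)
                        if rho is None:
                            continue
                        total += w * p
                        if rho <= w_inner:
                            inner += w * p
                        if rho <= w_outer:
                            outer += w * p
    if outer == 0.0:
        raise SimulationConfigError("no junction mass inside the outer window")
    return inner / outer
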