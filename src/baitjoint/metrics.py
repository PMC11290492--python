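"""Library-level repair metrics over classified junctions.

Conventions (fixed across the package):

* libraries are normalized to 500,000 read pairs for cross-library
  comparison (uniform downsampling without replacement; translocation
  rates are additionally expressed per 500,000 read pairs);
* microhomology-mediated (MMEJ) junctions are those with MH > 1 bp;
* the joint-structure distribution uses 41 bins: MH 20..1, direct,
  insertion 1..20, with out-of-range lengths counted separately;
* resection enrichment is N(|d| <= 10) / N(|d| <= 100) over prey
  junction offsets d;
* absolute translocation counts deduplicate on the junction identity
  key (Rname, Strand, Junction, B_Junction); relative frequencies are
  computed without deduplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import STRUCTURE_RANGE, ClassifiedJunction

NORMALIZATION_READ_PAIRS = 500_000

#: Canonical 41-bin structure axis, MH-side first.
STRUCTURE_BINS = (
    [f"MH{k}" for k in range(STRUCTURE_RANGE, 0, -1)]
    + ["direct"]
    + [f"INS{m}" for m in range(1, STRUCTURE_RANGE + 1)]
)


class MetricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# downsampling


def downsample(
    items: Sequence, n: int = NORMALIZATION_READ_PAIRS, seed: int = 0
) -> list:
    """Uniform sample of ``n`` items without replacement, order-preserving.

    When fewer than ``n`` items are available, returns them all and emits
    a warning (the library is then under the normalization depth).
    """
    items = list(items)
    if len(items) <= n:
        if len(items) < n:
            warnings.warn(
                f"only {len(items)} read pairs available, below the "
                f"normalization depth of {n}; using all of them",
                stacklevel=2,
            )
        return items
    rng = np.random.Generator(np.random.PCG64(seed))
    keep = rng.choice(len(items), size=n, replace=False)
    keep.sort()
    return [items[i] for i in keep]


# ---------------------------------------------------------------------------
# headline metrics


@dataclass(frozen=True)
class VjEfficiency:
    vj_count: int
    total_read_pairs: int

    @property
    def value(self) -> float:
        return self.vj_count / self.total_read_pairs if self.total_read_pairs else 0.0


def vj_efficiency(
    classified: Iterable[ClassifiedJunction], total_read_pairs: int
) -> VjEfficiency:
    """Fraction of all read pairs that yield a V-J joint (DEL + INV)."""
    if total_read_pairs <= 0:
        raise MetricsError("total_read_pairs must be positive")
    count = sum(1 for c in classified if c.category == "V_J")
    return VjEfficiency(count, total_read_pairs)


@dataclass(frozen=True)
class CeSeRatio:
    ce_count: int
    se_count: int

    @property
    def defined(self) -> bool:
        return self.se_count > 0

    @property
    def value(self) -> Optional[float]:
        """CE/SE ratio; None (undefined) when no SE junctions exist."""
        return self.ce_count / self.se_count if self.defined else None


def ce_se_ratio(classified: Iterable[ClassifiedJunction]) -> CeSeRatio:
    """Coding-end vs signal-end prey usage among V_J junctions."""
    ce = se = 0
    for c in classified:
        if c.category != "V_J":
            continue
        if c.end_type == "CE":
            ce += 1
        elif c.end_type == "SE":
            se += 1
    return CeSeRatio(ce, se)


@dataclass(frozen=True)
class StructureDistribution:
    counts: dict[str, int]  # keyed by STRUCTURE_BINS
    out_of_range_mh: int
    out_of_range_ins: int
    n: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.n == 0:
            return {b: 0.0 for b in STRUCTURE_BINS}
        return {b: self.counts[b] / self.n for b in STRUCTURE_BINS}

    @property
    def mmej_fraction(self) -> float:
        """Fraction of junctions with MH > 1 bp (in-range plus overflow)."""
        if self.n == 0:
            return 0.0
        mmej = sum(
            self.counts[f"MH{k}"] for k in range(2, STRUCTURE_RANGE + 1)
        ) + self.out_of_range_mh
        return mmej / self.n

    @property
    def direct_fraction(self) -> float:
        return self.counts["direct"] / self.n if self.n else 0.0


def structure_distribution(
    classified: Iterable[ClassifiedJunction], categories: Sequence[str] = ("V_J",)
) -> StructureDistribution:
    """41-bin joint-structure distribution over the selected categories."""
    counts = {b: 0 for b in STRUCTURE_BINS}
    oor_mh = oor_ins = 0
    n = 0
    for c in classified:
        if c.category not in categories or c.structure is None:
            continue
        n += 1
        s = c.structure
        if s.in_range:
            counts[s.label] += 1
        elif s.kind == "MH":
            oor_mh += 1
        else:
            oor_ins += 1
    return StructureDistribution(counts, oor_mh, oor_ins, n)


@dataclass(frozen=True)
class ResectionEnrichment:
    inner_count: int
    outer_count: int
    inner_bp: int = 10
    outer_bp: int = 100

    @property
    def defined(self) -> bool:
        return self.outer_count > 0

    @property
    def value(self) -> Optional[float]:
        return self.inner_count / self.outer_count if self.defined else None


def resection_enrichment(
    classified: Iterable[ClassifiedJunction],
    inner_bp: int = 10,
    outer_bp: int = 100,
) -> ResectionEnrichment:
    """Junction concentration at the scission point among V_J joints.

    N(|d| <= inner) / N(|d| <= outer) over strand-normalized prey
    junction offsets d.
    """
    inner = outer = 0
    for c in classified:
        if c.category != "V_J" or c.resection_offset is None:
            continue
        d = abs(c.resection_offset)
        if d <= outer_bp:
            outer += 1
            if d <= inner_bp:
                inner += 1
    return ResectionEnrichment(inner, outer, inner_bp, outer_bp)


def resection_profile(
    classified: Iterable[ClassifiedJunction], window_bp: int = 100
) -> pd.Series:
    """Junction counts by signed prey offset over [-window, +window]."""
    idx = range(-window_bp, window_bp + 1)
    counts = pd.Series(0, index=idx, dtype=int)
    for c in classified:
        if c.category != "V_J" or c.resection_offset is None:
            continue
        if -window_bp <= c.resection_offset <= window_bp:
            counts[c.resection_offset] += 1
    return counts


def stad_distribution(
    classified: Iterable[ClassifiedJunction], stad_labels: Sequence[str]
) -> pd.Series:
    """Percentage of V_J junctions per sTAD (sums to 100 when any exist)."""
    counts = pd.Series(0, index=list(stad_labels), dtype=int)
    for c in classified:
        if c.category == "V_J" and c.stad in counts.index:
            counts[c.stad] += 1
    total = counts.sum()
    return 100.0 * counts / total if total else counts.astype(float)


@dataclass(frozen=True)
class TranslocationFrequency:
    raw_count: int
    unique_count: int
    total_read_pairs: int

    @property
    def relative_per_normalized(self) -> float:
        """Junction count per 500,000 read pairs, without deduplication."""
        return self.raw_count * NORMALIZATION_READ_PAIRS / self.total_read_pairs

    @property
    def absolute(self) -> int:
        """Distinct translocation events (junction-identity deduplicated)."""
        return self.unique_count


def translocation_frequency(
    classified: Iterable[ClassifiedJunction],
    total_read_pairs: int,
    translocation_class: Optional[str] = None,
) -> TranslocationFrequency:
    if total_read_pairs <= 0:
        raise MetricsError("total_read_pairs must be positive")
    raw = 0
    unique: set[tuple[str, str, int, int]] = set()
    for c in classified:
        if c.category != "translocation":
            continue
        if translocation_class and c.translocation_class != translocation_class:
            continue
        raw += 1
        r = c.record
        unique.add((r.rname, r.strand, r.junction, r.b_junction))
    return TranslocationFrequency(raw, len(unique), total_read_pairs)


# ---------------------------------------------------------------------------
# summary table


@dataclass
class MetricsTable:
    """All headline metrics of one library, with sample sizes."""

    total_read_pairs: int
    category_counts: dict[str, int]
    vj: VjEfficiency
    ce_se: CeSeRatio
    structure: StructureDistribution
    enrichment: ResectionEnrichment
    stad_percent: pd.Series
    translocations: TranslocationFrequency
    translocations_receptor: TranslocationFrequency
    translocations_spontaneous: TranslocationFrequency
    extra: dict[str, float] = field(default_factory=dict)

    def rows(self) -> list[tuple[str, object, int]]:
        """(metric, value, n) rows for emission."""
        out: list[tuple[str, object, int]] = [
            ("total_read_pairs", self.total_read_pairs, self.total_read_pairs),
        ]
        for cat, n in sorted(self.category_counts.items()):
            out.append((f"junctions_{cat}", n, n))
        out += [
            ("vj_efficiency", self.vj.value, self.vj.total_read_pairs),
            ("ce_count", self.ce_se.ce_count, self.ce_se.ce_count),
            ("se_count", self.ce_se.se_count, self.ce_se.se_count),
            (
                "ce_se_ratio",
                self.ce_se.value if self.ce_se.defined else "undefined",
                self.ce_se.ce_count + self.ce_se.se_count,
            ),
            ("mmej_fraction", self.structure.mmej_fraction, self.structure.n),
            ("direct_fraction", self.structure.direct_fraction, self.structure.n),
            (
                "resection_enrichment",
                self.enrichment.value if self.enrichment.defined else "undefined",
                self.enrichment.outer_count,
            ),
        ]
        vj_n = self.category_counts.get("V_J", 0)
        for label, pct in self.stad_percent.items():
            out.append((f"stad_percent_{label}", pct, vj_n))
        for name, t in [
            ("translocations", self.translocations),
            ("translocations_receptor", self.translocations_receptor),
            ("translocations_spontaneous", self.translocations_spontaneous),
        ]:
            out.append(
                (f"{name}_per_{NORMALIZATION_READ_PAIRS}", t.relative_per_normalized, t.raw_count)
            )
            out.append((f"{name}_absolute", t.absolute, t.raw_count))
        for k, v in self.extra.items():
            out.append((k, v, self.total_read_pairs))
        return out

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("metric\tvalue\tn\n")
        for metric, value, n in self.rows():
            if isinstance(value, float):
                value = f"{value:.6g}"
            stream.write(f"{metric}\t{value}\t{n}\n")


def summarize(
    classified: Sequence[ClassifiedJunction],
    total_read_pairs: int,
    stad_labels: Sequence[str],
) -> MetricsTable:
    """Compute the full metrics table for one classified library."""
    category_counts: dict[str, int] = {}
    for c in classified:
        category_counts[c.category] = category_counts.get(c.category, 0) + 1
    return MetricsTable(
        total_read_pairs=total_read_pairs,
        category_counts=category_counts,
        vj=vj_efficiency(classified, total_read_pairs),
        ce_se=ce_se_ratio(classified),
        structure=structure_distribution(classified),
        enrichment=resection_enrichment(classified),
        stad_percent=stad_distribution(classified, stad_labels),
        translocations=translocation_frequency(classified, total_read_pairs),
        translocations_receptor=translocation_frequency(
            classified, total_read_pairs, "receptor_locus"
        ),
        translocations_spontaneous=translocation_frequency(
            classified, total_read_pairs, "spontaneous"
        ),
    )
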