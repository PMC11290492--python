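"""Relative vs absolute translocation frequencies.

Simulates a library with PCR-style duplicates and shows why the two
conventions differ: the relative frequency (junctions per 500,000 read
pairs, no deduplication) scales with amplification, while the absolute
count deduplicates on the junction identity key (Rname, Strand,
Junction, B_Junction) and approximates the number of distinct events.
"""

from baitjoint import (
    LibrarySimulator,
    SimulationConfig,
    build_toy_genome,
    call_library,
    classify_all,
)
from baitjoint.metrics import translocation_frequency

reference, spec = build_toy_genome(seed=0)

for dup in (0.0, 0.5):
    config = SimulationConfig(
        n_read_pairs=6000, seed=99, duplicate_rate=dup, translocation_rate=0.05
    )
    sim = LibrarySimulator(config, spec, reference)
    reads, _ = sim.simulate_library()
    calls = call_library(reads, sim.bait, reference)
    classified = classify_all(calls, spec, config.bait_name)
    t = translocation_frequency(classified, total_read_pairs=len(reads))
    print(
        f"duplicate_rate={dup:.1f}: {t.raw_count} translocation reads, "
        f"relative {t.relative_per_normalized:.0f} per 500k read pairs, "
        f"absolute {t.absolute} unique events"
    )
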