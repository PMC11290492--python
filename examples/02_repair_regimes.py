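"""Compare repair regimes by joint structure and resection.

Simulates three libraries — NHEJ-proficient, alternative end joining
(Ku-deficient-like), and MMEJ-dominant — and contrasts the signatures the
analysis recovers: direct-joint fraction, microhomology usage (MH > 1 bp),
and the concentration of junctions at the scission point.
"""

from baitjoint import (
    LibrarySimulator,
    SeedIndex,
    aej_config,
    build_toy_genome,
    call_library,
    classify_all,
    expected_resection_enrichment,
    mmej_dominant_config,
    nhej_config,
)
from baitjoint.metrics import resection_enrichment, structure_distribution

reference, spec = build_toy_genome(seed=0)
index = SeedIndex(reference)

print(f"{'regime':<15}{'direct':>8}{'MMEJ':>8}{'enrich':>8}{'model':>8}")
for make in (nhej_config, aej_config, mmej_dominant_config):
    config = make(n_read_pairs=8000, seed=7)
    sim = LibrarySimulator(config, spec, reference)
    reads, _ = sim.simulate_library()
    calls = call_library(reads, sim.bait, reference, index=index)
    vj = [c for c in classify_all(calls, spec, config.bait_name) if c.category == "V_J"]
    dist = structure_distribution(vj)
    enr = resection_enrichment(vj)
    model = expected_resection_enrichment(sim)
    print(
        f"{config.regime:<15}"
        f"{dist.direct_fraction:>8.3f}"
        f"{dist.mmej_fraction:>8.3f}"
        f"{enr.value:>8.3f}"
        f"{model:>8.3f}"
    )

print(
    "\nNHEJ keeps junctions direct and tight around the cut;"
    "\nMMEJ-dominant repair shifts mass into microhomology joints and"
    "\nlonger resection (lower enrichment). The 'model' column is the"
    "\nexact expectation enumerated from the generator's placement map."
)
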