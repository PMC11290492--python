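import collections
import math

import numpy as np
import pytest

from baitjoint import (
    LibrarySimulator,
    ResectionModel,
    SimulationConfig,
    expected_resection_enrichment,
    structure_oracle,
)
from baitjoint.simulate import (
    SimulationConfigError,
    mmej_dominant_config,
    nhej_config,
    parse_structure_key,
)


@pytest.fixture(scope="module")
def library(reference, spec):
    cfg = SimulationConfig(n_read_pairs=3000, seed=11)
    sim = LibrarySimulator(cfg, spec, reference)
    reads, truths = sim.simulate_library()
    return sim, reads, truths


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(SimulationConfigError, match="sums to"):
            SimulationConfig(structure_weights={"direct": 0.5, "MH1": 0.4})

    def test_negative_weight_rejected(self):
        with pytest.raises(SimulationConfigError, match="negative"):
            SimulationConfig(
                structure_weights={"direct": 1.2, "MH1": -0.2},
            )

    def test_structure_length_capped(self):
        with pytest.raises(SimulationConfigError, match="out of range"):
            SimulationConfig(structure_weights={"MH21": 1.0})

    def test_rates_capped(self):
        with pytest.raises(SimulationConfigError, match="beyond 1"):
            SimulationConfig(vj_rate=0.6, rejoin_rate=0.5)

    def test_read_length_sufficiency(self, reference, spec):
        with pytest.raises(SimulationConfigError, match="read_length"):
            LibrarySimulator(
                SimulationConfig(read_length=120), spec, reference
            )

    def test_resection_l_max_capped(self):
        with pytest.raises(SimulationConfigError, match="l_max"):
            ResectionModel(l_max=500)

    def test_parse_structure_key(self):
        assert parse_structure_key("direct") == ("direct", 0)
        assert parse_structure_key("MH4") == ("MH", 4)
        assert parse_structure_key("INS2") == ("insertion", 2)
        with pytest.raises(SimulationConfigError):
            parse_structure_key("bogus")


class TestResectionModel:
    def test_pmf_normalized(self):
        pmf = ResectionModel(w0=0.6, mean_bp=20, l_max=100).pmf()
        assert pmf[0] == pytest.approx(0.6)
        assert pmf.sum() == pytest.approx(1.0)
        assert (pmf >= 0).all()

    def test_point_mass_only(self):
        pmf = ResectionModel(w0=1.0).pmf()
        assert pmf[0] == 1.0
        assert pmf[1:].sum() == 0.0


class TestDeterminism:
    def test_same_seed_identical(self, reference, spec):
        cfg = SimulationConfig(n_read_pairs=200, seed=3)
        out1 = LibrarySimulator(cfg, spec, reference).simulate_library()
        out2 = LibrarySimulator(cfg, spec, reference).simulate_library()
        assert out1[0] == out2[0]
        assert [t.tlx for t in out1[1]] == [t.tlx for t in out2[1]]

    def test_seed_changes_output(self, reference, spec):
        a = LibrarySimulator(
            SimulationConfig(n_read_pairs=200, seed=3), spec, reference
        ).simulate_library()[0]
        b = LibrarySimulator(
            SimulationConfig(n_read_pairs=200, seed=4), spec, reference
        ).simulate_library()[0]
        assert a != b


class TestEventSampling:
    def test_class_frequencies_within_3_sigma(self, library):
        sim, reads, truths = library
        n = len(truths)
        counts = collections.Counter(t.event_class for t in truths)
        expected = {
            "V_J": sim.config.vj_rate,
            "rejoin": sim.config.rejoin_rate,
            "translocation": sim.config.translocation_rate,
            "unjoined": sim.config.unjoined_rate,
        }
        for cls, p in expected.items():
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(counts[cls] - n * p) <= 3 * sigma, cls

    def test_unjoined_reads_are_germline(self, library):
        sim, reads, truths = library
        germline = sim._bline.seq[: sim.config.read_length]
        by_name = dict(reads)
        for t in truths:
            if t.event_class == "unjoined":
                assert by_name[t.read_name] == germline
                assert t.tlx is None

    def test_rejoins_never_perfect(self, library):
        _, _, truths = library
        for t in truths:
            if t.event_class == "rejoin":
                # a (0,0) direct rejoin would be indistinguishable from germline
                assert not (
                    t.bait_resection == 0
                    and t.prey_resection == 0
                    and t.structure_kind == "direct"
                )

    def test_read_lengths(self, library):
        sim, reads, _ = library
        assert all(len(seq) == sim.config.read_length for _, seq in reads)


class TestStructureRealization:
    def test_every_junction_matches_oracle(self, library, reference):
        _, _, truths = library
        for t in truths:
            if t.tlx is None:
                continue
            res = structure_oracle(t.tlx, reference)
            assert (res.kind, res.length) == (t.structure_kind, t.structure_length), (
                t.read_name
            )

    def test_prey_resection_preserved_for_direct_and_insertion(self, reference, spec):
        sim = LibrarySimulator(SimulationConfig(), spec, reference)
        ctx = sim.vj_context(spec.segment("V1"), "CE")
        for kind, length in [("direct", 0), ("insertion", 1), ("insertion", 3)]:
            for rho0 in range(0, 101, 7):
                placed = ctx.place(kind, length, 0, rho0)
                assert placed is not None
                _, rho, _ = placed
                assert rho == rho0, (kind, length, rho0)

    def test_mh_lands_on_nearest_feasible_column(self, reference, spec):
        sim = LibrarySimulator(SimulationConfig(), spec, reference)
        ctx = sim.vj_context(spec.segment("V1"), "CE")
        for k in (1, 2, 3, 4):
            cols = ctx.feasibility("MH", k).any(axis=0).nonzero()[0]
            assert cols.size, k
            for rho0 in range(0, 101, 13):
                placed = ctx.place("MH", k, 0, rho0)
                assert placed is not None
                _, rho, l = placed
                assert 0 <= l <= k
                # realized column is the one minimizing |rho - rho0|
                best = min(abs(cols - rho0))
                assert abs(rho - rho0) == best, (k, rho0, rho)

    def test_structure_degradation_when_infeasible(self, reference, spec):
        sim = LibrarySimulator(SimulationConfig(), spec, reference)
        ctx = sim.vj_context(spec.segment("V1"), "CE")
        # a 20 bp exact microhomology will not exist in a 40 kb toy genome
        kind, length = ctx.effective_structure("MH", 20)
        assert (kind == "MH" and length < 20) or kind == "direct"
        assert ctx.feasibility(kind, length).any()

    def test_insertions_palindromic_flag_honest(self, reference, spec):
        cfg = nhej_config(n_read_pairs=1500, seed=21)
        sim = LibrarySimulator(cfg, spec, reference)
        _, truths = sim.simulate_library()
        ins = [t for t in truths if t.structure_kind == "insertion"]
        assert ins, "NHEJ preset should produce insertions"
        pal = [t for t in ins if t.palindromic]
        assert pal, "some insertions should be palindromic"
        for t in ins:
            res = structure_oracle(t.tlx, reference)
            if t.palindromic:
                assert res.palindromic


class TestDegenerateConfigs:
    def test_hybrid_zero_gives_no_hybrids(self, reference, spec):
        cfg = SimulationConfig(n_read_pairs=800, seed=5, hybrid_rate=0.0)
        sim = LibrarySimulator(cfg, spec, reference)
        _, truths = sim.simulate_library()
        vj = [t for t in truths if t.event_class == "V_J"]
        assert vj
        assert all(t.prey_end_type == sim.bait.side for t in vj)

    def test_w0_one_gives_zero_resection(self, reference, spec):
        cfg = SimulationConfig(
            n_read_pairs=600,
            seed=6,
            resection_model=ResectionModel(w0=1.0),
            structure_weights={"direct": 0.8, "INS2": 0.2},
            rejoin_rate=0.0,
            vj_rate=0.5,
        )
        sim = LibrarySimulator(cfg, spec, reference)
        _, truths = sim.simulate_library()
        vj = [t for t in truths if t.event_class == "V_J"]
        assert vj
        assert all(t.prey_resection == 0 for t in vj)

    def test_expected_enrichment_is_one_for_w0_one(self, reference, spec):
        # offset-preserving structures only: an emergent microhomology
        # drawn at the cut must move to where the homology exists, so the
        # exact-1.0 contract applies to direct/insertion joints
        cfg = SimulationConfig(
            resection_model=ResectionModel(w0=1.0),
            structure_weights={"direct": 0.8, "INS2": 0.2},
            rejoin_rate=0.0,
            vj_rate=0.5,
        )
        sim = LibrarySimulator(cfg, spec, reference)
        assert expected_resection_enrichment(sim) == pytest.approx(1.0)


class TestNoiseAndDuplicates:
    def test_error_rate_perturbs_reads(self, reference, spec):
        # truth tlx stores the clean molecule; the emitted read carries errors
        sim = LibrarySimulator(
            SimulationConfig(n_read_pairs=300, seed=9, error_rate=0.01),
            spec,
            reference,
        )
        reads, truths = sim.simulate_library()
        by_name = dict(reads)
        diffs = total = 0
        for t in truths:
            if t.tlx is None:
                continue
            emitted = by_name[t.read_name]
            assert len(emitted) == len(t.tlx.seq)
            diffs += sum(a != b for a, b in zip(emitted, t.tlx.seq))
            total += len(emitted)
        p = 0.01
        assert 0 < diffs
        assert abs(diffs - total * p) <= 4 * math.sqrt(total * p * (1 - p))

    def test_duplicates_share_junction_identity(self, reference, spec):
        cfg = SimulationConfig(n_read_pairs=500, seed=13, duplicate_rate=0.4)
        _, truths = LibrarySimulator(cfg, spec, reference).simulate_library()
        names = [t.read_name for t in truths]
        assert len(set(names)) == len(names)
        keys = [
            (t.tlx.rname, t.tlx.strand, t.tlx.junction, t.tlx.b_junction)
            for t in truths
            if t.tlx is not None
        ]
        assert len(set(keys)) < len(keys)  # duplicates collapse on identity


class TestPresets:
    def test_presets_validate_and_differ(self):
        a, b, c = SimulationConfig(), nhej_config(), mmej_dominant_config()
        assert {a.regime, b.regime, c.regime} == {"AEJ", "NHEJ", "MMEJ_dominant"}
        assert b.structure_weights != a.structure_weights
        assert c.structure_weights["direct"] < a.structure_weights["direct"]


class TestExpectedEnrichment:
    def test_between_zero_and_one(self, reference, spec):
        sim = LibrarySimulator(SimulationConfig(), spec, reference)
        e = expected_resection_enrichment(sim)
        assert 0.0 < e <= 1.0

    def test_monotone_in_w0(self, reference, spec):
        lo = LibrarySimulator(
            SimulationConfig(resection_model=ResectionModel(w0=0.2)), spec, reference
        )
        hi = LibrarySimulator(
            SimulationConfig(resection_model=ResectionModel(w0=0.8)), spec, reference
        )
        assert expected_resection_enrichment(lo) < expected_resection_enrichment(hi)
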