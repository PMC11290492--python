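import pytest

from baitjoint import (
    LibrarySimulator,
    SimulationConfig,
    TlxRecord,
    classify_all,
    classify_junction,
    joint_structure,
    structure_oracle,
)
from baitjoint.classify import (
    assign_end_type,
    categorize,
    classification_frame,
    configuration_of,
    resection_offset,
)


def make_record(
    junction=3000,
    strand="+",
    rname="chrL",
    b_qend=50,
    qstart=51,
    rspan=60,
    qlen=300,
    rstart=None,
    rend=None,
):
    if rstart is None or rend is None:
        rstart = junction if strand == "+" else junction - rspan + 1
        rend = junction + rspan - 1 if strand == "+" else junction
    return TlxRecord(
        qname="q",
        junc_id=1,
        rname=rname,
        junction=junction,
        strand=strand,
        rstart=rstart,
        rend=rend,
        b_rname="chrL",
        b_rstart=30000,
        b_rend=30140,
        b_strand="-",
        b_junction=30001,
        qstart=qstart,
        qend=min(qlen, qstart + (rend - rstart)),
        b_qstart=1,
        b_qend=b_qend,
        qlen=qlen,
        seq="",
    )


class TestJointStructure:
    def test_microhomology_from_overlap(self):
        # bait alignment ends at query base 50, prey begins at 48: 3 shared bases
        s = joint_structure(make_record(b_qend=50, qstart=48))
        assert (s.kind, s.length, s.label) == ("MH", 3, "MH3")
        assert s.is_mmej

    def test_direct_joint(self):
        s = joint_structure(make_record(b_qend=50, qstart=51))
        assert (s.kind, s.length, s.label) == ("direct", 0, "direct")
        assert not s.is_mmej

    def test_insertion(self):
        s = joint_structure(make_record(b_qend=50, qstart=53))
        assert (s.kind, s.length, s.label) == ("insertion", 2, "INS2")
        assert not s.is_mmej

    def test_single_base_mh_is_not_mmej(self):
        assert not joint_structure(make_record(b_qend=50, qstart=50)).is_mmej

    def test_out_of_range_flag(self):
        assert not joint_structure(make_record(b_qend=72, qstart=48)).in_range
        assert joint_structure(make_record(b_qend=67, qstart=48)).in_range


class TestCategorize:
    def test_vj_window(self, spec):
        cat, tclass, seg = categorize(make_record(junction=3150), spec, "J1CE")
        assert (cat, tclass, seg.name) == ("V_J", "n/a", "V1")

    def test_outside_window_is_intra_locus_other(self, spec):
        cat, _, seg = categorize(make_record(junction=3300), spec, "J1CE")
        assert (cat, seg) == ("intra_locus_other", None)

    def test_rejoin_region(self, spec):
        cat, _, _ = categorize(make_record(junction=29800), spec, "J1CE")
        assert cat == "rejoin"

    def test_receptor_translocation(self, spec):
        cat, tclass, _ = categorize(make_record(junction=5005, rname="chrP"), spec, "J1CE")
        assert (cat, tclass) == ("translocation", "receptor_locus")

    def test_spontaneous_translocation(self, spec):
        cat, tclass, _ = categorize(make_record(junction=8000, rname="chrD"), spec, "J1CE")
        assert (cat, tclass) == ("translocation", "spontaneous")


class TestEndType:
    def test_majority_left_of_plus_cut_is_ce(self, spec):
        seg = spec.segment("V1")  # '+', coding side left, cut 3000
        rec = make_record(junction=3000, strand="-", rstart=2941, rend=3000)
        et, amb = assign_end_type(rec, seg)
        assert (et, amb) == ("CE", False)

    def test_majority_right_is_se(self, spec):
        seg = spec.segment("V1")
        rec = make_record(junction=3001, strand="+", rstart=3001, rend=3060)
        et, amb = assign_end_type(rec, seg)
        assert (et, amb) == ("SE", False)

    def test_tie_resolved_toward_junction_and_flagged(self, spec):
        seg = spec.segment("V1")
        rec = make_record(junction=2991, strand="+", rstart=2991, rend=3010)
        et, amb = assign_end_type(rec, seg)
        assert amb
        assert et == "CE"  # junction base 2990 sits left of the cut

    def test_inverted_segment_flips_sides(self, spec):
        seg = spec.segment("V3")  # '-', coding side right, cut 10000
        rec = make_record(junction=10001, strand="+", rstart=10001, rend=10060)
        et, _ = assign_end_type(rec, seg)
        assert et == "CE"


class TestConfiguration:
    def test_concordant_geometry(self, spec):
        seg = spec.segment("V1")
        rec = make_record(junction=3000, strand="-", rstart=2941, rend=3000)
        conf, discordant = configuration_of(rec, seg, "CE")
        assert (conf, discordant) == ("DEL", False)

    def test_discordant_strand_flagged(self, spec):
        seg = spec.segment("V1")
        rec = make_record(junction=2941, strand="+", rstart=2941, rend=3000)
        conf, discordant = configuration_of(rec, seg, "CE")
        assert (conf, discordant) == ("DEL", True)


class TestResectionOffset:
    def test_zero_at_cut_minus_prey(self, spec):
        seg = spec.segment("V1")
        rec = make_record(junction=3000, strand="-", rstart=2941, rend=3000)
        assert resection_offset(rec, seg) == 0

    def test_negative_into_coding_body(self, spec):
        seg = spec.segment("V1")
        rec = make_record(junction=2995, strand="-", rstart=2936, rend=2995)
        assert resection_offset(rec, seg) == -5

    def test_positive_on_rss_side(self, spec):
        seg = spec.segment("V1")
        rec = make_record(junction=3008, strand="+", rstart=3008, rend=3060)
        assert resection_offset(rec, seg) == 7

    def test_minus_strand_segment_sign_flip(self, spec):
        seg = spec.segment("V3")  # '-' strand, cut 10000
        rec = make_record(junction=10006, strand="+", rstart=10006, rend=10060)
        assert resection_offset(rec, seg) == -5


@pytest.fixture(scope="module")
def run(reference, spec):
    cfg = SimulationConfig(n_read_pairs=1200, seed=29)
    sim = LibrarySimulator(cfg, spec, reference)
    _, truths = sim.simulate_library()
    records = [t.tlx for t in truths if t.tlx is not None]
    return truths, classify_all(records, spec, "J1CE")


class TestAgainstTruthAndOracle:
    def test_full_truth_concordance(self, run):
        truths, classified = run
        tb = {t.read_name: t for t in truths}
        for c in classified:
            t = tb[c.record.qname]
            assert c.category == t.event_class or (
                c.category == "translocation" and t.event_class == "translocation"
            )
            assert c.structure.label == t.structure_label
            if c.category == "V_J":
                assert c.segment.name == t.prey_segment
                assert c.end_type == t.prey_end_type
                assert c.configuration == t.configuration
                assert c.resection_offset == t.prey_resection
            if t.event_class == "translocation":
                assert c.translocation_class == t.translocation_class

    def test_structure_matches_oracle(self, run, reference):
        _, classified = run
        for c in classified:
            res = structure_oracle(c.record, reference)
            assert (res.kind, res.length) == (c.structure.kind, c.structure.length)

    def test_classification_frame_shape(self, run):
        _, classified = run
        frame = classification_frame(classified)
        assert len(frame) == len(classified)
        assert set(frame["category"]) <= {
            "V_J",
            "rejoin",
            "intra_locus_other",
            "translocation",
        }
        vj = frame[frame["category"] == "V_J"]
        assert vj["resection_offset"].notna().all()
        assert set(vj["stad"]) <= {"sTAD1-2", "sTAD3", "sTAD4", "sTAD5"}
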