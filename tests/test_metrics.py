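import io

import pytest

from baitjoint import downsample, summarize
from baitjoint.classify import ClassifiedJunction, JointStructure
from baitjoint.metrics import (
    STRUCTURE_BINS,
    MetricsError,
    ce_se_ratio,
    resection_enrichment,
    resection_profile,
    stad_distribution,
    structure_distribution,
    translocation_frequency,
    vj_efficiency,
)
from tests.test_classify import make_record


def cj(
    category="V_J",
    end_type="CE",
    offset=0,
    structure=("direct", 0),
    stad="sTAD5",
    tclass="n/a",
    junction=3000,
    rname="chrL",
    strand="+",
    b_junction=30001,
    qname="q",
):
    rec = make_record(junction=junction, strand=strand, rname=rname)
    rec.qname = qname
    rec.b_junction = b_junction
    return ClassifiedJunction(
        record=rec,
        category=category,
        translocation_class=tclass,
        end_type=end_type,
        structure=JointStructure(*structure),
        resection_offset=offset if category == "V_J" else None,
        stad=stad if category == "V_J" else None,
    )


class TestVjEfficiency:
    def test_counts_only_vj(self):
        cs = [cj(), cj(), cj(category="rejoin"), cj(category="translocation")]
        eff = vj_efficiency(cs, 10)
        assert (eff.vj_count, eff.value) == (2, 0.2)

    def test_zero_vj_gives_zero(self):
        assert vj_efficiency([cj(category="rejoin")], 100).value == 0.0

    def test_requires_positive_total(self):
        with pytest.raises(MetricsError):
            vj_efficiency([], 0)


class TestCeSeRatio:
    def test_hand_example(self):
        cs = [cj(end_type="CE")] * 90 + [cj(end_type="SE")] * 45
        r = ce_se_ratio(cs)
        assert (r.ce_count, r.se_count, r.value) == (90, 45, 2.0)

    def test_undefined_when_no_se(self):
        r = ce_se_ratio([cj(end_type="CE")] * 5)
        assert not r.defined
        assert r.value is None

    def test_non_vj_excluded(self):
        r = ce_se_ratio([cj(category="rejoin", end_type="SE"), cj(end_type="SE")])
        assert r.se_count == 1


class TestStructureDistribution:
    def test_41_bins(self):
        assert len(STRUCTURE_BINS) == 41
        assert STRUCTURE_BINS[0] == "MH20"
        assert STRUCTURE_BINS[20] == "direct"
        assert STRUCTURE_BINS[-1] == "INS20"

    def test_counts_and_fractions(self):
        cs = (
            [cj(structure=("direct", 0))] * 5
            + [cj(structure=("MH", 1))] * 3
            + [cj(structure=("MH", 3))] * 2
            + [cj(structure=("insertion", 2))] * 2
        )
        d = structure_distribution(cs)
        assert d.n == 12
        assert d.counts["direct"] == 5
        assert d.counts["MH1"] == 3
        assert d.counts["MH3"] == 2
        assert d.counts["INS2"] == 2
        assert d.mmej_fraction == pytest.approx(2 / 12)
        assert d.direct_fraction == pytest.approx(5 / 12)
        assert sum(d.fractions.values()) == pytest.approx(1.0)

    def test_out_of_range_bucketed_and_counted_as_mmej(self):
        cs = [cj(structure=("MH", 25)), cj(structure=("insertion", 30))]
        d = structure_distribution(cs)
        assert (d.out_of_range_mh, d.out_of_range_ins) == (1, 1)
        assert d.mmej_fraction == pytest.approx(0.5)

    def test_scope_selection(self):
        cs = [cj(structure=("MH", 2)), cj(category="rejoin", structure=("MH", 2))]
        assert structure_distribution(cs).n == 1
        assert structure_distribution(cs, ("V_J", "rejoin")).n == 2


class TestResectionEnrichment:
    def test_hand_example(self):
        offsets = [0, 3, -5, 50, -80]
        cs = [cj(offset=d) for d in offsets]
        e = resection_enrichment(cs)
        assert (e.inner_count, e.outer_count) == (3, 5)
        assert e.value == pytest.approx(0.6)

    def test_outside_outer_window_excluded(self):
        cs = [cj(offset=0), cj(offset=150)]
        e = resection_enrichment(cs)
        assert (e.inner_count, e.outer_count, e.value) == (1, 1, 1.0)

    def test_undefined_without_vj(self):
        e = resection_enrichment([cj(category="rejoin")])
        assert not e.defined
        assert e.value is None

    def test_profile_conserves_counts(self):
        cs = [cj(offset=d) for d in (0, 0, -7, 12, 99)]
        prof = resection_profile(cs)
        assert prof.sum() == 5
        assert prof[0] == 2
        assert prof[-7] == 1


class TestStadDistribution:
    def test_percentages(self):
        labels = ["sTAD1-2", "sTAD3", "sTAD4", "sTAD5"]
        cs = [cj(stad="sTAD5")] * 3 + [cj(stad="sTAD3")] * 1
        pct = stad_distribution(cs, labels)
        assert pct["sTAD5"] == pytest.approx(75.0)
        assert pct["sTAD3"] == pytest.approx(25.0)
        assert pct.sum() == pytest.approx(100.0)

    def test_empty_is_all_zero(self):
        pct = stad_distribution([], ["sTAD3"])
        assert pct.sum() == 0.0


class TestTranslocationFrequency:
    def test_dedup_contract(self):
        # 10 distinct junction identities, 3 copies each
        cs = []
        for i in range(10):
            for copy in range(3):
                cs.append(
                    cj(
                        category="translocation",
                        tclass="spontaneous",
                        rname="chrD",
                        junction=1000 + i,
                        qname=f"r{i}_{copy}",
                    )
                )
        t = translocation_frequency(cs, total_read_pairs=500_000)
        assert t.raw_count == 30
        assert t.absolute == 10
        assert t.relative_per_normalized == pytest.approx(30.0)

    def test_class_filter(self):
        cs = [
            cj(category="translocation", tclass="receptor_locus", rname="chrP"),
            cj(category="translocation", tclass="spontaneous", rname="chrD"),
        ]
        assert translocation_frequency(cs, 100, "receptor_locus").raw_count == 1
        assert translocation_frequency(cs, 100).raw_count == 2


class TestDownsample:
    def test_exact_subset_and_deterministic(self):
        items = list(range(1000))
        a = downsample(items, n=100, seed=4)
        b = downsample(items, n=100, seed=4)
        assert a == b
        assert len(a) == 100
        assert a == sorted(a)
        assert set(a) <= set(items)

    def test_warns_when_short(self):
        with pytest.warns(UserWarning, match="below the normalization depth"):
            out = downsample([1, 2, 3], n=10)
        assert out == [1, 2, 3]

    def test_seed_matters(self):
        items = list(range(1000))
        assert downsample(items, n=100, seed=1) != downsample(items, n=100, seed=2)


class TestSummarize:
    def test_table_rows_and_tsv(self):
        cs = (
            [cj(end_type="CE", offset=0)] * 4
            + [cj(end_type="SE", offset=30)] * 2
            + [cj(category="rejoin")] * 2
            + [
                cj(
                    category="translocation",
                    tclass="spontaneous",
                    rname="chrD",
                    junction=500,
                )
            ]
        )
        table = summarize(cs, total_read_pairs=100, stad_labels=["sTAD5"])
        rows = dict((name, value) for name, value, _ in table.rows())
        assert rows["vj_efficiency"] == pytest.approx(0.06)
        assert rows["ce_se_ratio"] == pytest.approx(2.0)
        assert rows["resection_enrichment"] == pytest.approx(4 / 6)
        assert rows["translocations_per_500000"] == pytest.approx(5000.0)
        assert rows["translocations_absolute"] == 1
        buf = io.StringIO()
        table.write_tsv(buf)
        assert buf.getvalue().startswith("metric\tvalue\tn\n")

    def test_undefined_ratio_emitted_as_text(self):
        table = summarize([cj(end_type="CE")], 10, ["sTAD5"])
        rows = dict((name, value) for name, value, _ in table.rows())
        assert rows["ce_se_ratio"] == "undefined"
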