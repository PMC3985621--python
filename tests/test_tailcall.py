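"""Non-templated 3' tail classification against hand-built hairpin fixtures."""

import pytest

from riscload import tailcall
from riscload.mirref import HairpinRecord, MatureRecord, link_matures
from riscload.readprep import Read
from riscload.tailcall import TailClassifier

# one mature embedded in one hairpin whose templated 3' continuation is GGCCA
M1 = "TGAGGTAGTAGGTTGTATAG"
H1 = "CCTAG" + M1 + "GGCCA"


def fixture(matures=None, hairpins=None):
    matures = matures or [MatureRecord("mir-1", M1)]
    hairpins = hairpins or [HairpinRecord("hp-1", H1)]
    return link_matures(matures, hairpins), hairpins


def read(seq, rid="r", pool="total"):
    return Read(rid, seq, pool)


class TestClassifyRead:
    def test_exact_mature_read_is_untailed(self):
        ms, hs = fixture()
        call = TailClassifier(ms, hs).classify(read(M1))
        assert (call.mirna_id, call.tail_seq, call.tailed, call.templated) == (
            "mir-1", "", False, False)

    def test_nontemplated_extension_is_tailed(self):
        # hairpin continues GG after the mature; AA cannot be templated
        ms, hs = fixture()
        call = TailClassifier(ms, hs).classify(read(M1 + "AA"))
        assert call.tailed and call.tail_seq == "AA" and not call.templated

    def test_templated_extension_is_never_a_tail(self):
        # the read mature+G is a contiguous hairpin substring: excluded
        # upfront, confirming templated isomiRs never count as tails
        ms, hs = fixture()
        call = TailClassifier(ms, hs).classify(read(M1 + "G"))
        assert not call.tailed and call.templated and call.tail_seq == "G"

    def test_second_hairpin_can_template_the_extension(self):
        # AA is non-templated on hp-1 but templated on hp-2 -> untailed
        hp2 = HairpinRecord("hp-2", "TTTT" + M1 + "AATCG")
        ms, hs = fixture(hairpins=[HairpinRecord("hp-1", H1), hp2])
        call = TailClassifier(ms, hs).classify(read(M1 + "AA"))
        assert not call.tailed

    def test_assigned_to_mature_of_closest_length(self):
        m20 = MatureRecord("len20", M1)  # 20 nt
        m22 = MatureRecord("len22", M1 + "GG")  # 22 nt, same 5' start
        hp = HairpinRecord("hp", "AAAC" + M1 + "GGTCAAT")
        ms, hs = fixture(matures=[m20, m22], hairpins=[hp])
        call = TailClassifier(ms, hs).classify(read(M1 + "GGCC"))  # 24 nt
        assert call.mirna_id == "len22"
        assert call.tail_seq == "CC"
        assert call.tailed

    def test_tie_break_is_lexicographic(self):
        a = MatureRecord("aaa", M1)
        b = MatureRecord("bbb", M1)
        hp = HairpinRecord("hp", "AAAC" + M1 + "GGTCAAT")
        ms, hs = fixture(matures=[a, b], hairpins=[hp])
        call = TailClassifier(ms, hs).classify(read(M1 + "CC"))
        assert call.mirna_id == "aaa"

    def test_order_of_matures_never_changes_calls(self):
        m20 = MatureRecord("len20", M1)
        m22 = MatureRecord("len22", M1 + "GG")
        hp = HairpinRecord("hp", "AAAC" + M1 + "GGTCAAT")
        ms_fwd, hs = fixture(matures=[m20, m22], hairpins=[hp])
        ms_rev, _ = fixture(matures=[m22, m20], hairpins=[hp])
        for seq in (M1, M1 + "G", M1 + "GG", M1 + "GGA", M1 + "TT"):
            c1 = TailClassifier(ms_fwd, hs).classify(read(seq))
            c2 = TailClassifier(ms_rev, hs).classify(read(seq))
            assert (c1.mirna_id, c1.tailed) == (c2.mirna_id, c2.tailed)

    def test_shifted_5prime_start_is_not_assigned(self):
        # discrete 5' start: a read missing the mature's first base has
        # no full-mature prefix and is never tail-called
        ms, hs = fixture()
        assert TailClassifier(ms, hs).classify(read(M1[1:] + "AA")) is None

    def test_n_in_extension_is_undetermined(self):
        ms, hs = fixture()
        call = TailClassifier(ms, hs).classify(read(M1 + "AN"))
        assert call.undetermined and not call.tailed

    def test_mature_without_hairpin_is_excluded(self):
        orphan = MatureRecord("orphan", "CCGGAATTCCGGAATTCCGG")
        ms = link_matures([orphan], [HairpinRecord("hp-1", H1)])
        assert TailClassifier(ms, [HairpinRecord("hp-1", H1)]).classify(
            read(orphan.seq + "AA")) is None

    def test_anywhere_in_hairpin_mode(self):
        # TAG occurs inside the hairpin though not at the mature's 3' end
        ms, hs = fixture()
        pos = TailClassifier(ms, hs, "positional").classify(read(M1 + "CTA"))
        anyw = TailClassifier(ms, hs, "anywhere_in_hairpin").classify(read(M1 + "CTA"))
        assert pos.tailed
        assert not anyw.tailed  # CTA occurs in the hairpin's 5' flank


class TestSummaries:
    def make_calls(self, n_tailed, n_untailed, pool="total", mid="mir-1"):
        calls = [tailcall.TailCall(f"t{i}", pool, mid, "AA", True, False)
                 for i in range(n_tailed)]
        calls += [tailcall.TailCall(f"u{i}", pool, mid, "", False, False)
                  for i in range(n_untailed)]
        return calls

    def test_percent_tailed(self):
        (s,) = tailcall.summarize_tails(self.make_calls(5, 95))
        assert s.pct_tailed == pytest.approx(5.0)
        assert s.n_reads == 100

    def test_zero_tailed_empty_composition(self):
        (s,) = tailcall.summarize_tails(self.make_calls(0, 10))
        assert s.pct_tailed == 0.0 and s.tail_composition == {}

    def test_undetermined_outside_denominator(self):
        calls = self.make_calls(1, 1)
        calls.append(tailcall.TailCall("x", "total", "mir-1", "AN", False, False,
                                       undetermined=True))
        (s,) = tailcall.summarize_tails(calls)
        assert s.n_reads == 2

    def test_matches_naive_recount(self, linked_small_sim):
        from riscload import readprep
        matures, hairpins, manifest, sim = linked_small_sim
        reads, _ = readprep.prepare_reads(sim.reads_total, manifest.adapter)
        calls = TailClassifier(matures, hairpins).classify_all(reads)
        summaries = {(s.mirna_id, s.pool): s for s in tailcall.summarize_tails(calls)}
        naive: dict[tuple, list] = {}
        for c in calls:
            if not c.undetermined:
                naive.setdefault((c.mirna_id, c.pool), []).append(c.tailed)
        assert set(naive) == set(summaries)
        for key, flags in naive.items():
            s = summaries[key]
            assert s.n_reads == len(flags)
            assert s.pct_tailed == pytest.approx(100 * sum(flags) / len(flags))

    def test_composition_counts_sum_to_n_tailed(self):
        calls = self.make_calls(4, 6)
        calls[0].tail_seq = "T"
        (s,) = tailcall.summarize_tails(calls)
        assert sum(s.tail_composition.values()) == s.n_tailed


class TestRatiosAndEnrichment:
    @pytest.mark.parametrize("pt,pi,expect", [(5.0, 2.5, 2.0), (3.0, 3.0, 1.0), (0.0, 4.0, 0.0)])
    def test_tail_ratio(self, pt, pi, expect):
        assert tailcall.tail_ratio(pt, pi) == pytest.approx(expect)

    def test_undefined_when_ip_zero(self):
        assert tailcall.tail_ratio(3.0, 0.0) is None

    def test_enrichment_fold_by_tail_sequence(self):
        def calls(pool, tails):
            return [tailcall.TailCall(f"{pool}{i}", pool, "m", t, True, False)
                    for i, t in enumerate(tails)]
        # G is 6% of tailed reads in total, 2% in IP -> fold 3
        total = calls("t", ["G"] * 6 + ["A"] * 94)
        ip = calls("i", ["G"] * 2 + ["A"] * 98)
        folds = tailcall.tail_enrichment_by_sequence(total, ip)
        assert folds["G"] == pytest.approx(3.0)

    def test_identical_composition_gives_unit_folds(self):
        def calls(pool):
            return [tailcall.TailCall(f"{pool}{i}", pool, "m", t, True, False)
                    for i, t in enumerate(["A", "A", "T", "CC"])]
        folds = tailcall.tail_enrichment_by_sequence(calls("t"), calls("i"))
        assert all(f == pytest.approx(1.0) for f in folds.values())

    def test_length_bins(self):
        calls = [tailcall.TailCall(str(i), "total", "m", t, True, False)
                 for i, t in enumerate(["A", "AT", "ATC", "ATCG", "ATCGA"])]
        assert tailcall.tail_length_distribution(calls) == {"1": 1, "2": 1, "3": 1, "4+": 2}
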