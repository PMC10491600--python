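"""eQTL-to-SV breakpoint matching and the expression-association report."""
import pytest

import pharmsv as pv
from pharmsv import synthetic as syn
from pharmsv.eqtl_xref import read_eqtl_tsv


def eqtl(start, end, sv_type=pv.SVType.DEL, gene="G1", eqtl_id="e1",
         tissue="liver", beta=0.5, bh_p=0.001, chrom="chr1"):
    return pv.EQTLRecord(eqtl_id, chrom, start, end, sv_type, gene,
                         tissue, beta, bh_p)


def sv_rec(sv_id, start, end, sv_type=pv.SVType.DEL, chrom="chr1"):
    return pv.SVRecord(sv_id, chrom, start, end, sv_type)


class TestMatching:
    def test_identical_intervals_same_type(self):
        [m] = pv.match_eqtl([eqtl(1000, 2000)], [sv_rec("s1", 1000, 2000)])
        assert (m.sv_id, m.d_start, m.d_end) == ("s1", 0, 0)
        assert m.overlap == 1.0 and m.same_type and m.near and m.included

    def test_offset_150bp_is_not_near(self):
        [m] = pv.match_eqtl([eqtl(1000, 2000)], [sv_rec("s1", 1150, 2150)])
        assert not m.near
        assert m.d_start == 150 and m.d_end == 150

    def test_overlap_0995_included(self):
        # 10,000 bp intervals offset by 50 bp: reciprocal overlap 0.995
        [m] = pv.match_eqtl([eqtl(0, 10_000)], [sv_rec("s1", 50, 10_050)])
        assert m.overlap == pytest.approx(0.995)
        assert m.included and m.near

    def test_included_requires_strict_99_percent(self):
        # offset 100 on a 10 kb interval -> overlap 0.99 exactly, excluded
        [m] = pv.match_eqtl([eqtl(0, 10_000)], [sv_rec("s1", 100, 10_100)])
        assert m.overlap == pytest.approx(0.99)
        assert not m.included

    def test_reciprocal_overlap_rejects_nested_tiny_sv(self):
        # tiny SV inside a large eQTL interval: one-sided overlap 1.0 but
        # reciprocal overlap is small
        [m] = pv.match_eqtl([eqtl(0, 10_000)], [sv_rec("s1", 4000, 4100)])
        assert m.overlap < 0.99 and not m.included

    def test_different_type_flagged(self):
        [m] = pv.match_eqtl([eqtl(0, 1000, sv_type=pv.SVType.DUP)],
                            [sv_rec("s1", 0, 1000, sv_type=pv.SVType.DEL)])
        assert m.included and not m.same_type

    def test_no_same_chromosome_sv_gives_none(self):
        [m] = pv.match_eqtl([eqtl(0, 1000, chrom="chr9")],
                            [sv_rec("s1", 0, 1000)])
        assert m.sv_id is None

    def test_insertion_matched_by_point(self):
        [m] = pv.match_eqtl([eqtl(500, 501, sv_type=pv.SVType.INS)],
                            [sv_rec("i1", 520, 521, sv_type=pv.SVType.INS)])
        assert m.near and m.overlap == 1.0
        [far] = pv.match_eqtl([eqtl(500, 501, sv_type=pv.SVType.INS)],
                              [sv_rec("i1", 800, 801, sv_type=pv.SVType.INS)])
        assert not far.near and far.overlap == 0.0

    def test_self_match_sanity(self, filtered):
        """Matching a cohort against itself yields all-self perfect matches."""
        svs = [r for r in filtered if r.sv_type != pv.SVType.INS][:40]
        eqtls = [eqtl(r.start, r.end, sv_type=r.sv_type, eqtl_id=r.sv_id)
                 for r in svs]
        for m in pv.match_eqtl(eqtls, svs):
            assert m.sv_id == m.eqtl.eqtl_id
            assert m.overlap == 1.0 and m.included and m.same_type

    def test_raising_min_overlap_never_adds_matches(self):
        svs = [sv_rec(f"s{i}", i * 1000, i * 1000 + 500) for i in range(20)]
        eqtls = [eqtl(i * 1000 + j, i * 1000 + 500 + j, eqtl_id=f"e{i}")
                 for i, j in zip(range(20), [0, 2, 5, 10, 20] * 4)]
        counts = [
            sum(m.included for m in pv.match_eqtl(eqtls, svs, min_overlap=mo))
            for mo in (0.9, 0.95, 0.99, 0.999)
        ]
        assert counts == sorted(counts, reverse=True)


class TestGeneratorScenarios:
    def test_match_fraction_one_zero_offset_all_matched(self, filtered):
        svs = list(filtered)[:30]
        gen = syn.generate_eqtls(svs, match_fraction=1.0, seed=2)
        matches = pv.match_eqtl(read_eqtl_tsv(gen.eqtl_tsv), svs)
        assert all(m.near and m.included for m in matches)

    def test_match_fraction_zero_no_matches(self, filtered):
        svs = list(filtered)[:30]
        gen = syn.generate_eqtls(svs, match_fraction=0.0, seed=2)
        matches = pv.match_eqtl(read_eqtl_tsv(gen.eqtl_tsv), svs)
        assert not any(m.near and m.included for m in matches)

    def test_planted_match_share_recovered(self, filtered):
        svs = list(filtered)
        gen = syn.generate_eqtls(svs, match_fraction=0.23, seed=4)
        matches = pv.match_eqtl(read_eqtl_tsv(gen.eqtl_tsv), svs)
        truth = gen.truth.set_index("eqtl_id")["matched"]
        for m in matches:
            assert (m.near and m.included) == bool(truth[m.eqtl.eqtl_id])


class TestReport:
    def test_rows_cover_planted_matches(self, filtered, annotated,
                                        member_to_cluster, cohort):
        svs = list(filtered)
        gene_by_sv = {
            row.sv_id: row.gene_id
            for row in cohort.truth[cohort.truth.gene_id != ""].itertuples()
        }
        gen = syn.generate_eqtls(svs, match_fraction=0.4,
                                 gene_by_sv=gene_by_sv, seed=6)
        matches = pv.match_eqtl(read_eqtl_tsv(gen.eqtl_tsv), svs)
        rep = pv.eqtl_report(matches, annotated)
        matched_ids = {m.eqtl.eqtl_id for m in matches if m.included}
        truth_matched = set(gen.truth[gen.truth.matched].eqtl_id)
        assert matched_ids == truth_matched
        assert rep.n_matched.sum() == len(truth_matched)
        # coding labels agree with the annotation truth where present
        labelled = rep[rep.sv_function != ""]
        tr = cohort.truth.set_index("sv_id")
        for row in labelled.itertuples():
            if not row.gene.startswith("gene_of_"):
                member_ids = [
                    s for s, g in gene_by_sv.items() if g == row.gene
                ]
                assert len(member_ids) >= 1

    def test_unmatched_eqtls_excluded(self):
        rep = pv.eqtl_report(
            pv.match_eqtl([eqtl(0, 1000, chrom="chrX")], []), []
        )
        assert rep.empty

    def test_neg_log10_column_accepted(self):
        tsv = ("eqtl_id\tchrom\tstart\tend\tsv_type\tgene\ttissue\tbeta\tneg_log10_bh\n"
               "e1\tchr1\t0\t1000\tDEL\tG1\tliver\t-0.8\t3.0\n")
        [rec] = read_eqtl_tsv(tsv)
        assert rec.bh_p == pytest.approx(1e-3)
        assert rec.neg_log10_bh == pytest.approx(3.0)
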