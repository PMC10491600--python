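"""TFBS filtering, SV-peak overlap, and tissue co-expression support."""
import numpy as np
import pandas as pd
import pytest

import pharmsv as pv
from pharmsv.annotate import FunctionalClass
from pharmsv.regulatory import DEFAULT_TISSUES, read_tfbs_bed, write_tfbs_bed


def peak(tf="CTCF", start=100, end=200, score=500, obs=3, tot=1264, chrom="chr1"):
    return pv.TFBSPeak(tf, chrom, start, end, score, obs, tot)


def nc_sv(sv_id, start, end, gene_id="G1", sv_type=pv.SVType.DEL, af=0.1):
    return pv.AnnotatedSV(
        sv=pv.ClusteredSV(sv_id, "chr1", start, end, sv_type, (sv_id,)),
        gene_id=gene_id, panel_class="CYP", coding=False,
        functional_class=FunctionalClass.NONE, af=af,
    )


class TestFilterTFBS:
    @pytest.mark.parametrize("score,obs,kept", [
        (199, 3, False),   # below the score cutoff
        (950, 1, False),   # single-study observation
        (200, 2, True),    # both boundaries inclusive
        (1000, 1264, True),
    ])
    def test_score_and_study_boundaries(self, score, obs, kept):
        out = pv.filter_tfbs([peak(score=score, obs=obs)])
        assert (len(out) == 1) is kept

    def test_invalid_study_counts_rejected(self):
        with pytest.raises(ValueError):
            peak(obs=5, tot=3)


class TestOverlap:
    def test_del_covering_one_peak(self):
        pairs = pv.overlap_tfbs([nc_sv("s1", 50, 300)], [peak()])
        assert [(s.sv_id, tf) for s, tf in pairs] == [("s1", "CTCF")]

    def test_two_peaks_same_tf_deduplicated(self):
        pairs = pv.overlap_tfbs(
            [nc_sv("s1", 50, 600)], [peak(start=100, end=200), peak(start=400, end=500)]
        )
        assert len(pairs) == 1

    def test_coding_sv_rejected(self):
        a = nc_sv("s1", 50, 300)
        a.coding = True
        with pytest.raises(ValueError):
            pv.overlap_tfbs([a], [peak()])

    def test_insertion_overlaps_by_point(self):
        ins = nc_sv("i1", 150, 151, sv_type=pv.SVType.INS)
        assert len(pv.overlap_tfbs([ins], [peak()])) == 1
        ins_out = nc_sv("i2", 250, 251, sv_type=pv.SVType.INS)
        assert pv.overlap_tfbs([ins_out], [peak()]) == []

    def test_pairs_match_bruteforce_all_pairs(self):
        rng = np.random.default_rng(21)
        svs = [nc_sv(f"s{i}", int(p), int(p) + int(rng.integers(50, 400)))
               for i, p in enumerate(rng.integers(0, 20_000, size=60))]
        tfs = ["CTCF", "FOS", "RAD21", "HNF4A"]
        peaks = [peak(tf=tfs[i % 4], start=int(p), end=int(p) + 80)
                 for i, p in enumerate(rng.integers(0, 20_000, size=80))]
        got = sorted((s.sv_id, tf) for s, tf in pv.overlap_tfbs(svs, peaks))
        expected = sorted({
            (s.sv_id, p.tf_name)
            for s in svs for p in peaks
            if s.sv.start < p.end and p.start < s.sv.end
        })
        assert got == expected


class TestCoexpression:
    @staticmethod
    def expr(cells=()):
        tissues = list(DEFAULT_TISSUES)
        df = pd.DataFrame(0.0, index=["G1", "CTCF"], columns=tissues)
        for row, tissue, v in cells:
            df.loc[row, tissue] = v
        return df

    def test_shared_tissue_retained(self):
        pairs = [(nc_sv("s1", 0, 100), "CTCF")]
        hits = pv.coexpression_filter(
            pairs, self.expr([("G1", "liver", 8.0), ("CTCF", "liver", 3.0)])
        )
        assert len(hits) == 1
        assert hits[0].tissues_supported == ("liver",)
        assert hits[0].direction_hint == "ablation"

    def test_tf_below_threshold_everywhere_dropped(self):
        hits = pv.coexpression_filter(
            [(nc_sv("s1", 0, 100), "CTCF")],
            self.expr([("G1", "liver", 8.0), ("CTCF", "liver", 0.5)]),
        )
        assert hits == []

    def test_disjoint_tissues_dropped(self):
        hits = pv.coexpression_filter(
            [(nc_sv("s1", 0, 100), "CTCF")],
            self.expr([("G1", "brain", 8.0), ("CTCF", "liver", 8.0)]),
        )
        assert hits == []

    def test_absent_gene_or_tf_dropped_not_crash(self):
        pairs = [(nc_sv("s1", 0, 100, gene_id="GHOST"), "CTCF")]
        assert pv.coexpression_filter(pairs, self.expr()) == []

    def test_unknown_tissue_panel_errors(self):
        with pytest.raises(ValueError, match="absent"):
            pv.coexpression_filter([], self.expr(), tissues=("spleen",))


class TestPipelineMonotonicityAndRecovery:
    def test_stagewise_monotonic_shrinkage(
        self, annotated, regulatory_layers, gene_set
    ):
        noncoding = [a for a in annotated if not a.coding]
        kept = pv.filter_tfbs(regulatory_layers.peaks)
        assert len(kept) <= len(regulatory_layers.peaks)
        pairs = pv.overlap_tfbs(noncoding, kept)
        hits = pv.coexpression_filter(
            pairs, regulatory_layers.expression, gene_set=gene_set
        )
        n_tfs = len({p.tf_name for p in regulatory_layers.peaks})
        assert len(hits) <= len(pairs) <= len(noncoding) * n_tfs

    def test_planted_hits_recovered_exactly(
        self, annotated, regulatory_layers, gene_set, member_to_cluster
    ):
        noncoding = [a for a in annotated if not a.coding]
        pairs = pv.overlap_tfbs(noncoding, pv.filter_tfbs(regulatory_layers.peaks))
        hits = pv.coexpression_filter(
            pairs, regulatory_layers.expression, gene_set=gene_set
        )
        got = sorted((h.sv.sv_id, h.gene_id, h.tf_name) for h in hits)
        planted = sorted(
            (member_to_cluster[r.sv_id], r.gene_id, r.tf)
            for r in regulatory_layers.truth.itertuples()
        )
        assert got == planted
        # each planted hit supported in its designed tissue
        by_key = {(h.sv.sv_id, h.tf_name): h.tissues_supported for h in hits}
        for r in regulatory_layers.truth.itertuples():
            assert r.tissue in by_key[(member_to_cluster[r.sv_id], r.tf)]


def test_bed_roundtrip(regulatory_layers):
    back = read_tfbs_bed(regulatory_layers.tfbs_bed)
    assert back == regulatory_layers.peaks
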