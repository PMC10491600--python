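"""Coding status, LOF/IGD classification, rarity and per-kb density."""
import numpy as np
import pytest

import pharmsv as pv
from pharmsv.annotate import FunctionalClass
from conftest import make_gene


def sv(start, end, sv_type, spectrum=None, **kw):
    return pv.ClusteredSV(
        cluster_id="c", chrom="chr1", start=start, end=end,
        sv_type=sv_type, members=("c",), mcnv_spectrum=spectrum, **kw,
    )


class TestCodingStatus:
    def test_del_covering_exon_is_coding(self, toy_gene):
        assert pv.set_coding_status(sv(1900, 2400, pv.SVType.DEL), toy_gene)

    def test_fully_intronic_del_is_noncoding(self, toy_gene):
        assert not pv.set_coding_status(sv(1300, 1900, pv.SVType.DEL), toy_gene)

    def test_insertion_upstream_of_first_exon_is_noncoding(self, toy_gene):
        # insertion point 5 bp upstream of exon 1
        assert not pv.set_coding_status(sv(995, 996, pv.SVType.INS), toy_gene)

    def test_insertion_inside_exon_is_coding(self, toy_gene):
        assert pv.set_coding_status(sv(1100, 1101, pv.SVType.INS), toy_gene)


class TestClassification:
    def test_del_spanning_exons_is_lof(self, toy_gene):
        assert pv.classify_function(sv(900, 3600, pv.SVType.DEL), toy_gene) \
            == FunctionalClass.LOF

    def test_whole_gene_dup_is_igd(self, toy_gene):
        assert pv.classify_function(sv(900, 3600, pv.SVType.DUP), toy_gene) \
            == FunctionalClass.IGD

    def test_partial_dup_frameshift_is_lof(self, toy_gene):
        # covers 100 exonic bases of exon 1 (100 % 3 == 1)
        assert pv.classify_function(sv(900, 1100, pv.SVType.DUP), toy_gene) \
            == FunctionalClass.LOF

    def test_partial_dup_inframe_is_unknown(self, toy_gene):
        # covers 99 exonic bases (99 % 3 == 0)
        assert pv.classify_function(sv(900, 1099, pv.SVType.DUP), toy_gene) \
            == FunctionalClass.UNKNOWN

    def test_exonic_insertion_is_lof(self, toy_gene):
        assert pv.classify_function(sv(3100, 3101, pv.SVType.INS), toy_gene) \
            == FunctionalClass.LOF

    def test_inv_with_internal_breakpoint_is_lof(self, toy_gene):
        # start inside intron 1, spans exons 2-3
        assert pv.classify_function(sv(1500, 3600, pv.SVType.INV), toy_gene) \
            == FunctionalClass.LOF

    def test_whole_gene_inversion_is_unknown(self, toy_gene):
        # both breakpoints outside the span: transcription unit preserved
        assert pv.classify_function(sv(500, 4000, pv.SVType.INV), toy_gene) \
            == FunctionalClass.UNKNOWN

    def test_cpx_touching_exon_is_unknown(self, toy_gene):
        assert pv.classify_function(sv(1100, 1300, pv.SVType.CPX), toy_gene) \
            == FunctionalClass.UNKNOWN

    def test_noncoding_sv_gets_none(self, toy_gene):
        assert pv.classify_function(sv(1300, 1500, pv.SVType.DEL), toy_gene) \
            == FunctionalClass.NONE

    def test_mcnv_components_classified_separately(self, toy_gene):
        m = sv(900, 3600, pv.SVType.MCNV, spectrum={0: 0.2, 2: 0.5, 3: 0.3})
        assert pv.classify_function(m, toy_gene, "del") == FunctionalClass.LOF
        assert pv.classify_function(m, toy_gene, "dup") == FunctionalClass.IGD
        with pytest.raises(ValueError):
            pv.classify_function(m, toy_gene)

    def test_utr_only_overlap_is_unknown_with_cds(self):
        gene = pv.GeneModel(
            "G", "G", "chr1", "+", ((1000, 2000),), cds=((1200, 1800),),
        )
        # touches the 5' UTR part of the exon only
        assert pv.classify_function(sv(900, 1100, pv.SVType.DEL), gene) \
            == FunctionalClass.UNKNOWN
        assert pv.classify_function(sv(900, 1300, pv.SVType.DEL), gene) \
            == FunctionalClass.LOF


class TestRarity:
    @pytest.mark.parametrize("af,expected", [
        (0.010, "common"),
        (0.0099, "rare"),
        (0.845, "common"),  # high-frequency deletions count as common
        (0.0, "rare"),
    ])
    def test_boundary(self, af, expected):
        assert pv.rarity_class(af) == expected

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            pv.rarity_class(1.5)


class TestEndToEndRecovery:
    def test_planted_classes_recovered_exactly(
        self, cohort, clusters, annotated, member_to_cluster
    ):
        """Confusion matrix of planted vs recovered classes is diagonal."""
        by_key = {(a.sv_id, a.gene_id, a.component or ""): a for a in annotated}
        truth = cohort.truth[cohort.truth.gene_id != ""]
        assert len(truth) > 30
        for row in truth.itertuples():
            cid = member_to_cluster[row.sv_id]
            a = by_key[(cid, row.gene_id, row.component)]
            assert a.functional_class.value == row.functional_class, row.kind
            assert a.coding == row.coding, row.kind

    def test_every_annotation_has_exactly_one_class(self, annotated):
        counts = {c: 0 for c in FunctionalClass}
        for a in annotated:
            counts[a.functional_class] += 1
        assert sum(counts.values()) == len(annotated)


class TestDensity:
    def test_per_kb_normalization(self):
        gs = pv.GeneSet()
        gs.add(make_gene([(0, 10_000)], gene_id="G10", panel_class="CYP"))
        svs = [
            pv.AnnotatedSV(
                sv=sv(100 * i, 100 * i + 60, pv.SVType.DEL), gene_id="G10",
                panel_class="CYP", coding=False,
                functional_class=FunctionalClass.NONE, af=0.001,
            )
            for i in range(5)
        ]
        for i, a in enumerate(svs):
            a.sv.cluster_id = f"c{i}"
        out = pv.density_table(svs, gs)
        row = out.per_gene.iloc[0]
        assert row.n_sv == 5 and row.sv_per_kb == pytest.approx(0.5)

    @staticmethod
    def _dense_geneset(count_fn):
        """100 genes (50 ADME, 50 target); count_fn(i, is_adme) -> SV count."""
        gs = pv.GeneSet()
        svs = []
        pos = 0
        for i in range(100):
            cls = "CYP" if i < 50 else "ion_channel"
            length = 10_000
            gs.add(make_gene([(pos, pos + length)], gene_id=f"g{i}", panel_class=cls))
            n = count_fn(i, i < 50)
            for j in range(n):
                a = pv.AnnotatedSV(
                    sv=pv.ClusteredSV(f"g{i}_s{j}", "chr1", pos, pos + 60,
                                      pv.SVType.DEL, (f"g{i}_s{j}",)),
                    gene_id=f"g{i}", panel_class=cls, coding=False,
                    functional_class=FunctionalClass.NONE, af=0.001,
                )
                svs.append(a)
            pos += length + 1000
        return gs, svs

    def test_identical_class_distributions_give_null_pvalue(self):
        gs, svs = self._dense_geneset(lambda i, adme: 1 + (i % 10))
        out = pv.density_table(svs, gs, compare=[("ADME", "target")])
        assert out.comparisons.iloc[0].p_value > 0.5

    def test_planted_twofold_density_shift_is_detected(self):
        rng = np.random.default_rng(6)
        gs, svs = self._dense_geneset(
            lambda i, adme: int(rng.poisson(10 if adme else 5))
        )
        out = pv.density_table(svs, gs, compare=[("ADME", "target")])
        assert out.comparisons.iloc[0].p_value < 0.01

    def test_empty_group_comparison_skipped_with_warning(self, toy_gene):
        gs = pv.GeneSet()
        gs.add(toy_gene)
        with pytest.warns(UserWarning, match="empty group"):
            out = pv.density_table([], gs, compare=[("ADME", "olfactory")])
        assert out.comparisons.empty
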