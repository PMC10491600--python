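"""SV table parsing, record-level filters and MCNV decomposition."""
import io

import pytest
from hypothesis import given, settings, strategies as st

import pharmsv as pv
from pharmsv.sv_ingest import MIN_SV_LENGTH
from pharmsv.synthetic import write_sv_vcf
from pharmsv import synthetic as syn


def test_tsv_mcnv_spectrum_parsed():
    tsv = (
        "sv_id\tchrom\tstart\tend\tsv_type\tfilter\tlength\taf\tmcnv_spectrum\n"
        "m1\tchr1\t100\t1100\tMCNV\tMULTIALLELIC\t1000\t0.2\t0:0.05,1:0.10,2:0.80,3:0.05\n"
    )
    table = pv.read_sv_table(tsv)
    rec = table.records[0]
    assert rec.sv_type == pv.SVType.MCNV
    assert rec.mcnv_spectrum == {0: 0.05, 1: 0.10, 2: 0.80, 3: 0.05}


def test_tsv_missing_population_frequency_is_absent_not_zero():
    tsv = (
        "sv_id\tchrom\tstart\tend\tsv_type\tfilter\tlength\taf\taf_afr\taf_eur\n"
        "d1\tchr1\t100\t400\tDEL\tPASS\t300\t0.01\t0.02\t\n"
    )
    rec = pv.read_sv_table(tsv).records[0]
    assert rec.af_by_pop == {"AFR": 0.02}
    assert "EUR" not in rec.af_by_pop


def test_unknown_sv_type_flagged_not_crash():
    tsv = (
        "sv_id\tchrom\tstart\tend\tsv_type\tfilter\tlength\taf\n"
        "x1\tchr1\t100\t400\tWIBBLE\tPASS\t300\t0.01\n"
        "x2\tchr1\t500\t900\tDEL\tPASS\t400\t0.01\n"
    )
    table = pv.read_sv_table(tsv)
    assert len(table.records) == 1
    assert table.flagged[0]["sv_id"] == "x1"
    assert table.conserved()


def test_negative_length_errors():
    with pytest.raises(ValueError, match="negative length"):
        pv.SVRecord("b", "chr1", 100, 400, pv.SVType.DEL, length_bp=-5)


def test_vcf_roundtrip_against_generator_truth(gene_set, tmp_path):
    cohort = syn.generate_sv_cohort(gene_set, seed=3)
    path = str(tmp_path / "cohort.vcf")
    write_sv_vcf(cohort.table, path)
    back = pv.read_sv_table(path, dialect="vcf")
    assert len(back) == len(cohort.table)
    for orig, rec in zip(cohort.table, back):
        assert (rec.sv_id, rec.chrom, rec.start, rec.end) == (
            orig.sv_id, orig.chrom, orig.start, orig.end
        )
        assert rec.sv_type == orig.sv_type
        assert rec.filters == orig.filters
        assert rec.length_bp == orig.length_bp
        assert rec.af_global == pytest.approx(orig.af_global, abs=5e-7)
        assert set(rec.af_by_pop) == set(orig.af_by_pop)
        if orig.mcnv_spectrum:
            assert rec.mcnv_spectrum.keys() == orig.mcnv_spectrum.keys()


def test_tsv_roundtrip_against_generator_truth(gene_set):
    cohort = syn.generate_sv_cohort(gene_set, seed=5)
    back = pv.read_sv_table(cohort.sv_tsv)
    assert len(back) == len(cohort.table)
    for orig, rec in zip(cohort.table, back):
        assert rec.sv_id == orig.sv_id
        assert (rec.start, rec.end, rec.sv_type, rec.filters) == (
            orig.start, orig.end, orig.sv_type, orig.filters
        )
        assert rec.singleton == orig.singleton


@pytest.mark.parametrize(
    "filters,sv_type,kept",
    [
        ({"PASS"}, pv.SVType.DEL, True),
        ({"LOW_CALL_RATE"}, pv.SVType.DEL, False),
        ({"MULTIALLELIC"}, pv.SVType.MCNV, True),
        ({"PASS", "MULTIALLELIC"}, pv.SVType.DUP, True),
        ({"PASS"}, pv.SVType.CTX, False),
        ({"PASS"}, pv.SVType.BND_UNRESOLVED, False),
    ],
)
def test_record_level_filters(filters, sv_type, kept):
    spectrum = {0: 0.1, 2: 0.9} if sv_type == pv.SVType.MCNV else None
    rec = pv.SVRecord("r", "chr1", 1000, 2000, sv_type,
                      filters=frozenset(filters), mcnv_spectrum=spectrum)
    table = pv.CohortSVTable(records=[rec], n_input=1)
    out = pv.filter_sv_records(table)
    assert (len(out) == 1) is kept
    assert out.conserved()


def test_short_record_removed():
    rec = pv.SVRecord("r", "chr1", 100, 130, pv.SVType.DEL)
    out = pv.filter_sv_records(pv.CohortSVTable(records=[rec], n_input=1))
    assert len(out) == 0
    assert out.removed_by_reason == {"too_short": 1}
    assert MIN_SV_LENGTH == 50


def test_filtering_is_idempotent_and_conserves_counts(cohort):
    once = pv.filter_sv_records(cohort.table)
    twice = pv.filter_sv_records(once)
    assert [r.sv_id for r in twice] == [r.sv_id for r in once]
    assert twice.removed_by_reason == once.removed_by_reason
    assert once.conserved()
    n_removed_truth = (cohort.truth.functional_class == "REMOVED").sum()
    assert len(cohort.table) - len(once) == n_removed_truth


# ---------------------------------------------------------------------------
# MCNV decomposition


def test_decompose_high_frequency_deletion_spectrum():
    rec = pv.SVRecord("g", "chr1", 0, 19000, pv.SVType.MCNV,
                      mcnv_spectrum={0: 0.845, 2: 0.155})
    assert pv.decompose_mcnv(rec) == (0.845, 0.0)


def test_decompose_reference_only_spectrum():
    rec = pv.SVRecord("r", "chr1", 0, 1000, pv.SVType.MCNV,
                      mcnv_spectrum={2: 1.0})
    assert pv.decompose_mcnv(rec) == (0.0, 0.0)


def test_decompose_requires_spectrum():
    rec = pv.SVRecord("d", "chr1", 0, 1000, pv.SVType.DEL)
    with pytest.raises(ValueError):
        pv.decompose_mcnv(rec)


@given(
    st.dictionaries(
        st.integers(min_value=0, max_value=6),
        st.floats(min_value=0.001, max_value=1.0),
        min_size=1, max_size=6,
    )
)
@settings(max_examples=200, deadline=None)
def test_decompose_conserves_spectrum_mass(raw):
    total = sum(raw.values())
    spectrum = {cn: f / total for cn, f in raw.items()}
    rec = pv.SVRecord("m", "chr1", 0, 1000, pv.SVType.MCNV,
                      mcnv_spectrum=spectrum)
    del_af, dup_af = pv.decompose_mcnv(rec)
    ref = spectrum.get(2, 0.0)
    assert del_af + dup_af + ref == pytest.approx(1.0, abs=1e-9)
    assert 0.0 <= del_af <= 1.0 and 0.0 <= dup_af <= 1.0
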