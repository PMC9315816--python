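"""Domain-type invariants and file-format round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvcircuits import io as cio
from cnvcircuits.core import (
    AnnotationTable,
    CircuitMap,
    ExpressionBundle,
    GeneAnnotation,
    GeneSetCollection,
    GenomicInterval,
    ParseError,
    PipelineConfig,
    PPIEdge,
    SubjectRecord,
    ValidationError,
)


# ---------------------------------------------------------------------------
# Type invariants (each declared invariant has a negative test)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(chrom="chr1", start=100, end=100),   # empty
        dict(chrom="chr1", start=200, end=100),   # inverted
        dict(chrom="chr1", start=-5, end=100),    # negative
        dict(chrom="", start=0, end=100),         # unnamed chromosome
    ],
)
def test_interval_rejects_invalid(kwargs):
    with pytest.raises(ValidationError):
        GenomicInterval(**kwargs)


def test_interval_overlap_bp():
    a = GenomicInterval("chr1", 100, 200)
    assert a.overlap_bp(GenomicInterval("chr1", 150, 300)) == 50
    assert a.overlap_bp(GenomicInterval("chr1", 200, 300)) == 0
    assert a.overlap_bp(GenomicInterval("chr2", 100, 200)) == 0


def test_annotation_rejects_duplicate_symbols_case_insensitively():
    iv = GenomicInterval("chr1", 0, 10)
    with pytest.raises(ValidationError):
        AnnotationTable([GeneAnnotation("abc", iv), GeneAnnotation("ABC", iv)])


def test_gene_set_collection_invariants():
    with pytest.raises(ValidationError):
        GeneSetCollection(sets={"P1": frozenset()})
    with pytest.raises(ValidationError):
        GeneSetCollection(sets={"P1": frozenset({"A", "B"})}, background=frozenset({"A"}))
    col = GeneSetCollection(sets={"P1": frozenset({"a", "B"})})
    assert col.sets["P1"] == {"A", "B"}  # canonicalised


def test_ppi_edge_invariants():
    with pytest.raises(ValidationError):
        PPIEdge("A", "a", 0.5)  # self-edge, case-insensitive
    with pytest.raises(ValidationError):
        PPIEdge("A", "B", 1.5)
    assert PPIEdge("A", "B", 0.0).confidence == 0.0


def test_subject_record_invariants():
    iv = GenomicInterval("chr1", 0, 10)
    with pytest.raises(ValidationError):
        SubjectRecord("s1", "normal", cnv_intervals=[iv])
    with pytest.raises(ValidationError):
        SubjectRecord("s2", "cnv", cnv_intervals=[])
    with pytest.raises(ValidationError):
        SubjectRecord("s3", "normal", pcq={"PCQ1": 9})
    with pytest.raises(ValidationError):
        SubjectRecord("s4", "weird")


def test_circuit_map_membership_is_case_insensitive():
    cmap = CircuitMap(circuits={"C1": frozenset({"STR", "ACC"})})
    assert cmap.circuits_for_region("str") == {"C1"}
    assert cmap.circuits_for_region("MD") == frozenset()
    with pytest.raises(ValidationError):
        CircuitMap(circuits={"C1": frozenset()})


def test_pipeline_config_defaults_match_study_settings():
    cfg = PipelineConfig()
    assert cfg.enrichment_alpha == 0.001
    assert cfg.ppi_min_confidence == 0.9
    assert cfg.coexpr_threshold == 0.7
    assert cfg.min_overlap_bp == 1
    with pytest.raises(ValidationError):
        PipelineConfig(enrichment_alpha=0.0)
    with pytest.raises(ValidationError):
        PipelineConfig(ppi_min_confidence=1.2)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def test_read_gmt_dedups_within_line(tmp_path):
    p = tmp_path / "x.gmt"
    p.write_text("P1\tdesc\tA\tB\tB\n")
    col = cio.read_gmt(p)
    assert col.sets == {"P1": frozenset({"A", "B"})}


def test_read_gmt_empty_file(tmp_path):
    p = tmp_path / "empty.gmt"
    p.write_text("")
    assert len(cio.read_gmt(p)) == 0


def test_read_gmt_malformed_line_names_line_number(tmp_path):
    p = tmp_path / "bad.gmt"
    p.write_text("P1\tdesc\tA\nP2only_two_fields\tdesc\n")
    with pytest.raises(ParseError, match="line 2"):
        cio.read_gmt(p)


def test_gmt_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    sets = {
        f"P{i}": frozenset(f"G{j}" for j in rng.choice(50, size=rng.integers(2, 9), replace=False))
        for i in range(10)
    }
    col = GeneSetCollection(sets=sets)
    path = tmp_path / "r.gmt"
    cio.write_gmt(col, path)
    back = cio.read_gmt(path)
    assert back.sets == col.sets


# ---------------------------------------------------------------------------
# Intervals and dialects
# ---------------------------------------------------------------------------

def test_bed_dialect_is_identity(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\tG1\n")
    [(name, iv)] = cio.read_intervals(p, dialect="bed")
    assert (name, iv.chrom, iv.start, iv.end) == ("G1", "chr1", 100, 200)


def test_one_based_inclusive_conversion(tmp_path):
    p = tmp_path / "a.tsv"
    p.write_text("chr1\t101\t200\tG1\n")
    [(_, iv)] = cio.read_intervals(p, dialect="one_based_inclusive")
    assert (iv.start, iv.end) == (100, 200)


def test_inverted_interval_after_conversion_rejected(tmp_path):
    p = tmp_path / "a.tsv"
    p.write_text("chr1\t201\t200\tG1\n")
    with pytest.raises(ValidationError):
        cio.read_intervals(p, dialect="one_based_inclusive")


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["chr1", "chr2", "chrX"]),
            st.integers(min_value=0, max_value=10**7),
            st.integers(min_value=1, max_value=10**5),
        ),
        min_size=1,
        max_size=30,
    ),
    st.sampled_from(["bed", "one_based_inclusive"]),
)
def test_interval_round_trip_both_dialects(tmp_path_factory, raw, dialect):
    """write_intervals then read_intervals is the identity in either dialect."""
    records = [
        (f"G{i}", GenomicInterval(chrom, start, start + length))
        for i, (chrom, start, length) in enumerate(raw)
    ]
    path = tmp_path_factory.mktemp("ivs") / "r.tsv"
    cio.write_intervals(records, path, dialect=dialect)
    back = cio.read_intervals(path, dialect=dialect)
    assert back == records


# ---------------------------------------------------------------------------
# Expression bundle
# ---------------------------------------------------------------------------

def _tiny_frames():
    matrix = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        index=["G1", "G2"],
        columns=["s1", "s2", "s3"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "region_code": ["ACC", "STR", "ACC"],
            "age_value": [8.0, 20.0, 100.0],
            "age_unit": ["pcw", "pcw", "postnatal_days"],
        }
    ).set_index("sample_id")
    return matrix, meta


def test_bundle_shape_and_profile():
    matrix, meta = _tiny_frames()
    b = ExpressionBundle(matrix, meta)
    assert (b.n_genes, b.n_samples) == (2, 3)
    assert list(b.profile("g1")) == [1.0, 2.0, 3.0]  # case-insensitive lookup


def test_bundle_rejects_id_mismatch_naming_the_sample(tmp_path):
    matrix, meta = _tiny_frames()
    cio_matrix = tmp_path / "m.tsv"
    cio_meta = tmp_path / "meta.tsv"
    matrix.to_csv(cio_matrix, sep="\t", index_label="gene")
    meta.drop(index="s2").reset_index().to_csv(cio_meta, sep="\t", index=False)
    with pytest.raises(ValidationError, match="s2"):
        cio.read_expression_bundle(cio_matrix, cio_meta)


@pytest.mark.parametrize(
    "mutate",
    [
        lambda m, t: m.__setitem__("s1", [-1.0, 4.0]),            # negative value
        lambda m, t: t.__setitem__("age_value", [0.0, 20.0, 1.0]),  # bad age
        lambda m, t: t.__setitem__("region_code", ["ACC", "??", "ACC"]),  # bad region
        lambda m, t: t.__setitem__("age_unit", ["pcw", "weeks", "pcw"]),  # bad unit
    ],
)
def test_bundle_rejects_invalid_values(mutate):
    matrix, meta = _tiny_frames()
    mutate(matrix, meta)
    with pytest.raises(ValidationError):
        ExpressionBundle(matrix, meta)


def test_expression_bundle_round_trip(tmp_path, universe):
    """A generated bundle survives write/read with identical values."""
    mp, tp = tmp_path / "m.tsv", tmp_path / "meta.tsv"
    cio.write_expression_bundle(universe.bundle, mp, tp)
    back = cio.read_expression_bundle(mp, tp)
    assert list(back.matrix.columns) == list(universe.bundle.matrix.columns)
    assert np.allclose(back.matrix.to_numpy(), universe.bundle.matrix.to_numpy(), atol=1e-9)
    assert list(back.sample_meta["region_code"]) == list(
        universe.bundle.sample_meta["region_code"]
    )


# ---------------------------------------------------------------------------
# PPI edges, circuit maps, subjects, gene lists
# ---------------------------------------------------------------------------

def test_ppi_string_scores_divided_by_1000(tmp_path):
    p = tmp_path / "e.tsv"
    p.write_text("A\tB\t900\nC\tD\t150\n")
    edges = cio.read_ppi_edges(p)
    assert [e.confidence for e in edges] == [0.9, 0.15]


def test_ppi_fractional_scores_kept(tmp_path):
    p = tmp_path / "e.tsv"
    p.write_text("A\tB\t0.9\nC\tD\t0.15\n")
    assert [e.confidence for e in cio.read_ppi_edges(p)] == [0.9, 0.15]


def test_ppi_round_trip(tmp_path, universe):
    p = tmp_path / "edges.tsv"
    cio.write_ppi_edges(universe.edges, p)
    back = cio.read_ppi_edges(p)
    assert len(back) == len(universe.edges)
    for a, b in zip(back, universe.edges):
        assert (a.gene_a, a.gene_b) == (b.gene_a, b.gene_b)
        assert a.confidence == pytest.approx(b.confidence, abs=1e-6)


def test_circuit_map_yaml_round_trip(tmp_path, universe):
    p = tmp_path / "c.yaml"
    cio.write_circuit_map(universe.circuit_map, p)
    back = cio.read_circuit_map(p)
    assert {k: set(v) for k, v in back.circuits.items()} == {
        k: set(v) for k, v in universe.circuit_map.circuits.items()
    }


def test_subjects_round_trip(tmp_path, cohort):
    p = tmp_path / "subjects.tsv"
    cio.write_subjects(cohort, p)
    back = cio.read_subjects(p)
    assert len(back) == len(cohort)
    for a, b in zip(back, cohort):
        assert a.subject_id == b.subject_id
        assert a.microarray_status == b.microarray_status
        assert a.cnv_intervals == b.cnv_intervals
        assert a.pcq == b.pcq
        assert set(a.vineland) == set(b.vineland)
        for k in a.vineland:
            assert a.vineland[k] == pytest.approx(b.vineland[k], abs=1e-6)


def test_gene_list_round_trip(tmp_path):
    p = tmp_path / "g.txt"
    cio.write_gene_list({"B", "A", "C"}, p)
    assert cio.read_gene_list(p) == {"A", "B", "C"}
    assert p.read_text() == "A\nB\nC\n"  # sorted, deterministic
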