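"""Circuit assignment, grouping, group comparisons and the scan."""

import numpy as np
import pytest
from scipy import stats

from cnvcircuits.association import (
    INTER_GROUP,
    assign_circuits,
    circuit_gene_lists,
    compare_groups,
    group_subjects,
    percent_change,
    percent_change_magnitude,
    run_association_scan,
    welch_from_summary,
)
from cnvcircuits.core import (
    AnnotationTable,
    CircuitMap,
    Epoch,
    GeneAnnotation,
    GenomicInterval,
    SubjectRecord,
    ValidationError,
    default_circuit_map,
)
from cnvcircuits.development import GeneSite


def _site(gene, region, epoch=Epoch.TRIMESTER1, expr=10.0):
    return GeneSite(gene=gene, region=region, epoch=epoch, mean_expression=expr)


# ---------------------------------------------------------------------------
# assign_circuits
# ---------------------------------------------------------------------------

def test_striatal_gene_joins_exactly_the_three_printed_circuits():
    cmap = default_circuit_map()
    [a] = assign_circuits([_site("G1", "STR")], cmap)
    assert a.circuits == {"Positive Valence", "Cognitive", "Social Processes"}


def test_unknown_region_gets_empty_assignment():
    cmap = default_circuit_map()
    [a] = assign_circuits([_site("G1", "CEREBELLUM")], cmap)
    assert a.circuits == frozenset()


def test_assignment_matches_bruteforce_membership_scan():
    rng = np.random.default_rng(13)
    regions = ["ACC", "STR", "Amy", "MD", "V1C", "IPC", "DLPFC", "Ocx"]
    for _ in range(200):
        n_circ = int(rng.integers(1, 6))
        cmap = CircuitMap(
            circuits={
                f"C{i}": frozenset(
                    rng.choice(regions, size=int(rng.integers(1, 5)), replace=False)
                )
                for i in range(n_circ)
            }
        )
        sites = [
            _site(f"G{j}", regions[int(rng.integers(len(regions)))])
            for j in range(int(rng.integers(1, 8)))
        ]
        out = assign_circuits(sites, cmap)
        for site, a in zip(sites, out):
            expected = {
                name
                for name, members in cmap.circuits.items()
                if site.region.upper() in {m.upper() for m in members}
            }
            assert a.circuits == expected and a.via_region == site.region


# ---------------------------------------------------------------------------
# group_subjects
# ---------------------------------------------------------------------------

def _annotation():
    return AnnotationTable(
        [
            GeneAnnotation("GA", GenomicInterval("chr1", 0, 100)),
            GeneAnnotation("GB", GenomicInterval("chr1", 200, 300)),
            GeneAnnotation("GC", GenomicInterval("chr2", 0, 100)),
        ]
    )


def test_grouping_splits_normals_and_circuit_carriers():
    ann = _annotation()
    subjects = [
        SubjectRecord("n1", "normal"),
        SubjectRecord("c1", "cnv", [GenomicInterval("chr1", 50, 250)]),   # GA+GB
        SubjectRecord("c2", "cnv", [GenomicInterval("chr2", 10, 20)]),    # GC only
    ]
    g1, g2 = group_subjects(subjects, {"GA"}, ann)
    assert [s.subject_id for s in g1] == ["n1"]
    assert [s.subject_id for s in g2] == ["c1"]  # c2 carries no circuit gene


def test_no_circuit_overlap_gives_empty_group2():
    ann = _annotation()
    subjects = [
        SubjectRecord("n1", "normal"),
        SubjectRecord("c1", "cnv", [GenomicInterval("chr2", 10, 20)]),
    ]
    _, g2 = group_subjects(subjects, {"GA", "GB"}, ann)
    assert g2 == []


def test_grouping_matches_bruteforce_overlap_scan(universe, cohort):
    from cnvcircuits.cnvmap import map_cnv_to_genes

    circuit_genes = {g.upper() for g in universe.causal_genes}
    g1, g2 = group_subjects(cohort, circuit_genes, universe.annotation)
    expected_g2 = []
    for s in cohort:
        if s.microarray_status != "cnv":
            continue
        hit = set()
        for cnv in s.cnv_intervals:
            hit |= map_cnv_to_genes(cnv, universe.annotation)
        if hit & circuit_genes:
            expected_g2.append(s.subject_id)
    assert [s.subject_id for s in g2] == expected_g2
    assert all(s.microarray_status == "normal" for s in g1)


def test_planted_cohort_group2_equals_designed_carriers(design, universe, cohort):
    """Group 2 for the causal gene list is exactly the designed carrier set."""
    circuit_genes = {g.upper() for g in universe.causal_genes}
    _, g2 = group_subjects(cohort, circuit_genes, universe.annotation)
    assert len(g2) == round(design.carrier_fraction * design.n_cnv)


# ---------------------------------------------------------------------------
# compare_groups / welch_from_summary
# ---------------------------------------------------------------------------

def test_identical_samples_give_t0_p1():
    r = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0], method="welch")
    assert (r.t_statistic, r.p_value) == (0.0, 1.0)


def test_welch_hand_computed_example():
    # groups (1,2,3) vs (2,3,4): t = -1/sqrt(2/3), Satterthwaite df = 4
    r = compare_groups([1, 2, 3], [2, 3, 4], method="welch")
    assert r.t_statistic == pytest.approx(-1.224744871, abs=1e-6)
    assert r.df == pytest.approx(4.0, abs=1e-9)
    assert r.p_value == pytest.approx(0.2878641, abs=1e-4)


def test_zero_variance_unequal_means_guarded():
    r = compare_groups([1.0, 1.0], [2.0, 2.0], method="welch")
    assert r.p_value > 0.0  # smallest positive representable, not zero
    assert r.p_value < 1e-300


def test_too_small_groups_rejected():
    with pytest.raises(ValidationError):
        compare_groups([1.0], [2.0, 3.0])


def test_welch_equals_pooled_for_balanced_equal_variance():
    rng = np.random.default_rng(4)
    x = rng.normal(size=12)
    y = x + 0.3  # same variance exactly, equal n
    w = compare_groups(x, y, method="welch")
    p = compare_groups(x, y, method="pooled")
    assert w.t_statistic == pytest.approx(p.t_statistic, rel=1e-12)
    assert w.df == pytest.approx(p.df, rel=1e-12)
    assert w.p_value == pytest.approx(p.p_value, rel=1e-12)


def test_compare_groups_matches_permutation_test():
    """On small samples the t-test p agrees with an independent 10,000
    -permutation reference within Monte-Carlo error."""
    rng = np.random.default_rng(8)
    for _ in range(3):
        x = rng.normal(0.0, 1.0, 8)
        y = rng.normal(0.8, 1.0, 8)
        r = compare_groups(x, y, method="pooled")
        pooled = np.concatenate([x, y])
        obs = abs(np.mean(x) - np.mean(y))
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(np.mean(pooled[:8]) - np.mean(pooled[8:])) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm + 1e-6)
        assert abs(r.p_value - p_perm) < max(0.02, mc_err)


def test_welch_from_summary_equal_means():
    t, df, p = welch_from_summary(5.0, 0.3, 10, 5.0, 0.4, 12)
    assert (t, p) == (0.0, 1.0)


def test_welch_from_summary_published_selfstim_row():
    """The published whole-cohort self-stimulatory-behavior row
    (47: 2.79 +/- 0.158 vs 90: 2.39 +/- 0.107) gives |t| ~ 2.10 and
    p < 0.05, consistent with the printed p = 0.037."""
    t, df, p = welch_from_summary(2.79, 0.158, 47, 2.39, 0.107, 90)
    assert abs(t) == pytest.approx(2.10, abs=0.01)
    assert p < 0.05


def test_welch_from_summary_consistent_with_raw_compare():
    rng = np.random.default_rng(21)
    x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1.3, 40)
    r = compare_groups(x, y, method="welch")
    t, df, p = welch_from_summary(r.mean1, r.se1, r.n1, r.mean2, r.se2, r.n2)
    assert t == pytest.approx(r.t_statistic, rel=1e-9)
    assert df == pytest.approx(r.df, rel=1e-9)
    assert p == pytest.approx(r.p_value, rel=1e-9)


def test_mannwhitney_option_runs():
    r = compare_groups([1, 2, 3, 4], [3, 4, 5, 6], method="mannwhitney")
    assert 0 < r.p_value <= 1
    assert np.isnan(r.df)


# ---------------------------------------------------------------------------
# percent_change
# ---------------------------------------------------------------------------

def test_percent_change_published_mouse_numbers():
    # alpha-band EEG power: knockout 73 vs control 112 -> ~35% decrease
    assert percent_change(112, 73) == pytest.approx(-34.82, abs=0.01)
    assert percent_change_magnitude(112, 73) == 35
    # brain weights: 0.37 g vs 0.41 g -> ~10% decrease
    assert percent_change(0.41, 0.37) == pytest.approx(-9.76, abs=0.01)
    assert percent_change_magnitude(0.41, 0.37) == 10


def test_percent_change_trivia():
    assert percent_change(5.0, 5.0) == 0.0
    with pytest.raises(ValidationError):
        percent_change(0.0, 1.0)


# ---------------------------------------------------------------------------
# run_association_scan
# ---------------------------------------------------------------------------

def test_scan_row_count_bookkeeping(universe, cohort):
    from cnvcircuits.development import map_gene_set

    mapping = map_gene_set(universe.causal_genes, universe.bundle)
    assignments = assign_circuits(mapping.sites, universe.circuit_map)
    results = run_association_scan(
        cohort, assignments, universe.circuit_map, universe.annotation
    )
    items = sorted({i for s in cohort for i in s.pcq}) + sorted(
        {i for s in cohort for i in s.vineland}
    )
    nonempty = sum(1 for genes in circuit_gene_lists(assignments).values() if genes)
    assert len(results) == (nonempty + 1) * len(items)
    # deterministic ordering: inter-group first, then circuits alphabetical
    assert results[0].circuit == INTER_GROUP
    circuits_seen = [r.circuit for r in results]
    assert circuits_seen == sorted(
        circuits_seen, key=lambda c: (c != INTER_GROUP, c)
    )


def test_scan_invariant_to_subject_ordering(universe, cohort):
    from cnvcircuits.development import map_gene_set

    mapping = map_gene_set(universe.causal_genes, universe.bundle)
    assignments = assign_circuits(mapping.sites, universe.circuit_map)
    a = run_association_scan(cohort, assignments, universe.circuit_map, universe.annotation)
    b = run_association_scan(
        list(reversed(cohort)), assignments, universe.circuit_map, universe.annotation
    )
    assert [(r.circuit, r.behavior_item, r.p_value) for r in a] == [
        (r.circuit, r.behavior_item, r.p_value) for r in b
    ]


def test_scan_skips_when_no_carriers(universe):
    subjects = [
        SubjectRecord(f"n{i}", "normal", pcq={"PCQ1": 3}) for i in range(4)
    ]
    mapping_sites = [_site("G0001", "STR")]
    assignments = assign_circuits(mapping_sites, universe.circuit_map)
    results = run_association_scan(
        subjects, assignments, universe.circuit_map, universe.annotation
    )
    assert results == []  # no CNV subjects at all -> every contrast skipped


def test_planted_effect_detected_in_target_cell(design, universe, cohort):
    from cnvcircuits.development import map_gene_set

    mapping = map_gene_set(universe.causal_genes, universe.bundle)
    assignments = assign_circuits(mapping.sites, universe.circuit_map)
    results = run_association_scan(
        cohort, assignments, universe.circuit_map, universe.annotation
    )
    target = [
        r
        for r in results
        if r.circuit == design.target_circuit and r.behavior_item == design.target_item
    ]
    assert len(target) == 1
    assert target[0].p_value <= 0.05
    # carriers score higher on the shifted item (Group 2 mean above Group 1)
    assert target[0].mean2 > target[0].mean1
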