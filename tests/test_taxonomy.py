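"""taxonomy_rules: dereplication, assignment, and novelty decision grids."""

from itertools import product

import numpy as np
import pytest

from cultcov import (
    NoveltyEvidence,
    PreconditionError,
    TaxonCluster,
    assign_to_reference,
    call_genus_novelty,
    call_species_novelty,
    dereplicate_isolates,
    global_identity,
    remove_failed,
)
from cultcov.taxonomy import (
    INDETERMINATE,
    novelty_report,
    read_evidence_table,
    write_novelty_report,
)
from cultcov.synth import DivergenceSpec, mutate_sequence, random_dna
from helpers import with_mismatches
from oracles import connected_components_at_threshold


# ---------------------------------------------------------------- dereplication

def _planted_groups(rng, n_groups=3, per_group=4, length=250):
    seqs = []
    for g in range(n_groups):
        anc = random_dna(length, rng, f"anc{g}")
        for m in range(per_group):
            spec = DivergenceSpec(0.005, seed=100 * g + m)
            var, _ = mutate_sequence(anc, spec, out_id=f"g{g}_m{m}")
            seqs.append(var)
    return seqs


def test_dereplicate_identical_copies(rng):
    anc = random_dna(200, rng, "anc")
    copies = [with_mismatches(anc, [], f"c{i}") for i in range(5)]
    clusters = dereplicate_isolates(copies)
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == [f"c{i}" for i in range(5)]


def test_dereplicate_recovers_planted_groups(rng):
    seqs = _planted_groups(rng)
    clusters = dereplicate_isolates(seqs, threshold=0.98)
    got = [frozenset(c.member_ids) for c in clusters]
    expected = [
        frozenset(s.id for s in seqs if s.id.startswith(f"g{g}_")) for g in range(3)
    ]
    assert sorted(got, key=sorted) == sorted(
        [frozenset(e) for e in expected], key=sorted
    )


def test_dereplicate_agrees_with_linkage_oracle(rng):
    # at 0.5% within-group divergence the greedy partition coincides with
    # single-linkage connected components
    seqs = _planted_groups(rng, n_groups=2, per_group=3)
    clusters = dereplicate_isolates(seqs, threshold=0.98)
    oracle = connected_components_at_threshold(
        seqs, 0.98, lambda a, b: global_identity(a, b).identity
    )
    assert sorted(
        [frozenset(c.member_ids) for c in clusters], key=sorted
    ) == sorted([frozenset(g) for g in oracle], key=sorted)


def test_dereplicate_partitions_input(rng):
    seqs = _planted_groups(rng, n_groups=2, per_group=3)
    clusters = dereplicate_isolates(seqs)
    members = [m for c in clusters for m in c.member_ids]
    assert sorted(members) == sorted(s.id for s in seqs)
    for c in clusters:
        assert c.centroid_id in c.member_ids


def test_dereplicate_threshold_extremes(rng):
    seqs = [random_dna(100, rng, f"s{i}") for i in range(4)]
    assert len(dereplicate_isolates(seqs, threshold=0.0)) == 1
    assert len(dereplicate_isolates(seqs, threshold=1.01)) == 4
    assert dereplicate_isolates([]) == []


def test_remove_failed_bookkeeping():
    clusters = [
        TaxonCluster("t1", "a", ["a", "b", "c"]),
        TaxonCluster("t2", "d", ["d"]),
        TaxonCluster("t3", "e", ["e", "f"]),
    ]
    kept = remove_failed(clusters, {"a", "d"})
    assert [c.taxon_id for c in kept] == ["t1", "t3"]
    assert kept[0].centroid_id == "b"  # centroid lost -> first survivor
    assert kept[0].member_ids == ["b", "c"]
    assert kept[1].member_ids == ["e", "f"]
    total_before = sum(len(c.member_ids) for c in clusters)
    total_after = sum(len(c.member_ids) for c in kept)
    assert total_before - total_after == 2


# ---------------------------------------------------------------- assignment

def test_assignment_exact_and_strict_threshold(rng):
    ref = random_dna(100, rng, "ref1")
    exact = with_mismatches(ref, [], "iso_exact")
    at_threshold = with_mismatches(ref, [0, 50], "iso_98")  # exactly 0.98
    below = with_mismatches(ref, [0, 25, 50], "iso_97")
    res = assign_to_reference(exact, [ref])
    assert res.assigned and res.reference_id == "ref1" and res.identity == 1.0
    # identity == threshold is NOT assigned (strict >)
    res = assign_to_reference(at_threshold, [ref])
    assert res.identity == pytest.approx(0.98)
    assert not res.assigned
    assert res.best_reference_id == "ref1"
    res = assign_to_reference(below, [ref])
    assert not res.assigned


def test_assignment_picks_best_reference(rng):
    ref1 = random_dna(120, rng, "ref1")
    ref2 = with_mismatches(ref1, list(range(0, 120, 4)), "ref2")
    iso = with_mismatches(ref1, [3], "iso")
    res = assign_to_reference(iso, [ref2, ref1])
    assert res.reference_id == "ref1"


def test_assignment_empty_refdb():
    with pytest.raises(PreconditionError):
        assign_to_reference(random_dna(50, np.random.default_rng(0)), [])


# ---------------------------------------------------------------- species rules

@pytest.mark.parametrize(
    "ssu,ani,ddh,expected",
    [
        (97.5, 80.0, 30.0, True),           # all three pass
        (99.0, 97.0, 80.0, False),          # all three fail
        (98.0, 80.0, 30.0, False),          # ssu boundary is strict
        (97.5, 95.0, 30.0, False),          # ani boundary is strict
        (97.5, 80.0, 70.0, False),          # ddh boundary is strict
        (97.999, 94.999, 69.999, True),     # just inside all three
        (97.5, None, 30.0, INDETERMINATE),  # missing ani cannot confirm
        (97.5, 80.0, None, INDETERMINATE),  # missing ddh cannot confirm
        (97.5, None, None, INDETERMINATE),
        (99.0, None, None, False),          # ssu alone can refute
        (97.5, 96.0, None, False),          # defined failing value refutes
    ],
)
def test_species_novelty_grid(ssu, ani, ddh, expected):
    ev = NoveltyEvidence("iso", ssu_identity_best=ssu, ani=ani, ddh=ddh)
    assert call_species_novelty(ev) == expected


def test_species_novelty_never_true_on_missing_evidence():
    # INDETERMINATE is a string, not truthy True
    ev = NoveltyEvidence("iso", 90.0)
    out = call_species_novelty(ev)
    assert out is not True
    assert out == INDETERMINATE


def test_evidence_range_validation():
    with pytest.raises(PreconditionError):
        NoveltyEvidence("iso", 101.0)
    with pytest.raises(PreconditionError):
        NoveltyEvidence("iso", 97.0, ani=-3.0)


# ---------------------------------------------------------------- genus rules

def _genus_evidence(ssu, pocp, clade, marker, pheno):
    return NoveltyEvidence(
        "iso",
        ssu_identity_best=ssu,
        ani=80.0,
        ddh=30.0,
        pocp=pocp,
        separate_clade=clade,
        marker_gene_novel_genus=marker,
        phenotype_distinct=pheno,
    )


def test_genus_novelty_exhaustive_grid():
    """Enumerate every combination of the five criteria's states.

    The expected call is recomputed here by directly counting satisfied
    criteria (unknown never counts), independently of the rule engine.
    """
    ssu_states = [(94.0, True), (95.0, True), (96.0, False)]  # <= 95 inclusive
    pocp_states = [(45.0, True), (50.0, False), (None, False)]
    tri = [(True, True), (False, False), (None, False)]
    for (ssu, s_ok), (pv, p_ok), (cl, c_ok), (mk, m_ok), (ph, f_ok) in product(
        ssu_states, pocp_states, tri, tri, tri
    ):
        ev = _genus_evidence(ssu, pv, cl, mk, ph)
        expected_met = sum([s_ok, p_ok, c_ok, m_ok, f_ok])
        call = call_genus_novelty(ev)
        assert len(call.criteria_met) == expected_met, (ssu, pv, cl, mk, ph)
        assert call.is_new_genus == (expected_met >= 3)
        assert call.is_new_species


def test_genus_requires_novel_species():
    ev = NoveltyEvidence("iso", 99.0, ani=80.0, ddh=30.0)
    with pytest.raises(PreconditionError):
        call_genus_novelty(ev)
    # INDETERMINATE species also blocks the genus evaluation
    ev = NoveltyEvidence("iso", 94.0)
    with pytest.raises(PreconditionError):
        call_genus_novelty(ev)


# ---------------------------------------------------------------- report I/O

def test_evidence_table_and_report_roundtrip(tmp_path):
    src = tmp_path / "evidence.tsv"
    src.write_text(
        "isolate_id\tssu_identity_best\tani\tddh\tpocp\tseparate_clade\t"
        "marker_gene_novel_genus\tphenotype_distinct\n"
        "isoA\t94.0\t80.0\t30.0\t45.0\ttrue\ttrue\tNA\n"
        "isoB\t99.0\tNA\tNA\tNA\tNA\tNA\tNA\n"
        "isoC\t97.5\tNA\t30.0\tNA\tNA\tNA\tNA\n"
    )
    evidence = read_evidence_table(src)
    assert len(evidence) == 3
    assert evidence[0].pocp == 45.0
    assert evidence[0].phenotype_distinct is None
    report = novelty_report(evidence)
    by_id = {r["isolate_id"]: r for r in report}
    assert by_id["isoA"]["species_call"] == "new_species"
    assert by_id["isoA"]["genus_call"] == "new_genus"  # ssu+pocp+clade+marker = 4
    assert by_id["isoB"]["species_call"] == "known_species"
    assert by_id["isoC"]["species_call"] == INDETERMINATE
    assert by_id["isoC"]["genus_call"] == "not_evaluated"
    out = tmp_path / "report.tsv"
    write_novelty_report(report, out)
    assert out.read_text().count("\n") == 4  # header + 3 rows


def test_evidence_table_bad_header(tmp_path):
    src = tmp_path / "evidence.tsv"
    src.write_text("isolate\tssu\nisoA\t94\n")
    from cultcov import FormatError

    with pytest.raises(FormatError):
        read_evidence_table(src)
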