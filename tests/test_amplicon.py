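"""amplicon_coverage: read-weighted catalog coverage, Venn splits, annotation."""

import math

import numpy as np
import pytest

from cultcov import (
    CatalogEntry,
    PreconditionError,
    annotation_rate,
    otu_hits,
    read_coverage,
    venn_coverage,
)
from cultcov.amplicon import GENUS_LEVEL_THRESHOLD, SPECIES_LEVEL_THRESHOLD
from cultcov.synth import random_dna
from helpers import make_table, with_mismatches


def _entry(i, ssu):
    return CatalogEntry(f"sp{i}", f"G{i}", ssu)


@pytest.fixture
def planted(rng):
    """Catalog of 3 references; 5 OTUs with known hit status at 97%.

    o1: identical to ref1 (hit); o2: 1% diverged from ref2 (hit);
    o3: exactly 97% identical to ref3 (NOT a hit, strict >);
    o4, o5: random (no hit).
    """
    refs = [random_dna(100, rng, f"ref{i}") for i in (1, 2, 3)]
    catalog = [_entry(i + 1, r) for i, r in enumerate(refs)]
    otus = {
        "o1": with_mismatches(refs[0], [], "o1"),
        "o2": with_mismatches(refs[1], [7], "o2"),
        "o3": with_mismatches(refs[2], [5, 25, 45], "o3"),
        "o4": random_dna(100, rng, "o4"),
        "o5": random_dna(100, rng, "o5"),
    }
    return catalog, otus


def test_otu_hits_planted(planted):
    catalog, otus = planted
    counts = np.ones((5, 2), dtype=int)
    table = make_table(otus, counts)
    hits = otu_hits(table, catalog, SPECIES_LEVEL_THRESHOLD)
    assert hits == {"o1": True, "o2": True, "o3": False, "o4": False, "o5": False}
    # the 97%-identical OTU becomes a hit at the genus-level threshold
    hits95 = otu_hits(table, catalog, GENUS_LEVEL_THRESHOLD)
    assert hits95["o3"] is True


def test_otu_hits_requires_rep_seqs(planted):
    catalog, otus = planted
    table = make_table(otus, np.ones((5, 1), dtype=int))
    table.rep_seqs.pop("o4")
    with pytest.raises(PreconditionError):
        otu_hits(table, catalog)


def test_read_coverage_fractions_and_sem(planted):
    catalog, otus = planted
    # per-sample reads: hits (o1+o2) carry 10/100, 30/100, 50/100 reads
    counts = np.array(
        [
            [5, 10, 30],    # o1 (hit)
            [5, 20, 20],    # o2 (hit)
            [40, 30, 25],   # o3
            [30, 20, 15],   # o4
            [20, 20, 10],   # o5
        ]
    )
    table = make_table(otus, counts)
    results, summary = read_coverage(table, catalog)
    fracs = [r.coverage for r in results]
    assert fracs == pytest.approx([0.10, 0.30, 0.50])
    assert summary.mean == pytest.approx(0.30)
    expected_sem = np.std([0.1, 0.3, 0.5], ddof=1) / math.sqrt(3)
    assert summary.sem == pytest.approx(expected_sem)
    assert summary.n_samples == 3


def test_read_coverage_empty_sample_undefined(planted):
    catalog, otus = planted
    counts = np.zeros((5, 2), dtype=int)
    counts[0, 0] = 10  # sample 2 stays empty
    table = make_table(otus, counts)
    results, summary = read_coverage(table, catalog)
    assert results[1].coverage is None
    assert summary.n_samples == 1
    assert summary.mean == pytest.approx(1.0)


def test_venn_decomposition_planted(rng):
    refs_a = [random_dna(100, rng, f"a{i}") for i in range(2)]
    refs_b = [random_dna(100, rng, f"b{i}") for i in range(2)]
    shared_ref = random_dna(100, rng, "sh")
    cat_a = [_entry(1, refs_a[0]), _entry(2, refs_a[1]), _entry(3, shared_ref)]
    cat_b = [_entry(4, refs_b[0]), _entry(5, refs_b[1]), _entry(6, shared_ref)]
    otus = {
        "oa": with_mismatches(refs_a[0], [], "oa"),      # A only
        "ob": with_mismatches(refs_b[0], [3], "ob"),     # B only
        "osh": with_mismatches(shared_ref, [], "osh"),   # shared
        "onone": random_dna(100, rng, "onone"),          # neither
    }
    counts = np.array([[25], [2], [16], [57]])
    table = make_table(otus, counts)
    venn = venn_coverage(table, cat_a, cat_b)
    assert venn.a_only[0] == pytest.approx(0.25)
    assert venn.b_only[0] == pytest.approx(0.02)
    assert venn.shared[0] == pytest.approx(0.16)
    assert venn.neither[0] == pytest.approx(0.57)
    assert venn.union[0] == pytest.approx(0.43)
    # partition invariants
    assert venn.a_only[0] + venn.b_only[0] + venn.shared[0] + venn.neither[0] == pytest.approx(1.0)
    summary = venn.summary()
    assert summary["union"].mean == pytest.approx(0.43)


def test_venn_identical_catalogs_puts_everything_shared(planted):
    catalog, otus = planted
    table = make_table(otus, np.ones((5, 1), dtype=int))
    venn = venn_coverage(table, catalog, catalog)
    assert venn.a_only[0] == 0.0
    assert venn.b_only[0] == 0.0
    assert venn.shared[0] == pytest.approx(2 / 5)  # o1 and o2 hit


def test_venn_empty_second_catalog(planted):
    catalog, otus = planted
    table = make_table(otus, np.ones((5, 1), dtype=int))
    venn = venn_coverage(table, catalog, [])
    assert venn.b_only[0] == 0.0
    assert venn.shared[0] == 0.0
    assert venn.a_only[0] == pytest.approx(2 / 5)


def test_coverage_monotone_in_catalog(rng):
    refs = [random_dna(100, rng, f"r{i}") for i in range(6)]
    otus = {
        f"o{i}": with_mismatches(refs[i], [i], f"o{i}") for i in range(6)
    }
    counts = rng.integers(1, 50, size=(6, 4))
    table = make_table(otus, counts)
    small = [_entry(i, refs[i]) for i in range(3)]
    large = [_entry(i, refs[i]) for i in range(6)]
    _, sum_small = read_coverage(table, small)
    _, sum_large = read_coverage(table, large)
    assert sum_large.mean >= sum_small.mean


def test_coverage_order_invariance(planted):
    catalog, otus = planted
    counts = np.array([[5, 1], [7, 2], [11, 3], [13, 4], [17, 5]])
    table = make_table(otus, counts)
    _, fwd = read_coverage(table, catalog)
    perm_ids = list(reversed(list(otus)))
    table2 = make_table(
        {k: otus[k] for k in perm_ids},
        np.array([counts[list(otus).index(k)] for k in perm_ids]),
    )
    _, rev = read_coverage(table2, catalog)
    assert fwd.mean == pytest.approx(rev.mean)
    assert fwd.sem == pytest.approx(rev.sem)


# ---------------------------------------------------------------- annotation rate

def test_annotation_rate_gain_planted(rng):
    base_refs = [random_dna(100, rng, f"base{i}") for i in range(2)]
    extra_ref = random_dna(100, rng, "extra")
    otus = {
        "o1": with_mismatches(base_refs[0], [], "o1"),   # in base
        "o2": with_mismatches(extra_ref, [2], "o2"),     # only in augmentation
        "o3": random_dna(100, rng, "o3"),                # nowhere
    }
    counts = np.array([[50], [40], [10]])
    table = make_table(otus, counts)
    rows, base, aug = annotation_rate(table, base_refs, [extra_ref])
    assert base.mean == pytest.approx(0.50)
    assert aug.mean == pytest.approx(0.90)
    assert rows[0].rate_base == pytest.approx(0.50)
    assert rows[0].rate_augmented == pytest.approx(0.90)
    assert rows[0].level == "species"


def test_annotation_rate_monotone_and_empty_augmentation(rng):
    refs = [random_dna(100, rng, f"r{i}") for i in range(3)]
    otus = {f"o{i}": with_mismatches(refs[i], [1], f"o{i}") for i in range(3)}
    otus["ox"] = random_dna(100, rng, "ox")
    counts = rng.integers(1, 30, size=(4, 3))
    table = make_table(otus, counts)
    rows, base, aug = annotation_rate(table, refs, [])
    assert base.mean == pytest.approx(aug.mean)
    rows, base, aug = annotation_rate(table, refs[:1], refs[1:], level="genus")
    assert aug.mean >= base.mean
    for r in rows:
        assert r.rate_augmented >= r.rate_base


def test_annotation_rate_unknown_level(planted):
    catalog, otus = planted
    table = make_table(otus, np.ones((5, 1), dtype=int))
    with pytest.raises(PreconditionError):
        annotation_rate(table, [catalog[0].ssu], [], level="phylum")
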