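"""Shared builders for the test suite."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from cultcov import (
    Alphabet,
    Catalog,
    CatalogEntry,
    OtuTable,
    SequenceRecord,
)
from cultcov.synth import random_dna

BASES = "ACGT"


def dna(seq_id: str, residues: str) -> SequenceRecord:
    return SequenceRecord(seq_id, residues, alphabet=Alphabet.DNA)


def prot(seq_id: str, residues: str) -> SequenceRecord:
    return SequenceRecord(seq_id, residues, alphabet=Alphabet.PROTEIN)


def other_base(base: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


def with_mismatches(rec: SequenceRecord, positions: Sequence[int], new_id: str) -> SequenceRecord:
    """Copy of a DNA record with substitutions at exactly the given positions."""
    chars = list(rec.residues)
    for p in positions:
        chars[p] = other_base(chars[p])
    return dna(new_id, "".join(chars))


def make_entry(
    species_id: str,
    genus: str,
    ssu: Optional[SequenceRecord] = None,
    rng: Optional[np.random.Generator] = None,
    length: int = 60,
) -> CatalogEntry:
    if ssu is None:
        rng = rng if rng is not None else np.random.default_rng(abs(hash(species_id)) % 2**31)
        ssu = random_dna(length, rng, seq_id=f"{species_id}_ssu")
    return CatalogEntry(species_id=species_id, genus=genus, ssu=ssu)


def make_catalog(name: str, specs: Sequence[tuple]) -> Catalog:
    """Catalog from (species_id, genus[, ssu]) tuples."""
    entries = []
    for spec in specs:
        if len(spec) == 3:
            entries.append(make_entry(spec[0], spec[1], ssu=spec[2]))
        else:
            entries.append(make_entry(spec[0], spec[1]))
    return Catalog(name, entries)


def make_table(
    otu_seqs: Dict[str, SequenceRecord],
    counts: np.ndarray,
    sample_ids: Optional[List[str]] = None,
    genus_labels: Optional[Dict[str, str]] = None,
) -> OtuTable:
    otu_ids = list(otu_seqs)
    counts = np.asarray(counts)
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(counts.shape[1])]
    return OtuTable(otu_ids, sample_ids, counts, dict(otu_seqs), genus_labels)
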