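"""Readers, writers and container types for all external formats.

The toolkit exchanges data through plain-text formats only: FASTA
(nucleotide and protein), tab-separated OTU count tables, tab-separated
taxonomy maps, tab-separated catalog manifests, and one-KO-per-line
annotation lists.  Parsing is strict: malformed input raises a
:class:`~cultcov.errors.FormatError` subclass naming the offending record
or line rather than silently coercing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    CrossReferenceError,
    DuplicateIdError,
    FormatError,
    MissingFileError,
)

logger = logging.getLogger(__name__)

_DNA_CHARS = set("ACGTN")
# 20 standard residues plus ambiguity/extended codes and stop.
_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

_KO_PATTERN = re.compile(r"^K\d+$")


class Alphabet(str, Enum):
    DNA = "dna"
    PROTEIN = "protein"


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled sequence (16S gene, genome contig, or protein)."""

    id: str
    residues: str
    description: str = ""
    alphabet: Alphabet = Alphabet.DNA

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has empty body")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        allowed = _DNA_CHARS if self.alphabet is Alphabet.DNA else _PROTEIN_CHARS
        bad = set(residues) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(bad)} not in "
                f"{self.alphabet.value} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.DNA) -> List[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Residues are upper-cased; record order is preserved.  Raises
    :class:`FormatError` on an empty sequence body (naming the line) and
    :class:`DuplicateIdError` on repeated ids.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    records: List[SequenceRecord] = []
    seen: Dict[str, int] = {}
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    for bio in SeqIO.parse(str(path), "fasta"):
        if not bio.id:
            raise FormatError(f"{path}: record {len(records) + 1} has an empty header")
        if len(bio.seq) == 0:
            line = _find_header_line(path, bio.description)
            raise FormatError(
                f"{path}: line {line}: record {bio.id!r} has an empty sequence body"
            )
        if bio.id in seen:
            raise DuplicateIdError(f"{path}: duplicate sequence id {bio.id!r}")
        seen[bio.id] = 1
        desc = bio.description[len(bio.id):].strip() if bio.description.startswith(bio.id) else bio.description
        records.append(
            SequenceRecord(id=bio.id, residues=str(bio.seq), description=desc, alphabet=alphabet)
        )
    return records


def _find_header_line(path: Path, description: str) -> int:
    target = ">" + description
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.rstrip("\n") == target:
                return i
    return -1


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA, preserving (id, residues) round-trip."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


@dataclass
class OtuTable:
    """OTU x sample count matrix with optional rep-seqs and genus labels."""

    otu_ids: List[str]
    sample_ids: List[str]
    counts: np.ndarray
    rep_seqs: Dict[str, SequenceRecord] = field(default_factory=dict)
    genus_labels: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise FormatError("OTU counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("OTU counts must be nonnegative")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise DuplicateIdError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdError("duplicate sample ids")
        otu_set = set(self.otu_ids)
        for oid in self.rep_seqs:
            if oid not in otu_set:
                raise CrossReferenceError(
                    f"representative sequence {oid!r} not present in count table"
                )

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def total_count(self) -> int:
        return int(self.counts.sum())

    def genus_of(self, otu_id: str) -> str:
        if self.genus_labels is None:
            return "unclassified"
        return self.genus_labels.get(otu_id, "unclassified")

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            otu_ids=list(self.otu_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx].copy(),
            rep_seqs=dict(self.rep_seqs),
            genus_labels=dict(self.genus_labels) if self.genus_labels else None,
        )


def read_otu_table(
    counts_path: str | Path,
    repseq_path: Optional[str | Path] = None,
    taxonomy_path: Optional[str | Path] = None,
    transpose: bool = False,
) -> OtuTable:
    """Read an OTU count table (TSV; OTUs in rows, samples in columns).

    ``transpose=True`` accepts the other orientation.  A taxonomy file is a
    headerless two-column TSV (otu_id <TAB> genus).  When ``repseq_path`` is
    given, every OTU in the table must carry a representative sequence.
    """
    counts_path = Path(counts_path)
    if not counts_path.exists():
        raise MissingFileError(str(counts_path))
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{counts_path}: non-numeric count value ({exc})") from exc
    if np.any(values != np.floor(values)):
        bad = np.argwhere(values != np.floor(values))[0]
        raise FormatError(
            f"{counts_path}: non-integer count at OTU {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    otu_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]

    rep_seqs: Dict[str, SequenceRecord] = {}
    if repseq_path is not None:
        otu_set = set(otu_ids)
        for rec in read_fasta(repseq_path, Alphabet.DNA):
            if rec.id not in otu_set:
                raise CrossReferenceError(
                    f"{repseq_path}: representative sequence {rec.id!r} not in count table"
                )
            rep_seqs[rec.id] = rec
        missing = otu_set - set(rep_seqs)
        if missing:
            raise CrossReferenceError(
                f"{repseq_path}: no representative sequence for OTUs "
                f"{sorted(missing)[:5]}"
            )

    genus_labels: Optional[Dict[str, str]] = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", header=None, dtype=str)
        if tax.shape[1] < 2:
            raise FormatError(f"{taxonomy_path}: expected two tab-separated columns")
        genus_labels = {
            str(row[0]).strip(): str(row[1]).strip() for row in tax.itertuples(index=False)
        }

    table = OtuTable(otu_ids, sample_ids, values.astype(np.int64), rep_seqs, genus_labels)
    logger.info(
        "read OTU table %s: %d OTUs x %d samples, %d reads",
        counts_path, table.n_otus, table.n_samples, table.total_count(),
    )
    return table


def write_otu_table(table: OtuTable, counts_path: str | Path) -> None:
    df = pd.DataFrame(table.counts, index=table.otu_ids, columns=table.sample_ids)
    df.index.name = "otu_id"
    df.to_csv(counts_path, sep="\t")


@dataclass
class CatalogEntry:
    """One collection species: 16S gene plus optional genome/proteome/KO set."""

    species_id: str
    genus: str
    ssu: SequenceRecord
    genome: Optional[List[SequenceRecord]] = None
    proteome: Optional[List[SequenceRecord]] = None
    ko_set: Optional[Set[str]] = None

    def __post_init__(self) -> None:
        self.genus = self.genus.strip()
        if self.ko_set is not None:
            bad = [k for k in self.ko_set if not _KO_PATTERN.match(k)]
            if bad:
                raise FormatError(
                    f"entry {self.species_id!r}: malformed KO ids {bad[:5]}"
                )


@dataclass
class Catalog:
    """A named culture collection."""

    name: str
    entries: List[CatalogEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise FormatError(f"catalog {self.name!r} is empty")
        ids = [e.species_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"catalog {self.name!r}: duplicate species ids {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def species_ids(self) -> Set[str]:
        return {e.species_id for e in self.entries}

    @property
    def genera(self) -> Set[str]:
        return {e.genus for e in self.entries}


def read_catalog(manifest_path: str | Path, name: Optional[str] = None) -> Catalog:
    """Assemble a catalog from a tab-separated manifest.

    Columns: species_id, genus, ssu_fasta, genome_fasta?, proteome_fasta?,
    ko_list?  (trailing columns optional / may be empty).  File paths are
    resolved relative to the manifest's directory.  An optional header row
    starting with ``species_id`` is skipped.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise MissingFileError(str(manifest_path))
    base = manifest_path.parent
    entries: List[CatalogEntry] = []
    with open(manifest_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0] == "species_id":
                continue
            if len(cols) < 3:
                raise FormatError(
                    f"{manifest_path}: line {lineno}: expected at least 3 columns"
                )
            cols += [""] * (6 - len(cols))
            species_id, genus, ssu_p, genome_p, proteome_p, ko_p = (c.strip() for c in cols[:6])
            if not ssu_p:
                raise MissingFileError(
                    f"{manifest_path}: entry {species_id!r} has no 16S FASTA"
                )
            ssu_path = base / ssu_p
            if not ssu_path.exists():
                raise MissingFileError(
                    f"entry {species_id!r}: 16S file {ssu_path} not found"
                )
            ssu = read_fasta(ssu_path, Alphabet.DNA)[0]
            genome = read_fasta(base / genome_p, Alphabet.DNA) if genome_p else None
            proteome = read_fasta(base / proteome_p, Alphabet.PROTEIN) if proteome_p else None
            ko_set = read_ko_list(base / ko_p) if ko_p else None
            entries.append(
                CatalogEntry(species_id, genus, ssu, genome, proteome, ko_set)
            )
    cat = Catalog(name or manifest_path.stem, entries)
    logger.info("read catalog %s: %d species, %d genera", cat.name, len(cat), len(cat.genera))
    return cat


def read_ko_list(path: str | Path) -> Set[str]:
    """Read a KO list (one id per line; extra columns ignored; duplicates collapsed)."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    kos: Set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.split()[0] if line.split() else ""
            if not token:
                continue
            if not _KO_PATTERN.match(token):
                raise FormatError(f"{path}: line {lineno}: {token!r} is not a KO id")
            kos.add(token)
    return kos


def catalog_union_summary(a: Catalog, b: Catalog) -> Dict[str, int]:
    """Species- and genus-level set arithmetic for merging two collections.

    Species identity is by ``species_id`` and genus identity by exact genus
    string, so two catalogs being merged must use a shared naming scheme.
    """
    sp_a, sp_b = a.species_ids, b.species_ids
    ge_a, ge_b = a.genera, b.genera
    return {
        "species_a": len(sp_a),
        "species_b": len(sp_b),
        "species_shared": len(sp_a & sp_b),
        "species_a_only": len(sp_a - sp_b),
        "species_b_only": len(sp_b - sp_a),
        "species_union": len(sp_a | sp_b),
        "genus_a": len(ge_a),
        "genus_b": len(ge_b),
        "genus_shared": len(ge_a & ge_b),
        "genus_a_only": len(ge_a - ge_b),
        "genus_b_only": len(ge_b - ge_a),
        "genus_union": len(ge_a | ge_b),
    }
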