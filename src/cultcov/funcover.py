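"""Functional coverage of metagenome KO pools and protein gene catalogs.

Genomes and metagenomes are reduced to binary KEGG-Orthology (KO)
presence/absence profiles.  The coverage of a target metagenome KO pool by
a set of genomes is |union of genome KOs intersected with the pool| /
|pool|.  Accumulation curves add genomes in random order (averaged over
permutations) to show how quickly a collection saturates a metagenome's
annotated functions.  Protein-level coverage of a nonredundant metagenome
gene catalog against a collection pan-proteome uses Smith-Waterman matches
at BLASTp-style thresholds (e-value 1e-5, query coverage 50%, identity 40%
or 60%).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Sequence, Set

import numpy as np

from .align import has_conserved_match
from .errors import FormatError, PreconditionError
from .io import SequenceRecord

logger = logging.getLogger(__name__)

_KO_PATTERN = re.compile(r"^K\d+$")


@dataclass(frozen=True)
class KoProfile:
    """Binary KO presence/absence set for one genome or metagenome."""

    owner_id: str
    kos: FrozenSet[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kos", frozenset(self.kos))
        bad = [k for k in self.kos if not _KO_PATTERN.match(k)]
        if bad:
            raise FormatError(f"{self.owner_id}: malformed KO ids {sorted(bad)[:5]}")

    def __len__(self) -> int:
        return len(self.kos)


def ko_union(profiles: Iterable[KoProfile], owner_id: str = "union") -> KoProfile:
    kos: Set[str] = set()
    for p in profiles:
        kos |= p.kos
    return KoProfile(owner_id, frozenset(kos))


def ko_coverage(target: KoProfile, selected: Sequence[KoProfile]) -> Optional[float]:
    """Fraction of the target KO pool present in the union of selected profiles.

    None (undefined) for an empty target pool.
    """
    if len(target) == 0:
        return None
    union = ko_union(selected).kos
    return len(union & target.kos) / len(target)


@dataclass
class AccumulationCurve:
    """Mean coverage of a target pool after k randomly chosen genomes."""

    k_values: List[int]
    mean_coverage: List[float]
    sd_coverage: List[float]
    draws: int
    seed: int

    def __post_init__(self) -> None:
        assert all(
            b >= a - 1e-12
            for a, b in zip(self.mean_coverage, self.mean_coverage[1:])
        ), "accumulation curve must be nondecreasing"


def accumulation_curve(
    profiles: Sequence[KoProfile],
    target: KoProfile,
    draws: int = 100,
    seed: int = 0,
) -> AccumulationCurve:
    """Random-incremental coverage curve, averaged over ``draws`` permutations.

    Deterministic given (seed, draws).  Each draw is a uniform permutation
    of the profiles; coverage is recorded after every prefix, so the k = N
    point equals the full-union coverage in every draw.
    """
    if draws < 1:
        raise PreconditionError("draws must be >= 1")
    if len(target) == 0:
        raise PreconditionError("empty target KO pool")
    if not profiles:
        raise PreconditionError("no profiles to accumulate")
    rng = np.random.default_rng(seed)
    n = len(profiles)
    target_kos = target.kos
    per_draw = np.empty((draws, n), dtype=float)
    for d in range(draws):
        order = rng.permutation(n)
        acc: Set[str] = set()
        for k, idx in enumerate(order):
            acc |= profiles[idx].kos & target_kos
            per_draw[d, k] = len(acc) / len(target_kos)
        assert np.all(np.diff(per_draw[d]) >= 0)
    return AccumulationCurve(
        k_values=list(range(1, n + 1)),
        mean_coverage=per_draw.mean(axis=0).tolist(),
        sd_coverage=per_draw.std(axis=0, ddof=1).tolist() if draws > 1 else [0.0] * n,
        draws=draws,
        seed=seed,
    )


@dataclass(frozen=True)
class KoPartition:
    """Group-specific and shared KO sets of two pools (e.g., two host genotypes)."""

    a_specific: FrozenSet[str]
    b_specific: FrozenSet[str]
    shared: FrozenSet[str]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.a_specific), len(self.b_specific), len(self.shared)


def ko_partition(a: KoProfile, b: KoProfile) -> KoPartition:
    """Exact set arithmetic: A-only, B-only, and shared KOs."""
    return KoPartition(
        a_specific=frozenset(a.kos - b.kos),
        b_specific=frozenset(b.kos - a.kos),
        shared=frozenset(a.kos & b.kos),
    )


def gene_catalog_coverage(
    catalog_proteins: Sequence[SequenceRecord],
    pangenome_proteins: Sequence[SequenceRecord],
    identity_cutoff: float,
    qcov_cutoff: float = 0.50,
    evalue_max: Optional[float] = 1e-5,
) -> Optional[float]:
    """Fraction of catalog genes matched by some pan-proteome protein.

    A gene is covered when a pan-proteome protein matches it at identity >=
    ``identity_cutoff`` with coverage >= ``qcov_cutoff`` of the gene's own
    length and e-value <= ``evalue_max`` (None disables the e-value
    condition).  None (undefined) for an empty catalog.
    """
    catalog_proteins = list(catalog_proteins)
    if not catalog_proteins:
        return None
    if not pangenome_proteins:
        raise PreconditionError("empty pan-proteome")
    db_len = sum(len(p) for p in pangenome_proteins)
    covered = sum(
        has_conserved_match(
            gene, pangenome_proteins, identity_cutoff, qcov_cutoff, evalue_max, db_len
        )
        for gene in catalog_proteins
    )
    frac = covered / len(catalog_proteins)
    logger.info(
        "gene_catalog_coverage: %d/%d genes covered at %.0f%% identity",
        covered, len(catalog_proteins), 100 * identity_cutoff,
    )
    return frac
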