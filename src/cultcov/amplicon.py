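"""Read-level coverage of culture collections over amplicon OTU tables.

An OTU "hits" a catalog when its representative sequence matches some
catalog 16S gene above an identity threshold (strict >; 0.97 at species
level, 0.95 at genus level).  Coverage is read-weighted: the covered
fraction of a sample is the share of its reads carried by hit OTUs, so the
headline numbers are proportions "of the total reads".  Sample summaries
are reported as mean +/- SEM across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._util import drop_none, mean_sem
from .align import AlignmentParams, DEFAULT_NT_PARAMS, global_identity
from .errors import PreconditionError
from .io import Catalog, CatalogEntry, OtuTable, SequenceRecord

logger = logging.getLogger(__name__)

SPECIES_LEVEL_THRESHOLD = 0.97
GENUS_LEVEL_THRESHOLD = 0.95


@dataclass(frozen=True)
class CoverageResult:
    sample_id: str
    covered_reads: int
    total_reads: int

    @property
    def coverage(self) -> Optional[float]:
        """Covered fraction; None for an empty sample (undefined, not 0)."""
        if self.total_reads == 0:
            return None
        return self.covered_reads / self.total_reads


@dataclass(frozen=True)
class CoverageSummary:
    mean: float
    sem: float
    n_samples: int


def _best_identity(
    rep: SequenceRecord,
    references: Sequence[SequenceRecord],
    params: AlignmentParams,
    stop_above: Optional[float] = None,
) -> float:
    best = 0.0
    for ref in references:
        ident = global_identity(rep, ref, params).identity
        if ident > best:
            best = ident
            if stop_above is not None and best > stop_above:
                break
    return best


def _catalog_ssu(catalog: Union[Catalog, Sequence[CatalogEntry]]) -> List[SequenceRecord]:
    entries = catalog.entries if isinstance(catalog, Catalog) else list(catalog)
    return [e.ssu for e in entries]


def otu_hits(
    table: OtuTable,
    catalog: Union[Catalog, Sequence[CatalogEntry]],
    identity_threshold: float = SPECIES_LEVEL_THRESHOLD,
    params: AlignmentParams = DEFAULT_NT_PARAMS,
) -> Dict[str, bool]:
    """Per-OTU flag: does the OTU match the catalog above the threshold?"""
    refs = _catalog_ssu(catalog)
    hits: Dict[str, bool] = {}
    for otu_id in table.otu_ids:
        rep = table.rep_seqs.get(otu_id)
        if rep is None:
            raise PreconditionError(f"OTU {otu_id!r} has no representative sequence")
        best = _best_identity(rep, refs, params, stop_above=identity_threshold)
        hits[otu_id] = best > identity_threshold
    n_hit = sum(hits.values())
    logger.info(
        "otu_hits: %d/%d OTUs above %.0f%% identity",
        n_hit, len(hits), 100 * identity_threshold,
    )
    return hits


def _coverage_from_hits(
    table: OtuTable, hits: Dict[str, bool]
) -> Tuple[List[CoverageResult], CoverageSummary]:
    mask = np.array([hits[o] for o in table.otu_ids], dtype=bool)
    totals = table.sample_totals()
    covered = table.counts[mask].sum(axis=0) if mask.any() else np.zeros_like(totals)
    results = [
        CoverageResult(s, int(c), int(t))
        for s, c, t in zip(table.sample_ids, covered, totals)
    ]
    fracs = drop_none([r.coverage for r in results])
    if not fracs:
        raise PreconditionError("no sample with reads; coverage summary undefined")
    m, sem = mean_sem(fracs)
    return results, CoverageSummary(m, sem, len(fracs))


def read_coverage(
    table: OtuTable,
    catalog: Union[Catalog, Sequence[CatalogEntry]],
    identity_threshold: float = SPECIES_LEVEL_THRESHOLD,
    params: AlignmentParams = DEFAULT_NT_PARAMS,
) -> Tuple[List[CoverageResult], CoverageSummary]:
    """Read-weighted per-sample coverage of a catalog, plus mean +/- SEM."""
    hits = otu_hits(table, catalog, identity_threshold, params)
    return _coverage_from_hits(table, hits)


@dataclass
class VennDecomposition:
    """Per-sample read fractions of two catalogs' joint coverage.

    Arrays are aligned with ``sample_ids``; entries are None for empty
    samples.  a_only + b_only + shared = union and union + neither = 1 hold
    per sample.
    """

    sample_ids: List[str]
    a_only: List[Optional[float]]
    b_only: List[Optional[float]]
    shared: List[Optional[float]]
    neither: List[Optional[float]]

    @property
    def union(self) -> List[Optional[float]]:
        return [
            None if a is None else a + b + s
            for a, b, s in zip(self.a_only, self.b_only, self.shared)
        ]

    def summary(self) -> Dict[str, CoverageSummary]:
        out: Dict[str, CoverageSummary] = {}
        for name in ("a_only", "b_only", "shared", "union", "neither"):
            vals = drop_none(getattr(self, name))
            m, sem = mean_sem(vals)
            out[name] = CoverageSummary(m, sem, len(vals))
        return out


def venn_coverage(
    table: OtuTable,
    catalog_a: Union[Catalog, Sequence[CatalogEntry]],
    catalog_b: Union[Catalog, Sequence[CatalogEntry]],
    identity_threshold: float = SPECIES_LEVEL_THRESHOLD,
    params: AlignmentParams = DEFAULT_NT_PARAMS,
) -> VennDecomposition:
    """Per-sample decomposition of reads into A-only / B-only / shared / neither."""
    hits_a = otu_hits(table, catalog_a, identity_threshold, params)
    hits_b = otu_hits(table, catalog_b, identity_threshold, params)
    in_a = np.array([hits_a[o] for o in table.otu_ids], dtype=bool)
    in_b = np.array([hits_b[o] for o in table.otu_ids], dtype=bool)
    totals = table.sample_totals().astype(float)

    def frac(mask: np.ndarray) -> List[Optional[float]]:
        reads = table.counts[mask].sum(axis=0) if mask.any() else np.zeros_like(totals)
        return [
            None if t == 0 else r / t for r, t in zip(reads.astype(float), totals)
        ]

    return VennDecomposition(
        sample_ids=list(table.sample_ids),
        a_only=frac(in_a & ~in_b),
        b_only=frac(~in_a & in_b),
        shared=frac(in_a & in_b),
        neither=frac(~in_a & ~in_b),
    )


@dataclass(frozen=True)
class AnnotationRateResult:
    sample_id: str
    rate_base: Optional[float]
    rate_augmented: Optional[float]
    level: str


def annotation_rate(
    table: OtuTable,
    refdb: Sequence[SequenceRecord],
    augmentation: Sequence[SequenceRecord],
    level: str = "species",
    params: AlignmentParams = DEFAULT_NT_PARAMS,
) -> Tuple[List[AnnotationRateResult], CoverageSummary, CoverageSummary]:
    """Read annotation rate under a base vs an augmented reference database.

    ``level`` selects the identity threshold: species > 0.97, genus > 0.95.
    Returns per-sample rates plus (base, augmented) mean +/- SEM summaries.
    Because the augmented database is the base plus extra records, the
    augmented rate can never fall below the base rate.
    """
    if level == "species":
        threshold = SPECIES_LEVEL_THRESHOLD
    elif level == "genus":
        threshold = GENUS_LEVEL_THRESHOLD
    else:
        raise PreconditionError(f"unknown level {level!r}")

    base_hit: Dict[str, bool] = {}
    aug_hit: Dict[str, bool] = {}
    for otu_id in table.otu_ids:
        rep = table.rep_seqs.get(otu_id)
        if rep is None:
            raise PreconditionError(f"OTU {otu_id!r} has no representative sequence")
        in_base = _best_identity(rep, refdb, params, stop_above=threshold) > threshold
        base_hit[otu_id] = in_base
        if in_base:
            aug_hit[otu_id] = True
        else:
            aug_hit[otu_id] = (
                _best_identity(rep, augmentation, params, stop_above=threshold) > threshold
                if len(augmentation) else False
            )

    base_res, base_summary = _coverage_from_hits(table, base_hit)
    aug_res, aug_summary = _coverage_from_hits(table, aug_hit)
    rows = [
        AnnotationRateResult(b.sample_id, b.coverage, a.coverage, level)
        for b, a in zip(base_res, aug_res)
    ]
    return rows, base_summary, aug_summary
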